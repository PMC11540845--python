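"""Partitioning of harmonized variants by anchor-trait significance and
effect-sign concordance.

Every variant falls in exactly one of three labels relative to a (target,
anchor) trait pair:

* ``noEA``       - anchor p-value above the threshold (default 0.05);
* ``concordant`` - anchor-associated, target and anchor effects share sign;
* ``discordant`` - anchor-associated, signs oppose.

Derived sets: ``EA`` = concordant ∪ discordant (the complement of noEA),
``ALL`` = every variant, and the ``shared`` subset (intersection of one
trait's set with another trait's set, scored with each trait's own weights
downstream).  A variant with an exactly zero effect but a significant
anchor p carries no sign information and is assigned to noEA with a logged
count (possible only with synthetic inputs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import StructureError
from .sumstats import HarmonizedFrame

log = logging.getLogger(__name__)

__all__ = ["PartitionAssignment", "classify_variants", "build_partitions",
           "shared_subset", "LABELS"]

LABELS = ("noEA", "concordant", "discordant")


def classify_variants(beta_target: np.ndarray, beta_anchor: np.ndarray,
                      p_anchor: np.ndarray, p_thresh: float = 0.05,
                      ) -> np.ndarray:
    """Vectorized per-SNP label under the printed sign/threshold rule."""
    beta_target = np.asarray(beta_target, dtype=float)
    beta_anchor = np.asarray(beta_anchor, dtype=float)
    p_anchor = np.asarray(p_anchor, dtype=float)
    sig = p_anchor <= p_thresh
    zero = sig & ((beta_target == 0.0) | (beta_anchor == 0.0))
    if zero.any():
        log.info("%d anchor-significant variants with a zero effect "
                 "assigned to noEA (no sign information)", int(zero.sum()))
    labels = np.full(beta_target.shape, "noEA", dtype=object)
    signed = sig & ~zero
    conc = signed & (np.sign(beta_target) == np.sign(beta_anchor))
    labels[signed] = "discordant"
    labels[conc] = "concordant"
    return labels.astype(str)


@dataclass
class PartitionAssignment:
    """Per-variant partition labels over a harmonized frame."""

    keys: np.ndarray
    labels: np.ndarray
    p_thresh: float
    target: str
    anchor: str
    frame_id: int  # identity of the frame the assignment was built on

    def __post_init__(self) -> None:
        if len(self.keys) != len(self.labels):
            raise StructureError("keys and labels differ in length")

    def variant_set(self, name: str) -> np.ndarray:
        """Keys of a named set: a label, 'all', or 'EA'."""
        if name == "all":
            return self.keys
        if name == "EA":
            return self.keys[np.isin(self.labels, ("concordant", "discordant"))]
        if name not in LABELS:
            raise KeyError(f"unknown partition set {name!r}")
        return self.keys[self.labels == name]

    def summary(self) -> dict[str, int]:
        out = {lab: int((self.labels == lab).sum()) for lab in LABELS}
        out["EA"] = out["concordant"] + out["discordant"]
        out["all"] = len(self.keys)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"key": self.keys, "label": self.labels})


def build_partitions(frame: HarmonizedFrame, target: str, anchor: str,
                     p_thresh: float = 0.05) -> PartitionAssignment:
    """Label every variant of a harmonized frame for one (target, anchor)
    pair.  Emits a size summary; an empty partition is a warning only."""
    for name in (target, anchor):
        if name not in frame.table_names:
            raise StructureError(f"table {name!r} not in harmonized frame")
    v = frame.variants
    labels = classify_variants(
        v[f"{target}_beta"].to_numpy(),
        v[f"{anchor}_beta"].to_numpy(),
        v[f"{anchor}_p"].to_numpy(),
        p_thresh=p_thresh,
    )
    assign = PartitionAssignment(
        keys=v["key"].to_numpy(), labels=labels, p_thresh=p_thresh,
        target=target, anchor=anchor, frame_id=id(frame),
    )
    counts = assign.summary()
    log.info("partitions for %s vs %s: %s", target, anchor, counts)
    for lab in LABELS:
        if counts[lab] == 0:
            log.warning("partition %r is empty", lab)
    return assign


def shared_subset(assign_a: PartitionAssignment, set_a: str,
                  assign_b: PartitionAssignment, set_b: str) -> np.ndarray:
    """Keys in both named sets; the two assignments must share a frame."""
    if assign_a.frame_id != assign_b.frame_id:
        raise StructureError(
            "shared_subset requires assignments built on the same frame")
    keys_a = assign_a.variant_set(set_a)
    keys_b = assign_b.variant_set(set_b)
    shared = np.intersect1d(keys_a, keys_b)
    if shared.size == 0:
        log.warning("shared subset %s/%s ∩ %s/%s is empty",
                    assign_a.target, set_a, assign_b.target, set_b)
    return shared
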