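import numpy as np
import pandas as pd
import pytest

from pgspart import synthetic_data as sd
from pgspart.sumstats import harmonize, sumstat_table_from_df


@pytest.fixture(scope="session")
def tiny_arch():
    return sd.ArchitectureSpec(M=400, L=20, seed=7)


@pytest.fixture(scope="session")
def tiny_effects(tiny_arch):
    return sd.draw_true_effects(tiny_arch)


@pytest.fixture(scope="session")
def tiny_genotypes(tiny_arch):
    return sd.simulate_genotypes(tiny_arch, n=600, seed=11)


@pytest.fixture(scope="session")
def tiny_tables(tiny_arch, tiny_effects):
    anchor_df, target_df = sd.simulate_sumstats(tiny_arch, tiny_effects,
                                                seed=13)
    return {
        "anchor": sumstat_table_from_df(anchor_df, name="anchor"),
        "target": sumstat_table_from_df(target_df, name="target"),
    }


@pytest.fixture(scope="session")
def tiny_frame(tiny_tables, tiny_genotypes):
    return harmonize(dict(tiny_tables), panel=tiny_genotypes.frame)


def make_sumstat_df(rows, **defaults):
    """Hand-written GWAS table builder for fixtures.

    ``rows`` is a list of dicts with any of SNP/CHR/BP/A1/A2/BETA/SE/P/FRQ/N;
    unspecified fields fall back to sensible defaults.
    """
    base = {"CHR": "1", "A1": "A", "A2": "G", "BETA": 0.01, "SE": 0.005,
            "P": 0.05, "FRQ": 0.3, "N": 10000}
    base.update(defaults)
    out = []
    for i, row in enumerate(rows):
        r = dict(base)
        r.setdefault("SNP", f"rs{i + 1}")
        r.setdefault("BP", 1000 * (i + 1))
        r.update(row)
        out.append(r)
    return pd.DataFrame(out)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
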