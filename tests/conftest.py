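import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from stratgwas import synth

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def evidence_flags() -> pd.DataFrame:
    """Published gene-evidence flag table for the two follow-up loci."""
    return pd.read_csv(DATA_DIR / "evidence_flags.tsv", sep="\t", dtype=str)


@pytest.fixture(scope="session")
def gene_table() -> pd.DataFrame:
    """Gene coordinates (build 37) for the two follow-up loci."""
    return pd.read_csv(DATA_DIR / "gene_table.tsv", sep="\t", dtype={"chr": str})


@pytest.fixture(scope="session")
def stratum_stats() -> pd.DataFrame:
    """Published per-stratum ORs / CIs / P-values for the highlighted variants."""
    return pd.read_csv(
        DATA_DIR / "stratum_stats.tsv", sep="\t",
        dtype={"chr": str}, na_values=["NA"],
    )


def beta_se_from_or_ci(or_: float, lo: float, hi: float) -> tuple[float, float]:
    """Recover (log-OR, se) from an odds ratio and its 95% CI."""
    return math.log(or_), (math.log(hi) - math.log(lo)) / (2 * 1.959964)


def beta_se_from_or_p(or_: float, p: float) -> tuple[float, float]:
    """Recover (log-OR, se) from an odds ratio and its two-sided P-value."""
    from scipy.special import ndtri

    beta = math.log(or_)
    z = -ndtri(p / 2.0)
    return beta, abs(beta) / z


@pytest.fixture(scope="session")
def null_dataset() -> synth.SyntheticDataset:
    """Small dataset with no genetic effects (shared across tests)."""
    cfg = synth.SimConfig(
        n_variants=300,
        maf_range=(0.05, 0.5),
        samples_per_group=(500, 500, 500, 500),
        seed=11,
    )
    return synth.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def cfh_like_dataset() -> synth.SyntheticDataset:
    """One strong age-interacting causal variant among null variants."""
    cfg = synth.SimConfig(
        n_variants=40,
        maf_range=(0.2, 0.5),
        samples_per_group=(1500, 1500, 1500, 1500),
        causal_effects=[(5, math.log(2.29), math.log(1.81))],
        seed=23,
    )
    return synth.simulate_dataset(cfg)


def make_known_loci(rng: np.random.Generator, n: int = 5) -> pd.DataFrame:
    """Synthetic known-loci table (rsid, chr, pos) for exclusion-window tests."""
    return pd.DataFrame(
        {
            "rsid": [f"rs{100 + i}" for i in range(n)],
            "chr": "1",
            "pos": rng.integers(1_000_000, 200_000_000, size=n),
        }
    )
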