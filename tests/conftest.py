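"""Shared fixtures: printed summary tables and small generated cohorts."""

import numpy as np
import pandas as pd
import pytest

import mirdosage as md

# Published per-miRNA FDR summary for the 14 expressed 13q miRNAs:
# (mirna, chrom, start bp, copy-number FDR, target-expression FDR or None=n.d.)
TABLE1_ROWS = [
    ("hsa-mir-20a", "13q", 90801327, 0.000, 0.000),
    ("hsa-mir-92a-1", "13q", 90801618, 0.000, None),
    ("hsa-mir-17", "13q", 90800874, 0.000, 0.001),
    ("hsa-mir-15a", "13q", 49521268, 0.000, 0.010),
    ("hsa-mir-19a", "13q", 90801194, 0.001, 0.052),
    ("hsa-mir-19b-1", "13q", 90801463, 0.002, None),
    ("hsa-mir-16-1", "13q", 49521123, 0.160, None),
    ("hsa-mir-18a", "13q", 90801011, 0.255, 0.017),
    ("hsa-mir-320d-1", "13q", 40199964, 0.360, None),
    ("hsa-mir-622", "13q", 89681504, 0.428, 0.633),
    ("hsa-mir-623", "13q", 98806372, 0.779, 0.050),
    ("hsa-mir-1297", "13q", 53784118, 0.807, 0.984),
    ("hsa-mir-1267", "13q", 106981565, 0.964, 0.989),
    ("hsa-mir-621", "13q", 40282935, 0.969, 0.906),
]

# Published prioritised targets of mir-15a: (gene, chrom, printed p, sign)
TABLE2_ROWS = [
    ("TYRO3", "15q", 0.001, "negative"),
    ("UCP2", "11q", 0.001, "negative"),
    ("RNF125", "18q", 0.001, "positive"),
    ("RASGEF1B", "4q", 0.008, "negative"),
    ("COPS2", "15q", 0.010, "negative"),
]


@pytest.fixture(scope="session")
def table1():
    df = pd.DataFrame(TABLE1_ROWS,
                      columns=["mirna", "chrom", "start", "cn_fdr", "target_fdr"])
    cn = df.rename(columns={"cn_fdr": "fdr"})[["mirna", "fdr"]]
    tg = pd.DataFrame({
        "mirna": df["mirna"],
        "fdr": df["target_fdr"].astype(float),
        "determined": df["target_fdr"].notna(),
    })
    return cn, tg


@pytest.fixture(scope="session")
def table2():
    return pd.DataFrame(TABLE2_ROWS, columns=["gene", "chrom", "p", "sign"])


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort shared by read-only tests (do not mutate)."""
    return md.generate_cohort(md.ScenarioConfig(
        seed=11, n_samples=40, n_genes=400, tool_false_targets=10))


@pytest.fixture(scope="session")
def small_config():
    return md.AnalysisConfig(seed=11, permutations=499, grid_points=6000)


@pytest.fixture(scope="session")
def small_gridcn(small_cohort, small_config):
    grid = md.build_grid(small_cohort.genome, small_config.grid_points)
    return md.segments_to_grid(small_cohort.profiles, grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
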