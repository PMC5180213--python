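import numpy as np
import pandas as pd
import pytest

from ibdarch import simulate


@pytest.fixture(scope="session")
def small_panel():
    """21 sites in two blocks (12 + 9), fixed MAFs, no LD."""
    return simulate.build_panel(
        [("b0", 12, 5_000, 40_000), ("b1", 9, 5_000, 40_000)],
        mafs=np.linspace(0.1, 0.45, 21),
    )


@pytest.fixture(scope="session")
def screen_cohort():
    return simulate.default_screen_cohort(seed=101)


@pytest.fixture()
def tiny_exome():
    """Hand-built 6-variant x 8-sample exome table for exact-count tests.

    Samples: 3 VEO children, 3 adults, 2 controls. Genotypes chosen so allele
    tallies and homozygote patterns are easy to verify by hand.
    """
    variants = pd.DataFrame({
        "var_id": [f"v{i}" for i in range(6)],
        "chrom": "1",
        "pos": [100, 200, 300, 400, 500, 600],
        "ref": "A", "alt": "G",
        "gene": ["G1", "G1", "G2", "G2", "G3", "G3"],
        "consequence": ["frameshift", "missense", "missense", "synonymous",
                        "missense", "stop_gained"],
        "cadd": [np.nan, 25.0, 3.0, np.nan, 15.0, np.nan],
        "maf_1kgp": [0.001, np.nan, 0.01, 0.005, 0.001, 0.001],
        "maf_esp": [0.002, np.nan, 0.01, 0.005, 0.001, 0.001],
        "maf_exac": [0.001, np.nan, 0.015, 0.004, 0.001, 0.001],
        "novel": [False, True, False, False, False, False],
    })
    samples = pd.DataFrame({
        "sample_id": ["c1", "c2", "c3", "a1", "a2", "a3", "h1", "h2"],
        "group": ["VEO-CD", "VEO-CD", "VEO-UC", "Adult-CD", "Adult-UC", "Adult-UC", "HC", "HC"],
        "diagnosis": ["CD", "CD", "UC", "CD", "UC", "UC", "HC", "HC"],
        "onset": ["pediatric", "pediatric", "pediatric", "adult", "adult", "adult",
                  "not_applicable", "not_applicable"],
    })
    genotypes = np.array([
        #  c1 c2 c3 a1 a2 a3 h1 h2
        [2, 2, 0, 1, 0, 0, 0, 0],   # v0 frameshift: hom in 2 children, het in 1 adult
        [2, 0, 0, 0, 0, 0, 0, 0],   # v1 damaging missense: hom in 1 child only
        [1, 1, 0, 1, 0, 0, 1, 0],   # v2 benign missense (CADD 3)
        [0, 1, 1, 0, 1, 0, 0, 1],   # v3 synonymous
        [2, 0, 2, 2, 0, 0, 0, 0],   # v4 damaging missense: hom 2 children + hom 1 adult
        [1, 1, 1, 1, 1, 1, 1, 1],   # v5 stop gained: het everywhere
    ], dtype=np.int8)
    return simulate.ExomeVariantTable(variants, genotypes, samples)
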