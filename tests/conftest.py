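import numpy as np
import pandas as pd
import pytest

from markerval.prioritize import ExpressionCohort
from markerval.synthio import PlantedGene, SimConfig, gen_expression_cohort, gen_qpcr_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Seed-1 default synthetic expression cohort (8 planted markers)."""
    return gen_expression_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_qpcr():
    """Seed-1 default synthetic qPCR cohort (field effect 3, cancer effect 10)."""
    return gen_qpcr_cohort(SimConfig(seed=1))


@pytest.fixture()
def tiny_cohort():
    """Hand-built 4-gene cohort with obvious structure for contract tests."""
    rng = np.random.default_rng(7)
    samples = [f"s{i}" for i in range(12)]
    groups = pd.Series(["N"] * 4 + ["T"] * 4 + ["M"] * 4, index=samples)
    mat = pd.DataFrame(
        rng.normal(8.0, 0.1, size=(4, 12)),
        index=["gA", "gB", "gC", "gD"],
        columns=samples,
    )
    mat.loc["gA", groups == "T"] += 3.0
    mat.loc["gA", groups == "M"] += 4.0
    tissue = pd.DataFrame(
        1.0, index=mat.index, columns=["prostate", "lung", "liver", "colon"]
    )
    tissue.loc["gA", "prostate"] = 10.0
    citations = pd.Series([1, 0, 99, 0], index=mat.index)
    survival = pd.DataFrame(
        {"time": rng.uniform(10, 100, 12), "event": [True] * 12}, index=samples
    )
    return ExpressionCohort(
        matrix=mat, groups=groups, survival=survival,
        tissue_scores=tissue, citations=citations,
    )
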