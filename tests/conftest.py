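import numpy as np
import pandas as pd
import pytest

from resistscreen import (
    GuideCountMatrix,
    GuideLibrary,
    SampleSheet,
)
from resistscreen.synthetic import SimConfig, plant_resistance_genes, simulate_screen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_toy_matrix(counts_by_sample: dict, guide_genes: dict, sheet_rows: list) -> GuideCountMatrix:
    """Assemble a GuideCountMatrix from plain dicts (tests' toy builder)."""
    library = GuideLibrary(
        pd.DataFrame({"guide_id": list(guide_genes), "gene": list(guide_genes.values())})
    )
    sheet = SampleSheet(
        pd.DataFrame(
            sheet_rows,
            columns=["sample_id", "cell_line", "screen_type", "condition", "drug", "replicate"],
        )
    )
    counts = pd.DataFrame(counts_by_sample, index=pd.Index(list(guide_genes), name="guide_id"))
    return GuideCountMatrix(counts=counts, library=library, samples=sheet)


@pytest.fixture
def toy_matrix():
    """2 genes x 2 guides + 1 control guide, 1 control + 1 treated sample."""
    guide_genes = {"g1_a": "G1", "g1_b": "G1", "g2_a": "G2", "g2_b": "G2", "nt_1": "NONTARGETING"}
    rows = [
        ("ctrl_r1", "CL1", "knockout", "control", "", 1),
        ("gem_r1", "CL1", "knockout", "treated", "gemcitabine", 1),
    ]
    counts = {
        "ctrl_r1": [100, 100, 100, 100, 100],
        "gem_r1": [400, 100, 25, 100, 100],
    }
    return make_toy_matrix(counts, guide_genes, rows)


@pytest.fixture(scope="session")
def planted_screen():
    """One default-design screen with 10 planted resistance genes (shared)."""
    rng = np.random.default_rng(777)
    cfg = SimConfig(seed=777, n_genes=200)
    cfg = plant_resistance_genes(cfg, n_planted=10, effect_log2=3.0, rng=rng)
    library, matrix, truth = simulate_screen(cfg, rng=rng)
    return {"config": cfg, "library": library, "matrix": matrix, "truth": truth}
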