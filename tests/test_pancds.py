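"""Expression normalization, z-scoring, weighted sensitivity scores, AUC."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from resistscreen import ExpressionMatrix
from resistscreen.io_formats import ExpressionState
from resistscreen.pancds import (
    DoseResponse,
    classify,
    dose_response_auc,
    sensitivity_score,
    vst_normalize,
    zscore_genes,
)
from resistscreen.synthetic import simulate_expression


def _raw(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def _zscored(values, genes=None, samples=None):
    m = _raw(values, genes, samples)
    return ExpressionMatrix(m.values, state=ExpressionState.zscored)


# --- normalization --------------------------------------------------------

def test_vst_zero_count_finite_and_formula():
    m = _raw([[0.0], [999.5]])
    out = vst_normalize(m)
    n = 0.5 + 1000.0
    assert out.values.iloc[0, 0] == pytest.approx(np.log2(1e6 * 0.5 / n + 1))
    assert np.isfinite(out.values.to_numpy()).all()
    assert out.state == ExpressionState.normalized


def test_vst_monotone_within_sample(rng):
    m = _raw(np.sort(rng.integers(0, 5000, size=(50, 1)).astype(float), axis=0))
    out = vst_normalize(m).values.to_numpy().ravel()
    assert np.all(np.diff(out) >= 0)


def test_vst_depth_invariance_at_high_counts(rng):
    """Doubling every count in a sample moves normalized values < 0.01 for
    genes above ~100 CPM (the +1 offset vanishes)."""
    counts = rng.integers(50, 5000, size=(200, 1)).astype(float)
    a = vst_normalize(_raw(counts)).values.to_numpy()
    b = vst_normalize(_raw(counts * 2)).values.to_numpy()
    cpm = 1e6 * counts / counts.sum()
    high = (cpm > 100).ravel()
    assert np.max(np.abs(a[high] - b[high])) < 0.01


def test_vst_rejects_negative_and_passes_through_normalized():
    with pytest.raises(ValueError, match="negative"):
        vst_normalize(_raw([[-1.0, 2.0]]))
    pre = ExpressionMatrix(_raw([[1.0, 2.0]]).values, state=ExpressionState.normalized)
    assert vst_normalize(pre).state == ExpressionState.normalized


# --- z-scoring ------------------------------------------------------------

def test_zscore_two_samples_closed_form():
    m = ExpressionMatrix(_raw([[1.0, 2.0]]).values, state=ExpressionState.normalized)
    z = zscore_genes(m, ddof=1)
    assert np.allclose(z.values.to_numpy(), [[-np.sqrt(0.5), np.sqrt(0.5)]])
    z0 = zscore_genes(m, ddof=0)
    assert np.allclose(z0.values.to_numpy(), [[-1.0, 1.0]])


def test_zscore_constant_gene_is_zero(caplog):
    m = ExpressionMatrix(_raw([[3.0, 3.0, 3.0], [1.0, 2.0, 3.0]]).values,
                         state=ExpressionState.normalized)
    with caplog.at_level("WARNING", logger="resistscreen"):
        z = zscore_genes(m)
    assert np.allclose(z.values.iloc[0], 0.0)
    assert any("constant" in r.message for r in caplog.records)


def test_zscore_rows_standardized(rng):
    m = ExpressionMatrix(_raw(rng.normal(size=(20, 10))).values,
                         state=ExpressionState.normalized)
    z = zscore_genes(m)
    assert np.allclose(z.values.mean(axis=1), 0, atol=1e-12)
    assert np.allclose(z.values.std(axis=1, ddof=1), 1, atol=1e-12)


# --- sensitivity score ----------------------------------------------------

def test_score_zero_weights_zero_everywhere():
    z = _zscored([[1.0, -1.0], [0.5, 2.0]])
    sc = sensitivity_score(z, pd.Series({"G0": 0.0, "G1": 0.0}))
    assert np.allclose(sc["resistance_score"], 0.0)


def test_score_single_gene_closed_form():
    z = _zscored([[-1.0, 0.0, 1.0]])
    sc = sensitivity_score(z, pd.Series({"G0": 2.0}))
    assert np.allclose(sc["resistance_score"], [-2.0, 0.0, 2.0])
    assert np.allclose(sc["predicted_sensitivity"], [2.0, 0.0, -2.0])


def test_score_invariant_to_gene_order_and_zero_weights(rng):
    vals = rng.normal(size=(30, 8))
    z = _zscored(vals)
    w = pd.Series(rng.normal(size=30), index=z.genes)
    w.iloc[10:20] = 0.0
    a = sensitivity_score(z, w)["resistance_score"].to_numpy()
    perm = rng.permutation(30)
    z2 = ExpressionMatrix(z.values.iloc[perm], state=ExpressionState.zscored)
    b = sensitivity_score(z2, w)["resistance_score"].to_numpy()
    assert np.allclose(a, b, atol=1e-12)
    # dropping the zero-weight genes entirely changes nothing
    keep = w[w != 0].index
    z3 = ExpressionMatrix(z.values.loc[keep], state=ExpressionState.zscored)
    c = sensitivity_score(z3, w)["resistance_score"].to_numpy()
    assert np.allclose(a, c, atol=1e-12)


def test_score_increases_with_resistance_gene_expression():
    """A resistance-weighted gene expressed higher in one sample strictly
    raises that sample's resistance score."""
    z = _zscored([[0.0, 0.0], [1.0, -1.0]])
    base = sensitivity_score(z, pd.Series({"G0": 3.0}))["resistance_score"]
    more = sensitivity_score(z, pd.Series({"G0": 3.0, "G1": 2.0}))["resistance_score"]
    assert more[0] > base[0] and more[1] < base[1]


def test_score_empty_intersection_errors():
    z = _zscored([[1.0, 2.0]])
    with pytest.raises(ValueError, match="shared"):
        sensitivity_score(z, pd.Series({"OTHER": 1.0}))


def test_score_recovers_latent_phenotype(rng):
    genes = [f"G{i:03d}" for i in range(300)]
    weights = {g: float(rng.uniform(1, 6)) for g in
               np.array(genes)[rng.choice(300, 50, replace=False)]}
    expr, phen = simulate_expression(genes, weights, n_samples=50, coupling=1.0, rng=rng)
    z = zscore_genes(vst_normalize(expr))
    sc = sensitivity_score(z, pd.Series(weights)).set_index("sample_id")
    rho = spearmanr(sc.loc[phen.index, "resistance_score"], phen).statistic
    assert rho >= 0.8


# --- classification -------------------------------------------------------

def test_median_split_ties_go_low():
    sc = pd.DataFrame({"sample_id": list("abcd"), "predicted_sensitivity": [1, 2, 3, 4]})
    out = classify(sc, rule="median")
    assert list(out["group"]) == ["low", "low", "high", "high"]


def test_tertiles_of_nine_equally_spaced():
    sc = pd.DataFrame({"sample_id": [f"s{i}" for i in range(9)],
                       "predicted_sensitivity": np.arange(9.0)})
    out = classify(sc, rule="tertile")
    assert list(out["group"]) == ["resistant"] * 3 + ["intermediate"] * 3 + ["sensitive"] * 3


def test_all_equal_scores_single_group(caplog):
    sc = pd.DataFrame({"sample_id": list("abc"), "predicted_sensitivity": [1.0, 1.0, 1.0]})
    with caplog.at_level("WARNING", logger="resistscreen"):
        out = classify(sc, rule="median")
    assert set(out["group"]) == {"all"}


# --- dose-response AUC ----------------------------------------------------

def test_auc_flat_curves():
    doses = np.array([1, 3, 10, 30, 100, 300], dtype=float)
    assert dose_response_auc(DoseResponse(doses, np.ones(6))) == pytest.approx(1.0)
    assert dose_response_auc(DoseResponse(doses, np.zeros(6))) == pytest.approx(0.0)


def test_dose_response_validation():
    with pytest.raises(ValueError, match="increasing"):
        DoseResponse(np.array([3.0, 1.0]), np.array([1.0, 1.0]))
    with pytest.raises(ValueError, match="positive"):
        DoseResponse(np.array([0.0, 1.0]), np.array([1.0, 1.0]))
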