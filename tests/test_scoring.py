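"""Guide filtering, L2FC computation, the gene L2FC sum, QC."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_toy_matrix
from oracles import oracle_cpm, oracle_top2_by_pairs
from resistscreen.scoring import (
    cpm_normalize,
    cross_cell_line,
    filter_guides,
    gene_l2fc_sum,
    guide_l2fc,
    multi_drug_mean,
    qc_replicate_correlation,
    replicate_min_l2fc,
    score_screen,
    top_variable_guides,
    weight_vector,
)
from resistscreen.synthetic import PlantedGene, SimConfig, simulate_screen


# --- CPM ------------------------------------------------------------------

def test_cpm_single_guide_is_one_million():
    df = pd.DataFrame({"s1": [7]}, index=["g1"])
    assert cpm_normalize(df, pseudocount=0.0).iloc[0, 0] == 1e6


def test_cpm_symmetry():
    df = pd.DataFrame({"s1": [1, 1]}, index=["g1", "g2"])
    assert (cpm_normalize(df, pseudocount=0.0)["s1"] == 5e5).all()


def test_cpm_columns_sum_to_million(rng):
    df = pd.DataFrame(rng.integers(0, 1000, size=(100, 6)))
    cpm = cpm_normalize(df, pseudocount=0.5)
    assert np.allclose(cpm.sum(axis=0), 1e6, rtol=1e-6)


def test_cpm_matches_bruteforce_oracle(rng):
    df = pd.DataFrame(rng.integers(0, 1000, size=(100, 6)))
    cpm = cpm_normalize(df, pseudocount=0.5)
    assert np.max(np.abs(cpm.to_numpy() - oracle_cpm(df.to_numpy(), 0.5))) < 1e-9


def test_cpm_all_zero_column_rejected():
    df = pd.DataFrame({"s1": [0, 0]})
    with pytest.raises(ValueError, match="all-zero"):
        cpm_normalize(df, pseudocount=0.0)


# --- guide filter ---------------------------------------------------------

def _filter_toy():
    """Counts exercising all four (control >=/< 10) x (treated >=/< 50) cells."""
    guide_genes = {"low_low": "G1", "low_high": "G1", "high_low": "G2", "high_high": "G2"}
    rows = [
        ("ctrl_r1", "CL1", "knockout", "control", "", 1),
        ("gem_r1", "CL1", "knockout", "treated", "gemcitabine", 1),
    ]
    counts = {
        "ctrl_r1": [9, 9, 1000, 1000],     # control counts
        "gem_r1": [49, 1000, 49, 1000],    # treated counts
    }
    return make_toy_matrix(counts, guide_genes, rows)


def test_filter_and_rule_excludes_only_double_low():
    mask, report = filter_guides(_filter_toy())
    excluded = set(mask.index[mask["gem_r1"]])
    assert excluded == {"low_low"}
    assert report.loc[0, "fraction_excluded"] == 0.25


def test_filter_boundary_cases():
    """control=9, treated=49 -> excluded; control=9, treated=1000 -> retained
    under AND (strong enrichment from a low baseline)."""
    mask, _ = filter_guides(_filter_toy())
    assert bool(mask.loc["low_low", "gem_r1"]) is True
    assert bool(mask.loc["low_high", "gem_r1"]) is False


def test_filter_or_rule():
    mask, _ = filter_guides(_filter_toy(), logic="or")
    assert set(mask.index[mask["gem_r1"]]) == {"low_low", "low_high", "high_low"}


def test_filter_default_screen_exclusion_under_two_percent(planted_screen):
    _, report = filter_guides(planted_screen["matrix"])
    assert report["fraction_excluded"].mean() < 0.02


# --- guide L2FC -----------------------------------------------------------

def _two_rep_matrix(treated_factor=4.0):
    guide_genes = {f"g{i}": f"G{(i % 3) + 1}" for i in range(6)}
    rows = []
    counts = {}
    base = np.array([100, 200, 300, 400, 500, 600])
    for rep in (1, 2):
        cid, tid = f"c_r{rep}", f"t_r{rep}"
        rows += [(cid, "CL1", "knockout", "control", "", rep),
                 (tid, "CL1", "knockout", "treated", "gem", rep)]
        counts[cid] = base
        counts[tid] = (base * treated_factor).astype(int)
    return make_toy_matrix(counts, guide_genes, rows)


def test_l2fc_identity_and_closed_form():
    mat = _two_rep_matrix(1.0)
    cpm = cpm_normalize(mat, pseudocount=0.0)
    fc = guide_l2fc(cpm, mat.samples, mat.library)
    assert np.allclose(fc["l2fc"], 0.0)
    mat4 = _two_rep_matrix(4.0)
    cpm4 = cpm_normalize(mat4, pseudocount=0.0)
    fc4 = guide_l2fc(cpm4, mat4.samples, mat4.library)
    # the 4x factor is global, so CPM absorbs it within each sample: L2FC 0.
    assert np.allclose(fc4["l2fc"], 0.0)


def test_l2fc_selective_enrichment_closed_form():
    """One guide at 4x its expected share in every replicate: replicate-min
    L2FC = 2 up to the renormalization by the enriched total."""
    guide_genes = {"hit": "G1", "g2": "G1", "g3": "G2", "g4": "G2"}
    rows, counts = [], {}
    for rep in (1, 2, 3):
        cid, tid = f"c_r{rep}", f"t_r{rep}"
        rows += [(cid, "CL1", "knockout", "control", "", rep),
                 (tid, "CL1", "knockout", "treated", "gem", rep)]
        counts[cid] = [1000, 1000, 1000, 1000]
        counts[tid] = [4000, 1000, 1000, 1000]
    mat = make_toy_matrix(counts, guide_genes, rows)
    cpm = cpm_normalize(mat, pseudocount=0.0)
    fc = guide_l2fc(cpm, mat.samples, mat.library)
    gmin = replicate_min_l2fc(fc)
    hit = gmin.set_index("guide_id").loc["hit", "replicate_min_l2fc"]
    expected = np.log2((4000 / 7000) / (1000 / 4000))
    assert hit == pytest.approx(expected, abs=1e-12)


def test_l2fc_antisymmetry(rng):
    """Swapping treated and control negates every replicate L2FC and turns
    the replicate-min into the negated replicate-max."""
    cfg = SimConfig(seed=5, n_genes=20, n_nontargeting=5, cell_lines=("A",),
                    drugs=("d1",), replicates=3, library_size=2e4)
    _, mat, _ = simulate_screen(cfg)
    cpm = cpm_normalize(mat, pseudocount=0.5)
    fc = guide_l2fc(cpm, mat.samples, mat.library)
    t = mat.samples.table.copy()
    swap = {"control": "treated", "treated": "control"}
    t["condition"] = t["condition"].map(swap)
    t.loc[t["condition"] == "control", "drug"] = ""
    t.loc[t["condition"] == "treated", "drug"] = "d1"
    from resistscreen.io_formats import SampleSheet
    fc_swapped = guide_l2fc(cpm, SampleSheet(t), mat.library)
    a = fc.sort_values(["guide_id", "replicate"])["l2fc"].to_numpy()
    b = fc_swapped.sort_values(["guide_id", "replicate"])["l2fc"].to_numpy()
    assert np.allclose(a, -b, atol=1e-12)
    gmin = replicate_min_l2fc(fc).set_index("guide_id")["replicate_min_l2fc"]
    gmax = fc_swapped.groupby("guide_id")["l2fc"].min()
    # min of negated = -(max of original)
    orig_max = fc.groupby("guide_id")["l2fc"].max()
    assert np.allclose(gmax.loc[gmin.index], -orig_max.loc[gmin.index])


def test_l2fc_matches_scalar_loop_oracle(rng):
    cfg = SimConfig(seed=9, n_genes=15, n_nontargeting=5, cell_lines=("A",),
                    drugs=("d1", "d2"), replicates=2, library_size=2e4)
    _, mat, _ = simulate_screen(cfg)
    cpm = cpm_normalize(mat, pseudocount=0.5)
    fc = guide_l2fc(cpm, mat.samples, mat.library).set_index(
        ["guide_id", "drug", "replicate"])
    for _, c in mat.samples.comparisons().iterrows():
        for g in cpm.index:
            want = np.log2(cpm.loc[g, c["treated_sample"]] / cpm.loc[g, c["control_sample"]])
            got = fc.loc[(g, c["drug"], c["replicate"]), "l2fc"]
            assert abs(got - want) < 1e-12


# --- gene L2FC sum --------------------------------------------------------

def _min_df(minima: dict, gene="G1"):
    rows = [dict(guide_id=g, gene=gene, cell_line="CL1", screen_type="knockout",
                 drug="gem", replicate_min_l2fc=v, n_replicates=3, filtered=False)
            for g, v in minima.items()]
    return pd.DataFrame(rows)


def test_gene_sum_top_two():
    out = gene_l2fc_sum(_min_df({"a": 3.0, "b": 2.0, "c": -1.0, "d": -5.0}))
    assert out.loc[0, "l2fc_sum"] == 5.0
    assert out.loc[0, "contributing_guides"] == "a,b"
    assert out.loc[0, "rank3_l2fc"] == -1.0


def test_gene_sum_tie_broken_lexicographically():
    out = gene_l2fc_sum(_min_df({"z": 1.5, "a": 1.5, "m": 1.5}))
    assert out.loc[0, "l2fc_sum"] == 3.0
    assert out.loc[0, "contributing_guides"] == "a,m"


def test_gene_sum_too_few_guides_is_na():
    df = _min_df({"a": 1.0, "b": 2.0})
    df.loc[df.guide_id == "b", "filtered"] = True
    df.loc[df.guide_id == "b", "replicate_min_l2fc"] = np.nan
    out = gene_l2fc_sum(df)
    assert out.loc[0, "too_few_guides"] and np.isnan(out.loc[0, "l2fc_sum"])


def test_gene_sum_nontargeting_never_scored():
    df = pd.concat([_min_df({"a": 1.0, "b": 2.0}),
                    _min_df({"nt1": 9.0, "nt2": 9.0}, gene="NONTARGETING")])
    out = gene_l2fc_sum(df)
    assert set(out["gene"]) == {"G1"}


def test_gene_sum_matches_bruteforce_pair_maximum(rng):
    """Top-2 sum equals the maximum pairwise sum over all guide pairs."""
    for _ in range(50):
        n = int(rng.integers(2, 8))
        minima = {f"g{i}": float(rng.normal()) for i in range(n)}
        out = gene_l2fc_sum(_min_df(minima))
        assert out.loc[0, "l2fc_sum"] == pytest.approx(
            oracle_top2_by_pairs(list(minima.values())), abs=1e-12)


def test_gene_sum_monotone_in_treated_counts():
    """Raising a contributing guide's treated counts never lowers the sum
    (in the realistic regime where no guide dominates the library)."""
    guide_genes = {"a": "G1", "b": "G1", "c": "G1"}
    guide_genes.update({f"f{i:03d}": f"F{i:03d}" for i in range(100)})
    rows, counts = [], {}
    for rep in (1, 2):
        rows += [(f"c_r{rep}", "CL1", "knockout", "control", "", rep),
                 (f"t_r{rep}", "CL1", "knockout", "treated", "gem", rep)]
        counts[f"c_r{rep}"] = [500, 500, 500] + [500] * 100
        counts[f"t_r{rep}"] = [800, 500, 300] + [500] * 100
    prev = -np.inf
    for bump in (0, 200, 400, 800):
        c2 = {k: list(v) for k, v in counts.items()}
        c2["t_r1"][0] += bump
        c2["t_r2"][0] += bump
        mat = make_toy_matrix(c2, guide_genes, rows)
        gs = score_screen(mat)["gene_scores"]
        val = float(gs.set_index("gene").loc["G1", "l2fc_sum"])
        assert val >= prev - 1e-12
        prev = val


# --- multi-drug & cross-cell-line ----------------------------------------

def _scores(rows):
    return pd.DataFrame(rows, columns=["gene", "cell_line", "screen_type", "drug", "l2fc_sum"])


def test_multi_drug_mean_trivial():
    gs = _scores([("G1", "CL1", "knockout", d, 4.0) for d in "abcd"])
    md = multi_drug_mean(gs)
    assert md.loc[0, "mean_l2fc_sum"] == 4.0 and md.loc[0, "n_drugs"] == 4


def test_multi_drug_missing_drug_errors_unless_allowed():
    gs = _scores([("G1", "CL1", "knockout", d, 4.0) for d in "abc"])
    with pytest.raises(ValueError, match="missing drug"):
        multi_drug_mean(gs, drugs=list("abcd"))
    md = multi_drug_mean(gs, drugs=list("abcd"), allow_missing_drugs=True)
    assert md.loc[0, "mean_l2fc_sum"] == 4.0


def test_multidrug_gene_outranks_single_drug_gene():
    """A gene with the effect in all four drugs beats an equal-effect
    single-drug gene on the multi-drug mean."""
    wins = 0
    for s in range(10):
        rng = np.random.default_rng(1000 + s)
        cfg = SimConfig(seed=s, n_genes=40, n_nontargeting=10, cell_lines=("A",),
                        library_size=1e5,
                        planted_resistance=(
                            PlantedGene("G01", 2, 3.0),
                            PlantedGene("G02", 2, 3.0, drugs=("gemcitabine",)),
                        ))
        _, mat, _ = simulate_screen(cfg, rng=rng)
        md = score_screen(mat)["multidrug"].set_index("gene")
        wins += md.loc["G01", "mean_l2fc_sum"] > md.loc["G02", "mean_l2fc_sum"]
    assert wins >= 9


def test_cross_cell_line_and_weight_vector():
    gs = _scores([
        ("G1", "CL1", "knockout", "gem", 4.0), ("G1", "CL2", "knockout", "gem", 2.0),
        ("G2", "CL1", "knockout", "gem", -1.0), ("G2", "CL2", "knockout", "gem", 3.0),
    ])
    w = weight_vector(gs, drug="gem")
    assert w["G1"] == 2.0 and w["G2"] == -1.0
    md = multi_drug_mean(gs, drugs=["gem"])
    cc = cross_cell_line(md).set_index("gene")
    assert cc.loc["G1", "min_across_cell_lines"] == 2.0
    assert cc.loc["G1", "mean_across_cell_lines"] == 3.0


# --- QC -------------------------------------------------------------------

def _qc_fc(seed=0):
    """Screen with 10 drug-shared and 10+10 drug-specific planted genes:
    replicates share all of a drug's effects, non-replicate pairs only the
    shared ones (plus control-sample noise)."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:02d}" for i in range(1, 61)]
    planted = [PlantedGene(g, 4, 2.5) for g in genes[:10]]
    planted += [PlantedGene(g, 4, 2.5, drugs=("d1",)) for g in genes[10:20]]
    planted += [PlantedGene(g, 4, 2.5, drugs=("d2",)) for g in genes[20:30]]
    cfg = SimConfig(seed=seed, n_genes=60, n_nontargeting=10, cell_lines=("A",),
                    drugs=("d1", "d2"), replicates=3, library_size=1e5,
                    planted_resistance=tuple(planted))
    _, mat, _ = simulate_screen(cfg, rng=rng)
    cpm = cpm_normalize(mat, pseudocount=0.5)
    return guide_l2fc(cpm, mat.samples, mat.library)


def test_qc_identical_samples_rho_one():
    fc = _qc_fc()
    dup = fc[(fc["drug"] == "d1") & (fc["replicate"] == 1)].copy()
    dup2 = dup.copy()
    dup2["replicate"] = 2
    res = qc_replicate_correlation(pd.concat([dup, dup2]), n_permutations=5,
                                   rng=np.random.default_rng(0))
    rep = res["pairs"][res["pairs"]["kind"] == "replicate"]
    assert np.allclose(rep["rho"], 1.0)


def test_qc_scrambled_null_near_zero():
    fc = _qc_fc(seed=2)
    res = qc_replicate_correlation(fc, n_permutations=200, rng=np.random.default_rng(0))
    null = res["pairs"][res["pairs"]["kind"] == "scrambled"]["rho"]
    assert abs(null.mean()) < 0.05


def test_qc_replicate_exceeds_nonreplicate_exceeds_null():
    """Drug-shared planted effects correlate replicates; drug-specific ones
    decorrelate non-replicates; scrambling kills everything."""
    means = {"replicate": [], "non_replicate": [], "scrambled": []}
    for s in range(3):
        fc = _qc_fc(seed=s)
        res = qc_replicate_correlation(fc, n_permutations=50, rng=np.random.default_rng(s))
        for kind in means:
            means[kind].append(res["pairs"][res["pairs"]["kind"] == kind]["rho"].mean())
    assert np.mean(means["replicate"]) > np.mean(means["non_replicate"]) > np.mean(means["scrambled"])


def test_qc_requires_two_replicates():
    fc = _qc_fc()
    with pytest.raises(ValueError, match="2 replicates"):
        qc_replicate_correlation(fc[fc["replicate"] == 1])


# --- top variable guides --------------------------------------------------

def test_top_variable_matches_bruteforce_and_handles_edges(rng, caplog):
    cpm = pd.DataFrame(rng.random(size=(30, 5)) * 100,
                       index=[f"g{i:02d}" for i in range(30)])
    cpm.iloc[0] = 7.0  # constant row
    with caplog.at_level("WARNING", logger="resistscreen"):
        top = top_variable_guides(cpm, n=10)
    assert "g00" not in top.index
    expected = cpm.drop(index="g00").var(axis=1, ddof=1).sort_values(ascending=False).index[:10]
    assert list(top.index) == list(expected)
    assert np.allclose(top.mean(axis=1), 0, atol=1e-12)
    assert np.allclose(top.std(axis=1, ddof=1), 1, atol=1e-12)
    big = top_variable_guides(cpm, n=100)
    assert len(big) == 29  # all non-constant rows, with a warning
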