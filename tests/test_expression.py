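"""Tests of TPM, inducibility, response classes, resistance and ordering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from gvreprog.containers import CountMatrix
from gvreprog.expression import (
    ClassificationConfig,
    call_inducible,
    classify_response,
    cluster_order,
    compute_tpm,
    correlate_groups,
    find_resistant,
    response_summary,
    top_expressed,
)


def _toy_cm(counts: dict, lengths: dict, meta_rows: dict) -> CountMatrix:
    genes = pd.Index(sorted(lengths), name="gene_id")
    cdf = pd.DataFrame(counts, index=genes)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    meta.index.name = "sample_id"
    return CountMatrix(cdf, pd.Series(lengths).reindex(genes), meta)


def _meta(sample, cell_type="MEF", condition="NT", timepoint="24h", rep=1):
    return {
        "cell_type": cell_type,
        "condition": condition,
        "timepoint": timepoint,
        "replicate": rep,
        "female_id": f"F{rep}",
    }


# -- TPM ------------------------------------------------------------------

def test_single_gene_tpm_is_one_million():
    cm = _toy_cm({"s1": [7]}, {"g1": 1000}, {"s1": _meta("s1")})
    expr = compute_tpm(cm)
    assert expr.tpm.loc["g1", "s1"] == pytest.approx(1e6)


def test_equal_counts_tpm_follows_inverse_length():
    cm = _toy_cm({"s1": [5, 5]}, {"g1": 1000, "g2": 2000}, {"s1": _meta("s1")})
    expr = compute_tpm(cm)
    assert expr.tpm.loc["g1", "s1"] == pytest.approx(666666.6667, rel=1e-6)
    assert expr.tpm.loc["g2", "s1"] == pytest.approx(333333.3333, rel=1e-6)


def test_tpm_matches_definition_formula(rng):
    """Random 50×4 matrix equals an independent loop-wise recomputation."""
    counts = rng.integers(0, 500, size=(50, 4))
    counts[0] += 1  # avoid an all-zero column
    lengths = rng.integers(200, 5000, size=50)
    genes = [f"g{i:03d}" for i in range(50)]
    samples = [f"s{j}" for j in range(4)]
    cm = _toy_cm(
        {s: counts[:, j] for j, s in enumerate(samples)},
        dict(zip(genes, lengths)),
        {s: _meta(s) for s in samples},
    )
    expr = compute_tpm(cm)
    for j, s in enumerate(samples):
        denom = sum(counts[i, j] / lengths[i] for i in range(50))
        for i, g in enumerate(genes):
            expected = 1e6 * (counts[i, j] / lengths[i]) / denom
            assert expr.tpm.loc[g, s] == pytest.approx(expected)


def test_all_zero_sample_raises():
    cm = _toy_cm({"s1": [0, 0]}, {"g1": 100, "g2": 100}, {"s1": _meta("s1")})
    with pytest.raises(ValueError, match="all-zero"):
        compute_tpm(cm)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    st.lists(
        st.lists(st.integers(0, 1000), min_size=5, max_size=5),
        min_size=2,
        max_size=6,
    )
)
def test_tpm_columns_sum_to_one_million(count_rows):
    arr = np.array(count_rows)  # genes × samples
    if (arr.sum(axis=0) == 0).any():
        arr[0] += 1
    genes = [f"g{i}" for i in range(arr.shape[0])]
    samples = [f"s{j}" for j in range(arr.shape[1])]
    cm = _toy_cm(
        {s: arr[:, j] for j, s in enumerate(samples)},
        {g: 100 + 13 * i for i, g in enumerate(genes)},
        {s: _meta(s) for s in samples},
    )
    expr = compute_tpm(cm)
    np.testing.assert_allclose(expr.tpm.sum(axis=0), 1e6, atol=1e-3)


# -- inducibility ---------------------------------------------------------

def _nt_only_cm(values: dict[str, dict[str, list[float]]], lengths: dict) -> CountMatrix:
    """values[cell_type][gene] = replicate TPM-proportional counts."""
    counts, meta = {}, {}
    for ct, gene_vals in values.items():
        n_rep = len(next(iter(gene_vals.values())))
        for r in range(n_rep):
            sid = f"{ct}_NT_24h_r{r + 1}"
            counts[sid] = [gene_vals[g][r] for g in sorted(lengths)]
            meta[sid] = _meta(sid, cell_type=ct, rep=r + 1)
    return _toy_cm(counts, lengths, meta)


def test_mean_below_threshold_not_inducible():
    # counts chosen so one gene's mean TPM lands below 1
    lengths = {"g1": 1000, "g2": 1000}
    cm = _nt_only_cm({"ESC": {"g1": [2, 4, 3], "g2": [9998, 9996, 9997]}}, lengths)
    expr = compute_tpm(cm)
    res = call_inducible(expr, ClassificationConfig(tpm_inducible=500.0), ["ESC"])
    assert res.sets["ESC"] == {"g2"}


def test_all_genes_inducible_degenerate_venn():
    lengths = {"g1": 500, "g2": 500}
    vals = {ct: {"g1": [10, 10, 10], "g2": [20, 20, 20]} for ct in ("ESC", "MEF", "MYO")}
    cm = _nt_only_cm(vals, lengths)
    expr = compute_tpm(cm)
    res = call_inducible(expr, ClassificationConfig(), ["ESC", "MEF", "MYO"])
    assert len(res.union) == 2
    assert res.venn["ESC&MEF&MYO"] == 2
    assert all(v == 0 for k, v in res.venn.items() if k != "ESC&MEF&MYO")


def test_venn_regions_match_set_enumeration(expr_exact, default_cfg):
    """Venn counts equal brute-force enumeration over membership patterns."""
    expr, truth = expr_exact
    cts = ["ESC", "MEF", "MYO"]
    res = call_inducible(expr, default_cfg, cts)
    # oracle: per-gene membership from the truth's expected TPM
    member = {
        ct: set(truth.table.index[truth.table[f"nt_tpm_{ct}"] >= 1.0]) for ct in cts
    }
    assert res.sets == member
    regions: dict[str, int] = {}
    for g in truth.table.index:
        key = "&".join([ct for ct in cts if g in member[ct]])
        if key:
            regions[key] = regions.get(key, 0) + 1
    for key, count in res.venn.items():
        assert count == regions.get(key, 0), key


def test_monotonicity_in_inducible_threshold(expr_small, default_cfg):
    expr, _ = expr_small
    low = call_inducible(expr, ClassificationConfig(tpm_inducible=1.0))
    high = call_inducible(expr, ClassificationConfig(tpm_inducible=5.0))
    for ct in low.sets:
        assert high.sets[ct] <= low.sets[ct]


# -- classification -------------------------------------------------------

def _donor_nt_cm(donor, nt, lengths):
    counts, meta = {}, {}
    genes = sorted(lengths)
    for r in range(3):
        counts[f"MEF_donor_0h_r{r + 1}"] = [donor[g] for g in genes]
        meta[f"MEF_donor_0h_r{r + 1}"] = _meta("", condition="donor", timepoint="0h", rep=r + 1)
        counts[f"MEF_NT_24h_r{r + 1}"] = [nt[g] for g in genes]
        meta[f"MEF_NT_24h_r{r + 1}"] = _meta("", rep=r + 1)
    return _toy_cm(counts, lengths, meta)


def test_silent_to_expressed_is_activated_and_expressed_up_is_enhanced():
    lengths = {"g1": 1000, "g2": 1000, "g3": 1000}
    # TPM scale: per-sample total forced by a large filler gene
    donor = {"g1": 0, "g2": 10, "g3": 999990}
    nt = {"g1": 50, "g2": 80, "g3": 999870}
    cm = _donor_nt_cm(donor, nt, lengths)
    r = classify_response(compute_tpm(cm), ClassificationConfig(), "MEF")
    assert r.loc["g1", "class"] == "activated"  # donor 0 → NT 50
    assert r.loc["g2", "class"] == "enhanced"  # FC 81/11 ≈ 7.4 ≥ 2
    assert r.loc["g3", "class"] == "unchanged"


def test_classes_partition_every_gene(expr_small, default_cfg):
    expr, _ = expr_small
    r = classify_response(expr, default_cfg, "ESC")
    assert r["class"].isin(["activated", "enhanced", "repressed", "unchanged"]).all()
    assert len(r) == len(expr.genes)
    pct = response_summary(r)
    assert pct.sum() == pytest.approx(100.0)


def test_noise_free_classification_recovers_truth(expr_exact, default_cfg):
    expr, truth = expr_exact
    for ct in ("ESC", "MEF", "MYO"):
        r = classify_response(expr, default_cfg, ct)
        assert (r["class"].values == truth.classes(ct).values).all()


def test_both_timepoints_classify_identically_in_noise_free_limit(expr_exact, default_cfg):
    expr, _ = expr_exact
    r24 = classify_response(expr, default_cfg, "MEF", timepoint="24h")
    r48 = classify_response(expr, default_cfg, "MEF", timepoint="48h")
    assert (r24["class"] == r48["class"]).all()


def test_missing_condition_raises(expr_small, default_cfg):
    expr, _ = expr_small
    with pytest.raises(ValueError, match="no (NT|donor) samples"):
        classify_response(expr, default_cfg, "HELA")


# -- resistance -----------------------------------------------------------

def test_low_focal_nt_flagged_resistant():
    lengths = {"g1": 1000, "filler": 1000}
    counts, meta = {}, {}
    levels = {"ESC": 100, "MEF": 120, "MYO": 5}
    for ct, v in levels.items():
        for r in range(3):
            # gene order is sorted: filler first, then g1
            counts[f"{ct}_NT_24h_r{r + 1}"] = [1_000_000 - v, v]
            meta[f"{ct}_NT_24h_r{r + 1}"] = _meta("", cell_type=ct, rep=r + 1)
            counts[f"{ct}_donor_0h_r{r + 1}"] = [1_000_000 - v, v]
            meta[f"{ct}_donor_0h_r{r + 1}"] = _meta(
                "", cell_type=ct, condition="donor", timepoint="0h", rep=r + 1
            )
    cm = _toy_cm(counts, lengths, meta)
    expr = compute_tpm(cm)
    cfg = ClassificationConfig()
    responses = {ct: classify_response(expr, cfg, ct) for ct in levels}
    res = find_resistant(expr, responses, cfg)
    assert "g1" in res["MYO"]  # (111+1)/(5+1) ≈ 18.7 ≥ 4
    assert "g1" not in res["ESC"] and "g1" not in res["MEF"]


def test_equal_expression_resistant_nowhere(expr_exact, default_cfg):
    expr, truth = expr_exact
    responses = {ct: classify_response(expr, default_cfg, ct) for ct in ("ESC", "MEF", "MYO")}
    res = find_resistant(expr, responses, default_cfg)
    # genes never forced resistant and identically induced across types
    flat = truth.table
    never = flat.index[
        ~(flat["resistant_ESC"] | flat["resistant_MEF"] | flat["resistant_MYO"])
        & (flat["base_class"] == "activated")
    ]
    flagged = set().union(*res.values())
    assert len(set(never) & flagged) == 0


def test_resistant_recovery_with_forced_myo_set(default_cfg):
    from gvreprog.synthetic import ExprSimConfig, simulate_expression

    cfg = ExprSimConfig(seed=2)  # defaults: MYO resistant fraction 0.10
    cm, truth = simulate_expression(cfg)
    expr = compute_tpm(cm)
    responses = {ct: classify_response(expr, default_cfg, ct) for ct in ("ESC", "MEF", "MYO")}
    res = find_resistant(expr, responses, default_cfg)
    true_set, pred = truth.resistant_set("MYO"), res["MYO"]
    sens = len(true_set & pred) / len(true_set)
    fdr = len(pred - true_set) / max(len(pred), 1)
    assert sens >= 0.9
    assert fdr <= 0.1


def test_monotonicity_in_resistance_fold_change(expr_small, default_cfg):
    expr, _ = expr_small
    responses = {ct: classify_response(expr, default_cfg, ct) for ct in ("ESC", "MEF", "MYO")}
    loose = find_resistant(expr, responses, ClassificationConfig(fc_resist=4.0))
    strict = find_resistant(expr, responses, ClassificationConfig(fc_resist=8.0))
    for ct in loose:
        assert strict[ct] <= loose[ct]


def test_pairwise_mode_is_superset_of_mean_mode(expr_small, default_cfg):
    expr, _ = expr_small
    responses = {ct: classify_response(expr, default_cfg, ct) for ct in ("ESC", "MEF", "MYO")}
    mean_sets = find_resistant(expr, responses, default_cfg, mode="mean")
    pair_sets = find_resistant(expr, responses, default_cfg, mode="pairwise")
    for ct in mean_sets:
        # a gene ≥4-fold below the mean of others is ≥4-fold below the max
        assert mean_sets[ct] <= pair_sets[ct]


def test_single_cell_type_raises(expr_small, default_cfg):
    expr, _ = expr_small
    responses = {"MEF": classify_response(expr, default_cfg, "MEF")}
    with pytest.raises(ValueError, match="2 cell types"):
        find_resistant(expr, responses, default_cfg)


# -- correlation ----------------------------------------------------------

def test_group_against_itself_is_one(expr_small):
    expr, _ = expr_small
    sel = {"cell_type": "MEF", "condition": "NT", "timepoint": "24h"}
    assert correlate_groups(expr, sel, sel) == pytest.approx(1.0)


def test_correlation_matches_definitional_formula(expr_small, default_cfg):
    expr, _ = expr_small
    a = {"cell_type": "MEF", "condition": "donor"}
    b = {"cell_type": "MEF", "condition": "NT"}
    r = correlate_groups(expr, a, b, default_cfg)
    x = np.log2(expr.group_mean(**a) + 1).to_numpy()
    y = np.log2(expr.group_mean(**b) + 1).to_numpy()
    xc, yc = x - x.mean(), y - y.mean()
    expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
    assert r == pytest.approx(expected, abs=1e-12)


def test_nt_samples_correlate_across_cell_types(expr_small, default_cfg):
    """After NT the three donor types converge to a shared induced state."""
    nt = {}
    for ct in ("ESC", "MEF", "MYO"):
        nt[ct] = {"cell_type": ct, "condition": "NT"}
    r_nt = correlate_groups(expr_small[0], nt["ESC"], nt["MYO"], default_cfg)
    r_donor_nt = correlate_groups(
        expr_small[0],
        {"cell_type": "MYO", "condition": "donor"},
        nt["MYO"],
        default_cfg,
    )
    assert r_nt > 0.9
    assert r_donor_nt < r_nt


# -- top-expressed ordering ----------------------------------------------

def test_top_expressed_full_length_is_permutation(expr_small):
    expr, _ = expr_small
    order = top_expressed(expr, "MYO", "NT", n=len(expr.genes))
    assert sorted(order) == sorted(expr.genes)


def test_top_expressed_tie_breaks_lexicographically():
    lengths = {"a1": 1000, "b1": 1000, "z0": 1000}
    cm = _nt_only_cm({"MYO": {"a1": [5, 5, 5], "b1": [5, 5, 5], "z0": [10, 10, 10]}}, lengths)
    expr = compute_tpm(cm)
    assert top_expressed(expr, "MYO", "NT", n=3) == ["z0", "a1", "b1"]


def test_top_expressed_matches_brute_force_sort(expr_small, rng):
    expr, _ = expr_small
    got = top_expressed(expr, "ESC", "NT", n=10)
    cols = expr.select_samples(cell_type="ESC", condition="NT")
    means = expr.tpm[cols].mean(axis=1)
    oracle = sorted(means.index, key=lambda g: (-means[g], g))[:10]
    assert got == oracle


def test_top_expressed_n_too_large_raises(expr_small):
    expr, _ = expr_small
    with pytest.raises(ValueError, match="exceeds"):
        top_expressed(expr, "ESC", "NT", n=len(expr.genes) + 1)


# -- clustering -----------------------------------------------------------

def test_identical_pair_merges_first():
    lengths = {f"g{i}": 1000 for i in range(6)}
    base = np.array([100, 10, 50, 5, 80, 20])
    counts = {
        "s1": base,
        "s2": base,  # identical to s1
        "s3": base[::-1].copy(),  # different profile
    }
    meta = {s: _meta(s) for s in counts}
    cm = _toy_cm({k: list(v) for k, v in counts.items()}, lengths, meta)
    expr = compute_tpm(cm)
    sample_order, _ = cluster_order(expr)
    i1, i2 = sample_order.index("s1"), sample_order.index("s2")
    assert abs(i1 - i2) == 1  # the identical pair is adjacent


def test_three_sample_dendrogram_matches_exhaustive_linkage(expr_small, default_cfg):
    """At n=3 the merge sequence is checkable by direct enumeration."""
    expr, _ = expr_small
    cols = [
        expr.select_samples(cell_type="ESC", condition="donor")[0],
        expr.select_samples(cell_type="MEF", condition="donor")[0],
        expr.select_samples(cell_type="MEF", condition="donor")[1],
    ]
    sub = expr.tpm[cols]
    logx = np.log2(sub.to_numpy() + 1)
    d = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            if i != j:
                d[i, j] = 1 - np.corrcoef(logx[:, i], logx[:, j])[0, 1]
    pairs = [(0, 1), (0, 2), (1, 2)]
    first = min(pairs, key=lambda p: d[p])
    z = linkage(squareform(d, checks=False), method="average")
    assert {int(z[0, 0]), int(z[0, 1])} == set(first)
    # second merge distance is the average of the two remaining distances
    rest = [p for p in pairs if p != first]
    assert z[1, 2] == pytest.approx(np.mean([d[p] for p in rest]))


def test_same_donor_type_samples_form_contiguous_blocks(expr_small, default_cfg):
    """Donor samples cluster by cell type (distinct donor programs)."""
    expr, _ = expr_small
    donor_cols = expr.select_samples(condition="donor")
    sub = expr.tpm[donor_cols]
    sample_order, gene_order = cluster_order(expr.__class__(tpm=sub, source=expr.source))
    types = [s.split("_")[0] for s in sample_order]
    # each cell type occupies one contiguous run of leaves
    runs = [t for i, t in enumerate(types) if i == 0 or types[i - 1] != t]
    assert len(runs) == 3


def test_constant_matrix_raises(default_cfg):
    lengths = {"g1": 1000, "g2": 1000}
    cm = _nt_only_cm({"MYO": {"g1": [5, 5, 5], "g2": [5, 5, 5]}}, lengths)
    expr = compute_tpm(cm)
    with pytest.raises(ValueError, match="constant|undefined"):
        cluster_order(expr)
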