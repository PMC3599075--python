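import numpy as np
import pandas as pd
import pytest
from scipy.stats import beta

from scarray.array_io import ExperimentSet, _normalize_annotation, _normalize_meta
from scarray.concordance import (DetectionProfile, MRatioProfile,
                                 build_m_ratio_profiles, call_detection,
                                 cluster_top_variable, m_ratio_correlations,
                                 pairwise_outlier_scan,
                                 random_pair_difference_correlation,
                                 rank_percentile, sensitivity_specificity)
from scarray.preprocess import run_preprocess
from scarray.synthetic_data import SimConfig, simulate_experiment, \
    simulate_patient_experiment


def _profile(group, values, threshold=300.0):
    idx = pd.Index([f"p{i}" for i in range(len(values))])
    return DetectionProfile(group, pd.Series(values, index=idx),
                            threshold, n_arrays=1)


# ---------------------------------------------------------------------------
# detection


def test_detection_strict_inequality():
    prof = _profile("1", [301.0, 300.0])
    assert prof.detected.tolist() == [True, False]


def test_threshold_zero_detects_all_positive(small_sim):
    prof = call_detection(small_sim, "10", threshold=0.0)
    positive = prof.mean_signal > 0
    assert (prof.detected == positive).all()


def test_detection_excludes_control_probes():
    ann = _normalize_annotation(pd.DataFrame({
        "probe_id": ["p1", "pc"], "is_control": [False, True]}))
    meta = _normalize_meta(pd.DataFrame({
        "sample_id": ["s1"], "group": ["1"], "day": ["d1"], "replicate": [1]}))
    af = pd.DataFrame({"s1": [500.0, 500.0]}, index=["p1", "pc"])
    es = ExperimentSet(ann, meta, af, af.copy())
    prof = call_detection(es, "1")
    assert list(prof.mean_signal.index) == ["p1"]


def test_detection_noise_free_matches_truth(noise_free_config):
    es = simulate_experiment(noise_free_config)
    for g in ("1", "5", "10"):
        det = call_detection(es, g).detected
        expr = es.truth.expressed[g].reindex(det.index)
        assert (det == expr).all()


# ---------------------------------------------------------------------------
# sensitivity / specificity


def test_sens_spec_hand_count():
    # gold detects {A,B,C,D}, test detects {A,B,C,X}, universe 6
    gold = _profile("g", [400, 400, 400, 400, 0, 0])
    test = _profile("t", [400, 400, 400, 0, 400, 0])
    rep = sensitivity_specificity(test, gold)
    assert rep.sensitivity == pytest.approx(0.75)
    assert rep.specificity == pytest.approx(0.5)
    assert rep.universe == 6
    assert (rep.n_both, rep.n_gold_only, rep.n_test_only, rep.n_neither) == \
        (3, 1, 1, 1)


def test_beta_ci_uniform_posterior():
    gold = _profile("g", [0.0])
    test = _profile("t", [0.0])
    rep = sensitivity_specificity(test, gold)
    # s=0, f=0 for sensitivity: no gold positives -> NaN point estimate but
    # the Beta(1,1) interval is the uniform quantiles
    assert rep.sensitivity_ci == (pytest.approx(0.025), pytest.approx(0.975))


def test_beta_ci_closed_form_10_0():
    gold = _profile("g", [400.0] * 10)
    test = _profile("t", [400.0] * 10)
    rep = sensitivity_specificity(test, gold)
    # Beta(11, 1): cdf(x) = x^11
    assert rep.sensitivity_ci[0] == pytest.approx(0.025 ** (1 / 11), abs=1e-9)
    assert rep.sensitivity_ci[1] == pytest.approx(0.975 ** (1 / 11), abs=1e-9)


def test_counts_sum_to_universe(small_sim):
    ns = run_preprocess(small_sim)
    rep = sensitivity_specificity(call_detection(ns, "1"),
                                  call_detection(ns, "10"))
    assert rep.universe == len(ns.noncontrol_probes())


def test_swap_symmetry(small_sim):
    ns = run_preprocess(small_sim)
    a = call_detection(ns, "1")
    b = call_detection(ns, "10")
    fwd = sensitivity_specificity(a, b)
    rev = sensitivity_specificity(b, a)
    # swapping roles: sensitivity becomes the PPV of the original counts
    ppv = fwd.n_both / (fwd.n_both + fwd.n_test_only)
    assert rev.sensitivity == pytest.approx(ppv)


def test_profiles_must_share_universe():
    with pytest.raises(ValueError):
        sensitivity_specificity(_profile("t", [1.0]), _profile("g", [1.0, 2.0]))


# ---------------------------------------------------------------------------
# M-ratio correlations


def _mprof(group, values):
    idx = pd.Index([f"p{i}" for i in range(len(values))])
    return MRatioProfile(group, pd.Series(np.asarray(values, float), index=idx))


def test_identical_profiles_correlate_one():
    a = _mprof("a", [1.0, 2.0, 3.0, 2.5])
    assert m_ratio_correlations(a, a, "pearson") == pytest.approx(1.0)
    assert m_ratio_correlations(a, a, "spearman") == pytest.approx(1.0)


def test_affine_invariance():
    a = _mprof("a", [1.0, 2.0, 3.0, 2.5])
    b = _mprof("b", 2.0 * a.mean_m.to_numpy() + 3.0)
    assert m_ratio_correlations(a, b, "pearson") == pytest.approx(1.0)
    assert m_ratio_correlations(a, b, "spearman") == pytest.approx(1.0)


def test_spearman_hand_computed_cycle():
    # ranks (1..5) vs (2,3,1,4,5): sum d^2 = 1+1+4 = 6;
    # rho = 1 - 6*6/(5*24) = 0.7
    a = _mprof("a", [10.0, 20.0, 30.0, 40.0, 50.0])
    b = _mprof("b", [20.0, 30.0, 10.0, 40.0, 50.0])
    assert m_ratio_correlations(a, b, "spearman") == pytest.approx(0.7)


def test_m_profiles_restricted_to_jointly_detected(small_sim):
    ns = run_preprocess(small_sim)
    profs = build_m_ratio_profiles(ns, ["1", "5", "10"])
    idx = profs["1"].mean_m.index
    for g in ("5", "10"):
        assert profs[g].mean_m.index.equals(idx)
    for g in ("1", "5", "10"):
        det = call_detection(ns, g).detected
        assert det.loc[idx].all()


# ---------------------------------------------------------------------------
# random-pair difference correlation


def test_pair_diff_identical_profiles():
    a = _mprof("a", [0.5, 1.5, -1.0, 2.0, 0.0, 3.0])
    r, _ = random_pair_difference_correlation(a, a, n_pairs=10, seed=1)
    assert r == pytest.approx(1.0)


def test_pair_diff_shift_invariance():
    a = _mprof("a", [0.5, 1.5, -1.0, 2.0, 0.0, 3.0])
    b = _mprof("b", a.mean_m.to_numpy() + 4.2)
    r, _ = random_pair_difference_correlation(a, b, n_pairs=15, seed=1)
    assert r == pytest.approx(1.0)


def test_pair_diff_exhaustive_matches_brute_force():
    rng = np.random.default_rng(17)
    a = _mprof("a", rng.normal(size=6))
    b = _mprof("b", rng.normal(size=6))
    r, log = random_pair_difference_correlation(a, b, n_pairs=15, seed=99)
    # brute-force oracle over all C(6,2)=15 pairs
    xa, xb = a.mean_m.to_numpy(), b.mean_m.to_numpy()
    da, db = [], []
    for i in range(6):
        for j in range(i + 1, 6):
            da.append(xa[i] - xa[j])
            db.append(xb[i] - xb[j])
    expected = np.corrcoef(da, db)[0, 1]
    assert r == pytest.approx(expected, abs=1e-12)
    assert len(log) == 15


def test_pair_diff_seed_reproducible():
    rng = np.random.default_rng(3)
    a = _mprof("a", rng.normal(size=40))
    b = _mprof("b", rng.normal(size=40))
    r1, log1 = random_pair_difference_correlation(a, b, n_pairs=100, seed=5)
    r2, log2 = random_pair_difference_correlation(a, b, n_pairs=100, seed=5)
    assert r1 == r2
    pd.testing.assert_frame_equal(log1, log2)


def test_pair_diff_rejects_too_many_pairs():
    a = _mprof("a", [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        random_pair_difference_correlation(a, a, n_pairs=4, seed=0)


def test_pair_diff_pairs_distinct():
    rng = np.random.default_rng(4)
    a = _mprof("a", rng.normal(size=10))
    _, log = random_pair_difference_correlation(a, a, n_pairs=30, seed=2)
    pairs = set(zip(log["probe_i"], log["probe_j"]))
    assert len(pairs) == 30


# ---------------------------------------------------------------------------
# pairwise outlier scan


def test_pairwise_scan_identical_arrays_no_outlier(small_sim):
    ns = run_preprocess(small_sim)
    ids = ns.samples_in_group("10")
    for s in ids[1:]:
        ns.m[s] = ns.m[ids[0]]
    rep = pairwise_outlier_scan(ns, "10")
    assert rep.exclusions == {}


def test_pairwise_scan_flags_noise_array(small_sim):
    ns = run_preprocess(small_sim)
    ids = ns.samples_in_group("10")
    rng = np.random.default_rng(0)
    ns.m[ids[0]] = rng.normal(size=len(ns.m))  # replace with pure noise
    rep = pairwise_outlier_scan(ns, "10")
    assert ids[0] in rep.exclusions


def test_pairwise_scan_needs_three_arrays(small_sim):
    ns = run_preprocess(small_sim)
    ns.samples.loc[ns.samples.group == "10", "qc_excluded"] = True
    ns.samples.loc[ns.samples.group == "10", "qc_reason"] = "x"
    keep = ns.samples_in_group("10")
    assert keep == []
    with pytest.raises(ValueError):
        pairwise_outlier_scan(ns, "10")


# ---------------------------------------------------------------------------
# clustering


def test_two_patient_groups_partition():
    cfg = SimConfig(n_probes=400, seed=21, capture_prob=0.6)
    es = simulate_patient_experiment(cfg, ["pA", "pB"], n_cells=5)
    ns = run_preprocess(es)
    res = cluster_top_variable(ns, n_genes=200)
    left, right = res.top_level_partition()
    labels = {s: res.sample_labels[s] for s in left}
    assert len(set(labels.values())) == 1
    assert {res.sample_labels[s] for s in right} != set(labels.values())


def test_cluster_n_genes_capped(small_sim):
    ns = run_preprocess(small_sim)
    res = cluster_top_variable(ns, n_genes=10 ** 6)
    assert len(res.selected_genes) == small_sim.n_probes


def test_cluster_duplicate_samples_adjacent(small_sim):
    ns = run_preprocess(small_sim)
    ids = list(ns.sample_ids)
    ns.af3[ids[1]] = ns.af3[ids[0]]
    res = cluster_top_variable(ns, n_genes=100)
    order = res.leaf_order
    assert abs(order.index(ids[0]) - order.index(ids[1])) == 1


def test_newick_export_parses(small_sim):
    ns = run_preprocess(small_sim)
    res = cluster_top_variable(ns, n_genes=50)
    nwk = res.to_newick()
    assert nwk.endswith(";")
    for s in res.leaf_order:
        assert s in nwk


# ---------------------------------------------------------------------------
# rank percentile


def test_rank_percentile_extremes(small_sim):
    ns = run_preprocess(small_sim)
    sig = call_detection(ns, "10").mean_signal
    ann = ns.annotation.set_index("probe_id")
    top_gene = ann.loc[sig.idxmax(), "gene_symbol"]
    tab = rank_percentile(ns, [top_gene])
    assert tab.loc[top_gene, "10"] == 100


def test_rank_percentile_matches_brute_force(small_sim):
    ns = run_preprocess(small_sim)
    genes = [g for g in ns.annotation["gene_symbol"][:5] if g]
    tab = rank_percentile(ns, genes, decimals=4)
    sig = call_detection(ns, "5").mean_signal
    ann = ns.annotation
    for g in genes:
        probes = ann.loc[(ann.gene_symbol == g) &
                         (~ann.is_control), "probe_id"]
        probes = [p for p in probes if p in sig.index]
        val = sig.loc[probes].max()
        expected = 100.0 * (sig <= val).sum() / len(sig)
        assert tab.loc[g, "5"] == pytest.approx(expected, abs=1e-3)


def test_rank_percentile_unknown_genes_rejected(small_sim):
    ns = run_preprocess(small_sim)
    with pytest.raises(ValueError):
        rank_percentile(ns, ["NOT_A_GENE"])
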