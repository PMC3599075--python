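import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from scarray.preprocess import (NormalizedSet, PreprocessConfig,
                                UnsupportedDesignError,
                                _normexp_conditional_mean, day_effect_correct,
                                estimate_day_shifts, loess_normalize,
                                normexp_correct, normexp_fit,
                                quantile_normalize, run_preprocess)
from scarray.synthetic_data import SimConfig, simulate_experiment


# ---------------------------------------------------------------------------
# day-effect correction


def _two_day_experiment(shift3=20.0, shift5=0.0, seed=0):
    return simulate_experiment(SimConfig(
        n_probes=400, groups=((1, 6),), days=("d1", "d2"), seed=seed,
        nonspecific_floor_mean=500.0, nonspecific_floor_sd=10.0,
        day_shift_af3=shift3, day_shift_af5=shift5))


def test_day_means_equal_after_correction():
    es = _two_day_experiment(shift3=120.0, shift5=40.0)
    corrected = day_effect_correct(es)
    meta = corrected.samples
    for mat in (corrected.af3, corrected.af5):
        d1 = meta.loc[meta.day == "d1", "sample_id"]
        d2 = meta.loc[meta.day == "d2", "sample_id"]
        assert mat[list(d1)].to_numpy().mean() == pytest.approx(
            mat[list(d2)].to_numpy().mean(), abs=1e-9)


def test_day1_arrays_untouched():
    es = _two_day_experiment(shift3=120.0)
    corrected = day_effect_correct(es)
    d1 = es.samples.loc[es.samples.day == "d1", "sample_id"].tolist()
    assert (corrected.af3[d1].to_numpy() == es.af3[d1].to_numpy()).all()


def test_single_day_group_identity():
    es = simulate_experiment(SimConfig(n_probes=100, groups=((1, 4),),
                                       days=("d1",), seed=1))
    corrected = day_effect_correct(es)
    assert (corrected.af3.to_numpy() == es.af3.to_numpy()).all()


def test_three_days_rejected():
    es = simulate_experiment(SimConfig(n_probes=50, groups=((1, 6),),
                                       days=("d1", "d2", "d3"), seed=1))
    with pytest.raises(UnsupportedDesignError):
        day_effect_correct(es)


def test_injected_shift_recovered():
    """Estimated day-2 minus day-1 mean shift ~ injected shift."""
    est = []
    for seed in range(10):
        es = _two_day_experiment(shift3=150.0, seed=seed)
        est.append(estimate_day_shifts(es)[("1", "af3")])
    # Monte-Carlo tolerance: biology is balanced across days by design
    assert np.mean(est) == pytest.approx(150.0, abs=60.0)


def test_forced_shift_example():
    """Day-1 mean 100 vs day-2 mean 120: day-2 shifted by -20."""
    from scarray.array_io import ExperimentSet, _normalize_annotation, _normalize_meta
    ann = _normalize_annotation(pd.DataFrame({"probe_id": ["p1", "p2"]}))
    meta = _normalize_meta(pd.DataFrame({
        "sample_id": ["a", "b"], "group": ["1", "1"],
        "day": ["d1", "d2"], "replicate": [1, 2]}))
    af3 = pd.DataFrame({"a": [90.0, 110.0], "b": [115.0, 125.0]},
                       index=["p1", "p2"])
    af5 = af3.copy()
    es = ExperimentSet(ann, meta, af3, af5)
    out = day_effect_correct(es)
    assert out.af3["b"].tolist() == [95.0, 105.0]
    assert out.af3["a"].tolist() == [90.0, 110.0]


# ---------------------------------------------------------------------------
# normexp


def _oracle_conditional_mean(x, mu, sigma, alpha):
    """Numerical-integration oracle for E[S | X = x], S~Exp(alpha), B~N(mu,s).

    Integrates over the background b = x - s (narrow normal peak), which
    keeps the integrand well-localized for every x.
    """
    lo = mu - 12 * sigma
    hi = min(mu + 12 * sigma, x)

    def num(b):
        return (x - b) * norm.pdf(b, mu, sigma) * np.exp(-(x - b) / alpha)

    def den(b):
        return norm.pdf(b, mu, sigma) * np.exp(-(x - b) / alpha)

    n, _ = quad(num, lo, hi, limit=200)
    d, _ = quad(den, lo, hi, limit=200)
    return n / d


@pytest.mark.parametrize("x", [50.0, 90.0, 110.0, 300.0, 1500.0, 5000.0])
def test_conditional_mean_matches_integration_oracle(x):
    mu, sigma, alpha = 100.0, 10.0, 1000.0
    expected = _oracle_conditional_mean(x, mu, sigma, alpha)
    got = _normexp_conditional_mean(np.array([x]), mu, sigma, alpha)[0]
    assert got == pytest.approx(expected, rel=1e-6, abs=1e-6)


def test_normexp_corrected_close_to_oracle_at_true_params():
    """Fitted-parameter correction tracks the true-parameter oracle (RMS)."""
    rng = np.random.default_rng(42)
    x = rng.normal(100, 10, size=5000) + rng.exponential(1000, size=5000)
    corrected = normexp_correct(x, offset=50.0)
    idx = np.linspace(0, len(x) - 1, 40).astype(int)
    xs = np.sort(x)[idx]
    oracle = np.array([_oracle_conditional_mean(v, 100.0, 10.0, 1000.0) + 50.0
                       for v in xs])
    got = normexp_correct(x, offset=50.0)
    got_at = pd.Series(got, index=x).loc[xs].to_numpy()
    rms = np.sqrt(np.mean((got_at - oracle) ** 2))
    assert rms < 75.0  # parameter-estimation tolerance on a 1000-scale signal


def test_normexp_large_signal_asymptote():
    mu, sigma, alpha = 100.0, 10.0, 1000.0
    x = np.array([50_000.0])
    got = _normexp_conditional_mean(x, mu, sigma, alpha) + 50.0
    # asymptote x - mu - sigma^2/alpha + 50 ~ x - mu + 50
    assert got[0] == pytest.approx(x[0] - mu + 50.0, abs=1.0)


def test_normexp_monotone_and_positive():
    rng = np.random.default_rng(3)
    x = rng.normal(80, 15, size=2000) + rng.exponential(400, size=2000)
    y = normexp_correct(x, offset=50.0)
    assert (y > 0).all()
    order = np.argsort(x)
    assert (np.diff(y[order]) > 0).all()


def test_normexp_degenerate_input_warns():
    with pytest.warns(UserWarning):
        y = normexp_correct(np.full(20, 7.0), offset=50.0)
    assert (y == 50.0).all()


def test_normexp_fit_recovers_rough_parameters():
    rng = np.random.default_rng(0)
    x = rng.normal(100, 10, size=20_000) + rng.exponential(1000, size=20_000)
    mu, sigma, alpha = normexp_fit(x)
    assert mu == pytest.approx(100.0, abs=40.0)
    assert alpha == pytest.approx(1000.0, rel=0.25)


# ---------------------------------------------------------------------------
# loess


def test_loess_zero_m_identity():
    rng = np.random.default_rng(1)
    a = rng.uniform(4, 14, size=200)
    out = loess_normalize(np.zeros(200), a)
    assert np.allclose(out, 0.0, atol=1e-12)


def test_loess_constant_trend_removed():
    rng = np.random.default_rng(2)
    a = rng.uniform(4, 14, size=200)
    out = loess_normalize(np.full(200, 2.0), a)
    assert np.allclose(out, 0.0, atol=1e-9)


def test_loess_removes_linear_trend():
    rng = np.random.default_rng(5)
    a = rng.uniform(4, 14, size=2000)
    m = 0.5 * a + rng.normal(0, 0.01, size=2000)
    out = loess_normalize(m, a)
    slope = np.polyfit(a, out, 1)[0]
    assert abs(slope) < 0.02


def test_loess_too_few_points():
    with pytest.raises(ValueError):
        loess_normalize(np.zeros(5), np.arange(5.0))


# ---------------------------------------------------------------------------
# quantile normalization


def test_quantile_two_array_example():
    # arrays [1,2,3] and [4,5,6] in log2 units -> both [2.5, 3.5, 4.5]
    mat = pd.DataFrame({"a": 2.0 ** np.array([1.0, 2.0, 3.0]),
                        "b": 2.0 ** np.array([4.0, 5.0, 6.0])})
    out = np.log2(quantile_normalize(mat).to_numpy())
    assert np.allclose(out[:, 0], [2.5, 3.5, 4.5], atol=1e-9)
    assert np.allclose(out[:, 1], [2.5, 3.5, 4.5], atol=1e-9)


def test_quantile_identical_arrays_unchanged():
    col = np.array([4.0, 1.0, 9.0, 2.0])
    mat = pd.DataFrame({"a": col, "b": col})
    out = quantile_normalize(mat)
    assert np.allclose(out.to_numpy()[:, 0], col, rtol=1e-12)


def test_quantile_column_permutation_equivariance():
    rng = np.random.default_rng(8)
    mat = pd.DataFrame(rng.lognormal(5, 1, size=(50, 4)),
                       columns=list("abcd"))
    out1 = quantile_normalize(mat)
    perm = ["c", "a", "d", "b"]
    out2 = quantile_normalize(mat[perm])
    assert np.allclose(out1[perm].to_numpy(), out2.to_numpy())


def test_quantile_sorted_columns_identical():
    rng = np.random.default_rng(9)
    mat = pd.DataFrame(rng.lognormal(6, 2, size=(300, 5)))
    out = np.log2(quantile_normalize(mat).to_numpy())
    ref = np.sort(out[:, 0])
    for j in range(1, 5):
        assert np.allclose(np.sort(out[:, j]), ref, atol=1e-9)


def test_quantile_ties_get_mean_of_tied_reference():
    mat = pd.DataFrame({"a": [2.0, 2.0, 8.0], "b": [2.0, 4.0, 8.0]})
    out = quantile_normalize(mat)
    # tied values in column a must stay tied
    assert out["a"].iloc[0] == out["a"].iloc[1]


def test_quantile_single_array_warns_identity():
    mat = pd.DataFrame({"a": [1.0, 2.0]})
    with pytest.warns(UserWarning):
        out = quantile_normalize(mat)
    assert (out.to_numpy() == mat.to_numpy()).all()


# ---------------------------------------------------------------------------
# full chain


def test_provenance_lists_four_steps(small_sim):
    ns = run_preprocess(small_sim)
    assert [s["step"] for s in ns.provenance] == [
        "day_effect_correct", "normexp_correct", "loess_normalize",
        "quantile_normalize"]


def test_run_preprocess_deterministic(small_sim):
    a = run_preprocess(small_sim)
    b = run_preprocess(small_sim)
    assert (a.af3.to_numpy() == b.af3.to_numpy()).all()
    assert (a.m.to_numpy() == b.m.to_numpy()).all()


def test_run_preprocess_rejects_excluded_samples(small_sim):
    es = small_sim.exclude_samples({small_sim.sample_ids[0]: "yield"})
    with pytest.raises(ValueError):
        run_preprocess(es)


def test_quantile_invariant_within_groups(small_sim):
    ns = run_preprocess(small_sim)
    for g in ns.groups():
        ids = ns.samples_in_group(g)
        logs = np.log2(ns.af3[ids].to_numpy())
        ref = np.sort(logs[:, 0])
        for j in range(1, logs.shape[1]):
            assert np.allclose(np.sort(logs[:, j]), ref, atol=1e-9)


def test_day_correction_is_strictly_within_group():
    """Correcting the joint set equals correcting each group in isolation."""
    es = simulate_experiment(SimConfig(
        n_probes=300, groups=((1, 4), (10, 4)), seed=2,
        day_shift_af3=100.0, nonspecific_floor_mean=400.0,
        nonspecific_floor_sd=10.0))
    joint = day_effect_correct(es)
    for g in ("1", "10"):
        ids = es.samples_in_group(g)
        sub = es.drop_excluded()
        keep = sub.samples["sample_id"].isin(ids)
        from scarray.array_io import ExperimentSet
        solo = ExperimentSet(sub.annotation.copy(),
                             sub.samples.loc[keep].reset_index(drop=True),
                             sub.af3[ids], sub.af5[ids])
        solo_corr = day_effect_correct(solo)
        assert (solo_corr.af3.to_numpy() == joint.af3[ids].to_numpy()).all()


def test_noise_free_mean_m_tracks_true_ratio(noise_free_config):
    es = simulate_experiment(noise_free_config)
    ns = run_preprocess(es)
    g = "10"
    ids = ns.samples_in_group(g)
    raw_ratio = np.log2(es.af3[ids].mean(axis=1).clip(lower=1e-12)
                        / es.af5[ids].mean(axis=1))
    expressed = es.truth.expressed[g]
    m_mean = ns.m[ids].mean(axis=1)
    diff = (m_mean - raw_ratio)[expressed]
    # constant offset allowed; spread around it must be small
    assert diff.std() < 0.35
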