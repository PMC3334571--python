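"""Normalization against a brute-force oracle, QC thresholds, batch checks."""

import numpy as np
import pandas as pd
import pytest

from methpop.preprocess import (
    batch_effect_check,
    normalize_intensities,
    quantile_normalize,
    replicate_concordance,
    sample_qc,
)
from methpop.simdata import simulate_raw_intensities, SimConfig
from methpop.types import BetaMatrix, IntensityTable, ValidationError


def _reference_quantile_normalize(X):
    """Brute-force oracle: sort each column, average order statistics
    across columns, map each value back to its rank's average."""
    X = np.asarray(X, float)
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        ranks = np.argsort(np.argsort(X[:, j]))
        out[:, j] = ref[ranks]
    return out


@pytest.mark.parametrize("seed", range(6))
def test_quantile_normalization_matches_oracle(seed):
    rng = np.random.default_rng(seed)
    X = rng.random((5, 5)) * 100
    assert np.allclose(quantile_normalize(X), _reference_quantile_normalize(X))


def test_quantile_normalization_equalizes_and_is_idempotent():
    rng = np.random.default_rng(3)
    X = rng.exponential(size=(40, 6))
    q = quantile_normalize(X)
    sorted_cols = np.sort(q, axis=0)
    for j in range(1, q.shape[1]):
        assert np.allclose(sorted_cols[:, 0], sorted_cols[:, j])
    assert np.allclose(quantile_normalize(q), q)


def test_quantile_normalization_ties_get_span_mean():
    # column with a tie: both tied values receive the mean of the two
    # reference order statistics they span
    X = np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
    q = quantile_normalize(X)
    ref = np.sort(X, axis=0).mean(axis=1)  # [5.5, 10.5, 17.5]
    assert q[0, 0] == q[1, 0] == pytest.approx((ref[0] + ref[1]) / 2)
    assert q[2, 0] == pytest.approx(ref[2])


def _single_sample_table(m, u, bg):
    data = pd.DataFrame(
        {
            "site": ["cg0"],
            "sample": ["s0"],
            "M": [m],
            "U": [u],
            "channel": ["green"],
            "n_beads": [10],
            "detection_p": [0.001],
        }
    )
    controls = pd.DataFrame(
        {"sample": ["s0", "s0"], "channel": ["green", "red"], "neg_mean": [bg, bg]}
    )
    return IntensityTable(data, controls)


def test_normalize_single_sample_is_plain_ratio():
    beta = normalize_intensities(_single_sample_table(100.0, 300.0, 0.0))
    assert beta.values.loc["cg0", "s0"] == pytest.approx(0.25)


def test_background_subtraction_cancels_offset():
    beta = normalize_intensities(_single_sample_table(150.0, 350.0, 50.0))
    assert beta.values.loc["cg0", "s0"] == pytest.approx(0.25)


def test_fully_methylated_site_with_background_only_u_channel():
    beta = normalize_intensities(_single_sample_table(2050.0, 50.0, 50.0))
    assert beta.values.loc["cg0", "s0"] == pytest.approx(1.0)


def test_zero_total_intensity_gives_missing_beta():
    beta = normalize_intensities(_single_sample_table(50.0, 50.0, 50.0))
    assert np.isnan(beta.values.loc["cg0", "s0"])


def test_round_trip_exact_when_sample_distributions_match():
    """With per-sample additive background and beta values that form the
    same multiset in every sample within each dye channel, the full
    pipeline - background subtraction, clamping, quantile normalization -
    recovers beta exactly (quantile normalization becomes the identity)."""
    green = np.array([0.05, 0.5, 0.95])  # sites 0,2,4 (alternating channels)
    red = np.array([0.2, 0.8, 0.33])  # sites 1,3,5
    rng = np.random.default_rng(5)
    cols = []
    for _ in range(7):
        g = rng.permutation(green)
        r = rng.permutation(red)
        cols.append(np.array([g[0], r[0], g[1], r[1], g[2], r[2]]))
    B = np.column_stack(cols)
    base = np.arange(6)  # site count only
    bm = BetaMatrix(
        pd.DataFrame(
            B,
            index=[f"cg{i}" for i in range(len(base))],
            columns=[f"s{j}" for j in range(7)],
        )
    )

    class _DS:
        beta = bm
        truth = None

    raw = simulate_raw_intensities(_DS, SimConfig(seed=11))
    rec = normalize_intensities(raw)
    err = np.abs(rec.values.loc[bm.values.index, bm.values.columns].to_numpy() - B)
    assert err.max() < 1e-9


def test_round_trip_close_on_simulated_cohort(small_cohort):
    ds, cfg = small_cohort
    raw = simulate_raw_intensities(ds, cfg)
    rec = normalize_intensities(raw)
    a = ds.beta.values.to_numpy()
    b = rec.values.loc[ds.beta.site_ids, ds.beta.sample_ids].to_numpy()
    assert np.corrcoef(a.ravel(), b.ravel())[0, 1] > 0.995


def _qc_table(n_sites, fail_sites, sample="s0"):
    nb = np.full(n_sites, 10)
    nb[:fail_sites] = 3  # fewer than five beads -> failing site
    data = pd.DataFrame(
        {
            "site": [f"cg{i}" for i in range(n_sites)],
            "sample": sample,
            "M": 100.0,
            "U": 100.0,
            "channel": "green",
            "n_beads": nb,
            "detection_p": 0.001,
        }
    )
    controls = pd.DataFrame(
        {"sample": [sample], "channel": ["green"], "neg_mean": [0.0]}
    )
    return IntensityTable(data, controls)


def test_sample_qc_all_good_passes():
    rep = sample_qc(_qc_table(100, 0))
    assert rep.samples["passed"].all()
    assert rep.samples["fail_frac"].iloc[0] == 0.0


def test_sample_qc_boundary_is_strict():
    # 4.9% failing passes; exactly 5.0% fails (strict inequality)
    assert sample_qc(_qc_table(1000, 49)).samples["passed"].iloc[0]
    assert not sample_qc(_qc_table(1000, 50)).samples["passed"].iloc[0]


def test_sample_qc_high_detection_p_fails_sites():
    t = _qc_table(100, 0)
    t.data.loc[:9, "detection_p"] = 0.5  # undetected signal -> failing
    rep = sample_qc(t)
    assert rep.samples["fail_frac"].iloc[0] == pytest.approx(0.10)
    assert not rep.samples["passed"].iloc[0]


def _beta_from(arr, prefix="s"):
    return BetaMatrix(
        pd.DataFrame(
            arr,
            index=[f"cg{i}" for i in range(arr.shape[0])],
            columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
        )
    )


def test_batch_effect_detected_when_planted():
    # A batch effect visible to profile-correlation is a batch-specific
    # per-site bias (e.g. a reagent lot shifting particular probes): it
    # raises within-batch correlations. (A constant offset shared by all
    # sites would leave Pearson correlations untouched.)
    rng = np.random.default_rng(2)
    base = rng.random((300, 12)) * 0.5 + 0.25
    batch_bias = rng.normal(0, 0.1, 300)
    base[:, 6:] += batch_bias[:, None]
    beta = _beta_from(np.clip(base, 0, 1))
    labels = pd.Series(["b1"] * 6 + ["b2"] * 6, index=beta.sample_ids)
    res = batch_effect_check(beta, labels)
    assert res["p_value"] < 0.05
    assert res["median_within"] > res["median_all"]


def test_batch_effect_null_calibration():
    rng = np.random.default_rng(4)
    beta = _beta_from(rng.random((200, 12)))
    pvals = []
    for s in range(15):
        perm = np.random.default_rng(s).permutation(12)
        labels = pd.Series(np.array(["b1"] * 6 + ["b2"] * 6)[perm],
                           index=beta.sample_ids)
        pvals.append(batch_effect_check(beta, labels)["p_value"])
    assert 0.2 < np.mean(pvals) < 0.8  # roughly uniform, not skewed


def test_batch_effect_extreme_within_batch_duplicates():
    rng = np.random.default_rng(6)
    cols = []
    for b in range(3):
        profile = rng.random(100)
        cols += [profile, profile + rng.normal(0, 1e-3, 100)]
    beta = _beta_from(np.clip(np.column_stack(cols), 0, 1))
    labels = pd.Series([f"b{i // 2}" for i in range(6)], index=beta.sample_ids)
    res = batch_effect_check(beta, labels)
    assert res["p_value"] < 0.05


def test_batch_effect_single_batch_is_error():
    beta = _beta_from(np.random.default_rng(0).random((50, 4)))
    labels = pd.Series(["b1"] * 4, index=beta.sample_ids)
    with pytest.raises(ValidationError):
        batch_effect_check(beta, labels)


def test_replicate_concordance_extremes_and_missing():
    rng = np.random.default_rng(8)
    x = rng.random(500)
    arr = np.column_stack([x, x, rng.random(500), np.full(500, 0.5)])
    beta = _beta_from(arr)
    res = replicate_concordance(beta, [("s0", "s1"), ("s0", "s2"), ("s0", "s3")])
    assert res["r2"].iloc[0] == pytest.approx(1.0)
    assert res["r2"].iloc[1] < 0.05
    assert np.isnan(res["r"].iloc[2])  # constant profile -> undefined


def test_replicate_concordance_noise_calibration():
    """Technical noise tuned for r2 = 0.99 is recovered within MC error."""
    rng = np.random.default_rng(9)
    n = 5000
    x = rng.uniform(0.2, 0.8, n)
    sd_x = x.std()
    sd_e = sd_x * np.sqrt(1 / 0.995 - 1)  # per-channel share so r2 ~ 0.99
    a = np.clip(x + rng.normal(0, sd_e, n), 0, 1)
    b = np.clip(x + rng.normal(0, sd_e, n), 0, 1)
    beta = _beta_from(np.column_stack([a, b]))
    r2 = replicate_concordance(beta, [("s0", "s1")])["r2"].iloc[0]
    assert r2 == pytest.approx(0.99, abs=0.005)
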