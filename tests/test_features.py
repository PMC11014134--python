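"""Time-domain / time-frequency features and the LDA baseline."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fessemg.features import (lda_fit, lda_predict, rest_epsilon,
                              sweep_epsilon_factor, tdf_features, tff_features)
from fessemg.preprocess import segment
from fessemg.simulate import generate_recording
from tests.conftest import FS, make_window


# -- time-domain features -------------------------------------------------------

def test_tdf_hand_counted_values():
    fv = tdf_features(make_window([1.0, -1.0, 1.0, -1.0]))
    vals = dict(zip(fv.names, fv.values))
    assert vals["MAV"] == 1.0
    assert vals["ZC"] == 3.0


def test_tdf_constant_window_has_no_activity():
    fv = tdf_features(make_window(np.full(100, 2.5)))
    vals = dict(zip(fv.names, fv.values))
    assert vals["WL"] == 0.0 and vals["ZC"] == 0.0 and vals["SSC"] == 0.0


def test_tdf_monotone_ramp_has_no_crossings():
    fv = tdf_features(make_window(np.linspace(-1, 1, 50)))
    vals = dict(zip(fv.names, fv.values))
    assert vals["SSC"] == 0.0
    # the ramp crosses zero once in value but sign-change count uses products
    assert vals["ZC"] == 1.0


def test_wl_printed_form_telescopes_and_conventional_does_not():
    x = np.array([0.0, 3.0, -1.0, 2.0])
    printed = dict(zip(*reversed(
        (tdf_features(make_window(x), wl_form="printed").values,
         tdf_features(make_window(x), wl_form="printed").names))))
    assert printed["WL"] == pytest.approx((x[-1] - x[0]) / len(x))
    conv = tdf_features(make_window(x), wl_form="conventional")
    assert dict(zip(conv.names, conv.values))["WL"] == pytest.approx(3 + 4 + 3)


def test_epsilon_gates_crossings():
    x = np.array([0.1, -0.1] * 10)
    assert dict(zip(*reversed((tdf_features(make_window(x), epsilon=0.5).values,
                               tdf_features(make_window(x), epsilon=0.5).names))
                    ))["ZC"] == 0.0


def test_rest_epsilon_uses_mean_square():
    rest = np.array([2.0, -2.0, 2.0, -2.0])
    assert rest_epsilon(rest, R=1.5) == pytest.approx(1.5 * 4.0)


@given(st.floats(0.1, 100.0))
def test_amplitude_covariance(scale):
    rng = np.random.default_rng(11)
    x = rng.standard_normal(500)
    a = tdf_features(make_window(x))
    b = tdf_features(make_window(scale * x))
    va, vb = dict(zip(a.names, a.values)), dict(zip(b.names, b.values))
    assert vb["MAV"] == pytest.approx(scale * va["MAV"], rel=1e-9)
    assert vb["ZC"] == va["ZC"] and vb["SSC"] == va["SSC"]  # eps=0: scale-free
    ta, tb = tff_features(make_window(x)), tff_features(make_window(scale * x))
    wa, wb = dict(zip(ta.names, ta.values)), dict(zip(tb.names, tb.values))
    assert wb["RMS"] == pytest.approx(scale * wa["RMS"], rel=1e-9)
    assert wb["iEMG"] == pytest.approx(scale * wa["iEMG"], rel=1e-9)
    assert wb["MF"] == pytest.approx(wa["MF"], rel=1e-9)


# -- time-frequency features -----------------------------------------------------

def test_tff_hand_values():
    fv = tff_features(make_window([3.0, -4.0]))
    vals = dict(zip(fv.names, fv.values))
    assert vals["RMS"] == pytest.approx(np.sqrt(12.5))
    assert vals["iEMG"] == pytest.approx(7.0)


def test_tff_tone_median_and_mean_frequency(tone_window):
    fv = tff_features(tone_window)
    vals = dict(zip(fv.names, fv.values))
    bin_hz = FS / 1024  # Welch segment length
    assert abs(vals["MF"] - 100.0) <= bin_hz
    assert abs(vals["MPF"] - 100.0) <= bin_hz


def test_tff_zero_window_flagged_degenerate():
    fv = tff_features(make_window(np.zeros(100)))
    assert fv.degenerate
    vals = dict(zip(fv.names, fv.values))
    assert vals["MF"] == 0.0 and vals["MPF"] == 0.0


def test_fatigue_lowers_median_frequency_feature(quiet_config):
    def mf(fatigue, seed):
        rec = generate_recording(replace(quiet_config, seed=seed),
                                 "ankle_dorsiflexion", fatigue, 0.5)
        win = segment(rec, 0.5, 0.0)[0]
        fv = tff_features(win)
        return dict(zip(fv.names, fv.values))["MF"]

    fresh = [mf("no_fatigue", 700 + s) for s in range(10)]
    tired = [mf("extreme", 700 + s) for s in range(10)]
    assert np.mean(tired) < np.mean(fresh)


# -- LDA ---------------------------------------------------------------------------

def _gaussian_classes(rng, n, d, separation):
    X = np.concatenate([rng.standard_normal((n, d)) - separation,
                        rng.standard_normal((n, d)) + separation])
    y = np.array([0] * n + [1] * n)
    return X, y


def test_lda_separates_distant_gaussians():
    rng = np.random.default_rng(0)
    X, y = _gaussian_classes(rng, 200, 5, 2.5)
    Xt, yt = _gaussian_classes(rng, 200, 5, 2.5)
    model = lda_fit(X, y)
    assert np.mean(lda_predict(model, Xt) == yt) > 0.99


def test_lda_identical_distributions_stay_near_chance():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((600, 4))
    y = np.array([0, 1, 2] * 200)
    model = lda_fit(X[:450], y[:450])
    acc = np.mean(lda_predict(model, X[450:]) == y[450:])
    assert abs(acc - 1 / 3) < 0.12  # ~3 sigma of binomial noise at n=150


def test_lda_refit_is_deterministic():
    rng = np.random.default_rng(2)
    X, y = _gaussian_classes(rng, 100, 3, 1.0)
    a, b = lda_fit(X, y), lda_fit(X, y)
    assert np.array_equal(a.means, b.means)
    assert np.array_equal(a.covariance, b.covariance)


def test_lda_predictions_invariant_under_affine_remap():
    rng = np.random.default_rng(3)
    X, y = _gaussian_classes(rng, 150, 4, 1.0)
    Xt, _ = _gaussian_classes(rng, 80, 4, 1.0)
    A = rng.standard_normal((4, 4)) + 4 * np.eye(4)
    b = rng.standard_normal(4)
    base = lda_predict(lda_fit(X, y), Xt)
    mapped = lda_predict(lda_fit(X @ A + b, y), Xt @ A + b)
    assert np.array_equal(base, mapped)


def test_lda_prior_breaks_equidistant_ties():
    X = np.array([[-1.0]] * 3 + [[1.0]] * 9, dtype=float)
    y = np.array([0] * 3 + [1] * 9)
    model = lda_fit(X, y)
    assert lda_predict(model, np.array([[0.0]]))[0] == 1  # higher prior


def test_lda_exact_class_mean_classified_correctly():
    rng = np.random.default_rng(4)
    X, y = _gaussian_classes(rng, 100, 3, 1.5)
    model = lda_fit(X, y)
    assert lda_predict(model, model.means[0][None, :])[0] == 0


def test_lda_dimension_mismatch_rejected():
    rng = np.random.default_rng(5)
    X, y = _gaussian_classes(rng, 50, 3, 1.0)
    with pytest.raises(ValueError, match="dimension"):
        lda_predict(lda_fit(X, y), np.zeros((2, 5)))


def test_lda_matches_sklearn_on_gaussian_data():
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    rng = np.random.default_rng(6)
    X, y = _gaussian_classes(rng, 300, 6, 0.35)
    Xt, _ = _gaussian_classes(rng, 200, 6, 0.35)
    ours = lda_predict(lda_fit(X, y), Xt)
    ref = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y).predict(Xt)
    assert np.mean(ours == ref) > 0.99


def test_motion_lda_beats_chance_by_3x(quiet_config):
    X, y = [], []
    for seed in range(12):
        from fessemg.simulate import generate_dataset
        for rec in generate_dataset(replace(quiet_config, seed=800 + seed), 3):
            wins = segment(rec, 0.5, 0.0)
            X.append(np.concatenate([
                tdf_features(w, wl_form="conventional").values for w in wins]))
            y.append(rec.motion_label)
    X, y = np.array(X), np.array(y)
    test = np.arange(len(y)) % 4 == 0
    model = lda_fit(X[~test], y[~test])
    acc = np.mean(lda_predict(model, X[test]) == y[test])
    assert acc >= 3 / 6


def test_epsilon_sweep_returns_grid_member(quiet_config):
    rec = generate_recording(quiet_config, "sitting", "no_fatigue", 1.0)
    rest = rec.clean[0]
    wins, labels = [], []
    for seed in range(8):
        for motion in ("sitting", "walking"):
            r = generate_recording(replace(quiet_config, seed=900 + seed),
                                   motion, "no_fatigue", 0.5)
            wins.append(segment(r, 0.5, 0.0)[0])
            labels.append(motion)
    r_best, eps = sweep_epsilon_factor(wins[:10], labels[:10], wins[10:],
                                       labels[10:], rest,
                                       r_grid=np.arange(0.0, 1.01, 0.25))
    assert r_best in {0.0, 0.25, 0.5, 0.75, 1.0}
    assert eps == pytest.approx(r_best * np.mean(rest**2))
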