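"""Hand-crafted sEMG features and the linear discriminant baseline.

Two classic feature sets:

* **Time-domain features (TDFs)** for motion recognition: mean absolute
  value (MAV), waveform length (WL), zero crossings (ZC) and slope-sign
  changes (SSC), the latter two gated by a noise threshold ``epsilon``.

  The WL definition followed here by default is the *published* one,
  ``WL = (1/N) * sum(x[i+1] - x[i])`` - note: no absolute value, so the sum
  telescopes to ``(x[N] - x[1]) / N``. This is almost certainly a typo for
  the conventional ``sum(|x[i+1] - x[i]|)``, which is available via
  ``wl_form='conventional'``; the default preserves the printed definition.

* **Time-frequency features (TFFs)** for fatigue recognition: RMS, integrated
  EMG (iEMG), median frequency (MF) and mean power frequency (MPF) of the
  Welch PSD. MF and MPF fall and RMS/iEMG rise as a muscle fatigues.

The baseline classifier is closed-form linear discriminant analysis (LDA)
with a small ridge on the pooled covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import SignalWindow
from .spectral import mean_power_frequency, median_frequency

TDF_NAMES = ("MAV", "WL", "ZC", "SSC")
TFF_NAMES = ("RMS", "iEMG", "MF", "MPF")


@dataclass
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]
    channel_id: int
    motion_label: str
    fatigue_label: str
    recording_id: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.names):
            raise ValueError("one value per feature name required")


def rest_epsilon(rest_signal: np.ndarray, R: float) -> float:
    """Noise gate ``epsilon = R * mean(x_rest^2)`` from a rest-segment signal.

    ``R`` is conventionally swept over 0..6 in steps of 0.02 and chosen by
    validation accuracy (see :func:`sweep_epsilon_factor`).
    """
    rest_signal = np.asarray(rest_signal, dtype=float)
    return float(R * np.mean(rest_signal**2))


def tdf_features(window: SignalWindow, epsilon: float = 0.0,
                 wl_form: str = "printed") -> FeatureVector:
    """MAV, WL, ZC, SSC of one window (see module docstring for WL forms)."""
    x = window.samples
    if x.size == 0:
        raise ValueError("empty window")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    mav = float(np.mean(np.abs(x)))
    dx = np.diff(x)
    if wl_form == "printed":
        wl = float(np.sum(dx) / x.size)
    elif wl_form == "conventional":
        wl = float(np.sum(np.abs(dx)))
    else:
        raise ValueError(f"wl_form must be 'printed' or 'conventional', got {wl_form!r}")
    zc = int(np.count_nonzero((x[:-1] * x[1:] < 0) & (np.abs(dx) > epsilon)))
    ssc = int(np.count_nonzero((x[1:-1] - x[:-2]) * (x[1:-1] - x[2:]) > epsilon))
    return FeatureVector(
        values=np.array([mav, wl, float(zc), float(ssc)]),
        names=TDF_NAMES,
        channel_id=window.channel_id,
        motion_label=window.motion_label,
        fatigue_label=window.fatigue_label,
        recording_id=window.recording_id,
    )


def tff_features(window: SignalWindow, nperseg: int = 1024,
                 overlap: float = 0.5,
                 band_hz: tuple[float, float] | None = (0.0, 500.0)
                 ) -> FeatureVector:
    """RMS, iEMG, median frequency and mean power frequency of one window.

    MF and MPF are evaluated on the PSD restricted to ``band_hz`` (default the
    0-500 Hz sEMG band): spectral fatigue indicators are conventionally read
    inside the physiological band, and out-of-band content of a cleaned FES
    recording is residual stimulation energy and sensor noise, not muscle.
    """
    x = window.samples
    if x.size == 0:
        raise ValueError("empty window")
    rms = float(np.sqrt(np.mean(x**2)))
    iemg = float(np.sum(np.abs(x)))
    degenerate = not np.any(x)
    if degenerate:
        mf = mpf = 0.0
    else:
        fs = window.sampling_rate_hz
        mf = median_frequency(x, fs, band_hz=band_hz, nperseg=nperseg,
                              overlap=overlap)
        mpf = mean_power_frequency(x, fs, band_hz=band_hz, nperseg=nperseg,
                                   overlap=overlap)
    return FeatureVector(
        values=np.array([rms, iemg, mf, mpf]),
        names=TFF_NAMES,
        channel_id=window.channel_id,
        motion_label=window.motion_label,
        fatigue_label=window.fatigue_label,
        recording_id=window.recording_id,
        degenerate=degenerate,
    )


@dataclass
class LDAModel:
    """Closed-form LDA: class means, ridge-regularized pooled covariance, priors."""

    class_labels: list
    means: np.ndarray          # (k, d)
    covariance: np.ndarray     # (d, d) pooled within-class, after ridge
    priors: np.ndarray         # (k,)
    _coef: np.ndarray = field(init=False, repr=False)       # (k, d)
    _intercept: np.ndarray = field(init=False, repr=False)  # (k,)

    def __post_init__(self) -> None:
        sigma_inv_mu = np.linalg.solve(self.covariance, self.means.T)  # (d, k)
        self._coef = sigma_inv_mu.T
        self._intercept = (-0.5 * np.einsum("kd,dk->k", self.means, sigma_inv_mu)
                           + np.log(self.priors))

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.means.shape[1]:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match model "
                f"dimension {self.means.shape[1]}"
            )
        return X @ self._coef.T + self._intercept


def lda_fit(X: np.ndarray, y, ridge_factor: float = 1e-6) -> LDAModel:
    """Fit LDA by closed-form estimation.

    Pooled within-class covariance is regularized with
    ``ridge_factor * trace(Sigma)/d * I`` to stay invertible at small n.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    labels = sorted(set(y.tolist()))
    if len(labels) < 2:
        raise ValueError("lda_fit requires at least 2 classes")
    k, (n, d) = len(labels), X.shape
    means = np.empty((k, d))
    priors = np.empty(k)
    cov = np.zeros((d, d))
    for i, lab in enumerate(labels):
        Xi = X[y == lab]
        means[i] = Xi.mean(axis=0)
        priors[i] = Xi.shape[0] / n
        centered = Xi - means[i]
        cov += centered.T @ centered
    cov /= max(n - k, 1)
    lam = ridge_factor * np.trace(cov) / d
    if lam <= 0:
        lam = ridge_factor
    cov = cov + lam * np.eye(d)
    eig = np.linalg.eigvalsh(cov)
    if eig[0] <= 0:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular even after ridge regularization; "
            "increase ridge_factor or add more samples per class"
        )
    return LDAModel(class_labels=labels, means=means, covariance=cov,
                    priors=priors)


def lda_predict(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Argmax of the linear discriminant scores; ties break by class order."""
    scores = model.decision_scores(X)
    idx = np.argmax(scores, axis=1)  # np.argmax returns first max: class order
    return np.asarray([model.class_labels[i] for i in idx])


def sweep_epsilon_factor(train_windows, train_labels, val_windows, val_labels,
                         rest_signal: np.ndarray,
                         r_grid: np.ndarray | None = None,
                         wl_form: str = "printed") -> tuple[float, float]:
    """Pick the ZC/SSC threshold factor R by validation accuracy.

    ``r_grid`` defaults to 0..6 in steps of 0.02. Returns ``(R, epsilon)``.
    Windows are per-channel; multi-channel concatenation is the caller's job.
    """
    if r_grid is None:
        r_grid = np.arange(0.0, 6.0 + 1e-9, 0.02)
    base = float(np.mean(np.asarray(rest_signal, dtype=float) ** 2))
    best_r, best_acc = 0.0, -1.0
    train_labels = np.asarray(train_labels)
    val_labels = np.asarray(val_labels)
    for r in r_grid:
        eps = r * base
        Xtr = np.array([tdf_features(w, eps, wl_form).values for w in train_windows])
        Xva = np.array([tdf_features(w, eps, wl_form).values for w in val_windows])
        model = lda_fit(Xtr, train_labels)
        acc = float(np.mean(lda_predict(model, Xva) == val_labels))
        if acc > best_acc:
            best_r, best_acc = float(r), acc
    return best_r, best_r * base
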