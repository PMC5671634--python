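"""Motor-imagery decoding chain.

Causal 5th-order Butterworth band-pass (8-12 Hz) -> 1-s sliding windows in
62.5-ms steps -> common spatial patterns (CSP) log-variance features ->
Fisher LDA -> logistic "action power" in [0, 1] -> strict-threshold
trigger emission (threshold 0.60).

``CSP`` and ``MotorImageryDecoder`` follow the scikit-learn estimator
protocol (``fit``/``transform``/``predict``, fitted attributes with a
trailing underscore) so they compose with sklearn model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .synthetic_data import MOTOR_IMAGERY, REST, EEGSession, TrialSchedule

DEFAULT_THRESHOLD = 0.60


class DecodingError(ValueError):
    pass


@dataclass(frozen=True)
class BandpassSpec:
    order: int = 5
    band: tuple[float, float] = (8.0, 12.0)

    def sos(self, fs: float) -> np.ndarray:
        lo, hi = self.band
        if not 0 < lo < hi < fs / 2:
            raise DecodingError(
                f"band edges must satisfy 0 < {lo} < {hi} < Nyquist ({fs / 2})"
            )
        return signal.butter(self.order, [lo, hi], btype="bandpass", fs=fs, output="sos")


@dataclass(frozen=True)
class WindowSpec:
    length_s: float = 1.0
    step_s: float = 0.0625

    def samples(self, fs: float) -> tuple[int, int]:
        L, S = self.length_s * fs, self.step_s * fs
        if S <= 0 or L < S:
            raise DecodingError("window spec requires 0 < step_s <= length_s")
        if abs(L - round(L)) > 1e-9 or abs(S - round(S)) > 1e-9:
            raise DecodingError("length_s*fs and step_s*fs must be integers")
        return int(round(L)), int(round(S))


def bandpass_filter(session: EEGSession, spec: BandpassSpec = BandpassSpec()) -> EEGSession:
    """Causal (forward-only) IIR filtering per channel, matching online use."""
    sos = spec.sos(session.fs)
    return EEGSession(
        data=signal.sosfilt(sos, session.data, axis=1),
        fs=session.fs,
        schedule=session.schedule,
    )


def slide_windows(
    data: np.ndarray, fs: float, spec: WindowSpec = WindowSpec()
) -> tuple[np.ndarray, np.ndarray]:
    """Segment (channels x samples) into overlapping windows.

    Returns (windows, end_times) with windows shaped
    (n_windows, channels, L); n_windows = floor((N - L) / S) + 1, or zero
    windows when the record is shorter than one window.
    """
    L, S = spec.samples(fs)
    n = data.shape[1]
    if n < L:
        return np.empty((0, data.shape[0], L)), np.empty(0)
    count = (n - L) // S + 1
    starts = np.arange(count) * S
    windows = np.stack([data[:, s : s + L] for s in starts])
    end_times = (starts + L) / fs
    return windows, end_times


# ---------------------------------------------------------------------------
# CSP


def _class_covariance(epochs: np.ndarray, ridge: float | None) -> np.ndarray:
    """Average of per-epoch trace-normalised covariances."""
    covs = []
    for e in epochs:
        c = e @ e.T
        tr = np.trace(c)
        if tr <= 0:
            raise DecodingError("zero-variance epoch in CSP fit")
        covs.append(c / tr)
    c = np.mean(covs, axis=0)
    n = c.shape[0]
    eps = (1e-6 * np.trace(c) / n) if ridge is None else ridge
    return c + eps * np.eye(n)


class CSP(TransformerMixin, BaseEstimator):
    """Two-class common spatial patterns with log-variance features.

    Solves the generalized eigenproblem ``C_mi w = lambda (C_rest + C_mi) w``
    on trace-normalised average class covariances and keeps ``n_pairs``
    filters from each spectral extreme.  ``transform`` maps a window to the
    normalised log-variances of the 2*n_pairs projected signals, which are
    invariant to a global scaling of the window.

    Attributes (after ``fit``): ``filters_`` ((2*n_pairs) x channels),
    ``eigenvalues_`` (per-filter motor-imagery variance ratios, descending-
    extremity order), ``class_order_``.
    """

    def __init__(self, n_pairs: int = 3, ridge: float | None = None):
        self.n_pairs = n_pairs
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise DecodingError(f"CSP needs exactly two classes, got {classes}")
        # canonical ordering: rest first when present
        if REST in classes:
            classes = np.array([REST, MOTOR_IMAGERY], dtype=object)
        ep_a, ep_b = X[y == classes[0]], X[y == classes[1]]
        if len(ep_a) < 2 or len(ep_b) < 2:
            raise DecodingError("CSP needs >= 2 epochs per class")
        c_a = _class_covariance(ep_a, self.ridge)
        c_b = _class_covariance(ep_b, self.ridge)
        pooled = c_a + c_b
        try:
            evals, evecs = linalg.eigh(c_b, pooled)
        except linalg.LinAlgError as exc:  # pragma: no cover
            raise DecodingError(
                "rank-deficient pooled covariance; increase the ridge term"
            ) from exc
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        k = self.n_pairs
        if 2 * k > len(evals):
            raise DecodingError(f"n_pairs={k} too large for {len(evals)} channels")
        keep = np.r_[np.arange(k), np.arange(len(evals) - k, len(evals))]
        self.filters_ = evecs[:, keep].T
        self.eigenvalues_ = evals[keep]
        self.class_order_ = tuple(classes)
        self.pooled_covariance_ = pooled
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        if single:
            X = X[None]
        if X.shape[1] != self.filters_.shape[1]:
            raise DecodingError(
                f"window has {X.shape[1]} channels, CSP expects {self.filters_.shape[1]}"
            )
        proj = np.einsum("fc,wct->wft", self.filters_, X)
        var = proj.var(axis=2, ddof=0)
        if np.any(var.sum(axis=1) <= 0) or np.any(var <= 0):
            raise DecodingError("zero-variance window in feature extraction")
        feats = np.log(var / var.sum(axis=1, keepdims=True))
        return feats[0] if single else feats


def fit_csp(epochs_rest, epochs_mi, n_pairs: int = 3) -> CSP:
    """Functional facade: fit CSP from per-class epoch arrays."""
    X = np.concatenate([np.asarray(epochs_rest), np.asarray(epochs_mi)])
    y = np.array([REST] * len(epochs_rest) + [MOTOR_IMAGERY] * len(epochs_mi), dtype=object)
    return CSP(n_pairs=n_pairs).fit(X, y)


def extract_features(window: np.ndarray, csp: CSP) -> np.ndarray:
    return csp.transform(window)


# ---------------------------------------------------------------------------
# LDA + action power


@dataclass
class LDAModel:
    """Fisher discriminant with pooled covariance; score = w.x + b,
    positive toward motor imagery."""

    weights: np.ndarray
    bias: float
    class_order: tuple[str, str] = (REST, MOTOR_IMAGERY)

    def score(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(features) @ self.weights + self.bias


def fit_lda(features, labels) -> LDAModel:
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise DecodingError("LDA needs both classes present")
    y = (labels == MOTOR_IMAGERY).astype(int)
    clf = LinearDiscriminantAnalysis(solver="lsqr")
    try:
        clf.fit(features, y)
    except linalg.LinAlgError as exc:  # pragma: no cover
        raise DecodingError("singular pooled covariance; enable shrinkage") from exc
    if not np.all(np.isfinite(clf.coef_)):
        raise DecodingError("singular pooled covariance; enable shrinkage")
    return LDAModel(weights=clf.coef_.ravel().copy(), bias=float(clf.intercept_[0]))


def score(features, model: LDAModel):
    return model.score(features)


@dataclass(frozen=True)
class ActionPowerCalibration:
    """Scale of the logistic squashing of LDA scores; fitted as the pooled
    standard deviation of training scores."""

    scale: float = 1.0

    @classmethod
    def fit(cls, training_scores) -> "ActionPowerCalibration":
        s = float(np.std(np.asarray(training_scores, dtype=float)))
        return cls(scale=s if s > 0 else 1.0)


def action_power(score, calibration: ActionPowerCalibration) -> np.ndarray | float:
    """Monotone logistic map of the LDA score into [0, 1]; 0.5 at the
    decision boundary."""
    z = np.asarray(score, dtype=float) / calibration.scale
    out = 0.5 * (1.0 + np.tanh(z / 2.0))  # numerically stable logistic
    return float(out) if np.isscalar(score) else out


# ---------------------------------------------------------------------------
# Full decoder


@dataclass(frozen=True)
class DecoderOutput:
    t_s: float
    state: str
    action_power: float


@dataclass(frozen=True)
class TriggerEvent:
    t_s: float


def _labeled_task_epochs(session: EEGSession) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial 4-s epochs with their labels; inter-trial data discarded."""
    epochs, labels = [], []
    for lab, sl in session.schedule.trial_sample_slices(session.fs):
        seg = session.data[:, sl]
        if seg.shape[1] == sl.stop - sl.start:
            epochs.append(seg)
            labels.append(lab)
    return np.stack(epochs), np.array(labels, dtype=object)


class MotorImageryDecoder(ClassifierMixin, BaseEstimator):
    """The full band-pass/CSP/LDA decoder as a sklearn-style classifier.

    ``fit`` consumes an ``EEGSession`` (cued training session); ``predict``
    and ``decode`` consume either an ``EEGSession`` stream or raw
    (channels x samples) data.  Windows fully inside a cued 4-s block
    inherit its label during training; inter-trial windows are discarded.
    """

    def __init__(
        self,
        bandpass: BandpassSpec = BandpassSpec(),
        windows: WindowSpec = WindowSpec(),
        n_pairs: int = 3,
        threshold: float = DEFAULT_THRESHOLD,
    ):
        self.bandpass = bandpass
        self.windows = windows
        self.n_pairs = n_pairs
        self.threshold = threshold

    # -- training --------------------------------------------------------
    def fit(self, session: EEGSession, y=None):
        filtered = bandpass_filter(session, self.bandpass)
        epochs, labels = _labeled_task_epochs(filtered)
        self.csp_ = CSP(n_pairs=self.n_pairs).fit(epochs, labels)
        feats, wlabels = [], []
        for ep, lab in zip(epochs, labels):
            w, _ = slide_windows(ep, session.fs, self.windows)
            if len(w):
                feats.append(self.csp_.transform(w))
                wlabels.extend([lab] * len(w))
        X = np.concatenate(feats)
        ylab = np.array(wlabels, dtype=object)
        self.lda_ = fit_lda(X, ylab)
        self.calibration_ = ActionPowerCalibration.fit(self.lda_.score(X))
        self.classes_ = np.array([REST, MOTOR_IMAGERY], dtype=object)
        return self

    # -- inference -------------------------------------------------------
    def _window_powers(self, session: EEGSession) -> tuple[np.ndarray, np.ndarray]:
        filtered = bandpass_filter(session, self.bandpass)
        w, t = slide_windows(filtered.data, session.fs, self.windows)
        if len(w) == 0:
            return np.empty(0), np.empty(0)
        if w.shape[1] != self.csp_.filters_.shape[1]:
            raise DecodingError("stream channel count does not match the fitted model")
        p = action_power(self.lda_.score(self.csp_.transform(w)), self.calibration_)
        return np.asarray(p), t

    def predict(self, session: EEGSession) -> np.ndarray:
        p, _ = self._window_powers(session)
        return np.where(p > self.threshold, MOTOR_IMAGERY, REST)

    def decode(self, session: EEGSession) -> tuple[list[DecoderOutput], list[TriggerEvent]]:
        p, t = self._window_powers(session)
        outputs, triggers = [], []
        for ti, pi in zip(t, p):
            mi = pi > self.threshold  # strict: "above 0.60"
            outputs.append(DecoderOutput(t_s=float(ti), state=MOTOR_IMAGERY if mi else REST,
                                         action_power=float(pi)))
            if mi:
                triggers.append(TriggerEvent(t_s=float(ti)))
        return outputs, triggers

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "bandpass": {"order": self.bandpass.order, "band": list(self.bandpass.band)},
            "windows": {"length_s": self.windows.length_s, "step_s": self.windows.step_s},
            "threshold": self.threshold,
            "csp": {
                "filters": self.filters_list(),
                "eigenvalues": self.csp_.eigenvalues_.tolist(),
                "n_pairs": self.csp_.n_pairs,
            },
            "lda": {"weights": self.lda_.weights.tolist(), "bias": self.lda_.bias},
            "action_power_scale": self.calibration_.scale,
        }

    def filters_list(self):
        return self.csp_.filters_.tolist()

    @classmethod
    def from_dict(cls, d: dict) -> "MotorImageryDecoder":
        self = cls(
            bandpass=BandpassSpec(order=d["bandpass"]["order"], band=tuple(d["bandpass"]["band"])),
            windows=WindowSpec(**d["windows"]),
            n_pairs=d["csp"]["n_pairs"],
            threshold=d["threshold"],
        )
        self.csp_ = CSP(n_pairs=d["csp"]["n_pairs"])
        self.csp_.filters_ = np.asarray(d["csp"]["filters"])
        self.csp_.eigenvalues_ = np.asarray(d["csp"]["eigenvalues"])
        self.csp_.class_order_ = (REST, MOTOR_IMAGERY)
        self.lda_ = LDAModel(weights=np.asarray(d["lda"]["weights"]), bias=d["lda"]["bias"])
        self.calibration_ = ActionPowerCalibration(scale=d["action_power_scale"])
        self.classes_ = np.array([REST, MOTOR_IMAGERY], dtype=object)
        return self


def decode_stream(
    session: EEGSession,
    decoder: MotorImageryDecoder,
) -> tuple[list[DecoderOutput], list[TriggerEvent]]:
    """Decode a continuous stream at the 62.5-ms window cadence."""
    return decoder.decode(session)


@dataclass(frozen=True)
class CVResult:
    accuracy_total: float
    accuracy_rest: float
    accuracy_mi: float
    fold_accuracies: tuple[float, ...]


def crossvalidate(
    session: EEGSession,
    k: int = 5,
    seed: int | None = None,
    decoder_params: dict | None = None,
) -> CVResult:
    """Trial-stratified k-fold cross-validation of the full chain.

    All sliding windows of a trial stay in one fold; CSP and LDA are refit
    inside each training fold only.  Accuracies are window-level.
    """
    if k < 2:
        raise DecodingError("k must be >= 2")
    params = decoder_params or {}
    proto = MotorImageryDecoder(**params)
    filtered = bandpass_filter(session, proto.bandpass)
    epochs, labels = _labeled_task_epochs(filtered)
    rng = np.random.default_rng(seed)

    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (REST, MOTOR_IMAGERY):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise DecodingError(f"k={k} exceeds per-class trial count {len(idx)}")
        rng.shuffle(idx)
        for i, trial in enumerate(idx):
            folds[i % k].append(int(trial))

    correct = {REST: 0, MOTOR_IMAGERY: 0}
    total = {REST: 0, MOTOR_IMAGERY: 0}
    fold_accs = []
    for fold in folds:
        train = np.setdiff1d(np.arange(len(labels)), fold)
        csp = CSP(n_pairs=proto.n_pairs).fit(epochs[train], labels[train])
        feats, wl = [], []
        for i in train:
            w, _ = slide_windows(epochs[i], session.fs, proto.windows)
            feats.append(csp.transform(w))
            wl.extend([labels[i]] * len(w))
        lda = fit_lda(np.concatenate(feats), np.array(wl, dtype=object))
        calib = ActionPowerCalibration.fit(lda.score(np.concatenate(feats)))
        fc = ft = 0
        for i in fold:
            w, _ = slide_windows(epochs[i], session.fs, proto.windows)
            p = action_power(lda.score(csp.transform(w)), calib)
            pred = np.where(np.asarray(p) > 0.5, MOTOR_IMAGERY, REST)
            c = int(np.sum(pred == labels[i]))
            correct[labels[i]] += c
            total[labels[i]] += len(w)
            fc += c
            ft += len(w)
        fold_accs.append(fc / ft)

    n_all = total[REST] + total[MOTOR_IMAGERY]
    return CVResult(
        accuracy_total=(correct[REST] + correct[MOTOR_IMAGERY]) / n_all,
        accuracy_rest=correct[REST] / total[REST],
        accuracy_mi=correct[MOTOR_IMAGERY] / total[MOTOR_IMAGERY],
        fold_accuracies=tuple(fold_accs),
    )
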