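"""Frame-level classifiers.

Two trained models mirror the measurement chain: Model 1 scores every frame
for live speech vs non-speech (device-generated TV/radio speech is a
non-speech negative it must learn to reject); Model 2 scores frames already
called speech for wearer vs other speaker.  Both are compact multilayer
perceptrons over log-spectrogram frame features — small enough to train per
cross-validation fold on one CPU in seconds.

A heuristic, training-free baseline voice-activity detector and a
truth-pass-through oracle classifier are provided for comparison and for
downstream pipeline tests.

Blinding contract: trainers consume only (frames, labels); participant group
membership is not part of the training interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .core import OTHER_SPEECH, WEARER_SPEECH, FrameTruth, is_live_speech
from .features import frame_features, log_spectrum
from .preprocess import FrameSet


@dataclass
class ModelSpec:
    """Architecture and training hyperparameters for a frame classifier."""

    feature_mode: str = "band_energy"
    context: int = 3
    hidden_layer_sizes: tuple = (64, 32)
    max_iter: int = 150
    learning_rate_init: float = 1e-3
    batch_size: int = 256
    max_train_frames: int = 20000  # balanced subsample cap per fit
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "feature_mode": self.feature_mode,
            "context": self.context,
            "hidden_layer_sizes": list(self.hidden_layer_sizes),
            "max_iter": self.max_iter,
            "learning_rate_init": self.learning_rate_init,
            "batch_size": self.batch_size,
            "max_train_frames": self.max_train_frames,
            "seed": self.seed,
        }


def default_spec(task: str = "speech") -> ModelSpec:
    """Packaged defaults per task.

    The speech/non-speech model reads the compact band/level feature set (it
    must tell live speech from the loudspeaker channel across unseen voices);
    the wearer/other model reads the level-contour proximity cues alone.
    Both generalize across speakers where raw spectra invite a
    speaker-identity shortcut under session-held-out validation.
    """
    if task == "speech":
        return ModelSpec()
    if task == "wearer":
        return ModelSpec(
            feature_mode="level_contour",
            hidden_layer_sizes=(32, 16),
            max_iter=60,
            max_train_frames=12000,
        )
    raise ValueError("task must be 'speech' or 'wearer'")


@dataclass
class AnnotatedFrames:
    """One preprocessed session: standardized frames with aligned truth."""

    session_id: str
    frameset: FrameSet
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.size != len(self.frameset):
            raise ValueError("labels must align one-to-one with frames")


class FrameClassifier:
    """Scaler + MLP over frame features; emits per-frame probabilities."""

    #: task name, set by subclass/trainer ("speech" or "wearer")
    task: str = "speech"

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.scaler = StandardScaler()
        self.net = MLPClassifier(
            hidden_layer_sizes=tuple(spec.hidden_layer_sizes),
            max_iter=spec.max_iter,
            learning_rate_init=spec.learning_rate_init,
            batch_size=spec.batch_size,
            random_state=spec.seed,
            early_stopping=False,
        )
        self.training_curve_: np.ndarray | None = None

    # -- features ---------------------------------------------------------
    def extract(self, frameset: FrameSet) -> np.ndarray:
        return frame_features(frameset, mode=self.spec.feature_mode, context=self.spec.context)

    # -- training ---------------------------------------------------------
    def fit_arrays(self, X: np.ndarray, y: np.ndarray) -> "FrameClassifier":
        y = np.asarray(y, dtype=bool)
        if y.all() or not y.any():
            raise ValueError("training corpus contains a single class")
        X, y = _balanced_subsample(X, y, self.spec.max_train_frames, self.spec.seed)
        Xs = self.scaler.fit_transform(X)
        self.net.fit(Xs, y.astype(int))
        self.training_curve_ = np.asarray(self.net.loss_curve_)
        return self

    # -- prediction -------------------------------------------------------
    def predict_proba_X(self, X: np.ndarray) -> np.ndarray:
        if X.shape[0] == 0:
            return np.empty(0)
        if X.shape[1] != self.scaler.n_features_in_:
            raise ValueError(
                f"feature length {X.shape[1]} does not match training ({self.scaler.n_features_in_})"
            )
        p = self.net.predict_proba(self.scaler.transform(X))[:, 1]
        return np.clip(p, 0.0, 1.0)

    def predict_proba_frames(self, frameset: FrameSet) -> np.ndarray:
        return self.predict_proba_X(self.extract(frameset))


def _balanced_subsample(X, y, cap, seed):
    """Cap training size with equal draws per class (speech is rare)."""
    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(y)
    idx_neg = np.flatnonzero(~y)
    per_class = min(cap // 2, idx_pos.size, idx_neg.size)
    pick = np.concatenate(
        [
            rng.choice(idx_pos, size=per_class, replace=False),
            rng.choice(idx_neg, size=per_class, replace=False),
        ]
    )
    pick.sort()
    return X[pick], y[pick]


# ---------------------------------------------------------------------------
# Trainers


def train_speech_detector(sessions, spec: ModelSpec | None = None, seed: int = 0) -> FrameClassifier:
    """Model 1: live speech (wearer or other) vs everything else.

    Device-generated speech is in the negative class by construction, so the
    model learns to reject the loudspeaker channel.
    """
    spec = _with_seed(spec, seed)
    model = FrameClassifier(spec)
    model.task = "speech"
    X, y = _stack(sessions, model, label_fn=lambda lab: is_live_speech(lab), mask_fn=None)
    return model.fit_arrays(X, y)


def train_wearer_classifier(sessions, spec: ModelSpec | None = None, seed: int = 0) -> FrameClassifier:
    """Model 2: wearer vs other speaker, trained on live-speech frames only."""
    spec = _with_seed(spec or default_spec("wearer"), seed)
    model = FrameClassifier(spec)
    model.task = "wearer"
    X, y = _stack(
        sessions,
        model,
        label_fn=lambda lab: lab == WEARER_SPEECH,
        mask_fn=lambda lab: is_live_speech(lab),
    )
    return model.fit_arrays(X, y)


def _with_seed(spec, seed):
    spec = spec or ModelSpec()
    if seed is not None:
        spec = ModelSpec(**{**spec.to_dict(), "seed": int(seed)})
    spec.hidden_layer_sizes = tuple(spec.hidden_layer_sizes)
    return spec


def _stack(sessions, model, label_fn, mask_fn):
    Xs, ys = [], []
    for s in sessions:
        labels = np.asarray(s.labels)
        X = model.extract(s.frameset)
        if mask_fn is not None:
            keep = mask_fn(labels)
            X, labels = X[keep], labels[keep]
        Xs.append(X)
        ys.append(label_fn(labels))
    return np.concatenate(Xs), np.concatenate(ys)


def predict_speech_prob(model: FrameClassifier, frameset: FrameSet) -> np.ndarray:
    """Per-frame probability of live speech, aligned to the FrameSet."""
    return model.predict_proba_frames(frameset)


def predict_wearer_prob(model: FrameClassifier, frameset: FrameSet, speech_frame_idx) -> np.ndarray:
    """Wearer probability for the frames already called speech.

    ``speech_frame_idx`` must index frames flagged as speech (Model-1 frame
    probability above 0.5 inside speech minutes); passing the full frame range
    of a recording that was not speech-screened is a contract violation.
    """
    idx = np.asarray(speech_frame_idx, dtype=int)
    if idx.size == 0:
        return np.empty(0)
    if idx.min() < 0 or idx.max() >= len(frameset):
        raise ValueError("speech frame indices outside the FrameSet")
    # Features are extracted over the full recording so context windows and
    # the energy floor see the same neighbourhood as in training, then the
    # speech-called rows are selected.
    return model.predict_proba_X(model.extract(frameset)[idx])


# ---------------------------------------------------------------------------
# Baseline VAD and oracle


def baseline_vad(frameset: FrameSet) -> np.ndarray:
    """Training-free voice-activity score from frame energy and flatness.

    Operates on *unnormalized* frames (per-frame standardization erases the
    energy cue this heuristic relies on).  Energy is referenced to the quiet
    floor of the recording (10th percentile of log-energy), squashed through a
    logistic, and discounted by spectral flatness so that tonal/harmonic
    frames score higher than equally loud noise.  No notion of device speech:
    a loud television scores high, which is exactly the failure mode the
    trained detector improves on.
    """
    f = frameset.frames
    if f.shape[0] == 0:
        return np.empty(0)
    if frameset.normalized:
        raise ValueError("baseline_vad expects unnormalized frames")
    log_e = np.log10(np.mean(f**2, axis=1) + 1e-12)
    floor = np.quantile(log_e, 0.10)
    p_energy = 1.0 / (1.0 + np.exp(-4.0 * (log_e - floor - 1.0)))
    spec = np.exp(2.0 * log_spectrum(f))  # power spectrum
    flatness = np.exp(np.mean(np.log(spec + 1e-20), axis=1)) / (np.mean(spec, axis=1) + 1e-20)
    return np.clip(p_energy * (1.0 - flatness) ** 0.25, 0.0, 1.0)


class OracleClassifier:
    """Pass-through classifier emitting ground truth as {0, 1} probabilities.

    Used to test everything downstream of the models in isolation: with the
    oracle plugged in, the aggregation pipeline must reproduce the
    generator's truth profiles exactly.
    """

    def __init__(self, task: str = "speech"):
        if task not in ("speech", "wearer"):
            raise ValueError("task must be 'speech' or 'wearer'")
        self.task = task

    def probs_from_truth(self, truth: FrameTruth | np.ndarray) -> np.ndarray:
        labels = truth.labels if isinstance(truth, FrameTruth) else np.asarray(truth)
        if self.task == "speech":
            return is_live_speech(labels).astype(float)
        return (labels == WEARER_SPEECH).astype(float)
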