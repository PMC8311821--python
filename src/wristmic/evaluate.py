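"""Leave-one-session-out cross-validation and confusion-matrix metrics.

Each recording session is held out once; a model is trained on all the
others and scored on the held-out session at the frame level.  Confusion
counts are pooled across folds (micro-average), which is how a single
accuracy/sensitivity/specificity triple is reported for an unbalanced
corpus; per-fold metrics are kept alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .classify import FrameClassifier, ModelSpec, default_spec, is_live_speech
from .core import WEARER_SPEECH


def loso_split(session_ids):
    """One fold per session: (train_ids, validation_id)."""
    ids = list(session_ids)
    if len(ids) < 2:
        raise ValueError("leave-one-session-out needs at least 2 sessions")
    return [([s for s in ids if s != held], held) for held in ids]


def confusion_metrics(y_true, probs, threshold: float = 0.5) -> dict:
    """Frame-level confusion counts and rates (%); positive call is p > threshold."""
    y_true = np.asarray(y_true, dtype=bool)
    probs = np.asarray(probs, dtype=float)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.size != probs.size:
        raise ValueError("truth and probabilities must align")
    pred = probs > threshold
    tp = int(np.sum(pred & y_true))
    fp = int(np.sum(pred & ~y_true))
    tn = int(np.sum(~pred & ~y_true))
    fn = int(np.sum(~pred & y_true))
    return _rates({"tp": tp, "fp": fp, "tn": tn, "fn": fn})


def _rates(counts: dict) -> dict:
    tp, fp, tn, fn = counts["tp"], counts["fp"], counts["tn"], counts["fn"]
    total = tp + fp + tn + fn
    out = dict(counts)
    out["accuracy"] = 100.0 * (tp + tn) / total if total else float("nan")
    out["sensitivity"] = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    out["specificity"] = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    prec = tp / (tp + fp) if tp + fp else float("nan")
    rec = tp / (tp + fn) if tp + fn else float("nan")
    out["f1"] = 100.0 * 2 * prec * rec / (prec + rec) if (tp and prec + rec) else 0.0
    return out


@dataclass
class EvalReport:
    task: str
    threshold: float
    folds: list = field(default_factory=list)  # per-fold dicts with session_id
    pooled: dict = field(default_factory=dict)
    fold_seeds: dict = field(default_factory=dict)
    incomplete: bool = False

    @property
    def accuracy(self) -> float:
        return self.pooled["accuracy"]

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "task": self.task,
                "threshold": self.threshold,
                "pooled": self.pooled,
                "folds": self.folds,
                "fold_seeds": self.fold_seeds,
                "incomplete": self.incomplete,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _task_arrays(task: str):
    if task == "speech":
        return (lambda lab: is_live_speech(lab)), (lambda lab: np.ones(lab.size, dtype=bool))
    if task == "wearer":
        return (lambda lab: lab == WEARER_SPEECH), (lambda lab: is_live_speech(lab))
    raise ValueError("task must be 'speech' or 'wearer'")


def evaluate_loso(
    sessions,
    task: str = "speech",
    spec: ModelSpec | None = None,
    seed: int = 0,
    threshold: float = 0.5,
    probs_fn=None,
) -> EvalReport:
    """LOSO evaluation of a frame classifier on an annotated corpus.

    ``sessions`` are :class:`~wristmic.classify.AnnotatedFrames`.  For the
    wearer task, training and evaluation are both restricted to live-speech
    truth frames.  ``probs_fn(session) -> per-frame probs for the whole
    session`` swaps in an untrained scorer (oracle, baseline VAD) under the
    same protocol; the task mask is applied to its output.

    Per-fold training seeds are derived from ``seed``; the report is
    deterministic given corpus + spec + seed.
    """
    spec = spec or default_spec(task)
    label_fn, mask_fn = _task_arrays(task)
    by_id = {s.session_id: s for s in sessions}
    folds = loso_split([s.session_id for s in sessions])

    template = FrameClassifier(spec)
    cache = {}
    for s in sessions:
        labels = np.asarray(s.labels)
        keep = mask_fn(labels)
        X = template.extract(s.frameset)[keep] if probs_fn is None else None
        cache[s.session_id] = (X, label_fn(labels[keep]), keep)

    fold_seeds = {
        held: int(ss.generate_state(1)[0] % (2**31))
        for (_, held), ss in zip(folds, np.random.SeedSequence(seed).spawn(len(folds)))
    }

    report = EvalReport(task=task, threshold=threshold, fold_seeds=fold_seeds)
    pooled = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
    for train_ids, held in folds:
        _, y_val, keep = cache[held]
        if probs_fn is not None:
            probs = np.asarray(probs_fn(by_id[held]))[keep] if keep.size else np.empty(0)
        else:
            Xtr = np.concatenate([cache[i][0] for i in train_ids])
            ytr = np.concatenate([cache[i][1] for i in train_ids])
            model = FrameClassifier(ModelSpec(**{**spec.to_dict(), "seed": fold_seeds[held]}))
            try:
                model.fit_arrays(Xtr, ytr)
            except ValueError:
                report.incomplete = True
                report.folds.append({"session_id": held, "failed": True})
                continue
            probs = model.predict_proba_X(cache[held][0])
        m = confusion_metrics(y_val, probs, threshold)
        m["session_id"] = held
        report.folds.append(m)
        for k in pooled:
            pooled[k] += m[k]
    report.pooled = _rates(pooled)
    return report
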