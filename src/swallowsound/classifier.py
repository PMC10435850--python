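"""AdaBoost-derived linear frame discriminator for fine-crackle frames.

The deployed discriminator is strictly linear: a frame with normalised
feature vector x (each component in [-1, 1]) receives the score

    y = sum_i a_i * x_i           (i = 1..148)

and is called a crackle frame when y exceeds a learned threshold.  The
coefficients a are obtained by boosting: depth-1 decision stumps on single
normalised features are combined by discrete AdaBoost (initial example
weights balanced per class, since crackle frames are rare), and the boosted
additive score H(x) is then projected onto the linear form by least squares
over the training frames.  The boosted ensemble is kept in the model's
training metadata for diagnostics; deployment uses only ``a`` and the
threshold.

The decision threshold maximises balanced accuracy on the training frames,
with candidate thresholds at midpoints between adjacent distinct scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .audio import AudioRecording, section_of
from .features import (
    FeatureExtractor,
    FeatureLayout,
    FeatureMatrix,
    FeatureNormalizer,
    FrameGrid,
    apply_normalizer,
    fit_normalizer,
)

DEFAULT_ROUNDS = 100


class TrainingError(ValueError):
    """Raised for degenerate teacher sets or model misuse."""


@dataclass(frozen=True)
class TeacherClip:
    """A labelled training clip.

    ``labels`` holds per-frame binary labels (1 = target sound present)
    matching the clip's frame grid; clip-level labels are broadcast to all
    frames at teacher-set assembly time.
    """

    recording: AudioRecording
    labels: np.ndarray
    clip_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=np.int8))


@dataclass(frozen=True)
class TeacherSet:
    clips: tuple[TeacherClip, ...]
    extractor: FeatureExtractor = field(default_factory=FeatureExtractor)

    def frame_data(self) -> tuple[np.ndarray, np.ndarray]:
        """Stacked raw feature matrix and frame labels over all clips."""
        mats, labels = [], []
        for clip in self.clips:
            grid, raw = self.extractor.extract_raw(section_of(clip.recording))
            if clip.labels.shape[0] != grid.n_frames:
                raise TrainingError(
                    f"clip {clip.clip_id!r}: {clip.labels.shape[0]} labels for "
                    f"{grid.n_frames} frames"
                )
            mats.append(raw)
            labels.append(clip.labels)
        return np.vstack(mats), np.concatenate(labels)


@dataclass(frozen=True)
class Stump:
    """Depth-1 weak learner: predict +1 iff polarity*(x[feature] - threshold) > 0."""

    feature: int
    threshold: float
    polarity: int
    alpha: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.where(self.polarity * (x[:, self.feature] - self.threshold) > 0, 1.0, -1.0)


@dataclass(frozen=True)
class CrackleModel:
    """Linear coefficients, decision threshold and the preprocessing state."""

    a: np.ndarray
    threshold: float
    normalizer: FeatureNormalizer
    layout: FeatureLayout
    training_meta: dict

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=np.float64)
        if a.shape != (self.layout.n,):
            raise TrainingError(f"coefficient vector shape {a.shape} != ({self.layout.n},)")
        if not np.all(np.isfinite(a)):
            raise TrainingError("non-finite coefficients")
        object.__setattr__(self, "a", a)

    def to_json(self) -> str:
        doc = {
            "layout": list(self.layout.names),
            "normalizer": self.normalizer.to_dict(),
            "a": self.a.tolist(),
            "threshold": self.threshold,
            "training_meta": self.training_meta,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CrackleModel":
        doc = json.loads(text)
        layout = FeatureLayout(names=tuple(doc["layout"]))
        return cls(
            a=np.asarray(doc["a"], dtype=np.float64),
            threshold=float(doc["threshold"]),
            normalizer=FeatureNormalizer.from_dict(doc["normalizer"]),
            layout=layout,
            training_meta=doc["training_meta"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "CrackleModel":
        return cls.from_json(Path(path).read_text())


@dataclass(frozen=True)
class FrameDecisions:
    """Per-frame linear scores and the thresholded presence track."""

    grid: FrameGrid
    y: np.ndarray
    present: np.ndarray
    threshold: float


# ---------------------------------------------------------------------------
# boosting internals


def _boost(
    x: np.ndarray, sign_labels: np.ndarray, rounds: int
) -> tuple[list[Stump], np.ndarray]:
    """Discrete AdaBoost with single-feature stumps.

    Returns the stumps and the boosted margin H(x) on the training set.
    Initial weights are balanced per class.  The stump search is exhaustive
    over all features and all midpoint thresholds, so training is fully
    deterministic and independent of example order.
    """
    n, d = x.shape
    pos = sign_labels > 0
    w = np.where(pos, 0.5 / max(pos.sum(), 1), 0.5 / max((~pos).sum(), 1)).astype(np.float64)

    order = np.argsort(x, axis=0, kind="stable")  # per-feature sort, reused each round
    x_sorted = np.take_along_axis(x, order, axis=0)
    y_sorted = sign_labels[order]  # (n, d)
    distinct = np.diff(x_sorted, axis=0) > 0  # valid split positions

    stumps: list[Stump] = []
    margin = np.zeros(n)
    for _ in range(rounds):
        w_sorted = w[order]
        signed = w_sorted * y_sorted
        cum = np.cumsum(signed, axis=0)  # cum[k, j] = sum over x<=x_sorted[k]
        total_pos = w[pos].sum()
        # stump "predict +1 if x > t": err(t) = w(pos, x<=t) + w(neg, x>t)
        #   = total_neg - (cum_neg_upto) ... expressed via cum of signed weights:
        # w(pos,<=t) = (cumW + cum)/2 with cumW = cumulative total weight
        cumW = np.cumsum(w_sorted, axis=0)
        w_pos_le = (cumW + cum) / 2.0
        w_neg_le = (cumW - cum) / 2.0
        total_neg = 1.0 - total_pos
        err_gt = w_pos_le[:-1] + (total_neg - w_neg_le[:-1])  # polarity +1
        err_le = 1.0 - err_gt  # polarity -1
        err_gt = np.where(distinct, err_gt, np.inf)
        err_le = np.where(distinct, err_le, np.inf)

        best_gt = np.unravel_index(np.argmin(err_gt), err_gt.shape)
        best_le = np.unravel_index(np.argmin(err_le), err_le.shape)
        if err_gt[best_gt] <= err_le[best_le]:
            k, j, polarity, err = best_gt[0], best_gt[1], 1, err_gt[best_gt]
        else:
            k, j, polarity, err = best_le[0], best_le[1], -1, err_le[best_le]
        if not np.isfinite(err):  # every feature constant
            break
        thr = 0.5 * (x_sorted[k, j] + x_sorted[k + 1, j])
        err = float(np.clip(err, 1e-12, 1.0 - 1e-12))
        if err >= 0.5:
            break
        alpha = 0.5 * np.log((1.0 - err) / err)
        stump = Stump(feature=int(j), threshold=float(thr), polarity=polarity, alpha=float(alpha))
        h = stump.predict(x)
        margin += alpha * h
        w *= np.exp(-alpha * sign_labels * h)
        w /= w.sum()
        stumps.append(stump)
        if err < 1e-10:
            break
    return stumps, margin


def choose_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, bool]:
    """Threshold on y maximising balanced accuracy of the rule ``y > t``.

    Candidates are midpoints between adjacent distinct sorted scores plus
    sentinels outside the range.  Ties in balanced accuracy are broken
    toward the middle candidate of the tied run.  Returns (threshold,
    degenerate_flag); a score distribution with a single distinct value is
    degenerate and yields that value as threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    if not labels.any() or labels.all():
        raise TrainingError("both classes required to choose a threshold")
    uniq = np.unique(scores)
    if uniq.size == 1:
        return float(uniq[0]), True
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    span = uniq[-1] - uniq[0]
    candidates = np.concatenate(([uniq[0] - 0.5 * span], mids, [uniq[-1] + 0.5 * span]))
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    pred = scores[None, :] > candidates[:, None]
    sens = (pred & labels[None, :]).sum(axis=1) / n_pos
    spec = (~pred & ~labels[None, :]).sum(axis=1) / n_neg
    bal = (sens + spec) / 2.0
    best = bal.max()
    tied = np.flatnonzero(np.isclose(bal, best))
    pick = tied[len(tied) // 2]
    return float(candidates[pick]), False


def train(
    teacher: TeacherSet,
    rounds: int = DEFAULT_ROUNDS,
    seed: int = 0,
) -> CrackleModel:
    """Fit the linear crackle discriminator from a labelled teacher set.

    The pipeline is: extract raw features for every clip, fit the min-max
    normaliser on all training frames, boost stumps on the normalised
    features, project the boosted margin onto ``y = a . x`` by least
    squares (no intercept; the threshold absorbs any offset), and pick the
    balanced-accuracy threshold on the linear scores.  Fully deterministic;
    ``seed`` is recorded in the training metadata.
    """
    if not teacher.clips:
        raise TrainingError("empty teacher set")
    raw, labels = teacher.frame_data()
    return train_from_frames(raw, labels, teacher.extractor, rounds=rounds, seed=seed)


def train_from_frames(
    raw: np.ndarray,
    labels: np.ndarray,
    extractor: FeatureExtractor,
    rounds: int = DEFAULT_ROUNDS,
    seed: int = 0,
) -> CrackleModel:
    labels = np.asarray(labels).astype(np.int8)
    if labels.min() == labels.max():
        raise TrainingError("teacher frames contain a single class")
    layout = extractor.layout
    normalizer = fit_normalizer([raw], layout)
    x = normalizer.transform(raw)
    sign_labels = np.where(labels > 0, 1.0, -1.0)

    stumps, margin = _boost(x, sign_labels, rounds)
    if stumps:
        a, *_ = np.linalg.lstsq(x, margin, rcond=None)
    else:
        a = np.zeros(layout.n)
    y_lin = x @ a
    threshold, degenerate = choose_threshold(y_lin, labels > 0)

    present = y_lin > threshold
    train_bal_acc = 0.5 * (
        present[labels > 0].mean() + (~present[labels == 0]).mean()
    )
    meta = {
        "rounds": rounds,
        "rounds_used": len(stumps),
        "seed": seed,
        "degenerate_threshold": degenerate,
        "train_balanced_accuracy": float(train_bal_acc),
        "train_error": float((present != (labels > 0)).mean()),
        "feature_config": extractor.config(),
        "stumps": [
            {"feature": s.feature, "threshold": s.threshold,
             "polarity": s.polarity, "alpha": s.alpha}
            for s in stumps
        ],
    }
    return CrackleModel(a=a, threshold=threshold, normalizer=normalizer,
                        layout=layout, training_meta=meta)


def score_frames(features: FeatureMatrix, model: CrackleModel) -> FrameDecisions:
    """Exact dot-product scores and thresholded presence per frame."""
    if features.layout.names != model.layout.names:
        raise TrainingError("feature layout does not match the model's layout")
    y = features.values @ model.a
    return FrameDecisions(grid=features.grid, y=y, present=y > model.threshold,
                         threshold=model.threshold)


def classify_section(section, model: CrackleModel) -> FrameDecisions:
    """Convenience: extract features with the model's config and score them."""
    extractor = FeatureExtractor.from_config(model.training_meta["feature_config"])
    grid, raw = extractor.extract_raw(section)
    feats = apply_normalizer(grid, raw, model.normalizer)
    return score_frames(feats, model)
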