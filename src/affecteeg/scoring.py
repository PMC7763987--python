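"""Per-participant emotion scores on the common (-1, 1) valence/arousal scale.

Two sources feed the same scale: the EEG ensemble emits continuous scores in
[-1, 1] directly, while the self-assessment questionnaire yields integer
marks on a nine-point metric whose endpoints map to -1 (very negative /
calm) and +1 (very positive / aroused) with the midpoint at 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "EmotionScore",
    "AnnotationRecord",
    "rescale_nine_point",
    "rescale_nine_point_array",
    "nine_point_from_score",
    "score_participant",
    "circumplex_coordinates",
    "plot_circumplex",
]


@dataclass(frozen=True)
class EmotionScore:
    """A participant's (valence, arousal) point with its provenance."""

    participant: str
    source: Literal["EEG", "annotation"]
    valence: float
    arousal: float

    def __post_init__(self) -> None:
        for name, v in (("valence", self.valence), ("arousal", self.arousal)):
            if not np.isfinite(v) or not -1.0 <= v <= 1.0:
                raise ValueError(f"{name} must be finite and within [-1, 1], got {v}")
        if self.source not in ("EEG", "annotation"):
            raise ValueError(f"unknown score source {self.source!r}")


@dataclass(frozen=True)
class AnnotationRecord:
    """Raw nine-point questionnaire marks for one participant."""

    participant: str
    valence_mark: int
    arousal_mark: int

    def __post_init__(self) -> None:
        for name, m in (("valence_mark", self.valence_mark), ("arousal_mark", self.arousal_mark)):
            _check_mark(m, name)

    def to_score(self) -> EmotionScore:
        return EmotionScore(
            participant=self.participant,
            source="annotation",
            valence=rescale_nine_point(self.valence_mark),
            arousal=rescale_nine_point(self.arousal_mark),
        )


def _check_mark(mark, name: str = "mark") -> int:
    # marks are discrete points on the questionnaire; fractional values are a
    # data error, not something to round away
    if isinstance(mark, float) and not mark.is_integer():
        raise ValueError(f"{name} must be an integer 1..9, got fractional {mark}")
    m = int(mark)
    if m != mark or not 1 <= m <= 9:
        raise ValueError(f"{name} must be an integer 1..9, got {mark!r}")
    return m


def rescale_nine_point(mark: int) -> float:
    """Map a nine-point mark to (-1, 1) via the affine rule ``(mark - 5) / 4``.

    Mark 1 → -1 (very negative), 5 → 0 (neutral), 9 → +1 (very positive).
    """
    return (_check_mark(mark) - 5) / 4


def rescale_nine_point_array(marks) -> np.ndarray:
    """Vectorized :func:`rescale_nine_point` with the same validation."""
    a = np.asarray(marks)
    if a.size and (np.any(a != np.floor(a)) or np.any(a < 1) or np.any(a > 9)):
        bad = a[(a != np.floor(a)) | (a < 1) | (a > 9)]
        raise ValueError(f"marks must be integers 1..9; offending values: {bad[:5]}")
    return (a.astype(float) - 5.0) / 4.0


def nine_point_from_score(value: float) -> int:
    """Exact inverse of :func:`rescale_nine_point` on its range {-1, -0.75, ..., 1}."""
    mark = 4.0 * value + 5.0
    if not np.isclose(mark, round(mark), atol=1e-12) or not 1 <= round(mark) <= 9:
        raise ValueError(f"{value} is not the rescaled image of a nine-point mark")
    return int(round(mark))


def score_participant(
    trial_scores: Sequence[tuple[float, float]],
    participant: str = "",
    source: Literal["EEG", "annotation"] = "EEG",
) -> EmotionScore:
    """Aggregate per-trial (valence, arousal) scores into one participant score.

    The aggregate is the unweighted arithmetic mean over trials (here,
    typically the ten 10 s stimulus epochs of one viewing session), clipped
    to [-1, 1].  The mean is permutation-invariant by construction.
    """
    arr = np.asarray(list(trial_scores), dtype=float)
    if arr.size == 0:
        raise ValueError("trial_scores must be non-empty")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("trial_scores must be a sequence of (valence, arousal) pairs")
    v, a = np.clip(arr.mean(axis=0), -1.0, 1.0)
    return EmotionScore(participant=participant, source=source, valence=float(v), arousal=float(a))


def circumplex_coordinates(score: EmotionScore) -> tuple[float, float]:
    """Embed a score in the circumplex plane: x = valence, y = arousal."""
    return (score.valence, score.arousal)


def plot_circumplex(scores: Iterable[EmotionScore], ax=None, **scatter_kw):
    """Scatter scores on the valence/arousal plane (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    pts = np.array([circumplex_coordinates(s) for s in scores])
    ax.scatter(pts[:, 0], pts[:, 1], **scatter_kw)
    ax.axhline(0, color="0.7", lw=0.8)
    ax.axvline(0, color="0.7", lw=0.8)
    ax.set_xlim(-1, 1)
    ax.set_ylim(-1, 1)
    ax.set_xlabel("valence")
    ax.set_ylabel("arousal")
    return ax
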