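"""Two-group affect statistics: pooled t-tests and Cohen's d.

The experimental design compares two independent participant groups (one
viewing photographic surgical images, one viewing illustrated versions) on
four score columns: EEG-estimated valence/arousal and user-annotated
valence/arousal, all expressed on the common (-1, 1) scale.  Two families of
comparisons are made:

* between-group — group1 vs group2 for each score column (tests the null
  hypothesis H0 that photographic and illustrated images evoke the same
  emotional response);
* between-method — EEG-estimated vs rescaled user-annotated scores within
  each group (tests the null hypothesis H1 that the two estimation methods
  agree).

Cohen's d here uses the pooled standard deviation with the *total-n*
denominator, ``sqrt((SSx + SSy) / (nx + ny))``; the more common unbiased
``nx + ny - 2`` denominator is available via ``denominator="n-2"``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scoring import rescale_nine_point_array

__all__ = [
    "SampleSummary",
    "GroupComparison",
    "AnalysisReport",
    "pooled_sd",
    "pooled_two_sample_t",
    "cohens_d",
    "compare_samples",
    "analyze_experiment",
]

#: p values below this are reported as an interval upper bound, never as 0.
P_UNDERFLOW = 1e-300

SCORE_COLUMNS = ("eeg_valence", "eeg_arousal", "user_valence", "user_arousal")


@dataclass(frozen=True)
class SampleSummary:
    """Sufficient statistics of one sample: size, mean, sum of squared deviations."""

    n: int
    mean: float
    ss: float

    @classmethod
    def of(cls, x: np.ndarray) -> "SampleSummary":
        x = np.asarray(x, dtype=float)
        if x.ndim != 1:
            raise ValueError("sample must be one-dimensional")
        m = float(x.mean())
        return cls(n=x.size, mean=m, ss=float(np.sum((x - m) ** 2)))


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample comparison bundle: t-test and standardized mean difference."""

    label: str
    x: SampleSummary
    y: SampleSummary
    sd_pooled: float
    t: float
    df: float
    p: float
    d: float
    #: True when the analytic p underflowed below ``P_UNDERFLOW``; ``p`` then
    #: holds the underflow bound and must be read as "p < bound".
    p_is_upper_bound: bool = False

    @property
    def d_magnitude(self) -> float:
        return abs(self.d)

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "n_x": self.x.n,
            "mean_x": self.x.mean,
            "n_y": self.y.n,
            "mean_y": self.y.mean,
            "sd_pooled": self.sd_pooled,
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "p_is_upper_bound": self.p_is_upper_bound,
            "d": self.d,
            "abs_d": self.d_magnitude,
        }


def _validate_pair(x, y, min_n: int = 2) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < min_n or y.size < min_n:
        raise ValueError(f"both samples need at least {min_n} observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    return x, y


def pooled_sd(x, y, denominator: Literal["n", "n-2"] = "n") -> float:
    """Pooled standard deviation of two samples.

    ``denominator="n"`` divides the summed squared deviations by
    ``nx + ny`` (the convention used throughout this package's effect
    sizes); ``"n-2"`` gives the usual unbiased pooled variance.
    """
    x, y = _validate_pair(x, y)
    ssx = float(np.sum((x - x.mean()) ** 2))
    ssy = float(np.sum((y - y.mean()) ** 2))
    if denominator == "n":
        den = x.size + y.size
    elif denominator == "n-2":
        den = x.size + y.size - 2
    else:
        raise ValueError("denominator must be 'n' or 'n-2'")
    return math.sqrt((ssx + ssy) / den)


def pooled_two_sample_t(x, y, equal_var: bool = True) -> tuple[float, float, float]:
    """Two-sample t-test; returns ``(t, df, p)`` with a two-sided p.

    The default is the equal-variance Student form with
    ``df = nx + ny - 2``; ``equal_var=False`` switches to the Welch form
    with Welch–Satterthwaite degrees of freedom.

    Degenerate inputs are resolved explicitly: two identical constant
    samples give ``t = 0, p = 1``; constant samples with unequal means have
    an infinite statistic, reported as ``t = ±inf`` with the p value flagged
    as an underflow bound by :func:`compare_samples`.
    """
    x, y = _validate_pair(x, y)
    nx, ny = x.size, y.size
    if equal_var:
        df = float(nx + ny - 2)
    else:
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        num = (vx / nx + vy / ny) ** 2
        den = (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        df = float(num / den) if den > 0 else float(nx + ny - 2)

    sp = pooled_sd(x, y, "n-2") if equal_var else None
    if (equal_var and sp == 0.0) or (not equal_var and x.var(ddof=1) + y.var(ddof=1) == 0.0):
        if math.isclose(x.mean(), y.mean(), abs_tol=0.0):
            return 0.0, df, 1.0
        t = math.inf if x.mean() > y.mean() else -math.inf
        return t, df, 0.0

    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), df, float(res.pvalue)


def cohens_d(x, y, denominator: Literal["n", "n-2"] = "n") -> float:
    """Signed Cohen's d: ``(mean(x) - mean(y)) / SD_pooled``.

    Positive d means sample ``x`` has the larger mean.  A zero pooled SD is
    an error unless the means are also equal, in which case d = 0.
    """
    x, y = _validate_pair(x, y)
    sd = pooled_sd(x, y, denominator)
    diff = float(x.mean() - y.mean())
    if sd == 0.0:
        if diff == 0.0:
            return 0.0
        raise ZeroDivisionError(
            "pooled SD is zero but the sample means differ; d is undefined"
        )
    return diff / sd


def compare_samples(
    label: str,
    x,
    y,
    *,
    d_denominator: Literal["n", "n-2"] = "n",
    equal_var: bool = True,
) -> GroupComparison:
    """Run the t-test and effect size for one pair of samples."""
    x, y = _validate_pair(x, y)
    t, df, p = pooled_two_sample_t(x, y, equal_var=equal_var)
    underflow = p < P_UNDERFLOW
    if underflow:
        p = P_UNDERFLOW
    sd = pooled_sd(x, y, d_denominator)
    try:
        d = cohens_d(x, y, d_denominator)
    except ZeroDivisionError:
        d = math.copysign(math.inf, float(np.mean(x) - np.mean(y)))
    return GroupComparison(
        label=label,
        x=SampleSummary.of(x),
        y=SampleSummary.of(y),
        sd_pooled=sd,
        t=t,
        df=df,
        p=p,
        d=d,
        p_is_upper_bound=underflow,
    )


@dataclass
class AnalysisReport:
    """All eight comparisons of the two-group experiment, plus verdicts.

    ``between_group`` maps each score column to the group1-vs-group2
    comparison; ``between_method`` maps ``"{valence|arousal}/{group}"`` to
    the EEG-vs-annotation comparison within that group (annotation marks
    rescaled to (-1, 1) first, so both methods share a scale).
    """

    between_group: dict[str, GroupComparison]
    between_method: dict[str, GroupComparison]
    alpha: float
    group_names: tuple[str, str]
    #: verdict "reject" / "fail-to-reject" for H0 (between-group) per column
    h0_verdicts: dict[str, str] = field(default_factory=dict)
    #: verdict for H1 (between-method) per comparison key
    h1_verdicts: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.h0_verdicts:
            self.h0_verdicts = {
                k: "reject" if c.p < self.alpha else "fail-to-reject"
                for k, c in self.between_group.items()
            }
        if not self.h1_verdicts:
            self.h1_verdicts = {
                k: "reject" if c.p < self.alpha else "fail-to-reject"
                for k, c in self.between_method.items()
            }

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """Tabular analogues: between-group p, between-method p, and the two d tables."""
        g = pd.DataFrame([c.as_dict() for c in self.between_group.values()])
        m = pd.DataFrame([c.as_dict() for c in self.between_method.values()])
        return {
            "between_group_t": g.drop(columns=["d", "abs_d"]),
            "between_method_t": m.drop(columns=["d", "abs_d"]),
            "between_group_d": g[["label", "d", "abs_d"]],
            "between_method_d": m[["label", "d", "abs_d"]],
        }

    def summary(self) -> str:
        """Compact human-readable rendering of all eight comparisons."""
        def fmt_p(c: GroupComparison) -> str:
            return ("< " if c.p_is_upper_bound else "") + f"{c.p:.3g}"

        lines = ["between-group (t, p, |d|):"]
        for k, c in self.between_group.items():
            lines.append(f"  {k:<22} t = {c.t:8.3f}   p = {fmt_p(c):<10} "
                         f"|d| = {c.d_magnitude:.2f}")
        lines.append("between-method (p, |d|):")
        for k, c in self.between_method.items():
            lines.append(f"  {k:<22} p = {fmt_p(c):<10} |d| = {c.d_magnitude:.2f}")
        lines.append(f"H0 (groups differ?) verdicts at alpha={self.alpha:g}: "
                     + ", ".join(f"{k}={v}" for k, v in self.h0_verdicts.items()))
        lines.append(f"H1 (methods agree?) verdicts at alpha={self.alpha:g}: "
                     + ", ".join(f"{k}={v}" for k, v in self.h1_verdicts.items()))
        return "\n".join(lines)

    def to_json(self, **kwargs) -> str:
        payload = {
            "alpha": self.alpha,
            "groups": list(self.group_names),
            "between_group": {k: c.as_dict() for k, c in self.between_group.items()},
            "between_method": {k: c.as_dict() for k, c in self.between_method.items()},
            "h0_verdicts": self.h0_verdicts,
            "h1_verdicts": self.h1_verdicts,
        }
        return json.dumps(payload, indent=2, **kwargs)


def analyze_experiment(
    scores: pd.DataFrame,
    *,
    alpha: float = 0.05,
    d_denominator: Literal["n", "n-2"] = "n",
    equal_var: bool = True,
) -> AnalysisReport:
    """Run the full two-group analysis over a per-participant score table.

    ``scores`` must carry the columns ``participant``, ``group``,
    ``eeg_valence``, ``eeg_arousal``, ``user_valence``, ``user_arousal``,
    with exactly two groups in first-appearance order (group1, group2).
    User-annotated marks are integers on the nine-point scale and are mapped
    to (-1, 1) via ``(u - 5) / 4`` before any comparison, so every test runs
    on the common scale.  Note the t statistic and d are invariant under
    that affine map, so between-group results on the user columns are
    identical whether raw or rescaled marks are used.
    """
    required = {"group", *SCORE_COLUMNS}
    missing = required.difference(scores.columns)
    if missing:
        raise KeyError(f"score table is missing column(s): {sorted(missing)}")
    groups = list(dict.fromkeys(scores["group"]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups!r}")
    g1, g2 = groups
    sub = {g: scores[scores["group"] == g] for g in groups}

    def col(g: str, name: str) -> np.ndarray:
        v = sub[g][name].to_numpy()
        if name.startswith("user"):
            return rescale_nine_point_array(v)
        return np.asarray(v, dtype=float)

    kw = dict(d_denominator=d_denominator, equal_var=equal_var)
    between_group = {
        name: compare_samples(f"{name}: {g1} vs {g2}", col(g1, name), col(g2, name), **kw)
        for name in SCORE_COLUMNS
    }
    between_method = {}
    for dim in ("valence", "arousal"):
        for g in groups:
            key = f"{dim}/{g}"
            between_method[key] = compare_samples(
                f"{dim} ({g}): EEG vs annotation",
                col(g, f"eeg_{dim}"),
                col(g, f"user_{dim}"),
                **kw,
            )
    return AnalysisReport(
        between_group=between_group,
        between_method=between_method,
        alpha=alpha,
        group_names=(g1, g2),
    )
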