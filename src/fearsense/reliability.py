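"""Reliability statistics for the four fear-measurement modalities.

The protocol measures each subject before and after a fear stimulus on four
modalities: EEG (delta/beta ratio), blinking rate, facial temperature and a
subjective questionnaire.  This module implements the statistical layer that
decides which modalities respond reliably:

* Welch's unequal-variance two-sample t-test on pre vs post groups (accepting
  either raw vectors or published mean/SD/n summaries),
* Cohen's d in the pooled form |m2 - m1| / sqrt((s1^2 + s2^2) / 2) with
  small/medium/large labels assigned by the nearest of the conventional
  anchors 0.2 / 0.5 / 0.8,
* sign alignment (facial temperature and EEG fall under fear while blink
  rate and subjective scores rise, so the former are negated before
  correlating),
* pairwise OLS regression (gradient, R^2), the 4x4 Pearson correlation
  matrix of per-subject pre-to-post changes, and per-modality sums of
  off-diagonal correlations,
* ranking of modalities by effect size and by correlation sum, and
* baseline compensation using an emotionally neutral video clip.

The pre/post comparison deliberately uses the *unpaired* unequal-variance
test even though the groups are the same subjects, mirroring the protocol
this package reimplements; a paired option is exposed but not the default.
No multiple-testing correction is applied by default for the same reason.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MODALITY_ORDER",
    "NEGATED_MODALITIES",
    "GroupSummary",
    "WelchResult",
    "EffectSizeResult",
    "RankingResult",
    "ReliabilityReport",
    "welch_t_test",
    "cohens_d",
    "effect_size_label",
    "sign_align",
    "pairwise_regression",
    "correlation_matrix",
    "correlation_sums",
    "rank_modalities",
    "neutral_compensation",
    "build_report",
]

#: canonical modality order used in reports and correlation matrices
MODALITY_ORDER = ("EEG", "blinking_rate", "facial_temperature", "subjective_evaluation")

#: modalities that decrease under fear and are negated before correlation
NEGATED_MODALITIES = frozenset({"facial_temperature", "EEG"})

_EFFECT_ANCHORS = ((0.2, "Small"), (0.5, "Medium"), (0.8, "Large"))


@dataclass(frozen=True)
class GroupSummary:
    """Mean, standard deviation and size of one measurement group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("standard deviation must be non-negative")
        if self.n < 2:
            raise ValueError("group size must be at least 2")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "GroupSummary":
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValueError("need at least 2 values")
        return cls(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=int(arr.size))


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class EffectSizeResult:
    d: float
    label: str


@dataclass(frozen=True)
class RankingResult:
    by_effect_size: tuple[str, ...]
    by_correlation_sum: tuple[str, ...]
    top2_consensus: tuple[str, ...]
    tied: bool = False


@dataclass(frozen=True)
class ReliabilityReport:
    welch: Mapping[str, WelchResult]
    effect_sizes: Mapping[str, EffectSizeResult]
    correlation: pd.DataFrame
    correlation_sums: Mapping[str, float]
    ranking: RankingResult


def _as_summary(g) -> GroupSummary:
    if isinstance(g, GroupSummary):
        return g
    return GroupSummary.from_values(g)


def welch_t_test(g1, g2, paired: bool = False) -> WelchResult:
    """Two-tailed t-test on two groups given raw values or summaries.

    The default is Welch's unpaired unequal-variance test with
    Welch-Satterthwaite degrees of freedom.  ``paired=True`` runs a paired
    t-test instead and requires raw vectors of equal length.  Two groups that
    are both constant and equal return t = 0, p = 1.
    """
    if paired:
        a = np.asarray(g1, dtype=float)
        b = np.asarray(g2, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("paired test requires equal-length raw vectors")
        diff = a - b
        sd = diff.std(ddof=1)
        if sd == 0:
            return WelchResult(t=0.0, df=float(a.size - 1), p=1.0) if diff[0] == 0 else \
                WelchResult(t=math.inf, df=float(a.size - 1), p=0.0)
        t = float(diff.mean() / (sd / math.sqrt(a.size)))
        df = float(a.size - 1)
        return WelchResult(t=t, df=df, p=float(2 * stats.t.sf(abs(t), df)))
    s1, s2 = _as_summary(g1), _as_summary(g2)
    v1, v2 = s1.sd**2 / s1.n, s2.sd**2 / s2.n
    se2 = v1 + v2
    if se2 == 0:
        if s1.mean == s2.mean:
            return WelchResult(t=0.0, df=float(s1.n + s2.n - 2), p=1.0)
        raise ValueError("both groups constant with different means: t undefined")
    t = (s1.mean - s2.mean) / math.sqrt(se2)
    df = se2**2 / (v1**2 / (s1.n - 1) + v2**2 / (s2.n - 1))
    p = float(2 * stats.t.sf(abs(t), df))
    return WelchResult(t=float(t), df=float(df), p=p)


def cohens_d(g1, g2) -> float:
    """Standardized mean difference |m2 - m1| / sqrt((s1^2 + s2^2) / 2).

    The pooled denominator is the root mean square of the two group SDs
    (equivalent to the classic pooled SD for equal group sizes); the result is
    reported as an absolute value so increases and decreases rank alike.
    """
    s1, s2 = _as_summary(g1), _as_summary(g2)
    if s1.n != s2.n:
        warnings.warn(
            f"unequal group sizes ({s1.n} vs {s2.n}): the RMS-pooled denominator "
            "assumes a balanced design",
            stacklevel=2,
        )
    pooled = math.sqrt((s1.sd**2 + s2.sd**2) / 2.0)
    if pooled == 0:
        raise ValueError("zero pooled standard deviation: d undefined")
    return abs(s2.mean - s1.mean) / pooled


def effect_size_label(d: float) -> str:
    """Label an effect size by the nearest conventional anchor (0.2/0.5/0.8).

    Ties between anchors go to the larger label; any d of at least 0.8 is
    Large.  Negative inputs are taken in absolute value.
    """
    d = abs(d)
    if d >= _EFFECT_ANCHORS[-1][0]:
        return "Large"
    best = min(
        reversed(_EFFECT_ANCHORS), key=lambda item: round(abs(d - item[0]), 9)
    )  # reversed + stable min -> exact midpoints pick the larger anchor
    return best[1]


def effect_size(g1, g2) -> EffectSizeResult:
    d = cohens_d(g1, g2)
    return EffectSizeResult(d=d, label=effect_size_label(d))


def sign_align(deltas: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Negate the modalities that fall under fear so all respond in one direction.

    Facial temperature and the EEG delta/beta ratio decrease with fear while
    blink rate and subjective scores increase; multiplying the former by -1
    puts all four on a common "more fear = larger" axis before correlating.
    Applying the alignment twice restores the input.
    """
    return {
        name: -np.asarray(v, dtype=float)
        if name in NEGATED_MODALITIES
        else np.asarray(v, dtype=float)
        for name, v in deltas.items()
    }


def pairwise_regression(x, y) -> tuple[float, float]:
    """OLS best-fit line of y on x: returns (gradient, R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need at least 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: regression undefined")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.rvalue**2)


def correlation_matrix(deltas: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Pearson correlation matrix of per-subject changes across modalities.

    Rows/columns follow :data:`MODALITY_ORDER` for the canonical four
    modalities (extra keys keep insertion order after them).  Raises if any
    vector is constant, naming the offending modality.
    """
    names = [n for n in MODALITY_ORDER if n in deltas]
    names += [n for n in deltas if n not in names]
    if len(names) < 2:
        raise ValueError("need at least two modalities")
    arrs = []
    for n in names:
        v = np.asarray(deltas[n], dtype=float)
        if v.size < 3:
            raise ValueError(f"modality {n!r} has fewer than 3 values")
        if np.ptp(v) == 0:
            raise ValueError(f"modality {n!r} is constant: correlation undefined")
        arrs.append(v)
    if len({a.size for a in arrs}) != 1:
        raise ValueError("modalities have unequal numbers of subjects")
    mat = np.corrcoef(np.vstack(arrs))
    return pd.DataFrame(mat, index=names, columns=names)


def correlation_sums(matrix: pd.DataFrame | np.ndarray) -> dict[str, float]:
    """Per-modality sum of correlations with the *other* modalities.

    For each row of a symmetric unit-diagonal correlation matrix, the sum of
    the off-diagonal entries; a modality consistent with the others scores
    high.  Raises on a non-square, asymmetric or non-unit-diagonal matrix.
    """
    if isinstance(matrix, pd.DataFrame):
        names = list(matrix.index)
        mat = matrix.to_numpy(dtype=float)
    else:
        mat = np.asarray(matrix, dtype=float)
        names = [f"m{i}" for i in range(mat.shape[0])]
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-12):
        raise ValueError("correlation matrix must have a unit diagonal")
    return {name: float(mat[i].sum() - mat[i, i]) for i, name in enumerate(names)}


def _rank(values: Mapping[str, float]) -> tuple[tuple[str, ...], bool]:
    names = list(values)
    ordered = sorted(names, key=lambda n: -values[n])  # stable: ties keep input order
    tied = len({round(values[n], 12) for n in names}) < len(names)
    return tuple(ordered), tied


def rank_modalities(
    effect_sizes: Mapping[str, EffectSizeResult | float],
    corr_sums: Mapping[str, float],
) -> RankingResult:
    """Order modalities by effect size and by correlation sum.

    Returns both orderings (descending) plus the consensus list of modalities
    ranked in the top two by *both* criteria — the modalities the protocol
    would call reliable.  Ties preserve input order and set the tie flag.
    """
    d_values = {
        n: (v.d if isinstance(v, EffectSizeResult) else float(v))
        for n, v in effect_sizes.items()
    }
    by_d, tied_d = _rank(d_values)
    by_sum, tied_s = _rank(dict(corr_sums))
    top2 = tuple(n for n in by_d[:2] if n in by_sum[:2])
    return RankingResult(
        by_effect_size=by_d,
        by_correlation_sum=by_sum,
        top2_consensus=top2,
        tied=tied_d or tied_s,
    )


def neutral_compensation(
    horror_deltas: Mapping[str, Mapping[object, float]] | pd.Series,
    neutral_deltas: Mapping[str, Mapping[object, float]] | pd.Series,
) -> dict:
    """Subtract the neutral-clip change from the fear-stimulus change per subject.

    Both arguments map subject -> (post - pre) change under one condition (or
    modality -> {subject: change}); subject sets must match.  The compensated
    change isolates the stimulus-driven component from drift that also occurs
    while watching emotionally neutral content.
    """
    h = dict(horror_deltas)
    n = dict(neutral_deltas)
    if set(h) != set(n):
        raise ValueError(
            f"subject/modality sets differ: {sorted(set(h) ^ set(n), key=str)}"
        )
    out = {}
    for key, hv in h.items():
        if isinstance(hv, Mapping):
            out[key] = neutral_compensation(hv, n[key])
        else:
            out[key] = float(hv) - float(n[key])
    return out


# ---------------------------------------------------------------------------
# Cohort-table helpers

def cohort_deltas(cohort: pd.DataFrame, condition: str = "horror") -> dict[str, np.ndarray]:
    """Per-subject (post - pre) change per modality from a long cohort table.

    The table needs columns subject, modality, condition, phase, value with
    phase in {pre, post}.
    """
    sub = cohort[cohort["condition"] == condition]
    out: dict[str, np.ndarray] = {}
    for modality, grp in sub.groupby("modality", sort=False):
        wide = grp.pivot(index="subject", columns="phase", values="value")
        if not {"pre", "post"} <= set(wide.columns):
            raise ValueError(f"modality {modality!r} lacks pre/post phases")
        out[str(modality)] = (wide["post"] - wide["pre"]).to_numpy(dtype=float)
    return out


def build_report(
    cohort: pd.DataFrame,
    condition: str = "horror",
    neutral_condition: str | None = None,
) -> ReliabilityReport:
    """Full reliability analysis of a long cohort table.

    Runs Welch tests and effect sizes per modality on the pre/post groups,
    sign-aligns per-subject changes (after optional neutral-baseline
    compensation when ``neutral_condition`` is given), and derives the
    correlation matrix, correlation sums and modality ranking.
    """
    sub = cohort[cohort["condition"] == condition]
    if sub.empty:
        raise ValueError(f"no rows for condition {condition!r}")
    welch: dict[str, WelchResult] = {}
    effects: dict[str, EffectSizeResult] = {}
    for modality, grp in sub.groupby("modality", sort=False):
        pre = grp.loc[grp["phase"] == "pre", "value"].to_numpy(dtype=float)
        post = grp.loc[grp["phase"] == "post", "value"].to_numpy(dtype=float)
        welch[str(modality)] = welch_t_test(pre, post)
        effects[str(modality)] = effect_size(pre, post)
    deltas = cohort_deltas(cohort, condition)
    if neutral_condition is not None:
        neutral = cohort_deltas(cohort, neutral_condition)
        deltas = {
            m: np.asarray(deltas[m]) - np.asarray(neutral[m]) for m in deltas
        }
    aligned = sign_align(deltas)
    corr = correlation_matrix(aligned)
    sums = correlation_sums(corr)
    ranking = rank_modalities(effects, sums)
    return ReliabilityReport(
        welch=welch,
        effect_sizes=effects,
        correlation=corr,
        correlation_sums=sums,
        ranking=ranking,
    )


def read_cohort(path) -> pd.DataFrame:
    """Read a long cohort table (subject, modality, condition, phase, value)."""
    df = pd.read_csv(path)
    required = {"subject", "modality", "condition", "phase", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing column(s): {sorted(missing)}")
    return df
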