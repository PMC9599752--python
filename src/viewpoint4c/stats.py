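"""Region-restricted differential contact testing.

Contacts between two conditions are compared fragment-wise inside a named
target region: fragment scores are pooled across replicates within each
condition, a D'Agostino–Pearson omnibus test documents departure from
normality in each group (advisory — it justifies the nonparametric choice
but never blocks the comparison), and an unpaired two-tailed Mann–Whitney U
test delivers the p-value, annotated with the conventional significance
stars (* p < 0.05, ** p < 0.01, *** p < 0.001, **** p <= 0.0001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

from .regions import Region
from .scoring import ScoreTrack

DEFAULT_STAR_MAP: tuple[tuple[float, str], ...] = (
    (1e-4, "****"),
    (1e-3, "***"),
    (1e-2, "**"),
    (5e-2, "*"),
)


@dataclass(frozen=True)
class StatsParams:
    """alpha: significance level; star_map: ascending (threshold, label)
    pairs — the smallest threshold is inclusive (p <= 1e-4 earns ****), the
    rest strict; exact_max_n: largest group size for exact Mann–Whitney
    enumeration (ties always force the tie-corrected normal approximation)."""

    alpha: float = 0.05
    star_map: tuple[tuple[float, str], ...] = DEFAULT_STAR_MAP
    exact_max_n: int = 8

    def __post_init__(self) -> None:
        thresholds = [t for t, _ in self.star_map]
        if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
            raise ValueError("star_map thresholds must be strictly increasing")

    def stars(self, p: float) -> str:
        """Map a p-value to its significance label ('ns' if none)."""
        if not np.isfinite(p):
            return "ns"
        lowest_thr, lowest_label = self.star_map[0]
        if p <= lowest_thr:
            return lowest_label
        for thr, label in self.star_map[1:]:
            if p < thr:
                return label
        return "ns"


class NormalityResult(NamedTuple):
    k2: float
    p: float
    n: int
    applicable: bool


@dataclass(frozen=True)
class TestResult:
    """Outcome of one region-level differential contact comparison."""

    region: Region | None
    stage: str
    n1: int
    n2: int
    U: float
    p_two_tailed: float
    normality_p: tuple[float, float] = (float("nan"), float("nan"))
    normality_rejected: tuple[bool, bool] = (False, False)
    stars: str = "ns"
    method: str = "asymptotic"

    def __post_init__(self) -> None:
        if not (0 <= self.U <= self.n1 * self.n2):
            raise ValueError(f"U={self.U} outside [0, n1*n2={self.n1 * self.n2}]")
        if not (0 <= self.p_two_tailed <= 1):
            raise ValueError(f"p={self.p_two_tailed} outside [0, 1]")


def extract_region_scores(track: ScoreTrack, region: Region) -> np.ndarray:
    """Scores of retained fragments whose midpoint lies in ``region``,
    in fragment order. Empty result is a warning, not an error."""
    if region.chrom != track.chrom:
        raise ValueError(
            f"region {region} is not on track chromosome {track.chrom}"
        )
    mid = track.midpoints
    mask = (mid >= region.start) & (mid < region.end)
    if not mask.any():
        warnings.warn(f"no retained fragments with midpoint in {region}", stacklevel=2)
    return track.scores[mask]


def dagostino_pearson(x: Sequence[float]) -> NormalityResult:
    """D'Agostino–Pearson omnibus normality test.

    K2 is the sum of the squared z-transforms of the sample skewness
    (D'Agostino) and kurtosis (Anscombe–Glynn), referred to chi-square with
    2 df. Needs n >= 8; smaller samples return a not-applicable result.
    """
    arr = np.asarray(x, dtype=float)
    n = len(arr)
    if n < 8:
        warnings.warn(
            f"D'Agostino-Pearson needs n >= 8 (got {n}); returning not-applicable",
            stacklevel=2,
        )
        return NormalityResult(float("nan"), float("nan"), n, False)
    if np.ptp(arr) == 0:
        raise ValueError("zero-variance input: normality test moments undefined")
    k2, p = sps.normaltest(arr)
    return NormalityResult(float(k2), float(p), n, True)


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    params: StatsParams | None = None,
    region: Region | None = None,
    stage: str = "raw",
) -> TestResult:
    """Unpaired two-tailed Mann–Whitney U test.

    U is computed from rank sums with midranks for ties. The two-tailed p
    comes from the exact null distribution of U when both groups have at
    most ``exact_max_n`` observations and the pooled sample is tie-free,
    otherwise from the tie-corrected normal approximation with continuity
    correction. If every pooled value is identical there is no evidence
    either way and p = 1.
    """
    params = params or StatsParams()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("Mann-Whitney requires both groups non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n1 + n2
    if np.ptp(pooled) == 0:
        return _build_result(
            region, stage, n1, n2, U=n1 * n2 / 2.0, p=1.0, method="degenerate",
            x=x, y=y, params=params,
        )
    if max(n1, n2) <= params.exact_max_n and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "asymptotic"
    return _build_result(
        region, stage, n1, n2, U=float(res.statistic), p=float(min(res.pvalue, 1.0)),
        method=method, x=x, y=y, params=params,
    )


def _gated_normality(v: np.ndarray, alpha: float) -> tuple[float, bool]:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nr = dagostino_pearson(v)
    except ValueError:
        return float("nan"), False
    if not nr.applicable:
        return float("nan"), False
    return nr.p, bool(nr.p < alpha)


def _build_result(region, stage, n1, n2, U, p, method, x, y, params) -> TestResult:
    p1, rej1 = _gated_normality(x, params.alpha)
    p2, rej2 = _gated_normality(y, params.alpha)
    return TestResult(
        region=region,
        stage=stage,
        n1=n1,
        n2=n2,
        U=U,
        p_two_tailed=p,
        normality_p=(p1, p2),
        normality_rejected=(rej1, rej2),
        stars=params.stars(p),
        method=method,
    )


def compare_conditions(
    tracks_a: Sequence[Mapping[str, ScoreTrack]],
    tracks_b: Sequence[Mapping[str, ScoreTrack]],
    region: Region,
    params: StatsParams | None = None,
    stages: Sequence[str] = ("normalized", "profile_corrected"),
) -> dict[str, TestResult]:
    """Region-level two-condition comparison, per processing stage.

    Each condition is a list of replicates, each replicate a mapping
    stage -> ScoreTrack (as produced by ``signal.process_replicate``).
    Within a condition, region fragment scores are pooled across replicates
    — fragments are the sampling unit — then gated by the normality test and
    compared by Mann–Whitney.
    """
    params = params or StatsParams()
    results: dict[str, TestResult] = {}
    for stage in stages:
        groups = []
        for label, cond in (("A", tracks_a), ("B", tracks_b)):
            vecs = []
            for r, rep in enumerate(cond):
                if stage not in rep:
                    raise ValueError(
                        f"stage {stage!r} missing from condition {label} replicate {r}"
                    )
                vecs.append(extract_region_scores(rep[stage], region))
            groups.append(np.concatenate(vecs) if vecs else np.array([]))
        ga, gb = groups
        if len(ga) < 2 or len(gb) < 2:
            raise ValueError(
                f"region {region} holds fewer than 2 scored fragments per group "
                f"at stage {stage!r} (n1={len(ga)}, n2={len(gb)})"
            )
        results[stage] = mann_whitney_u(ga, gb, params, region=region, stage=stage)
    return results
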