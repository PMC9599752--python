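"""Fragment-score normalization, smoothing, and distance-decay correction.

The processing chain mirrors standard viewpoint-based 4C practice:

1. *Local-mean normalization* — divide every fragment score by the mean score
   of fragments whose midpoints fall within ±1 Mb of the bait center, making
   profiles comparable across libraries of different depth.
2. *Running mean* — an 11-fragment centered moving average used for browser
   tracks (visualization only; statistics run on unsmoothed scores).
3. *Profile correction* — contact frequency decays with genomic distance d
   roughly as a power law with exponent −1 in cis; fitting
   log10(score) = a − log10(d) by least squares with the slope fixed at −1
   gives the expected background, and dividing observed by expected yields a
   distance-independent enrichment score in which specific loops stand out.

Stage transitions are enforced as raw → normalized → {smoothed |
profile_corrected}; profile correction runs on unsmoothed normalized scores
so fragment-level tests are not artificially autocorrelated by the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .regions import Region
from .scoring import ScoreTrack

LOG10 = np.log(10.0)


@dataclass(frozen=True)
class SignalParams:
    """Tunable parameters of the signal chain.

    norm_halfwidth:   half-width (bp) of the normalization window around the
                      bait center (default 1 Mb).
    smooth_window:    running-mean window in fragments; odd (default 11).
    fit_min_distance: smallest bait distance (bp) entering the decay fit;
                      fragments closer than this get corrected scores flagged
                      as extrapolated (default 5 kb, beyond the exclusion).
    fit_max_distance: largest bait distance entering the fit (default 2 Mb,
                      the cis/TAD scale on which the power law holds).
    """

    norm_halfwidth: int = 1_000_000
    smooth_window: int = 11
    fit_min_distance: int = 5_000
    fit_max_distance: int = 2_000_000

    def __post_init__(self) -> None:
        if self.norm_halfwidth <= 0:
            raise ValueError("norm_halfwidth must be > 0")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 1")
        if not (0 < self.fit_min_distance < self.fit_max_distance):
            raise ValueError("need 0 < fit_min_distance < fit_max_distance")


@dataclass(frozen=True)
class DecayFit:
    """Least-squares intercept of log10(score) = intercept − log10(distance).

    The slope is fixed at −1 (not estimated); the intercept is therefore the
    mean of log10(score) + log10(distance) over the fitted fragments, and
    ``stderr`` is its standard error.
    """

    intercept: float
    fixed_slope: float = -1.0
    n_points: int = 0
    fit_range: tuple[float, float] = (0.0, float("inf"))
    stderr: float = float("nan")

    def expected(self, distance: np.ndarray) -> np.ndarray:
        """Expected normalized score at bait distance d: 10^a * d^slope."""
        d = np.asarray(distance, dtype=float)
        return 10.0 ** (self.intercept + self.fixed_slope * np.log10(d))


def _require_stage(track: ScoreTrack, expected: str, op: str) -> None:
    if track.stage != expected:
        raise ValueError(
            f"{op} requires a {expected!r}-stage track, got {track.stage!r} "
            "(processing order is raw -> normalized -> smoothed/profile_corrected)"
        )


def normalize_local_mean(track: ScoreTrack, params: SignalParams | None = None) -> ScoreTrack:
    """Divide scores by the mean score of fragments within ±norm_halfwidth
    of the bait center (fragment midpoints define window membership)."""
    params = params or SignalParams()
    _require_stage(track, "raw", "normalize_local_mean")
    if track.bait is None:
        raise ValueError("track has no bait region; set bait before normalizing")
    center = track.bait.midpoint
    d = track.distances(center)
    in_window = d <= params.norm_halfwidth
    window = f"{track.chrom}:{center - params.norm_halfwidth:.0f}-{center + params.norm_halfwidth:.0f}"
    if not in_window.any():
        raise ValueError(f"no retained fragments in normalization window {window}")
    mean = float(track.scores[in_window].mean())
    if mean <= 0:
        raise ValueError(f"normalization window {window} has zero mean score")
    return track.with_scores(track.scores / mean, "normalized", norm_window_mean=mean)


def running_mean(track: ScoreTrack, params: SignalParams | None = None) -> ScoreTrack:
    """Centered moving average over ``smooth_window`` fragments.

    At chromosome edges the window is clipped to the available fragments,
    so a window covering the whole track returns the grand mean everywhere.
    """
    params = params or SignalParams()
    _require_stage(track, "normalized", "running_mean")
    n = len(track)
    w = params.smooth_window
    if n == 0:
        return track.with_scores(track.scores, "smoothed")
    half = w // 2
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    csum = np.concatenate(([0.0], np.cumsum(track.scores)))
    smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    return track.with_scores(smoothed, "smoothed", smooth_window=w)


def fit_decay(track: ScoreTrack, params: SignalParams | None = None) -> DecayFit:
    """Fit the fixed-slope (−1) log-log decay model to positive-score
    fragments with bait distance inside [fit_min_distance, fit_max_distance].

    Zero-score fragments are excluded (log undefined); fewer than two
    eligible fragments is an error.
    """
    params = params or SignalParams()
    _require_stage(track, "normalized", "fit_decay")
    d = track.distances()
    eligible = (
        (track.scores > 0) & (d >= params.fit_min_distance) & (d <= params.fit_max_distance)
    )
    n = int(eligible.sum())
    if n < 2:
        raise ValueError(
            f"decay fit needs >= 2 positive-score fragments in "
            f"[{params.fit_min_distance}, {params.fit_max_distance}] bp; found {n}"
        )
    resid = np.log10(track.scores[eligible]) + np.log10(d[eligible])
    intercept = float(resid.mean())
    stderr = float(resid.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return DecayFit(
        intercept=intercept,
        fixed_slope=-1.0,
        n_points=n,
        fit_range=(float(params.fit_min_distance), float(params.fit_max_distance)),
        stderr=stderr,
    )


def profile_correct(
    track: ScoreTrack, fit: DecayFit, params: SignalParams | None = None
) -> ScoreTrack:
    """Divide normalized scores by the fitted expected decay 10^a / d.

    Fragments closer to the bait than the fit range are still corrected but
    flagged in ``track.extrapolated``. A fragment at distance 0 means the
    bait fragment survived exclusion and is an error. Zero scores stay zero.
    """
    _require_stage(track, "normalized", "profile_correct")
    d = track.distances()
    if np.any(d == 0):
        raise ValueError(
            "fragment at zero bait distance: viewpoint exclusion was not applied"
        )
    corrected = track.scores / fit.expected(d)
    new = track.with_scores(corrected, "profile_corrected", decay_intercept=fit.intercept)
    new.extrapolated = d < fit.fit_range[0]
    return new


def process_replicate(
    raw: ScoreTrack,
    excluded: Region | None = None,
    params: SignalParams | None = None,
) -> dict[str, ScoreTrack]:
    """Run one raw track through exclusion and all signal stages.

    Returns {'raw': post-exclusion raw, 'normalized', 'smoothed',
    'profile_corrected'} tracks; smoothing and profile correction both start
    from the unsmoothed normalized track.
    """
    from .scoring import exclude_viewpoint

    params = params or SignalParams()
    if excluded is not None:
        raw = exclude_viewpoint(raw, excluded)
    normalized = normalize_local_mean(raw, params)
    smoothed = running_mean(normalized, params)
    fit = fit_decay(normalized, params)
    corrected = profile_correct(normalized, fit, params)
    corrected.meta["decay_fit"] = fit
    return {
        "raw": raw,
        "normalized": normalized,
        "smoothed": smoothed,
        "profile_corrected": corrected,
    }
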