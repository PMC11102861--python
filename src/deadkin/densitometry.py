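"""Gel-lane densitometry: band segmentation, quantification, normalization.

A denaturing gel resolves the deadenylation intermediates into a ladder of
bands, one per species.  The input contract here is the 1D lane profile
(pixel intensities summed across the lane width, one value per pixel row
along the migration axis); a rectangular image region is collapsed by
row-sum first.  Band boundaries are located at local maxima of the discrete
second difference of the (lightly smoothed) profile — the curvature peaks
at the valleys between bands.  Each species' intensity is the maximum
profile value inside its segment.

Unity-based normalization (division by the global maximum) produces the
matrix used for rate fitting; column-wise normalization is for heatmap
display only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator, TransformerMixin

from .kinetics import TimeCourseMatrix

__all__ = [
    "LaneProfile",
    "BandSegmentation",
    "find_band_boundaries",
    "quantify_bands",
    "normalize_assay",
    "normalize_columns",
    "BandQuantifier",
    "UnityNormalizer",
    "ColumnNormalizer",
]


@dataclass
class LaneProfile:
    """1D intensity profile along the migration axis (top row first)."""

    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim == 2:
            # rectangular lane region: collapse across the lane width
            self.intensity = self.intensity.sum(axis=1)
        if self.intensity.ndim != 1 or self.intensity.size < 4:
            raise ValueError("lane profile must be a 1D vector of length >= 4")
        if np.any(self.intensity < 0):
            raise ValueError("lane intensities must be nonnegative")

    def __len__(self) -> int:
        return self.intensity.size


@dataclass
class BandSegmentation:
    """Ordered internal boundaries partitioning a profile into band segments.

    ``boundaries`` holds ``n_bands - 1`` strictly increasing row indices;
    segment ``k`` (0-based, species index ``k + 1``) covers rows
    ``[boundaries[k-1], boundaries[k])`` with the outer segments extended
    to the profile ends.  Segments are non-overlapping and exhaustive.
    """

    boundaries: np.ndarray
    n_rows: int

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if self.boundaries.size and (
            self.boundaries[0] <= 0 or self.boundaries[-1] >= self.n_rows
        ):
            raise ValueError("boundaries must lie strictly inside the profile")

    @property
    def n_bands(self) -> int:
        return self.boundaries.size + 1

    def segments(self) -> list[tuple[int, int]]:
        edges = np.concatenate(([0], self.boundaries, [self.n_rows]))
        return [(int(edges[k]), int(edges[k + 1])) for k in range(self.n_bands)]


def _second_difference(y: np.ndarray) -> np.ndarray:
    """Discrete second difference, padded to the input length."""
    d2 = np.zeros_like(y)
    d2[1:-1] = y[:-2] - 2 * y[1:-1] + y[2:]
    return d2


def find_band_boundaries(
    profile: LaneProfile | np.ndarray,
    expected_bands: int,
    smooth_width: int = 3,
    overrides: dict[int, int] | None = None,
) -> BandSegmentation:
    """Segment a lane profile into ``expected_bands`` band segments.

    Separator candidates are the profile minima between bands of the
    smoothed profile, ranked by the discrete second difference there (for
    overlapping bands the curvature peaks exactly at the inter-band
    valley; for resolved bands it degrades gracefully to zero and the
    minimum alone decides).  The ``expected_bands - 1`` highest-curvature
    candidates are kept; among equally scored candidates the subset
    giving the most even segment widths wins, reflecting the
    near-uniform single-nucleotide band spacing of the gels.
    ``overrides`` maps boundary index (0-based, top to bottom) to a
    replacement row, standing in for the manual boundary curation done on
    real gels.
    """
    if not isinstance(profile, LaneProfile):
        profile = LaneProfile(profile)
    y = profile.intensity
    if expected_bands < 1:
        raise ValueError("expected_bands must be >= 1")
    if y.size <= 3 * expected_bands:
        raise ValueError(
            f"profile of length {y.size} too short for {expected_bands} bands"
        )
    needed = expected_bands - 1
    if needed == 0:
        return BandSegmentation(np.array([], dtype=int), y.size)

    if smooth_width > 1:
        y = uniform_filter1d(y, size=smooth_width, mode="nearest")
    d2 = _second_difference(y)
    # separators sit at the profile minima between bands, where the second
    # difference peaks; plateau minima (fully resolved bands with a flat gap)
    # are taken at their midpoint
    cand, _ = find_peaks(-y, plateau_size=1)
    if cand.size < needed:
        if np.ptp(profile.intensity) == 0:
            raise ValueError("flat profile: no band structure to segment")
        raise ValueError(
            f"found only {cand.size} candidate separators, need {needed} "
            f"({needed - cand.size} short)"
        )

    scores = d2[cand]
    if cand.size == needed:
        chosen = np.sort(cand)
    else:
        order = np.argsort(scores)[::-1]
        cutoff = scores[order[needed - 1]]
        sure = cand[scores > cutoff]
        tied = np.sort(cand[scores == cutoff])
        k = needed - sure.size
        chosen = np.sort(np.concatenate([sure, _most_even_subset(sure, tied, k, y.size)]))
    for idx, row in (overrides or {}).items():
        if not 0 <= idx < needed:
            raise ValueError(f"override index {idx} outside 0..{needed - 1}")
        chosen[idx] = row
    chosen = np.sort(chosen)
    return BandSegmentation(chosen, y.size)


def _most_even_subset(sure, tied, k, n_rows) -> np.ndarray:
    """Pick k of the tied candidates minimizing segment-width variance."""
    from itertools import combinations

    if k <= 0:
        return np.array([], dtype=int)
    if len(tied) == k:
        return tied
    best, best_var = None, np.inf
    for combo in combinations(tied, k):
        edges = np.sort(np.concatenate([[0], sure, combo, [n_rows]]))
        var = np.var(np.diff(edges))
        if var < best_var:
            best, best_var = np.array(combo), var
    return best


def quantify_bands(
    profile: LaneProfile | np.ndarray, seg: BandSegmentation
) -> np.ndarray:
    """Per-species intensity: the maximum profile value in each segment."""
    if not isinstance(profile, LaneProfile):
        profile = LaneProfile(profile)
    if seg.n_rows != len(profile):
        raise ValueError("segmentation does not match profile length")
    out = np.empty(seg.n_bands)
    for k, (lo, hi) in enumerate(seg.segments()):
        if hi <= lo:
            raise ValueError(f"segment {k} is empty")
        out[k] = profile.intensity[lo:hi].max()
    return out


def normalize_assay(tc: TimeCourseMatrix) -> TimeCourseMatrix:
    """Unity-based normalization over the whole assay (the fitting target).

    Every entry is divided by the global maximum, so the output lies in
    [0, 1] with maximum exactly 1.  Idempotent and scale-invariant.
    """
    m = tc.values.max()
    if m <= 0:
        raise ValueError("cannot normalize an all-zero matrix")
    return TimeCourseMatrix(tc.values / m, tc.times, normalized="assay")


def normalize_columns(tc: TimeCourseMatrix) -> TimeCourseMatrix:
    """Column-specific unity normalization, for heatmap display only."""
    maxes = tc.values.max(axis=0)
    out = tc.values.copy()
    zero = maxes <= 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} zero column(s) left at zero during column "
            "normalization",
            stacklevel=2,
        )
    nz = ~zero
    out[:, nz] = out[:, nz] / maxes[nz]
    return TimeCourseMatrix(out, tc.times, normalized="columns")


class BandQuantifier(BaseEstimator, TransformerMixin):
    """Estimator wrapper: learn a segmentation, then quantify lanes.

    ``fit`` locates band boundaries on a reference profile (typically the
    marker lane or the first time point); ``transform`` applies the learnt
    segmentation to one or more lane profiles and returns the per-species
    intensity vectors, stacked species x lane.
    """

    def __init__(self, expected_bands: int = 21, smooth_width: int = 3, overrides=None):
        self.expected_bands = expected_bands
        self.smooth_width = smooth_width
        self.overrides = overrides

    def fit(self, X, y=None):
        profile = X[0] if isinstance(X, (list, tuple)) else X
        self.segmentation_ = find_band_boundaries(
            profile, self.expected_bands, self.smooth_width, self.overrides
        )
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "segmentation_"):
            raise RuntimeError("BandQuantifier must be fit before transform")
        profiles = X if isinstance(X, (list, tuple)) else [X]
        return np.column_stack([quantify_bands(p, self.segmentation_) for p in profiles])


class _StatelessNormalizer(BaseEstimator, TransformerMixin):
    def fit(self, X, y=None):
        return self


class UnityNormalizer(_StatelessNormalizer):
    """Transformer form of :func:`normalize_assay`."""

    def transform(self, X: TimeCourseMatrix) -> TimeCourseMatrix:
        return normalize_assay(X)


class ColumnNormalizer(_StatelessNormalizer):
    """Transformer form of :func:`normalize_columns`."""

    def transform(self, X: TimeCourseMatrix) -> TimeCourseMatrix:
        return normalize_columns(X)
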