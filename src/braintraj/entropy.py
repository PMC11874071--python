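"""Sample entropy of voxel time series and regional aggregation.

Sample entropy (SampEn) quantifies the irregularity of a time series as
``-ln(A/B)``, where ``B`` counts pairs of distinct length-``m`` templates
whose Chebyshev distance is at most ``r`` and ``A`` counts the same for
length-``m+1`` templates. Self-matches are excluded. Higher values mean
fewer repeating patterns (more irregular signal); the measure is bounded
below by 0 because every (m+1)-match is also an m-match.

Conventions fixed here (documented in docs/methods.md):

* the tolerance is ``r_frac`` times the sample SD (n-1 denominator) of each
  series' own coarse-grained values, making SampEn invariant to affine
  rescaling of the signal;
* both template lengths use the same ``N - m`` starting positions, so A and
  B count over comparable sets (the standard estimator);
* a constant series has SampEn 0; if no template pair matches at either
  length the value is undefined (NaN) and excluded from regional averages.

The pairwise counting is O(N^2) per series and runs through a numba-compiled
kernel when numba is importable, with an equivalent vectorized numpy
fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, LengthError, ParameterError
from .io import BoldVolume, Parcellation

logger = logging.getLogger(__name__)

try:  # pragma: no cover - exercised implicitly
    import numba

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False


@dataclass
class EntropyParams:
    """SampEn parameters: embedding dimension m, tolerance fraction, coarse-graining scale."""

    m: int = 1
    r_frac: float = 0.15
    scale: int = 1

    def __post_init__(self) -> None:
        if not (isinstance(self.m, (int, np.integer)) and self.m >= 1):
            raise ParameterError(f"embedding dimension m must be a positive integer, got {self.m}")
        if not (self.r_frac > 0):
            raise ParameterError(f"tolerance fraction must be positive, got {self.r_frac}")
        if not (isinstance(self.scale, (int, np.integer)) and self.scale >= 1):
            raise ParameterError(f"scale factor must be a positive integer, got {self.scale}")


@dataclass
class RegionalEntropyProfile:
    """Per-subject regional mean SampEn plus whole-brain summary."""

    subject_id: str
    region_entropy: dict[int, float]       # region id -> mean SampEn over defined voxels (NaN if none)
    whole_brain: float
    n_voxels_used: dict[int, int] = field(default_factory=dict)
    n_voxels_dropped: dict[int, int] = field(default_factory=dict)


def coarse_grain(series, scale: int) -> np.ndarray:
    """Nonoverlapping block means of length ``scale``; scale=1 is the identity."""
    if not (isinstance(scale, (int, np.integer)) and scale >= 1):
        raise ParameterError(f"scale must be a positive integer, got {scale}")
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1:
        raise ParameterError("series must be one-dimensional")
    if x.size < scale:
        raise LengthError(f"series length {x.size} < scale {scale}")
    if scale == 1:
        return x.copy()
    n_blocks = x.size // scale
    return x[: n_blocks * scale].reshape(n_blocks, scale).mean(axis=1)


def _sampen_counts_numpy(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Template-pair counts (A, B) via vectorized pair masks (memory O(N^2))."""
    n = x.size
    n_templates = n - m  # same start positions for both lengths
    # Chebyshev distance over the first m coordinates for all pairs of starts.
    d_m = np.zeros((n_templates, n_templates))
    for k in range(m):
        d_m = np.maximum(d_m, np.abs(x[k:k + n_templates, None] - x[None, k:k + n_templates]))
    d_m1 = np.maximum(d_m, np.abs(x[m:m + n_templates, None] - x[None, m:m + n_templates]))
    iu = np.triu_indices(n_templates, k=1)
    b = int(np.count_nonzero(d_m[iu] <= r))
    a = int(np.count_nonzero(d_m1[iu] <= r))
    return a, b


if HAVE_NUMBA:

    @numba.njit(cache=True)
    def _sampen_counts_kernel(x, m, r):  # pragma: no cover - compiled
        n = x.size
        n_templates = n - m
        a = 0
        b = 0
        for i in range(n_templates):
            for j in range(i + 1, n_templates):
                d = 0.0
                for k in range(m):
                    dk = abs(x[i + k] - x[j + k])
                    if dk > d:
                        d = dk
                if d <= r:
                    b += 1
                    if abs(x[i + m] - x[j + m]) <= r:
                        a += 1
        return a, b

    def _sampen_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
        a, b = _sampen_counts_kernel(np.ascontiguousarray(x), m, r)
        return int(a), int(b)

else:
    _sampen_counts = _sampen_counts_numpy


def sample_entropy(series, params: EntropyParams | None = None) -> float:
    """SampEn of one series; NaN when undefined (no matching template pairs).

    The series is coarse-grained first; the tolerance is ``r_frac`` times the
    sample SD of the coarse-grained series. A constant series returns 0 (the
    r -> 0+ limit where all distances are zero).
    """
    p = params if params is not None else EntropyParams()
    x = coarse_grain(series, p.scale)
    n = x.size
    if n < p.m + 2:
        raise LengthError(f"coarse-grained length {n} < m + 2 = {p.m + 2}")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return 0.0
    r = p.r_frac * sd
    a, b = _sampen_counts(x, p.m, r)
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


def sample_entropy_many(X: np.ndarray, params: EntropyParams | None = None) -> np.ndarray:
    """SampEn for each row of a (voxels x timepoints) matrix."""
    p = params if params is not None else EntropyParams()
    X = np.asarray(X, dtype=np.float64)
    out = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        out[i] = sample_entropy(X[i], p)
    return out


def select_m(min_series_length: int) -> int:
    """Largest embedding dimension m with 10^m strictly below the shortest series."""
    if not (isinstance(min_series_length, (int, np.integer)) and min_series_length > 10):
        raise ParameterError(
            f"no admissible m: shortest series length must exceed 10, got {min_series_length}")
    m = 1
    while 10 ** (m + 1) < min_series_length:
        m += 1
    return m


def regional_profile(vol: BoldVolume, parc: Parcellation,
                     params: EntropyParams | None = None,
                     voxel_weighted_whole_brain: bool = False) -> RegionalEntropyProfile:
    """Aggregate per-voxel SampEn to regional means and a whole-brain summary.

    Region value = arithmetic mean of the defined voxel values within the
    region's labels, over masked voxels. Voxels with undefined SampEn are
    dropped from the mean and counted. The whole-brain summary is by default
    the unweighted mean of the regional means; a voxel-weighted alternative
    (mean over all defined voxels) is available.
    """
    p = params if params is not None else EntropyParams()
    if vol.data.shape[:3] != parc.labels.shape:
        raise AlignmentError(
            f"BOLD spatial shape {vol.data.shape[:3]} != parcellation shape {parc.labels.shape}")
    mask = vol.voxel_mask & (parc.labels > 0)
    series = vol.data[mask]                    # (n_voxels, t)
    voxel_labels = parc.labels[mask]
    values = sample_entropy_many(series, p) if series.size else np.empty(0)

    region_entropy: dict[int, float] = {}
    n_used: dict[int, int] = {}
    n_dropped: dict[int, int] = {}
    for rid in parc.region_ids:
        v = values[voxel_labels == rid]
        defined = v[np.isfinite(v)]
        n_used[rid] = int(defined.size)
        n_dropped[rid] = int(v.size - defined.size)
        if defined.size == 0:
            region_entropy[rid] = float("nan")
            logger.warning("subject %s region %d: no defined voxel SampEn values",
                           vol.subject_id, rid)
        else:
            region_entropy[rid] = float(defined.mean())

    region_values = np.array(list(region_entropy.values()))
    if voxel_weighted_whole_brain:
        defined_all = values[np.isfinite(values)]
        whole = float(defined_all.mean()) if defined_all.size else float("nan")
    else:
        defined_regions = region_values[np.isfinite(region_values)]
        whole = float(defined_regions.mean()) if defined_regions.size else float("nan")
    return RegionalEntropyProfile(subject_id=vol.subject_id, region_entropy=region_entropy,
                                  whole_brain=whole, n_voxels_used=n_used,
                                  n_voxels_dropped=n_dropped)


def profiles_to_frame(profiles: list[RegionalEntropyProfile]) -> "pd.DataFrame":
    """One row per subject; columns R<id> per region plus whole_brain."""
    import pandas as pd

    rows = []
    for p in profiles:
        row = {"subject_id": p.subject_id}
        row.update({f"R{rid}": v for rid, v in sorted(p.region_entropy.items())})
        row["whole_brain"] = p.whole_brain
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")
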