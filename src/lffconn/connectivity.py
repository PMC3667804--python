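"""Seed-based correlation mapping and supra-threshold voxel statistics.

The significance machinery follows the classic low-frequency-fluctuation
convention: after ideal low-pass filtering at cutoff ``fc`` the series of
``N`` samples at repetition time ``TR`` retains a fraction ``2 fc TR`` of
its spectrum, so the effective degrees of freedom for a Pearson correlation
are::

    nu = N * 2 * fc * TR - 2

and a correlation magnitude r is significant at one-sided level p when
``t = r * sqrt(nu / (1 - r^2))`` exceeds the upper-p quantile of the t
distribution with nu degrees of freedom.  The bandwidth-ratio rule is exact
for the ideal filter used here (validated against a Monte-Carlo null in the
test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateSeedError, ParameterError, SampleSizeError
from .io import BoldRun, RoiSpec, roi_to_voxels

__all__ = [
    "CorrelationMap",
    "SessionResult",
    "seed_reference",
    "correlation_map",
    "effective_df",
    "r_critical",
    "count_significant",
    "normalize_counts",
    "group_tmap",
]


@dataclass
class CorrelationMap:
    """Per-voxel Pearson correlation with a seed reference.

    ``r`` is NaN at voxels whose timecourse has zero variance (undefined,
    deliberately distinct from 0).
    """

    r: np.ndarray
    effective_df: float
    p_threshold: float
    r_critical: float
    seed: RoiSpec | None = None

    @property
    def significant(self) -> np.ndarray:
        """Boolean volume of defined voxels with r >= r_critical (ties count)."""
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.r, nan=-np.inf) >= self.r_critical


@dataclass
class SessionResult:
    """Supra-threshold voxel counts for one rat-session, per region mask."""

    rat_id: str
    condition: str
    seed_name: str
    counts: dict[str, int]
    normalized: dict[str, float] = field(default_factory=dict)


def seed_reference(run: BoldRun, roi: RoiSpec) -> np.ndarray:
    """Mean timecourse over the ROI voxels of an already-preprocessed run.

    No variance normalization is applied (Pearson correlation is
    scale-invariant).  Raises :class:`DegenerateSeedError` if the mean
    series has zero variance.
    """
    idx = roi_to_voxels(roi, run.geometry)
    tcs = run.data[idx[:, 0], idx[:, 1], idx[:, 2], :]
    ref = tcs.mean(axis=0)
    if np.ptp(ref) == 0:
        raise DegenerateSeedError(
            f"seed {roi.name!r}: ROI mean timecourse has zero variance"
        )
    return ref


def correlation_map(
    run: BoldRun,
    reference: np.ndarray,
    p_threshold: float = 2.5e-5,
    cutoff_hz: float = 0.08,
    sidedness: str = "one",
) -> CorrelationMap:
    """Voxel-wise lag-0 Pearson correlation of a preprocessed run with a reference.

    The significance threshold recorded on the map uses the effective
    degrees of freedom of the filtered series (see :func:`effective_df`).
    Zero-variance voxels get r = NaN.
    """
    reference = np.asarray(reference, dtype=np.float64)
    if reference.ndim != 1 or reference.size != run.data.shape[3]:
        raise ParameterError(
            f"reference length {reference.size} != run time length {run.data.shape[3]}"
        )
    ref = reference - reference.mean()
    ref_ss = float(ref @ ref)
    if ref_ss == 0:
        raise DegenerateSeedError("reference timecourse has zero variance")

    flat = run.data.reshape(-1, run.data.shape[3]).astype(np.float64)
    centered = flat - flat.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", centered, centered)
    cov = centered @ ref
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(ss * ref_ss)
    r[ss == 0] = np.nan
    r = np.clip(r, -1.0, 1.0, out=r)

    df = effective_df(run.n_volumes, run.tr_s, cutoff_hz)
    rc = r_critical(p_threshold, df, sidedness)
    return CorrelationMap(
        r=r.reshape(run.data.shape[:3]),
        effective_df=df,
        p_threshold=p_threshold,
        r_critical=rc,
    )


def effective_df(n_timepoints: int, tr_s: float, cutoff_hz: float) -> float:
    """Effective degrees of freedom of a low-pass-filtered correlation.

    ``nu = N * (2 * fc * TR) - 2``: the sample count scaled by the retained
    spectral fraction, minus 2 for the correlation.  Requires nu >= 3.
    """
    nyquist = 1.0 / (2.0 * tr_s)
    if cutoff_hz >= nyquist - 1e-15:
        raise ParameterError(f"cutoff {cutoff_hz} Hz must be below Nyquist {nyquist:g} Hz")
    if cutoff_hz <= 0:
        raise ParameterError("cutoff must be positive")
    df = n_timepoints * (2.0 * cutoff_hz * tr_s) - 2.0
    if df < 3:
        raise ParameterError(
            f"effective df {df:.2f} < 3: series too short or band too narrow "
            f"(n={n_timepoints}, TR={tr_s}, cutoff={cutoff_hz})"
        )
    return df


def r_critical(p_threshold: float, effective_df: float, sidedness: str = "one") -> float:
    """Correlation magnitude whose t statistic attains tail probability p.

    One-sided positive by default (the pipeline counts *synchronized*, i.e.
    positively correlated, voxels); ``sidedness='two'`` uses p/2 per tail.
    """
    if not 0 < p_threshold < 1:
        raise ParameterError(f"p threshold must be in (0, 1), got {p_threshold}")
    if effective_df < 3:
        raise ParameterError(f"effective df must be >= 3, got {effective_df}")
    if sidedness not in ("one", "two"):
        raise ParameterError(f"sidedness must be 'one' or 'two', got {sidedness!r}")
    p = p_threshold if sidedness == "one" else p_threshold / 2.0
    t = stats.t.isf(p, effective_df)
    if t <= 0:
        return 0.0
    return float(t / np.sqrt(t * t + effective_df))


def count_significant(cmap: CorrelationMap, region_mask: np.ndarray) -> int:
    """Number of mask voxels with r >= r_critical; NaN voxels never count."""
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != cmap.r.shape:
        raise ParameterError(
            f"mask shape {region_mask.shape} != map shape {cmap.r.shape}"
        )
    return int(np.count_nonzero(cmap.significant & region_mask))


def normalize_counts(
    session_counts: dict[str, int], preop_counts: dict[str, int]
) -> dict[str, float]:
    """Per-region count / preoperative count; NaN where the preop count is 0."""
    out: dict[str, float] = {}
    for region, c in session_counts.items():
        pre = preop_counts.get(region, 0)
        out[region] = float(c) / pre if pre > 0 else float("nan")
    return out


def group_tmap(
    per_rat_maps: list[CorrelationMap], p_threshold: float = 0.001
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-wise one-sample group test of Fisher-z-transformed correlations.

    Each rat's r map is Fisher z-transformed and tested against 0 across
    rats (one-sided positive).  Returns ``(t, p, significant)`` volumes;
    voxels that are undefined in any rat, or have zero between-rat variance
    with a nonzero mean, are NaN in t and p.  The all-zero degenerate case
    yields t = 0, p = 1.
    """
    if len(per_rat_maps) < 3:
        raise SampleSizeError(f"need >= 3 rats for a group map, got {len(per_rat_maps)}")
    shape = per_rat_maps[0].r.shape
    for m in per_rat_maps:
        if m.r.shape != shape:
            raise ParameterError("all correlation maps must share one grid")
    rs = np.stack([m.r for m in per_rat_maps], axis=0)
    rs = np.clip(rs, -1.0 + 1e-12, 1.0 - 1e-12)
    z = np.arctanh(rs)
    k = z.shape[0]
    mean = z.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    t = np.full(shape, np.nan)
    p = np.full(shape, np.nan)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(k))
    p[ok] = stats.t.sf(t[ok], k - 1)
    degenerate_null = (~ok) & (mean == 0)
    t[degenerate_null] = 0.0
    p[degenerate_null] = 1.0
    undefined = np.isnan(rs).any(axis=0)
    t[undefined] = np.nan
    p[undefined] = np.nan
    with np.errstate(invalid="ignore"):
        significant = np.nan_to_num(p, nan=1.0) < p_threshold
    return t, p, significant
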