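"""Accuracy/precision scoring of acquisition schemes and comparisons.

Accuracy is the root mean squared difference (RMSD) between bootstrap
samples and the fully-sampled reference; precision is the standard deviation
across bootstrap samples, with precision defined as SD^-2.  Angular metrics
(helix and sheetlet angles) are axial quantities with period 180°, so
differences are wrapped to (-90°, 90°] and SDs are taken about the circular
(doubled-angle) mean; both wrapped and plain variants are available because
published pipelines rarely state which they use.

Scheme comparisons use paired t-tests across replicates with Bonferroni-Holm
multiplicity correction, plus normal-approximation confidence intervals of
means over pooled bootstrap samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ANGULAR_METRICS",
    "wrapped_difference",
    "rmsd_map",
    "sd_map",
    "precision_map",
    "roi_mean",
    "sector_labels",
    "holm_adjust",
    "paired_comparison_matrix",
    "percent_change",
    "ci_mean",
    "summarize_run",
    "ComparisonReport",
]

#: Metrics treated as axial angles (period 180 degrees).
ANGULAR_METRICS = frozenset({"ha", "e2a"})


class EvaluateError(ValueError):
    """Invalid evaluation request."""


def _is_angular(metric_kind: str) -> bool:
    if metric_kind in ANGULAR_METRICS or metric_kind == "angular":
        return True
    if metric_kind in {"md", "fa", "abs_e2a", "linear"}:
        return False
    raise EvaluateError(f"unknown metric kind {metric_kind!r}")


def wrapped_difference(a, b):
    """Axial difference a - b wrapped to (-90, 90] degrees.

    The minimal-magnitude equivalent modulo 180° with sign preserved, e.g.
    89° vs -89° gives +2°.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    out = -(np.mod(-d + 90.0, 180.0)) + 90.0
    return float(out) if np.ndim(out) == 0 else out


def rmsd_map(samples: np.ndarray, reference: np.ndarray, metric_kind: str) -> np.ndarray:
    """Per-voxel RMSD of bootstrap samples against the reference map.

    ``samples`` is (S, V), ``reference`` (V,).  Angular metrics use wrapped
    differences.
    """
    s = np.atleast_2d(np.asarray(samples, dtype=float))
    r = np.asarray(reference, dtype=float)
    delta = wrapped_difference(s, r[None, :]) if _is_angular(metric_kind) else s - r
    return np.sqrt(np.mean(delta**2, axis=0))


def _circular_axial_mean(samples: np.ndarray) -> np.ndarray:
    """Mean of axial angles (degrees, period 180) via the doubled-angle map."""
    two = np.deg2rad(2.0 * samples)
    mean = np.arctan2(np.sin(two).mean(axis=0), np.cos(two).mean(axis=0))
    return np.rad2deg(mean) / 2.0


def sd_map(samples: np.ndarray, metric_kind: str, wrapped: bool = True) -> np.ndarray:
    """Per-voxel SD across bootstrap samples (n-1 denominator).

    For angular metrics (with ``wrapped=True``) deviations are wrapped about
    the circular-aware axial mean before the SD.
    """
    s = np.atleast_2d(np.asarray(samples, dtype=float))
    if s.shape[0] < 2:
        raise EvaluateError("SD requires at least 2 samples")
    if _is_angular(metric_kind) and wrapped:
        center = _circular_axial_mean(s)
        dev = wrapped_difference(s, center[None, :])
        return np.sqrt((dev**2).sum(axis=0) / (s.shape[0] - 1))
    return s.std(axis=0, ddof=1)


def precision_map(samples: np.ndarray, metric_kind: str) -> np.ndarray:
    """Precision = SD^-2; +inf where samples are identical."""
    sd = sd_map(samples, metric_kind)
    with np.errstate(divide="ignore"):
        return np.where(sd > 0, 1.0 / np.where(sd > 0, sd, 1.0) ** 2, np.inf)


# ---------------------------------------------------------------------------
# ROI aggregation with sector exclusion
# ---------------------------------------------------------------------------


def sector_labels(
    coords: np.ndarray, center: np.ndarray, n_sectors: int = 12
) -> np.ndarray:
    """Assign each voxel to one of ``n_sectors`` equal azimuth wedges about
    the LV center (wedge 0 starts at azimuth -180°)."""
    xy = np.asarray(coords, dtype=float)
    az = np.arctan2(xy[:, 1] - center[1], xy[:, 0] - center[0])
    lab = np.floor((az + np.pi) / (2 * np.pi / n_sectors)).astype(int)
    return np.clip(lab, 0, n_sectors - 1)


def roi_mean(
    values: np.ndarray,
    coords: np.ndarray | None = None,
    center: np.ndarray | None = None,
    excluded_sectors: tuple[int, ...] = (),
    included_sectors: tuple[int, ...] | None = None,
    n_sectors: int = 12,
) -> float:
    """Voxel mean over the ROI, skipping excluded azimuth sectors.

    ``included_sectors`` (e.g. two contiguous wedges as a septal ROI
    stand-in) restricts the ROI before exclusions are applied.  NaN voxels
    (undefined angles) are ignored.  An empty effective ROI is an error.
    """
    vals = np.asarray(values, dtype=float).ravel()
    keep = np.ones(vals.size, dtype=bool)
    if excluded_sectors or included_sectors is not None:
        if coords is None or center is None:
            raise EvaluateError("sector selection needs voxel coords and center")
        lab = sector_labels(coords, center, n_sectors)
        if included_sectors is not None:
            keep &= np.isin(lab, included_sectors)
        if excluded_sectors:
            keep &= ~np.isin(lab, excluded_sectors)
    kept = vals[keep]
    kept = kept[np.isfinite(kept)]
    if kept.size == 0:
        raise EvaluateError("empty ROI after sector exclusion")
    return float(kept.mean())


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def holm_adjust(pvalues) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values (original order)."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise EvaluateError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def ci_mean(samples: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation CI of the mean over pooled samples."""
    s = np.asarray(samples, dtype=float).ravel()
    s = s[np.isfinite(s)]
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * s.std(ddof=1) / np.sqrt(s.size)
    mean = s.mean()
    return (float(mean - half), float(mean + half))


def percent_change(a, b):
    """100 * (a - b) / b; negative when ``a`` improves on ``b`` (smaller)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(b == 0):
        raise EvaluateError("zero denominator in percent change")
    out = 100.0 * (a - b) / b
    return float(out) if out.ndim == 0 else out


@dataclass
class ComparisonReport:
    """Pairwise paired-t comparison of schemes for one statistic.

    Matrices are symmetric with p = 1 on the diagonal (a scheme compared
    with itself); ``p_adjusted`` applies Holm correction over the upper
    triangle of the matrix.
    """

    schemes: list[str]
    p_raw: np.ndarray
    p_adjusted: np.ndarray

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return self.p_adjusted < alpha


def paired_comparison_matrix(values_by_scheme: dict[str, np.ndarray]) -> ComparisonReport:
    """Paired t-tests between every pair of schemes across replicates.

    ``values_by_scheme`` maps scheme name to an aligned (R,) array of
    per-replicate statistics (the same replicates for every scheme).  Zero
    paired differences (a scheme against itself) give p = 1 by convention.
    """
    names = list(values_by_scheme)
    arrays = [np.asarray(values_by_scheme[n], dtype=float).ravel() for n in names]
    r = arrays[0].size
    if any(a.size != r for a in arrays):
        raise EvaluateError("replicate arrays must be aligned (equal length)")
    if r < 3:
        raise EvaluateError("paired comparison needs >= 3 replicates")
    k = len(names)
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            diff = arrays[i] - arrays[j]
            if np.allclose(diff, 0.0):
                pij = 1.0
            else:
                pij = float(stats.ttest_rel(arrays[i], arrays[j]).pvalue)
            p[i, j] = p[j, i] = pij
    iu = np.triu_indices(k, 1)
    adj = np.ones((k, k))
    if iu[0].size:
        adj_flat = holm_adjust(p[iu])
        adj[iu] = adj_flat
        adj[(iu[1], iu[0])] = adj_flat
    return ComparisonReport(schemes=names, p_raw=p, p_adjusted=adj)


# ---------------------------------------------------------------------------
# Bootstrap summaries
# ---------------------------------------------------------------------------


def summarize_run(
    metric_samples: np.ndarray,
    metric_names: tuple[str, ...],
    reference: dict[str, np.ndarray],
    coords: np.ndarray | None = None,
    center: np.ndarray | None = None,
    excluded_sectors: tuple[int, ...] = (),
    scheme: str = "",
) -> pd.DataFrame:
    """Tidy per-metric summary of one bootstrap run.

    For each metric: ROI means of the per-voxel mean, RMSD versus the
    reference map, and SD across samples.  Returns rows
    ``(scheme, metric, statistic, value)``.
    """
    rows = []
    for m_i, name in enumerate(metric_names):
        samples = metric_samples[:, :, m_i]  # (S, V)
        ref = reference[name]
        kind = name if name in ANGULAR_METRICS else "linear"
        mean_vox = (
            _circular_axial_mean(samples) if kind != "linear" else samples.mean(axis=0)
        )
        stat_maps = {
            "mean": mean_vox,
            "rmsd": rmsd_map(samples, ref, kind),
            "sd": sd_map(samples, kind),
        }
        for stat, vox in stat_maps.items():
            rows.append(
                {
                    "scheme": scheme,
                    "metric": name,
                    "statistic": stat,
                    "value": roi_mean(
                        vox,
                        coords=coords,
                        center=center,
                        excluded_sectors=excluded_sectors,
                    ),
                }
            )
    return pd.DataFrame(rows)
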