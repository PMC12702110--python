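"""Cardiac DTI metrics: MD, FA, helix angle, sheetlet angle.

Angles are measured in a cylindrical coordinate system centered on the LV
blood pool, defined slice-wise: radial points outward from the center of
mass of the myocardial segmentation, longitudinal is the slice normal, and
circumferential completes the right-handed triad (counter-clockwise when
viewed from base).

Conventions (fixed constants of this package):

* helix angle HA: signed angle of the primary eigenvector's projection onto
  the circumferential-longitudinal plane, from circumferential toward
  longitudinal, in (-90°, 90°];
* sheetlet angle E2A: the primary eigenvector is first projected into the
  wall-tangent plane and flipped so its circumferential component is
  non-negative; the cross-myocyte direction is its 90° rotation within that
  plane (longitudinal-positive); E2A is the signed angle of the secondary
  eigenvector's projection onto the cross-myocyte/radial plane, from
  cross-myocyte toward radial, in (-90°, 90°].

All angle outputs are invariant to eigenvector sign flips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MetricMaps",
    "center_of_mass",
    "local_frame",
    "frame_field",
    "md",
    "fa",
    "helix_angle",
    "sheetlet_angle",
    "compute_metric_maps",
    "UNDEFINED_ANGLE",
]

#: Sentinel for angles whose defining projection is degenerate.
UNDEFINED_ANGLE = np.nan

_PROJ_TOL = 1e-6


class MetricError(ValueError):
    """Invalid input to a cardiac metric computation."""


@dataclass(frozen=True)
class MetricMaps:
    """Per-voxel cardiac DTI parameter maps (NaN outside the mask)."""

    md: np.ndarray
    fa: np.ndarray
    ha: np.ndarray
    e2a: np.ndarray

    @property
    def abs_e2a(self) -> np.ndarray:
        return np.abs(self.e2a)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "md": self.md,
            "fa": self.fa,
            "ha": self.ha,
            "e2a": self.e2a,
            "abs_e2a": self.abs_e2a,
        }


def center_of_mass(mask: np.ndarray) -> np.ndarray:
    """Unweighted centroid (voxel coords) of a slice mask."""
    if not np.any(mask):
        raise MetricError("empty mask has no center of mass")
    return np.argwhere(mask).mean(axis=0)


def local_frame(
    voxel: np.ndarray, center: np.ndarray, slice_normal: np.ndarray | None = None
) -> np.ndarray:
    """Orthonormal (radial, circumferential, longitudinal) triad at a voxel.

    Radial is the in-plane unit vector from the center to the voxel;
    longitudinal is the slice normal; circumferential = longitudinal x
    radial, so the triad is right-handed with determinant +1.
    """
    longi = np.array([0.0, 0.0, 1.0]) if slice_normal is None else np.asarray(
        slice_normal, dtype=float
    )
    longi = longi / np.linalg.norm(longi)
    v = np.zeros(3)
    v[:2] = np.asarray(voxel, dtype=float)[:2] - np.asarray(center, dtype=float)[:2]
    v -= (v @ longi) * longi
    norm = np.linalg.norm(v)
    if norm < _PROJ_TOL:
        raise MetricError("voxel coincides with the LV center; radial undefined")
    radial = v / norm
    circ = np.cross(longi, radial)
    return np.stack([radial, circ, longi])


def frame_field(mask: np.ndarray, center: np.ndarray | None = None) -> np.ndarray:
    """Local frames for every voxel of a slice grid (vectorized).

    Returns an (nx, ny, 3, 3) array of row-stacked (radial, circumferential,
    longitudinal) triads relative to ``center`` (default: mask centroid).
    """
    if center is None:
        center = center_of_mass(mask)
    nx, ny = mask.shape
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    dx = ii - center[0]
    dy = jj - center[1]
    az = np.arctan2(dy, dx)
    frames = np.zeros((nx, ny, 3, 3))
    frames[..., 0, 0] = np.cos(az)
    frames[..., 0, 1] = np.sin(az)
    frames[..., 1, 0] = -np.sin(az)
    frames[..., 1, 1] = np.cos(az)
    frames[..., 2, 2] = 1.0
    return frames


# ---------------------------------------------------------------------------
# Scalar invariants
# ---------------------------------------------------------------------------


def _clipped_eigvalsh(tensors: np.ndarray) -> np.ndarray:
    """Ascending eigenvalues with negatives clipped to 0 (fit noise repair)."""
    lam = np.linalg.eigvalsh(tensors)
    return np.clip(lam, 0.0, None)


def md(tensor: np.ndarray) -> np.ndarray | float:
    """Mean diffusivity: trace / 3.  Works on (..., 3, 3) stacks."""
    t = np.asarray(tensor, dtype=float)
    out = np.trace(t, axis1=-2, axis2=-1) / 3.0
    return float(out) if out.ndim == 0 else out


def fa(tensor: np.ndarray) -> np.ndarray | float:
    """Fractional anisotropy from eigenvalues (clipped at 0); FA(0) = 0."""
    t = np.asarray(tensor, dtype=float)
    lam = _clipped_eigvalsh(t)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(((lam - mean) ** 2).sum(axis=-1))
    den = np.sqrt((lam**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, np.sqrt(1.5) * num / np.where(den > 0, den, 1.0), 0.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Angles
# ---------------------------------------------------------------------------


def _wrap_half_turn(angle_deg: np.ndarray | float):
    """Wrap to the axial range (-90, 90]."""
    a = -np.mod(-np.asarray(angle_deg, dtype=float) + 90.0, 180.0) + 90.0
    return float(a) if np.ndim(a) == 0 else a


def helix_angle(e1: np.ndarray, frame: np.ndarray) -> float:
    """Helix angle of the primary eigenvector, degrees in (-90, 90].

    Projects ``e1`` onto the circumferential-longitudinal plane and measures
    the signed angle from circumferential toward longitudinal.  Invariant to
    ``e1 -> -e1``.  Returns NaN when ``e1`` is (numerically) radial.
    """
    radial, circ, longi = frame
    hc = float(np.dot(e1, circ))
    hl = float(np.dot(e1, longi))
    if np.hypot(hc, hl) < _PROJ_TOL:
        return UNDEFINED_ANGLE
    return _wrap_half_turn(np.rad2deg(np.arctan2(hl, hc)))


def _cross_myocyte(e1: np.ndarray, frame: np.ndarray) -> np.ndarray:
    """In-wall direction orthogonal to the myocyte axis.

    The projection of ``e1`` into the wall-tangent (circumferential-
    longitudinal) plane is flipped to non-negative circumferential component
    and rotated by 90° within the plane (longitudinal-positive result), which
    fixes the sheetlet-angle sign convention independent of eigenvector sign.
    """
    radial, circ, longi = frame
    hc = float(np.dot(e1, circ))
    hl = float(np.dot(e1, longi))
    norm = np.hypot(hc, hl)
    if norm < _PROJ_TOL:
        raise MetricError("myocyte axis is radial; cross-myocyte undefined")
    hc, hl = hc / norm, hl / norm
    if hc < 0 or (hc == 0 and hl < 0):
        hc, hl = -hc, -hl
    return -hl * circ + hc * longi


def sheetlet_angle(e2: np.ndarray, frame: np.ndarray, e1: np.ndarray) -> float:
    """Sheetlet angle E2A of the secondary eigenvector, degrees in (-90, 90].

    Signed angle between the projection of ``e2`` onto the
    cross-myocyte/radial plane and the cross-myocyte direction, positive
    toward radial.  Invariant to sign flips of both ``e1`` and ``e2``.
    Returns NaN for a degenerate projection.
    """
    radial = frame[0]
    cm = _cross_myocyte(e1, frame)
    pc = float(np.dot(e2, cm))
    pr = float(np.dot(e2, radial))
    if np.hypot(pc, pr) < _PROJ_TOL:
        return UNDEFINED_ANGLE
    return _wrap_half_turn(np.rad2deg(np.arctan2(pr, pc)))


def compute_metric_maps(
    tensors: np.ndarray,
    frames: np.ndarray,
    mask: np.ndarray | None = None,
) -> MetricMaps:
    """MD/FA/HA/E2A maps from a tensor field.

    ``tensors`` and ``frames`` are (..., 3, 3) aligned arrays; with a grid
    ``mask``, outputs are full-grid maps with NaN outside, otherwise flat
    per-voxel arrays.
    """
    t = np.asarray(tensors, dtype=float)
    f = np.asarray(frames, dtype=float)
    if mask is not None:
        t_flat = t[mask]
        f_flat = f[mask]
    else:
        t_flat = t.reshape(-1, 3, 3)
        f_flat = f.reshape(-1, 3, 3)

    md_v = md(t_flat)
    fa_v = fa(t_flat)
    lam, vec = np.linalg.eigh(t_flat)  # ascending
    e1s = vec[..., :, 2]
    e2s = vec[..., :, 1]
    ha_v = np.array(
        [helix_angle(e1, fr) for e1, fr in zip(e1s, f_flat)]
    )
    e2a_v = np.array(
        [
            sheetlet_angle(e2, fr, e1)
            for e1, e2, fr in zip(e1s, e2s, f_flat)
        ]
    )
    if mask is None:
        return MetricMaps(md=md_v, fa=fa_v, ha=ha_v, e2a=e2a_v)
    full = {}
    for key, flat in (("md", md_v), ("fa", fa_v), ("ha", ha_v), ("e2a", e2a_v)):
        grid = np.full(mask.shape, np.nan)
        grid[mask] = flat
        full[key] = grid
    return MetricMaps(**full)
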