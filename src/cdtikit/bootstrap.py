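"""Repetition bootknife: stratified bootstrap with jackknife-style removal.

Each diffusion-encoding direction (within each b-shell) is a stratum.  A
bootknife sample removes one uniformly chosen image from every active
stratum and then draws the requested number of images with replacement from
the remainder.  The removal corrects the small-sample variance
underestimation of the plain bootstrap, which matters here because strata
hold only a handful of repetitions.

Stratum draws consume independent seeded substreams, so adding or removing
strata does not perturb the sequences of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .cardiometrics import compute_metric_maps, frame_field
from .phantom import DWIStack
from .schemes import AcquisitionPlan
from .tensorfit import RobustFitConfig, design_matrix, fit_lls, fit_robust, fit_wls

__all__ = [
    "StratumPool",
    "BootstrapRun",
    "plan_strata",
    "bootknife_sample",
    "run_bootstrap",
    "METRIC_NAMES",
]

METRIC_NAMES = ("md", "fa", "ha", "e2a", "abs_e2a")


class BootstrapError(ValueError):
    """Invalid bootstrap request."""


@dataclass(frozen=True)
class StratumPool:
    """One stratum: the available volume indices and the requested count."""

    stratum_id: str
    indices: np.ndarray
    requested: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        if self.requested < 0:
            raise BootstrapError("requested count must be non-negative")
        if self.requested > 0 and idx.size < 2:
            raise BootstrapError(
                f"stratum {self.stratum_id}: pool of {idx.size} image(s) cannot "
                "support bootknife resampling (one image must be removable)"
            )
        if self.requested > idx.size:
            raise BootstrapError(
                f"stratum {self.stratum_id}: requested {self.requested} "
                f"repetitions but only {idx.size} acquired"
            )


@dataclass
class BootstrapRun:
    """Bootknife output: selections and per-sample metric values.

    ``metric_samples`` is (n_samples, V, len(METRIC_NAMES)) over masked
    voxels; ``selections`` lists each sample's chosen volume indices.
    """

    n_samples: int
    seed: int
    selections: list[np.ndarray]
    metric_samples: np.ndarray
    metric_names: tuple[str, ...] = METRIC_NAMES

    def metric(self, name: str) -> np.ndarray:
        """(n_samples, V) slice for one metric."""
        return self.metric_samples[:, :, self.metric_names.index(name)]


def _directions_match(d1: np.ndarray, d2: np.ndarray, tol: float = 1e-8) -> bool:
    return bool(abs(abs(float(d1 @ d2)) - 1.0) <= tol)


def plan_strata(
    stack: DWIStack, plan: AcquisitionPlan, seed: int = 0
) -> list[StratumPool]:
    """Stratum pools of a plan drawn from an acquired (or simulated) stack.

    For every plan direction with a positive repetition count, collects the
    stack volumes with the same b-value and (antipodally equivalent)
    direction.  Raises :class:`BootstrapError`, naming the stratum, when the
    stack cannot supply the requested repetitions.
    """
    pools: list[StratumPool] = []
    for sch, counts in plan.shells:
        for dir_i, requested in enumerate(counts):
            if requested == 0:
                continue
            d = sch.directions[dir_i]
            idxs = [
                i
                for i, (b, g) in enumerate(zip(stack.bvals, stack.bvecs))
                if abs(b - sch.b_value) < 1e-6 and _directions_match(d, g)
            ]
            pool = StratumPool(
                stratum_id=f"{sch.name}:b{sch.b_value:g}:d{dir_i}",
                indices=np.array(idxs, dtype=int),
                requested=int(requested),
            )
            pools.append(pool)
    return pools


def bootknife_sample(
    pools: list[StratumPool], seed: int, sample_index: int = 0
) -> np.ndarray:
    """One bootknife selection: per stratum, remove one random image, then
    draw the requested count with replacement from the remainder.

    Deterministic in ``(seed, sample_index)``; each stratum uses its own
    substream keyed by position, so selections in one stratum are unaffected
    by the composition of the others.
    """
    selected: list[np.ndarray] = []
    for pool in pools:
        if pool.requested == 0:
            continue
        # substream keyed by a stable hash of the stratum id, not position
        key = zlib.crc32(pool.stratum_id.encode()) & 0x7FFFFFFF
        rng = np.random.default_rng([seed & 0x7FFFFFFF, sample_index, key])
        removed = rng.integers(pool.indices.size)
        remainder = np.delete(pool.indices, removed)
        selected.append(rng.choice(remainder, size=pool.requested, replace=True))
    return np.concatenate(selected) if selected else np.array([], dtype=int)


_FITTERS = {"lls": fit_lls, "wls": fit_wls, "robust": fit_robust}


def run_bootstrap(
    stack: DWIStack,
    plan: AcquisitionPlan,
    mask: np.ndarray,
    n_samples: int = 500,
    seed: int = 0,
    fit_method: str = "robust",
    fit_config: RobustFitConfig | None = None,
    frames: np.ndarray | None = None,
    center: np.ndarray | None = None,
) -> BootstrapRun:
    """Bootknife resampling of a plan: selection -> tensor fit -> metrics.

    For each of ``n_samples`` samples, draws a bootknife selection from the
    plan's strata, fits the tensor to the selected volumes, and computes the
    cardiac metric maps on the masked voxels.  500 samples (the default) are
    ample for stable accuracy/precision estimates.
    """
    if fit_method not in _FITTERS:
        raise BootstrapError(f"unknown fit method {fit_method!r}")
    pools = plan_strata(stack, plan, seed=seed)
    signals_all = stack.volume_signals(mask)  # (V, N)
    if frames is None:
        frames = frame_field(mask, center=center)
    frames_masked = frames[mask]

    v = int(mask.sum())
    out = np.empty((n_samples, v, len(METRIC_NAMES)))
    selections: list[np.ndarray] = []
    for s_i in range(n_samples):
        sel = bootknife_sample(pools, seed=seed, sample_index=s_i)
        selections.append(sel)
        design = design_matrix(stack.bvals[sel], stack.bvecs[sel])
        sig = signals_all[:, sel]
        try:
            if fit_method == "robust":
                fit = fit_robust(sig, design, config=fit_config)
            else:
                fit = _FITTERS[fit_method](sig, design)
        except Exception as exc:  # noqa: BLE001 - tag failing sample
            raise BootstrapError(f"fit failed in bootstrap sample {s_i}") from exc
        maps = compute_metric_maps(fit.tensors, frames_masked)
        for m_i, name in enumerate(METRIC_NAMES):
            out[s_i, :, m_i] = maps.as_dict()[name]
    return BootstrapRun(
        n_samples=n_samples,
        seed=seed,
        selections=selections,
        metric_samples=out,
    )
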