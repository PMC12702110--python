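"""Diffusion-encoding scheme design and acquisition-plan algebra.

A diffusion-encoding scheme (DES) is an ordered set of unit gradient
directions at a single b-value.  Because diffusion encoding is antipodally
symmetric (``g`` and ``-g`` measure the same thing), schemes are designed by
minimizing an antipodally symmetrized electrostatic energy, and scored by the
condition number of the second-moment transformation matrix that maps the six
unique tensor elements to log-signals.  Lower condition numbers mean better
noise propagation in tensor estimation.

An acquisition plan combines a high-b shell (b = 500 s/mm²) and a low-b shell
(b = 50 s/mm², three orthogonal directions) with per-direction repetition
counts, following the two-shell cardiac DTI protocol family in which the
number of low-b volumes is a fixed fraction of the number of high-b volumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DirectionScheme",
    "AcquisitionPlan",
    "encoding_matrix",
    "condition_number",
    "scheme_energy",
    "generate_repulsion_scheme",
    "generate_incremental_scheme",
    "best_circular_subsample",
    "circular_window",
    "dual_gradient_scheme",
    "icosahedral_scheme",
    "orthogonal_scheme",
    "allocate_per_direction",
    "build_plan",
    "enumerate_study_plans",
    "reference_plan",
    "write_fsl_gradients",
    "read_fsl_gradients",
]

#: Default low/high diffusion weightings of the protocol family (s/mm²).
B_LOW = 50.0
B_HIGH = 500.0

#: Default nominal TR: 3 R-R intervals at 60 bpm (seconds per volume).
NOMINAL_TR_S = 3.0

_UNIT_TOL = 1e-9


class SchemeError(ValueError):
    """Invalid diffusion-encoding scheme or plan request."""


@dataclass(frozen=True)
class DirectionScheme:
    """Ordered unit diffusion-encoding directions at one b-value.

    Order is meaningful: incrementally optimized schemes are constructed so
    that every prefix is itself a usable scheme.  Directions are treated as
    axes (``d`` and ``-d`` are equivalent).
    """

    directions: np.ndarray
    b_value: float
    name: str = ""

    def __post_init__(self) -> None:
        d = np.atleast_2d(np.asarray(self.directions, dtype=float))
        if d.ndim != 2 or d.shape[1] != 3:
            raise SchemeError(f"directions must be (N, 3); got {d.shape}")
        norms = np.linalg.norm(d, axis=1)
        if not np.all(np.abs(norms - 1.0) <= 1e-6):
            raise SchemeError("directions must be unit vectors")
        # renormalize exactly; frozen dataclass -> object.__setattr__
        d = d / norms[:, None]
        d.flags.writeable = False
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "b_value", float(self.b_value))

    def __len__(self) -> int:
        return self.directions.shape[0]


def encoding_matrix(scheme: DirectionScheme | np.ndarray) -> np.ndarray:
    """Second-moment transformation matrix, one row per direction.

    Row i is ``(gx², gy², gz², 2 gx gy, 2 gx gz, 2 gy gz)``: the linear map
    from the six unique diffusion-tensor elements to ``g·D·g``.  The b-value
    and the log-S0 intercept are deliberately excluded; the condition number
    of this geometry-only matrix is the standard figure of merit for a
    direction set.
    """
    if isinstance(scheme, DirectionScheme):
        g = scheme.directions
    else:
        g = np.atleast_2d(np.asarray(scheme, dtype=float))
        norms = np.linalg.norm(g, axis=1)
        if not np.all(np.abs(norms - 1.0) <= 1e-6):
            raise SchemeError("directions must be unit vectors")
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack(
        [gx**2, gy**2, gz**2, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz]
    )


def condition_number(scheme: DirectionScheme | np.ndarray) -> float:
    """Ratio of largest to smallest singular value of the encoding matrix.

    Rotation invariant and >= 1.  A rank-deficient direction set (e.g. all
    coplanar) cannot determine the tensor and raises :class:`SchemeError`.
    """
    m = encoding_matrix(scheme)
    if m.shape[0] < 6:
        raise SchemeError("condition number requires at least 6 directions")
    s = np.linalg.svd(m, compute_uv=False)
    if s[-1] <= s[0] * 1e-12:
        raise SchemeError("rank-deficient direction set (infinite condition number)")
    return float(s[0] / s[-1])


# ---------------------------------------------------------------------------
# Electrostatic repulsion on the antipodally symmetrized sphere
# ---------------------------------------------------------------------------


def _pair_terms(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise |di - dj| and |di + dj| with the diagonal masked out."""
    diff = np.linalg.norm(d[:, None, :] - d[None, :, :], axis=-1)
    summ = np.linalg.norm(d[:, None, :] + d[None, :, :], axis=-1)
    np.fill_diagonal(diff, np.inf)
    np.fill_diagonal(summ, np.inf)
    return diff, summ


def scheme_energy(directions: np.ndarray) -> float:
    """Antipodally symmetrized Coulomb energy sum_{i<j} 1/|di-dj| + 1/|di+dj|."""
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    if d.shape[0] < 2:
        return 0.0
    diff, summ = _pair_terms(d)
    return float(0.5 * (1.0 / diff + 1.0 / summ).sum())


def _energy_gradient(d: np.ndarray) -> np.ndarray:
    dif = d[:, None, :] - d[None, :, :]
    sm = d[:, None, :] + d[None, :, :]
    ndif = np.linalg.norm(dif, axis=-1)
    nsm = np.linalg.norm(sm, axis=-1)
    np.fill_diagonal(ndif, np.inf)
    np.fill_diagonal(nsm, np.inf)
    # dE/d(di) = sum_j -(di-dj)/|di-dj|^3 - (di+dj)/|di+dj|^3
    return -(dif / ndif[..., None] ** 3).sum(axis=1) - (sm / nsm[..., None] ** 3).sum(
        axis=1
    )


def _repulsion_optimize(d0: np.ndarray, iters: int) -> np.ndarray:
    """Projected gradient descent on the unit sphere with backtracking."""
    d = d0 / np.linalg.norm(d0, axis=1, keepdims=True)
    energy = scheme_energy(d)
    step = 1e-2
    for _ in range(iters):
        grad = _energy_gradient(d)
        # project onto tangent space so steps stay near the sphere
        grad = grad - (grad * d).sum(axis=1, keepdims=True) * d
        gmax = np.abs(grad).max()
        if gmax < 1e-14:
            break
        trial = d - step * grad
        trial /= np.linalg.norm(trial, axis=1, keepdims=True)
        e_trial = scheme_energy(trial)
        if e_trial < energy:
            d, energy = trial, e_trial
            step *= 1.1
        else:
            step *= 0.5
            if step < 1e-16:
                break
    return d


def generate_repulsion_scheme(
    n: int,
    seed: int = 0,
    iters: int = 10_000,
    b_value: float = B_HIGH,
    name: str | None = None,
) -> DirectionScheme:
    """Generate ``n`` unit directions by electrostatic-repulsion optimization.

    Minimizes the antipodally symmetrized Coulomb energy by projected
    gradient descent from a seeded random start.  Deterministic given
    ``seed``.  Well-converged 30-direction sets reach encoding condition
    numbers near 1.59; 6-direction sets approach the icosahedral optimum
    sqrt(5/2) ~ 1.581.
    """
    if n < 6:
        raise SchemeError("repulsion schemes need n >= 6 directions")
    rng = np.random.default_rng(seed)
    d0 = rng.standard_normal((n, 3))
    d = _repulsion_optimize(d0, iters)
    return DirectionScheme(d, b_value, name or f"rep{n}")


def _greedy_incremental_order(d: np.ndarray) -> np.ndarray:
    """Order points so each prefix has minimal symmetrized Coulomb energy.

    Greedy: start from the point closest to +z (a fixed, arbitrary anchor),
    then repeatedly append the remaining point that minimizes the energy of
    the extended prefix.
    """
    n = d.shape[0]
    remaining = list(range(n))
    first = int(np.argmax(np.abs(d[:, 2])))
    order = [first]
    remaining.remove(first)
    # incremental pairwise energy: cost of adding j = sum over chosen i
    while remaining:
        chosen = d[order]
        cand = d[remaining]
        dif = np.linalg.norm(cand[:, None, :] - chosen[None, :, :], axis=-1)
        sm = np.linalg.norm(cand[:, None, :] + chosen[None, :, :], axis=-1)
        add_cost = (1.0 / dif + 1.0 / sm).sum(axis=1)
        k = int(np.argmin(add_cost))
        order.append(remaining.pop(k))
    return np.array(order, dtype=int)


def _prefix_condition_numbers(d: np.ndarray) -> np.ndarray:
    """Encoding condition number of every prefix of length 6..len(d)."""
    out = []
    for k in range(6, len(d) + 1):
        m = encoding_matrix(d[:k])
        s = np.linalg.svd(m, compute_uv=False)
        out.append(s[0] / s[-1] if s[-1] > 1e-12 * s[0] else np.inf)
    return np.array(out)


def _repair_prefix_conditioning(
    d: np.ndarray, target: float = 2.0, sweeps: int = 10
) -> np.ndarray:
    """Swap elements of an ordering to pull every prefix condition number
    toward ``target``.

    For each prefix length whose condition number exceeds ``target``, tries
    every swap of an in-prefix element with a later element and accepts the
    swap that most reduces the running maximum prefix condition number.
    Leaves the direction *set* unchanged (pure reordering).
    """
    d = d.copy()
    n = len(d)
    for _ in range(sweeps):
        changed = False
        for k in range(6, n + 1):
            cns = _prefix_condition_numbers(d[:k])
            if cns[-1] <= target:
                continue
            best, best_val = None, cns.max()
            for i in range(k):
                for j in range(k, n):
                    trial = d.copy()
                    trial[[i, j]] = trial[[j, i]]
                    val = _prefix_condition_numbers(trial[:k]).max()
                    if val < best_val - 1e-9:
                        best_val, best = val, (i, j)
            if best is not None:
                i, j = best
                d[[i, j]] = d[[j, i]]
                changed = True
        if not changed:
            break
    return d


def generate_incremental_scheme(
    n_total: int,
    seed: int = 0,
    iters: int = 10_000,
    b_value: float = B_HIGH,
    name: str | None = None,
) -> DirectionScheme:
    """Repulsion-optimized scheme reordered for incremental sampling.

    The full direction set equals :func:`generate_repulsion_scheme`; the
    ordering is chosen greedily so that every prefix is itself a well-spread
    scheme (followed by a swap pass that keeps every prefix's encoding
    condition number low), making the scheme robust to premature scan
    termination and amenable to sequential (circular-window) subsampling.
    """
    if n_total < 6:
        raise SchemeError("incremental schemes need n_total >= 6 directions")
    base = generate_repulsion_scheme(n_total, seed=seed, iters=iters, b_value=b_value)
    order = _greedy_incremental_order(base.directions)
    d = _repair_prefix_conditioning(base.directions[order])
    return DirectionScheme(d, b_value, name or f"inc{n_total}")


def circular_window(
    scheme: DirectionScheme, start: int, nd: int, name: str | None = None
) -> DirectionScheme:
    """Contiguous window of ``nd`` directions starting at ``start`` (0-based),
    wrapping past the end of the scheme."""
    n = len(scheme)
    idx = (start + np.arange(nd)) % n
    return DirectionScheme(
        scheme.directions[idx], scheme.b_value, name or f"{scheme.name}w{nd}"
    )


def best_circular_subsample(
    scheme: DirectionScheme,
    nd: int,
    within: tuple[int, int] | None = None,
) -> tuple[int, float]:
    """Best sequential subsample: the circular window with minimal condition
    number.

    Evaluates every circular window of length ``nd`` (wrapping past the last
    direction) and returns ``(start_index, condition_number)`` of the best
    one; ties break toward the smallest start index.  ``within=(s, m)``
    restricts the search to windows fully contained in the circular window of
    length ``m`` starting at ``s`` (used to nest subsampled schemes inside an
    acquired parent window).
    """
    n = len(scheme)
    if nd < 6:
        raise SchemeError("windows need nd >= 6 directions")
    if nd > n:
        raise SchemeError(f"window length {nd} exceeds scheme size {n}")
    if within is None:
        starts = range(n)
    else:
        s0, m = within
        if nd > m:
            raise SchemeError("window longer than the containing window")
        starts = [(s0 + k) % n for k in range(m - nd + 1)]
    best_start, best_cn = -1, np.inf
    for s in starts:
        cn = condition_number(circular_window(scheme, s, nd))
        if cn < best_cn - 1e-15:
            best_start, best_cn = s, cn
    return best_start, float(best_cn)


# ---------------------------------------------------------------------------
# Reference direction sets
# ---------------------------------------------------------------------------


def dual_gradient_scheme(b_value: float = B_HIGH) -> DirectionScheme:
    """Classic 6-direction dual-gradient scheme; encoding condition number 2.00."""
    d = np.array(
        [[1, 1, 0], [1, -1, 0], [0, 1, 1], [0, 1, -1], [1, 0, 1], [-1, 0, 1]],
        dtype=float,
    ) / np.sqrt(2.0)
    return DirectionScheme(d, b_value, "dualgrad6")


def icosahedral_scheme(b_value: float = B_HIGH) -> DirectionScheme:
    """Six icosahedron-vertex directions (one per antipodal pair).

    This is the optimally conditioned 6-direction scheme; its encoding
    condition number is sqrt(5/2) ~ 1.5811.
    """
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    d = np.array(
        [
            [0, 1, phi],
            [0, -1, phi],
            [1, phi, 0],
            [-1, phi, 0],
            [phi, 0, 1],
            [phi, 0, -1],
        ],
        dtype=float,
    )
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return DirectionScheme(d, b_value, "icosa6")


def orthogonal_scheme(b_value: float = B_LOW) -> DirectionScheme:
    """Three orthogonal axes; the standard low-b acquisition set."""
    return DirectionScheme(np.eye(3), b_value, "orth3")


# ---------------------------------------------------------------------------
# Acquisition plans
# ---------------------------------------------------------------------------


def allocate_per_direction(na: int, nd: int, seed: int = 0) -> np.ndarray:
    """Split ``na`` volumes across ``nd`` directions as evenly as possible.

    Each direction gets ``floor(na/nd)``; the remainder is assigned, one
    volume each, to distinct directions chosen uniformly at random, so counts
    differ by at most 1.
    """
    if nd < 1:
        raise SchemeError("need at least one direction")
    if na < 0:
        raise SchemeError("volume count must be non-negative")
    base, rem = divmod(na, nd)
    counts = np.full(nd, base, dtype=int)
    if rem:
        rng = np.random.default_rng(seed)
        counts[rng.choice(nd, size=rem, replace=False)] += 1
    return counts


@dataclass(frozen=True)
class AcquisitionPlan:
    """A full sampling design: shells with per-direction repetition counts.

    ``shells`` holds ``(DirectionScheme, counts)`` pairs; ``counts[i]`` is the
    number of volumes acquired along direction ``i`` of that shell.  Volume
    totals satisfy ``na_all = na_b50 + na_b500`` and the nominal duration is
    ``na_all * nominal_tr_s`` (TR of 3 s = three R-R intervals at 60 bpm).
    """

    shells: tuple[tuple[DirectionScheme, np.ndarray], ...]
    name: str
    nominal_tr_s: float = NOMINAL_TR_S

    def __post_init__(self) -> None:
        shells = tuple(
            (sch, np.asarray(cnt, dtype=int)) for sch, cnt in self.shells
        )
        for sch, cnt in shells:
            if len(cnt) != len(sch):
                raise SchemeError("per-direction counts must match scheme length")
            if np.any(cnt < 0):
                raise SchemeError("negative repetition count")
        object.__setattr__(self, "shells", shells)

    @property
    def na_b50(self) -> int:
        return int(
            sum(cnt.sum() for sch, cnt in self.shells if sch.b_value < 100)
        )

    @property
    def na_b500(self) -> int:
        return int(
            sum(cnt.sum() for sch, cnt in self.shells if sch.b_value >= 100)
        )

    @property
    def na_all(self) -> int:
        return self.na_b50 + self.na_b500

    @property
    def nr_b500(self) -> float:
        """Mean repetitions per high-b direction (fractional for incomplete shells)."""
        nd = sum(len(sch) for sch, _ in self.shells if sch.b_value >= 100)
        return self.na_b500 / nd if nd else 0.0

    @property
    def nominal_time_s(self) -> float:
        return self.na_all * self.nominal_tr_s


def build_plan(
    des: DirectionScheme,
    na_b500: int,
    b50_divisor: int,
    low_b_scheme: DirectionScheme | None = None,
    seed: int = 0,
    nominal_tr_s: float = NOMINAL_TR_S,
) -> AcquisitionPlan:
    """Build a two-shell plan with ``na_b50 = na_b500 / b50_divisor``.

    ``na_b500`` must be exactly divisible by the divisor (the standard
    divisors 10, 5, 3, 2 all divide the volume counts 30/60/90/120); no
    silent rounding.  Per-direction counts come from
    :func:`allocate_per_direction` on each shell.
    """
    if low_b_scheme is None:
        low_b_scheme = orthogonal_scheme()
    if na_b500 % b50_divisor:
        raise SchemeError(
            f"na_b500={na_b500} not divisible by b50 divisor {b50_divisor}"
        )
    na_b50 = na_b500 // b50_divisor
    hi_counts = allocate_per_direction(na_b500, len(des), seed=seed)
    lo_counts = allocate_per_direction(na_b50, len(low_b_scheme), seed=seed + 1)
    name = f"{des.name}_{na_b500}_{na_b50}"
    return AcquisitionPlan(
        shells=((low_b_scheme, lo_counts), (des, hi_counts)),
        name=name,
        nominal_tr_s=nominal_tr_s,
    )


#: Study grid: high-b volume counts and low-b divisors of the 96-plan design.
STUDY_NA_B500 = (30, 60, 90, 120)
STUDY_B50_DIVISORS = (10, 5, 3, 2)

#: Reference-session repetition counts: (shell key, NR).
REFERENCE_NR = {"orth3": 24, "inc30": 12, "inc6": 8, "icosa6": 20, "rep30": 4}


def study_direction_schemes(seed: int = 0, iters: int = 10_000) -> dict[str, DirectionScheme]:
    """The six high-b direction sets of the study design.

    Four are nested circular windows (6/10/18/30 directions) of one
    61-direction incremental scheme — the 6/10/18-direction windows are
    constrained to lie inside the 30-direction window, because the reference
    session only acquires the 30- and 6-direction windows and the deepest
    plans need the pooled repetitions (e.g. 20 repetitions of each
    6-direction stratum = 8 from the 6-window shell + 12 from the 30-window
    shell) — plus the icosahedral 6-direction scheme and an independent
    repulsion-optimized 30-direction scheme.
    """
    master = generate_incremental_scheme(61, seed=seed, iters=iters)
    s30, _ = best_circular_subsample(master, 30)
    s18, _ = best_circular_subsample(master, 18, within=(s30, 30))
    s10, _ = best_circular_subsample(master, 10, within=(s30, 30))
    s6, _ = best_circular_subsample(master, 6, within=(s30, 30))
    return {
        "inc6": circular_window(master, s6, 6, name="inc6"),
        "inc10": circular_window(master, s10, 10, name="inc10"),
        "inc18": circular_window(master, s18, 18, name="inc18"),
        "inc30": circular_window(master, s30, 30, name="inc30"),
        "icosa6": icosahedral_scheme(),
        "rep30": generate_repulsion_scheme(30, seed=seed + 1, iters=iters),
    }


def reference_plan(
    schemes: dict[str, DirectionScheme] | None = None, seed: int = 0
) -> AcquisitionPlan:
    """The 720-volume reference session: 24x3 low-b volumes plus 12x30 + 8x6
    + 20x6 + 4x30 high-b volumes (36 min at TR 3 s)."""
    if schemes is None:
        schemes = study_direction_schemes(seed=seed)
    shells = [(orthogonal_scheme(), np.full(3, REFERENCE_NR["orth3"]))]
    for key in ("inc30", "inc6", "icosa6", "rep30"):
        sch = schemes[key]
        shells.append((sch, np.full(len(sch), REFERENCE_NR[key])))
    plan = AcquisitionPlan(shells=tuple(shells), name="", nominal_tr_s=NOMINAL_TR_S)
    name = f"all_{plan.na_b500}_{plan.na_b50}"
    return AcquisitionPlan(shells=tuple(shells), name=name, nominal_tr_s=NOMINAL_TR_S)


def enumerate_study_plans(
    seed: int = 0,
    schemes: dict[str, DirectionScheme] | None = None,
    include_reference: bool = True,
) -> list[AcquisitionPlan]:
    """All 96 subsampled plans (6 DES x 4 high-b counts x 4 low-b divisors),
    optionally followed by the 720-volume reference plan."""
    if schemes is None:
        schemes = study_direction_schemes(seed=seed)
    plans = []
    for key in ("inc6", "inc10", "inc18", "inc30", "icosa6", "rep30"):
        for na_b500 in STUDY_NA_B500:
            for div in STUDY_B50_DIVISORS:
                plans.append(
                    build_plan(schemes[key], na_b500, div, seed=seed)
                )
    if include_reference:
        plans.append(reference_plan(schemes=schemes, seed=seed))
    return plans


# ---------------------------------------------------------------------------
# I/O: FSL-dialect bvec/bval and JSON scheme files
# ---------------------------------------------------------------------------


def plan_gradient_table(plan: AcquisitionPlan) -> tuple[np.ndarray, np.ndarray, list[dict]]:
    """Expand a plan into per-volume (bvals, bvecs, metadata) in acquisition
    order: shells in order, directions in order, repetitions innermost."""
    bvals, bvecs, meta = [], [], []
    for shell_i, (sch, counts) in enumerate(plan.shells):
        for dir_i, c in enumerate(counts):
            for rep in range(int(c)):
                bvals.append(sch.b_value)
                bvecs.append(sch.directions[dir_i])
                meta.append(
                    {
                        "shell": shell_i,
                        "scheme": sch.name,
                        "b_value": sch.b_value,
                        "direction_index": dir_i,
                        "repetition": rep,
                        "stratum": f"{sch.name}:b{sch.b_value:g}:d{dir_i}",
                    }
                )
    return np.array(bvals), np.array(bvecs), meta


def write_fsl_gradients(path_stem: str | Path, bvals: np.ndarray, bvecs: np.ndarray) -> None:
    """Write ``<stem>.bval`` (1 x N) and ``<stem>.bvec`` (3 x N), FSL dialect."""
    stem = Path(path_stem)
    np.savetxt(stem.with_suffix(".bval"), bvals[None, :], fmt="%.6g")
    np.savetxt(stem.with_suffix(".bvec"), np.asarray(bvecs).T, fmt="%.8f")


def read_fsl_gradients(path_stem: str | Path) -> tuple[np.ndarray, np.ndarray]:
    stem = Path(path_stem)
    bvals = np.loadtxt(stem.with_suffix(".bval")).ravel()
    bvecs = np.loadtxt(stem.with_suffix(".bvec"))
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return bvals, bvecs


def scheme_to_json(scheme: DirectionScheme, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "name": scheme.name,
                "b_value": scheme.b_value,
                "directions": scheme.directions.tolist(),
            },
            indent=2,
        )
    )


def scheme_from_json(path: str | Path) -> DirectionScheme:
    obj = json.loads(Path(path).read_text())
    return DirectionScheme(
        np.array(obj["directions"]), obj["b_value"], obj.get("name", "")
    )


def plan_to_json(plan: AcquisitionPlan, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "name": plan.name,
                "nominal_tr_s": plan.nominal_tr_s,
                "shells": [
                    {
                        "scheme": {
                            "name": sch.name,
                            "b_value": sch.b_value,
                            "directions": sch.directions.tolist(),
                        },
                        "counts": cnt.tolist(),
                    }
                    for sch, cnt in plan.shells
                ],
            },
            indent=2,
        )
    )


def plan_from_json(path: str | Path) -> AcquisitionPlan:
    obj = json.loads(Path(path).read_text())
    shells = tuple(
        (
            DirectionScheme(
                np.array(sh["scheme"]["directions"]),
                sh["scheme"]["b_value"],
                sh["scheme"]["name"],
            ),
            np.array(sh["counts"], dtype=int),
        )
        for sh in obj["shells"]
    )
    return AcquisitionPlan(
        shells=shells, name=obj["name"], nominal_tr_s=obj["nominal_tr_s"]
    )
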