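"""Stability-region atlas over the (f_h, f_p) plane.

Maps out, for each modeling framework, where the coexistence
equilibrium is locally stable as a function of the attack-rate
elasticities: f_h on the abscissa (Type II to the left of zero,
Type III to the right) and f_p on the ordinate (interference below
zero, cooperation above).  Both frameworks share the necessary
condition 1 + f_h + f_p > 0; the second boundary is

    continuous:  f_p = r*f_h/gamma            (a line through the origin)
    discrete:    f_p = [R + (f_h*(R-1) - R)*R**f_h] / (R*(R**f_h - 1))

The discrete boundary passes through (f_h, f_p) = (1, 0) for every R —
a Type III response alone needs f_h > 1 in discrete time, against
f_h > 0 in continuous time — and both boundaries rotate anticlockwise
with increasing reproduction.  Cross-framework comparisons use the
matched convention r = log R, gamma = 1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from . import discrete as _disc
from .continuous import ContinuousParams
from .core import ANALYTIC_MARGINAL_TOL, NumericalError, PreconditionError
from .discrete import DiscreteParams

__all__ = [
    "RegionGrid",
    "BoundarySummary",
    "boundary_fp_continuous",
    "boundary_fp_discrete",
    "corner_point",
    "scan_region",
    "asymptotic_limits",
    "boundary_summary",
    "matched_continuous_params",
    "agreement_fraction",
    "is_stable_subset",
    "plot_region",
]

Framework = Literal["continuous", "discrete"]

STABLE, MARGINAL, UNSTABLE = 1, 0, -1

DEFAULT_FH_RANGE = (-1.0, 3.0)
DEFAULT_FP_RANGE = (-1.5, 1.5)
DEFAULT_RESOLUTION = (301, 301)


def matched_continuous_params(R: float) -> ContinuousParams:
    """Continuous parameters matched to reproduction R: r = log R, gamma = 1."""
    return ContinuousParams(math.log(R), 1.0)


def boundary_fp_continuous(fh, params: ContinuousParams):
    """Critical f_p = r*f_h/gamma of the continuous trace condition."""
    out = params.r * np.asarray(fh, dtype=float) / params.gamma
    return float(out) if out.ndim == 0 else out


def boundary_fp_discrete(fh, R: float):
    """Critical f_p of the discrete framework (removable singularity at 0)."""
    return _disc.critical_fp(fh, R)


def _coerce_R(params) -> float:
    if isinstance(params, DiscreteParams):
        return params.R
    return DiscreteParams(float(params)).R


def corner_point(framework: Framework, params) -> tuple[float, float]:
    """Third-quadrant meeting point of the two stability boundaries.

    Continuous: f_h = -1/(1 + r/gamma) in closed form.  Discrete: the
    boundary curve is intersected with f_p = -1 - f_h by bracketed
    root-finding and cross-checked against the closed form
    [log R - log(2R - 1)]/log R.
    """
    if framework == "continuous":
        r, g = params.r, params.gamma
        fh = -1.0 / (1.0 + r / g)
        return fh, -1.0 - fh
    if framework == "discrete":
        R = _coerce_R(params)
        gfun = lambda fh: _disc.critical_fp(fh, R) - (-1.0 - fh)
        lo, hi = -1.0 + 1e-12, 0.999
        if gfun(lo) * gfun(hi) > 0:
            raise NumericalError("failed to bracket the discrete corner point")
        fh = brentq(gfun, lo, hi, xtol=1e-15)
        closed = (math.log(R) - math.log(2.0 * R - 1.0)) / math.log(R)
        if abs(fh - closed) > 1e-8:
            raise NumericalError(
                f"numeric corner {fh} disagrees with closed form {closed}"
            )
        return fh, -1.0 - fh
    raise ValueError(f"unknown framework {framework!r}")


@dataclass(frozen=True)
class RegionGrid:
    """Stability verdicts on an (f_h, f_p) lattice for one framework.

    ``verdict[i, j]`` scores the point (fh_axis[j], fp_axis[i]) with
    +1 stable, 0 marginal (on a boundary within tolerance), -1
    unstable.  ``params`` records the generating parameters and
    ``convention`` the cross-framework matching in force.
    """

    fh_axis: np.ndarray
    fp_axis: np.ndarray
    verdict: np.ndarray
    framework: str
    params: dict = field(default_factory=dict)
    convention: str = "r = log R, gamma = 1"

    def __post_init__(self) -> None:
        if self.verdict.shape != (len(self.fp_axis), len(self.fh_axis)):
            raise ValueError("verdict shape must be (len(fp_axis), len(fh_axis))")

    @property
    def stable_mask(self) -> np.ndarray:
        return self.verdict == STABLE

    @property
    def stable_fraction(self) -> float:
        return float(np.mean(self.stable_mask))

    def write_text(self, matrix_path, meta_path=None) -> None:
        """Delimited verdict matrix plus a JSON sidecar with the axes."""
        np.savetxt(matrix_path, self.verdict, fmt="%d", delimiter="\t")
        if meta_path is None:
            meta_path = str(matrix_path) + ".meta.json"
        meta = {
            "framework": self.framework,
            "params": self.params,
            "convention": self.convention,
            "fh_axis": [float(self.fh_axis[0]), float(self.fh_axis[-1]),
                        int(len(self.fh_axis))],
            "fp_axis": [float(self.fp_axis[0]), float(self.fp_axis[-1]),
                        int(len(self.fp_axis))],
            "codes": {"stable": STABLE, "marginal": MARGINAL,
                      "unstable": UNSTABLE},
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=1)


def _verdict_from_slacks(slacks, tol: float = ANALYTIC_MARGINAL_TOL) -> np.ndarray:
    mn = np.minimum.reduce([np.asarray(s, dtype=float) for s in slacks])
    return np.where(mn > tol, STABLE, np.where(mn < -tol, UNSTABLE, MARGINAL)).astype(
        np.int8
    )


def scan_region(
    framework: Framework,
    params,
    fh_range: tuple[float, float] = DEFAULT_FH_RANGE,
    fp_range: tuple[float, float] = DEFAULT_FP_RANGE,
    resolution: tuple[int, int] = DEFAULT_RESOLUTION,
    verify_fraction: float = 0.0,
    seed: int = 20220412,
) -> RegionGrid:
    """Evaluate the analytic stability verdict on a lattice.

    The continuous verdict uses the trace/determinant criteria, the
    discrete verdict the full three Jury conditions, so cells scanned
    outside the admissible band f_p >= -1 (kept to render the shared
    necessary-condition line) are still scored correctly.  With
    ``verify_fraction`` > 0 a seeded random subsample of cells is
    re-scored through the per-point eigenvalue/Jury routines and exact
    agreement is required away from marginal cells.
    """
    if fh_range[0] >= fh_range[1] or fp_range[0] >= fp_range[1]:
        raise PreconditionError("scan ranges must be nonempty (lo < hi)")
    nh, npts = resolution
    if nh < 2 or npts < 2:
        raise PreconditionError("resolution must be at least 2x2")
    fh_axis = np.linspace(fh_range[0], fh_range[1], nh)
    fp_axis = np.linspace(fp_range[0], fp_range[1], npts)
    FH, FP = np.meshgrid(fh_axis, fp_axis)
    if framework == "continuous":
        cp = params if isinstance(params, ContinuousParams) else ContinuousParams(*params)
        cond1 = cp.r * FH / cp.gamma - FP   # negative-trace margin (scaled)
        cond2 = 1.0 + FH + FP               # positive-determinant margin
        verdict = _verdict_from_slacks([cond1, cond2])
        pdict = {"r": cp.r, "gamma": cp.gamma}
    elif framework == "discrete":
        R = _coerce_R(params)
        j1, j2, j3 = _disc.jury_slacks(FH, FP, R)
        verdict = _verdict_from_slacks([j1, j2, j3])
        pdict = {"R": R}
    else:
        raise ValueError(f"unknown framework {framework!r}")
    grid = RegionGrid(fh_axis, fp_axis, verdict, framework, pdict)
    if verify_fraction > 0.0:
        _verify_subsample(grid, params, verify_fraction, seed)
    return grid


def _verify_subsample(
    grid: RegionGrid, params, fraction: float, seed: int
) -> None:
    """Re-score random cells via the per-point stability routines."""
    from .continuous import lv_stability

    rng = np.random.default_rng(seed)
    ncells = grid.verdict.size
    k = max(1, int(round(fraction * ncells)))
    idx = rng.choice(ncells, size=min(k, ncells), replace=False)
    rows, cols = np.unravel_index(idx, grid.verdict.shape)
    code = {"stable": STABLE, "unstable": UNSTABLE, "marginal": MARGINAL}
    for i, j in zip(rows, cols):
        fh = float(grid.fh_axis[j])
        fp = float(grid.fp_axis[i])
        if fh < -1.0 or fp < -1.0:
            continue  # outside the admissible band of the per-point routines
        if grid.framework == "continuous":
            v = lv_stability((fh, fp), ContinuousParams(**grid.params))
            pointwise = code[v.details["eigen_status"].value]
        else:
            v = _disc.nb_stability((fh, fp), grid.params["R"])
            pointwise = code[v.details["jury_status"].value]
        cell = int(grid.verdict[i, j])
        if MARGINAL in (cell, pointwise):
            continue
        if cell != pointwise:
            raise NumericalError(
                f"grid verdict {cell} disagrees with pointwise verdict "
                f"{pointwise} at (fh={fh}, fp={fp})"
            )


def agreement_fraction(a: RegionGrid, b: RegionGrid) -> float:
    """Fraction of matching verdicts over cells non-marginal in both grids."""
    if a.verdict.shape != b.verdict.shape:
        raise ValueError("grids must share a lattice")
    ok = (a.verdict != MARGINAL) & (b.verdict != MARGINAL)
    if not np.any(ok):
        return 1.0
    return float(np.mean(a.verdict[ok] == b.verdict[ok]))


def is_stable_subset(inner: RegionGrid, outer: RegionGrid) -> bool:
    """True if every non-marginal cell stable in ``inner`` is stable in ``outer``."""
    if inner.verdict.shape != outer.verdict.shape:
        raise ValueError("grids must share a lattice")
    mask = (inner.verdict == STABLE) & (outer.verdict != MARGINAL)
    return bool(np.all(outer.verdict[mask] == STABLE))


@dataclass(frozen=True)
class BoundarySummary:
    """Anchor points of one framework's stability region."""

    framework: str
    growth: float  # R (discrete) or r (continuous, gamma folded in)
    corner_fh: float
    corner_fp: float
    fp_intercept: float  # critical f_p at f_h = 0
    fh_intercept: float  # f_h where the boundary crosses f_p = 0


def boundary_summary(framework: Framework, params) -> BoundarySummary:
    """Corner point and axis intercepts of the stability boundary."""
    cfh, cfp = corner_point(framework, params)
    if framework == "continuous":
        growth = params.r / params.gamma
        fp0 = boundary_fp_continuous(0.0, params)
        fh0 = 0.0
        resid = abs(boundary_fp_continuous(cfh, params) - cfp)
    else:
        R = _coerce_R(params)
        growth = R
        fp0 = boundary_fp_discrete(0.0, R)
        fh0 = brentq(lambda fh: _disc.critical_fp(fh, R), 0.25, 1.75, xtol=1e-15)
        resid = abs(boundary_fp_discrete(cfh, R) - cfp)
    if resid > 1e-8 or abs(1.0 + cfh + cfp) > 1e-8:
        raise NumericalError("corner point fails its defining equations")
    return BoundarySummary(framework, growth, cfh, cfp, float(fp0), float(fh0))


@dataclass(frozen=True)
class AsymptoticLimit:
    """Limiting stability boundary of a framework, with numeric evidence."""

    framework: str
    direction: str
    lines: tuple[str, ...]
    verification: dict

    @property
    def converged(self) -> bool:
        return all(v <= tol for v, tol in self.verification.values())


def asymptotic_limits(framework: Framework, direction: str) -> AsymptoticLimit:
    """Limiting boundary lines at vanishing / infinite host reproduction.

    Verifies convergence numerically at R = 1 + 1e-6 (or r = 1e-6) and
    R = 1e6 (or r = 1e6); the limits are approached slowly in log R, so
    positions are checked to 1e-2.  Verification maps a check name to
    (observed error, tolerance).
    """
    tol = 1e-2
    if direction not in ("R_to_1", "R_to_inf"):
        raise ValueError(f"unknown direction {direction!r}")
    if framework == "continuous":
        if direction == "R_to_1":
            p = ContinuousParams(1e-6, 1.0)
            corner = corner_point("continuous", p)
            checks = {
                "corner_fh_to_-1": (abs(corner[0] + 1.0), tol),
                "boundary_fp_at_fh_1": (abs(boundary_fp_continuous(1.0, p)), tol),
            }
            return AsymptoticLimit(
                "continuous", direction,
                ("f_p < 0", "1 + f_h + f_p > 0"), checks,
            )
        p = ContinuousParams(1e6, 1.0)
        # boundary slope r/gamma diverges: the region collapses to f_h > 0
        checks = {
            "corner_fh_to_0": (abs(corner_point("continuous", p)[0]), tol),
            "fh_at_fp_1": (abs(1.0 * p.gamma / p.r), tol),
        }
        return AsymptoticLimit("continuous", direction, ("f_h > 0",), checks)
    if framework == "discrete":
        if direction == "R_to_1":
            R = 1.0 + 1e-6
            fh_sample = np.linspace(-0.9, 2.0, 30)
            dev = float(np.max(np.abs(_disc.critical_fp(fh_sample, R))))
            checks = {"boundary_fp_to_0": (dev, tol)}
            return AsymptoticLimit(
                "discrete", direction, ("f_p < 0", "1 + f_h + f_p > 0"), checks,
            )
        R = 1e6
        corner = corner_point("discrete", R)
        fh_sample = np.linspace(0.5, 2.0, 30)
        dev = float(
            np.max(np.abs(_disc.critical_fp(fh_sample, R) - (fh_sample - 1.0)))
        )
        # the corner sits at f_h = -log(2 - 1/R)/log R exactly, so it
        # approaches (0, -1) only at rate log 2/log R; bound accordingly
        corner_tol = 1.2 * math.log(2.0) / math.log(R)
        checks = {
            "boundary_to_fh_minus_1": (dev, tol),
            "corner_to_(0,-1)_fh": (abs(corner[0]), corner_tol),
            "corner_to_(0,-1)_fp": (abs(corner[1] + 1.0), corner_tol),
        }
        return AsymptoticLimit(
            "discrete", direction, ("f_p < f_h - 1", "1 + f_h + f_p > 0"), checks,
        )
    raise ValueError(f"unknown framework {framework!r}")


def plot_region(grid: RegionGrid, path=None, ax=None):
    """Shade the stable region grey over the (f_h, f_p) plane.

    Requires matplotlib (optional dependency).  Returns the axes.
    """
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    shade = (grid.verdict == STABLE).astype(float)
    ax.pcolormesh(
        grid.fh_axis, grid.fp_axis, shade, cmap="Greys", vmin=0.0, vmax=2.0,
        shading="nearest",
    )
    ax.axhline(0.0, color="k", lw=0.5)
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel(r"$f_h$")
    ax.set_ylabel(r"$f_p$")
    label = ", ".join(f"{k}={v:g}" for k, v in grid.params.items())
    ax.set_title(f"{grid.framework} ({label})")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
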