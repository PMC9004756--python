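"""Shared result containers and trajectory classification.

Holds the types common to the continuous-time and discrete-time
frameworks: the coexistence equilibrium, the stability verdict (analytic
slacks plus eigenvalues), simulated trajectories, and the envelope-based
classification used to cross-validate analytic verdicts by simulation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Equilibrium",
    "StabilityStatus",
    "StabilityVerdict",
    "Trajectory",
    "PreconditionError",
    "NumericalError",
    "classify_trajectory",
    "ANALYTIC_MARGINAL_TOL",
    "EIGEN_MARGINAL_TOL",
]

# |slack| at or below this is classified marginal for analytic criteria;
# the classical models sit exactly on the boundary so this must be tiny.
ANALYTIC_MARGINAL_TOL = 1e-9
# eigenvalue verdicts use max|Re(lambda)| (continuous) or
# |spectral radius - 1| (discrete) against this
EIGEN_MARGINAL_TOL = 1e-6


class PreconditionError(ValueError):
    """A documented precondition of an operation was violated."""


class NumericalError(RuntimeError):
    """An integrator or root-finder failed; message carries diagnostics."""


@dataclass(frozen=True)
class Equilibrium:
    """Nontrivial coexistence fixed point (host, parasitoid)."""

    hstar: float
    pstar: float

    def __post_init__(self) -> None:
        if not (self.hstar > 0 and self.pstar > 0):
            raise PreconditionError(
                f"nontrivial equilibrium must be strictly positive, "
                f"got ({self.hstar}, {self.pstar})"
            )

    def __iter__(self):
        yield self.hstar
        yield self.pstar


class StabilityStatus(str, enum.Enum):
    STABLE = "stable"
    UNSTABLE = "unstable"
    MARGINAL = "marginal"


@dataclass(frozen=True)
class StabilityVerdict:
    """Outcome of a local stability analysis.

    cond1_slack is the signed margin of the framework's trace/boundary
    inequality (positive on the stable side); cond2_slack is the margin
    of the shared necessary condition 1 + f_h + f_p > 0.  ``details``
    carries method-specific extras (Jury slacks, eigen status, ...).
    """

    status: StabilityStatus
    cond1_slack: float
    cond2_slack: float
    eigenvalues: tuple[complex, complex]
    method: str = "analytic"
    details: dict = field(default_factory=dict)

    @property
    def is_stable(self) -> bool:
        return self.status is StabilityStatus.STABLE


def status_from_slacks(
    slacks, tol: float = ANALYTIC_MARGINAL_TOL
) -> StabilityStatus:
    """Stable iff every slack > tol; unstable if any < -tol; else marginal."""
    slacks = np.asarray(slacks, dtype=float)
    if np.any(slacks < -tol):
        return StabilityStatus.UNSTABLE
    if np.all(slacks > tol):
        return StabilityStatus.STABLE
    return StabilityStatus.MARGINAL


@dataclass(frozen=True)
class Trajectory:
    """Time series of host and parasitoid densities.

    ``times`` is monotone (continuous time or generation index);
    densities are nonnegative and the three arrays share a length.
    """

    times: np.ndarray
    host: np.ndarray
    parasitoid: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        h = np.asarray(self.host, dtype=float)
        p = np.asarray(self.parasitoid, dtype=float)
        if not (len(t) == len(h) == len(p)):
            raise ValueError("times, host, parasitoid must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "host", h)
        object.__setattr__(self, "parasitoid", p)

    def __len__(self) -> int:
        return len(self.times)

    def write_tsv(self, path, time_label: str = "time") -> None:
        """Export as delimited text with a header line."""
        data = np.column_stack([self.times, self.host, self.parasitoid])
        np.savetxt(
            path,
            data,
            delimiter="\t",
            header=f"{time_label}\thost\tparasitoid",
            comments="",
        )


def deviation(traj: Trajectory, eq: Equilibrium) -> np.ndarray:
    """Relative Euclidean distance of the trajectory from the equilibrium."""
    dh = (traj.host - eq.hstar) / eq.hstar
    dp = (traj.parasitoid - eq.pstar) / eq.pstar
    return np.hypot(dh, dp)


def classify_trajectory(
    traj: Trajectory,
    eq: Equilibrium,
    damped_ratio: float = 0.9,
    diverging_ratio: float = 1.1,
    growth_factor: float = 100.0,
    min_points: int = 30,
) -> str:
    """Classify a perturbed trajectory as damped, neutral or diverging.

    Compares the peak deviation from equilibrium over the last third of
    the record with the peak over the first third.  The ratio thresholds
    leave a neutral band wide enough to absorb integrator noise at the
    neutrally stable point.  An orbit whose late deviation exceeds
    ``growth_factor`` times the initial perturbation is diverging even
    if its envelope has saturated (growth onto a bounded attractor away
    from the equilibrium looks flat in the envelope ratio).
    """
    if len(traj) < min_points:
        raise PreconditionError(
            f"trajectory too short to classify ({len(traj)} < {min_points})"
        )
    dev = deviation(traj, eq)
    n = len(dev)
    first = float(np.max(dev[: n // 3]))
    last = float(np.max(dev[-(n // 3):]))
    if dev[0] > 0.0 and last > growth_factor * dev[0]:
        return "diverging"
    if first == 0.0:
        # started exactly at equilibrium: any growth is divergence
        return "diverging" if last > 0 else "neutral"
    ratio = last / first
    if ratio < damped_ratio:
        return "damped"
    if ratio > diverging_ratio:
        return "diverging"
    return "neutral"
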