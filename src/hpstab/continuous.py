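"""Generalized Lotka-Volterra host-parasitoid model.

The model couples exponential host growth to parasitoid attack with an
arbitrary density-dependent rate f(h, p):

    dh/dt = r*h - f(h, p)*h*p
    dp/dt = f(h, p)*h*p - gamma*p

where r is the host per-capita growth rate and 1/gamma the mean
parasitoid lifespan.  The nontrivial equilibrium satisfies
f(h*, p*) = r/p* with p* = r*h*/gamma.  Linearising at that point gives
the Jacobian

    A = [[-r*f_h,      -gamma*(1+f_p)],
         [ r*(1+f_h),   gamma*f_p   ]]

whose trace is -r*f_h + gamma*f_p and determinant r*gamma*(1+f_h+f_p),
so the equilibrium is asymptotically stable iff

    f_p < r*f_h/gamma      and      1 + f_h + f_p > 0.

With f_h = f_p = 0 (constant attack rate) both eigenvalues are purely
imaginary: the classical neutrally stable cycles with period
2*pi/sqrt(r*gamma).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.signal import find_peaks

from .attack_rates import AttackRateModel, Family, as_sensitivities, evaluate
from .core import (
    EIGEN_MARGINAL_TOL,
    Equilibrium,
    NumericalError,
    PreconditionError,
    StabilityStatus,
    StabilityVerdict,
    Trajectory,
    classify_trajectory,
    status_from_slacks,
)

__all__ = [
    "ContinuousParams",
    "lv_equilibrium",
    "lv_jacobian",
    "lv_stability",
    "lv_simulate",
    "lv_classify_trajectory",
    "neutral_period",
    "estimate_period",
]

_EQ_RESIDUAL_TOL = 1e-10


@dataclass(frozen=True)
class ContinuousParams:
    """Host growth rate r and parasitoid mortality rate gamma (1/time)."""

    r: float
    gamma: float

    def __post_init__(self) -> None:
        if not (self.r > 0 and self.gamma > 0):
            raise PreconditionError(
                f"require r > 0 and gamma > 0, got r={self.r}, gamma={self.gamma}"
            )


def neutral_period(params: ContinuousParams) -> float:
    """Cycle period 2*pi/sqrt(r*gamma) of the neutrally stable model."""
    return 2.0 * math.pi / math.sqrt(params.r * params.gamma)


def _host_balance(model: AttackRateModel, params: ContinuousParams, h: float) -> float:
    """h*f(h, r*h/gamma) - gamma: zero at the equilibrium host density."""
    p = params.r * h / params.gamma
    return h * evaluate(model, h, p) - params.gamma


def lv_equilibrium(model: AttackRateModel, params: ContinuousParams) -> Equilibrium:
    """Unique nontrivial equilibrium of the generalized model.

    Uses the closed form where the family admits one and bracketed
    root-finding on the host balance h*f(h, r*h/gamma) = gamma
    otherwise.  For the Hill-type family the handling time must be
    shorter than the mean parasitoid lifespan (Th < 1/gamma), which is
    exactly the condition for the balance to be monotone with a single
    crossing.
    """
    r, gamma = params.r, params.gamma
    pr = model.params
    fam = model.family
    if fam is Family.CONSTANT:
        c = pr["c"]
        h = gamma / c
    elif fam is Family.TYPE2:
        c1, Th = pr["c1"], pr["Th"]
        if Th >= 1.0 / gamma:
            raise PreconditionError(
                f"uniqueness requires Th < 1/gamma (Th={Th}, 1/gamma={1/gamma})"
            )
        h = gamma / (c1 * (1.0 - gamma * Th))
    elif fam is Family.GENERALIZED_HILL:
        Th = pr["Th"]
        if Th >= 1.0 / gamma:
            raise PreconditionError(
                f"uniqueness requires Th < 1/gamma (Th={Th}, 1/gamma={1/gamma})"
            )
        h = _bracketed_host_root(model, params)
    elif fam is Family.PARASITOID_POWER:
        c1, alpha = pr["c1"], pr["alpha"]
        p = (r / c1) ** (1.0 / (1.0 + alpha))
        h = p * gamma / r
    elif fam is Family.MONOMIAL:
        a, b, c = pr["a"], pr["b"], pr["c"]
        if 1.0 + a + b <= 0:
            raise PreconditionError(
                "monomial equilibrium requires 1 + a + b > 0 for a unique "
                f"positive solution (got a={a}, b={b})"
            )
        # c*h**(1+a)*(r*h/gamma)**b = gamma
        h = (gamma * (gamma / r) ** b / c) ** (1.0 / (1.0 + a + b))
    else:  # pragma: no cover
        h = _bracketed_host_root(model, params)
    p = r * h / gamma
    eq = Equilibrium(h, p)
    _check_residual(model, params, eq)
    return eq


def _bracketed_host_root(model: AttackRateModel, params: ContinuousParams) -> float:
    """Expanding-bracket Brent solve of the host balance in log h."""
    g = lambda lh: _host_balance(model, params, math.exp(lh))
    lo, hi = 0.0, 0.0
    glo = ghi = g(0.0)
    for _ in range(80):
        if glo < 0 < ghi:
            break
        if glo >= 0:
            lo -= 1.0
            glo = g(lo)
        if ghi <= 0:
            hi += 1.0
            ghi = g(hi)
    else:
        raise NumericalError(
            "no sign change found for the equilibrium host balance; "
            "the model may not admit a nontrivial equilibrium"
        )
    return math.exp(brentq(g, lo, hi, xtol=1e-300, rtol=1e-15))


def _check_residual(
    model: AttackRateModel, params: ContinuousParams, eq: Equilibrium
) -> None:
    f = evaluate(model, eq.hstar, eq.pstar)
    res1 = abs(f - params.r / eq.pstar) / (params.r / eq.pstar)
    res2 = abs(eq.pstar - params.r * eq.hstar / params.gamma) / eq.pstar
    if max(res1, res2) > _EQ_RESIDUAL_TOL:
        raise NumericalError(
            f"equilibrium residual {max(res1, res2):.2e} exceeds "
            f"{_EQ_RESIDUAL_TOL:.0e}"
        )


def lv_jacobian(sens, params: ContinuousParams) -> np.ndarray:
    """Jacobian of the model at the equilibrium, in (r, gamma, f_h, f_p).

    trace = -r*f_h + gamma*f_p; det = r*gamma*(1 + f_h + f_p).
    """
    fh, fp = as_sensitivities(sens)
    r, g = params.r, params.gamma
    return np.array([[-r * fh, -g * (1.0 + fp)], [r * (1.0 + fh), g * fp]])


def lv_stability(sens, params: ContinuousParams) -> StabilityVerdict:
    """Analytic + eigenvalue verdict for the continuous framework.

    Analytically stable iff f_p < r*f_h/gamma (negative trace) and
    1 + f_h + f_p > 0 (positive determinant); slacks are the signed
    margins of those inequalities.
    """
    s = as_sensitivities(sens)
    r, g = params.r, params.gamma
    cond1 = r * s.fh / g - s.fp
    cond2 = 1.0 + s.fh + s.fp
    status = status_from_slacks([cond1, cond2])
    lam = np.linalg.eigvals(lv_jacobian(s, params))
    max_re = float(np.max(lam.real))
    if max_re < -EIGEN_MARGINAL_TOL:
        eig_status = StabilityStatus.STABLE
    elif max_re > EIGEN_MARGINAL_TOL:
        eig_status = StabilityStatus.UNSTABLE
    else:
        eig_status = StabilityStatus.MARGINAL
    return StabilityVerdict(
        status=status,
        cond1_slack=cond1,
        cond2_slack=cond2,
        eigenvalues=(complex(lam[0]), complex(lam[1])),
        method="analytic",
        details={"eigen_status": eig_status, "max_re_eigenvalue": max_re},
    )


def lv_simulate(
    model: AttackRateModel,
    params: ContinuousParams,
    init,
    horizon: float,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    n_points: int | None = None,
) -> Trajectory:
    """Integrate the model from positive initial densities.

    The system is integrated in log densities, which keeps both
    populations strictly positive by construction and preserves the
    classical conserved quantity to the stated tolerances.  ``init`` is
    an (h0, p0) pair or :class:`Equilibrium`.
    """
    h0, p0 = tuple(init)
    if not (h0 > 0 and p0 > 0):
        raise PreconditionError("initial densities must be positive")
    if horizon <= 0:
        raise PreconditionError("horizon must be positive")
    r, g = params.r, params.gamma

    def rhs(t, y):
        h, p = math.exp(y[0]), math.exp(y[1])
        f = evaluate(model, h, p)
        return (r - f * p, f * h - g)

    if n_points is None:
        n_points = max(500, int(round(80 * horizon / neutral_period(params))))
    t_eval = np.linspace(0.0, horizon, n_points)

    # stop once log densities leave a wide window: the orbit is clearly
    # diverging and further integration would only overflow
    def escaped(t, y):
        return 100.0 - max(abs(y[0]), abs(y[1]))

    escaped.terminal = True
    escaped.direction = -1
    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        [math.log(h0), math.log(p0)],
        method="DOP853",
        t_eval=t_eval,
        events=escaped,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        # super-exponential orbits blow up in finite time and starve the
        # step-size control before the escape event can fire; a solver
        # death far from the initial scale is that divergence, not an
        # integration defect
        y0 = np.array([math.log(h0), math.log(p0)])
        far_out = sol.t.size > 30 and float(
            np.max(np.abs(sol.y - y0[:, None]))
        ) > math.log(50.0)
        if not far_out:
            raise NumericalError(f"ODE integration failed: {sol.message}")
    return Trajectory(sol.t, np.exp(sol.y[0]), np.exp(sol.y[1]))


def lv_classify_trajectory(traj: Trajectory, eq: Equilibrium) -> str:
    """Envelope classification (damped / neutral / diverging) near ``eq``."""
    return classify_trajectory(traj, eq)


def estimate_period(traj: Trajectory) -> float:
    """Mean peak-to-peak spacing of the host series."""
    idx, _ = find_peaks(traj.host)
    if len(idx) < 2:
        raise NumericalError("fewer than two host peaks; horizon too short")
    return float(np.mean(np.diff(traj.times[idx])))


def lv_conserved_quantity(
    model: AttackRateModel, params: ContinuousParams, traj: Trajectory
) -> np.ndarray:
    """Classical first integral c*(h+p) - gamma*log h - r*log p.

    Exact only for the constant-rate family; its relative drift along a
    simulated orbit is the integrator-quality diagnostic.
    """
    if model.family is not Family.CONSTANT:
        raise PreconditionError("conserved quantity requires the constant family")
    c = model.params["c"]
    return (
        c * (traj.host + traj.parasitoid)
        - params.gamma * np.log(traj.host)
        - params.r * np.log(traj.parasitoid)
    )
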