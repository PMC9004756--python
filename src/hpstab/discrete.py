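"""Generalized Nicholson-Bailey model via the semi-discrete formalism.

Year-to-year dynamics of adult hosts H_t and parasitoids P_t are
derived mechanistically: within each season the host's vulnerable
larval stage (initial density R*H_t, where R > 1 is the number of
viable eggs per adult host) is attacked by P_t parasitoids over a
window tau in [0, T].  With a monomial attack rate per host
c = L**f_h * P_t**f_p and no within-season mortality the within-season
system integrates in closed form, giving the map

    H_{t+1} = R*H_t * (1 + f_h*(R*H_t)**f_h * P_t**(1+f_p))**(-1/f_h)
    P_{t+1} = R*H_t - H_{t+1}

which reduces to the classical Nicholson-Bailey model
H_{t+1} = R*H_t*exp(-c*P_t) as f_h -> 0, f_p = 0.  The unique
nontrivial equilibrium is

    H* = [(1 - R**(-f_h)) / (f_h*(R-1)**(1+f_p))]**(1/(1+f_h+f_p)),
    P* = (R-1)*H*,

and with s = (1 - R**(-f_h))/f_h (-> log R as f_h -> 0) and
m = (1+f_p)*s/(R-1) the Jacobian at the equilibrium reduces to

    A = [[R**(-f_h),     -m],
         [R - R**(-f_h),  m]],   Tr = R**(-f_h) + m,  Det = R*m.

The Jury conditions 1 - Det > 0, 1 - Tr + Det > 0, 1 + Tr + Det > 0
characterise local stability; the second is identically s*(1+f_h+f_p)
(the shared necessary condition) and the third always holds on the
admissible domain, so stability is equivalent to

    f_p < [R + (f_h*(R-1) - R)*R**f_h] / (R*(R**f_h - 1)),
    1 + f_h + f_p > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

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
    "DiscreteParams",
    "SeasonSpec",
    "MapState",
    "season_integrate",
    "nb_generalized_map",
    "nb_phenomenological_map",
    "nb_equilibrium",
    "nb_jacobian",
    "nb_stability",
    "nb_iterate",
    "nb_classify_trajectory",
    "critical_fp",
    "jury_slacks",
]

# below this |f_h| the bracket form (1 + f_h*x)**(-1/f_h) switches to
# its exponential limit exp(-x)
_FH_SWITCH = 1e-8
_EQ_RESIDUAL_TOL = 1e-10
DIVERGENCE_CEILING_FACTOR = 1e12


@dataclass(frozen=True)
class DiscreteParams:
    """Viable eggs per adult host per generation; R > 1 for coexistence."""

    R: float

    def __post_init__(self) -> None:
        if not self.R > 1.0:
            raise PreconditionError(f"require R > 1, got R={self.R}")


@dataclass(frozen=True)
class MapState:
    """Adult host and parasitoid densities in one year."""

    H: float
    P: float

    def __post_init__(self) -> None:
        if self.H < 0 or self.P < 0:
            raise PreconditionError(
                f"densities must be nonnegative, got ({self.H}, {self.P})"
            )

    def __iter__(self):
        yield self.H
        yield self.P


@dataclass(frozen=True)
class SeasonSpec:
    """Within-season dynamics of the host's vulnerable stage.

    ``attack`` is a constant or monomial rate; the monomial's parasitoid
    factor uses the start-of-season adult density P_t (the density that
    sets the attack phenotype for the year).  Death rates default to
    zero, the setting under which the closed-form map is exact, and the
    vulnerable window T defaults to 1.
    """

    attack: AttackRateModel
    gammaP: float = 0.0
    gammaL: float = 0.0
    gammaI: float = 0.0
    T: float = 1.0

    def __post_init__(self) -> None:
        if self.attack.family not in (Family.CONSTANT, Family.MONOMIAL):
            raise PreconditionError(
                "season attack rate must be the constant or monomial family"
            )
        if min(self.gammaP, self.gammaL, self.gammaI) < 0 or self.T <= 0:
            raise PreconditionError("death rates must be >= 0 and T > 0")


def season_integrate(
    spec: SeasonSpec, state, R: float, full_output: bool = False
):
    """Integrate the within-season system over tau in [0, T].

    State variables: P (searching parasitoids), L (unparasitized
    larvae, initial R*H), I (parasitized larvae, initial 0):

        dP/dtau = -gammaP * P
        dL/dtau = -c(L, P_t)*P*L - gammaL * L
        dI/dtau =  c(L, P_t)*P*L - gammaI * I

    Returns (L(T), I(T)), or the full (tau, P, L, I) arrays when
    ``full_output`` is set.  With all death rates zero, L + I = R*H is
    conserved along the season.
    """
    H0, P0 = tuple(state)
    L0 = R * H0

    def rate(L: float) -> float:
        if L <= 0 or P0 <= 0:
            return 0.0
        return evaluate(spec.attack, L, P0)

    def rhs(tau, y):
        P, L, I = y
        enc = rate(L) * P * max(L, 0.0)
        return (-spec.gammaP * P, -enc - spec.gammaL * L, enc - spec.gammaI * I)

    t_eval = np.linspace(0.0, spec.T, 200) if full_output else None
    sol = solve_ivp(
        rhs,
        (0.0, spec.T),
        [P0, L0, 0.0],
        method="DOP853",
        rtol=1e-11,
        atol=1e-13,
        t_eval=t_eval,
    )
    if not sol.success:
        raise NumericalError(f"within-season integration failed: {sol.message}")
    if full_output:
        return sol.t, sol.y[0], sol.y[1], sol.y[2]
    return float(sol.y[1, -1]), float(sol.y[2, -1])


def nb_generalized_map(state, sens, R: float) -> MapState:
    """One-year update of the generalized map.

    For f_h < 0 the within-season larval density can reach zero in
    finite time; when the bracket 1 + f_h*(R*H)**f_h*P**(1+f_p) is
    non-positive every larva is parasitized and H' = 0, P' = R*H.
    """
    H, P = tuple(state)
    fh, fp = as_sensitivities(sens)
    if H < 0 or P < 0:
        raise PreconditionError("densities must be nonnegative")
    if H == 0.0:
        return MapState(0.0, 0.0)
    RH = R * H
    x = (P ** (1.0 + fp)) if P > 0 else 0.0
    if abs(fh) < _FH_SWITCH:
        Hn = RH * math.exp(-x)
    else:
        x *= RH**fh
        if fh < 0 and 1.0 + fh * x <= 0.0:
            return MapState(0.0, RH)  # finite-time host depletion
        # (1 + fh*x)**(-1/fh) via log1p for uniform accuracy in fh
        Hn = RH * math.exp(-math.log1p(fh * x) / fh)
    return MapState(Hn, RH - Hn)


def nb_phenomenological_map(state, model: AttackRateModel, R: float) -> MapState:
    """Reference update that substitutes f(H_t, P_t) into the classical map.

    H' = R*H*exp(-f(H, P)*P).  Provided for documentation contrast with
    the mechanistic (semi-discrete) map, which can disagree with it
    qualitatively; not used by the stability atlas.
    """
    H, P = tuple(state)
    if H <= 0:
        return MapState(0.0, 0.0)
    if P <= 0:
        return MapState(R * H, 0.0)
    f = evaluate(model, H, P)
    Hn = R * H * math.exp(-f * P)
    return MapState(Hn, R * H - Hn)


def _s_factor(fh: float, R: float) -> float:
    """s = (1 - R**(-f_h))/f_h, continuous through f_h = 0 (-> log R)."""
    lnR = math.log(R)
    if fh == 0.0:
        return lnR
    return -math.expm1(-fh * lnR) / fh


def _closed_form_hstar(fh: float, fp: float, R: float) -> float:
    s = _s_factor(fh, R)
    return (s / (R - 1.0) ** (1.0 + fp)) ** (1.0 / (1.0 + fh + fp))


def nb_equilibrium(sens, R: float) -> Equilibrium:
    """Unique nontrivial fixed point, with P* = (R-1)*H* exactly.

    The fixed point is solved on log H (positivity enforced) with the
    closed form as initial guess and cross-check; the fixed-point
    residual of the map is verified below 1e-10 relative.
    """
    fh, fp = as_sensitivities(sens)
    if not R > 1.0:
        raise PreconditionError(f"nontrivial equilibrium requires R > 1, got {R}")
    if not 1.0 + fh + fp > 0.0:
        raise PreconditionError(
            f"nontrivial equilibrium requires 1 + fh + fp > 0, "
            f"got 1 + {fh} + {fp} = {1 + fh + fp}"
        )
    guess = _closed_form_hstar(fh, fp, R)

    def g(logH: float) -> float:
        H = math.exp(logH)
        Hn, _ = nb_generalized_map((H, (R - 1.0) * H), (fh, fp), R)
        if Hn <= 0:
            return -1.0  # over-depleted: H' < H
        return math.log(Hn) - logH

    lg = math.log(guess)
    lo, hi = lg - 0.5, lg + 0.5
    glo, ghi = g(lo), g(hi)
    for _ in range(60):
        # g is decreasing in log H: positive below the root, negative above
        if glo > 0 > ghi:
            break
        if glo <= 0:
            lo -= 0.5
            glo = g(lo)
        if ghi >= 0:
            hi += 0.5
            ghi = g(hi)
    else:
        raise NumericalError("failed to bracket the fixed point")
    H = math.exp(brentq(g, lo, hi, xtol=1e-300, rtol=1e-15))
    P = (R - 1.0) * H
    Hn, Pn = nb_generalized_map((H, P), (fh, fp), R)
    if abs(Hn - H) / H > _EQ_RESIDUAL_TOL or abs(Pn - P) / P > _EQ_RESIDUAL_TOL:
        raise NumericalError("fixed-point residual exceeds 1e-10 relative")
    return Equilibrium(H, P)


def nb_jacobian(sens, R: float) -> np.ndarray:
    """Jacobian of the map at the equilibrium, reduced to (f_h, f_p, R)."""
    fh, fp = as_sensitivities(sens)
    if not R > 1.0:
        raise PreconditionError(f"require R > 1, got {R}")
    if not 1.0 + fh + fp > 0.0:
        raise PreconditionError("require 1 + fh + fp > 0")
    s = _s_factor(fh, R)
    m = (1.0 + fp) * s / (R - 1.0)
    a11 = math.exp(-fh * math.log(R))
    return np.array([[a11, -m], [R - a11, m]])


def jury_slacks(fh, fp, R):
    """Signed margins (1-Det, 1-Tr+Det, 1+Tr+Det) of the Jury conditions.

    Vectorised over (fh, fp); valid for any fp (the reduction of the
    Jacobian to (f_h, f_p, R) holds identically), which lets the atlas
    score lattice cells outside the admissible band correctly.
    """
    fh = np.asarray(fh, dtype=float)
    fp = np.asarray(fp, dtype=float)
    lnR = math.log(R)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(fh == 0.0, lnR, -np.expm1(-fh * lnR) / np.where(fh == 0, 1, fh))
    m = (1.0 + fp) * s / (R - 1.0)
    a11 = np.exp(-fh * lnR)
    tr = a11 + m
    det = R * m
    return 1.0 - det, 1.0 - tr + det, 1.0 + tr + det


def critical_fp(fh, R: float):
    """Critical parasitoid sensitivity below which the map is stable.

    The boundary f_p = [R + (f_h*(R-1) - R)*R**f_h] / (R*(R**f_h - 1)),
    with its removable singularity at f_h = 0 filled by the limit
    (R - 1 - R*log R)/(R*log R).  Vectorised over f_h.
    """
    fh_arr = np.asarray(fh, dtype=float)
    lnR = math.log(R)
    e = np.expm1(fh_arr * lnR)  # R**fh - 1
    num = fh_arr * (R - 1.0) * (e + 1.0) - R * e
    small = np.abs(fh_arr) < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            small, (R - 1.0 - R * lnR) / (R * lnR), num / np.where(small, 1.0, R * e)
        )
    if out.ndim == 0:
        return float(out)
    return out


def nb_stability(sens, R: float) -> StabilityVerdict:
    """Analytic boundary verdict plus full Jury/eigenvalue analysis.

    cond1_slack is critical_fp(f_h, R) - f_p; cond2_slack is
    1 + f_h + f_p.  The details record all three Jury slacks and the
    spectral radius; analytic and Jury verdicts agree away from the
    boundary by construction of the criteria.
    """
    fh, fp = as_sensitivities(sens)
    cond1 = critical_fp(fh, R) - fp
    cond2 = 1.0 + fh + fp
    status = status_from_slacks([cond1, cond2])
    j1, j2, j3 = jury_slacks(fh, fp, R)
    jury_status = status_from_slacks([float(j1), float(j2), float(j3)])
    if cond2 > 0:
        lam = np.linalg.eigvals(nb_jacobian((fh, fp), R))
        rho = float(np.max(np.abs(lam)))
        eig = (complex(lam[0]), complex(lam[1]))
    else:
        # no admissible equilibrium Jacobian; Jury slacks already decide
        rho = math.nan
        eig = (complex(math.nan), complex(math.nan))
    if not math.isnan(rho):
        if rho < 1.0 - EIGEN_MARGINAL_TOL:
            eig_status = StabilityStatus.STABLE
        elif rho > 1.0 + EIGEN_MARGINAL_TOL:
            eig_status = StabilityStatus.UNSTABLE
        else:
            eig_status = StabilityStatus.MARGINAL
    else:
        eig_status = StabilityStatus.UNSTABLE
    return StabilityVerdict(
        status=status,
        cond1_slack=float(cond1),
        cond2_slack=float(cond2),
        eigenvalues=eig,
        method="analytic",
        details={
            "jury": (float(j1), float(j2), float(j3)),
            "jury_status": jury_status,
            "spectral_radius": rho,
            "eigen_status": eig_status,
        },
    )


def nb_iterate(
    state,
    sens,
    R: float,
    generations: int,
    ceiling: float | None = None,
) -> Trajectory:
    """Iterate the map for a number of generations.

    Densities are capped at ``ceiling`` (default 1e12 times the
    equilibrium host density, or 1e12 times the initial scale when no
    admissible equilibrium exists); a capped run classifies as
    diverging under the envelope criterion.
    """
    H, P = tuple(state)
    fh, fp = as_sensitivities(sens)
    if generations < 1:
        raise PreconditionError("need at least one generation")
    if ceiling is None:
        try:
            eq = nb_equilibrium((fh, fp), R)
            scale = eq.hstar
        except (PreconditionError, NumericalError):
            scale = max(H, P, 1.0)
        ceiling = DIVERGENCE_CEILING_FACTOR * scale
    Hs = np.empty(generations + 1)
    Ps = np.empty(generations + 1)
    Hs[0], Ps[0] = H, P
    n = generations
    for t in range(generations):
        H, P = nb_generalized_map((H, P), (fh, fp), R)
        H, P = min(H, ceiling), min(P, ceiling)
        Hs[t + 1], Ps[t + 1] = H, P
        if H == 0.0 and P == 0.0:
            # extinction is absorbing: stop rather than record zeros forever
            n = t + 1
            break
    return Trajectory(np.arange(n + 1, dtype=float), Hs[: n + 1], Ps[: n + 1])


def nb_classify_trajectory(traj: Trajectory, eq: Equilibrium) -> str:
    """Envelope classification of an iterated-map run.

    Instability of the map typically manifests as oscillations that grow
    until the host crashes and both populations go extinct; a run ending
    at zero host therefore classifies as diverging outright, and only
    surviving runs fall through to the envelope criterion used for the
    continuous model.
    """
    if traj.host[-1] == 0.0:
        return "diverging"
    return classify_trajectory(traj, eq)
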