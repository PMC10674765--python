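"""Closed-form compartmental disposition models for an intravenous bolus.

All functions use a single consistent unit system: time in minutes, amounts
in ng, volumes in mL, clearances/flows in mL/min, concentrations in ng/mL.

The central objects are the one- and two-compartment IV-bolus solutions and
the first-order effect-compartment (biophase) concentration that drives the
pharmacodynamic stage.  A high-accuracy ODE integrator (`ode_oracle`) of the
same mass-balance system is provided for cross-checking the closed forms; it
is intended for tests, not for production evaluation.

Two-compartment notation
------------------------
Micro rate constants (1/min)::

    k10 = Cl / V1      elimination from central
    k12 = Q  / V1      central -> peripheral
    k21 = Q  / V2      peripheral -> central

Hybrid rates ``alpha > beta > 0`` are the roots of
``s**2 - (k10+k12+k21)*s + k10*k21 = 0``; they are computed without
subtracting near-equal quantities (``beta = k10*k21/alpha``).

The bolus solution is the biexponential

    C(t) = (dose/V1) * (A*exp(-alpha*t) + B*exp(-beta*t))

with ``A = (alpha-k21)/(alpha-beta)`` and ``B = (k21-beta)/(alpha-beta)``.

The biophase concentration Ce solves ``dCe/dt = ke0*(C - Ce), Ce(0)=0`` and
has the closed form

    Ce(t) = (dose/V1)*ke0 * sum_i c_i*(exp(-lam_i*t) - exp(-ke0*t))/(ke0-lam_i)

over the exponentials of C; when ke0 is within relative 1e-6 of a hybrid
rate the confluent limit ``t*exp(-lam*t)`` is used instead of the unstable
quotient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DomainError

__all__ = [
    "PKIndividualParams",
    "EffectSiteParams",
    "conc_1cpt_bolus",
    "conc_2cpt_bolus",
    "conc_2cpt_infusion",
    "conc_effect_site",
    "ode_oracle",
    "hybrid_rates",
    "conc1_profile",
    "conc2_profile",
    "effect_site_profile",
]

#: relative tolerance below which ke0 is treated as confluent with a hybrid rate
_CONFLUENT_RTOL = 1e-6


@dataclass(frozen=True)
class PKIndividualParams:
    """Structural PK parameters of one subject.

    Parameters
    ----------
    Cl : float
        Elimination clearance, mL/min.
    V1 : float
        Central volume of distribution, mL.
    Q : float, optional
        Intercompartmental flow, mL/min.  ``None`` selects the
        one-compartment model.
    V2 : float, optional
        Peripheral volume of distribution, mL.
    """

    Cl: float
    V1: float
    Q: Optional[float] = None
    V2: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.Cl > 0 and self.V1 > 0):
            raise DomainError(f"Cl and V1 must be strictly positive, got Cl={self.Cl}, V1={self.V1}")
        if (self.Q is None) != (self.V2 is None):
            raise DomainError("Q and V2 must be supplied together (two-compartment) or both omitted")
        if self.Q is not None and not (self.Q > 0 and self.V2 > 0):
            raise DomainError(f"Q and V2 must be strictly positive, got Q={self.Q}, V2={self.V2}")

    @property
    def is_two_compartment(self) -> bool:
        return self.Q is not None

    @property
    def k10(self) -> float:
        return self.Cl / self.V1

    @property
    def k12(self) -> float:
        return 0.0 if self.Q is None else self.Q / self.V1

    @property
    def k21(self) -> float:
        return 0.0 if self.Q is None else self.Q / self.V2

    def hybrid(self) -> tuple[float, float]:
        """Return (alpha, beta) for the two-compartment model."""
        if not self.is_two_compartment:
            raise DomainError("hybrid rates are defined for the two-compartment model only")
        a, b = hybrid_rates(self.k10, self.k12, self.k21)
        return float(a), float(b)


@dataclass(frozen=True)
class EffectSiteParams:
    """Biophase link parameter: first-order equilibration rate ke0 (1/min)."""

    ke0: float

    def __post_init__(self) -> None:
        if not self.ke0 > 0:
            raise DomainError(f"ke0 must be strictly positive, got {self.ke0}")


def hybrid_rates(k10, k12, k21):
    """Stable hybrid rate constants (alpha, beta) of the 2-compartment model.

    Vectorised over the inputs.  alpha is the larger root; beta is recovered
    as ``k10*k21/alpha`` to avoid catastrophic cancellation when the roots
    are far apart.
    """
    k10 = np.asarray(k10, dtype=float)
    s = k10 + k12 + k21
    p = k10 * k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * p, 0.0))
    alpha = 0.5 * (s + disc)
    beta = p / alpha
    return alpha, beta


def _bolus_coeffs(k10, k12, k21):
    """Return alpha, beta and the biexponential coefficients A, B."""
    alpha, beta = hybrid_rates(k10, k12, k21)
    denom = alpha - beta
    # degenerate alpha == beta can only arise on a measure-zero parameter set;
    # nudge to keep the expression finite
    denom = np.where(denom <= 0, np.finfo(float).tiny, denom)
    A = (alpha - k21) / denom
    B = (k21 - beta) / denom
    return alpha, beta, A, B


def conc2_profile(Cl, V1, Q, V2, dose, t):
    """Vectorised two-compartment bolus concentration.

    All arguments broadcast; typical use is per-observation-row evaluation
    with per-row subject parameters during estimation.
    """
    Cl, V1, Q, V2 = (np.asarray(x, dtype=float) for x in (Cl, V1, Q, V2))
    t = np.asarray(t, dtype=float)
    k10, k12, k21 = Cl / V1, Q / V1, Q / V2
    alpha, beta, A, B = _bolus_coeffs(k10, k12, k21)
    return dose / V1 * (A * np.exp(-alpha * t) + B * np.exp(-beta * t))


def conc1_profile(Cl, V1, dose, t):
    """Vectorised one-compartment bolus concentration."""
    Cl, V1 = np.asarray(Cl, dtype=float), np.asarray(V1, dtype=float)
    t = np.asarray(t, dtype=float)
    return dose / V1 * np.exp(-(Cl / V1) * t)


def effect_site_profile(Cl, V1, Q, V2, ke0, dose, t):
    """Vectorised biophase concentration for the two-compartment bolus.

    Uses the closed-form double-exponential convolution; switches to the
    confluent limit term ``t*exp(-lam*t)`` where ke0 coincides with a hybrid
    rate to within relative 1e-6.
    """
    Cl, V1, Q, V2, ke0 = (np.asarray(x, dtype=float) for x in (Cl, V1, Q, V2, ke0))
    t = np.asarray(t, dtype=float)
    k10, k12, k21 = Cl / V1, Q / V1, Q / V2
    alpha, beta, A, B = _bolus_coeffs(k10, k12, k21)
    out = 0.0
    e_ke0 = np.exp(-ke0 * t)
    for lam, c in ((alpha, A), (beta, B)):
        d = ke0 - lam
        confluent = np.abs(d) < _CONFLUENT_RTOL * lam
        d_safe = np.where(confluent, 1.0, d)
        regular = c * (np.exp(-lam * t) - e_ke0) / d_safe
        limit = c * t * np.exp(-lam * t)
        out = out + np.where(confluent, limit, regular)
    return dose / V1 * ke0 * out


def effect_site_infusion_profile(Cl, V1, Q, V2, ke0, dose, tinf, t):
    """Biophase concentration for a zero-order infusion of duration tinf.

    Exact piecewise closed form obtained by convolving the infusion plasma
    solution with the first-order biophase kernel.  Vectorised over ``t``.
    """
    Cl, V1, Q, V2 = (np.asarray(x, dtype=float) for x in (Cl, V1, Q, V2))
    t = np.asarray(t, dtype=float)
    ke0 = float(ke0)
    if not tinf > 0:
        raise DomainError("infusion duration must be positive")
    k10, k12, k21 = Cl / V1, Q / V1, Q / V2
    alpha, beta, A, B = _bolus_coeffs(k10, k12, k21)
    rate_c = dose / tinf / V1

    def quotient(lam, tau):
        d = ke0 - lam
        confluent = np.abs(d) < _CONFLUENT_RTOL * lam
        d_safe = np.where(confluent, 1.0, d)
        reg = (np.exp(-lam * tau) - np.exp(-ke0 * tau)) / d_safe
        lim = tau * np.exp(-lam * tau)
        return np.where(confluent, lim, reg)

    t_on = np.minimum(t, tinf)
    # Ce at the end of the "on" portion reached by time t (t_on <= tinf)
    ce_on = 0.0
    for lam, c in ((alpha, A), (beta, B)):
        ce_on = ce_on + c / lam * ((1.0 - np.exp(-ke0 * t_on)) - ke0 * quotient(lam, t_on))
    ce_on = rate_c * ce_on

    tau = np.maximum(t - tinf, 0.0)
    post = np.zeros_like(tau)
    for lam, c in ((alpha, A), (beta, B)):
        a_i = c / lam * (1.0 - np.exp(-lam * tinf))
        post = post + a_i * quotient(lam, tau)
    ce = np.where(t <= tinf, ce_on, ce_on * np.exp(-ke0 * tau) + rate_c * ke0 * post)
    return ce


def _effect_site_profile_1cpt(Cl, V1, ke0, dose, t):
    """Biophase concentration driven by the one-compartment bolus."""
    Cl, V1, ke0 = (np.asarray(x, dtype=float) for x in (Cl, V1, ke0))
    t = np.asarray(t, dtype=float)
    lam = Cl / V1
    d = ke0 - lam
    confluent = np.abs(d) < _CONFLUENT_RTOL * lam
    d_safe = np.where(confluent, 1.0, d)
    regular = (np.exp(-lam * t) - np.exp(-ke0 * t)) / d_safe
    limit = t * np.exp(-lam * t)
    return dose / V1 * ke0 * np.where(confluent, limit, regular)


def conc_2cpt_bolus(p: PKIndividualParams, dose: float, t):
    """Two-compartment IV-bolus concentration C(t), ng/mL.

    ``t`` may be a scalar or array of minutes (>= 0); ``dose`` is in ng.
    """
    _check_dose_time(dose, t)
    if not p.is_two_compartment:
        raise DomainError("conc_2cpt_bolus requires Q and V2")
    return conc2_profile(p.Cl, p.V1, p.Q, p.V2, dose, t)


def conc_1cpt_bolus(p: PKIndividualParams, dose: float, t):
    """One-compartment IV-bolus concentration C(t) = (dose/V1)*exp(-Cl/V1*t)."""
    _check_dose_time(dose, t)
    return conc1_profile(p.Cl, p.V1, dose, t)


def conc_2cpt_infusion(p: PKIndividualParams, dose: float, tinf: float, t):
    """Two-compartment concentration for a zero-order infusion of duration tinf.

    Provided for completeness; the study design is a single bolus, which is
    the ``tinf -> 0`` limit of this function.
    """
    _check_dose_time(dose, t)
    if not tinf > 0:
        raise DomainError("infusion duration must be positive; use conc_2cpt_bolus for a bolus")
    t = np.asarray(t, dtype=float)
    k10, k12, k21 = p.k10, p.k12, p.k21
    alpha, beta, A, B = _bolus_coeffs(k10, k12, k21)
    rate = dose / tinf
    out = 0.0
    for lam, c in ((alpha, A), (beta, B)):
        during = c / lam * (1.0 - np.exp(-lam * np.minimum(t, tinf)))
        after = np.where(t > tinf, np.exp(-lam * (t - np.minimum(t, tinf))), 1.0)
        out = out + during * after
    return rate / p.V1 * out


def conc_effect_site(p: PKIndividualParams, e: EffectSiteParams, dose: float, t):
    """Biophase concentration Ce(t) for a bolus, ng/mL.

    Solves ``dCe/dt = ke0*(C(t) - Ce)``, ``Ce(0) = 0`` in closed form for
    either structural model.
    """
    _check_dose_time(dose, t)
    if p.is_two_compartment:
        return effect_site_profile(p.Cl, p.V1, p.Q, p.V2, e.ke0, dose, t)
    return _effect_site_profile_1cpt(p.Cl, p.V1, e.ke0, dose, t)


def _check_dose_time(dose, t) -> None:
    if not dose > 0:
        raise DomainError(f"dose must be strictly positive, got {dose}")
    if np.any(np.asarray(t) < 0):
        raise DomainError("times must be non-negative")


@dataclass(frozen=True)
class OracleTrajectories:
    """Output of :func:`ode_oracle`: trajectories on the requested grid."""

    t: np.ndarray
    conc: np.ndarray          # central concentration, ng/mL
    ce: np.ndarray            # biophase concentration, ng/mL
    central: np.ndarray       # amount in central compartment, ng
    peripheral: np.ndarray    # amount in peripheral compartment, ng
    eliminated: np.ndarray    # cumulative eliminated amount, ng


def ode_oracle(
    p: PKIndividualParams,
    e: Optional[EffectSiteParams],
    dose: float,
    t_grid,
    rtol: float = 1e-11,
) -> OracleTrajectories:
    """Numerically integrate the compartmental mass-balance system.

    Independent cross-check for the closed-form solutions (test oracle).
    States: central amount, peripheral amount, cumulative eliminated amount,
    biophase concentration.  Uses an implicit (Radau) integrator because the
    hybrid rates may differ by many orders of magnitude.
    """
    _check_dose_time(dose, t_grid)
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    k10, k12, k21 = p.k10, p.k12, p.k21
    ke0 = e.ke0 if e is not None else 0.0
    V1 = p.V1

    def rhs(_t, y):
        a1, a2, _elim, ce = y
        return [
            -(k10 + k12) * a1 + k21 * a2,
            k12 * a1 - k21 * a2,
            k10 * a1,
            ke0 * (a1 / V1 - ce),
        ]

    t0, t1 = 0.0, float(t_grid.max()) if t_grid.size else 0.0
    eval_t = t_grid
    sol = solve_ivp(
        rhs,
        (t0, max(t1, 1e-9)),
        [dose, 0.0, 0.0, 0.0],
        method="Radau",
        t_eval=eval_t,
        rtol=rtol,
        atol=dose * 1e-14,
    )
    if not sol.success:  # pragma: no cover - integrator failure is a test error
        raise RuntimeError(f"ODE oracle failed: {sol.message}")
    a1, a2, elim, ce = sol.y
    return OracleTrajectories(
        t=sol.t, conc=a1 / V1, ce=ce, central=a1, peripheral=a2, eliminated=elim
    )
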