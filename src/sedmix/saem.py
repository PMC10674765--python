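"""Nonlinear mixed-effects estimation by SAEM with an MCMC E-step.

The population model is the classic pharmacometric one: each subject ``i``
has structural parameters

    theta_ij = theta_pj * exp(eta_ij),        eta_ij ~ N(0, omega_j**2)

(for parameters bounded in (0,1), e.g. a maximal-inhibition fraction, the
lognormal law is replaced by a logit-normal one), and observations

    y = f(theta_i, design) + eps,   sd(eps) = sigma_add            (additive)
    y = f(theta_i, design) * (1 + eps_p), sd(eps_p) = sigma_prop   (proportional)

or the combined form ``sd = sqrt(sigma_add**2 + (sigma_prop*f)**2)``.

Estimation alternates

* **E step** — Metropolis-Hastings sampling of each subject's transformed
  individual parameters ``phi_i`` given the current population parameters
  (one independence kernel drawn from the population law plus componentwise
  random-walk sweeps with acceptance-rate adaptation),
* **SA step** — stochastic approximation of the complete-data sufficient
  statistics with step size 1 during the exploratory phase and ``1/(k-K1)``
  during the smoothing phase,
* **M step** — closed-form updates of the fixed effects, random-effect
  (co)variances and residual-error magnitudes from the smoothed statistics.

During the exploratory phase the variance components follow a simulated
annealing constraint (they may shrink by at most a fixed factor per
iteration and never below a floor), which prevents premature collapse of the
random-effect and residual variances.

The marginal likelihood (OFV = -2 log L) is computed by per-subject
importance sampling with a proposal centred at the empirical Bayes mode,
and information criteria follow the pharmacometric conventions::

    AIC  = OFV + 2 P
    BIC  = OFV + P log N_subjects
    BICc = OFV + P_subject log N_subjects + P_residual log N_observations

where subject-level parameters (fixed effects and random-effect SDs) are
penalised by the number of subjects and residual-error parameters by the
number of observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

from .dataio import LongitudinalDataset, ObsType, get_logger
from .errors import DesignError, DomainError, InitializationError
from .structural import conc1_profile, conc2_profile

__all__ = [
    "PopulationModel",
    "SAEMSettings",
    "FitResult",
    "Design",
    "build_pk_design",
    "saem_fit",
    "saem_fit_design",
    "log_likelihood",
    "log_likelihood_design",
    "information_criteria",
    "ebe_estimates",
    "cv_percent",
    "random_effect_correlation",
    "simulate_design",
]

log = get_logger("saem")

STRUCTURAL_PARAMS: Dict[str, tuple] = {
    "1cpt": ("Cl", "V1"),
    "2cpt": ("Cl", "V1", "Q", "V2"),
}

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# population model
# ---------------------------------------------------------------------------
def _default_transform(name: str) -> str:
    return "logit" if name == "Imax" else "log"


@dataclass
class PopulationModel:
    """Population law of a structural model.

    ``theta`` are the fixed effects on the natural scale, ``omega`` the SDs
    of the (log- or logit-scale) random effects.  An omega of 0 declares a
    parameter without between-subject variability.
    """

    structural: str
    theta: Dict[str, float]
    omega: Dict[str, float]
    error_model: str = "proportional"
    sigma_add: float = 0.0
    sigma_prop: float = 0.0
    transforms: Dict[str, str] = field(default_factory=dict)
    fix_theta: tuple = ()
    fix_omega: tuple = ()
    full_covariance: bool = False
    #: filled by the fit when full_covariance is used
    omega_corr: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.error_model not in ("additive", "proportional", "combined"):
            raise DomainError(f"unknown error model {self.error_model!r}")
        for name, value in self.theta.items():
            tr = self.transform_of(name)
            if tr == "log" and not value > 0:
                raise DomainError(f"theta[{name}]={value} must be > 0")
            if tr == "logit" and not (0.0 < value < 1.0):
                raise DomainError(f"theta[{name}]={value} must lie in (0, 1)")
        for name, value in self.omega.items():
            if value < 0:
                raise DomainError(f"omega[{name}]={value} must be >= 0")
        if self.sigma_add < 0 or self.sigma_prop < 0:
            raise DomainError("error SDs must be non-negative")
        active = {"additive": self.sigma_add, "proportional": self.sigma_prop,
                  "combined": self.sigma_add + self.sigma_prop}[self.error_model]
        if not active > 0:
            raise DomainError("at least one residual error component must be strictly positive")

    @property
    def param_names(self) -> tuple:
        canonical = STRUCTURAL_PARAMS.get(self.structural)
        if canonical is not None:
            missing = [n for n in canonical if n not in self.theta]
            if missing:
                raise DomainError(f"{self.structural} model needs theta for {missing}")
            return canonical
        return tuple(self.theta.keys())

    def transform_of(self, name: str) -> str:
        return self.transforms.get(name, _default_transform(name))

    # -- scale transforms --------------------------------------------------
    def to_phi(self, theta_vec: np.ndarray) -> np.ndarray:
        out = np.empty_like(theta_vec, dtype=float)
        for j, name in enumerate(self.param_names):
            out[..., j] = logit(theta_vec[..., j]) if self.transform_of(name) == "logit" else np.log(theta_vec[..., j])
        return out

    def to_natural(self, phi: np.ndarray) -> np.ndarray:
        out = np.empty_like(phi, dtype=float)
        for j, name in enumerate(self.param_names):
            out[..., j] = expit(phi[..., j]) if self.transform_of(name) == "logit" else np.exp(phi[..., j])
        return out

    def theta_vector(self) -> np.ndarray:
        return np.array([self.theta[n] for n in self.param_names], dtype=float)

    def omega_vector(self) -> np.ndarray:
        return np.array([self.omega.get(n, 0.0) for n in self.param_names], dtype=float)

    def results_table(self) -> pd.DataFrame:
        """Estimates in the layout of a population-parameter table."""
        rows = []
        for name in self.param_names:
            rows.append({"parameter": name, "estimate": self.theta[name], "CV%": np.nan})
        for name in self.param_names:
            om = self.omega.get(name, 0.0)
            if om > 0:
                cv = cv_percent(om) if self.transform_of(name) == "log" else np.nan
                rows.append({"parameter": f"omega_{name}", "estimate": om, "CV%": cv})
        if self.error_model in ("additive", "combined"):
            rows.append({"parameter": "sigma_add", "estimate": self.sigma_add, "CV%": np.nan})
        if self.error_model in ("proportional", "combined"):
            rows.append({"parameter": "sigma_prop", "estimate": self.sigma_prop, "CV%": np.nan})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# designs: the bridge between a dataset and a structural prediction
# ---------------------------------------------------------------------------
@dataclass
class Design:
    """Observation rows plus a row-wise structural prediction function.

    ``rowfn(X, P)`` maps the per-row covariate arrays ``X`` and a per-row
    parameter matrix ``P`` (natural scale, one row per observation) to
    predictions; everything else is bookkeeping.
    """

    y: np.ndarray
    subject_index: np.ndarray
    subject_ids: list
    param_names: tuple
    X: Dict[str, np.ndarray]
    rowfn: Callable[[Dict[str, np.ndarray], np.ndarray], np.ndarray]

    def __post_init__(self) -> None:
        self.n_subjects = len(self.subject_ids)
        self.n_obs = len(self.y)
        self.row_slices = [np.flatnonzero(self.subject_index == i) for i in range(self.n_subjects)]

    def predict(self, theta_nat: np.ndarray) -> np.ndarray:
        """Predictions for all rows given an (n_subjects, p) parameter matrix."""
        return self.rowfn(self.X, theta_nat[self.subject_index])

    def predict_subject(self, theta_i: np.ndarray, i: int) -> np.ndarray:
        rows = self.row_slices[i]
        Xi = {k: v[rows] for k, v in self.X.items()}
        P = np.broadcast_to(theta_i, (len(rows), len(theta_i)))
        return self.rowfn(Xi, P)


def _pk_rowfn_2cpt(X, P):
    return conc2_profile(P[:, 0], P[:, 1], P[:, 2], P[:, 3], X["dose"], X["t"])


def _pk_rowfn_1cpt(X, P):
    return conc1_profile(P[:, 0], P[:, 1], X["dose"], X["t"])


def build_pk_design(ds: LongitudinalDataset, structural: str) -> Design:
    """Design for the concentration data of a dataset (DVID=1, MDV=0 rows)."""
    if structural not in STRUCTURAL_PARAMS:
        raise DomainError(f"unknown structural model {structural!r}")
    obs = ds.observations(ObsType.CONC)
    subject_ids = sorted(ds.subject_ids)
    idx_of = {sid: i for i, sid in enumerate(subject_ids)}
    doses = ds.dose_per_subject()
    silent = [sid for sid in subject_ids if sid not in set(obs["ID"])]
    if silent:
        log.warning("subjects with no usable concentration rows kept at the population prior: %s", silent)
    subject_index = obs["ID"].map(idx_of).to_numpy()
    X = {"t": obs["TIME"].to_numpy(dtype=float),
         "dose": obs["ID"].map(doses).to_numpy(dtype=float)}
    rowfn = _pk_rowfn_2cpt if structural == "2cpt" else _pk_rowfn_1cpt
    return Design(y=obs["DV"].to_numpy(dtype=float), subject_index=subject_index,
                  subject_ids=subject_ids, param_names=STRUCTURAL_PARAMS[structural],
                  X=X, rowfn=rowfn)


# ---------------------------------------------------------------------------
# residual error
# ---------------------------------------------------------------------------
def _residual_sd(f: np.ndarray, error_model: str, sa: float, sp: float) -> np.ndarray:
    if error_model == "additive":
        return np.full_like(f, max(sa, 1e-12))
    if error_model == "proportional":
        return np.maximum(sp * np.abs(f), 1e-12)
    return np.sqrt(sa * sa + (sp * f) ** 2) + 1e-300


def _row_loglik(y, f, error_model, sa, sp):
    sd = _residual_sd(f, error_model, sa, sp)
    z = (y - f) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG2PI


# ---------------------------------------------------------------------------
# settings and result containers
# ---------------------------------------------------------------------------
@dataclass
class SAEMSettings:
    """Iteration schedule and reproducibility knobs for :func:`saem_fit`."""

    seed: int
    n_exploratory: int = 300
    n_smoothing: int = 200
    n_chains: int = 2
    n_sweeps: int = 2            # componentwise random-walk sweeps per iteration
    n_joint: int = 2             # adaptive joint (correlated) random-walk steps
    target_accept: float = 0.35
    adapt_rate: float = 0.08
    omega_floor: float = 1e-3
    sigma_floor: float = 1e-6
    anneal: float = 0.95         # max per-iteration shrink factor of variances in phase 1
    map_start: bool = True       # start chains at per-subject posterior modes
    compute_ofv: bool = False
    ofv_nsim: int = 1000
    compute_rse: bool = False
    rse_nsim: int = 300


@dataclass
class FitResult:
    """Population estimates with uncertainty, fit statistics and EBEs."""

    model: PopulationModel
    ebes: pd.DataFrame                 # ID + natural-scale individual parameters
    trace: pd.DataFrame
    seed: int
    settings: SAEMSettings
    n_subjects: int
    n_observations: int
    rse: Optional[Dict[str, float]] = None
    ofv: Optional[float] = None
    ofv_se: Optional[float] = None
    aic: Optional[float] = None
    bic: Optional[float] = None
    bicc: Optional[float] = None

    def results_table(self) -> pd.DataFrame:
        tab = self.model.results_table()
        if self.rse:
            tab["RSE%"] = [self.rse.get(p, np.nan) for p in tab["parameter"]]
        return tab


# ---------------------------------------------------------------------------
# scalar helpers
# ---------------------------------------------------------------------------
def cv_percent(omega: float) -> float:
    """CV% implied by a lognormal random effect: 100*sqrt(exp(omega^2)-1)."""
    if omega < 0:
        raise DomainError(f"omega must be >= 0, got {omega}")
    return 100.0 * math.sqrt(math.expm1(omega * omega))


def random_effect_correlation(covariance: float, omega1: float, omega2: float) -> float:
    """Correlation of two random effects from their covariance and SDs."""
    if not (omega1 > 0 and omega2 > 0):
        raise DomainError("omegas must be strictly positive")
    r = covariance / (omega1 * omega2)
    if abs(r) > 1.0 + 1e-12:
        raise DomainError(f"|correlation| = {abs(r):.4f} > 1: covariance matrix is invalid")
    return float(np.clip(r, -1.0, 1.0))


def information_criteria(ofv: float, n_subjects: int, n_observations: int,
                         n_subject_params: int, n_residual_params: int):
    """AIC/BIC/BICc with the hybrid (subject vs observation) BICc penalty."""
    if n_subjects <= 0 or n_observations <= 0:
        raise DomainError("counts must be positive")
    P = n_subject_params + n_residual_params
    aic = ofv + 2.0 * P
    bic = ofv + P * math.log(n_subjects)
    bicc = ofv + n_subject_params * math.log(n_subjects) + n_residual_params * math.log(n_observations)
    return aic, bic, bicc


# ---------------------------------------------------------------------------
# SAEM core
# ---------------------------------------------------------------------------
class _State:
    """Mutable estimation state on the transformed (phi) scale."""

    def __init__(self, model: PopulationModel):
        self.model = model
        self.names = model.param_names
        self.p = len(self.names)
        self.mu = model.to_phi(model.theta_vector())
        om = model.omega_vector()
        self.omega = om.copy()
        # parameters declared without IIV get an annealed auxiliary spread so
        # that the MH sampler can still move them (their omega is reported as 0)
        self.no_iiv = om == 0.0
        self.aux = np.where(self.no_iiv, 0.3, 0.0)
        self.fixed_theta = np.array([n in model.fix_theta for n in self.names])
        self.fixed_omega = np.array([n in model.fix_omega for n in self.names])
        self.sampled = ~(self.no_iiv & self.fixed_theta)
        self.sa = model.sigma_add
        self.sp = model.sigma_prop
        self.full_cov = model.full_covariance
        self.Omega = np.diag(np.maximum(self.omega, 1e-12) ** 2) if self.full_cov else None

    def spread(self) -> np.ndarray:
        """Effective per-parameter sampling SD (omega or auxiliary)."""
        if self.full_cov:
            diag = np.sqrt(np.diag(self.Omega))
        else:
            diag = self.omega
        return np.where(self.no_iiv, self.aux, np.maximum(diag, 1e-6))

    def prior_logpdf(self, phi: np.ndarray) -> np.ndarray:
        """Per-subject log-density of phi under the current population law."""
        sampled = self.sampled
        if self.full_cov and not self.no_iiv.any():
            L = np.linalg.cholesky(self.Omega + 1e-12 * np.eye(self.p))
            z = np.linalg.solve(L, (phi - self.mu).T).T
            return -0.5 * np.sum(z * z, axis=1) - np.log(np.diag(L)).sum() - 0.5 * self.p * _LOG2PI
        sd = self.spread()
        z = (phi[:, sampled] - self.mu[sampled]) / sd[sampled]
        return -0.5 * np.sum(z * z, axis=1) - np.log(sd[sampled]).sum() - 0.5 * sampled.sum() * _LOG2PI

    def natural_theta(self) -> Dict[str, float]:
        vals = self.model.to_natural(self.mu)
        return {n: float(v) for n, v in zip(self.names, vals)}

    def to_model(self) -> PopulationModel:
        omega = {n: (0.0 if self.no_iiv[j] else float(self.omega[j])) for j, n in enumerate(self.names)}
        corr = None
        if self.full_cov:
            d = np.sqrt(np.diag(self.Omega))
            corr = self.Omega / np.outer(d, d)
        return replace(self.model, theta=self.natural_theta(), omega=omega,
                       sigma_add=float(self.sa), sigma_prop=float(self.sp), omega_corr=corr)


def _subject_logliks(design: Design, model: PopulationModel, phi: np.ndarray,
                     sa: float, sp: float) -> np.ndarray:
    theta = model.to_natural(phi)
    f = design.predict(theta)
    rows = _row_loglik(design.y, f, model.error_model, sa, sp)
    return np.bincount(design.subject_index, weights=rows, minlength=design.n_subjects)


def _map_phi(design: Design, state: _State, phi0: np.ndarray) -> np.ndarray:
    """Per-subject posterior modes of phi (empirical Bayes modes)."""
    model, sampled = state.model, state.sampled
    sd = state.spread()
    out = phi0.copy()
    free = np.flatnonzero(sampled)
    if free.size == 0:
        return out
    for i in range(design.n_subjects):
        rows = design.row_slices[i]

        def nll(x, i=i, rows=rows):
            phi_i = out[i].copy()
            phi_i[free] = x
            theta_i = model.to_natural(phi_i)
            if rows.size:
                f = design.predict_subject(theta_i, i)
                ll = _row_loglik(design.y[rows], f, model.error_model, state.sa, state.sp).sum()
            else:
                ll = 0.0
            z = (phi_i[free] - state.mu[free]) / sd[free]
            return -(ll - 0.5 * np.sum(z * z))

        res = optimize.minimize(nll, out[i, free], method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 400 * free.size})
        out[i, free] = res.x
    return out


def saem_fit_design(design: Design, model: PopulationModel, settings: SAEMSettings) -> FitResult:
    """Run SAEM on an explicit :class:`Design` (used by both PK and PD stages)."""
    if design.n_subjects < 2:
        raise DesignError("SAEM requires at least 2 subjects")
    rng = np.random.default_rng(settings.seed)
    state = _State(model)
    N, p = design.n_subjects, state.p
    nc = settings.n_chains

    phi = np.tile(state.mu, (nc, N, 1))
    phi += 0.1 * state.spread() * rng.standard_normal(phi.shape) * state.sampled
    ll0 = _subject_logliks(design, model, phi[0], state.sa, state.sp)
    if not np.all(np.isfinite(ll0)):
        raise InitializationError(
            "non-finite likelihood at the initial values; rescale the initial estimates")
    if settings.map_start:
        phi_map = _map_phi(design, state, phi[0])
        phi = np.tile(phi_map, (nc, 1, 1))

    cur_ll = np.stack([_subject_logliks(design, model, phi[c], state.sa, state.sp) for c in range(nc)])

    K1, K2 = settings.n_exploratory, settings.n_smoothing
    scale = np.full(p, 0.4)
    acc_count = np.zeros(p)
    acc_tries = np.zeros(p)
    # adaptive joint kernel: explores correlated (ridge) directions of the
    # individual posteriors using the across-subject sample covariance
    joint_scale = 0.5
    joint_acc = 0.0
    joint_tries = 0.0
    joint_L: Optional[np.ndarray] = None

    # smoothed sufficient statistics
    S1 = np.zeros(p)
    S2 = np.zeros((p, p)) if state.full_cov else np.zeros(p)
    R_abs = np.zeros(design.n_obs)   # squared residuals
    R_rel = np.zeros(design.n_obs)   # squared relative residuals
    F2 = np.zeros(design.n_obs)      # squared predictions
    trace_rows = []
    free = np.flatnonzero(state.sampled)

    for k in range(1, K1 + K2 + 1):
        gamma = 1.0 if k <= K1 else 1.0 / (k - K1)

        # ---------------- E step -----------------------------------------
        sd = state.spread()
        for c in range(nc):
            # independence kernel: propose from the population law; for the
            # diagonal case prior and proposal cancel in the MH ratio
            prop = phi[c].copy()
            prop[:, free] = state.mu[free] + sd[free] * rng.standard_normal((N, free.size))
            prop_ll = _subject_logliks(design, model, prop, state.sa, state.sp)
            if state.full_cov:
                cur_prior = state.prior_logpdf(phi[c])
                prop_prior = state.prior_logpdf(prop)
                q_cur = -0.5 * np.sum(((phi[c][:, free] - state.mu[free]) / sd[free]) ** 2, axis=1)
                q_prop = -0.5 * np.sum(((prop[:, free] - state.mu[free]) / sd[free]) ** 2, axis=1)
                ratio = (prop_ll + prop_prior + q_cur) - (cur_ll[c] + cur_prior + q_prop)
            else:
                ratio = prop_ll - cur_ll[c]
            accept = np.log(rng.uniform(size=N)) < ratio
            phi[c][accept] = prop[accept]
            cur_ll[c][accept] = prop_ll[accept]

            # componentwise independence: refresh one coordinate from the
            # population law (restores prior-width dispersion for subjects
            # whose data barely constrain that coordinate)
            cur_prior = state.prior_logpdf(phi[c])
            for j in free:
                prop = phi[c].copy()
                prop[:, j] = state.mu[j] + sd[j] * rng.standard_normal(N)
                prop_ll = _subject_logliks(design, model, prop, state.sa, state.sp)
                if state.full_cov:
                    prop_prior = state.prior_logpdf(prop)
                    q_cur = -0.5 * ((phi[c][:, j] - state.mu[j]) / sd[j]) ** 2
                    q_prop = -0.5 * ((prop[:, j] - state.mu[j]) / sd[j]) ** 2
                    ratio = (prop_ll + prop_prior + q_cur) - (cur_ll[c] + cur_prior + q_prop)
                else:
                    ratio = prop_ll - cur_ll[c]
                accept = np.log(rng.uniform(size=N)) < ratio
                phi[c][accept] = prop[accept]
                cur_ll[c][accept] = prop_ll[accept]
                if state.full_cov:
                    cur_prior = np.where(accept, prop_prior, cur_prior)
            cur_prior = state.prior_logpdf(phi[c])

            # componentwise random walks
            for _ in range(settings.n_sweeps):
                for j in free:
                    prop = phi[c].copy()
                    prop[:, j] += scale[j] * sd[j] * rng.standard_normal(N)
                    prop_ll = _subject_logliks(design, model, prop, state.sa, state.sp)
                    prop_prior = state.prior_logpdf(prop)
                    ratio = (prop_ll + prop_prior) - (cur_ll[c] + cur_prior)
                    accept = np.log(rng.uniform(size=N)) < ratio
                    phi[c][accept] = prop[accept]
                    cur_ll[c][accept] = prop_ll[accept]
                    cur_prior = np.where(accept, prop_prior, cur_prior)
                    acc_count[j] += accept.sum()
                    acc_tries[j] += N

            # joint adaptive random walk along the learned covariance
            if joint_L is not None:
                for _ in range(settings.n_joint):
                    step = rng.standard_normal((N, free.size)) @ joint_L.T
                    prop = phi[c].copy()
                    prop[:, free] += joint_scale * step
                    prop_ll = _subject_logliks(design, model, prop, state.sa, state.sp)
                    prop_prior = state.prior_logpdf(prop)
                    ratio = (prop_ll + prop_prior) - (cur_ll[c] + cur_prior)
                    accept = np.log(rng.uniform(size=N)) < ratio
                    phi[c][accept] = prop[accept]
                    cur_ll[c][accept] = prop_ll[accept]
                    cur_prior = np.where(accept, prop_prior, cur_prior)
                    joint_acc += accept.sum()
                    joint_tries += N

        # learn the joint proposal shape from the pooled current samples
        pooled = phi.reshape(nc * N, p)[:, free]
        if free.size >= 2 and nc * N > 5:
            C_emp = np.cov(pooled, rowvar=False)
            C_emp += 1e-8 * np.eye(free.size) * max(np.trace(C_emp) / free.size, 1e-12)
            try:
                joint_L = np.linalg.cholesky(C_emp) * (2.38 / math.sqrt(free.size))
            except np.linalg.LinAlgError:
                joint_L = None
        if joint_tries > 0:
            joint_scale *= math.exp(settings.adapt_rate * (joint_acc / joint_tries - 0.25))
            joint_scale = float(np.clip(joint_scale, 1e-3, 10.0))
            joint_acc = joint_tries = 0.0

        # adapt random-walk scales toward the target acceptance rate
        with np.errstate(invalid="ignore"):
            rate = np.where(acc_tries > 0, acc_count / np.maximum(acc_tries, 1), settings.target_accept)
        scale *= np.exp(settings.adapt_rate * (rate - settings.target_accept))
        scale = np.clip(scale, 1e-3, 10.0)
        acc_count[:] = 0
        acc_tries[:] = 0

        # ---------------- SA step ----------------------------------------
        s1 = phi.mean(axis=0).sum(axis=0)                      # sum over subjects, mean over chains
        if state.full_cov:
            s2 = np.einsum("cnp,cnq->pq", phi, phi) / nc
        else:
            s2 = (phi ** 2).mean(axis=0).sum(axis=0)
        r_abs = np.zeros(design.n_obs)
        r_rel = np.zeros(design.n_obs)
        f2 = np.zeros(design.n_obs)
        for c in range(nc):
            f = design.predict(model.to_natural(phi[c]))
            res = design.y - f
            r_abs += res ** 2
            r_rel += (res / np.maximum(np.abs(f), 1e-12)) ** 2
            f2 += f ** 2
        r_abs /= nc
        r_rel /= nc
        f2 /= nc

        S1 += gamma * (s1 - S1)
        S2 += gamma * (s2 - S2)
        R_abs += gamma * (r_abs - R_abs)
        R_rel += gamma * (r_rel - R_rel)
        F2 += gamma * (f2 - F2)

        # ---------------- M step -----------------------------------------
        mu_new = S1 / N
        state.mu = np.where(state.fixed_theta, state.mu, mu_new)
        if state.full_cov:
            Om_new = S2 / N - np.outer(state.mu, state.mu)
            w, V = np.linalg.eigh(0.5 * (Om_new + Om_new.T))
            Om_new = (V * np.maximum(w, settings.omega_floor ** 2)) @ V.T
            if k <= K1:
                lo = settings.anneal * np.diag(state.Omega)
                d = np.maximum(np.diag(Om_new), lo)
                scale_d = np.sqrt(d / np.maximum(np.diag(Om_new), 1e-300))
                Om_new = Om_new * np.outer(scale_d, scale_d)
            state.Omega = Om_new
            state.omega = np.sqrt(np.diag(Om_new))
        else:
            var_new = np.maximum(S2 / N - state.mu ** 2, settings.omega_floor ** 2)
            if k <= K1:
                var_new = np.maximum(var_new, settings.anneal * state.omega ** 2)
            omega_new = np.sqrt(var_new)
            update = state.sampled & ~state.no_iiv & ~state.fixed_omega
            state.omega = np.where(update, omega_new, state.omega)
        state.aux = np.maximum(state.aux * 0.97, 5 * settings.omega_floor)

        sa_new, sp_new = state.sa, state.sp
        if model.error_model == "additive":
            sa_new = math.sqrt(max(R_abs.mean(), settings.sigma_floor ** 2))
        elif model.error_model == "proportional":
            sp_new = math.sqrt(max(R_rel.mean(), settings.sigma_floor ** 2))
        else:
            def neg2ll(x):
                v = x[0] ** 2 + (x[1] ** 2) * F2
                return float(np.sum(np.log(v) + R_abs / v))
            res = optimize.minimize(neg2ll, [max(state.sa, 1e-3), max(state.sp, 1e-3)],
                                    method="Nelder-Mead", options={"xatol": 1e-8, "maxiter": 200})
            sa_new, sp_new = abs(res.x[0]), abs(res.x[1])
        if k <= K1:  # annealing: variances shrink by at most `anneal` per iteration
            sa_new = max(sa_new, math.sqrt(settings.anneal) * state.sa)
            sp_new = max(sp_new, math.sqrt(settings.anneal) * state.sp)
        state.sa, state.sp = max(sa_new, settings.sigma_floor), max(sp_new, settings.sigma_floor)

        # a single mid-exploratory re-localisation of the chains at the
        # current posterior modes; sharpens convergence when the residual
        # error is (near) zero and the posterior far narrower than at start
        if settings.map_start and k == max(K1 // 2, 1) and K1 > 1:
            phi_map = _map_phi(design, state, phi.mean(axis=0))
            phi = np.tile(phi_map, (nc, 1, 1))
            cur_ll = np.stack([_subject_logliks(design, model, phi[c], state.sa, state.sp)
                               for c in range(nc)])

        row = {"iteration": k, "phase": 1 if k <= K1 else 2}
        row.update({n: v for n, v in state.natural_theta().items()})
        row.update({f"omega_{n}": (0.0 if state.no_iiv[j] else state.omega[j])
                    for j, n in enumerate(state.names)})
        row["sigma_add"] = state.sa
        row["sigma_prop"] = state.sp
        trace_rows.append(row)

    final = state.to_model()
    ebe_phi = _map_phi(design, state, phi.mean(axis=0))
    ebe_nat = final.to_natural(ebe_phi)
    ebes = pd.DataFrame(ebe_nat, columns=list(state.names))
    ebes.insert(0, "ID", design.subject_ids)

    result = FitResult(model=final, ebes=ebes, trace=pd.DataFrame(trace_rows),
                       seed=settings.seed, settings=settings,
                       n_subjects=N, n_observations=design.n_obs)
    if settings.compute_ofv or settings.compute_rse:
        ofv, ofv_se = log_likelihood_design(design, final, settings.ofv_nsim,
                                            seed=settings.seed + 101, ebe_phi=ebe_phi)
        result.ofv, result.ofv_se = ofv, ofv_se
        n_subj_params = int((~state.fixed_theta).sum() + ((~state.no_iiv) & (~state.fixed_omega)).sum())
        n_resid = {"additive": 1, "proportional": 1, "combined": 2}[model.error_model]
        result.aic, result.bic, result.bicc = information_criteria(
            ofv, N, design.n_obs, n_subj_params, n_resid)
        if settings.compute_rse:
            result.rse = _rse_bhhh(design, final, ebe_phi, settings.rse_nsim, settings.seed + 202)
    return result


def saem_fit(ds: LongitudinalDataset, model: PopulationModel, settings: SAEMSettings) -> FitResult:
    """Fit the population PK model to the concentration rows of a dataset."""
    design = build_pk_design(ds, model.structural)
    return saem_fit_design(design, model, settings)


# ---------------------------------------------------------------------------
# marginal likelihood by importance sampling
# ---------------------------------------------------------------------------
def _is_subject_loglik(design: Design, model: PopulationModel, state: _State,
                       center: np.ndarray, nsim: int, z: np.ndarray, i: int):
    """Importance-sampling log-marginal-likelihood of one subject.

    Proposal: normal centred at the EBE mode with spread 1.5x the population
    SD (inflated to cover the integrand's tails).  Parameters without
    between-subject variability are held at their population value; only the
    true random effects are integrated.
    """
    free = np.flatnonzero(state.sampled & ~state.no_iiv)
    center = center.copy()
    center[state.no_iiv] = state.mu[state.no_iiv]
    if free.size == 0:
        theta_i = model.to_natural(center)
        rows = design.row_slices[i]
        f = design.predict_subject(theta_i, i)
        return float(_row_loglik(design.y[rows], f, model.error_model, state.sa, state.sp).sum()), 0.0
    sd_prop = 1.5 * np.maximum(state.spread()[free], 0.05)
    phi_s = np.tile(center, (nsim, 1))
    phi_s[:, free] = center[free] + sd_prop * z[:, : free.size]
    theta_s = model.to_natural(phi_s)
    rows = design.row_slices[i]
    Xi = {k: np.repeat(v[rows][None, :], nsim, axis=0).ravel() for k, v in design.X.items()}
    P = np.repeat(theta_s, len(rows), axis=0)
    f = design.rowfn(Xi, P).reshape(nsim, len(rows))
    ll_rows = _row_loglik(design.y[rows], f, model.error_model, state.sa, state.sp).sum(axis=1) if rows.size else np.zeros(nsim)
    zq = (phi_s[:, free] - center[free]) / sd_prop
    log_q = -0.5 * np.sum(zq * zq, axis=1) - np.log(sd_prop).sum() - 0.5 * free.size * _LOG2PI
    sd_pr = state.spread()[free]
    zp = (phi_s[:, free] - state.mu[free]) / sd_pr
    log_prior = -0.5 * np.sum(zp * zp, axis=1) - np.log(sd_pr).sum() - 0.5 * free.size * _LOG2PI
    log_w = ll_rows + log_prior - log_q
    m = log_w.max()
    w = np.exp(log_w - m)
    mean_w = w.mean()
    ll = m + math.log(mean_w)
    var_ll = float(w.var() / (nsim * mean_w ** 2))
    return float(ll), var_ll


def log_likelihood_design(design: Design, model: PopulationModel, nsim: int,
                          seed: int, ebe_phi: Optional[np.ndarray] = None):
    """OFV (-2 log-likelihood) of a model on a design, with its Monte-Carlo SE."""
    if nsim < 2:
        raise DomainError("nsim must be >= 2")
    state = _State(model)
    if ebe_phi is None:
        ebe_phi = _map_phi(design, state, np.tile(state.mu, (design.n_subjects, 1)))
    rng = np.random.default_rng(seed)
    total, var = 0.0, 0.0
    for i in range(design.n_subjects):
        z = rng.standard_normal((nsim, state.p))
        ll, v = _is_subject_loglik(design, model, state, ebe_phi[i], nsim, z, i)
        total += ll
        var += v
    return -2.0 * total, 2.0 * math.sqrt(var)


def log_likelihood(ds: LongitudinalDataset, model: PopulationModel, nsim: int, seed: int):
    """OFV of a population PK model on a dataset (importance sampling)."""
    design = build_pk_design(ds, model.structural)
    return log_likelihood_design(design, model, nsim, seed)


def ebe_estimates(ds: LongitudinalDataset, model: PopulationModel) -> pd.DataFrame:
    """Per-subject empirical Bayes (MAP) parameter estimates, natural scale."""
    design = build_pk_design(ds, model.structural)
    return ebe_estimates_design(design, model)


def ebe_estimates_design(design: Design, model: PopulationModel) -> pd.DataFrame:
    state = _State(model)
    phi0 = np.tile(state.mu, (design.n_subjects, 1))
    phi = _map_phi(design, state, phi0)
    nat = model.to_natural(phi)
    out = pd.DataFrame(nat, columns=list(model.param_names))
    out.insert(0, "ID", design.subject_ids)
    return out


# ---------------------------------------------------------------------------
# RSE via the BHHH (score outer-product) estimator
# ---------------------------------------------------------------------------
def _pack_params(model: PopulationModel):
    names, values = [], []
    for n in model.param_names:
        if n not in model.fix_theta:
            names.append(n)
            values.append(model.theta[n])
    for n in model.param_names:
        om = model.omega.get(n, 0.0)
        if om > 0 and n not in model.fix_omega:
            names.append(f"omega_{n}")
            values.append(om)
    if model.error_model in ("additive", "combined"):
        names.append("sigma_add")
        values.append(model.sigma_add)
    if model.error_model in ("proportional", "combined"):
        names.append("sigma_prop")
        values.append(model.sigma_prop)
    return names, np.array(values, dtype=float)


def _unpack_params(model: PopulationModel, names, values) -> PopulationModel:
    theta = dict(model.theta)
    omega = dict(model.omega)
    sa, sp = model.sigma_add, model.sigma_prop
    for n, v in zip(names, values):
        if n.startswith("omega_"):
            omega[n[6:]] = v
        elif n == "sigma_add":
            sa = v
        elif n == "sigma_prop":
            sp = v
        else:
            theta[n] = v
    return replace(model, theta=theta, omega=omega, sigma_add=sa, sigma_prop=sp)


def _rse_bhhh(design: Design, model: PopulationModel, ebe_phi: np.ndarray,
              nsim: int, seed: int) -> Dict[str, float]:
    """RSE% from the outer product of per-subject score vectors.

    Scores are numeric central differences of importance-sampled per-subject
    log-likelihood contributions, with common random numbers and a fixed
    proposal so the differences are smooth in the population parameters.
    """
    names, values = _pack_params(model)
    rng = np.random.default_rng(seed)
    state0 = _State(model)
    Z = [rng.standard_normal((nsim, state0.p)) for _ in range(design.n_subjects)]

    def per_subject_ll(vals):
        m = _unpack_params(model, names, vals)
        st = _State(m)
        return np.array([
            _is_subject_loglik(design, m, st, ebe_phi[i], nsim, Z[i], i)[0]
            for i in range(design.n_subjects)
        ])

    G = np.zeros((design.n_subjects, len(names)))
    for j, v in enumerate(values):
        h = 1e-3 * max(abs(v), 1e-4)
        up, down = values.copy(), values.copy()
        up[j] += h
        down[j] = max(down[j] - h, 1e-12)
        G[:, j] = (per_subject_ll(up) - per_subject_ll(down)) / (up[j] - down[j])
    info = G.T @ G
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return {n: float(100.0 * s / abs(v)) if v != 0 else np.inf
            for n, v, s in zip(names, values, se)}


# ---------------------------------------------------------------------------
# simulation under a population model (shared by diagnostics)
# ---------------------------------------------------------------------------
def simulate_design(design: Design, model: PopulationModel, rng: np.random.Generator) -> np.ndarray:
    """One replicate of the design's observations simulated under the model."""
    state = _State(model)
    eta = np.zeros((design.n_subjects, state.p))
    sd = np.where(state.no_iiv, 0.0, state.omega)
    if model.full_covariance and state.Omega is not None:
        L = np.linalg.cholesky(state.Omega + 1e-12 * np.eye(state.p))
        eta = rng.standard_normal((design.n_subjects, state.p)) @ L.T
    else:
        eta = sd * rng.standard_normal((design.n_subjects, state.p))
    theta = model.to_natural(state.mu + eta)
    f = design.predict(theta)
    sd_res = _residual_sd(f, model.error_model, model.sigma_add, model.sigma_prop)
    return f + sd_res * rng.standard_normal(len(f))
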