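"""Sequential pharmacodynamic stage: BIS versus (biophase) concentration.

The sedation depth signal (BIS, 0-100) is related to drug exposure through
an inhibitory maximal-effect model evaluated at the effect-compartment
concentration Ce::

    E(Ce) = E0 * (1 - Imax * Ce / (Ce + IC50))                 (plain Imax)
    E(Ce) = E0 * (1 - Imax * Ce**g / (Ce**g + IC50**g))        (sigmoid Imax)

with baseline ``E0``, maximal inhibition fraction ``Imax`` in (0,1),
half-maximal biophase concentration ``IC50`` (ng/mL) and Hill exponent
``g``; the sigmoid form reduces exactly to the plain one at ``g = 1``.

Because effect lags concentration, a plot of effect against *plasma*
concentration traces a hysteresis loop.  Counterclockwise loops are the
signature of a distributional (biophase) delay and can be collapsed by
choosing the first-order equilibration rate ke0 that minimises the signed
loop area of effect against Ce(ke0); clockwise loops (proteresis) indicate
tolerance-like mechanisms and cannot be removed by a biophase, so the
collapse routine warns but proceeds when asked to collapse one.

The population PD fit is *sequential*: individual PK parameters are fixed
at their empirical Bayes estimates from the PK stage and only the PD
parameters are estimated (lognormal between-subject variability on E0 and
IC50, logit-normal on Imax, additive residual error on BIS).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .dataio import LongitudinalDataset, ObsType, get_logger
from .errors import DomainError, LinkageError, ValidationError
from .saem import Design, FitResult, PopulationModel, SAEMSettings, saem_fit_design
from .structural import (
    PKIndividualParams,
    _effect_site_profile_1cpt,
    conc_2cpt_bolus,
    conc_2cpt_infusion,
    effect_site_infusion_profile,
    effect_site_profile,
)

__all__ = [
    "PDParams",
    "HysteresisResult",
    "imax_effect",
    "sigmoid_imax_effect",
    "loop_direction",
    "collapse_hysteresis",
    "sequential_pd_fit",
    "build_pd_design",
]

log = get_logger("pdlink")


@dataclass(frozen=True)
class PDParams:
    """Pharmacodynamic parameters of one subject (or population typical values).

    E0 is the baseline BIS, Imax the maximal inhibition fraction, IC50 the
    half-maximal inhibitory biophase concentration (ng/mL), gamma the Hill
    exponent (1 = plain Imax model) and ke0 the optional biophase rate.
    """

    E0: float
    Imax: float
    IC50: float
    gamma: float = 1.0
    ke0: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.E0 <= 100.0):
            raise DomainError(f"E0={self.E0} must lie in (0, 100]")
        if not (0.0 < self.Imax < 1.0):
            raise DomainError(f"Imax={self.Imax} must lie in (0, 1)")
        if not self.IC50 > 0:
            raise DomainError(f"IC50={self.IC50} must be > 0")
        if not self.gamma > 0:
            raise DomainError(f"gamma={self.gamma} must be > 0")
        if self.ke0 is not None and not self.ke0 > 0:
            raise DomainError(f"ke0={self.ke0} must be > 0")


def _inhibition_fraction(ce, ic50, gamma):
    ce = np.asarray(ce, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(ce > 0, (ic50 / np.maximum(ce, 1e-300)) ** gamma, np.inf)
    return 1.0 / (1.0 + ratio)


def imax_effect(ce, p: PDParams):
    """Plain inhibitory Emax effect: E0*(1 - Imax*Ce/(Ce+IC50)).

    Monotone non-increasing in ``ce`` with range (E0*(1-Imax), E0].
    """
    if np.any(np.asarray(ce) < 0):
        raise DomainError("biophase concentration must be >= 0")
    return p.E0 * (1.0 - p.Imax * _inhibition_fraction(ce, p.IC50, 1.0))


def sigmoid_imax_effect(ce, p: PDParams):
    """Sigmoid (Hill) inhibitory Emax effect; gamma=1 reduces to imax_effect."""
    if np.any(np.asarray(ce) < 0):
        raise DomainError("biophase concentration must be >= 0")
    if not p.gamma > 0:
        raise DomainError("gamma must be > 0")
    return p.E0 * (1.0 - p.Imax * _inhibition_fraction(ce, p.IC50, p.gamma))


# ---------------------------------------------------------------------------
# hysteresis
# ---------------------------------------------------------------------------
@dataclass
class HysteresisResult:
    """Signed loop area, direction, and (optionally) the collapse solution.

    The sign convention follows the shoelace formula on the time-ordered
    closed polygon in the (concentration, effect) plane: positive area =
    counterclockwise (effect lags concentration), negative = clockwise
    (proteresis).  ``direction`` is "none" when |area| falls below the
    detection threshold relative to the loop's bounding box.
    """

    area: float
    direction: str
    ke0_star: Optional[float] = None
    area_uncollapsed: Optional[float] = None
    ce: Optional[np.ndarray] = None
    effect: Optional[np.ndarray] = None


#: |signed area| below this fraction of the bounding-box area counts as "no loop".
#: On a ~10-point profile an immediate (loop-free) effect still leaves ~2% of
#: box area from chord discretisation of the curved exposure-response relation;
#: genuine lag loops on such grids run an order of magnitude larger.
_AREA_REL_THRESHOLD = 0.05


def _signed_loop_area(x, y) -> float:
    """Shoelace signed area of the closed polygon through (x_k, y_k)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _classify(area: float, x, y) -> str:
    """Direction on the pharmacological response scale.

    "counterclockwise" means the response lags exposure (distributional /
    biophase delay), "clockwise" means it leads (tolerance, proteresis).
    For an inhibitory readout such as BIS — which falls as exposure rises —
    the raw geometric orientation is inverted, so the effect axis is first
    oriented by the sign of the effect-exposure association.
    """
    box = (np.max(x) - np.min(x)) * (np.max(y) - np.min(y))
    if box <= 0 or abs(area) < _AREA_REL_THRESHOLD * box:
        return "none"
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    polarity = np.sign(np.cov(x, y)[0, 1])
    oriented = area * (polarity if polarity != 0 else 1.0)
    return "counterclockwise" if oriented > 0 else "clockwise"


def loop_direction(times, conc, effect) -> HysteresisResult:
    """Signed area and direction of the effect-vs-concentration loop.

    ``times`` must be strictly increasing and align with ``conc`` and
    ``effect``; at least 4 points are required to enclose any area.  The
    reported ``area`` is the raw shoelace area in the (conc, effect) plane;
    ``direction`` is classified on the response scale (see above), and is
    meaningful when the exposure profile rises and falls within the window.
    """
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    effect = np.asarray(effect, dtype=float)
    if times.size < 4:
        raise ValidationError("at least 4 time-ordered points are required")
    if not (len(times) == len(conc) == len(effect)):
        raise ValidationError("times, conc and effect must be aligned")
    if np.any(np.diff(times) <= 0):
        raise ValidationError("times must be strictly increasing")
    area = _signed_loop_area(conc, effect)
    return HysteresisResult(area=area, direction=_classify(area, conc, effect))


def collapse_hysteresis(
    times,
    pk: PKIndividualParams,
    dose: float,
    effect,
    ke0_bounds: tuple = (1e-3, 10.0),
    n_grid: int = 60,
    tinf: Optional[float] = None,
) -> HysteresisResult:
    """Holford–Sheiner collapse: find ke0 minimising the loop area vs Ce(ke0).

    A log-spaced ke0 grid scan is refined by bounded scalar minimisation of
    |signed area|.  ``area_uncollapsed`` is the signed area against plasma
    concentration (the ke0 -> infinity limit); the returned ``ce``/``effect``
    pairs are the collapsed relation used for PD fitting.  A clockwise input
    loop is flagged with a warning (a biophase delay cannot produce it) but
    the collapse proceeds.

    The loop area is only interpretable when exposure rises and falls within
    the observation window; ``tinf`` selects the zero-order-infusion input of
    that shape (``None`` = instantaneous bolus).
    """
    times = np.asarray(times, dtype=float)
    effect = np.asarray(effect, dtype=float)
    if np.ptp(effect) == 0:
        raise DomainError("no effect dynamics to collapse (flat effect series)")
    if tinf is None:
        conc = conc_2cpt_bolus(pk, dose, times)
    else:
        conc = conc_2cpt_infusion(pk, dose, tinf, times)
    raw = loop_direction(times, conc, effect)
    if raw.direction == "clockwise":
        log.warning(
            "uncollapsed loop is clockwise (proteresis); an effect compartment "
            "addresses counterclockwise lag - proceeding anyway")

    def ce_at(ke0):
        if tinf is None:
            return effect_site_profile(pk.Cl, pk.V1, pk.Q, pk.V2, ke0, dose, times)
        return effect_site_infusion_profile(pk.Cl, pk.V1, pk.Q, pk.V2, ke0, dose, tinf, times)

    def abs_area(log_ke0):
        return abs(_signed_loop_area(ce_at(np.exp(log_ke0)), effect))

    lo, hi = np.log(ke0_bounds[0]), np.log(ke0_bounds[1])
    grid = np.linspace(lo, hi, n_grid)
    areas = np.array([abs_area(g) for g in grid])
    j = int(np.argmin(areas))
    a = grid[max(j - 1, 0)]
    b = grid[min(j + 1, n_grid - 1)]
    res = optimize.minimize_scalar(abs_area, bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-6})
    ke0_star = float(np.exp(res.x))
    ce_star = ce_at(ke0_star)
    area_star = _signed_loop_area(ce_star, effect)
    if abs(area_star) > abs(raw.area):
        # collapse must never be worse than no biophase at all
        ke0_star = float(ke0_bounds[1])
        ce_star = ce_at(ke0_star)
        area_star = _signed_loop_area(ce_star, effect)
    return HysteresisResult(
        area=area_star,
        direction=raw.direction,
        ke0_star=ke0_star,
        area_uncollapsed=raw.area,
        ce=ce_star,
        effect=effect,
    )


# ---------------------------------------------------------------------------
# sequential population PD fit
# ---------------------------------------------------------------------------
_PD_DEFAULT_INIT = {"E0": 60.0, "Imax": 0.1, "IC50": 10.0}
_PD_DEFAULT_OMEGA = {"E0": 0.3, "Imax": 0.5, "IC50": 1.0}


def build_pd_design(
    ds: LongitudinalDataset,
    ebes: pd.DataFrame,
    model_kind: str = "imax",
    ke0: Optional[float] = 0.1,
    estimate_ke0: bool = False,
) -> Design:
    """Design for the BIS rows with individual PK fixed at the EBE table.

    ``ebes`` must have an ID column plus the PK parameter columns (Cl, V1
    and, for the two-compartment model, Q and V2).
    """
    if model_kind not in ("imax", "sigmoid"):
        raise DomainError(f"unknown PD model kind {model_kind!r}")
    obs = ds.observations(ObsType.BIS)
    if len(obs) == 0:
        raise ValidationError("dataset contains no usable BIS rows")
    subject_ids = sorted(obs["ID"].unique())
    ebe_ids = set(ebes["ID"])
    missing = [sid for sid in subject_ids if sid not in ebe_ids]
    if missing:
        raise LinkageError(f"no individual PK estimate for subject(s) with BIS data: {missing}")
    idx_of = {sid: i for i, sid in enumerate(subject_ids)}
    ebe = ebes.set_index("ID")
    doses = ds.dose_per_subject()
    two_cpt = "Q" in ebe.columns and "V2" in ebe.columns

    subject_index = obs["ID"].map(idx_of).to_numpy()
    X = {
        "t": obs["TIME"].to_numpy(dtype=float),
        "dose": obs["ID"].map(doses).to_numpy(dtype=float),
        "Cl": obs["ID"].map(ebe["Cl"]).to_numpy(dtype=float),
        "V1": obs["ID"].map(ebe["V1"]).to_numpy(dtype=float),
    }
    if two_cpt:
        X["Q"] = obs["ID"].map(ebe["Q"]).to_numpy(dtype=float)
        X["V2"] = obs["ID"].map(ebe["V2"]).to_numpy(dtype=float)
    if not estimate_ke0:
        if ke0 is None or not ke0 > 0:
            raise DomainError("a fixed ke0 > 0 is required unless estimate_ke0=True")
        X["ke0"] = np.full(len(obs), float(ke0))

    param_names = ["E0", "Imax", "IC50"]
    if model_kind == "sigmoid":
        param_names.append("gamma")
    if estimate_ke0:
        param_names.append("ke0")
    name_idx = {n: j for j, n in enumerate(param_names)}

    def rowfn(Xr, P):
        ke0_row = P[:, name_idx["ke0"]] if estimate_ke0 else Xr["ke0"]
        if two_cpt:
            ce = effect_site_profile(Xr["Cl"], Xr["V1"], Xr["Q"], Xr["V2"],
                                     ke0_row, Xr["dose"], Xr["t"])
        else:
            ce = _effect_site_profile_1cpt(Xr["Cl"], Xr["V1"], ke0_row, Xr["dose"], Xr["t"])
        gamma = P[:, name_idx["gamma"]] if model_kind == "sigmoid" else 1.0
        frac = _inhibition_fraction(ce, P[:, name_idx["IC50"]], gamma)
        return P[:, name_idx["E0"]] * (1.0 - P[:, name_idx["Imax"]] * frac)

    return Design(y=obs["DV"].to_numpy(dtype=float), subject_index=subject_index,
                  subject_ids=subject_ids, param_names=tuple(param_names),
                  X=X, rowfn=rowfn)


def sequential_pd_fit(
    ds: LongitudinalDataset,
    ebes: pd.DataFrame,
    model_kind: str = "imax",
    settings: Optional[SAEMSettings] = None,
    ke0: Optional[float] = 0.1,
    estimate_ke0: bool = False,
    init_theta: Optional[Dict[str, float]] = None,
    init_omega: Optional[Dict[str, float]] = None,
    sigma_add: float = 5.0,
) -> FitResult:
    """Population SAEM fit of the PD stage with PK fixed at individual EBEs.

    Returns a :class:`FitResult` shaped like a PD parameter table (E0, Imax,
    IC50 and optionally gamma/ke0, their random-effect SDs and the additive
    residual SD on the BIS scale).
    """
    design = build_pd_design(ds, ebes, model_kind=model_kind, ke0=ke0, estimate_ke0=estimate_ke0)
    theta = dict(_PD_DEFAULT_INIT)
    omega = dict(_PD_DEFAULT_OMEGA)
    if model_kind == "sigmoid":
        theta["gamma"] = 1.5
        omega["gamma"] = 0.0
    if estimate_ke0:
        theta["ke0"] = ke0 if (ke0 and ke0 > 0) else 0.1
        omega["ke0"] = 0.0
    if init_theta:
        theta.update(init_theta)
    if init_omega:
        omega.update(init_omega)
    model = PopulationModel(structural=f"pd_{model_kind}", theta=theta, omega=omega,
                            error_model="additive", sigma_add=sigma_add)
    if settings is None:
        settings = SAEMSettings(seed=20231101)
    return saem_fit_design(design, model, settings)
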