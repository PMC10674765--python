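"""Synthetic cohorts with the statistical structure of the sedation study.

The emulated design: pediatric subjects in three age strata (preschoolers
2-5 y, schoolchildren 6-12 y, adolescents 13-17 y, default sizes 26/40/31),
each receiving a single IV bolus of 0.05 mg/kg at t=0, with three blood
samples per subject drawn uniformly without replacement from the grid
{5, 10, 15, 20, 25, 30, 45, 60, 90, 120} min and a BIS reading recorded at
each blood draw.

Concentrations follow the two-compartment bolus model with lognormal
between-subject variability and proportional residual error; BIS follows
the effect-compartment Imax model (lognormal variability on E0 and IC50,
logit-normal on Imax) with additive residual error, truncated to [0, 100].

Default population truth is the fitted pediatric midazolam parameter set
(Cl 0.48 mL/min, V1 23.59 mL, Q 5091.62 mL/min, V2 6792.42 mL; E0 57.63,
Imax 0.088, IC50 13.57 ng/mL) with its reported random-effect SDs.  The
residual-error magnitudes (20% proportional for concentration, 4 BIS units
additive), the biophase rate ke0 = 0.1/min and the age-typical weight
distributions (lognormal around 16/32/55 kg, CV 15%) are package
assumptions, configurable on the design.  Concentrations below the assay's
lower limit of quantification (default 10 ng/mL) are kept in the dataset
but flagged MDV=1 so they do not enter any likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .dataio import LongitudinalDataset, get_logger
from .errors import DesignError
from .saem import PopulationModel
from .structural import conc1_profile, conc2_profile, effect_site_profile

__all__ = [
    "Stratum",
    "CohortDesign",
    "pk_truth",
    "pd_truth",
    "generate_cohort",
    "generate_rich_cohort",
    "mean_profiles",
    "SAMPLING_GRID",
]

log = get_logger("synthetic")

SAMPLING_GRID: Tuple[float, ...] = (5, 10, 15, 20, 25, 30, 45, 60, 90, 120)


def pk_truth(sigma_prop: float = 0.2) -> PopulationModel:
    """Two-compartment population PK truth used as the default simulation law."""
    return PopulationModel(
        structural="2cpt",
        theta={"Cl": 0.48, "V1": 23.59, "Q": 5091.62, "V2": 6792.42},
        omega={"Cl": 2.66, "V1": 2.86, "Q": 1.86, "V2": 1.26},
        error_model="proportional",
        sigma_prop=sigma_prop,
    )


def pd_truth() -> Dict[str, Dict[str, float]]:
    """Default PD population truth: typical values and random-effect SDs."""
    return {
        "theta": {"E0": 57.63, "Imax": 0.088, "IC50": 13.57},
        "omega": {"E0": 0.19, "Imax": 0.78, "IC50": 2.99},
    }


@dataclass(frozen=True)
class Stratum:
    """One age stratum: size, age range (years) and weight distribution (kg)."""

    label: str
    n: int
    age_range: Tuple[int, int]
    weight_median: float
    weight_cv: float = 0.15

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise DesignError(f"stratum {self.label!r}: n must be > 0")
        if self.weight_median <= 0:
            raise DesignError(f"stratum {self.label!r}: weight median must be > 0")


def _default_strata() -> Tuple[Stratum, ...]:
    return (
        Stratum("preschoolers", 26, (2, 5), 16.0),
        Stratum("schoolchildren", 40, (6, 12), 32.0),
        Stratum("adolescents", 31, (13, 17), 55.0),
    )


@dataclass
class CohortDesign:
    """Study design + simulation truth for :func:`generate_cohort`."""

    strata: Tuple[Stratum, ...] = field(default_factory=_default_strata)
    dose_mg_per_kg: float = 0.05
    grid: Tuple[float, ...] = SAMPLING_GRID
    samples_per_subject: int = 3
    pk_model: PopulationModel = field(default_factory=pk_truth)
    pd_theta: Dict[str, float] = field(default_factory=lambda: pd_truth()["theta"])
    pd_omega: Dict[str, float] = field(default_factory=lambda: pd_truth()["omega"])
    bis_sigma_add: float = 4.0
    ke0: float = 0.1
    lloq: float = 10.0
    include_bis: bool = True
    seed: int = 20231101

    def __post_init__(self) -> None:
        grid = tuple(self.grid)
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise DesignError("sampling grid must be strictly increasing")
        if self.samples_per_subject > len(grid):
            raise DesignError("samples per subject exceeds the grid size")
        if self.dose_mg_per_kg <= 0:
            raise DesignError("dose rule must produce a positive amount")

    @property
    def n_subjects(self) -> int:
        return sum(s.n for s in self.strata)


def generate_cohort(
    design: CohortDesign,
    seed: Optional[int] = None,
    return_truth: bool = False,
    full_grid: bool = False,
):
    """Simulate one cohort; deterministic given the seed.

    Returns the :class:`LongitudinalDataset`, or ``(dataset, truth)`` when
    ``return_truth`` is set, where ``truth`` is a per-subject table of the
    simulated individual parameters (the simulation record needed for
    sequential-fit and recovery experiments).
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    pk = design.pk_model
    pk_names = list(pk.param_names)
    mu = pk.to_phi(pk.theta_vector())
    om = pk.omega_vector()
    grid = np.asarray(design.grid, dtype=float)
    n_t = len(grid) if full_grid else design.samples_per_subject

    ids, groups, ages, weights, sexes = [], [], [], [], []
    truth_rows = []
    events = []
    k = 0
    for stratum in design.strata:
        for _ in range(stratum.n):
            k += 1
            sid = f"S{k:04d}"
            age = int(rng.integers(stratum.age_range[0], stratum.age_range[1] + 1))
            sdlog = np.sqrt(np.log1p(stratum.weight_cv ** 2))
            weight = float(stratum.weight_median * np.exp(sdlog * rng.standard_normal())) if stratum.weight_cv > 0 else stratum.weight_median
            sex = "M" if rng.uniform() < 0.5 else "F"
            dose_ng = design.dose_mg_per_kg * weight * 1e6
            if not dose_ng > 0:
                raise DesignError("dose rule produced a non-positive amount")

            phi = mu + om * rng.standard_normal(len(mu))
            theta_i = {n: v for n, v in zip(pk_names, pk.to_natural(phi))}

            times = np.sort(rng.choice(grid, size=n_t, replace=False)) if not full_grid else grid

            if pk.structural == "1cpt":
                conc_true = conc1_profile(theta_i["Cl"], theta_i["V1"], dose_ng, times)
            else:
                conc_true = conc2_profile(theta_i["Cl"], theta_i["V1"], theta_i["Q"],
                                          theta_i["V2"], dose_ng, times)
            conc_obs = conc_true * (1.0 + pk.sigma_prop * rng.standard_normal(n_t))
            if pk.error_model in ("additive", "combined"):
                conc_obs = conc_obs + pk.sigma_add * rng.standard_normal(n_t)
            conc_obs = np.maximum(conc_obs, 0.0)

            pd_i = {}
            if design.include_bis:
                pd_i = {
                    "E0": float(np.exp(np.log(design.pd_theta["E0"]) + design.pd_omega["E0"] * rng.standard_normal())),
                    "Imax": float(expit(logit(design.pd_theta["Imax"]) + design.pd_omega["Imax"] * rng.standard_normal())),
                    "IC50": float(np.exp(np.log(design.pd_theta["IC50"]) + design.pd_omega["IC50"] * rng.standard_normal())),
                }
                if pk.structural == "1cpt":
                    from .structural import _effect_site_profile_1cpt

                    ce = _effect_site_profile_1cpt(theta_i["Cl"], theta_i["V1"],
                                                   design.ke0, dose_ng, times)
                else:
                    ce = effect_site_profile(theta_i["Cl"], theta_i["V1"], theta_i["Q"],
                                             theta_i["V2"], design.ke0, dose_ng, times)
                bis_clean = pd_i["E0"] * (1.0 - pd_i["Imax"] * ce / (ce + pd_i["IC50"]))
                bis_obs = np.clip(bis_clean + design.bis_sigma_add * rng.standard_normal(n_t), 0.0, 100.0)

            events.append({"ID": sid, "TIME": 0.0, "AMT": dose_ng, "DV": np.nan,
                           "DVID": 0, "EVID": 1, "MDV": 1})
            for j, t in enumerate(times):
                blq = conc_obs[j] < design.lloq
                events.append({"ID": sid, "TIME": float(t), "AMT": np.nan,
                               "DV": float(conc_obs[j]), "DVID": 1, "EVID": 0,
                               "MDV": 1 if blq else 0})
            if design.include_bis:
                for j, t in enumerate(times):
                    events.append({"ID": sid, "TIME": float(t), "AMT": np.nan,
                                   "DV": float(bis_obs[j]), "DVID": 2, "EVID": 0,
                                   "MDV": 0})

            ids.append(sid)
            groups.append(stratum.label)
            ages.append(age)
            weights.append(weight)
            sexes.append(sex)
            truth_rows.append({"ID": sid, "WEIGHT": weight, "DOSE": dose_ng,
                               **theta_i, **pd_i, "ke0": design.ke0})

    covariates = pd.DataFrame({"ID": ids, "GROUP": groups, "AGE": ages,
                               "WEIGHT": weights, "SEX": sexes})
    ds = LongitudinalDataset(pd.DataFrame(events), covariates)
    if return_truth:
        return ds, pd.DataFrame(truth_rows)
    return ds


def generate_rich_cohort(design: CohortDesign, seed: Optional[int] = None,
                         return_truth: bool = False):
    """As :func:`generate_cohort` but observing every grid time per subject."""
    return generate_cohort(design, seed=seed, return_truth=return_truth, full_grid=True)


def mean_profiles(ds: LongitudinalDataset, grid: Optional[Tuple[float, ...]] = None) -> pd.DataFrame:
    """Per-time mean concentration and mean BIS with SEM (population profile).

    The output is the input to the population-level (mean-profile)
    hysteresis analysis.  Times with a single observation get SEM = NaN;
    grid times with no observation are dropped with a warning.
    """
    from .dataio import ObsType

    rows = []
    times = sorted(set(grid)) if grid is not None else sorted(ds.observations()["TIME"].unique())
    conc = ds.observations(ObsType.CONC)
    bis = ds.observations(ObsType.BIS)
    for t in times:
        c = conc.loc[conc["TIME"] == t, "DV"].to_numpy()
        b = bis.loc[bis["TIME"] == t, "DV"].to_numpy()
        if len(c) == 0 and len(b) == 0:
            log.warning("no observations at t=%g; bin dropped", t)
            continue
        rows.append({
            "TIME": float(t),
            "conc_mean": float(c.mean()) if len(c) else np.nan,
            "conc_sem": float(c.std(ddof=1) / np.sqrt(len(c))) if len(c) > 1 else np.nan,
            "conc_n": len(c),
            "bis_mean": float(b.mean()) if len(b) else np.nan,
            "bis_sem": float(b.std(ddof=1) / np.sqrt(len(b))) if len(b) > 1 else np.nan,
            "bis_n": len(b),
        })
    return pd.DataFrame(rows)
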