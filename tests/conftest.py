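import numpy as np
import pandas as pd
import pytest

from sedmix.dataio import LongitudinalDataset
from sedmix.saem import PopulationModel, SAEMSettings
from sedmix.structural import EffectSiteParams, PKIndividualParams
from sedmix.synthetic import CohortDesign, Stratum


@pytest.fixture
def published_pk() -> PKIndividualParams:
    """Typical pediatric midazolam two-compartment parameters (mL, mL/min)."""
    return PKIndividualParams(Cl=0.48, V1=23.59, Q=5091.62, V2=6792.42)


@pytest.fixture
def biophase() -> EffectSiteParams:
    return EffectSiteParams(ke0=0.1)


@pytest.fixture
def study_grid() -> np.ndarray:
    return np.array([5.0, 10, 15, 20, 25, 30, 45, 60, 90, 120])


@pytest.fixture
def toy_dataset() -> LongitudinalDataset:
    """Two subjects, one bolus each, three concentration observations each."""
    rows = []
    for sid, dose in (("A", 1.0e6), ("B", 2.0e6)):
        rows.append({"ID": sid, "TIME": 0.0, "AMT": dose, "DV": np.nan,
                     "DVID": 0, "EVID": 1, "MDV": 1})
        for t, dv in ((5.0, 150.0), (30.0, 120.0), (120.0, 90.0)):
            rows.append({"ID": sid, "TIME": t, "AMT": np.nan, "DV": dv,
                         "DVID": 1, "EVID": 0, "MDV": 0})
    cov = pd.DataFrame({"ID": ["A", "B"], "GROUP": ["preschoolers", "adolescents"],
                        "AGE": [4, 15], "WEIGHT": [20.0, 40.0], "SEX": ["M", "F"]})
    return LongitudinalDataset(pd.DataFrame(rows), cov)


@pytest.fixture
def identifiable_truth() -> PopulationModel:
    """A 2-cpt law whose both phases are visible on the 5-120 min grid."""
    return PopulationModel(
        structural="2cpt",
        theta={"Cl": 40.0, "V1": 1000.0, "Q": 50.0, "V2": 3000.0},
        omega={"Cl": 0.3, "V1": 0.3, "Q": 0.3, "V2": 0.3},
        error_model="proportional",
        sigma_prop=0.15,
    )


def small_design(n: int, model: PopulationModel, seed: int, include_bis: bool = False) -> CohortDesign:
    return CohortDesign(
        strata=(Stratum("test", n, (2, 17), 20.0, weight_cv=0.0),),
        pk_model=model,
        include_bis=include_bis,
        seed=seed,
    )


def fast_settings(seed: int, **kw) -> SAEMSettings:
    base = dict(n_exploratory=100, n_smoothing=60, n_chains=1)
    base.update(kw)
    return SAEMSettings(seed=seed, **base)
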