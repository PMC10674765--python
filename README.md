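# sedmix

Population PK-PD modelling of intravenous bolus sedation in children:
two-compartment mixed-effects pharmacokinetics estimated by SAEM, a
sequential effect-compartment Imax stage for the Bispectral Index (BIS),
hysteresis-loop analysis, and simulation-based diagnostics (NPDE, pc-VPC).

The package is aimed at pharmacometricians working with sparse pediatric
sedation studies: a cohort receives a single IV midazolam bolus
(0.05 mg/kg), three blood samples per child are drawn from a randomized
grid between 5 and 120 min, and depth of sedation is scored by BIS at each
draw. `sedmix` provides the full analysis pipeline for such data plus a
synthetic-cohort generator that emulates the design, so every stage is
testable end to end without patient data.

## Models

PK: two-compartment IV bolus disposition,

    C(t) = (D/V1) · (A·e^(−αt) + B·e^(−βt)),

with lognormal between-subject variability `θ_i = θ_p·e^η`, `η ~ N(0, ω²)`,
and additive/proportional/combined residual error, estimated by SAEM
(MCMC E-step, stochastic-approximation M-step), with OFV/AIC/BIC/BICc by
importance sampling.

PD (sequential, PK fixed at individual estimates): effect-compartment
concentration `dCe/dt = ke0·(C − Ce)` driving an inhibitory Emax model,

    BIS = E0 · (1 − Imax·Ce^γ / (Ce^γ + IC50^γ)),      γ = 1 by default,

with hysteresis-loop direction detection and Holford–Sheiner collapse
(choose ke0 minimising the loop area) as separable operations.

Units package-wide: minutes, ng, mL, mL/min, ng/mL; BIS on 0–100.

## Worked example

```python
from sedmix import (CohortDesign, generate_cohort, PopulationModel,
                    SAEMSettings, saem_fit, sequential_pd_fit)

design = CohortDesign(seed=42)          # 97 children, 3 strata, sparse sampling
ds = generate_cohort(design)

init = PopulationModel(structural="2cpt",
                       theta={"Cl": 0.5, "V1": 20.0, "Q": 5000.0, "V2": 7000.0},
                       omega={"Cl": 3.0, "V1": 3.0, "Q": 2.0, "V2": 1.0},
                       error_model="proportional", sigma_prop=0.2)
fit = saem_fit(ds, init, SAEMSettings(seed=43, compute_ofv=True))
print(fit.results_table())
pd_fit = sequential_pd_fit(ds, fit.ebes, settings=SAEMSettings(seed=44), ke0=0.1)
print(pd_fit.results_table())
```

Output (abridged):

     parameter  estimate     CV%
            V2   5675.32     NaN
      omega_V2      1.20  180.37
    sigma_prop      0.20     NaN
    OFV 3610.7  BIC 3651.9

     parameter  estimate     CV%
            E0    56.975     NaN
      omega_E0     0.184   18.58
     sigma_add     3.760     NaN

Reading the numbers: from 97 children with 3 samples each, the total
volume of distribution (V2 ≈ 5.7 L vs the generating 6.8 L), its
variability, the residual error and the PD baseline (E0 ≈ 57.0 vs 57.63)
are recovered well, while Cl, V1 and Q come back with order-of-magnitude
scatter — the flat concentration profile of this regime carries almost no
information about them (the corresponding published relative standard
errors are ≈140–150%). `docs/methods.md` discusses this identifiability
limit in detail.

## Command line

A thin CLI wires the stages with YAML configs, explicit seeds, and CSV/PNG
outputs:

    sedmix simulate  --seed 7 --out run/
    sedmix fit-pk    --data run/cohort.csv --out run/ --compare
    sedmix fit-pd    --data run/cohort.csv --pk-fit run/ --out run/pd/
    sedmix diagnose  --data run/cohort.csv --pk-fit run/ --out run/diag/
    sedmix hysteresis --data run/cohort.csv --pk-fit run/ --out run/hyst/

Exit codes: 0 success, 2 validation/format, 3 convergence, 4 missing
upstream stage.

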