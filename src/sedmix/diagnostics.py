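"""Simulation-based model evaluation: NPDE, pc-VPC, observed vs predicted.

All diagnostics are deterministic given (dataset, model, seed): replicate
datasets are simulated under the population model with the original design
(same subjects, doses and sampling times), and the observed data are located
within the simulated reference distribution.

* **NPDE** (normalized prediction distribution errors): per subject, the
  observed and simulated observation vectors are decorrelated with the
  inverse Cholesky factor of the empirical simulated covariance; each
  decorrelated observation's rank among its decorrelated simulations gives a
  prediction discrepancy that is mapped through the inverse normal CDF.
  Under a correct model the NPDE are standard normal.
* **pc-VPC** (prediction-corrected visual predictive check): observations
  and simulations are rescaled by ``median bin population prediction /
  row population prediction`` before computing time-binned percentiles, and
  the observed percentiles are compared with 95% confidence bands of the
  same percentiles across simulated replicates.
* **observed vs individual-predicted** pairs with the identity-line trend
  and the fraction of points inside the 90% prediction interval implied by
  the residual-error model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .dataio import LongitudinalDataset, get_logger
from .errors import DomainError
from .saem import (
    Design,
    FitResult,
    PopulationModel,
    _residual_sd,
    build_pk_design,
    simulate_design,
)

__all__ = [
    "DiagnosticsBundle",
    "npde",
    "npde_design",
    "pc_vpc",
    "pc_vpc_design",
    "obs_vs_pred",
    "plot_obs_vs_pred",
    "plot_npde",
    "plot_pc_vpc",
]

log = get_logger("diagnostics")


@dataclass
class DiagnosticsBundle:
    """Container for the three diagnostic products of one fit."""

    obs_pred: pd.DataFrame
    obs_pred_summary: dict
    npde: pd.DataFrame
    vpc: pd.DataFrame
    vpc_summary: dict
    nsim: int
    seed: int


# ---------------------------------------------------------------------------
# NPDE
# ---------------------------------------------------------------------------
def npde_design(design: Design, model: PopulationModel, nsim: int, seed: int) -> pd.DataFrame:
    if nsim < 100:
        raise DomainError("NPDE needs nsim >= 100")
    rng = np.random.default_rng(seed)
    sims = np.stack([simulate_design(design, model, rng) for _ in range(nsim)])
    values = np.empty(design.n_obs)
    for i, rows in enumerate(design.row_slices):
        if rows.size == 0:
            continue
        Y = design.y[rows]
        S = sims[:, rows]                       # (nsim, n_i)
        m = S.mean(axis=0)
        C = np.atleast_2d(np.cov(S, rowvar=False))
        try:
            L = np.linalg.cholesky(C + 1e-10 * np.eye(rows.size) * max(np.trace(C) / rows.size, 1e-30))
            y_star = np.linalg.solve(L, Y - m)
            s_star = np.linalg.solve(L, (S - m).T)   # (n_i, nsim)
        except np.linalg.LinAlgError:
            log.warning("singular simulated covariance for subject %s; variance-only decorrelation",
                        design.subject_ids[i])
            sd = np.sqrt(np.maximum(np.diag(C), 1e-30))
            y_star = (Y - m) / sd
            s_star = ((S - m) / sd).T
        below = (s_star < y_star[:, None]).sum(axis=1)
        ties = (s_star == y_star[:, None]).sum(axis=1)
        u = rng.uniform(size=rows.size)
        pd_val = (below + u * (ties + 1.0)) / (nsim + 1.0)
        pd_val = np.clip(pd_val, 1.0 / (2.0 * nsim), 1.0 - 1.0 / (2.0 * nsim))
        values[rows] = ndtri(pd_val)
    out = pd.DataFrame({
        "ID": np.asarray(design.subject_ids, dtype=object)[design.subject_index],
        "TIME": design.X["t"],
        "DV": design.y,
        "NPDE": values,
    })
    return out


def npde(ds: LongitudinalDataset, model: PopulationModel, nsim: int, seed: int) -> pd.DataFrame:
    """NPDE for the concentration data of a dataset under a population model."""
    return npde_design(build_pk_design(ds, model.structural), model, nsim, seed)


# ---------------------------------------------------------------------------
# pc-VPC
# ---------------------------------------------------------------------------
def _bin_edges_from_times(times: np.ndarray) -> np.ndarray:
    """Edges midway between the distinct design times (design-based binning)."""
    uniq = np.unique(times)
    mids = 0.5 * (uniq[1:] + uniq[:-1])
    return np.concatenate([[uniq[0] - 0.5], mids, [uniq[-1] + 0.5]])


def pc_vpc_design(
    design: Design,
    model: PopulationModel,
    nsim: int,
    seed: int,
    bins: Optional[Sequence[float]] = None,
    percentiles: Sequence[float] = (5.0, 50.0, 95.0),
    ci: float = 95.0,
):
    if nsim < 200:
        raise DomainError("pc-VPC needs nsim >= 200")
    rng = np.random.default_rng(seed)
    t = design.X["t"]
    edges = np.asarray(bins, dtype=float) if bins is not None else _bin_edges_from_times(t)
    which = np.digitize(t, edges) - 1
    n_bins = len(edges) - 1

    state_theta = model.theta_vector()
    pop = design.predict(np.tile(state_theta, (design.n_subjects, 1)))
    ok = pop > 0
    if not ok.all():
        log.warning("%d rows with non-positive population prediction excluded from pc-VPC", (~ok).sum())

    sims = np.stack([simulate_design(design, model, rng) for _ in range(nsim)])

    lo_q, hi_q = (100.0 - ci) / 2.0, 100.0 - (100.0 - ci) / 2.0
    rows_out = []
    n_outside = 0
    n_points = 0
    for b in range(n_bins):
        mask = (which == b) & ok
        if mask.sum() == 0:
            log.warning("empty pc-VPC bin [%g, %g) dropped", edges[b], edges[b + 1])
            continue
        med_pop = np.median(pop[mask])
        corr = med_pop / pop[mask]
        pc_obs = design.y[mask] * corr
        pc_sim = sims[:, mask] * corr           # (nsim, n_b)
        row = {"bin_mid": float(np.median(t[mask])), "n_obs": int(mask.sum())}
        for q in percentiles:
            obs_q = float(np.percentile(pc_obs, q))
            sim_q = np.percentile(pc_sim, q, axis=1)
            lo, hi = np.percentile(sim_q, [lo_q, hi_q])
            row[f"obs_p{q:g}"] = obs_q
            row[f"sim_lo_p{q:g}"] = float(lo)
            row[f"sim_hi_p{q:g}"] = float(hi)
            row[f"sim_med_p{q:g}"] = float(np.median(sim_q))
            n_points += 1
            if not (lo <= obs_q <= hi):
                n_outside += 1
        rows_out.append(row)
    table = pd.DataFrame(rows_out)
    summary = {
        "n_percentile_points": n_points,
        "n_outside_band": n_outside,
        "fraction_outside": n_outside / n_points if n_points else np.nan,
        "nsim": nsim,
        "seed": seed,
    }
    return table, summary


def pc_vpc(ds: LongitudinalDataset, model: PopulationModel, nsim: int, seed: int,
           bins: Optional[Sequence[float]] = None,
           percentiles: Sequence[float] = (5.0, 50.0, 95.0)):
    """Prediction-corrected VPC table and out-of-band summary for CONC data."""
    return pc_vpc_design(build_pk_design(ds, model.structural), model, nsim, seed,
                         bins=bins, percentiles=percentiles)


# ---------------------------------------------------------------------------
# observed vs individual predictions
# ---------------------------------------------------------------------------
def obs_vs_pred(ds: LongitudinalDataset, fit: FitResult):
    """Observed vs individual-predicted pairs with identity-line summary.

    Returns ``(table, summary)`` where summary holds the trend-line slope and
    intercept and the fraction of observations inside the 90% prediction
    interval implied by the residual-error model.
    """
    design = build_pk_design(ds, fit.model.structural)
    ebe = fit.ebes.set_index("ID").loc[list(design.subject_ids)]
    theta = ebe[list(design.param_names)].to_numpy(dtype=float)
    ipred = design.predict(theta)
    table = pd.DataFrame({
        "ID": np.asarray(design.subject_ids, dtype=object)[design.subject_index],
        "TIME": design.X["t"],
        "observed": design.y,
        "ipred": ipred,
    })
    slope, intercept = np.polyfit(ipred, design.y, 1)
    sd = _residual_sd(ipred, fit.model.error_model, fit.model.sigma_add, fit.model.sigma_prop)
    inside = np.abs(design.y - ipred) <= 1.6448536269514722 * sd
    summary = {
        "slope": float(slope),
        "intercept": float(intercept),
        "fraction_in_90pi": float(inside.mean()),
        "n": int(len(ipred)),
    }
    return table, summary


# ---------------------------------------------------------------------------
# plots (CLI surface)
# ---------------------------------------------------------------------------
def _savefig(fig, path):
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    import matplotlib.pyplot as plt

    plt.close(fig)


def plot_obs_vs_pred(table: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.loglog(table["ipred"], table["observed"], "o", ms=3, alpha=0.5)
    lim = [min(table["ipred"].min(), table["observed"].min()),
           max(table["ipred"].max(), table["observed"].max())]
    ax.plot(lim, lim, "k--", lw=1)
    ax.set_xlabel("individual prediction (ng/mL)")
    ax.set_ylabel("observed (ng/mL)")
    _savefig(fig, path)


def plot_npde(table: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].plot(table["TIME"], table["NPDE"], "o", ms=3, alpha=0.5)
    axes[0].axhline(0, color="k", lw=1)
    for y in (-3, 3):
        axes[0].axhline(y, color="r", ls="--", lw=1)
    axes[0].set_xlabel("time (min)")
    axes[0].set_ylabel("NPDE")
    axes[1].hist(table["NPDE"], bins=20, density=True, alpha=0.7)
    x = np.linspace(-4, 4, 200)
    axes[1].plot(x, np.exp(-0.5 * x * x) / np.sqrt(2 * np.pi), "k-", lw=1)
    axes[1].set_xlabel("NPDE")
    _savefig(fig, path)


def plot_pc_vpc(table: pd.DataFrame, path, percentiles=(5.0, 50.0, 95.0)) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for q in percentiles:
        ax.fill_between(table["bin_mid"], table[f"sim_lo_p{q:g}"], table[f"sim_hi_p{q:g}"],
                        alpha=0.25)
        ax.plot(table["bin_mid"], table[f"obs_p{q:g}"], "-o", ms=3, label=f"obs p{q:g}")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("prediction-corrected concentration (ng/mL)")
    ax.legend(fontsize=8)
    _savefig(fig, path)
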