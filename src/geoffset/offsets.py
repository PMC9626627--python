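"""Climate maladaptation metrics: RONA and the three genomic offsets.

RONA (risk of non-adaptedness) is the mean absolute allele-frequency shift
required by a population to track a projected climate, read off per-locus
linear regressions of allele frequency on the current value of a variable
and weighted by the regression R^2.

Genomic offsets are Euclidean distances in turnover-transformed climate
space: local (same place, current vs future), forward (minimum over
destinations reachable within a dispersal cap), and reverse (minimum over
contemporary source populations for a location's future climate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import AlleleFreqMatrix, EnvMatrix
from .landscape import haversine_km
from .turnover import TurnoverModel, transform_climate


# ---------------------------------------------------------------------------
# RONA
# ---------------------------------------------------------------------------

@dataclass
class RonaTable:
    per_model: pd.DataFrame  # population, variable, model, scenario, rona
    summary: pd.DataFrame  # population, variable, scenario, mean, se
    regressions: pd.DataFrame  # variant_id, variable, intercept, slope, r2


def _locus_regressions(F: AlleleFreqMatrix, x: np.ndarray, loci: Sequence[str]) -> pd.DataFrame:
    sub = F.subset_variants(list(loci))
    Y = sub.imputed()
    xc = x - x.mean()
    ssx = (xc**2).sum()
    slope = (xc @ (Y - Y.mean(axis=0))) / ssx
    intercept = Y.mean(axis=0) - slope * x.mean()
    fitted = intercept + np.outer(x, slope)
    ss_res = ((Y - fitted) ** 2).sum(axis=0)
    ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    return pd.DataFrame(
        {"variant_id": list(loci), "intercept": intercept, "slope": slope, "r2": r2}
    )


def rona(
    F: AlleleFreqMatrix,
    assoc: Mapping[str, Sequence[str]],
    E_cur: EnvMatrix,
    E_futs: Sequence[EnvMatrix],
    weight_by_r2: bool = True,
) -> RonaTable:
    """RONA per (population, variable, climate model, scenario).

    For each variable and associated locus, fit p = a + b*e on current
    climate across populations; per population the locus RONA under a future
    slice is |clip01(a + b*e_fut) - clip01(a + b*e_cur)|, and the population
    RONA is the R^2-weighted mean over loci.  Per-scenario means and SEs are
    taken across climate models.
    """
    pops = F.populations
    if len(pops) < 3:
        raise ValueError("RONA regressions need at least 3 populations")
    E_cur = E_cur.reindex(pops)
    reg_frames = []
    rows = []
    for var, loci in assoc.items():
        if len(loci) == 0:
            warnings.warn(f"variable {var!r} has no associated loci; skipped")
            continue
        x = E_cur.column(var)
        reg = _locus_regressions(F, x, loci)
        reg.insert(0, "variable", var)
        reg_frames.append(reg)
        a = reg["intercept"].to_numpy()
        b = reg["slope"].to_numpy()
        w = reg["r2"].to_numpy() if weight_by_r2 else np.ones(len(reg))
        w_sum = w.sum()
        if w_sum == 0:
            w = np.ones(len(reg))
            w_sum = w.sum()
        p_cur = np.clip(a + np.outer(x, b), 0.0, 1.0)
        for E_fut in E_futs:
            x_fut = E_fut.reindex(pops).column(var)
            p_fut = np.clip(a + np.outer(x_fut, b), 0.0, 1.0)
            shift = np.abs(p_fut - p_cur)  # pops x loci
            pop_rona = shift @ w / w_sum
            for pop, val in zip(pops, pop_rona):
                rows.append((pop, var, E_fut.model, E_fut.scenario, val))
    per_model = pd.DataFrame(rows, columns=["population", "variable", "model", "scenario", "rona"])
    if per_model.empty:
        raise ValueError("no variables with associated loci")
    grouped = per_model.groupby(["population", "variable", "scenario"])["rona"]
    summary = grouped.agg(["mean", "sem"]).rename(columns={"sem": "se"}).reset_index()
    summary["se"] = summary["se"].fillna(0.0)
    regressions = pd.concat(reg_frames, ignore_index=True)
    return RonaTable(per_model, summary, regressions)


# ---------------------------------------------------------------------------
# Genomic offsets in turnover space
# ---------------------------------------------------------------------------

def local_offset(model: TurnoverModel, E_cur: EnvMatrix, E_fut: EnvMatrix) -> pd.Series:
    """Per-site Euclidean distance between transformed current and future
    climate at the same site."""
    if E_cur.site_ids != E_fut.site_ids:
        raise ValueError("current and future grids must share cells")
    T_cur = transform_climate(model, E_cur).to_numpy()
    T_fut = transform_climate(model, E_fut).to_numpy()
    d = np.sqrt(((T_cur - T_fut) ** 2).sum(axis=1))
    return pd.Series(d, index=E_cur.site_ids, name="local_offset")


def forward_offset(
    model: TurnoverModel,
    sources_cur: EnvMatrix,
    source_coords: pd.DataFrame,
    grid_fut: EnvMatrix,
    grid_coords: pd.DataFrame,
    d_max: Sequence[float] = (100.0, 250.0, 500.0, 1000.0, np.inf),
) -> pd.DataFrame:
    """Minimum offset each source can achieve by migrating within a cap.

    Returns sources x caps (columns ``forward_100`` ... ``forward_inf``, km).
    An empty reachable set yields NaN with a warning.
    """
    T_src = transform_climate(model, sources_cur).to_numpy()
    T_fut = transform_climate(model, grid_fut).to_numpy()
    dist_genomic = np.sqrt(
        ((T_src[:, None, :] - T_fut[None, :, :]) ** 2).sum(axis=2)
    )  # sources x cells
    km = haversine_km(
        source_coords["lon"].to_numpy()[:, None],
        source_coords["lat"].to_numpy()[:, None],
        grid_coords["lon"].to_numpy()[None, :],
        grid_coords["lat"].to_numpy()[None, :],
    )
    out = {}
    for cap in d_max:
        masked = np.where(km <= cap, dist_genomic, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vals = np.nanmin(masked, axis=1)
        if np.isnan(vals).any():
            warnings.warn(f"some sources reach no grid cell within {cap} km")
        label = "forward_inf" if np.isinf(cap) else f"forward_{int(cap)}"
        out[label] = vals
    return pd.DataFrame(out, index=sources_cur.site_ids)


def reverse_offset(
    model: TurnoverModel, pops_cur: EnvMatrix, grid_fut: EnvMatrix
) -> pd.Series:
    """Per-cell minimum offset between the cell's future climate and any
    contemporary population's current climate."""
    if len(pops_cur.site_ids) < 1:
        raise ValueError("need at least one contemporary population")
    T_pop = transform_climate(model, pops_cur).to_numpy()
    T_fut = transform_climate(model, grid_fut).to_numpy()
    d = np.sqrt(((T_fut[:, None, :] - T_pop[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
    return pd.Series(d, index=grid_fut.site_ids, name="reverse_offset")


def average_models(
    per_model: Mapping[str, pd.Series | pd.DataFrame]
) -> tuple[pd.Series | pd.DataFrame, pd.Series | pd.DataFrame, pd.DataFrame]:
    """Arithmetic mean and SE across climate models plus the pairwise
    Pearson correlation matrix of per-model values."""
    names = list(per_model)
    frames = [per_model[m] for m in names]
    first = frames[0]
    for f in frames[1:]:
        if not f.index.equals(first.index):
            raise ValueError("per-model inputs must share their index")
        if isinstance(f, pd.DataFrame) and not f.columns.equals(first.columns):
            raise ValueError("per-model inputs must share their columns")
    stack = np.stack([np.asarray(f, dtype=float) for f in frames])
    mean = stack.mean(axis=0)
    se = stack.std(axis=0, ddof=1) / np.sqrt(len(frames)) if len(frames) > 1 else np.zeros_like(mean)
    flat = stack.reshape(len(frames), -1)
    corr = np.corrcoef(flat) if len(frames) > 1 else np.ones((1, 1))
    wrap = (lambda a: pd.DataFrame(a, index=first.index, columns=first.columns)) if isinstance(
        first, pd.DataFrame
    ) else (lambda a: pd.Series(a, index=first.index))
    return wrap(mean), wrap(se), pd.DataFrame(corr, index=names, columns=names)


def rgb_composite(local: pd.Series, forward: pd.Series, reverse: pd.Series) -> pd.DataFrame:
    """Min-max scale each metric over the grid to [0, 255] (rounded half-up)
    as the red/green/blue channels; a constant metric maps to 0."""
    def scale(s: pd.Series) -> np.ndarray:
        v = s.to_numpy(float)
        rng = v.max() - v.min()
        if rng == 0:
            return np.zeros(len(v), dtype=int)
        return np.floor((v - v.min()) / rng * 255.0 + 0.5).astype(int)

    if not (local.index.equals(forward.index) and local.index.equals(reverse.index)):
        raise ValueError("RGB channels must be aligned on the same grid")
    return pd.DataFrame(
        {"R": scale(local), "G": scale(forward), "B": scale(reverse)}, index=local.index
    )
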