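"""Population-genetic statistics: Weir-Cockerham F_ST, nucleotide diversity,
LD pruning, PCA structure proxies, and the adaptive-vs-random F_ST contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import MISSING, GenotypeMatrix, PopulationMap


@dataclass
class FstResult:
    """Multi-site Weir-Cockerham theta plus per-site variance components.

    ``theta`` is the ratio-of-sums estimate over all populations;
    ``pairwise`` holds the same estimator computed for every population pair
    (the estimator can be negative for undifferentiated pairs and is kept
    unclamped here).  ``components`` retains per-site a (among-population),
    b (among individuals within populations) and c (within individuals).
    """

    theta: float
    pairwise: pd.DataFrame
    components: pd.DataFrame  # index variant_id, columns a, b, c

    def __post_init__(self) -> None:
        P = self.pairwise.to_numpy()
        if not np.allclose(P, P.T, equal_nan=True):
            raise ValueError("pairwise F_ST matrix must be symmetric")
        np.fill_diagonal(P, 0.0)
        self.pairwise = pd.DataFrame(P, index=self.pairwise.index, columns=self.pairwise.columns)


def _pop_site_summaries(G: GenotypeMatrix, M: PopulationMap, pops: Sequence[str]):
    """Per population and site: called sample size n, alt freq p, het rate h."""
    labels = M.pop_of(G.individuals)
    dos = G.dosage
    called = dos != MISSING
    n = np.empty((len(pops), G.n_var))
    p = np.empty_like(n)
    h = np.empty_like(n)
    for i, pop in enumerate(pops):
        rows = labels == pop
        sub, subc = dos[rows], called[rows]
        ni = subc.sum(axis=0)
        n[i] = ni
        with np.errstate(invalid="ignore", divide="ignore"):
            p[i] = np.where(ni > 0, np.where(subc, sub, 0).sum(axis=0) / (2 * np.maximum(ni, 1)), np.nan)
            h[i] = np.where(ni > 0, ((sub == 1) & subc).sum(axis=0) / np.maximum(ni, 1), np.nan)
    return n, p, h


def wc_site_components(
    G: GenotypeMatrix, M: PopulationMap, pops: Sequence[str] | None = None
) -> pd.DataFrame:
    """Weir & Cockerham (1984) per-site variance components a, b, c.

    Sites where any contributing population has no called individuals are
    returned as NaN (excluded from ratio-of-sums aggregation).
    """
    pops = list(pops) if pops is not None else M.populations
    if len(pops) < 2:
        raise ValueError("F_ST requires at least 2 populations")
    n, p, h = _pop_site_summaries(G, M, pops)
    r = len(pops)
    usable = (n >= 1).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n.mean(axis=0)
        nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    comp = np.column_stack([a, b, c])
    comp[~usable] = np.nan
    return pd.DataFrame(comp, index=G.variants, columns=["a", "b", "c"])


def theta_from_components(comp: pd.DataFrame) -> float:
    """Ratio-of-sums ("weighted") multi-site theta; NaN component sites skipped."""
    arr = comp.to_numpy()
    ok = ~np.isnan(arr).any(axis=1)
    denom = arr[ok].sum(axis=0)
    total = denom.sum()
    if total == 0:
        return np.nan
    return float(denom[0] / total)


def weir_cockerham_fst(
    G: GenotypeMatrix, M: PopulationMap, pops: Sequence[str] | None = None
) -> FstResult:
    """Multi-site Weir-Cockerham F_ST over all populations plus all pairs."""
    pops = list(pops) if pops is not None else M.populations
    if len(pops) < 2:
        raise ValueError("F_ST requires at least 2 populations")
    comp = wc_site_components(G, M, pops)
    theta = theta_from_components(comp)
    P = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            pair_comp = wc_site_components(G, M, [pops[i], pops[j]])
            P[i, j] = P[j, i] = theta_from_components(pair_comp)
    return FstResult(theta, pd.DataFrame(P, index=pops, columns=pops), comp)


def nucleotide_diversity(
    G: GenotypeMatrix, M: PopulationMap, denominator_sites: int
) -> pd.Series:
    """Per-population pi: sum over sites of c_ref*c_alt / C(n,2), divided by
    the total callable site count (polymorphic plus monomorphic)."""
    if denominator_sites < G.n_var:
        raise ValueError("denominator_sites must be >= number of variant sites")
    if denominator_sites == 0:
        raise ValueError("denominator_sites must be positive")
    pops = M.populations
    n, p, _ = _pop_site_summaries(G, M, pops)
    n_alleles = 2 * n
    c_alt = p * n_alleles
    c_ref = n_alleles - c_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        site_pi = np.where(
            n_alleles >= 2, c_ref * c_alt / (n_alleles * (n_alleles - 1) / 2.0), 0.0
        )
    pi = np.nansum(site_pi, axis=1) / denominator_sites
    return pd.Series(pi, index=pops, name="pi")


def ld_prune(
    G: GenotypeMatrix, window_snps: int = 50, step: int = 10, r2_max: float = 0.2
) -> list[str]:
    """plink-style "indep-pairwise" pruning: within each sliding window the
    later member of any pair with dosage r^2 > ``r2_max`` is removed."""
    n_var = G.n_var
    if n_var < 2:
        return list(G.variants)
    X = G.dosage_float()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    keep = np.ones(n_var, dtype=bool)
    start = 0
    while True:
        window = np.where(keep[start : start + window_snps])[0] + start
        if len(window) > 1:
            sub = X[:, window]
            sd = sub.std(axis=0)
            ok = sd > 0
            with np.errstate(invalid="ignore"):
                corr = np.corrcoef(sub[:, ok], rowvar=False)
            idx = window[ok]
            for ii in range(len(idx)):
                if not keep[idx[ii]]:
                    continue
                for jj in range(ii + 1, len(idx)):
                    if keep[idx[jj]] and corr[ii, jj] ** 2 > r2_max:
                        keep[idx[jj]] = False
        if start + window_snps >= n_var:
            break
        start += step
    return [v for v, k in zip(G.variants, keep) if k]


@dataclass
class StructureProxies:
    """Individual and population scores on the leading PCs of the dosage matrix."""

    ind_scores: pd.DataFrame  # individuals x PC1..PCk
    pop_scores: pd.DataFrame  # populations x PC1..PCk
    eigenvalues: np.ndarray


def pca_structure(G: GenotypeMatrix, M: PopulationMap, k: int = 3) -> StructureProxies:
    """PCA of the column-centered (mean-imputed) dosage matrix via SVD."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= min(G.n_ind, G.n_var):
        raise ValueError("k must be < min(n_individuals, n_variants)")
    X = G.dosage_float()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    X -= X.mean(axis=0)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * S[:k]
    cols = [f"PC{i + 1}" for i in range(k)]
    ind_scores = pd.DataFrame(scores, index=G.individuals, columns=cols)
    labels = M.pop_of(G.individuals)
    pop_scores = ind_scores.groupby(pd.Series(labels, index=ind_scores.index)).mean()
    pop_scores = pop_scores.loc[[p for p in M.populations if p in pop_scores.index]]
    eig = (S[:k] ** 2) / max(G.n_ind - 1, 1)
    return StructureProxies(ind_scores, pop_scores, eig)


@dataclass
class FstContrast:
    """Observed mean F_ST of a focal variant set vs random same-size draws."""

    theta_focal: float
    theta_random: np.ndarray
    p_value: float
    n_draws: int


def fst_adaptive_vs_random(
    G: GenotypeMatrix,
    M: PopulationMap,
    adaptive_ids: Sequence[str],
    n_draws: int = 1000,
    seed: int = 0,
) -> FstContrast:
    """One-sided permutation test: is multi-site F_ST over the focal set
    larger than over random same-size variant sets?
    p = (1 + #{random >= focal}) / (1 + n_draws)."""
    adaptive_ids = list(adaptive_ids)
    if not adaptive_ids:
        raise ValueError("adaptive_ids must be non-empty")
    if len(adaptive_ids) > G.n_var:
        raise ValueError("focal set larger than the variant universe")
    comp = wc_site_components(G, M).to_numpy()
    index = {v: i for i, v in enumerate(G.variants)}
    focal = np.array([index[v] for v in adaptive_ids])

    def theta_of(rows: np.ndarray) -> float:
        sub = comp[rows]
        ok = ~np.isnan(sub).any(axis=1)
        sums = sub[ok].sum(axis=0)
        total = sums.sum()
        return sums[0] / total if total != 0 else np.nan

    theta_focal = theta_of(focal)
    rng = np.random.default_rng(seed)
    theta_random = np.array(
        [theta_of(rng.choice(G.n_var, size=len(focal), replace=False)) for _ in range(n_draws)]
    )
    p = (1 + np.sum(theta_random >= theta_focal)) / (1 + n_draws)
    return FstContrast(theta_focal, theta_random, float(p), n_draws)
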