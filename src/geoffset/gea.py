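"""Genotype-environment association scans.

Two complementary detectors feed a "core adaptive" intersection:

* a univariate latent-factor scan (the lfmm2-style estimator): K latent
  factors from an SVD of the centered dosage matrix absorb background
  structure, each variant is regressed on [1, env, U], and z-scores are
  recalibrated by the genomic inflation factor before Benjamini-Hochberg
  FDR control per variable;
* redundancy analysis (RDA) on population allele frequencies constrained by
  the pruned environmental variables, flagging variants whose loadings sit
  more than ``sd_cutoff`` standard deviations from the mean on any retained
  constrained axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import AlleleFreqMatrix, EnvMatrix, GenotypeMatrix

CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, df=1))


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted q-values (monotone, q(p=1) = 1)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class LfmmFit:
    """Per-variant, per-variable association evidence from the latent scan."""

    effects: pd.DataFrame  # variants x variables, OLS effect of env
    z: pd.DataFrame
    p: pd.DataFrame  # inflation-calibrated p-values
    q: pd.DataFrame  # BH q-values (per variable)
    lambda_gc: pd.Series  # genomic inflation factor per variable
    K: int
    U: np.ndarray  # latent factor scores, n_ind x K
    fdr: float

    @property
    def hits(self) -> pd.Series:
        """Variant flagged if q <= fdr for at least one variable."""
        return (self.q <= self.fdr).any(axis=1)

    def hit_variables(self) -> pd.Series:
        sig = self.q <= self.fdr
        return sig.apply(lambda row: ",".join(row.index[row]), axis=1)


def lfmm_scan(
    G: GenotypeMatrix,
    E_individual: pd.DataFrame,
    K: int = 3,
    fdr: float = 0.05,
) -> LfmmFit:
    """Latent-factor association scan of dosages against each variable.

    ``E_individual`` is indexed by individual id (each individual inherits
    its population's climate).  The K latent factors are the leading left
    singular vectors of the genotype matrix residualized on the full
    environmental design (the ridge limit of the joint latent-factor
    estimator) so that they absorb background structure without swallowing
    the environmental signal itself.  For every variable separately, the
    scan fits dosage ~ 1 + env + U by OLS, computes z = effect/SE,
    estimates the genomic inflation factor
    lambda = median(z^2) / median(chi2_1), and calibrates p-values as
    P(chi2_1 > z^2 / lambda).
    """
    n = G.n_ind
    if K >= n:
        raise ValueError(f"K={K} must be smaller than the number of individuals ({n})")
    E = E_individual.loc[G.individuals]
    X_g = G.dosage_float()
    col_mean = np.nanmean(X_g, axis=0)
    nan_r, nan_c = np.where(np.isnan(X_g))
    X_g[nan_r, nan_c] = col_mean[nan_c]
    Y = X_g - X_g.mean(axis=0)

    if K > 0:
        E_all = E.to_numpy(float)
        sd = E_all.std(axis=0)
        E_all = (E_all - E_all.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        Q, _ = np.linalg.qr(np.column_stack([np.ones(n), E_all]))
        resid_g = Y - Q @ (Q.T @ Y)
        Uk, _, _ = np.linalg.svd(resid_g, full_matrices=False)
        U = Uk[:, :K]
    else:
        U = np.empty((n, 0))

    variables = list(E.columns)
    L = G.n_var
    eff = np.empty((L, len(variables)))
    zs = np.empty_like(eff)
    ps = np.empty_like(eff)
    qs = np.empty_like(eff)
    lambdas = np.empty(len(variables))
    for vi, var in enumerate(variables):
        e = E[var].to_numpy(float)
        if np.std(e) == 0:
            raise ValueError(f"environmental variable {var!r} is constant")
        e = (e - e.mean()) / e.std()
        X = np.column_stack([np.ones(n), e, U])
        XtX_inv = np.linalg.inv(X.T @ X)
        B = XtX_inv @ (X.T @ Y)  # (K+2) x L
        resid = Y - X @ B
        dof = n - X.shape[1]
        sigma2 = (resid**2).sum(axis=0) / dof
        se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 1e-300))
        z = B[1] / se
        lam = np.median(z**2) / CHI2_MEDIAN_1DF
        lam = max(lam, 1e-12)
        p = stats.chi2.sf(z**2 / lam, df=1)
        eff[:, vi] = B[1]
        zs[:, vi] = z
        ps[:, vi] = p
        qs[:, vi] = benjamini_hochberg(p)
        lambdas[vi] = lam

    idx = list(G.variants)
    return LfmmFit(
        effects=pd.DataFrame(eff, index=idx, columns=variables),
        z=pd.DataFrame(zs, index=idx, columns=variables),
        p=pd.DataFrame(ps, index=idx, columns=variables),
        q=pd.DataFrame(qs, index=idx, columns=variables),
        lambda_gc=pd.Series(lambdas, index=variables, name="lambda_gc"),
        K=K,
        U=U,
        fdr=fdr,
    )


def select_env_variables(
    E: EnvMatrix, importance: Sequence[str], r_max: float = 0.6
) -> list[str]:
    """Greedy multicollinearity pruning: walk variables in descending
    importance, keeping one iff its |Spearman r| with every kept variable
    stays below ``r_max``."""
    if len(E.variables) == 0:
        raise ValueError("empty environmental matrix")
    df = E.df
    kept: list[str] = []
    for var in importance:
        ok = True
        for prev in kept:
            r = stats.spearmanr(df[var], df[prev]).statistic
            if abs(r) >= r_max:
                ok = False
                break
        if ok:
            kept.append(var)
    return kept


@dataclass
class RdaFit:
    """Constrained-ordination fit on population allele frequencies."""

    site_scores: pd.DataFrame  # populations x retained axes
    loadings: pd.DataFrame  # variants x retained axes (variant-axis correlations)
    eigenvalues: np.ndarray
    k_axes: int
    sd_cutoff: float
    hits: list[str]


def rda_scan(
    F: AlleleFreqMatrix,
    E_pop: EnvMatrix,
    sd_cutoff: float = 3.0,
    k_axes: int = 3,
) -> RdaFit:
    """RDA loading-outlier scan.

    Fits Y_hat = X (X'X)^-1 X' Y with Y the centered frequency matrix and X
    the standardized kept variables; constrained axes come from the SVD of
    Y_hat, variant loadings are the right singular vectors ("species
    scores", so a variant's loading folds in both its alignment with the
    axis and its frequency variance), and a variant is a hit when its
    loading lies more than ``sd_cutoff`` SDs from the loading mean on any of
    the first ``k_axes`` axes.
    """
    E_pop = E_pop.reindex(F.populations)
    Y = F.imputed()
    Y = Y - Y.mean(axis=0)
    X = E_pop.values
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = [v for v, s in zip(E_pop.variables, sd) if s == 0]
        raise ValueError(f"constant environmental variables: {bad}")
    X = (X - X.mean(axis=0)) / sd
    xtx = X.T @ X
    if np.linalg.cond(xtx) > 1e12:
        raise np.linalg.LinAlgError(
            "singular predictor cross-product; prune correlated variables first"
        )
    B = np.linalg.solve(xtx, X.T @ Y)
    Y_hat = X @ B
    Usvd, S, Vt = np.linalg.svd(Y_hat, full_matrices=False)
    rank = min(np.sum(S > S[0] * 1e-12) if len(S) else 0, X.shape[1])
    k = min(k_axes, rank)
    axes = Usvd[:, :k]
    loadings = Vt[:k].T
    # fix SVD sign indeterminacy: largest-|element| of each axis positive
    for a in range(k):
        i_max = np.argmax(np.abs(axes[:, a]))
        if axes[i_max, a] < 0:
            axes[:, a] = -axes[:, a]
            loadings[:, a] = -loadings[:, a]
    eig = (S[:k] ** 2) / max(len(F.populations) - 1, 1)
    load_df = pd.DataFrame(
        loadings, index=F.variants, columns=[f"RDA{i + 1}" for i in range(k)]
    )
    mean = load_df.mean(axis=0)
    sd_l = load_df.std(axis=0)
    outlier = (load_df - mean).abs() > sd_cutoff * sd_l
    hits = load_df.index[outlier.any(axis=1)].tolist()
    scores = pd.DataFrame(axes * S[:k], index=F.populations, columns=load_df.columns)
    return RdaFit(scores, load_df, eig, k, sd_cutoff, hits)


@dataclass
class GeaResult:
    """Per-variant hit flags from both detectors and their intersection."""

    table: pd.DataFrame  # variant_id index; lfmm_hit, rda_hit, core_hit, ...

    @property
    def core_ids(self) -> list[str]:
        return self.table.index[self.table["core_hit"]].tolist()

    @property
    def lfmm_ids(self) -> list[str]:
        return self.table.index[self.table["lfmm_hit"]].tolist()

    def counts_by_class(self) -> pd.DataFrame:
        return self.table.groupby("vclass")[["lfmm_hit", "rda_hit", "core_hit"]].sum()


def intersect_core(
    lfmm: LfmmFit, rda_hits: Sequence[str], vclass: pd.Series | None = None
) -> GeaResult:
    """Core adaptive set = variants flagged by both LFMM and RDA."""
    universe = set(lfmm.q.index)
    extra = set(rda_hits) - universe
    if extra:
        raise ValueError(f"RDA hits outside the LFMM variant universe: {sorted(extra)[:5]}")
    lfmm_hit = lfmm.hits
    rda_flag = pd.Series(False, index=lfmm.q.index)
    rda_flag.loc[list(rda_hits)] = True
    table = pd.DataFrame(
        {
            "lfmm_hit": lfmm_hit,
            "rda_hit": rda_flag,
            "core_hit": lfmm_hit & rda_flag,
            "variables": lfmm.hit_variables(),
            "q_min": lfmm.q.min(axis=1),
        }
    )
    table["vclass"] = vclass.reindex(table.index) if vclass is not None else "unknown"
    return GeaResult(table)
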