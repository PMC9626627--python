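"""Isolation-by-distance / isolation-by-environment machinery.

Distance matrices (great-circle km, Rousset-linearized F_ST, Euclidean
environmental distance), Mantel and partial Mantel permutation tests, and
partial-RDA variance partitioning of allele-frequency variation into
climate, geography and population-structure components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import AlleleFreqMatrix, EnvMatrix, PopulationMap
from .popgen import FstResult, StructureProxies

EARTH_RADIUS_KM = 6371.0088
#: linearized value substituted when theta == 1 exactly
FST_SENTINEL = 1e9


@dataclass
class DistanceMatrix:
    kind: str  # geographic_km | linearized_fst | environmental
    values: pd.DataFrame  # population x population, symmetric, zero diagonal

    def __post_init__(self) -> None:
        V = self.values.to_numpy(float)
        if not np.allclose(V, V.T):
            raise ValueError("distance matrix must be symmetric")
        np.fill_diagonal(V, 0.0)
        self.values = pd.DataFrame(V, index=self.values.index, columns=self.values.columns)

    @property
    def populations(self) -> list[str]:
        return list(self.values.index)

    def lower_triangle(self) -> np.ndarray:
        V = self.values.to_numpy()
        iu = np.tril_indices(len(V), k=-1)
        return V[iu]


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km (Earth radius 6371.0088 km)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon, dlat = lon2 - lon1, lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def geographic_distances(M: PopulationMap) -> DistanceMatrix:
    pops = M.populations
    lon = M.coords["lon"].to_numpy()
    lat = M.coords["lat"].to_numpy()
    D = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    return DistanceMatrix("geographic_km", pd.DataFrame(D, index=pops, columns=pops))


def linearized_fst(fst: FstResult | pd.DataFrame) -> DistanceMatrix:
    """Rousset linearization theta/(1-theta), with theta clamped at 0 so the
    distance stays non-negative; theta == 1 maps to a large sentinel."""
    P = fst.pairwise if isinstance(fst, FstResult) else fst
    theta = np.maximum(P.to_numpy(float), 0.0)
    if (theta >= 1.0).any():
        warnings.warn("theta == 1 encountered; using sentinel linearized distance")
    with np.errstate(divide="ignore"):
        lin = np.where(theta >= 1.0, FST_SENTINEL, theta / (1.0 - np.minimum(theta, 1 - 1e-15)))
    np.fill_diagonal(lin, 0.0)
    return DistanceMatrix("linearized_fst", pd.DataFrame(lin, index=P.index, columns=P.columns))


def environmental_distances(E_pop: EnvMatrix) -> DistanceMatrix:
    """Euclidean distance on z-scored environmental variables."""
    X = E_pop.values
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    D = np.sqrt(((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2))
    return DistanceMatrix(
        "environmental", pd.DataFrame(D, index=E_pop.site_ids, columns=E_pop.site_ids)
    )


def distance_matrices(
    M: PopulationMap, fst: FstResult | pd.DataFrame, E_pop: EnvMatrix
) -> tuple[DistanceMatrix, DistanceMatrix, DistanceMatrix]:
    """(geographic_km, linearized_fst, environmental) on a shared ordering."""
    return geographic_distances(M), linearized_fst(fst), environmental_distances(E_pop)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    partial: str | None = None  # kind of the controlled matrix, if any


def _check_alignment(*mats: DistanceMatrix) -> int:
    pops = mats[0].populations
    for m in mats[1:]:
        if m.populations != pops:
            raise ValueError("distance matrices must share the population ordering")
    return len(pops)


def _perm_lower_triangles(
    values: np.ndarray, perms: np.ndarray, iu: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """Lower-triangle vectors of values[perm][:, perm] for a stack of perms."""
    return values[perms[:, iu[0]], perms[:, iu[1]]]


def mantel(A: DistanceMatrix, B: DistanceMatrix, n_perm: int = 999, seed: int = 0) -> MantelResult:
    """Mantel test: Pearson r over lower-triangle entries, one-sided upper
    p-value from jointly permuting B's population labels."""
    n = _check_alignment(A, B)
    iu = np.tril_indices(n, k=-1)
    a = A.lower_triangle()
    b = B.lower_triangle()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("Mantel statistic undefined for a constant matrix")
    r_obs = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    bv = _perm_lower_triangles(B.values.to_numpy(), perms, iu)
    r_perm = _rowwise_corr(bv, a)
    p = (1 + np.sum(r_perm >= r_obs)) / (1 + n_perm)
    return MantelResult(r_obs, float(p), n_perm)


def _rowwise_corr(rows: np.ndarray, vec: np.ndarray) -> np.ndarray:
    rows_c = rows - rows.mean(axis=1, keepdims=True)
    vec_c = vec - vec.mean()
    denom = np.sqrt((rows_c**2).sum(axis=1) * (vec_c**2).sum())
    return (rows_c @ vec_c) / denom


def _residualize(y: np.ndarray, c: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(c), c])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_mantel(
    A: DistanceMatrix, B: DistanceMatrix, C: DistanceMatrix, n_perm: int = 999, seed: int = 0
) -> MantelResult:
    """Partial Mantel: correlate A and B after residualizing both on C.

    Permutations relabel A's populations before residualization (raw-matrix
    permutation), matching the residual-method convention.
    """
    n = _check_alignment(A, B, C)
    iu = np.tril_indices(n, k=-1)
    a, b, c = A.lower_triangle(), B.lower_triangle(), C.lower_triangle()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("Mantel statistic undefined for a constant matrix")
    ra = _residualize(a, c)
    rb = _residualize(b, c)
    # a matrix (numerically) identical to the control residualizes to zero
    if np.std(ra) <= 1e-10 * np.std(a) or np.std(rb) <= 1e-10 * np.std(b):
        r_obs = 0.0
    else:
        r_obs = float(np.corrcoef(ra, rb)[0, 1])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    av = _perm_lower_triangles(A.values.to_numpy(), perms, iu)
    # residualize every permuted a-vector on c in one least-squares solve
    X = np.column_stack([np.ones_like(c), c])
    beta, *_ = np.linalg.lstsq(X, av.T, rcond=None)
    resid = av - (X @ beta).T
    r_perm = _rowwise_corr(resid, rb)
    p = (1 + np.sum(r_perm >= r_obs)) / (1 + n_perm)
    return MantelResult(r_obs, float(p), n_perm, partial=C.kind)


# ---------------------------------------------------------------------------
# Partial-RDA variance partitioning
# ---------------------------------------------------------------------------

@dataclass
class VariancePartition:
    """Adjusted-R^2 decomposition of allele-frequency variation into
    climate / geography / structure exclusive and shared fractions."""

    fractions: pd.Series  # named fractions, may be slightly negative
    r2_adj_full: float

    def __post_init__(self) -> None:
        total = (
            self.fractions[
                [
                    "clim_exclusive",
                    "geog_exclusive",
                    "struct_exclusive",
                    "clim_geog_shared",
                    "clim_struct_shared",
                    "geog_struct_shared",
                    "all_shared",
                ]
            ].sum()
        )
        if abs(total - self.r2_adj_full) > 1e-9:
            raise ValueError("variance fractions must sum to the full-model adjusted R^2")


def _multivariate_r2(Y: np.ndarray, X: np.ndarray) -> float:
    """Fraction of total sum of squares of centered Y explained by [1, X]."""
    Xd = np.column_stack([np.ones(len(Y)), X])
    B, *_ = np.linalg.lstsq(Xd, Y, rcond=None)
    fitted = Xd @ B
    ss_tot = (Y**2).sum()
    return float((fitted**2).sum() / ss_tot)


def _adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel correction: 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def partial_rda_partition(
    F_subset: AlleleFreqMatrix,
    clim: EnvMatrix,
    M: PopulationMap,
    struct: StructureProxies | pd.DataFrame,
) -> VariancePartition:
    """Partition allele-frequency variance between climate, geography
    (lon/lat) and population structure (leading PC scores) via the adjusted
    R^2 of the 7 nested RDA models and inclusion-exclusion."""
    pops = F_subset.populations
    Y = F_subset.imputed()
    Y = Y - Y.mean(axis=0)
    clim_X = clim.reindex(pops).values
    geog_X = M.coords.loc[pops, ["lon", "lat"]].to_numpy()
    struct_df = struct.pop_scores if isinstance(struct, StructureProxies) else struct
    struct_X = struct_df.loc[pops].to_numpy()

    def z(X: np.ndarray) -> np.ndarray:
        sd = X.std(axis=0)
        return (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    blocks = {"clim": z(clim_X), "geog": z(geog_X), "struct": z(struct_X)}
    n = len(pops)
    p_total = sum(b.shape[1] for b in blocks.values())
    if n <= p_total:
        raise ValueError("need more populations than total predictors")
    full_X = np.column_stack(list(blocks.values()))
    if np.linalg.matrix_rank(full_X) < full_X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient combined design")

    def r2adj(names: tuple[str, ...]) -> float:
        X = np.column_stack([blocks[nm] for nm in names])
        return _adjusted_r2(_multivariate_r2(Y, X), n, X.shape[1])

    r_c = r2adj(("clim",))
    r_g = r2adj(("geog",))
    r_s = r2adj(("struct",))
    r_cg = r2adj(("clim", "geog"))
    r_cs = r2adj(("clim", "struct"))
    r_gs = r2adj(("geog", "struct"))
    r_full = r2adj(("clim", "geog", "struct"))

    frac = {
        "clim_exclusive": r_full - r_gs,
        "geog_exclusive": r_full - r_cs,
        "struct_exclusive": r_full - r_cg,
    }
    # pairwise shared fractions by the standard varpart identities
    frac["clim_geog_shared"] = r_gs + r_cs - r_s - r_full
    frac["clim_struct_shared"] = r_gs + r_cg - r_g - r_full
    frac["geog_struct_shared"] = r_cs + r_cg - r_c - r_full
    frac["all_shared"] = (
        r_full
        - frac["clim_exclusive"]
        - frac["geog_exclusive"]
        - frac["struct_exclusive"]
        - frac["clim_geog_shared"]
        - frac["clim_struct_shared"]
        - frac["geog_struct_shared"]
    )
    frac["residual"] = 1.0 - r_full
    return VariancePartition(pd.Series(frac), r_full)


def ibd_ibe_tests(
    geo: DistanceMatrix,
    gen: DistanceMatrix,
    env: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Convenience: Mantel IBD, Mantel IBE and partial Mantel IBE|geography."""
    rows = []
    ibd = mantel(gen, geo, n_perm, seed)
    rows.append(("IBD", ibd.r, ibd.p, "none"))
    ibe = mantel(gen, env, n_perm, seed)
    rows.append(("IBE", ibe.r, ibe.p, "none"))
    ibe_partial = partial_mantel(gen, env, geo, n_perm, seed)
    rows.append(("IBE|geo", ibe_partial.r, ibe_partial.p, "geographic_km"))
    return pd.DataFrame(rows, columns=["test", "r", "p", "controlled"])
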