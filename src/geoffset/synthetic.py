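"""Synthetic landscape generator.

Emulates the statistical structure of a range-wide resequencing study of a
temperate forest tree: ~24 populations with a north/south split and
isolation by distance, 19 correlated bioclimatic variables on a smooth
spatial surface, neutral loci drifting under a hierarchical
Balding-Nichols model, clinal adaptive loci of small effect whose
population frequencies track one causal variable, and future climate
surfaces for four climate models under two emission scenarios
(SSP370 shifted harder than SSP126).

Every surface is a deterministic function of (lon, lat) built from random
Fourier features, so populations and arbitrary grid lattices see the same
climate fields and every output is bit-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import (
    MISSING,
    EnvMatrix,
    GenotypeMatrix,
    PopulationMap,
    VariantTable,
    write_env_matrix,
    write_population_map,
    write_variant_table,
    write_vcf,
)

#: sampling domain (degrees): roughly a NE-Asia shaped lon/lat box
LON_RANGE = (122.0, 132.0)
LAT_RANGE = (40.0, 53.0)
#: latitude separating the southern and northern ancestry groups
GROUP_SPLIT_LAT = 46.5

DEFAULT_MODELS = ("BCC-CSM2-MR", "ACCESS-CM2", "CanESM5", "GISS-E2-1-G")

DEFAULT_FUNC_PROBS = {
    "synonymous": 0.05,
    "tolerated": 0.03,
    "deleterious": 0.015,
    "LOF": 0.005,
    "noncoding": 0.90,
}


@dataclass
class SimConfig:
    """Knobs of the synthetic landscape; defaults are the study conditions."""

    seed: int = 0
    n_pops: int = 24
    n_ind_per_pop: int = 10
    n_neutral: int = 5000
    n_adaptive: int = 100
    n_env: int = 19
    n_causal_env: int = 6
    beta_range: tuple[float, float] = (0.5, 1.5)
    drift_F: float = 0.05
    env_noise_sd: float = 0.3
    adaptive_noise_sd: float = 0.25
    missing_rate: float = 0.02
    sv_fraction: float = 0.01
    indel_fraction: float = 0.10
    func_class_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FUNC_PROBS)
    )
    future_models: tuple[str, ...] = DEFAULT_MODELS
    scenarios: tuple[str, ...] = ("SSP126", "SSP370")
    delta_scale: dict[str, float] = field(
        default_factory=lambda: {"SSP126": 1.0, "SSP370": 2.0}
    )
    window: str = "2061-2080"

    def __post_init__(self) -> None:
        total = sum(self.func_class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("func_class_probs must sum to 1")
        if "SSP126" in self.delta_scale and "SSP370" in self.delta_scale:
            if not self.delta_scale["SSP370"] > self.delta_scale["SSP126"]:
                raise ValueError("delta_scale[SSP370] must exceed delta_scale[SSP126]")
        if self.n_pops < 3:
            raise ValueError("need at least 3 populations (regressions undefined)")


@dataclass
class TruthTable:
    """Ground truth of the simulation, for parameter-recovery tests."""

    adaptive: pd.DataFrame  # variant_id, causal_var, alpha, beta
    pop_groups: pd.Series  # population_id -> ancestry group ("south"/"north")
    ancestral: pd.Series  # variant_id -> "ref"/"alt"
    load_factors: pd.Series | None = None  # population_id -> planted factor

    @property
    def adaptive_ids(self) -> list[str]:
        return self.adaptive["variant_id"].tolist()

    @property
    def causal_variables(self) -> list[str]:
        return sorted(self.adaptive["causal_var"].unique())


class _SmoothField:
    """Random-Fourier-feature Gaussian field over unit-square coordinates."""

    def __init__(self, rng: np.random.Generator, length_scale: float = 0.4, m: int = 48):
        self.omega = rng.normal(0.0, 1.0 / length_scale, size=(m, 2))
        self.phase = rng.uniform(0.0, 2.0 * np.pi, size=m)
        self.coef = rng.normal(0.0, np.sqrt(2.0 / m), size=m)

    def __call__(self, uv: np.ndarray) -> np.ndarray:
        return np.cos(uv @ self.omega.T + self.phase) @ self.coef


class LandscapeFields:
    """Deterministic climate surfaces shared by populations and grids.

    19 variables load on 6 latent spatial fields (linear gradient + smooth
    noise); the first variable of each latent group is the designated causal
    variable and has the cleanest loading, the rest are noisier correlates.
    Future surfaces add a scenario-scaled, model-specific smooth delta field.
    """

    def __init__(self, cfg: SimConfig):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
        self.cfg = cfg
        n_env, n_groups = cfg.n_env, cfg.n_causal_env
        # assign variables to latent groups round-robin: group g holds
        # variables g, g+n_groups, ... ; the first member is causal
        self.var_names = [f"BIO{i + 1}" for i in range(n_env)]
        self.var_group = np.arange(n_env) % n_groups
        self.causal_vars = [self.var_names[g] for g in range(n_groups)]
        self.latents = []
        for _ in range(n_groups):
            grad = rng.normal(0.0, 1.0, size=2)
            grad /= np.linalg.norm(grad)
            self.latents.append((grad, _SmoothField(rng)))
        self.loading = np.empty(n_env)
        self.idio = []
        for i in range(n_env):
            causal = i < n_groups
            self.loading[i] = 0.95 if causal else rng.uniform(0.55, 0.85)
            self.idio.append(_SmoothField(rng, length_scale=0.25))
        # variable-specific units: temperature-like for the first 10,
        # precipitation-like for the rest (BIOCLIM convention)
        self.var_mean = np.where(np.arange(n_env) < 10, rng.uniform(-5, 20, n_env),
                                 rng.uniform(200, 800, n_env))
        self.var_scale = np.where(np.arange(n_env) < 10, rng.uniform(3, 8, n_env),
                                  rng.uniform(80, 200, n_env))
        # future deltas: shared directional shift per variable (warming for
        # temperature, mixed sign for precipitation) plus model-specific fields
        self.base_shift = np.where(
            np.arange(n_env) < 10,
            rng.uniform(0.5, 1.0, n_env),
            rng.uniform(-0.6, 0.6, n_env),
        )
        self.model_fields: dict[str, list[_SmoothField]] = {}
        self.model_offset: dict[str, np.ndarray] = {}
        for model in cfg.future_models:
            self.model_fields[model] = [_SmoothField(rng) for _ in range(n_env)]
            self.model_offset[model] = rng.normal(0.0, 0.15, n_env)

    def _unit(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        u = (np.asarray(lon) - LON_RANGE[0]) / (LON_RANGE[1] - LON_RANGE[0])
        v = (np.asarray(lat) - LAT_RANGE[0]) / (LAT_RANGE[1] - LAT_RANGE[0])
        return np.column_stack([u, v])

    def standardized(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """Unit-variance-ish climate surface values, sites x variables."""
        uv = self._unit(lon, lat)
        lat_vals = np.stack(
            [grad[0] * uv[:, 0] + grad[1] * uv[:, 1] + 0.5 * f(uv)
             for grad, f in self.latents],
            axis=1,
        )
        lat_vals = (lat_vals - lat_vals.mean(0)) / np.maximum(lat_vals.std(0), 1e-12)
        out = np.empty((len(uv), self.cfg.n_env))
        for i in range(self.cfg.n_env):
            w = self.loading[i]
            noise = self.idio[i](uv)
            noise = noise / max(np.std(noise), 1e-12) if len(uv) > 2 else noise
            out[:, i] = w * lat_vals[:, self.var_group[i]] + np.sqrt(1 - w * w) * noise
        return out

    def current(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        return self.var_mean + self.var_scale * self.standardized(lon, lat)

    def delta(self, lon: np.ndarray, lat: np.ndarray, model: str, scenario: str) -> np.ndarray:
        """Future-minus-current climate change surface (variable units)."""
        uv = self._unit(lon, lat)
        scale = self.cfg.delta_scale[scenario]
        out = np.empty((len(uv), self.cfg.n_env))
        for i in range(self.cfg.n_env):
            shape = self.model_fields[model][i](uv)
            out[:, i] = (
                scale
                * self.var_scale[i]
                * (self.base_shift[i] + self.model_offset[model][i] + 0.3 * shape)
            )
        return out

    def future(self, lon, lat, model: str, scenario: str) -> np.ndarray:
        return self.current(lon, lat) + self.delta(lon, lat, model, scenario)


def _env_matrices(
    fields: LandscapeFields, site_ids: Sequence[str], lon: np.ndarray, lat: np.ndarray,
    cfg: SimConfig,
) -> tuple[EnvMatrix, list[EnvMatrix]]:
    cur = EnvMatrix(site_ids, fields.var_names, fields.current(lon, lat), period="current")
    futs = [
        EnvMatrix(
            site_ids,
            fields.var_names,
            fields.future(lon, lat, model, scen),
            period="future",
            model=model,
            scenario=scen,
            window=cfg.window,
        )
        for scen in cfg.scenarios
        for model in cfg.future_models
    ]
    return cur, futs


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Draw offspring frequencies around ``p`` with differentiation ``F``."""
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return np.clip(rng.beta(np.maximum(a, 1e-9), np.maximum(b, 1e-9)), 1e-6, 1 - 1e-6)


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_landscape(
    cfg: SimConfig, out_dir: str | Path | None = None
) -> tuple[VariantTable, GenotypeMatrix, PopulationMap, EnvMatrix, list[EnvMatrix], TruthTable]:
    """Generate one synthetic landscape dataset.

    Neutral loci: ancestral frequency ~ U(0.1, 0.9), then hierarchical
    Balding-Nichols drift (ancestral -> ancestry group -> population), which
    yields both the north/south split and positive isolation by distance.
    Adaptive loci: logit(p_pop) = alpha + beta * z(causal variable) + noise.
    Genotypes: Binomial(2, p_pop) with ``missing_rate`` masking.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    fields = LandscapeFields(cfg)

    # --- populations: half in the southern box, half in the northern box ---
    n_south = cfg.n_pops // 2
    pops = [f"P{i + 1:02d}" for i in range(cfg.n_pops)]
    lon = rng.uniform(*LON_RANGE, cfg.n_pops)
    lat = np.concatenate([
        rng.uniform(LAT_RANGE[0] + 0.3, GROUP_SPLIT_LAT - 0.8, n_south),
        rng.uniform(GROUP_SPLIT_LAT + 0.8, LAT_RANGE[1] - 0.3, cfg.n_pops - n_south),
    ])
    groups = np.array(["south"] * n_south + ["north"] * (cfg.n_pops - n_south))
    coords = pd.DataFrame({"lon": lon, "lat": lat}, index=pops)
    individuals = [f"{p}_i{j + 1:02d}" for p in pops for j in range(cfg.n_ind_per_pop)]
    ind_to_pop = {ind: ind.split("_")[0] for ind in individuals}
    popmap = PopulationMap(ind_to_pop, coords)

    # --- environment ---
    env_cur, env_futs = _env_matrices(fields, pops, lon, lat, cfg)
    env_std = fields.standardized(lon, lat)  # z-scored climate for clines

    # --- variant bookkeeping ---
    n_var = cfg.n_neutral + cfg.n_adaptive
    order = rng.permutation(n_var)
    adaptive_mask = np.zeros(n_var, bool)
    adaptive_mask[order[: cfg.n_adaptive]] = True
    variant_ids = [f"v{i + 1:06d}" for i in range(n_var)]

    # --- population allele frequencies ---
    freq = np.empty((cfg.n_pops, n_var))
    p_anc = rng.uniform(0.1, 0.9, n_var)
    south = groups == "south"
    # north/south divergence is mild relative to within-population drift
    # (secondary contact after recent divergence), so the between-group
    # Balding-Nichols F is a fraction of the per-population drift F
    F_between = max(cfg.drift_F / 5.0, 1e-4)
    truth_rows = []
    causal_idx = [fields.var_names.index(v) for v in fields.causal_vars]
    n_causal = len(causal_idx)
    for j in range(n_var):
        if adaptive_mask[j]:
            k = causal_idx[len(truth_rows) % n_causal]
            alpha = _logit(np.clip(p_anc[j], 0.2, 0.8))
            beta = rng.choice([-1.0, 1.0]) * rng.uniform(*cfg.beta_range)
            z = env_std[:, k]
            z = (z - z.mean()) / max(z.std(), 1e-12)
            logits = alpha + beta * z + rng.normal(0.0, cfg.adaptive_noise_sd, cfg.n_pops)
            freq[:, j] = np.clip(_expit(logits), 1e-6, 1 - 1e-6)
            truth_rows.append((variant_ids[j], fields.var_names[k], alpha, beta))
        else:
            p_group = _balding_nichols(rng, np.repeat(p_anc[j], 2), F_between)
            base = np.where(south, p_group[0], p_group[1])
            freq[:, j] = _balding_nichols(rng, base, cfg.drift_F)

    # --- genotypes ---
    pop_index = np.repeat(np.arange(cfg.n_pops), cfg.n_ind_per_pop)
    dosage = rng.binomial(2, freq[pop_index]).astype(np.int8)
    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = MISSING

    # --- annotation ---
    vclass_draw = rng.random(n_var)
    vclass = np.where(
        vclass_draw < cfg.sv_fraction,
        "SV",
        np.where(vclass_draw < cfg.sv_fraction + cfg.indel_fraction, "INDEL", "SNP"),
    )
    func_names = list(cfg.func_class_probs)
    func = rng.choice(func_names, size=n_var, p=[cfg.func_class_probs[k] for k in func_names])
    bases = np.array(list("ACGT"))
    chrom = np.array([f"LG{(i % 19) + 1:02d}" for i in range(n_var)])
    pos = np.empty(n_var, dtype=int)
    for c in np.unique(chrom):
        idx = np.where(chrom == c)[0]
        pos[idx] = np.cumsum(rng.integers(200, 5000, len(idx)))
    ref = bases[rng.integers(0, 4, n_var)]
    alt = np.empty(n_var, dtype=object)
    for j in range(n_var):
        if vclass[j] == "SNP":
            alt[j] = str(rng.choice([b for b in bases if b != ref[j]]))
        elif vclass[j] == "INDEL":
            ins = "".join(rng.choice(bases, rng.integers(1, 11)))
            alt[j] = ref[j] + ins
        else:
            alt[j] = "<DEL>"
    variants = VariantTable(
        pd.DataFrame(
            {
                "variant_id": variant_ids,
                "chrom": chrom,
                "pos": pos,
                "vclass": vclass,
                "ref_allele": ref,
                "alt_allele": alt,
                "ancestral": "ref",
                "func_class": func,
            }
        )
    )
    genotypes = GenotypeMatrix(individuals, variant_ids, dosage)
    truth = TruthTable(
        adaptive=pd.DataFrame(truth_rows, columns=["variant_id", "causal_var", "alpha", "beta"]),
        pop_groups=pd.Series(groups, index=pops, name="group"),
        ancestral=pd.Series("ref", index=variant_ids, name="ancestral"),
    )

    if out_dir is not None:
        write_outputs(Path(out_dir), variants, genotypes, popmap, env_cur, env_futs, truth)
    return variants, genotypes, popmap, env_cur, env_futs, truth


def write_outputs(
    out_dir: Path,
    variants: VariantTable,
    genotypes: GenotypeMatrix,
    popmap: PopulationMap,
    env_cur: EnvMatrix,
    env_futs: list[EnvMatrix],
    truth: TruthTable,
) -> None:
    """Persist the full simulated file set (VCF + TSVs + truth.tsv)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    write_vcf(out_dir / "genotypes.vcf", variants, genotypes)
    write_variant_table(variants, out_dir / "variants.tsv")
    write_population_map(popmap, out_dir / "populations.tsv")
    write_env_matrix(env_cur, out_dir / "env_current_none_none.tsv")
    for E in env_futs:
        write_env_matrix(E, out_dir / f"env_future_{E.model}_{E.scenario}.tsv")
    truth.adaptive.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    truth.pop_groups.rename_axis("population_id").reset_index().to_csv(
        out_dir / "truth_groups.tsv", sep="\t", index=False
    )


def plant_load_gradient(
    genotypes: GenotypeMatrix,
    popmap: PopulationMap,
    variants: VariantTable,
    factors: dict[str, float],
    seed: int = 0,
    categories: tuple[str, ...] = ("deleterious", "LOF"),
) -> tuple[GenotypeMatrix, pd.Series]:
    """Inflate derived-allele frequencies at burden categories in chosen pops.

    For each population with factor f >= 1, genotypes at ``categories`` sites
    are redrawn as Binomial(2, min(1, f * p_pop)) where p_pop is the observed
    derived frequency.  f == 1 leaves the population untouched.  Returns the
    modified matrix and the planted factor ordering.
    """
    for pop, f in factors.items():
        if f < 1.0:
            raise ValueError(f"load factor for {pop} must be >= 1 (got {f})")
    vdf = variants.df
    target = vdf["func_class"].isin(categories).to_numpy()
    for cat in categories:
        if not (vdf["func_class"] == cat).any():
            raise ValueError(f"no variants in requested category {cat!r}")
    dosage = genotypes.dosage.copy()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    pop_labels = popmap.pop_of(genotypes.individuals)
    tcols = np.where(target)[0]
    for pop, f in factors.items():
        if f == 1.0:
            continue
        rows = np.where(pop_labels == pop)[0]
        sub = dosage[np.ix_(rows, tcols)]
        called = sub != MISSING
        n_all = 2 * called.sum(axis=0)
        p = np.where(n_all > 0, np.where(called, sub, 0).sum(axis=0) / np.maximum(n_all, 1), 0.0)
        p_new = np.minimum(1.0, f * p)
        redraw = rng.binomial(2, np.broadcast_to(p_new, sub.shape)).astype(np.int8)
        redraw[~called] = MISSING
        dosage[np.ix_(rows, tcols)] = redraw
    order = pd.Series(factors, name="load_factor").sort_values(ascending=False)
    return GenotypeMatrix(genotypes.individuals, genotypes.variants, dosage), order


@dataclass
class Grid:
    """Lattice of cells covering the species range with climate surfaces."""

    coords: pd.DataFrame  # index cell_id, columns lon, lat
    env_current: EnvMatrix
    env_future: list[EnvMatrix]

    def nearest_cell(self, lon: float, lat: float) -> str:
        d2 = (self.coords["lon"] - lon) ** 2 + (self.coords["lat"] - lat) ** 2
        return str(d2.idxmin())

    def future_for(self, model: str, scenario: str) -> EnvMatrix:
        for E in self.env_future:
            if E.model == model and E.scenario == scenario:
                return E
        raise KeyError(f"no future grid for model={model} scenario={scenario}")


def make_grid(cfg: SimConfig, resolution: int | tuple[int, int] = 20) -> Grid:
    """Evaluate the climate surfaces on a lon/lat lattice covering the range."""
    nx, ny = (resolution, resolution) if isinstance(resolution, int) else resolution
    if nx < 2 or ny < 2:
        raise ValueError("resolution must be >= 2 per axis")
    fields = LandscapeFields(cfg)
    xs = np.linspace(*LON_RANGE, nx)
    ys = np.linspace(*LAT_RANGE, ny)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    lon, lat = gx.ravel(), gy.ravel()
    cells = [f"cell{i + 1:05d}" for i in range(len(lon))]
    coords = pd.DataFrame({"lon": lon, "lat": lat}, index=cells)
    env_cur, env_futs = _env_matrices(fields, cells, lon, lat, cfg)
    return Grid(coords, env_cur, env_futs)
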