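"""End-to-end pipeline orchestration.

Stage order mirrors the analysis workflow: simulate (or load) data ->
allele frequencies + MAF filter -> population-genetic structure -> GEA scan
-> IBD/IBE -> turnover model -> offsets (RONA + grid offsets) -> genetic
load -> report.  Every stage writes TSV/JSON artifacts into the run
directory and a manifest records parameters, seeds and artifact checksums,
so a rerun with an identical config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_data as cd
from . import gea as gea_mod
from . import landscape as ls
from . import load as load_mod
from . import offsets as off
from . import popgen as pg
from . import synthetic as syn
from . import turnover as tv

STAGES = ("simulate", "freqs", "popgen", "gea", "ibd_ibe", "turnover", "offset", "load", "report")

#: artifacts each stage needs from upstream (stage -> producing stage)
_REQUIRES = {
    "freqs": "simulate",
    "popgen": "freqs",
    "gea": "freqs",
    "ibd_ibe": "gea",
    "turnover": "gea",
    "offset": "turnover",
    "load": "offset",
    "report": "offset",
}


@dataclass
class RunConfig:
    """Parameters for a full pipeline run (defaults mirror the stage APIs)."""

    out_dir: str = "run"
    sim: syn.SimConfig = field(default_factory=syn.SimConfig)
    maf_threshold: float = 0.10
    K: int = 3
    fdr: float = 0.05
    sd_cutoff: float = 3.0
    r_max: float = 0.6
    k_axes: int = 3
    n_perm: int = 999
    n_trees: int = 200
    ranking_trees: int = 100
    grid_resolution: int = 20
    d_max: tuple[float, ...] = (100.0, 250.0, 500.0, 1000.0, float("inf"))
    n_draws: int = 1000
    load_mode: str = "allele_count"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["d_max"] = ["inf" if np.isinf(x) else x for x in self.d_max]
        d["sim"]["func_class_probs"] = dict(self.sim.func_class_probs)
        return d


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class _Context:
    """In-memory objects flowing between stages."""

    variants: cd.VariantTable | None = None
    genotypes: cd.GenotypeMatrix | None = None
    popmap: cd.PopulationMap | None = None
    env_cur: cd.EnvMatrix | None = None
    env_futs: list[cd.EnvMatrix] | None = None
    truth: syn.TruthTable | None = None
    freqs: cd.AlleleFreqMatrix | None = None
    kept_ids: list[str] | None = None
    fst: pg.FstResult | None = None
    structure: pg.StructureProxies | None = None
    lfmm: gea_mod.LfmmFit | None = None
    gea: gea_mod.GeaResult | None = None
    selected_vars: list[str] | None = None
    model: tv.TurnoverModel | None = None
    grid: syn.Grid | None = None
    offsets_pop: pd.DataFrame | None = None


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = STAGES) -> Path:
    """Run the requested stages in order; returns the run directory."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    stages = tuple(s for s in STAGES if s in stages)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ctx = _Context()
    log: list[str] = []

    for stage in stages:
        need = _REQUIRES.get(stage)
        if need and not _stage_loaded(ctx, need):
            if not _try_load(ctx, cfg, out, need):
                raise PipelineError(
                    f"stage {stage!r} requires artifacts from {need!r}; run {need!r} first"
                )
        _STAGE_FUNCS[stage](ctx, cfg, out, log)

    manifest = {
        "config": cfg.to_dict(),
        "stages": list(stages),
        "log": log,
        "artifacts": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def _stage_loaded(ctx: _Context, stage: str) -> bool:
    return {
        "simulate": ctx.genotypes is not None,
        "freqs": ctx.freqs is not None,
        "popgen": ctx.structure is not None,
        "gea": ctx.gea is not None,
        "turnover": ctx.model is not None,
        "offset": ctx.offsets_pop is not None,
    }.get(stage, True)


def _try_load(ctx: _Context, cfg: RunConfig, out: Path, stage: str) -> bool:
    """Reload upstream artifacts from disk where that is supported."""
    if stage == "simulate":
        data = out / "data"
        if not (data / "genotypes.vcf").exists():
            return False
        ctx.variants, ctx.genotypes = cd.read_vcf(data / "genotypes.vcf")
        # VCF stores annotation, but the TSV keeps full fidelity
        ctx.variants = cd.read_variant_table(data / "variants.tsv")
        ctx.popmap = cd.read_population_map(data / "populations.tsv")
        ctx.env_cur = cd.read_env_matrix(data / "env_current_none_none.tsv")
        ctx.env_futs = [
            cd.read_env_matrix(p) for p in sorted(data.glob("env_future_*.tsv"))
        ]
        return True
    if stage == "freqs" and (out / "freqs.tsv").exists():
        ctx.freqs = cd.read_freq_matrix(out / "freqs.tsv")
        ctx.kept_ids = list(ctx.freqs.variants)
        return True
    return False


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(ctx: _Context, cfg: RunConfig, out: Path, log: list[str]) -> None:
    (ctx.variants, ctx.genotypes, ctx.popmap, ctx.env_cur, ctx.env_futs, ctx.truth) = (
        syn.simulate_landscape(cfg.sim, out_dir=out / "data")
    )
    log.append(
        f"simulate: {ctx.genotypes.n_ind} individuals, {ctx.genotypes.n_var} variants, "
        f"{len(ctx.popmap.populations)} populations"
    )


def _stage_freqs(ctx: _Context, cfg: RunConfig, out: Path, log: list[str]) -> None:
    G_kept, kept = cd.maf_filter(ctx.genotypes, cfg.maf_threshold)
    ctx.kept_ids = kept
    ctx.genotypes_kept = G_kept
    ctx.freqs = cd.allele_frequencies(G_kept, ctx.popmap)
    cd.write_freq_matrix(ctx.freqs, out / "freqs.tsv")
    log.append(
        f"freqs: MAF>{cfg.maf_threshold:g} kept {len(kept)}/{ctx.genotypes.n_var} variants"
    )


def _stage_popgen(ctx: _Context, cfg: RunConfig, out: Path, log: list[str]) -> None:
    G = getattr(ctx, "genotypes_kept", None)
    if G is None:
        G = ctx.genotypes.subset_variants(ctx.kept_ids)
    pruned = pg.ld_prune(G)
    G_pruned = G.subset_variants(pruned)
    ctx.structure = pg.pca_structure(G_pruned, ctx.popmap, k=3)
    ctx.fst = pg.weir_cockerham_fst(G_pruned, ctx.popmap)
    pi = pg.nucleotide_diversity(G, ctx.popmap, denominator_sites=ctx.genotypes.n_var)
    pairs = ctx.fst.pairwise.stack().rename_axis(["pop_i", "pop_j"]).rename("theta")
    pairs.reset_index().to_csv(out / "fst.tsv", sep="\t", index=False)
    pi.rename_axis("population").reset_index().to_csv(out / "pi.tsv", sep="\t", index=False)
    ctx.structure.pop_scores.rename_axis("population").reset_index().to_csv(
        out / "pca_scores.tsv", sep="\t", index=False
    )
    (out / "pruned_variants.txt").write_text("\n".join(pruned) + "\n")
    ctx.pruned_ids = pruned
    log.append(
        f"popgen: {len(pruned)} pruned variants, multi-site theta={ctx.fst.theta:.4f}"
    )


def _stage_gea(ctx: _Context, cfg: RunConfig, out: Path, log: list[str]) -> None:
    G = getattr(ctx, "genotypes_kept", None)
    if G is None:
        G = ctx.genotypes.subset_variants(ctx.kept_ids)
    env_ind = _env_per_individual(ctx.env_cur, ctx.popmap, G.individuals)
    ctx.lfmm = gea_mod.lfmm_scan(G, env_ind, K=cfg.K, fdr=cfg.fdr)
    lfmm_ids = ctx.lfmm.hits[ctx.lfmm.hits].index.tolist()
    # variable ranking for multicollinearity pruning: turnover fit on the
    # LFMM hit set (all variables), then greedy |r| < r_max selection
    if lfmm_ids:
        F_hits = ctx.freqs.subset_variants(lfmm_ids)
        ranking_model = tv.fit_turnover(
            F_hits, ctx.env_cur, n_trees=cfg.ranking_trees, seed=cfg.seed + 11
        )
        ranking = tv.variable_importance(ranking_model)["predictor"].tolist()
    else:
        ranking = list(ctx.env_cur.variables)
    ctx.selected_vars = gea_mod.select_env_variables(ctx.env_cur, ranking, cfg.r_max)
    rda = gea_mod.rda_scan(
        ctx.freqs, ctx.env_cur.select(ctx.selected_vars), cfg.sd_cutoff, cfg.k_axes
    )
    vclass = ctx.variants.df.set_index("variant_id")["vclass"]
    ctx.gea = gea_mod.intersect_core(ctx.lfmm, rda.hits, vclass)
    ctx.gea.table["max_abs_loading"] = rda.loadings.abs().max(axis=1)
    ctx.gea.table.rename_axis("variant_id").reset_index().to_csv(
        out / "gea_hits.tsv", sep="\t", index=False
    )
    ctx.lfmm.lambda_gc.rename_axis("variable").reset_index().to_csv(
        out / "lfmm_lambda.tsv", sep="\t", index=False
    )
    (out / "selected_variables.txt").write_text("\n".join(ctx.selected_vars) + "\n")
    log.append(
        f"gea: {len(lfmm_ids)} LFMM hits, {len(rda.hits)} RDA hits, "
        f"{len(ctx.gea.core_ids)} core adaptive variants; vars={ctx.selected_vars}"
    )


def _stage_ibd_ibe(ctx: _Context, cfg: RunConfig, out: Path, log: list[str]) -> None:
    if ctx.fst is None:
        raise PipelineError("stage 'ibd_ibe' requires artifacts from 'popgen'; run 'popgen' first")
    geo = ls.geographic_distances(ctx.popmap)
    env = ls.environmental_distances(ctx.env_cur)
    rows = []
    for label, ids in (
        ("neutral", getattr(ctx, "pruned_ids", ctx.kept_ids)),
        ("adaptive", ctx.gea.core_ids),
    ):
        if not ids:
            continue
        G_set = ctx.genotypes.subset_variants(ids)
        fst = pg.weir_cockerham_fst(G_set, ctx.popmap)
        gen = ls.linearized_fst(fst)
        tests = ls.ibd_ibe_tests(geo, gen, env, cfg.n_perm, cfg.seed + 21)
        tests.insert(0, "variant_set", label)
        rows.append(tests)
    mantel_df = pd.concat(rows, ignore_index=True)
    mantel_df.to_csv(out / "mantel.tsv", sep="\t", index=False)
    if ctx.gea.core_ids and ctx.structure is not None:
        vp = ls.partial_rda_partition(
            ctx.freqs.subset_variants(ctx.gea.core_ids),
            ctx.env_cur.select(ctx.selected_vars),
            ctx.popmap,
            ctx.structure,
        )
        vp.fractions.rename_axis("fraction").reset_index(name="value").to_csv(
            out / "varpart.tsv", sep="\t", index=False
        )
    log.append("ibd_ibe: wrote mantel.tsv and varpart.tsv")


def _stage_turnover(ctx: _Context, cfg: RunConfig, out: Path, log: list[str]) -> None:
    core = ctx.gea.core_ids
    if not core:
        raise PipelineError("turnover stage needs a non-empty core adaptive set")
    ctx.model = tv.fit_turnover(
        ctx.freqs.subset_variants(core), ctx.env_cur, n_trees=cfg.n_trees, seed=cfg.seed + 31
    )
    ctx.model.to_json(out / "turnover.json")
    tv.variable_importance(ctx.model).to_csv(out / "variable_importance.tsv", sep="\t", index=False)
    log.append(
        f"turnover: {len(ctx.model.locus_r2)} loci retained "
        f"(dropped {len(core) - len(ctx.model.locus_r2)} with R^2<=0)"
    )


def _stage_offset(ctx: _Context, cfg: RunConfig, out: Path, log: list[str]) -> None:
    # RONA per variable on core loci significant for that variable
    assoc = {
        var: [
            v
            for v in ctx.gea.core_ids
            if ctx.lfmm.q.at[v, var] <= cfg.fdr
        ]
        for var in ctx.lfmm.q.columns
    }
    assoc = {k: v for k, v in assoc.items() if v}
    rona_tab = off.rona(ctx.freqs, assoc, ctx.env_cur, ctx.env_futs)
    merged = rona_tab.summary.merge(
        rona_tab.per_model.pivot_table(
            index=["population", "variable", "scenario"], columns="model", values="rona"
        ).reset_index(),
        on=["population", "variable", "scenario"],
    )
    merged.to_csv(out / "rona.tsv", sep="\t", index=False)

    ctx.grid = syn.make_grid(cfg.sim, cfg.grid_resolution)
    pops_cur = ctx.env_cur
    scen_frames = []
    pop_rows = []
    corr_rows = []
    scenarios = sorted({E.scenario for E in ctx.grid.env_future})
    for scen in scenarios:
        local_by_model, fwd_cell_by_model, rev_by_model, fwd_pop_by_model = {}, {}, {}, {}
        for E_fut in [E for E in ctx.grid.env_future if E.scenario == scen]:
            m = E_fut.model
            local_by_model[m] = off.local_offset(ctx.model, ctx.grid.env_current, E_fut)
            fwd_cell_by_model[m] = off.forward_offset(
                ctx.model, ctx.grid.env_current, ctx.grid.coords, E_fut, ctx.grid.coords,
                d_max=(float("inf"),),
            )["forward_inf"]
            rev_by_model[m] = off.reverse_offset(ctx.model, pops_cur, E_fut)
            fwd_pop_by_model[m] = off.forward_offset(
                ctx.model, pops_cur, ctx.popmap.coords, E_fut, ctx.grid.coords, cfg.d_max
            )
        local_mean, _, corr = off.average_models(local_by_model)
        corr_rows.append((scen, "local", float(np.nanmean(corr.to_numpy()[np.triu_indices(len(corr), 1)]))))
        fwd_mean, _, _ = off.average_models(fwd_cell_by_model)
        rev_mean, _, _ = off.average_models(rev_by_model)
        fwd_pop_mean, _, _ = off.average_models(fwd_pop_by_model)
        rgb = off.rgb_composite(local_mean, fwd_mean, rev_mean)
        frame = pd.DataFrame(
            {
                "cell": ctx.grid.coords.index,
                "lon": ctx.grid.coords["lon"].to_numpy(),
                "lat": ctx.grid.coords["lat"].to_numpy(),
                "scenario": scen,
                "local": local_mean.to_numpy(),
                "forward_inf_cell": fwd_mean.to_numpy(),
                "reverse": rev_mean.to_numpy(),
                "R": rgb["R"].to_numpy(),
                "G": rgb["G"].to_numpy(),
                "B": rgb["B"].to_numpy(),
            }
        )
        scen_frames.append(frame)
        fp = fwd_pop_mean.copy()
        fp.insert(0, "scenario", scen)
        fp.insert(0, "population", fp.index)
        # population-cell local offset: at the nearest grid cell
        near = [ctx.grid.nearest_cell(lon, lat) for lon, lat in
                ctx.popmap.coords[["lon", "lat"]].itertuples(index=False)]
        fp["local"] = local_mean.loc[near].to_numpy()
        fp["reverse_at_pop"] = rev_mean.loc[near].to_numpy()
        pop_rows.append(fp)
    pd.concat(scen_frames, ignore_index=True).to_csv(out / "offsets.tsv", sep="\t", index=False)
    ctx.offsets_pop = pd.concat(pop_rows, ignore_index=True)
    ctx.offsets_pop.to_csv(out / "offsets_populations.tsv", sep="\t", index=False)
    pd.DataFrame(corr_rows, columns=["scenario", "metric", "mean_model_corr"]).to_csv(
        out / "model_correlations.tsv", sep="\t", index=False
    )
    log.append(f"offset: scenarios {scenarios}, grid {len(ctx.grid.coords)} cells")


def _stage_load(ctx: _Context, cfg: RunConfig, out: Path, log: list[str]) -> None:
    ratios = load_mod.load_ratios(ctx.genotypes, ctx.popmap, ctx.variants, mode=cfg.load_mode)
    burden = load_mod.sv_burden(ctx.genotypes, ctx.popmap, ctx.variants)
    pi = pg.nucleotide_diversity(ctx.genotypes, ctx.popmap, denominator_sites=ctx.genotypes.n_var)
    table = ratios.join(burden).join(pi)
    table.rename_axis("population").reset_index().to_csv(out / "load.tsv", sep="\t", index=False)
    corr_frames = []
    for scen, sub in ctx.offsets_pop.groupby("scenario"):
        offs = sub.set_index("population")[
            [c for c in sub.columns if c.startswith("forward_") or c in ("local", "reverse_at_pop")]
        ]
        proxies = table[[c for c in table.columns if c.endswith("_ratio")] + ["sv_burden", "pi"]]
        corr_frames.append(load_mod.correlate_load_offset(proxies, offs, scenario=scen))
    pd.concat(corr_frames, ignore_index=True).to_csv(
        out / "load_offset_corr.tsv", sep="\t", index=False
    )
    log.append("load: wrote load.tsv and load_offset_corr.tsv")


def _stage_report(ctx: _Context, cfg: RunConfig, out: Path, log: list[str]) -> None:
    write_report(out)
    log.append("report: wrote report.md")


def write_report(run_dir: str | Path) -> Path:
    """Regenerate the human-readable markdown summary from run artifacts."""
    run_dir = Path(run_dir)
    lines = ["# Pipeline run summary", ""]
    warn: list[str] = []

    def table(path: Path, title: str, n: int = 12) -> None:
        if not path.exists():
            warn.append(f"missing artifact: {path.name}")
            return
        df = pd.read_csv(path, sep="\t")
        lines.append(f"## {title}\n")
        lines.append(df.head(n).to_markdown(index=False))
        if len(df) > n:
            lines.append(f"\n({len(df)} rows total)")
        lines.append("")

    gea_path = run_dir / "gea_hits.tsv"
    if gea_path.exists():
        gea = pd.read_csv(gea_path, sep="\t")
        counts = gea.groupby("vclass")[["lfmm_hit", "rda_hit", "core_hit"]].sum()
        lines.append("## Candidate adaptive variants by class\n")
        if counts.values.sum() == 0:
            lines.append("No candidate variants were detected.\n")
        else:
            lines.append(counts.reset_index().to_markdown(index=False))
        lines.append("")
    else:
        warn.append("missing artifact: gea_hits.tsv")
    table(run_dir / "variable_importance.tsv", "Environmental variable importance")
    table(run_dir / "mantel.tsv", "IBD / IBE Mantel tests")
    table(run_dir / "varpart.tsv", "Partial-RDA variance partition")
    table(run_dir / "rona.tsv", "RONA (per population x variable x scenario)")
    table(run_dir / "offsets_populations.tsv", "Genomic offsets at populations")
    table(run_dir / "load_offset_corr.tsv", "Offset vs genetic load correlations")
    if warn:
        lines.append("## Warnings\n")
        lines.extend(f"- {w}" for w in warn)
        lines.append("")
    path = run_dir / "report.md"
    path.write_text("\n".join(lines))
    return path


def _env_per_individual(
    E_pop: cd.EnvMatrix, M: cd.PopulationMap, individuals: list[str]
) -> pd.DataFrame:
    """Individuals inherit their population's climate values."""
    df = E_pop.df
    labels = M.pop_of(individuals)
    return pd.DataFrame(df.loc[labels].to_numpy(), index=individuals, columns=df.columns)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "freqs": _stage_freqs,
    "popgen": _stage_popgen,
    "gea": _stage_gea,
    "ibd_ibe": _stage_ibd_ibe,
    "turnover": _stage_turnover,
    "offset": _stage_offset,
    "load": _stage_load,
    "report": _stage_report,
}
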