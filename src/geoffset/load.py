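"""Genetic-load proxies per population and their correlation with offsets.

Load proxies follow the derived-allele convention: with the ancestral state
known per variant, the derived-allele burden in a functional category
(tolerated / deleterious / loss-of-function) is expressed relative to the
synonymous burden.  SV burden is the mean per-individual ratio of
heterozygous structural variants to heterozygous SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import GenotypeMatrix, PopulationMap, VariantTable

LOAD_CATEGORIES = ("tolerated", "deleterious", "LOF")


def _derived_dosage(G: GenotypeMatrix, variants: VariantTable) -> np.ndarray:
    """Derived-allele dosage: alt dosage where ancestral==ref, flipped where
    ancestral==alt; columns with unknown ancestral state are NaN."""
    vdf = variants.df.set_index("variant_id").loc[G.variants]
    dos = G.dosage_float()
    anc = vdf["ancestral"].to_numpy()
    dos[:, anc == "alt"] = 2.0 - dos[:, anc == "alt"]
    dos[:, anc == "unknown"] = np.nan
    return dos


@dataclass
class LoadTable:
    """Per-population derived-allele counts, load ratios and SV burden."""

    table: pd.DataFrame  # index population; counts, ratios, sv_burden


def load_ratios(
    G: GenotypeMatrix,
    M: PopulationMap,
    variants: VariantTable,
    mode: str = "allele_count",
) -> pd.DataFrame:
    """Derived-allele load per population relative to synonymous variants.

    ``allele_count`` (default) counts derived alleles dosage-weighted over
    individuals; ``segregating_variant`` counts variants at which the derived
    allele segregates in the population.
    """
    if mode not in ("allele_count", "segregating_variant"):
        raise ValueError(f"unknown mode {mode!r}")
    vdf = variants.df.set_index("variant_id").loc[G.variants]
    derived = _derived_dosage(G, variants)
    labels = M.pop_of(G.individuals)
    func = vdf["func_class"].to_numpy()
    cats = LOAD_CATEGORIES + ("synonymous",)
    rows = {}
    for pop in M.populations:
        sub = derived[labels == pop]
        counts = {}
        for cat in cats:
            cols = func == cat
            block = sub[:, cols]
            if mode == "allele_count":
                counts[cat] = int(np.nansum(block))
            else:
                pop_derived = np.nansum(block, axis=0)
                counts[cat] = int(np.sum(pop_derived > 0))
        if counts["synonymous"] == 0:
            raise ValueError(f"population {pop} has zero synonymous denominator")
        row = {f"n_{c}": counts[c] for c in cats}
        for cat in LOAD_CATEGORIES:
            row[f"{cat}_syn_ratio"] = counts[cat] / counts["synonymous"]
        rows[pop] = row
    return pd.DataFrame.from_dict(rows, orient="index").loc[M.populations]


def sv_burden(G: GenotypeMatrix, M: PopulationMap, variants: VariantTable) -> pd.Series:
    """Mean over individuals of (#het SVs / #het SNPs) per population.

    Individuals without a single heterozygous SNP are excluded with a
    warning rather than dividing by zero.
    """
    vdf = variants.df.set_index("variant_id").loc[G.variants]
    vclass = vdf["vclass"].to_numpy()
    if not (vclass == "SV").any():
        raise ValueError("no structural variants in the dataset")
    het = G.dosage == 1
    het_sv = het[:, vclass == "SV"].sum(axis=1)
    het_snp = het[:, vclass == "SNP"].sum(axis=1)
    ok = het_snp > 0
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} individuals without het SNPs")
    labels = M.pop_of(G.individuals)
    ratio = het_sv[ok] / het_snp[ok]
    s = pd.Series(ratio, index=np.array(G.individuals)[ok]).groupby(
        pd.Series(labels[ok], index=np.array(G.individuals)[ok])
    ).mean()
    return s.reindex(M.populations).rename("sv_burden")


def correlate_load_offset(
    load: pd.DataFrame,
    offsets: pd.DataFrame,
    scenario: str = "none",
    method: str = "spearman",
) -> pd.DataFrame:
    """Spearman rho (average-rank ties, two-sided t-approximation p) between
    every offset metric and every load proxy across populations."""
    if method != "spearman":
        raise ValueError("only Spearman correlation is supported")
    common = load.index.intersection(offsets.index)
    if len(common) < 5:
        raise ValueError("need at least 5 populations for correlations")
    rows = []
    for off_col in offsets.columns:
        x = offsets.loc[common, off_col].to_numpy(float)
        for load_col in load.columns:
            y = load.loc[common, load_col].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append((off_col, load_col, scenario, np.nan, np.nan))
                continue
            res = stats.spearmanr(x, y)
            rows.append((off_col, load_col, scenario, float(res.statistic), float(res.pvalue)))
    return pd.DataFrame(rows, columns=["offset_metric", "load_proxy", "scenario", "rho", "p"])
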