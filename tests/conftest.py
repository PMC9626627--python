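"""Shared fixtures: the default synthetic landscape and the fitted GEA chain.

The heavyweight objects (default simulation, LFMM scan, RDA core set,
turnover model) are session-scoped so the acceptance-style tests and the
unit tests reuse one computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from geoffset import (
    allele_frequencies,
    intersect_core,
    lfmm_scan,
    maf_filter,
    rda_scan,
    select_env_variables,
)
from geoffset.pipeline import _env_per_individual
from geoffset.synthetic import SimConfig, simulate_landscape
from geoffset.turnover import fit_turnover, variable_importance


@dataclass
class Dataset:
    cfg: SimConfig
    variants: object
    genotypes: object
    popmap: object
    env_cur: object
    env_futs: list
    truth: object


@pytest.fixture(scope="session")
def default_sim() -> Dataset:
    """The default study conditions: 24 pops x 10 ind, 5000 neutral + 100
    planted clinal loci, 19 climate variables, seed 0."""
    cfg = SimConfig()
    return Dataset(cfg, *simulate_landscape(cfg))


@pytest.fixture(scope="session")
def small_sim() -> Dataset:
    """A lighter landscape for unit tests that only need realistic shapes."""
    cfg = SimConfig(seed=7, n_neutral=600, n_adaptive=40)
    return Dataset(cfg, *simulate_landscape(cfg))


@dataclass
class GeaChain:
    dataset: Dataset
    genotypes_maf: object
    freqs: object
    lfmm: object
    selected_vars: list[str]
    rda: object
    gea: object


@pytest.fixture(scope="session")
def gea_chain(default_sim: Dataset) -> GeaChain:
    """MAF filter -> LFMM -> variable ranking/pruning -> RDA -> core set."""
    G, _ = maf_filter(default_sim.genotypes, 0.10)
    F = allele_frequencies(G, default_sim.popmap)
    env_ind = _env_per_individual(default_sim.env_cur, default_sim.popmap, G.individuals)
    lfmm = lfmm_scan(G, env_ind, K=3, fdr=0.05)
    lfmm_ids = lfmm.hits[lfmm.hits].index.tolist()
    ranking_model = fit_turnover(F.subset_variants(lfmm_ids), default_sim.env_cur, n_trees=100, seed=11)
    ranking = variable_importance(ranking_model)["predictor"].tolist()
    selected = select_env_variables(default_sim.env_cur, ranking, 0.6)
    rda = rda_scan(F, default_sim.env_cur.select(selected), 3.0, 3)
    gea = intersect_core(lfmm, rda.hits)
    return GeaChain(default_sim, G, F, lfmm, selected, rda, gea)


@pytest.fixture(scope="session")
def core_turnover(gea_chain: GeaChain):
    """Turnover model fitted on the core adaptive set (pipeline default)."""
    return fit_turnover(
        gea_chain.freqs.subset_variants(gea_chain.gea.core_ids),
        gea_chain.dataset.env_cur,
        n_trees=500,
        seed=31,
    )
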