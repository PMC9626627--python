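"""Population-genetic statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from geoffset.core_data import MISSING, GenotypeMatrix, PopulationMap, allele_frequencies
from geoffset.popgen import (
    fst_adaptive_vs_random,
    ld_prune,
    nucleotide_diversity,
    pca_structure,
    theta_from_components,
    wc_site_components,
    weir_cockerham_fst,
)


def _popmap(pops, per_pop):
    inds = [f"{p}_i{k}" for p in pops for k in range(per_pop)]
    coords = pd.DataFrame(
        {"lon": np.linspace(100, 101, len(pops)), "lat": np.linspace(40, 41, len(pops))},
        index=pops,
    )
    return inds, PopulationMap({i: i.split("_")[0] for i in inds}, coords)


def _wc_oracle(dosage, labels, pops):
    """Direct per-site transcription of the 1984 variance-component formulas."""
    a_list, b_list, c_list = [], [], []
    r = len(pops)
    for site in range(dosage.shape[1]):
        n, p, h = [], [], []
        for pop in pops:
            d = dosage[labels == pop, site]
            d = d[d != MISSING]
            n.append(len(d))
            p.append(d.sum() / (2 * len(d)))
            h.append(np.mean(d == 1))
        n, p, h = map(np.array, (n, p, h))
        nbar = n.mean()
        nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
        pbar = (n * p).sum() / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n * h).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        a_list.append(a)
        b_list.append(b)
        c_list.append(hbar / 2)
    return np.array(a_list), np.array(b_list), np.array(c_list)


class TestWeirCockerham:
    def test_matches_direct_formula_oracle(self):
        """4 pops x 6 individuals x 50 loci with missing calls."""
        rng = np.random.default_rng(42)
        pops = ["A", "B", "C", "D"]
        inds, M = _popmap(pops, 6)
        dosage = rng.integers(0, 3, (24, 50)).astype(np.int8)
        dosage[rng.random((24, 50)) < 0.05] = MISSING
        G = GenotypeMatrix(inds, [f"v{j}" for j in range(50)], dosage)
        comp = wc_site_components(G, M)
        labels = M.pop_of(inds)
        a, b, c = _wc_oracle(dosage, labels, pops)
        assert np.allclose(comp["a"], a, atol=1e-12, equal_nan=True)
        assert np.allclose(comp["b"], b, atol=1e-12, equal_nan=True)
        assert np.allclose(comp["c"], c, atol=1e-12, equal_nan=True)
        theta = theta_from_components(comp)
        ok = ~np.isnan(a + b + c)
        assert theta == pytest.approx(a[ok].sum() / (a + b + c)[ok].sum(), abs=1e-12)

    def test_fixed_alternative_pops_give_theta_one(self):
        inds, M = _popmap(["A", "B"], 20)
        dosage = np.zeros((40, 10), np.int8)
        dosage[20:] = 2
        G = GenotypeMatrix(inds, [f"v{j}" for j in range(10)], dosage)
        assert weir_cockerham_fst(G, M).theta == pytest.approx(1.0, abs=1e-12)

    def test_identical_pops_give_small_nonpositive_theta(self):
        rng = np.random.default_rng(3)
        inds, M = _popmap(["A", "B"], 15)
        half = rng.integers(0, 3, (15, 40)).astype(np.int8)
        G = GenotypeMatrix(inds, [f"v{j}" for j in range(40)], np.vstack([half, half]))
        theta = weir_cockerham_fst(G, M).theta
        assert theta <= 0 and abs(theta) < 0.1

    def test_requires_two_populations(self):
        inds, M = _popmap(["A"], 4)
        G = GenotypeMatrix(inds, ["v0"], np.zeros((4, 1), np.int8))
        with pytest.raises(ValueError):
            weir_cockerham_fst(G, M)


class TestNucleotideDiversity:
    def test_site_arithmetic(self):
        # one pop of 2 diploids: counts 2 ref / 2 alt -> site pi = 4/6 = 2/3
        inds, M = _popmap(["A"], 2)
        G = GenotypeMatrix(inds, ["poly", "mono"], np.array([[2, 0], [0, 0]], np.int8))
        pi = nucleotide_diversity(G, M, denominator_sites=2)
        assert pi["A"] == pytest.approx((2 / 3) / 2)

    def test_monomorphic_contributes_zero(self):
        inds, M = _popmap(["A"], 3)
        G = GenotypeMatrix(inds, ["m"], np.full((3, 1), 2, np.int8))
        assert nucleotide_diversity(G, M, denominator_sites=1)["A"] == 0.0

    def test_allele_label_swap_invariance(self, small_sim):
        G = small_sim.genotypes
        pi1 = nucleotide_diversity(G, small_sim.popmap, denominator_sites=G.n_var)
        flipped = G.dosage.copy()
        called = flipped != MISSING
        flipped[called] = 2 - flipped[called]
        G2 = GenotypeMatrix(G.individuals, G.variants, flipped)
        pi2 = nucleotide_diversity(G2, small_sim.popmap, denominator_sites=G.n_var)
        assert np.allclose(pi1, pi2)

    def test_denominator_validation(self):
        inds, M = _popmap(["A"], 2)
        G = GenotypeMatrix(inds, ["v0", "v1"], np.zeros((2, 2), np.int8))
        with pytest.raises(ValueError):
            nucleotide_diversity(G, M, denominator_sites=1)


class TestLdPrune:
    def test_duplicate_columns_reduced_to_one(self):
        rng = np.random.default_rng(5)
        base = rng.integers(0, 3, (30, 5)).astype(np.int8)
        dosage = np.repeat(base, 2, axis=1)  # v0,v0',v1,v1',...
        G = GenotypeMatrix(
            [f"i{k}" for k in range(30)], [f"v{j}" for j in range(10)], dosage
        )
        kept = ld_prune(G)
        assert len(kept) == 5
        assert kept == [f"v{j}" for j in range(0, 10, 2)]  # later duplicate removed

    def test_independent_loci_mostly_retained(self, small_sim):
        kept = ld_prune(small_sim.genotypes)
        assert len(kept) / small_sim.genotypes.n_var >= 0.95

    def test_default_parameters_echo_plink_convention(self):
        import inspect

        sig = inspect.signature(ld_prune)
        assert sig.parameters["window_snps"].default == 50
        assert sig.parameters["step"].default == 10
        assert sig.parameters["r2_max"].default == 0.2


class TestPca:
    def test_scores_orthogonal_and_eigenvalues_sorted(self, small_sim):
        res = pca_structure(small_sim.genotypes, small_sim.popmap, k=3)
        S = res.ind_scores.to_numpy()
        gram = S.T @ S
        assert np.allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-6)
        assert (np.diff(res.eigenvalues) <= 1e-9).all()

    def test_pc1_separates_ancestry_groups(self, small_sim):
        res = pca_structure(small_sim.genotypes, small_sim.popmap, k=3)
        groups = small_sim.truth.pop_groups
        pc1 = res.pop_scores["PC1"]
        south = pc1[groups[groups == "south"].index]
        north = pc1[groups[groups == "north"].index]
        # complete separation of the two groups along PC1
        assert south.max() < north.min() or north.max() < south.min()

    def test_invalid_k(self, small_sim):
        with pytest.raises(ValueError):
            pca_structure(small_sim.genotypes, small_sim.popmap, k=0)


class TestFstContrast:
    def test_degenerate_single_draw(self, small_sim):
        res = fst_adaptive_vs_random(
            small_sim.genotypes, small_sim.popmap, small_sim.truth.adaptive_ids[:10],
            n_draws=1, seed=0,
        )
        assert res.p_value in (0.5, 1.0)

    def test_planted_loci_are_differentiated(self, small_sim):
        res = fst_adaptive_vs_random(
            small_sim.genotypes, small_sim.popmap, small_sim.truth.adaptive_ids,
            n_draws=200, seed=1,
        )
        assert res.theta_focal > np.mean(res.theta_random)
        assert res.p_value <= 0.05

    def test_empty_focal_set_rejected(self, small_sim):
        with pytest.raises(ValueError):
            fst_adaptive_vs_random(small_sim.genotypes, small_sim.popmap, [], seed=0)
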