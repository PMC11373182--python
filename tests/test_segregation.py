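"""Peeling, the enumeration oracle, EM estimation, EAC and GPI."""

import math

import numpy as np
import pytest
from conftest import (random_acyclic_pedigree, random_looped_pedigree,
                      random_penetrance, random_phenotypes)

from seggwas import segregation as seg
from seggwas.pedigree import Individual, Pedigree
from seggwas.penetrance import HORN_START, PenetranceMatrix
from seggwas.phenotypes import MISSING, PhenotypeTable

IDENTITY = PenetranceMatrix.identity()


def point_mass_probs(ids, states):
    ordered = np.zeros((len(ids), 4))
    ordered[np.arange(len(ids)), states] = 1.0
    return seg.GenotypeProbabilities(list(ids), ordered)


class TestMendelianTransmission:
    @pytest.mark.parametrize("dist,expected", [
        ((0, 0, 0, 1), (0.0, 1.0)),          # certain AA
        ((0, 1, 0, 0), (0.5, 0.5)),          # certain heterozygous
        ((0.25, 0.25, 0.25, 0.25), (0.5, 0.5)),  # direct weighted sum
        ((1, 0, 0, 0), (1.0, 0.0)),
    ])
    def test_allele_distribution(self, dist, expected):
        assert seg.mendelian_transmission(dist) == pytest.approx(expected)

    def test_rejects_wrong_shape(self):
        with pytest.raises(ValueError):
            seg.mendelian_transmission([0.5, 0.5])


class TestPeeling:
    def test_unrelated_unphenotyped_is_hardy_weinberg(self):
        ped = Pedigree([Individual("x")], sex_recorded=False)
        probs = seg.peel_genotype_probabilities(
            ped, PhenotypeTable({}), seg.SegregationModel(0.5, HORN_START))
        assert probs.unordered[0] == pytest.approx([0.25, 0.5, 0.25])

    def test_child_of_certain_aa_sire(self):
        # sire is horned => certainly AA under complete penetrance
        ped = Pedigree([Individual("s"), Individual("d"),
                        Individual("k", "s", "d")], sex_recorded=False)
        probs = seg.peel_genotype_probabilities(
            ped, PhenotypeTable({"s": 2}), seg.SegregationModel(0.5, IDENTITY))
        k = probs.ids.index("k")
        assert probs.unordered[k] == pytest.approx([0.0, 0.5, 0.5])

    def test_all_missing_phenotypes_give_prior_only(self):
        ped = Pedigree([Individual("s"), Individual("d"),
                        Individual("k", "s", "d")], sex_recorded=False)
        q = 0.3
        probs = seg.peel_genotype_probabilities(
            ped, PhenotypeTable({"s": MISSING, "k": MISSING}),
            seg.SegregationModel(q, HORN_START))
        hw = [(1 - q) ** 2, 2 * q * (1 - q), q ** 2]
        for row in probs.unordered:
            assert row == pytest.approx(hw)

    def test_contradiction_names_the_individual(self):
        # aa x aa parents cannot produce a horned (AA-only) child
        ped = Pedigree([Individual("s"), Individual("d"),
                        Individual("k", "s", "d")], sex_recorded=False)
        phen = PhenotypeTable({"s": 0, "d": 0, "k": 2})
        with pytest.raises(seg.ModelDataContradiction) as err:
            seg.peel_genotype_probabilities(
                ped, phen, seg.SegregationModel(0.5, IDENTITY))
        assert err.value.individual in ("s", "d", "k")

    def test_probability_conservation(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            ped = random_acyclic_pedigree(rng, 12)
            probs = seg.peel_genotype_probabilities(
                ped, random_phenotypes(rng, ped),
                seg.SegregationModel(rng.uniform(0.1, 0.9),
                                     random_penetrance(rng)))
            assert np.allclose(probs.ordered.sum(axis=1), 1.0, atol=1e-9)
            assert (probs.ordered >= 0).all()


class TestBruteForce:
    def test_single_founder_hardy_weinberg(self):
        ped = Pedigree([Individual("x")], sex_recorded=False)
        probs = seg.brute_force_probabilities(
            ped, PhenotypeTable({}), seg.SegregationModel(0.3, HORN_START))
        assert probs.unordered[0] == pytest.approx([0.49, 0.42, 0.09])

    def test_trio_complete_penetrance_point_masses(self, trio):
        phen = PhenotypeTable({"sire": 2, "dam": 0, "kid": 1})
        probs = seg.brute_force_probabilities(
            trio, phen, seg.SegregationModel(0.5, IDENTITY))
        expected = {"sire": [0, 0, 1], "dam": [1, 0, 0], "kid": [0, 1, 0]}
        for ident, exp in expected.items():
            assert probs.unordered[probs.ids.index(ident)] == pytest.approx(exp)

    def test_horned_child_is_certain_class2(self, trio):
        # only genotype class 2 can be horned under the canonical start
        probs = seg.brute_force_probabilities(
            trio, PhenotypeTable({"kid": 2}), seg.SegregationModel(0.4, HORN_START))
        assert probs.unordered[probs.ids.index("kid")][2] == pytest.approx(1.0)

    def test_refuses_large_pedigrees(self):
        rng = np.random.default_rng(0)
        ped = random_acyclic_pedigree(rng, 15)
        with pytest.raises(seg.SegregationError, match="refused"):
            seg.brute_force_probabilities(
                ped, PhenotypeTable({}), seg.SegregationModel(0.5, HORN_START))


class TestOracleEquivalence:
    """Production peel vs exhaustive enumeration on small pedigrees."""

    @pytest.mark.parametrize("seed", range(6))
    def test_acyclic(self, seed):
        rng = np.random.default_rng(100 + seed)
        ped = random_acyclic_pedigree(rng, int(rng.integers(4, 11)))
        phen = random_phenotypes(rng, ped)
        model = seg.SegregationModel(rng.uniform(0.1, 0.9),
                                     random_penetrance(rng))
        bf = seg.brute_force_probabilities(ped, phen, model)
        pl = seg.peel_genotype_probabilities(ped, phen, model)
        assert np.abs(bf.ordered - pl.ordered).max() < 1e-6

    @pytest.mark.parametrize("seed", range(6))
    def test_looped(self, seed):
        rng = np.random.default_rng(200 + seed)
        ped = random_looped_pedigree(rng, int(rng.integers(6, 11)))
        phen = random_phenotypes(rng, ped)
        model = seg.SegregationModel(rng.uniform(0.1, 0.9),
                                     random_penetrance(rng))
        bf = seg.brute_force_probabilities(ped, phen, model)
        pl = seg.peel_genotype_probabilities(ped, phen, model)
        assert np.abs(bf.ordered - pl.ordered).max() < 1e-3


class TestEstimatePenetrance:
    def test_two_certain_class2_animals(self):
        probs = point_mass_probs(["a", "b"], [3, 3])  # both AA
        pen = seg.estimate_penetrance(probs, PhenotypeTable({"a": 2, "b": 1}),
                                      prev=HORN_START)
        assert pen.entries[:, 2] == pytest.approx([0.0, 0.5, 0.5])
        # data-free columns retain the previous values
        assert pen.entries[:, 0] == pytest.approx(HORN_START.entries[:, 0])

    def test_point_mass_truth_table(self):
        states = [0, 0, 1, 2, 3, 3]
        y = {f"i{k}": c for k, c in enumerate([0, 0, 1, 1, 2, 2])}
        probs = point_mass_probs(list(y), states)
        pen = seg.estimate_penetrance(probs, PhenotypeTable(y))
        assert np.allclose(pen.entries, np.eye(3))

    def test_fuzzy_probabilities_match_weighted_ratio_oracle(self):
        rng = np.random.default_rng(3)
        ordered = rng.dirichlet(np.ones(4), size=5)
        ids = [f"i{k}" for k in range(5)]
        y = {ids[k]: int(rng.integers(0, 3)) for k in range(4)}  # one missing
        probs = seg.GenotypeProbabilities(ids, ordered)
        pen = seg.estimate_penetrance(probs, PhenotypeTable(y))
        u = probs.unordered
        for g in range(3):
            denom = sum(u[k, g] for k in range(4))
            for cls in range(3):
                num = sum(u[k, g] for k in range(4) if y[ids[k]] == cls)
                assert pen.entries[cls, g] == pytest.approx(num / denom)

    def test_all_missing_rejected(self):
        probs = point_mass_probs(["a"], [0])
        with pytest.raises(seg.SegregationError):
            seg.estimate_penetrance(probs, PhenotypeTable({}))


class TestAlleleFrequency:
    def _founder_ped(self, n):
        return Pedigree([Individual(f"f{k}") for k in range(n)],
                        sex_recorded=False)

    def test_known_founder_eacs(self):
        ped = self._founder_ped(4)
        probs = point_mass_probs(ped.ids, [3, 1, 2, 0])  # EAC 2, 1, 1, 0
        assert seg.estimate_allele_frequency(probs, ped) == pytest.approx(0.5)

    def test_all_aa_clamped_above_zero(self):
        ped = self._founder_ped(3)
        probs = point_mass_probs(ped.ids, [0, 0, 0])
        q = seg.estimate_allele_frequency(probs, ped)
        assert q == pytest.approx(seg.Q_MIN)

    def test_hardy_weinberg_self_consistency(self):
        ped = self._founder_ped(2)
        hw = seg.hardy_weinberg_ordered(0.3)
        probs = seg.GenotypeProbabilities(ped.ids, np.tile(hw, (2, 1)))
        assert seg.estimate_allele_frequency(probs, ped) == pytest.approx(0.3)

    def test_non_founders_excluded(self):
        ped = Pedigree([Individual("f1"), Individual("f2"),
                        Individual("k", "f1", "f2")], sex_recorded=False)
        probs = point_mass_probs(ped.ids, [3, 0, 3])  # child AA ignored
        assert seg.estimate_allele_frequency(probs, ped) == pytest.approx(0.5)


class TestEacGpi:
    @pytest.mark.parametrize("state,expected", [(0, 0.0), (3, 2.0)])
    def test_eac_point_masses(self, state, expected):
        probs = point_mass_probs(["x"], [state])
        assert seg.compute_eac(probs)[0] == pytest.approx(expected)

    def test_eac_split_heterozygote(self):
        probs = seg.GenotypeProbabilities(["x"], np.array([[0, .5, .5, 0.]]))
        assert seg.compute_eac(probs)[0] == pytest.approx(1.0)

    def test_gpi_point_mass_is_100(self):
        probs = point_mass_probs(["x", "y"], [0, 3])
        assert seg.compute_gpi(probs, 0.37) == pytest.approx([100.0, 100.0])

    def test_gpi_hardy_weinberg_is_0(self):
        for q in (0.2, 0.5, 0.73):
            probs = seg.GenotypeProbabilities(
                ["x"], seg.hardy_weinberg_ordered(q)[None, :])
            assert seg.compute_gpi(probs, q)[0] == pytest.approx(0.0, abs=1e-5)

    def test_gpi_intermediate_closed_form(self):
        # unordered (0.5, 0.5, 0) at q = 0.5: posterior allele-count
        # variance 0.25, prior variance 0.5 -> 100*sqrt(1 - 0.5) = 70.7107
        probs = seg.GenotypeProbabilities(["x"], np.array([[0.5, 0.25, 0.25, 0.0]]))
        assert seg.compute_gpi(probs, 0.5)[0] == pytest.approx(
            100.0 * math.sqrt(0.5))

    def test_mean_gpi_subset(self):
        probs = point_mass_probs(["a", "b"], [0, 3])
        probs.ordered[1] = seg.hardy_weinberg_ordered(0.5)
        assert seg.mean_gpi(probs, 0.5, ids=["a"]) == pytest.approx(100.0)
        assert seg.mean_gpi(probs, 0.5) == pytest.approx(50.0)

    def test_gpi_requires_interior_q(self):
        probs = point_mass_probs(["a"], [0])
        with pytest.raises(seg.SegregationError):
            seg.compute_gpi(probs, 1.0)


class TestSymmetry:
    """Relabeling alleles (a<->A) must mirror the EAC exactly."""

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_allele_relabel_mirrors_eac(self, seed):
        rng = np.random.default_rng(seed)
        ped = random_acyclic_pedigree(rng, 9)
        phen = random_phenotypes(rng, ped)
        pen = random_penetrance(rng)
        q = rng.uniform(0.1, 0.9)
        probs = seg.peel_genotype_probabilities(
            ped, phen, seg.SegregationModel(q, pen))
        flipped = seg.peel_genotype_probabilities(
            ped, phen, seg.SegregationModel(1 - q, pen.flipped()))
        assert np.allclose(seg.compute_eac(probs) + seg.compute_eac(flipped),
                           2.0, atol=1e-9)


class TestEmFit:
    def test_loglikelihood_nondecreasing(self):
        # exact E-step => each EM step cannot lower the observed-data
        # log-likelihood (verified with the enumeration oracle)
        for seed in (21, 22):
            rng = np.random.default_rng(seed)
            ped = random_acyclic_pedigree(rng, 8)
            phen = random_phenotypes(rng, ped, p_observed=0.9)
            init = seg.SegregationModel(0.4, random_penetrance(rng))
            fit = seg.fit_segregation_model(ped, phen, init, max_em_iter=40)
            lls = [seg.brute_force_loglikelihood(ped, phen, m)
                   for m in fit.history]
            assert all(b - a >= -1e-9 for a, b in zip(lls, lls[1:]))

    def test_identity_data_recovers_identity_penetrance(self):
        # phenotype == genotype class everywhere: complete information
        from seggwas.simulate import (PedigreeDesign, assign_phenotypes,
                                      gene_drop, synthesize_pedigree)
        rng = np.random.default_rng(31)
        ped = synthesize_pedigree(PedigreeDesign(
            generations=2, sires_per_generation=4, dams_per_sire=5,
            offspring_per_dam=3, seed=31))
        founders = ped.founders
        counts = rng.binomial(2, 0.45, size=(len(founders), 1))
        tg = gene_drop(ped, counts, rng)
        phen = assign_phenotypes(tg.ids, tg.counts[:, 0], IDENTITY, rng)
        init = seg.SegregationModel(0.2, HORN_START.soften(0.05))
        fit = seg.fit_segregation_model(ped, phen, init)
        assert fit.converged
        assert fit.model.penetrance.max_abs_diff(IDENTITY) < 1e-3
        founder_freq = tg.counts[[tg.ids.index(f) for f in founders], 0].mean() / 2
        assert fit.model.q == pytest.approx(founder_freq, abs=1e-3)
        # EM stops at em_tol=1e-5, leaving that much off-diagonal mass
        assert np.allclose(fit.eac, tg.counts[:, 0], atol=1e-4)
        assert np.allclose(fit.gpi, 100.0, atol=0.1)

    def test_stability_across_starting_values(self):
        from seggwas.simulate import (PedigreeDesign, assign_phenotypes,
                                      gene_drop, synthesize_pedigree)
        from seggwas.penetrance import SCENARIO_PENETRANCE
        rng = np.random.default_rng(41)
        ped = synthesize_pedigree(PedigreeDesign(
            generations=3, sires_per_generation=5, dams_per_sire=6,
            offspring_per_dam=4, seed=41))
        counts = rng.binomial(2, 0.5, size=(len(ped.founders), 1))
        tg = gene_drop(ped, counts, rng)
        phen = assign_phenotypes(tg.ids, tg.counts[:, 0],
                                 SCENARIO_PENETRANCE[2], rng)
        start_a = seg.SegregationModel(0.5, HORN_START.soften(0.01))
        start_b = seg.SegregationModel(
            0.3, PenetranceMatrix([[0.8, 0.3, 0.1], [0.1, 0.5, 0.2],
                                   [0.1, 0.2, 0.7]]))
        fit_a = seg.fit_segregation_model(ped, phen, start_a)
        fit_b = seg.fit_segregation_model(ped, phen, start_b)
        assert fit_a.model.penetrance.max_abs_diff(fit_b.model.penetrance) < 1e-3
        assert fit_a.model.q == pytest.approx(fit_b.model.q, abs=1e-3)

    def test_nonconvergence_is_flagged_not_fatal(self):
        rng = np.random.default_rng(51)
        ped = random_acyclic_pedigree(rng, 10)
        phen = random_phenotypes(rng, ped)
        init = seg.SegregationModel(0.4, random_penetrance(rng))
        fit = seg.fit_segregation_model(ped, phen, init, max_em_iter=1)
        assert not fit.converged
        assert fit.n_em_iterations == 1


class TestMonotoneInformation:
    """Averaged over its possible values, observing a phenotype cannot
    make an individual's genotype distribution less informative.

    (A *particular* contrarian record can spread the posterior, so the
    pointwise version of this property does not hold; the expectation
    version is the information-theoretic fact checked here, by
    enumeration.)
    """

    @pytest.mark.parametrize("seed", [61, 62, 63])
    def test_expected_posterior_entropy_never_increases(self, seed):
        rng = np.random.default_rng(seed)
        ped = random_acyclic_pedigree(rng, 6)
        target = ped.ids[int(rng.integers(0, len(ped)))]
        phen = random_phenotypes(rng, ped, p_observed=0.5).restrict(
            [i for i in ped.ids if i != target])
        model = seg.SegregationModel(rng.uniform(0.2, 0.8),
                                     random_penetrance(rng))

        def entropy(u):
            return -(u[u > 0] * np.log(u[u > 0])).sum()

        base = seg.brute_force_probabilities(ped, phen, model)
        t = base.ids.index(target)
        h_without = entropy(base.unordered[t])
        # predictive distribution of the new record, then E[H(posterior)]
        h_with = 0.0
        for cls in range(3):
            p_cls = float(base.unordered[t]
                          @ model.penetrance.entries[cls, :])
            if p_cls == 0:
                continue
            phen2 = PhenotypeTable(dict(list(phen.items()) + [(target, cls)]))
            post = seg.brute_force_probabilities(ped, phen2, model)
            h_with += p_cls * entropy(post.unordered[post.ids.index(target)])
        assert h_with <= h_without + 1e-9


class TestEacTableIo:
    def test_roundtrip_and_sidecar(self, tmp_path, trio):
        phen = PhenotypeTable({"sire": 2, "dam": 0})
        init = seg.SegregationModel(0.5, HORN_START.soften(0.01))
        fit = seg.fit_segregation_model(trio, phen, init, max_em_iter=30)
        path = tmp_path / "eac.tsv"
        seg.write_eac_table(fit, path)
        back = seg.read_eac_table(path)
        assert list(back.index) == fit.ids
        assert np.allclose(back["eac"], np.round(fit.eac, 6))
        sidecar = path.with_suffix(".tsv.json")
        assert sidecar.exists()
        import json
        meta = json.loads(sidecar.read_text())
        assert meta["q"] == pytest.approx(fit.model.q)
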