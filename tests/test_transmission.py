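"""Gametogenesis, crossing, and the exact enumeration oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wormbench import (
    Chromosome,
    EngineConfig,
    ExtrachromosomalArray,
    Sex,
    brood_from_distribution,
    build_genotype,
    enumerate_offspring,
    fertilize,
    make_gamete,
    mate,
    self_cross,
)
from wormbench.genetics import GREEN, DPY, RED, GeneticsError
from wormbench.transmission import _gamete_chromosomes


def three_sigma(p, n):
    return 3 * math.sqrt(p * (1 - p) / n)


class TestMakeGamete:
    def test_homozygous_parent_gametes_identical(self, registry, rng):
        parent = build_genotype(registry, hom=("vsIs28", "e61"))
        keys = {tuple(sorted((c.value, h.key())
                             for c, h in g.autosome_map().items()))
                for g in (make_gamete(parent, registry, rng)
                          for _ in range(50))}
        assert len(keys) == 1

    def test_translocation_halves_cosegregate(self, registry, rng,
                                              mendelian):
        """nT1/+ gametes carry both halves or both normal homologs, each
        side at 1/2."""
        parent = build_genotype(registry, balancer_het=("nT1",))
        n = 10000
        n_bal = 0
        for _ in range(n):
            auto, _x = _gamete_chromosomes(parent, registry, rng, mendelian)
            sides = {auto[Chromosome.IV].balancer, auto[Chromosome.V].balancer}
            assert sides in ({None}, {"nT1"})  # never a single half
            if sides == {"nT1"}:
                n_bal += 1
        assert abs(n_bal / n - 0.5) < three_sigma(0.5, n)

    def test_array_with_full_transmission_always_flagged(self, registry,
                                                         rng):
        registry.add_array(ExtrachromosomalArray("alwaysEx",
                                                 frozenset({GREEN}), 1.0))
        parent = build_genotype(registry, arrays=("alwaysEx",))
        assert all("alwaysEx" in make_gamete(parent, registry, rng).arrays
                   for _ in range(20))

    def test_inviable_parent_rejected(self, registry, rng):
        parent = build_genotype(registry, balancer_hom=("nT1",))
        with pytest.raises(GeneticsError):
            make_gamete(parent, registry, rng)


class TestFertilize:
    def test_nullo_x_sperm_gives_male(self, registry, rng):
        herm = build_genotype(registry)
        male = build_genotype(registry, male=True)
        egg = make_gamete(herm, registry, rng)
        sperm = next(g for g in (make_gamete(male, registry, rng)
                                 for _ in range(100)) if g.x is None)
        child = fertilize(egg, sperm, registry)
        assert child.x_count == 1

    def test_wild_type_gametes_give_viable_hermaphrodite(self, registry,
                                                         rng):
        from wormbench import Viability, sex_of, viability_of

        herm = build_genotype(registry)
        child = fertilize(make_gamete(herm, registry, rng),
                          make_gamete(herm, registry, rng), registry)
        assert viability_of(child, registry) is Viability.VIABLE
        assert sex_of(child) is Sex.HERMAPHRODITE

    def test_balanced_gametes_give_viable_balancer_het(self, registry, rng):
        from wormbench import Viability, viability_of

        wild = build_genotype(registry)
        carrier = build_genotype(registry, balancer_het=("nT1",), male=True)
        sperm = next(g for g in (make_gamete(carrier, registry, rng)
                                 for _ in range(100))
                     if g.autosome_map()[Chromosome.IV].balancer == "nT1"
                     and g.x is not None)
        child = fertilize(make_gamete(wild, registry, rng), sperm, registry)
        assert viability_of(child, registry) is Viability.VIABLE


class TestBroods:
    def test_true_breeding_double_homozygote(self, registry, rng):
        parent = build_genotype(registry, hom=("vsIs28", "e61"))
        brood = self_cross(parent, 200, registry, rng)
        assert all({GREEN, DPY} <= w.phenotype for w in brood)

    def test_green_fraction_in_het_self(self, registry, rng, mendelian):
        parent = build_genotype(registry, hom=("e61",), het=("vsIs28",))
        brood = self_cross(parent, 10000, registry, rng, mendelian)
        green = sum(1 for w in brood if GREEN in w.phenotype) / len(brood)
        assert all(DPY in w.phenotype for w in brood)
        assert abs(green - 0.75) < three_sigma(0.75, 10000)

    def test_empty_brood(self, registry, rng):
        parent = build_genotype(registry)
        assert self_cross(parent, 0, registry, rng) == []

    def test_male_cannot_self(self, registry, rng):
        with pytest.raises(GeneticsError):
            self_cross(build_genotype(registry, male=True), 5, registry, rng)

    def test_cross_progeny_all_green_from_homozygous_mother(self, registry,
                                                            rng):
        herm = build_genotype(registry, hom=("vsIs28",))
        male = build_genotype(registry, male=True)
        brood = mate(herm, male, 300, registry, rng)
        assert all(GREEN in w.phenotype for w in brood)

    def test_cross_sex_ratio_is_half(self, registry, rng):
        herm = build_genotype(registry)
        male = build_genotype(registry, male=True)
        brood = mate(herm, male, 10000, registry, rng)
        frac = sum(1 for w in brood if w.sex is Sex.MALE) / len(brood)
        assert abs(frac - 0.5) < three_sigma(0.5, 10000)

    def test_two_hermaphrodites_cannot_mate(self, registry, rng):
        herm = build_genotype(registry)
        with pytest.raises(GeneticsError):
            mate(herm, herm, 5, registry, rng)

    def test_spontaneous_males_at_config_rate(self, registry, rng):
        cfg = EngineConfig(male_rate=0.05)
        brood = self_cross(build_genotype(registry), 4000, registry, rng,
                           cfg)
        frac = sum(1 for w in brood if w.sex is Sex.MALE) / len(brood)
        assert abs(frac - 0.05) < three_sigma(0.05, 4000)


class TestEnumerate:
    def test_double_het_self_dpy_green_is_3_16(self, registry, mendelian):
        # frozen oracle value: 16 equiprobable allele combinations, of
        # which 3 are (e61/e61, >=1 vsIs28)
        parent = build_genotype(registry, het=("vsIs28", "e61"))
        dist = enumerate_offspring(parent, None, registry, mendelian)
        p = dist.fraction(lambda c: {DPY, GREEN} <= c.phenotype)
        assert p == pytest.approx(3 / 16, abs=1e-12)

    def test_f3_stage_fractions(self, registry, mendelian):
        parent = build_genotype(registry, hom=("e61",), het=("vsIs28",))
        dist = enumerate_offspring(parent, None, registry, mendelian)
        assert dist.fraction(lambda c: GREEN in c.phenotype) == \
            pytest.approx(0.75, abs=1e-12)
        assert dist.fraction(lambda c: DPY in c.phenotype) == \
            pytest.approx(1.0, abs=1e-12)

    def test_homozygote_self_is_single_class(self, registry, mendelian):
        parent = build_genotype(registry, hom=("vsIs28", "e61"))
        dist = enumerate_offspring(parent, None, registry, mendelian)
        assert len(dist.classes) == 1
        assert dist.classes[0].probability == pytest.approx(1.0)

    def test_probabilities_sum_to_one_and_condition(self, registry,
                                                    mendelian):
        parent = build_genotype(registry, balancer_het=("nT1",),
                                het=("vsIs28",))
        dist = enumerate_offspring(parent, None, registry, mendelian)
        assert dist.total == pytest.approx(1.0, abs=1e-12)
        assert sum(c.probability for c in dist.viable_classes) == \
            pytest.approx(1.0, abs=1e-12)
        assert dist.p_viable == pytest.approx(0.75, abs=1e-12)

    def test_no_single_translocation_half_in_viable_classes(self, registry,
                                                            mendelian):
        parent = build_genotype(registry, balancer_het=("nT1", "hT2"))
        dist = enumerate_offspring(parent, None, registry, mendelian)
        for cls in dist.viable_classes:
            for name in ("nT1", "hT2"):
                bal = registry.balancer(name)
                copies = {sum(h.balancer == name for h in
                              cls.genotype.chromosomes[c])
                          for c in bal.balanced}
                assert len(copies) == 1  # full sets only

    def test_array_transmission_independent_of_chromosomal_loci(
            self, registry, mendelian):
        """Carrier probability equals p in every chromosomal class."""
        parent = build_genotype(registry, het=("e61",), arrays=("qhEx265",))
        dist = enumerate_offspring(parent, None, registry, mendelian)
        p_overall = dist.fraction(lambda c: "qhEx265" in c.genotype.arrays)
        p_given_dpy = dist.fraction(
            lambda c: "qhEx265" in c.genotype.arrays,
            given=lambda c: DPY in c.phenotype)
        assert p_overall == pytest.approx(0.65, abs=1e-12)
        assert p_given_dpy == pytest.approx(0.65, abs=1e-12)

    def test_epsilon_unsupported_in_oracle(self, registry):
        parent = build_genotype(registry, balancer_het=("nT1",))
        with pytest.raises(GeneticsError):
            enumerate_offspring(parent, None, registry,
                                EngineConfig(epsilon=0.01))

    def test_simulator_matches_oracle_balancer_self(self, registry, rng,
                                                    mendelian):
        parent = build_genotype(registry, balancer_het=("nT1",),
                                het=("vsIs28",))
        dist = enumerate_offspring(parent, None, registry, mendelian)
        brood = self_cross(parent, 8000, registry, rng, mendelian)
        counts = {}
        for w in brood:
            counts[w.genotype.key()] = counts.get(w.genotype.key(), 0) + 1
        for cls in dist.viable_classes:
            obs = counts.get(cls.genotype.key(), 0) / len(brood)
            assert abs(obs - cls.probability) < three_sigma(
                cls.probability, len(brood)) + 1e-9


class TestExactBroods:
    def test_counts_match_distribution(self, registry, mendelian):
        parent = build_genotype(registry, hom=("e61",), het=("vsIs28",))
        dist = enumerate_offspring(parent, None, registry, mendelian)
        brood = brood_from_distribution(dist, 40, registry)
        assert len(brood) == 40
        n_green = sum(1 for w in brood if GREEN in w.phenotype)
        assert n_green == 30  # exactly 0.75 * 40

    def test_classes_are_interleaved(self, registry, mendelian):
        parent = build_genotype(registry, het=("vsIs28",))
        dist = enumerate_offspring(parent, None, registry, mendelian)
        brood = brood_from_distribution(dist, 12, registry)
        # the first k worms (k = number of classes) already span every class
        keys = [w.genotype.key() for w in brood]
        n_classes = len(dist.viable_classes)
        assert len(set(keys[:n_classes])) == n_classes


@settings(max_examples=30, deadline=None)
@given(
    hom=st.sets(st.sampled_from(["e61", "vsIs28", "vsIs33"]), max_size=2),
    het=st.sets(st.sampled_from(["e61", "vsIs28", "vsIs33"]), max_size=2),
    balancer=st.sampled_from([None, "nT1", "mIn1", "eT1"]),
    arrays=st.sets(st.sampled_from(["qhEx265", "qnEx615"]), max_size=1),
)
def test_enumeration_is_a_distribution(hom, het, balancer, arrays):
    """For arbitrary parents the oracle returns a proper distribution and
    deterministic phenotypes."""
    from wormbench import default_registry

    registry = default_registry()
    het = het - hom
    parent = build_genotype(
        registry, hom=sorted(hom), het=sorted(het),
        balancer_het=(balancer,) if balancer else (), arrays=sorted(arrays))
    dist = enumerate_offspring(parent, None, registry,
                               EngineConfig(male_rate=0.0))
    assert dist.total == pytest.approx(1.0, abs=1e-12)
    assert all(0 <= c.probability <= 1 for c in dist.classes)
    if dist.p_viable > 0:
        assert sum(c.probability for c in dist.viable_classes) == \
            pytest.approx(1.0, abs=1e-12)
    again = enumerate_offspring(parent, None, registry,
                                EngineConfig(male_rate=0.0))
    assert {c.genotype.key(): c.phenotype for c in dist.classes} == \
        {c.genotype.key(): c.phenotype for c in again.classes}
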