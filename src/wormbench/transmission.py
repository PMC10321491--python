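"""Gametogenesis, crossing/selfing, and the exact enumeration oracle.

The sampling path (:func:`make_gamete`, :func:`self_cross`, :func:`mate`)
draws individual offspring from a seeded ``numpy`` generator; the oracle
(:func:`enumerate_offspring`) computes the exact offspring genotype
distribution by taking the product of the two parental gamete-class
distributions.  Both obey the same segregation model:

* each autosome assorts independently (no recombination map; linkage is
  binary at chromosome scale),
* the two halves of a reciprocal translocation segregate together
  (alternate segregation), so a gamete carries either both halves or
  both normal homologs -- unbalanced, aneuploid-producing products are
  folded into the redraw of inviable conceptions unless
  ``emit_unbalanced`` is switched on,
* hermaphrodite gametes always carry an X; male gametes carry the X or
  no X with probability 1/2 each,
* extrachromosomal arrays are transmitted per conception with their
  ``transmission_prob`` (per gamete for free-duplication-like elements),
  so the carrier count in a brood of *n* is Binomial(n, p).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .genetics import (
    AUTOSOMES,
    BalancerKind,
    Chromosome,
    GeneRegistry,
    GeneticsError,
    Genotype,
    Haplotype,
    Individual,
    Sex,
    Viability,
    make_individual,
    phenotype_of,
    sex_of,
    viability_of,
)

SELF = None  # sentinel: enumerate_offspring(parent, SELF) is a self-cross


@dataclass
class EngineConfig:
    """Tunable parameters of the transmission model.

    male_rate          spontaneous X-nondisjunction male rate in self broods
    epsilon            breakthrough recombination probability per meiosis
                       between a balancer and its normal homolog (sampling
                       only; the enumeration oracle requires 0)
    emit_unbalanced    emit unbalanced translocation gametes instead of
                       folding them into the inviable-redraw
    unbalanced_prob    probability of independent (unbalanced) assortment
                       per meiosis when emit_unbalanced is on
    redraw_inviable    redraw inviable conceptions so brood size n means
                       scorable animals; if off, inviable conceptions are
                       returned as dead records
    brood_size         default brood size for protocol drivers
    """

    male_rate: float = 0.002
    epsilon: float = 0.0
    emit_unbalanced: bool = False
    unbalanced_prob: float = 0.5
    redraw_inviable: bool = True
    max_redraws: int = 10000
    brood_size: int = 100

    def to_dict(self) -> dict:
        return {
            "male_rate": self.male_rate,
            "epsilon": self.epsilon,
            "emit_unbalanced": self.emit_unbalanced,
            "unbalanced_prob": self.unbalanced_prob,
            "redraw_inviable": self.redraw_inviable,
            "max_redraws": self.max_redraws,
            "brood_size": self.brood_size,
        }


DEFAULT_CONFIG = EngineConfig()


@dataclass(frozen=True)
class Gamete:
    """A haploid product: one haplotype per autosome, an optional X, and
    flags for the arrays it carries."""

    autosomes: tuple  # tuple of (Chromosome, Haplotype), ordered
    x: Optional[Haplotype]
    arrays: frozenset = frozenset()

    def autosome_map(self) -> dict:
        return dict(self.autosomes)


# ---------------------------------------------------------------------------
# segregation units
# ---------------------------------------------------------------------------

def _segregation_units(genotype: Genotype, registry: GeneRegistry):
    """Partition the autosomes into independently assorting units.

    Chromosomes tied together by a heterozygous translocation form one
    joint unit (their haplotype choices are coupled); every other
    autosome is its own unit.
    """
    grouped: dict = {}
    for c in AUTOSOMES:
        for h in genotype.chromosomes[c]:
            if h.balancer is not None:
                bal = registry.balancer(h.balancer)
                if bal.kind is BalancerKind.RECIPROCAL_TRANSLOCATION:
                    grouped.setdefault(h.balancer, set()).add(c)
    units = []
    claimed: set = set()
    for name, chroms in grouped.items():
        bal = registry.balancer(name)
        members = tuple(sorted(bal.balanced, key=lambda c: c.value))
        units.append(("trans", name, members))
        claimed |= set(members)
    for c in AUTOSOMES:
        if c not in claimed:
            units.append(("chrom", None, (c,)))
    return units


def _split_pair(pair, name):
    """Order a homolog pair as (balancer side, normal side) for balancer
    ``name``; for homozygous slots both entries are the same type."""
    a, b = pair
    if a.balancer == name:
        return a, b
    return b, a


def _maybe_recombine(pair, registry, rng, epsilon):
    """Breakthrough recombination: with probability epsilon swap the
    non-marker alleles between a balancer haplotype and its normal
    homolog before segregation."""
    if epsilon <= 0.0:
        return pair
    a, b = pair
    if (a.balancer is None) == (b.balancer is None):
        return pair
    if rng.random() >= epsilon:
        return pair
    bal_hap, norm_hap = (a, b) if a.balancer is not None else (b, a)
    marker = registry.balancer(bal_hap.balancer).marker_allele
    bal_cargo = bal_hap.alleles - {marker}
    new_bal = Haplotype(bal_hap.chromosome,
                        (bal_hap.alleles - bal_cargo) | norm_hap.alleles,
                        balancer=bal_hap.balancer)
    new_norm = Haplotype(norm_hap.chromosome, bal_cargo)
    return (new_bal, new_norm) if a.balancer is not None else (new_norm,
                                                               new_bal)


# ---------------------------------------------------------------------------
# sampling path
# ---------------------------------------------------------------------------

def _gamete_chromosomes(parent: Genotype, registry: GeneRegistry, rng,
                        config: EngineConfig):
    """Draw the chromosomal content of one gamete (no arrays)."""
    chosen: dict = {}
    for kind, name, members in _segregation_units(parent, registry):
        if kind == "trans":
            independent = (config.emit_unbalanced
                           and rng.random() < config.unbalanced_prob)
            side = rng.random() < 0.5  # True -> balancer side
            for c in members:
                pair = _maybe_recombine(parent.chromosomes[c], registry, rng,
                                        config.epsilon)
                bal_hap, norm_hap = _split_pair(pair, name)
                if independent:
                    chosen[c] = bal_hap if rng.random() < 0.5 else norm_hap
                else:
                    chosen[c] = bal_hap if side else norm_hap
        else:
            c = members[0]
            pair = _maybe_recombine(parent.chromosomes[c], registry, rng,
                                    config.epsilon)
            chosen[c] = pair[0] if rng.random() < 0.5 else pair[1]

    x_haps = parent.x_haplotypes
    if len(x_haps) == 2:  # hermaphrodite: every gamete carries an X
        x = x_haps[0] if rng.random() < 0.5 else x_haps[1]
    else:  # male: X sperm and nullo-X sperm at 1/2 each
        x = x_haps[0] if rng.random() < 0.5 else None
    return chosen, x


def make_gamete(parent: Genotype, registry: GeneRegistry, rng,
                config: EngineConfig = DEFAULT_CONFIG) -> Gamete:
    """Draw one gamete from a viable parent.

    Arrays are flagged with their transmission probability (the marginal
    for a single gamete); brood-level operations instead draw array
    transmission once per conception, see module docstring.
    """
    if viability_of(parent, registry) is not Viability.VIABLE:
        raise GeneticsError("cannot draw gametes from an inviable parent")
    chosen, x = _gamete_chromosomes(parent, registry, rng, config)
    arrays = frozenset(
        a for a in parent.arrays
        if rng.random() < registry.array(a).transmission_prob
    )
    return Gamete(tuple(sorted(chosen.items(), key=lambda kv: kv[0].value)),
                  x, arrays)


def fertilize(egg: Gamete, sperm: Gamete, registry: GeneRegistry) -> Genotype:
    """Combine two gametes into a zygote genotype (union of haplotypes
    per slot, union of array flags; sex falls out of the X count)."""
    egg_auto = egg.autosome_map()
    sperm_auto = sperm.autosome_map()
    chromosomes: dict = {
        c: (egg_auto[c], sperm_auto[c]) for c in AUTOSOMES
    }
    x_haps = tuple(h for h in (egg.x, sperm.x) if h is not None)
    if x_haps:
        chromosomes[Chromosome.X] = x_haps
    return Genotype(chromosomes, egg.arrays | sperm.arrays)


def _conceive(mother: Genotype, father: Optional[Genotype],
              registry: GeneRegistry, rng, config: EngineConfig,
              selfing: bool) -> Genotype:
    """One conception. Arrays are drawn per offspring: standard arrays
    once over the union of parental arrays; per-gamete elements once per
    transmitting gamete."""
    egg_chroms, egg_x = _gamete_chromosomes(mother, registry, rng, config)
    sperm_parent = mother if selfing else father
    sperm_chroms, sperm_x = _gamete_chromosomes(sperm_parent, registry, rng,
                                                config)
    chromosomes: dict = {c: (egg_chroms[c], sperm_chroms[c])
                         for c in AUTOSOMES}
    x_haps = tuple(h for h in (egg_x, sperm_x) if h is not None)
    # Spontaneous males in self broods arise by X nondisjunction.
    if selfing and len(x_haps) == 2 and rng.random() < config.male_rate:
        x_haps = x_haps[:1]
    if x_haps:
        chromosomes[Chromosome.X] = x_haps

    arrays: set = set()
    parental_arrays = mother.arrays | sperm_parent.arrays
    for name in parental_arrays:
        arr = registry.array(name)
        if arr.per_gamete:
            n_carrier_gametes = (name in mother.arrays) + (
                name in sperm_parent.arrays)
            carried = any(rng.random() < arr.transmission_prob
                          for _ in range(n_carrier_gametes))
        else:
            carried = rng.random() < arr.transmission_prob
        if carried:
            arrays.add(name)
    return Genotype(chromosomes, frozenset(arrays))


def _brood(mother: Genotype, father: Optional[Genotype], n: int,
           registry: GeneRegistry, rng, config: EngineConfig,
           selfing: bool, uid_prefix: str) -> list:
    out = []
    for i in range(n):
        geno = _conceive(mother, father, registry, rng, config, selfing)
        redraws = 0
        while (viability_of(geno, registry) is Viability.INVIABLE
               and config.redraw_inviable):
            redraws += 1
            if redraws > config.max_redraws:
                raise GeneticsError("exceeded max_redraws; no viable "
                                    "offspring possible?")
            geno = _conceive(mother, father, registry, rng, config, selfing)
        uid = f"{uid_prefix}{i:04d}"
        if viability_of(geno, registry) is Viability.INVIABLE:
            out.append(Individual(uid, geno, Sex.HERMAPHRODITE, frozenset(),
                                  stage="dead", alive=False))
        else:
            out.append(make_individual(uid, geno, registry, stage="L1"))
    return out


def self_cross(herm: Genotype, n: int, registry: GeneRegistry, rng,
               config: EngineConfig = DEFAULT_CONFIG,
               uid_prefix: str = "self-") -> list:
    """Sample ``n`` offspring from a selfing hermaphrodite."""
    if sex_of(herm) is not Sex.HERMAPHRODITE:
        raise GeneticsError("self_cross requires a hermaphrodite")
    return _brood(herm, None, n, registry, rng, config, True, uid_prefix)


def mate(herm: Genotype, male: Genotype, n: int, registry: GeneRegistry, rng,
         config: EngineConfig = DEFAULT_CONFIG,
         uid_prefix: str = "x-") -> list:
    """Sample ``n`` cross-progeny of a hermaphrodite and a male.

    The male's X vs nullo-X sperm make the expected sex ratio 1:1.
    """
    if sex_of(herm) is not Sex.HERMAPHRODITE:
        raise GeneticsError("mate: first parent must be a hermaphrodite")
    if sex_of(male) is not Sex.MALE:
        raise GeneticsError("mate: second parent must be a male")
    return _brood(herm, male, n, registry, rng, config, False, uid_prefix)


# ---------------------------------------------------------------------------
# enumeration oracle
# ---------------------------------------------------------------------------

@dataclass
class OffspringClass:
    genotype: Genotype
    probability: float
    viable: bool
    sex: Optional[Sex]
    phenotype: frozenset


@dataclass
class OffspringDistribution:
    """Exact offspring distribution of a cross or self.

    ``classes`` covers viable and inviable conceptions and sums to 1;
    ``viable_classes`` renormalizes over the viable ones.
    """

    classes: list

    @property
    def total(self) -> float:
        return sum(c.probability for c in self.classes)

    @property
    def p_viable(self) -> float:
        return sum(c.probability for c in self.classes if c.viable)

    @property
    def viable_classes(self) -> list:
        pv = self.p_viable
        if pv == 0:
            return []
        return [replace(c, probability=c.probability / pv)
                for c in self.classes if c.viable]

    def fraction(self, predicate, *, given=None, viable_only: bool = True
                 ) -> float:
        """P(predicate | given) over the (viable-conditioned) classes.

        ``predicate`` and ``given`` take an :class:`OffspringClass`.
        """
        pool = self.viable_classes if viable_only else self.classes
        if given is not None:
            pool = [c for c in pool if given(c)]
        denom = sum(c.probability for c in pool)
        if denom == 0:
            raise GeneticsError("conditioning event has probability 0")
        return sum(c.probability for c in pool if predicate(c)) / denom

    def phenotype_fractions(self, viable_only: bool = True) -> dict:
        """Probability mass per phenotype-tag set."""
        pool = self.viable_classes if viable_only else self.classes
        out: dict = {}
        for c in pool:
            key = tuple(sorted(c.phenotype))
            out[key] = out.get(key, 0.0) + c.probability
        return out

    def to_frame(self, registry: GeneRegistry):
        import pandas as pd

        rows = []
        for c in sorted(self.classes, key=lambda c: -c.probability):
            rows.append({
                "genotype": format_genotype(c.genotype, registry),
                "probability": c.probability,
                "viable": c.viable,
                "sex": c.sex.value if c.sex else "",
                "phenotype": ";".join(sorted(c.phenotype)),
            })
        return pd.DataFrame(rows)


def _gamete_class_dist(parent: Genotype, registry: GeneRegistry,
                       config: EngineConfig) -> list:
    """All gamete classes of a parent with exact probabilities.

    Returns a list of ((autosome haplotype map, x haplotype or None,
    frozenset of per-gamete array flags), probability).
    """
    if config.epsilon != 0.0:
        raise GeneticsError("enumerate_offspring requires epsilon == 0")
    unit_outcomes = []  # per unit: list of (dict chrom->hap, prob)
    for kind, name, members in _segregation_units(parent, registry):
        if kind == "trans":
            sides = []
            for which in (0, 1):  # 0: balancer side, 1: normal side
                pick = {}
                for c in members:
                    bal_hap, norm_hap = _split_pair(parent.chromosomes[c],
                                                    name)
                    pick[c] = bal_hap if which == 0 else norm_hap
                sides.append(pick)
            if config.emit_unbalanced:
                q = config.unbalanced_prob
                outcomes: dict = {}
                # coupled component
                for pick in sides:
                    key = tuple(pick[c].key() for c in members)
                    outcomes.setdefault(key, [pick, 0.0])[1] += (1 - q) / 2
                # independent component
                for combo in itertools.product(*(
                        parent.chromosomes[c] for c in members)):
                    pick = dict(zip(members, combo))
                    key = tuple(pick[c].key() for c in members)
                    outcomes.setdefault(key, [pick, 0.0])[1] += (
                        q * 0.5 ** len(members))
                unit_outcomes.append([(p, pr) for p, pr in
                                      outcomes.values()])
            else:
                unit_outcomes.append([(sides[0], 0.5), (sides[1], 0.5)])
        else:
            c = members[0]
            a, b = parent.chromosomes[c]
            if a.key() == b.key():
                unit_outcomes.append([({c: a}, 1.0)])
            else:
                unit_outcomes.append([({c: a}, 0.5), ({c: b}, 0.5)])

    x_haps = parent.x_haplotypes
    if len(x_haps) == 2:
        if x_haps[0].key() == x_haps[1].key():
            x_outcomes = [(x_haps[0], 1.0)]
        else:
            x_outcomes = [(x_haps[0], 0.5), (x_haps[1], 0.5)]
    else:
        x_outcomes = [(x_haps[0], 0.5), (None, 0.5)]

    # per-gamete array elements expand inside the gamete classes
    pg_arrays = [registry.array(a) for a in sorted(parent.arrays)
                 if registry.array(a).per_gamete]
    array_outcomes = [(frozenset(), 1.0)]
    for arr in pg_arrays:
        array_outcomes = [
            (flags | extra, p * q)
            for flags, p in array_outcomes
            for extra, q in ((frozenset({arr.name}), arr.transmission_prob),
                             (frozenset(), 1 - arr.transmission_prob))
            if p * q > 0
        ]

    classes = []
    for combo in itertools.product(*unit_outcomes):
        auto: dict = {}
        p_auto = 1.0
        for pick, pr in combo:
            auto.update(pick)
            p_auto *= pr
        for x, px in x_outcomes:
            for flags, pa in array_outcomes:
                p = p_auto * px * pa
                if p > 0:
                    classes.append(((auto, x, flags), p))
    return classes


def enumerate_offspring(
    parent_a: Genotype,
    parent_b: Optional[Genotype] = SELF,
    registry: GeneRegistry = None,
    config: EngineConfig = DEFAULT_CONFIG,
) -> OffspringDistribution:
    """Exact offspring genotype distribution of a mating or a self.

    The product of the two parental gamete-class distributions is taken
    over segregation units, X transmission and array carry/no-carry
    branches; classes are keyed by canonical genotype.  Spontaneous-male
    nondisjunction is not modeled here (exact Mendelian oracle).
    """
    if registry is None:
        raise TypeError("registry is required")
    selfing = parent_b is SELF
    if selfing and sex_of(parent_a) is not Sex.HERMAPHRODITE:
        raise GeneticsError("a self-cross requires a hermaphrodite")
    mother = parent_a
    father = parent_a if selfing else parent_b
    if not selfing:
        if sex_of(mother) is not Sex.HERMAPHRODITE:
            raise GeneticsError("first parent must be a hermaphrodite")
        if sex_of(father) is not Sex.MALE:
            raise GeneticsError("second parent must be a male")

    egg_classes = _gamete_class_dist(mother, registry, config)
    sperm_classes = _gamete_class_dist(father, registry, config)

    # standard (per-conception) array branches over the parental union
    std_arrays = [registry.array(a)
                  for a in sorted(mother.arrays | father.arrays)
                  if not registry.array(a).per_gamete]
    array_branches = [(frozenset(), 1.0)]
    for arr in std_arrays:
        array_branches = [
            (flags | extra, p * q)
            for flags, p in array_branches
            for extra, q in ((frozenset({arr.name}), arr.transmission_prob),
                             (frozenset(), 1 - arr.transmission_prob))
            if p * q > 0
        ]

    acc: dict = {}
    for (egg_auto, egg_x, egg_arr), pe in egg_classes:
        for (sp_auto, sp_x, sp_arr), ps in sperm_classes:
            chromosomes = {c: (egg_auto[c], sp_auto[c]) for c in AUTOSOMES}
            x_haps = tuple(h for h in (egg_x, sp_x) if h is not None)
            if x_haps:
                chromosomes[Chromosome.X] = x_haps
            base_arrays = egg_arr | sp_arr
            for flags, pa in array_branches:
                geno = Genotype(chromosomes, base_arrays | flags)
                p = pe * ps * pa
                key = geno.key()
                if key in acc:
                    acc[key][1] += p
                else:
                    acc[key] = [geno, p]

    classes = []
    for geno, p in acc.values():
        viable = viability_of(geno, registry) is Viability.VIABLE
        try:
            sex = sex_of(geno)
        except Exception:
            sex = None
        pheno = phenotype_of(geno, registry) if viable else frozenset()
        classes.append(OffspringClass(geno, p, viable, sex, pheno))
    dist = OffspringDistribution(classes)
    assert abs(dist.total - 1.0) < 1e-12, "probabilities must sum to 1"
    return dist


def brood_from_distribution(dist: OffspringDistribution, n: int,
                            registry: GeneRegistry,
                            uid_prefix: str = "ex-") -> list:
    """Deterministic brood whose class counts match the viable-conditioned
    enumeration as closely as integer counts allow (largest-remainder
    apportionment), interleaved across classes so that any contiguous or
    evenly spaced selection spans all genotype classes.

    This is the enumeration-backed brood mode of the protocol drivers.
    """
    classes = sorted(dist.viable_classes,
                     key=lambda c: (-c.probability, c.genotype.key()))
    if not classes:
        raise GeneticsError("no viable offspring classes")
    raw = [c.probability * n for c in classes]
    counts = [math.floor(r) for r in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(classes)), key=lambda i: -(raw[i] - counts[i]))
    for i in order[:remainder]:
        counts[i] += 1
    pools = [[c] * k for c, k in zip(classes, counts)]
    out = []
    i = 0
    while any(pools):
        for pool in pools:
            if pool:
                c = pool.pop()
                out.append(make_individual(f"{uid_prefix}{i:04d}", c.genotype,
                                           registry, stage="L1"))
                i += 1
    return out


def format_genotype(genotype: Genotype, registry: GeneRegistry) -> str:
    """Compact human-readable genotype string, e.g.
    ``I:e61/e61; II:vsIs28/+; [qhEx265]``."""
    parts = []
    for c in Chromosome:
        if c not in genotype.chromosomes:
            continue
        haps = genotype.chromosomes[c]

        def one(h: Haplotype) -> str:
            core = ",".join(sorted(h.alleles)) or "+"
            return f"{h.balancer}({core})" if h.balancer else core

        rendered = "/".join(one(h) for h in haps)
        if len(haps) == 1:
            rendered += "/0"
        if any(h.alleles or h.balancer for h in haps) or len(haps) == 1:
            parts.append(f"{c.value}:{rendered}")
    if genotype.arrays:
        parts.append("[" + ",".join(sorted(genotype.arrays)) + "]")
    return "; ".join(parts) if parts else "wild-type"


def brood_to_frame(brood: Sequence, registry: GeneRegistry):
    """One row per individual: id, parents, sex, phenotype, genotype."""
    import pandas as pd

    rows = [{
        "id": w.uid,
        "parents": ";".join(w.parents),
        "sex": w.sex.value,
        "stage": w.stage,
        "alive": w.alive,
        "phenotype": ";".join(sorted(w.phenotype)),
        "genotype": format_genotype(w.genotype, registry),
    } for w in brood]
    return pd.DataFrame(rows, columns=["id", "parents", "sex", "stage",
                                       "alive", "phenotype", "genotype"])
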