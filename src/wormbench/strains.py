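"""Synthetic strain definitions and fixture generators.

Every pipeline in the package (crossing, linkage mapping, integration
screening) consumes populations built here, so all stages are testable
without external data.  The default registry mirrors the strains the
procedures assume:

====== ==============================================================
N2      wild type (self stocks throw rare spontaneous males)
CB61    dpy-5(e61) I homozygote; recessive Dumpy morphology
LX831   vsIs28 [dop-1p::GFP] homozygote; dominant Green
LX811   vsIs33 [dop-3p::RFP] homozygote; dominant Red (default on V)
hT2 strain   hT2[qIs48] (I;III) balanced heterozygote, Green marker
eT1 strain   eT1[umnIs12] (III;V) balanced heterozygote, Green marker
nT1 strain   nT1[qIs51] (IV;V) balanced heterozygote, Green marker
mIn1 strain  mIn1[mIs14] (II) balanced heterozygote, Green marker
NQ1155  wild type carrying dominant Green array qnEx615 [myo-2p::GFP]
YX293   wild type carrying Green array qhEx265 (~65% transmission)
YX256   mixed population, ~half carrying a Green sorting array
====== ==============================================================

Chromosome placements that are configuration facts rather than model
outputs (dpy-5 on I, vsIs28 on II, vsIs33 on V) are set here and can be
overridden through the registry config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

from .genetics import (
    Allele,
    BalancerDef,
    BalancerKind,
    Chromosome,
    Dominance,
    ExtrachromosomalArray,
    GREEN,
    GeneRegistry,
    Genotype,
    HomozygoteFate,
    Individual,
    Locus,
    RED,
    DPY,
    UNC,
    build_genotype,
    make_individual,
)

#: Which chromosomes each linkage test interrogates.
DEFAULT_COVERAGE = {
    "hT2": frozenset({Chromosome.I, Chromosome.III}),
    "eT1": frozenset({Chromosome.III, Chromosome.V}),
    "nT1": frozenset({Chromosome.IV, Chromosome.V}),
    "mIn1": frozenset({Chromosome.II}),
    "X": frozenset({Chromosome.X}),
}

BALANCER_NAMES = ("hT2", "eT1", "nT1", "mIn1")


def default_registry() -> GeneRegistry:
    """The registry used by all bundled strains and protocols."""
    reg = GeneRegistry()
    reg.add_locus(Locus("dpy-5", Chromosome.I, "dpy-5"))
    reg.add_locus(Locus("vsIs28", Chromosome.II, "dop-1p::GFP insertion"))
    reg.add_locus(Locus("vsIs33", Chromosome.V, "dop-3p::RFP insertion"))
    reg.add_allele(Allele("e61", "dpy-5", Dominance.RECESSIVE,
                          frozenset({DPY})))
    reg.add_allele(Allele("vsIs28", "vsIs28", Dominance.DOMINANT,
                          frozenset({GREEN})))
    reg.add_allele(Allele("vsIs33", "vsIs33", Dominance.DOMINANT,
                          frozenset({RED})))

    # Balancer markers live at pseudo-loci on the marker chromosome.
    marker_specs = [
        ("qIs48", Chromosome.I),
        ("umnIs12", Chromosome.III),
        ("qIs51", Chromosome.IV),
        ("mIs14", Chromosome.II),
    ]
    for symbol, chrom in marker_specs:
        reg.add_locus(Locus(symbol, chrom, f"{symbol} (myo-2::GFP)"))
        reg.add_allele(Allele(symbol, symbol, Dominance.DOMINANT,
                              frozenset({GREEN})))

    reg.add_balancer(BalancerDef(
        "hT2", BalancerKind.RECIPROCAL_TRANSLOCATION,
        frozenset({Chromosome.I, Chromosome.III}), "qIs48",
        HomozygoteFate.LETHAL))
    reg.add_balancer(BalancerDef(
        "eT1", BalancerKind.RECIPROCAL_TRANSLOCATION,
        frozenset({Chromosome.III, Chromosome.V}), "umnIs12",
        HomozygoteFate.VIABLE_WITH_PHENOTYPE, frozenset({UNC})))
    reg.add_balancer(BalancerDef(
        "nT1", BalancerKind.RECIPROCAL_TRANSLOCATION,
        frozenset({Chromosome.IV, Chromosome.V}), "qIs51",
        HomozygoteFate.LETHAL))
    reg.add_balancer(BalancerDef(
        "mIn1", BalancerKind.INVERSION, frozenset({Chromosome.II}), "mIs14",
        HomozygoteFate.VIABLE))

    reg.add_array(ExtrachromosomalArray(
        "qhEx265", frozenset({GREEN}), 0.65))
    reg.add_array(ExtrachromosomalArray(
        "qnEx615", frozenset({GREEN}), 0.65))
    reg.add_array(ExtrachromosomalArray(
        "sortEx1", frozenset({GREEN}), 0.65))
    return reg


@dataclass
class StrainSpec:
    """A named strain: genotype template plus population structure."""

    name: str
    description: str
    genotype: Callable  # (registry, male: bool) -> Genotype
    male_fraction: float = 0.002
    carrier_fraction: float = 1.0  # fraction of the stock carrying arrays
    default_size: int = 100

    def make_genotype(self, registry: GeneRegistry, male: bool = False,
                      carrier: bool = True) -> Genotype:
        geno = self.genotype(registry, male)
        if not carrier and geno.arrays:
            geno = Genotype(geno.chromosomes, frozenset())
        return geno


def _simple(hom=(), het=(), balancer_het=(), arrays=()):
    def factory(reg: GeneRegistry, male: bool) -> Genotype:
        return build_genotype(reg, hom=hom, het=het,
                              balancer_het=balancer_het, arrays=arrays,
                              male=male)
    return factory


def default_strains() -> dict:
    specs = [
        StrainSpec("N2", "wild type", _simple()),
        StrainSpec("CB61", "dpy-5(e61) I homozygote", _simple(hom=("e61",))),
        StrainSpec("LX831", "vsIs28 [dop-1p::GFP] homozygote",
                   _simple(hom=("vsIs28",))),
        StrainSpec("LX811", "vsIs33 [dop-3p::RFP] homozygote",
                   _simple(hom=("vsIs33",))),
        StrainSpec("NQ1155", "wild type + qnEx615 [myo-2p::GFP] array",
                   _simple(arrays=("qnEx615",))),
        StrainSpec("YX293", "wild type + qhEx265 array (~65% transmission)",
                   _simple(arrays=("qhEx265",))),
        StrainSpec("YX256", "mixed sorting stock, ~half Green array carriers",
                   _simple(arrays=("sortEx1",)), carrier_fraction=0.5),
    ]
    for bal in BALANCER_NAMES:
        specs.append(StrainSpec(
            f"{bal}-strain", f"{bal} balanced heterozygote (Green marker)",
            _simple(balancer_het=(bal,))))
    return {s.name: s for s in specs}


DEFAULT_STRAINS = default_strains()


def make_strain_population(
    spec: StrainSpec,
    n: int,
    registry: GeneRegistry,
    rng,
    male_fraction: Optional[float] = None,
    uid_prefix: Optional[str] = None,
) -> list:
    """``n`` individuals from a strain stock.

    Sex is Bernoulli(male_fraction); array carriage is
    Bernoulli(carrier_fraction).  Same seed, same population.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    mf = spec.male_fraction if male_fraction is None else male_fraction
    prefix = uid_prefix if uid_prefix is not None else f"{spec.name}-"
    out = []
    for i in range(n):
        male = rng.random() < mf
        carrier = rng.random() < spec.carrier_fraction
        geno = spec.make_genotype(registry, male=male, carrier=carrier)
        out.append(make_individual(f"{prefix}{i:04d}", geno, registry))
    return out


# ---------------------------------------------------------------------------
# mapping scenario
# ---------------------------------------------------------------------------

UNPLACED = None  # sentinel true_chromosome for the unlinked control

#: Name of the free-duplication-like element used for the unplaced control:
#: per-gamete transmission 1/2 makes it segregate exactly like an unlinked
#: heterozygous dominant locus in every scheme.
FREE_DUP = "qhFree1"


@dataclass
class MappingScenario:
    """Strain set for one linkage-mapping experiment.

    ``transgene_herm`` is the Red strain of interest (hermaphrodite);
    ``balancer_strains`` maps balancer name -> Green balanced-het
    genotype factory; ``helper_male`` carries the dominant Green array
    used to identify cross-progeny in the X test.
    """

    true_chromosome: Optional[Chromosome]
    transgene: str
    registry: GeneRegistry
    transgene_herm: Genotype
    balancer_strains: dict  # name -> {"herm": Genotype, "male": Genotype}
    helper_male: Genotype
    coverage: dict = field(default_factory=lambda: dict(DEFAULT_COVERAGE))


def make_mapping_scenario(
    true_chromosome: Optional[Chromosome],
    registry: Optional[GeneRegistry] = None,
    transgene: str = "vsIs33",
) -> MappingScenario:
    """Build the strain set with the Red transgene integrated on
    ``true_chromosome`` (or carried on a free-duplication element for the
    unplaced control).  Deterministic: no sampling happens here."""
    reg = registry if registry is not None else default_registry()
    if true_chromosome is UNPLACED:
        if FREE_DUP not in reg.arrays:
            reg.add_array(ExtrachromosomalArray(
                FREE_DUP, frozenset({RED}), 0.5, per_gamete=True))
        herm = build_genotype(reg, arrays=(FREE_DUP,))
        tg = FREE_DUP
    else:
        tg = f"{transgene}@{true_chromosome.value}"
        if tg not in reg.alleles:
            reg.add_locus(Locus(tg, true_chromosome, f"{transgene} insertion"))
            reg.add_allele(Allele(tg, tg, Dominance.DOMINANT,
                                  frozenset({RED})))
        herm = build_genotype(reg, hom=(tg,))

    balancer_strains = {
        name: {
            "herm": build_genotype(reg, balancer_het=(name,)),
            "male": build_genotype(reg, balancer_het=(name,), male=True),
        }
        for name in BALANCER_NAMES
    }
    helper_male = build_genotype(reg, arrays=("qnEx615",), male=True)
    return MappingScenario(true_chromosome, tg, reg, herm, balancer_strains,
                           helper_male)


def make_sorting_plate(n: int, carrier_fraction: float, registry, rng,
                       array: str = "sortEx1"):
    """Mixed-stage plate with Bernoulli(carrier_fraction) Green carriers,
    as used by fluorescence-sorting throughput tasks."""
    from .bench import Plate

    stages = ("L1", "L2", "L3", "L4", "adult")
    worms = []
    for i in range(n):
        carrier = rng.random() < carrier_fraction
        geno = build_genotype(registry, arrays=(array,) if carrier else ())
        w = make_individual(f"sort-{i:04d}", geno, registry,
                            stage=stages[int(rng.integers(len(stages)))])
        worms.append(w)
    return Plate(barcode="sorting", label="sorting fixture", worms=worms)
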