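"""Core genetic model for *C. elegans* transmission simulation.

This module defines the genetic universe used throughout the package:
the six chromosomes (five autosomes plus X), loci and alleles with
dominant/recessive expression, balancer elements (reciprocal
translocations and inversions carrying dominant fluorescent markers),
extrachromosomal transgenic arrays, and diploid genotypes built from
per-chromosome haplotypes.  Hermaphrodites are diploid for all six
chromosomes; males are diploid for the autosomes and haploid for X.

Three pure maps operate on genotypes:

* :func:`phenotype_of` -- genotype to the set of expressed phenotype tags,
* :func:`viability_of` -- genotype to viable/inviable (aneuploidy from
  unbalanced translocation products, lethal balancer homozygotes),
* :func:`sex_of`      -- X-haplotype count to hermaphrodite/male.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional


class Chromosome(enum.Enum):
    """The six *C. elegans* chromosomes; X is the only sex chromosome."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"
    X = "X"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def is_autosome(self) -> bool:
        return self is not Chromosome.X


AUTOSOMES: tuple[Chromosome, ...] = tuple(
    c for c in Chromosome if c is not Chromosome.X
)

#: Stable ordering used for canonicalization.
_CHROM_ORDER = {c: i for i, c in enumerate(Chromosome)}


class Dominance(enum.Enum):
    DOMINANT = "dominant"
    RECESSIVE = "recessive"


class Sex(enum.Enum):
    HERMAPHRODITE = "hermaphrodite"
    MALE = "male"


class Viability(enum.Enum):
    VIABLE = "viable"
    INVIABLE = "inviable"


class BalancerKind(enum.Enum):
    RECIPROCAL_TRANSLOCATION = "reciprocal_translocation"
    INVERSION = "inversion"


class HomozygoteFate(enum.Enum):
    LETHAL = "lethal"
    VIABLE = "viable"
    VIABLE_WITH_PHENOTYPE = "viable_with_phenotype"


# Common phenotype tags.  The tag vocabulary is open: any string is a valid
# tag; these constants only name the ones used by the bundled strains.
GREEN = "Green"
RED = "Red"
DPY = "Dpy"
UNC = "Unc"
ROL = "Rol"
MUV = "Muv"


class RegistryError(KeyError):
    """An allele, locus, balancer or array reference is unknown/duplicated."""


class KaryotypeError(ValueError):
    """A genotype has an impossible chromosome complement."""


class GeneticsError(ValueError):
    """A genetic operation was applied to an invalid input."""


@dataclass(frozen=True)
class Locus:
    """A named position on a chromosome (e.g. dpy-5 on I)."""

    id: str
    chromosome: Chromosome
    name: str = ""


@dataclass(frozen=True)
class Allele:
    """A variant at a locus with a dominance mode and phenotype tags."""

    symbol: str
    locus: str
    dominance: Dominance
    tags: frozenset = frozenset()

    @property
    def is_dominant(self) -> bool:
        return self.dominance is Dominance.DOMINANT


@dataclass(frozen=True)
class BalancerDef:
    """A balancer element: reciprocal translocation or inversion.

    Translocations balance exactly two chromosomes and create
    pseudo-linkage between them (their two halves co-segregate in the
    alternate-segregation model).  Inversions balance one chromosome.
    The GFP marker allele rides on the balancer haplotype of
    ``marker_chromosome`` and is expressed dominantly.
    """

    name: str
    kind: BalancerKind
    balanced: frozenset
    marker_allele: str
    homozygote_fate: HomozygoteFate
    homozygote_tags: frozenset = frozenset()

    def __post_init__(self) -> None:
        n = len(self.balanced)
        if self.kind is BalancerKind.RECIPROCAL_TRANSLOCATION and n != 2:
            raise ValueError(
                f"translocation {self.name} must balance exactly 2 "
                f"chromosomes, got {n}"
            )
        if self.kind is BalancerKind.INVERSION and n != 1:
            raise ValueError(
                f"inversion {self.name} must balance exactly 1 chromosome, "
                f"got {n}"
            )

    @property
    def marker_chromosome(self) -> Chromosome:
        return min(self.balanced, key=_CHROM_ORDER.__getitem__)


@dataclass(frozen=True)
class ExtrachromosomalArray:
    """A transgenic array not attached to any chromosome.

    ``transmission_prob`` is the per-offspring probability that a
    carrier parent passes the array on.  With ``per_gamete=True`` the
    element instead segregates like a free duplication: each gamete of a
    carrier receives it independently with ``transmission_prob`` and the
    zygote carries it if either gamete does (this makes p = 0.5
    reproduce the segregation of an unlinked heterozygous locus).
    """

    name: str
    tags: frozenset = frozenset()
    transmission_prob: float = 0.65
    per_gamete: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.transmission_prob <= 1.0:
            raise ValueError(
                f"transmission_prob must be in [0,1], got "
                f"{self.transmission_prob}"
            )


@dataclass(frozen=True)
class Haplotype:
    """Content of one chromosome slot: a normal homolog or a balancer
    element (one translocation half, or an inverted chromosome), plus the
    alleles riding on it."""

    chromosome: Chromosome
    alleles: frozenset = frozenset()
    balancer: Optional[str] = None

    @property
    def is_balancer(self) -> bool:
        return self.balancer is not None

    def key(self) -> tuple:
        return (
            self.chromosome.value,
            self.balancer or "",
            tuple(sorted(self.alleles)),
        )


@dataclass
class Genotype:
    """A diploid genotype: two haplotypes per autosome, one or two X
    haplotypes, and a set of carried extrachromosomal arrays."""

    chromosomes: dict
    arrays: frozenset = frozenset()

    @property
    def x_haplotypes(self) -> tuple:
        return self.chromosomes.get(Chromosome.X, ())

    @property
    def x_count(self) -> int:
        return len(self.x_haplotypes)

    def key(self) -> tuple:
        """Canonical hashable key (order of homologs is irrelevant)."""
        chrom_part = tuple(
            (c.value, tuple(sorted(h.key() for h in self.chromosomes[c])))
            for c in Chromosome
            if c in self.chromosomes
        )
        return (chrom_part, tuple(sorted(self.arrays)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genotype):
            return NotImplemented
        return self.key() == other.key()

    def __hash__(self) -> int:
        return hash(self.key())


@dataclass
class Individual:
    """A worm: genotype plus derived sex/phenotype and bench bookkeeping."""

    uid: str
    genotype: Genotype
    sex: Sex
    phenotype: frozenset
    stage: str = "L4"
    parents: tuple = ()
    alive: bool = True

    def has(self, tag: str) -> bool:
        return tag in self.phenotype


class GeneRegistry:
    """Registry of loci, alleles, balancers and arrays.

    All genotype operations resolve symbols through a registry so that
    fixtures, configs and reports agree on the genetic universe.
    """

    def __init__(self) -> None:
        self.loci: dict = {}
        self.alleles: dict = {}
        self.balancers: dict = {}
        self.arrays: dict = {}

    # -- registration -------------------------------------------------
    def add_locus(self, locus: Locus) -> Locus:
        if locus.id in self.loci:
            raise RegistryError(f"duplicate locus {locus.id!r}")
        self.loci[locus.id] = locus
        return locus

    def add_allele(self, allele: Allele) -> Allele:
        if allele.symbol in self.alleles:
            raise RegistryError(f"duplicate allele {allele.symbol!r}")
        if allele.locus not in self.loci:
            raise RegistryError(f"allele {allele.symbol!r} references "
                                f"unknown locus {allele.locus!r}")
        self.alleles[allele.symbol] = allele
        return allele

    def add_balancer(self, bal: BalancerDef) -> BalancerDef:
        if bal.name in self.balancers:
            raise RegistryError(f"duplicate balancer {bal.name!r}")
        marker = self.alleles.get(bal.marker_allele)
        if marker is None:
            raise RegistryError(f"balancer {bal.name!r} references unknown "
                                f"marker allele {bal.marker_allele!r}")
        if GREEN not in marker.tags:
            raise ValueError(f"balancer marker {marker.symbol!r} must carry "
                             f"the {GREEN!r} tag")
        self.balancers[bal.name] = bal
        return bal

    def add_array(self, array: ExtrachromosomalArray) -> ExtrachromosomalArray:
        if array.name in self.arrays:
            raise RegistryError(f"duplicate array {array.name!r}")
        self.arrays[array.name] = array
        return array

    # -- lookup -------------------------------------------------------
    def allele(self, symbol: str) -> Allele:
        try:
            return self.alleles[symbol]
        except KeyError:
            raise RegistryError(f"unknown allele {symbol!r}") from None

    def locus(self, locus_id: str) -> Locus:
        try:
            return self.loci[locus_id]
        except KeyError:
            raise RegistryError(f"unknown locus {locus_id!r}") from None

    def balancer(self, name: str) -> BalancerDef:
        try:
            return self.balancers[name]
        except KeyError:
            raise RegistryError(f"unknown balancer {name!r}") from None

    def array(self, name: str) -> ExtrachromosomalArray:
        try:
            return self.arrays[name]
        except KeyError:
            raise RegistryError(f"unknown array {name!r}") from None

    def allele_chromosome(self, symbol: str) -> Chromosome:
        return self.locus(self.allele(symbol).locus).chromosome

    # -- serialization ------------------------------------------------
    def to_config(self) -> dict:
        """Plain-dict form, round-trippable through YAML."""
        return {
            "loci": [
                {"id": l.id, "chromosome": l.chromosome.value, "name": l.name}
                for l in self.loci.values()
            ],
            "alleles": [
                {
                    "symbol": a.symbol,
                    "locus": a.locus,
                    "dominance": a.dominance.value,
                    "tags": sorted(a.tags),
                }
                for a in self.alleles.values()
            ],
            "balancers": [
                {
                    "name": b.name,
                    "kind": b.kind.value,
                    "balanced": sorted(c.value for c in b.balanced),
                    "marker_allele": b.marker_allele,
                    "homozygote_fate": b.homozygote_fate.value,
                    "homozygote_tags": sorted(b.homozygote_tags),
                }
                for b in self.balancers.values()
            ],
            "arrays": [
                {
                    "name": x.name,
                    "tags": sorted(x.tags),
                    "transmission_prob": x.transmission_prob,
                    "per_gamete": x.per_gamete,
                }
                for x in self.arrays.values()
            ],
        }

    @classmethod
    def from_config(cls, cfg: Mapping) -> "GeneRegistry":
        reg = cls()
        for l in cfg.get("loci", ()):
            reg.add_locus(Locus(l["id"], Chromosome(l["chromosome"]),
                                l.get("name", "")))
        for a in cfg.get("alleles", ()):
            reg.add_allele(Allele(a["symbol"], a["locus"],
                                  Dominance(a["dominance"]),
                                  frozenset(a.get("tags", ()))))
        for b in cfg.get("balancers", ()):
            reg.add_balancer(BalancerDef(
                b["name"], BalancerKind(b["kind"]),
                frozenset(Chromosome(c) for c in b["balanced"]),
                b["marker_allele"],
                HomozygoteFate(b["homozygote_fate"]),
                frozenset(b.get("homozygote_tags", ())),
            ))
        for x in cfg.get("arrays", ()):
            reg.add_array(ExtrachromosomalArray(
                x["name"], frozenset(x.get("tags", ())),
                float(x.get("transmission_prob", 0.65)),
                bool(x.get("per_gamete", False)),
            ))
        return reg

    def to_csv(self, path) -> None:
        """Lossless wide-table CSV (one row per registry entry)."""
        import pandas as pd

        rows = []
        for l in self.loci.values():
            rows.append({"kind": "locus", "name": l.id,
                         "chromosome": l.chromosome.value, "label": l.name})
        for a in self.alleles.values():
            rows.append({"kind": "allele", "name": a.symbol,
                         "locus": a.locus, "dominance": a.dominance.value,
                         "tags": ";".join(sorted(a.tags))})
        for b in self.balancers.values():
            rows.append({"kind": "balancer", "name": b.name,
                         "balancer_kind": b.kind.value,
                         "chromosome": ";".join(sorted(c.value
                                                       for c in b.balanced)),
                         "marker": b.marker_allele,
                         "fate": b.homozygote_fate.value,
                         "tags": ";".join(sorted(b.homozygote_tags))})
        for x in self.arrays.values():
            rows.append({"kind": "array", "name": x.name,
                         "tags": ";".join(sorted(x.tags)),
                         "transmission_prob": x.transmission_prob,
                         "per_gamete": x.per_gamete})
        cols = ["kind", "name", "chromosome", "label", "locus", "dominance",
                "balancer_kind", "marker", "fate", "tags",
                "transmission_prob", "per_gamete"]
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GeneRegistry":
        import pandas as pd

        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        reg = cls()

        def tags(row):
            return frozenset(t for t in row["tags"].split(";") if t)

        for _, row in frame[frame["kind"] == "locus"].iterrows():
            reg.add_locus(Locus(row["name"], Chromosome(row["chromosome"]),
                                row["label"]))
        for _, row in frame[frame["kind"] == "allele"].iterrows():
            reg.add_allele(Allele(row["name"], row["locus"],
                                  Dominance(row["dominance"]), tags(row)))
        for _, row in frame[frame["kind"] == "balancer"].iterrows():
            reg.add_balancer(BalancerDef(
                row["name"], BalancerKind(row["balancer_kind"]),
                frozenset(Chromosome(c)
                          for c in row["chromosome"].split(";")),
                row["marker"], HomozygoteFate(row["fate"]), tags(row)))
        for _, row in frame[frame["kind"] == "array"].iterrows():
            reg.add_array(ExtrachromosomalArray(
                row["name"], tags(row), float(row["transmission_prob"]),
                row["per_gamete"] == "True"))
        return reg

    def to_frame(self):
        """Flat table of registry entries (one row per entry) for reports."""
        import pandas as pd

        rows = []
        for l in self.loci.values():
            rows.append({"kind": "locus", "name": l.id,
                         "chromosome": l.chromosome.value,
                         "detail": l.name, "tags": ""})
        for a in self.alleles.values():
            rows.append({"kind": "allele", "name": a.symbol,
                         "chromosome": self.loci[a.locus].chromosome.value,
                         "detail": a.dominance.value,
                         "tags": ";".join(sorted(a.tags))})
        for b in self.balancers.values():
            rows.append({"kind": "balancer", "name": b.name,
                         "chromosome": ";".join(sorted(c.value
                                                       for c in b.balanced)),
                         "detail": f"{b.kind.value}:{b.homozygote_fate.value}",
                         "tags": b.marker_allele})
        for x in self.arrays.values():
            rows.append({"kind": "array", "name": x.name,
                         "chromosome": "-",
                         "detail": f"p={x.transmission_prob}",
                         "tags": ";".join(sorted(x.tags))})
        return pd.DataFrame(rows,
                            columns=["kind", "name", "chromosome", "detail",
                                     "tags"])


# ---------------------------------------------------------------------------
# Genotype construction
# ---------------------------------------------------------------------------

def build_genotype(
    registry: GeneRegistry,
    *,
    hom: Iterable[str] = (),
    het: Iterable[str] = (),
    balancer_het: Iterable[str] = (),
    balancer_hom: Iterable[str] = (),
    arrays: Iterable[str] = (),
    male: bool = False,
) -> Genotype:
    """Assemble a genotype from allele symbols and balancer names.

    ``hom`` alleles go on both homologs, ``het`` on the first homolog
    only.  Balancer elements replace the *second* homolog of each
    chromosome they balance (both for ``balancer_hom``), so a ``het``
    transgene on a balanced chromosome sits in cis to the normal
    homolog -- the configuration produced by selecting doubly marked F1s.
    For males the X slot holds a single haplotype and X-linked alleles
    (hom or het) are hemizygous.
    """
    alleles_by_chrom: dict = {c: ([], []) for c in Chromosome}
    for sym in hom:
        c = registry.allele_chromosome(sym)
        alleles_by_chrom[c][0].append(sym)
        alleles_by_chrom[c][1].append(sym)
    for sym in het:
        c = registry.allele_chromosome(sym)
        alleles_by_chrom[c][0].append(sym)

    chromosomes: dict = {}
    for c in Chromosome:
        h0 = Haplotype(c, frozenset(alleles_by_chrom[c][0]))
        h1 = Haplotype(c, frozenset(alleles_by_chrom[c][1]))
        if c is Chromosome.X and male:
            chromosomes[c] = (h0,)  # hemizygous: hom and het collapse
        else:
            chromosomes[c] = (h0, h1)

    def _balancer_haps(name: str) -> dict:
        bal = registry.balancer(name)
        out = {}
        for c in bal.balanced:
            marker = (frozenset({bal.marker_allele})
                      if c is bal.marker_chromosome else frozenset())
            out[c] = Haplotype(c, marker, balancer=name)
        return out

    for name in balancer_het:
        for c, hap in _balancer_haps(name).items():
            pair = chromosomes[c]
            if len(pair) != 2:
                raise GeneticsError(f"cannot balance haploid slot {c}")
            chromosomes[c] = (pair[0], hap)
    for name in balancer_hom:
        for c, hap in _balancer_haps(name).items():
            chromosomes[c] = (hap, hap)

    for a in arrays:
        registry.array(a)  # existence check
    return Genotype(chromosomes, frozenset(arrays))


# ---------------------------------------------------------------------------
# Genotype -> phenotype / viability / sex
# ---------------------------------------------------------------------------

def sex_of(genotype: Genotype) -> Sex:
    """XX -> hermaphrodite, X0 -> male; anything else is an invalid
    karyotype."""
    n = genotype.x_count
    if n == 2:
        return Sex.HERMAPHRODITE
    if n == 1:
        return Sex.MALE
    raise KaryotypeError(f"invalid X haplotype count {n}")


def viability_of(genotype: Genotype, registry: GeneRegistry) -> Viability:
    """Inviable iff aneuploid (a translocation half without its partner)
    or homozygous for a balancer whose homozygote fate is lethal."""
    # Translocation balance: within the genotype, each half of a
    # translocation must be present in equal copy number on both balanced
    # chromosomes (0, 1 or 2 full sets).
    counts: dict = {}
    for c, haps in genotype.chromosomes.items():
        for h in haps:
            if h.balancer is not None:
                counts.setdefault(h.balancer, {})[c] = (
                    counts.get(h.balancer, {}).get(c, 0) + 1
                )
    for name, per_chrom in counts.items():
        bal = registry.balancer(name)
        copy_numbers = {per_chrom.get(c, 0) for c in bal.balanced}
        if bal.kind is BalancerKind.RECIPROCAL_TRANSLOCATION:
            if len(copy_numbers) != 1:
                return Viability.INVIABLE
        n_copies = max(copy_numbers)
        if n_copies == 2 and bal.homozygote_fate is HomozygoteFate.LETHAL:
            return Viability.INVIABLE
    return Viability.VIABLE


def phenotype_of(
    genotype: Genotype,
    registry: GeneRegistry,
    rng=None,
    penetrance: Optional[Mapping] = None,
) -> frozenset:
    """Expressed phenotype tags of a genotype.

    Dominant alleles (and balancer markers, and array tags) express with
    one copy; recessive alleles require every haplotype of their slot to
    carry them, so hemizygous males express X-linked recessives.  The
    optional ``penetrance`` mapping (tag -> probability) stochastically
    drops tags and requires ``rng``.
    """
    tags: set = set()
    counts: dict = {}
    ploidy: dict = {}
    for c, haps in genotype.chromosomes.items():
        for h in haps:
            for sym in h.alleles:
                counts[sym] = counts.get(sym, 0) + 1
                ploidy[sym] = len(haps)
    for sym, n in counts.items():
        allele = registry.allele(sym)
        if allele.is_dominant or n == ploidy[sym]:
            tags |= allele.tags
    for name in genotype.arrays:
        tags |= registry.array(name).tags
    # Homozygous balancers with a visible homozygote phenotype (e.g. Unc).
    bal_copy: dict = {}
    for c, haps in genotype.chromosomes.items():
        for h in haps:
            if h.balancer is not None:
                key = (h.balancer, c)
                bal_copy[key] = bal_copy.get(key, 0) + 1
    for (name, _c), n in bal_copy.items():
        if n == 2:
            bal = registry.balancer(name)
            if bal.homozygote_fate is HomozygoteFate.VIABLE_WITH_PHENOTYPE:
                tags |= bal.homozygote_tags

    if penetrance:
        if rng is None:
            raise GeneticsError("penetrance < 1 requires an rng")
        tags = {t for t in tags
                if penetrance.get(t, 1.0) >= 1.0
                or rng.random() < penetrance[t]}
    return frozenset(tags)


def make_individual(
    uid: str,
    genotype: Genotype,
    registry: GeneRegistry,
    stage: str = "L4",
    parents: tuple = (),
) -> Individual:
    """Convenience constructor deriving sex and phenotype."""
    return Individual(uid, genotype, sex_of(genotype),
                      phenotype_of(genotype, registry),
                      stage=stage, parents=parents)
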