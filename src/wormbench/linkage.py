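"""Chromosome-scale linkage mapping with balancers and the Linkage Index.

The autosomal scheme crosses a Green balanced-heterozygote male to the
Red strain of interest, selects a doubly fluorescent F1 hermaphrodite
and lets it self.  Because the balancer suppresses recombination over
the chromosomes it covers, a transgene on a covered chromosome stays in
cis to the normal homolog: every nonGreen F2 is then homozygous for that
homolog and Red (expected fraction 1.0), whereas an uncovered transgene
assorts independently (expected fraction 3/4 Red among nonGreen).

The X scheme crosses the Red strain to wild-type males carrying a
dominant Green helper array, picks a Red-Green F1 male, and mates him to
wild-type hermaphrodites.  F2 males inherit their X from their mother,
so an X-linked transgene never reaches them (expected 0 Red among F2
males) while an autosomal one reaches half of them (expected 1/2).

The Linkage Index normalizes an observed fraction between those two
anchors:

    LI = (p_obs - p_unlinked) / (p_linked - p_unlinked),  clipped to [-1, 1]

so LI = 1 at the fully linked expectation and LI = 0 at the unlinked one.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from scipy import stats

from .bench import ProtocolFailure
from .genetics import (
    Chromosome,
    GREEN,
    GeneRegistry,
    Genotype,
    RED,
    Sex,
)
from .strains import DEFAULT_COVERAGE, MappingScenario
from .transmission import EngineConfig, DEFAULT_CONFIG, mate, self_cross


class TestKind(enum.Enum):
    __test__ = False  # not a pytest class

    AUTOSOMAL_BALANCER = "autosomal_balancer"
    X_LINKED = "x_linked"


def expected_fraction(test_kind: TestKind, linked: bool) -> float:
    """Analytic segregation expectation for one test cell.

    autosomal: P(Red | nonGreen F2) = 1 if linked else 3/4
    X:         P(Red | F2 male)     = 0 if linked else 1/2
    """
    if test_kind is TestKind.AUTOSOMAL_BALANCER:
        return 1.0 if linked else 0.75
    return 0.0 if linked else 0.5


def linkage_index(p_obs: float, test_kind: TestKind) -> float:
    """Normalized linkage strength in [-1, 1]: 1 at the fully linked
    expectation, 0 at the unlinked expectation."""
    if not 0.0 <= p_obs <= 1.0:
        raise ValueError(f"p_obs must be in [0,1], got {p_obs}")
    p_linked = expected_fraction(test_kind, True)
    p_unlinked = expected_fraction(test_kind, False)
    raw = (p_obs - p_unlinked) / (p_linked - p_unlinked)
    return max(-1.0, min(1.0, raw))


@dataclass
class LinkageTestSpec:
    test_kind: TestKind
    transgene: str
    balancer: Optional[str] = None  # autosomal tests only
    n_scored: int = 200
    brood_size: int = 120
    max_broods: int = 400
    score_males: bool = False  # autosomal scoring excludes males by default

    def __post_init__(self) -> None:
        if self.n_scored <= 0:
            raise ValueError("n_scored must be > 0")
        if self.test_kind is TestKind.AUTOSOMAL_BALANCER and not self.balancer:
            raise ValueError("autosomal test requires a balancer")


@dataclass
class LinkageTestResult:
    """Observed vs expected segregation for one test.

    ``scored_total`` counts informative animals (nonGreen F2 for the
    autosomal test, F2 males for the X test); ``p_value`` is the exact
    two-sided binomial test of H0: p = p_unlinked, reported alongside
    the Linkage Index because LI alone carries no sampling theory.
    """

    test_name: str
    test_kind: TestKind
    scored_total: int
    scored_positive: int
    p_obs: float
    p_linked_expected: float
    p_unlinked_expected: float
    linkage_index: float
    p_value: float

    @classmethod
    def from_counts(cls, test_name: str, test_kind: TestKind,
                    positive: int, total: int) -> "LinkageTestResult":
        p_obs = positive / total
        li = linkage_index(p_obs, test_kind)
        p_unl = expected_fraction(test_kind, False)
        pval = stats.binomtest(positive, total, p_unl).pvalue
        return cls(test_name, test_kind, total, positive, p_obs,
                   expected_fraction(test_kind, True), p_unl, li, pval)


def _select_f1(brood, want_tags, sex: Sex, attempts_left: int):
    for w in brood:
        if (w.alive and w.sex is sex and want_tags <= w.phenotype):
            return w
    return None


def run_autosomal_linkage_test(
    spec: LinkageTestSpec,
    scenario: MappingScenario,
    config: EngineConfig = DEFAULT_CONFIG,
    rng=None,
) -> LinkageTestResult:
    """One balancer test: Green balanced-het male x Red hermaphrodite,
    select a Red-Green F1 hermaphrodite, self it, and score Red among
    nonGreen F2 until ``n_scored`` informative animals are seen."""
    reg = scenario.registry
    male = scenario.balancer_strains[spec.balancer]["male"]
    herm = scenario.transgene_herm

    f1 = None
    for attempt in range(10):
        brood = mate(herm, male, spec.brood_size, reg, rng, config,
                     uid_prefix=f"f1-{attempt}-")
        f1 = _select_f1(brood, {RED, GREEN}, Sex.HERMAPHRODITE, attempt)
        if f1 is not None:
            break
    if f1 is None:
        raise ProtocolFailure(
            f"{spec.balancer}-F1-selection",
            "no Red-Green F1 hermaphrodite found")

    positive = total = 0
    for batch in range(spec.max_broods):
        if total >= spec.n_scored:
            break
        for w in self_cross(f1.genotype, spec.brood_size, reg, rng, config,
                            uid_prefix=f"f2-{batch}-"):
            if not w.alive:
                continue
            if not spec.score_males and w.sex is Sex.MALE:
                continue
            if GREEN in w.phenotype:
                continue
            total += 1
            if RED in w.phenotype:
                positive += 1
            if total >= spec.n_scored:
                break
    if total < spec.n_scored:
        raise ProtocolFailure(f"{spec.balancer}-F2-scoring",
                              f"only {total} informative F2 found")
    return LinkageTestResult.from_counts(spec.balancer, spec.test_kind,
                                         positive, total)


def run_x_linkage_test(
    spec: LinkageTestSpec,
    scenario: MappingScenario,
    config: EngineConfig = DEFAULT_CONFIG,
    rng=None,
) -> LinkageTestResult:
    """The X test: Red hermaphrodite x Green-array helper male, select a
    Red-Green F1 male, mate him to wild-type hermaphrodites, and score
    Red among F2 males until ``n_scored`` males are seen."""
    reg = scenario.registry
    herm = scenario.transgene_herm
    helper = scenario.helper_male

    f1 = None
    for attempt in range(10):
        brood = mate(herm, helper, spec.brood_size, reg, rng, config,
                     uid_prefix=f"xf1-{attempt}-")
        f1 = _select_f1(brood, {RED, GREEN}, Sex.MALE, attempt)
        if f1 is not None:
            break
    if f1 is None:
        raise ProtocolFailure("X-F1-selection",
                              "no Red-Green F1 male found")

    from .strains import DEFAULT_STRAINS

    n2_herm = DEFAULT_STRAINS["N2"].make_genotype(reg)
    positive = total = 0
    for batch in range(spec.max_broods):
        if total >= spec.n_scored:
            break
        for w in mate(n2_herm, f1.genotype, spec.brood_size, reg, rng,
                      config, uid_prefix=f"xf2-{batch}-"):
            if not w.alive or w.sex is not Sex.MALE:
                continue
            total += 1
            if RED in w.phenotype:
                positive += 1
            if total >= spec.n_scored:
                break
    if total < spec.n_scored:
        raise ProtocolFailure("X-F2-scoring",
                              f"only {total} F2 males found")
    return LinkageTestResult.from_counts("X", spec.test_kind, positive, total)


@dataclass
class LinkageMap:
    """All test results for one transgene plus the inferred placement."""

    coverage: dict
    results: dict  # test name -> LinkageTestResult
    inferred: set
    threshold: float

    @property
    def indices(self) -> dict:
        return {name: r.linkage_index for name, r in self.results.items()}

    def to_frame(self):
        """Tests x chromosomes matrix with each test's LI replicated
        across its covered chromosomes (heat-map layout)."""
        import numpy as np
        import pandas as pd

        chroms = [c.value for c in Chromosome]
        data = {}
        for name, result in self.results.items():
            row = {c: np.nan for c in chroms}
            for c in self.coverage[name]:
                row[c.value] = result.linkage_index
            data[name] = row
        return pd.DataFrame(data).T.reindex(columns=chroms)

    def to_summary(self) -> dict:
        return {
            "threshold": self.threshold,
            "inferred_chromosomes": sorted(c.value for c in self.inferred),
            "tests": {
                name: {
                    "kind": r.test_kind.value,
                    "scored_total": r.scored_total,
                    "scored_positive": r.scored_positive,
                    "p_obs": r.p_obs,
                    "p_linked_expected": r.p_linked_expected,
                    "p_unlinked_expected": r.p_unlinked_expected,
                    "linkage_index": r.linkage_index,
                    "p_value": r.p_value,
                    "coverage": sorted(c.value for c in self.coverage[name]),
                }
                for name, r in self.results.items()
            },
        }


def infer_chromosome(
    results: Mapping,
    coverage: Mapping = DEFAULT_COVERAGE,
    threshold: float = 0.5,
) -> set:
    """Chromosomes consistent with the linked/unlinked calls.

    A test is called linked if its LI >= threshold.  A chromosome is
    implicated iff it lies in every linked test's coverage and in no
    unlinked test's coverage; an inconsistent pattern gives the empty
    set.  ``results`` maps test name -> LinkageTestResult or LI value.
    """
    def li_of(v) -> float:
        return v.linkage_index if hasattr(v, "linkage_index") else float(v)

    candidates = set(Chromosome)
    for name, result in results.items():
        cov = coverage[name]
        if li_of(result) >= threshold:
            candidates &= cov
        else:
            candidates -= cov
    return candidates


def run_all_linkage_tests(
    scenario: MappingScenario,
    n_scored: int = 200,
    config: EngineConfig = DEFAULT_CONFIG,
    rng=None,
    threshold: float = 0.5,
    brood_size: int = 120,
) -> LinkageMap:
    """Run the four balancer tests plus the X test and infer placement."""
    results: dict = {}
    for name in ("hT2", "eT1", "nT1", "mIn1"):
        spec = LinkageTestSpec(TestKind.AUTOSOMAL_BALANCER,
                               scenario.transgene, balancer=name,
                               n_scored=n_scored, brood_size=brood_size)
        results[name] = run_autosomal_linkage_test(spec, scenario, config,
                                                   rng)
    spec = LinkageTestSpec(TestKind.X_LINKED, scenario.transgene,
                           n_scored=n_scored, brood_size=brood_size)
    results["X"] = run_x_linkage_test(spec, scenario, config, rng)
    inferred = infer_chromosome(results, scenario.coverage, threshold)
    return LinkageMap(dict(scenario.coverage), results, inferred, threshold)
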