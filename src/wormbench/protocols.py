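"""High-level genetic procedures on the virtual bench.

:func:`run_genetic_cross` drives the multi-generation hybridization of a
dominant Green transgenic strain with a recessive Dumpy mutant: generate
transgenic males, mate them to the mutant, single doubly marked F1 and
F2 animals, and screen F5 broods for lines in which the Green marker
breeds true (100% transmission means homozygous).

:func:`run_integration_screen` models the array-integration workflow: a
mutagenized P0 population yields F1 lines each of which carries a
heterozygous genomic integration with probability ``p_integration``
(otherwise the transgene remains an extrachromosomal array); singled F2
lines are called integrants iff every screened progeny in every screened
generation carries the marker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .bench import (
    ActionRates,
    Plate,
    ProtocolFailure,
    VirtualBench,
    WormPredicate,
    cross_worms,
)
from .genetics import (
    Allele,
    Chromosome,
    AUTOSOMES,
    Dominance,
    DPY,
    GREEN,
    GeneRegistry,
    Genotype,
    Individual,
    Locus,
    Sex,
    build_genotype,
    make_individual,
)
from .strains import DEFAULT_STRAINS, make_strain_population
from .transmission import (
    DEFAULT_CONFIG,
    EngineConfig,
    brood_from_distribution,
    enumerate_offspring,
    format_genotype,
    mate,
    self_cross,
)


# ---------------------------------------------------------------------------
# genetic cross
# ---------------------------------------------------------------------------

@dataclass
class CrossConfig:
    """Parameters of the automated hybridization protocol.

    The pick counts mirror the published workflow (17 males + 4
    hermaphrodites for male generation, 6 males + 2 hermaphrodites for
    the P0 mating, 2 F1 / 3 F2 / 11 F4 singled, F5 screened for 100%
    Green).  ``exact_broods`` switches broods from sampled to
    enumeration-backed (deterministic class counts).
    """

    transgene: str = "vsIs28"
    mutant_allele: str = "e61"
    n_gen_males: int = 17
    n_gen_herms: int = 4
    n_p0_males: int = 6
    n_p0_herms: int = 2
    n_f1: int = 2
    n_f2: int = 3
    n_f4: int = 11
    f5_screen_n: int = 40
    retries: int = 3
    exact_broods: bool = False
    n2_stock_size: int = 80
    n2_stock_male_fraction: float = 0.35  # male-enriched mating stock
    strain_stock_size: int = 30


@dataclass
class LineResult:
    line_id: str
    plate: str
    n_screened: int
    fraction_green: float
    homozygous: bool


@dataclass
class CrossReport:
    success: bool
    failure_stage: Optional[str]
    lines: list = field(default_factory=list)
    stage_metrics: dict = field(default_factory=dict)
    lineage: list = field(default_factory=list)
    final_genotype: str = ""
    breeds_true: Optional[bool] = None
    bench: Optional[VirtualBench] = None

    @property
    def homozygous_lines(self) -> list:
        return [l for l in self.lines if l.homozygous]

    def lineage_frame(self):
        import pandas as pd

        return pd.DataFrame(self.lineage, columns=[
            "generation", "worm", "phenotype", "src_plate", "dst_plate"])


def _brood(herm: Genotype, male: Optional[Genotype], n: int,
           registry: GeneRegistry, rng, engine: EngineConfig, exact: bool,
           prefix: str) -> list:
    if exact:
        dist = enumerate_offspring(herm, male, registry, engine)
        return brood_from_distribution(dist, n, registry, uid_prefix=prefix)
    if male is None:
        return self_cross(herm, n, registry, rng, engine, uid_prefix=prefix)
    return mate(herm, male, n, registry, rng, engine, uid_prefix=prefix)


def _single(bench: VirtualBench, sources: list, predicate: WormPredicate,
            n: int, generation: str, cfg: CrossConfig, lineage: list) -> list:
    """Single ``n`` matching worms from the source plates onto fresh
    plates (round-robin across sources).

    In exact-brood mode candidates are taken evenly spaced across the
    class-interleaved brood so the singled set spans genotype classes;
    otherwise the candidate is drawn at random.  Returns the new plates;
    raises ProtocolFailure when fewer than ``n`` singlings succeed.
    """
    plates: list = []
    per_source = [n // len(sources)] * len(sources)
    for i in range(n % len(sources)):
        per_source[i] += 1
    for src, quota in zip(sources, per_source):
        candidates = bench.screen(src, predicate)
        if cfg.exact_broods and candidates:
            step = len(candidates) / max(quota, 1)
            ordered = [candidates[min(int((j + 0.5) * step),
                                      len(candidates) - 1)]
                       for j in range(quota)]
        else:
            ordered = [None] * quota
        for j in range(quota):
            dst = bench.new_plate(label=f"{generation} isolate",
                                  generation=generation,
                                  parent_barcodes=src.barcode)
            moved = False
            for _attempt in range(cfg.retries * 3):
                if ordered[j] is not None and ordered[j].alive \
                        and any(w is ordered[j] for w in src.worms):
                    worm = ordered[j]
                    outcome = bench.transfer(src, worm, dst)
                else:
                    outcome = bench.pick_retry(src, predicate, dst,
                                               cfg.retries)
                if outcome.status == "moved":
                    if dst.live_worms():
                        moved = True
                        w = dst.live_worms()[0]
                        lineage.append({
                            "generation": generation, "worm": w.uid,
                            "phenotype": ";".join(sorted(w.phenotype)),
                            "src_plate": src.barcode,
                            "dst_plate": dst.barcode})
                        break
                    # singled worm died post-pick: try another candidate
                    ordered[j] = None
                    continue
                if outcome.status == "not_found":
                    break
            if moved:
                plates.append(dst)
    if len(plates) < n:
        raise ProtocolFailure(f"single-{generation}",
                              f"needed {n} isolates, got {len(plates)}")
    return plates


def run_genetic_cross(
    registry: GeneRegistry,
    cfg: CrossConfig,
    rates: ActionRates,
    engine: EngineConfig,
    rng,
) -> CrossReport:
    """Execute the full hybridization scheme on a virtual bench.

    Returns a report rather than raising on protocol failure, so callers
    can branch on ``report.success`` / ``report.failure_stage``.
    """
    bench = VirtualBench(registry, rates, rng)
    lineage: list = []
    metrics: dict = {}
    herm_pred = WormPredicate(sex=Sex.HERMAPHRODITE)
    male_pred = WormPredicate(sex=Sex.MALE)

    try:
        # -- stock plates ------------------------------------------------
        n2 = bench.new_plate("N2 mating stock", "N2", "stock")
        bench.seed_plate(n2, make_strain_population(
            DEFAULT_STRAINS["N2"], cfg.n2_stock_size, registry, rng,
            male_fraction=cfg.n2_stock_male_fraction, uid_prefix="N2-"))
        lx = bench.new_plate("transgenic stock", "LX831", "stock")
        bench.seed_plate(lx, make_strain_population(
            DEFAULT_STRAINS["LX831"], cfg.strain_stock_size, registry, rng,
            uid_prefix="LX831-"))
        cb = bench.new_plate("mutant stock", "CB61", "stock")
        bench.seed_plate(cb, make_strain_population(
            DEFAULT_STRAINS["CB61"], cfg.strain_stock_size, registry, rng,
            uid_prefix="CB61-"))

        # -- male generation: wild-type males x transgenic herms ---------
        gen_plate = bench.new_plate("male generation mating", "cross",
                                    "gen")
        bench.execute(cross_worms(n2.barcode, cfg.n_gen_males, lx.barcode,
                                  cfg.n_gen_herms, gen_plate.barcode,
                                  male_pred, herm_pred, cfg.retries))
        males = [w for w in gen_plate.live_worms() if w.sex is Sex.MALE]
        herms = [w for w in gen_plate.live_worms()
                 if w.sex is Sex.HERMAPHRODITE]
        if not males or not herms:
            raise ProtocolFailure("male-generation",
                                  "mating plate lacks one sex")
        metrics["gen_males_picked"] = len(males)
        gen_brood = _brood(herms[0].genotype, males[0].genotype,
                           engine.brood_size, registry, rng, engine,
                           cfg.exact_broods, "gen-")
        gen_progeny = bench.new_plate("male generation progeny", "cross",
                                      "gen-F1", gen_plate.barcode)
        bench.seed_plate(gen_progeny, gen_brood)
        green_males = bench.screen(gen_progeny, WormPredicate(
            tags_all=frozenset({GREEN}), sex=Sex.MALE))
        metrics["gen_green_male_fraction"] = (
            len(green_males) / max(1, len(gen_progeny.live_worms())))
        if not green_males:
            raise ProtocolFailure("male-generation",
                                  "no Green males among progeny")

        # -- P0: Green transgenic males x Dumpy hermaphrodites -----------
        p0 = bench.new_plate("P0 mating", "cross", "P0",
                             gen_progeny.barcode)
        bench.execute(cross_worms(
            gen_progeny.barcode, cfg.n_p0_males, cb.barcode, cfg.n_p0_herms,
            p0.barcode,
            WormPredicate(tags_all=frozenset({GREEN}), sex=Sex.MALE),
            herm_pred, cfg.retries))
        p0_males = [w for w in p0.live_worms()
                    if w.sex is Sex.MALE and GREEN in w.phenotype]
        p0_herms = [w for w in p0.live_worms()
                    if w.sex is Sex.HERMAPHRODITE]
        if not p0_males or not p0_herms:
            raise ProtocolFailure("P0-mating", "mating plate lacks one sex")
        f1_brood = _brood(p0_herms[0].genotype, p0_males[0].genotype,
                          engine.brood_size, registry, rng, engine,
                          cfg.exact_broods, "F1-")
        f1_plate = bench.new_plate("F1 progeny", "cross", "F1", p0.barcode)
        bench.seed_plate(f1_plate, f1_brood)

        # -- F1: single Green non-Dpy hermaphrodites ---------------------
        f1_pred = WormPredicate(tags_all=frozenset({GREEN}),
                                tags_none=frozenset({DPY}),
                                sex=Sex.HERMAPHRODITE)
        f1_isolates = _single(bench, [f1_plate], f1_pred, cfg.n_f1, "F1",
                              cfg, lineage)

        # -- F2: self F1s, single Dpy-Green ------------------------------
        f2_plates = []
        dpy_green_fracs = []
        for plate in f1_isolates:
            founder = plate.live_worms()[0]
            brood = _brood(founder.genotype, None, engine.brood_size,
                           registry, rng, engine, cfg.exact_broods,
                           f"{plate.barcode}-F2-")
            progeny = bench.new_plate("F2 progeny", "cross", "F2",
                                      plate.barcode)
            bench.seed_plate(progeny, brood)
            n_dg = len(bench.screen(progeny, WormPredicate(
                tags_all=frozenset({DPY, GREEN}))))
            dpy_green_fracs.append(n_dg / max(1, len(progeny.live_worms())))
            f2_plates.append(progeny)
        metrics["f2_dpy_green_fraction"] = (
            sum(dpy_green_fracs) / len(dpy_green_fracs))
        f2_pred = WormPredicate(tags_all=frozenset({DPY, GREEN}),
                                sex=Sex.HERMAPHRODITE)
        f2_isolates = _single(bench, f2_plates, f2_pred, cfg.n_f2, "F2",
                              cfg, lineage)

        # -- F3: self F2s, verify Dpy breeds true, single Dpy-Green F4s --
        f3_plates = []
        f3_green = []
        f3_dpy = []
        for plate in f2_isolates:
            founder = plate.live_worms()[0]
            brood = _brood(founder.genotype, None, engine.brood_size,
                           registry, rng, engine, cfg.exact_broods,
                           f"{plate.barcode}-F3-")
            progeny = bench.new_plate("F3 progeny", "cross", "F3",
                                      plate.barcode)
            bench.seed_plate(progeny, brood)
            live = progeny.live_worms()
            f3_dpy.append(sum(1 for w in live if DPY in w.phenotype)
                          / max(1, len(live)))
            f3_green.append(sum(1 for w in live if GREEN in w.phenotype)
                            / max(1, len(live)))
            f3_plates.append(progeny)
        metrics["f3_dpy_fraction"] = sum(f3_dpy) / len(f3_dpy)
        metrics["f3_green_fraction"] = sum(f3_green) / len(f3_green)
        f4_isolates = _single(bench, f3_plates, f2_pred, cfg.n_f4, "F4",
                              cfg, lineage)

        # -- F5: screen each F4 line for 100% Green ----------------------
        lines = []
        for plate in f4_isolates:
            founder = plate.live_worms()[0]
            brood = _brood(founder.genotype, None, cfg.f5_screen_n,
                           registry, rng, engine, cfg.exact_broods,
                           f"{plate.barcode}-F5-")
            progeny = bench.new_plate("F5 screen", "cross", "F5",
                                      plate.barcode)
            bench.seed_plate(progeny, brood)
            live = progeny.live_worms()
            n_green = len(bench.screen(progeny, WormPredicate(
                tags_all=frozenset({GREEN}))))
            frac = n_green / max(1, len(live))
            lines.append(LineResult(founder.uid, progeny.barcode,
                                    len(live), frac, frac == 1.0))
        report = CrossReport(True, None, lines, metrics, lineage,
                             bench=bench)
        if not report.homozygous_lines:
            report.success = False
            report.failure_stage = "F5-homozygosity-screen"
            return report

        # -- confirmation: the homozygous line breeds true ----------------
        winner = next(l for l in lines if l.homozygous)
        founder_plate = bench.plate(winner.plate)
        founder = founder_plate.live_worms()[0]
        report.final_genotype = format_genotype(founder.genotype, registry)
        confirm = _brood(founder.genotype, None, cfg.f5_screen_n, registry,
                         rng, engine, cfg.exact_broods, "confirm-")
        report.breeds_true = all(
            GREEN in w.phenotype and DPY in w.phenotype
            for w in confirm if w.alive)
        return report
    except ProtocolFailure as exc:
        return CrossReport(False, exc.stage, stage_metrics=metrics,
                           lineage=lineage, bench=bench)


# ---------------------------------------------------------------------------
# genomic integration screen
# ---------------------------------------------------------------------------

@dataclass
class IntegrationConfig:
    """Parameters of the array-integration screen.

    ``p_integration`` is the per-F1-line probability that the array
    integrated (heterozygously, on a random autosome) -- the mutagenesis
    step enters the model only through it.  A line is called an
    integrant iff 100% of ``screen_n`` progeny carry the marker in every
    one of ``generations`` screened generations; called lines are then
    confirmed over ``confirm_generations`` more.
    """

    array: str = "qhEx265"
    p_integration: float = 0.01
    n_f1: int = 216
    n_f2: int = 612
    screen_n: int = 30
    generations: int = 2
    confirm_generations: int = 2
    max_founder_tries: int = 200


@dataclass
class F2LineRecord:
    line_id: str
    f1_id: str
    true_state: str  # "homozygous" | "heterozygous" | "array"
    called: bool
    confirmed: Optional[bool]
    generations_passed: int


@dataclass
class IntegrationReport:
    config: IntegrationConfig
    records: list

    @property
    def called_lines(self) -> list:
        return [r for r in self.records if r.called]

    @property
    def false_positives(self) -> list:
        return [r for r in self.records if r.called and r.true_state ==
                "array"]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([{
            "line_id": r.line_id, "f1_id": r.f1_id,
            "true_state": r.true_state, "called": r.called,
            "confirmed": r.confirmed,
            "generations_passed": r.generations_passed,
        } for r in self.records])


def false_positive_probability(p_array: float, screen_n: int,
                               generations: int) -> float:
    """Closed form: a non-integrated line passes every screen only if all
    screen_n x generations progeny independently inherit the array."""
    return p_array ** (screen_n * generations)


def het_pass_probability(screen_n: int) -> float:
    """Closed form: a heterozygous integrant passes one generation's
    screen iff all screen_n self-progeny carry the marker (each with
    probability 3/4)."""
    return 0.75 ** screen_n


def _integration_allele(registry: GeneRegistry, array_name: str,
                        chrom: Chromosome) -> str:
    symbol = f"{array_name}Is@{chrom.value}"
    if symbol not in registry.alleles:
        registry.add_locus(Locus(symbol, chrom, f"integrated {array_name}"))
        registry.add_allele(Allele(
            symbol, symbol, Dominance.DOMINANT,
            registry.array(array_name).tags))
    return symbol


def _screen_line(founder: Genotype, marker_tags, n_generations: int,
                 screen_n: int, registry: GeneRegistry, rng,
                 engine: EngineConfig) -> int:
    """Number of consecutive generations (up to n_generations) in which
    every one of screen_n progeny carries the marker."""
    current = founder
    passed = 0
    for _gen in range(n_generations):
        brood = self_cross(current, screen_n, registry, rng, engine,
                           uid_prefix="scr-")
        carriers = [w for w in brood if marker_tags <= w.phenotype]
        if len(carriers) < len(brood):
            return passed
        passed += 1
        founders = [w for w in carriers if w.sex is Sex.HERMAPHRODITE]
        if not founders:
            return passed
        current = founders[int(rng.integers(len(founders)))].genotype
    return passed


def run_integration_screen(
    registry: GeneRegistry,
    cfg: IntegrationConfig,
    rng,
    engine: EngineConfig = DEFAULT_CONFIG,
) -> IntegrationReport:
    """Simulate the F1/F2 singling and multi-generation 100%-transmission
    screen; returns one record per F2 line."""
    array = registry.array(cfg.array)
    marker_tags = set(array.tags)

    # F1 founders: integrated (het, random autosome) or array carriers.
    f1_genotypes = []
    for i in range(cfg.n_f1):
        if rng.random() < cfg.p_integration:
            chrom = AUTOSOMES[int(rng.integers(len(AUTOSOMES)))]
            sym = _integration_allele(registry, cfg.array, chrom)
            f1_genotypes.append((f"F1-{i:04d}", "integrated",
                                 build_genotype(registry, het=(sym,)), sym))
        else:
            f1_genotypes.append((f"F1-{i:04d}", "array",
                                 build_genotype(registry,
                                                arrays=(cfg.array,)), None))

    # F2 singling: distribute n_f2 across F1 lines; each singled F2 is a
    # marker-positive self-progeny of its F1.
    per_f1 = [cfg.n_f2 // cfg.n_f1] * cfg.n_f1
    for i in range(cfg.n_f2 % cfg.n_f1):
        per_f1[i] += 1

    records = []
    line_no = 0
    for (f1_id, state, f1_geno, sym), quota in zip(f1_genotypes, per_f1):
        for _ in range(quota):
            f2 = None
            for _try in range(cfg.max_founder_tries):
                cand = self_cross(f1_geno, 1, registry, rng, engine,
                                  uid_prefix="f2c-")[0]
                if (cand.alive and cand.sex is Sex.HERMAPHRODITE
                        and marker_tags <= cand.phenotype):
                    f2 = cand
                    break
            if f2 is None:
                continue  # no fluorescent F2 recovered from this F1
            if state == "array":
                true_state = "array"
            else:
                copies = sum(sym in h.alleles
                             for haps in f2.genotype.chromosomes.values()
                             for h in haps)
                true_state = "homozygous" if copies == 2 else "heterozygous"
            passed = _screen_line(f2.genotype, marker_tags, cfg.generations,
                                  cfg.screen_n, registry, rng, engine)
            called = passed == cfg.generations
            confirmed = None
            if called and cfg.confirm_generations > 0:
                extra = _screen_line(f2.genotype, marker_tags,
                                     cfg.confirm_generations, cfg.screen_n,
                                     registry, rng, engine)
                confirmed = extra == cfg.confirm_generations
            line_no += 1
            records.append(F2LineRecord(f"F2-{line_no:04d}", f1_id,
                                        true_state, called, confirmed,
                                        passed))
    return IntegrationReport(cfg, records)
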