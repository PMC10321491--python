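"""The virtual bench: barcoded plates, stochastic picking and screening,
and the low/mid/high-level protocol-script hierarchy.

The bench replaces robot hardware with seeded stochastic action
outcomes: picking up and putting down each succeed with ~0.9 by default,
picked animals survive with ~0.97, plates can be flagged contaminated.
Identical seed and configuration give byte-identical run logs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Iterable, Optional, Sequence

from .genetics import GeneRegistry, Individual, Sex


class ProtocolFailure(Exception):
    """A protocol stage could not be satisfied (after retries)."""

    def __init__(self, stage: str, message: str = ""):
        self.stage = stage
        super().__init__(f"protocol failure at stage {stage!r}: {message}")


class PlateDBError(KeyError):
    """Duplicate or missing barcode in the plate database."""


@dataclass
class ActionRates:
    """Stochastic outcome rates of bench actions (all probabilities).

    Defaults reflect a robotic bench: ~90% per pick-up and per put-down
    attempt and ~97% post-pick survival.  ``manual_baseline`` carries the
    3.4% per-plate contamination incidence of manual picking as a preset.
    """

    pick_up_success: float = 0.90
    put_down_success: float = 0.90
    post_pick_survival: float = 0.97
    escape_prob: float = 0.01
    phenotype_error: float = 0.0
    contamination_prob_per_plate: float = 0.0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")

    @classmethod
    def perfect(cls) -> "ActionRates":
        return cls(1.0, 1.0, 1.0, 0.0, 0.0, 0.0)

    @classmethod
    def manual_baseline(cls) -> "ActionRates":
        return cls(contamination_prob_per_plate=0.034)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Plate:
    """A physical (virtual) agar plate holding worms."""

    barcode: str
    label: str = ""
    worms: list = field(default_factory=list)
    seeded_lawn: bool = True
    contaminated: bool = False

    def live_worms(self) -> list:
        return [w for w in self.worms if w.alive]


@dataclass
class PlateRecord:
    barcode: str
    label: str = ""
    strain: str = ""
    generation: str = ""
    parent_barcodes: str = ""
    created_step: int = 0


class PlateDB:
    """Barcode-keyed catalog of plates, persisted as CSV."""

    COLUMNS = ["barcode", "label", "strain", "generation",
               "parent_barcodes", "created_step"]

    def __init__(self) -> None:
        self.records: dict = {}

    def register(self, record: PlateRecord) -> PlateRecord:
        if record.barcode in self.records:
            raise PlateDBError(f"duplicate barcode {record.barcode!r}")
        self.records[record.barcode] = record
        return record

    def lookup(self, barcode: str) -> PlateRecord:
        try:
            return self.records[barcode]
        except KeyError:
            raise PlateDBError(f"unknown barcode {barcode!r}") from None

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = [asdict(r) for r in self.records.values()]
        pd.DataFrame(rows, columns=self.COLUMNS).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PlateDB":
        import pandas as pd

        db = cls()
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        for _, row in frame.iterrows():
            db.register(PlateRecord(
                row["barcode"], row["label"], row["strain"],
                row["generation"], row["parent_barcodes"],
                int(row["created_step"] or 0)))
        return db

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PlateDB):
            return NotImplemented
        return self.records == other.records


# ---------------------------------------------------------------------------
# predicates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WormPredicate:
    """Phenotype/sex/stage filter, e.g. Green non-Dpy L4 hermaphrodites."""

    tags_all: frozenset = frozenset()
    tags_none: frozenset = frozenset()
    sex: Optional[Sex] = None
    stage: Optional[str] = None

    def matches(self, worm: Individual) -> bool:
        if not worm.alive:
            return False
        if self.tags_all - worm.phenotype:
            return False
        if self.tags_none & worm.phenotype:
            return False
        if self.sex is not None and worm.sex is not self.sex:
            return False
        if self.stage is not None and worm.stage != self.stage:
            return False
        return True

    def describe(self) -> str:
        bits = []
        if self.tags_all:
            bits.append("+".join(sorted(self.tags_all)))
        if self.tags_none:
            bits.append("non(" + "+".join(sorted(self.tags_none)) + ")")
        if self.sex:
            bits.append(self.sex.value)
        if self.stage:
            bits.append(self.stage)
        return " ".join(bits) or "any"


def _observed_match(worm: Individual, predicate: WormPredicate, rates, rng
                    ) -> bool:
    """True match, independently flipped with phenotype_error probability
    (a misclassified worm either slips through or is missed)."""
    true_match = predicate.matches(worm)
    if rates.phenotype_error > 0 and rng.random() < rates.phenotype_error:
        return not true_match
    return true_match


# ---------------------------------------------------------------------------
# atomic actions
# ---------------------------------------------------------------------------

@dataclass
class PickOutcome:
    status: str  # moved | failed | died | escaped | not_found
    worm_uid: Optional[str] = None
    src: Optional[str] = None
    dst: Optional[str] = None
    died_after_transfer: bool = False


def pick_worm(src: Plate, predicate: WormPredicate, dst: Plate,
              rates: ActionRates, rng) -> PickOutcome:
    """Attempt to transfer one worm matching ``predicate`` from ``src`` to
    ``dst``.

    Success (the worm moves) requires both the pick-up and the put-down
    Bernoulli draws; on failure the worm stays, escapes, or dies.  The
    post-pick survival draw happens after a successful transfer and marks
    the worm dead on the destination.
    """
    candidates = [w for w in src.worms
                  if _observed_match(w, predicate, rates, rng)]
    if not candidates:
        return PickOutcome("not_found", src=src.barcode, dst=dst.barcode)
    worm = candidates[int(rng.integers(len(candidates)))]
    return attempt_transfer(worm, src, dst, rates, rng)


def attempt_transfer(worm: Individual, src: Plate, dst: Plate,
                     rates: ActionRates, rng) -> PickOutcome:
    """Stochastic transfer of a *specific* worm (the tail of pick_worm)."""
    if rng.random() >= rates.pick_up_success:
        if rng.random() < rates.escape_prob:
            src.worms.remove(worm)
            return PickOutcome("escaped", worm.uid, src.barcode, dst.barcode)
        return PickOutcome("failed", worm.uid, src.barcode, dst.barcode)

    src.worms.remove(worm)
    if rng.random() >= rates.put_down_success:
        if rng.random() < rates.escape_prob:
            return PickOutcome("escaped", worm.uid, src.barcode, dst.barcode)
        src.worms.append(worm)  # dropped back onto the source plate
        return PickOutcome("failed", worm.uid, src.barcode, dst.barcode)

    dst.worms.append(worm)
    died = rng.random() >= rates.post_pick_survival
    if died:
        worm.alive = False
        worm.stage = "dead"
    return PickOutcome("moved", worm.uid, src.barcode, dst.barcode,
                       died_after_transfer=died)


def screen_plate(plate: Plate, predicate: WormPredicate, rates: ActionRates,
                 rng) -> list:
    """Worms on the plate observed to match (phenotype_error flips each
    observation independently).  A contaminated plate screens empty."""
    if plate.contaminated:
        return []
    return [w for w in plate.worms
            if _observed_match(w, predicate, rates, rng)]


# ---------------------------------------------------------------------------
# protocol scripts
# ---------------------------------------------------------------------------

LEVELS = ("low", "mid", "high")

#: Atomic (low-level) action names the executor understands.
LOW_LEVEL_ACTIONS = ("sterilize", "find_worm", "pick_worm", "put_down")


@dataclass
class ProtocolScript:
    """A node in the low/mid/high script hierarchy.

    High-level scripts contain only mid-level children; mid-level only
    low-level; low-level scripts are atomic.
    """

    level: str
    name: str
    args: dict = field(default_factory=dict)
    children: tuple = ()

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown script level {self.level!r}")
        allowed_child = {"high": "mid", "mid": "low", "low": None}[self.level]
        for child in self.children:
            if allowed_child is None:
                raise ValueError("low-level scripts are atomic")
            if child.level != allowed_child:
                raise ValueError(
                    f"{self.level}-level script {self.name!r} may only "
                    f"contain {allowed_child}-level children, got "
                    f"{child.level!r} ({child.name!r})")

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolScript":
        return cls(d["level"], d["name"], dict(d.get("args", {})),
                   tuple(cls.from_dict(c) for c in d.get("children", ())))

    def to_dict(self) -> dict:
        return {"level": self.level, "name": self.name, "args": self.args,
                "children": [c.to_dict() for c in self.children]}

    @classmethod
    def from_yaml(cls, path) -> "ProtocolScript":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def pick_n_worms(src: str, dst: str, n: int, predicate: WormPredicate,
                 retries: int = 3) -> ProtocolScript:
    """Mid-level: pick ``n`` worms matching the predicate from src to dst,
    iterating sterilize/pick low-level actions."""
    children = []
    for _ in range(n):
        children.append(ProtocolScript("low", "sterilize"))
        children.append(ProtocolScript("low", "pick_worm", {
            "src": src, "dst": dst, "predicate": predicate,
            "retries": retries}))
    return ProtocolScript("mid", "PickNWorms",
                          {"src": src, "dst": dst, "n": n,
                           "predicate": predicate, "retries": retries},
                          tuple(children))


def single_worms(src: str, dst_list: Sequence, predicate: WormPredicate,
                 retries: int = 3) -> ProtocolScript:
    """Mid-level: transfer one matching worm onto each destination plate
    (singling founds one clonal line per plate)."""
    children = []
    for dst in dst_list:
        children.append(ProtocolScript("low", "sterilize"))
        children.append(ProtocolScript("low", "pick_worm", {
            "src": src, "dst": dst, "predicate": predicate,
            "retries": retries}))
    return ProtocolScript("mid", "SingleWorms",
                          {"src": src, "dsts": list(dst_list),
                           "predicate": predicate, "retries": retries},
                          tuple(children))


def screen_plates(barcodes: Sequence, predicate: WormPredicate
                  ) -> ProtocolScript:
    children = tuple(ProtocolScript("low", "find_worm",
                                    {"plate": b, "predicate": predicate})
                     for b in barcodes)
    return ProtocolScript("mid", "ScreenPlates",
                          {"plates": list(barcodes), "predicate": predicate},
                          children)


def cross_worms(males_src: str, n_males: int, herms_src: str, n_herms: int,
                dst: str, male_predicate: WormPredicate,
                herm_predicate: WormPredicate,
                retries: int = 3) -> ProtocolScript:
    """High-level: set up a mating by picking males then hermaphrodites
    onto one plate -- two PickNWorms calls."""
    return ProtocolScript("high", "CrossWorms",
                          {"males_src": males_src, "n_males": n_males,
                           "herms_src": herms_src, "n_herms": n_herms,
                           "dst": dst},
                          (pick_n_worms(males_src, dst, n_males,
                                        male_predicate, retries),
                           pick_n_worms(herms_src, dst, n_herms,
                                        herm_predicate, retries)))


# ---------------------------------------------------------------------------
# the bench itself
# ---------------------------------------------------------------------------

class VirtualBench:
    """Plates + database + rates + seeded rng + an append-only run log.

    Every action appends one log entry (a plain dict), so identical seed
    and configuration reproduce the log byte-for-byte.
    """

    def __init__(self, registry: GeneRegistry, rates: ActionRates, rng):
        self.registry = registry
        self.rates = rates
        self.rng = rng
        self.db = PlateDB()
        self.plates: dict = {}
        self.log: list = []
        self.graveyard: list = []  # uids recorded dead
        self.escaped: list = []  # uids lost from the bench
        self._step = 0
        self._barcode_counter = 0

    # -- plates ---------------------------------------------------------
    def new_plate(self, label: str = "", strain: str = "",
                  generation: str = "", parent_barcodes: str = "") -> Plate:
        self._barcode_counter += 1
        barcode = f"P{self._barcode_counter:05d}"
        plate = Plate(barcode, label)
        if (self.rates.contamination_prob_per_plate > 0
                and self.rng.random()
                < self.rates.contamination_prob_per_plate):
            plate.contaminated = True
        self.plates[barcode] = plate
        self.db.register(PlateRecord(barcode, label, strain, generation,
                                     parent_barcodes, self._step))
        self._log("new_plate", plate=barcode, label=label,
                  contaminated=plate.contaminated)
        return plate

    def plate(self, barcode: str) -> Plate:
        try:
            return self.plates[barcode]
        except KeyError:
            raise PlateDBError(f"unknown barcode {barcode!r}") from None

    def seed_plate(self, plate: Plate, worms: Iterable) -> None:
        worms = list(worms)
        plate.worms.extend(worms)
        self._log("seed_plate", plate=plate.barcode, n=len(worms))

    def advance_generation(self, plate: Plate, stage: str = "adult") -> None:
        """Age tick: advance every live worm on the plate to ``stage``."""
        for w in plate.live_worms():
            w.stage = stage
        self._log("advance_generation", plate=plate.barcode, stage=stage)

    # -- actions ----------------------------------------------------------
    def pick(self, src: Plate, predicate: WormPredicate, dst: Plate
             ) -> PickOutcome:
        outcome = pick_worm(src, predicate, dst, self.rates, self.rng)
        if outcome.status == "escaped":
            self.escaped.append(outcome.worm_uid)
        if outcome.died_after_transfer:
            self.graveyard.append(outcome.worm_uid)
        self._log("pick_worm", src=src.barcode, dst=dst.barcode,
                  predicate=predicate.describe(), status=outcome.status,
                  worm=outcome.worm_uid,
                  died_after=outcome.died_after_transfer)
        return outcome

    def transfer(self, src: Plate, worm: Individual, dst: Plate
                 ) -> PickOutcome:
        """Stochastic transfer of a chosen worm (used when a protocol has
        already decided which animal to single)."""
        outcome = attempt_transfer(worm, src, dst, self.rates, self.rng)
        if outcome.status == "escaped":
            self.escaped.append(outcome.worm_uid)
        if outcome.died_after_transfer:
            self.graveyard.append(outcome.worm_uid)
        self._log("transfer", src=src.barcode, dst=dst.barcode,
                  status=outcome.status, worm=outcome.worm_uid,
                  died_after=outcome.died_after_transfer)
        return outcome

    def pick_retry(self, src: Plate, predicate: WormPredicate, dst: Plate,
                   retries: int = 3) -> PickOutcome:
        """Up to ``retries`` attempts; stops early on move/not-found."""
        outcome = PickOutcome("failed")
        for _ in range(max(1, retries)):
            outcome = self.pick(src, predicate, dst)
            if outcome.status in ("moved", "not_found"):
                break
        return outcome

    def screen(self, plate: Plate, predicate: WormPredicate) -> list:
        found = screen_plate(plate, predicate, self.rates, self.rng)
        self._log("screen_plate", plate=plate.barcode,
                  predicate=predicate.describe(), n_found=len(found),
                  contaminated=plate.contaminated)
        return found

    # -- script execution -------------------------------------------------
    def execute(self, script: ProtocolScript) -> list:
        """Depth-first execution; returns the slice of the run log this
        call appended.  Terminates for any finite script."""
        start = len(self.log)
        self._execute_node(script)
        return self.log[start:]

    def _execute_node(self, script: ProtocolScript) -> None:
        self._step += 1
        self._log("script_enter", level=script.level, name=script.name)
        if script.level == "low":
            self._run_low(script)
        else:
            moved_target = None
            if script.name in ("PickNWorms", "SingleWorms"):
                moved_target = (script.args.get("n")
                                or len(script.args.get("dsts", ())))
            moved_before = self._count_moves()
            for child in script.children:
                self._execute_node(child)
            if moved_target is not None:
                moved = self._count_moves() - moved_before
                if moved < moved_target:
                    self._log("protocol_failure", script=script.name,
                              wanted=moved_target, achieved=moved)
        self._log("script_exit", level=script.level, name=script.name)

    def _count_moves(self) -> int:
        return sum(1 for e in self.log
                   if e["action"] == "pick_worm" and e["status"] == "moved")

    def _run_low(self, script: ProtocolScript) -> None:
        name = script.name
        if name not in LOW_LEVEL_ACTIONS:
            raise ValueError(f"unknown low-level action {name!r}")
        if name in ("sterilize", "put_down"):
            self._log(name)
        elif name == "find_worm":
            plate = self.plate(script.args["plate"])
            self.screen(plate, script.args["predicate"])
        elif name == "pick_worm":
            src = self.plate(script.args["src"])
            dst = self.plate(script.args["dst"])
            self.pick_retry(src, script.args["predicate"], dst,
                            script.args.get("retries", 3))

    # -- bookkeeping -------------------------------------------------------
    def _log(self, action: str, **fields) -> None:
        entry = {"step": self._step, "action": action}
        entry.update(fields)
        self.log.append(entry)

    def log_jsonl(self) -> str:
        return "\n".join(json.dumps(e, sort_keys=True, default=str)
                         for e in self.log)

    def census(self) -> dict:
        """Worm conservation accounting: every worm created on the bench is
        on exactly one plate or recorded dead/escaped."""
        on_plates = [w.uid for p in self.plates.values() for w in p.worms]
        return {
            "on_plates": len(on_plates),
            "dead_on_plates": sum(1 for p in self.plates.values()
                                  for w in p.worms if not w.alive),
            "escaped": len(self.escaped),
        }
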