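"""Virtual bench: plates, stochastic actions, scripts, and the database."""

import math

import numpy as np
import pytest

from wormbench import (
    ActionRates,
    Plate,
    PlateDB,
    PlateDBError,
    PlateRecord,
    ProtocolScript,
    Sex,
    VirtualBench,
    WormPredicate,
    build_genotype,
    cross_worms,
    make_individual,
    pick_worm,
    pick_n_worms,
    screen_plate,
)
from wormbench.genetics import GREEN
from wormbench.strains import DEFAULT_STRAINS, make_strain_population


def _worm(registry, uid="w0", **kwargs):
    return make_individual(uid, build_genotype(registry, **kwargs), registry)


def _plate(registry, n=1, barcode="src", **kwargs):
    return Plate(barcode, worms=[_worm(registry, f"w{i}", **kwargs)
                                 for i in range(n)])


class TestActionRates:
    def test_probability_validation(self):
        with pytest.raises(ValueError):
            ActionRates(pick_up_success=1.2)

    def test_presets(self):
        assert ActionRates.perfect().pick_up_success == 1.0
        assert ActionRates.manual_baseline(
        ).contamination_prob_per_plate == 0.034


class TestPickWorm:
    def test_perfect_rates_move_deterministically(self, registry, rng):
        src = _plate(registry)
        dst = Plate("dst")
        out = pick_worm(src, WormPredicate(), dst, ActionRates.perfect(),
                        rng)
        assert out.status == "moved"
        assert not src.worms and len(dst.worms) == 1

    def test_no_match_is_not_found(self, registry, rng):
        src = _plate(registry)  # N2: not Green
        out = pick_worm(src, WormPredicate(tags_all=frozenset({GREEN})),
                        Plate("dst"), ActionRates.perfect(), rng)
        assert out.status == "not_found"
        assert len(src.worms) == 1

    def test_success_rate_is_product_of_stage_rates(self, registry, rng):
        """Transfer succeeds iff both the pick-up and put-down Bernoulli
        draws do: 0.9 x 0.9 at defaults."""
        rates = ActionRates(escape_prob=0.0, post_pick_survival=1.0)
        n, moved = 10000, 0
        worm = _worm(registry)
        for _ in range(n):
            src = Plate("src", worms=[worm])
            out = pick_worm(src, WormPredicate(), Plate("dst"), rates, rng)
            moved += out.status == "moved"
        p = 0.9 * 0.9
        assert abs(moved / n - p) < 3 * math.sqrt(p * (1 - p) / n)


class TestScreenPlate:
    def test_exact_matches_without_error(self, registry, rng):
        plate = _plate(registry, n=5, hom=("vsIs28",))
        plate.worms += _plate(registry, n=3).worms
        found = screen_plate(plate, WormPredicate(tags_all=frozenset(
            {GREEN})), ActionRates.perfect(), rng)
        assert len(found) == 5

    def test_misclassification_rate(self, registry, rng):
        plate = _plate(registry, n=100, hom=("vsIs28",))
        rates = ActionRates(phenotype_error=0.1)
        counts = [len(screen_plate(plate, WormPredicate(
            tags_all=frozenset({GREEN})), rates, rng)) for _ in range(200)]
        mean = sum(counts) / len(counts)
        assert abs(mean - 90) < 3 * math.sqrt(100 * 0.1 * 0.9 / 200) + 1

    def test_empty_plate(self, registry, rng):
        assert screen_plate(Plate("p"), WormPredicate(),
                            ActionRates.perfect(), rng) == []

    def test_contaminated_plate_screens_empty(self, registry, rng):
        plate = _plate(registry, n=4)
        plate.contaminated = True
        assert screen_plate(plate, WormPredicate(), ActionRates.perfect(),
                            rng) == []


class TestPlateDB:
    def test_register_lookup_round_trip(self):
        db = PlateDB()
        rec = PlateRecord("B1", "label", "N2", "P0", "", 0)
        db.register(rec)
        assert db.lookup("B1") == rec

    def test_duplicate_and_missing_barcodes(self):
        db = PlateDB()
        db.register(PlateRecord("B1"))
        with pytest.raises(PlateDBError):
            db.register(PlateRecord("B1"))
        with pytest.raises(PlateDBError):
            db.lookup("B2")

    def test_csv_round_trip(self, tmp_path):
        db = PlateDB()
        db.register(PlateRecord("B1", "F1 isolate", "LX831", "F1", "B0", 3))
        db.register(PlateRecord("B2", "", "", "", "", 0))
        path = tmp_path / "plates.csv"
        db.to_csv(path)
        assert PlateDB.from_csv(path) == db


class TestScriptHierarchy:
    def test_levels_enforced(self):
        low = ProtocolScript("low", "sterilize")
        mid = ProtocolScript("mid", "PickNWorms", children=(low,))
        ProtocolScript("high", "CrossWorms", children=(mid,))  # ok
        with pytest.raises(ValueError):
            ProtocolScript("high", "bad", children=(low,))
        with pytest.raises(ValueError):
            ProtocolScript("low", "bad", children=(low,))

    def test_cross_worms_expands_to_two_pick_n_worms(self):
        script = cross_worms("males", 6, "herms", 2, "dst",
                             WormPredicate(sex=Sex.MALE),
                             WormPredicate(sex=Sex.HERMAPHRODITE))
        assert script.level == "high"
        assert [c.name for c in script.children] == ["PickNWorms",
                                                     "PickNWorms"]
        assert script.children[0].args["n"] == 6
        assert script.children[1].args["n"] == 2

    def test_dict_round_trip(self):
        script = pick_n_worms("a", "b", 2, WormPredicate())
        clone = ProtocolScript.from_dict(script.to_dict())
        assert clone.name == script.name
        assert len(clone.children) == len(script.children)


class TestExecute:
    def _bench(self, registry, rates, seed=7):
        return VirtualBench(registry, rates, np.random.default_rng(seed))

    def test_empty_script_logs_only_enter_exit(self, registry):
        bench = self._bench(registry, ActionRates.perfect())
        log = bench.execute(ProtocolScript("high", "noop"))
        assert [e["action"] for e in log] == ["script_enter", "script_exit"]

    def test_pick_n_worms_moves_exactly_n_at_perfect_rates(self, registry):
        bench = self._bench(registry, ActionRates.perfect())
        src = bench.new_plate("stock")
        dst = bench.new_plate("mating")
        bench.seed_plate(src, make_strain_population(
            DEFAULT_STRAINS["N2"], 40, registry, bench.rng,
            male_fraction=0.6))
        bench.execute(pick_n_worms(src.barcode, dst.barcode, 17,
                                   WormPredicate(sex=Sex.MALE)))
        assert len(dst.worms) == 17
        assert all(w.sex is Sex.MALE for w in dst.worms)

    def test_unknown_barcode_raises(self, registry):
        bench = self._bench(registry, ActionRates.perfect())
        script = pick_n_worms("ghost", "ghost2", 1, WormPredicate())
        with pytest.raises(PlateDBError):
            bench.execute(script)

    def test_unsatisfiable_step_records_failure(self, registry):
        bench = self._bench(registry, ActionRates.perfect())
        src = bench.new_plate("empty")
        dst = bench.new_plate("dst")
        log = bench.execute(pick_n_worms(src.barcode, dst.barcode, 2,
                                         WormPredicate()))
        assert any(e["action"] == "protocol_failure" for e in log)

    def test_identical_seed_identical_log(self, registry):
        def run(seed):
            bench = self._bench(registry, ActionRates(), seed=seed)
            src = bench.new_plate("stock")
            dst = bench.new_plate("dst")
            bench.seed_plate(src, make_strain_population(
                DEFAULT_STRAINS["LX831"], 30, registry, bench.rng))
            bench.execute(pick_n_worms(src.barcode, dst.barcode, 5,
                                       WormPredicate(tags_all=frozenset(
                                           {GREEN}))))
            return bench.log_jsonl()

        assert run(3) == run(3)
        assert run(3) != run(4)

    def test_worm_conservation(self, registry):
        """Every worm is on exactly one plate or recorded escaped."""
        bench = self._bench(registry, ActionRates(escape_prob=0.2,
                                                  post_pick_survival=0.8))
        src = bench.new_plate("stock")
        dst = bench.new_plate("dst")
        n0 = 50
        bench.seed_plate(src, make_strain_population(
            DEFAULT_STRAINS["N2"], n0, registry, bench.rng))
        for _ in range(100):
            bench.pick(src, WormPredicate(), dst)
        census = bench.census()
        assert census["on_plates"] + census["escaped"] == n0
        uids = [w.uid for p in bench.plates.values() for w in p.worms]
        assert len(uids) == len(set(uids))
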