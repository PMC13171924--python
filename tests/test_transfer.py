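import numpy as np
import pytest

from tubertrace import (
    CountTable,
    GroupKey,
    PresenceMap,
    SampleMetadata,
    classify_transfer,
    flow_proportions,
    presence_sets,
    shared_unique,
    validate_dataset,
)
from tubertrace.transfer import round_half_away


def _key(gen, comp="flesh", cv="N", field=None):
    return GroupKey(generation=gen, compartment=comp, cultivar=cv, field=field)


def _pmap(**sets_by_gen):
    return PresenceMap({_key(g): frozenset(s) for g, s in sets_by_gen.items()})


class TestPresenceSets:
    def _dataset(self, counts):
        counts = np.asarray(counts)
        table = CountTable(
            [f"t{i}" for i in range(counts.shape[0])],
            [f"s{j}" for j in range(counts.shape[1])],
            counts,
        )
        meta = [
            SampleMetadata(f"s{j}", "seed", "flesh", "N")
            for j in range(counts.shape[1])
        ]
        return validate_dataset(table, meta)

    def test_single_read_counts_as_present(self):
        ds = self._dataset([[0, 0, 1]])
        pm = presence_sets(ds, ["generation"])
        assert pm.get(GroupKey(generation="seed")) == {"t0"}

    def test_prevalence_threshold_excludes(self):
        ds = self._dataset([[0, 0, 1]])
        pm = presence_sets(ds, ["generation"], min_prevalence=2)
        assert pm.get(GroupKey(generation="seed")) == frozenset()

    def test_monotone_in_thresholds(self, rng):
        counts = rng.integers(0, 3, size=(30, 6))
        ds = self._dataset(counts)
        loose = presence_sets(ds, ["generation"], min_prevalence=1)
        strict = presence_sets(ds, ["generation"], min_prevalence=2)
        key = GroupKey(generation="seed")
        assert strict.get(key) <= loose.get(key)


class TestClassifyTransfer:
    def test_first_transition_modes_agree(self):
        pm = _pmap(seed={"a", "b", "c"}, daughter={"b", "c", "d", "e"})
        for mode in ("seed_baseline", "chain"):
            cls = classify_transfer(pm, ("flesh", "N", None), mode=mode,
                                    generations=("seed", "daughter"))
            gt = cls.per_generation["daughter"]
            assert gt.vertical_set == {"b", "c"}
            assert gt.horizontal_set == {"d", "e"}
            assert gt.vertical_pct == pytest.approx(50.0)
            assert gt.horizontal_pct == pytest.approx(50.0)

    def test_hand_checked_three_generation_sets(self):
        # A0={a,b,c}, A1={b,c,d}, A2={c,d,e}: chain vertical at g2 = {c};
        # seed-baseline vertical at g2 = {c}; horizontal = {d,e} (66.67%)
        pm = _pmap(seed={"a", "b", "c"}, daughter={"b", "c", "d"},
                   granddaughter={"c", "d", "e"})
        for mode in ("seed_baseline", "chain"):
            cls = classify_transfer(pm, ("flesh", "N", None), mode=mode)
            gt = cls.per_generation["granddaughter"]
            assert gt.vertical_set == {"c"}
            assert gt.horizontal_set == {"d", "e"}
            assert gt.vertical_pct == pytest.approx(100 / 3)
            assert gt.horizontal_pct == pytest.approx(200 / 3)

    def test_identity_case_full_vertical(self):
        pm = _pmap(seed={"a", "b"}, daughter={"a", "b"})
        cls = classify_transfer(pm, ("flesh", "N", None),
                                generations=("seed", "daughter"))
        gt = cls.per_generation["daughter"]
        assert gt.vertical_pct == 100.0 and gt.horizontal_pct == 0.0

    def test_partition_property(self, rng):
        universe = [f"t{i}" for i in range(40)]
        sets = {
            g: set(rng.choice(universe, size=rng.integers(5, 30), replace=False))
            for g in ("seed", "daughter", "granddaughter")
        }
        sets["seed"].add("t0")
        pm = _pmap(**sets)
        for mode in ("seed_baseline", "chain"):
            cls = classify_transfer(pm, ("flesh", "N", None), mode=mode)
            for gt in cls.per_generation.values():
                assert gt.vertical_set | gt.horizontal_set == gt.present
                assert not gt.vertical_set & gt.horizontal_set

    def test_chain_vertical_sets_non_increasing(self):
        pm = _pmap(seed=set("abcdef"), daughter=set("abcz"),
                   granddaughter=set("abxyz"))
        cls = classify_transfer(pm, ("flesh", "N", None), mode="chain")
        v1 = cls.per_generation["daughter"].vertical_set
        v2 = cls.per_generation["granddaughter"].vertical_set
        assert v2 <= v1 <= cls.seed_set

    def test_empty_seed_errors(self):
        pm = _pmap(seed=set(), daughter={"a"})
        with pytest.raises(ValueError, match="seed"):
            classify_transfer(pm, ("flesh", "N", None),
                              generations=("seed", "daughter"))


class TestFlowProportions:
    @pytest.mark.parametrize(
        "entering,retained,pct,rounded",
        [(13, 10, 76.92307692307692, 77), (34, 20, 58.82352941176471, 59),
         (12, 12, 100.0, 100), (40, 32, 80.0, 80)],
    )
    def test_stage_retention_arithmetic(self, entering, retained, pct, rounded):
        first = {f"t{i}" for i in range(entering)}
        second = {f"t{i}" for i in range(retained)}
        pm = _pmap(daughter=first, granddaughter=second)
        fr = flow_proportions(pm, [_key("daughter"), _key("granddaughter")])
        stage = fr.stages[1]
        assert len(stage.entering) == entering and len(stage.retained) == retained
        assert stage.pct_exact == pytest.approx(pct)
        assert stage.pct_rounded == rounded

    def test_retained_chain_is_nested(self):
        pm = _pmap(seed=set("abcdef"), daughter=set("abcdx"),
                   granddaughter=set("abq"))
        fr = flow_proportions(
            pm, [_key("seed"), _key("daughter"), _key("granddaughter")]
        )
        assert fr.stages[2].entering == fr.stages[1].retained
        assert fr.stages[2].retained <= fr.stages[1].retained

    def test_empty_entering_na(self):
        pm = _pmap(seed=set("ab"), daughter=set("xy"), granddaughter=set("a"))
        with pytest.warns(UserWarning, match="empty entering"):
            fr = flow_proportions(
                pm, [_key("seed"), _key("daughter"), _key("granddaughter")]
            )
        assert np.isnan(fr.stages[2].pct_exact)

    def test_rounding_half_away(self):
        assert round_half_away(76.5) == 77
        assert round_half_away(58.5) == 59
        assert round_half_away(58.49) == 58


class TestSharedUnique:
    def test_disjoint_sets(self):
        pm = _pmap(seed={"a", "b"}, daughter={"c", "d", "e"})
        k1, k2 = _key("seed"), _key("daughter")
        cells = shared_unique(pm, [k1, k2])
        assert cells[frozenset([k1])] == 2
        assert cells[frozenset([k2])] == 3
        assert frozenset([k1, k2]) not in cells

    def test_identical_sets_single_cell(self):
        pm = _pmap(seed={"a", "b"}, daughter={"a", "b"})
        k1, k2 = _key("seed"), _key("daughter")
        cells = shared_unique(pm, [k1, k2])
        assert cells == {frozenset([k1, k2]): 2}

    def test_cells_sum_to_union(self, rng):
        universe = [f"t{i}" for i in range(30)]
        sets = {
            g: set(rng.choice(universe, size=rng.integers(1, 25), replace=False))
            for g in ("seed", "daughter", "granddaughter")
        }
        pm = _pmap(**sets)
        keys = [_key(g) for g in sets]
        cells = shared_unique(pm, keys)
        union = set().union(*sets.values())
        assert sum(cells.values()) == len(union)


class TestAgreementWithTruth:
    def test_labels_match_simulation_truth_exactly(self, small_sim):
        """With the detection guarantee on, classification reproduces the
        generator's vertical/horizontal labels for every detected taxon."""
        ds, truth = small_sim
        presence = presence_sets(ds)
        origin = dict(zip(truth.taxa["taxon_id"], truth.taxa["origin"]))
        checked = 0
        for cv in ("Nadine", "Royal_Blue"):
            for comp in ("flesh", "peel"):
                for fld in ("Brunswick", "Murdoch"):
                    cls = classify_transfer(presence, (comp, cv, fld), mode="chain")
                    for gt in cls.per_generation.values():
                        for t in gt.vertical_set:
                            assert origin[t] == "vertical_core"
                            checked += 1
                        for t in gt.horizontal_set:
                            assert origin[t] == "horizontal"
                            checked += 1
        assert checked > 100
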