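import itertools

import numpy as np
import pandas as pd
import pytest

from acetyltempo import (
    ContrastOutcome,
    TemporalClass,
    aggregate_to_proteins,
    classify_directions,
    classify_site,
    classify_table,
    contrast_all,
    ordered_matrix,
    shared_unique,
    transform,
)
from acetyltempo.synthetic_data import SimulationDesign, simulate_dataset

# Hand-enumerated truth table over all 27 (dir6, dir24, dir24v6) triples,
# written from the class definitions (not from the implementation):
# the 24h-vs-6h direction matters only when both vs-untreated calls are none.
HAND_TABLE = {
    ("up", "up"): "PERSISTENT_UP",
    ("down", "down"): "PERSISTENT_DOWN",
    ("down", "up"): "EARLY_DOWN_LATE_UP",
    ("up", "down"): "EARLY_UP_LATE_DOWN",
    ("none", "up"): "LATE_UP",
    ("none", "down"): "LATE_DOWN",
    ("up", "none"): "EARLY_TRANSIENT_UP",
    ("down", "none"): "EARLY_TRANSIENT_DOWN",
    ("none", "none"): None,  # resolved by the 24h-vs-6h direction below
}


def expected_class(d6, d24, d24v6):
    base = HAND_TABLE[(d6, d24)]
    if base is not None:
        return base
    if d24v6 == "up":
        return "PSEUDOSILENT_UP"
    if d24v6 == "down":
        return "PSEUDOSILENT_DOWN"
    return "UNCHANGED"


def _outcome(site, label, direction):
    sig = direction != "none"
    lfc = {"up": 1.0, "down": -1.0, "none": 0.1}[direction]
    return ContrastOutcome(site, label, lfc, 2.0 * lfc, 0.01 if sig else 0.5,
                           sig, direction)


class TestClassifier:
    def test_all_27_combinations_match_hand_enumeration(self):
        for d6, d24, d24v6 in itertools.product(["up", "down", "none"],
                                                repeat=3):
            got = classify_directions(d6, d24, d24v6)
            assert got.name == expected_class(d6, d24, d24v6), (d6, d24, d24v6)

    def test_exactly_one_class_per_combination(self):
        seen = [classify_directions(*c)
                for c in itertools.product(["up", "down", "none"], repeat=3)]
        assert all(isinstance(c, TemporalClass) for c in seen)
        # every class except the artificial ones appears
        assert {c.name for c in seen} == {c.name for c in TemporalClass}

    def test_classify_site_checks_site_identity(self):
        a = _outcome("P_K1", "6hAmAc_vs_UnT", "up")
        b = _outcome("P_K2", "24hAmAc_vs_UnT", "up")
        c = _outcome("P_K1", "24hAmAc_vs_6hAmAc", "none")
        with pytest.raises(ValueError):
            classify_site(a, b, c)
        assert classify_site(
            a, _outcome("P_K1", "24hAmAc_vs_UnT", "up"), c
        ) is TemporalClass.PERSISTENT_UP

    def test_24v6_ignored_when_vs_unt_significant(self):
        for d24v6 in ("up", "down", "none"):
            assert classify_directions("up", "up", d24v6) is \
                TemporalClass.PERSISTENT_UP

    def test_condition_flip_maps_late_to_early_transient(self):
        # swapping the 6h and 24h labels exchanges LATE_* and
        # EARLY_TRANSIENT_* while fixing PERSISTENT_* and UNCHANGED
        for d6, d24, d246 in itertools.product(["up", "down", "none"],
                                               repeat=3):
            flip = {"up": "down", "down": "up", "none": "none"}
            orig = classify_directions(d6, d24, d246)
            swapped = classify_directions(d24, d6, flip[d246])
            mapping = {
                "LATE_UP": "EARLY_TRANSIENT_UP",
                "LATE_DOWN": "EARLY_TRANSIENT_DOWN",
                "EARLY_TRANSIENT_UP": "LATE_UP",
                "EARLY_TRANSIENT_DOWN": "LATE_DOWN",
                "EARLY_DOWN_LATE_UP": "EARLY_UP_LATE_DOWN",
                "EARLY_UP_LATE_DOWN": "EARLY_DOWN_LATE_UP",
                "PSEUDOSILENT_UP": "PSEUDOSILENT_DOWN",
                "PSEUDOSILENT_DOWN": "PSEUDOSILENT_UP",
            }
            assert swapped.name == mapping.get(orig.name, orig.name)


def _site_classes(dataset):
    table = dataset[0]
    logt = transform(table)
    cons = contrast_all(
        logt, [("UnT", "6hAmAc"), ("UnT", "24hAmAc"), ("6hAmAc", "24hAmAc")]
    )
    return classify_table(cons, "6hAmAc_vs_UnT", "24hAmAc_vs_UnT",
                          "24hAmAc_vs_6hAmAc")


class TestAggregation:
    def test_single_site_proteins_identity(self):
        # every protein has exactly one site -> DAP set == projected DAS set
        d = SimulationDesign(n_proteins=120, sites_per_protein=(1, 1), seed=21)
        ds = simulate_dataset(d)
        sc = _site_classes(ds)
        calls = aggregate_to_proteins(sc)
        das_up = {s.split("_K")[0] for s in sc.index
                  if sc.loc[s, "direction_24h"] == "up"}
        dap_up = set(calls.index[calls["dap_24h"] == "up"])
        assert das_up == dap_up

    def test_mixed_and_up_rules(self, small_dataset):
        sc = _site_classes(small_dataset)
        calls = aggregate_to_proteins(sc)
        sc = sc.assign(protein=[s.split("_K")[0] for s in sc.index])
        for pid, grp in sc.groupby("protein"):
            ups = (grp["direction_24h"] == "up").sum()
            downs = (grp["direction_24h"] == "down").sum()
            want = ("mixed" if ups and downs else
                    "up" if ups else "down" if downs else "none")
            assert calls.loc[pid, "dap_24h"] == want

    def test_protein_class_from_most_significant_24h_site(self,
                                                          small_dataset):
        sc = _site_classes(small_dataset)
        calls = aggregate_to_proteins(sc)
        sc = sc.assign(protein=[s.split("_K")[0] for s in sc.index],
                       position=[int(s.split("_K")[1]) for s in sc.index])
        for pid, grp in sc.groupby("protein"):
            best = grp.sort_values(["p_value_24h", "position"]).iloc[0]
            assert calls.loc[pid, "temporal_class"] == best["temporal_class"]

    def test_orphan_site_rejected(self, small_dataset):
        sc = _site_classes(small_dataset)
        mapping = pd.Series({s: s.split("_K")[0] for s in sc.index[:-1]})
        with pytest.raises(ValueError, match="unknown protein"):
            aggregate_to_proteins(sc, site_proteins=mapping)


class TestSetLogic:
    def test_equal_sets(self):
        s, a, b = shared_unique({"x", "y"}, {"x", "y"})
        assert s == {"x", "y"} and not a and not b

    def test_disjoint(self):
        s, a, b = shared_unique({"x"}, {"y"})
        assert not s and a == {"x"} and b == {"y"}

    def test_union_identity_random(self):
        rng = np.random.default_rng(42)
        universe = [f"g{i}" for i in range(60)]
        for _ in range(1000):
            a = set(rng.choice(universe, rng.integers(0, 30), replace=False))
            b = set(rng.choice(universe, rng.integers(0, 30), replace=False))
            shared, only_a, only_b = shared_unique(a, b)
            assert len(shared) + len(only_a) + len(only_b) == len(a | b)
            assert len(a) + len(b) - len(a & b) == len(a | b)


class TestOrderedMatrix:
    def test_rows_grouped_by_class_then_p(self, small_dataset):
        sc = _site_classes(small_dataset)
        logt = transform(small_dataset[0])
        mat = ordered_matrix(sc, logt.data)
        classes = sc.loc[mat.index, "temporal_class"]
        ranks = [list(TemporalClass.__members__).index(c) for c in classes]
        assert ranks == sorted(ranks)
        assert set(mat.index) == set(sc.index)
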