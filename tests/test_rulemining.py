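import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_frequent_itemsets, fisher_enumeration_oracle
from dmetpipe.io_dmet import NOCALL, GenotypeTable, PhenotypeAssignment
from dmetpipe.rulemining import (
    Transaction,
    _build_tree,
    build_transactions,
    class_item,
    fisher_filter,
    fp_growth,
    generate_rules,
    genotype_item,
    mine_class_rules,
    split_and_rank_rules,
)


def _pheno(n_a, n_b):
    assignment = {f"A{i}": "RESP" for i in range(n_a)}
    assignment.update({f"B{i}": "NoRESP" for i in range(n_b)})
    return PhenotypeAssignment(("RESP", "NoRESP"), assignment)


def _random_table(rng, pheno, n_probes=25):
    samples = list(pheno.assignment)
    calls = rng.choice(["A/A", "A/G", "G/G", NOCALL],
                       size=(n_probes, len(samples)), p=[0.4, 0.3, 0.2, 0.1])
    return GenotypeTable(
        pd.DataFrame(calls, index=[f"P{i:02d}" for i in range(n_probes)], columns=samples)
    )


class TestFisherFilter:
    def test_threshold_one_keeps_everything(self, rng):
        pheno = _pheno(6, 6)
        t = _random_table(rng, pheno)
        assert fisher_filter(t, pheno, 1.0).probe_ids == t.probe_ids

    def test_perfect_separator_survives_strict_threshold(self):
        pheno = _pheno(6, 6)
        samples = list(pheno.assignment)
        t = GenotypeTable(pd.DataFrame(
            {"SEP": ["C/T"] * 6 + ["C/C"] * 6}, index=samples).T)
        assert fisher_filter(t, pheno, 0.01).probe_ids == ["SEP"]

    def test_retained_set_matches_per_row_oracle(self, rng):
        pheno = _pheno(8, 8)
        t = _random_table(rng, pheno, n_probes=40)
        threshold = 0.3
        kept = fisher_filter(t, pheno, threshold).probe_ids

        expected = []
        for probe in t.probe_ids:
            row = t.calls.loc[probe]
            best = 1.0
            for cat in sorted(set(row) - {NOCALL}):
                a = sum(1 for s in pheno.samples_in("RESP") if row[s] == cat)
                b = sum(1 for s in pheno.samples_in("RESP") if row[s] not in (cat, NOCALL))
                c = sum(1 for s in pheno.samples_in("NoRESP") if row[s] == cat)
                d = sum(1 for s in pheno.samples_in("NoRESP") if row[s] not in (cat, NOCALL))
                best = min(best, fisher_enumeration_oracle(a, b, c, d))
            if best <= threshold:
                expected.append(probe)
        assert kept == expected

    def test_threshold_domain(self, rng):
        pheno = _pheno(3, 3)
        t = _random_table(rng, pheno, n_probes=3)
        for bad in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                fisher_filter(t, pheno, bad)


class TestTransactions:
    def test_items_per_sample(self):
        pheno = _pheno(1, 1)
        t = GenotypeTable(pd.DataFrame(
            {"P1": ["A/A", "A/G"], "P2": [NOCALL, "A/A"], "P3": ["G/G", NOCALL],
             "P4": [NOCALL, NOCALL], "P5": ["A/A", "A/A"]},
            index=["A0", "B0"]).T)
        tx = build_transactions(t, pheno)
        by_id = {x.sample_id: x for x in tx}
        # A0: 3 of 5 probes called -> 3 genotype items + 1 class item
        assert len(by_id["A0"].items) == 4
        assert class_item("RESP") in by_id["A0"].items

    def test_unassigned_sample_has_no_transaction(self):
        pheno = _pheno(1, 1)
        t = GenotypeTable(pd.DataFrame(
            {"P1": ["A/A", "A/G", "G/G"]}, index=["A0", "B0", "X"]).T)
        tx = build_transactions(t, pheno)
        assert {x.sample_id for x in tx} == {"A0", "B0"}

    def test_item_occurrences_equal_called_cells(self, rng):
        pheno = _pheno(5, 5)
        t = _random_table(rng, pheno, n_probes=10)
        tx = build_transactions(t, pheno)
        genotype_items = sum(
            sum(1 for it in x.items if it[0] == "g") for x in tx
        )
        called = (t.calls != NOCALL).to_numpy().sum()
        assert genotype_items == called


class TestFPGrowth:
    def test_hand_enumerated_example(self):
        # {AB, AB, AC}: {A}:3/3, {B}:2/3, {A,B}:2/3; C alone is 1/3 < 2/3
        tx = [{"A", "B"}, {"A", "B"}, {"A", "C"}]
        out = fp_growth(tx, 2 / 3)
        assert out == {
            frozenset({"A"}): 1.0,
            frozenset({"B"}): pytest.approx(2 / 3),
            frozenset({"A", "B"}): pytest.approx(2 / 3),
        }

    def test_min_support_one_means_every_transaction(self):
        tx = [{"A", "B"}, {"A", "B", "C"}, {"A", "B"}]
        out = fp_growth(tx, 1.0)
        assert set(out) == {frozenset({"A"}), frozenset({"B"}), frozenset({"A", "B"})}

    def test_empty_transactions(self):
        assert fp_growth([], 0.5) == {}

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        items = [f"i{k}" for k in range(8)]
        tx = [
            set(rng.choice(items, size=rng.integers(1, 7), replace=False))
            for _ in range(50)
        ]
        min_support = float(rng.choice([0.1, 0.2, 0.3, 0.5]))
        mined = fp_growth(tx, min_support)
        oracle = brute_force_frequent_itemsets(tx, min_support)
        assert set(mined) == set(oracle)
        for k in mined:
            assert mined[k] == pytest.approx(oracle[k])

    def test_anti_monotonicity(self, rng):
        items = [f"i{k}" for k in range(10)]
        tx = [set(rng.choice(items, size=rng.integers(1, 8), replace=False))
              for _ in range(60)]
        mined = fp_growth(tx, 0.15)
        for itemset in mined:
            for it in itemset:
                sub = itemset - {it}
                if sub:
                    assert sub in mined
                    assert mined[sub] >= mined[itemset] - 1e-12

    def test_independent_of_transaction_order(self, rng):
        items = [f"i{k}" for k in range(9)]
        tx = [set(rng.choice(items, size=rng.integers(1, 7), replace=False))
              for _ in range(40)]
        a = fp_growth(tx, 0.2)
        b = fp_growth(list(reversed(tx)), 0.2)
        assert a == b

    def test_fp_tree_chain_counts_equal_scan_supports(self, rng):
        items = [f"i{k}" for k in range(7)]
        tx = [frozenset(rng.choice(items, size=rng.integers(1, 6), replace=False))
              for _ in range(30)]
        tree = _build_tree([(t, 1) for t in tx], min_count=1)
        for it in items:
            scan = sum(1 for t in tx if it in t)
            if scan:
                assert tree.item_support(it) == scan


class TestRules:
    def test_confidence_ratio(self):
        g1 = genotype_item("P1", "A/A")
        frequent = {
            frozenset({g1}): 0.5,
            frozenset({g1, class_item("RESP")}): 0.4,
            frozenset({class_item("RESP")}): 0.6,
        }
        rules = generate_rules(frequent, 0.5, ("RESP", "NoRESP"))
        assert len(rules) == 1
        r = rules[0]
        assert r.consequent == "RESP"
        assert r.confidence == pytest.approx(0.8)
        assert r.support == pytest.approx(0.4)
        assert r.antecedent_support == pytest.approx(0.5)

    def test_itemsets_without_class_item_yield_no_rule(self):
        g1, g2 = genotype_item("P1", "A/A"), genotype_item("P2", "A/G")
        frequent = {frozenset({g1}): 0.5, frozenset({g1, g2}): 0.3, frozenset({g2}): 0.4}
        assert generate_rules(frequent, 0.1, ("RESP", "NoRESP")) == []

    def test_min_confidence_cutoff(self):
        g1 = genotype_item("P1", "A/A")
        frequent = {
            frozenset({g1}): 0.5,
            frozenset({g1, class_item("RESP")}): 0.3,
        }
        assert generate_rules(frequent, 0.7, ("RESP", "NoRESP")) == []
        assert len(generate_rules(frequent, 0.6, ("RESP", "NoRESP"))) == 1

    def test_split_and_rank(self):
        g = [genotype_item(f"P{i}", "A/A") for i in range(4)]
        from dmetpipe.rulemining import AssociationRule

        rules = [
            AssociationRule(frozenset({g[0]}), "RESP", 0.4, 0.9, 0.45),
            AssociationRule(frozenset({g[1]}), "NoRESP", 0.3, 0.95, 0.32),
            AssociationRule(frozenset({g[2]}), "RESP", 0.5, 0.9, 0.55),
            AssociationRule(frozenset({g[3]}), "RESP", 0.2, 0.7, 0.28),
        ]
        ranked = split_and_rank_rules(rules)
        assert [len(ranked["RESP"]), len(ranked["NoRESP"])] == [3, 1]
        resp = ranked["RESP"]
        # confidence desc, ties by support desc
        assert [r.confidence for r in resp] == [0.9, 0.9, 0.7]
        assert resp[0].support == 0.5
        # concatenation is a permutation of the input
        assert sorted(map(id, resp + ranked["NoRESP"])) == sorted(map(id, rules))

    def test_planted_rule_recovered_with_stated_confidence(self):
        from dmetpipe.synthetic_data import PlantedRule, SimulationSpec, simulate_dataset

        spec = SimulationSpec(
            n_samples=500,
            n_probes=12,
            maf_range=(0.3, 0.4),
            nocall_rate=0.0,
            planted_rules=[
                PlantedRule(
                    antecedent=[(0, "A/G"), (1, "A/G")],
                    target_class="RESP",
                    probability=0.9,
                )
            ],
            seed=11,
        )
        table, pheno, _, truth = simulate_dataset(spec)
        ranked = mine_class_rules(
            table, pheno, fisher_threshold=0.05, min_support=0.05, min_confidence=0.5
        )
        want = frozenset(
            {genotype_item("AM_10000", "A/G"), genotype_item("AM_10001", "A/G")}
        )
        hits = [r for r in ranked["RESP"] if r.antecedent == want]
        assert hits, "planted rule was not mined"
        assert hits[0].confidence == pytest.approx(0.9, abs=0.05)
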