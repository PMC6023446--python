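"""Class-association rule mining over genotype transactions.

Each class-assigned sample becomes one transaction holding a genotype item
per called probe plus exactly one class item (RESP or NoRESP).  Before
mining, a Fisher filter prunes probes whose best (minimum) raw per-category
Fisher p exceeds a user threshold — this shrinks the search space and is
deliberately independent of the corrected statistical screen.  Frequent
itemsets are then mined with an FP-Growth variant (support scan, infrequent
item drop, support-descending item order, FP-tree insertion, recursive
conditional-pattern-base mining with the single-path shortcut), and rules
are emitted only with a class item as consequent, kept when their confidence
meets the minimum, split per class and ranked by confidence.

Minimum support is measured against all transactions, not per class; this,
like the correction family upstream, is recorded in output metadata.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .io_dmet import NOCALL, GenotypeTable, PhenotypeAssignment
from .stats import ContingencyTable2x2, _per_class_category_counts, fisher_exact_two_sided

# Items are plain tuples so they hash and sort deterministically:
#   ("g", probe_id, genotype)  — genotype item
#   ("c", class_label)         — class item
Item = tuple


def genotype_item(probe_id: str, genotype: str) -> Item:
    return ("g", probe_id, genotype)

def class_item(label: str) -> Item:
    return ("c", label)


@dataclass(frozen=True)
class Transaction:
    sample_id: str
    items: frozenset


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset  # genotype items only, non-empty
    consequent: str        # class label
    support: float
    confidence: float
    antecedent_support: float

    def antecedent_tokens(self) -> str:
        toks = sorted(f"{probe}={geno}" for _, probe, geno in self.antecedent)
        return ";".join(toks)


def fisher_filter(
    table: GenotypeTable, assignment: PhenotypeAssignment, threshold: float = 0.05
) -> GenotypeTable:
    """Keep probes whose minimum raw per-genotype Fisher p is <= threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("fisher_filter threshold must lie in (0, 1]")
    assignment.require_nonempty()
    counts_a, counts_b = _per_class_category_counts(table, assignment)
    keep = []
    for probe in table.probe_ids:
        ca = counts_a.loc[probe] if probe in counts_a.index else pd.Series(dtype=int)
        cb = counts_b.loc[probe] if probe in counts_b.index else pd.Series(dtype=int)
        total_a, total_b = int(ca.sum()), int(cb.sum())
        best = math.inf
        for cat in set(ca[ca > 0].index) | set(cb[cb > 0].index):
            a, c = int(ca.get(cat, 0)), int(cb.get(cat, 0))
            t = ContingencyTable2x2(a, total_a - a, c, total_b - c)
            best = min(best, fisher_exact_two_sided(t))
        if best <= threshold:
            keep.append(probe)
    return table.subset_probes(keep)


def build_transactions(
    table: GenotypeTable, assignment: PhenotypeAssignment
) -> list[Transaction]:
    """One transaction per class-assigned sample; NoCall probes omitted."""
    out = []
    for sample in table.sample_ids:
        label = assignment.assignment.get(sample)
        if label is None:
            continue
        items = {
            genotype_item(probe, call)
            for probe, call in table.calls[sample].items()
            if call != NOCALL
        }
        items.add(class_item(label))
        out.append(Transaction(sample, frozenset(items)))
    return out


# ---------------------------------------------------------------------------
# FP-tree

class _FPNode:
    __slots__ = ("item", "count", "parent", "children", "next")

    def __init__(self, item, parent):
        self.item = item
        self.count = 0
        self.parent = parent
        self.children: dict = {}
        self.next: _FPNode | None = None


@dataclass
class FPTree:
    root: _FPNode
    header: dict = field(default_factory=dict)  # item -> chain head
    order: dict = field(default_factory=dict)   # item -> rank in mining order

    def item_support(self, item) -> int:
        total, node = 0, self.header.get(item)
        while node is not None:
            total += node.count
            node = node.next
        return total


def _build_tree(weighted_transactions, min_count) -> FPTree:
    """Build an FP-tree from (itemset, weight) pairs, dropping infrequent items."""
    counts: Counter = Counter()
    for items, w in weighted_transactions:
        for it in items:
            counts[it] += w
    frequent = {it: c for it, c in counts.items() if c >= min_count}
    ordered = sorted(frequent, key=lambda it: (-frequent[it], it))
    rank = {it: i for i, it in enumerate(ordered)}
    tree = FPTree(_FPNode(None, None), {}, rank)
    tails: dict = {}
    for items, w in weighted_transactions:
        path = sorted((it for it in items if it in rank), key=rank.__getitem__)
        node = tree.root
        for it in path:
            child = node.children.get(it)
            if child is None:
                child = _FPNode(it, node)
                node.children[it] = child
                if it in tails:
                    tails[it].next = child
                else:
                    tree.header[it] = child
                tails[it] = child
            child.count += w
            node = child
    return tree


def _single_path(tree: FPTree):
    """Return the (item, count) list if the tree is one path, else None."""
    path, node = [], tree.root
    while node.children:
        if len(node.children) > 1:
            return None
        (node,) = node.children.values()
        path.append((node.item, node.count))
    return path


def _mine(tree: FPTree, suffix: frozenset, min_count: int, out: dict) -> None:
    path = _single_path(tree)
    if path is not None:
        # single-path shortcut: every combination of path items is frequent
        for r in range(1, len(path) + 1):
            for combo in itertools.combinations(path, r):
                support = min(c for _, c in combo)
                if support >= min_count:
                    itemset = suffix | frozenset(it for it, _ in combo)
                    out[itemset] = support
        return
    # least-frequent first over the header table
    for item in sorted(tree.header, key=lambda it: tree.order[it], reverse=True):
        support = tree.item_support(item)
        if support < min_count:
            continue
        itemset = suffix | {item}
        out[itemset] = support
        # conditional pattern base: prefix paths of every node carrying `item`
        base = []
        node = tree.header[item]
        while node is not None:
            prefix, p = [], node.parent
            while p is not None and p.item is not None:
                prefix.append(p.item)
                p = p.parent
            if prefix:
                base.append((prefix, node.count))
            node = node.next
        if base:
            cond = _build_tree(base, min_count)
            _mine(cond, itemset, min_count, out)


def fp_growth(transactions, min_support: float) -> dict[frozenset, float]:
    """All itemsets with support >= min_support, mapped to exact support.

    ``transactions`` is an iterable of `Transaction` or raw item iterables;
    support is the fraction of all transactions containing the itemset.
    """
    if not 0 < min_support <= 1:
        raise ValueError("min_support must lie in (0, 1]")
    tx = [t.items if isinstance(t, Transaction) else frozenset(t) for t in transactions]
    n = len(tx)
    if n == 0:
        return {}
    min_count = max(1, math.ceil(min_support * n - 1e-9))
    tree = _build_tree([(t, 1) for t in tx], min_count)
    counts: dict[frozenset, int] = {}
    _mine(tree, frozenset(), min_count, counts)
    return {items: c / n for items, c in counts.items()}


def generate_rules(
    frequent: dict[frozenset, float],
    min_confidence: float,
    class_labels,
) -> list[AssociationRule]:
    """Turn frequent itemsets into class-consequent rules.

    One candidate per frequent itemset containing exactly one class item and
    at least one genotype item; the antecedent support is read from the
    frequent-itemset map (anti-monotonicity guarantees it is present).
    """
    if not 0 < min_confidence <= 1:
        raise ValueError("min_confidence must lie in (0, 1]")
    class_items = {class_item(label) for label in class_labels}
    rules = []
    for itemset, support in frequent.items():
        cls = itemset & class_items
        if len(cls) != 1:
            continue
        antecedent = itemset - cls
        if not antecedent:
            continue
        ant_support = frequent[antecedent]
        confidence = support / ant_support
        if confidence >= min_confidence - 1e-12:
            (consequent,) = cls
            rules.append(
                AssociationRule(antecedent, consequent[1], support, confidence, ant_support)
            )
    return rules


def split_and_rank_rules(rules) -> dict[str, list[AssociationRule]]:
    """Partition rules by consequent class, rank by confidence within class.

    Ties break by support descending, then antecedent token string, giving a
    fully deterministic order.
    """
    by_class: dict[str, list[AssociationRule]] = {}
    for rule in rules:
        by_class.setdefault(rule.consequent, []).append(rule)
    for label, lst in by_class.items():
        lst.sort(key=lambda r: (-r.confidence, -r.support, r.antecedent_tokens()))
    return by_class


def rules_frame(rules) -> pd.DataFrame:
    """Tabular view used by the results writer."""
    return pd.DataFrame(
        [
            {
                "antecedent": r.antecedent_tokens(),
                "consequent": r.consequent,
                "support": r.support,
                "confidence": r.confidence,
                "antecedent_support": r.antecedent_support,
            }
            for r in rules
        ],
        columns=["antecedent", "consequent", "support", "confidence", "antecedent_support"],
    )


def mine_class_rules(
    table: GenotypeTable,
    assignment: PhenotypeAssignment,
    fisher_threshold: float = 0.05,
    min_support: float = 0.2,
    min_confidence: float = 0.8,
) -> dict[str, list[AssociationRule]]:
    """Full mining stage: Fisher filter -> transactions -> FP-Growth -> rules."""
    pruned = fisher_filter(table, assignment, fisher_threshold)
    tx = build_transactions(pruned, assignment)
    frequent = fp_growth(tx, min_support) if tx else {}
    rules = generate_rules(frequent, min_confidence, assignment.class_labels)
    ranked = split_and_rank_rules(rules)
    for label in assignment.class_labels:
        ranked.setdefault(label, [])
    return ranked
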