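"""FP-growth frequent-itemset mining, with a brute-force oracle.

The miner compresses the transaction database into a frequent-pattern tree
(a prefix tree over items sorted by descending support) and extracts
frequent itemsets recursively from conditional pattern bases, without
candidate generation.  All supports are exact: counting is integral and the
``support >= minsup`` comparison is made on integer counts
(``count >= ceil(minsup * |T|)``, inclusive at the threshold) so no itemset
is misclassified by a float edge.

``brute_force_frequent`` enumerates every candidate subset directly and
serves as the independent oracle in the test suite; it is guarded to small
alphabets and is not a production path.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

from .encoding import Transaction

#: Transactions are accepted as Transaction objects or bare item sets.
TransactionLike = Union[Transaction, frozenset, set]

#: Default cap on mined itemset size.  Rule antecedent+consequent sizes of
#: interest here are small (<= 4 items total); the cap bounds combinatorial
#: blowup on dense Likert baskets and is configurable everywhere.
DEFAULT_MAX_LEN = 4


def _itemsets(transactions: Sequence[TransactionLike]) -> list[frozenset]:
    return [
        t.items if isinstance(t, Transaction) else frozenset(t) for t in transactions
    ]


def min_count(minsup: float, n_transactions: int) -> int:
    """Smallest integer count with count / n >= minsup (at least 1).

    The tiny slack absorbs float error in ``minsup * n`` so an exact
    threshold (e.g. 0.2 of 10) is inclusive.
    """
    return max(1, math.ceil(minsup * n_transactions - 1e-9))


@dataclass(frozen=True)
class FrequentItemset:
    """An itemset with its exact occurrence count and support fraction."""

    items: frozenset[str]
    count: int
    support: float

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("frequent itemset must be non-empty")


# ---------------------------------------------------------------------------
# Support


def support_count(itemset: Iterable[str], transactions: Sequence[TransactionLike]) -> int:
    """Number of transactions containing every item of ``itemset``."""
    target = frozenset(itemset)
    return sum(1 for t in _itemsets(transactions) if target <= t)


def support(itemset: Iterable[str], transactions: Sequence[TransactionLike]) -> float:
    """Fraction of transactions containing all of ``itemset``.

    ``support({}) = 1`` by convention (vacuous containment).  Raises on an
    empty transaction list, where the fraction is undefined.
    """
    if len(transactions) == 0:
        raise ValueError("support undefined for an empty transaction list")
    return support_count(itemset, transactions) / len(transactions)


# ---------------------------------------------------------------------------
# FP-tree


class FPNode:
    """Node of an FP-tree: one item occurrence on a prefix path."""

    __slots__ = ("item", "count", "parent", "children", "node_link")

    def __init__(self, item: Optional[str], parent: Optional["FPNode"]):
        self.item = item  # None marks the root sentinel
        self.count = 0
        self.parent = parent
        self.children: dict[str, FPNode] = {}
        self.node_link: Optional[FPNode] = None


class FPTree:
    """Prefix tree over frequent items in a fixed total order.

    ``item_order`` sorts items by descending support with ties broken by
    ascending item code, so every root-to-leaf path lists items in strictly
    decreasing rank and two runs on the same input build identical trees.
    """

    def __init__(self, item_counts: dict[str, int]):
        self.root = FPNode(None, None)
        # rank: most frequent item first; deterministic tie-break on code
        ordered = sorted(item_counts, key=lambda i: (-item_counts[i], i))
        self.rank: dict[str, int] = {item: r for r, item in enumerate(ordered)}
        self.header: dict[str, int] = {item: 0 for item in ordered}
        self._first: dict[str, FPNode] = {}
        self._tails: dict[str, FPNode] = {}

    @property
    def item_order(self) -> list[str]:
        return sorted(self.rank, key=self.rank.get)

    def insert(self, items: Iterable[str], count: int = 1) -> None:
        """Insert one (conditional) transaction, keeping only ranked items."""
        path = sorted((i for i in items if i in self.rank), key=self.rank.get)
        self.root.count += count
        node = self.root
        for item in path:
            child = node.children.get(item)
            if child is None:
                child = FPNode(item, node)
                node.children[item] = child
                tail = self._tails.get(item)
                if tail is None:
                    self._first[item] = child
                else:
                    tail.node_link = child
                self._tails[item] = child
            child.count += count
            self.header[item] += count
            node = child

    def nodes_for(self, item: str):
        """Iterate all nodes holding ``item`` via the node-link chain."""
        node = self._first.get(item)
        while node is not None:
            yield node
            node = node.node_link

    def prefix_paths(self, item: str) -> list[tuple[list[str], int]]:
        """Conditional pattern base: (path items above node, node count)."""
        paths = []
        for node in self.nodes_for(item):
            path = []
            parent = node.parent
            while parent is not None and parent.item is not None:
                path.append(parent.item)
                parent = parent.parent
            paths.append((path, node.count))
        return paths


def build_fptree(
    transactions: Sequence[TransactionLike], minsup: float
) -> FPTree:
    """Build the FP-tree over items with support >= minsup."""
    if not 0 < minsup <= 1:
        raise ValueError("minsup must be in (0, 1]")
    baskets = _itemsets(transactions)
    threshold = min_count(minsup, len(baskets))
    counts: dict[str, int] = {}
    for basket in baskets:
        for item in basket:
            counts[item] = counts.get(item, 0) + 1
    frequent = {i: c for i, c in counts.items() if c >= threshold}
    tree = FPTree(frequent)
    for basket in baskets:
        tree.insert(basket)
    return tree


# ---------------------------------------------------------------------------
# Mining


def mine_frequent(
    transactions: Sequence[TransactionLike],
    minsup: float,
    max_len: Optional[int] = None,
) -> list[FrequentItemset]:
    """All itemsets with support >= minsup (size <= max_len if given).

    Output is sorted by (itemset size, item codes) and carries exact counts,
    so two runs on the same input are identical.
    """
    if not 0 < minsup <= 1:
        raise ValueError("minsup must be in (0, 1]")
    if max_len is not None and max_len < 1:
        raise ValueError("max_len must be a positive integer")
    baskets = _itemsets(transactions)
    n = len(baskets)
    if n == 0:
        return []
    threshold = min_count(minsup, n)

    results: dict[frozenset, int] = {}

    def grow(tree: FPTree, suffix: tuple[str, ...]) -> None:
        # visit items least-frequent first so conditional trees stay small
        for item in reversed(tree.item_order):
            count = tree.header[item]
            if count < threshold:
                continue
            itemset = frozenset((item, *suffix))
            results[itemset] = count
            if max_len is not None and len(itemset) >= max_len:
                continue
            base = tree.prefix_paths(item)
            cond_counts: dict[str, int] = {}
            for path, path_count in base:
                for path_item in path:
                    cond_counts[path_item] = cond_counts.get(path_item, 0) + path_count
            cond_frequent = {i: c for i, c in cond_counts.items() if c >= threshold}
            if not cond_frequent:
                continue
            cond_tree = FPTree(cond_frequent)
            for path, path_count in base:
                cond_tree.insert(path, path_count)
            grow(cond_tree, tuple(itemset))

    tree = build_fptree(baskets, minsup)
    grow(tree, ())

    out = [
        FrequentItemset(items=items, count=count, support=count / n)
        for items, count in results.items()
    ]
    out.sort(key=lambda f: (len(f.items), tuple(sorted(f.items))))
    return out


def brute_force_frequent(
    transactions: Sequence[TransactionLike],
    minsup: float,
    max_len: Optional[int] = None,
    max_items: int = 20,
) -> list[FrequentItemset]:
    """Oracle miner: enumerate every candidate subset and count directly.

    Same contract and output format as :func:`mine_frequent`.  Guarded to at
    most ``max_items`` distinct observed items; exponential by design.
    """
    if not 0 < minsup <= 1:
        raise ValueError("minsup must be in (0, 1]")
    baskets = _itemsets(transactions)
    n = len(baskets)
    if n == 0:
        return []
    alphabet = sorted(set().union(*baskets)) if baskets else []
    if len(alphabet) > max_items:
        raise ValueError(
            f"{len(alphabet)} distinct items exceeds the brute-force guard "
            f"({max_items})"
        )
    threshold = min_count(minsup, n)
    top = len(alphabet) if max_len is None else min(max_len, len(alphabet))
    out = []
    for size in range(1, top + 1):
        for combo in itertools.combinations(alphabet, size):
            target = frozenset(combo)
            count = sum(1 for basket in baskets if target <= basket)
            if count >= threshold:
                out.append(
                    FrequentItemset(items=target, count=count, support=count / n)
                )
    out.sort(key=lambda f: (len(f.items), tuple(sorted(f.items))))
    return out
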