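"""Apriori frequent-itemset mining over patient transactions.

Each patient becomes one transaction: a token per mutated panel gene
("ASXL1:mut"), optionally a token per wild-type gene ("ASXL1:wt"), and
exactly one outcome token ("OUTCOME:RESP" or "OUTCOME:NONRESP").  Mining is
classic level-wise Apriori with downward-closure pruning; an exhaustive
enumeration oracle with the same output contract is provided for testing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort

__all__ = [
    "OUTCOME_RESP",
    "OUTCOME_NONRESP",
    "Transaction",
    "FrequentItemset",
    "encode_transactions",
    "mine_frequent",
    "brute_force_frequent",
    "write_itemsets_tsv",
]

OUTCOME_RESP = "OUTCOME:RESP"
OUTCOME_NONRESP = "OUTCOME:NONRESP"
_OUTCOME_TOKENS = frozenset({OUTCOME_RESP, OUTCOME_NONRESP})


@dataclass(frozen=True)
class Transaction:
    """One patient's item set: gene tokens plus exactly one outcome token."""

    sample_id: str
    items: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "items", frozenset(self.items))
        n_outcome = len(self.items & _OUTCOME_TOKENS)
        if n_outcome != 1:
            raise ValueError(
                f"transaction {self.sample_id}: expected exactly one outcome "
                f"token, found {n_outcome}"
            )


@dataclass(frozen=True)
class FrequentItemset:
    items: frozenset[str]
    support_count: int
    support_frac: float

    def __post_init__(self):
        object.__setattr__(self, "items", frozenset(self.items))
        if not (0.0 < self.support_frac <= 1.0):
            raise ValueError("support_frac must be in (0, 1]")


def encode_transactions(
    cohort: Cohort, include_wildtype: bool = False
) -> list[Transaction]:
    """Encode evaluable patients as transactions.

    Patients with an UNKNOWN response category are excluded.  With
    ``include_wildtype`` a ``GENE:wt`` token is emitted for every unmutated
    panel gene (off by default; it inflates the item universe 29-fold for
    typical mutation frequencies).
    """
    out = []
    for profile, record in zip(cohort.profiles, cohort.clinical):
        if not record.response.evaluable():
            continue
        items = {f"{g}:mut" for g in profile.mutated_genes}
        if include_wildtype:
            items |= {
                f"{g}:wt" for g in cohort.panel if g not in profile.mutated_genes
            }
        items.add(OUTCOME_RESP if record.response.responder() else OUTCOME_NONRESP)
        out.append(Transaction(profile.sample_id, frozenset(items)))
    return out


def _sorted_itemsets(
    counted: dict[frozenset, int], n: int
) -> list[FrequentItemset]:
    keys = sorted(counted, key=lambda s: (len(s), tuple(sorted(s))))
    return [FrequentItemset(k, counted[k], counted[k] / n) for k in keys]


def _items_of(t) -> frozenset:
    return t.items if hasattr(t, "items") and not isinstance(t, dict) else frozenset(t)


def _transaction_matrix(transactions) -> tuple[np.ndarray, list[str]]:
    itemsets = [_items_of(t) for t in transactions]
    universe = sorted({it for s in itemsets for it in s})
    index = {it: j for j, it in enumerate(universe)}
    mat = np.zeros((len(transactions), len(universe)), dtype=bool)
    for i, s in enumerate(itemsets):
        for it in s:
            mat[i, index[it]] = True
    return mat, universe


def mine_frequent(
    transactions: list[Transaction],
    min_support_count: int,
    max_len: int = 5,
) -> list[FrequentItemset]:
    """Level-wise Apriori.

    Returns exactly the itemsets of size 1..max_len whose support count
    meets ``min_support_count``, sorted by (size, lexicographic items).
    Candidate (k)-itemsets are generated by joining (k-1)-itemsets sharing a
    (k-2)-prefix and pruned by downward closure before counting.
    """
    if not transactions:
        raise ValueError("transactions must be non-empty")
    if min_support_count < 1:
        raise ValueError("min_support_count must be >= 1")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    n = len(transactions)
    mat, universe = _transaction_matrix(transactions)

    counted: dict[frozenset, int] = {}
    col_counts = mat.sum(axis=0)
    level: list[tuple[int, ...]] = []  # frequent itemsets as sorted column-index tuples
    for j, c in enumerate(col_counts):
        if c >= min_support_count:
            counted[frozenset({universe[j]})] = int(c)
            level.append((j,))
    k = 1
    while level and k < max_len:
        level_set = set(level)
        candidates: list[tuple[int, ...]] = []
        # join step: two frequent k-sets sharing their first k-1 indices
        for a, b in itertools.combinations(sorted(level), 2):
            if a[:-1] != b[:-1]:
                continue
            cand = a + (b[-1],)
            # prune step: every k-subset must be frequent
            if all(
                cand[:i] + cand[i + 1:] in level_set for i in range(len(cand))
            ):
                candidates.append(cand)
        next_level = []
        for cand in candidates:
            c = int(mat[:, list(cand)].all(axis=1).sum())
            if c >= min_support_count:
                counted[frozenset(universe[j] for j in cand)] = c
                next_level.append(cand)
        level = next_level
        k += 1
    return _sorted_itemsets(counted, n)


def brute_force_frequent(
    transactions: list[Transaction],
    min_support_count: int,
    max_len: int = 5,
) -> list[FrequentItemset]:
    """Exhaustive-enumeration oracle with mine_frequent's output contract.

    Counts every subset of the item universe up to ``max_len`` directly;
    guarded to universes of <= 20 items.
    """
    if not transactions:
        raise ValueError("transactions must be non-empty")
    mat, universe = _transaction_matrix(transactions)
    if len(universe) > 20:
        raise ValueError(
            f"brute-force oracle refuses universes > 20 items "
            f"(got {len(universe)})"
        )
    n = len(transactions)
    counted: dict[frozenset, int] = {}
    for size in range(1, min(max_len, len(universe)) + 1):
        for combo in itertools.combinations(range(len(universe)), size):
            c = int(mat[:, list(combo)].all(axis=1).sum())
            if c >= min_support_count:
                counted[frozenset(universe[j] for j in combo)] = c
    return _sorted_itemsets(counted, n)


def write_itemsets_tsv(path, itemsets: list[FrequentItemset]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("items\tsupport_count\tsupport_frac\n")
        for s in itemsets:
            fh.write(
                f"{'|'.join(sorted(s.items))}\t{s.support_count}\t"
                f"{s.support_frac:.6g}\n"
            )
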