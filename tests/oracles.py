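"""Independent brute-force oracles used only by the tests.

Each oracle is deliberately naive (exhaustive recursion / pair counting /
path enumeration) and shares no code with the implementation it checks.
"""

from functools import lru_cache
from itertools import product


def edit_distance_recursive(s1: str, s2: str) -> int:
    """Textbook exhaustive recursion for the unit-cost edit distance."""

    @lru_cache(maxsize=None)
    def go(i: int, j: int) -> int:
        if i == len(s1):
            return len(s2) - j
        if j == len(s2):
            return len(s1) - i
        cost = 0 if s1[i] == s2[j] else 1
        return min(
            go(i + 1, j) + 1,  # delete from s1
            go(i, j + 1) + 1,  # insert into s1
            go(i + 1, j + 1) + cost,  # substitute / match
        )

    return go(0, 0)


def auroc_pair_counting(scores, labels) -> float:
    """Fraction of (positive, negative) pairs won by the positive; ties 0.5."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def dd_path_enumeration(parent_edges: dict[str, set[str]], targets: set[str], delta: float) -> dict[str, float]:
    """Contribution of every ancestor by explicit path enumeration.

    DD(d) = delta ** (length of the shortest directed child->parent path
    from any target node to d), the unrolled form of the max-decay
    recursion.  ``parent_edges`` maps child -> set of parents.
    """
    contributions: dict[str, float] = {}

    def walk(node: str, depth: int) -> None:
        value = delta**depth
        if value > contributions.get(node, 0.0):
            contributions[node] = value
            for parent in parent_edges.get(node, ()):  # keep exploring best paths
                walk(parent, depth + 1)

    for t in targets:
        walk(t, 0)
    return contributions


def all_weight_tuples(n_sources: int, units: int):
    """Explicit enumeration of integer compositions of ``units``."""
    return [
        combo
        for combo in product(range(units + 1), repeat=n_sources)
        if sum(combo) == units
    ]
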