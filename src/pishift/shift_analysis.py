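"""Inter-species pI divergence analysis.

Pairwise absolute pI differences across ortholog families, the
non-parametric shift threshold 2*(Q3 - median), permutation significance,
discretization of pI into acidic/neutral/basic, and minimum state-change
counts on a species tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path
from typing import Iterable, Mapping, Optional

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "OrthologPISet",
    "ShiftResult",
    "SpeciesTree",
    "DEFAULT_BOUNDS",
    "pairwise_diffs",
    "shift_threshold",
    "flag_shifters",
    "permutation_pvalue",
    "discretize_pi",
    "fitch_shift_count",
]

#: Default acidic/basic bounds for discretization (config-exposed).
DEFAULT_BOUNDS = (6.8, 7.2)

#: Above this family count, permutation p-values are always sampled.
_EXHAUSTIVE_LIMIT = 9


@dataclass
class OrthologPISet:
    """Per-family, per-species pI values."""

    families: dict
    species: list

    def __post_init__(self) -> None:
        for family, values in self.families.items():
            for sp, pi in values.items():
                if sp not in self.species:
                    raise ValueError(f"family {family!r}: unknown species {sp!r}")
                if not math.isfinite(pi):
                    raise ValueError(f"family {family!r}, species {sp!r}: non-finite pI")

    @classmethod
    def from_table(cls, table: pd.DataFrame | str | Path) -> "OrthologPISet":
        """Build from a TSV/DataFrame with columns family, species, pI."""
        if not isinstance(table, pd.DataFrame):
            table = pd.read_csv(table, sep="\t")
        for column in ("family", "species", "pI"):
            if column not in table.columns:
                raise ValueError(f"pI table missing required column {column!r}")
        families: dict[str, dict[str, float]] = {}
        species: list[str] = []
        for row in table.itertuples(index=False):
            families.setdefault(str(row.family), {})[str(row.species)] = float(row.pI)
            if str(row.species) not in species:
                species.append(str(row.species))
        return cls(families=families, species=species)

    def to_table(self) -> pd.DataFrame:
        rows = [
            {"family": family, "species": sp, "pI": pi}
            for family, values in self.families.items()
            for sp, pi in values.items()
        ]
        return pd.DataFrame(rows, columns=["family", "species", "pI"])


@dataclass
class ShiftResult:
    """Outcome of thresholding one species pair."""

    species_pair: tuple
    abs_diff: dict
    threshold: float
    flagged: set
    perm_pvalue: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")


def pairwise_diffs(piset: OrthologPISet, a: str, b: str) -> dict:
    """Absolute pI difference per family; families lacking either species drop out."""
    if a == b:
        raise ValueError("species pair must be two distinct species")
    for sp in (a, b):
        if sp not in piset.species:
            raise KeyError(f"unknown species {sp!r} (have {piset.species})")
    diffs = {}
    for family, values in piset.families.items():
        if a in values and b in values:
            diffs[family] = abs(values[a] - values[b])
    return diffs


def shift_threshold(diffs: Iterable[float]) -> float:
    """The non-parametric shift threshold 2 * (Q3 - median).

    Quartiles use linear interpolation between order statistics at
    plotting positions (k-1)/(n-1).  Requires at least 4 values.
    """
    values = np.asarray(list(diffs), dtype=float)
    if values.size < 4:
        raise ValueError(f"need at least 4 differences to set a threshold, got {values.size}")
    q3, median = np.quantile(values, [0.75, 0.5], method="linear")
    return float(2.0 * (q3 - median))


def flag_shifters(
    diffs: Mapping[str, float],
    threshold: float,
    species_pair: tuple = ("A", "B"),
) -> ShiftResult:
    """Families whose absolute difference strictly exceeds the threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    flagged = {family for family, diff in diffs.items() if diff > threshold}
    return ShiftResult(
        species_pair=tuple(species_pair),
        abs_diff=dict(diffs),
        threshold=float(threshold),
        flagged=flagged,
    )


def permutation_pvalue(
    piset: OrthologPISet,
    a: str,
    b: str,
    family: str,
    n_perm: int = 1000,
    seed: int = 42,
    mode: str = "protein",
) -> float:
    """Permutation p-value for one family's pI shift.

    Species-B pI values are shuffled across the families shared by both
    species (A fixed) and the family's absolute difference is recomputed
    each time.  ``mode="protein"`` compares the permuted difference to the
    observed one; ``mode="threshold"`` additionally recomputes the shift
    threshold per permutation and compares exceedance margins
    (difference minus threshold).

    Sampled estimate: p = (1 + #{permuted stat >= observed}) / (n_perm + 1).
    When every label permutation can be enumerated (small family counts and
    n_perm >= n!), the exact enumeration p-value is returned instead.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("protein", "threshold"):
        raise ValueError(f"mode must be 'protein' or 'threshold', got {mode!r}")
    diffs = pairwise_diffs(piset, a, b)
    if family not in diffs:
        raise KeyError(f"family {family!r} is not present in both {a!r} and {b!r}")
    order = sorted(diffs)
    idx = order.index(family)
    a_vec = np.array([piset.families[f][a] for f in order], dtype=float)
    b_vec = np.array([piset.families[f][b] for f in order], dtype=float)

    if mode == "threshold" and len(order) < 4:
        raise ValueError("mode='threshold' needs at least 4 shared families")

    def statistic(bv: np.ndarray) -> float:
        d = np.abs(a_vec - bv)
        if mode == "protein":
            return float(d[idx])
        return float(d[idx]) - shift_threshold(d)

    observed = statistic(b_vec)

    n = len(order)
    if n <= _EXHAUSTIVE_LIMIT and n_perm >= math.factorial(n):
        hits = total = 0
        for perm in permutations(range(n)):
            total += 1
            if statistic(b_vec[list(perm)]) >= observed:
                hits += 1
        return hits / total  # identity permutation guarantees hits >= 1

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if statistic(rng.permutation(b_vec)) >= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def discretize_pi(pi: float, bounds: tuple = DEFAULT_BOUNDS) -> str:
    """Map a pI to 'acidic' (< low), 'basic' (> high) or 'neutral'."""
    low, high = bounds
    if not low < high:
        raise ValueError(f"bounds must satisfy low < high, got {bounds}")
    if pi < low:
        return "acidic"
    if pi > high:
        return "basic"
    return "neutral"


@dataclass
class SpeciesTree:
    """A rooted species tree with unique leaf labels (Newick-backed)."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            raise ValueError("species tree has duplicate leaf labels")

    @classmethod
    def from_newick(cls, source: str | Path) -> "SpeciesTree":
        """Parse from a Newick file path or a Newick string."""
        text = None
        if isinstance(source, Path) or (isinstance(source, str) and Path(source).is_file()):
            text = Path(source).read_text()
        else:
            text = str(source)
        try:
            tree = dendropy.Tree.get(data=text, schema="newick")
        except Exception as exc:
            if "uplicate" in str(exc):
                raise ValueError("species tree has duplicate leaf labels") from exc
            raise
        return cls(tree=tree)

    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]


def fitch_shift_count(tree: SpeciesTree, states: Mapping[str, str]) -> int:
    """Minimum number of state changes explaining the leaf states.

    Exact small-parsimony count (unit-cost Sankoff dynamic programme, so
    multifurcating trees are handled exactly) over whatever state alphabet
    appears in ``states``.
    """
    leaves = tree.leaf_labels()
    missing = [label for label in leaves if label not in states]
    if missing:
        raise ValueError(f"no state for leaf/leaves: {', '.join(sorted(missing))}")
    extra = sorted(set(states) - set(leaves))
    if extra:
        raise ValueError(f"state-table species not in tree: {', '.join(extra)}")
    alphabet = sorted(set(states.values()))
    index = {state: i for i, state in enumerate(alphabet)}
    k = len(alphabet)
    inf = float("inf")

    cost: dict[int, list[float]] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            vec = [inf] * k
            vec[index[states[node.taxon.label]]] = 0.0
            cost[id(node)] = vec
        else:
            vec = []
            for s in range(k):
                total = 0.0
                for child in node.child_nodes():
                    child_cost = cost[id(child)]
                    total += min(
                        child_cost[t] + (0.0 if t == s else 1.0) for t in range(k)
                    )
                vec.append(total)
            cost[id(node)] = vec
    return int(min(cost[id(tree.tree.seed_node)]))
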