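"""Shared fixtures and independent oracles."""

from __future__ import annotations

import math
from itertools import product

import numpy as np
import pytest

from pishift.isoelectric import IonizableGroupSet


def grid_scan_pi(groups: IonizableGroupSet, lo=-2.0, hi=16.0, step=0.001) -> float:
    """Independent pI oracle: dense grid scan of the charge curve.

    Returns the grid pH with the smallest absolute charge (the charge
    curve is strictly decreasing, so that point brackets the root to
    within one step).
    """
    grid = np.arange(lo, hi + step, step)
    charge = np.zeros_like(grid)
    for (pka, polarity), count in groups.items():
        if polarity == "base":
            charge += count / (1.0 + 10.0 ** (grid - pka))
        else:
            charge -= count / (1.0 + 10.0 ** (pka - grid))
    return float(grid[np.argmin(np.abs(charge))])


def hypergeom_tail_p(a: int, b: int, c: int, d: int) -> float:
    """Independent Fisher oracle: exact hypergeometric upper tail.

    P(X >= a) where X counts selected&charged draws with margins fixed:
    population a+b+c+d, charged a+b, selected a+c.
    """
    total = a + b + c + d
    charged = a + b
    selected = a + c
    lo = max(0, selected - (total - charged))
    hi = min(charged, selected)
    denom = math.comb(total, selected)
    tail = sum(
        math.comb(charged, k) * math.comb(total - charged, selected - k)
        for k in range(a, hi + 1)
    )
    assert lo <= a <= hi
    return tail / denom


def brute_force_parsimony(tree, states: dict) -> int:
    """Independent Fitch oracle: enumerate all internal-state assignments.

    Unit-cost minimum over assignments drawn from the observed state
    alphabet (sufficient for unit costs).
    """
    alphabet = sorted(set(states.values()))
    nodes = list(tree.tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    best = math.inf
    for assignment in product(alphabet, repeat=len(internal)):
        label = {id(n): s for n, s in zip(internal, assignment)}
        for n in nodes:
            if n.is_leaf():
                label[id(n)] = states[n.taxon.label]
        cost = 0
        for n in nodes:
            if n.parent_node is not None:
                cost += label[id(n)] != label[id(n.parent_node)]
        best = min(best, cost)
    return int(best)


@pytest.fixture
def write_fasta_file(tmp_path):
    """Write raw FASTA text entries (header, seq) to a temp file."""

    def _write(entries, name="input.fasta"):
        path = tmp_path / name
        with open(path, "w") as handle:
            for header, seq in entries:
                handle.write(f">{header}\n{seq}\n")
        return path

    return _write
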