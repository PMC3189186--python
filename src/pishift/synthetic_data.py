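"""Synthetic inputs with known ground truth.

Random proteins with controlled charge composition, hill-climb mutation
toward a target pI, proteome-scale ortholog pI sets with planted outlier
families, and selection-site tables with a planted enrichment odds ratio.
All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .isoelectric import DEFAULT_PKA_TABLE, PKaTable, sequence_pi
from .seqio import ProteinRecord, SelectionSiteRecord
from .shift_analysis import OrthologPISet

__all__ = [
    "BASIC_RESIDUES",
    "ACIDIC_RESIDUES",
    "NEUTRAL_RESIDUES",
    "SyntheticProteomeSpec",
    "SyntheticSelectionSpec",
    "TargetPIError",
    "random_protein",
    "mutate_to_target_pi",
    "simulate_proteome",
    "simulate_family",
    "plant_selection_sites",
]

BASIC_RESIDUES = "RKH"
ACIDIC_RESIDUES = "DECY"
NEUTRAL_RESIDUES = "GASTLVPNQ"


@dataclass(frozen=True)
class SyntheticProteomeSpec:
    """Parameters of a proteome-scale ortholog pI simulation."""

    n_families: int
    species: tuple
    background_sigma: float
    outliers: tuple = ()  # pairs (family, target_abs_shift)
    length_range: tuple = (80, 300)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_families < 4:
            raise ValueError("n_families must be >= 4")
        if len(self.species) < 2:
            raise ValueError("need at least two species")
        if self.background_sigma < 0:
            raise ValueError("background_sigma must be >= 0")
        names = [family for family, _ in self.outliers]
        if len(names) != len(set(names)):
            raise ValueError("duplicate outlier family")
        for family, shift in self.outliers:
            if shift <= 0:
                raise ValueError(f"outlier {family!r}: target shift must be > 0")


@dataclass(frozen=True)
class SyntheticSelectionSpec:
    """Parameters of a planted selection-enrichment simulation."""

    n_sites: int
    charged_fraction: float
    base_selected_rate: float
    odds_ratio: float
    alpha: float = 0.05
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for name in ("charged_fraction", "base_selected_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.odds_ratio < 0:
            raise ValueError("odds_ratio must be >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


class TargetPIError(RuntimeError):
    """Raised when the hill-climb cannot reach the target pI.

    Carries the best sequence reached and its pI.
    """

    def __init__(self, message: str, best_sequence: str, best_pi: float):
        super().__init__(message)
        self.best_sequence = best_sequence
        self.best_pi = best_pi


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_protein(
    length: int,
    charged_fraction: float,
    basic_bias: float = 0.5,
    seed=0,
) -> str:
    """IID random sequence with a controlled ionizable-residue content.

    Each position is ionizable with probability ``charged_fraction``
    (basic with probability ``basic_bias``, else acidic), otherwise a
    neutral residue.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    for name, value in (("charged_fraction", charged_fraction), ("basic_bias", basic_bias)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {value}")
    rng = _as_rng(seed)
    letters = []
    for _ in range(length):
        if rng.random() < charged_fraction:
            pool = BASIC_RESIDUES if rng.random() < basic_bias else ACIDIC_RESIDUES
        else:
            pool = NEUTRAL_RESIDUES
        letters.append(pool[rng.integers(len(pool))])
    return "".join(letters)


def mutate_to_target_pi(
    sequence: str,
    target_pi: float,
    tolerance: float = 0.1,
    max_steps: int = 500,
    seed=0,
    table: PKaTable = DEFAULT_PKA_TABLE,
) -> str:
    """Greedy hill-climb of single charged<->neutral substitutions.

    At each step the composition-level move (replace one residue of letter
    X by letter Y) bringing the pI closest to ``target_pi`` is applied at a
    randomly chosen eligible position.  Length is preserved and every move
    swaps between the charged and neutral classes (charged -> G, or
    neutral -> one of R/K/H/D/E/C/Y; the weak groups H, C and Y give the
    climb fine steps near neutrality).  Raises :class:`TargetPIError`
    (carrying the best-achieved pI) if the target is not reached within
    ``max_steps``.
    """
    if tolerance < 0.02:
        raise ValueError("tolerance must be >= 0.02 (twice the pI solver precision)")
    rng = _as_rng(seed)
    seq = list(sequence)
    current = sequence_pi("".join(seq), table=table)

    def legal_moves(residues: Sequence[str]) -> list:
        present = set(residues)
        moves = [(x, "G") for x in BASIC_RESIDUES + ACIDIC_RESIDUES if x in present]
        neutral_from = next((x for x in NEUTRAL_RESIDUES if x in present), None)
        if neutral_from is not None:
            moves += [(neutral_from, y) for y in BASIC_RESIDUES + ACIDIC_RESIDUES]
        return moves

    def applied(residues: list, move: tuple) -> list:
        x, y = move
        copy = list(residues)
        copy[copy.index(x)] = y
        return copy

    def apply_at_random_position(move: tuple) -> None:
        x, y = move
        positions = [i for i, letter in enumerate(seq) if letter == x]
        seq[int(rng.choice(positions))] = y

    steps = 0
    while steps < max_steps:
        if abs(current - target_pi) <= tolerance:
            return "".join(seq)
        best_gap = abs(current - target_pi)
        best_single, best_pi = None, current
        for move in legal_moves(seq):
            candidate = sequence_pi("".join(applied(seq, move)), table=table)
            gap = abs(candidate - target_pi)
            if gap < best_gap:
                best_single, best_gap, best_pi = move, gap, candidate
        if best_single is not None:
            apply_at_random_position(best_single)
            current = best_pi
            steps += 1
            continue
        # Single moves all overshoot: try the best pair of moves (e.g. one
        # strong base plus one weak acid lands between two single steps).
        best_pair, best_gap = None, abs(current - target_pi)
        for first in legal_moves(seq):
            once = applied(seq, first)
            for second in legal_moves(once):
                candidate = sequence_pi("".join(applied(once, second)), table=table)
                gap = abs(candidate - target_pi)
                if gap < best_gap:
                    best_pair, best_gap, best_pi = (first, second), gap, candidate
        if best_pair is None or steps + 2 > max_steps:
            break  # stuck: no one- or two-substitution improvement
        apply_at_random_position(best_pair[0])
        apply_at_random_position(best_pair[1])
        current = best_pi
        steps += 2
    if abs(current - target_pi) <= tolerance:
        return "".join(seq)
    raise TargetPIError(
        f"could not reach target pI {target_pi} (best {current:.2f})",
        best_sequence="".join(seq),
        best_pi=current,
    )


def simulate_proteome(spec: SyntheticProteomeSpec) -> tuple:
    """Ortholog pI set with half-normal background shifts and planted outliers.

    The first species carries each family's base pI; every other species
    deviates by N(0, background_sigma), except in outlier families where
    the deviation is exactly the planted target shift (random sign).
    Returns ``(OrthologPISet, set of planted outlier families)``.
    """
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.n_families))
    names = [f"F{i + 1:0{width}d}" for i in range(spec.n_families)]
    outlier_map = dict(spec.outliers)
    unknown = set(outlier_map) - set(names)
    if unknown:
        raise ValueError(f"outlier family names not generated: {sorted(unknown)}")
    families: dict[str, dict[str, float]] = {}
    ref = spec.species[0]
    for name in names:
        base = float(rng.uniform(4.0, 10.0))
        values = {ref: base}
        for sp in spec.species[1:]:
            if name in outlier_map:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                values[sp] = base + sign * outlier_map[name]
            else:
                values[sp] = base + float(rng.normal(0.0, spec.background_sigma))
        families[name] = values
    piset = OrthologPISet(families=families, species=list(spec.species))
    return piset, set(outlier_map)


def simulate_family(
    family: str,
    target_pis: Mapping[str, float],
    length: int = 150,
    seed: int = 42,
    tolerance: float = 0.1,
) -> list:
    """Sequence-level ortholog family whose members hit given target pIs.

    Builds one random backbone, then hill-climbs a copy per species toward
    that species' target pI.  Returns :class:`ProteinRecord` objects.
    """
    rng = np.random.default_rng(seed)
    backbone = random_protein(length, charged_fraction=0.25, basic_bias=0.5, seed=rng)
    records = []
    for sp, target in target_pis.items():
        seq = mutate_to_target_pi(backbone, target, tolerance=tolerance, max_steps=4 * length, seed=rng)
        records.append(ProteinRecord(id=f"{family}_{sp}", species=sp, family=family, sequence=seq))
    return records


def plant_selection_sites(spec: SyntheticSelectionSpec) -> tuple:
    """Charge classes and selection calls with a planted odds ratio.

    Site charge classes are Bernoulli(charged_fraction).  Selection flags
    are Bernoulli with P(selected | neutral) = base_selected_rate and the
    odds multiplied by ``odds_ratio`` for charged sites.  P-values are
    drawn consistent with ``spec.alpha`` (selected ~ U(0, alpha], others
    ~ U(alpha, 1)), omega > 1 iff selected.

    Returns ``(charge_classes, records, true_odds_ratio)``.
    """
    rng = np.random.default_rng(spec.seed)
    p_neutral = spec.base_selected_rate
    if p_neutral >= 1.0 and spec.odds_ratio > 0:
        raise ValueError("base_selected_rate of 1.0 leaves no room for an odds adjustment")
    odds_neutral = p_neutral / (1.0 - p_neutral) if p_neutral < 1.0 else float("inf")
    odds_charged = odds_neutral * spec.odds_ratio
    p_charged = odds_charged / (1.0 + odds_charged) if np.isfinite(odds_charged) else 1.0
    if not 0.0 <= p_charged <= 1.0:
        raise ValueError(f"charged selection probability {p_charged} outside [0, 1]")

    charge_classes: dict[int, str] = {}
    records: list[SelectionSiteRecord] = []
    for site in range(1, spec.n_sites + 1):
        charged = rng.random() < spec.charged_fraction
        charge_classes[site] = "charged" if charged else "neutral"
        selected = rng.random() < (p_charged if charged else p_neutral)
        if selected:
            pvalue = float(rng.uniform(0.0, spec.alpha))
            omega = float(rng.uniform(1.0, 5.0)) + 1e-6
        else:
            pvalue = float(rng.uniform(spec.alpha, 1.0))
            omega = float(rng.uniform(0.0, 1.0))
        records.append(SelectionSiteRecord(site=site, omega=omega, pvalue=pvalue))
    return charge_classes, records, spec.odds_ratio
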