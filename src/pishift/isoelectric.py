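"""Isoelectric-point engine.

Models a protein as a multiset of independent ionizable groups, evaluates
its net charge at any pH with the Henderson-Hasselbalch relation, and
solves for the zero-charge pH (the isoelectric point, pI) by bisection.

The default pKa scale covers the seven ionizable side chains (R, K, Y, C,
H, E, D) plus the free termini.  Phosphorylation and sialylated
glycosylation can contribute extra acidic groups via
:class:`PTMChargeModel`.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PKaTable",
    "PTMChargeModel",
    "IonizableGroupSet",
    "DEFAULT_PKA_TABLE",
    "DEFAULT_PTM_MODEL",
    "build_groups",
    "net_charge",
    "isoelectric_point",
    "protein_pi",
    "sequence_pi",
    "load_pka_table",
]

ACID = "acid"
BASE = "base"

_MAX_BISECTION_ITERATIONS = 200


@dataclass(frozen=True)
class PKaTable:
    """pKa values and acid/base polarity for every ionizable group.

    ``residue_pka`` maps a one-letter residue code to ``(pKa, polarity)``
    where polarity is ``"acid"`` or ``"base"``.  Residues absent from the
    map contribute no charge.
    """

    residue_pka: Mapping[str, tuple[float, str]]
    nterm_pka: float
    cterm_pka: float

    def __post_init__(self) -> None:
        for letter, (pka, polarity) in self.residue_pka.items():
            if polarity not in (ACID, BASE):
                raise ValueError(f"residue {letter!r}: polarity must be 'acid' or 'base', got {polarity!r}")
            if not 0.0 < pka < 14.0:
                raise ValueError(f"residue {letter!r}: pKa {pka} outside (0, 14)")
        for name, pka in (("N-terminus", self.nterm_pka), ("C-terminus", self.cterm_pka)):
            if not 0.0 < pka < 14.0:
                raise ValueError(f"{name}: pKa {pka} outside (0, 14)")


#: The built-in scale used throughout the analysis.
DEFAULT_PKA_TABLE = PKaTable(
    residue_pka={
        "R": (12.48, BASE),
        "K": (10.54, BASE),
        "Y": (10.46, ACID),
        "C": (8.18, ACID),
        "H": (6.04, BASE),
        "E": (4.07, ACID),
        "D": (3.90, ACID),
    },
    nterm_pka=8.0,
    cterm_pka=3.1,
)


@dataclass(frozen=True)
class PTMChargeModel:
    """Extra acidic groups contributed by post-translational modifications.

    Each phosphosite adds one acid group per pKa in ``phospho_pkas``
    (default: a two-proton phosphate).  Each glycosite adds
    ``sialic_per_glyco`` acid groups at ``sialic_pka``; the default of 0
    means glycosylation has no charge effect.
    """

    phospho_pkas: tuple[float, ...] = (1.2, 6.5)
    sialic_per_glyco: int = 0
    sialic_pka: float = 2.6

    def __post_init__(self) -> None:
        if self.sialic_per_glyco < 0:
            raise ValueError("sialic_per_glyco must be >= 0")


DEFAULT_PTM_MODEL = PTMChargeModel()


@dataclass
class IonizableGroupSet:
    """Multiset of ``(pKa, polarity) -> count`` ionizable groups."""

    counts: Counter = field(default_factory=Counter)

    def add(self, pka: float, polarity: str, n: int = 1) -> None:
        if polarity not in (ACID, BASE):
            raise ValueError(f"polarity must be 'acid' or 'base', got {polarity!r}")
        if n < 0:
            raise ValueError("count must be >= 0")
        if n:
            self.counts[(float(pka), polarity)] += n

    def total(self) -> int:
        return sum(self.counts.values())

    def items(self) -> Iterable[tuple[tuple[float, str], int]]:
        return self.counts.items()


def build_groups(
    sequence: str,
    table: PKaTable = DEFAULT_PKA_TABLE,
    ptms: Sequence = (),
    ptm_model: PTMChargeModel = DEFAULT_PTM_MODEL,
) -> IonizableGroupSet:
    """Collect the ionizable groups of a mature sequence.

    One group per ionizable side chain, one group per free terminus, plus
    PTM-contributed groups under ``ptm_model``.  Residues not in the table
    (e.g. ``X``) carry no group.

    Raises ``ValueError`` for an empty sequence or a PTM positioned beyond
    the sequence end.
    """
    if not sequence:
        raise ValueError("cannot build ionizable groups for an empty sequence")
    groups = IonizableGroupSet()
    for letter, n in Counter(sequence).items():
        entry = table.residue_pka.get(letter)
        if entry is not None:
            pka, polarity = entry
            groups.add(pka, polarity, n)
    groups.add(table.nterm_pka, BASE, 1)
    groups.add(table.cterm_pka, ACID, 1)
    for ptm in ptms:
        if ptm.position > len(sequence):
            raise ValueError(
                f"PTM at position {ptm.position} beyond sequence end ({len(sequence)} residues)"
            )
        if ptm.kind == "phospho":
            for pka in ptm_model.phospho_pkas:
                groups.add(pka, ACID, 1)
        elif ptm.kind == "glyco":
            groups.add(ptm_model.sialic_pka, ACID, ptm_model.sialic_per_glyco)
        else:  # pragma: no cover - PTMAnnotation validates its own vocabulary
            raise ValueError(f"unknown PTM kind {ptm.kind!r}")
    return groups


def net_charge(groups: IonizableGroupSet, ph: float) -> float:
    """Net charge (elementary-charge units) at ``ph``.

    charge = sum_base count/(1+10^(pH-pKa)) - sum_acid count/(1+10^(pKa-pH));
    strictly decreasing in pH for any non-empty group set.
    """
    charge = 0.0
    for (pka, polarity), count in groups.items():
        if polarity == BASE:
            charge += count / (1.0 + 10.0 ** (ph - pka))
        else:
            charge -= count / (1.0 + 10.0 ** (pka - ph))
    return charge


def isoelectric_point(
    groups: IonizableGroupSet,
    precision: float = 0.01,
    bracket: tuple[float, float] = (0.0, 14.0),
) -> float:
    """Zero-charge pH by bisection, rounded to two decimals.

    The bracket must straddle the root (positive charge at the low end,
    negative at the high end); if the default 0..14 bracket does not, it is
    widened once to -2..16.  The bisection interval is shrunk well below
    ``precision`` so the rounded result is within ``precision`` of the true
    root.
    """
    if precision <= 0:
        raise ValueError("precision must be positive")
    lo, hi = bracket
    f_lo, f_hi = net_charge(groups, lo), net_charge(groups, hi)
    if not (f_lo > 0.0 and f_hi < 0.0):
        lo, hi = -2.0, 16.0
        f_lo, f_hi = net_charge(groups, lo), net_charge(groups, hi)
        if not (f_lo > 0.0 and f_hi < 0.0):
            raise ValueError("no isoelectric point in bracket")
    # Quarter of the requested precision keeps the 2-decimal rounding error
    # plus the bracketing error within the precision contract.
    tol = precision / 4.0
    for _ in range(_MAX_BISECTION_ITERATIONS):
        mid = 0.5 * (lo + hi)
        f_mid = net_charge(groups, mid)
        if f_mid == 0.0:
            return round(mid, 2)
        if f_mid > 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo <= tol:
            break
    return round(0.5 * (lo + hi), 2)


def sequence_pi(
    sequence: str,
    table: PKaTable = DEFAULT_PKA_TABLE,
    ptms: Sequence = (),
    ptm_model: PTMChargeModel = DEFAULT_PTM_MODEL,
    precision: float = 0.01,
) -> float:
    """pI of a bare amino-acid string (termini included)."""
    return isoelectric_point(build_groups(sequence, table, ptms, ptm_model), precision=precision)


def protein_pi(
    record,
    table: PKaTable = DEFAULT_PKA_TABLE,
    use_ptms: bool = False,
    ptm_model: PTMChargeModel = DEFAULT_PTM_MODEL,
    precision: float = 0.01,
) -> float:
    """pI of a :class:`~pishift.seqio.ProteinRecord` (mature sequence).

    With ``use_ptms`` off, the record's PTM annotations are ignored.
    """
    ptms = record.ptms if use_ptms else ()
    return sequence_pi(record.sequence, table=table, ptms=ptms, ptm_model=ptm_model, precision=precision)


def load_pka_table(path: str | Path) -> PKaTable:
    """Read an alternative pKa scale from a 3-column TSV.

    Columns: ``group`` (residue letter, ``nterm`` or ``cterm``), ``pka``,
    ``polarity`` (``acid``/``base``; ignored for the termini, which are
    always base/acid respectively).
    """
    residue_pka: dict[str, tuple[float, str]] = {}
    nterm = cterm = None
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"group", "pka", "polarity"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            missing = sorted(required - set(reader.fieldnames or []))
            raise ValueError(f"pKa table missing column(s): {', '.join(missing)}")
        for row in reader:
            group = row["group"].strip()
            pka = float(row["pka"])
            if group.lower() == "nterm":
                nterm = pka
            elif group.lower() == "cterm":
                cterm = pka
            else:
                if len(group) != 1:
                    raise ValueError(f"bad group label {group!r} in pKa table")
                residue_pka[group.upper()] = (pka, row["polarity"].strip().lower())
    if nterm is None or cterm is None:
        raise ValueError("pKa table must define both 'nterm' and 'cterm' rows")
    return PKaTable(residue_pka=residue_pka, nterm_pka=nterm, cterm_pka=cterm)
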