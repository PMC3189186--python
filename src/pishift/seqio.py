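"""Readers and writers for the external formats consumed by the analysis.

FASTA protein sets (with a ``family|species|id`` header convention),
aligned FASTA / Clustal alignments, and the small TSV side tables (signal
cleavage positions, PTM annotations, per-site selection statistics).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

from Bio import AlignIO, SeqIO

__all__ = [
    "VALID_RESIDUES",
    "ProteinRecord",
    "PTMAnnotation",
    "Alignment",
    "SelectionSiteRecord",
    "read_fasta",
    "write_fasta",
    "apply_signal_cleavage",
    "read_alignment",
    "extract_alignable_region",
    "read_selection_table",
    "read_cleavage_table",
    "read_ptm_table",
]

#: 20 standard residues plus the unknown placeholder X.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

PTM_KINDS = frozenset({"phospho", "glyco"})
PTM_EVIDENCE = frozenset({"experimental", "by_similarity", "potential"})

DEFAULT_HEADER_DELIMITER = "|"
GAP = "-"


@dataclass(frozen=True)
class PTMAnnotation:
    """A phosphorylation or glycosylation site on a mature sequence."""

    position: int  # 1-based index into the mature sequence
    kind: str
    evidence: str = "experimental"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"PTM position must be >= 1, got {self.position}")
        if self.kind not in PTM_KINDS:
            raise ValueError(f"PTM kind must be one of {sorted(PTM_KINDS)}, got {self.kind!r}")
        if self.evidence not in PTM_EVIDENCE:
            raise ValueError(
                f"PTM evidence must be one of {sorted(PTM_EVIDENCE)}, got {self.evidence!r}"
            )


@dataclass
class ProteinRecord:
    """One mature protein sequence with its species/family labels and PTMs."""

    id: str
    species: str
    family: str
    sequence: str
    ptms: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue(s) {''.join(sorted(bad))!r} "
                "(expected the 20 standard letters or X)"
            )
        for ptm in self.ptms:
            if ptm.position > len(self.sequence):
                raise ValueError(
                    f"record {self.id!r}: PTM position {ptm.position} beyond "
                    f"sequence length {len(self.sequence)}"
                )


@dataclass
class Alignment:
    """A multiple alignment keyed by species; all rows equally long."""

    rows: dict

    def __post_init__(self) -> None:
        lengths = {species: len(seq) for species, seq in self.rows.items()}
        if len(set(lengths.values())) > 1:
            detail = ", ".join(f"{sp}={n}" for sp, n in lengths.items())
            raise ValueError(f"alignment rows have unequal lengths: {detail}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()), ""))

    @property
    def species(self) -> list[str]:
        return list(self.rows)

    def ungapped(self, species: str) -> str:
        return self.rows[species].replace(GAP, "")


@dataclass(frozen=True)
class SelectionSiteRecord:
    """Per-alignment-site selection evidence (SLR-style)."""

    site: int  # 1-based alignment column
    omega: float
    pvalue: float
    note: str = ""

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError(f"site {self.site}: omega must be >= 0, got {self.omega}")
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError(f"site {self.site}: pvalue {self.pvalue} outside [0, 1]")


def _parse_header(header: str, delimiter: str) -> tuple[str, str, str]:
    """Split a FASTA header into (family, species, id)."""
    parts = header.split(delimiter)
    if len(parts) == 3:
        return parts[0], parts[1], parts[2]
    return "", "", header


def read_fasta(path: str | Path, delimiter: str = DEFAULT_HEADER_DELIMITER) -> list[ProteinRecord]:
    """Read protein records from FASTA.

    Headers are parsed as ``family|species|id`` (configurable delimiter);
    headers without three fields keep the whole header as the id.
    Sequences are uppercased and trailing/internal ``*`` stop symbols are
    stripped with a warning.  Characters outside the 21-letter alphabet
    raise a ``ValueError`` naming the offending record.
    """
    entries = list(SeqIO.parse(str(path), "fasta"))
    if not entries:
        raise ValueError(f"{path}: no FASTA records found")
    records = []
    for entry in entries:
        family, species, rec_id = _parse_header(entry.id, delimiter)
        seq = str(entry.seq).upper()
        if "*" in seq:
            warnings.warn(f"record {rec_id!r}: stripping '*' stop symbol(s)", stacklevel=2)
            seq = seq.replace("*", "")
        records.append(ProteinRecord(id=rec_id, species=species, family=family, sequence=seq))
    return records


def write_fasta(
    records: Sequence[ProteinRecord],
    path: str | Path,
    delimiter: str = DEFAULT_HEADER_DELIMITER,
    width: int = 60,
) -> None:
    """Write records with ``family|species|id`` headers (read_fasta inverse)."""
    with open(path, "w") as handle:
        for rec in records:
            if rec.family or rec.species:
                header = delimiter.join((rec.family, rec.species, rec.id))
            else:
                header = rec.id
            handle.write(f">{header}\n")
            for start in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[start : start + width] + "\n")


def apply_signal_cleavage(record: ProteinRecord, cleavage_pos: int) -> ProteinRecord:
    """Remove the signal peptide (residues 1..cleavage_pos).

    PTM positions shift by ``-cleavage_pos``; PTMs inside the removed
    prefix are dropped with a warning.  ``cleavage_pos = 0`` returns the
    record unchanged.
    """
    if cleavage_pos < 0:
        raise ValueError(f"record {record.id!r}: cleavage position must be >= 0")
    if cleavage_pos >= len(record.sequence):
        raise ValueError(
            f"record {record.id!r}: cleavage position {cleavage_pos} >= "
            f"sequence length {len(record.sequence)}"
        )
    if cleavage_pos == 0:
        return record
    kept, dropped = [], []
    for ptm in record.ptms:
        if ptm.position <= cleavage_pos:
            dropped.append(ptm)
        else:
            kept.append(replace(ptm, position=ptm.position - cleavage_pos))
    if dropped:
        warnings.warn(
            f"record {record.id!r}: dropped {len(dropped)} PTM(s) inside the signal peptide",
            stacklevel=2,
        )
    return ProteinRecord(
        id=record.id,
        species=record.species,
        family=record.family,
        sequence=record.sequence[cleavage_pos:],
        ptms=kept,
    )


def read_alignment(
    path: str | Path,
    format: str = "fasta",
    delimiter: str = DEFAULT_HEADER_DELIMITER,
) -> Alignment:
    """Read an aligned FASTA or Clustal file into an :class:`Alignment`.

    Row keys are the species field of three-part headers, otherwise the
    whole header.  Ragged rows raise a ``ValueError`` reporting lengths.
    """
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {format!r}")
    if format == "fasta":
        entries = list(SeqIO.parse(str(path), "fasta"))
    else:
        entries = list(AlignIO.read(str(path), "clustal"))
    if not entries:
        raise ValueError(f"{path}: no alignment rows found")
    rows: dict[str, str] = {}
    for entry in entries:
        _, species, rec_id = _parse_header(entry.id, delimiter)
        key = species or rec_id
        if key in rows:
            raise ValueError(f"{path}: duplicate alignment row for {key!r}")
        rows[key] = str(entry.seq).upper()
    return Alignment(rows=rows)


def extract_alignable_region(aln: Alignment, ref_species: str, other_species: str) -> str:
    """Residues of ``ref_species`` at columns where both species are non-gap."""
    for species in (ref_species, other_species):
        if species not in aln.rows:
            raise KeyError(f"species {species!r} not in alignment (have {aln.species})")
    ref_row = aln.rows[ref_species]
    other_row = aln.rows[other_species]
    return "".join(r for r, o in zip(ref_row, other_row) if r != GAP and o != GAP)


def read_selection_table(path: str | Path) -> list[SelectionSiteRecord]:
    """Read a per-site selection TSV with columns site, omega, pvalue.

    Extra columns are tolerated (a ``note`` column is carried through);
    records come back sorted by site; duplicate sites are an error.
    """
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        fields = set(reader.fieldnames or [])
        for column in ("site", "omega", "pvalue"):
            if column not in fields:
                raise ValueError(f"{path}: missing required column {column!r}")
        records = [
            SelectionSiteRecord(
                site=int(row["site"]),
                omega=float(row["omega"]),
                pvalue=float(row["pvalue"]),
                note=(row.get("note") or "").strip(),
            )
            for row in reader
        ]
    seen: set[int] = set()
    for rec in records:
        if rec.site in seen:
            raise ValueError(f"{path}: duplicate site {rec.site}")
        seen.add(rec.site)
    return sorted(records, key=lambda r: r.site)


def read_cleavage_table(path: str | Path) -> dict[str, int]:
    """Read a 2-column TSV (id, cleavage_pos) of signal-peptide lengths."""
    table: dict[str, int] = {}
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        fields = set(reader.fieldnames or [])
        for column in ("id", "cleavage_pos"):
            if column not in fields:
                raise ValueError(f"{path}: missing required column {column!r}")
        for row in reader:
            table[row["id"]] = int(row["cleavage_pos"])
    return table


def read_ptm_table(path: str | Path) -> dict[str, list[PTMAnnotation]]:
    """Read a PTM TSV (id, position, kind, evidence) grouped by record id."""
    table: dict[str, list[PTMAnnotation]] = {}
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        fields = set(reader.fieldnames or [])
        for column in ("id", "position", "kind"):
            if column not in fields:
                raise ValueError(f"{path}: missing required column {column!r}")
        for row in reader:
            ptm = PTMAnnotation(
                position=int(row["position"]),
                kind=row["kind"].strip(),
                evidence=(row.get("evidence") or "experimental").strip(),
            )
            table.setdefault(row["id"], []).append(ptm)
    return table
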