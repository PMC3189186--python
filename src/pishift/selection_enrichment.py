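"""Enrichment of positively selected sites among ionizable residues.

Classifies alignment columns as charge-affecting or neutral in a reference
species, calls selected sites from an SLR-style table, and runs a
one-sided exact test for over-representation of selected sites among the
ionizable residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats
from scipy.stats.contingency import odds_ratio as _exact_odds_ratio

from .seqio import Alignment, SelectionSiteRecord

__all__ = [
    "IONIZABLE_RESIDUES",
    "ContingencyTable",
    "EnrichmentResult",
    "classify_site_charge",
    "classify_alignment_charges",
    "call_selected_sites",
    "enrichment_test",
    "odds_ratio_ci",
]

#: Residues whose side chains carry an ionizable group.
IONIZABLE_RESIDUES = frozenset("RKHDECY")

CHARGED, NEUTRAL, GAP_CLASS = "charged", "neutral", "gap"


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: selection call (rows collapsed below) x charge class.

    a: selected & charged, b: not-selected & charged,
    c: selected & neutral, d: not-selected & neutral.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be >= 0")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_rows(self) -> list[list[int]]:
        """Rows charged/neutral, columns selected/not-selected."""
        return [[self.a, self.b], [self.c, self.d]]


@dataclass(frozen=True)
class EnrichmentResult:
    table: ContingencyTable
    frac_charged_selected: float
    frac_neutral_selected: float
    expected_random: float
    fisher_p: float
    odds_ratio: float
    test: str = "fisher"

    def as_dict(self) -> dict:
        return {
            "table": {"a": self.table.a, "b": self.table.b, "c": self.table.c, "d": self.table.d},
            "frac_charged_selected": self.frac_charged_selected,
            "frac_neutral_selected": self.frac_neutral_selected,
            "expected_random": self.expected_random,
            "pvalue": self.fisher_p,
            "odds_ratio": self.odds_ratio,
            "test": self.test,
        }


def classify_site_charge(aln: Alignment, ref_species: str, site: int) -> str:
    """'charged' / 'neutral' / 'gap' for one 1-based alignment column."""
    if ref_species not in aln.rows:
        raise KeyError(f"species {ref_species!r} not in alignment (have {aln.species})")
    if not 1 <= site <= aln.length:
        raise ValueError(f"site {site} outside alignment columns 1..{aln.length}")
    residue = aln.rows[ref_species][site - 1]
    if residue == "-":
        return GAP_CLASS
    return CHARGED if residue in IONIZABLE_RESIDUES else NEUTRAL


def classify_alignment_charges(aln: Alignment, ref_species: str) -> dict:
    """Charge class for every alignment column (1-based site -> class)."""
    return {
        site: classify_site_charge(aln, ref_species, site) for site in range(1, aln.length + 1)
    }


def call_selected_sites(records: Sequence[SelectionSiteRecord], alpha: float = 0.05) -> set:
    """Sites with pvalue <= alpha AND omega > 1."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return {rec.site for rec in records if rec.pvalue <= alpha and rec.omega > 1.0}


def enrichment_test(
    selected: Iterable[int],
    charge_classes: Mapping[int, str],
    test: str = "fisher",
) -> EnrichmentResult:
    """Test over-representation of selected sites among charged residues.

    Gap-class sites are excluded from both margins.  The default test is
    the one-sided Fisher exact test; ``test="chi2"`` substitutes the
    (two-sided) chi-square statistic for comparison.
    """
    if test not in ("fisher", "chi2"):
        raise ValueError(f"test must be 'fisher' or 'chi2', got {test!r}")
    selected = set(selected)
    unknown = selected - set(charge_classes)
    if unknown:
        raise ValueError(f"selected site(s) without a charge class: {sorted(unknown)}")
    a = b = c = d = 0
    for site, cls in charge_classes.items():
        if cls == GAP_CLASS:
            continue
        if cls == CHARGED:
            if site in selected:
                a += 1
            else:
                b += 1
        elif cls == NEUTRAL:
            if site in selected:
                c += 1
            else:
                d += 1
        else:
            raise ValueError(f"site {site}: unknown charge class {cls!r}")
    table = ContingencyTable(a, b, c, d)
    if table.total == 0:
        raise ValueError("no classified (non-gap) sites to test")

    if test == "fisher":
        sample_or, pvalue = stats.fisher_exact(table.as_rows(), alternative="greater")
    else:
        sample_or = _sample_odds_ratio(table)
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            pvalue = 1.0  # degenerate margin: chi-square undefined
        else:
            pvalue = float(stats.chi2_contingency(table.as_rows(), correction=True)[1])

    return EnrichmentResult(
        table=table,
        frac_charged_selected=a / (a + b) if a + b else 0.0,
        frac_neutral_selected=c / (c + d) if c + d else 0.0,
        expected_random=(a + c) / table.total,
        fisher_p=float(pvalue),
        odds_ratio=float(sample_or),
        test=test,
    )


def _sample_odds_ratio(table: ContingencyTable) -> float:
    num, den = table.a * table.d, table.b * table.c
    if den == 0:
        return float("inf") if num > 0 else float("nan")
    return num / den


def odds_ratio_ci(table: ContingencyTable, confidence_level: float = 0.95) -> tuple:
    """Exact (conditional MLE) confidence interval for the odds ratio."""
    result = _exact_odds_ratio(table.as_rows(), kind="conditional")
    interval = result.confidence_interval(confidence_level=confidence_level)
    return (float(interval.low), float(interval.high))
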