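"""LTR orientation, CGI-promoter association, differential LTR methylation,
methylation spreading, and the copy-filtering rules.

A gene has a CGI promoter when any CGI overlaps TSS +/- 1.5 kb. For
full-length elements the proximal LTR is the one whose nearest edge is
closer to the gene TSS (ties break to the 5' LTR, flagged). Orientation
bias is a one-sample proportion test against 0.5; CGI association between
the 5'- and 3'-proximal classes is a two-sample proportion test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .model import CgiInterval, ErvRecord, GeneRecord, distance_between
from .methylation import BisulfiteCloneSet, MethylationCall, methylation_fraction
from .stats import (
    DegenerateTableError,
    TestResult,
    mann_whitney,
    one_proportion_test,
    two_proportion_test,
)

__all__ = [
    "CGI_PROMOTER_WINDOW",
    "SPREADING_THRESHOLD",
    "LtrOrientationCall",
    "OrientationCgiSummary",
    "SpreadingAssessment",
    "CopyFilterRow",
    "CopyFilterReport",
    "classify_cgi_promoter",
    "annotate_cgi_promoters",
    "proximal_ltr",
    "orientation_cgi_table",
    "compare_ltr_methylation",
    "assess_spreading",
    "filter_copies",
]

CGI_PROMOTER_WINDOW = 1500
SPREADING_THRESHOLD = 0.10
DEFAULT_MAX_TSS = 3

FILTER_REASONS = ("no_est_or_expression_data", "gene_misannotated",
                  "too_many_tss", "inside_upstream_gene")


@dataclass(frozen=True)
class LtrOrientationCall:
    erv_id: str
    gene_id: str
    proximal_ltr: str  # "5prime" | "3prime"
    distance_to_tss: int
    promoter_is_cgi: Optional[bool] = None
    tie: bool = False

    def __post_init__(self) -> None:
        if self.proximal_ltr not in ("5prime", "3prime"):
            raise ValueError(f"bad proximal_ltr {self.proximal_ltr!r}")
        if self.distance_to_tss < 0:
            raise ValueError("distance must be >= 0")


@dataclass(frozen=True)
class OrientationCgiSummary:
    n_5prime: int
    n_3prime: int
    cgi_5prime: int
    cgi_3prime: int
    orientation_test: Optional[TestResult]
    association_test: Optional[TestResult]
    flags: Tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.n_5prime + self.n_3prime


@dataclass(frozen=True)
class SpreadingAssessment:
    erv_id: str
    gene_id: str
    erv_methylation: float
    promoter_methylation: float
    distance_to_tss: int
    cgi: Optional[bool]
    tissue: str
    spreading_call: bool


@dataclass(frozen=True)
class CopyFilterRow:
    erv_id: str
    passed: bool
    reasons: Tuple[str, ...]

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must hold exactly when no reasons are present")


@dataclass(frozen=True)
class CopyFilterReport:
    rows: Tuple[CopyFilterRow, ...]

    @property
    def passed_ids(self) -> Tuple[str, ...]:
        return tuple(r.erv_id for r in self.rows if r.passed)

    def counts_by_reason(self) -> Dict[str, int]:
        counts = {r: 0 for r in FILTER_REASONS}
        for row in self.rows:
            for reason in row.reasons:
                counts[reason] += 1
        return counts


def classify_cgi_promoter(gene: GeneRecord, cgis: Sequence[CgiInterval],
                          window: int = CGI_PROMOTER_WINDOW) -> bool:
    """True iff any CGI overlaps [tss - window, tss + window) (half-open)."""
    lo, hi = gene.tss - window, gene.tss + window
    return any(c.chrom == gene.chrom and c.start < hi and c.end > lo for c in cgis)


def annotate_cgi_promoters(genes: Sequence[GeneRecord], cgis: Sequence[CgiInterval],
                           window: int = CGI_PROMOTER_WINDOW) -> List[GeneRecord]:
    return [replace(g, promoter_is_cgi=classify_cgi_promoter(g, cgis, window))
            for g in genes]


def proximal_ltr(erv: ErvRecord, gene: GeneRecord) -> LtrOrientationCall:
    """Which LTR of a full-length element lies closer to the gene TSS."""
    if erv.element_type != "full_length":
        raise ValueError(f"ERV {erv.erv_id}: proximal LTR undefined for solo elements")
    if erv.chrom != gene.chrom:
        raise ValueError(f"ERV {erv.erv_id} and gene {gene.gene_id} on different chromosomes")
    d5 = distance_between(erv.ltr5, gene.tss)
    d3 = distance_between(erv.ltr3, gene.tss)
    tie = d5 == d3
    which = "5prime" if d5 <= d3 else "3prime"
    return LtrOrientationCall(erv.erv_id, gene.gene_id, which, min(d5, d3),
                              promoter_is_cgi=gene.promoter_is_cgi, tie=tie)


def orientation_cgi_table(calls: Sequence[LtrOrientationCall]) -> OrientationCgiSummary:
    """Counts plus the two headline tests: orientation bias against 0.5 and
    CGI-promoter association between the 5'- and 3'-proximal classes."""
    if not calls:
        raise ValueError("no orientation calls")
    five = [c for c in calls if c.proximal_ltr == "5prime"]
    three = [c for c in calls if c.proximal_ltr == "3prime"]
    cgi5 = sum(1 for c in five if c.promoter_is_cgi)
    cgi3 = sum(1 for c in three if c.promoter_is_cgi)
    flags: List[str] = []
    orientation: Optional[TestResult] = None
    association: Optional[TestResult] = None
    if not five or not three:
        flags.append("degenerate_orientation")
    orientation = one_proportion_test(len(five), len(calls), 0.5, continuity=True)
    if five and three:
        try:
            association = two_proportion_test(cgi5, len(five), cgi3, len(three),
                                              continuity=True)
        except DegenerateTableError:
            flags.append("degenerate_association")
    else:
        flags.append("degenerate_association")
    if any(c.tie for c in calls):
        flags.append("ties_present")
    return OrientationCgiSummary(len(five), len(three), cgi5, cgi3,
                                 orientation, association, tuple(flags))


def compare_ltr_methylation(ltr5_clones: BisulfiteCloneSet,
                            ltr3_clones: BisulfiteCloneSet,
                            method: str = "auto") -> TestResult:
    """Mann-Whitney U on per-clone methylated fractions of the two LTRs.

    Both clone sets are expected to have passed conversion QC and dedup.
    """
    if not ltr5_clones.clones or not ltr3_clones.clones:
        raise ValueError("both LTR clone sets must be non-empty after QC")
    a = [c.fraction_methylated for c in ltr5_clones.clones]
    b = [c.fraction_methylated for c in ltr3_clones.clones]
    return mann_whitney(a, b, method=method)


def assess_spreading(erv_call: MethylationCall, promoter_set: BisulfiteCloneSet,
                     distance_to_tss: int, cgi: Optional[bool],
                     threshold: float = SPREADING_THRESHOLD) -> SpreadingAssessment:
    """Spreading is called iff the ERV is methylated and the promoter's
    methylated-CpG fraction reaches the threshold (boundary inclusive)."""
    if erv_call.tissue != promoter_set.tissue:
        raise ValueError(
            f"tissue mismatch: ERV call in {erv_call.tissue!r}, "
            f"promoter clones in {promoter_set.tissue!r}")
    promoter = methylation_fraction(promoter_set)
    spreading = (erv_call.call == "methylated"
                 and promoter.fraction >= threshold)
    erv_level = erv_call.fraction if erv_call.fraction is not None else erv_call.score
    return SpreadingAssessment(
        erv_id=erv_call.region_id, gene_id=promoter_set.region_id,
        erv_methylation=erv_level, promoter_methylation=promoter.fraction,
        distance_to_tss=distance_to_tss, cgi=cgi, tissue=erv_call.tissue,
        spreading_call=bool(spreading))


REQUIRED_EVIDENCE_COLUMNS = ("erv_id", "est_or_expression_available",
                             "gene_annotation_ok", "tss_count", "inside_upstream_gene")


def filter_copies(evidence, max_tss: int = DEFAULT_MAX_TSS) -> CopyFilterReport:
    """Apply the copy-selection rules to a per-copy evidence table.

    ``evidence`` is a pandas DataFrame with columns: erv_id,
    est_or_expression_available (bool), gene_annotation_ok (bool),
    tss_count (int), inside_upstream_gene (bool). Copies with more than
    ``max_tss`` TSSs at the associated gene are excluded.
    """
    for col in REQUIRED_EVIDENCE_COLUMNS:
        if col not in evidence.columns:
            raise KeyError(f"evidence table missing required column {col!r}")
    rows: List[CopyFilterRow] = []
    for rec in evidence.to_dict("records"):
        reasons: List[str] = []
        if not rec["est_or_expression_available"]:
            reasons.append("no_est_or_expression_data")
        if not rec["gene_annotation_ok"]:
            reasons.append("gene_misannotated")
        if int(rec["tss_count"]) > max_tss:
            reasons.append("too_many_tss")
        if rec["inside_upstream_gene"]:
            reasons.append("inside_upstream_gene")
        rows.append(CopyFilterRow(str(rec["erv_id"]), not reasons, tuple(reasons)))
    return CopyFilterReport(tuple(rows))
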