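"""Domain types for the ERV-gene analysis pipeline.

All coordinates are 0-based, half-open intervals (BED convention).
TSS and TTS are point coordinates at the strand-appropriate gene edge.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ValidationError",
    "DifferentChromosomesError",
    "GenomeModel",
    "GeneRecord",
    "CgiInterval",
    "ErvRecord",
    "SignalTrack",
    "ExpressionTable",
    "distance_between",
]

ERV_FAMILIES = ("ETn/MusD", "IAP")
ELEMENT_TYPES = ("solo", "full_length")
POLYMORPHISM_STATES = ("fixed", "polymorphic")


class ValidationError(ValueError):
    """Raised when a record violates its structural invariants."""


class DifferentChromosomesError(ValueError):
    """Raised when a distance is requested across chromosomes."""


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome names and lengths; the coordinate universe for simulation."""

    chromosomes: Tuple[Tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if not isinstance(length, (int, np.integer)) or length < 1:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "chromosomes", tuple((str(n), int(L)) for n, L in self.chromosomes))

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def lengths(self) -> Tuple[int, ...]:
        return tuple(L for _, L in self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(self.lengths)

    def length_of(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)


@dataclass(frozen=True)
class GeneRecord:
    """A gene reduced to its TSS/TTS anchors.

    On the + strand ``tss < tts``; on the - strand ``tss > tts`` in genomic
    coordinates. ``promoter_is_cgi`` is filled in downstream by CGI overlap
    classification and is None until then.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    promoter_is_cgi: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.tss == self.tts:
            raise ValidationError(f"gene {self.gene_id}: tss == tts")
        if self.strand == "+" and self.tss > self.tts:
            raise ValidationError(f"gene {self.gene_id}: + strand requires tss < tts")
        if self.strand == "-" and self.tss < self.tts:
            raise ValidationError(f"gene {self.gene_id}: - strand requires tss > tts")

    @property
    def start(self) -> int:
        return min(self.tss, self.tts)

    @property
    def end(self) -> int:
        return max(self.tss, self.tts)


@dataclass(frozen=True)
class CgiInterval:
    """A CpG island interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"CGI {self.chrom}:{self.start}-{self.end}: start must be < end")


@dataclass(frozen=True)
class ErvRecord:
    """One ERV copy with optional LTR substructure.

    A full-length element carries two disjoint LTR intervals inside its span,
    ordered by strand (5' LTR leftmost on +, rightmost on -). A solo element
    is a single LTR spanning the whole record.
    """

    erv_id: str
    family: str
    element_type: str
    chrom: str
    start: int
    end: int
    strand: str
    ltr5: Optional[Tuple[int, int]] = None
    ltr3: Optional[Tuple[int, int]] = None
    fixed_or_polymorphic: str = "fixed"

    def __post_init__(self) -> None:
        eid = self.erv_id
        if self.family not in ERV_FAMILIES:
            raise ValidationError(f"ERV {eid}: unknown family {self.family!r}")
        if self.element_type not in ELEMENT_TYPES:
            raise ValidationError(f"ERV {eid}: unknown element_type {self.element_type!r}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"ERV {eid}: strand must be '+' or '-'")
        if not self.start < self.end:
            raise ValidationError(f"ERV {eid}: start must be < end")
        if self.fixed_or_polymorphic not in POLYMORPHISM_STATES:
            raise ValidationError(f"ERV {eid}: bad polymorphism state {self.fixed_or_polymorphic!r}")
        if self.element_type == "full_length":
            if self.ltr5 is None or self.ltr3 is None:
                raise ValidationError(f"ERV {eid}: full-length element requires both LTRs")
            for name, (s, e) in (("ltr5", self.ltr5), ("ltr3", self.ltr3)):
                if not (self.start <= s < e <= self.end):
                    raise ValidationError(f"ERV {eid}: {name} [{s},{e}) outside element span")
            if not (self.ltr5[1] <= self.ltr3[0] or self.ltr3[1] <= self.ltr5[0]):
                raise ValidationError(f"ERV {eid}: LTR intervals overlap")
            if self.strand == "+" and not self.ltr5[0] < self.ltr3[0]:
                raise ValidationError(f"ERV {eid}: + strand requires 5' LTR left of 3' LTR")
            if self.strand == "-" and not self.ltr5[0] > self.ltr3[0]:
                raise ValidationError(f"ERV {eid}: - strand requires 5' LTR right of 3' LTR")
        else:  # solo
            present = [x for x in (self.ltr5, self.ltr3) if x is not None]
            if len(present) != 1:
                raise ValidationError(f"ERV {eid}: solo element requires exactly one LTR")
            if present[0] != (self.start, self.end):
                raise ValidationError(f"ERV {eid}: solo LTR must span the whole element")

    @property
    def solo_ltr(self) -> Tuple[int, int]:
        if self.element_type != "solo":
            raise ValidationError(f"ERV {self.erv_id}: not a solo element")
        return self.ltr5 if self.ltr5 is not None else self.ltr3  # type: ignore[return-value]


class SignalTrack:
    """Sorted, non-overlapping per-chromosome signal intervals (bedGraph model).

    Positions not covered by any interval read back as 0.
    """

    def __init__(self, intervals: Iterable[Tuple[str, int, int, float]]):
        per_chrom: dict = {}
        for chrom, start, end, value in intervals:
            if not start < end:
                raise ValidationError(f"signal interval {chrom}:{start}-{end} empty")
            if not np.isfinite(value):
                raise ValidationError(f"signal value at {chrom}:{start}-{end} not finite")
            per_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        self._starts: dict = {}
        self._ends: dict = {}
        self._values: dict = {}
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            for (s0, e0, _), (s1, e1, _) in zip(ivs, ivs[1:]):
                if s1 < e0:
                    raise ValidationError(
                        f"overlapping signal intervals on {chrom}: [{s0},{e0}) and [{s1},{e1})"
                    )
            self._starts[chrom] = np.array([s for s, _, _ in ivs], dtype=np.int64)
            self._ends[chrom] = np.array([e for _, e, _ in ivs], dtype=np.int64)
            self._values[chrom] = np.array([v for _, _, v in ivs], dtype=float)

    @property
    def chromosomes(self) -> Tuple[str, ...]:
        return tuple(sorted(self._starts))

    def intervals(self) -> Iterable[Tuple[str, int, int, float]]:
        for chrom in self.chromosomes:
            for s, e, v in zip(self._starts[chrom], self._ends[chrom], self._values[chrom]):
                yield chrom, int(s), int(e), float(v)

    def query(self, chrom: str, pos: int) -> float:
        """Signal at a single base; 0.0 outside covered intervals."""
        if chrom not in self._starts:
            return 0.0
        i = int(np.searchsorted(self._starts[chrom], pos, side="right")) - 1
        if i >= 0 and pos < self._ends[chrom][i]:
            return float(self._values[chrom][i])
        return 0.0

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        """Overlap-weighted mean signal over [start, end); gaps count as 0."""
        if end <= start:
            return self.query(chrom, start)
        if chrom not in self._starts:
            return 0.0
        starts, ends, values = self._starts[chrom], self._ends[chrom], self._values[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        return float(np.sum(ov * values[lo:hi]) / (end - start))


class ExpressionTable:
    """Binary expression state per (gene, tissue); a total function."""

    def __init__(self, states: Mapping[Tuple[str, str], bool],
                 genes: Sequence[str], tissues: Sequence[str]):
        self.genes = tuple(genes)
        self.tissues = tuple(tissues)
        for g in self.genes:
            for t in self.tissues:
                if (g, t) not in states:
                    raise ValidationError(f"missing expression state for ({g}, {t})")
        self._states = {k: bool(v) for k, v in states.items()}

    def is_expressed(self, gene_id: str, tissue: str) -> bool:
        return self._states[(gene_id, tissue)]

    def expressed_tissues(self, gene_id: str) -> Tuple[str, ...]:
        return tuple(t for t in self.tissues if self._states[(gene_id, t)])

    def items(self):
        return self._states.items()


def distance_between(interval: Tuple[int, int], point: int) -> int:
    """Unsigned distance from a half-open interval [start, end) to a point.

    0 when the point lies inside the interval; otherwise the gap from the
    nearer edge: ``start - point`` on the left, ``point - end`` on the right
    (half-open edge arithmetic, so a point one base left of ``start`` is at
    distance 1 while a point at ``end`` is at distance 0).
    """
    start, end = interval
    if start <= point < end:
        return 0
    if point < start:
        return start - point
    return point - end
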