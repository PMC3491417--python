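"""Orientation-normalized chromatin-signal profiles over ERV-gene
intervening regions.

Each region spans from the gene-proximal ERV edge to the gene TSS, extended
by a fixed flank on both sides. Signal is sampled as overlap-weighted means
over n_points equal windows along the TE -> TSS axis; rows whose TE lies to
the right genomically are flipped so the TE is always the left end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import ErvRecord, GeneRecord, SignalTrack

__all__ = [
    "DEFAULT_FLANK",
    "FALLBACK_FLANK",
    "InterveningRegion",
    "ProfileMatrix",
    "intervening_region",
    "choose_flank",
    "extract_profile",
    "orient_and_average",
    "chip_enrichment",
]

DEFAULT_FLANK = 400
FALLBACK_FLANK = 200
DEFAULT_N_POINTS = 100


@dataclass(frozen=True)
class InterveningRegion:
    """The sequence between an ERV's gene-proximal edge and a gene TSS."""

    erv_id: str
    gene_id: str
    chrom: str
    te_edge: int
    tss: int
    orientation: str  # te_left | te_right (genomic position of the TE)
    zero_length: bool = False

    def __post_init__(self) -> None:
        if self.orientation not in ("te_left", "te_right"):
            raise ValueError(f"bad orientation {self.orientation!r}")

    @property
    def span(self) -> Tuple[int, int]:
        return (min(self.te_edge, self.tss), max(self.te_edge, self.tss))

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]


@dataclass
class ProfileMatrix:
    """Per-region signal rows on a common TE -> TSS axis (TE at the left)."""

    rows: np.ndarray  # shape (n_regions, n_points)
    mark: str
    flank: int
    region_ids: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.rows = np.atleast_2d(np.asarray(self.rows, dtype=float))
        if self.region_ids and len(self.region_ids) != self.rows.shape[0]:
            raise ValueError("region_ids length does not match row count")

    @property
    def n_points(self) -> int:
        return self.rows.shape[1]

    @property
    def mean_profile(self) -> np.ndarray:
        return self.rows.mean(axis=0)

    @property
    def sd_profile(self) -> np.ndarray:
        return self.rows.std(axis=0, ddof=0)


def intervening_region(erv: ErvRecord, gene: GeneRecord) -> InterveningRegion:
    """Region between the gene-proximal ERV edge and the TSS; zero-length
    (flagged) when the ERV overlaps the TSS."""
    if erv.chrom != gene.chrom:
        raise ValueError(f"ERV {erv.erv_id} and gene {gene.gene_id} on different chromosomes")
    tss = gene.tss
    if erv.start <= tss < erv.end:
        return InterveningRegion(erv.erv_id, gene.gene_id, erv.chrom, tss, tss,
                                 "te_left", zero_length=True)
    if erv.end <= tss:
        return InterveningRegion(erv.erv_id, gene.gene_id, erv.chrom, erv.end, tss, "te_left")
    return InterveningRegion(erv.erv_id, gene.gene_id, erv.chrom, erv.start, tss, "te_right")


def choose_flank(regions: Sequence[InterveningRegion],
                 preferred: int = DEFAULT_FLANK,
                 fallback: int = FALLBACK_FLANK,
                 min_length: Optional[int] = None) -> int:
    """Common flank for a region set: the preferred flank unless some region
    is too short to support it, then the fallback (regions shorter than the
    fallback are tolerated as documented exceptions)."""
    limit = min_length if min_length is not None else preferred
    if all(r.length >= limit for r in regions):
        return preferred
    return fallback


def extract_profile(region: InterveningRegion, track: SignalTrack,
                    flank: int = DEFAULT_FLANK,
                    n_points: int = DEFAULT_N_POINTS) -> Tuple[np.ndarray, List[str]]:
    """Sample the signal at n_points equal windows across
    [te_edge - flank, tss + flank] in the TE -> TSS direction.

    Windows are overlap-weighted bedGraph means; gaps read 0. Windows
    extending below coordinate 0 are truncated with a flag. Returns the
    profile row and any flags.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    flags: List[str] = []
    if region.zero_length:
        flags.append("zero_length_region")
    lo = region.span[0] - flank
    hi = region.span[1] + flank
    if lo < 0:
        flags.append("flank_truncated")
        lo = 0
    edges = np.linspace(lo, hi, n_points + 1)
    row = np.array([track.window_mean(region.chrom,
                                      int(math.floor(edges[i])),
                                      int(math.ceil(edges[i + 1])))
                    for i in range(n_points)])
    if region.orientation == "te_right":
        row = row[::-1].copy()
    return row, flags


def orient_and_average(rows: Sequence[np.ndarray], orientations: Sequence[str],
                       mark: str, flank: int = DEFAULT_FLANK,
                       region_ids: Sequence[str] = (),
                       pre_oriented: bool = False) -> ProfileMatrix:
    """Stack rows into a ProfileMatrix, flipping te_right rows so the TE is
    at the left end (``pre_oriented`` rows, e.g. from extract_profile, are
    already flipped and pass through unchanged)."""
    if not len(rows):
        raise ValueError("need at least one profile row")
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise ValueError(f"rows have mixed lengths {sorted(lengths)}")
    if len(orientations) != len(rows):
        raise ValueError("one orientation per row required")
    out = []
    for row, orient in zip(rows, orientations):
        if orient not in ("te_left", "te_right"):
            raise ValueError(f"bad orientation {orient!r}")
        row = np.asarray(row, dtype=float)
        if orient == "te_right" and not pre_oriented:
            row = row[::-1]
        out.append(row)
    return ProfileMatrix(np.vstack(out), mark=mark, flank=flank,
                         region_ids=tuple(region_ids))


def chip_enrichment(ct_input: float, ct_ip: float, efficiency: float) -> float:
    """ChIP-qPCR enrichment: efficiency ** (Ct_input - Ct_IP); no spike
    normalization."""
    if not (math.isfinite(ct_input) and math.isfinite(ct_ip)):
        raise ValueError("Ct values must be finite")
    if efficiency <= 1:
        raise ValueError(f"efficiency must exceed 1, got {efficiency}")
    return efficiency ** (ct_input - ct_ip)
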