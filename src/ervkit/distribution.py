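"""Expected-vs-observed ERV distance distributions and depletion-zone
detection.

The expected distribution comes from repeated uniform random insertion over
the genome (chromosome chosen proportional to length), distances to the
nearest TSS/TTS anchor binned and averaged over replicates. Each bin is
compared with the observed distribution by a proportion-equality test, and
the depletion threshold is the lower boundary of the first (smallest
distance) bin that is not significant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import ErvRecord, GeneRecord, GenomeModel, distance_between
from .stats import DegenerateTableError, TestResult, two_proportion_test

__all__ = [
    "BinResult",
    "DistanceDistribution",
    "anchor_positions",
    "simulate_expected",
    "observed_distances",
    "bin_distances",
    "per_bin_tests",
    "detect_threshold",
    "distribution_analysis",
]

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 500
DEFAULT_MAX_DIST = 10_000
DEFAULT_N = 1_000_000
DEFAULT_REPS = 3


@dataclass(frozen=True)
class BinResult:
    lo: int
    hi: int
    observed: int
    expected: float
    test: Optional[TestResult]
    degenerate: bool = False

    @property
    def p_value(self) -> float:
        return self.test.p_value if self.test is not None else math.nan

    @property
    def stars(self) -> str:
        return self.test.stars if self.test is not None else ""


@dataclass
class DistanceDistribution:
    anchor: str
    family: str
    bin_width: int
    bins: List[BinResult]
    n_observed: int
    n_expected_total: int
    threshold: Optional[int] = None
    threshold_flags: Tuple[str, ...] = ()

    def to_rows(self) -> List[Dict]:
        rows = []
        for b in self.bins:
            rows.append({
                "anchor": self.anchor, "family": self.family,
                "lo": b.lo, "hi": b.hi,
                "observed": b.observed, "expected": round(b.expected, 3),
                "obs_prop": b.observed / self.n_observed if self.n_observed else math.nan,
                "exp_prop": b.expected / self.n_expected_total if self.n_expected_total else math.nan,
                "statistic": b.test.statistic if b.test else math.nan,
                "p_value": b.p_value,
                "stars": b.stars,
                "degenerate": b.degenerate,
            })
        return rows


def anchor_positions(genes: Sequence[GeneRecord], anchor: str) -> Dict[str, np.ndarray]:
    """Sorted anchor coordinates (TSS or TTS) per chromosome."""
    if anchor not in ("tss", "tts"):
        raise ValueError(f"anchor must be 'tss' or 'tts', got {anchor!r}")
    per_chrom: Dict[str, List[int]] = {}
    for g in genes:
        per_chrom.setdefault(g.chrom, []).append(g.tss if anchor == "tss" else g.tts)
    return {c: np.sort(np.array(v, dtype=np.int64)) for c, v in per_chrom.items()}


def _nearest_distances(anchors: np.ndarray, points: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(anchors, points)
    left = np.where(idx > 0,
                    np.abs(points - anchors[np.maximum(idx - 1, 0)]), np.iinfo(np.int64).max)
    right = np.where(idx < anchors.size,
                     np.abs(anchors[np.minimum(idx, anchors.size - 1)] - points),
                     np.iinfo(np.int64).max)
    return np.minimum(left, right)


def bin_distances(distances: np.ndarray, bin_width: int, max_dist: int) -> np.ndarray:
    """Counts per contiguous bin [0,w), [w,2w) ... up to max_dist."""
    n_bins = max_dist // bin_width
    d = np.asarray(distances)
    d = d[(d >= 0) & (d < n_bins * bin_width)]
    return np.bincount((d // bin_width).astype(np.int64), minlength=n_bins)[:n_bins]


def simulate_expected(genome: GenomeModel, genes: Sequence[GeneRecord], anchor: str,
                      n: int = DEFAULT_N, reps: int = DEFAULT_REPS, seed: int = 0,
                      bin_width: int = DEFAULT_BIN_WIDTH,
                      max_dist: int = DEFAULT_MAX_DIST) -> np.ndarray:
    """Per-bin expected counts: ``reps`` replicates of ``n`` uniform random
    insertion points, binned by nearest-anchor distance, then averaged."""
    if n < 1 or reps < 1:
        raise ValueError("n and reps must be >= 1")
    if not genes:
        raise ValueError("cannot simulate expected distribution with no genes")
    anchors = anchor_positions(genes, anchor)
    rng = np.random.default_rng(seed)
    lengths = np.array(genome.lengths, dtype=np.int64)
    cum = np.cumsum(lengths)
    per_rep = []
    for _ in range(reps):
        offsets = rng.integers(0, cum[-1], size=n)
        chrom_idx = np.searchsorted(cum, offsets, side="right")
        positions = offsets - (cum[chrom_idx] - lengths[chrom_idx])
        counts = np.zeros(max_dist // bin_width, dtype=np.int64)
        for ci, name in enumerate(genome.names):
            if name not in anchors:
                continue
            pts = positions[chrom_idx == ci]
            if pts.size:
                counts += bin_distances(_nearest_distances(anchors[name], pts),
                                        bin_width, max_dist)
        per_rep.append(counts)
    return np.mean(per_rep, axis=0)


def observed_distances(ervs: Sequence[ErvRecord], genes: Sequence[GeneRecord],
                       anchor: str) -> List[Tuple[str, int, str]]:
    """Unsigned edge distance of each ERV to its nearest anchor, with a
    position class relative to the chosen gene.

    Ties between equidistant anchors resolve to the lower coordinate. ERVs
    on chromosomes with no genes are excluded with a logged warning.
    """
    anchors = anchor_positions(genes, anchor)
    by_anchor: Dict[Tuple[str, int], GeneRecord] = {}
    for g in genes:
        pos = g.tss if anchor == "tss" else g.tts
        key = (g.chrom, pos)
        if key not in by_anchor or g.gene_id < by_anchor[key].gene_id:
            by_anchor[key] = g
    out = []
    for erv in ervs:
        arr = anchors.get(erv.chrom)
        if arr is None or arr.size == 0:
            logger.warning("ERV %s on chromosome %s with no genes; excluded",
                           erv.erv_id, erv.chrom)
            continue
        i = int(np.searchsorted(arr, erv.start))
        j = int(np.searchsorted(arr, erv.end - 1, side="right"))
        cands = {int(arr[k]) for k in range(max(i - 1, 0), min(j + 1, arr.size))}
        best = min(cands, key=lambda a: (distance_between((erv.start, erv.end), a), a))
        dist = distance_between((erv.start, erv.end), best)
        gene = by_anchor[(erv.chrom, best)]
        mid = (erv.start + erv.end) // 2
        if gene.start <= mid < gene.end:
            pos_class = "inside"
        elif (mid < gene.start) == (gene.strand == "+"):
            pos_class = "upstream"
        else:
            pos_class = "downstream"
        out.append((erv.erv_id, int(dist), pos_class))
    return out


def per_bin_tests(observed_counts: np.ndarray, n_observed: int,
                  expected_counts: np.ndarray, n_expected: int,
                  anchor: str = "tss", family: str = "all",
                  bin_width: int = DEFAULT_BIN_WIDTH,
                  continuity: bool = True) -> DistanceDistribution:
    """Per-bin proportion-equality tests of observed vs expected counts.

    Denominators are all observed copies and all simulated insertions
    (including those beyond the binned window). Expected counts enter as
    round(average); degenerate bins (both zero) carry a flag and no test.
    """
    if len(observed_counts) != len(expected_counts):
        raise ValueError("observed and expected binnings differ")
    bins: List[BinResult] = []
    for k, (obs, exp) in enumerate(zip(observed_counts, expected_counts)):
        lo, hi = k * bin_width, (k + 1) * bin_width
        try:
            test = two_proportion_test(int(obs), n_observed, int(round(exp)),
                                       n_expected, continuity=continuity)
            bins.append(BinResult(lo, hi, int(obs), float(exp), test))
        except DegenerateTableError:
            bins.append(BinResult(lo, hi, int(obs), float(exp), None, degenerate=True))
    return DistanceDistribution(anchor=anchor, family=family, bin_width=bin_width,
                                bins=bins, n_observed=n_observed,
                                n_expected_total=n_expected)


def detect_threshold(dist: DistanceDistribution, alpha: float = 0.05) -> Optional[int]:
    """Depletion threshold: lower boundary of the first non-significant bin.

    Degenerate bins count as non-significant. A non-significant first bin
    yields threshold 0 with flag ``no_depletion``; all bins significant
    yields the window end with flag ``all_significant``. Significant bins
    occurring beyond the threshold are flagged ``non_monotone``.
    """
    flags: List[str] = []
    threshold: Optional[int] = None
    for k, b in enumerate(dist.bins):
        significant = (not b.degenerate) and b.p_value < alpha
        if not significant:
            threshold = b.lo
            if any((not later.degenerate) and later.p_value < alpha
                   for later in dist.bins[k + 1:]):
                flags.append("non_monotone")
            break
    if threshold is None:
        threshold = dist.bins[-1].hi if dist.bins else 0
        flags.append("all_significant")
    elif threshold == 0:
        flags.append("no_depletion")
    dist.threshold = threshold
    dist.threshold_flags = tuple(flags)
    return threshold


def distribution_analysis(ervs: Sequence[ErvRecord], genes: Sequence[GeneRecord],
                          genome: GenomeModel, anchor: str = "tss",
                          family: Optional[str] = None,
                          bin_width: int = DEFAULT_BIN_WIDTH,
                          max_dist: int = DEFAULT_MAX_DIST,
                          n: int = DEFAULT_N, reps: int = DEFAULT_REPS,
                          seed: int = 0, alpha: float = 0.05) -> DistanceDistribution:
    """End-to-end: observed binning, expected simulation, per-bin tests,
    threshold detection, for one family (or all)."""
    subset = [e for e in ervs if family is None or e.family == family]
    obs = observed_distances(subset, genes, anchor)
    obs_counts = bin_distances(np.array([d for _, d, _ in obs], dtype=np.int64),
                               bin_width, max_dist)
    exp_counts = simulate_expected(genome, genes, anchor, n=n, reps=reps, seed=seed,
                                   bin_width=bin_width, max_dist=max_dist)
    dist = per_bin_tests(obs_counts, len(obs), exp_counts, n,
                         anchor=anchor, family=family or "all", bin_width=bin_width)
    detect_threshold(dist, alpha=alpha)
    return dist
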