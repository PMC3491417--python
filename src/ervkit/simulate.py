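"""Synthetic input generators for every stage of the pipeline.

Every generator is deterministic under ``SimulationConfig.seed`` (each one
derives its own child seed, so generators can be called independently and
still reproduce what a full run would have produced). Generators emit the
exact formats the readers in :mod:`ervkit.io` consume, plus ground-truth
sidecars (true methylation levels, PCR-duplicate identities, selection
parameters) so downstream stages can be tested as parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .model import (
    CgiInterval,
    ErvRecord,
    ExpressionTable,
    GeneRecord,
    GenomeModel,
    SignalTrack,
    distance_between,
)
from .methylation import BisulfiteCloneSet, Clone
from . import io as eio

__all__ = [
    "CapacityError",
    "SelectionModel",
    "MethylationModel",
    "BisulfiteModel",
    "CtModel",
    "SignalModel",
    "ErvModel",
    "SimulationConfig",
    "make_genome_and_genes",
    "sample_insertions",
    "simulate_bisulfite_clones",
    "clones_to_reads",
    "make_bisulfite_reference",
    "simulate_ct_table",
    "simulate_signal_tracks",
    "write_simulation",
]

DEFAULT_TISSUES = ("liver", "spleen", "kidney", "pancreas", "testis")
FAMILY_TAGS = {"ETn/MusD": "ETn", "IAP": "IAP"}


class CapacityError(RuntimeError):
    """Requested feature density cannot be placed without overlap."""


@dataclass(frozen=True)
class SelectionModel:
    """Retention probability of an insertion as a function of its
    edge-distance to the nearest TSS."""

    kind: str = "none"  # none | hard_exclusion | logistic
    d_sel: int = 1500       # hard_exclusion: reject everything closer than this
    d50: int = 1500         # logistic: distance of 50% retention
    slope: float = 0.005    # logistic: steepness per base

    def retention_probability(self, distance: np.ndarray) -> np.ndarray:
        distance = np.asarray(distance, dtype=float)
        if self.kind == "none":
            return np.ones_like(distance)
        if self.kind == "hard_exclusion":
            return (distance >= self.d_sel).astype(float)
        if self.kind == "logistic":
            return 1.0 / (1.0 + np.exp(-self.slope * (distance - self.d50)))
        raise ValueError(f"unknown selection kind {self.kind!r}")


@dataclass(frozen=True)
class MethylationModel:
    """Family baselines plus the near-TSS hypomethylation rule."""

    family_baseline: Dict[str, float] = field(
        default_factory=lambda: {"ETn/MusD": 0.85, "IAP": 0.95})
    near_tss_unmethylated_families: Tuple[str, ...] = ("ETn/MusD",)
    near_tss_distance: int = 1500
    near_tss_level: float = 0.05
    promoter_level: float = 0.01
    copy_level_sd: float = 0.05


@dataclass(frozen=True)
class BisulfiteModel:
    clones_per_region: int = 20
    cpgs_per_region: int = 20
    conversion_failure_rate: float = 0.01
    duplicate_rate: float = 0.0
    region_length: int = 400


@dataclass(frozen=True)
class CtModel:
    base_ct: float = 20.0
    efficiency: float = 2.0
    noise_sd: float = 0.3
    capture_scale: float = 1.0
    floor: float = 0.01


@dataclass(frozen=True)
class SignalModel:
    tss_peak_height: float = 10.0
    decay_length: int = 500
    ctcf_boundary_fraction: float = 0.3
    ctcf_peak_height: float = 6.0
    ctcf_peak_width: int = 200
    background_sd: float = 0.1
    bin_size: int = 25
    window: int = 5000  # background emitted within this much of each feature


@dataclass(frozen=True)
class ErvModel:
    n_per_family: Dict[str, int] = field(
        default_factory=lambda: {"ETn/MusD": 300, "IAP": 300})
    full_length_fraction: float = 0.4
    full_length_span: int = 5000
    solo_span: int = 400
    ltr_span: int = 400
    polymorphic_fraction: float = 0.1
    max_attempts_factor: int = 200


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 5
    chrom_length: int = 2_000_000
    n_genes: int = 200
    gene_length_range: Tuple[int, int] = (5_000, 20_000)
    cgi_promoter_fraction: float = 0.6
    cgi_half_width: int = 500
    tissues: Tuple[str, ...] = DEFAULT_TISSUES
    expressed_fraction: float = 0.5
    erv: ErvModel = field(default_factory=ErvModel)
    selection: SelectionModel = field(default_factory=SelectionModel)
    methylation: MethylationModel = field(default_factory=MethylationModel)
    bisulfite: BisulfiteModel = field(default_factory=BisulfiteModel)
    ct: CtModel = field(default_factory=CtModel)
    signal: SignalModel = field(default_factory=SignalModel)

    def rng(self, salt: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(salt)])

    @classmethod
    def from_dict(cls, d: Dict) -> "SimulationConfig":
        d = dict(d)
        for key, sub in (("erv", ErvModel), ("selection", SelectionModel),
                         ("methylation", MethylationModel), ("bisulfite", BisulfiteModel),
                         ("ct", CtModel), ("signal", SignalModel)):
            if key in d and isinstance(d[key], dict):
                sub_d = dict(d[key])
                if key == "methylation" and "near_tss_unmethylated_families" in sub_d:
                    sub_d["near_tss_unmethylated_families"] = tuple(
                        sub_d["near_tss_unmethylated_families"])
                d[key] = sub(**sub_d)
        for key in ("tissues", "gene_length_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# salts for per-generator child seeds
_SALT_GENOME = 1
_SALT_INSERTIONS = 2
_SALT_BISULFITE = 3
_SALT_CT = 4
_SALT_SIGNAL = 5


def make_genome_and_genes(config: SimulationConfig
                          ) -> Tuple[GenomeModel, List[GeneRecord], List[CgiInterval],
                                     ExpressionTable]:
    """Synthesize a genome with non-overlapping stranded genes, CGIs over a
    configured fraction of promoters, and a binary expression table."""
    rng = config.rng(_SALT_GENOME)
    genome = GenomeModel(tuple((f"chr{i + 1}", config.chrom_length)
                               for i in range(config.n_chromosomes)))
    lo, hi = config.gene_length_range
    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in genome.names}
    genes: List[GeneRecord] = []
    cgis: List[CgiInterval] = []
    max_attempts = 1000 * config.n_genes + 1000
    attempts = 0
    i = 0
    while len(genes) < config.n_genes:
        attempts += 1
        if attempts > max_attempts:
            raise CapacityError(
                f"placed only {len(genes)}/{config.n_genes} genes after {attempts} attempts")
        chrom = genome.names[int(rng.integers(config.n_chromosomes))]
        length = int(rng.integers(lo, hi + 1))
        if length >= config.chrom_length - 2:
            raise CapacityError("gene length exceeds chromosome length")
        start = int(rng.integers(1, config.chrom_length - length))
        end = start + length
        if any(s < end and start < e for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        tss, tts = (start, end) if strand == "+" else (end, start)
        has_cgi = bool(rng.random() < config.cgi_promoter_fraction)
        genes.append(GeneRecord(f"gene{i:04d}", chrom, strand, tss, tts,
                                promoter_is_cgi=has_cgi))
        if has_cgi:
            w = config.cgi_half_width
            cgis.append(CgiInterval(chrom, max(0, tss - w),
                                    min(config.chrom_length, tss + w)))
        i += 1
    states = {(g.gene_id, t): bool(rng.random() < config.expressed_fraction)
              for g in genes for t in config.tissues}
    expression = ExpressionTable(states, [g.gene_id for g in genes], list(config.tissues))
    return genome, genes, cgis, expression


def _tss_positions(genes: Sequence[GeneRecord]) -> Dict[str, np.ndarray]:
    per_chrom: Dict[str, List[int]] = {}
    for g in genes:
        per_chrom.setdefault(g.chrom, []).append(g.tss)
    return {c: np.sort(np.array(v, dtype=np.int64)) for c, v in per_chrom.items()}


def _nearest_point_distance(anchors: np.ndarray, points: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(anchors, points)
    left = np.where(idx > 0, np.abs(points - anchors[np.maximum(idx - 1, 0)]), np.inf)
    right = np.where(idx < anchors.size, np.abs(anchors[np.minimum(idx, anchors.size - 1)] - points),
                     np.inf)
    return np.minimum(left, right)


def _edge_distance_to_nearest_tss(chrom: str, start: int, end: int,
                                  tss_by_chrom: Dict[str, np.ndarray]) -> float:
    anchors = tss_by_chrom.get(chrom)
    if anchors is None or anchors.size == 0:
        return math.inf
    i = int(np.searchsorted(anchors, start))
    j = int(np.searchsorted(anchors, end - 1, side="right"))
    if i < j:  # an anchor falls inside [start, end)
        return 0.0
    best = math.inf
    if i > 0:
        best = min(best, start - int(anchors[i - 1]))
    if i < anchors.size:
        best = min(best, int(anchors[i]) - end)
    return max(best, 0.0)


def sample_insertions(config: SimulationConfig, genome: GenomeModel,
                      genes: Sequence[GeneRecord]) -> List[ErvRecord]:
    """Sample ERV insertions uniformly over the genome, dress them with
    element spans and LTR substructure, and thin them by the selection
    function of edge-distance to the nearest TSS."""
    rng = config.rng(_SALT_INSERTIONS)
    tss_by_chrom = _tss_positions(genes)
    lengths = np.array(genome.lengths, dtype=float)
    chrom_probs = lengths / lengths.sum()
    ervs: List[ErvRecord] = []
    em = config.erv
    for family in sorted(em.n_per_family):
        target = em.n_per_family[family]
        tag = FAMILY_TAGS.get(family, family.replace("/", ""))
        kept = 0
        attempts = 0
        max_attempts = em.max_attempts_factor * max(target, 1)
        while kept < target:
            attempts += 1
            if attempts > max_attempts:
                raise CapacityError(
                    f"{family}: retained only {kept}/{target} insertions "
                    f"after {attempts} attempts (selection too strict?)")
            ci = int(rng.choice(len(chrom_probs), p=chrom_probs))
            chrom, chrom_len = genome.chromosomes[ci]
            full_length = bool(rng.random() < em.full_length_fraction)
            span = em.full_length_span if full_length else em.solo_span
            if span >= chrom_len:
                raise CapacityError("element span exceeds chromosome length")
            start = int(rng.integers(0, chrom_len - span))
            end = start + span
            dist = _edge_distance_to_nearest_tss(chrom, start, end, tss_by_chrom)
            if math.isinf(dist):
                dist = 10 * config.methylation.near_tss_distance  # no genes on chrom
            p_keep = float(config.selection.retention_probability(np.array([dist]))[0])
            if rng.random() >= p_keep:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            if full_length:
                left = (start, start + em.ltr_span)
                right = (end - em.ltr_span, end)
                ltr5, ltr3 = (left, right) if strand == "+" else (right, left)
                element_type = "full_length"
            else:
                ltr5, ltr3 = (start, end), None
                element_type = "solo"
            poly = "polymorphic" if rng.random() < em.polymorphic_fraction else "fixed"
            ervs.append(ErvRecord(
                erv_id=f"{tag}_{kept:05d}", family=family, element_type=element_type,
                chrom=chrom, start=start, end=end, strand=strand,
                ltr5=ltr5, ltr3=ltr3, fixed_or_polymorphic=poly))
            kept += 1
    return ervs


def make_bisulfite_reference(length: int, n_cpgs: int,
                             rng: np.random.Generator) -> str:
    """Random reference with exactly ``n_cpgs`` CpG dinucleotides plus
    scattered non-CpG cytosines (needed for conversion-rate QC)."""
    if length < 2 * n_cpgs + 2:
        raise ValueError("region too short for requested CpG count")
    bases = rng.choice(list("ACGT"), size=length, p=[0.3, 0.2, 0.2, 0.3])
    seq = list("".join(bases))
    for i in range(length - 1):  # strip accidental CpGs
        if seq[i] == "C" and seq[i + 1] == "G":
            seq[i + 1] = "A"
    step = length // (n_cpgs + 1)
    for k in range(n_cpgs):  # plant CpGs at regular offsets
        pos = step * (k + 1) - 1
        seq[pos], seq[pos + 1] = "C", "G"
        if pos + 2 < length and seq[pos + 2] == "G":
            seq[pos + 2] = "A"  # avoid creating an overlapping CpG
    return "".join(seq)


def simulate_bisulfite_clones(config: SimulationConfig, region_id: str,
                              true_level: float, tissue: str = "liver",
                              rng: Optional[np.random.Generator] = None,
                              ) -> Tuple[BisulfiteCloneSet, Dict]:
    """Simulate sequenced clones for one region at a true methylation level.

    Each CpG is methylated with probability ``true_level``; each non-CpG
    cytosine fails conversion at ``conversion_failure_rate``; with
    probability ``duplicate_rate`` a clone is an exact PCR duplicate (same
    pattern and same error positions) of a uniformly chosen earlier clone.
    Returns the clone set and a ground-truth sidecar dict (reference
    sequence, true level, and duplicate_of mapping).
    """
    if rng is None:
        rng = np.random.default_rng(
            [int(config.seed), _SALT_BISULFITE, abs(hash(region_id)) % (2 ** 31)])
    bm = config.bisulfite
    reference = make_bisulfite_reference(bm.region_length, bm.cpgs_per_region, rng)
    noncpg_c = [i for i in range(len(reference))
                if reference[i] == "C"
                and not (i + 1 < len(reference) and reference[i + 1] == "G")]
    clones: List[Clone] = []
    duplicate_of: Dict[str, Optional[str]] = {}
    for k in range(bm.clones_per_region):
        cid = f"{region_id}_clone{k:03d}"
        if clones and rng.random() < bm.duplicate_rate:
            src = int(rng.integers(len(clones)))
            template = clones[src]
            clones.append(Clone(template.cpg_calls, template.nonconversion_positions,
                                template.n_noncpg_c, clone_id=cid))
            duplicate_of[cid] = clones[src].clone_id
            continue
        calls = tuple(bool(rng.random() < true_level) for _ in range(bm.cpgs_per_region))
        errors = frozenset(i for i in noncpg_c
                           if rng.random() < bm.conversion_failure_rate)
        clones.append(Clone(calls, errors, len(noncpg_c), clone_id=cid))
        duplicate_of[cid] = None
    clone_set = BisulfiteCloneSet(region_id, tissue, tuple(clones))
    truth = {"reference": reference, "true_level": true_level,
             "duplicate_of": duplicate_of}
    return clone_set, truth


def clones_to_reads(reference: str, clone_set: BisulfiteCloneSet) -> Dict[str, str]:
    """Render clones as bisulfite-converted reads against their reference
    (inverse of :func:`ervkit.methylation.bisulfite_from_reads`)."""
    cpg_positions = [i for i in range(len(reference) - 1)
                     if reference[i] == "C" and reference[i + 1] == "G"]
    cpg_set = set(cpg_positions)
    reads: Dict[str, str] = {}
    for clone in clone_set.clones:
        seq = list(reference)
        for pos, call in zip(cpg_positions, clone.cpg_calls):
            seq[pos] = "C" if call else "T"
        for i, base in enumerate(reference):
            if base == "C" and i not in cpg_set:
                seq[i] = "C" if i in clone.nonconversion_positions else "T"
        reads[clone.clone_id] = "".join(seq)
    return reads


def simulate_ct_table(config: SimulationConfig,
                      regions: Sequence[Tuple[str, str, float]],
                      rng: Optional[np.random.Generator] = None):
    """Simulate a MeDIP-qPCR Ct table for (region_id, tissue, true_level)
    triples, plus one spike-in row (true level 1) per batch.

    Ct_IP = Ct_input - log_eff(level * capture_scale + floor) + N(0, noise_sd),
    so with no noise the spike-normalized score recovers
    (level * capture + floor) / (capture + floor) exactly.
    """
    import pandas as pd

    if rng is None:
        rng = np.random.default_rng([int(config.seed), _SALT_CT])
    cm = config.ct
    rows = []

    def ct_ip_for(level: float) -> float:
        signal = level * cm.capture_scale + cm.floor
        if signal <= 0:
            raise ValueError("capture signal must be positive (set floor > 0)")
        delta = math.log(signal) / math.log(cm.efficiency)
        noise = float(rng.normal(0, cm.noise_sd)) if cm.noise_sd > 0 else 0.0
        return cm.base_ct - delta + noise

    rows.append({"region_id": "spike", "tissue": "spike",
                 "ct_input": cm.base_ct, "ct_ip": ct_ip_for(1.0),
                 "efficiency": cm.efficiency, "batch_id": "batch1",
                 "is_spike": True})
    for region_id, tissue, level in regions:
        rows.append({"region_id": region_id, "tissue": tissue,
                     "ct_input": cm.base_ct, "ct_ip": ct_ip_for(level),
                     "efficiency": cm.efficiency, "batch_id": "batch1",
                     "is_spike": False})
    return pd.DataFrame(rows)


def simulate_signal_tracks(config: SimulationConfig, genome: GenomeModel,
                           genes: Sequence[GeneRecord], ervs: Sequence[ErvRecord],
                           expression: ExpressionTable, tissue: str,
                           ) -> Dict[str, SignalTrack]:
    """Simulate H3K4me3/CTCF/Input bedGraph-style tracks.

    Expressed genes get a TSS peak decaying exponentially into both flanks;
    a configured fraction of (ERV, nearest-gene) intervening regions get a
    CTCF point peak at their midpoint; background Gaussian noise covers the
    neighborhood (``signal.window``) of every feature. Binned at
    ``signal.bin_size`` resolution.
    """
    rng = config.rng(_SALT_SIGNAL)
    sm = config.signal
    nbins = {c: (L + sm.bin_size - 1) // sm.bin_size for c, L in genome.chromosomes}
    h3k4 = {c: np.zeros(n) for c, n in nbins.items()}
    ctcf = {c: np.zeros(n) for c, n in nbins.items()}
    covered = {c: np.zeros(n, dtype=bool) for c, n in nbins.items()}

    def mark_window(chrom: str, center: int) -> None:
        lo = max(0, (center - sm.window) // sm.bin_size)
        hi = min(nbins[chrom], (center + sm.window) // sm.bin_size + 1)
        covered[chrom][lo:hi] = True

    for g in genes:
        mark_window(g.chrom, g.tss)
        if not expression.is_expressed(g.gene_id, tissue):
            continue
        reach = 6 * sm.decay_length
        lo = max(0, (g.tss - reach) // sm.bin_size)
        hi = min(nbins[g.chrom], (g.tss + reach) // sm.bin_size + 1)
        centers = (np.arange(lo, hi) + 0.5) * sm.bin_size
        h3k4[g.chrom][lo:hi] += sm.tss_peak_height * np.exp(
            -np.abs(centers - g.tss) / sm.decay_length)

    tss_by_chrom = _tss_positions(genes)
    for erv in ervs:
        mark_window(erv.chrom, erv.start)
        mark_window(erv.chrom, erv.end)
        anchors = tss_by_chrom.get(erv.chrom)
        if anchors is None or anchors.size == 0:
            continue
        d_left = _edge_distance_to_nearest_tss(erv.chrom, erv.start, erv.end, tss_by_chrom)
        if d_left == 0 or math.isinf(d_left):
            continue
        i = int(np.searchsorted(anchors, erv.start))
        cands = [int(anchors[j]) for j in (i - 1, i) if 0 <= j < anchors.size]
        tss = min(cands, key=lambda t: min(abs(t - erv.start), abs(t - erv.end)))
        if rng.random() >= sm.ctcf_boundary_fraction:
            continue
        edge = erv.end if tss >= erv.end else erv.start
        mid = (edge + tss) // 2
        lo = max(0, (mid - sm.ctcf_peak_width) // sm.bin_size)
        hi = min(nbins[erv.chrom], (mid + sm.ctcf_peak_width) // sm.bin_size + 1)
        centers = (np.arange(lo, hi) + 0.5) * sm.bin_size
        ctcf[erv.chrom][lo:hi] += sm.ctcf_peak_height * np.exp(
            -0.5 * ((centers - mid) / (sm.ctcf_peak_width / 2)) ** 2)

    tracks: Dict[str, SignalTrack] = {}
    for name, values in (("h3k4me3", h3k4), ("ctcf", ctcf), ("input", None)):
        intervals = []
        for chrom, L in genome.chromosomes:
            mask = covered[chrom]
            vals = np.zeros(nbins[chrom]) if values is None else values[chrom].copy()
            if sm.background_sd > 0:
                noise = rng.normal(0, sm.background_sd, size=int(mask.sum()))
                vals[mask] = np.maximum(vals[mask] + noise, 0.0)
            idx = np.nonzero(mask | (vals > 0))[0]
            for b in idx:
                s = int(b) * sm.bin_size
                e = min(s + sm.bin_size, L)
                if vals[b] != 0.0:
                    intervals.append((chrom, s, e, float(vals[b])))
        tracks[name] = SignalTrack(intervals)
    return tracks


def _methylation_truth(config: SimulationConfig, ervs: Sequence[ErvRecord],
                       genes: Sequence[GeneRecord], expression: ExpressionTable,
                       ) -> List[Dict]:
    """Per-ERV ground truth: nearest gene, distance, tissue, true levels for
    the element (and each LTR of full-length copies)."""
    rng = config.rng(_SALT_BISULFITE)
    mm = config.methylation
    tss_by_chrom = _tss_positions(genes)
    genes_by_tss: Dict[Tuple[str, int], GeneRecord] = {}
    for g in genes:
        genes_by_tss.setdefault((g.chrom, g.tss), g)
    truth = []
    for erv in ervs:
        anchors = tss_by_chrom.get(erv.chrom)
        if anchors is None or anchors.size == 0:
            continue
        dist = _edge_distance_to_nearest_tss(erv.chrom, erv.start, erv.end, tss_by_chrom)
        i = int(np.searchsorted(anchors, erv.start))
        cands = [int(anchors[j]) for j in (i - 1, i) if 0 <= j < anchors.size]
        tss = min(cands, key=lambda t: (distance_between((erv.start, erv.end), t), t))
        gene = genes_by_tss[(erv.chrom, tss)]
        near = dist < mm.near_tss_distance
        base = mm.family_baseline[erv.family]
        level = float(np.clip(base + rng.normal(0, mm.copy_level_sd), 0.0, 1.0))
        hypo = near and erv.family in mm.near_tss_unmethylated_families
        if hypo:
            level = mm.near_tss_level
        expressed = expression.expressed_tissues(gene.gene_id)
        tissue = expressed[0] if expressed else config.tissues[0]
        entry = {"erv_id": erv.erv_id, "family": erv.family,
                 "element_type": erv.element_type, "gene_id": gene.gene_id,
                 "distance_to_tss": int(dist), "near_tss": near, "tissue": tissue,
                 "erv_level": level, "promoter_level": mm.promoter_level}
        if erv.element_type == "full_length":
            # near-TSS hypomethylation affects the gene-proximal LTR only
            d5 = min(abs(erv.ltr5[0] - tss), abs(erv.ltr5[1] - tss))
            d3 = min(abs(erv.ltr3[0] - tss), abs(erv.ltr3[1] - tss))
            proximal = "ltr5" if d5 <= d3 else "ltr3"
            distal_level = float(np.clip(base + rng.normal(0, mm.copy_level_sd), 0.0, 1.0))
            if hypo:
                entry["ltr5_level"] = mm.near_tss_level if proximal == "ltr5" else distal_level
                entry["ltr3_level"] = mm.near_tss_level if proximal == "ltr3" else distal_level
            else:
                entry["ltr5_level"] = level
                entry["ltr3_level"] = distal_level
        truth.append(entry)
    return truth


def write_simulation(config: SimulationConfig, outdir) -> Dict[str, Path]:
    """Generate and write the full synthetic input bundle.

    Emits genome.chrom.sizes, genes.bed, cgis.bed, expression.tsv, ervs.bed,
    ct_table.tsv, per-region bisulfite FASTA (reference + clone reads),
    bedGraph tracks, and ground-truth sidecar TSVs. Returns a path map.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "bisulfite").mkdir(exist_ok=True)
    (outdir / "tracks").mkdir(exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)

    genome, genes, cgis, expression = make_genome_and_genes(config)
    ervs = sample_insertions(config, genome, genes)
    paths = {
        "genome": outdir / "genome.chrom.sizes",
        "genes": outdir / "genes.bed",
        "cgis": outdir / "cgis.bed",
        "expression": outdir / "expression.tsv",
        "ervs": outdir / "ervs.bed",
        "ct_table": outdir / "ct_table.tsv",
        "regions": outdir / "regions.tsv",
        "evidence": outdir / "evidence.tsv",
        "truth_methylation": outdir / "truth" / "methylation.tsv",
        "truth_selection": outdir / "truth" / "selection.yaml",
        "truth_duplicates": outdir / "truth" / "duplicates.tsv",
        "bisulfite_dir": outdir / "bisulfite",
        "tracks_dir": outdir / "tracks",
    }
    eio.write_genome(paths["genome"], genome)
    eio.write_features(paths["genes"], genes)
    eio.write_features(paths["cgis"], cgis)
    eio.write_expression_table(paths["expression"], expression)
    eio.write_features(paths["ervs"], ervs)

    truth = _methylation_truth(config, ervs, genes, expression)
    pd.DataFrame(truth).to_csv(paths["truth_methylation"], sep="\t", index=False)
    with open(paths["truth_selection"], "w") as fh:
        yaml.safe_dump(asdict(config.selection), fh)

    # bisulfite clone sets: ERV body (solo) or both LTRs (full-length), plus
    # the promoter of the nearest gene for near-TSS copies
    dup_rows = []
    ct_regions = []
    manifest_rows = []
    promoters_done = set()
    for entry in truth:
        if entry["element_type"] == "full_length":
            regions = [(f"{entry['erv_id']}_ltr5", "ltr5", entry["ltr5_level"]),
                       (f"{entry['erv_id']}_ltr3", "ltr3", entry["ltr3_level"])]
            ct_level = (entry["ltr5_level"] + entry["ltr3_level"]) / 2
        else:
            regions = [(entry["erv_id"], "erv", entry["erv_level"])]
            ct_level = entry["erv_level"]
        if entry["near_tss"] and entry["gene_id"] not in promoters_done:
            regions.append((f"promoter_{entry['gene_id']}", "promoter",
                            entry["promoter_level"]))
            promoters_done.add(entry["gene_id"])
        for region_id, source, level in regions:
            clone_set, rt = simulate_bisulfite_clones(config, region_id, level,
                                                      tissue=entry["tissue"])
            reads = clones_to_reads(rt["reference"], clone_set)
            eio.write_fasta(outdir / "bisulfite" / f"{region_id}.ref.fa",
                            {region_id: rt["reference"]})
            eio.write_fasta(outdir / "bisulfite" / f"{region_id}.reads.fa", reads)
            for cid, src in rt["duplicate_of"].items():
                dup_rows.append({"region_id": region_id, "clone_id": cid,
                                 "duplicate_of": src if src else "."})
            manifest_rows.append({"region_id": region_id, "tissue": entry["tissue"],
                                  "source": source, "erv_id": entry["erv_id"],
                                  "gene_id": entry["gene_id"]})
        ct_regions.append((entry["erv_id"], entry["tissue"], ct_level))
    pd.DataFrame(dup_rows).to_csv(paths["truth_duplicates"], sep="\t", index=False)
    pd.DataFrame(manifest_rows).to_csv(paths["regions"], sep="\t", index=False)

    ct = simulate_ct_table(config, ct_regions)
    ct.to_csv(paths["ct_table"], sep="\t", index=False)

    # per-copy evidence flags for the copy filter (inputs, mostly clean)
    ev_rng = config.rng(6)
    evidence = pd.DataFrame({
        "erv_id": [e.erv_id for e in ervs],
        "est_or_expression_available": ev_rng.random(len(ervs)) < 0.95,
        "gene_annotation_ok": ev_rng.random(len(ervs)) < 0.95,
        "tss_count": 1 + ev_rng.poisson(0.5, size=len(ervs)),
        "inside_upstream_gene": ev_rng.random(len(ervs)) < 0.05,
    })
    evidence.to_csv(paths["evidence"], sep="\t", index=False)

    tissue = config.tissues[0]
    tracks = simulate_signal_tracks(config, genome, genes, ervs, expression, tissue)
    for mark, track in tracks.items():
        eio.write_bedgraph(outdir / "tracks" / f"{mark}.bedgraph", track)
    return paths
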