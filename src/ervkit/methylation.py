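"""Methylation quantification from MeDIP-qPCR Ct tables and bisulfite clones.

MeDIP enrichment is ``efficiency ** (Ct_input - Ct_IP)``, normalized by the
spike-in control of the same batch; scores below 0.2 call unmethylated.
Bisulfite clones pass QC when their non-CpG conversion rate exceeds 95%
(strict) and are deduplicated on (CpG pattern, non-conversion error set)
exact identity, keeping the first of each duplicate group.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .stats import TestResult, spearman

__all__ = [
    "IndeterminateRateError",
    "Clone",
    "BisulfiteCloneSet",
    "MedipMeasurement",
    "MethylationCall",
    "UNMETHYLATED_THRESHOLD",
    "CONVERSION_THRESHOLD",
    "medip_score",
    "conversion_rate",
    "passes_conversion",
    "dedup_clones",
    "qc_clones",
    "methylation_fraction",
    "medip_bisulfite_concordance",
    "bisulfite_from_reads",
]

UNMETHYLATED_THRESHOLD = 0.2
CONVERSION_THRESHOLD = 0.95


class IndeterminateRateError(ValueError):
    """Conversion rate undefined: the clone has no non-CpG cytosines."""


@dataclass(frozen=True)
class Clone:
    """One sequenced bisulfite clone.

    ``cpg_calls`` holds one entry per reference CpG site: True (methylated),
    False (unmethylated) or None (ambiguous base, skipped).
    ``nonconversion_positions`` are the non-CpG cytosine offsets that failed
    conversion; ``n_noncpg_c`` is the total number of non-CpG cytosines.
    """

    cpg_calls: Tuple[Optional[bool], ...]
    nonconversion_positions: frozenset = frozenset()
    n_noncpg_c: int = 0
    clone_id: str = ""

    def __post_init__(self) -> None:
        if len(self.nonconversion_positions) > self.n_noncpg_c:
            raise ValueError(
                f"clone {self.clone_id}: more non-conversion errors than non-CpG cytosines")

    @property
    def fraction_methylated(self) -> float:
        calls = [c for c in self.cpg_calls if c is not None]
        if not calls:
            raise ValueError(f"clone {self.clone_id}: no scorable CpG calls")
        return sum(calls) / len(calls)


@dataclass(frozen=True)
class BisulfiteCloneSet:
    region_id: str
    tissue: str
    clones: Tuple[Clone, ...]

    def __post_init__(self) -> None:
        lengths = {len(c.cpg_calls) for c in self.clones}
        if len(lengths) > 1:
            raise ValueError(
                f"region {self.region_id}: clones disagree on CpG site count: {sorted(lengths)}")


@dataclass(frozen=True)
class MedipMeasurement:
    """One qPCR measurement pair for a region in a tissue."""

    region_id: str
    tissue: str
    ct_input: float
    ct_ip: float
    efficiency: float
    batch_id: str = "batch1"

    def __post_init__(self) -> None:
        for name, ct in (("ct_input", self.ct_input), ("ct_ip", self.ct_ip)):
            if not math.isfinite(ct) or ct < 0:
                raise ValueError(f"{self.region_id}: {name} must be finite and >= 0, got {ct}")
        if self.efficiency <= 1:
            raise ValueError(f"{self.region_id}: efficiency must exceed 1, got {self.efficiency}")

    @property
    def raw_enrichment(self) -> float:
        return self.efficiency ** (self.ct_input - self.ct_ip)


@dataclass(frozen=True)
class MethylationCall:
    region_id: str
    tissue: str
    score: float
    call: str
    method: str
    fraction: Optional[float] = None
    n_clones: Optional[int] = None

    def __post_init__(self) -> None:
        if self.call not in ("methylated", "unmethylated"):
            raise ValueError(f"bad call {self.call!r}")
        if self.score < 0:
            raise ValueError(f"negative score {self.score}")


def _make_call(score: float, threshold: float) -> str:
    return "unmethylated" if score < threshold else "methylated"


def medip_score(m: MedipMeasurement, spikes, *,
                threshold: float = UNMETHYLATED_THRESHOLD,
                spike_mode: str = "mean") -> MethylationCall:
    """Spike-normalized MeDIP score and methylated/unmethylated call.

    ``spikes`` is one MedipMeasurement or a sequence from the same batch;
    by default the raw enrichments of all supplied spikes are averaged
    (``spike_mode='first'`` uses only the first).
    """
    if isinstance(spikes, MedipMeasurement):
        spikes = [spikes]
    spikes = [s for s in spikes if s.batch_id == m.batch_id]
    if not spikes:
        raise ValueError(f"no spike-in measurement for batch {m.batch_id!r}")
    if spike_mode == "first":
        spikes = spikes[:1]
    elif spike_mode != "mean":
        raise ValueError(f"unknown spike_mode {spike_mode!r}")
    spike_raw = float(np.mean([s.raw_enrichment for s in spikes]))
    score = m.raw_enrichment / spike_raw
    return MethylationCall(m.region_id, m.tissue, score,
                           _make_call(score, threshold), "medip")


def conversion_rate(clone: Clone) -> float:
    """Fraction of non-CpG cytosines that converted (C -> T)."""
    if clone.n_noncpg_c == 0:
        raise IndeterminateRateError(
            f"clone {clone.clone_id}: no non-CpG cytosines; conversion rate indeterminate")
    return 1.0 - len(clone.nonconversion_positions) / clone.n_noncpg_c


def passes_conversion(clone: Clone, threshold: float = CONVERSION_THRESHOLD) -> bool:
    """Strict conversion filter: rate must exceed the threshold.

    A clone with no non-CpG cytosines cannot be assessed and does not pass
    (callers see the flag through qc_clones' report).
    """
    try:
        return conversion_rate(clone) > threshold
    except IndeterminateRateError:
        return False


def dedup_clones(clone_set: BisulfiteCloneSet) -> BisulfiteCloneSet:
    """Drop PCR duplicates: keep a clone when its CpG pattern OR its
    non-conversion error set is unique among clones retained so far;
    exact duplicates in both collapse to the first occurrence."""
    retained: List[Clone] = []
    for clone in clone_set.clones:
        dup = any(c.cpg_calls == clone.cpg_calls
                  and c.nonconversion_positions == clone.nonconversion_positions
                  for c in retained)
        if not dup:
            retained.append(clone)
    return replace(clone_set, clones=tuple(retained))


def qc_clones(clone_set: BisulfiteCloneSet,
              conversion_threshold: float = CONVERSION_THRESHOLD) -> Tuple[BisulfiteCloneSet, Dict]:
    """Conversion filter then dedup; returns the retained set and a QC report."""
    flagged_indeterminate = [c.clone_id for c in clone_set.clones if c.n_noncpg_c == 0]
    converted = tuple(c for c in clone_set.clones
                      if c.n_noncpg_c > 0 and passes_conversion(c, conversion_threshold))
    deduped = dedup_clones(replace(clone_set, clones=converted))
    report = {
        "n_input": len(clone_set.clones),
        "n_failed_conversion": len(clone_set.clones) - len(converted) - len(flagged_indeterminate),
        "n_indeterminate_conversion": len(flagged_indeterminate),
        "indeterminate_clone_ids": flagged_indeterminate,
        "n_duplicates_removed": len(converted) - len(deduped.clones),
        "n_retained": len(deduped.clones),
    }
    return deduped, report


def methylation_fraction(clone_set: BisulfiteCloneSet,
                         threshold: float = UNMETHYLATED_THRESHOLD) -> MethylationCall:
    """Methylated fraction of all scorable CpG calls over retained clones."""
    if not clone_set.clones:
        raise ValueError(f"region {clone_set.region_id}: no clones to quantify")
    total = meth = 0
    for clone in clone_set.clones:
        for call in clone.cpg_calls:
            if call is not None:
                total += 1
                meth += call
    if total == 0:
        raise ValueError(f"region {clone_set.region_id}: no scorable CpG calls")
    fraction = meth / total
    return MethylationCall(clone_set.region_id, clone_set.tissue, fraction,
                           _make_call(fraction, threshold), "bisulfite",
                           fraction=fraction, n_clones=len(clone_set.clones))


def medip_bisulfite_concordance(calls_medip: Sequence[MethylationCall],
                                calls_bisulfite: Sequence[MethylationCall]) -> TestResult:
    """Spearman correlation of MeDIP scores vs bisulfite fractions over the
    (region, tissue) pairs measured by both methods."""
    medip = {(c.region_id, c.tissue): c.score for c in calls_medip}
    bis = {(c.region_id, c.tissue): c.fraction for c in calls_bisulfite}
    shared = sorted(set(medip) & set(bis))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared (region, tissue) pairs, got {len(shared)}")
    return spearman([medip[k] for k in shared], [bis[k] for k in shared])


def bisulfite_from_reads(reference: str, reads: Dict[str, str],
                         region_id: str = "", tissue: str = "") -> BisulfiteCloneSet:
    """Score bisulfite clone reads against their (unconverted) reference.

    Reads must be ungapped and reference-length. Reference CpG cytosines are
    scored methylated (C) / unmethylated (T); non-CpG cytosines count toward
    the conversion rate (C = unconverted error, T = converted).
    """
    reference = reference.upper()
    cpg_positions = [i for i in range(len(reference) - 1)
                     if reference[i] == "C" and reference[i + 1] == "G"]
    noncpg_c_positions = [i for i, base in enumerate(reference)
                          if base == "C" and i not in set(cpg_positions)]
    clones = []
    for name, read in reads.items():
        read = read.upper()
        if len(read) != len(reference):
            raise ValueError(
                f"read {name}: length {len(read)} != reference length {len(reference)}")
        calls: List[Optional[bool]] = []
        for i in cpg_positions:
            base = read[i]
            if base == "C":
                calls.append(True)
            elif base == "T":
                calls.append(False)
            else:
                warnings.warn(f"read {name}: ambiguous base {base!r} at CpG {i}; skipped")
                calls.append(None)
        errors = []
        for i in noncpg_c_positions:
            base = read[i]
            if base == "C":
                errors.append(i)
            elif base != "T":
                warnings.warn(f"read {name}: ambiguous base {base!r} at non-CpG C {i}; skipped")
        clones.append(Clone(tuple(calls), frozenset(errors),
                            len(noncpg_c_positions), clone_id=name))
    return BisulfiteCloneSet(region_id, tissue, tuple(clones))
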