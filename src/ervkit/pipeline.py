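"""Config-driven end-to-end orchestration: synthesize inputs, run every
analysis stage, and write the report tables
(distance distributions with thresholds, methylation calls with an evidence
ledger, LTR comparison, orientation/CGI association, spreading assessment,
and chromatin profile matrices).

All thresholds live in :class:`RunConfig`; stage code takes them as
arguments and holds no literals.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .architecture import (
    annotate_cgi_promoters,
    assess_spreading,
    compare_ltr_methylation,
    filter_copies,
    orientation_cgi_table,
    proximal_ltr,
)
from .distribution import distribution_analysis
from .methylation import (
    BisulfiteCloneSet,
    MedipMeasurement,
    bisulfite_from_reads,
    medip_bisulfite_concordance,
    medip_score,
    methylation_fraction,
    qc_clones,
)
from .model import ErvRecord, GeneRecord, distance_between
from .profiles import (
    choose_flank,
    extract_profile,
    intervening_region,
    orient_and_average,
)
from .simulate import SimulationConfig, write_simulation
from .stats import DegenerateTableError

__all__ = ["Thresholds", "RunConfig", "StageError", "run_pipeline", "summarize_calls"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class Thresholds:
    unmethylated: float = 0.2
    spreading: float = 0.10
    significance: float = 0.05
    conversion: float = 0.95
    cgi_window: int = 1500
    max_tss: int = 3

    def __post_init__(self) -> None:
        for name in ("unmethylated", "spreading", "significance", "conversion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"threshold {name}={v} outside [0,1]")
        if self.cgi_window < 0 or self.max_tss < 1:
            raise ValueError("cgi_window must be >= 0 and max_tss >= 1")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    bin_width: int = 500
    max_dist: int = 10_000
    expected_n: int = 100_000
    expected_reps: int = 3
    flank: int = 400
    flank_fallback: int = 200
    n_points: int = 100
    ltr_screen_window: int = 5_000
    stages: Tuple[str, ...] = ("distribution", "methylation", "architecture", "profiles")

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: Dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = Thresholds(**d["thresholds"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "seed" in d and "simulation" not in d:
            d["simulation"] = SimulationConfig(seed=int(d["seed"]))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def summarize_calls(calls: pd.DataFrame, thresholds_by_family: Dict[str, int]
                    ) -> pd.DataFrame:
    """Group methylation calls into near/far x family classes.

    ``calls`` needs columns erv_id, family, distance, call. A copy is
    'near' when its distance is strictly below the family's detected
    threshold. Empty groups report n=0 and NaN fraction.
    """
    for col in ("erv_id", "family", "distance", "call"):
        if col not in calls.columns:
            raise KeyError(f"calls table missing column {col!r}")
    rows = []
    for family in sorted(calls["family"].unique()):
        threshold = thresholds_by_family.get(family, 0)
        sub = calls[calls["family"] == family]
        for group, mask in (("near", sub["distance"] < threshold),
                            ("far", sub["distance"] >= threshold)):
            grp = sub[mask]
            n = len(grp)
            frac = float((grp["call"] == "methylated").mean()) if n else float("nan")
            rows.append({"family": family, "group": group,
                         "threshold": threshold, "n": n,
                         "fraction_methylated": frac})
    return pd.DataFrame(rows)


def _read_bisulfite_region(bis_dir: Path, region_id: str, tissue: str,
                           conversion_threshold: float) -> Tuple[BisulfiteCloneSet, Dict]:
    ref = eio.read_fasta(bis_dir / f"{region_id}.ref.fa")[region_id]
    reads = eio.read_fasta(bis_dir / f"{region_id}.reads.fa")
    clone_set = bisulfite_from_reads(ref, reads, region_id=region_id, tissue=tissue)
    return qc_clones(clone_set, conversion_threshold)


def _nearest_gene_map(ervs: Sequence[ErvRecord], genes: Sequence[GeneRecord]
                      ) -> Dict[str, Tuple[GeneRecord, int]]:
    by_chrom: Dict[str, List[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: Dict[str, Tuple[GeneRecord, int]] = {}
    for erv in ervs:
        cands = by_chrom.get(erv.chrom, [])
        if not cands:
            continue
        gene = min(cands, key=lambda g: (distance_between((erv.start, erv.end), g.tss),
                                         g.tss))
        out[erv.erv_id] = (gene, distance_between((erv.start, erv.end), gene.tss))
    return out


def run_pipeline(config: RunConfig, outdir) -> Dict[str, Path]:
    """Run all enabled stages end to end on freshly synthesized inputs.

    Deterministic under the config seed; returns a map of report paths.
    Stage failures raise :class:`StageError` naming the stage (partial
    outputs written so far are retained).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reports = outdir / "reports"
    reports.mkdir(exist_ok=True)
    out: Dict[str, Path] = {}
    counts: Dict[str, object] = {}

    try:
        paths = write_simulation(config.simulation, outdir / "inputs")
    except Exception as exc:
        raise StageError(f"stage 'simulate' failed: {exc}") from exc

    genome = eio.read_genome(paths["genome"])
    genes = eio.read_features(paths["genes"], "gene")
    cgis = eio.read_features(paths["cgis"], "cgi")
    ervs = eio.read_features(paths["ervs"], "erv")
    manifest = pd.read_csv(paths["regions"], sep="\t")
    genes = annotate_cgi_promoters(genes, cgis, config.thresholds.cgi_window)
    gene_by_id = {g.gene_id: g for g in genes}
    erv_by_id = {e.erv_id: e for e in ervs}
    nearest = _nearest_gene_map(ervs, genes)
    counts["n_genes"] = len(genes)
    counts["n_ervs"] = len(ervs)

    thresholds_by_family: Dict[str, int] = {}
    if "distribution" in config.stages:
        try:
            rows = []
            trows = []
            for family in sorted({e.family for e in ervs}):
                for anchor in ("tss", "tts"):
                    dist = distribution_analysis(
                        ervs, genes, genome, anchor=anchor, family=family,
                        bin_width=config.bin_width, max_dist=config.max_dist,
                        n=config.expected_n, reps=config.expected_reps,
                        seed=config.seed, alpha=config.thresholds.significance)
                    rows.extend(dist.to_rows())
                    trows.append({"family": family, "anchor": anchor,
                                  "threshold": dist.threshold,
                                  "flags": ",".join(dist.threshold_flags)})
                    if anchor == "tss":
                        thresholds_by_family[family] = dist.threshold
            out["distribution"] = reports / "distribution.tsv"
            out["thresholds"] = reports / "thresholds.tsv"
            pd.DataFrame(rows).to_csv(out["distribution"], sep="\t", index=False)
            pd.DataFrame(trows).to_csv(out["thresholds"], sep="\t", index=False)
        except Exception as exc:
            raise StageError(f"stage 'distribution' failed: {exc}") from exc

    bis_calls: Dict[str, object] = {}
    qc_rows: List[Dict] = []
    clone_sets: Dict[str, BisulfiteCloneSet] = {}
    if "methylation" in config.stages:
        try:
            ct = pd.read_csv(paths["ct_table"], sep="\t")
            spikes = [MedipMeasurement(r.region_id, r.tissue, r.ct_input, r.ct_ip,
                                       r.efficiency, r.batch_id)
                      for r in ct[ct["is_spike"]].itertuples()]
            medip_calls = []
            for r in ct[~ct["is_spike"]].itertuples():
                m = MedipMeasurement(r.region_id, r.tissue, r.ct_input, r.ct_ip,
                                     r.efficiency, r.batch_id)
                medip_calls.append(medip_score(m, spikes,
                                               threshold=config.thresholds.unmethylated))

            for r in manifest.itertuples():
                clone_set, report = _read_bisulfite_region(
                    Path(paths["bisulfite_dir"]), r.region_id, r.tissue,
                    config.thresholds.conversion)
                clone_sets[r.region_id] = clone_set
                qc_rows.append({"region_id": r.region_id, **{
                    k: v for k, v in report.items() if not isinstance(v, list)}})
                if clone_set.clones:
                    bis_calls[r.region_id] = methylation_fraction(
                        clone_set, config.thresholds.unmethylated)

            # per-ERV bisulfite fraction: solo = its own region; full-length =
            # clones of both LTRs pooled
            erv_bis_calls = []
            for erv in ervs:
                if erv.element_type == "solo":
                    call = bis_calls.get(erv.erv_id)
                    if call is not None:
                        erv_bis_calls.append(call)
                else:
                    parts = [clone_sets.get(f"{erv.erv_id}_ltr5"),
                             clone_sets.get(f"{erv.erv_id}_ltr3")]
                    parts = [p for p in parts if p is not None and p.clones]
                    if parts:
                        pooled = BisulfiteCloneSet(
                            erv.erv_id, parts[0].tissue,
                            tuple(c for p in parts for c in p.clones))
                        erv_bis_calls.append(methylation_fraction(
                            pooled, config.thresholds.unmethylated))
            concordance = medip_bisulfite_concordance(medip_calls, erv_bis_calls)
            counts["medip_bisulfite_spearman_r"] = concordance.statistic
            counts["medip_bisulfite_spearman_p"] = concordance.p_value

            ledger_rows = []
            bis_by_region = {c.region_id: c for c in erv_bis_calls}
            for call in medip_calls:
                bis = bis_by_region.get(call.region_id)
                evidence = ["medip"] + (["bisulfite"] if bis is not None else [])
                confirmed = bis is not None and bis.call == call.call
                ledger_rows.append({
                    "region_id": call.region_id, "tissue": call.tissue,
                    "medip_score": call.score, "medip_call": call.call,
                    "bisulfite_fraction": bis.fraction if bis else float("nan"),
                    "bisulfite_call": bis.call if bis else ".",
                    "evidence": ",".join(evidence),
                    "confirmed": confirmed})
            out["methylation_calls"] = reports / "methylation_calls.tsv"
            pd.DataFrame(ledger_rows).to_csv(out["methylation_calls"], sep="\t", index=False)
            out["bisulfite_qc"] = reports / "bisulfite_qc.tsv"
            pd.DataFrame(qc_rows).to_csv(out["bisulfite_qc"], sep="\t", index=False)

            calls_df = pd.DataFrame([
                {"erv_id": c.region_id, "family": erv_by_id[c.region_id].family,
                 "distance": nearest[c.region_id][1], "call": c.call}
                for c in medip_calls if c.region_id in erv_by_id and c.region_id in nearest])
            summary = summarize_calls(calls_df, thresholds_by_family)
            out["call_summary"] = reports / "call_summary.tsv"
            summary.to_csv(out["call_summary"], sep="\t", index=False)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage 'methylation' failed: {exc}") from exc

    if "architecture" in config.stages:
        try:
            full_length_near = [
                e for e in ervs
                if e.element_type == "full_length" and e.erv_id in nearest
                and nearest[e.erv_id][1] <= config.ltr_screen_window]
            calls = [proximal_ltr(e, nearest[e.erv_id][0]) for e in full_length_near]
            table1_rows = []
            for family in sorted({e.family for e in full_length_near}):
                fam_calls = [c for c in calls
                             if erv_by_id[c.erv_id].family == family]
                if not fam_calls:
                    continue
                summary = orientation_cgi_table(fam_calls)
                table1_rows.append({
                    "family": family, "n": summary.n,
                    "n_5prime": summary.n_5prime, "n_3prime": summary.n_3prime,
                    "pct_cgi_5prime": 100 * summary.cgi_5prime / summary.n_5prime
                    if summary.n_5prime else float("nan"),
                    "pct_cgi_3prime": 100 * summary.cgi_3prime / summary.n_3prime
                    if summary.n_3prime else float("nan"),
                    "orientation_p": summary.orientation_test.p_value
                    if summary.orientation_test else float("nan"),
                    "association_p": summary.association_test.p_value
                    if summary.association_test else float("nan"),
                    "flags": ",".join(summary.flags)})
            out["table1"] = reports / "orientation_cgi.tsv"
            table1_cols = ["family", "n", "n_5prime", "n_3prime",
                           "pct_cgi_5prime", "pct_cgi_3prime",
                           "orientation_p", "association_p", "flags"]
            pd.DataFrame(table1_rows, columns=table1_cols).to_csv(out["table1"], sep="\t", index=False)

            ltr_rows = []
            for erv in full_length_near:
                s5 = clone_sets.get(f"{erv.erv_id}_ltr5")
                s3 = clone_sets.get(f"{erv.erv_id}_ltr3")
                if not (s5 and s3 and s5.clones and s3.clones):
                    continue
                test = compare_ltr_methylation(s5, s3)
                ltr_rows.append({
                    "erv_id": erv.erv_id, "family": erv.family,
                    "ltr5_fraction": methylation_fraction(s5).fraction,
                    "ltr3_fraction": methylation_fraction(s3).fraction,
                    "U": test.statistic, "p_value": test.p_value,
                    "stars": test.stars})
            out["ltr_comparison"] = reports / "ltr_comparison.tsv"
            ltr_cols = ["erv_id", "family", "ltr5_fraction", "ltr3_fraction",
                        "U", "p_value", "stars"]
            pd.DataFrame(ltr_rows, columns=ltr_cols).to_csv(out["ltr_comparison"], sep="\t", index=False)

            spread_rows = []
            for r in manifest[manifest["source"] == "promoter"].itertuples():
                promoter_set = clone_sets.get(r.region_id)
                erv = erv_by_id.get(r.erv_id)
                if not (promoter_set and promoter_set.clones and erv):
                    continue
                gene, dist = nearest[erv.erv_id]
                if erv.element_type == "solo":
                    erv_set = clone_sets.get(erv.erv_id)
                else:
                    near_ltr = proximal_ltr(erv, gene).proximal_ltr
                    tag = "ltr5" if near_ltr == "5prime" else "ltr3"
                    erv_set = clone_sets.get(f"{erv.erv_id}_{tag}")
                if not (erv_set and erv_set.clones):
                    continue
                erv_call = methylation_fraction(erv_set, config.thresholds.unmethylated)
                assessment = assess_spreading(erv_call, promoter_set, dist,
                                              gene.promoter_is_cgi,
                                              config.thresholds.spreading)
                spread_rows.append({
                    "erv_id": erv.erv_id, "family": erv.family,
                    "element_type": erv.element_type, "gene_id": gene.gene_id,
                    "distance_to_tss": dist,
                    "pct_erv_methylation": 100 * assessment.erv_methylation,
                    "pct_promoter_methylation": 100 * assessment.promoter_methylation,
                    "cgi_promoter": assessment.cgi, "tissue": assessment.tissue,
                    "spreading": assessment.spreading_call})
            out["table2"] = reports / "spreading.tsv"
            table2_cols = ["erv_id", "family", "element_type", "gene_id",
                           "distance_to_tss", "pct_erv_methylation",
                           "pct_promoter_methylation", "cgi_promoter", "tissue",
                           "spreading"]
            pd.DataFrame(spread_rows, columns=table2_cols).to_csv(out["table2"], sep="\t", index=False)

            evidence = pd.read_csv(paths["evidence"], sep="\t")
            report = filter_copies(evidence, max_tss=config.thresholds.max_tss)
            out["copy_filter"] = reports / "copy_filter.tsv"
            pd.DataFrame([{"erv_id": r.erv_id, "passed": r.passed,
                           "reasons": ",".join(r.reasons)}
                          for r in report.rows]).to_csv(out["copy_filter"],
                                                        sep="\t", index=False)
            counts["copy_filter_in"] = len(report.rows)
            counts["copy_filter_passed"] = len(report.passed_ids)
            counts["copy_filter_by_reason"] = report.counts_by_reason()
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage 'architecture' failed: {exc}") from exc

    if "profiles" in config.stages:
        try:
            near_threshold = max(thresholds_by_family.values(), default=2000) or 2000
            regions = []
            for erv in ervs:
                if erv.erv_id not in nearest:
                    continue
                gene, dist = nearest[erv.erv_id]
                if 0 < dist < near_threshold:
                    regions.append(intervening_region(erv, gene))
            if regions:
                flank = choose_flank(regions, config.flank, config.flank_fallback)
                for mark in ("h3k4me3", "ctcf", "input"):
                    track = eio.read_bedgraph(
                        Path(paths["tracks_dir"]) / f"{mark}.bedgraph")
                    rows = []
                    ids = []
                    for region in regions:
                        row, _flags = extract_profile(region, track, flank,
                                                      config.n_points)
                        rows.append(row)
                        ids.append(f"{region.erv_id}:{region.gene_id}")
                    matrix = orient_and_average(
                        rows, ["te_left"] * len(rows), mark, flank,
                        region_ids=ids, pre_oriented=True)
                    mat_df = pd.DataFrame(matrix.rows, index=ids)
                    mat_path = reports / f"profile_{mark}.tsv"
                    mat_df.to_csv(mat_path, sep="\t")
                    mean_df = pd.DataFrame({
                        "point": np.arange(matrix.n_points),
                        "mean": matrix.mean_profile, "sd": matrix.sd_profile})
                    mean_path = reports / f"profile_{mark}_mean.tsv"
                    mean_df.to_csv(mean_path, sep="\t", index=False)
                    out[f"profile_{mark}"] = mat_path
                    out[f"profile_{mark}_mean"] = mean_path
                counts["n_profile_regions"] = len(regions)
                counts["profile_flank"] = flank
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage 'profiles' failed: {exc}") from exc

    log = {"config_hash": config.config_hash(), "seed": config.seed,
           "stages": list(config.stages), "counts": counts,
           "thresholds_by_family": thresholds_by_family}
    out["run_log"] = outdir / "run_log.json"
    with open(out["run_log"], "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return out
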