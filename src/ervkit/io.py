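"""Readers and writers for the formats the pipeline touches.

BED6 carries genes and CGIs. ERVs travel in an extended-BED dialect whose
columns 7+ are: family, element_type, ltr5_start, ltr5_end, ltr3_start,
ltr3_end, polymorphism (missing LTR coordinates written as ``.``). Signal
tracks are 4-column bedGraph. All files are plain text, tab- or
whitespace-delimited, 0-based half-open.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .model import (
    CgiInterval,
    ErvRecord,
    ExpressionTable,
    GeneRecord,
    GenomeModel,
    SignalTrack,
    ValidationError,
)

__all__ = [
    "ParseError",
    "read_features",
    "write_features",
    "read_bedgraph",
    "write_bedgraph",
    "read_genome",
    "write_genome",
    "read_expression_table",
    "write_expression_table",
    "read_fasta",
    "write_fasta",
]

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input line; message carries the file and line number."""


def _fields(line: str) -> List[str]:
    return line.rstrip("\n").split("\t") if "\t" in line else line.split()


def _int_field(raw: str, path: PathLike, lineno: int, what: str) -> int:
    try:
        return int(raw)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: {what} is not an integer: {raw!r}") from None


def _opt_interval(lo_raw: str, hi_raw: str, path: PathLike, lineno: int,
                  what: str) -> Optional[Tuple[int, int]]:
    if lo_raw == "." and hi_raw == ".":
        return None
    return (_int_field(lo_raw, path, lineno, f"{what} start"),
            _int_field(hi_raw, path, lineno, f"{what} end"))


def read_features(path: PathLike, kind: str) -> list:
    """Read gene, CGI, or ERV records from a BED-style file.

    kind='gene': BED6; TSS/TTS assigned from strand (TSS at the left edge
    on +, at the right edge on -). kind='cgi': first 3 BED columns.
    kind='erv': the extended-BED dialect described in the module docstring.
    """
    if kind not in ("gene", "cgi", "erv"):
        raise ValueError(f"unknown feature kind {kind!r}")
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _fields(line)
            try:
                records.append(_parse_feature(f, kind, path, lineno))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return records


def _parse_feature(f: List[str], kind: str, path: PathLike, lineno: int):
    if kind == "cgi":
        if len(f) < 3:
            raise ParseError(f"{path}:{lineno}: CGI line needs >= 3 columns, got {len(f)}")
        return CgiInterval(chrom=f[0],
                           start=_int_field(f[1], path, lineno, "start"),
                           end=_int_field(f[2], path, lineno, "end"))
    if len(f) < 6:
        raise ParseError(f"{path}:{lineno}: {kind} line needs >= 6 columns, got {len(f)}")
    start = _int_field(f[1], path, lineno, "start")
    end = _int_field(f[2], path, lineno, "end")
    name, strand = f[3], f[5]
    if strand not in ("+", "-"):
        raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
    if kind == "gene":
        tss, tts = (start, end) if strand == "+" else (end, start)
        return GeneRecord(gene_id=name, chrom=f[0], strand=strand, tss=tss, tts=tts)
    # kind == "erv"
    if len(f) < 13:
        raise ParseError(f"{path}:{lineno}: ERV line needs 13 columns, got {len(f)}")
    return ErvRecord(
        erv_id=name, family=f[6], element_type=f[7], chrom=f[0],
        start=start, end=end, strand=strand,
        ltr5=_opt_interval(f[8], f[9], path, lineno, "ltr5"),
        ltr3=_opt_interval(f[10], f[11], path, lineno, "ltr3"),
        fixed_or_polymorphic=f[12],
    )


def write_features(path: PathLike, records: Sequence) -> None:
    """Write gene/CGI/ERV records back to their BED dialects (round-trips)."""
    with open(path, "w") as fh:
        for r in records:
            if isinstance(r, CgiInterval):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
            elif isinstance(r, GeneRecord):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\t0\t{r.strand}\n")
            elif isinstance(r, ErvRecord):
                l5 = r.ltr5 if r.ltr5 is not None else (".", ".")
                l3 = r.ltr3 if r.ltr3 is not None else (".", ".")
                fh.write("\t".join(map(str, [
                    r.chrom, r.start, r.end, r.erv_id, 0, r.strand,
                    r.family, r.element_type, l5[0], l5[1], l3[0], l3[1],
                    r.fixed_or_polymorphic])) + "\n")
            else:
                raise TypeError(f"cannot serialize {type(r).__name__}")


def read_bedgraph(path: PathLike) -> SignalTrack:
    """Read a 4-column bedGraph into a SignalTrack (gaps query as 0)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _fields(line)
            if len(f) < 4:
                raise ParseError(f"{path}:{lineno}: bedGraph line needs 4 columns, got {len(f)}")
            try:
                value = float(f[3])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad signal value {f[3]!r}") from None
            intervals.append((f[0],
                              _int_field(f[1], path, lineno, "start"),
                              _int_field(f[2], path, lineno, "end"),
                              value))
    return SignalTrack(intervals)


def write_bedgraph(path: PathLike, track: SignalTrack) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.intervals():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_genome(path: PathLike) -> GenomeModel:
    """Read a 2-column chrom-sizes file."""
    chroms = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = _fields(line)
            if len(f) < 2:
                raise ParseError(f"{path}:{lineno}: chrom-sizes line needs 2 columns")
            chroms.append((f[0], _int_field(f[1], path, lineno, "length")))
    return GenomeModel(chromosomes=tuple(chroms))


def write_genome(path: PathLike, genome: GenomeModel) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")


def read_expression_table(path: PathLike) -> ExpressionTable:
    """Read a TSV with columns gene_id, tissue, state in {expressed, silent}."""
    states: Dict[Tuple[str, str], bool] = {}
    genes: List[str] = []
    tissues: List[str] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            state = row["state"]
            if state not in ("expressed", "silent"):
                raise ParseError(f"{path}:{lineno}: bad state {state!r}")
            g, t = row["gene_id"], row["tissue"]
            if g not in genes:
                genes.append(g)
            if t not in tissues:
                tissues.append(t)
            states[(g, t)] = state == "expressed"
    return ExpressionTable(states, genes, tissues)


def write_expression_table(path: PathLike, table: ExpressionTable) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttissue\tstate\n")
        for g in table.genes:
            for t in table.tissues:
                state = "expressed" if table.is_expressed(g, t) else "silent"
                fh.write(f"{g}\t{t}\t{state}\n")


def read_fasta(path: PathLike) -> Dict[str, str]:
    """Minimal FASTA reader returning an ordered name -> sequence mapping."""
    seqs: Dict[str, str] = {}
    name = None
    chunks: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(path: PathLike, seqs: Dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
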