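"""Readers and writers for every external format the pipeline touches.

All genomic coordinates are stored 0-based half-open internally; any
conversion to a 1-based convention happens only at the I/O boundary.
Readers are total on valid inputs and raise on malformed ones — nothing
is silently skipped.

Formats handled here: CTSS tag tables (TSV: chrom, pos, strand, count),
UCSC chain files, BED6 locus annotations, FASTA, newick, Ct tables,
two-channel fluorescence traces and the candidate table emitted by the
screen.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A file violated the grammar of its declared format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class CtssRecord:
    """One CAGE 5'-end position: `count` tags start at `pos` on `strand`."""

    chrom: str
    pos: int
    strand: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"stored CTSS records need count >= 1, got {self.count}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.pos < 0:
            raise ValueError("pos must be >= 0")


class CtssLibrary:
    """One CAGE library: per-position 5'-end tag counts plus the library total.

    The total is the TPM denominator, so it always equals the sum of all
    stored counts.  Records are kept sorted by (chrom, pos, strand) in a
    DataFrame for vectorised interval counting.
    """

    def __init__(self, library_id: str, records: Iterable[CtssRecord]) -> None:
        self.library_id = library_id
        rows = [(r.chrom, r.pos, r.strand, r.count) for r in records]
        df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "count"])
        if len(df):
            df = df.astype({"pos": "int64", "count": "int64"})
            df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort")
            df = df.reset_index(drop=True)
        self.df = df
        self.total_tags = int(df["count"].sum()) if len(df) else 0

    @property
    def records(self) -> list[CtssRecord]:
        return [
            CtssRecord(r.chrom, int(r.pos), r.strand, int(r.count))
            for r in self.df.itertuples(index=False)
        ]

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class Chain:
    """One UCSC chain: colinear aligned blocks from a source to a target genome.

    Follows the UCSC convention that the file's `t` side is the source
    (coordinates being lifted FROM) and `q` the target.  Minus-strand
    target coordinates are converted at parse time to plus-strand
    half-open intervals; `blocks` keeps the raw (size, dt, dq) triples so
    writing round-trips exactly.
    """

    score: int
    source_name: str
    source_size: int
    source_start: int
    source_end: int
    target_name: str
    target_size: int
    target_strand: str  # '+' or '-'; source strand is always '+'
    target_start: int   # plus-strand coordinates, half-open
    target_end: int
    chain_id: str
    blocks: list[tuple[int, int, int]] = field(default_factory=list)

    def aligned_blocks(self) -> list[tuple[int, int, int]]:
        """Yield (source_start, source_end, target_start_stranded) per block.

        `target_start_stranded` is the position, in target-strand
        coordinates, aligned to `source_start`; callers convert to
        plus-strand space (see `map_position`).
        """
        out = []
        s = self.source_start
        # chain block coordinates on the target run in target-strand space
        t = self.target_size - self.target_end if self.target_strand == "-" else self.target_start
        for size, dt, dq in self.blocks:
            out.append((s, s + size, t))
            s += size + dt
            t += size + dq
        return out

    def map_position(self, pos: int) -> tuple[str, int, str] | None:
        """Map one source base to (target_chrom, target_pos_plus, strand)."""
        for bs, be, t0 in self.aligned_blocks():
            if bs <= pos < be:
                t_stranded = t0 + (pos - bs)
                if self.target_strand == "+":
                    return (self.target_name, t_stranded, "+")
                return (self.target_name, self.target_size - 1 - t_stranded, "-")
        return None


@dataclass
class ChainSet:
    chains: list[Chain]

    def overlapping(self, interval: GenomicInterval) -> list[Chain]:
        return [
            c
            for c in self.chains
            if c.source_name == interval.chrom
            and c.source_start < interval.end
            and interval.start < c.source_end
        ]


@dataclass(frozen=True)
class LocusAnnotation:
    """An annotated gene or pseudogene locus with its canonical TSS."""

    locus_id: str
    interval: GenomicInterval
    annotated_tss: int
    biotype: str = "gene"  # 'gene' or 'pseudogene'

    def __post_init__(self) -> None:
        iv = self.interval
        if not (iv.start <= self.annotated_tss <= iv.end - 1):
            raise ValueError(
                f"{self.locus_id}: annotated_tss {self.annotated_tss} outside "
                f"locus [{iv.start}, {iv.end})"
            )
        if self.biotype not in ("gene", "pseudogene"):
            raise ValueError(f"biotype must be gene|pseudogene, got {self.biotype!r}")


# ---------------------------------------------------------------------------
# CTSS
# ---------------------------------------------------------------------------

def read_ctss(path, library_id: str | None = None) -> CtssLibrary:
    """Read a CTSS table: tab-separated chrom, 0-based pos, strand, count."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(
                    f"{path}: line {lineno}: expected 4 tab-separated fields, "
                    f"got {len(parts)}"
                )
            chrom, pos_s, strand, count_s = parts
            try:
                pos, count = int(pos_s), int(count_s)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if count < 0:
                raise FormatError(f"{path}: line {lineno}: negative count {count}")
            if count == 0:
                raise FormatError(f"{path}: line {lineno}: zero count not storable")
            try:
                records.append(CtssRecord(chrom, pos, strand, count))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    if library_id is None:
        library_id = str(path)
    return CtssLibrary(library_id, records)


def write_ctss(library: CtssLibrary, path) -> None:
    with open(path, "w") as fh:
        for r in library.df.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.pos}\t{r.strand}\t{r.count}\n")


# ---------------------------------------------------------------------------
# UCSC chain
# ---------------------------------------------------------------------------

def read_chain(path) -> ChainSet:
    """Parse a UCSC chain file; block arithmetic is verified per chain."""
    chains: list[Chain] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or line.startswith("#"):
            continue
        if not line.startswith("chain"):
            raise FormatError(f"{path}: expected 'chain' header, got: {line!r}")
        f = line.split()
        if len(f) != 13:
            raise FormatError(f"{path}: malformed chain header: {line!r}")
        (_, score, t_name, t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end, cid) = f
        if t_strand != "+":
            raise FormatError(f"{path}: chain {cid}: source strand must be '+'")
        if q_strand not in ("+", "-"):
            raise FormatError(f"{path}: chain {cid}: bad target strand {q_strand!r}")
        t_size, t_start, t_end = int(t_size), int(t_start), int(t_end)
        q_size, q_start, q_end = int(q_size), int(q_start), int(q_end)
        blocks: list[tuple[int, int, int]] = []
        while i < len(lines):
            bl = lines[i].strip()
            i += 1
            if not bl:
                break
            parts = bl.split()
            if len(parts) == 1:
                blocks.append((int(parts[0]), 0, 0))
                break
            if len(parts) == 3:
                blocks.append((int(parts[0]), int(parts[1]), int(parts[2])))
            else:
                raise FormatError(f"{path}: chain {cid}: bad block line {bl!r}")
        if not blocks:
            raise FormatError(f"{path}: chain {cid}: no alignment blocks")
        if any(size < 1 for size, _, _ in blocks):
            raise FormatError(f"{path}: chain {cid}: block size < 1")
        t_span = sum(s + dt for s, dt, _ in blocks)
        q_span = sum(s + dq for s, _, dq in blocks)
        if t_span != t_end - t_start or q_span != q_end - q_start:
            raise FormatError(
                f"{path}: chain {cid}: blocks span ({t_span}, {q_span}) do not "
                f"reconstruct declared spans ({t_end - t_start}, {q_end - q_start})"
            )
        # store target coordinates on the plus strand, half-open
        if q_strand == "-":
            q_plus_start, q_plus_end = q_size - q_end, q_size - q_start
        else:
            q_plus_start, q_plus_end = q_start, q_end
        chains.append(
            Chain(
                score=int(score),
                source_name=t_name, source_size=t_size,
                source_start=t_start, source_end=t_end,
                target_name=q_name, target_size=q_size,
                target_strand=q_strand,
                target_start=q_plus_start, target_end=q_plus_end,
                chain_id=cid, blocks=blocks,
            )
        )
    return ChainSet(chains)


def write_chain(chain_set: ChainSet, path) -> None:
    with open(path, "w") as fh:
        for c in chain_set.chains:
            if c.target_strand == "-":
                q_start = c.target_size - c.target_end
                q_end = c.target_size - c.target_start
            else:
                q_start, q_end = c.target_start, c.target_end
            fh.write(
                f"chain {c.score} {c.source_name} {c.source_size} + "
                f"{c.source_start} {c.source_end} {c.target_name} "
                f"{c.target_size} {c.target_strand} {q_start} {q_end} "
                f"{c.chain_id}\n"
            )
            for j, (size, dt, dq) in enumerate(c.blocks):
                if j == len(c.blocks) - 1:
                    fh.write(f"{size}\n")
                else:
                    fh.write(f"{size} {dt} {dq}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def read_bed(path) -> list[LocusAnnotation]:
    """Read BED6 loci. The TSS is the start for '+' loci, end-1 for '-'.

    An optional 7th column carries the biotype (gene/pseudogene);
    absent means gene.
    """
    loci: list[LocusAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}: line {lineno}: need >= 6 BED fields")
            chrom, start_s, end_s, name, _score, strand = parts[:6]
            biotype = parts[6] if len(parts) > 6 else "gene"
            try:
                iv = GenomicInterval(chrom, int(start_s), int(end_s), strand)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if name in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate locus id {name!r}")
            seen.add(name)
            tss = iv.start if strand == "+" else iv.end - 1
            loci.append(LocusAnnotation(name, iv, tss, biotype))
    return loci


def write_bed(loci: Sequence[LocusAnnotation], path) -> None:
    with open(path, "w") as fh:
        for l in loci:
            iv = l.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{l.locus_id}\t0\t"
                f"{iv.strand}\t{l.biotype}\n"
            )


# ---------------------------------------------------------------------------
# FASTA / newick
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {label: sequence} mapping."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate FASTA label {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_newick(tree, path) -> None:
    """Serialise a phylogenetic tree (see parsimony_phylo.Tree) to newick."""
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Tabular: Ct tables, traces, candidate table
# ---------------------------------------------------------------------------

def read_ct_table(path) -> pd.DataFrame:
    """Ct TSV: columns sample, gene, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    needed = {"sample", "gene", "replicate", "ct"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: Ct table needs columns {sorted(needed)}")
    if not (df["ct"].gt(0) & df["ct"].notna()).all():
        raise FormatError(f"{path}: Ct values must be finite and > 0")
    return df


def write_ct_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_traces(path) -> pd.DataFrame:
    """Trace TSV: columns trace_id, time, f340, f380."""
    df = pd.read_csv(path, sep="\t")
    needed = {"trace_id", "time", "f340", "f380"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: trace table needs columns {sorted(needed)}")
    return df


def write_traces(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_candidates(table: pd.DataFrame, path) -> None:
    """Candidate table as TSV with header, deterministic column order."""
    table.to_csv(path, sep="\t", index=False)


def read_candidates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
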