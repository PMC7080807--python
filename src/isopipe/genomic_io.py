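"""Readers and writers for the plain-text formats used by the pipeline.

BED12 carries reads and isoforms, GTF carries annotation (in) and isoforms
(out), a TSV junction table carries short-read splice-junction support, and
TSVs carry the sample manifest and counts matrices.  All coordinate
normalization to the internal 0-based half-open convention happens here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .models import (
    Annotation,
    Blocks,
    Isoform,
    Junction,
    ReadAlignment,
    SampleManifest,
    Transcript,
    ValidationError,
)

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# BED12
# ---------------------------------------------------------------------------

def _blocks_from_bed12(
    chrom_start: int, chrom_end: int, count: int, sizes: str, starts: str, lineno: int
) -> Blocks:
    try:
        size_list = [int(x) for x in sizes.rstrip(",").split(",")]
        start_list = [int(x) for x in starts.rstrip(",").split(",")]
    except ValueError as exc:
        raise ParseError(f"line {lineno}: bad blockSizes/blockStarts") from exc
    if len(size_list) != count or len(start_list) != count:
        raise ParseError(
            f"line {lineno}: blockCount {count} does not match "
            f"{len(size_list)} sizes / {len(start_list)} starts"
        )
    blocks = tuple(
        (chrom_start + off, chrom_start + off + size)
        for off, size in zip(start_list, size_list)
    )
    if start_list[0] != 0 or blocks[-1][1] != chrom_end:
        raise ParseError(
            f"line {lineno}: blocks inconsistent with chromStart/chromEnd"
        )
    return blocks


def read_bed12(path: Union[str, os.PathLike], sample_id: str = "") -> list[ReadAlignment]:
    """Parse a BED12 file into :class:`ReadAlignment` records.

    ``strand`` "." is kept as unknown.  Record order is preserved.
    """
    out: list[ReadAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"line {lineno}: expected 12 fields, got {len(fields)}")
            try:
                chrom_start = int(fields[1])
                chrom_end = int(fields[2])
                count = int(fields[9])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinate") from exc
            blocks = _blocks_from_bed12(
                chrom_start, chrom_end, count, fields[10], fields[11], lineno
            )
            strand = fields[5] if fields[5] in ("+", "-") else "."
            try:
                out.append(
                    ReadAlignment(
                        read_id=fields[3],
                        chrom=fields[0],
                        strand=strand,
                        blocks=blocks,
                        sample_id=sample_id,
                    )
                )
            except ValidationError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    return out


def write_bed12(records: Iterable, path: Union[str, os.PathLike]) -> None:
    """Write reads or isoforms as BED12.

    Accepts any object with ``chrom``, ``strand``, ``blocks`` and either a
    ``read_id`` or ``isoform_id`` name attribute; isoform ``support`` is
    written to the score column when present.
    """
    with open(path, "w") as fh:
        for rec in records:
            name = getattr(rec, "read_id", None) or getattr(rec, "isoform_id", "")
            score = getattr(rec, "support", 0)
            blocks = rec.blocks
            start = blocks[0][0]
            end = blocks[-1][1]
            sizes = ",".join(str(e - s) for s, e in blocks)
            starts = ",".join(str(s - start) for s, e in blocks)
            fh.write(
                "\t".join(
                    [
                        rec.chrom,
                        str(start),
                        str(end),
                        name,
                        str(min(int(score), 1000)),
                        rec.strand if rec.strand in ("+", "-") else ".",
                        str(start),
                        str(end),
                        "0",
                        str(len(blocks)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path: Union[str, os.PathLike]) -> Annotation:
    """Parse a GTF into an :class:`Annotation`.

    Coordinates are converted from 1-based closed to 0-based half-open.
    Junctions are derived from consecutive exons of each transcript;
    single-exon transcripts contribute none.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    ann = Annotation()

    def _attr(feat, key: str) -> Optional[str]:
        vals = feat.attributes.get(key)
        return vals[0] if vals else None

    for feat in db.all_features():
        ftype = feat.featuretype
        if ftype not in ("exon", "start_codon", "stop_codon", "gene", "transcript"):
            continue
        gene_id = _attr(feat, "gene_id")
        biotype = _attr(feat, "gene_biotype") or _attr(feat, "gene_type")
        if gene_id and biotype and gene_id not in ann.gene_biotype:
            ann.gene_biotype[gene_id] = (
                "protein_coding" if biotype == "protein_coding" else "other"
            )
        if ftype in ("gene", "transcript"):
            continue
        tid = _attr(feat, "transcript_id")
        if tid is None:
            raise ParseError(f"{ftype} without transcript_id at {feat.seqid}:{feat.start}")
        iv = (feat.start - 1, feat.end)  # GTF 1-based closed -> half-open
        if ftype == "exon":
            exons.setdefault(tid, []).append(iv)
            meta[tid] = (gene_id or tid, feat.seqid, feat.strand)
        elif ftype == "start_codon":
            prev = ann.start_codons.get(tid)
            # keep the full codon span if split across lines
            ann.start_codons[tid] = (
                iv if prev is None else (min(prev[0], iv[0]), max(prev[1], iv[1]))
            )
        elif ftype == "stop_codon":
            prev = ann.stop_codons.get(tid)
            ann.stop_codons[tid] = (
                iv if prev is None else (min(prev[0], iv[0]), max(prev[1], iv[1]))
            )

    for tid, ivs in exons.items():
        gene_id, chrom, strand = meta[tid]
        ivs = sorted(ivs)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValidationError(
                    f"transcript {tid}: overlapping exons ({s1},{e1}) ({s2},{e2})"
                )
        ann.transcripts[tid] = Transcript(tid, gene_id, chrom, strand, tuple(ivs))
        ann.gene_biotype.setdefault(gene_id, "other")
    return ann


def write_gtf(
    isoforms: Iterable[Isoform],
    path: Union[str, os.PathLike],
    source: str = "isopipe",
    start_codons: Optional[Mapping[str, tuple[int, int]]] = None,
    gene_biotype: Optional[Mapping[str, str]] = None,
) -> None:
    """Write isoforms as GTF transcripts/exons (1-based closed on output)."""
    start_codons = start_codons or {}
    gene_biotype = gene_biotype or {}
    with open(path, "w") as fh:
        for iso in isoforms:
            gene = iso.gene_id or iso.isoform_id
            biotype = gene_biotype.get(gene, "protein_coding")
            attrs = (
                f'gene_id "{gene}"; transcript_id "{iso.isoform_id}"; '
                f'gene_biotype "{biotype}";'
            )
            strand = iso.strand if iso.strand in ("+", "-") else "."
            fh.write(
                "\t".join(
                    [
                        iso.chrom,
                        source,
                        "transcript",
                        str(iso.start + 1),
                        str(iso.end),
                        ".",
                        strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for s, e in iso.blocks:
                fh.write(
                    "\t".join(
                        [iso.chrom, source, "exon", str(s + 1), str(e), ".", strand, ".", attrs]
                    )
                    + "\n"
                )
            sc = start_codons.get(iso.isoform_id)
            if sc is not None:
                fh.write(
                    "\t".join(
                        [
                            iso.chrom,
                            source,
                            "start_codon",
                            str(sc[0] + 1),
                            str(sc[1]),
                            ".",
                            strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Junction support table
# ---------------------------------------------------------------------------

@dataclass
class JunctionSupport:
    """Short-read (and/or annotation) junction evidence.

    ``entries`` maps :class:`Junction` to ``(source, unique_read_count)``.
    """

    entries: dict[Junction, tuple[str, int]]

    def __contains__(self, j: Junction) -> bool:
        return j in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def read_junction_tab(
    path: Union[str, os.PathLike],
    min_unique: int = 3,
    one_based: bool = True,
) -> JunctionSupport:
    """Read a tab-delimited junction table.

    Columns: chrom, intron start, intron end, strand, unique read count.
    The default dialect is 1-based closed intron coordinates (STAR-style);
    set ``one_based=False`` for BED-style half-open input.  Entries below
    ``min_unique`` are dropped.
    """
    entries: dict[Junction, tuple[str, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(f"line {lineno}: expected 5 columns")
            chrom, start_s, end_s, strand, count_s = fields[:5]
            try:
                start, end, count = int(start_s), int(end_s), int(count_s)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer field") from exc
            if count < 0:
                raise ValidationError(f"line {lineno}: negative count {count}")
            if strand not in ("+", "-"):
                raise ParseError(f"line {lineno}: bad strand {strand!r}")
            if one_based:
                start -= 1  # closed 1-based start -> 0-based; end already half-open
            if count < min_unique:
                continue
            j = Junction(chrom, start, end, strand)
            prev = entries.get(j)
            if prev is not None:
                count = max(count, prev[1])
            entries[j] = ("short_read", count)
    return JunctionSupport(entries)


# ---------------------------------------------------------------------------
# Manifest and counts
# ---------------------------------------------------------------------------

def read_manifest(path: Union[str, os.PathLike]) -> SampleManifest:
    """Read a sample manifest TSV: sample_id, condition, batch (no header)."""
    samples: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"line {lineno}: expected sample, condition[, batch]")
            batch = fields[2] if len(fields) > 2 else "1"
            samples[fields[0]] = (fields[1], batch)
    return SampleManifest(samples)


def write_manifest(manifest: SampleManifest, path: Union[str, os.PathLike]) -> None:
    with open(path, "w") as fh:
        for sample, (cond, batch) in manifest.samples.items():
            fh.write(f"{sample}\t{cond}\t{batch}\n")


def read_counts(path: Union[str, os.PathLike]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    if (df.to_numpy() < 0).any():
        raise ValidationError("negative entries in counts matrix")
    return df


def write_counts(counts: pd.DataFrame, path: Union[str, os.PathLike]) -> None:
    counts.to_csv(path, sep="\t", index_label="isoform_id")


# ---------------------------------------------------------------------------
# Genome sequence
# ---------------------------------------------------------------------------

def open_genome(path: Union[str, os.PathLike]):
    """Open a FASTA genome for random access (pyfaidx-backed)."""
    from pyfaidx import Fasta

    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


def write_fasta(seqs: Mapping[str, str], path: Union[str, os.PathLike], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def contig_length(genome, chrom: str) -> int:
    seq = genome[chrom]
    return len(seq)


def extract_spliced_sequence(genome, chrom: str, blocks: Blocks, strand: str) -> str:
    """Concatenated exon sequence; reverse-complemented on the minus strand.

    ``genome`` may be a pyfaidx ``Fasta`` (raw mode) or a plain
    ``dict[str, str]``.
    """
    n = contig_length(genome, chrom)
    parts = []
    for s, e in blocks:
        if s < 0 or e > n:
            raise ValidationError(f"block ({s}, {e}) outside contig {chrom} (len {n})")
        parts.append(str(genome[chrom][s:e]).upper())
    seq = "".join(parts)
    return reverse_complement(seq) if strand == "-" else seq
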