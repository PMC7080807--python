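"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based half-open.  GTF input/output is converted
at the I/O boundary (:mod:`isopipe.genomic_io`); everything else in the
package assumes BED-style intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Iterable, Mapping, Optional, Sequence, Tuple

Blocks = Tuple[Tuple[int, int], ...]

STRANDS = ("+", "-", ".")


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


def _check_blocks(blocks: Blocks) -> None:
    if not blocks:
        raise ValidationError("at least one block required")
    prev_end = None
    for start, end in blocks:
        if end <= start:
            raise ValidationError(f"degenerate block ({start}, {end})")
        if prev_end is not None and start < prev_end:
            raise ValidationError(
                f"blocks overlap or are unsorted near ({start}, {end})"
            )
        prev_end = end


@dataclass(frozen=True, order=True)
class Junction:
    """One intron: ``start`` is the first intronic base, ``end`` one past the
    last.  Donor (5'SS) and acceptor (3'SS) designation is strand-dependent.
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"junction end {self.end} <= start {self.start}")

    @property
    def donor(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def acceptor(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def junctions_of_blocks(chrom: str, strand: str, blocks: Blocks) -> Tuple[Junction, ...]:
    return tuple(
        Junction(chrom, blocks[i][1], blocks[i + 1][0], strand)
        for i in range(len(blocks) - 1)
    )


@dataclass
class ReadAlignment:
    """One read's exon blocks on the genome."""

    read_id: str
    chrom: str
    strand: str  # "+", "-", or "." (unknown)
    blocks: Blocks
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.blocks = tuple(tuple(b) for b in self.blocks)
        _check_blocks(self.blocks)
        if self.strand not in STRANDS:
            raise ValidationError(f"bad strand {self.strand!r}")

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    def junctions(self) -> Tuple[Junction, ...]:
        strand = self.strand if self.strand != "." else "+"
        return junctions_of_blocks(self.chrom, strand, self.blocks)

    @property
    def is_spliced(self) -> bool:
        return len(self.blocks) > 1


@dataclass(frozen=True)
class JunctionChain:
    """Ordered splice junctions of a read or isoform; the identity key when
    collapsing reads into isoforms.  May be empty (single-exon)."""

    chrom: str
    strand: str
    junctions: Tuple[Junction, ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.junctions, self.junctions[1:]):
            if b.start < a.end:
                raise ValidationError("chain junctions unsorted or overlapping")

    def __len__(self) -> int:
        return len(self.junctions)

    def __iter__(self):
        return iter(self.junctions)


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    blocks: Blocks

    def __post_init__(self) -> None:
        self.blocks = tuple(tuple(b) for b in self.blocks)
        _check_blocks(self.blocks)

    def junctions(self) -> Tuple[Junction, ...]:
        return junctions_of_blocks(self.chrom, self.strand, self.blocks)

    @property
    def chain(self) -> JunctionChain:
        return JunctionChain(self.chrom, self.strand, self.junctions())

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]


@dataclass
class Annotation:
    """Parsed gene annotation: transcript structures plus the derived
    junction set, annotated start/stop codons, and gene biotypes."""

    transcripts: dict[str, Transcript] = field(default_factory=dict)
    start_codons: dict[str, Tuple[int, int]] = field(default_factory=dict)
    stop_codons: dict[str, Tuple[int, int]] = field(default_factory=dict)
    gene_biotype: dict[str, str] = field(default_factory=dict)

    @cached_property
    def junctions(self) -> frozenset[Junction]:
        out: set[Junction] = set()
        for tx in self.transcripts.values():
            out.update(tx.junctions())
        return frozenset(out)

    @cached_property
    def genes(self) -> dict[str, list[Transcript]]:
        out: dict[str, list[Transcript]] = {}
        for tx in self.transcripts.values():
            out.setdefault(tx.gene_id, []).append(tx)
        return out

    def coding_genes(self) -> set[str]:
        return {g for g, b in self.gene_biotype.items() if b == "protein_coding"}


ISOFORM_CATEGORIES = (
    "annotated",
    "novel_combination",
    "retained_intron",
    "novel_exon",
    "novel_site",
)


@dataclass
class Isoform:
    isoform_id: str
    chrom: str
    strand: str
    blocks: Blocks
    gene_id: Optional[str] = None
    support: int = 0
    category: Optional[str] = None

    def __post_init__(self) -> None:
        self.blocks = tuple(tuple(b) for b in self.blocks)
        _check_blocks(self.blocks)

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware genomic coordinate)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    def junctions(self) -> Tuple[Junction, ...]:
        return junctions_of_blocks(self.chrom, self.strand, self.blocks)

    @property
    def chain(self) -> JunctionChain:
        return JunctionChain(self.chrom, self.strand, self.junctions())

    @property
    def is_spliced(self) -> bool:
        return len(self.blocks) > 1


def blocks_from_chain(
    chain: JunctionChain, start: int, end: int
) -> Blocks:
    """Rebuild exon blocks from a junction chain plus outer coordinates."""
    if not chain.junctions:
        return ((start, end),)
    first = chain.junctions[0]
    last = chain.junctions[-1]
    if start >= first.start or end <= last.end:
        raise ValidationError(
            f"ends ({start}, {end}) do not enclose chain "
            f"[{first.start}, {last.end}]"
        )
    blocks = [(start, first.start)]
    for a, b in zip(chain.junctions, chain.junctions[1:]):
        blocks.append((a.end, b.start))
    blocks.append((last.end, end))
    return tuple(blocks)


@dataclass
class SampleManifest:
    """sample_id -> (condition, batch)."""

    samples: dict[str, Tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValidationError("manifest has no samples")

    @property
    def conditions(self) -> Tuple[str, ...]:
        seen: list[str] = []
        for cond, _ in self.samples.values():
            if cond not in seen:
                seen.append(cond)
        return tuple(seen)

    def condition_of(self, sample_id: str) -> str:
        return self.samples[sample_id][0]

    def samples_for(self, condition: str) -> list[str]:
        out = [s for s, (c, _) in self.samples.items() if c == condition]
        if not out:
            raise ValidationError(f"no samples for condition {condition!r}")
        return out

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)
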