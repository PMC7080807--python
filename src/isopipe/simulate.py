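"""Synthetic genomes, annotations, isoforms, and noisy long reads with
known ground truth.

Genes are laid out on a synthetic contig with planted alternative
splicing structures (cassette exons, alternative donors/acceptors,
retained introns).  Reads are drawn per isoform and sample with optional
splice-site jitter and 5' truncation; every stochastic choice is recorded
so downstream modules can be tested against the generating truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np

from . import genomic_io
from .models import (
    Annotation,
    Blocks,
    Isoform,
    ReadAlignment,
    SampleManifest,
    Transcript,
    ValidationError,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 5
    isoforms_per_gene: Tuple[int, int] = (2, 3)
    n_exons: Tuple[int, int] = (4, 6)
    exon_len: Tuple[int, int] = (100, 200)
    intron_len: Tuple[int, int] = (150, 300)
    alt_ss_delta: int = 21  # shift of a planted alternative splice site
    jitter: int = 0  # max |offset| per junction endpoint; 0 = noiseless
    jitter_min: int = 0  # >0 forces |offset| >= jitter_min
    truncation_prob: float = 0.0
    truncation_mode: str = "first_exon"  # or "transcript_frac"
    truncation_frac: Tuple[float, float] = (0.1, 0.5)
    samples: dict = field(default_factory=lambda: {"s1": "A"})
    reads_per_isoform: int = 10
    spacer: int = 800
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if self.jitter < 0 or self.jitter_min < 0:
            raise ValidationError("jitter must be >= 0")
        if self.truncation_mode not in ("first_exon", "transcript_frac"):
            raise ValidationError(f"bad truncation_mode {self.truncation_mode!r}")
        if self.exon_len[0] < 30:
            raise ValidationError("exons shorter than 30 nt are not supported")


@dataclass
class TruthGene:
    gene_id: str
    chrom: str
    strand: str
    isoforms: list[Isoform]
    variants: list[tuple[str, str]]  # (isoform_id, planted variant kind)
    start_codon: Optional[Tuple[int, int]] = None


@dataclass
class LocusSet:
    genome: dict[str, str]
    annotation: Annotation
    genes: list[TruthGene]

    @property
    def isoforms(self) -> list[Isoform]:
        return [iso for g in self.genes for iso in g.isoforms]


def _variant_kind(strand: str, kind: str) -> str:
    """Strand-aware event type of a planted structural variant."""
    if kind == "skip_exon":
        return "ES"
    if kind == "retain_intron":
        return "IR"
    if kind == "shift_exon_start":
        return "A3SS" if strand == "+" else "A5SS"
    return "A5SS" if strand == "+" else "A3SS"  # shift_exon_end


def _make_gene_blocks(
    rng: np.random.Generator, config: SimConfig, offset: int
) -> Blocks:
    k = int(rng.integers(config.n_exons[0], config.n_exons[1] + 1))
    blocks = []
    pos = offset
    for i in range(k):
        elen = int(rng.integers(config.exon_len[0], config.exon_len[1] + 1))
        blocks.append((pos, pos + elen))
        pos += elen
        if i < k - 1:
            pos += int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
    return tuple(blocks)


def _apply_variant(
    base: Blocks, kind: str, exon_idx: int, delta: int
) -> Optional[Blocks]:
    blocks = [list(b) for b in base]
    if kind == "skip_exon":
        if not 0 < exon_idx < len(blocks) - 1:
            return None
        del blocks[exon_idx]
    elif kind == "retain_intron":
        if exon_idx >= len(blocks) - 1:
            return None
        blocks[exon_idx][1] = blocks[exon_idx + 1][1]
        del blocks[exon_idx + 1]
    elif kind == "shift_exon_start":
        if exon_idx == 0 or delta >= blocks[exon_idx][1] - blocks[exon_idx][0] - 10:
            return None
        blocks[exon_idx][0] += delta
    elif kind == "shift_exon_end":
        if exon_idx >= len(blocks) - 1 or delta >= blocks[exon_idx][1] - blocks[exon_idx][0] - 10:
            return None
        blocks[exon_idx][1] -= delta
    else:
        raise ValueError(kind)
    return tuple(tuple(b) for b in blocks)


_VARIANT_CYCLE = ("skip_exon", "shift_exon_start", "retain_intron", "shift_exon_end")


def make_locus_set(config: SimConfig, rng: Optional[np.random.Generator] = None) -> LocusSet:
    """Deterministically build (genome, annotation, truth isoforms).

    One contig; genes alternate strand and are separated by spacers.  The
    first isoform of each gene carries the full exon structure; each
    additional isoform plants one structural variant (cassette skip,
    alternative splice-site shift, or intron retention).  Junction motifs
    (GT..AG in transcript orientation) and an ATG start codon are planted
    into the random background sequence.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    genes: list[TruthGene] = []
    annotation = Annotation()
    offset = config.spacer
    for g in range(config.n_genes):
        gene_id = f"g{g:03d}"
        strand = "+" if g % 2 == 0 else "-"
        base = _make_gene_blocks(rng, config, offset)
        n_iso = int(rng.integers(config.isoforms_per_gene[0], config.isoforms_per_gene[1] + 1))
        isoforms: list[Isoform] = []
        variants: list[tuple[str, str]] = []
        iso0 = Isoform(f"{gene_id}.i0", config.chrom, strand, base, gene_id=gene_id)
        isoforms.append(iso0)
        k = len(base)
        vi = 0
        attempts = 0
        while len(isoforms) < n_iso and attempts < 4 * n_iso:
            kind = _VARIANT_CYCLE[vi % len(_VARIANT_CYCLE)]
            exon_idx = 1 + (vi % max(1, k - 2))
            vi += 1
            attempts += 1
            if kind == "retain_intron" and strand == "-":
                # keep the retained intron away from the transcript-first
                # intron so 5' truncation cannot erase the discriminating
                # evidence of the IR isoform
                if exon_idx > k - 3:
                    exon_idx = k - 3
                if exon_idx < 1:
                    continue
            blocks = _apply_variant(base, kind, exon_idx, config.alt_ss_delta)
            if blocks is None or any(blocks == i.blocks for i in isoforms):
                continue
            iso = Isoform(
                f"{gene_id}.i{len(isoforms)}", config.chrom, strand, blocks, gene_id=gene_id
            )
            isoforms.append(iso)
            variants.append((iso.isoform_id, _variant_kind(strand, kind)))

        # start codon planted near the transcript 5' end of the base isoform
        if strand == "+":
            sc = (base[0][0] + 9, base[0][0] + 12)
        else:
            sc = (base[-1][1] - 12, base[-1][1] - 9)
        genes.append(TruthGene(gene_id, config.chrom, strand, isoforms, variants, sc))

        for iso in isoforms:
            tid = iso.isoform_id
            annotation.transcripts[tid] = Transcript(
                tid, gene_id, config.chrom, strand, iso.blocks
            )
        annotation.start_codons[f"{gene_id}.i0"] = sc
        annotation.gene_biotype[gene_id] = "protein_coding"
        offset = base[-1][1] + config.spacer

    # random background sequence, then plant splice motifs and start codons
    length = offset + config.spacer
    arr = _BASES[rng.integers(0, 4, size=length)].copy()

    def put(pos: int, s: str) -> None:
        arr[pos : pos + len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)

    for gene in genes:
        for iso in gene.isoforms:
            for j in iso.junctions():
                if gene.strand == "+":
                    put(j.start, "GT")
                    put(j.end - 2, "AG")
                else:
                    put(j.start, "CT")
                    put(j.end - 2, "AC")
        if gene.start_codon is not None:
            put(gene.start_codon[0], "ATG" if gene.strand == "+" else "CAT")

    genome = {config.chrom: arr.tobytes().decode()}
    return LocusSet(genome, annotation, genes)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadTruth:
    isoform_id: str
    truncation: int  # 5' nt removed (transcript space)
    jitter: list  # per junction (donor-side delta, acceptor-side delta)


@dataclass
class GroundTruth:
    reads: dict[str, ReadTruth] = field(default_factory=dict)
    counts: dict[str, dict[str, int]] = field(default_factory=dict)  # iso -> sample -> n

    def to_json(self) -> str:
        return json.dumps(
            {
                "reads": {r: asdict(t) for r, t in self.reads.items()},
                "counts": self.counts,
            },
            indent=1,
            sort_keys=True,
        )


def uniform_abundance(
    isoforms: Sequence[Isoform], samples: Mapping[str, str], reads_per_isoform: int
) -> dict[str, dict[str, int]]:
    return {
        iso.isoform_id: {s: reads_per_isoform for s in samples} for iso in isoforms
    }


def abundance_from_psi(
    inclusion_id: str,
    exclusion_id: str,
    psi_by_condition: Mapping[str, float],
    coverage: int,
    samples: Mapping[str, str],
) -> dict[str, dict[str, int]]:
    """Split a fixed per-sample coverage between the inclusion and exclusion
    isoforms of a planted event according to a per-condition PSI (0-100)."""
    out = {inclusion_id: {}, exclusion_id: {}}
    for sample, cond in samples.items():
        psi = psi_by_condition[cond]
        inc = int(round(coverage * psi / 100.0))
        out[inclusion_id][sample] = inc
        out[exclusion_id][sample] = coverage - inc
    return out


def _truncate_blocks(blocks: Blocks, strand: str, loss: int) -> Blocks:
    """Remove ``loss`` nt from the transcript 5' end, mapped to the genome."""
    if loss <= 0:
        return blocks
    ordered = list(blocks) if strand == "+" else list(reversed(blocks))
    out: list[tuple[int, int]] = []
    remaining = loss
    for idx, (s, e) in enumerate(ordered):
        ln = e - s
        if remaining >= ln:
            remaining -= ln
            continue
        if strand == "+":
            out.append((s + remaining, e))
        else:
            out.append((s, e - remaining))
        out += ordered[idx + 1 :]
        break
    if not out:  # degenerate: keep the transcript's last base
        s, e = ordered[-1]
        out = [(e - 1, e)] if strand == "+" else [(s, s + 1)]
    return tuple(sorted(out))


def _jitter_blocks(
    blocks: Blocks, rng: np.random.Generator, jmax: int, jmin: int
) -> tuple[Blocks, list]:
    """Independently jitter every junction endpoint; exons never collapse
    below 1 nt (deltas are clamped).  Returns blocks and applied deltas."""
    bl = [list(b) for b in blocks]
    applied = []

    def draw() -> int:
        if jmax == 0:
            return 0
        if jmin <= 0:
            return int(rng.integers(-jmax, jmax + 1))
        mag = int(rng.integers(jmin, jmax + 1))
        sign = 1 if rng.integers(0, 2) else -1
        return sign * mag

    for i in range(len(bl) - 1):
        d_end = draw()  # moves left block end (donor side on +)
        d_start = draw()  # moves right block start
        new_end = bl[i][1] + d_end
        if new_end <= bl[i][0]:
            new_end = bl[i][0] + 1
        new_start = bl[i + 1][0] + d_start
        if new_start >= bl[i + 1][1]:
            new_start = bl[i + 1][1] - 1
        if new_start < new_end:  # keep the intron non-degenerate
            new_start = new_end + 1 if new_end + 1 < bl[i + 1][1] else bl[i + 1][0]
        applied.append((new_end - blocks[i][1], new_start - blocks[i + 1][0]))
        bl[i][1] = new_end
        bl[i + 1][0] = new_start
    return tuple(tuple(b) for b in bl), applied


def simulate_reads(
    locus: LocusSet,
    config: SimConfig,
    abundance: Optional[Mapping[str, Mapping[str, int]]] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[ReadAlignment], GroundTruth]:
    """Generate reads per isoform and sample with recorded ground truth."""
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    if abundance is None:
        abundance = uniform_abundance(locus.isoforms, config.samples, config.reads_per_isoform)

    by_id = {iso.isoform_id: iso for iso in locus.isoforms}
    truth = GroundTruth()
    reads: list[ReadAlignment] = []
    for sample in sorted(config.samples):
        for iso_id in sorted(abundance):
            n = abundance[iso_id].get(sample, 0)
            if n <= 0:
                continue
            iso = by_id[iso_id]
            truth.counts.setdefault(iso_id, {})[sample] = n
            first_exon_tx_len = (
                iso.blocks[0][1] - iso.blocks[0][0]
                if iso.strand == "+"
                else iso.blocks[-1][1] - iso.blocks[-1][0]
            )
            for i in range(n):
                read_id = f"{sample}:{iso_id}:{i}"
                blocks = iso.blocks
                loss = 0
                if config.truncation_prob > 0 and rng.random() < config.truncation_prob:
                    if config.truncation_mode == "first_exon":
                        loss = int(rng.integers(0, max(1, first_exon_tx_len - 1)))
                    else:
                        frac = rng.uniform(*config.truncation_frac)
                        loss = int(frac * iso.spliced_length)
                    blocks = _truncate_blocks(blocks, iso.strand, loss)
                blocks, applied = _jitter_blocks(blocks, rng, config.jitter, config.jitter_min)
                reads.append(
                    ReadAlignment(read_id, iso.chrom, iso.strand, blocks, sample)
                )
                truth.reads[read_id] = ReadTruth(iso_id, loss, applied)
    return reads, truth


def write_simulation(
    outdir,
    locus: LocusSet,
    reads: Sequence[ReadAlignment],
    config: SimConfig,
    truth: GroundTruth,
) -> None:
    """Emit genome.fa, annotation.gtf, reads.<sample>.bed, manifest.tsv and
    truth.json into ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    genomic_io.write_fasta(locus.genome, os.path.join(outdir, "genome.fa"))
    start_codons = {
        f"{g.gene_id}.i0": g.start_codon for g in locus.genes if g.start_codon
    }
    genomic_io.write_gtf(
        locus.isoforms,
        os.path.join(outdir, "annotation.gtf"),
        start_codons=start_codons,
        gene_biotype={g.gene_id: "protein_coding" for g in locus.genes},
    )
    by_sample: dict[str, list[ReadAlignment]] = {}
    for r in reads:
        by_sample.setdefault(r.sample_id, []).append(r)
    for sample, rs in sorted(by_sample.items()):
        genomic_io.write_bed12(rs, os.path.join(outdir, f"reads.{sample}.bed"))
    manifest = SampleManifest({s: (c, "1") for s, c in config.samples.items()})
    genomic_io.write_manifest(manifest, os.path.join(outdir, "manifest.tsv"))
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        fh.write(truth.to_json())
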