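import numpy as np
import pytest

from isopipe.models import Annotation, Isoform, Junction, Transcript


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genome():
    # 120 nt with fixed content for sequence-dependent assertions
    rng = np.random.default_rng(7)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=120))
    return {"chr1": seq}


def make_transcript(tid, gene, chrom, strand, blocks):
    return Transcript(tid, gene, chrom, strand, tuple(blocks))


@pytest.fixture
def two_exon_annotation():
    ann = Annotation()
    ann.transcripts["t1"] = make_transcript(
        "t1", "gA", "chr1", "+", [(100, 200), (300, 400)]
    )
    ann.gene_biotype["gA"] = "protein_coding"
    return ann


def random_gene_isoforms(rng, gene_id="g", chrom="chrR", strand="+", max_isoforms=8):
    """Random same-gene isoform set built over a shared boundary grid so
    junctions coincide across isoforms (exercises event callers)."""
    n_exons = int(rng.integers(3, 7))
    bounds = []
    pos = int(rng.integers(0, 50))
    for _ in range(n_exons):
        pos += int(rng.integers(40, 120))
        s = pos
        pos += int(rng.integers(40, 120))
        bounds.append((s, pos))
    base = tuple(bounds)
    isoforms = [Isoform(f"{gene_id}.0", chrom, strand, base, gene_id=gene_id)]
    n_extra = int(rng.integers(1, max_isoforms))
    for i in range(n_extra):
        kind = rng.choice(["skip", "shift_start", "shift_end", "retain"])
        blocks = [list(b) for b in base]
        k = len(blocks)
        if kind == "skip" and k > 2:
            del blocks[int(rng.integers(1, k - 1))]
        elif kind == "shift_start":
            j = int(rng.integers(1, k))
            delta = int(rng.integers(3, 30))
            if blocks[j][1] - blocks[j][0] > delta + 5:
                blocks[j][0] += delta
        elif kind == "shift_end":
            j = int(rng.integers(0, k - 1))
            delta = int(rng.integers(3, 30))
            if blocks[j][1] - blocks[j][0] > delta + 5:
                blocks[j][1] -= delta
        elif kind == "retain" and k > 1:
            j = int(rng.integers(0, k - 1))
            blocks[j][1] = blocks[j + 1][1]
            del blocks[j + 1]
        cand = tuple(tuple(b) for b in blocks)
        if any(cand == iso.blocks for iso in isoforms):
            continue
        isoforms.append(
            Isoform(f"{gene_id}.{len(isoforms)}", chrom, strand, cand, gene_id=gene_id)
        )
    return isoforms


def random_isoform_set(rng, n_genes=4):
    out = []
    for g in range(n_genes):
        strand = "+" if int(rng.integers(0, 2)) else "-"
        out.extend(
            random_gene_isoforms(rng, gene_id=f"g{g}", chrom=f"chr{g}", strand=strand)
        )
    return out
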