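"""Collapse fully corrected reads into a high-confidence isoform set.

Reads sharing a junction chain are grouped; each group yields one
representative isoform with transcription start/end sites called from read
end density (best_only mode).  All reads — including those that could not
be fully corrected — are then reassigned to first-pass isoforms under a
unique-best-match contract, and isoforms below the supporting-read
threshold are dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np

from .models import (
    Annotation,
    Isoform,
    Junction,
    JunctionChain,
    ReadAlignment,
    blocks_from_chain,
)


@dataclass
class ReadGroup:
    chain: JunctionChain
    reads: list[ReadAlignment]


def group_by_chain(reads: Iterable[ReadAlignment]) -> list[ReadGroup]:
    """Group fully corrected reads by exact junction-chain equality.

    Single-exon reads (empty chains) are grouped separately by overlapping
    locus (single-linkage interval overlap per chrom/strand).
    """
    spliced: dict[tuple, ReadGroup] = {}
    single: dict[tuple[str, str], list[ReadAlignment]] = {}
    for read in reads:
        if read.is_spliced:
            chain = JunctionChain(read.chrom, read.strand, read.junctions())
            key = (read.chrom, read.strand, chain.junctions)
            grp = spliced.get(key)
            if grp is None:
                spliced[key] = ReadGroup(chain, [read])
            else:
                grp.reads.append(read)
        else:
            single.setdefault((read.chrom, read.strand), []).append(read)

    groups = list(spliced.values())
    for (chrom, strand), rs in single.items():
        rs_sorted = sorted(rs, key=lambda r: (r.start, r.end))
        cluster: list[ReadAlignment] = []
        cluster_end = None
        for r in rs_sorted:
            if cluster and r.start >= cluster_end:
                groups.append(ReadGroup(JunctionChain(chrom, strand, ()), cluster))
                cluster = []
                cluster_end = None
            cluster.append(r)
            cluster_end = r.end if cluster_end is None else max(cluster_end, r.end)
        if cluster:
            groups.append(ReadGroup(JunctionChain(chrom, strand, ()), cluster))
    return groups


def _cluster_mode(coords: Sequence[int], window: int, outward: str) -> int:
    """Single-linkage cluster coordinates within ``window``; return the modal
    coordinate of the largest cluster.

    ``outward`` is "left" for start sites and "right" for end sites; ties
    (equal cluster sizes, equal mode frequencies) resolve to the coordinate
    producing the longer transcript, i.e. the outward-most one.
    """
    xs = sorted(coords)
    clusters: list[list[int]] = [[xs[0]]]
    for x in xs[1:]:
        if x - clusters[-1][-1] <= window:
            clusters[-1].append(x)
        else:
            clusters.append([x])

    def mode_of(cluster: list[int]) -> int:
        counts = Counter(cluster)
        top = max(counts.values())
        modes = [c for c, n in counts.items() if n == top]
        return min(modes) if outward == "left" else max(modes)

    best = None
    best_key = None
    for cl in clusters:
        m = mode_of(cl)
        # larger cluster wins; tie -> outward-most mode
        tiebreak = -m if outward == "left" else m
        key = (len(cl), tiebreak)
        if best_key is None or key > best_key:
            best, best_key = m, key
    return best


def call_ends(
    reads: Sequence[ReadAlignment], end_window: int = 100
) -> tuple[int, int]:
    """Representative (genomic start, genomic end) for a read group.

    Start and end coordinates are clustered independently within
    ``end_window`` and the modal coordinate of the dominant cluster is
    returned for each (best_only mode).
    """
    if not reads:
        raise ValueError("empty read group")
    start = _cluster_mode([r.start for r in reads], end_window, "left")
    end = _cluster_mode([r.end for r in reads], end_window, "right")
    return start, end


def first_pass(
    groups: Iterable[ReadGroup],
    end_window: int = 100,
    id_prefix: str = "iso",
) -> list[Isoform]:
    """One representative isoform per junction chain (best_only)."""
    isoforms: list[Isoform] = []
    ordered = sorted(
        groups,
        key=lambda g: (
            g.chain.chrom,
            g.chain.strand,
            g.reads[0].start,
            tuple((j.start, j.end) for j in g.chain.junctions),
        ),
    )
    for i, grp in enumerate(ordered):
        start, end = call_ends(grp.reads, end_window)
        blocks = blocks_from_chain(grp.chain, start, end)
        isoforms.append(
            Isoform(
                isoform_id=f"{id_prefix}{i:05d}",
                chrom=grp.chain.chrom,
                strand=grp.chain.strand,
                blocks=blocks,
                support=len(grp.reads),
            )
        )
    return isoforms


@dataclass
class Assignment:
    isoform_id: Optional[str]
    reason: str  # unique | ambiguous | no_match | too_short


def _match_chain(
    read_junctions: Tuple[Junction, ...],
    iso_junctions: Tuple[Junction, ...],
    window: int,
) -> Optional[tuple[int, int]]:
    """Match read junctions to a contiguous subchain of the isoform chain.

    Returns (first, last) matched isoform indices, or None.
    """
    if not read_junctions:
        return None
    idxs = []
    for rj in read_junctions:
        hit = None
        for k, ij in enumerate(iso_junctions):
            if abs(rj.start - ij.start) <= window and abs(rj.end - ij.end) <= window:
                hit = k
                break
        if hit is None:
            return None
        idxs.append(hit)
    for a, b in zip(idxs, idxs[1:]):
        if b != a + 1:
            return None
    return idxs[0], idxs[-1]


def _compatible(
    read: ReadAlignment, iso: Isoform, window: int, end_slack: int
) -> bool:
    if read.chrom != iso.chrom:
        return False
    if read.strand in ("+", "-") and read.strand != iso.strand:
        return False
    if not read.is_spliced:
        # single-exon read must lie within one isoform exon; terminal exons
        # are extended by end_slack to tolerate ragged ends
        s, e = read.blocks[0]
        n = len(iso.blocks)
        for k, (bs, be) in enumerate(iso.blocks):
            lo = bs - end_slack if k == 0 else bs
            hi = be + end_slack if k == n - 1 else be
            if s >= lo and e <= hi:
                return True
        return False
    match = _match_chain(read.junctions(), iso.junctions(), window)
    if match is None:
        return False
    first, last = match
    chain = iso.junctions()
    # the read's outer exons must not span further isoform junctions
    # (otherwise the read retains an intron relative to this isoform)
    if first > 0 and read.start < chain[first - 1].end - window:
        return False
    if last < len(chain) - 1 and read.end > chain[last + 1].start + window:
        return False
    if read.start < iso.start - end_slack or read.end > iso.end + end_slack:
        return False
    return True


def assign_reads(
    reads: Iterable[ReadAlignment],
    isoforms: Sequence[Isoform],
    window: int = 10,
    end_slack: int = 200,
) -> dict[str, Assignment]:
    """Assign every read to at most one isoform.

    A read compatible with exactly one isoform is assigned (unique); >1
    compatible isoforms leave it unassigned (ambiguous — the structural
    analogue of a MAPQ < 1 realignment), 0 leave it no_match.  Single-exon
    reads matching several isoforms are flagged too_short.
    """
    if not isoforms:
        raise ValueError("isoform set is empty")
    by_chrom: dict[str, list[Isoform]] = {}
    for iso in isoforms:
        by_chrom.setdefault(iso.chrom, []).append(iso)
    out: dict[str, Assignment] = {}
    for read in reads:
        hits = [
            iso
            for iso in by_chrom.get(read.chrom, ())
            if _compatible(read, iso, window, end_slack)
        ]
        if len(hits) == 1:
            out[read.read_id] = Assignment(hits[0].isoform_id, "unique")
        elif len(hits) == 0:
            out[read.read_id] = Assignment(None, "no_match")
        else:
            reason = "ambiguous" if read.is_spliced else "too_short"
            out[read.read_id] = Assignment(None, reason)
    return out


def filter_isoforms(
    isoforms: Sequence[Isoform],
    assignment: Mapping[str, Assignment],
    min_support: int = 3,
) -> list[Isoform]:
    """Keep isoforms with >= ``min_support`` uniquely assigned reads."""
    support = Counter(
        a.isoform_id for a in assignment.values() if a.reason == "unique"
    )
    kept = []
    for iso in isoforms:
        n = support.get(iso.isoform_id, 0)
        if n >= min_support:
            iso.support = n
            kept.append(iso)
    return kept


def _exonic_overlap(blocks_a, blocks_b) -> int:
    total = 0
    for s1, e1 in blocks_a:
        for s2, e2 in blocks_b:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def assign_gene(iso: Isoform, annotation: Annotation) -> Optional[str]:
    """Annotated gene sharing the most junctions; ties break by exonic
    overlap; no overlap at all returns None (caller invents a locus id)."""
    iso_j = set(iso.junctions())
    candidates: list[tuple[int, int, str]] = []
    for gene_id, txs in annotation.genes.items():
        shared = 0
        overlap = 0
        for tx in txs:
            if tx.chrom != iso.chrom or tx.strand != iso.strand:
                continue
            shared = max(shared, len(iso_j & set(tx.junctions())))
            overlap = max(overlap, _exonic_overlap(iso.blocks, tx.blocks))
        if shared or overlap:
            candidates.append((shared, overlap, gene_id))
    if not candidates:
        return None
    # most shared junctions, then most exonic overlap, then smallest gene id
    candidates.sort(key=lambda t: (-t[0], -t[1], t[2]))
    return candidates[0][2]


def categorize_vs_annotation(iso: Isoform, annotation: Annotation) -> str:
    """Compare an isoform's structure with the annotation.

    Precedence: annotated > novel_site > retained_intron > novel_exon >
    novel_combination.
    """
    iso_chain = iso.junctions()
    gene = iso.gene_id if iso.gene_id in annotation.genes else assign_gene(iso, annotation)
    gene_txs = annotation.genes.get(gene, []) if gene else []

    for tx in annotation.transcripts.values():
        if (
            tx.chrom == iso.chrom
            and tx.strand == iso.strand
            and tx.junctions() == iso_chain
        ):
            return "annotated"

    ann_sites: set[tuple[str, int]] = set()
    for j in annotation.junctions:
        if j.chrom == iso.chrom and j.strand == iso.strand:
            ann_sites.add(("donor", j.donor))
            ann_sites.add(("acceptor", j.acceptor))
    for j in iso_chain:
        if ("donor", j.donor) not in ann_sites or ("acceptor", j.acceptor) not in ann_sites:
            return "novel_site"

    gene_junctions: set[Junction] = set()
    gene_exons: list[tuple[int, int]] = []
    for tx in gene_txs:
        gene_junctions.update(tx.junctions())
        gene_exons.extend(tx.blocks)
    for aj in gene_junctions:
        for s, e in iso.blocks:
            if s <= aj.start and aj.end <= e:
                return "retained_intron"
    for s, e in iso.blocks:
        if not any(min(e, ge) > max(s, gs) for gs, ge in gene_exons):
            return "novel_exon"
    return "novel_combination"


def annotate_isoforms(isoforms: Sequence[Isoform], annotation: Annotation) -> None:
    """Fill gene_id and category in place."""
    for iso in isoforms:
        gene = assign_gene(iso, annotation)
        iso.gene_id = gene if gene is not None else f"novel_locus_{iso.chrom}_{iso.start}"
        iso.category = categorize_vs_annotation(iso, annotation)


def collapse_pipeline(
    corrected: Sequence[ReadAlignment],
    all_reads: Sequence[ReadAlignment],
    annotation: Optional[Annotation] = None,
    min_support: int = 3,
    end_window: int = 100,
    window: int = 10,
    end_slack: int = 200,
) -> tuple[list[Isoform], dict[str, Assignment]]:
    """correct-read groups -> first pass -> reassignment -> support filter."""
    groups = group_by_chain(corrected)
    firstpass = first_pass(groups, end_window=end_window)
    assignment = assign_reads(all_reads, firstpass, window=window, end_slack=end_slack)
    final = filter_isoforms(firstpass, assignment, min_support=min_support)
    # restrict the reported assignment to surviving isoforms
    surviving = {iso.isoform_id for iso in final}
    for rid, a in assignment.items():
        if a.isoform_id is not None and a.isoform_id not in surviving:
            assignment[rid] = Assignment(None, "no_match")
    if annotation is not None:
        annotate_isoforms(final, annotation)
    return final, assignment


def saturation_curve(
    reads: Sequence[ReadAlignment],
    depths: Sequence[int],
    run: Callable[[Sequence[ReadAlignment]], Sequence],
    seed: int = 0,
) -> dict[int, int]:
    """Subsample reads without replacement at each depth and re-run ``run``
    (a callable returning the final isoform list); report isoform counts."""
    out: dict[int, int] = {}
    for depth in depths:
        if depth > len(reads):
            raise ValueError(f"depth {depth} exceeds {len(reads)} reads")
        if depth == 0:
            out[0] = 0
            continue
        rng = np.random.default_rng([seed, depth])
        idx = rng.choice(len(reads), size=depth, replace=False)
        sub = [reads[i] for i in sorted(idx)]
        out[depth] = len(run(sub))
    return out
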