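"""Isoform productivity classification via annotated start codons and the
55-nt premature-termination-codon rule.

An isoform is translated from an annotated start codon that projects into
its exons; if the first in-frame stop ends 55 nt or more upstream of the
last splice junction (in transcript coordinates) the isoform is
unproductive.  Two start-selection strategies (5'-most vs longest ORF) must
agree, otherwise the isoform is excluded as ambiguous.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .diffsplice import SpliceEvent, mann_whitney_u
from .genomic_io import extract_spliced_sequence
from .models import Annotation, Isoform, SampleManifest
from .quantify import fold_change

STOP_CODONS = ("TAA", "TAG", "TGA")

CALLS = ("productive", "unproductive", "no_start_stop", "ambiguous_excluded")


@dataclass
class ProductivityCall:
    isoform_id: str
    call: str
    start_tx: Optional[int] = None  # transcript coordinate of the start codon
    stop_tx: Optional[int] = None  # transcript coordinate of the stop's last base
    last_junction_tx: Optional[int] = None
    ptc_distance: Optional[int] = None


def genomic_to_tx(iso: Isoform, g: int) -> Optional[int]:
    """Map a genomic base position into transcript coordinates, or None if
    it falls outside the isoform's exons."""
    blocks = iso.blocks if iso.strand == "+" else tuple(reversed(iso.blocks))
    cum = 0
    for s, e in blocks:
        if s <= g < e:
            return cum + (g - s if iso.strand == "+" else e - 1 - g)
        cum += e - s
    return None


def last_junction_tx(iso: Isoform) -> Optional[int]:
    """Transcript coordinate of the 3'-most splice junction (the boundary
    before the final exon), or None for single-exon isoforms."""
    if not iso.is_spliced:
        return None
    last_exon = iso.blocks[-1] if iso.strand == "+" else iso.blocks[0]
    return iso.spliced_length - (last_exon[1] - last_exon[0])


def _candidate_starts(iso: Isoform, annotation: Annotation, seq: str) -> list[int]:
    """Transcript positions of annotated start codons that project wholly
    into the isoform's exons and still read ATG after splicing."""
    out: set[int] = set()
    for tid, (s, e) in annotation.start_codons.items():
        tx = annotation.transcripts.get(tid)
        if tx is not None and (tx.chrom != iso.chrom or tx.strand != iso.strand):
            continue
        positions = [genomic_to_tx(iso, g) for g in range(s, e)]
        mapped = sorted(p for p in positions if p is not None)
        if len(mapped) != 3:
            continue
        t0 = mapped[0]
        # the three bases must be the codon's spliced projection, in order
        if mapped != [t0, t0 + 1, t0 + 2] and len(set(mapped)) != 3:
            continue
        if seq[mapped[0]] + seq[mapped[1]] + seq[mapped[2]] != "ATG":
            continue
        # a junction-split codon is allowed only if the spliced trimer is
        # contiguous in transcript space
        if mapped != [t0, t0 + 1, t0 + 2]:
            continue
        out.add(t0)
    return sorted(out)


def _first_stop(seq: str, t0: int) -> Optional[int]:
    """Transcript position of the first in-frame stop codon at/after t0."""
    for i in range(t0, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return i
    return None


def classify_productivity(
    iso: Isoform,
    annotation: Annotation,
    genome,
    ptc_min: int = 55,
) -> ProductivityCall:
    """Classify one isoform as productive / unproductive / no_start_stop /
    ambiguous_excluded.

    ptc_distance = (transcript coordinate of the last splice junction) -
    (1-based transcript coordinate of the stop codon's last base);
    unproductive iff ptc_distance >= ``ptc_min``.  Single-exon isoforms have
    no junction and are productive whenever an ORF exists.
    """
    seq = extract_spliced_sequence(genome, iso.chrom, iso.blocks, iso.strand)
    starts = _candidate_starts(iso, annotation, seq)
    if not starts:
        return ProductivityCall(iso.isoform_id, "no_start_stop")

    ljt = last_junction_tx(iso)

    def evaluate(t0: int) -> ProductivityCall:
        stop = _first_stop(seq, t0)
        if stop is None:
            return ProductivityCall(iso.isoform_id, "no_start_stop", start_tx=t0)
        stop_last = stop + 2
        if ljt is None:
            return ProductivityCall(
                iso.isoform_id, "productive", start_tx=t0, stop_tx=stop_last
            )
        dist = ljt - (stop_last + 1)
        call = "unproductive" if dist >= ptc_min else "productive"
        return ProductivityCall(
            iso.isoform_id,
            call,
            start_tx=t0,
            stop_tx=stop_last,
            last_junction_tx=ljt,
            ptc_distance=dist,
        )

    # strategy 1: 5'-most start; strategy 2: start yielding the longest ORF
    s1 = starts[0]

    def orf_len(t0: int) -> int:
        stop = _first_stop(seq, t0)
        return (stop + 3 - t0) if stop is not None else (len(seq) - t0)

    s2 = max(starts, key=lambda t0: (orf_len(t0), -t0))
    call1 = evaluate(s1)
    if s1 == s2:
        return call1
    call2 = evaluate(s2)
    if call1.call != call2.call:
        return ProductivityCall(iso.isoform_id, "ambiguous_excluded")
    return call1


def classify_all(
    isoforms: Sequence[Isoform],
    annotation: Annotation,
    genome,
    ptc_min: int = 55,
) -> dict[str, ProductivityCall]:
    return {
        iso.isoform_id: classify_productivity(iso, annotation, genome, ptc_min)
        for iso in isoforms
    }


# ---------------------------------------------------------------------------
# Cross-tabulations
# ---------------------------------------------------------------------------

CROSSTAB_CATEGORIES = (
    "productive_spliced",
    "productive_IR",
    "unproductive_spliced",
    "unproductive_IR",
)


@dataclass
class ProductivityCrossTab:
    members: dict[str, list[str]]  # category -> isoform ids
    log2_fc: dict[str, list[float]]  # category -> fold changes
    tests: dict[Tuple[str, str], Tuple[float, float]]  # (cat, cat) -> (U, p)


def ir_productivity_crosstab(
    isoforms: Sequence[Isoform],
    calls: Mapping[str, ProductivityCall],
    ir_events: Sequence[SpliceEvent],
    norm: pd.DataFrame,
    manifest: SampleManifest,
    cond_focal: str,
    cond_ref: str,
    min_median: float = 10.0,
) -> ProductivityCrossTab:
    """2x2 productivity x IR categories with per-category log2 fold-change
    distributions and pairwise Mann-Whitney U tests.

    An isoform counts as IR iff it is an inclusion isoform of >= 1 intron
    retention event.
    """
    ir_ids: set[str] = set()
    for ev in ir_events:
        if ev.etype == "IR":
            ir_ids.update(ev.inclusion_isoforms)

    members: dict[str, list[str]] = {c: [] for c in CROSSTAB_CATEGORIES}
    for iso in isoforms:
        call = calls.get(iso.isoform_id)
        if call is None or call.call not in ("productive", "unproductive"):
            continue
        suffix = "IR" if iso.isoform_id in ir_ids else "spliced"
        members[f"{call.call}_{suffix}"].append(iso.isoform_id)

    fc = fold_change(norm, manifest, cond_focal, cond_ref, min_median)
    log2_fc: dict[str, list[float]] = {}
    for cat, ids in members.items():
        vals = fc.loc[[i for i in ids if i in fc.index], "log2_fc"].dropna()
        log2_fc[cat] = [float(v) for v in vals]

    tests: dict[Tuple[str, str], Tuple[float, float]] = {}
    for c1, c2 in itertools.combinations(CROSSTAB_CATEGORIES, 2):
        if log2_fc[c1] and log2_fc[c2]:
            tests[(c1, c2)] = mann_whitney_u(log2_fc[c1], log2_fc[c2])
    return ProductivityCrossTab(members, log2_fc, tests)


def _cds_spans(annotation: Annotation) -> list[tuple[str, str, int, int]]:
    """(chrom, strand, lo, hi) spans of coding regions of protein-coding
    transcripts, from annotated start (and stop, when present) codons."""
    spans = []
    coding = annotation.coding_genes()
    for tid, sc in annotation.start_codons.items():
        tx = annotation.transcripts.get(tid)
        if tx is None or tx.gene_id not in coding:
            continue
        stop = annotation.stop_codons.get(tid)
        lo, hi = sc
        if stop is not None:
            lo, hi = min(lo, stop[0]), max(hi, stop[1])
        else:
            # no stop codon recorded: extend to the transcript 3' end
            lo, hi = min(lo, tx.start), max(hi, tx.end)
        spans.append((tx.chrom, tx.strand, lo, hi))
    return spans


def alt3_frame_table(
    a3ss_events: Sequence[SpliceEvent],
    calls: Mapping[str, ProductivityCall],
    counts: pd.DataFrame,
    manifest: SampleManifest,
    cond_focal: str,
    cond_ref: str,
    annotation: Annotation,
    min_counts: int = 20,
    pseudocount: int = 1,
) -> pd.DataFrame:
    """Frame preservation vs productivity for alternative 3'SS events where
    the proximal site is preferred in the focal condition.

    Only events whose splice sites fall inside a coding transcript's CDS
    span are reported; proximal-site isoforms with >= ``min_counts`` summed
    over focal-condition samples are tallied by productivity call.
    """
    focal_samples = [s for s in manifest.samples_for(cond_focal) if s in counts.columns]
    ref_samples = [s for s in manifest.samples_for(cond_ref) if s in counts.columns]
    spans = _cds_spans(annotation)

    rows = []
    for ev in a3ss_events:
        if ev.etype != "A3SS" or ev.proximal_ss is None:
            continue
        in_cds = any(
            chrom == ev.chrom
            and strand == ev.strand
            and lo <= min(ev.proximal_ss, ev.distal_ss)
            and max(ev.proximal_ss, ev.distal_ss) <= hi
            for chrom, strand, lo, hi in spans
        )
        if not in_cds:
            continue
        inc_ids = [i for i in ev.inclusion_isoforms if i in counts.index]
        exc_ids = [i for i in ev.exclusion_isoforms if i in counts.index]

        def psi(samples):
            inc = counts.loc[inc_ids, samples].sum().sum() if inc_ids else 0
            exc = counts.loc[exc_ids, samples].sum().sum() if exc_ids else 0
            return 100.0 * (inc + pseudocount) / (inc + exc + 2 * pseudocount)

        if psi(focal_samples) <= psi(ref_samples):
            continue
        tallies = {"productive": 0, "unproductive": 0, "no_start_stop": 0}
        for iso_id in inc_ids:
            if counts.loc[iso_id, focal_samples].sum() < min_counts:
                continue
            call = calls.get(iso_id)
            if call is not None and call.call in tallies:
                tallies[call.call] += 1
        rows.append(
            {
                "event_id": ev.event_id,
                "proximal_ss": ev.proximal_ss,
                "distal_ss": ev.distal_ss,
                "multiple_of_3": abs(ev.proximal_ss - ev.distal_ss) % 3 == 0,
                "productive": tallies["productive"],
                "unproductive": tallies["unproductive"],
                "no_start_stop": tallies["no_start_stop"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "proximal_ss",
            "distal_ss",
            "multiple_of_3",
            "productive",
            "unproductive",
            "no_start_stop",
        ],
    )
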