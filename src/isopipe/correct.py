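"""Splice-site correction of noisy spliced read alignments.

Small alignment gaps (indel artifacts) are filled, then each read splice
site is snapped to the nearest valid splice site within a fixed window.
Valid sites come from the annotation, from short-read junction support, or
both; sites with no support within the window make the junction
uncorrectable and the read is excluded from the fully corrected set.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

from .genomic_io import JunctionSupport
from .models import Annotation, Blocks, Junction, ReadAlignment, ValidationError

# provenance preference when two valid sites are equidistant
_PROVENANCE_RANK = {"both": 0, "annotation": 1, "short_read": 2}


def fill_small_gaps(aln: ReadAlignment, max_gap: int = 30) -> ReadAlignment:
    """Merge adjacent blocks separated by a gap smaller than ``max_gap``.

    Gaps >= ``max_gap`` are kept as candidate introns.  Idempotent.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    merged: list[list[int]] = [list(aln.blocks[0])]
    for s, e in aln.blocks[1:]:
        if s - merged[-1][1] < max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    blocks = tuple((s, e) for s, e in merged)
    if blocks == aln.blocks:
        return aln
    return ReadAlignment(aln.read_id, aln.chrom, aln.strand, blocks, aln.sample_id)


@dataclass
class ValidSiteSet:
    """Valid splice-site coordinates keyed by (chrom, strand, side).

    ``side`` is "donor" or "acceptor".  Each coordinate carries a provenance
    label: annotation, short_read, or both.
    """

    _coords: dict[tuple[str, str, str], list[int]] = field(default_factory=dict)
    _provenance: dict[tuple[str, str, str], dict[int, str]] = field(default_factory=dict)

    def add(self, chrom: str, strand: str, side: str, coord: int, source: str) -> None:
        key = (chrom, strand, side)
        prov = self._provenance.setdefault(key, {})
        old = prov.get(coord)
        if old is None:
            prov[coord] = source
            coords = self._coords.setdefault(key, [])
            bisect.insort(coords, coord)
        elif old != source:
            prov[coord] = "both"

    def add_junction(self, j: Junction, source: str) -> None:
        self.add(j.chrom, j.strand, "donor", j.donor, source)
        self.add(j.chrom, j.strand, "acceptor", j.acceptor, source)

    def __len__(self) -> int:
        return sum(len(v) for v in self._coords.values())

    def contains(self, chrom: str, strand: str, side: str, coord: int) -> bool:
        return coord in self._provenance.get((chrom, strand, side), {})

    def provenance(self, chrom: str, strand: str, side: str, coord: int) -> Optional[str]:
        return self._provenance.get((chrom, strand, side), {}).get(coord)

    def nearest(
        self, chrom: str, strand: str, side: str, coord: int, window: int
    ) -> Optional[int]:
        """Nearest valid site with \\|delta\\| <= window, or None.

        Equidistant ties prefer provenance both > annotation > short_read,
        then the smaller genomic coordinate.
        """
        key = (chrom, strand, side)
        coords = self._coords.get(key)
        if not coords:
            return None
        i = bisect.bisect_left(coords, coord)
        candidates = []
        if i < len(coords):
            candidates.append(coords[i])
        if i > 0:
            candidates.append(coords[i - 1])
        prov = self._provenance[key]
        best = None
        best_key = None
        for c in candidates:
            d = abs(c - coord)
            if d > window:
                continue
            k = (d, _PROVENANCE_RANK[prov[c]], c)
            if best_key is None or k < best_key:
                best, best_key = c, k
        return best

    def junction_is_valid(self, j: Junction) -> bool:
        return self.contains(j.chrom, j.strand, "donor", j.donor) and self.contains(
            j.chrom, j.strand, "acceptor", j.acceptor
        )


def build_valid_sites(
    annotation: Annotation, support: Optional[JunctionSupport] = None
) -> ValidSiteSet:
    """Union of annotation-derived and (pre-filtered) short-read splice sites."""
    sites = ValidSiteSet()
    for j in annotation.junctions:
        sites.add_junction(j, "annotation")
    if support is not None:
        for j in support.entries:
            sites.add_junction(j, "short_read")
    if len(sites) == 0:
        raise ValidationError("no valid splice sites: correction impossible")
    return sites


@dataclass
class JunctionOutcome:
    junction: Junction
    status: str  # already_valid | snapped | uncorrectable
    delta_donor: Optional[int] = None
    delta_acceptor: Optional[int] = None
    corrected: Optional[Junction] = None


@dataclass
class CorrectionResult:
    read_id: str
    status: str  # fully_corrected | partially_corrected | unspliced
    read: ReadAlignment  # corrected blocks (uncorrectable junctions left as-is)
    outcomes: list[JunctionOutcome]


def _infer_strand(aln: ReadAlignment, sites: ValidSiteSet) -> Optional[str]:
    # Unknown-strand reads inherit strand from the first junction whose
    # endpoints are both valid on a strand; "+" checked first (deterministic).
    for j in aln.junctions():
        for strand in ("+", "-"):
            cand = Junction(j.chrom, j.start, j.end, strand)
            if sites.junction_is_valid(cand):
                return strand
    return None


def correct_read(
    aln: ReadAlignment, sites: ValidSiteSet, window: int = 10
) -> CorrectionResult:
    """Snap each junction endpoint to the nearest valid site within ``window``.

    Donor and acceptor are corrected independently.  A junction whose
    endpoint has no valid site in the window, or whose correction would
    create an empty or inverted exon, is marked uncorrectable.  Sites are
    never invented.
    """
    if not aln.is_spliced:
        return CorrectionResult(aln.read_id, "unspliced", aln, [])

    strand = aln.strand
    if strand == ".":
        inferred = _infer_strand(aln, sites)
        if inferred is None:
            outcomes = [
                JunctionOutcome(j, "uncorrectable") for j in aln.junctions()
            ]
            return CorrectionResult(aln.read_id, "partially_corrected", aln, outcomes)
        strand = inferred

    chrom = aln.chrom
    outcomes: list[JunctionOutcome] = []
    new_bounds: list[tuple[int, int]] = []  # corrected (intron start, intron end)
    junctions = tuple(
        Junction(chrom, aln.blocks[i][1], aln.blocks[i + 1][0], strand)
        for i in range(len(aln.blocks) - 1)
    )
    for j in junctions:
        new_donor = sites.nearest(chrom, strand, "donor", j.donor, window)
        new_acceptor = sites.nearest(chrom, strand, "acceptor", j.acceptor, window)
        if new_donor is None or new_acceptor is None:
            outcomes.append(JunctionOutcome(j, "uncorrectable"))
            new_bounds.append((j.start, j.end))
            continue
        if strand == "+":
            start, end = new_donor, new_acceptor
            dd, da = new_donor - j.donor, new_acceptor - j.acceptor
        else:
            start, end = new_acceptor, new_donor
            dd, da = new_donor - j.donor, new_acceptor - j.acceptor
        if end <= start:
            outcomes.append(JunctionOutcome(j, "uncorrectable"))
            new_bounds.append((j.start, j.end))
            continue
        status = "already_valid" if (dd == 0 and da == 0) else "snapped"
        outcomes.append(
            JunctionOutcome(
                j,
                status,
                delta_donor=dd,
                delta_acceptor=da,
                corrected=Junction(chrom, start, end, strand),
            )
        )
        new_bounds.append((start, end))

    # rebuild blocks; reject corrections that would create empty/inverted exons
    block_starts = [aln.blocks[0][0]] + [b[1] for b in new_bounds]
    block_ends = [b[0] for b in new_bounds] + [aln.blocks[-1][1]]
    blocks = list(zip(block_starts, block_ends))
    bad = set()
    for i, (s, e) in enumerate(blocks):
        if e <= s:
            # exon squashed by correction of flanking junction(s): mark both
            if i > 0:
                bad.add(i - 1)
            if i < len(new_bounds):
                bad.add(i)
    if bad:
        for i in sorted(bad):
            j = junctions[i]
            outcomes[i] = JunctionOutcome(j, "uncorrectable")
            new_bounds[i] = (j.start, j.end)
        block_starts = [aln.blocks[0][0]] + [b[1] for b in new_bounds]
        block_ends = [b[0] for b in new_bounds] + [aln.blocks[-1][1]]
        blocks = list(zip(block_starts, block_ends))

    fully = all(o.status in ("already_valid", "snapped") for o in outcomes)
    corrected = ReadAlignment(
        aln.read_id, chrom, strand, tuple(blocks), aln.sample_id
    )
    return CorrectionResult(
        aln.read_id,
        "fully_corrected" if fully else "partially_corrected",
        corrected,
        outcomes,
    )


def correct_reads(
    alns: Iterable[ReadAlignment],
    sites: ValidSiteSet,
    window: int = 10,
    max_gap: int = 30,
) -> list[CorrectionResult]:
    return [correct_read(fill_small_gaps(a, max_gap), sites, window) for a in alns]


def partition_reads(
    results: Iterable[CorrectionResult],
) -> tuple[list[ReadAlignment], list[ReadAlignment], list[ReadAlignment]]:
    """Split correction results into (corrected, uncorrected, unspliced) reads."""
    corrected: list[ReadAlignment] = []
    uncorrected: list[ReadAlignment] = []
    unspliced: list[ReadAlignment] = []
    for res in results:
        if res.status == "fully_corrected":
            corrected.append(res.read)
        elif res.status == "unspliced":
            unspliced.append(res.read)
        else:
            uncorrected.append(res.read)
    return corrected, uncorrected, unspliced
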