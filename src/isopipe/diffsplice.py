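"""Alternative-splicing event calling, PSI quantification, and testing.

Events (alternative 3'/5' splice sites, cassette exons, intron retention)
are called structurally from the final isoform set.  Per-sample PSI uses a
pseudocount; unreplicated designs are tested with Fisher's exact test and
replicated designs with a beta-binomial likelihood-ratio test.  p values
are Benjamini-Hochberg corrected within each event type.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import betaln, gammaln

from .genomic_io import extract_spliced_sequence, reverse_complement
from .models import Annotation, Isoform, Junction, SampleManifest, ValidationError

EVENT_TYPES = ("A3SS", "A5SS", "ES", "IR")


@dataclass
class SpliceEvent:
    event_id: str
    etype: str  # A3SS | A5SS | ES | IR
    chrom: str
    strand: str
    gene_id: Optional[str]
    inclusion_isoforms: frozenset
    exclusion_isoforms: frozenset
    # contrast coordinates; meaning depends on etype
    shared_ss: Optional[int] = None  # A3SS/A5SS
    proximal_ss: Optional[int] = None
    distal_ss: Optional[int] = None
    intron: Optional[Tuple[int, int]] = None  # IR
    exon: Optional[Tuple[int, int]] = None  # ES cassette exon
    test_exempt: bool = False

    def __post_init__(self) -> None:
        if self.inclusion_isoforms & self.exclusion_isoforms:
            raise ValidationError(
                f"{self.event_id}: inclusion/exclusion isoform sets overlap"
            )


def _by_gene(isoforms: Sequence[Isoform]) -> dict[str, list[Isoform]]:
    out: dict[str, list[Isoform]] = {}
    for iso in isoforms:
        out.setdefault(iso.gene_id or iso.isoform_id, []).append(iso)
    return out


# ---------------------------------------------------------------------------
# Event calling
# ---------------------------------------------------------------------------

def call_ir(isoforms: Sequence[Isoform]) -> list[SpliceEvent]:
    """An intron retained iff completely spanned by a same-gene isoform exon.

    Inclusion isoforms span the intron with an exon; exclusion isoforms
    splice it out (carry the exact junction).  Events are merged by intron
    coordinates.
    """
    events: list[SpliceEvent] = []
    for gene_id, isos in _by_gene(isoforms).items():
        seen: set[Tuple[str, int, int, str]] = set()
        for iso in isos:
            for j in iso.junctions():
                key = (j.chrom, j.start, j.end, j.strand)
                if key in seen:
                    continue
                seen.add(key)
                spanning = frozenset(
                    other.isoform_id
                    for other in isos
                    if other.strand == iso.strand
                    and any(s <= j.start and j.end <= e for s, e in other.blocks)
                )
                if not spanning:
                    continue
                splicing = frozenset(
                    other.isoform_id for other in isos if j in other.junctions()
                )
                events.append(
                    SpliceEvent(
                        event_id=f"IR:{j.chrom}:{j.start}-{j.end}:{j.strand}",
                        etype="IR",
                        chrom=j.chrom,
                        strand=j.strand,
                        gene_id=gene_id,
                        inclusion_isoforms=spanning,
                        exclusion_isoforms=splicing,
                        intron=(j.start, j.end),
                    )
                )
    return events


def _flank_exon(iso: Isoform, j: Junction, which: str) -> Optional[Tuple[int, int]]:
    """Exon adjacent to the alternative splice site of junction ``j``.

    ``which`` is "acceptor" (exon downstream of the acceptor in transcript
    orientation) or "donor" (exon upstream of the donor).
    """
    for s, e in iso.blocks:
        if which == "acceptor":
            if (j.strand == "+" and s == j.end) or (j.strand == "-" and e == j.start):
                return (s, e)
        else:
            if (j.strand == "+" and e == j.start) or (j.strand == "-" and s == j.end):
                return (s, e)
    return None


def call_alt_ss(
    isoforms: Sequence[Isoform], side: str, exempt_dist: int = 10
) -> list[SpliceEvent]:
    """Alternative 3' (acceptor) or 5' (donor) splice-site events.

    Junctions are grouped by the splice site on the non-alternative side;
    every pair of distinct alternative sites whose flanking exons overlap
    forms one event.  Pairs within ``exempt_dist`` of each other are
    flagged ``test_exempt``.  Proximal means closer to the shared site.
    """
    if side not in ("3prime", "5prime"):
        raise ValueError("side must be '3prime' or '5prime'")
    etype = "A3SS" if side == "3prime" else "A5SS"
    alt_side = "acceptor" if side == "3prime" else "donor"
    events: list[SpliceEvent] = []
    for gene_id, isos in _by_gene(isoforms).items():
        # junction -> containing isoforms
        jmap: dict[Junction, set[str]] = {}
        for iso in isos:
            for j in iso.junctions():
                jmap.setdefault(j, set()).add(iso.isoform_id)
        groups: dict[Tuple[str, str, int], list[Junction]] = {}
        for j in jmap:
            shared = j.donor if side == "3prime" else j.acceptor
            groups.setdefault((j.chrom, j.strand, shared), []).append(j)
        for (chrom, strand, shared), js in groups.items():
            js = sorted(js, key=lambda x: (x.start, x.end))
            for j1, j2 in itertools.combinations(js, 2):
                a1 = j1.acceptor if side == "3prime" else j1.donor
                a2 = j2.acceptor if side == "3prime" else j2.donor
                if a1 == a2:
                    continue
                # alternative sites must land in overlapping exons
                exons1 = [
                    _flank_exon(iso, j1, alt_side)
                    for iso in isos
                    if iso.isoform_id in jmap[j1]
                ]
                exons2 = [
                    _flank_exon(iso, j2, alt_side)
                    for iso in isos
                    if iso.isoform_id in jmap[j2]
                ]
                overlapping = any(
                    e1 is not None
                    and e2 is not None
                    and min(e1[1], e2[1]) > max(e1[0], e2[0])
                    for e1 in exons1
                    for e2 in exons2
                )
                if not overlapping:
                    continue
                if abs(a1 - shared) <= abs(a2 - shared):
                    prox_j, dist_j = j1, j2
                    prox, dist = a1, a2
                else:
                    prox_j, dist_j = j2, j1
                    prox, dist = a2, a1
                inc = frozenset(jmap[prox_j]) - frozenset(jmap[dist_j])
                exc = frozenset(jmap[dist_j]) - frozenset(jmap[prox_j])
                if not inc or not exc:
                    continue
                events.append(
                    SpliceEvent(
                        event_id=f"{etype}:{chrom}:{strand}:{shared}:{prox}|{dist}",
                        etype=etype,
                        chrom=chrom,
                        strand=strand,
                        gene_id=gene_id,
                        inclusion_isoforms=inc,
                        exclusion_isoforms=exc,
                        shared_ss=shared,
                        proximal_ss=prox,
                        distal_ss=dist,
                        test_exempt=abs(a1 - a2) <= exempt_dist,
                    )
                )
    return events


def call_es(isoforms: Sequence[Isoform]) -> list[SpliceEvent]:
    """Cassette-exon events.

    An internal exon flanked by junctions (a, s) and (t, b) is a cassette
    iff another same-gene isoform carries the spanning junction (a, b).
    """
    events: list[SpliceEvent] = []
    for gene_id, isos in _by_gene(isoforms).items():
        jmap: dict[Junction, set[str]] = {}
        for iso in isos:
            for j in iso.junctions():
                jmap.setdefault(j, set()).add(iso.isoform_id)
        seen: set[Tuple] = set()
        for iso in isos:
            js = iso.junctions()
            for j1, j2 in zip(js, js[1:]):
                span = Junction(j1.chrom, j1.start, j2.end, j1.strand)
                if span not in jmap:
                    continue
                key = (j1.chrom, j1.strand, j1.start, j1.end, j2.start, j2.end)
                if key in seen:
                    continue
                seen.add(key)
                inc = frozenset(jmap[j1] & jmap[j2]) - frozenset(jmap[span])
                exc = frozenset(jmap[span]) - frozenset(jmap[j1] & jmap[j2])
                if not inc or not exc:
                    continue
                events.append(
                    SpliceEvent(
                        event_id=(
                            f"ES:{j1.chrom}:{j1.strand}:{j1.end}-{j2.start}"
                            f"@{j1.start}-{j2.end}"
                        ),
                        etype="ES",
                        chrom=j1.chrom,
                        strand=j1.strand,
                        gene_id=gene_id,
                        inclusion_isoforms=inc,
                        exclusion_isoforms=exc,
                        exon=(j1.end, j2.start),
                    )
                )
    return events


# ---------------------------------------------------------------------------
# Quantification and filtering
# ---------------------------------------------------------------------------

@dataclass
class EventQuant:
    event: SpliceEvent
    inc: pd.Series  # raw inclusion counts per sample
    exc: pd.Series
    psi: pd.Series  # percent spliced-in, pseudocounted
    pseudocount: int = 1

    def coverage(self) -> pd.Series:
        return self.inc + self.exc

    def psi_by_condition(self, manifest: SampleManifest) -> dict[str, float]:
        out = {}
        for cond in manifest.conditions:
            samples = [s for s in manifest.samples_for(cond) if s in self.psi.index]
            out[cond] = float(self.psi[samples].mean())
        return out

    def dpsi(self, manifest: SampleManifest, cond_focal: str, cond_ref: str) -> float:
        by_cond = self.psi_by_condition(manifest)
        return by_cond[cond_focal] - by_cond[cond_ref]


def quantify_event(
    event: SpliceEvent, counts: pd.DataFrame, pseudocount: int = 1
) -> EventQuant:
    """Sum isoform counts per side; PSI = 100 (inc+pc) / (inc+exc+2 pc)."""
    inc_ids = [i for i in event.inclusion_isoforms if i in counts.index]
    exc_ids = [i for i in event.exclusion_isoforms if i in counts.index]
    if not event.inclusion_isoforms or not event.exclusion_isoforms:
        raise ValidationError(f"{event.event_id}: empty isoform set")
    inc = counts.loc[inc_ids].sum(axis=0) if inc_ids else pd.Series(0, index=counts.columns)
    exc = counts.loc[exc_ids].sum(axis=0) if exc_ids else pd.Series(0, index=counts.columns)
    psi = 100.0 * (inc + pseudocount) / (inc + exc + 2 * pseudocount)
    return EventQuant(event, inc, exc, psi, pseudocount)


def passes_coverage_filter(
    coverage: Mapping[str, float],
    manifest: SampleManifest,
    min_cov: int = 25,
    min_samples: int = 4,
    min_per_cond: int = 2,
) -> bool:
    """Coverage rule: >= ``min_samples`` samples with coverage >= ``min_cov``,
    with each condition contributing >= ``min_per_cond`` of them."""
    passing = [s for s in manifest if coverage.get(s, 0) >= min_cov]
    if len(passing) < min_samples:
        return False
    for cond in manifest.conditions:
        n = sum(1 for s in passing if manifest.condition_of(s) == cond)
        if n < min_per_cond:
            return False
    return True


def filter_events(
    quants: Sequence[EventQuant],
    manifest: SampleManifest,
    min_cov: int = 25,
    min_samples: int = 4,
    min_per_cond: int = 2,
) -> list[EventQuant]:
    """Testable subset: coverage rule satisfied and not test-exempt."""
    return [
        q
        for q in quants
        if not q.event.test_exempt
        and passes_coverage_filter(
            q.coverage().to_dict(), manifest, min_cov, min_samples, min_per_cond
        )
    ]


# ---------------------------------------------------------------------------
# Statistical tests
# ---------------------------------------------------------------------------

def fisher_test(inc_a: int, exc_a: int, inc_b: int, exc_b: int) -> float:
    """Two-sided Fisher's exact p on raw counts (no pseudocount)."""
    table = [[inc_a, exc_a], [inc_b, exc_b]]
    if min(sum(table[0]), sum(table[1])) == 0:
        return 1.0
    if min(inc_a + inc_b, exc_a + exc_b) == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def _bb_negll(k: np.ndarray, n: np.ndarray, p: float, rho: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    rho = min(max(rho, 1e-9), 1 - 1e-9)
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho
    ll = (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + betaln(k + a, n - k + b)
        - betaln(a, b)
    )
    return -float(np.sum(ll))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _logit(p: float) -> float:
    p = min(max(p, 1e-6), 1 - 1e-6)
    return math.log(p / (1 - p))


def _bb_fit_p(k: np.ndarray, n: np.ndarray, rho: float) -> float:
    """Minimized negative log-likelihood over the inclusion proportion with
    the dispersion held fixed (bounded 1-D optimization on the logit scale)."""
    res = optimize.minimize_scalar(
        lambda x: _bb_negll(k, n, _expit(x), rho),
        bounds=(-12.0, 12.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.fun)


def bb_lrt(
    inc: Sequence[float],
    exc: Sequence[float],
    conditions: Sequence[str],
) -> float:
    """Beta-binomial likelihood-ratio test for a condition effect on the
    inclusion proportion.

    Null: one proportion shared across conditions; alternative: one per
    condition.  The shared dispersion is profiled out under the null and
    held fixed for both fits — re-estimating it under the alternative
    inflates the statistic badly at replicate counts this small.  p from
    chi-square with 1 df on twice the log-likelihood gain.  Returns NaN on
    non-convergence.
    """
    k = np.asarray(inc, dtype=float)
    n = k + np.asarray(exc, dtype=float)
    labels = np.asarray(conditions)
    levels = sorted(set(labels.tolist()))
    if len(levels) != 2:
        raise ValidationError(f"expected 2 conditions, got {levels}")
    mask_a = labels == levels[0]
    if mask_a.sum() < 2 or (~mask_a).sum() < 2:
        raise ValidationError("bb_lrt requires >=2 samples per condition")
    if np.any(n <= 0):
        return float("nan")

    def null_profile(x: float) -> float:
        return _bb_fit_p(k, n, _expit(x))

    prof = optimize.minimize_scalar(
        null_profile,
        bounds=(-14.0, 3.0),
        method="bounded",
        options={"xatol": 1e-6},
    )
    if not prof.success:
        return float("nan")
    rho = _expit(float(prof.x))
    ll_null = float(prof.fun)
    ll_alt = _bb_fit_p(k[mask_a], n[mask_a], rho) + _bb_fit_p(
        k[~mask_a], n[~mask_a], rho
    )
    lr = max(0.0, 2.0 * (ll_null - ll_alt))
    return float(stats.chi2.sf(lr, df=1))


@dataclass
class EventTest:
    event_id: str
    etype: str
    dpsi: float
    raw_p: float
    corrected_p: float = float("nan")
    significant: bool = False
    test_exempt: bool = False


def test_events(
    quants: Sequence[EventQuant],
    manifest: SampleManifest,
    cond_focal: str,
    cond_ref: str,
    pseudocount: int = 1,
) -> list[EventTest]:
    """Test every quantified event for a condition effect.

    With one sample per condition a Fisher's exact test on raw counts is
    used; with replicates, the beta-binomial LRT on pseudocounted counts.
    """
    samples_f = manifest.samples_for(cond_focal)
    samples_r = manifest.samples_for(cond_ref)
    replicated = len(samples_f) >= 2 and len(samples_r) >= 2
    out: list[EventTest] = []
    for q in quants:
        dpsi = q.dpsi(manifest, cond_focal, cond_ref)
        if replicated:
            samples = samples_f + samples_r
            inc = [q.inc[s] + pseudocount for s in samples]
            exc = [q.exc[s] + pseudocount for s in samples]
            conds = [manifest.condition_of(s) for s in samples]
            raw_p = bb_lrt(inc, exc, conds)
        else:
            sf, sr = samples_f[0], samples_r[0]
            raw_p = fisher_test(
                int(q.inc[sf]), int(q.exc[sf]), int(q.inc[sr]), int(q.exc[sr])
            )
        out.append(
            EventTest(
                event_id=q.event.event_id,
                etype=q.event.etype,
                dpsi=dpsi,
                raw_p=raw_p,
                test_exempt=q.event.test_exempt,
            )
        )
    return out


def correct_and_flag(
    tests: Sequence[EventTest], alpha: float = 0.1, dpsi_min: float = 10.0
) -> list[EventTest]:
    """Benjamini-Hochberg within each event type; significant iff the
    corrected p clears ``alpha`` AND \\|dPSI\\| clears ``dpsi_min``."""
    from statsmodels.stats.multitest import multipletests

    by_type: dict[str, list[EventTest]] = {}
    for t in tests:
        by_type.setdefault(t.etype, []).append(t)
    for etype, group in by_type.items():
        testable = [t for t in group if not math.isnan(t.raw_p)]
        if testable:
            _, corrected, _, _ = multipletests(
                [t.raw_p for t in testable], method="fdr_bh"
            )
            for t, c in zip(testable, corrected):
                t.corrected_p = float(c)
                t.significant = c < alpha and abs(t.dpsi) > dpsi_min
    return list(tests)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def mann_whitney_u(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    exact_limit: int = 12,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with midrank ties.

    Exact by enumeration of all group assignments when
    ``len(a) + len(b) <= exact_limit``; otherwise a tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = a.size, b.size
    n = na + nb
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:na].sum() - na * (na + 1) / 2.0)

    if n <= exact_limit:
        # work with doubled ranks so tie midranks stay integral
        r2 = np.rint(2 * ranks).astype(int)
        obs = int(round(2 * u1))
        lo = hi = total = 0
        base = na * (na + 1)  # doubled version of na(na+1)/2 * 2
        for combo in itertools.combinations(range(n), na):
            u2 = int(r2[list(combo)].sum()) - base
            total += 1
            if u2 <= obs:
                lo += 1
            if u2 >= obs:
                hi += 1
        p = min(1.0, 2.0 * min(lo, hi) / total)
        return u1, p

    mu = na * nb / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sigma2 = na * nb / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u1, 1.0
    z = (abs(u1 - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    return u1, min(1.0, 2.0 * float(stats.norm.sf(z)))


# ---------------------------------------------------------------------------
# Splice-site sequence summaries
# ---------------------------------------------------------------------------

def _acceptor_upstream_seq(genome, chrom: str, acceptor: int, strand: str, length: int) -> str:
    """Transcript-oriented sequence immediately upstream of an acceptor.

    The returned string's last base is the one adjacent to the acceptor.
    """
    if strand == "+":
        lo = max(0, acceptor - length)
        return str(genome[chrom][lo:acceptor]).upper()
    seq = str(genome[chrom][acceptor : acceptor + length]).upper()
    return reverse_complement(seq)


def nearest_nongag_ag(upstream: str, window: int) -> Optional[int]:
    """Distance (negative) to the nearest upstream trimer ending in AG whose
    trimer is not GAG.  ``upstream`` is transcript-oriented, ending at the
    canonical acceptor."""
    L = len(upstream)
    for d in range(1, window + 1):
        end = L - d
        start = end - 3
        if start < 0:
            break
        trimer = upstream[start:end]
        if trimer.endswith("AG") and trimer != "GAG":
            return -d
    return None


def ss_distance_distribution(
    a3ss_events: Sequence[SpliceEvent],
    annotation: Annotation,
    genome,
    control_window: int = 100,
) -> tuple[list[int], list[int], float, float]:
    """Observed alternative-vs-canonical 3'SS distances and a genome control.

    Observed: signed distance (negative = upstream in transcript
    orientation) from each event's alternative acceptor to its canonical
    (annotated, else distal) acceptor.  Control: for every canonical
    acceptor, distance to the nearest upstream non-GAG AG-trimer within
    ``control_window``.  Returns (observed, control, U, two-sided p).
    """
    ann_acceptors: set[tuple[str, str, int]] = set()
    for j in annotation.junctions:
        ann_acceptors.add((j.chrom, j.strand, j.acceptor))

    observed: list[int] = []
    canonical_sites: set[tuple[str, str, int]] = set()
    for ev in a3ss_events:
        if ev.etype != "A3SS":
            continue
        prox, dist = ev.proximal_ss, ev.distal_ss
        prox_ann = (ev.chrom, ev.strand, prox) in ann_acceptors
        dist_ann = (ev.chrom, ev.strand, dist) in ann_acceptors
        if prox_ann and not dist_ann:
            canonical, alt = prox, dist
        elif dist_ann and not prox_ann:
            canonical, alt = dist, prox
        else:
            canonical, alt = dist, prox
        if ev.strand == "+":
            d = alt - canonical
        else:
            d = canonical - alt
        observed.append(d)
        canonical_sites.add((ev.chrom, ev.strand, canonical))

    control: list[int] = []
    for chrom, strand, acc in sorted(canonical_sites):
        try:
            upstream = _acceptor_upstream_seq(
                genome, chrom, acc, strand, control_window + 3
            )
        except (KeyError, IndexError):
            continue
        d = nearest_nongag_ag(upstream, control_window)
        if d is not None:
            control.append(d)

    if observed and control:
        u, p = mann_whitney_u(observed, control)
    else:
        u, p = float("nan"), float("nan")
    return observed, control, u, p


def motif_matrix(
    sites: Iterable[tuple[str, int, str]],
    genome,
    up: int = 25,
    down: int = 3,
) -> pd.DataFrame:
    """Position frequency matrix around strand-oriented splice sites.

    ``sites`` yields (chrom, coordinate, strand); the window spans
    [-up, +down) in transcript orientation.  Rows (positions) sum to 1.
    Sites too close to a contig edge are skipped.
    """
    positions = list(range(-up, down))
    counts = np.zeros((len(positions), 4), dtype=float)
    bases = "ACGT"
    idx = {c: i for i, c in enumerate(bases)}
    for chrom, pos, strand in sites:
        try:
            if strand == "+":
                lo, hi = pos - up, pos + down
                if lo < 0:
                    continue
                seq = str(genome[chrom][lo:hi]).upper()
            else:
                lo, hi = pos - down, pos + up
                if lo < 0:
                    continue
                seq = reverse_complement(str(genome[chrom][lo:hi]).upper())
        except (KeyError, IndexError):
            continue
        if len(seq) != up + down:
            continue
        for i, base in enumerate(seq):
            if base in idx:
                counts[i, idx[base]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        freqs = np.divide(counts, totals, out=np.zeros_like(counts), where=totals > 0)
    return pd.DataFrame(freqs, index=positions, columns=list(bases))


# ---------------------------------------------------------------------------
# Differential isoform usage
# ---------------------------------------------------------------------------

def diff_isoform_usage(
    counts: pd.DataFrame,
    isoform_to_gene: Mapping[str, str],
    manifest: SampleManifest,
    cond_focal: str,
    cond_ref: str,
    min_cov: int = 25,
    min_samples: int = 4,
    alpha: float = 0.1,
    dusage_min: float = 10.0,
    pseudocount: int = 1,
) -> pd.DataFrame:
    """Isoform-vs-rest-of-gene usage tests via the beta-binomial LRT.

    Genes need >= ``min_cov`` reads in >= ``min_samples`` samples;
    single-isoform genes are skipped.  BH correction across all tested
    isoforms; usage is reported in percentage points.
    """
    from statsmodels.stats.multitest import multipletests

    genes: dict[str, list[str]] = {}
    for iso in counts.index:
        genes.setdefault(isoform_to_gene.get(iso, iso), []).append(iso)

    samples = [s for s in manifest if s in counts.columns]
    conds = [manifest.condition_of(s) for s in samples]
    focal_mask = np.array([c == cond_focal for c in conds])
    ref_mask = np.array([c == cond_ref for c in conds])

    rows = []
    for gene, isos in sorted(genes.items()):
        if len(isos) < 2:
            continue
        totals = counts.loc[isos, samples].sum(axis=0)
        if int((totals >= min_cov).sum()) < min_samples:
            continue
        for iso in isos:
            inc = counts.loc[iso, samples].to_numpy(dtype=float)
            exc = totals.to_numpy(dtype=float) - inc
            usage = 100.0 * (inc + pseudocount) / (totals.to_numpy() + 2 * pseudocount)
            d_usage = float(usage[focal_mask].mean() - usage[ref_mask].mean())
            try:
                raw_p = bb_lrt(inc + pseudocount, exc + pseudocount, conds)
            except ValidationError:
                raw_p = float("nan")
            rows.append(
                {
                    "isoform_id": iso,
                    "gene_id": gene,
                    "d_usage": d_usage,
                    "raw_p": raw_p,
                }
            )
    df = pd.DataFrame(
        rows, columns=["isoform_id", "gene_id", "d_usage", "raw_p"]
    ).set_index("isoform_id")
    df["corrected_p"] = np.nan
    df["significant"] = False
    testable = df.index[df["raw_p"].notna()]
    if len(testable):
        _, corrected, _, _ = multipletests(df.loc[testable, "raw_p"], method="fdr_bh")
        df.loc[testable, "corrected_p"] = corrected
        df.loc[testable, "significant"] = (df.loc[testable, "corrected_p"] < alpha) & (
            df.loc[testable, "d_usage"].abs() > dusage_min
        )
    return df
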