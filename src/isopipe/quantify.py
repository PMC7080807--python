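"""Isoform counting, upper-quartile normalization, and summary statistics."""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .collapse import Assignment
from .models import Isoform, ReadAlignment, SampleManifest, ValidationError


def count_matrix(
    assignments: Mapping[str, Mapping[str, Assignment]],
    isoform_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Counts of uniquely assigned reads: isoform_id x sample_id.

    ``assignments`` maps sample_id -> {read_id: Assignment}.  Ambiguous and
    unmatched reads contribute nothing.
    """
    samples = list(assignments)
    rows: set[str] = set(isoform_ids or [])
    for per_sample in assignments.values():
        for a in per_sample.values():
            if a.reason == "unique":
                rows.add(a.isoform_id)
    index = sorted(rows)
    mat = pd.DataFrame(0, index=index, columns=samples, dtype=int)
    for sample, per_sample in assignments.items():
        for a in per_sample.values():
            if a.reason == "unique":
                mat.at[a.isoform_id, sample] += 1
    return mat


def gene_counts(
    counts: pd.DataFrame, isoform_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    genes = pd.Series(
        {i: isoform_to_gene.get(i, i) for i in counts.index}, name="gene"
    )
    return counts.groupby(genes).sum()


def upper_quartile_factors(
    counts: pd.DataFrame,
    isoform_to_gene: Mapping[str, str],
    gene_biotype: Mapping[str, str],
    exclude_zeros: bool = True,
) -> pd.Series:
    """Per-sample 75th percentile of protein-coding gene-level counts.

    The quantile uses linear interpolation between closest ranks; zero-count
    coding genes are excluded by default.
    """
    by_gene = gene_counts(counts, isoform_to_gene)
    coding = [g for g in by_gene.index if gene_biotype.get(g) == "protein_coding"]
    if not coding:
        raise ValidationError("no protein-coding genes in counts")
    sub = by_gene.loc[coding]
    factors = {}
    for sample in counts.columns:
        vals = sub[sample].to_numpy(dtype=float)
        if exclude_zeros:
            vals = vals[vals > 0]
        if vals.size == 0:
            raise ValidationError(
                f"sample {sample}: no expressed protein-coding genes"
            )
        f = float(np.percentile(vals, 75))
        if f <= 0:
            raise ValidationError(f"sample {sample}: normalization factor 0")
        factors[sample] = f
    return pd.Series(factors)


def upper_quartile_normalize(
    counts: pd.DataFrame,
    isoform_to_gene: Mapping[str, str],
    gene_biotype: Mapping[str, str],
    exclude_zeros: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Divide every count by its sample's upper-quartile factor."""
    factors = upper_quartile_factors(counts, isoform_to_gene, gene_biotype, exclude_zeros)
    return counts / factors, factors


def fold_change(
    norm: pd.DataFrame,
    manifest: SampleManifest,
    cond_a: str,
    cond_b: str,
    min_median: float = 10.0,
) -> pd.DataFrame:
    """log2 of median(cond_a) / median(cond_b) per isoform.

    Isoforms where both condition medians fall below ``min_median`` are
    excluded (reason low_expression); a zero denominator excludes with
    reason zero_median.
    """
    for cond in (cond_a, cond_b):
        if cond not in manifest.conditions:
            raise ValidationError(f"unknown condition {cond!r}")
    samples_a = [s for s in manifest.samples_for(cond_a) if s in norm.columns]
    samples_b = [s for s in manifest.samples_for(cond_b) if s in norm.columns]
    med_a = norm[samples_a].median(axis=1)
    med_b = norm[samples_b].median(axis=1)
    log2_fc = pd.Series(np.nan, index=norm.index)
    reason = pd.Series("ok", index=norm.index)
    low = (med_a < min_median) & (med_b < min_median)
    reason[low] = "low_expression"
    zero = (~low) & (med_b == 0)
    reason[zero] = "zero_median"
    ok = (~low) & (~zero)
    log2_fc[ok] = np.log2(med_a[ok] / med_b[ok])
    return pd.DataFrame(
        {"median_a": med_a, "median_b": med_b, "log2_fc": log2_fc, "reason": reason}
    )


def _exonic_overlap(blocks_a, blocks_b) -> int:
    total = 0
    for s1, e1 in blocks_a:
        for s2, e2 in blocks_b:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def full_length_stats(
    reads: Sequence[ReadAlignment],
    assignment: Mapping[str, Assignment],
    isoforms: Sequence[Isoform],
    threshold: float = 0.8,
) -> pd.Series:
    """Per-sample fraction of assigned reads covering >= ``threshold`` of
    their isoform's spliced length (exonic coordinates)."""
    by_id = {iso.isoform_id: iso for iso in isoforms}
    full = {}
    total = {}
    for read in reads:
        a = assignment.get(read.read_id)
        if a is None or a.reason != "unique":
            continue
        iso = by_id[a.isoform_id]
        cov = _exonic_overlap(read.blocks, iso.blocks) / iso.spliced_length
        total[read.sample_id] = total.get(read.sample_id, 0) + 1
        if cov >= threshold:
            full[read.sample_id] = full.get(read.sample_id, 0) + 1
    return pd.Series(
        {s: full.get(s, 0) / n for s, n in sorted(total.items())}, dtype=float
    )


def gene_summary(
    isoforms: Sequence[Isoform], counts: Optional[pd.DataFrame] = None
) -> tuple[int, float]:
    """(genes detected, fraction of detected genes with >=2 isoforms)."""
    expressed = set(counts.index[counts.sum(axis=1) > 0]) if counts is not None else None
    per_gene: dict[str, int] = {}
    for iso in isoforms:
        if expressed is not None and iso.isoform_id not in expressed:
            continue
        per_gene[iso.gene_id] = per_gene.get(iso.gene_id, 0) + 1
    n = len(per_gene)
    if n == 0:
        return 0, 0.0
    multi = sum(1 for v in per_gene.values() if v >= 2)
    return n, multi / n
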