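"""Cross-transect reporting arithmetic: outlier shares, overlaps, gene hits.

Pure set and interval arithmetic over (chrom, pos)-keyed locus sets and
flank-extended gene intervals — exact, order-independent, idempotent.
Percentage conventions follow the reporting style of hybrid-zone papers:
chromosome shares to one decimal, overlap and region shares to the nearest
integer (both configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class TransectReport:
    transect: str
    n_tested: int
    n_significant: int
    per_chromosome: dict[str, int]
    chromosome_shares: dict[str, float]
    n_v_gt_10: int
    mean_v: float | None
    gene_hits: list[str] = field(default_factory=list)


def chromosome_share(counts_per_chrom: dict[str, int], chrom: str, ndigits: int = 1) -> float:
    """Percentage of significant loci on one chromosome (one decimal)."""
    total = sum(counts_per_chrom.values())
    if total == 0:
        return 0.0
    return round(100.0 * counts_per_chrom.get(chrom, 0) / total, ndigits)


def overlap_between_transects(set_a, set_b, ndigits: int = 0) -> dict:
    """Shared outlier loci between two transects, keyed by (chrom, pos).

    Returns n_shared plus the shared percentage of each set, rounded to the
    nearest integer by default. Symmetric in n_shared; the percentages swap
    under argument exchange.
    """
    a = set(set_a)
    b = set(set_b)
    shared = a & b
    def pct(n, d):
        if d == 0:
            return 0.0
        v = round(100.0 * n / d, ndigits)
        return v if ndigits else float(int(v))
    return {
        "n_shared": len(shared),
        "pct_a": pct(len(shared), len(a)),
        "pct_b": pct(len(shared), len(b)),
    }


def match_genes(outlier_loci, gene_intervals: pd.DataFrame) -> set[str]:
    """Unique genes hit by outlier SNPs within flank-extended intervals.

    ``outlier_loci`` is an iterable of (chrom, pos); ``gene_intervals`` a
    frame from :func:`clinekit.core_io.read_gff_genes` (columns gene_id,
    chrom, search_start, search_end). A SNP hits a gene when its position
    lies inside the closed extended interval.
    """
    hits: set[str] = set()
    by_chrom = {c: sub for c, sub in gene_intervals.groupby("chrom", sort=False)}
    for chrom, pos in outlier_loci:
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        inside = (sub["search_start"] <= pos) & (pos <= sub["search_end"])
        hits.update(sub.loc[inside, "gene_id"])
    return hits


def gene_overlap(genes_a: set[str], genes_b: set[str]) -> dict:
    """Shared and transect-unique gene counts across two transects."""
    shared = genes_a & genes_b
    return {
        "n_a": len(genes_a),
        "n_b": len(genes_b),
        "n_shared": len(shared),
        "n_union_minus_shared": len(genes_a | genes_b) - len(shared),
        "shared": sorted(shared),
    }


def region_share(outlier_loci, chrom: str, start: int, end: int, ndigits: int = 0) -> float:
    """Percentage of outlier loci inside [start, end] on one chromosome."""
    loci = list(outlier_loci)
    if not loci:
        return 0.0
    inside = sum(1 for c, p in loci if c == chrom and start <= p <= end)
    v = round(100.0 * inside / len(loci), ndigits)
    return v if ndigits else float(int(v))


def build_transect_report(
    transect: str,
    fits,
    gene_intervals: pd.DataFrame | None = None,
) -> TransectReport:
    """Summaries of a transect's genomic-cline fits in one structure."""
    sig = [f for f in fits if f.significant_restricted]
    per_chrom: dict[str, int] = {}
    for f in sig:
        chrom = f.locus[0] if f.locus else "?"
        per_chrom[chrom] = per_chrom.get(chrom, 0) + 1
    shares = {c: chromosome_share(per_chrom, c) for c in per_chrom}
    genes: list[str] = []
    if gene_intervals is not None:
        genes = sorted(
            match_genes((f.locus for f in sig if f.locus), gene_intervals)
        )
    vs = [f.v_mean for f in sig]
    return TransectReport(
        transect=transect,
        n_tested=len(list(fits)),
        n_significant=len(sig),
        per_chromosome=per_chrom,
        chromosome_shares=shares,
        n_v_gt_10=sum(1 for v in vs if v > 10),
        mean_v=(sum(vs) / len(vs)) if vs else None,
        gene_hits=genes,
    )
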