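"""Population-genetic summaries: PCA, Weir–Cockerham F_ST, inbreeding F,
least-admixed filtering, and mtDNA mitotyping.

The F_ST estimator is the Weir & Cockerham (1984) two-population theta-hat
built from the variance components a (among populations), b (among
individuals within populations) and c (within individuals); windows use the
ratio-of-sums form sum(a) / sum(a + b + c), the standard multi-locus
combination. Negative per-SNP estimates (finite-sample noise) are reported
as-is, not clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GenotypeMatrix, thin_loci_by_window

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    coords: np.ndarray  # (n_samples, k)
    explained_variance_ratio: np.ndarray
    sample_ids: list[str]


def _imputed_centered(counts: np.ndarray, ploidy: np.ndarray):
    """Dosage on a diploid scale, mean-imputed and mean-centered per locus.

    Hemizygous entries are doubled so one Z/mt copy spans the same 0..2
    range as a diploid genotype; loci with no data are flagged for removal.
    """
    c = counts.astype(float)
    p = ploidy.astype(float)
    obs = (counts >= 0) & (ploidy > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dose = np.where(obs, 2.0 * c / np.maximum(p, 1), np.nan)
    col_mean = np.nanmean(np.where(obs, dose, np.nan), axis=0)
    empty = ~obs.any(axis=0)
    dose = np.where(obs, dose, col_mean[None, :])
    dose = dose - col_mean[None, :]
    return dose, empty


def pca(gm: GenotypeMatrix, thin_bp: int | None = 10_000, k: int = 10) -> PcaResult:
    """PCA of the mean-centered genotype matrix.

    Loci are thinned to one per ``thin_bp`` window (pass None to skip),
    missing genotypes are imputed by the locus mean, and the top-k
    principal coordinates of the sample covariance are returned.
    """
    if gm.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if thin_bp:
        gm = gm.subset_loci(thin_loci_by_window(gm.loci, thin_bp))
    dose, empty = _imputed_centered(gm.counts, gm.ploidy)
    if empty.any():
        logger.warning("dropping %d all-missing locus/loci", int(empty.sum()))
        dose = dose[:, ~empty]
    dose = np.where(np.isnan(dose), 0.0, dose)
    k = min(k, gm.n_samples - 1, dose.shape[1])
    from sklearn.decomposition import PCA as SkPCA

    model = SkPCA(n_components=k, svd_solver="full")
    coords = model.fit_transform(dose)
    return PcaResult(coords, model.explained_variance_ratio_, list(gm.samples))


def _wc_components(countsA, ploidyA, countsB, ploidyB):
    """Weir & Cockerham (1984) per-locus variance components for two pops.

    Only diploid genotypes enter (the estimator's heterozygosity terms are
    undefined for hemizygous calls). Returns (a, b, c, defined) arrays.
    """

    def pop_stats(c, p):
        ok = (c >= 0) & (p == 2)
        n = ok.sum(axis=0).astype(float)  # diploid individuals with data
        alt = np.where(ok, c, 0).sum(axis=0).astype(float)
        het = np.where(ok, c == 1, False).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pfreq = np.where(n > 0, alt / (2 * n), np.nan)
            hfreq = np.where(n > 0, het / n, np.nan)
        return n, pfreq, hfreq

    n1, p1, h1 = pop_stats(countsA, ploidyA)
    n2, p2, h2 = pop_stats(countsB, ploidyB)
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        cc = hbar / 2.0
    poly = ~((pbar == 0) | (pbar == 1)) & (n1 >= 2) & (n2 >= 2) & (nbar > 1)
    defined = poly & np.isfinite(a) & np.isfinite(b) & np.isfinite(cc)
    return a, b, cc, defined


def wc_fst_snp(gm: GenotypeMatrix, pop_a_samples, pop_b_samples) -> pd.DataFrame:
    """Per-SNP Weir–Cockerham theta-hat between two sample sets.

    Loci monomorphic across both populations (or with < 2 diploid
    individuals with data in either) are reported as NaN, not 0. Estimates
    may be negative.
    """
    ia = gm.sample_index(pop_a_samples)
    ib = gm.sample_index(pop_b_samples)
    a, b, cc, defined = _wc_components(
        gm.counts[ia], gm.ploidy[ia], gm.counts[ib], gm.ploidy[ib]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(defined, a / (a + b + cc), np.nan)
    out = gm.loci[["chrom", "pos"]].copy()
    out["fst"] = theta
    out["a"] = np.where(defined, a, np.nan)
    out["abc"] = np.where(defined, a + b + cc, np.nan)
    return out


def wc_fst_windowed(
    gm: GenotypeMatrix,
    pop_a_samples,
    pop_b_samples,
    window_bp: int = 25_000,
    step_bp: int = 5_000,
    chrom_lengths: dict[str, int] | None = None,
    anchor: int = 1,
) -> pd.DataFrame:
    """Sliding-window F_ST as ratio-of-sums of Weir–Cockerham components.

    Windows start at ``anchor`` and advance by ``step_bp``; only windows
    fully inside the chromosome (length from ``chrom_lengths`` or the last
    SNP position) are emitted. Windows with no defined SNP get NaN.
    """
    snp = wc_fst_snp(gm, pop_a_samples, pop_b_samples)
    rows = []
    for chrom, sub in snp.groupby("chrom", sort=False):
        length = (
            chrom_lengths.get(chrom, int(sub["pos"].max()))
            if chrom_lengths
            else int(sub["pos"].max())
        )
        pos = sub["pos"].to_numpy()
        a = sub["a"].to_numpy()
        abc = sub["abc"].to_numpy()
        ok = np.isfinite(abc)
        start = anchor
        while start + window_bp - 1 <= length:
            end = start + window_bp - 1
            inside = (pos >= start) & (pos <= end)
            use = inside & ok
            n_snps = int(inside.sum())
            denom = abc[use].sum()
            fst = a[use].sum() / denom if use.any() and denom != 0 else np.nan
            rows.append((chrom, start, end, fst, n_snps))
            start += step_bp
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "fst", "n_snps"])


def individual_inbreeding_f(
    gm: GenotypeMatrix, loci_mask: np.ndarray | None = None
) -> pd.Series:
    """Method-of-moments inbreeding coefficient per individual.

    F = (O_hom - E_hom) / (L_used - E_hom), with the expected homozygosity
    at locus l computed from the cohort allele frequency with the usual
    finite-sample correction: E_hom_l = 1 - 2 p_l (1 - p_l) n_l / (n_l - 1),
    n_l the number of allele copies observed at l. Only diploid genotypes
    enter. Strongly negative values flag heterozygote excess (e.g.
    inversion heterozygotes over the inverted region).
    """
    counts = gm.counts
    ploidy = gm.ploidy
    if loci_mask is not None:
        counts = counts[:, loci_mask]
        ploidy = ploidy[:, loci_mask]
    dip = (counts >= 0) & (ploidy == 2)
    alt_total = np.where((counts >= 0) & (ploidy > 0), counts, 0).sum(axis=0)
    n_copies = np.where((counts >= 0) & (ploidy > 0), ploidy, 0).sum(axis=0).astype(
        float
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_copies > 0, alt_total / n_copies, np.nan)
        e_het = 2.0 * p * (1 - p) * np.where(n_copies > 1, n_copies / (n_copies - 1), np.nan)
    usable = dip & np.isfinite(e_het)[None, :]
    o_hom = (usable & (counts != 1)).sum(axis=1).astype(float)
    l_used = usable.sum(axis=1).astype(float)
    e_hom = np.where(usable, 1.0 - e_het[None, :], 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(l_used > e_hom, (o_hom - e_hom) / (l_used - e_hom), np.nan)
    return pd.Series(f, index=gm.samples, name="F")


def select_least_admixed(
    h_means: pd.Series,
    hets: pd.Series,
    h_threshold: float = 0.1,
    het_threshold: float = 0.1,
) -> dict[str, list[str]]:
    """The least-admixed filter: h < 0.1 or > 0.9, heterozygosity < 0.1.

    Returns {"P0": [...], "P1": [...]} sample-id lists; idempotent and
    order-independent set arithmetic.
    """
    h = h_means.reindex(hets.index)
    p0 = (h < h_threshold) & (hets < het_threshold)
    p1 = (h > 1 - h_threshold) & (hets < het_threshold)
    return {
        "P0": sorted(h.index[p0.fillna(False)]),
        "P1": sorted(h.index[p1.fillna(False)]),
    }


def assign_mitotype(
    gm_mt: GenotypeMatrix,
    reference_clades: dict[str, list[str]],
    k: int = 2,
) -> pd.DataFrame:
    """Assign every sample the mtDNA clade of its nearest reference centroid.

    PCA on the mtDNA variants (no thinning), centroids of the allopatric
    reference samples of each clade in the top-``k`` PC plane, nearest
    centroid by Euclidean distance. Exact ties break deterministically by
    clade label order and are flagged.
    """
    res = pca(gm_mt, thin_bp=None, k=k)
    coords = res.coords
    index = {s: i for i, s in enumerate(gm_mt.samples)}
    clades = sorted(reference_clades)
    centroids = {}
    for clade in clades:
        rows = [index[s] for s in reference_clades[clade]]
        if not rows:
            raise ValueError(f"clade {clade!r} has no reference samples")
        centroids[clade] = coords[rows].mean(axis=0)
    out = []
    for i, sid in enumerate(gm_mt.samples):
        d = {cl: float(np.linalg.norm(coords[i] - centroids[cl])) for cl in clades}
        dmin = min(d.values())
        nearest = [cl for cl in clades if d[cl] == dmin]
        out.append((sid, nearest[0], dmin, len(nearest) > 1))
    return pd.DataFrame(out, columns=["sample_id", "mitotype", "distance", "tie"])
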