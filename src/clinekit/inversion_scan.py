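"""Detection of large polymorphic inversions from local PCA structure.

A segregating, recombination-suppressed inversion shows up on a chromosome
as (1) a block of SNPs whose genotypes are strongly associated with the
leading local principal components — a stepwise plateau in a Manhattan-style
score track — and (2) three discrete sample clusters on PC1 inside the
block (two arrangement homozygotes plus heterozygotes), the heterozygote
cluster carrying a strong excess of heterozygosity (lowest individual F).

Boundaries are read off the score track by least-squares changepoint
segmentation: an exact dynamic program fits piecewise-constant models with
1..max segments, the segment number is chosen by BIC, and a candidate
region qualifies only if its mean score exceeds the outside mean by a
configurable factor and spans a minimum fraction of the chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GenotypeMatrix
from .popgen_stats import _imputed_centered, individual_inbreeding_f, pca

logger = logging.getLogger(__name__)


@dataclass
class InversionCall:
    chrom: str
    start_bp: int
    end_bp: int
    score_track: pd.DataFrame  # pos, score
    haplotype_groups: pd.Series  # per-sample label in {AA, AB, BB}
    group_mean_f: dict[str, float]
    ab_lowest_f: bool
    warnings: list[str] = field(default_factory=list)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def length_mb(self) -> float:
        return inversion_length(self.start_bp, self.end_bp)


def inversion_length(start_bp: int, end_bp: int) -> float:
    """Span in Mb to one decimal, defined as (end - start) / 1e6."""
    return round((end_bp - start_bp) / 1e6, 1)


def _logistic_lrt(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Vectorized likelihood-ratio test of logistic(y ~ x) per SNP column.

    y: (n,) binary group membership; x: (n, S) genotype dosages. Newton
    iterations with clipped linear predictors; perfect separation simply
    drives the deviance toward the null deviance (a huge score), which is
    the desired behaviour for a scan statistic. Returns -log10 p (chi2, 1 df).
    """
    n, S = x.shape
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        return np.zeros(S)
    ll0 = n * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar))
    b0 = np.full(S, np.log(ybar / (1 - ybar)))
    b1 = np.zeros(S)
    yv = y[:, None]
    for _ in range(40):
        eta = np.clip(b0[None, :] + b1[None, :] * x, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-10)
        r = yv - mu
        g0 = r.sum(axis=0)
        g1 = (x * r).sum(axis=0)
        h00 = w.sum(axis=0) + 1e-8
        h01 = (w * x).sum(axis=0)
        h11 = (w * x * x).sum(axis=0) + 1e-8
        det = h00 * h11 - h01 * h01
        db0 = (h11 * g0 - h01 * g1) / det
        db1 = (h00 * g1 - h01 * g0) / det
        step = np.clip(np.stack([db0, db1]), -5, 5)
        b0 += step[0]
        b1 += step[1]
        if np.max(np.abs(step)) < 1e-8:
            break
    eta = np.clip(b0[None, :] + b1[None, :] * x, -30, 30)
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    ll1 = (yv * np.log(mu) + (1 - yv) * np.log1p(-mu)).sum(axis=0)
    lrt = np.maximum(2.0 * (ll1 - ll0), 0.0)
    p = np.maximum(stats.chi2.sf(lrt, df=1), 1e-300)
    return -np.log10(p)


def snp_pc_association(gm_chrom: GenotypeMatrix, k: int = 2) -> pd.DataFrame:
    """Per-SNP association score with the top local PCs of one chromosome.

    PCA over the chromosome's SNPs (no thinning); each SNP's genotype is
    tested against membership in each PC's halves (above/below the median
    coordinate) by a logistic likelihood-ratio test; the score is the max
    over PCs of -log10 p. Monomorphic SNPs score 0.
    """
    if gm_chrom.n_samples < 10:
        raise ValueError("need at least 10 samples")
    if gm_chrom.loci["chrom"].nunique() != 1:
        raise ValueError("matrix must be restricted to one chromosome")
    res = pca(gm_chrom, thin_bp=None, k=k)
    dose, empty = _imputed_centered(gm_chrom.counts, gm_chrom.ploidy)
    dose = np.where(np.isnan(dose), 0.0, dose)
    mono = dose.std(axis=0) == 0
    scores = np.zeros(gm_chrom.n_loci)
    for j in range(res.coords.shape[1]):
        coord = res.coords[:, j]
        y = (coord > np.median(coord)).astype(float)
        s = _logistic_lrt(y, dose)
        scores = np.maximum(scores, s)
    scores[mono | empty] = 0.0
    return pd.DataFrame(
        {"pos": gm_chrom.loci["pos"].to_numpy(), "score": scores}
    )


def _segment_dp(values: np.ndarray, max_segments: int):
    """Exact least-squares segmentation into 1..max_segments pieces.

    Returns (costs, boundaries) where costs[m] is the optimal SSE with m+1
    segments and boundaries[m] the list of segment start indices.
    """
    t = len(values)
    s1 = np.concatenate([[0.0], np.cumsum(values)])
    s2 = np.concatenate([[0.0], np.cumsum(values**2)])

    def sse(i, j):  # [i, j), vectorized over i or j
        n = j - i
        tot = s1[j] - s1[i]
        return (s2[j] - s2[i]) - tot**2 / np.maximum(n, 1)

    big = np.inf
    cost = np.full((max_segments, t + 1), big)
    back = np.zeros((max_segments, t + 1), dtype=int)
    idx = np.arange(t + 1)
    cost[0] = np.where(idx >= 1, sse(0, idx), big)
    for m in range(1, max_segments):
        for j in range(m + 1, t + 1):
            i = np.arange(m, j)
            cand = cost[m - 1, i] + sse(i, j)
            best = np.argmin(cand)
            cost[m, j] = cand[best]
            back[m, j] = i[best]
    costs = cost[:, t]
    bounds = []
    for m in range(max_segments):
        cuts = []
        j = t
        for mm in range(m, 0, -1):
            j = back[mm, j]
            cuts.append(j)
        bounds.append([0] + sorted(cuts))
    return costs, bounds


def detect_boundaries(
    score_track: pd.DataFrame,
    factor: float = 3.0,
    min_frac: float = 0.05,
    max_segments: int = 5,
    z: float = 3.0,
    bridge: int = 2,
) -> tuple[tuple[int, int] | None, list[str]]:
    """Stepwise-block boundaries from a per-SNP association score track.

    Segments the score track by exact least-squares changepoints (number of
    segments by BIC, up to ``max_segments``), then calls the contiguous
    high-scoring run whose mean exceeds the outside mean by ``factor`` and
    whose bp span covers at least ``min_frac`` of the chromosome's SNP
    extent. The run must also clear the outside mean by ``z`` outside
    standard deviations, which rejects noise plateaus when the outside mean
    sits near zero (both rules are ratios/linear in the score scale, so the
    call is invariant to uniform rescaling).

    Boundaries of the called core are then snapped to the block edges by a
    binarize-and-bridge pass: SNPs are classified high/low against the
    midpoint of the block and outside means, and the block extends over
    every high SNP reachable from the core across gaps of at most
    ``bridge`` low SNPs (isolated uninformative SNPs inside a real
    non-recombining block otherwise drag the least-squares cut inward).
    Returns ((start_bp, end_bp), warnings) or (None, warnings); with
    several disjoint qualifying regions the highest-mean one is returned
    with a warning.
    """
    warnings_: list[str] = []
    pos = score_track["pos"].to_numpy()
    scores = score_track["score"].to_numpy().astype(float)
    t = len(scores)
    if t < 10:
        return None, ["score track too short"]
    order = np.argsort(pos)
    pos, scores = pos[order], scores[order]

    costs, bounds = _segment_dp(scores, max_segments)
    n = float(t)
    # BIC over segment count: each extra segment spends one mean + one cut
    var_floor = max(np.var(scores) * 1e-12, 1e-300)
    bic = np.array(
        [
            n * np.log(max(costs[m] / n, var_floor)) + 2.0 * (m + 1) * np.log(n)
            for m in range(max_segments)
        ]
    )
    m_best = int(np.argmin(bic))
    if m_best == 0:
        return None, warnings_
    cuts = bounds[m_best] + [t]
    seg_spans = [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]
    extent = pos[-1] - pos[0]

    candidates = []
    nseg = len(seg_spans)
    for i in range(nseg):
        for j in range(i, nseg):
            lo, hi = seg_spans[i][0], seg_spans[j][1]
            if lo == 0 and hi == t:
                continue
            inside = scores[lo:hi]
            outside = np.concatenate([scores[:lo], scores[hi:]])
            mean_in = inside.mean()
            mean_out = outside.mean() if outside.size else 0.0
            std_out = outside.std() if outside.size else 0.0
            span = pos[hi - 1] - pos[lo]
            if (
                mean_in > factor * max(mean_out, 1e-12)
                and mean_in > mean_out + z * std_out
                and span >= min_frac * extent
            ):
                candidates.append((mean_in, mean_out, lo, hi))
    if not candidates:
        return None, warnings_
    # prune nested/overlapping cores: keep maximal-mean disjoint ones
    candidates.sort(reverse=True)
    chosen: list[tuple[float, float, int, int]] = []
    for mean_in, mean_out, lo, hi in candidates:
        if all(hi <= lo2 or lo >= hi2 for _, _, lo2, hi2 in chosen):
            chosen.append((mean_in, mean_out, lo, hi))
    if len(chosen) > 1:
        warnings_.append(
            f"{len(chosen)} qualifying regions; returning the highest-mean one"
        )
    mean_in, mean_out, lo, hi = max(chosen)
    # snap to block edges: bridge over runs of <= `bridge` low SNPs
    tau = 0.5 * (mean_in + mean_out)
    high = scores > tau
    new_lo, gap = lo, 0
    for jdx in range(lo - 1, -1, -1):
        if high[jdx]:
            new_lo, gap = jdx, 0
        else:
            gap += 1
            if gap > bridge:
                break
    new_hi, gap = hi - 1, 0
    for jdx in range(hi, t):
        if high[jdx]:
            new_hi, gap = jdx, 0
        else:
            gap += 1
            if gap > bridge:
                break
    # trim low edges inside the core as well
    while new_lo < new_hi and not high[new_lo]:
        new_lo += 1
    while new_hi > new_lo and not high[new_hi]:
        new_hi -= 1
    if len(chosen) == 1:
        # masked re-scan: does a secondary block hide behind this one?
        keep = np.ones(t, dtype=bool)
        keep[new_lo : new_hi + 1] = False
        if keep.sum() >= 10:
            rest = pd.DataFrame({"pos": pos[keep], "score": scores[keep]})
            secondary, _ = detect_boundaries(
                rest, factor=factor, min_frac=min_frac,
                max_segments=max_segments, z=z, bridge=0,
            )
            if secondary is not None:
                warnings_.append(
                    f"secondary qualifying region near {secondary}; "
                    "returning the higher-scoring one (re-run masked to call it)"
                )
    return (int(pos[new_lo]), int(pos[new_hi])), warnings_


def assign_haplotype_groups(
    gm_region: GenotypeMatrix, seed: int = 0, max_groups: int = 3
) -> tuple[pd.Series, dict[str, float], bool, list[str]]:
    """Cluster samples into inversion haplotype groups on local PC1.

    A 1-D Gaussian mixture on PC1 with the component count (1..3) chosen by
    BIC. Groups are labelled AA/AB/BB by their mean genotype dosage inside
    the region (AA lowest); the AB (heterozygote) group is validated as
    having the lowest mean individual inbreeding F, flagged otherwise.
    Returns (labels, group mean F, ab_lowest_f, warnings).
    """
    from sklearn.mixture import GaussianMixture

    warnings_: list[str] = []
    res = pca(gm_region, thin_bp=None, k=2)
    pc1 = res.coords[:, :1]
    best = None
    for ncomp in range(1, max_groups + 1):
        gmm = GaussianMixture(
            n_components=ncomp, covariance_type="tied", n_init=5,
            random_state=seed, reg_covar=1e-6,
        ).fit(pc1)
        b = gmm.bic(pc1)
        if best is None or b < best[0]:
            best = (b, ncomp, gmm)
    _, ncomp, gmm = best
    comp = gmm.predict(pc1)
    dose, _ = _imputed_centered(gm_region.counts, gm_region.ploidy)
    dose = np.where(np.isnan(dose), 0.0, dose)
    mean_dose = np.array([dose[comp == c].mean() for c in range(ncomp)])
    # arrangement homozygotes differ by ~2 alt copies per locus; clusters
    # closer than half a copy are noise on a monomorphic block
    if ncomp > 1 and mean_dose.max() - mean_dose.min() < 0.5:
        ncomp = 1
        comp = np.zeros(len(comp), dtype=int)
        mean_dose = mean_dose[:1]
    order = np.argsort(mean_dose)
    if ncomp == 3:
        names = {order[0]: "AA", order[1]: "AB", order[2]: "BB"}
    elif ncomp == 2:
        names = {order[0]: "AA", order[1]: "BB"}
        warnings_.append("only 2 haplotype groups supported by BIC")
    else:
        names = {order[0]: "AA"}
        warnings_.append("single haplotype group; no heterozygotes detected")
    labels = pd.Series(
        [names[c] for c in comp], index=gm_region.samples, name="haplotype_group"
    )
    f = individual_inbreeding_f(gm_region)
    group_mean_f = {
        g: float(f[labels == g].mean()) for g in sorted(set(labels))
    }
    ab_lowest = True
    if "AB" in group_mean_f and len(group_mean_f) > 1:
        ab_lowest = group_mean_f["AB"] == min(group_mean_f.values())
        if not ab_lowest:
            warnings_.append("AB group does not have the lowest mean F")
    return labels, group_mean_f, ab_lowest, warnings_


def scan_inversion(
    gm: GenotypeMatrix,
    chrom: str,
    k: int = 2,
    factor: float = 3.0,
    min_frac: float = 0.05,
    seed: int = 0,
) -> InversionCall | None:
    """Full scan of one chromosome: score, boundaries, haplotype groups."""
    sub = gm.restrict_chrom(chrom)
    track = snp_pc_association(sub, k=k)
    region, warnings_ = detect_boundaries(track, factor=factor, min_frac=min_frac)
    if region is None:
        return None
    start, end = region
    in_region = (sub.loci["pos"] >= start) & (sub.loci["pos"] <= end)
    labels, group_f, ab_lowest, w2 = assign_haplotype_groups(
        sub.subset_loci(in_region.to_numpy()), seed=seed
    )
    return InversionCall(
        chrom=chrom,
        start_bp=start,
        end_bp=end,
        score_track=track,
        haplotype_groups=labels,
        group_mean_f=group_f,
        ab_lowest_f=ab_lowest,
        warnings=warnings_ + w2,
    )
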