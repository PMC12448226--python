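"""Diagnostic panels, Bayesian hybrid indexes, and hybrid-class labels.

The hybrid index h of an individual is the proportion of its allele copies
at species-diagnostic loci that derive from the parental-1 species. With a
fixed diagnostic panel each non-missing allele copy is P1-derived
independently with probability h, so the likelihood is binomial in the
P1-copy total; the sampler is a random-walk Metropolis on logit(h) with a
Beta(0.5, 0.5) (Jeffreys) prior, which keeps the estimator honest at the
h -> 0/1 boundaries where parental samples sit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _mcmc
from .core_io import DEFAULT_HAPLOID_CHROMS, GenotypeMatrix, thin_loci_by_window

logger = logging.getLogger(__name__)


@dataclass
class DiagnosticPanel:
    """Loci fixed for alternative alleles between the two reference panels.

    ``p1_is_alt[j]`` records the parental orientation: True when the alt
    allele is the one carried by the P1 reference panel at locus j.
    """

    loci: pd.DataFrame  # chrom, pos, ref, alt
    p1_is_alt: np.ndarray

    def __len__(self) -> int:
        return len(self.loci)

    def swapped(self) -> "DiagnosticPanel":
        return DiagnosticPanel(self.loci.copy(), ~self.p1_is_alt)


@dataclass
class HybridIndexPosterior:
    sample_id: str
    h_mean: float
    h_ci: tuple[float, float]
    draws: np.ndarray
    n_copies_used: int
    prior_only: bool = False


def select_diagnostic(
    gm: GenotypeMatrix,
    panel_a_samples,
    panel_b_samples,
    thin_bp: int = 10_000,
    exclude_chroms=DEFAULT_HAPLOID_CHROMS,
) -> DiagnosticPanel:
    """Loci where the two reference panels are fixed for alternative alleles.

    A locus qualifies when every observed allele copy in panel A carries one
    allele and every observed copy in panel B carries the other (per-SNP
    F_ST = 1 after missing-data exclusion), both panels having data. The
    qualifying set is then thinned to one locus per ``thin_bp`` window.
    mtDNA pseudo-chromosomes are excluded: the nuclear hybrid index must not
    absorb the uniparentally inherited mitotype.
    """
    ia = gm.sample_index(panel_a_samples)
    ib = gm.sample_index(panel_b_samples)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("both reference panels must be nonempty")

    def fixed_state(idx):
        c = gm.counts[idx]
        p = gm.ploidy[idx]
        obs = (c >= 0) & (p > 0)
        alt = np.where(obs, c, 0).sum(axis=0)
        tot = np.where(obs, p, 0).sum(axis=0)
        all_ref = (alt == 0) & (tot > 0)
        all_alt = (alt == tot) & (tot > 0)
        return all_ref, all_alt

    a_ref, a_alt = fixed_state(ia)
    b_ref, b_alt = fixed_state(ib)
    qualifies = (a_ref & b_alt) | (a_alt & b_ref)
    if exclude_chroms:
        qualifies &= ~gm.loci["chrom"].isin(exclude_chroms).to_numpy()
    if not qualifies.any():
        raise ValueError(
            "no loci fixed for alternative alleles between the panels; "
            "larger or purer reference panels are needed"
        )
    loci = gm.loci.loc[qualifies, ["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    p1_is_alt = b_alt[qualifies]  # P1 == panel B
    keep = thin_loci_by_window(loci, thin_bp)
    return DiagnosticPanel(loci.iloc[keep].reset_index(drop=True), p1_is_alt[keep])


def panel_copy_counts(
    gm: GenotypeMatrix, panel: DiagnosticPanel
) -> tuple[np.ndarray, np.ndarray]:
    """Per sample x panel-locus (P1 allele copies, total observed copies)."""
    key = pd.MultiIndex.from_frame(gm.loci[["chrom", "pos"]])
    want = pd.MultiIndex.from_frame(panel.loci[["chrom", "pos"]])
    idx = key.get_indexer(want)
    if np.any(idx < 0):
        missing = panel.loci.iloc[np.flatnonzero(idx < 0)[0]]
        raise KeyError(
            f"panel locus {missing['chrom']}:{missing['pos']} absent from matrix"
        )
    c = gm.counts[:, idx].astype(np.int32)
    p = gm.ploidy[:, idx].astype(np.int32)
    obs = (c >= 0) & (p > 0)
    p1 = np.where(panel.p1_is_alt[None, :], c, p - c)
    p1 = np.where(obs, p1, 0)
    total = np.where(obs, p, 0)
    return p1, total


def estimate_hybrid_index(
    gm: GenotypeMatrix,
    panel: DiagnosticPanel,
    burn: int = 5000,
    keep: int = 10_000,
    seed: int | None = None,
    prior: tuple[float, float] = (0.5, 0.5),
) -> list[HybridIndexPosterior]:
    """Posterior hybrid index per sample by random-walk Metropolis.

    Each non-missing allele copy at a diagnostic locus is the P1 allele
    independently with probability h; female Z loci contribute one copy
    (hemizygous). Samples with zero observed copies get the prior back,
    flagged ``prior_only``. All chains run vectorized with per-chain
    adaptive steps.
    """
    if len(panel) == 0:
        raise ValueError("empty diagnostic panel")
    rng = np.random.default_rng(seed)
    p1, total = panel_copy_counts(gm, panel)
    k = p1.sum(axis=1).astype(float)
    n = total.sum(axis=1).astype(float)
    a, b = prior

    def logpost(theta):
        # posterior on the logit scale: Jacobian folds the prior into
        # h^(k+a) (1-h)^(n-k+b); stable logistic log-terms
        log_h = -np.logaddexp(0.0, -theta)
        log_1mh = -theta + log_h
        return (k + a) * log_h + (n - k + b) * log_1mh

    theta0 = np.log((k + a) / (n - k + b))
    draws_t, _ = _mcmc.batch_random_walk(logpost, theta0, burn, keep, rng)
    draws = 1.0 / (1.0 + np.exp(-draws_t))

    out = []
    for i, sid in enumerate(gm.samples):
        d = draws[:, i]
        lo, hi = np.quantile(d, [0.025, 0.975])
        prior_only = n[i] == 0
        if prior_only:
            logger.warning("sample %s has no diagnostic data; prior returned", sid)
        out.append(
            HybridIndexPosterior(
                sample_id=sid,
                h_mean=float(d.mean()),
                h_ci=(float(lo), float(hi)),
                draws=d,
                n_copies_used=int(n[i]),
                prior_only=bool(prior_only),
            )
        )
    return out


def interspecific_heterozygosity(
    gm: GenotypeMatrix, panel: DiagnosticPanel
) -> pd.Series:
    """Fraction of non-missing diploid diagnostic loci heterozygous per sample.

    Hemizygous entries (female Z, mtDNA) carry no heterozygosity information
    and are excluded. Samples with no usable loci get NaN.
    """
    key = pd.MultiIndex.from_frame(gm.loci[["chrom", "pos"]])
    want = pd.MultiIndex.from_frame(panel.loci[["chrom", "pos"]])
    idx = key.get_indexer(want)
    c = gm.counts[:, idx]
    p = gm.ploidy[:, idx]
    usable = (c >= 0) & (p == 2)
    het = ((c == 1) & usable).sum(axis=1)
    n = usable.sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    if np.isnan(frac).any():
        logger.warning(
            "%d sample(s) had no diploid diagnostic data", int(np.isnan(frac).sum())
        )
    return pd.Series(frac, index=gm.samples, name="het")


@dataclass
class ClassThresholds:
    """Hybrid-class decision rules, matching the least-admixed filter style."""

    f1_het_min: float = 0.95
    f1_h_halfwidth: float = 0.05
    parental_h: float = 0.1  # h < 0.1 or h > 0.9
    parental_het_max: float = 0.1


def classify_hybrid(
    h_mean: float, het: float, thresholds: ClassThresholds | None = None
) -> str:
    """Label a sample F1 / parental-like / admixed from (h, heterozygosity)."""
    t = thresholds or ClassThresholds()
    if het >= t.f1_het_min and abs(h_mean - 0.5) <= t.f1_h_halfwidth:
        return "F1"
    if h_mean < t.parental_h and het < t.parental_het_max:
        return "parental_P0"
    if h_mean > 1 - t.parental_h and het < t.parental_het_max:
        return "parental_P1"
    return "admixed/backcross"
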