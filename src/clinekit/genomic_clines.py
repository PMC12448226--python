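"""Per-locus Bayesian genomic clines against genome-wide hybrid index.

A genomic cline relates the probability that an allele copy at a locus is
P1-derived to the carrier's genome-wide hybrid index h:

    phi(h; v, c) = logistic( v * (logit h - logit c) )

v is the cline steepness (v = 1: the locus transitions at the genome-wide
average rate; v > 1: sigmoidal, introgression restricted on both sides of
the centre) and c the hybrid-index value where the locus ancestry
probability is 1/2. Sampling is random-walk Metropolis on (ln v, logit c)
with Normal(0, 1.5^2) priors on both transformed coordinates; the
significance call for restricted introgression is v > 1 with a two-sided
MCMC tail probability p_v < alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _mcmc

logger = logging.getLogger(__name__)

_H_EPS = 1e-6


@dataclass
class GenomicClineFit:
    locus: tuple[str, int] | None
    v_mean: float
    v_ci: tuple[float, float]
    centre_mean: float
    p_v: float
    significant_restricted: bool
    v_draws: np.ndarray
    centre_draws: np.ndarray
    warning: str | None = None


def phi(h, v, centre):
    """Locus ancestry probability at hybrid index h.

    Vectorized over any broadcastable combination; h = 0 and 1 map to 0 and
    1 exactly (continuity limits).
    """
    h = np.asarray(h, dtype=float)
    v = np.asarray(v, dtype=float)
    centre = np.asarray(centre, dtype=float)
    hc = np.clip(h, _H_EPS, 1 - _H_EPS)
    logit_h = np.log(hc) - np.log1p(-hc)
    logit_c = np.log(centre) - np.log1p(-centre)
    out = 1.0 / (1.0 + np.exp(-v * (logit_h - logit_c)))
    out = np.where(h <= 0.0, 0.0, out)
    out = np.where(h >= 1.0, 1.0, out)
    return out if out.ndim else float(out)


def fit_genomic_clines(
    p1_copies: np.ndarray,
    total_copies: np.ndarray,
    h_means: np.ndarray,
    burn: int = 5000,
    keep: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
    prior_sd: float = 1.5,
    loci: pd.DataFrame | None = None,
    fdr: bool = False,
) -> list[GenomicClineFit]:
    """Fit genomic clines for a batch of loci in one vectorized sampler.

    ``p1_copies``/``total_copies`` are (n_loci, n_samples) P1-allele copy
    counts and observed copy numbers (0 where missing); ``h_means`` the
    per-sample genome-wide hybrid indexes, treated as fixed. Each locus
    gets an independent (ln v, logit c) chain; all chains run together.

    ``fdr=True`` applies Benjamini–Hochberg to the p_v values before the
    significance call (off by default: the per-locus alpha rule).
    """
    y = np.asarray(p1_copies, dtype=float)
    m = np.asarray(total_copies, dtype=float)
    if y.ndim == 1:
        y = y[None, :]
        m = m[None, :]
    L, N = y.shape
    h = np.asarray(h_means, dtype=float)
    n_informative = (m > 0).sum(axis=1)
    if np.any(n_informative < 20):
        logger.warning(
            "%d locus/loci have < 20 samples with data", int((n_informative < 20).sum())
        )

    hc = np.clip(h, _H_EPS, 1 - _H_EPS)
    logit_h = np.log(hc) - np.log1p(-hc)  # (N,)

    warnings_ = [None] * L
    admixed = (h > 0.05) & (h < 0.95)
    for j in range(L):
        obs = m[j] > 0
        sel = obs & admixed
        if sel.any():
            frac = y[j, sel].sum() / m[j, sel].sum()
            if frac in (0.0, 1.0):
                warnings_[j] = "monomorphic among admixed samples"

    rng = np.random.default_rng(seed)

    def loglik(ln_v, logit_c):
        vv = np.exp(ln_v)[:, None]
        eta = vv * (logit_h[None, :] - logit_c[:, None])
        eta = np.clip(eta, -35.0, 35.0)
        p = 1.0 / (1.0 + np.exp(-eta))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return (y * np.log(p) + (m - y) * np.log1p(-p)).sum(axis=1)

    def logprior(ln_v, logit_c):
        return -0.5 * (ln_v**2 + logit_c**2) / prior_sd**2

    # blockwise MH: the two coordinates are proposed jointly per locus
    ln_v = np.zeros(L)
    logit_c = np.zeros(L)
    lp = loglik(ln_v, logit_c) + logprior(ln_v, logit_c)
    steps_v = np.full(L, 0.3)
    steps_c = np.full(L, 0.3)
    draws_v = np.empty((keep, L))
    draws_c = np.empty((keep, L))
    acc = np.zeros(L)
    for it in range(burn + keep):
        prop_v = ln_v + steps_v * rng.standard_normal(L)
        prop_c = logit_c + steps_c * rng.standard_normal(L)
        lp_prop = loglik(prop_v, prop_c) + logprior(prop_v, prop_c)
        accept = np.log(rng.random(L)) < lp_prop - lp
        ln_v[accept] = prop_v[accept]
        logit_c[accept] = prop_c[accept]
        lp[accept] = lp_prop[accept]
        if it < burn:
            acc += accept
            if (it + 1) % _mcmc.ADAPT_EVERY == 0:
                _mcmc.adapt_steps(steps_v, acc, _mcmc.ADAPT_EVERY)
                _mcmc.adapt_steps(steps_c, acc, _mcmc.ADAPT_EVERY)
                acc[:] = 0
        else:
            draws_v[it - burn] = ln_v
            draws_c[it - burn] = logit_c

    v_draws = np.exp(draws_v)
    c_draws = 1.0 / (1.0 + np.exp(-draws_c))
    pr_gt = (draws_v > 0).mean(axis=0)
    p_v = 2.0 * np.minimum(pr_gt, 1.0 - pr_gt)

    p_eff = p_v.copy()
    if fdr:
        order = np.argsort(p_v)
        ranked = p_v[order] * L / (np.arange(L) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        p_eff[order] = np.minimum(ranked, 1.0)

    fits = []
    for j in range(L):
        vm = float(v_draws[:, j].mean())
        lo, hi = np.quantile(v_draws[:, j], [0.025, 0.975])
        fits.append(
            GenomicClineFit(
                locus=(
                    (loci.iloc[j]["chrom"], int(loci.iloc[j]["pos"]))
                    if loci is not None
                    else None
                ),
                v_mean=vm,
                v_ci=(float(lo), float(hi)),
                centre_mean=float(c_draws[:, j].mean()),
                p_v=float(p_v[j]),
                significant_restricted=bool(vm > 1.0 and p_eff[j] < alpha),
                v_draws=v_draws[:, j],
                centre_draws=c_draws[:, j],
                warning=warnings_[j],
            )
        )
    return fits


def fit_genomic_cline(
    p1_copies, total_copies, h_means, **kwargs
) -> GenomicClineFit:
    """Single-locus convenience wrapper around :func:`fit_genomic_clines`."""
    return fit_genomic_clines(p1_copies, total_copies, h_means, **kwargs)[0]


def summarize_steepness(
    fits: list[GenomicClineFit], transect: str = ""
) -> dict:
    """Arithmetic over restricted-introgression calls.

    Returns the mean steepness among significant loci, the count of
    significant loci with v > 10, and per-chromosome significant counts.
    An empty significant set yields an empty summary, not an error.
    """
    if not fits:
        raise ValueError("no fits to summarize")
    sig = [f for f in fits if f.significant_restricted]
    per_chrom: dict[str, int] = {}
    for f in sig:
        chrom = f.locus[0] if f.locus else "?"
        per_chrom[chrom] = per_chrom.get(chrom, 0) + 1
    return {
        "transect": transect,
        "n_tested": len(fits),
        "n_significant": len(sig),
        "mean_v_significant": (
            float(np.mean([f.v_mean for f in sig])) if sig else None
        ),
        "n_v_gt_10": sum(1 for f in sig if f.v_mean > 10),
        "per_chromosome": per_chrom,
    }
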