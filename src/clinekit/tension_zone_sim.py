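"""Forward-time individual-based simulation of a moving tension zone.

A 1-D stepping-stone of D demes with N diploid individuals each, initialized
at secondary contact (left demes fixed for allele 0, right demes for allele
2 at every locus). Each generation runs migration (nearest-neighbour, rate
m, reflecting edges), viability selection, and within-deme random mating
with fitness-proportional parent sampling and free recombination among
unlinked loci (soft selection: deme sizes stay fixed at N).

Two selection pressures act:

* underdominance: fitness factor (1 - s) per ancestry-heterozygous locus
  among the selected loci — the classic tension-zone mechanism that holds
  the cline steep independent of the environment;
* a moving ecotone: factor (1 - s_env)^d where d is the fraction of a
  genome's selected allele copies mismatching the side of the environmental
  boundary b(t) = b(0) + r t the deme is on. The advancing boundary drags
  the zone at rate r demes/generation, emulating climate-driven movement.

The genome carries ``l_selected`` loci under both pressures plus
``l_neutral`` neutral markers; genome-wide ancestry (the hybrid index fed
to genomic-cline fitting) is the allele fraction over all loci, so selected
loci can show steeper-than-background clines while at s = 0 every locus
tracks the genome average (v ~ 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genomic_clines import fit_genomic_clines


@dataclass
class SimConfig:
    n_demes: int = 24
    n_per_deme: int = 120
    l_selected: int = 8
    l_neutral: int = 24
    s: float = 0.1  # selection against ancestry heterozygotes, per locus
    s_env: float = 0.05  # ecotonal selection against mismatched allele copies
    m: float = 0.25  # nearest-neighbour migration rate
    r: float = 0.0  # boundary movement, demes per generation
    generations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_demes < 10:
            raise ValueError("need at least 10 demes")
        if not (0 <= self.m <= 0.5):
            raise ValueError("migration rate must be in [0, 0.5]")
        for name in ("s", "s_env", "r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_loci(self) -> int:
        return self.l_selected + self.l_neutral


@dataclass
class SimState:
    generation: int
    genotypes: np.ndarray  # (D, N, L) alt-allele counts in {0,1,2}
    boundary0: float

    def boundary(self, cfg: SimConfig) -> float:
        return self.boundary0 + cfg.r * self.generation


def init_zone(cfg: SimConfig) -> SimState:
    """Secondary-contact start: a step function at the midpoint."""
    d, n, l = cfg.n_demes, cfg.n_per_deme, cfg.n_loci
    g = np.zeros((d, n, l), dtype=np.int8)
    g[d // 2 :] = 2
    return SimState(generation=0, genotypes=g, boundary0=d / 2.0)


def _fitness(g: np.ndarray, deme_pos: float, boundary: float, cfg: SimConfig):
    """Viability of each individual in one deme's (n, L) genotype block."""
    sel = g[:, : cfg.l_selected]
    het = (sel == 1).sum(axis=1)
    w = (1.0 - cfg.s) ** het
    if cfg.s_env > 0:
        copies = 2.0 * cfg.l_selected
        if deme_pos < boundary:  # left of the ecotone favours allele 0
            mismatch = sel.sum(axis=1) / copies
        else:
            mismatch = (2 * cfg.l_selected - sel.sum(axis=1)) / copies
        w = w * (1.0 - cfg.s_env) ** mismatch
    return w


def step(state: SimState, cfg: SimConfig, rng: np.random.Generator) -> SimState:
    """One generation: migration, viability selection, reproduction."""
    d, n, l = cfg.n_demes, cfg.n_per_deme, cfg.n_loci
    g = state.genotypes

    # migration: each adult moves to an adjacent deme w.p. m (direction
    # uniform; a move off the edge reflects back to the origin deme)
    flat = g.reshape(d * n, l)
    home = np.repeat(np.arange(d), n)
    move = rng.random(d * n) < cfg.m
    direction = np.where(rng.random(d * n) < 0.5, -1, 1)
    dest = home + np.where(move, direction, 0)
    dest = np.clip(dest, 0, d - 1)  # a reflected move off the edge stays home

    boundary = state.boundary(cfg)
    new_g = np.empty_like(g)
    for deme in range(d):
        pool = flat[dest == deme]
        if len(pool) == 0:
            # vanishingly rare for m <= 0.5; repopulate from nearest neighbour
            side = 1 if deme == 0 else -1
            pool = flat[dest == deme + side]
        w = _fitness(pool, deme + 0.5, boundary, cfg)
        total = w.sum()
        probs = w / total if total > 0 else np.full(len(pool), 1.0 / len(pool))
        mothers = rng.choice(len(pool), size=n, p=probs)
        fathers = rng.choice(len(pool), size=n, p=probs)
        # free recombination: each parent transmits one allele per locus
        gm_ = pool[mothers]
        gf = pool[fathers]
        new_g[deme] = (
            rng.binomial(1, gm_ / 2.0) + rng.binomial(1, gf / 2.0)
        ).astype(np.int8)
    return SimState(state.generation + 1, new_g, state.boundary0)


def run(cfg: SimConfig, record_every: int | None = None):
    """Simulate ``cfg.generations`` generations from secondary contact.

    Returns (final state, snapshots) where snapshots maps generation ->
    state (empty unless ``record_every`` is set). Fixed seed gives a
    bit-identical trajectory.
    """
    rng = np.random.default_rng(cfg.seed)
    state = init_zone(cfg)
    snapshots: dict[int, SimState] = {}
    for _ in range(cfg.generations):
        state = step(state, cfg, rng)
        if record_every and state.generation % record_every == 0:
            snapshots[state.generation] = SimState(
                state.generation, state.genotypes.copy(), state.boundary0
            )
    return state, snapshots


def deme_frequencies(state: SimState) -> np.ndarray:
    """(D, L) alt-allele frequencies per deme."""
    return state.genotypes.mean(axis=(1,)) / 2.0


def hybrid_indexes(state: SimState) -> np.ndarray:
    """(D, N) genome-wide ancestry: alt-allele fraction over all loci."""
    return state.genotypes.mean(axis=2) / 2.0


def sigmoid_width(state: SimState, loci=None) -> float:
    """Cline width of the deme-mean ancestry profile (least squares).

    Fits 1/(1+exp(-4(x-c)/w)) to the per-deme mean ancestry by
    Levenberg–Marquardt; x is the deme index + 0.5. ``loci`` restricts the
    profile to a locus subset (e.g. the selected loci, whose cline reaches
    the tension-zone equilibrium; neutral loci keep flattening forever). A
    quick deterministic width readout for simulation summaries (the full
    Bayesian machinery in the geographic-cline module is overkill inside
    experiment grids).
    """
    from scipy.optimize import curve_fit

    d = state.genotypes.shape[0]
    x = np.arange(d) + 0.5
    g = state.genotypes if loci is None else state.genotypes[:, :, loci]
    y = g.mean(axis=(1, 2)) / 2.0

    def f(x, c, w):
        return 1.0 / (1.0 + np.exp(-4.0 * (x - c) / np.maximum(w, 1e-6)))

    try:
        popt, _ = curve_fit(
            f, x, y, p0=[d / 2.0, d / 4.0], maxfev=5000,
            bounds=([0.0, 1e-3], [d, 10.0 * d]),
        )
    except RuntimeError:
        return float("nan")
    return float(popt[1])


def fit_cline_steepness(
    state: SimState,
    cfg: SimConfig,
    burn: int = 500,
    keep: int = 1500,
    seed: int = 0,
) -> np.ndarray:
    """Posterior-median genomic-cline steepness v of each selected locus.

    Hybrid indexes are the genome-wide allele fractions over all loci;
    clines are fitted for the selected loci only. The posterior median is
    used (not the mean): under weak data the lognormal-tailed posterior of
    v has mean ~ exp(prior_sd^2/2) even when nothing departs from the
    genome-wide average, while its median stays at 1.
    """
    h = hybrid_indexes(state).reshape(-1)
    g = state.genotypes.reshape(-1, cfg.n_loci)
    y = g[:, : cfg.l_selected].T.astype(float)  # (L_sel, n_ind)
    m = np.full_like(y, 2.0)
    fits = fit_genomic_clines(y, m, h, burn=burn, keep=keep, seed=seed)
    return np.array([float(np.median(f.v_draws)) for f in fits])


def run_experiment_grid(
    s_values,
    r_values,
    replicates: int = 2,
    cfg: SimConfig | None = None,
    mcmc_burn: int = 500,
    mcmc_keep: int = 1500,
) -> pd.DataFrame:
    """Mean genomic-cline steepness and geographic width per (s, r) cell.

    For each cell the zone is simulated ``replicates`` times with distinct
    seeds; v-bar averages the posterior-mean steepness over selected loci
    and replicates; width is the sigmoid width of the deme-mean ancestry
    profile (deme units).
    """
    base = cfg or SimConfig()
    rows = []
    for si, s in enumerate(s_values):
        for ri, r in enumerate(r_values):
            vbars = []
            widths = []
            for rep in range(replicates):
                seed = base.seed + 1000 * si + 100 * ri + rep
                c = replace(base, s=float(s), r=float(r), seed=seed)
                state, _ = run(c)
                v = fit_cline_steepness(
                    state, c, burn=mcmc_burn, keep=mcmc_keep, seed=seed
                )
                vbars.append(float(np.mean(v)))
                widths.append(sigmoid_width(state))
            rows.append(
                {
                    "s": float(s),
                    "r": float(r),
                    "v_bar": float(np.mean(vbars)),
                    "width": float(np.nanmean(widths)),
                    "replicates": replicates,
                }
            )
    return pd.DataFrame(rows)
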