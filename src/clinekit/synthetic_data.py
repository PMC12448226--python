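"""Synthetic hybrid-zone datasets with the structure the analyses assume.

Emulates two parental reference panels fixed for alternative alleles at
species-diagnostic SNPs, admixed individuals spanning F1/F2/backcross
classes, a sigmoid genome-wide ancestry cline along a one-dimensional
transect, a three-clade mtDNA haplotype system, and an optional Z-linked
recombination-suppressed inversion block segregating as three multilocus
haplotype states. Everything is driven by one RNG seed; a fixed seed fixes
every emitted file byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import MISSING, GenotypeMatrix, write_sample_table, write_vcf

MT_CHROM = "chrM"

#: mtDNA clade labels: parental-0 species, and western/eastern clades of the
#: parental-1 species (three PCA clusters)
DEFAULT_MT_CLADES = ("P0", "P1_west", "P1_east")


@dataclass
class ChromSpec:
    name: str
    length_bp: int
    is_z: bool = False


@dataclass
class InversionSpec:
    chrom: str
    start_bp: int
    end_bp: int
    #: frequency of the inverted (P1-type) arrangement among transect samples;
    #: None couples it to each sample's ancestry q
    freq: float | None = None
    #: per-locus genotype flip noise inside the block
    noise: float = 0.01


@dataclass
class SyntheticConfig:
    """Study-condition knobs for the generator.

    Defaults mirror the sampling design the analyses expect: modest parental
    reference panels, a transect of ~130 birds, diagnostic loci spaced 10 kb
    apart so the 1-per-10 kb thinning keeps them all, and a sigmoid ancestry
    cline along the transect.
    """

    n_parental_each: int = 15
    n_transect: int = 130
    l_diag: int = 500
    l_background: int = 300
    chroms: list[ChromSpec] = field(
        default_factory=lambda: [
            ChromSpec("chr1", 8_000_000),
            ChromSpec("chr2", 5_000_000),
            ChromSpec("Z_1", 6_000_000, is_z=True),
        ]
    )
    transect_length_km: float = 100.0
    cline_center_km: float = 50.0
    cline_width_km: float = 20.0
    #: concentration of the Beta noise of per-sample ancestry around the cline
    q_concentration: float = 30.0
    balding_nichols_F: float = 0.02
    inversion: InversionSpec | None = None
    mt_clades: tuple[str, str, str] = DEFAULT_MT_CLADES
    mt_n_variants: int = 24
    #: which P1 mtDNA clade the transect carries
    transect_mt_clade: str = "P1_west"
    female_fraction: float = 0.5
    diag_spacing_bp: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (
            ("n_parental_each", self.n_parental_each),
            ("n_transect", self.n_transect),
            ("l_diag", self.l_diag),
            ("l_background", self.l_background),
        ):
            if v <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.inversion is not None:
            chrom = {c.name: c for c in self.chroms}.get(self.inversion.chrom)
            if chrom is None or not (
                1 <= self.inversion.start_bp < self.inversion.end_bp <= chrom.length_bp
            ):
                raise ValueError("inversion region must lie inside its chromosome")


def _place_loci(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Locus table: diagnostic loci on a fixed grid, background loci random."""
    lengths = np.array([c.length_bp for c in cfg.chroms], dtype=float)
    n_diag = np.floor(cfg.l_diag * lengths / lengths.sum()).astype(int)
    n_diag[0] += cfg.l_diag - n_diag.sum()
    n_bg = np.floor(cfg.l_background * lengths / lengths.sum()).astype(int)
    n_bg[0] += cfg.l_background - n_bg.sum()

    rows = []
    for chrom, nd, nb in zip(cfg.chroms, n_diag, n_bg):
        capacity = chrom.length_bp // cfg.diag_spacing_bp
        if nd > capacity:
            raise ValueError(f"{chrom.name}: too many diagnostic loci for spacing")
        diag_pos = cfg.diag_spacing_bp * np.arange(1, nd + 1)
        taken = set(diag_pos.tolist())
        bg_pos = []
        while len(bg_pos) < nb:
            p = int(rng.integers(1, chrom.length_bp + 1))
            if p not in taken:
                taken.add(p)
                bg_pos.append(p)
        for p in diag_pos:
            rows.append((chrom.name, int(p), True, chrom.is_z))
        for p in bg_pos:
            rows.append((chrom.name, int(p), False, chrom.is_z))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "is_diag", "is_z"])
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=len(df))
    alt = (ref + rng.integers(1, 4, size=len(df))) % 4
    df["ref"] = bases[ref]
    df["alt"] = bases[alt]
    return df


def _mt_loci(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    pos = np.sort(rng.choice(np.arange(100, 16_000), cfg.mt_n_variants, replace=False))
    bases = np.array(list("ACGT"))
    ref = rng.integers(0, 4, size=len(pos))
    alt = (ref + rng.integers(1, 4, size=len(pos))) % 4
    return pd.DataFrame(
        {"chrom": MT_CHROM, "pos": pos, "ref": bases[ref], "alt": bases[alt]}
    )


def mt_clade_patterns(cfg: SyntheticConfig) -> dict[str, np.ndarray]:
    """Alt-allele pattern of each mtDNA clade over the mt variant grid.

    P0 carries the reference at every site; both P1 clades share a
    species-diagnostic block and each has a clade-private block, giving
    three separable clusters.
    """
    m = cfg.mt_n_variants
    third = m // 3
    p0 = np.zeros(m, dtype=np.int16)
    shared = np.zeros(m, dtype=np.int16)
    shared[:third] = 1
    west = shared.copy()
    west[third : 2 * third] = 1
    east = shared.copy()
    east[2 * third :] = 1
    c0, c1, c2 = cfg.mt_clades
    return {c0: p0, c1: west, c2: east}


def _sex_ploidy(
    loci: pd.DataFrame, sexes: np.ndarray
) -> np.ndarray:
    """Per sample x locus ploidy: Z loci are haploid in females."""
    is_z = loci["is_z"].to_numpy() if "is_z" in loci else np.zeros(len(loci), bool)
    ploidy = np.full((len(sexes), len(loci)), 2, dtype=np.int8)
    ploidy[np.ix_(sexes == "F", is_z)] = 1
    return ploidy


def _draw_sexes(n: int, cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    return np.where(rng.random(n) < cfg.female_fraction, "F", "M")


def make_parental_panels(
    cfg: SyntheticConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Two allopatric reference panels plus the locus blueprint.

    Diagnostic loci are fixed for the ref allele (count 0) in panel A (P0)
    and for the alt allele in panel B (P1); background allele frequencies
    follow a Balding–Nichols model around a shared ancestral frequency with
    differentiation ``cfg.balding_nichols_F``.

    Returns (genotypes, sample table, locus blueprint). The blueprint (with
    is_diag/is_z flags and per-panel background frequencies) is reused by
    :func:`make_transect` so panels and transect share one locus set.
    """
    rng = np.random.default_rng(cfg.seed)
    loci = _place_loci(cfg, rng)
    mt = _mt_loci(cfg, rng)

    p_anc = rng.uniform(0.1, 0.9, size=len(loci))
    F = cfg.balding_nichols_F
    if F > 0:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        pA = rng.beta(a, b)
        pB = rng.beta(a, b)
    else:
        pA = p_anc.copy()
        pB = p_anc.copy()
    loci = loci.assign(pA=pA, pB=pB)

    n_each = cfg.n_parental_each
    sexes = _draw_sexes(2 * n_each, cfg, rng)
    ploidy = _sex_ploidy(loci, sexes)
    counts = np.empty((2 * n_each, len(loci)), dtype=np.int16)
    is_diag = loci["is_diag"].to_numpy()
    for i in range(2 * n_each):
        in_b = i >= n_each
        pf = loci["pB"].to_numpy() if in_b else loci["pA"].to_numpy()
        counts[i] = rng.binomial(ploidy[i], pf)
        counts[i, is_diag] = ploidy[i, is_diag] if in_b else 0

    patterns = mt_clade_patterns(cfg)
    c0, c1, c2 = cfg.mt_clades
    mt_counts = np.empty((2 * n_each, len(mt)), dtype=np.int16)
    for i in range(2 * n_each):
        if i < n_each:
            clade = c0
        else:
            clade = c1 if (i - n_each) % 2 == 0 else c2
        mt_counts[i] = patterns[clade]

    samples = [f"A{i:03d}" for i in range(n_each)] + [
        f"B{i:03d}" for i in range(n_each)
    ]
    mitotypes = [c0] * n_each + [
        c1 if i % 2 == 0 else c2 for i in range(n_each)
    ]
    table = pd.DataFrame(
        {
            "sample_id": samples,
            "population_label": ["allopatric-P0"] * n_each + ["allopatric-P1"] * n_each,
            "latitude": np.nan,
            "longitude": np.nan,
            "sex": sexes,
            "mitotype": mitotypes,
        }
    )

    full_loci = pd.concat(
        [loci[["chrom", "pos", "ref", "alt"]], mt[["chrom", "pos", "ref", "alt"]]],
        ignore_index=True,
    )
    full_counts = np.concatenate([counts, mt_counts], axis=1)
    full_ploidy = np.concatenate(
        [ploidy, np.ones_like(mt_counts, dtype=np.int8)], axis=1
    )
    gm = GenotypeMatrix(samples, full_loci, full_counts, full_ploidy)
    return gm, table, loci


HYBRID_CLASSES = ("P0", "P1", "F1", "F2", "BC1_P0", "BC1_P1", "late_backcross")


def make_hybrid_class(
    hybrid_class: str,
    n_loci: int,
    rng: np.random.Generator,
    g: int | None = None,
) -> np.ndarray:
    """Diagnostic-locus alt (P1) allele counts for one diploid individual.

    F1 is heterozygous everywhere; F2 segregates 1:2:1; first-generation
    backcrosses draw {0,1} or {1,2} with probability 1/2; a late backcross of
    generation *g* toward P0 carries each P1 allele copy with probability
    2^-g.
    """
    if hybrid_class == "P0":
        return np.zeros(n_loci, dtype=np.int16)
    if hybrid_class == "P1":
        return np.full(n_loci, 2, dtype=np.int16)
    if hybrid_class == "F1":
        return np.ones(n_loci, dtype=np.int16)
    if hybrid_class == "F2":
        return rng.binomial(2, 0.5, size=n_loci).astype(np.int16)
    if hybrid_class == "BC1_P0":
        return rng.binomial(1, 0.5, size=n_loci).astype(np.int16)
    if hybrid_class == "BC1_P1":
        return (1 + rng.binomial(1, 0.5, size=n_loci)).astype(np.int16)
    if hybrid_class == "late_backcross":
        if g is None or g < 1:
            raise ValueError("late_backcross requires generation g >= 1")
        # one chromosome set is pure P0; the other carries P1 alleles w.p. 2^-(g-1)
        # so each of the two copies is P1-derived with overall probability 2^-g
        p = 2.0 ** (-(g - 1))
        return rng.binomial(1, p, size=n_loci).astype(np.int16)
    raise ValueError(f"unknown hybrid class {hybrid_class!r}")


def sigmoid_cline(x, center: float, width: float) -> np.ndarray:
    """Expected P1 ancestry at transect position x (km)."""
    arg = np.clip(-4.0 * (np.asarray(x, float) - center) / width, -700, 700)
    return 1.0 / (1.0 + np.exp(arg))


#: transect line anchor (latitude, longitude) and eastward bearing
TRANSECT_ORIGIN = (40.0, -95.0)


def transect_latlon(x_km) -> tuple[np.ndarray, np.ndarray]:
    """Place transect distances on a west-to-east line on the globe."""
    lat0, lon0 = TRANSECT_ORIGIN
    x = np.asarray(x_km, dtype=float)
    lat = np.full_like(x, lat0)
    lon = lon0 + x / (111.32 * math.cos(math.radians(lat0)))
    return lat, lon


def make_transect(
    cfg: SyntheticConfig,
    loci_blueprint: pd.DataFrame | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Admixed transect samples along a sigmoid genome-wide ancestry cline.

    Each sample sits at a position x on [0, transect length]; its ancestry q
    is Beta-distributed around the sigmoid 1/(1+exp(-4(x-c)/w)); every
    diagnostic allele copy is P1-derived independently with probability q;
    the mtDNA clade is the transect's P1 clade with probability q, else P0.
    If an inversion block is configured, diagnostic genotypes inside it are
    overridden by one of the three non-recombined haplotype-pair states
    (AA/AB/BB), drawn consistently per sample.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    if loci_blueprint is None:
        blue_rng = np.random.default_rng(cfg.seed)
        loci_blueprint = _place_loci(cfg, blue_rng)
        mt = _mt_loci(cfg, blue_rng)
        p_anc = blue_rng.uniform(0.1, 0.9, size=len(loci_blueprint))
        F = cfg.balding_nichols_F
        if F > 0:
            a = p_anc * (1 - F) / F
            b = (1 - p_anc) * (1 - F) / F
            loci_blueprint = loci_blueprint.assign(
                pA=blue_rng.beta(a, b), pB=blue_rng.beta(a, b)
            )
        else:
            loci_blueprint = loci_blueprint.assign(pA=p_anc, pB=p_anc)
    else:
        blue_rng = np.random.default_rng(cfg.seed)
        _ = _place_loci(cfg, blue_rng)  # advance to the mt grid
        mt = _mt_loci(cfg, blue_rng)

    n = cfg.n_transect
    x = np.sort(rng.uniform(0.0, cfg.transect_length_km, size=n))
    mean_q = sigmoid_cline(x, cfg.cline_center_km, cfg.cline_width_km)
    kappa = cfg.q_concentration
    eps = 1e-4
    mq = np.clip(mean_q, eps, 1 - eps)
    q = rng.beta(mq * kappa, (1 - mq) * kappa)

    sexes = _draw_sexes(n, cfg, rng)
    ploidy = _sex_ploidy(loci_blueprint, sexes)
    is_diag = loci_blueprint["is_diag"].to_numpy()
    counts = np.empty((n, len(loci_blueprint)), dtype=np.int16)
    pA = loci_blueprint["pA"].to_numpy()
    pB = loci_blueprint["pB"].to_numpy()
    for i in range(n):
        p_eff = q[i] * 1.0 + (1 - q[i]) * 0.0
        counts[i, is_diag] = rng.binomial(ploidy[i, is_diag], p_eff)
        # background: each copy from a P1 parent w.p. q, then its panel freq
        bg = ~is_diag
        p_mix = q[i] * pB[bg] + (1 - q[i]) * pA[bg]
        counts[i, bg] = rng.binomial(ploidy[i, bg], p_mix)

    inv_state = np.full(n, "", dtype=object)
    if cfg.inversion is not None:
        inv = cfg.inversion
        chrom = loci_blueprint["chrom"].to_numpy()
        pos = loci_blueprint["pos"].to_numpy()
        in_block = (
            (chrom == inv.chrom) & (pos >= inv.start_bp) & (pos <= inv.end_bp)
        )
        nb = int(in_block.sum())
        # recombination suppression freezes one haplotype per arrangement:
        # opposite alleles at diagnostic loci, panel-frequency draws at
        # background loci (which may be uninformative, as in real blocks)
        hap_a = np.where(is_diag[in_block], 0, rng.binomial(1, pA[in_block]))
        hap_b = np.where(is_diag[in_block], 1, rng.binomial(1, pB[in_block]))
        for i in range(n):
            f = q[i] if inv.freq is None else inv.freq
            pl = ploidy[i, in_block]
            hemizygous = pl.size and pl.min() == 1
            if hemizygous:
                dose = int(rng.random() < f)
                inv_state[i] = "B" if dose else "A"
                base = (hap_b if dose else hap_a).astype(np.int16)
            else:
                dose = int(rng.binomial(2, f))
                inv_state[i] = ("AA", "AB", "BB")[dose]
                n_b = dose
                base = (
                    hap_a * (2 - n_b) + hap_b * n_b
                    if n_b in (0, 2)
                    else hap_a + hap_b
                ).astype(np.int16)
            flip = rng.random(nb) < inv.noise
            noisy = base.copy()
            noisy[flip] = rng.integers(0, pl[flip] + 1)
            counts[i, in_block] = np.minimum(noisy, pl)

    patterns = mt_clade_patterns(cfg)
    p0_clade = cfg.mt_clades[0]
    mito = np.where(rng.random(n) < q, cfg.transect_mt_clade, p0_clade)
    mt_counts = np.stack([patterns[c] for c in mito])

    lat, lon = transect_latlon(x)
    samples = [f"T{i:03d}" for i in range(n)]
    table = pd.DataFrame(
        {
            "sample_id": samples,
            "population_label": "transect",
            "latitude": lat,
            "longitude": lon,
            "sex": sexes,
            "mitotype": mito,
            "distance_km": x,
            "true_q": q,
            "inversion_state": inv_state,
        }
    )

    full_loci = pd.concat(
        [
            loci_blueprint[["chrom", "pos", "ref", "alt"]],
            mt[["chrom", "pos", "ref", "alt"]],
        ],
        ignore_index=True,
    )
    full_counts = np.concatenate([counts, mt_counts], axis=1)
    full_ploidy = np.concatenate(
        [ploidy, np.ones_like(mt_counts, dtype=np.int8)], axis=1
    )
    gm = GenotypeMatrix(samples, full_loci, full_counts, full_ploidy)
    return gm, table


def concat_matrices(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Stack two matrices over the same locus set (samples appended)."""
    if not a.loci[["chrom", "pos"]].equals(b.loci[["chrom", "pos"]]):
        raise ValueError("matrices have different locus sets")
    return GenotypeMatrix(
        samples=list(a.samples) + list(b.samples),
        loci=a.loci.copy(),
        counts=np.concatenate([a.counts, b.counts], axis=0),
        ploidy=np.concatenate([a.ploidy, b.ploidy], axis=0),
    )


def make_dataset(cfg: SyntheticConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Parental panels plus transect in one matrix / sample table."""
    gm_par, tab_par, blueprint = make_parental_panels(cfg)
    gm_tr, tab_tr = make_transect(cfg, loci_blueprint=blueprint)
    gm = concat_matrices(gm_par, gm_tr)
    table = pd.concat([tab_par, tab_tr], ignore_index=True)
    return gm, table


def toy_gene_models(cfg: SyntheticConfig, rng: np.random.Generator, n_per_chrom=4):
    """Small GFF3-ready gene set for annotation tests."""
    rows = []
    k = 0
    for chrom in cfg.chroms:
        for _ in range(n_per_chrom):
            start = int(rng.integers(1, max(2, chrom.length_bp - 20_000)))
            end = start + int(rng.integers(500, 15_000))
            rows.append((chrom.name, start, end, "+" if k % 2 == 0 else "-", f"gene{k:03d}"))
            k += 1
    return rows


def write_gff(rows, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, start, end, strand, gid in rows:
            fh.write(
                f"{chrom}\tclinekit\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}\n"
            )


def write_dataset(cfg: SyntheticConfig, out_dir) -> dict[str, str]:
    """Emit genotypes.vcf + samples.tsv + genes.gff3 under ``out_dir``."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    gm, table = make_dataset(cfg)
    paths = {
        "vcf": os.path.join(out_dir, "genotypes.vcf"),
        "samples": os.path.join(out_dir, "samples.tsv"),
        "gff": os.path.join(out_dir, "genes.gff3"),
    }
    write_vcf(gm, paths["vcf"])
    write_sample_table(table, paths["samples"])
    write_gff(toy_gene_models(cfg, np.random.default_rng(cfg.seed + 2)), paths["gff"])
    return paths
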