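"""Domain containers and file I/O shared by every analysis stage.

Genotypes are held as an alt-allele count matrix (samples x loci) with an
explicit per-entry ploidy, so hemizygous Z loci in female birds (ZW system:
one Z copy) and haploid mtDNA carry one allele copy instead of two.
Coordinates are 1-based inclusive throughout (VCF/GFF convention).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: chromosome names treated as the avian Z (hemizygous in females)
DEFAULT_Z_CHROMS = frozenset({"Z", "chrZ", "Z_1"})
#: chromosome names treated as haploid in everyone (mtDNA pseudo-chromosome)
DEFAULT_HAPLOID_CHROMS = frozenset({"chrM", "MT", "mtDNA"})

LOCI_COLUMNS = ["chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """samples x biallelic loci alt-allele counts with per-entry ploidy.

    ``counts[i, j]`` is the number of alt alleles carried by sample *i* at
    locus *j*, in ``{0..ploidy[i, j]}``, or :data:`MISSING`. ``ploidy`` is 2
    on autosomes, 1 on the Z for females and on haploid chromosomes, and 0
    where the copy number is unknown (unknown sex on Z).
    """

    samples: list[str]
    loci: pd.DataFrame  # columns chrom, pos, ref, alt
    counts: np.ndarray  # int16 (n_samples, n_loci)
    ploidy: np.ndarray  # int8  (n_samples, n_loci)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int16)
        self.ploidy = np.asarray(self.ploidy, dtype=np.int8)
        n, m = self.counts.shape
        if len(self.samples) != n or len(self.loci) != m:
            raise ValueError("inconsistent GenotypeMatrix dimensions")
        if self.ploidy.shape != (n, m):
            raise ValueError("ploidy shape must match counts")
        obs = self.counts >= 0
        if np.any(self.counts[obs] > self.ploidy[obs]):
            raise ValueError("allele count exceeds ploidy")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from exc

    def subset_loci(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=self.loci.iloc[idx].reset_index(drop=True),
            counts=self.counts[:, idx],
            ploidy=self.ploidy[:, idx],
        )

    def subset_samples(self, ids) -> "GenotypeMatrix":
        idx = self.sample_index(ids)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            loci=self.loci.copy(),
            counts=self.counts[idx],
            ploidy=self.ploidy[idx],
        )

    def restrict_chrom(self, chrom: str) -> "GenotypeMatrix":
        return self.subset_loci((self.loci["chrom"] == chrom).to_numpy())


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


def _gt_to_count(gt: tuple) -> tuple[int, int]:
    """Return (alt count, called copies) from a cyvcf2 genotype tuple."""
    alleles = [a for a in gt[:-1] if a is not None and a >= 0]
    return sum(1 for a in alleles if a > 0), len(alleles)


def read_vcf_biallelic(
    path,
    sex_map: dict[str, str] | None = None,
    z_chroms=DEFAULT_Z_CHROMS,
    haploid_chroms=DEFAULT_HAPLOID_CHROMS,
) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are dropped. On Z chromosomes, female
    samples (``sex_map[id] == "F"``) are coerced to ploidy 1: a diploid-coded
    homozygote becomes one allele copy and a diploid-coded heterozygote
    becomes missing (treated as a genotyping artifact and counted in a log
    message). Samples of unknown sex get ploidy 0 / missing on Z, with a
    warning. The file must be coordinate-sorted within each chromosome and
    chromosome blocks must be contiguous.
    """
    from cyvcf2 import VCF

    sex_map = sex_map or {}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sex = np.array([sex_map.get(s, "unknown") for s in samples])

    chroms: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    count_cols: list[np.ndarray] = []
    ploidy_cols: list[np.ndarray] = []

    seen_chroms: set[str] = set()
    last_chrom = None
    last_pos = -1
    n_female_z_het = 0
    warned_unknown_sex = False

    for rec in vcf:
        if rec.CHROM != last_chrom:
            if rec.CHROM in seen_chroms:
                raise ValueError(
                    f"VCF not sorted: chromosome {rec.CHROM} reappears at "
                    f"{rec.CHROM}:{rec.POS}"
                )
            seen_chroms.add(rec.CHROM)
            last_chrom = rec.CHROM
            last_pos = -1
        if rec.POS < last_pos:
            raise ValueError(
                f"VCF not sorted: record {rec.CHROM}:{rec.POS} after "
                f"position {last_pos}"
            )
        last_pos = rec.POS
        if len(rec.ALT) != 1 or not rec.is_snp:
            continue

        c = np.empty(len(samples), dtype=np.int16)
        p = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            alt_n, copies = _gt_to_count(tuple(gt))
            if copies == 0:
                c[i], p[i] = MISSING, 2
            else:
                c[i], p[i] = alt_n, copies

        is_z = rec.CHROM in z_chroms
        if rec.CHROM in haploid_chroms:
            # haploid chromosome: collapse diploid-coded calls to one copy
            het = (c == 1) & (p == 2)
            c[het] = MISSING
            c[(c == 2) & (p == 2)] = 1
            p[:] = 1
        elif is_z:
            fem = sex == "F"
            het = fem & (c == 1) & (p == 2)
            n_female_z_het += int(het.sum())
            c[het] = MISSING
            hom_alt = fem & (c == 2)
            c[hom_alt] = 1
            p[fem] = 1
            unk = sex == "unknown"
            if unk.any():
                if not warned_unknown_sex:
                    logger.warning(
                        "Z-chromosome loci present but %d sample(s) have "
                        "unknown sex; their Z genotypes are set to missing",
                        int(unk.sum()),
                    )
                    warned_unknown_sex = True
                c[unk] = MISSING
                p[unk] = 0

        chroms.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        count_cols.append(c)
        ploidy_cols.append(p)

    if n_female_z_het:
        logger.warning(
            "set %d female heterozygous Z genotype(s) to missing", n_female_z_het
        )

    loci = pd.DataFrame({"chrom": chroms, "pos": pos, "ref": ref, "alt": alt})
    n = len(samples)
    counts = (
        np.stack(count_cols, axis=1) if count_cols else np.empty((n, 0), np.int16)
    )
    ploidy = (
        np.stack(ploidy_cols, axis=1) if ploidy_cols else np.empty((n, 0), np.int8)
    )
    return GenotypeMatrix(samples, loci, counts, ploidy)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as a minimal VCF v4.2 text file.

    Haploid entries are written as single-allele GT fields, missing as
    ``./.`` (diploid) or ``.`` (haploid), so a round trip through
    :func:`read_vcf_biallelic` reproduces the counts exactly.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=clinekit\n")
        for chrom in pd.unique(gm.loci["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        chrom_arr = gm.loci["chrom"].to_numpy()
        pos_arr = gm.loci["pos"].to_numpy()
        ref_arr = gm.loci["ref"].to_numpy()
        alt_arr = gm.loci["alt"].to_numpy()
        for j in range(gm.n_loci):
            gts = []
            for i in range(gm.n_samples):
                c, p = gm.counts[i, j], gm.ploidy[i, j]
                if p == 1:
                    gts.append("." if c < 0 else str(min(int(c), 1)))
                else:
                    if c < 0:
                        gts.append("./.")
                    elif c == 0:
                        gts.append("0/0")
                    elif c == 1:
                        gts.append("0/1")
                    else:
                        gts.append("1/1")
            fh.write(
                f"{chrom_arr[j]}\t{pos_arr[j]}\t.\t{ref_arr[j]}\t{alt_arr[j]}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def thin_loci_by_window(loci: pd.DataFrame, window_bp: int) -> np.ndarray:
    """Indices of the lowest-position locus in each nonempty fixed window.

    Windows are fixed-origin: ``[k*window_bp + 1, (k+1)*window_bp]`` per
    chromosome. Chromosome order is preserved.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    keep: list[int] = []
    pos = loci["pos"].to_numpy()
    for chrom in pd.unique(loci["chrom"]):
        idx = np.flatnonzero((loci["chrom"] == chrom).to_numpy())
        order = idx[np.argsort(pos[idx], kind="stable")]
        win = (pos[order] - 1) // window_bp
        first = np.ones(len(order), dtype=bool)
        first[1:] = win[1:] != win[:-1]
        keep.extend(order[first])
    return np.array(sorted(keep), dtype=int)


def thin_by_window(gm: GenotypeMatrix, window_bp: int) -> GenotypeMatrix:
    """Retain one locus (the lowest position) per fixed window per chromosome."""
    if gm.n_loci == 0:
        return gm
    return gm.subset_loci(thin_loci_by_window(gm.loci, window_bp))


def read_gff_genes(path, flank_bp: int = 5000) -> pd.DataFrame:
    """Gene search intervals from a GFF3: reading frames extended by a flank.

    Returns a DataFrame with columns gene_id, chrom, start, end, strand,
    search_start, search_end where ``search_start = max(1, start - flank)``
    and ``search_end = end + flank`` (1-based inclusive).
    """
    import gffutils

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ValueError(f"malformed GFF3 line {lineno}: {line[:80]!r}")

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append(
            {
                "gene_id": gene_id,
                "chrom": feat.seqid,
                "start": feat.start,
                "end": feat.end,
                "strand": feat.strand or "+",
                "search_start": max(1, feat.start - flank_bp),
                "search_end": feat.end + flank_bp,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "chrom", "start", "end", "strand",
            "search_start", "search_end",
        ],
    )


SAMPLE_COLUMNS = ["sample_id", "population_label", "latitude", "longitude", "sex"]


def read_sample_table(path) -> pd.DataFrame:
    """Tab-separated sample metadata with a header line.

    Required columns: sample_id, population_label. Optional: latitude,
    longitude, sex, mitotype, distance_km. Sample ids must be unique.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "population_label"):
        if col not in df.columns:
            raise ValueError(f"sample table missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r}")
    if "sex" not in df.columns:
        df["sex"] = "unknown"
    return df


def write_sample_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def sex_map_from_table(df: pd.DataFrame) -> dict[str, str]:
    return dict(zip(df["sample_id"], df.get("sex", "unknown")))
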