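import numpy as np
import pandas as pd
import pytest

from clinekit import inversion_scan as inv
from clinekit import synthetic_data as sd


def inversion_fixture(seed=7, freq=0.5, start=400_000, end=1_400_000,
                      n=90, l_diag=200, chrom_len=2_200_000):
    """Ancestry-homogeneous transect with a segregating planted block."""
    cfg = sd.SyntheticConfig(
        seed=seed, n_transect=n, l_diag=l_diag, l_background=40,
        chroms=[sd.ChromSpec("Z_1", chrom_len, is_z=True)],
        cline_center_km=-200.0,
        inversion=sd.InversionSpec("Z_1", start, end, freq=freq),
        female_fraction=0.0,
    )
    return sd.make_transect(cfg)


class TestAssociationScore:
    def test_planted_block_scores_dwarf_outside(self):
        gm, _ = inversion_fixture()
        track = inv.snp_pc_association(gm.restrict_chrom("Z_1"))
        inside = track[track.pos.between(400_000, 1_400_000)]["score"]
        outside = track[~track.pos.between(400_000, 1_400_000)]["score"]
        assert inside.median() > 5 * max(outside.median(), 1e-6)

    def test_perfectly_partitioning_snp_tops_noise(self):
        gm, _ = inversion_fixture()
        track = inv.snp_pc_association(gm.restrict_chrom("Z_1"))
        inside_max = track[track.pos.between(400_000, 1_400_000)]["score"].max()
        outside_max = track[~track.pos.between(400_000, 1_400_000)]["score"].max()
        assert inside_max > outside_max

    def test_permuted_genotypes_follow_null(self):
        from scipy.stats import kstest

        # permutation oracle for the per-PC test: genotypes shuffled
        # against a fixed group membership give uniform LRT p-values
        rng = np.random.default_rng(0)
        y = (np.arange(120) < 60).astype(float)
        rng.shuffle(y)
        x = rng.binomial(2, 0.4, size=(120, 400)).astype(float)
        pvals = 10.0 ** (-inv._logistic_lrt(y, x))
        assert kstest(pvals, "uniform").statistic < 0.08

        # the public score is the max over 2 PCs, so on permuted data the
        # nominal 0.05 exceedance sits near 1 - 0.95^2, not far above it
        gm, _ = inversion_fixture()
        sub = gm.restrict_chrom("Z_1")
        counts = sub.counts.copy()
        for j in range(counts.shape[1]):
            rng.shuffle(counts[:, j])
        sub = sub.__class__(sub.samples, sub.loci, counts, sub.ploidy)
        track = inv.snp_pc_association(sub)
        frac = (10.0 ** (-track["score"].to_numpy()) < 0.05).mean()
        assert frac < 0.30
        # and the permuted track never supports an inversion call
        region, _ = inv.detect_boundaries(track)
        assert region is None

    def test_monomorphic_snp_scores_zero(self):
        gm, _ = inversion_fixture()
        sub = gm.restrict_chrom("Z_1")
        counts = sub.counts.copy()
        counts[:, 0] = 2
        sub = sub.__class__(sub.samples, sub.loci, counts, sub.ploidy)
        track = inv.snp_pc_association(sub)
        assert track["score"].iloc[0] == 0.0


class TestDetectBoundaries:
    def test_flat_track_yields_none(self):
        rng = np.random.default_rng(0)
        flat = pd.DataFrame({"pos": np.arange(1, 501) * 1000,
                             "score": rng.chisquare(1, 500) / 2})
        region, _ = inv.detect_boundaries(flat)
        assert region is None

    def test_planted_region_recovered_within_two_spacings(self):
        rng = np.random.default_rng(1)
        pos = np.arange(1, 501) * 1000
        score = rng.chisquare(1, 500) / 2
        score[150:350] += 15  # [30%, 70%] of the chromosome
        region, _ = inv.detect_boundaries(pd.DataFrame({"pos": pos, "score": score}))
        assert region is not None
        assert abs(region[0] - 151_000) <= 2_000
        assert abs(region[1] - 350_000) <= 2_000

    def test_two_regions_returns_higher_with_warning(self):
        rng = np.random.default_rng(2)
        pos = np.arange(1, 501) * 1000
        score = rng.chisquare(1, 500) / 2
        score[100:150] += 20
        score[300:380] += 40
        region, warnings = inv.detect_boundaries(pd.DataFrame({"pos": pos, "score": score}))
        assert 290_000 <= region[0] <= 305_000
        assert 375_000 <= region[1] <= 385_000
        assert any("secondary" in w or "qualifying regions" in w for w in warnings)

    def test_invariant_to_uniform_rescaling(self):
        rng = np.random.default_rng(3)
        pos = np.arange(1, 401) * 1000
        score = rng.chisquare(1, 400) / 2
        score[120:280] += 12
        track = pd.DataFrame({"pos": pos, "score": score})
        r1, _ = inv.detect_boundaries(track)
        r2, _ = inv.detect_boundaries(track.assign(score=track.score * 81.7))
        assert r1 == r2


class TestInversionLength:
    @pytest.mark.parametrize(
        "start,end,mb",
        [
            (4_019_600, 139_615_224, 135.6),
            (4_019_600, 137_849_599, 133.8),
            (70_257_022, 138_784_640, 68.5),
        ],
    )
    def test_span_rounds_to_one_decimal(self, start, end, mb):
        assert inv.inversion_length(start, end) == mb

    def test_exact_integer_arithmetic_round_trips(self):
        start, end = 1_230_000, 4_780_000
        call_mb = inv.inversion_length(start, end)
        assert call_mb == round((end - start) / 1e6, 1)


class TestHaplotypeGroups:
    def test_planted_groups_recovered_exactly(self):
        gm, table = inversion_fixture(seed=11, freq=0.5)
        in_block = gm.loci["pos"].between(400_000, 1_400_000).to_numpy()
        labels, group_f, ab_lowest, _ = inv.assign_haplotype_groups(
            gm.subset_loci(in_block), seed=0
        )
        truth = table.set_index("sample_id")["inversion_state"]
        assert (labels.sort_index() == truth.sort_index()).all()
        assert ab_lowest
        assert group_f["AB"] == min(group_f.values())

    def test_monomorphic_arrangement_gives_single_group(self):
        gm, _ = inversion_fixture(seed=12, freq=0.0)
        in_block = gm.loci["pos"].between(400_000, 1_400_000).to_numpy()
        labels, _, _, warnings = inv.assign_haplotype_groups(
            gm.subset_loci(in_block), seed=0
        )
        assert set(labels) == {"AA"}
        assert any("single haplotype group" in w for w in warnings)


class TestFullScan:
    def test_boundary_recovery_across_seeds(self):
        hits = 0
        for seed in range(20):
            cfg = sd.SyntheticConfig(
                seed=seed, n_transect=80, l_diag=300, l_background=60,
                chroms=[sd.ChromSpec("Z_1", 3_200_000, is_z=True)],
                cline_center_km=-200.0,
                inversion=sd.InversionSpec("Z_1", 900_000, 2_100_000, freq=0.5),
                female_fraction=0.0,
            )
            gm, _ = sd.make_transect(cfg)
            call = inv.scan_inversion(gm, "Z_1", seed=0)
            # tolerance: two inter-SNP spacings of the 10 kb diagnostic grid
            if (
                call is not None
                and abs(call.start_bp - 900_000) <= 20_000
                and abs(call.end_bp - 2_100_000) <= 20_000
            ):
                hits += 1
        assert hits >= 18

    def test_no_inversion_chromosome_returns_none(self):
        cfg = sd.SyntheticConfig(
            seed=5, n_transect=60, l_diag=150, l_background=150,
            chroms=[sd.ChromSpec("chr1", 1_600_000)],
            cline_center_km=-200.0,
        )
        gm, _ = sd.make_transect(cfg)
        assert inv.scan_inversion(gm, "chr1", seed=0) is None
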