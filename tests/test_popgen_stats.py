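import numpy as np
import pandas as pd
import pytest

from clinekit import popgen_stats as pg
from clinekit import synthetic_data as sd
from conftest import make_gm


def wc_theta_oracle(genotypes_a, genotypes_b):
    """Straight transliteration of the 1984 two-population variance
    components for one biallelic locus of diploid genotypes (alt counts)."""
    ga = np.asarray(genotypes_a, float)
    gb = np.asarray(genotypes_b, float)
    n1, n2 = len(ga), len(gb)
    p1, p2 = ga.sum() / (2 * n1), gb.sum() / (2 * n2)
    h1, h2 = (ga == 1).mean(), (gb == 1).mean()
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = (
        nbar
        / (nbar - 1)
        * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    )
    c = hbar / 2
    denom = a + b + c
    return (a, denom, a / denom if denom != 0 else np.nan)


class TestPerSnpFst:
    def test_fixed_difference_is_one(self):
        gm = make_gm([[0], [0], [0], [2], [2], [2]])
        out = pg.wc_fst_snp(gm, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert out["fst"].iloc[0] == pytest.approx(1.0)

    def test_monomorphic_is_undefined_not_zero(self):
        gm = make_gm([[0], [0], [0], [0], [0], [0]])
        out = pg.wc_fst_snp(gm, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert np.isnan(out["fst"].iloc[0])

    def test_identical_polymorphic_counts_nonpositive(self):
        gm = make_gm([[0], [1], [2], [0], [1], [2]])
        out = pg.wc_fst_snp(gm, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert out["fst"].iloc[0] <= 0

    def test_matches_direct_1984_oracle(self):
        # 10 + 10 diploids at alt frequencies 0.9 vs 0.1
        ga = [2] * 8 + [1] * 2
        gb = [0] * 8 + [1] * 2
        gm = make_gm([[g] for g in ga + gb])
        pops = [f"s{i}" for i in range(10)], [f"s{i}" for i in range(10, 20)]
        got = pg.wc_fst_snp(gm, *pops)["fst"].iloc[0]
        _, _, want = wc_theta_oracle(ga, gb)
        assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_fixtures_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ga = rng.binomial(2, rng.uniform(0.1, 0.9), size=12)
        gb = rng.binomial(2, rng.uniform(0.1, 0.9), size=9)
        gm = make_gm([[g] for g in np.concatenate([ga, gb])])
        pops = [f"s{i}" for i in range(12)], [f"s{i}" for i in range(12, 21)]
        got = pg.wc_fst_snp(gm, *pops)["fst"].iloc[0]
        _, _, want = wc_theta_oracle(ga, gb)
        if np.isnan(want):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(want, abs=1e-12)


class TestWindowedFst:
    def test_window_count_arithmetic(self):
        # length 100,000, 25 kb window, 5 kb step -> 16 fully inside
        counts = np.zeros((4, 10), dtype=np.int16)
        counts[2:] = 2
        gm = make_gm(counts)
        out = pg.wc_fst_windowed(
            gm, ["s0", "s1"], ["s2", "s3"],
            chrom_lengths={"chr1": 100_000},
        )
        assert len(out) == (100_000 - 25_000) // 5_000 + 1 == 16

    def test_all_fixed_window_is_one(self):
        counts = np.zeros((4, 5), dtype=np.int16)
        counts[2:] = 2
        gm = make_gm(counts, spacing=1_000)
        out = pg.wc_fst_windowed(gm, ["s0", "s1"], ["s2", "s3"],
                                 chrom_lengths={"chr1": 25_000})
        assert out["fst"].iloc[0] == pytest.approx(1.0)

    def test_ratio_of_sums_not_mean_of_ratios(self):
        rng = np.random.default_rng(4)
        # heterogeneous fixture: one fixed difference + noisy loci
        ga = np.column_stack([np.zeros(10), rng.binomial(2, 0.5, (10, 4)).T.T])
        gb = np.column_stack([np.full(10, 2), rng.binomial(2, 0.4, (10, 4))])
        counts = np.vstack([ga, gb]).astype(np.int16)
        gm = make_gm(counts, spacing=1_000)
        pops = [f"s{i}" for i in range(10)], [f"s{i}" for i in range(10, 20)]
        win = pg.wc_fst_windowed(gm, *pops, window_bp=25_000, step_bp=25_000,
                                 chrom_lengths={"chr1": 25_000})
        # oracle: per-locus a and a+b+c summed
        num = den = 0.0
        ratios = []
        for j in range(5):
            a, abc, theta = wc_theta_oracle(counts[:10, j], counts[10:, j])
            if np.isfinite(abc) and abc != 0:
                num += a
                den += abc
                ratios.append(theta)
        assert win["fst"].iloc[0] == pytest.approx(num / den, abs=1e-12)
        assert win["fst"].iloc[0] != pytest.approx(np.mean(ratios), abs=1e-6)


class TestPca:
    def test_separated_panels_dominate_pc1(self):
        cfg = sd.SyntheticConfig(seed=2, n_parental_each=10, l_diag=150,
                                 l_background=15, balding_nichols_F=0.0)
        gm, table, _ = sd.make_parental_panels(cfg)
        res = pg.pca(gm, thin_bp=None, k=4)
        assert res.explained_variance_ratio[0] > 0.9
        pc1 = pd.Series(res.coords[:, 0], index=res.sample_ids)
        a = table[table.population_label == "allopatric-P0"].sample_id
        b = table[table.population_label == "allopatric-P1"].sample_id
        assert (pc1[a].max() < pc1[b].min()) or (pc1[b].max() < pc1[a].min())

    def test_duplicated_sample_identical_coordinates(self):
        rng = np.random.default_rng(1)
        counts = rng.binomial(2, 0.4, size=(6, 50)).astype(np.int16)
        counts = np.vstack([counts, counts[:1]])
        gm = make_gm(counts)
        res = pg.pca(gm, thin_bp=None, k=3)
        np.testing.assert_allclose(res.coords[0], res.coords[6], atol=1e-9)

    def test_admixed_samples_fall_between_panels(self, small_dataset, panel_ids):
        _, gm, table = small_dataset
        a, b = panel_ids
        res = pg.pca(gm, thin_bp=10_000, k=2)
        pc1 = pd.Series(res.coords[:, 0], index=res.sample_ids)
        lo, hi = sorted([pc1[a].mean(), pc1[b].mean()])
        mid = table[(table.true_q > 0.35) & (table.true_q < 0.65)].sample_id
        if len(mid):
            assert ((pc1[mid] > lo) & (pc1[mid] < hi)).all()

    def test_locus_order_permutation_invariant_up_to_sign(self):
        rng = np.random.default_rng(7)
        counts = rng.binomial(2, 0.3, size=(8, 40)).astype(np.int16)
        gm = make_gm(counts)
        perm = rng.permutation(40)
        gm_p = gm.subset_loci(perm)
        r1 = pg.pca(gm, thin_bp=None, k=2)
        r2 = pg.pca(gm_p, thin_bp=None, k=2)
        for j in range(2):
            same = np.allclose(r1.coords[:, j], r2.coords[:, j], atol=1e-8)
            flip = np.allclose(r1.coords[:, j], -r2.coords[:, j], atol=1e-8)
            assert same or flip


class TestInbreedingF:
    def test_full_heterozygote_strongly_negative(self):
        counts = np.vstack([
            np.ones((1, 40)),
            np.zeros((5, 40)),
            np.full((5, 40), 2),
        ]).astype(np.int16)
        gm = make_gm(counts)
        f = pg.individual_inbreeding_f(gm)
        assert f.iloc[0] < -0.5

    def test_fully_homozygous_near_one(self):
        rng = np.random.default_rng(0)
        base = rng.binomial(2, 0.5, size=(10, 60)).astype(np.int16)
        base[0] = np.where(base[0] == 1, 0, base[0])
        gm = make_gm(base)
        f = pg.individual_inbreeding_f(gm)
        assert f.iloc[0] > 0.5


class TestLeastAdmixed:
    def _series(self, pairs):
        h = pd.Series({k: v[0] for k, v in pairs.items()})
        het = pd.Series({k: v[1] for k, v in pairs.items()})
        return h, het

    def test_threshold_rules(self):
        h, het = self._series({
            "p0": (0.05, 0.05),
            "p1": (0.95, 0.05),
            "hy": (0.5, 0.9),
            "hf": (0.95, 0.15),
        })
        out = pg.select_least_admixed(h, het)
        assert out == {"P0": ["p0"], "P1": ["p1"]}

    def test_idempotent_and_order_independent(self):
        rng = np.random.default_rng(5)
        ids = [f"x{i}" for i in range(30)]
        h = pd.Series(rng.uniform(0, 1, 30), index=ids)
        het = pd.Series(rng.uniform(0, 0.3, 30), index=ids)
        out1 = pg.select_least_admixed(h, het)
        shuffled = rng.permutation(ids)
        out2 = pg.select_least_admixed(h[shuffled], het[shuffled])
        assert out1 == out2
        kept = out1["P0"] + out1["P1"]
        out3 = pg.select_least_admixed(h[kept], het[kept])
        assert out3 == out1


class TestMitotype:
    def _mt_gm(self, patterns, clades):
        counts = np.array([patterns[c] for c in clades], dtype=np.int16)
        m = counts.shape[1]
        loci = pd.DataFrame({"chrom": "chrM", "pos": 100 + np.arange(m),
                             "ref": "A", "alt": "C"})
        samples = [f"mt{i}" for i in range(len(clades))]
        from clinekit.core_io import GenotypeMatrix

        return GenotypeMatrix(samples, loci, counts,
                              np.ones_like(counts, dtype=np.int8)), samples

    def test_references_assign_to_their_own_clade(self):
        cfg = sd.SyntheticConfig()
        patterns = sd.mt_clade_patterns(cfg)
        clades = ["P0"] * 4 + ["P1_west"] * 4 + ["P1_east"] * 4
        gm, samples = self._mt_gm(patterns, clades)
        refs = {c: [s for s, cl in zip(samples, clades) if cl == c]
                for c in set(clades)}
        out = pg.assign_mitotype(gm, refs).set_index("sample_id")
        for s, c in zip(samples, clades):
            assert out.loc[s, "mitotype"] == c

    def test_admixed_sample_gets_p1_clade(self):
        cfg = sd.SyntheticConfig()
        patterns = sd.mt_clade_patterns(cfg)
        clades = ["P0"] * 4 + ["P1_west"] * 4 + ["P1_east"] * 4 + ["P1_west"]
        gm, samples = self._mt_gm(patterns, clades)
        refs = {c: [s for s, cl in zip(samples[:-1], clades) if cl == c][:4]
                for c in ("P0", "P1_west", "P1_east")}
        out = pg.assign_mitotype(gm, refs).set_index("sample_id")
        assert out.loc[samples[-1], "mitotype"] == "P1_west"

    def test_equidistant_tie_breaks_by_label_order_and_flags(self):
        # two reference clades at mirrored coordinates; a sample at the origin
        counts = np.array(
            [[0, 0], [0, 0], [1, 1], [1, 1], [0, 1]], dtype=np.int16
        )
        loci = pd.DataFrame({"chrom": "chrM", "pos": [100, 200],
                             "ref": "A", "alt": "C"})
        from clinekit.core_io import GenotypeMatrix

        gm = GenotypeMatrix([f"m{i}" for i in range(5)], loci, counts,
                            np.ones_like(counts, dtype=np.int8))
        out = pg.assign_mitotype(
            gm, {"cladeA": ["m0", "m1"], "cladeB": ["m2", "m3"]}
        ).set_index("sample_id")
        assert out.loc["m4", "tie"]
        assert out.loc["m4", "mitotype"] == "cladeA"
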