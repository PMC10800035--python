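import numpy as np
import pytest

from hetassoc.io import MISSING
from hetassoc.qc import (
    QCConfig,
    allele_frequencies,
    check_sex,
    filter_hwe,
    filter_maf,
    filter_missingness,
    find_duplicates,
    hwe_exact_test,
    run_qc,
)
from hetassoc.simulate import SimulationConfig, generate_cohort, simulate_genotypes

from conftest import make_matrix, make_samples
from oracles import hwe_exact_oracle


class TestAlleleFrequencies:
    @pytest.mark.parametrize(
        "calls, p_alt, maf, n_called",
        [
            ([[0], [1], [2]], 0.5, 0.5, 3),
            ([[2], [2], [2]], 1.0, 0.0, 3),
            ([[0], [1], [MISSING]], 0.25, 0.25, 2),
        ],
    )
    def test_examples(self, calls, p_alt, maf, n_called):
        f = allele_frequencies(make_matrix(calls))
        assert f.p_alt[0] == pytest.approx(p_alt)
        assert f.maf[0] == pytest.approx(maf)
        assert f.n_called[0] == n_called

    def test_all_missing_flagged_not_fatal(self):
        f = allele_frequencies(make_matrix([[MISSING], [MISSING]]))
        assert np.isnan(f.p_alt[0])


class TestMafFilter:
    def test_boundaries(self):
        # maf per variant: 0.009..., 0.05, 0.25
        calls = np.zeros((500, 3), dtype=np.int8)
        calls[:9, 0] = 1  # maf 9/1000 = 0.009
        calls[:50, 1] = 1  # maf 0.05
        calls[:250, 2] = 1  # maf 0.25
        g = make_matrix(calls)
        f = allele_frequencies(g)
        kept, removed = filter_maf(g, f, 0.01)
        assert removed == ["v0"]  # 0.009 removed at threshold 0.01
        kept2, removed2 = filter_maf(g, f, 0.1)
        assert set(removed2) == {"v0", "v1"}  # 0.05 removed at 0.1
        kept3, removed3 = filter_maf(g, f, 0.0)
        assert removed3 == []  # only monomorphic would go

    def test_monomorphic_removed_at_zero(self):
        g = make_matrix([[0, 1], [0, 1]])
        f = allele_frequencies(g)
        _, removed = filter_maf(g, f, 0.0)
        assert removed == ["v0"]

    def test_idempotent(self, random_matrix):
        f = allele_frequencies(random_matrix)
        g1, r1 = filter_maf(random_matrix, f, 0.1)
        f1 = allele_frequencies(g1)
        g2, r2 = filter_maf(g1, f1, 0.1)
        assert r2 == [] and g1.equals(g2)

    def test_bad_threshold(self, random_matrix):
        f = allele_frequencies(random_matrix)
        with pytest.raises(ValueError):
            filter_maf(random_matrix, f, 0.6)


class TestMissingnessFilter:
    def test_boundary_strict(self):
        calls = np.ones((10, 2), dtype=np.int8)
        calls[0, 0] = MISSING  # rate 0.10 > 0.05 -> removed
        g = make_matrix(calls)
        _, removed = filter_missingness(g, 0.05)
        assert removed == ["v0"]
        # exactly at threshold retained (strict >)
        _, removed = filter_missingness(g, 0.10)
        assert removed == []

    def test_bad_threshold(self, random_matrix):
        with pytest.raises(ValueError):
            filter_missingness(random_matrix, 1.5)


class TestHweExact:
    def test_extreme_het_excess(self):
        assert hwe_exact_test(0, 100, 0) < 1e-20

    def test_monomorphic(self):
        assert hwe_exact_test(50, 0, 0) == 1.0

    def test_matches_enumeration_oracle_exhaustive(self):
        """Exhaustive sweep of all genotype-count triples with total <= 50."""
        total_checked = 0
        for n in range(1, 51):
            for n_alt_allele in range(0, n + 1):
                for het in range(n_alt_allele % 2, n_alt_allele + 1, 2):
                    hom_alt = (n_alt_allele - het) // 2
                    hom_ref = n - het - hom_alt
                    if hom_ref < 0:
                        continue
                    got = hwe_exact_test(hom_ref, het, hom_alt)
                    want = hwe_exact_oracle(hom_ref, het, hom_alt)
                    assert got == pytest.approx(want, rel=1e-9), (
                        hom_ref, het, hom_alt,
                    )
                    total_checked += 1
        assert total_checked > 5000

    def test_negative_counts(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


class TestHweFilter:
    def test_deficit_removed_equilibrium_kept(self):
        p = np.full(20, 0.3)
        g_bad = simulate_genotypes(p, np.full(500, 0.8), seed=11)
        _, removed = filter_hwe(g_bad, 1e-6)
        assert len(removed) == 20  # F=0.8 at n=500: power ~ 1
        g_ok = simulate_genotypes(p, np.zeros(500), seed=12)
        _, removed_ok = filter_hwe(g_ok, 1e-6)
        assert removed_ok == []

    def test_level_under_null(self):
        """Removal rate under HWE approximates alpha."""
        p = np.random.default_rng(5).uniform(0.1, 0.5, 2000)
        g = simulate_genotypes(p, np.zeros(300), seed=13)
        _, removed = filter_hwe(g, 0.01)
        # exact test is conservative; binomial 3-sigma band around <= alpha
        assert len(removed) <= 2000 * 0.01 + 3 * np.sqrt(2000 * 0.01 * 0.99)

    def test_bad_alpha(self, random_matrix):
        with pytest.raises(ValueError):
            filter_hwe(random_matrix, 0.0)


class TestDuplicates:
    def test_exact_copy_found(self, rng):
        calls = rng.integers(0, 3, size=(5, 200)).astype(np.int8)
        calls[4] = calls[0]
        g = make_matrix(calls)
        pairs = find_duplicates(g, 0.95)
        assert [(a, b) for a, b, _ in pairs] == [("S0", "S4")]
        assert pairs[0][2] == 1.0

    def test_independent_samples_below_threshold(self, rng):
        p = rng.uniform(0.05, 0.5, 1000)
        g = simulate_genotypes(p, np.zeros(2), seed=21)
        pairs = find_duplicates(g, 0.95)
        assert pairs == []

    def test_single_sample(self):
        assert find_duplicates(make_matrix([[0, 1, 2]])) == []

    def test_low_overlap_warns(self):
        calls = np.full((2, 60), MISSING, dtype=np.int8)
        calls[:, :10] = 1
        with pytest.warns(UserWarning, match="overlapping"):
            pairs = find_duplicates(make_matrix(calls), 0.95)
        assert pairs == []


class TestCheckSex:
    def _xy_cohort(self):
        # 200 X variants; S0 het-rich (female-like), S1 het-free (male-like)
        calls = np.zeros((2, 200), dtype=np.int8)
        calls[0, ::2] = 1
        calls[1, ::2] = 2
        g = make_matrix(calls, chroms=["X"] * 200)
        return g

    def test_flags_discordant(self):
        g = self._xy_cohort()
        s = make_samples(
            [
                ("S0", "control", "none", 50, "male", 25, "no"),  # het 0.5 male
                ("S1", "control", "none", 50, "female", 25, "no"),  # het 0 female
            ]
        )
        assert set(check_sex(g, s)) == {"S0", "S1"}

    def test_concordant_pass(self):
        g = self._xy_cohort()
        s = make_samples(
            [
                ("S0", "control", "none", 50, "female", 25, "no"),
                ("S1", "control", "none", 50, "male", 25, "no"),
            ]
        )
        assert check_sex(g, s) == []

    def test_no_x_variants_warns(self, toy_cohort):
        g, s = toy_cohort
        with pytest.warns(UserWarning, match="no X-chromosome"):
            assert check_sex(g, s) == []


class TestRunQc:
    def test_injected_artifact_accounting(self):
        cfg = SimulationConfig(
            n_samples=300, n_snps=1500, seed=7,
            n_hwe_violations=10, n_duplicates=1, n_sex_swaps=0,
            missing_rate=0.0,
        )
        # inject 5 high-missingness variants by hand
        g, s, truth = generate_cohort(cfg)
        calls = g.calls.copy()
        auto = np.flatnonzero(g.autosomal_mask())
        hwe_ids = set(truth.hwe_violation_ids)
        miss_idx = [j for j in auto if g.variant_ids[j] not in hwe_ids][:5]
        calls[: int(0.2 * g.n_samples), miss_idx] = MISSING
        g = make_matrix(calls, chroms=g.variants.chrom, samples=g.samples)

        g2, s2, report = run_qc(g, s, QCConfig(maf_min=0.0))
        report.validate()
        assert report.removed_duplicate_samples == 1
        assert report.removed_by_hwe == 10
        assert report.removed_by_missingness == 5
        assert report.n_samples_out == report.n_samples_in - 1

    def test_clean_fixture_untouched(self):
        cfg = SimulationConfig(
            n_samples=200, n_snps=500, seed=8, missing_rate=0.0, n_x_snps=50,
        )
        g, s, _ = generate_cohort(cfg)
        g2, s2, report = run_qc(g, s, QCConfig(maf_min=0.0))
        assert report.removed_duplicate_samples == 0
        assert report.removed_sex_discordant == 0
        assert report.removed_by_missingness == 0
        assert report.removed_by_hwe == 0

    def test_thresholds_echoed(self, toy_cohort):
        g, s = toy_cohort
        _, _, report = run_qc(g, s, QCConfig(maf_min=0.01, miss_max=0.05))
        assert report.thresholds.maf_min == 0.01
        assert report.thresholds.miss_max == 0.05

    def test_duplicate_keeps_less_missing_member(self, rng):
        calls = rng.integers(0, 3, size=(4, 300)).astype(np.int8)
        calls[3] = calls[0]
        calls[0, :10] = MISSING  # S0 has more missing than its copy S3
        g = make_matrix(calls)
        s = make_samples(
            [(f"S{i}", "case", "knee", 60, "female", 30, "no") for i in range(3)]
            + [("S3", "control", "none", 55, "female", 28, "no")]
        )
        g2, _, report = run_qc(g, s, QCConfig(maf_min=0.0, miss_max=1.0, hwe_alpha=1e-12))
        assert "S0" in report.removed_sample_ids
        assert "S3" in g2.samples

    def test_everything_removed_is_hard_error(self):
        g = make_matrix([[1, 1], [1, 1], [1, 1]])  # all-het: HWE-dead variants
        s = make_samples(
            [
                ("S0", "case", "knee", 60, "female", 30, "no"),
                ("S1", "control", "none", 55, "female", 28, "no"),
                ("S2", "control", "none", 52, "male", 26, "no"),
            ]
        )
        with pytest.raises(RuntimeError, match="QC removed everything"):
            run_qc(g, s, QCConfig(hwe_alpha=0.9))

    def test_filter_order_invariance_when_independent(self, rng):
        """If no variant fails two filters, the surviving set is order-free."""
        p = rng.uniform(0.2, 0.5, 200)
        g = simulate_genotypes(p, np.zeros(100), seed=31)
        calls = g.calls.copy()
        calls[:20, :3] = MISSING  # 3 variants -> 20% missing
        g = make_matrix(calls, chroms=g.variants.chrom, samples=g.samples)
        f = allele_frequencies(g)
        ga, ra = filter_missingness(g, 0.05)
        ga, rb = filter_maf(ga, allele_frequencies(ga), 0.1)
        gb, rc = filter_maf(g, f, 0.1)
        gb, rd = filter_missingness(gb, 0.05)
        assert sorted(ra + rb) == sorted(rc + rd)
        assert sorted(ga.variant_ids) == sorted(gb.variant_ids)
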