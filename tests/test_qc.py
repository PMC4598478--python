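"""Every QC rule at its boundary, plus the relatedness and LD estimators
against simulation and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import snpset as ss
from snpset.simulate import LocusPlan, SimulationTruth

from conftest import dosage_column, gm_from_dosages


# ---------------------------------------------------------------------------
# masking and sample filtering
# ---------------------------------------------------------------------------

class TestCallMasking:
    def test_threshold_is_strict(self):
        """Quality exactly at the 0.25 cutoff is retained; below is masked."""
        q = np.array([[0.25, 0.249, 1.0]])
        gm = gm_from_dosages(np.array([[1, 1, 1]]), quality=q)
        masked, n = ss.mask_low_quality_calls(gm)
        assert n == 1
        assert not masked.is_missing[0, 0]  # exactly 0.25 kept
        assert masked.is_missing[0, 1]  # 0.249 masked
        assert not masked.is_missing[0, 2]

    def test_all_good_identity(self):
        gm = gm_from_dosages(np.tile([0, 1, 2], (5, 1)))
        masked, n = ss.mask_low_quality_calls(gm)
        assert n == 0
        assert np.array_equal(masked.a1, gm.a1)


class TestSampleMissingness:
    def _gm_with_missing(self, n_missing: int):
        d = np.tile(dosage_column(30, 40, 30)[:, None], (1, 100))
        d[0, :n_missing] = -1
        return gm_from_dosages(d)

    def test_exactly_ten_percent_retained(self):
        gm = self._gm_with_missing(10)
        kept, excluded = ss.filter_samples_by_missingness(gm)
        assert excluded == []
        assert kept.n_subjects == 100

    def test_over_ten_percent_excluded(self):
        gm = self._gm_with_missing(11)
        kept, excluded = ss.filter_samples_by_missingness(gm)
        assert [s for s, _ in excluded] == ["S000"]
        assert excluded[0][1] == pytest.approx(0.11)
        assert kept.n_subjects == 99

    def test_complete_matrix_untouched(self):
        gm = self._gm_with_missing(0)
        kept, excluded = ss.filter_samples_by_missingness(gm)
        assert excluded == [] and kept.n_subjects == 100


# ---------------------------------------------------------------------------
# genotype grouping
# ---------------------------------------------------------------------------

class TestGrouping:
    @pytest.mark.parametrize(
        "counts, expect_labels, expect_counts",
        [
            ((380, 30, 7), ["AA", "AG+GG"], [380, 37]),  # minor-hom merged
            ((200, 150, 50), ["AA", "AG", "GG"], [200, 150, 50]),  # untouched
            ((381, 36, 0), ["AA", "AG+GG"], [381, 36]),  # two-class locus
        ],
    )
    def test_merge_rule(self, counts, expect_labels, expect_counts):
        gm = gm_from_dosages(dosage_column(*counts)[:, None])
        g = ss.make_grouping(gm, 0)
        assert not g.excluded
        assert g.labels == expect_labels
        assert g.counts == expect_counts

    def test_combined_still_small_excludes(self):
        gm = gm_from_dosages(dosage_column(400, 6, 3)[:, None])
        g = ss.make_grouping(gm, 0)
        assert g.excluded
        assert "9 < 10" in g.reason

    def test_monomorphic_excluded(self):
        gm = gm_from_dosages(np.zeros((50, 1), dtype=int))
        g = ss.make_grouping(gm, 0)
        assert g.excluded and g.reason == "monomorphic"

    def test_male_x_hemizygotes_join_homozygote_classes(self):
        d = np.array([[0], [2], [0], [1], [2]])
        gm = gm_from_dosages(d, chromosomes=["X"], sex=["M", "M", "F", "F", "F"])
        cfg = ss.QCConfig(min_group_count=1)
        g = ss.make_grouping(gm, 0, cfg)
        # males dose 0/2 -> classes major-hom / minor-hom
        assert g.counts == [2, 1, 2]


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

class TestHWE:
    def test_exact_equilibrium(self):
        gm = gm_from_dosages(dosage_column(25, 50, 25)[:, None])
        chi2, p, flag = ss.hwe_chi_square(gm, 0)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_deviation(self):
        """Counts (30, 40, 30): allele freq 0.5, expected (25, 50, 25),
        chi^2 = 25/25 + 100/50 + 25/25 = 4."""
        gm = gm_from_dosages(dosage_column(30, 40, 30)[:, None])
        chi2, p, flag = ss.hwe_chi_square(gm, 0)
        assert chi2 == pytest.approx(4.0, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(4.0, 1), abs=1e-12)
        assert p == pytest.approx(0.0455, abs=2e-4)

    def test_x_uses_females_only(self):
        d_f = dosage_column(30, 40, 30)
        gm_f = gm_from_dosages(d_f[:, None], chromosomes=["X"])
        # add 50 males, all major hemizygotes: must not change the result
        d_m = np.concatenate([d_f, np.zeros(50, dtype=int)])
        sex = ["F"] * 100 + ["M"] * 50
        gm_fm = gm_from_dosages(d_m[:, None], chromosomes=["X"], sex=sex)
        assert ss.hwe_chi_square(gm_f, 0)[0] == pytest.approx(
            ss.hwe_chi_square(gm_fm, 0)[0]
        )

    def test_monomorphic_untestable(self):
        gm = gm_from_dosages(np.zeros((40, 1), dtype=int))
        assert ss.hwe_chi_square(gm, 0)[2] == "untestable"

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.tuples(
            st.integers(2, 300), st.integers(2, 300), st.integers(2, 300)
        )
    )
    def test_matches_brute_force_expected_table(self, counts):
        """Oracle: explicitly tabulate HWE-expected counts from the allele
        frequency and form the Pearson statistic term by term."""
        n_aa, n_ab, n_bb = counts
        gm = gm_from_dosages(dosage_column(n_aa, n_ab, n_bb)[:, None])
        chi2, p, flag = ss.hwe_chi_square(gm, 0)
        n = n_aa + n_ab + n_bb
        q = (n_ab + 2 * n_bb) / (2 * n)  # minor-ish allele frequency
        expected = [n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q * q]
        oracle = sum(
            (o - e) ** 2 / e
            for o, e in zip([n_aa, n_ab, n_bb], expected)
        )
        assert chi2 == pytest.approx(oracle, abs=1e-10)


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

class TestLD:
    def test_duplicate_and_anticorrelated(self):
        d = dosage_column(30, 40, 30)
        flipped = 2 - d
        gm = gm_from_dosages(np.column_stack([d, d, flipped]))
        assert ss.pairwise_r2(gm, 0, 1) == pytest.approx(1.0)
        assert ss.pairwise_r2(gm, 0, 2) == pytest.approx(1.0)  # square of -1

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=(80, 2))
        gm = gm_from_dosages(d)
        assert ss.pairwise_r2(gm, 0, 1) == pytest.approx(
            ss.pairwise_r2(gm, 1, 0), abs=1e-12
        )

    def test_independent_loci_near_zero(self):
        truth = SimulationTruth(
            n_subjects=10_000, n_male=0,
            loci_plan=[LocusPlan("a", "1", 1, 0.3, 0),
                       LocusPlan("b", "1", 2, 0.3, 1)],
            missing_rate=0.0, low_quality_rate=0.0, seed=3,
        )
        gm = ss.simulate_genotypes(truth)
        assert ss.pairwise_r2(gm, "a", "b") < 0.01

    def test_prune_drops_second_of_identical_pair(self):
        d = dosage_column(30, 40, 30)
        gm = gm_from_dosages(np.column_stack([d, d]), positions=[100, 200])
        retained, dropped = ss.ld_prune(gm)
        assert retained == ["L000"]
        assert dropped[0][0] == "L001" and dropped[0][1] == "L000"
        assert dropped[0][2] == pytest.approx(1.0)

    def test_prune_chain_traces_greedy_scan(self):
        """A-B and B-C in high LD but A-C below threshold: B drops against
        A; C is then compared to retained A only and survives."""
        A = dosage_column(20, 20, 20)
        B = A.copy()
        B[55] = 0
        C = A.copy()
        C[[0, 17, 19, 24, 55]] = [1, 2, 1, 2, 0]
        gm = gm_from_dosages(np.column_stack([A, B, C]),
                             positions=[100, 200, 300])
        # verify the premises of the trace
        assert ss.pairwise_r2(gm, 0, 1) > 0.8
        assert ss.pairwise_r2(gm, 1, 2) > 0.8
        assert ss.pairwise_r2(gm, 0, 2) <= 0.8
        retained, dropped = ss.ld_prune(gm)
        assert retained == ["L000", "L002"]
        assert [d[0] for d in dropped] == ["L001"]

    def test_independent_panel_untouched(self):
        rng = np.random.default_rng(1)
        gm = gm_from_dosages(rng.integers(0, 3, size=(200, 6)))
        retained, dropped = ss.ld_prune(gm)
        assert len(retained) == 6 and dropped == []

    def test_different_chromosomes_never_pruned(self):
        d = dosage_column(30, 40, 30)
        gm = gm_from_dosages(np.column_stack([d, d]), chromosomes=["1", "2"])
        retained, dropped = ss.ld_prune(gm)
        assert len(retained) == 2


# ---------------------------------------------------------------------------
# relatedness
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def related_study():
    plan = [
        LocusPlan(f"l{i}", str(1 + i % 22), 10_000 * i + 1,
                  0.1 + 0.4 * ((3 * i) % 11) / 11, block=i)
        for i in range(500)
    ]
    truth = SimulationTruth(
        n_subjects=60, n_male=25, loci_plan=plan,
        missing_rate=0.0, low_quality_rate=0.0,
        related_pairs=["duplicate", "parent_child"], seed=5,
    )
    gm = ss.simulate_genotypes(truth)
    return ss.estimate_pi_hat(gm)


class TestPiHat:
    def test_duplicate_pair_near_one(self, related_study):
        df = related_study
        dup = df[(df.subject_a == "S0001") & (df.subject_b == "R001")]
        assert float(dup.pi_hat.iloc[0]) >= 0.95
        assert bool(dup.flagged.iloc[0])

    def test_parent_child_near_half(self, related_study):
        df = related_study
        pc = df[(df.subject_a == "S0002") & (df.subject_b == "R002")]
        assert float(pc.pi_hat.iloc[0]) == pytest.approx(0.5, abs=0.1)

    def test_unrelated_near_zero(self, related_study):
        df = related_study
        unrel = df[~df.subject_b.str.startswith("R")]
        assert unrel.pi_hat.mean() <= 0.1
        assert unrel.pi_hat.max() < 0.5

    def test_probabilities_clamped_and_normalized(self, related_study):
        df = related_study
        probs = df[["p_ibd0", "p_ibd1", "p_ibd2"]].to_numpy()
        assert (probs >= 0).all() and (probs <= 1).all()
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_few_loci_warns_low_confidence(self):
        gm = gm_from_dosages(
            np.random.default_rng(0).integers(0, 3, size=(10, 5))
        )
        with pytest.warns(UserWarning, match="low-confidence"):
            df = ss.estimate_pi_hat(gm)
        assert df.low_confidence.all()


# ---------------------------------------------------------------------------
# the full cascade
# ---------------------------------------------------------------------------

class TestRunQC:
    def test_clean_study_untouched_and_idempotent(self):
        truth = ss.default_truth(target_planted_r2=0.0, seed=31, n_loci=24,
                                 n_tight_blocks=0, missing_rate=0.0,
                                 low_quality_rate=0.0)
        gm = ss.simulate_genotypes(truth)
        clean, groupings, report = ss.run_qc(gm, relatedness=False)
        assert report.excluded_subjects == []
        assert report.masked_calls == 0
        assert report.retained_loci + len(report.excluded_loci) + len(
            report.ld_dropped
        ) == 24
        # idempotence: second pass changes nothing
        clean2, _, report2 = ss.run_qc(clean, relatedness=False)
        assert clean2.n_subjects == clean.n_subjects
        assert clean2.n_loci == clean.n_loci
        assert report2.excluded_loci == [] and report2.ld_dropped == []

    def test_constructed_removals_each_with_reason(self):
        """One bad sample, one rare-genotype locus, one duplicated locus:
        exactly those three removals, each attributed correctly."""
        rng = np.random.default_rng(2)
        n = 120
        d = np.column_stack(
            [
                rng.integers(0, 3, n),  # L000 fine
                dosage_column(111, 6, 3),  # L001 combined group of 9
                rng.integers(0, 3, n),  # L002 fine
                np.zeros(n, dtype=int),  # L003 duplicate of L004 below
                rng.integers(0, 3, n),  # L004 fine
            ]
        )
        d[:, 3] = d[:, 2]  # exact duplicate of L002, later position
        d[0, :4] = -1  # subject S000 missing 4/5 = 80% of calls
        gm = gm_from_dosages(d, positions=[100, 200, 300, 400, 500])
        clean, groupings, report = ss.run_qc(gm, relatedness=False)
        assert [s for s, _ in report.excluded_subjects] == ["S000"]
        assert [l for l, _ in report.excluded_loci] == ["L001"]
        assert "9 < 10" in report.excluded_loci[0][1]
        assert [d_[0] for d_ in report.ld_dropped] == ["L003"]
        assert report.ld_dropped[0][1] == "L002"
        assert clean.n_subjects == 119 and clean.n_loci == 3

    def test_conservation_checked(self, planted_study):
        report = planted_study["report"]
        report.check_conservation()
        assert report.input_subjects == 417
        assert report.input_loci == 99

    def test_hwe_exclude_policy(self):
        truth = ss.default_truth(target_planted_r2=0.0, seed=33, n_loci=24,
                                 n_tight_blocks=0)
        truth = SimulationTruth.from_dict(
            {**truth.to_dict(), "hwe_violator": "rs10000", "hwe_excess": 0.7}
        )
        gm = ss.simulate_genotypes(truth)
        cfg = ss.QCConfig(hwe_policy="exclude")
        clean, _, report = ss.run_qc(gm, cfg, relatedness=False)
        assert any(
            l == "rs10000" and "Hardy-Weinberg" in r
            for l, r in report.excluded_loci
        )

    def test_config_ranges_validated(self):
        with pytest.raises(ValueError, match="ld_r2_max"):
            ss.QCConfig(ld_r2_max=1.5)
        with pytest.raises(ValueError, match="hwe_policy"):
            ss.QCConfig(hwe_policy="drop")
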