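"""Generator properties: determinism, LD structure, HWE by construction,
planted-effect calibration."""

import warnings

import numpy as np
import pytest

import snpset as ss
from snpset.simulate import LocusPlan, SimulationTruth, _simulate_complete


def _plan(n, maf=0.3, block_size=1, chrom="1"):
    return [
        LocusPlan(f"l{i}", chrom, 1000 * (i + 1), maf, block=i // block_size)
        for i in range(n)
    ]


def test_seed_determinism():
    truth = ss.default_truth(target_planted_r2=0.08, seed=42, n_loci=30,
                             n_tight_blocks=2)
    g1, p1, c1 = ss.simulate_study(truth)
    g2, p2, c2 = ss.simulate_study(truth)
    assert np.array_equal(g1.a1, g2.a1) and np.array_equal(g1.a2, g2.a2)
    assert np.array_equal(g1.quality, g2.quality)
    assert p1.frame.equals(p2.frame)
    assert c1.planted_effects == c2.planted_effects


def test_perfect_block_duplicates_haplotypes():
    """within_block_r2 = 1 with equal MAFs -> dosage r^2 exactly 1."""
    plan = [
        LocusPlan("a", "1", 100, 0.3, block=0),
        LocusPlan("b", "1", 200, 0.3, block=0),
    ]
    truth = SimulationTruth(
        n_subjects=300, n_male=0, loci_plan=plan, within_block_r2=1.0,
        missing_rate=0.0, low_quality_rate=0.0, seed=1,
    )
    gm = ss.simulate_genotypes(truth)
    assert ss.pairwise_r2(gm, "a", "b") == pytest.approx(1.0)
    assert np.array_equal(gm.a1[:, 0], gm.a1[:, 1])


def test_cross_block_independence():
    truth = SimulationTruth(
        n_subjects=10_000, n_male=0,
        loci_plan=_plan(6, block_size=2), within_block_r2=0.9,
        missing_rate=0.0, low_quality_rate=0.0, seed=2,
    )
    gm = ss.simulate_genotypes(truth)
    assert ss.pairwise_r2(gm, "l0", "l2") < 0.01
    assert ss.pairwise_r2(gm, "l1", "l4") < 0.01
    # within-block pairs hit their target
    assert ss.pairwise_r2(gm, "l0", "l1") == pytest.approx(0.9, abs=0.05)


def test_unreachable_r2_warns_and_uses_best():
    plan = [
        LocusPlan("a", "1", 100, 0.05, block=0),
        LocusPlan("b", "1", 200, 0.45, block=0),
    ]
    truth = SimulationTruth(
        n_subjects=4000, n_male=0, loci_plan=plan, within_block_r2=0.9,
        missing_rate=0.0, low_quality_rate=0.0, seed=3,
    )
    with pytest.warns(UserWarning, match="unreachable"):
        gm = ss.simulate_genotypes(truth)
    assert ss.pairwise_r2(gm, "a", "b") < 0.9


def test_duplicate_pair_identical_calls():
    truth = SimulationTruth(
        n_subjects=50, n_male=20, loci_plan=_plan(30),
        related_pairs=["duplicate"], seed=4,
    )
    gm = ss.simulate_genotypes(truth)
    i, j = gm.subject_ids.index("S0001"), gm.subject_ids.index("R001")
    both = ~gm.is_missing[i] & ~gm.is_missing[j]
    assert np.array_equal(gm.a1[i, both], gm.a1[j, both])
    assert np.array_equal(gm.a2[i, both], gm.a2[j, both])


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="MAF"):
        SimulationTruth(loci_plan=[LocusPlan("a", "1", 1, 0.6, 0)])
    with pytest.raises(ValueError, match="unknown locus"):
        SimulationTruth(loci_plan=_plan(2), planted_effects=[("zz", 1.0)])
    with pytest.raises(ValueError, match="relationship"):
        SimulationTruth(loci_plan=_plan(2), related_pairs=["cousin"])


def test_truth_config_round_trip():
    truth = ss.default_truth(target_planted_r2=0.08, seed=9, n_loci=20,
                             n_tight_blocks=1)
    assert SimulationTruth.from_dict(truth.to_dict()) == truth


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

class TestCalibration:
    def _study(self, seed=5):
        truth = ss.default_truth(target_planted_r2=0.08, seed=seed, n_loci=30,
                                 n_tight_blocks=0, missing_rate=0.0,
                                 low_quality_rate=0.0)
        gm = ss.simulate_genotypes(truth)
        return truth, gm

    def test_target_zero_gives_zero_betas(self):
        truth, gm = self._study()
        truth0 = ss.SimulationTruth.from_dict({**truth.to_dict(),
                                               "target_planted_r2": 0.0})
        cal = ss.calibrate_effect_sizes(truth0, gm)
        assert all(b == 0.0 for _, b in cal.planted_effects)

    def test_noise_scaling_identity(self):
        """Closed form: beta* = noise_sd * sqrt(t/(1-t)) / sd(planted term),
        so scaling noise_sd by s scales every calibrated beta by s."""
        truth, gm = self._study()
        cal1 = ss.calibrate_effect_sizes(truth, gm)
        truth2 = ss.SimulationTruth.from_dict(
            {**truth.to_dict(), "noise_sd": 2.0 * truth.noise_sd}
        )
        cal2 = ss.calibrate_effect_sizes(truth2, gm)
        for (l1, b1), (l2, b2) in zip(cal1.planted_effects, cal2.planted_effects):
            assert l1 == l2
            assert b2 == pytest.approx(2.0 * b1, abs=1e-10 * abs(b1))

    def test_single_locus_half_maf_closed_form(self):
        """One planted biallelic locus with exact HWE counts at MAF 0.5:
        Var(code) = 0.5 on the 1/2/3 scale, so a target of 0.5 forces
        beta^2 * Var(code) = noise_sd^2."""
        from conftest import gm_from_dosages, dosage_column

        gm = gm_from_dosages(dosage_column(100, 200, 100)[:, None])
        truth = SimulationTruth(
            n_subjects=400, n_male=0,
            loci_plan=[LocusPlan("L000", "1", 1000, 0.5, 0)],
            planted_effects=[("L000", 1.0)],
            target_planted_r2=0.5,
            noise_sd=100.0,
            seed=0,
        )
        cal = ss.calibrate_effect_sizes(truth, gm)
        beta = cal.planted_effects[0][1]
        assert beta**2 * 0.5 == pytest.approx(truth.noise_sd**2, rel=1e-10)

    def test_monomorphic_planted_errors(self):
        from conftest import gm_from_dosages

        gm = gm_from_dosages(np.zeros((50, 1), dtype=int))
        truth = SimulationTruth(
            n_subjects=50, n_male=0,
            loci_plan=[LocusPlan("L000", "1", 1000, 0.5, 0)],
            planted_effects=[("L000", 1.0)],
            target_planted_r2=0.1,
            seed=0,
        )
        with pytest.raises(ValueError, match="monomorphic"):
            ss.calibrate_effect_sizes(truth, gm)


def test_null_phenotype_uncorrelated_with_codes():
    """No planted effects: every locus coding is null against the
    covariate-residualized volume."""
    truth = ss.default_truth(target_planted_r2=0.0, seed=6, n_loci=30,
                             n_tight_blocks=0, missing_rate=0.0,
                             low_quality_rate=0.0)
    gm, pheno, _ = ss.simulate_study(truth)
    res = ss.residualize_volume(pheno, ks_monte_carlo=500)
    codes = ss.code_genotypes(gm, ss.minor_allele_index(gm)).codes
    n = gm.n_subjects
    for j in range(codes.shape[1]):
        c = codes[:, j]
        if np.nanstd(c) == 0:
            continue
        r = np.corrcoef(c, res.residuals)[0, 1]
        assert abs(r) < 3 / np.sqrt(n)


def test_zero_noise_no_effects_gives_zero_residuals():
    truth = ss.default_truth(target_planted_r2=0.0, seed=8, n_loci=10,
                             n_tight_blocks=0, noise_sd=0.0)
    gm, pheno, _ = ss.simulate_study(truth)
    res = ss.residualize_volume(pheno, ks_monte_carlo=0)
    # volume is an exact linear function of sex and ICV
    assert np.abs(res.residuals).max() < 1e-6


def test_planted_r2_converges_to_target():
    """Realized planted share of the covariate-residualized variance
    approaches the 8% target at large n (Monte Carlo calibration)."""
    import statsmodels.api as sm

    fractions = []
    for seed in range(8):
        truth = ss.default_truth(target_planted_r2=0.08, seed=100 + seed,
                                 n_loci=30, n_tight_blocks=0,
                                 missing_rate=0.0, low_quality_rate=0.0,
                                 n_subjects=5000, n_male=2400)
        gm, pheno, cal = ss.simulate_study(truth)
        res = ss.residualize_volume(pheno, ks_monte_carlo=0)
        planted_ids = [l for l, _ in cal.planted_effects]
        codes = ss.code_genotypes(gm, ss.minor_allele_index(gm))
        X = codes.columns(planted_ids)
        X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
        fit = sm.OLS(res.residuals, sm.add_constant(X)).fit()
        fractions.append(fit.rsquared)
    assert np.mean(fractions) == pytest.approx(0.08, abs=0.01)


def test_hwe_holds_by_construction():
    """Across simulated loci the HWE test flags at close to its nominal
    1% rate (binomial tolerance), and the designated violator is caught."""
    n_flagged, n_loci = 0, 0
    for seed in range(5):
        truth = ss.default_truth(target_planted_r2=0.0, seed=200 + seed,
                                 missing_rate=0.0, low_quality_rate=0.0)
        gm = ss.simulate_genotypes(truth)
        for j in range(gm.n_loci):
            chi2, p, flag = ss.hwe_chi_square(gm, j)
            if flag == "ok":
                n_loci += 1
                n_flagged += p < 0.01
    # 1% nominal; allow up to ~3x by binomial noise over ~500 loci
    assert n_flagged <= max(3, 3 * 0.01 * n_loci)

    truth = ss.default_truth(target_planted_r2=0.0, seed=300)
    truth = ss.SimulationTruth.from_dict(
        {**truth.to_dict(), "hwe_violator": "rs10050", "hwe_excess": 0.6}
    )
    gm = ss.simulate_genotypes(truth)
    chi2, p, flag = ss.hwe_chi_square(gm, gm.locus_index("rs10050"))
    assert flag == "ok" and p < 1e-6
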