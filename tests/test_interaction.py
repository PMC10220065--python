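"""PRS-by-stratum interaction test: summary form, individual oracle, per-variant test."""

import numpy as np
import pytest

import strataprs as sp
from strataprs.exceptions import ValidationError


def symmetric_stats(M=1, z=1.5, var=0.5, n=1000):
    """Stats with identical values in both strata (exact null)."""
    shape = (2, M)
    return sp.StratifiedSnpStats(
        snp_ids=[f"snp{t:05d}" for t in range(M)],
        effect_alleles=["A"] * M,
        other_alleles=["G"] * M,
        z_meandiff=np.full(shape, z),
        z_logistic=np.full(shape, z),
        var_case=np.full(shape, var),
        var_control=np.full(shape, var),
        n_case=np.array([n, n], dtype=float),
        n_control=np.array([n, n], dtype=float),
        eaf=np.full(shape, 0.3),
    )


def weights_for(stats_or_cohort, beta):
    return sp.PrsWeightSet(
        snp_ids=list(stats_or_cohort.snp_ids),
        effect_alleles=list(stats_or_cohort.effect_alleles),
        weights=np.asarray(beta, dtype=float),
    )


class TestSummaryForm:
    def test_identical_strata_give_null(self):
        stats = symmetric_stats()
        res = sp.interaction_test_summary(stats, weights_for(stats, [0.2]))
        assert res.Z == pytest.approx(0.0, abs=1e-14)
        assert res.p == pytest.approx(1.0)

    def test_z_equals_contribution_sum(self, null_cohort, null_weights):
        summ = sp.summarize_cohort(null_cohort, include_logistic=False)
        res = sp.interaction_test_summary(summ.stats, null_weights, z_source="meandiff")
        assert res.Z == pytest.approx(res.contributions.sum(), abs=1e-10)

    def test_weight_rescaling_invariance(self, null_cohort, small_panel):
        _, beta = small_panel
        summ = sp.summarize_cohort(null_cohort, include_logistic=False)
        r1 = sp.interaction_test_summary(
            summ.stats, weights_for(null_cohort, beta), z_source="meandiff")
        r2 = sp.interaction_test_summary(
            summ.stats, weights_for(null_cohort, 2.0 * beta), z_source="meandiff")
        assert r1.Z == pytest.approx(r2.Z, abs=1e-12)

    def test_snp_reordering_invariance(self, null_cohort, small_panel):
        _, beta = small_panel
        summ = sp.summarize_cohort(null_cohort, include_logistic=False)
        r1 = sp.interaction_test_summary(
            summ.stats, weights_for(null_cohort, beta), z_source="meandiff")
        rng = np.random.default_rng(0)
        perm = rng.permutation(null_cohort.M)
        s = summ.stats
        shuffled = sp.StratifiedSnpStats(
            snp_ids=[s.snp_ids[i] for i in perm],
            effect_alleles=[s.effect_alleles[i] for i in perm],
            other_alleles=[s.other_alleles[i] for i in perm],
            z_meandiff=s.z_meandiff[:, perm],
            var_case=s.var_case[:, perm],
            var_control=s.var_control[:, perm],
            n_case=s.n_case[:, perm],
            n_control=s.n_control[:, perm],
            eaf=s.eaf[:, perm],
        )
        r2 = sp.interaction_test_summary(
            shuffled, weights_for(null_cohort, beta), z_source="meandiff")
        assert r1.Z == pytest.approx(r2.Z, abs=1e-12)

    def test_all_zero_weights_error(self, null_cohort):
        summ = sp.summarize_cohort(null_cohort, include_logistic=False)
        with pytest.raises(ValidationError, match="zero"):
            sp.interaction_test_summary(
                summ.stats, weights_for(null_cohort, np.zeros(null_cohort.M)),
                z_source="meandiff")

    def test_missing_stratum_stats_error_and_drop(self, null_cohort, small_panel):
        _, beta = small_panel
        summ = sp.summarize_cohort(null_cohort, include_logistic=False)
        summ.stats.z_meandiff[1, 3] = np.nan
        w = weights_for(null_cohort, beta)
        with pytest.raises(ValidationError, match="undefined"):
            sp.interaction_test_summary(summ.stats, w, z_source="meandiff")
        res = sp.interaction_test_summary(summ.stats, w, z_source="meandiff",
                                          drop_missing=True)
        assert res.contributions.size == null_cohort.M - 1

    def test_hwe_variance_option(self, null_cohort, null_weights):
        summ = sp.summarize_cohort(null_cohort, include_logistic=False)
        res = sp.interaction_test_summary(summ.stats, null_weights,
                                          z_source="meandiff", variance_source="hwe")
        assert np.isfinite(res.Z)


class TestIndividualForm:
    def test_duplicated_stratum_is_null(self, small_panel):
        eafs, beta = small_panel
        cfg = sp.CohortConfig(M=25, eafs=eafs, beta_never=beta, beta_ever=beta,
                              n_cases_never=200, n_controls_never=200,
                              n_cases_ever=2, n_controls_ever=2, seed=1)
        c = sp.simulate_cohort(cfg)
        never = c.stratum == "never"
        dup = sp.IndividualCohort(
            genotypes=np.vstack([c.genotypes[never], c.genotypes[never]]),
            case_flag=np.concatenate([c.case_flag[never], c.case_flag[never]]),
            stratum=np.concatenate([np.full(never.sum(), "never"),
                                    np.full(never.sum(), "ever")]),
            snp_ids=c.snp_ids, effect_alleles=c.effect_alleles,
            other_alleles=c.other_alleles,
        )
        res = sp.interaction_test_individual(dup, weights_for(c, beta))
        assert res.Z == pytest.approx(0.0, abs=1e-12)

    def test_weight_doubling_invariance(self, null_cohort, small_panel):
        _, beta = small_panel
        r1 = sp.interaction_test_individual(null_cohort, weights_for(null_cohort, beta))
        r2 = sp.interaction_test_individual(null_cohort, weights_for(null_cohort, 2 * beta))
        assert r1.Z == pytest.approx(r2.Z, abs=1e-12)

    def test_missing_cell_error(self, null_cohort, null_weights):
        only_never = null_cohort.stratum == "never"
        c = sp.IndividualCohort(
            genotypes=null_cohort.genotypes[only_never],
            case_flag=null_cohort.case_flag[only_never],
            stratum=null_cohort.stratum[only_never],
            snp_ids=null_cohort.snp_ids,
            effect_alleles=null_cohort.effect_alleles,
            other_alleles=null_cohort.other_alleles,
        )
        with pytest.raises(ValidationError):
            sp.interaction_test_individual(c, null_weights)

    def test_permutation_null_unit_variance(self, null_cohort, null_weights):
        # shuffling stratum labels kills any interaction: Z should be ~N(0,1)
        rng = np.random.default_rng(8)
        zs = np.empty(1000)
        labels = null_cohort.stratum.copy()
        for i in range(1000):
            perm = sp.IndividualCohort(
                genotypes=null_cohort.genotypes,
                case_flag=null_cohort.case_flag,
                stratum=rng.permutation(labels),
                snp_ids=null_cohort.snp_ids,
                effect_alleles=null_cohort.effect_alleles,
                other_alleles=null_cohort.other_alleles,
            )
            zs[i] = sp.interaction_test_individual(perm, null_weights).Z
        assert 0.9 < zs.std(ddof=1) < 1.1


class TestEquivalence:
    def test_summary_equals_individual_with_meandiff(self, null_cohort, null_weights):
        summ = sp.summarize_cohort(null_cohort, include_logistic=False)
        rs = sp.interaction_test_summary(summ.stats, null_weights, z_source="meandiff")
        ri = sp.interaction_test_individual(null_cohort, null_weights)
        assert abs(rs.Z - ri.Z) < 1e-8
        assert np.allclose(rs.contributions, ri.contributions, atol=1e-10)

    def test_logistic_z_close_at_moderate_n(self, small_panel):
        eafs, beta = small_panel
        cfg = sp.CohortConfig(M=25, eafs=eafs, beta_never=beta, beta_ever=beta,
                              n_cases_never=2000, n_controls_never=2000,
                              n_cases_ever=2000, n_controls_ever=2000, seed=77)
        c = sp.simulate_cohort(cfg)
        summ = sp.summarize_cohort(c)
        w = weights_for(c, beta)
        z_lr = sp.interaction_test_summary(summ.stats, w, z_source="logistic").Z
        z_ind = sp.interaction_test_individual(c, w).Z
        assert abs(z_lr - z_ind) < 0.15


class TestPowerMonotone:
    def test_power_grows_with_effect_gap(self, small_panel):
        eafs, beta = small_panel
        mean_signal = []
        for gap in (0.0, 0.15, 0.3):
            zs = []
            for seed in range(30):
                cfg = sp.CohortConfig(
                    M=25, eafs=eafs, beta_never=beta + gap, beta_ever=beta,
                    n_cases_never=500, n_controls_never=500,
                    n_cases_ever=500, n_controls_ever=500, seed=1000 + seed)
                c = sp.simulate_cohort(cfg)
                summ = sp.summarize_cohort(c, include_logistic=False)
                zs.append(sp.interaction_test_summary(
                    summ.stats, weights_for(c, beta + gap), z_source="meandiff").Z)
            # stronger never-smoker effects push Z negative (ever minus never)
            mean_signal.append(-np.mean(zs))
        assert mean_signal[0] < mean_signal[1] < mean_signal[2]


class TestPerSnpInteraction:
    def rec(self, **kw):
        base = dict(snp_id="rs9", chrom="1", pos=5, effect_allele="A",
                    other_allele="G", eaf=0.4, beta=0.3, se=0.1,
                    n_cases=500, n_controls=500, stratum="never")
        base.update(kw)
        return sp.VariantRecord(**base)

    def test_identical_records(self):
        z, p = sp.per_snp_interaction(self.rec(), self.rec(stratum="ever"))
        assert z == 0.0
        assert p == 1.0

    def test_hand_computed_example(self):
        z, p = sp.per_snp_interaction(
            self.rec(beta=0.3, se=0.1),
            self.rec(beta=0.0, se=0.1, stratum="ever"),
        )
        assert z == pytest.approx(2.1213, abs=1e-4)
        assert p == pytest.approx(0.0339, abs=1e-4)

    def test_allele_flip_harmonised(self):
        plain = sp.per_snp_interaction(
            self.rec(beta=0.3), self.rec(beta=0.1, stratum="ever"))
        flipped = sp.per_snp_interaction(
            self.rec(beta=0.3),
            self.rec(beta=-0.1, eaf=0.6, effect_allele="G", other_allele="A",
                     stratum="ever"),
        )
        assert plain == pytest.approx(flipped)
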