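"""Cohort generator: states, dosage model, count sampling, follow-up cascade."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from niptscreen.nipt_caller import CallItem, NIPTCall
from niptscreen.synthetic_cohort import (
    RAA_CHROM_POOL,
    CohortConfig,
    ConfigError,
    FollowupConfig,
    KaryotypeState,
    draw_fetal_fractions,
    expected_proportions,
    sample_cohort,
    simulate_counts,
    simulate_followup,
)

DEPTH = 8_000_000


def quiet_config(**overrides) -> CohortConfig:
    zeros = dict(
        prev_t21=0, prev_t18=0, prev_t13=0, prev_sca=0, prev_raa=0, prev_cnv=0,
        cpm_fp_rate=0.0, cpm_fn_rate=0.0,
    )
    zeros.update(overrides)
    return CohortConfig(**zeros)


class TestKaryotypeState:
    @pytest.mark.parametrize(
        "state",
        [
            KaryotypeState.euploid(),
            KaryotypeState("T21"),
            KaryotypeState("XO", mosaic_fraction=0.35),
            KaryotypeState("RAA", raa_chrom="chr16", raa_kind="trisomy", mosaic_fraction=0.42),
            KaryotypeState("CNV", cnv_segment=("chr16", 1_000_000, 3_000_000, 1)),
        ],
    )
    def test_string_codes_round_trip(self, state):
        assert KaryotypeState.from_string(state.to_string()) == state

    def test_invalid_states_rejected(self):
        with pytest.raises(ValueError):
            KaryotypeState("RAA")  # missing chromosome
        with pytest.raises(ValueError):
            KaryotypeState("CNV", cnv_segment=("chr1", 5_000_000, 1_000_000, 1))
        with pytest.raises(ValueError):
            KaryotypeState("T21", mosaic_fraction=0.0)


class TestSampleCohort:
    def test_zero_prevalence_gives_concordant_euploid_cohort(self):
        cases = sample_cohort(quiet_config(), 500, seed=1)
        assert all(c.fetal_state == KaryotypeState.euploid() for c in cases)
        assert all(c.placental_state == c.fetal_state for c in cases)

    def test_same_seed_reproduces_cohort_bitwise(self, config):
        a = sample_cohort(config, 400, seed=99)
        b = sample_cohort(config, 400, seed=99)
        assert a == b

    def test_nonpositive_n_rejected(self, config):
        with pytest.raises(ValueError):
            sample_cohort(config, 0, seed=1)

    def test_prevalences_summing_to_one_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(prev_sca=0.999, prev_raa=0.01)

    def test_abnormal_count_in_exact_binomial_interval(self, config):
        """Binomial oracle at the full cohort size: the number of abnormal
        fetuses must fall in the exact central 99% interval of
        Binomial(n, total prevalence)."""
        n = 60_193
        cases = sample_cohort(config, n, seed=2026)
        abnormal = sum(c.fetal_state.is_abnormal for c in cases)
        lo = stats.binom.ppf(0.005, n, config.total_prevalence)
        hi = stats.binom.ppf(0.995, n, config.total_prevalence)
        assert lo <= abnormal <= hi

    def test_demographics_and_ff_within_documented_ranges(self, config):
        cases = sample_cohort(config, 3000, seed=7)
        ages = np.array([c.maternal_age for c in cases])
        gests = np.array([c.gestational_age for c in cases])
        ffs = np.array([c.fetal_fraction for c in cases])
        assert ages.min() >= 18 and ages.max() <= 34
        assert gests.min() >= 11 and gests.max() <= 23
        assert ffs.min() > 0.005 and ffs.max() < 0.40
        assert abs(ages.mean() - 29.6) < 0.3
        assert abs(gests.mean() - 15.4) < 0.2

    def test_forced_sex_and_raa_pool(self):
        config = quiet_config(prev_sca=0.25, prev_raa=0.25)
        cases = sample_cohort(config, 2000, seed=3)
        for c in cases:
            forced = c.fetal_state.forced_sex
            if forced:
                assert c.fetal_sex == forced
            if c.fetal_state.category == "RAA":
                assert c.fetal_state.raa_chrom in RAA_CHROM_POOL

    def test_discordance_only_through_cpm_channels(self):
        config = quiet_config(prev_t21=0.05, prev_sca=0.05, prev_raa=0.05)
        cases = sample_cohort(config, 2000, seed=11)
        assert all(c.placental_state == c.fetal_state for c in cases)

    def test_ff_band_and_redraw_frequency(self, config):
        """~85% of FF mass in the 5-16% band, and the QC redraw fraction
        stays below 2% (the emulated programme observed 0.67%)."""
        rng = np.random.default_rng(13)
        ffs = draw_fetal_fractions(config, 20_000, rng)
        band = ((ffs >= 0.05) & (ffs <= 0.16)).mean()
        assert 0.82 < band < 0.88
        assert (ffs < config.qc_ff_threshold).mean() < 0.02


class TestExpectedProportions:
    def _enumeration_oracle(self, baseline, fetal_copies, ff):
        """Genome-dosage enumeration: maternal 2 copies of everything plus a
        fetal genome with explicit copy numbers, weighted (1-ff)/ff, then
        normalized once."""
        f = baseline.chrom_female
        per_copy = f / 2.0
        w = (1 - ff) * f + ff * per_copy * fetal_copies
        w[baseline.y_index] = f[baseline.y_index] + ff * fetal_copies[
            baseline.y_index
        ] * baseline.chry_single_copy_weight
        return w / w.sum()

    def test_euploid_female_is_identity(self, baseline):
        out = expected_proportions(KaryotypeState.euploid(), 0.12, baseline, "female")
        np.testing.assert_allclose(out, baseline.chrom_female, rtol=0, atol=1e-15)

    def test_t21_matches_enumeration_oracle(self, cmap, baseline):
        ff = 0.10
        out = expected_proportions(KaryotypeState("T21"), ff, baseline, "female")
        copies = np.full(24, 2.0)
        copies[cmap.chrom_index["chr21"]] = 3.0
        copies[baseline.y_index] = 0.0
        oracle = self._enumeration_oracle(baseline, copies, ff)
        np.testing.assert_allclose(out, oracle, rtol=1e-12)
        # closed form for the affected chromosome
        p21 = baseline.chrom_female[cmap.chrom_index["chr21"]]
        assert out[cmap.chrom_index["chr21"]] == pytest.approx(
            p21 * 1.05 / (1 + p21 * 0.05), rel=1e-12
        )

    def test_xo_depresses_chrx_and_matches_oracle(self, cmap, baseline):
        ff = 0.10
        out = expected_proportions(KaryotypeState("XO"), ff, baseline, "female")
        xi = baseline.x_index
        assert out[xi] < baseline.chrom_female[xi]
        copies = np.full(24, 2.0)
        copies[xi] = 1.0
        copies[baseline.y_index] = 0.0
        oracle = self._enumeration_oracle(baseline, copies, ff)
        np.testing.assert_allclose(out, oracle, rtol=1e-12)

    def test_bin_level_aggregates_to_chromosome_level(self, cmap, baseline):
        state = KaryotypeState("CNV", cnv_segment=("chr4", 30_000_000, 40_000_000, 1))
        chrom = expected_proportions(state, 0.12, baseline, "female", level="chrom")
        bins = expected_proportions(state, 0.12, baseline, "female", level="bin")
        summed = np.bincount(cmap.bin_chroms, weights=bins, minlength=24)
        np.testing.assert_allclose(summed, chrom, rtol=1e-12)

    def test_ff_out_of_range_rejected(self, baseline):
        with pytest.raises(ValueError):
            expected_proportions(KaryotypeState.euploid(), 1.0, baseline, "female")

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        ff=st.floats(0.02, 0.3),
        m=st.floats(0.1, 1.0),
        kind=st.sampled_from(["trisomy", "monosomy"]),
    )
    def test_dosage_monotone_in_ff_and_mosaic(self, baseline, ff, m, kind):
        """Trisomy raises (monosomy lowers) the affected chromosome's expected
        proportion strictly monotonically in both FF and mosaic fraction."""
        cmap = baseline.cmap
        ci = cmap.chrom_index["chr16"]

        def prop(ff_, m_):
            state = KaryotypeState("RAA", raa_chrom="chr16", raa_kind=kind, mosaic_fraction=m_)
            return expected_proportions(state, ff_, baseline, "female")[ci]

        base = prop(ff, m)
        sign = 1 if kind == "trisomy" else -1
        assert sign * (prop(ff + 0.05, m) - base) > 0
        if m <= 0.9:
            assert sign * (prop(ff, m + 0.1) - base) > 0


class TestSimulateCounts:
    def test_counts_conserve_totals(self, cmap, baseline):
        exp = expected_proportions(KaryotypeState.euploid(), 0.1, baseline, "male")
        profile = simulate_counts(exp, 100_000, 3, cmap)
        profile.validate(cmap)
        assert profile.total == 100_000
        bexp = expected_proportions(KaryotypeState.euploid(), 0.1, baseline, "male", level="bin")
        bprofile = simulate_counts(bexp, 100_000, 3, cmap)
        bprofile.validate(cmap)  # bin sums equal chromosome counts

    def test_zero_reads_rejected(self, cmap, baseline):
        with pytest.raises(ValueError):
            simulate_counts(baseline.chrom_female, 0, 3, cmap)

    def test_unnormalized_vector_rejected(self, cmap, baseline):
        with pytest.raises(ValueError):
            simulate_counts(baseline.chrom_female * 1.01, 100, 3, cmap)

    def test_chr21_mean_matches_clt_oracle(self, cmap, baseline):
        """10,000 euploid draws at 8e6 reads: the empirical chr21 proportion
        mean lies within 4 standard errors of the baseline (CLT oracle)."""
        rng = np.random.default_rng(17)
        p = baseline.chrom_female
        counts = rng.multinomial(DEPTH, p, size=10_000)
        i21 = cmap.chrom_index["chr21"]
        se = np.sqrt(p[i21] * (1 - p[i21]) / DEPTH) / np.sqrt(10_000)
        assert abs(counts[:, i21].mean() / DEPTH - p[i21]) < 4 * se


class TestFollowup:
    def _tp_call(self, category="T21", chrom="chr21"):
        return NIPTCall(result="positive", calls=(CallItem(category, chrom=chrom),))

    def _case(self, state):
        from niptscreen.synthetic_cohort import SimulatedCase

        return SimulatedCase(
            case_id="c1", maternal_age=30, gestational_age=15, fetal_sex="female",
            fetal_state=state, placental_state=state, fetal_fraction=0.1,
        )

    def test_confirmed_common_trisomy_always_terminates_at_rate_one(self):
        rates = FollowupConfig(uptake=1.0)
        case = self._case(KaryotypeState("T21"))
        rng = np.random.default_rng(4)
        for _ in range(50):
            rec = simulate_followup(self._tp_call(), case, rates, rng)
            assert rec.confirmed == "true_positive"
            assert rec.outcome == "termination"

    def test_zero_uptake_refuses_everything(self):
        rates = FollowupConfig(uptake=0.0, refuse_postnatal_test=0.0)
        case = self._case(KaryotypeState("T21"))
        rng = np.random.default_rng(4)
        recs = [simulate_followup(self._tp_call(), case, rates, rng) for _ in range(50)]
        assert all(r.amniocentesis == "refused" for r in recs)
        assert all(r.confirmed == "not_applicable" for r in recs)

    def test_negative_call_is_unconfirmed_livebirth(self):
        rec = simulate_followup(
            NIPTCall(result="negative"), self._case(KaryotypeState.euploid()),
            FollowupConfig(), 1,
        )
        assert rec == type(rec)("c1", "not_applicable", "not_applicable", "livebirth")

    def test_sca_termination_rate_matches_binomial_oracle(self):
        """10,000 confirmed-TP SCA records: termination frequency within the
        exact central 99% binomial interval of the configured 0.7807."""
        rates = FollowupConfig(uptake=1.0)
        case = self._case(KaryotypeState("XO"))
        call = self._tp_call("XO", "chrX")
        rng = np.random.default_rng(21)
        n = 10_000
        terms = sum(
            simulate_followup(call, case, rates, rng).outcome == "termination"
            for _ in range(n)
        )
        assert stats.binom.ppf(0.005, n, 0.7807) <= terms <= stats.binom.ppf(0.995, n, 0.7807)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ConfigError):
            FollowupConfig(uptake=1.2)
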