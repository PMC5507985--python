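"""Synthetic-data generator: decay models, signal rules, determinism."""

import numpy as np
import pytest
from scipy import stats as sps

from mirdegrade.model import ValidationError
from mirdegrade.simulate import (
    DecayModel,
    SimConfig,
    default_decay_models,
    draw_truth,
    simulate_control_experiment,
    simulate_rin,
    simulate_timecourse,
)


class TestSimulateRin:
    def test_intact_at_harvest_for_every_shape(self):
        models = [
            DecayModel("liver", "RT", "hyperbolic", {"tau": 3.0}, 0.0),
            DecayModel("brain", "RT", "linear", {"slope": 0.075}, 0.0),
            DecayModel("heart", "RT", "two_phase",
                       {"plateau_h": 24.0, "slope": 0.1}, 0.0),
        ]
        for m in models:
            assert simulate_rin(m, 0) == 10.0

    def test_liver_rt_hyperbolic_reaches_rin_4_at_6_hours(self):
        m = DecayModel("liver", "RT", "hyperbolic", {"tau": 3.0}, 0.0)
        assert simulate_rin(m, 6) == pytest.approx(4.0)

    def test_brain_4c_stays_above_7_at_96_hours(self):
        m = default_decay_models(noise_sd=0.0)[("brain", "4C")]
        assert simulate_rin(m, 96) > 7.0

    def test_negative_time_rejected(self):
        m = default_decay_models(0.0)[("liver", "RT")]
        with pytest.raises(ValidationError):
            simulate_rin(m, -1)

    def test_noise_free_rin_non_increasing_in_time(self):
        for model in default_decay_models(noise_sd=0.0).values():
            rins = [model.predict(t) for t in np.linspace(0, 96, 40)]
            assert all(b <= a + 1e-12 for a, b in zip(rins, rins[1:]))

    def test_clamped_to_valid_range(self):
        m = DecayModel("liver", "4C", "linear", {"slope": 1.0}, 0.0)
        assert simulate_rin(m, 96) == 1.0


class TestTruthDraw:
    def test_effect_signs_by_class(self, default_study):
        for t in default_study.truth:
            if t.klass == "resilient":
                assert t.effect_log2 == 0
            elif t.klass == "sensitive":
                assert t.effect_log2 < 0
            else:
                assert t.effect_log2 > 0

    def test_empty_simulation_rejected(self):
        with pytest.raises(ValidationError):
            SimConfig(n_resilient=0, n_sensitive=0, n_artifact=0,
                      n_dna_background=0)

    def test_artifact_sequences_are_transcript_substrings(self):
        truth, annotation, transcripts = draw_truth(SimConfig(seed=3))
        ann = {a.mirna_id: a for a in annotation}
        artifacts = [t for t in truth if t.klass == "artifact"][:25]
        for t in artifacts:
            seq = ann[t.mirna_id].mature_sequence
            assert any(seq in tx for tx in transcripts.values())

    def test_version_mixture_recent_bias_for_artifacts(self, default_study):
        versions = {k: [] for k in ("artifact", "sensitive", "resilient")}
        for t in default_study.truth:
            if t.klass in versions:
                versions[t.klass].append(t.first_version)
        assert np.median(versions["artifact"]) >= 16
        assert np.median(versions["sensitive"]) <= 9
        assert np.median(versions["resilient"]) <= 9


class TestTimecourse:
    def test_design_has_48_samples(self, default_study):
        assert default_study.timecourse.n_samples == 48
        assert len(default_study.timecourse_meta) == 48

    def test_noise_free_resilient_is_constant(self, noise_free_study):
        tc, truth = noise_free_study.timecourse, noise_free_study.truth
        for t in truth:
            if t.klass == "resilient":
                row = tc.values.loc[t.mirna_id].to_numpy()
                assert np.allclose(row, row[0])

    def test_noise_free_signal_is_exact_function_of_design(self, noise_free_study):
        tc = noise_free_study.timecourse
        meta = {m.sample_id: m for m in noise_free_study.timecourse_meta}
        for t in noise_free_study.truth[::5]:
            for sid in tc.sample_ids[::7]:
                d = (10.0 - meta[sid].rin) / 9.0
                expected = t.baseline_log2 + t.effect_log2 * d
                assert np.log2(tc.values.loc[t.mirna_id, sid]) == pytest.approx(
                    expected, abs=1e-9
                )

    def test_effect_recovered_between_extreme_rin(self):
        # noise-free artifact with a +2 effect differs by exactly 2 log2 units
        # between a fully intact (RIN 10) and fully degraded (RIN 1) sample
        sim = SimConfig(n_resilient=1, n_sensitive=1, n_artifact=1,
                        n_dna_background=1,
                        effect_artifact=(2.0, 2.0),
                        noise_sd_log2=0.0, rin_noise_sd=0.0, seed=0)
        models = {
            (tissue, temp): DecayModel(tissue, temp, "linear",
                                       {"slope": 9.0 / 96.0}, 0.0)
            for tissue in ("liver", "heart", "brain")
            for temp in ("4C", "RT")
        }
        tc, meta, _, truth = simulate_timecourse(sim, models)
        art = next(t for t in truth if t.klass == "artifact")
        by_id = {m.sample_id: m for m in meta}
        intact = next(s for s in tc.sample_ids if by_id[s].rin == 10.0)
        degraded = next(s for s in tc.sample_ids if by_id[s].rin == 1.0)
        diff = np.log2(tc.values.loc[art.mirna_id, degraded]) - np.log2(
            tc.values.loc[art.mirna_id, intact]
        )
        assert diff == pytest.approx(2.0, abs=1e-9)

    def test_class_sign_of_rin_correlation(self, default_study):
        """Sensitive miRNAs correlate positively with RIN, artifacts
        negatively, for at least 95% of miRNAs of those classes."""
        tc = default_study.timecourse
        rin = np.array([m.rin for m in default_study.timecourse_meta])
        logx = np.log2(tc.values.to_numpy())
        ok = {"sensitive": [], "artifact": []}
        for i, t in enumerate(default_study.truth):
            if t.klass not in ok:
                continue
            r = sps.pearsonr(logx[i], rin).statistic
            ok[t.klass].append(r > 0 if t.klass == "sensitive" else r < 0)
        assert np.mean(ok["sensitive"]) >= 0.95
        assert np.mean(ok["artifact"]) >= 0.95

    def test_artifact_signal_monotone_in_degradation_index(self, noise_free_study):
        tc = noise_free_study.timecourse
        meta = noise_free_study.timecourse_meta
        d = np.array([(10 - m.rin) / 9 for m in meta])
        order = np.argsort(d)
        for t in noise_free_study.truth:
            row = np.log2(tc.values.loc[t.mirna_id].to_numpy())[order]
            diffs = np.diff(row)
            if t.klass == "artifact":
                assert (diffs >= -1e-9).all()
            elif t.klass == "sensitive":
                assert (diffs <= 1e-9).all()

    def test_seed_reproducibility_bit_identical(self):
        sim = SimConfig(n_resilient=5, n_sensitive=5, n_artifact=5,
                        n_dna_background=5, seed=11)
        a = simulate_timecourse(sim)
        b = simulate_timecourse(sim)
        assert a[0].values.equals(b[0].values)
        assert a[0].detected.equals(b[0].detected)
        assert a[1] == b[1] and a[3] == b[3]


class TestControlExperiment:
    def test_design_has_24_samples_in_8_conditions(self, default_study):
        meta = default_study.control_meta
        assert len(meta) == 24
        conditions = {
            (m.time_h, m.rna_fraction, m.dnase, m.rnase_units) for m in meta
        }
        assert len(conditions) == 8

    def test_artifact_detected_at_full_rnase_dose(self, noise_free_study):
        ctl = noise_free_study.control
        meta = noise_free_study.control_meta
        high = [m.sample_id for m in meta
                if m.rna_fraction == "depleted" and (m.rnase_units or 0) > 0.1]
        for t in noise_free_study.truth:
            if t.klass != "artifact":
                continue
            for sid in high:
                assert np.log2(ctl.values.loc[t.mirna_id, sid]) == pytest.approx(
                    t.baseline_log2 + t.effect_log2, abs=1e-9
                )
                assert ctl.detected.loc[t.mirna_id, sid]

    def test_sensitive_not_detected_in_depleted_arms(self, noise_free_study):
        ctl = noise_free_study.control
        meta = noise_free_study.control_meta
        depleted = [m.sample_id for m in meta if m.rna_fraction == "depleted"]
        for t in noise_free_study.truth:
            if t.klass == "sensitive":
                assert not ctl.detected.loc[t.mirna_id, depleted].any()

    def test_dnase_contrast_equals_effect_for_dna_background(self, noise_free_study):
        ctl = noise_free_study.control
        meta = noise_free_study.control_meta
        deg = lambda m: m.rna_fraction == "with_small_rna" and m.time_h > 0
        no_dnase = [m.sample_id for m in meta if deg(m) and m.dnase == "no"]
        with_dnase = [m.sample_id for m in meta if deg(m) and m.dnase == "yes"]
        for t in noise_free_study.truth:
            if t.klass != "dna_background":
                continue
            diff = np.log2(ctl.values.loc[t.mirna_id, no_dnase]).mean() - np.log2(
                ctl.values.loc[t.mirna_id, with_dnase]
            ).mean()
            assert diff == pytest.approx(t.effect_log2, abs=1e-9)

    def test_detected_count_rises_with_degradation(self, default_study):
        """Degraded samples detect more probes than intact ones (the
        cross-hybridization influx), and RNase-fragmented depleted RNA
        detects more than intact depleted RNA."""
        ctl = default_study.control
        meta = default_study.control_meta
        counts = ctl.detected.sum(axis=0)

        def mean_count(pred):
            return np.mean([counts[m.sample_id] for m in meta if pred(m)])

        ws = lambda m: m.rna_fraction == "with_small_rna"
        assert mean_count(lambda m: ws(m) and m.time_h > 0) > mean_count(
            lambda m: ws(m) and m.time_h == 0
        )
        assert mean_count(
            lambda m: m.rna_fraction == "depleted" and (m.rnase_units or 0) > 0
        ) > mean_count(
            lambda m: m.rna_fraction == "depleted" and (m.rnase_units or 0) == 0
        )

    def test_seed_reproducibility(self):
        sim = SimConfig(n_resilient=5, n_sensitive=5, n_artifact=5,
                        n_dna_background=5, seed=13)
        a = simulate_control_experiment(sim)
        b = simulate_control_experiment(sim)
        assert a[0].values.equals(b[0].values)
        assert a[1] == b[1]

    def test_shared_truth_with_timecourse(self):
        sim = SimConfig(n_resilient=3, n_sensitive=3, n_artifact=3,
                        n_dna_background=3, seed=5)
        _, _, _, truth_tc = simulate_timecourse(sim)
        _, _, truth_ctl = simulate_control_experiment(sim)
        assert truth_tc == truth_ctl
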