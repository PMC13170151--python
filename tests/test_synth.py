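"""Synthetic cohort generator: determinism, planted effects, manifest."""

import numpy as np
import pytest

from mseeg.preprocess import common_average, extract_clean_segment, filter_chain
from mseeg.spectral import peak_alpha_frequency, welch_psd
from mseeg.asymmetry import subject_dirbsi
from mseeg.montage import roi_signal
from mseeg.synth import (CohortConfig, EffectError, EffectSpec,
                         default_effects, draw_subject_params,
                         generate_cohort, generate_subject, inject_artifacts,
                         sample_features)


@pytest.fixture(scope="module")
def small_config():
    return CohortConfig(group_sizes={"HC": 2, "P1": 2}, seed=7)


class TestEffectSpecValidation:
    def test_unreachable_coherence_rejected(self):
        with pytest.raises(EffectError, match="unreachable"):
            EffectSpec(group="HC", coherence={("F", "AM", "theta"): (1.0, 0.0)})

    def test_paf_outside_alpha_rejected(self):
        with pytest.raises(EffectError, match="alpha band"):
            EffectSpec(group="HC", paf_mean_hz=14.0)

    def test_dirbsi_outside_range_rejected(self):
        with pytest.raises(EffectError):
            EffectSpec(group="HC", dirbsi={"theta": (1.5, 0.0)})

    def test_config_validation(self):
        with pytest.raises(EffectError):
            CohortConfig(fs=100)
        with pytest.raises(EffectError):
            CohortConfig(duration_s=30)
        with pytest.raises(EffectError):
            CohortConfig(group_sizes={"HC": 1})


class TestGenerateSubject:
    def test_same_seed_bit_identical(self, geodesic, small_config):
        eff = default_effects()["HC"]
        a = generate_subject(small_config, eff, 123, geodesic)
        b = generate_subject(small_config, eff, 123, geodesic)
        assert np.array_equal(a.data, b.data)

    def test_noiseless_single_oscillator_gives_exact_paf(self, geodesic):
        cfg = CohortConfig(group_sizes={"HC": 2}, seed=0, noise_amp=0.0)
        eff = EffectSpec(group="HC", paf_mean_hz=10.0, paf_sd_hz=0.0,
                         roi_band_power_db={("AM", "alpha"): (-10.0, 0.0)})
        rec = generate_subject(cfg, eff, 5, geodesic)
        seg = common_average(extract_clean_segment(filter_chain(rec)))
        series = roi_signal(seg.data, list(seg.channels), geodesic, "AM")
        res = peak_alpha_frequency(welch_psd(series, rec.fs))
        assert res.paf_hz == pytest.approx(10.0, abs=1e-9)

    def test_noiseless_planted_asymmetry_recovered(self, geodesic):
        """dirBSI planted at 1/3 (right:left power 2:1) recovers exactly-ish."""
        cfg = CohortConfig(group_sizes={"HC": 2}, seed=0, noise_amp=0.0)
        eff = EffectSpec(
            group="HC", paf_mean_hz=10.0, paf_sd_hz=0.0,
            roi_band_power_db={(r, b): (-10.0, 0.0)
                               for r in ("F", "AM", "C", "UM", "P", "O")
                               for b in ("theta", "alpha", "beta1")},
            dirbsi={b: (1 / 3, 0.0) for b in ("theta", "alpha", "beta1")},
        )
        rec = generate_subject(cfg, eff, 11, geodesic)
        seg = common_average(extract_clean_segment(filter_chain(rec)))
        bsi = subject_dirbsi(seg.data, list(seg.channels), geodesic, rec.fs)
        for band in ("theta", "alpha", "beta1"):
            assert bsi[band] == pytest.approx(1 / 3, abs=0.05)

    def test_left_lesion_mirrored_channels(self, geodesic, small_config):
        eff = default_effects()["P1"]
        canon = generate_subject(small_config, eff, 321, geodesic, "right")
        mirrored = generate_subject(small_config, eff, 321, geodesic, "left")
        perm = geodesic.flip_permutation()
        assert np.array_equal(mirrored.data[perm], canon.data)


class TestGenerateCohort:
    def test_default_sizes(self, geodesic):
        cfg = CohortConfig(seed=1)
        # sizes only; generating 79 subjects here would be wasteful
        assert sum(cfg.group_sizes.values()) == 79
        assert cfg.group_sizes == {"HC": 22, "P1": 22, "P2": 18, "P3": 17}

    def test_small_cohort_manifest(self, geodesic):
        cfg = CohortConfig(group_sizes={"HC": 2, "P1": 4, "P2": 0, "P3": 2}, seed=3)
        recs, manifest = generate_cohort(cfg, default_effects(), geodesic)
        assert len(recs) == 8
        assert set(manifest.group) == {"HC", "P1", "P3"}
        assert list(manifest.columns[:3]) == ["subject_id", "group", "lesion_side"]
        assert (manifest.loc[manifest.group == "HC", "lesion_side"] == "none").all()
        # lesion_side_mix = 0.5 over 4 P1 patients -> 2 left
        assert (manifest.loc[manifest.group == "P1", "lesion_side"] == "left").sum() == 2
        assert manifest.loc[manifest.group != "HC", "FMA"].notna().all()
        assert manifest.loc[manifest.group == "HC", "FMA"].isna().all()

    def test_cohort_deterministic(self, geodesic):
        cfg = CohortConfig(group_sizes={"HC": 2, "P1": 2}, seed=9)
        a, ma = generate_cohort(cfg, default_effects(), geodesic)
        b, mb = generate_cohort(cfg, default_effects(), geodesic)
        assert all(np.array_equal(x.data, y.data) for x, y in zip(a, b))
        assert ma.equals(mb)


class TestInjectArtifacts:
    def test_zero_spikes_identity(self, geodesic, small_config):
        rec = generate_subject(small_config, default_effects()["HC"], 2, geodesic)
        out = inject_artifacts(rec, 150.0, [])
        assert np.array_equal(out.data, rec.data)

    def test_spike_above_threshold_excludes_window(self, geodesic):
        cfg = CohortConfig(group_sizes={"HC": 2}, seed=7, duration_s=100.0)
        rec = generate_subject(cfg, default_effects()["HC"], 2, geodesic)
        out = inject_artifacts(rec, 150.0, [5.0])
        seg = extract_clean_segment(filter_chain(out))
        assert 2 not in seg.provenance["source_windows"]
        assert np.max(np.abs(seg.data)) <= 100.0

    def test_spike_below_threshold_retained(self, geodesic):
        cfg = CohortConfig(group_sizes={"HC": 2}, seed=7, duration_s=100.0)
        rec = generate_subject(cfg, default_effects()["HC"], 2, geodesic)
        out = inject_artifacts(rec, 80.0, [5.0])  # filtered peak stays under 100
        seg = extract_clean_segment(filter_chain(out))
        assert 2 in seg.provenance["source_windows"]

    def test_spike_outside_duration_rejected(self, geodesic, small_config):
        rec = generate_subject(small_config, default_effects()["HC"], 2, geodesic)
        with pytest.raises(EffectError):
            inject_artifacts(rec, 150.0, [1000.0])


class TestFeatureDraws:
    def test_marginal_distributions_match_targets(self):
        eff = default_effects()["HC"]
        rng = np.random.default_rng(0)
        draws = [draw_subject_params(eff, rng) for _ in range(4000)]
        alpha_am = np.array([d["power_db"][("AM", "alpha")] for d in draws])
        assert np.mean(alpha_am) == pytest.approx(-14.89, abs=0.4)
        # draws are clipped (global +-2 sd, residual +-2.5 sd), which
        # shrinks the marginal sd to ~0.96 of the nominal target
        from scipy import stats as sps

        def tvar(c):  # variance of a winsorized standard normal
            inside = (2 * sps.norm.cdf(c) - 1) - 2 * c * sps.norm.pdf(c)
            return inside + 2 * c**2 * sps.norm.sf(c)

        expected_sd = 7.88 * np.sqrt(0.95**2 * tvar(2.0) + (1 - 0.95**2) * tvar(2.5))
        assert np.std(alpha_am) == pytest.approx(expected_sd, rel=0.05)
        theta_bsi = np.array([d["dirbsi"]["theta"] for d in draws])
        assert np.mean(theta_bsi) == pytest.approx(-0.026, abs=0.01)

    def test_sample_features_shape_and_groups(self):
        df = sample_features({"HC": 5, "P1": 4}, seed=1)
        assert len(df) == 9
        assert {"psd:AM:alpha", "dirbsi:theta", "fc:F-AM:theta", "paf:AM"} <= set(df.columns)
        assert df.group.value_counts().to_dict() == {"HC": 5, "P1": 4}

    def test_behavior_scores_within_scale_ranges(self):
        df = sample_features({"P1": 50}, seed=2)
        assert df.MMT.between(0, 5).all()
        assert df.FMA.between(0, 66).all()
        assert df.MMSE.between(0, 30).all()
        assert df.ADL.between(0, 100).all()
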