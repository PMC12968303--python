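"""Preprocessing-chain contracts, checked against quadrature oracles and
the generator's planted ground truth."""

import warnings

import numpy as np
import pandas as pd
import pytest

from breathvoc import chrom as ch
from breathvoc.synth import ChromSpec, make_chromatogram

from conftest import window_area


def apex_frame(entries):
    """Build a detect_peaks-style frame from (rt, height, sigma, index)."""
    return pd.DataFrame(
        [dict(rt=r, height=h, sigma_est=s, index=i) for r, h, s, i in entries]
    )


class TestRemoveSpikes:
    def test_smooth_trace_unchanged(self, clean_peak, cfg):
        chrom, _ = clean_peak
        out = ch.remove_spikes(chrom, cfg)
        assert np.array_equal(out.intensity, chrom.intensity)

    def test_planted_impulse_removed(self, cfg):
        noise = 1.0
        spec = ChromSpec(
            duration_s=200, sampling_hz=5, peaks=((100, 80, 2.0),),
            noise_sd=noise, seed=21,
        )
        chrom, _ = make_chromatogram(spec)
        clean = chrom.intensity.copy()
        spiked = clean.copy()
        spiked[700] += 50 * noise  # off-peak grid point (t = 140 s)
        out = ch.remove_spikes(chrom.with_intensity(spiked), cfg)
        assert np.max(np.abs(out.intensity - clean)) < 5 * noise

    def test_impulse_at_first_point_edge_truncated(self, cfg):
        y = np.zeros(50)
        y[0] = 100.0
        chrom = ch.Chromatogram(time_s=np.arange(50) * 0.2, intensity=y)
        out = ch.remove_spikes(chrom, cfg)
        assert out.intensity[0] == 0.0

    def test_short_trace_rejected(self, cfg):
        chrom = ch.Chromatogram(time_s=np.arange(5) * 0.2, intensity=np.zeros(5))
        with pytest.raises(ValueError, match="shorter"):
            ch.remove_spikes(chrom, cfg)


class TestCorrectBaseline:
    def test_constant_offset_removed(self, cfg):
        spec = ChromSpec(duration_s=300, sampling_hz=5, baseline=(500.0, 0, 0))
        chrom, _ = make_chromatogram(spec)
        out = ch.correct_baseline(chrom, cfg)
        assert np.max(np.abs(out.intensity)) < 1e-3

    def test_linear_drift_preserves_peak_area(self, cfg):
        spec = ChromSpec(
            duration_s=900, sampling_hz=5, peaks=((450, 100.0, 2.0),),
            baseline=(0.0, 200.0 / 900.0, 0.0),
        )
        chrom, _ = make_chromatogram(spec)
        out = ch.correct_baseline(chrom, cfg)
        assert window_area(out, 450, 30) == pytest.approx(100.0, rel=0.02)

    def test_near_idempotent_on_baseline_free_trace(self, cfg):
        spec = ChromSpec(duration_s=900, sampling_hz=5, peaks=((450, 100.0, 2.0),))
        chrom, _ = make_chromatogram(spec)
        before = window_area(chrom, 450, 30)
        after = window_area(ch.correct_baseline(chrom, cfg), 450, 30)
        assert abs(after - before) / before < 0.01

    def test_nonfinite_rejected(self, cfg):
        y = np.zeros(50)
        chrom = ch.Chromatogram(time_s=np.arange(50) * 0.2, intensity=y)
        chrom.intensity[3] = np.nan  # bypass constructor check
        with pytest.raises(ValueError):
            ch.correct_baseline(chrom, cfg)


class TestCorrectOverload:
    def test_identity_without_saturation(self, clean_peak, cfg):
        chrom, _ = clean_peak
        out = ch.correct_overload(chrom, cfg)
        assert np.array_equal(out.intensity, chrom.intensity)

    def test_clipped_peak_restored(self, cfg):
        sig = 3.0
        area = 1000 * sig * np.sqrt(2 * np.pi)
        spec = ChromSpec(
            duration_s=300, sampling_hz=5, peaks=((150, area, sig),),
            saturation_level=600.0,
        )
        chrom, _ = make_chromatogram(spec)
        out = ch.correct_overload(chrom, cfg)
        assert out.intensity.max() == pytest.approx(1000.0, rel=0.10)
        assert window_area(out, 150, 30) == pytest.approx(area, rel=0.10)

    def test_unrecoverable_plateau_rejected(self, cfg):
        y = np.full(100, 10.0)
        chrom = ch.Chromatogram(
            time_s=np.arange(100) * 0.2, intensity=y, saturation_level=10.0
        )
        with pytest.raises(ValueError, match="plateau"):
            ch.correct_overload(chrom, cfg)


class TestSmooth:
    def test_constant_trace_unchanged(self, cfg):
        chrom = ch.Chromatogram(time_s=np.arange(100) * 0.2, intensity=np.full(100, 7.0))
        out = ch.smooth(chrom, cfg)
        assert np.allclose(out.intensity, 7.0, atol=1e-12)

    def test_noise_variance_reduced(self, cfg):
        rng = np.random.default_rng(0)
        chrom = ch.Chromatogram(
            time_s=np.arange(2000) * 0.2, intensity=rng.normal(0, 10, 2000)
        )
        out = ch.smooth(chrom, cfg)
        assert out.intensity.std() < chrom.intensity.std()

    def test_broad_peak_area_conserved(self, cfg):
        spec = ChromSpec(duration_s=900, sampling_hz=5, peaks=((450, 100.0, 8.0),))
        chrom, _ = make_chromatogram(spec)
        out = ch.smooth(chrom, cfg)
        assert window_area(out, 450, 70) == pytest.approx(
            window_area(chrom, 450, 70), rel=0.005
        )


class TestDetectPeaks:
    def test_single_gaussian_apex_within_one_step(self, cfg):
        spec = ChromSpec(duration_s=300, sampling_hz=5, peaks=((150.1, 100.0, 2.0),))
        chrom, _ = make_chromatogram(spec)
        apexes = ch.detect_peaks(ch.smooth(chrom, cfg), cfg)
        assert len(apexes) == 1
        assert abs(apexes.loc[0, "rt"] - 150.1) <= chrom.dt

    def test_flat_noise_trace_yields_nothing(self, cfg):
        spec = ChromSpec(duration_s=300, sampling_hz=5, noise_sd=1.0, seed=8)
        chrom, _ = make_chromatogram(spec)
        assert len(ch.detect_peaks(ch.smooth(chrom, cfg), cfg)) == 0

    def test_well_separated_doublet_resolved(self, cfg):
        spec = ChromSpec(
            duration_s=300, sampling_hz=5,
            peaks=((140, 100.0, 2.0), (156, 100.0, 2.0)),  # 8 sigma apart
        )
        chrom, _ = make_chromatogram(spec)
        assert len(ch.detect_peaks(ch.smooth(chrom, cfg), cfg)) == 2


class TestClusterCoeluting:
    def test_resolved_apexes_stay_singletons(self, cfg):
        spec = ChromSpec(
            duration_s=300, sampling_hz=5,
            peaks=((140, 100.0, 2.0), (180, 100.0, 2.0)),  # 20 sigma apart
        )
        chrom, _ = make_chromatogram(spec)
        sm = ch.smooth(chrom, cfg)
        apexes = ch.detect_peaks(sm, cfg)
        assert ch.cluster_coeluting(apexes, sm, cfg) == [[0], [1]]

    def test_overlapping_apexes_merge(self, cfg):
        h = 100 / (2.0 * np.sqrt(2 * np.pi))
        apexes = apex_frame([(140.0, 2 * h, 2.0, 700), (143.0, h, 2.0, 715)])
        spec = ChromSpec(
            duration_s=300, sampling_hz=5,
            peaks=((140, 200.0, 2.0), (143, 100.0, 2.0)),
        )
        chrom, _ = make_chromatogram(spec)
        assert ch.cluster_coeluting(apexes, chrom, cfg) == [[0, 1]]

    def test_transitive_closure_chains(self, cfg):
        h = 20.0
        apexes = apex_frame(
            [(100.0, h, 2.0, 500), (104.0, h, 2.0, 520), (108.0, h, 2.0, 540),
             (200.0, h, 2.0, 1000)]
        )
        spec = ChromSpec(
            duration_s=300, sampling_hz=5,
            peaks=tuple((rt, 100.0, 2.0) for rt in (100, 104, 108, 200)),
        )
        chrom, _ = make_chromatogram(spec)
        assert ch.cluster_coeluting(apexes, chrom, cfg) == [[0, 1, 2], [3]]


class TestFitCluster:
    def test_single_clean_peak_recovered(self, clean_peak, cfg):
        chrom, truth = clean_peak
        h = truth.loc[0, "height"]
        apexes = apex_frame([(150.0, h, 2.0, 750)])
        rec = ch.fit_cluster(chrom, apexes, cfg)
        assert len(rec) == 1
        assert rec.loc[0, "area"] == pytest.approx(100.0, rel=0.005)
        assert rec.loc[0, "sigma_s"] == pytest.approx(2.0, rel=0.01)

    def test_fitted_area_matches_quadrature(self, clean_peak, cfg):
        chrom, truth = clean_peak
        apexes = apex_frame([(150.0, truth.loc[0, "height"], 2.0, 750)])
        rec = ch.fit_cluster(chrom, apexes, cfg)
        assert rec.loc[0, "area"] == pytest.approx(
            window_area(chrom, 150, 30), rel=0.01
        )

    def test_overlapped_doublet_areas_recovered(self, cfg):
        sig = 2.0
        h2 = 100 / (sig * np.sqrt(2 * np.pi))
        noise = h2 / 50  # SNR 50 on the smaller component
        spec = ChromSpec(
            duration_s=120, sampling_hz=5,
            peaks=((50, 200.0, sig), (53.0, 100.0, sig)),
            noise_sd=noise, seed=17,
        )
        chrom, _ = make_chromatogram(spec)
        apexes = apex_frame([(50.0, 2 * h2, sig, 250), (53.0, h2, sig, 265)])
        rec = ch.fit_cluster(chrom, apexes, cfg)
        assert len(rec) == 2
        assert rec.loc[0, "area"] == pytest.approx(200.0, rel=0.05)
        assert rec.loc[1, "area"] == pytest.approx(100.0, rel=0.05)

    def test_area_height_sigma_consistency(self, clean_peak, cfg):
        chrom, truth = clean_peak
        apexes = apex_frame([(150.0, truth.loc[0, "height"], 2.0, 750)])
        rec = ch.fit_cluster(chrom, apexes, cfg)
        assert rec.loc[0, "area"] == pytest.approx(
            rec.loc[0, "height"] * rec.loc[0, "sigma_s"] * np.sqrt(2 * np.pi)
        )


class TestProcessChromatogram:
    @staticmethod
    def five_peak_spec(seed, noise_sd=1.0):
        r = np.random.default_rng(seed)
        rts = np.sort(100 + r.random(5) * 700)
        while np.min(np.diff(rts)) < 40:
            rts = np.sort(100 + r.random(5) * 700)
        sigs = 1.5 + r.random(5) * 1.5
        areas = 50 * noise_sd * sigs * np.sqrt(2 * np.pi)  # SNR 50 per apex
        return ChromSpec(
            duration_s=900, sampling_hz=5, peaks=tuple(zip(rts, areas, sigs)),
            baseline=(20.0, 0.02, 5.0), noise_sd=noise_sd,
            spike_rate=2.0, spike_amplitude=50 * noise_sd, seed=seed,
        )

    def test_five_planted_peaks_recovered(self, cfg):
        chrom, truth = make_chromatogram(self.five_peak_spec(123))
        table = ch.process_chromatogram(chrom, cfg)
        assert len(table) == 5
        for _, row in truth.iterrows():
            match = table.iloc[(table["apex_rt_s"] - row["apex_rt_s"]).abs().argmin()]
            assert match["area"] == pytest.approx(row["area"], rel=0.03)

    def test_flat_trace_gives_empty_table(self, cfg):
        spec = ChromSpec(duration_s=300, sampling_hz=5, noise_sd=0.5, seed=1)
        chrom, _ = make_chromatogram(spec)
        table = ch.process_chromatogram(chrom, cfg)
        assert len(table) == 0
        assert list(table.columns) == ["sample_id"] + ch.PEAK_COLUMNS

    def test_deterministic(self, cfg):
        chrom, _ = make_chromatogram(self.five_peak_spec(5))
        a = ch.process_chromatogram(chrom, cfg)
        b = ch.process_chromatogram(chrom, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_area_conservation_within_clusters(self, cfg):
        """Sum of fitted component areas tracks the direct segment integral."""
        sig = 2.0
        h = 100 / (sig * np.sqrt(2 * np.pi))
        spec = ChromSpec(
            duration_s=200, sampling_hz=5,
            peaks=((100, 200.0, sig), (104.0, 100.0, sig)),
            noise_sd=h / 20, seed=3,  # SNR 20
        )
        chrom, _ = make_chromatogram(spec)
        table = ch.process_chromatogram(chrom, cfg)
        fitted = table["area"].sum()
        direct = window_area(chrom, 102, 14)
        assert fitted == pytest.approx(direct, rel=0.05)

    def test_error_grows_with_noise(self, cfg):
        """Mean |area error| is non-decreasing over an increasing noise grid."""
        noise_grid = [0.5, 2.0, 8.0]
        mean_err = []
        for noise in noise_grid:
            errs = []
            for seed in range(50):
                sig = 2.0
                area = 50 * sig * np.sqrt(2 * np.pi)
                spec = ChromSpec(
                    duration_s=120, sampling_hz=5, peaks=((60, area, sig),),
                    noise_sd=noise, seed=seed,
                )
                chrom, _ = make_chromatogram(spec)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    table = ch.process_chromatogram(chrom, cfg)
                if len(table):
                    j = (table["apex_rt_s"] - 60).abs().idxmin()
                    errs.append(abs(table.loc[j, "area"] - area) / area)
                else:
                    errs.append(1.0)
            mean_err.append(np.mean(errs))
        assert mean_err[0] <= mean_err[1] <= mean_err[2]

    def test_no_hallucinated_peaks_on_null_traces(self, cfg):
        fp = 0
        for seed in range(100):
            spec = ChromSpec(duration_s=300, sampling_hz=5, noise_sd=1.0, seed=seed)
            chrom, _ = make_chromatogram(spec)
            fp += len(ch.detect_peaks(ch.smooth(chrom, cfg), cfg))
        assert fp / 100 < 0.1


class TestChromatogramValidation:
    def test_nonuniform_grid_rejected(self):
        t = np.array([0.0, 0.2, 0.5, 0.6])
        with pytest.raises(ValueError, match="constant step"):
            ch.Chromatogram(time_s=t, intensity=np.zeros(4))

    def test_decreasing_grid_rejected(self):
        t = np.array([0.0, 0.2, 0.1, 0.3])
        with pytest.raises(ValueError, match="increasing"):
            ch.Chromatogram(time_s=t, intensity=np.zeros(4))

    def test_roundtrip_io(self, tmp_path, clean_peak):
        chrom, _ = clean_peak
        path = tmp_path / "c.csv"
        ch.write_chromatogram(chrom, path)
        back = ch.read_chromatogram(path, sample_id="s1")
        assert np.allclose(back.intensity, chrom.intensity)
        assert back.sample_id == "s1"
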