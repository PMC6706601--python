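"""TIC normalization, mass recalibration, peak detection, targeted extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nitroquant as nq
from nitroquant.preprocess import (
    InternalStandardError,
    PreprocessError,
    RecalibrationError,
    average_replicates,
    detect_peaks,
    extract_ion_abundance,
    recalibrate_mass_axis,
    tic_normalize,
)
from nitroquant.simulate import SampleTruth, render_spectrum
from nitroquant.spectrum import Spectrum, default_grid


def _gaussian_spectrum(centers_heights, sigma=0.05, sample_id="s"):
    grid = default_grid()
    y = np.zeros_like(grid)
    for c, h in centers_heights:
        y += h * np.exp(-0.5 * ((grid - c) / sigma) ** 2)
    return Spectrum(mz=grid, intensity=y, sample_id=sample_id)


class TestTicNormalize:
    def test_sums_to_one_and_idempotent(self, nf_model):
        s = render_spectrum(SampleTruth({"TNT": 10.0}), nf_model, seed=1)
        n1 = tic_normalize(s)
        assert n1.total_intensity == pytest.approx(1.0, rel=1e-12)
        n2 = tic_normalize(n1)
        assert np.allclose(n1.intensity, n2.intensity, rtol=1e-12)
        assert n1.has_flag("tic_normalized")

    @given(st.floats(min_value=1e-3, max_value=1e6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_invariance(self, c):
        s = _gaussian_spectrum([(200.0, 3.0), (250.0, 1.0)])
        scaled = s.with_intensity(s.intensity * c)
        assert np.allclose(
            tic_normalize(s).intensity, tic_normalize(scaled).intensity, rtol=1e-9
        )

    def test_two_point_hand_example(self):
        s = Spectrum(mz=np.array([100.0, 101.0]), intensity=np.array([3.0, 1.0]))
        assert tic_normalize(s).intensity == pytest.approx([0.75, 0.25])

    def test_all_zero_rejected(self):
        s = Spectrum(mz=np.array([100.0, 101.0]), intensity=np.zeros(2))
        with pytest.raises(PreprocessError):
            tic_normalize(s)


class TestRecalibrate:
    def test_constant_shift_corrected(self):
        # peaks deposited 0.30 Da above their true channels
        shifted = _gaussian_spectrum([(216.30, 100.0), (156.30, 50.0), (227.30, 30.0)])
        out, report = recalibrate_mass_axis(shifted, [216.0, 156.0])
        peaks = detect_peaks(out, snr_threshold=0)
        apex216 = peaks.loc[(peaks.mz - 216.0).abs().idxmin(), "mz"]
        assert abs(apex216 - 216.0) <= 0.02
        assert report["shift"] == pytest.approx(-0.30, abs=0.02)

    def test_zero_shift_identity(self):
        s = _gaussian_spectrum([(216.0, 100.0), (156.0, 50.0)])
        out, report = recalibrate_mass_axis(s, [216.0, 156.0])
        assert np.allclose(out.intensity, s.intensity, atol=1e-9 * s.intensity.max())
        assert abs(report["shift"]) < 1e-6

    def test_missing_references_rejected(self):
        s = _gaussian_spectrum([(250.0, 100.0)])
        with pytest.raises(RecalibrationError, match="no calibration reference"):
            recalibrate_mass_axis(s, [216.0, 156.0])

    def test_shift_and_stretch_corrected(self):
        # observed = 1.001 × true + 0.1 at both references
        true_refs = np.array([156.0, 216.0])
        obs = 1.001 * true_refs + 0.1
        s = _gaussian_spectrum(list(zip(obs, [50.0, 100.0])))
        out, _ = recalibrate_mass_axis(s, list(true_refs))
        peaks = detect_peaks(out, snr_threshold=0)
        for ref in true_refs:
            apex = peaks.loc[(peaks.mz - ref).abs().idxmin(), "mz"]
            assert abs(apex - ref) <= 0.02


class TestDetectPeaks:
    def test_noise_free_tnt_spectrum_channels(self, nf_model):
        import dataclasses

        # interference off: a TNT-only deposit shows exactly the TNT ions,
        # the internal standard pair and the two matrix ions
        model = dataclasses.replace(nf_model, interference={})
        s = render_spectrum(SampleTruth({"TNT": 10.0}), model, seed=0)
        peaks = detect_peaks(s, snr_threshold=5)
        found = sorted(round(m) for m in peaks.mz)
        assert set(found) == {156, 157, 200, 211, 216, 227}

    def test_flat_spectrum_empty(self):
        s = Spectrum(mz=np.array([100.0, 101.0, 102.0]), intensity=np.zeros(3))
        assert detect_peaks(s).empty

    def test_apex_interpolation_on_off_grid_gaussian(self):
        # apex placed between grid points; quadratic interpolation recovers it
        grid = default_grid()
        center = 200.004
        y = np.exp(-0.5 * ((grid - center) / 0.05) ** 2)
        s = Spectrum(mz=grid, intensity=y)
        peaks = detect_peaks(s, snr_threshold=0)
        assert len(peaks) == 1
        assert peaks.iloc[0]["mz"] == pytest.approx(center, abs=0.005)

    def test_apexes_match_brute_force_oracle(self, nf_model):
        """Detected apexes equal an argmax-plus-parabola oracle computed
        directly on the intensity array."""
        s = render_spectrum(SampleTruth({"TNT": 10.0, "DNT": 4.0}), nf_model, seed=0)
        peaks = detect_peaks(s, snr_threshold=5)
        y, mz = s.intensity, s.mz
        step = mz[1] - mz[0]
        for _, row in peaks.iterrows():
            k = int(np.argmax(np.where(np.abs(mz - row.mz) < 0.3, y, -np.inf)))
            d = 0.5 * (y[k - 1] - y[k + 1]) / (y[k - 1] - 2 * y[k] + y[k + 1])
            assert row.mz == pytest.approx(mz[k] + d * step, abs=1e-12)


class TestExtractIonAbundance:
    def test_is_channel_normalizes_to_one(self, registry, nf_model):
        s = render_spectrum(SampleTruth({"TNT": 10.0}, sample_id="a"), nf_model, seed=0)
        rows = extract_ion_abundance(
            s, registry.quant_channels(), is_mz=registry.is_mz
        )
        is_row = rows[rows.channel_mz == 216.0].iloc[0]
        assert is_row["is_normalized"] == pytest.approx(1.0, rel=1e-12)

    def test_constructed_ratio_recovered(self, registry):
        s = _gaussian_spectrum([(216.0, 100.0), (227.0, 40.0)])
        rows = extract_ion_abundance(s, registry.quant_channels(), is_mz=216.0)
        r = rows[rows.channel_mz == 227.0].iloc[0]
        assert r["is_normalized"] == pytest.approx(0.4, rel=1e-6)

    def test_blank_channel_reads_baseline(self, registry, nf_model):
        s = render_spectrum(SampleTruth({}, sample_id="blank"), nf_model, seed=0)
        rows = extract_ion_abundance(s, registry.quant_channels(), is_mz=216.0)
        assert rows[rows.channel_mz == 227.0].iloc[0]["raw"] == 0.0

    def test_missing_internal_standard_rejected(self, registry):
        s = _gaussian_spectrum([(227.0, 40.0)])
        with pytest.raises(InternalStandardError):
            extract_ion_abundance(s, registry.quant_channels(), is_mz=216.0)

    def test_normalized_invariant_under_global_scaling(self, registry, default_model):
        s = render_spectrum(SampleTruth({"TNT": 10.0}), default_model, seed=4)
        rows1 = extract_ion_abundance(s, registry.quant_channels(), is_mz=216.0)
        rows2 = extract_ion_abundance(
            s.with_intensity(s.intensity * 37.5), registry.quant_channels(), is_mz=216.0
        )
        assert np.allclose(rows1["is_normalized"], rows2["is_normalized"], rtol=1e-12)

    def test_extraction_monotone_in_true_response(self, registry, nf_model):
        vals = []
        for c in (1.0, 5.0, 20.0, 60.0):
            s = render_spectrum(SampleTruth({"TNT": c}), nf_model, seed=0)
            rows = extract_ion_abundance(s, registry.quant_channels(), is_mz=216.0)
            vals.append(rows[rows.channel_mz == 227.0].iloc[0]["is_normalized"])
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_order_of_tic_and_recalibration_immaterial(self, registry, nf_model):
        s = render_spectrum(SampleTruth({"TNT": 10.0}), nf_model, seed=0)
        a, _ = recalibrate_mass_axis(s, [216.0, 156.0])
        a = tic_normalize(a)
        b, _ = recalibrate_mass_axis(tic_normalize(s), [216.0, 156.0])
        ra = extract_ion_abundance(a, registry.quant_channels(), is_mz=216.0)
        rb = extract_ion_abundance(b, registry.quant_channels(), is_mz=216.0)
        assert np.allclose(ra["is_normalized"], rb["is_normalized"], rtol=1e-9)


class TestAverageReplicates:
    def test_identical_spots_zero_sd(self, registry, nf_model):
        truth = SampleTruth({"TNT": 10.0}, sample_id="s")
        rows = [
            extract_ion_abundance(
                render_spectrum(truth, nf_model, seed=None, replicate=i + 1),
                registry.quant_channels(),
                is_mz=216.0,
            )
            for i in range(3)
        ]
        import pandas as pd

        out = average_replicates(pd.concat(rows, ignore_index=True))
        assert (out["sd"].abs() < 1e-12).all()  # identical spots, up to fp dust
        assert (out["n"] == 3).all()

    def test_hand_mean_and_sd(self):
        import pandas as pd

        rows = pd.DataFrame(
            {
                "sample_id": ["s"] * 3,
                "replicate": [1, 2, 3],
                "channel_mz": [227.0] * 3,
                "channel_label": ["TNT"] * 3,
                "group": ["TNT"] * 3,
                "raw": [1, 1, 1],
                "is_normalized": [0.9, 1.0, 1.1],
            }
        )
        out = average_replicates(rows)
        assert out.iloc[0]["mean"] == pytest.approx(1.0)
        assert out.iloc[0]["sd"] == pytest.approx(0.1)

    def test_mixed_samples_rejected(self):
        import pandas as pd

        rows = pd.DataFrame(
            {
                "sample_id": ["a", "b"],
                "replicate": [1, 1],
                "channel_mz": [227.0, 227.0],
                "channel_label": ["TNT", "TNT"],
                "group": ["TNT", "TNT"],
                "raw": [1, 1],
                "is_normalized": [1.0, 1.0],
            }
        )
        with pytest.raises(PreprocessError):
            average_replicates(rows)
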