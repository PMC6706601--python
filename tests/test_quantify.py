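"""Calibration inversion, sequential interference correction, soil reporting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nitroquant as nq
from nitroquant.calibrate import CalibrationModel
from nitroquant.quantify import (
    ChannelEstimate,
    QuantifyError,
    average_channel_estimates,
    extract_to_soil_concentration,
    invert_sequential,
    invert_simple,
    replicate_summary,
)
from nitroquant.simulate import SampleTruth, soil_to_extract


def _model(mz, a, b, kind="simple", b_tnt=None, lod=None, group="TNT"):
    return CalibrationModel(
        channel_mz=mz, label=f"{group} {mz:g}", group=group, kind=kind,
        intercept=a, slope_own=b, slope_tnt=b_tnt, resid_sd=0.0, r2=1.0,
        range_min=1.0, range_max=75.0, n_points=7, lod=lod,
    )


class TestInvertSimple:
    def test_direct_arithmetic(self):
        est = invert_simple(_model(227.0, 0.0, 0.02), 0.2)
        assert est.value == pytest.approx(10.0, rel=1e-12)
        assert not est.below_lod and not est.negative

    def test_abundance_at_intercept_flags_below_lod(self):
        est = invert_simple(_model(227.0, 0.05, 0.02, lod=0.5), 0.05)
        assert est.value == pytest.approx(0.0, abs=1e-12)
        assert est.below_lod

    def test_negative_reported_not_clamped(self):
        est = invert_simple(_model(227.0, 0.05, 0.02), 0.01)
        assert est.value == pytest.approx(-2.0, rel=1e-9)
        assert est.negative

    def test_degenerate_model_rejected(self):
        bad = _model(227.0, 0.0, 0.02)
        bad.degenerate = True
        with pytest.raises(QuantifyError):
            invert_simple(bad, 0.2)


class TestChannelAveraging:
    def test_mean_of_two_channels(self):
        ests = [ChannelEstimate(227.0, 10.0), ChannelEstimate(211.0, 12.0)]
        assert average_channel_estimates(ests, "TNT").value == pytest.approx(11.0)

    def test_single_channel_identity(self):
        [est] = [ChannelEstimate(213.0, 7.0)]
        assert average_channel_estimates([est], "TNB").value == 7.0

    def test_flagged_channels_excluded_unless_all_flagged(self):
        ests = [
            ChannelEstimate(227.0, 10.0),
            ChannelEstimate(211.0, 0.1, below_lod=True),
        ]
        out = average_channel_estimates(ests, "TNT")
        assert out.value == 10.0 and not out.below_lod
        all_flagged = [
            ChannelEstimate(227.0, 0.2, below_lod=True),
            ChannelEstimate(211.0, 0.1, below_lod=True),
        ]
        out = average_channel_estimates(all_flagged, "TNT")
        assert out.value == pytest.approx(0.15)
        assert out.below_lod

    def test_empty_rejected(self):
        with pytest.raises(QuantifyError):
            average_channel_estimates([], "TNT")


class TestSequentialInversion:
    def _models(self, kappa=0.25):
        return {
            227.0: _model(227.0, 0.0, 0.020, group="TNT"),
            211.0: _model(211.0, 0.0, 0.010, group="TNT"),
            197.0: _model(197.0, 0.0, 0.018, kind="interference",
                          b_tnt=kappa * 0.018, group="ADNT"),
            181.0: _model(181.0, 0.0, 0.009, kind="interference",
                          b_tnt=kappa * 0.009, group="ADNT"),
        }

    def test_zero_tnt_reduces_to_simple(self):
        models = self._models()
        abundances = {227.0: 0.0, 211.0: 0.0, 197.0: 0.09, 181.0: 0.045}
        out = invert_sequential(models, abundances)
        assert out["TNT"].value == pytest.approx(0.0, abs=1e-12)
        assert out["ADNT"].value == pytest.approx(5.0, rel=1e-12)

    def test_mixture_recovered_exactly(self):
        models = self._models()
        c_tnt, c_adnt = 20.0, 5.0
        abundances = {
            227.0: 0.020 * c_tnt,
            211.0: 0.010 * c_tnt,
            197.0: 0.018 * c_adnt + 0.25 * 0.018 * c_tnt,
            181.0: 0.009 * c_adnt + 0.25 * 0.009 * c_tnt,
        }
        out = invert_sequential(models, abundances)
        assert out["TNT"].value == pytest.approx(c_tnt, rel=1e-9)
        assert out["ADNT"].value == pytest.approx(c_adnt, rel=1e-9)

    def test_tnt_only_sample_sequential_vs_simple(self):
        """With TNT alone, the sequential ADNT estimate vanishes while the
        naive single-channel inversion reads the interference as ADNT."""
        models = self._models()
        c_tnt = 20.0
        abundances = {
            227.0: 0.020 * c_tnt,
            211.0: 0.010 * c_tnt,
            197.0: 0.25 * 0.018 * c_tnt,
            181.0: 0.25 * 0.009 * c_tnt,
        }
        seq = invert_sequential(models, abundances)
        assert seq["ADNT"].value == pytest.approx(0.0, abs=1e-9)
        naive = invert_simple(_model(197.0, 0.0, 0.018, group="ADNT"), abundances[197.0])
        assert naive.value == pytest.approx(5.0, rel=1e-9)

    def test_interference_without_tnt_channels_rejected(self):
        models = {197.0: _model(197.0, 0.0, 0.018, kind="interference",
                                b_tnt=0.0045, group="ADNT")}
        with pytest.raises(QuantifyError):
            invert_sequential(models, {197.0: 0.1})


class TestSoilConversion:
    @pytest.mark.parametrize(
        "c,mass,vol,dil,expected",
        [
            (0.5, 2.0, 4.0, 1.0, 1.0),
            (0.0, 2.0, 4.0, 1.0, 0.0),
            (25.0, 2.0, 4.0, 10.0, 500.0),
        ],
    )
    def test_worked_examples(self, c, mass, vol, dil, expected):
        assert extract_to_soil_concentration(c, mass, vol, dil) == pytest.approx(
            expected, rel=1e-12
        )

    def test_invalid_provenance_rejected(self):
        with pytest.raises(QuantifyError):
            extract_to_soil_concentration(1.0, 0.0, 4.0)
        with pytest.raises(QuantifyError):
            extract_to_soil_concentration(1.0, 2.0, 4.0, 0.5)

    @given(
        st.floats(min_value=0, max_value=1e4),
        st.floats(min_value=0.1, max_value=100),
        st.floats(min_value=0.1, max_value=100),
        st.floats(min_value=1, max_value=100),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_round_trip_identity(self, mgkg, mass, vol, dil):
        c = soil_to_extract(mgkg, mass, vol, dil)
        back = extract_to_soil_concentration(c, mass, vol, dil)
        assert back == pytest.approx(mgkg, abs=1e-12 + 1e-12 * mgkg)


class TestReplicateSummary:
    def _spots(self, values, group="TNT"):
        from nitroquant.quantify import GroupEstimate

        return {
            i + 1: {group: GroupEstimate(group, v)} for i, v in enumerate(values)
        }

    def test_hand_mean_and_rsd(self):
        out = replicate_summary(self._spots([9.0, 10.0, 11.0]), sample_id="s")
        row = out.iloc[0]
        assert row["mean_ng_per_ul"] == pytest.approx(10.0)
        assert row["rsd_pct"] == pytest.approx(10.0)
        assert row["n_spots"] == 3

    def test_identical_spots_zero_rsd(self):
        out = replicate_summary(self._spots([5.0, 5.0, 5.0]))
        assert out.iloc[0]["rsd_pct"] == pytest.approx(0.0)

    def test_single_spot_sd_unavailable(self):
        out = replicate_summary(self._spots([5.0]))
        assert np.isnan(out.iloc[0]["sd_ng_per_ul"])
        assert np.isnan(out.iloc[0]["rsd_pct"])

    def test_deviation_from_reference(self):
        out = replicate_summary(self._spots([8.0, 8.0, 8.0]), reference={"TNT": 10.0})
        assert out.iloc[0]["deviation_pct"] == pytest.approx(-20.0)

    def test_soil_units_attached(self):
        out = replicate_summary(
            self._spots([0.5, 0.5, 0.5]), soil_mass_g=2.0, extract_volume_ml=4.0
        )
        assert out.iloc[0]["soil_mg_per_kg"] == pytest.approx(1.0)

    def test_soil_reference_deviation(self):
        out = replicate_summary(
            self._spots([0.5, 0.5, 0.5]),
            soil_mass_g=2.0, extract_volume_ml=4.0,
            reference={"TNT": 2.0}, reference_units="soil",
        )
        assert out.iloc[0]["deviation_pct"] == pytest.approx(-50.0)


class TestEndToEndNoiseFree:
    def test_simple_pipeline_recovers_mixture_truth(self, nf_model, nf_simple_models):
        """Full noise-free round trip at 25 ng/µL: simulate → preprocess →
        invert, for every analyte group in the calibration mixture."""
        groups = ["TNT", "ADNT", "DNT", "NT", "TNB", "DNB"]
        truth = SampleTruth({g: 25.0 for g in groups}, sample_id="rt")
        reps = nq.simulate_replicate_set(truth, nf_model, 3, seed=55)
        res = nq.quantify_sample(reps, nf_simple_models, mode="simple")
        for g in groups:
            val = res[res.analyte == g].iloc[0]["mean_ng_per_ul"]
            assert val == pytest.approx(25.0, rel=1e-6)

    def test_sequential_pipeline_recovers_tnt_adnt(self, nf_model, nf_interference_models):
        truth = SampleTruth({"TNT": 20.0, "ADNT": 5.0}, sample_id="mix")
        reps = nq.simulate_replicate_set(truth, nf_model, 3, seed=56)
        res = nq.quantify_sample(reps, nf_interference_models, mode="sequential")
        assert res[res.analyte == "TNT"].iloc[0]["mean_ng_per_ul"] == pytest.approx(
            20.0, rel=1e-6
        )
        assert res[res.analyte == "ADNT"].iloc[0]["mean_ng_per_ul"] == pytest.approx(
            5.0, rel=1e-6
        )

    def test_tnt_identical_between_modes(self, nf_model, nf_interference_models):
        truth = SampleTruth({"TNT": 30.0, "ADNT": 10.0}, sample_id="m")
        reps = nq.simulate_replicate_set(truth, nf_model, 3, seed=57)
        seq = nq.quantify_sample(reps, nf_interference_models, mode="sequential")
        sim = nq.quantify_sample(reps, nf_interference_models, mode="simple")
        t_seq = seq[seq.analyte == "TNT"].iloc[0]["mean_ng_per_ul"]
        t_sim = sim[sim.analyte == "TNT"].iloc[0]["mean_ng_per_ul"]
        assert t_seq == t_sim
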