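"""Processing-chain tests: apodization, transform, phasing, baseline, axis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import curve_fit

from qnmr.containers import AcquisitionParams
from qnmr.processing import (
    apply_phase,
    auto_phase,
    baseline_correct,
    exponential_apodize,
    reference_axis,
    transform_to_spectrum,
)
from qnmr.quantification import IntegrationRegion, integrate_region
from qnmr.signal_model import (
    AnalyteSpec,
    Line,
    SampleSpec,
    add_polynomial_baseline,
    synthesize_fid,
)

from conftest import make_sample


def _single_line_fid(acq, position_ppm=6.175, width_hz=0.5, conc=5.0, seed=0):
    analyte = AnalyteSpec(
        "probe", 100.0, 100.0, 1, 1.5, (Line(position_ppm, 1.0, width_hz),)
    )
    return synthesize_fid(make_sample((analyte, conc)), acq, seed=seed)


@pytest.fixture(scope="module")
def mixture_spectrum():
    """A realistic three-signal spectrum used by the phasing/baseline tests."""
    from qnmr.presets import AZELASTINE, FLUTICASONE, INOSITOL

    acq = AcquisitionParams(data_points=8192)
    sample = make_sample(
        (FLUTICASONE, 5.0), (AZELASTINE, 5.0), (INOSITOL, 10.0)
    )
    fid = exponential_apodize(synthesize_fid(sample, acq, seed=7), 0.3)
    return transform_to_spectrum(fid)


class TestApodize:
    def test_zero_lb_is_identity(self, small_acq):
        fid = _single_line_fid(small_acq)
        out = exponential_apodize(fid, 0.0)
        assert np.array_equal(out.samples, fid.samples)

    @given(lb=st.floats(0.0, 5.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_first_sample_unchanged(self, lb):
        acq = AcquisitionParams(data_points=256)
        fid = _single_line_fid(acq)
        out = exponential_apodize(fid, lb)
        assert out.samples[0] == fid.samples[0]

    def test_negative_lb_rejected(self, small_acq):
        with pytest.raises(ValueError):
            exponential_apodize(_single_line_fid(small_acq), -0.1)

    def test_linewidth_additivity(self):
        # 0.5 Hz natural width + 0.3 Hz broadening -> 0.8 Hz Lorentzian FWHM
        acq = AcquisitionParams(data_points=16384)
        fid = exponential_apodize(_single_line_fid(acq, width_hz=0.5), 0.3)
        spec = transform_to_spectrum(fid, zero_fill_to=65536)
        hz = (spec.ppm - 6.175) * acq.spectrometer_frequency_mhz
        sel = np.abs(hz) < 20

        def lorentz(f, a, f0, w):
            return a * (w / 2) / ((w / 2) ** 2 + (f - f0) ** 2)

        popt, _ = curve_fit(lorentz, hz[sel], spec.real[sel], p0=[1e-3, 0.0, 1.0])
        assert popt[2] == pytest.approx(0.8, rel=0.02)


class TestTransform:
    def test_zero_fid_gives_zero_spectrum(self, small_acq):
        fid = synthesize_fid(SampleSpec(components=[]), small_acq, seed=0)
        spec = transform_to_spectrum(fid)
        assert np.all(spec.real == 0) and np.all(spec.imag == 0)

    def test_axis_descending_and_centred_on_offset(self, small_acq):
        spec = transform_to_spectrum(_single_line_fid(small_acq))
        assert np.all(np.diff(spec.ppm) < 0)
        lo, hi = small_acq.window_ppm
        assert spec.ppm[0] == pytest.approx(hi, abs=0.01)
        assert spec.ppm[-1] == pytest.approx(lo, abs=0.01)

    def test_on_resonance_line_is_lorentzian_at_offset(self):
        # closed-form transform pair: damped exponential -> Lorentzian of
        # total area A/2 centred at the carrier
        acq = AcquisitionParams(data_points=32768)
        fid = exponential_apodize(_single_line_fid(acq, width_hz=0.5), 0.3)
        spec = transform_to_spectrum(fid)
        peak_ppm = spec.ppm[np.argmax(spec.real)]
        assert peak_ppm == pytest.approx(6.175, abs=0.001)
        area_hz = (
            integrate_region(
                spec, IntegrationRegion("p", 6.0, 6.35, "probe")
            ).absolute_area
            * acq.spectrometer_frequency_mhz
        )
        amplitude = fid.samples[0].real
        assert area_hz == pytest.approx(amplitude / 2.0, rel=5e-3)

    def test_zero_fill_preserves_region_integrals(self):
        # holds for an FID that has decayed within the acquisition window
        acq = AcquisitionParams(data_points=32768)
        fid = exponential_apodize(_single_line_fid(acq), 0.3)
        region = IntegrationRegion("p", 6.0, 6.35, "probe")
        base = integrate_region(transform_to_spectrum(fid), region).absolute_area
        filled = integrate_region(
            transform_to_spectrum(fid, zero_fill_to=2 * acq.data_points),
            region,
        ).absolute_area
        assert filled == pytest.approx(base, rel=1e-3)

    def test_zero_fill_below_length_rejected(self, small_acq):
        with pytest.raises(ValueError):
            transform_to_spectrum(_single_line_fid(small_acq), zero_fill_to=16)


class TestAutoPhase:
    def test_already_phased_spectrum_needs_under_one_degree(self, mixture_spectrum):
        out = auto_phase(mixture_spectrum)
        params = out.processing_log[-1][1]
        assert abs(params["phi0_deg"]) < 1.0

    def test_recovers_injected_zero_order_phase(self, mixture_spectrum):
        bad = apply_phase(mixture_spectrum, 30.0)
        out = auto_phase(bad)
        params = out.processing_log[-1][1]
        residual = (params["phi0_deg"] + 30.0 + 180.0) % 360.0 - 180.0
        assert abs(residual) < 1.0

    def test_recovers_injected_phase_pair(self, mixture_spectrum):
        bad = apply_phase(mixture_spectrum, 20.0, 40.0)
        out = auto_phase(bad)
        params = out.processing_log[-1][1]
        res0 = (params["phi0_deg"] + 20.0 + 180.0) % 360.0 - 180.0
        assert abs(res0) < 2.0
        assert abs(params["phi1_deg"] + 40.0) < 2.0

    def test_idempotent_within_tolerance(self, mixture_spectrum):
        once = auto_phase(apply_phase(mixture_spectrum, 25.0))
        twice = auto_phase(once)
        region = IntegrationRegion("f", 6.27, 6.34, "FLP")
        a1 = integrate_region(once, region).absolute_area
        a2 = integrate_region(twice, region).absolute_area
        assert a2 == pytest.approx(a1, rel=1e-3)


class TestBaseline:
    def test_constant_offset_removed(self, mixture_spectrum):
        shifted = mixture_spectrum.copy()
        shifted.real = shifted.real + 5.0
        out = baseline_correct(shifted, [(3.5, 3.9), (6.1, 6.5), (8.1, 8.5)])
        free = out.slice_indices(10.0, 12.0)
        assert abs(out.real[free].mean()) < 5.0 * 1e-6

    def test_linear_ramp_removed_without_touching_areas(self, mixture_spectrum):
        region = IntegrationRegion("f", 6.27, 6.34, "FLP")
        clean_area = integrate_region(mixture_spectrum, region).absolute_area
        ramped = add_polynomial_baseline(mixture_spectrum, (0.5, -0.05))
        out = baseline_correct(
            ramped, [(3.5, 3.9), (6.1, 6.5), (8.1, 8.5)], order=2
        )
        corrected_area = integrate_region(out, region).absolute_area
        assert corrected_area == pytest.approx(clean_area, rel=1e-2)

    def test_clean_spectrum_unchanged(self, mixture_spectrum):
        out = baseline_correct(
            mixture_spectrum, [(3.5, 3.9), (6.1, 6.5), (8.1, 8.5)]
        )
        scale = np.abs(mixture_spectrum.real).max()
        assert np.abs(out.real - mixture_spectrum.real).max() < 1e-4 * scale

    def test_everything_excluded_raises(self, mixture_spectrum):
        with pytest.raises(ValueError, match="signal-free"):
            baseline_correct(mixture_spectrum, [(-10.0, 20.0)])


class TestReferenceAxis:
    def test_rigid_shift_to_assigned_value(self, small_acq):
        # solvent-like line sitting at 2.48 ppm, assigned 2.50
        fid = _single_line_fid(small_acq, position_ppm=2.48, conc=20.0)
        spec = transform_to_spectrum(exponential_apodize(fid, 0.3))
        out = reference_axis(spec, 2.48, 2.50)
        params = out.processing_log[-1][1]
        assert params["shift_ppm"] == pytest.approx(0.02, abs=2e-3)
        peak_ppm = out.ppm[np.argmax(out.real)]
        assert peak_ppm == pytest.approx(2.50, abs=2e-3)

    def test_already_referenced_is_identity_within_grid(self, small_acq):
        fid = _single_line_fid(small_acq, position_ppm=2.50, conc=20.0)
        spec = transform_to_spectrum(exponential_apodize(fid, 0.3))
        out = reference_axis(spec, 2.50, 2.50)
        step = abs(np.diff(spec.ppm).mean())
        assert abs(out.processing_log[-1][1]["shift_ppm"]) <= step

    def test_missing_reference_line_raises(self, mixture_spectrum):
        with pytest.raises(ValueError, match="no reference line"):
            reference_axis(mixture_spectrum, 11.0, 11.0)


class TestChainInvariants:
    def test_area_conserved_through_full_chain(self):
        # apodize + zero-fill + phase + baseline changes well-separated
        # region integrals by < 1 %
        from qnmr.presets import FLUTICASONE, INOSITOL

        acq = AcquisitionParams(data_points=16384)
        sample = make_sample((FLUTICASONE, 5.0), (INOSITOL, 10.0))
        fid = synthesize_fid(sample, acq, seed=11)
        raw = transform_to_spectrum(exponential_apodize(fid, 0.3))
        processed = baseline_correct(
            auto_phase(
                transform_to_spectrum(
                    exponential_apodize(fid, 0.3), zero_fill_to=32768
                )
            ),
            [(3.6, 3.8), (6.2, 6.4)],
        )
        for low, high, owner in [(6.27, 6.34, "FLP"), (3.68, 3.73, "inositol")]:
            region = IntegrationRegion(owner, low, high, owner)
            a_raw = integrate_region(raw, region).absolute_area
            a_proc = integrate_region(processed, region).absolute_area
            assert a_proc == pytest.approx(a_raw, rel=1e-2)

    def test_chain_is_deterministic_with_identical_log(self, small_acq):
        fid = _single_line_fid(small_acq, seed=5)

        def run():
            spec = transform_to_spectrum(exponential_apodize(fid, 0.3))
            spec = auto_phase(spec)
            return baseline_correct(spec, [(6.0, 6.4)])

        a, b = run(), run()
        assert np.array_equal(a.real, b.real)
        assert np.array_equal(a.ppm, b.ppm)
        assert a.processing_log == b.processing_log

    def test_processing_log_is_append_only_record(self, small_acq):
        fid = _single_line_fid(small_acq)
        spec = transform_to_spectrum(exponential_apodize(fid, 0.3))
        spec = auto_phase(spec)
        spec = baseline_correct(spec, [(6.0, 6.4)])
        steps = [s for s, _ in spec.processing_log]
        assert steps == [
            "exponential_apodize",
            "transform_to_spectrum",
            "auto_phase",
            "baseline_correct",
        ]
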