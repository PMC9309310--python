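"""Regression models and Govardovskii template spectra."""

import numpy as np
import pytest

from opsintune.descriptors import DescriptorSet
from opsintune.spectral import (govardovskii_template, load_model,
                                predict_rh2, predict_sws2, spectrum_panel,
                                write_spectra_tsv)
from opsintune.tuning_rules import SpectralPrediction

# descriptor medians and printed lambda-max per pigment (two-term model
# inputs: torsion15, rmsf_auc)
RH2_ROWS = [
    ("Rh2-1", 3.64, 0.79, 471.5),
    ("Rh2-2", 3.06, 0.76, 475.5),
    ("Rh2-3", 0.41, 1.12, 511.2),
    ("Rh2-4", 0.84, 1.10, 506.4),
]


def rh2_descriptors(torsion15, rmsf):
    return DescriptorSet(torsion15_median=torsion15, rmsf_auc=rmsf)


def sws2_descriptors(angle3, torsion3, torsion12):
    return DescriptorSet(angle3_median=angle3, torsion3_median=torsion3,
                         torsion12_median=torsion12)


class TestRh2Model:
    @pytest.mark.parametrize("name,t15,rmsf,printed", RH2_ROWS)
    def test_printed_descriptor_rows(self, name, t15, rmsf, printed):
        pred = predict_rh2(rh2_descriptors(t15, rmsf))
        assert pred.lambda_max == pytest.approx(printed, abs=0.5)
        assert pred.method == "regression"

    def test_intercept(self):
        pred = predict_rh2(rh2_descriptors(0.0, 0.0))
        assert pred.lambda_max == pytest.approx(475.628)

    def test_unit_inputs_arithmetic_oracle(self):
        # 475.628 - 8.720 + 34.925 computed independently
        pred = predict_rh2(rh2_descriptors(1.0, 1.0))
        assert pred.lambda_max == pytest.approx(501.833)

    def test_missing_descriptor_errors(self):
        with pytest.raises(ValueError, match="rmsf_auc"):
            predict_rh2(DescriptorSet(torsion15_median=1.0))

    def test_affine_in_descriptors(self, rng):
        d1 = rh2_descriptors(*rng.uniform(0, 2, size=2))
        d2 = rh2_descriptors(*rng.uniform(0, 2, size=2))
        for alpha in (0.0, 0.25, 0.5, 1.0):
            mix = rh2_descriptors(
                alpha * d1.torsion15_median + (1 - alpha) * d2.torsion15_median,
                alpha * d1.rmsf_auc + (1 - alpha) * d2.rmsf_auc)
            expected = (alpha * predict_rh2(d1).lambda_max
                        + (1 - alpha) * predict_rh2(d2).lambda_max)
            assert predict_rh2(mix).lambda_max == pytest.approx(expected)


class TestSws2Model:
    def test_printed_descriptor_row(self):
        pred = predict_sws2(sws2_descriptors(132.33, 2.14, -5.1))
        assert pred.lambda_max == pytest.approx(420.04, abs=0.05)

    def test_intercept_flagged_out_of_range(self):
        pred = predict_sws2(sws2_descriptors(0.0, 0.0, 0.0))
        assert pred.lambda_max == pytest.approx(2677.5348)
        assert "out_of_range" in pred.flags

    def test_arithmetic_oracle_off_range(self):
        # 2677.5348 - 17.052*100 computed independently
        pred = predict_sws2(sws2_descriptors(100.0, 0.0, 0.0))
        assert pred.lambda_max == pytest.approx(972.3348)
        assert "out_of_range" in pred.flags

    def test_missing_descriptor_errors(self):
        with pytest.raises(ValueError, match="torsion12"):
            predict_sws2(DescriptorSet(angle3_median=1.0,
                                       torsion3_median=1.0))


class TestModelLoading:
    def test_packaged_models_resolve(self):
        m = load_model("rh2_two_term")
        assert m.intercept == pytest.approx(475.628)
        assert dict(m.terms)["rmsf_auc"] == pytest.approx(34.925)

    def test_custom_model_json(self, tmp_path):
        p = tmp_path / "m.json"
        p.write_text('{"name": "toy", "intercept": 1.0, '
                     '"terms": [["rmsf_auc", 2.0]]}')
        m = load_model(p)
        assert m.evaluate(DescriptorSet(rmsf_auc=3.0)) == pytest.approx(7.0)

    def test_unknown_descriptor_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"name": "bad", "intercept": 0.0, '
                     '"terms": [["wavelength", 1.0]]}')
        with pytest.raises(ValueError, match="wavelength"):
            load_model(p)


def independent_template(lambda_max, wl):
    """Independent re-implementation of the published A1 alpha-band
    formula, written from the constants, as a dual-route oracle."""
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-(lambda_max - 300.0) ** 2 / 11940.0)
    denom = (np.exp(69.7 * (a - x)) + np.exp(28.0 * (0.922 - x))
             + np.exp(-14.9 * (1.104 - x)) + 0.674)
    return 1.0 / denom


class TestGovardovskiiTemplate:
    def test_peak_is_exactly_one_at_nearest_grid_point(self):
        grid = np.arange(300.0, 701.0, 1.0)
        for lam in (360.0, 420.0, 471.5, 509.0, 560.0):
            s = govardovskii_template(lam, grid)
            peak_idx = int(np.argmax(s.absorbance))
            nearest = int(np.argmin(np.abs(grid - lam)))
            assert peak_idx == nearest
            assert s.absorbance[peak_idx] == 1.0

    def test_unimodal_over_visible_grid(self):
        grid = np.arange(300.0, 701.0, 1.0)
        for lam in (360.0, 420.0, 509.0, 560.0):
            ab = govardovskii_template(lam, grid).absorbance
            diffs = np.sign(np.diff(ab))
            # strictly one sign change: rising limb then falling limb
            changes = np.sum(np.diff(diffs[diffs != 0]) != 0)
            assert changes <= 1

    def test_long_wave_limb_decreasing(self):
        s = govardovskii_template(509.0)
        tail = s.absorbance[s.wavelengths > 509.0]
        assert np.all(np.diff(tail) < 0)

    def test_matches_independent_reimplementation(self):
        grid = np.arange(300.0, 701.0, 0.5)
        for lam in (360.0, 420.04, 471.5, 509.0, 560.0):
            s = govardovskii_template(lam, grid)
            ours = s.absorbance
            theirs = independent_template(lam, grid)
            theirs = theirs / theirs.max()
            assert np.max(np.abs(ours - theirs)) < 1e-9
            # spot value at the classic x = 0.922 point
            wl = lam / 0.922
            ours_at = govardovskii_template(lam, np.array([wl - 1, wl, wl + 1]))
            assert ours_at.absorbance[1] * ours_at.absorbance.max() >= 0

    def test_beta_band_adds_short_wave_shoulder(self):
        grid = np.arange(300.0, 701.0, 1.0)
        alpha = govardovskii_template(500.0, grid).absorbance
        both = govardovskii_template(500.0, grid,
                                     include_beta=True).absorbance
        short = grid < 400
        assert np.all(both[short] >= alpha[short] - 1e-12)
        assert both[short].max() > alpha[short].max()

    def test_out_of_band_lambda_rejected(self):
        with pytest.raises(ValueError):
            govardovskii_template(250.0)


class TestSpectrumPanel:
    def predictions(self, lams):
        return [SpectralPrediction(pigment_id=f"p{i}", opsin_class="rh2",
                                   lambda_max=lam, method="regression")
                for i, lam in enumerate(lams)]

    def test_eleven_pigment_panel(self, tmp_path):
        lams = [360, 420, 472, 476, 511, 506, 560, 553, 546, 553, 509]
        preds = self.predictions(lams)
        panel = spectrum_panel(preds)
        assert len(panel) == 11
        for lam, s in zip(lams, panel):
            assert s.wavelengths[np.argmax(s.absorbance)] == \
                pytest.approx(lam, abs=0.5)
        out = tmp_path / "spectra.tsv"
        write_spectra_tsv(preds, panel, out)
        lines = out.read_text().splitlines()
        assert len(lines) == 1 + 11 * 401

    def test_empty_list(self):
        assert spectrum_panel([]) == []

    def test_identical_lambda_identical_spectra(self):
        panel = spectrum_panel(self.predictions([500.0, 500.0]))
        assert np.array_equal(panel[0].absorbance, panel[1].absorbance)

    def test_non_numeric_predictions_skipped(self):
        preds = self.predictions([500.0])
        preds.append(SpectralPrediction(
            pigment_id="violet", opsin_class="sws1", lambda_max=None,
            method="rule_based", notes=["non-UVS"]))
        assert len(spectrum_panel(preds)) == 1
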