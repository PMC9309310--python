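"""Descriptor-to-lambda-max regressions and visual-pigment templates.

Two printed regression models map chromophore-dynamics descriptors to the
peak absorbance wavelength of a photopigment:

* RH2 (two-term):  lambda_max = 475.628 - 8.720 * Torsion15
                                       + 34.925 * RMSF(LYS+RET)
* SWS2 (three-term): lambda_max = 2677.5348 - 17.052 * Angle3
                                          + 5.1634 * Torsion3
                                          + 2.3642 * Torsion12

The SWS2 intercept is large because Angle3 sits near 132 degrees; the
model is an affine fit, valid only near the descriptor ranges it was
trained on, so raw evaluations far outside the class's physical window are
returned with an ``out_of_range`` flag rather than clipped.

Full dark spectra are generated with the Govardovskii A1 visual-pigment
template, which produces a normalized absorbance curve from lambda_max
alone. The default is the alpha band only, which is unimodal over the
visible range; the short-wave beta band (a secondary cis peak near
350 nm) can be switched on where a two-band spectrum is wanted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .descriptors import DescriptorSet
from .tuning_rules import CLASS_RANGES, SpectralPrediction

__all__ = [
    "RegressionModel",
    "AbsorbanceSpectrum",
    "load_model",
    "predict_rh2",
    "predict_sws2",
    "govardovskii_template",
    "spectrum_panel",
    "write_spectra_tsv",
]


@dataclass
class RegressionModel:
    """An affine descriptor -> lambda_max model."""

    name: str
    intercept: float
    terms: list[tuple[str, float]]

    def __post_init__(self) -> None:
        valid = {"torsion15_median", "angle3_median", "torsion3_median",
                 "torsion12_median", "rmsf_auc"}
        for desc, coef in self.terms:
            if desc not in valid:
                raise ValueError(f"{self.name}: unknown descriptor {desc!r}")
            if not np.isfinite(coef):
                raise ValueError(f"{self.name}: non-finite coefficient for {desc}")

    def evaluate(self, d: DescriptorSet) -> float:
        value = self.intercept
        for desc, coef in self.terms:
            x = getattr(d, desc)
            if x is None:
                raise ValueError(
                    f"{self.name}: descriptor {desc} missing from input")
            value += coef * x
        return value


@dataclass
class AbsorbanceSpectrum:
    """A normalized dark spectrum on a wavelength grid."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    lambda_max: float

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.shape != self.absorbance.shape:
            raise ValueError("grid and absorbance shapes differ")


def load_model(name_or_path: str | Path) -> RegressionModel:
    """Load a model from the packaged set (``rh2_two_term``,
    ``sws2_three_term``) or from a JSON file path."""
    packaged = {"rh2_two_term": "rh2_two_term.json",
                "sws2_three_term": "sws2_three_term.json"}
    if str(name_or_path) in packaged:
        ref = resources.files("opsintune.data") / packaged[str(name_or_path)]
        with resources.as_file(ref) as p, open(p) as fh:
            raw = json.load(fh)
    else:
        with open(name_or_path) as fh:
            raw = json.load(fh)
    return RegressionModel(name=raw["name"], intercept=raw["intercept"],
                           terms=[(d, c) for d, c in raw["terms"]])


def _wrap_prediction(pigment_id: str, opsin_class: str, value: float,
                     model: RegressionModel) -> SpectralPrediction:
    lo, hi = CLASS_RANGES[opsin_class]
    flags = []
    if not lo - 40 <= value <= hi + 40:
        # far outside the physical window for the class: the affine model
        # was evaluated off its training range
        flags.append("out_of_range")
    return SpectralPrediction(
        pigment_id=pigment_id, opsin_class=opsin_class,
        lambda_max=float(value), method="regression", flags=flags,
        notes=[f"model {model.name}"],
    )


def predict_rh2(d: DescriptorSet) -> SpectralPrediction:
    """Two-term RH2 model: Torsion15 and the RMSF(LYS+RET) curve area."""
    model = load_model("rh2_two_term")
    return _wrap_prediction(d.pigment_id, "rh2", model.evaluate(d), model)


def predict_sws2(d: DescriptorSet) -> SpectralPrediction:
    """Three-term SWS2 model: Angle3, Torsion3 and Torsion12 medians."""
    model = load_model("sws2_three_term")
    return _wrap_prediction(d.pigment_id, "sws2", model.evaluate(d), model)


# ---------------------------------------------------------------------------
# Govardovskii A1 template

# alpha-band constants of the A1 pigment template
_A, _B, _C, _D = 69.7, 28.0, -14.9, 0.674
_b, _c = 0.922, 1.104


def _alpha_band(wavelengths: np.ndarray, lambda_max: float) -> np.ndarray:
    x = lambda_max / wavelengths
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    return 1.0 / (np.exp(_A * (a - x)) + np.exp(_B * (_b - x))
                  + np.exp(_C * (_c - x)) + _D)


def _beta_band(wavelengths: np.ndarray, lambda_max: float) -> np.ndarray:
    a_beta = 0.26
    lm_beta = 189.0 + 0.315 * lambda_max
    b_beta = -40.5 + 0.195 * lambda_max
    return a_beta * np.exp(-(((wavelengths - lm_beta) / b_beta) ** 2))


def govardovskii_template(lambda_max: float,
                          grid: np.ndarray | None = None,
                          include_beta: bool = False) -> AbsorbanceSpectrum:
    """Normalized A1 dark spectrum for a pigment of given lambda_max.

    The alpha band alone (default) is unimodal; ``include_beta=True`` adds
    the published beta band, giving the two-band spectrum real pigments
    show below ~400 nm. Output is rescaled so the maximum on the grid is
    exactly 1. A grid that does not bracket lambda_max is accepted (the
    spectrum is still well defined) but normalization is then relative to
    the on-grid maximum.
    """
    if not 300.0 <= lambda_max <= 650.0:
        raise ValueError(f"lambda_max {lambda_max} nm outside 300-650 nm")
    if grid is None:
        grid = np.arange(300.0, 701.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a sorted 1D wavelength array")
    absorbance = _alpha_band(grid, lambda_max)
    if include_beta:
        absorbance = absorbance + _beta_band(grid, lambda_max)
    absorbance = absorbance / absorbance.max()
    return AbsorbanceSpectrum(wavelengths=grid, absorbance=absorbance,
                              lambda_max=lambda_max)


def spectrum_panel(predictions: list[SpectralPrediction],
                   grid: np.ndarray | None = None,
                   include_beta: bool = False) -> list[AbsorbanceSpectrum]:
    """One normalized template per numeric prediction on a shared grid.

    Predictions lacking a numeric lambda_max are skipped (the qualitative
    SWS1 violet call, for instance, has no single peak to draw).
    """
    if grid is None:
        grid = np.arange(300.0, 701.0, 1.0)
    spectra = []
    for p in predictions:
        if p.lambda_max is None:
            continue
        spectra.append(govardovskii_template(p.lambda_max, grid,
                                             include_beta=include_beta))
    return spectra


def write_spectra_tsv(predictions: list[SpectralPrediction],
                      spectra: list[AbsorbanceSpectrum],
                      path: str | Path) -> None:
    """Tidy TSV: pigment_id, wavelength_nm, absorbance."""
    numeric = [p for p in predictions if p.lambda_max is not None]
    with open(path, "w") as fh:
        fh.write("pigment_id\twavelength_nm\tabsorbance\n")
        for p, s in zip(numeric, spectra):
            for wl, ab in zip(s.wavelengths, s.absorbance):
                fh.write(f"{p.pigment_id}\t{wl:g}\t{ab:.9f}\n")
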