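"""Bacterial-activity rates from raw assay signals.

Two assay chains are covered:

* **Heterotrophic carbon production (HCP)** from ³H-leucine
  incorporation: net DPM (sample minus killed control) is converted to
  moles of leucine via the tracer specific activity (1 Ci =
  2.22×10¹² DPM), scaled to nmol Leu L⁻¹ h⁻¹, and converted to carbon
  with 1.55 kg C mol⁻¹ Leu times a twofold isotope dilution.

* **Leucine aminopeptidase activity** from AMC fluorescence: the
  blank-corrected fluorescence increase over the incubation is divided
  by the slope of an AMC standard calibration line, giving nM AMC h⁻¹.
  Rates of the predator-associated microbial consortium are measured in
  diluted vials and corrected as rate×dilution − seawater rate, per
  individual.

Both chains are linear in their signals and inverse-linear in
incubation time; negative corrected rates floor at 0 with a warning
(expected at low signal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import ValidationError, logger

DPM_PER_CI = 2.22e12
LEU_TO_CARBON_KG_PER_MOL = 1.55   # ≡ 1.55 μg C per nmol Leu
ISOTOPE_DILUTION = 2.0


@dataclass(frozen=True)
class LeucineAssay:
    """One bottle × timepoint ³H-leucine incubation."""

    dpm_samples: tuple[float, ...]    # replicate aliquots
    dpm_killed: float                 # TCA-killed control
    sample_volume: float              # mL
    incubation: float                 # h
    specific_activity: float = 52.9   # Ci mmol⁻¹
    added_conc: float = 20.0          # nM tracer

    def __post_init__(self) -> None:
        if min(self.dpm_samples, default=0) < 0 or self.dpm_killed < 0:
            raise ValidationError("DPM values must be >= 0")
        if self.incubation <= 0 or self.sample_volume <= 0:
            raise ValidationError("incubation and sample_volume must be > 0")
        if self.specific_activity <= 0:
            raise ValidationError("specific_activity must be > 0")


@dataclass(frozen=True)
class FluorescenceAssay:
    """Start/end fluorescence of one substrate incubation plus its blank."""

    f_start: float
    f_end: float
    blank_start: float
    blank_end: float
    incubation: float                # h
    dilution_factor: float = 1.0     # 1 bulk water, 10 predator vials

    def __post_init__(self) -> None:
        if self.incubation <= 0:
            raise ValidationError("incubation must be > 0")
        if self.dilution_factor < 1:
            raise ValidationError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line fluorescence = slope·[AMC] + intercept."""

    slope: float           # FU per nM
    intercept: float       # FU
    r_squared: float
    n_standards: int

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValidationError("calibration slope must be > 0")
        if self.n_standards < 2:
            raise ValidationError("calibration needs >= 2 standards")


def fit_calibration(standards: Sequence[tuple[float, float]]) -> CalibrationCurve:
    """Ordinary least squares line through (concentration nM, fluorescence)
    standards; requires >= 2 distinct concentrations."""
    conc = np.asarray([s[0] for s in standards], dtype=float)
    fl = np.asarray([s[1] for s in standards], dtype=float)
    if len(conc) < 2 or np.ptp(conc) == 0:
        raise ValidationError("calibration needs >= 2 distinct concentrations")
    fit = stats.linregress(conc, fl)
    return CalibrationCurve(float(fit.slope), float(fit.intercept),
                            float(fit.rvalue) ** 2, len(conc))


def aminopeptidase_rate(assay: FluorescenceAssay, calib: CalibrationCurve) -> float:
    """Hydrolysis rate (nM AMC h⁻¹): blank-corrected fluorescence increase
    over slope over incubation time; negative corrected increase → 0."""
    dF = (assay.f_end - assay.f_start) - (assay.blank_end - assay.blank_start)
    if dF < 0:
        logger.warning("aminopeptidase_rate: negative corrected increase %.3g FU, floored to 0", dF)
        return 0.0
    return dF / calib.slope / assay.incubation


def ephyra_associated_rate(vial_rate: float, dilution: float,
                           seawater_rate: float, n_individuals: int = 1) -> float:
    """Per-individual hydrolysis rate of the predator-associated
    consortium: (vial rate × dilution − ambient seawater rate)/n."""
    if dilution < 1:
        raise ValidationError("dilution must be >= 1")
    if n_individuals < 1:
        raise ValidationError("n_individuals must be >= 1")
    rate = (vial_rate * dilution - seawater_rate) / n_individuals
    if rate < 0:
        logger.warning("ephyra_associated_rate: negative rate %.3g floored to 0", rate)
        return 0.0
    return rate


def leucine_incorporation(assay: LeucineAssay) -> float:
    """Leucine incorporation rate (nmol Leu L⁻¹ h⁻¹) from DPM.

    net DPM = mean(samples) − killed (floored at 0); moles via
    DPM / (2.22×10¹² DPM Ci⁻¹ × SA Ci mmol⁻¹); scaled per litre per hour.
    """
    net = float(np.mean(assay.dpm_samples)) - assay.dpm_killed
    if net < 0:
        logger.warning("leucine_incorporation: net DPM %.3g floored to 0", net)
        net = 0.0
    mmol = net / (DPM_PER_CI * assay.specific_activity)
    nmol = mmol * 1e6
    litres = assay.sample_volume / 1000.0
    return nmol / litres / assay.incubation


def heterotrophic_carbon_production(leu_rate: float,
                                    conversion: float = LEU_TO_CARBON_KG_PER_MOL,
                                    isotope_dilution: float = ISOTOPE_DILUTION) -> float:
    """HCP (μg C L⁻¹ h⁻¹) = leucine rate (nmol L⁻¹ h⁻¹) × 1.55 μg C nmol⁻¹
    × twofold isotope dilution."""
    if leu_rate < 0:
        raise ValidationError("leu_rate must be >= 0")
    return leu_rate * conversion * isotope_dilution
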