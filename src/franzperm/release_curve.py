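"""Sampling-corrected cumulative release and percent-of-dose profiles.

In a Franz cell with withdraw-and-replace sampling, each withdrawn
aliquot removes analyte from the receptor, so later concentration
readings under-report the total amount transferred. The cumulative
amount permeated per unit area at sample *n* corrects for this:

    Qn = (Cn·Vc + Σ_{i=1..n−1} Ci·Vs) / A        [µg/cm²]

where Cn is the measured receptor concentration at sample n (µg/mL),
Vc the receptor volume (mL), Vs the withdrawn-aliquot volume (mL) and
A the orifice area (cm²). The correction is exact mass bookkeeping:
under ideal sampling, Qn·A equals the true mass transferred through the
membrane by time n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .study_data import (
    AnalyteSpec,
    ConcentrationSeries,
    ConfigError,
    DoseSpec,
    FranzCellSpec,
    ValidationError,
)

CENSOR_POLICIES = ("zero", "half_loq", "keep")


def censor_below_loq(
    series: ConcentrationSeries,
    analyte: AnalyteSpec | None = None,
    policy: str = "zero",
) -> ConcentrationSeries:
    """Apply the assay limit-of-quantification to a concentration series.

    Readings strictly below the LoQ are replaced according to ``policy``:
    ``zero`` (default) sets them to 0, ``half_loq`` to LoQ/2, ``keep``
    leaves them untouched. A reading exactly at the LoQ is quantifiable
    and is never altered. The number of replacements is recorded in
    ``metadata['n_censored']``.
    """
    if policy not in CENSOR_POLICIES:
        raise ConfigError(f"unknown censoring policy {policy!r}; expected one of {CENSOR_POLICIES}")
    analyte = analyte or series.analyte
    if analyte is None:
        raise ConfigError(f"{series.cell_id}: no analyte (hence no LoQ) available for censoring")
    if policy == "keep":
        out = series.replace(metadata={**series.metadata, "n_censored": 0})
        return out
    loq = analyte.loq_ug_ml
    c = series.concentrations_ug_ml.copy()
    below = c < loq
    c[below] = 0.0 if policy == "zero" else loq / 2.0
    return series.replace(
        concentrations_ug_ml=c,
        metadata={**series.metadata, "n_censored": int(below.sum()), "censor_policy": policy},
    )


@dataclass
class CumulativeProfile:
    """Cumulative amount permeated per unit area over the sampling times."""

    cell_id: str
    times_h: np.ndarray
    qn_ug_cm2: np.ndarray
    n_samples: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.qn_ug_cm2 = np.asarray(self.qn_ug_cm2, dtype=float)
        if self.times_h.shape != self.qn_ug_cm2.shape:
            raise ValidationError(f"{self.cell_id}: times and Qn must align")
        if not self.n_samples:
            self.n_samples = self.times_h.size

    def __len__(self) -> int:
        return self.times_h.size


@dataclass
class PercentProfile:
    """Cumulative permeation expressed as percent of the applied dose."""

    times_h: np.ndarray
    percent: np.ndarray
    basis: str = "applied_dose"

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.percent = np.asarray(self.percent, dtype=float)


def cumulative_amount(series: ConcentrationSeries, cell: FranzCellSpec) -> CumulativeProfile:
    """Compute the sampling-corrected cumulative amount Qn (µg/cm²).

    The correction sum runs over all strictly earlier samples, including
    a time-0 sample when present (it is typically ~0 but participates
    like any other withdrawn aliquot). Negative measured concentrations
    (instrument noise) are clipped to 0 first; the clip count is reported
    in ``metadata['n_clipped_negative']``.
    """
    vc, vs, area = cell.receptor_volume_ml, cell.sample_volume_ml, cell.orifice_area_cm2
    if vs >= vc:
        raise ValidationError("sample volume Vs must be smaller than receptor volume Vc")
    c = np.asarray(series.concentrations_ug_ml, dtype=float)
    n_neg = int((c < 0).sum())
    if n_neg:
        c = np.clip(c, 0.0, None)
    # running sum of earlier withdrawn-aliquot masses: Σ_{i<n} Ci·Vs
    prior = np.concatenate([[0.0], np.cumsum(c[:-1] * vs)]) if c.size else np.empty(0)
    qn = (c * vc + prior) / area
    return CumulativeProfile(
        cell_id=series.cell_id,
        times_h=series.times_h.copy(),
        qn_ug_cm2=qn,
        metadata={**series.metadata, "n_clipped_negative": n_neg},
    )


def percent_of_dose(
    profile: CumulativeProfile,
    dose: DoseSpec,
    cell: FranzCellSpec,
    basis: str = "applied_dose",
) -> PercentProfile:
    """Express a cumulative profile as cumulative percent permeated.

    With ``basis='applied_dose'`` (default), percent_n = Qn·A / dose × 100,
    i.e. the fraction of the applied donor mass found in the receptor.
    ``basis='recovered'`` normalizes by the final cumulative amount
    instead, which rescales the terminal point to 100%.
    """
    mass = profile.qn_ug_cm2 * cell.orifice_area_cm2
    if basis == "applied_dose":
        denom = dose.applied_mass_ug
        if denom <= 0:
            raise ValidationError("applied mass must be positive")
    elif basis == "recovered":
        denom = float(mass[-1]) if mass.size else 0.0
        if denom <= 0:
            raise ValidationError("cannot normalize by recovered amount: final amount is zero")
    else:
        raise ConfigError(f"unknown percent basis {basis!r}")
    return PercentProfile(times_h=profile.times_h.copy(), percent=mass / denom * 100.0, basis=basis)
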