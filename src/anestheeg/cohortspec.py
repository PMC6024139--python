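"""Age-varying population spectrogram.

The cohort's spectral development is summarized by evaluating, at each age on
a 0.5-year grid from 2 to 23 years, the per-frequency median spectrum over all
subjects within ±2 years of that age. The median is taken in dB (equivalently
in linear power, since the median commutes with monotone transforms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral import SpectralEstimate


@dataclass
class AgeVaryingSpectrogram:
    """Median power (dB) on an age × frequency grid; NaN where a bin is empty."""

    age_grid: np.ndarray
    freqs: np.ndarray
    power_db: np.ndarray
    n_subjects_per_bin: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format (age, freq, power_db, n) table."""
        ages = np.repeat(self.age_grid, self.freqs.size)
        freqs = np.tile(self.freqs, self.age_grid.size)
        n = np.repeat(self.n_subjects_per_bin, self.freqs.size)
        return pd.DataFrame(
            {"age": ages, "freq": freqs,
             "power_db": self.power_db.ravel(), "n": n}
        )


def age_varying_spectrogram(
    spectra: list[SpectralEstimate],
    ages: list[float],
    lo_age: float = 2.0,
    hi_age: float = 23.0,
    halfwidth: float = 2.0,
    step: float = 0.5,
) -> AgeVaryingSpectrogram:
    """Per-frequency median spectrum in overlapping ±``halfwidth``-year windows.

    One spectrum per subject (their selected-epoch spectrum) on a common
    frequency grid; grid ages run from ``lo_age`` to ``hi_age`` in ``step``
    increments. Empty bins are flagged NaN with count 0, not interpolated.
    """
    if not spectra:
        raise ValueError("no subjects")
    if len(spectra) != len(ages):
        raise ValueError("one age per spectrum required")
    freqs = spectra[0].freqs
    for est in spectra[1:]:
        if est.freqs.shape != freqs.shape or not np.allclose(est.freqs, freqs):
            raise ValueError("frequency grid mismatch")
    power = np.stack([est.power_db for est in spectra])
    if power.ndim != 2:
        raise ValueError("expected one spectrum (not a spectrogram) per subject")
    ages_arr = np.asarray(ages, dtype=float)
    age_grid = np.round(np.arange(lo_age, hi_age + step / 2, step), 10)
    out = np.full((age_grid.size, freqs.size), np.nan)
    counts = np.zeros(age_grid.size, dtype=int)
    for i, a in enumerate(age_grid):
        mask = np.abs(ages_arr - a) <= halfwidth
        counts[i] = int(mask.sum())
        if counts[i]:
            out[i] = np.median(power[mask], axis=0)
    return AgeVaryingSpectrogram(age_grid, freqs.copy(), out, counts)
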