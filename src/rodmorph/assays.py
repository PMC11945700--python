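"""Non-imaging readouts: Laurdan generalized polarization and growth curves.

Laurdan is a membrane probe whose emission shifts with lipid packing: in an
ordered (gel-like) membrane it emits near 440 nm, in a fluid membrane the
emission red-shifts toward 490 nm.  Generalized polarization condenses the
spectrum into one number,

    GP = (RFI_440 - RFI_490) / (RFI_440 + RFI_490),

bounded in [-1, 1]; lower GP means a more fluid membrane.  Growth curves
(OD600 over time, replicate wells) are summarised as mean ± sample SD per
timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "EmissionSpectrum",
    "GPResult",
    "GrowthCurve",
    "laurdan_gp",
    "gp_from_spectrum",
    "growth_summary",
]


@dataclass(frozen=True)
class EmissionSpectrum:
    """One emission scan: wavelengths (nm, strictly ascending) and RFI."""

    wavelengths: np.ndarray
    rfi: np.ndarray
    sample_id: str = ""
    replicate: int = 0
    blank_rfi: Optional[np.ndarray] = None  # unstained-control spectrum

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        r = np.asarray(self.rfi, dtype=float)
        if w.ndim != 1 or w.size != r.size:
            raise ValueError("wavelengths and rfi must be 1-D and equal length")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly ascending")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "rfi", r)
        if self.blank_rfi is not None:
            b = np.asarray(self.blank_rfi, dtype=float)
            if b.size != w.size:
                raise ValueError("blank_rfi length must match wavelengths")
            object.__setattr__(self, "blank_rfi", b)


@dataclass(frozen=True)
class GPResult:
    gp: float
    rfi_440: float
    rfi_490: float
    blank_subtracted: bool = False

    def __post_init__(self) -> None:
        if abs(self.gp) > 1.0 + 1e-12:
            raise ValueError("GP must lie in [-1, 1]")


@dataclass(frozen=True)
class GrowthCurve:
    """OD600 time series: times in hours, od600 as (replicate, timepoint)."""

    time: np.ndarray
    od600: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        if od.ndim != 2:
            raise ValueError("od600 must be a replicate x timepoint matrix")
        if od.shape[0] < 2:
            raise ValueError("need >= 2 replicates for an SD")
        if od.shape[1] != t.size:
            raise ValueError("ragged replicates: od600 columns must match time")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly ascending")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "od600", od)


def laurdan_gp(rfi_440: float, rfi_490: float,
               blank_subtracted: bool = False) -> GPResult:
    """GP = (RFI440 - RFI490) / (RFI440 + RFI490)."""
    if rfi_440 < 0 or rfi_490 < 0:
        raise ValueError("intensities must be non-negative")
    denom = rfi_440 + rfi_490
    if denom <= 0:
        raise ValueError("RFI440 + RFI490 must be positive")
    return GPResult(gp=(rfi_440 - rfi_490) / denom, rfi_440=float(rfi_440),
                    rfi_490=float(rfi_490), blank_subtracted=blank_subtracted)


def _nearest(spectrum: EmissionSpectrum, target_nm: float) -> float:
    """RFI at the sampled wavelength nearest ``target_nm`` (tie -> lower).

    Blank subtraction (when a blank spectrum is attached) happens before
    extraction; negative post-subtraction intensities are floored at 0.
    """
    w = spectrum.wavelengths
    if target_nm < w[0] or target_nm > w[-1]:
        raise ValueError(f"{target_nm} nm outside the scanned range "
                         f"[{w[0]}, {w[-1]}]")
    d = np.abs(w - target_nm)
    # ties broken toward the lower wavelength: argmin takes the first min
    i = int(np.argmin(d))
    rfi = spectrum.rfi
    if spectrum.blank_rfi is not None:
        rfi = np.maximum(rfi - spectrum.blank_rfi, 0.0)
    return float(rfi[i])


def gp_from_spectrum(spectrum: EmissionSpectrum) -> GPResult:
    """GP from a full emission scan (needs coverage of 440 and 490 nm)."""
    r440 = _nearest(spectrum, 440.0)
    r490 = _nearest(spectrum, 490.0)
    return laurdan_gp(r440, r490,
                      blank_subtracted=spectrum.blank_rfi is not None)


def growth_summary(curve: GrowthCurve):
    """Per-timepoint mean ± sample SD table (one row per timepoint)."""
    import pandas as pd

    return pd.DataFrame({
        "time_h": curve.time,
        "mean_od600": curve.od600.mean(axis=0),
        "sd_od600": curve.od600.std(axis=0, ddof=1),
    })
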