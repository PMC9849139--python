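"""Fluorescence -> concentration -> copies-per-NPC conversions.

Calibrated imaging converts background-subtracted fluorescence intensity to
protein concentration (nM) through a linear FCS-derived calibration.  The
nuclear-envelope concentration, measured inside a thin mask of width
``mask_width`` (um, treated as an effective slab thickness), converts to a
surface density (copies/um^2); dividing by the NPC surface density
(NPC/um^2, from STED counting on fixed nuclei, optionally corrected for
fixation shrinkage) yields copies per NPC.  Multiplying a compartment
concentration by its volume gives absolute pool sizes.

Unit chain: nM -> copies/um^3 (x 0.602214), x um -> copies/um^2,
/ (NPC/um^2) -> copies/NPC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["CalibrationCurve", "StoichiometryRecord", "NM_UM3_TO_COPIES",
           "intensity_to_concentration", "copies_per_pore",
           "corrected_npc_density", "copies_timecourse", "compartment_pool"]

#: molecules per (nM * um^3): 1e-9 mol/L * N_A / 1e15 um^3/L
NM_UM3_TO_COPIES = 6.02214076e-1


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear intensity-to-concentration calibration from FCS.

    ``concentration = slope * (intensity - background_intensity) + intercept``
    """

    slope: float                 # nM per intensity unit
    intercept: float = 0.0       # nM
    background_intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"calibration slope must be positive, got {self.slope}")


@dataclass(frozen=True)
class StoichiometryRecord:
    """Inputs of the copies-per-NPC calculation for one Nup."""

    nup_id: str
    ne_surface_density: float       # copies / um^2 on the nuclear envelope
    npc_density: float              # NPC / um^2 as measured (fixed cells)
    shrinkage: float = 0.0          # volume fraction lost to fixation, e.g. 0.091

    def __post_init__(self) -> None:
        if self.npc_density <= 0:
            raise ValueError("NPC density must be positive")
        if not (0.0 <= self.shrinkage < 1.0):
            raise ValueError("shrinkage must be a volume fraction in [0, 1)")


def intensity_to_concentration(intensity, cal: CalibrationCurve) -> np.ndarray:
    """Apply the linear calibration after background subtraction (nM).

    Values that come out negative (background fluctuations) are floored at
    0 with a warning; they are never propagated downstream.
    """
    intensity = np.asarray(intensity, float)
    conc = cal.slope * (intensity - cal.background_intensity) + cal.intercept
    if np.any(conc < 0):
        warnings.warn("negative concentration after background subtraction; "
                      "floored at 0", stacklevel=2)
        conc = np.maximum(conc, 0.0)
    if conc.ndim == 0:
        return float(conc)
    return conc


def corrected_npc_density(npc_density: float, shrinkage: float,
                          mode: str = "area") -> float:
    """NPC density corrected for fixation-induced nuclear shrinkage.

    Fixation shrinks the nucleus, so densities counted on fixed nuclei
    overestimate the live density.  The stated shrinkage is a volume
    fraction ``s``; in ``"area"`` mode the surface area scales as
    ``(1-s)^(2/3)`` and the live density is ``measured * (1-s)^(2/3)``.
    ``"volume"`` mode applies the volume factor ``(1-s)`` directly for
    users who prefer the uncorrected-area convention.
    """
    if mode == "area":
        return npc_density * (1.0 - shrinkage) ** (2.0 / 3.0)
    if mode == "volume":
        return npc_density * (1.0 - shrinkage)
    raise ValueError(f"unknown shrinkage mode {mode!r}")


def copies_per_pore(record: StoichiometryRecord, shrinkage_mode: str = "area"
                    ) -> float:
    """Copies per NPC = NE surface density / shrinkage-corrected NPC density."""
    density = corrected_npc_density(record.npc_density, record.shrinkage,
                                    shrinkage_mode)
    return record.ne_surface_density / density


def concentration_to_surface_density(concentration_nM, mask_width_um: float = 0.75
                                     ) -> np.ndarray:
    """Convert a mask concentration (nM) to copies/um^2.

    The nuclear-envelope mask of width ``mask_width_um`` is treated as the
    effective slab thickness: copies/um^2 = nM * 0.602214 * width.
    """
    return np.asarray(concentration_nM, float) * NM_UM3_TO_COPIES * mask_width_um


def copies_timecourse(curve, amplitude: float | None = None, *,
                      total_ne_copies=None, area_um2=None,
                      npc_density: float | None = None) -> np.ndarray:
    """Copies per assembling NPC over time.

    Two entry points:

    * normalized assembly ``curve`` (0..1) plus a mature-copy ``amplitude``
      (externally imposed for subphysiologically expressed Nups, e.g. 32
      for Nup153 and 16 for Pom121): ``copies(t) = amplitude * curve(t)``;
    * ``total_ne_copies(t)`` with the nuclear surface ``area_um2(t)`` and
      the (constant) ``npc_density``:
      ``copies(t) = total(t) / (area(t) * npc_density)``.
    """
    if amplitude is not None:
        return float(amplitude) * np.asarray(curve, float)
    if total_ne_copies is None or area_um2 is None or npc_density is None:
        raise ValueError("provide either an amplitude or "
                         "(total_ne_copies, area_um2, npc_density)")
    total = np.asarray(total_ne_copies, float)
    area = np.asarray(area_um2, float)
    if total.shape != area.shape:
        raise ValueError("total_ne_copies and area_um2 must share a grid")
    return total / (area * npc_density)


def compartment_pool(concentration_nM: float, volume_um3: float) -> float:
    """Absolute copy count of a compartment pool: nM x um^3 x 0.602214."""
    if concentration_nM < 0 or volume_um3 < 0:
        raise ValueError("concentration and volume must be non-negative")
    return concentration_nM * volume_um3 * NM_UM3_TO_COPIES


def copies_table(kinetics_curves: Mapping[str, np.ndarray], t,
                 amplitudes: Mapping[str, float]) -> pd.DataFrame:
    """Tidy copies-per-NPC table (nup, t_min, copies) from normalized curves."""
    rows = []
    t = np.asarray(t, float)
    for nup in sorted(kinetics_curves):
        rows.append(pd.DataFrame({
            "nup": nup, "t_min": t,
            "copies": copies_timecourse(kinetics_curves[nup],
                                        amplitudes[nup])}))
    return pd.concat(rows, ignore_index=True)
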