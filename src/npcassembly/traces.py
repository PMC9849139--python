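"""Containers and preprocessing for dual-region nuclear-envelope traces.

A :class:`RegionTraces` holds, for one Nup, the mean background-subtracted
and normalized fluorescence in the non-core and core regions of the nuclear
envelope on a shared time grid (minutes after anaphase onset), together with
the per-time-point standard deviations used as chi-square weights.

Raw traces are preprocessed the way the imaging pipeline treats them:
the background is the average of the first three time points, and the
curves are normalized by their average over the 100-120 min plateau window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["RegionTraces", "PreprocessingError", "preprocess",
           "traces_to_frame", "frame_to_traces", "write_traces_csv",
           "read_traces_csv"]


class PreprocessingError(ValueError):
    """Raised when a trace cannot be background-subtracted or normalized."""


@dataclass(frozen=True)
class RegionTraces:
    """Non-core and core intensity time series of one Nup.

    Attributes
    ----------
    t : ndarray, minutes after anaphase onset (shared by both regions)
    non_core, core : ndarray, mean normalized intensities N(t_j), C(t_j)
    sigma_non_core, sigma_core : ndarray, per-time-point standard deviations
    n_cells : int, number of cells averaged per time point
    """

    t: np.ndarray
    non_core: np.ndarray
    core: np.ndarray
    sigma_non_core: np.ndarray
    sigma_core: np.ndarray
    n_cells: int = 1

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, float) for a in
                  (self.t, self.non_core, self.core,
                   self.sigma_non_core, self.sigma_core)]
        for name, arr in zip(("t", "non_core", "core",
                              "sigma_non_core", "sigma_core"), arrays):
            object.__setattr__(self, name, arr)
            if arr.shape != arrays[0].shape:
                raise ValueError(f"{name} does not match the time grid shape")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def n_points(self) -> int:
        return self.t.size


def preprocess(traces: RegionTraces, n_background: int = 3,
               norm_window: tuple[float, float] = (100.0, 120.0)) -> RegionTraces:
    """Background-subtract and normalize one Nup's regional traces.

    The background of each region is the mean of its first ``n_background``
    time points; the normalization constant is the mean of the
    background-subtracted curve inside ``norm_window`` (inclusive).  The
    standard deviations are rescaled by the same normalization factor so
    that standardized residuals are unchanged.

    Raises
    ------
    PreprocessingError
        If the grid does not cover the background points or the window, or
        if a plateau is (numerically) zero, e.g. for a constant trace.
    """
    if traces.n_points < n_background:
        raise PreprocessingError(
            f"need at least {n_background} initial points for the background")
    in_window = (traces.t >= norm_window[0]) & (traces.t <= norm_window[1])
    if not np.any(in_window):
        raise PreprocessingError(
            f"normalization window {norm_window} not covered by the time grid")

    def _one(y: np.ndarray, sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        background = float(np.mean(y[:n_background]))
        shifted = y - background
        plateau = float(np.mean(shifted[in_window]))
        if plateau <= 0 or not np.isfinite(plateau) or np.isclose(plateau, 0.0):
            raise PreprocessingError(
                "plateau mean over the normalization window is zero or "
                "negative; trace cannot be normalized")
        return shifted / plateau, sigma / plateau

    non_core, s_n = _one(traces.non_core, traces.sigma_non_core)
    core, s_c = _one(traces.core, traces.sigma_core)
    return replace(traces, non_core=non_core, core=core,
                   sigma_non_core=s_n, sigma_core=s_c)


# ---------------------------------------------------------------------------
# tidy CSV interchange: columns nup, region, t_min, mean, sd, n_cells

def traces_to_frame(traces: Mapping[str, RegionTraces]) -> pd.DataFrame:
    rows = []
    for nup, tr in traces.items():
        for region, mean, sd in (("non_core", tr.non_core, tr.sigma_non_core),
                                 ("core", tr.core, tr.sigma_core)):
            rows.append(pd.DataFrame({
                "nup": nup, "region": region, "t_min": tr.t,
                "mean": mean, "sd": sd, "n_cells": tr.n_cells}))
    return pd.concat(rows, ignore_index=True)


def frame_to_traces(df: pd.DataFrame) -> dict[str, RegionTraces]:
    out: dict[str, RegionTraces] = {}
    for nup, group in df.groupby("nup", sort=True):
        pieces = {}
        for region, sub in group.groupby("region"):
            sub = sub.sort_values("t_min")
            pieces[region] = sub
        if set(pieces) != {"non_core", "core"}:
            raise ValueError(f"nup {nup!r} must have non_core and core regions")
        nc, co = pieces["non_core"], pieces["core"]
        if not np.array_equal(nc["t_min"].to_numpy(), co["t_min"].to_numpy()):
            raise ValueError(f"nup {nup!r}: regions are on different time grids")
        out[str(nup)] = RegionTraces(
            t=nc["t_min"].to_numpy(float),
            non_core=nc["mean"].to_numpy(float),
            core=co["mean"].to_numpy(float),
            sigma_non_core=nc["sd"].to_numpy(float),
            sigma_core=co["sd"].to_numpy(float),
            n_cells=int(nc["n_cells"].iloc[0]),
        )
    return out


def write_traces_csv(traces: Mapping[str, RegionTraces], path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces_csv(path) -> dict[str, RegionTraces]:
    return frame_to_traces(pd.read_csv(path))
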