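"""Synthetic dual-region trace generation.

The generator is the forward model of the kinetic theory: noiseless means
are the exact two-component mixtures of delayed Hill curves, and noise is
additive Gaussian with a time-constant standard deviation on the
normalized mean trace (matching the chi-square weighting used in
fitting).  With a fixed seed the output is bit-identical.

``REFERENCE_PANEL`` is a 10-Nup parameter set representative of human NPC
assembly: postmitotic assembly essentially complete by ~15 min with the
Y-complex, Pom121 and Nup153 arriving within the first minutes, the
central ring shortly after and the filament proteins (Nup214, Tpr,
Nup358) last; interphase assembly stretched over ~100 min, initiated by
Nup153 then Pom121 then the Y-complex, with the nuclear filament Tpr and
Nup214 recruited *before* the central ring complex — the inverted order
relative to the postmitotic pathway — and Nup358 terminal in both.
``DEFAULT_MIXING`` carries the global regional fractions
(f_n = 0.857, f_c = 0.295) and the 2-min core initiation delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .kinetics import MixingParams, NupKinetics, mix_forward
from .traces import RegionTraces

__all__ = ["SimulationConfig", "simulate_region_traces",
           "DEFAULT_MIXING", "REFERENCE_PANEL", "REFERENCE_AMPLITUDES"]

DEFAULT_MIXING = MixingParams(f_n=0.857, f_c=0.295, d_c=2.0)

#: (n_p, K_p, n_i, K_i) per Nup; medians in minutes.
REFERENCE_PANEL: tuple[NupKinetics, ...] = (
    NupKinetics("Nup107", n_p=2.5, K_p=1.2, n_i=4.0, K_i=30.0),
    NupKinetics("Seh1",   n_p=2.4, K_p=1.3, n_i=4.0, K_i=31.0),
    NupKinetics("Nup153", n_p=2.6, K_p=1.0, n_i=5.0, K_i=12.0),
    NupKinetics("Pom121", n_p=2.2, K_p=1.4, n_i=4.5, K_i=20.0),
    NupKinetics("Nup93",  n_p=3.0, K_p=2.5, n_i=3.5, K_i=60.0),
    NupKinetics("Nup205", n_p=2.8, K_p=2.8, n_i=3.5, K_i=65.0),
    NupKinetics("Nup62",  n_p=3.0, K_p=3.2, n_i=3.2, K_i=70.0),
    NupKinetics("Nup214", n_p=2.5, K_p=5.5, n_i=3.8, K_i=42.0),
    NupKinetics("Tpr",    n_p=2.2, K_p=6.5, n_i=4.0, K_i=38.0),
    NupKinetics("Nup358", n_p=2.0, K_p=10.0, n_i=4.0, K_i=85.0),
)

#: mature copies per NPC (multiples of 8; 16/32/48 classes)
REFERENCE_AMPLITUDES: dict[str, float] = {
    "Nup107": 32, "Seh1": 32, "Nup153": 32, "Pom121": 16, "Nup93": 32,
    "Nup205": 16, "Nup62": 32, "Nup214": 16, "Tpr": 16, "Nup358": 16,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of one synthetic imaging experiment.

    Defaults emulate the live-imaging protocol: 30-s sampling (0.5 min)
    from anaphase onset to 120 min.  ``noise_sd`` is the standard
    deviation of the additive Gaussian noise on the normalized mean trace
    (relative to the plateau value 1); ``cells_per_nup`` is carried into
    the traces as metadata.  A 60-s cadence (as used for Pom121) is a
    ``time_step`` choice, not a special case.
    """

    kinetics: tuple[NupKinetics, ...] = REFERENCE_PANEL
    mixing: MixingParams = DEFAULT_MIXING
    time_step: float = 0.5
    t_max: float = 120.0
    noise_sd: float = 0.01
    cells_per_nup: int = 20
    seed: int = 0
    amplitudes: Mapping[str, float] = field(
        default_factory=lambda: dict(REFERENCE_AMPLITUDES))

    def __post_init__(self) -> None:
        if self.time_step <= 0 or self.t_max <= 0:
            raise ValueError("time_step and t_max must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def nup_count(self) -> int:
        return len(self.kinetics)

    @property
    def t_grid(self) -> np.ndarray:
        n = int(round(self.t_max / self.time_step))
        return np.arange(n + 1) * self.time_step


def simulate_region_traces(config: SimulationConfig,
                           scale_by_amplitude: bool = False
                           ) -> dict[str, RegionTraces]:
    """Generate dual-region traces for every Nup in the configuration.

    Noiseless means follow the mixture model exactly (0 before the
    regional delay, plateau 1 — or the Nup's copy amplitude when
    ``scale_by_amplitude``); the reported per-point standard deviations
    equal the injected noise SD.
    """
    rng = np.random.default_rng(config.seed)
    t = config.t_grid
    out: dict[str, RegionTraces] = {}
    for kin in config.kinetics:
        n_curve, c_curve = mix_forward(kin, config.mixing, t)
        scale = (float(config.amplitudes[kin.nup_id])
                 if scale_by_amplitude else 1.0)
        n_curve = scale * n_curve
        c_curve = scale * c_curve
        sd = config.noise_sd * scale
        if config.noise_sd > 0:
            n_curve = n_curve + rng.normal(0.0, sd, t.size)
            c_curve = c_curve + rng.normal(0.0, sd, t.size)
        sigma = np.full(t.size, sd)
        out[kin.nup_id] = RegionTraces(
            t=t, non_core=n_curve, core=c_curve,
            sigma_non_core=sigma, sigma_core=sigma,
            n_cells=config.cells_per_nup)
    return out
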