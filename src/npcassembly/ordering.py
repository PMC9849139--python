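"""Assembly-timing statistics: median time, duration, ordering, correlation.

An assembly curve is a cumulative distribution of binding events, so its
Hill parameters summarize when and how sharply a Nup assembles: the median
assembly time is ``K`` (half of the binding events have occurred), and the
assembly duration is the window holding the central 80% of events (from
fraction alpha1 = 0.1 to alpha2 = 0.9),

    dT = K * ((alpha2/(1-alpha2))^(1/n) - (alpha1/(1-alpha1))^(1/n))
       = K * (9^(1/n) - 9^(-1/n)).

Both are intrinsic to the assembly mechanism and independent of the
initiation delay.  Ordering Nups by median time per pathway, with their
copy-number amplitudes attached, gives the assembly-order map; a positive
correlation between median time and duration across Nups is the kinetic
signature of a sequential mechanism (see :mod:`npcassembly.chain`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .kinetics import NupKinetics

__all__ = ["ALPHA1", "ALPHA2", "median_and_duration", "order_summary",
           "rank_inversions", "time_duration_correlation", "CorrelationResult"]

ALPHA1 = 0.1
ALPHA2 = 0.9
_PATHWAY_PARAMS = {"postmitotic": ("n_p", "K_p"), "interphase": ("n_i", "K_i")}


def median_and_duration(kin: NupKinetics, pathway: str) -> tuple[float, float]:
    """Median assembly time and 80%-bracket duration for one pathway.

    ``pathway`` is ``"postmitotic"`` (uses ``n_p, K_p``) or
    ``"interphase"`` (uses ``n_i, K_i``).  Delay-independent by definition.
    """
    try:
        n_name, k_name = _PATHWAY_PARAMS[pathway]
    except KeyError:
        raise ValueError(f"unknown pathway {pathway!r}") from None
    n = getattr(kin, n_name)
    K = getattr(kin, k_name)
    ratio = ALPHA2 / (1.0 - ALPHA2)        # = 9 for the 0.1/0.9 bracket
    duration = K * (ratio ** (1.0 / n) - ratio ** (-1.0 / n))
    return K, duration


def order_summary(kinetics: Mapping[str, NupKinetics],
                  amplitudes: Mapping[str, float] | None = None,
                  include_delay: float = 0.0) -> pd.DataFrame:
    """Per-pathway table of Nups ordered by median assembly time.

    Columns: nup, pathway, median_min, duration_min, copies.  Ties in the
    median are broken by Nup label for reproducibility.  ``include_delay``
    optionally shifts the reported medians by the core initiation delay
    (the default convention keeps timings delay-free).
    """
    rows = []
    for nup in sorted(kinetics):
        kin = kinetics[nup]
        for pathway in ("postmitotic", "interphase"):
            median, duration = median_and_duration(kin, pathway)
            rows.append({
                "nup": nup, "pathway": pathway,
                "median_min": median + include_delay,
                "duration_min": duration,
                "copies": float(amplitudes[nup]) if amplitudes else np.nan,
            })
    df = pd.DataFrame(rows)
    df = df.sort_values(["pathway", "median_min", "nup"],
                        kind="stable").reset_index(drop=True)
    df["rank"] = df.groupby("pathway").cumcount() + 1
    return df


def rank_inversions(summary: pd.DataFrame) -> list[tuple[str, str]]:
    """Pairs of Nups whose assembly order differs between the two pathways.

    A pair (a, b) is reported when a assembles strictly before b
    postmitotically but strictly after b in interphase (or vice versa) --
    e.g. the central-ring vs nuclear-filament inversion.
    """
    ranks = {pathway: dict(zip(sub["nup"], sub["rank"]))
             for pathway, sub in summary.groupby("pathway")}
    pm, ip = ranks.get("postmitotic", {}), ranks.get("interphase", {})
    nups = sorted(set(pm) & set(ip))
    out = []
    for i, a in enumerate(nups):
        for b in nups[i + 1:]:
            if (pm[a] - pm[b]) * (ip[a] - ip[b]) < 0:
                out.append((a, b))
    return out


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float
    pvalue: float
    method: str
    degenerate: bool = False    # zero variance in either coordinate


def time_duration_correlation(summary: pd.DataFrame, method: str = "spearman"
                              ) -> dict[str, CorrelationResult]:
    """Correlation of (median time, duration) pairs, per pathway.

    Rank (Spearman) correlation by default; ``method="pearson"`` for the
    linear statistic.  Requires >= 3 Nups per pathway; zero variance in
    either coordinate is flagged as degenerate (NaN coefficient).
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    out = {}
    for pathway, sub in summary.groupby("pathway"):
        x = sub["median_min"].to_numpy()
        y = sub["duration_min"].to_numpy()
        if x.size < 3:
            raise ValueError(
                f"correlation undefined for {pathway}: need >= 3 Nups, got {x.size}")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[pathway] = CorrelationResult(np.nan, np.nan, method, True)
            continue
        if method == "spearman":
            r, p = stats.spearmanr(x, y)
        else:
            r, p = stats.pearsonr(x, y)
        out[pathway] = CorrelationResult(float(r), float(p), method)
    return out
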