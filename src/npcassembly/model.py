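"""Weighted least-squares estimation of the two-component assembly model.

The estimation problem: for ``P`` Nups observed in two nuclear-envelope
regions, minimize the weighted sum of squared standardized residuals

    chi2 = sum_j [ ((N(t_j) - n(t_j)) / sigma_N(t_j))^2
                 + ((C(t_j) - c(t_j)) / sigma_C(t_j))^2 ]

over the per-Nup Hill parameters ``(n_p, K_p, n_i, K_i)`` and the mixing
parameters.  Two parameterizations are supported:

``reduced``
    one global ``(f_n, f_c, d_c)`` shared by all Nups -> ``4 P + 3`` free
    parameters;
``full``
    per-Nup fractions ``(f_n, f_c)`` plus one shared delay ``d_c`` ->
    ``6 P + 1`` free parameters.

The core delay ``d_c`` is estimated by a discrete grid search (default
0-6 min in 1-min steps) with a continuous bounded least-squares fit nested
inside each grid point; ``K`` and ``n`` are log-parameterized to enforce
positivity.  Confidence intervals come from the profile likelihood: the
interval for a parameter is the set of fixed values whose re-optimized
chi2 stays below the minimum plus the chi-square(1 d.f.) quantile.

Usage follows the Model/Results convention::

    model = NupAssemblyModel(traces, mode="reduced")
    res = model.fit(seed=0)
    print(res.summary())
    ci = res.profile_ci("f_n")
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares
from scipy.special import expit
from scipy.stats import chi2 as _chi2_dist

from .kinetics import (AssemblyCurvePair, InvalidParameterError, MixingParams,
                       NupKinetics, mix_forward, unmix)
from .traces import RegionTraces, frame_to_traces

__all__ = [
    "FitSpec", "NupAssemblyModel", "NupAssemblyResults", "ProfileInterval",
    "chi_square", "compare_bic", "profile_interval_from_function",
    "WeightingError", "FitFailureError", "ComparisonError",
]

_LOGN_BOUNDS = (math.log(0.2), math.log(50.0))
_LOGK_BOUNDS = (math.log(0.05), math.log(1000.0))
_F_BOUNDS = (0.0, 1.0)


class WeightingError(ValueError):
    """A standard deviation used as a chi-square weight is not positive."""


class FitFailureError(RuntimeError):
    """No multistart run converged; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class ComparisonError(ValueError):
    """Two fits cannot be compared because they use different data."""


@dataclass(frozen=True)
class FitSpec:
    """Configuration of one estimation run.

    ``dc_grid`` is the candidate set for the core initiation delay in
    minutes (discrete grid search); ``multistart`` perturbed restarts guard
    against local minima of the multimodal Hill objective; ``sigma_floor``
    replaces non-positive standard deviations so that noiseless synthetic
    data remain fittable.
    """

    mode: str = "reduced"
    dc_grid: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    multistart: int = 8
    seed: int = 0
    sigma_floor: float = 1e-3
    xtol: float = 1e-10
    ftol: float = 1e-10
    max_nfev: int = 2000

    def __post_init__(self) -> None:
        if self.mode not in ("reduced", "full"):
            raise ValueError(f"mode must be 'reduced' or 'full', got {self.mode!r}")
        if len(self.dc_grid) == 0 or min(self.dc_grid) < 0:
            raise ValueError("dc_grid must be non-empty and non-negative")
        if self.multistart < 1:
            raise ValueError("multistart must be >= 1")


@dataclass(frozen=True)
class ProfileInterval:
    """Profile-likelihood confidence interval for a single parameter."""

    estimate: float
    lower: float
    upper: float
    level: float
    lower_at_bound: bool = False
    upper_at_bound: bool = False

    @property
    def one_sided(self) -> bool:
        return self.lower_at_bound or self.upper_at_bound


# ---------------------------------------------------------------------------
# chi-square


def _floored(sigma: np.ndarray, floor: float) -> np.ndarray:
    if floor == 0:
        if np.any(sigma <= 0):
            raise WeightingError("zero/negative sigma with sigma_floor=0")
        return sigma
    return np.maximum(sigma, floor)


def chi_square(kinetics: Mapping[str, NupKinetics],
               mixing: "MixingParams | Mapping[str, MixingParams]",
               traces: Mapping[str, RegionTraces],
               sigma_floor: float = 0.0) -> float:
    """Weighted sum of squared standardized residuals over all Nups.

    ``mixing`` may be a single shared :class:`MixingParams` (reduced model)
    or a per-Nup mapping (full model).  Exactly 0 when the model curves
    equal the data.
    """
    total = 0.0
    for nup, tr in traces.items():
        kin = kinetics[nup]
        mix = mixing[nup] if isinstance(mixing, Mapping) else mixing
        n_model, c_model = mix_forward(kin, mix, tr.t)
        sn = _floored(tr.sigma_non_core, sigma_floor)
        sc = _floored(tr.sigma_core, sigma_floor)
        total += float(np.sum(((tr.non_core - n_model) / sn) ** 2))
        total += float(np.sum(((tr.core - c_model) / sc) ** 2))
    return total


# ---------------------------------------------------------------------------
# vectorized residual engine

class _Stack:
    """Per-grid stacked data arrays for vectorized residual evaluation."""

    def __init__(self, t: np.ndarray, nup_idx: list[int],
                 N: np.ndarray, C: np.ndarray, Sn: np.ndarray, Sc: np.ndarray):
        self.t = t
        self.nup_idx = nup_idx          # columns in the global nup ordering
        self.N, self.C, self.Sn, self.Sc = N, C, Sn, Sc
        with np.errstate(divide="ignore"):
            self.log_t = np.where(t > 0, np.log(np.maximum(t, 1e-300)), -np.inf)

    def log_t_delayed(self, dc: float) -> np.ndarray:
        dt = self.t - dc
        with np.errstate(divide="ignore"):
            return np.where(dt > 0, np.log(np.maximum(dt, 1e-300)), -np.inf)


def _build_stacks(traces: Mapping[str, RegionTraces], nups: Sequence[str],
                  sigma_floor: float) -> list[_Stack]:
    groups: dict[bytes, list[int]] = {}
    for i, nup in enumerate(nups):
        key = traces[nup].t.tobytes()
        groups.setdefault(key, []).append(i)
    stacks = []
    for idxs in groups.values():
        t = traces[nups[idxs[0]]].t
        N = np.stack([traces[nups[i]].non_core for i in idxs])
        C = np.stack([traces[nups[i]].core for i in idxs])
        Sn = np.stack([_floored(traces[nups[i]].sigma_non_core, sigma_floor)
                       for i in idxs])
        Sc = np.stack([_floored(traces[nups[i]].sigma_core, sigma_floor)
                       for i in idxs])
        stacks.append(_Stack(t, idxs, N, C, Sn, Sc))
    return stacks


def _hill_block(log_t: np.ndarray, logn: np.ndarray, logK: np.ndarray) -> np.ndarray:
    # shape (P, M); log_t may contain -inf (t at/before the delay -> 0)
    n = np.exp(logn)
    arg = n[:, None] * (log_t[None, :] - logK[:, None])
    return expit(arg)


def _residuals_reduced(x: np.ndarray, stacks: list[_Stack], dc: float,
                       n_nups: int) -> np.ndarray:
    f_n, f_c = x[0], x[1]
    kin = x[2:].reshape(n_nups, 4)      # logn_p, logK_p, logn_i, logK_i
    out = []
    for st in stacks:
        k = kin[st.nup_idx]
        lt0 = st.log_t
        ltc = st.log_t_delayed(dc)
        pm_n = _hill_block(lt0, k[:, 0], k[:, 1])
        ip_n = _hill_block(lt0, k[:, 2], k[:, 3])
        pm_c = _hill_block(ltc, k[:, 0], k[:, 1])
        ip_c = _hill_block(ltc, k[:, 2], k[:, 3])
        n_model = f_n * pm_n + (1 - f_n) * ip_n
        c_model = f_c * pm_c + (1 - f_c) * ip_c
        out.append(((n_model - st.N) / st.Sn).ravel())
        out.append(((c_model - st.C) / st.Sc).ravel())
    return np.concatenate(out)


def _residuals_full_single(x: np.ndarray, st: _Stack, row: int, dc: float) -> np.ndarray:
    f_n, f_c = x[0], x[1]
    k = x[2:][None, :]
    lt0, ltc = st.log_t, st.log_t_delayed(dc)
    pm_n = _hill_block(lt0, k[:, 0], k[:, 1])[0]
    ip_n = _hill_block(lt0, k[:, 2], k[:, 3])[0]
    pm_c = _hill_block(ltc, k[:, 0], k[:, 1])[0]
    ip_c = _hill_block(ltc, k[:, 2], k[:, 3])[0]
    n_model = f_n * pm_n + (1 - f_n) * ip_n
    c_model = f_c * pm_c + (1 - f_c) * ip_c
    return np.concatenate([(n_model - st.N[row]) / st.Sn[row],
                           (c_model - st.C[row]) / st.Sc[row]])


# ---------------------------------------------------------------------------
# model


class NupAssemblyModel:
    """Two-component NPC assembly model over a panel of Nup region traces.

    Parameters
    ----------
    traces : mapping of nup id -> :class:`RegionTraces`
        Background-subtracted, normalized dual-region traces.
    mode : {"reduced", "full"}
        Shared vs per-Nup mixing fractions (the delay is always shared).
    """

    def __init__(self, traces: Mapping[str, RegionTraces], mode: str = "reduced",
                 dc_grid: Sequence[float] = (0, 1, 2, 3, 4, 5, 6),
                 sigma_floor: float = 1e-3):
        if not traces:
            raise ValueError("at least one Nup trace is required")
        self.traces = {nup: traces[nup] for nup in sorted(traces)}
        self.nups = list(self.traces)
        self.mode = mode
        self.dc_grid = tuple(float(d) for d in dc_grid)
        self.sigma_floor = float(sigma_floor)
        self._spec_defaults = FitSpec(mode=mode, dc_grid=self.dc_grid,
                                      sigma_floor=self.sigma_floor)
        self._stacks = _build_stacks(self.traces, self.nups, self.sigma_floor)
        self._row_of: dict[str, tuple[_Stack, int]] = {}
        for st in self._stacks:
            for row, i in enumerate(st.nup_idx):
                self._row_of[self.nups[i]] = (st, row)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "NupAssemblyModel":
        """Build the model from a tidy frame (nup, region, t_min, mean, sd)."""
        return cls(frame_to_traces(df), **kwargs)

    # -- bookkeeping ---------------------------------------------------

    @property
    def n_nups(self) -> int:
        return len(self.nups)

    @property
    def n_params(self) -> int:
        """Number of free parameters: ``4P + 3`` reduced, ``6P + 1`` full."""
        P = self.n_nups
        return 4 * P + 3 if self.mode == "reduced" else 6 * P + 1

    @property
    def n_obs(self) -> int:
        """Total residual count (both regions, all Nups, all time points)."""
        return sum(2 * tr.n_points for tr in self.traces.values())

    def _data_fingerprint(self) -> tuple:
        total = sum(float(np.sum(tr.non_core) + np.sum(tr.core))
                    for tr in self.traces.values())
        return (tuple(self.nups), self.n_obs, round(total, 9))

    # -- initial values ------------------------------------------------

    def _heuristic_kinetics_init(self, f_n: float, f_c: float, dc: float
                                 ) -> np.ndarray:
        """Data-driven starting values via crude unmixing and level crossings."""
        init = np.empty((self.n_nups, 4))
        mix = MixingParams(f_n=f_n, f_c=f_c, d_c=dc)
        for i, nup in enumerate(self.nups):
            tr = self.traces[nup]
            pair = unmix(tr.non_core, tr.core, mix, tr.t)
            for j, (curve, delay) in enumerate(((pair.pm, 0.0), (pair.ip, 0.0))):
                y = np.clip(curve, 0.0, 1.2)
                if y.size >= 5:     # light smoothing against noise
                    y = np.convolve(y, np.ones(5) / 5.0, mode="same")
                K0 = _crossing_time(tr.t, y, 0.5)
                t25 = _crossing_time(tr.t, y, 0.25)
                if K0 is None:
                    K0 = 0.5 * tr.t[-1]
                n0 = 2.0
                if t25 is not None and 0 < t25 < K0:
                    n0 = math.log(3.0) / math.log(K0 / t25)
                n0 = float(np.clip(n0, 0.5, 20.0))
                K0 = float(np.clip(K0, 0.1, 500.0))
                init[i, 2 * j] = math.log(n0)
                init[i, 2 * j + 1] = math.log(K0)
        return init

    # -- fitting -------------------------------------------------------

    def fit(self, spec: FitSpec | None = None, *, multistart: int | None = None,
            seed: int | None = None) -> "NupAssemblyResults":
        """Estimate all parameters; deterministic given ``seed``.

        The delay grid is scanned exhaustively; at each candidate delay a
        bounded nonlinear least-squares fit is run from ``multistart``
        starting points (one data-driven, the rest seeded perturbations)
        and the best chi2 over the whole grid is returned.
        """
        if spec is None:
            spec = self._spec_defaults
        if spec.mode != self.mode or tuple(spec.dc_grid) != self.dc_grid:
            spec = FitSpec(mode=self.mode, dc_grid=self.dc_grid,
                           multistart=spec.multistart, seed=spec.seed,
                           sigma_floor=self.sigma_floor, xtol=spec.xtol,
                           ftol=spec.ftol, max_nfev=spec.max_nfev)
        if multistart is not None:
            spec = FitSpec(**{**spec.__dict__, "multistart": multistart})
        if seed is not None:
            spec = FitSpec(**{**spec.__dict__, "seed": seed})

        rng = np.random.default_rng(spec.seed)
        dc_chi2: dict[float, float] = {}
        best = None
        for dc in spec.dc_grid:
            if self.mode == "reduced":
                x, cost, diag = self._fit_reduced_at_dc(dc, spec, rng)
            else:
                x, cost, diag = self._fit_full_at_dc(dc, spec, rng)
            dc_chi2[dc] = cost
            if best is None or cost < best[1]:
                best = (x, cost, dc, diag)
        if best is None or best[0] is None:
            raise FitFailureError("no multistart run converged at any delay",
                                  best[3] if best else None)
        x, chi2_min, dc, _ = best
        return self._make_results(x, chi2_min, dc, dc_chi2, spec)

    def _starts_reduced(self, dc: float, spec: FitSpec, rng) -> list[np.ndarray]:
        base = np.concatenate([[0.8, 0.3],
                               self._heuristic_kinetics_init(0.8, 0.3, dc).ravel()])
        starts = [base]
        for _ in range(spec.multistart - 1):
            pert = base.copy()
            pert[0] = np.clip(base[0] + rng.uniform(-0.15, 0.15), 0.05, 1.0)
            pert[1] = np.clip(base[1] + rng.uniform(-0.15, 0.15), 0.0, 0.9)
            pert[2:] += rng.normal(0.0, 0.3, size=base.size - 2)
            starts.append(pert)
        return starts

    def _reduced_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        P = self.n_nups
        lo = np.concatenate([[_F_BOUNDS[0], _F_BOUNDS[0]],
                             np.tile([_LOGN_BOUNDS[0], _LOGK_BOUNDS[0]] * 2, P)])
        hi = np.concatenate([[_F_BOUNDS[1], _F_BOUNDS[1]],
                             np.tile([_LOGN_BOUNDS[1], _LOGK_BOUNDS[1]] * 2, P)])
        return lo, hi

    def _reduced_sparsity(self) -> np.ndarray:
        P = self.n_nups
        n_free = 2 + 4 * P
        blocks = []
        for st in self._stacks:
            for i in st.nup_idx:            # non-core rows of this stack
                row = np.zeros(n_free, bool)
                row[:2] = True
                row[2 + 4 * i: 6 + 4 * i] = True
                blocks.append(np.tile(row, (st.t.size, 1)))
            for i in st.nup_idx:            # core rows
                row = np.zeros(n_free, bool)
                row[:2] = True
                row[2 + 4 * i: 6 + 4 * i] = True
                blocks.append(np.tile(row, (st.t.size, 1)))
        return np.vstack(blocks)

    def _fit_reduced_at_dc(self, dc: float, spec: FitSpec, rng):
        lo, hi = self._reduced_bounds()
        sparsity = self._reduced_sparsity()
        best_x, best_cost, diags = None, np.inf, []
        for x0 in self._starts_reduced(dc, spec, rng):
            x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
            sol = least_squares(
                _residuals_reduced, x0, bounds=(lo, hi),
                args=(self._stacks, dc, self.n_nups),
                jac_sparsity=sparsity, xtol=spec.xtol, ftol=spec.ftol,
                max_nfev=spec.max_nfev, method="trf")
            diags.append((sol.status, 2 * sol.cost))
            if sol.status > 0 and 2 * sol.cost < best_cost:
                best_x, best_cost = sol.x, 2 * sol.cost
        return best_x, best_cost, diags

    def _fit_full_at_dc(self, dc: float, spec: FitSpec, rng):
        lo = np.array([_F_BOUNDS[0], _F_BOUNDS[0], _LOGN_BOUNDS[0],
                       _LOGK_BOUNDS[0], _LOGN_BOUNDS[0], _LOGK_BOUNDS[0]])
        hi = np.array([_F_BOUNDS[1], _F_BOUNDS[1], _LOGN_BOUNDS[1],
                       _LOGK_BOUNDS[1], _LOGN_BOUNDS[1], _LOGK_BOUNDS[1]])
        kin_init = self._heuristic_kinetics_init(0.8, 0.3, dc)
        xs, total, diags = [], 0.0, []
        for i, nup in enumerate(self.nups):
            st, row = self._row_of[nup]
            base = np.concatenate([[0.8, 0.3], kin_init[i]])
            best_x, best_cost = None, np.inf
            for s in range(spec.multistart):
                x0 = base.copy()
                if s > 0:
                    x0[:2] = np.clip(x0[:2] + rng.uniform(-0.15, 0.15, 2), 0.01, 0.99)
                    x0[2:] += rng.normal(0.0, 0.3, 4)
                x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
                sol = least_squares(_residuals_full_single, x0, bounds=(lo, hi),
                                    args=(st, row, dc), xtol=spec.xtol,
                                    ftol=spec.ftol, max_nfev=spec.max_nfev,
                                    method="trf")
                diags.append((nup, sol.status, 2 * sol.cost))
                if sol.status > 0 and 2 * sol.cost < best_cost:
                    best_x, best_cost = sol.x, 2 * sol.cost
            if best_x is None:
                return None, np.inf, diags
            xs.append(best_x)
            total += best_cost
        return np.concatenate(xs), total, diags

    # -- results assembly ----------------------------------------------

    def _decode(self, x: np.ndarray, dc: float):
        kinetics: dict[str, NupKinetics] = {}
        if self.mode == "reduced":
            mixing = MixingParams(f_n=float(x[0]), f_c=float(x[1]), d_c=dc)
            kin = x[2:].reshape(self.n_nups, 4)
            for i, nup in enumerate(self.nups):
                kinetics[nup] = NupKinetics(
                    nup_id=nup, n_p=math.exp(kin[i, 0]), K_p=math.exp(kin[i, 1]),
                    n_i=math.exp(kin[i, 2]), K_i=math.exp(kin[i, 3]))
            return kinetics, mixing
        mixing_by_nup: dict[str, MixingParams] = {}
        per = x.reshape(self.n_nups, 6)
        for i, nup in enumerate(self.nups):
            mixing_by_nup[nup] = MixingParams(f_n=float(per[i, 0]),
                                              f_c=float(per[i, 1]), d_c=dc)
            kinetics[nup] = NupKinetics(
                nup_id=nup, n_p=math.exp(per[i, 2]), K_p=math.exp(per[i, 3]),
                n_i=math.exp(per[i, 4]), K_i=math.exp(per[i, 5]))
        return kinetics, mixing_by_nup

    def _make_results(self, x, chi2_min, dc, dc_chi2, spec):
        kinetics, mixing = self._decode(x, dc)
        ss_tot = 0.0
        for st in self._stacks:
            z = np.concatenate([(st.N / st.Sn).ravel(), (st.C / st.Sc).ravel()])
            ss_tot += float(np.sum((z - z.mean()) ** 2))
        r2 = 1.0 - chi2_min / ss_tot if ss_tot > 0 else np.nan
        bic = chi2_min + self.n_params * math.log(self.n_obs)
        return NupAssemblyResults(
            model=self, spec=spec, x=np.asarray(x, float), kinetics=kinetics,
            mixing=mixing, d_c=dc, chi2=chi2_min, dc_chi2=dict(dc_chi2),
            n_params=self.n_params, n_obs=self.n_obs, r2=r2, bic=bic)


def _crossing_time(t: np.ndarray, y: np.ndarray, level: float) -> float | None:
    above = y >= level
    if not above.any():
        return None
    k = int(np.argmax(above))
    if k == 0:
        return float(t[0])
    t0, t1 = t[k - 1], t[k]
    y0, y1 = y[k - 1], y[k]
    if y1 == y0:
        return float(t1)
    return float(t0 + (level - y0) * (t1 - t0) / (y1 - y0))


# ---------------------------------------------------------------------------
# results


@dataclass
class NupAssemblyResults:
    """Point estimates, fit diagnostics and profile-likelihood intervals."""

    model: NupAssemblyModel
    spec: FitSpec
    x: np.ndarray                       # internal parameter vector at optimum
    kinetics: dict[str, NupKinetics]
    mixing: "MixingParams | dict[str, MixingParams]"
    d_c: float
    chi2: float
    dc_chi2: dict[float, float]         # grid-search chi2 profile over d_c
    n_params: int
    n_obs: int
    r2: float
    bic: float
    ci: dict = field(default_factory=dict)

    # -- prediction ----------------------------------------------------

    def mixing_for(self, nup: str) -> MixingParams:
        return self.mixing[nup] if isinstance(self.mixing, dict) else self.mixing

    def predict(self, nup: str, t=None) -> tuple[np.ndarray, np.ndarray]:
        """Fitted (non-core, core) model curves for one Nup."""
        tr = self.model.traces[nup]
        t = tr.t if t is None else np.asarray(t, float)
        return mix_forward(self.kinetics[nup], self.mixing_for(nup), t)

    def unmixed(self, nup: str) -> AssemblyCurvePair:
        """Kinetically unmixed (pm, ip) data curves for one Nup."""
        tr = self.model.traces[nup]
        return unmix(tr.non_core, tr.core, self.mixing_for(nup), tr.t)

    def unmixed_model(self, nup: str, t=None) -> AssemblyCurvePair:
        """Noise-free unmixed curves evaluated from the fitted Hill model."""
        tr = self.model.traces[nup]
        t = tr.t if t is None else np.asarray(t, float)
        kin = self.kinetics[nup]
        from .kinetics import hill_curve
        return AssemblyCurvePair(t=t, pm=hill_curve(t, kin.n_p, kin.K_p),
                                 ip=hill_curve(t, kin.n_i, kin.K_i))

    def curves_frame(self, nup: str) -> pd.DataFrame:
        pair = self.unmixed_model(nup)
        return pd.DataFrame({"t_min": pair.t, "pm": pair.pm, "ip": pair.ip})

    # -- profile likelihood ---------------------------------------------

    def _param_index(self, param) -> tuple[int, bool]:
        """Map a parameter name to (index in x, is_log_scale)."""
        kin_names = ("n_p", "K_p", "n_i", "K_i")
        if self.model.mode == "reduced":
            if param == "f_n":
                return 0, False
            if param == "f_c":
                return 1, False
            nup, name = param
            i = self.model.nups.index(nup)
            return 2 + 4 * i + kin_names.index(name), True
        nup, name = param
        i = self.model.nups.index(nup)
        names = ("f_n", "f_c") + kin_names
        j = names.index(name)
        return 6 * i + j, j >= 2

    def _refit_fixed(self, idx: int, value: float, x_warm: np.ndarray) -> float:
        """Re-optimize all remaining parameters with x[idx] pinned."""
        model, spec, dc = self.model, self.spec, self.d_c
        if model.mode == "reduced":
            lo, hi = model._reduced_bounds()
            sparsity = model._reduced_sparsity()
            free = np.ones(x_warm.size, bool)
            free[idx] = False

            def resid(xf):
                x = x_warm.copy()
                x[idx] = value
                x[free] = xf
                return _residuals_reduced(x, model._stacks, dc, model.n_nups)

            x0 = np.clip(x_warm[free], lo[free] + 1e-12, hi[free] - 1e-12)
            sol = least_squares(resid, x0, bounds=(lo[free], hi[free]),
                                jac_sparsity=sparsity[:, free],
                                xtol=spec.xtol, ftol=spec.ftol,
                                max_nfev=spec.max_nfev, method="trf")
            return 2 * sol.cost
        # full mode: only the owning Nup's block needs re-optimization
        i = idx // 6
        nup = model.nups[i]
        st, row = model._row_of[nup]
        lo = np.array([0.0, 0.0, _LOGN_BOUNDS[0], _LOGK_BOUNDS[0],
                       _LOGN_BOUNDS[0], _LOGK_BOUNDS[0]])
        hi = np.array([1.0, 1.0, _LOGN_BOUNDS[1], _LOGK_BOUNDS[1],
                       _LOGN_BOUNDS[1], _LOGK_BOUNDS[1]])
        block = x_warm[6 * i: 6 * i + 6].copy()
        j = idx % 6
        free = np.ones(6, bool)
        free[j] = False

        def resid(xf):
            xb = block.copy()
            xb[j] = value
            xb[free] = xf
            return _residuals_full_single(xb, st, row, dc)

        sol = least_squares(resid, np.clip(block[free], lo[free] + 1e-12,
                                           hi[free] - 1e-12),
                            bounds=(lo[free], hi[free]), xtol=spec.xtol,
                            ftol=spec.ftol, max_nfev=spec.max_nfev, method="trf")
        other = self.chi2 - self._block_chi2(i)
        return other + 2 * sol.cost

    def _block_chi2(self, i: int) -> float:
        nup = self.model.nups[i]
        st, row = self.model._row_of[nup]
        r = _residuals_full_single(self.x[6 * i: 6 * i + 6], st, row, self.d_c)
        return float(np.sum(r ** 2))

    def profile_ci(self, param, level: float = 0.95) -> ProfileInterval:
        """95% (by default) profile-likelihood interval for one parameter.

        ``param`` is ``"f_n"``/``"f_c"`` (reduced mode) or a tuple
        ``(nup_id, name)`` with ``name`` in ``n_p, K_p, n_i, K_i`` (plus
        ``f_n, f_c`` in full mode).  ``K`` and ``n`` are profiled on the
        log scale and the interval is reported in natural units.  An
        endpoint that runs into a parameter bound before crossing the
        chi-square threshold is flagged as one-sided.
        """
        idx, is_log = self._param_index(param)
        est_internal = float(self.x[idx])
        if self.model.mode == "reduced":
            lo, hi = self.model._reduced_bounds()
        else:
            lo = np.tile([0.0, 0.0, _LOGN_BOUNDS[0], _LOGK_BOUNDS[0],
                          _LOGN_BOUNDS[0], _LOGK_BOUNDS[0]], self.model.n_nups)
            hi = np.tile([1.0, 1.0, _LOGN_BOUNDS[1], _LOGK_BOUNDS[1],
                          _LOGN_BOUNDS[1], _LOGK_BOUNDS[1]], self.model.n_nups)
        bounds = (float(lo[idx]), float(hi[idx]))

        def prof(v: float) -> float:
            return self._refit_fixed(idx, v, self.x)

        interval = profile_interval_from_function(
            prof, est_internal, self.chi2, level=level, bounds=bounds,
            scale=0.02 if not is_log else 0.05)
        if is_log:
            interval = ProfileInterval(
                estimate=math.exp(interval.estimate),
                lower=math.exp(interval.lower), upper=math.exp(interval.upper),
                level=level, lower_at_bound=interval.lower_at_bound,
                upper_at_bound=interval.upper_at_bound)
        self.ci[param] = interval
        return interval

    # -- reporting ------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Two-component NPC assembly model",
            "=" * 64,
            f"mode: {self.model.mode:<10} nups: {self.model.n_nups}"
            f"    free parameters: {self.n_params}",
            f"chi2: {self.chi2:.6g}    residuals: {self.n_obs}"
            f"    R2: {self.r2:.4f}    BIC: {self.bic:.6g}",
            f"core delay d_c: {self.d_c:g} min "
            f"(grid {min(self.dc_chi2):g}..{max(self.dc_chi2):g})",
        ]
        if isinstance(self.mixing, MixingParams):
            lines.append(f"shared fractions: f_n = {self.mixing.f_n:.4f},"
                         f" f_c = {self.mixing.f_c:.4f}")
        lines.append("-" * 64)
        header = f"{'nup':<10}{'n_p':>8}{'K_p':>9}{'n_i':>8}{'K_i':>9}"
        if isinstance(self.mixing, dict):
            header += f"{'f_n':>8}{'f_c':>8}"
        lines.append(header)
        for nup, kin in self.kinetics.items():
            row = (f"{nup:<10}{kin.n_p:>8.3f}{kin.K_p:>9.3f}"
                   f"{kin.n_i:>8.3f}{kin.K_i:>9.3f}")
            if isinstance(self.mixing, dict):
                mix = self.mixing[nup]
                row += f"{mix.f_n:>8.3f}{mix.f_c:>8.3f}"
            lines.append(row)
        lines.append("=" * 64)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# generic profile-interval engine and model comparison


def profile_interval_from_function(profile_chi2, estimate: float,
                                   chi2_min: float, level: float = 0.95,
                                   bounds: tuple[float, float] = (-np.inf, np.inf),
                                   scale: float | None = None,
                                   max_doublings: int = 40) -> ProfileInterval:
    """Invert a 1-D chi2 profile into a confidence interval.

    Expands geometrically from the estimate in each direction until the
    profiled chi2 crosses ``chi2_min + chi2_quantile(level, 1 d.f.)``, then
    locates the crossing by root bracketing.  A direction that reaches its
    bound before crossing is reported as open (one-sided interval).
    In the Gaussian limit (quadratic chi2 with curvature ``1/sigma^2``)
    this reproduces ``estimate +/- 1.96 sigma`` at the 95% level.
    """
    threshold = chi2_min + float(_chi2_dist.ppf(level, 1))
    if scale is None:
        scale = max(0.05 * abs(estimate), 1e-3)

    def endpoint(direction: int) -> tuple[float, bool]:
        bound = bounds[1] if direction > 0 else bounds[0]
        step = scale
        inner = estimate
        for _ in range(max_doublings):
            cand = estimate + direction * step
            at_bound = ((direction > 0 and cand >= bound)
                        or (direction < 0 and cand <= bound))
            if at_bound:
                cand = bound
            val = profile_chi2(cand)
            if val >= threshold:
                root = brentq(lambda v: profile_chi2(v) - threshold,
                              min(inner, cand), max(inner, cand),
                              xtol=max(1e-6, 1e-4 * scale))
                return float(root), False
            if at_bound:
                return float(bound), True
            inner = cand
            step *= 2.0
        return float(inner), True

    lower, lower_open = endpoint(-1)
    upper, upper_open = endpoint(+1)
    return ProfileInterval(estimate=estimate, lower=lower, upper=upper,
                           level=level, lower_at_bound=lower_open,
                           upper_at_bound=upper_open)


def compare_bic(fit_reduced: NupAssemblyResults,
                fit_full: NupAssemblyResults) -> float:
    """``delta BIC = BIC_reduced - BIC_full``; negative favours the reduced
    (shared-fraction) model.  Raises :class:`ComparisonError` if the two
    fits were not computed on identical data."""
    if (fit_reduced.model._data_fingerprint()
            != fit_full.model._data_fingerprint()):
        raise ComparisonError("fits were computed on different data")
    return float(fit_reduced.bic - fit_full.bic)
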