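"""Gaussian-mixture protein densities and model-to-density correlation.

A structure's forward density is a Gaussian mixture with two components
per subcomplex copy (each copy's beads are split along their principal
axis and each half is summarized by its mean and covariance, broadened by
the bead radii).  The agreement of two densities p and q is their
normalized L2 inner product

    cc(p, q) = <p, q> / sqrt(<p, p> <q, q>),   <p, q> = integral p q dV,

computed in closed form from pairwise Gaussian overlap integrals
(the integral of N(mu_i, S_i) * N(nu_j, L_j) is the Gaussian density
N(mu_i - nu_j; 0, S_i + L_j)).  cc is 1 for a density against itself and
tends to 0 for disjoint supports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .geometry import StaticStructure, SubcomplexType

__all__ = ["GaussianMixtureDensity", "gmm_overlap", "density_correlation",
           "structure_density", "write_density_csv", "read_density_csv"]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class GaussianMixtureDensity:
    """Weighted sum of 3-D Gaussians (weights need not sum to 1)."""

    weights: np.ndarray             # (K,)
    means: np.ndarray               # (K, 3)
    covariances: np.ndarray         # (K, 3, 3)

    def __post_init__(self) -> None:
        w = np.atleast_1d(np.asarray(self.weights, float))
        m = np.atleast_2d(np.asarray(self.means, float))
        c = np.asarray(self.covariances, float)
        if c.ndim == 2:
            c = c[None]
        if w.shape[0] == 0:
            raise ValueError("a mixture needs at least one component")
        if not (w.shape[0] == m.shape[0] == c.shape[0]) or m.shape[1] != 3 \
                or c.shape[1:] != (3, 3):
            raise ValueError("inconsistent mixture shapes")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "covariances", c)

    @property
    def n_components(self) -> int:
        return self.weights.size

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Density values at (N, 3) points (used by the voxel oracle)."""
        points = np.atleast_2d(np.asarray(points, float))
        out = np.zeros(points.shape[0])
        for w, mu, cov in zip(self.weights, self.means, self.covariances):
            diff = points - mu
            inv = np.linalg.inv(cov)
            logdet = np.linalg.slogdet(cov)[1]
            q = np.einsum("ni,ij,nj->n", diff, inv, diff)
            out += w * np.exp(-0.5 * (q + 3 * _LOG_2PI + logdet))
        return out


def gmm_overlap(a: GaussianMixtureDensity, b: GaussianMixtureDensity) -> float:
    """L2 inner product of two mixtures via analytic Gaussian overlaps."""
    cov = a.covariances[:, None] + b.covariances[None, :]      # (Ka, Kb, 3, 3)
    diff = a.means[:, None, :] - b.means[None, :, :]           # (Ka, Kb, 3)
    inv = np.linalg.inv(cov)
    logdet = np.linalg.slogdet(cov)[1]
    q = np.einsum("abi,abij,abj->ab", diff, inv, diff)
    dens = np.exp(-0.5 * (q + 3 * _LOG_2PI + logdet))
    return float(np.einsum("a,b,ab->", a.weights, b.weights, dens))


def density_correlation(a: GaussianMixtureDensity,
                        b: GaussianMixtureDensity) -> float:
    """Normalized overlap correlation in [0, 1] (1 = identical shape)."""
    if a.n_components == 0 or b.n_components == 0:
        raise ValueError("cannot correlate an empty mixture")
    ab = gmm_overlap(a, b)
    aa = gmm_overlap(a, a)
    bb = gmm_overlap(b, b)
    return ab / np.sqrt(aa * bb)


def _beads_to_components(points: np.ndarray, radii: np.ndarray,
                         n_components: int = 2):
    """Split one copy's beads along the principal axis into components."""
    if points.shape[0] < 2 or n_components == 1:
        groups = [np.arange(points.shape[0])]
    else:
        centered = points - points.mean(axis=0)
        axis = np.linalg.svd(centered, full_matrices=False)[2][0]
        proj = centered @ axis
        order = np.argsort(proj, kind="stable")
        groups = [g for g in np.array_split(order, n_components) if g.size]
    out = []
    for g in groups:
        pts, r = points[g], radii[g]
        mean = pts.mean(axis=0)
        cov = np.zeros((3, 3))
        if g.size > 1:
            d = pts - mean
            cov = d.T @ d / g.size
        cov = cov + np.mean(r ** 2) * np.eye(3)     # bead-size broadening
        out.append((float(g.size), mean, cov))
    return out


def structure_density(structure: StaticStructure,
                      types: Mapping[str, SubcomplexType],
                      n_components_per_copy: int = 2,
                      jitter_sd: float = 0.0,
                      rng: np.random.Generator | None = None
                      ) -> GaussianMixtureDensity:
    """Forward-model density of a structure (2 Gaussians per copy).

    ``jitter_sd`` adds isotropic Gaussian displacement (nm) to every bead
    before the mixture is built; used by the synthetic-system generator to
    emulate imperfect target densities.
    """
    expanded = structure.expand(types)
    positions = expanded.positions
    if jitter_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        positions = positions + rng.normal(0.0, jitter_sd, positions.shape)
    weights, means, covs = [], [], []
    for key in dict.fromkeys(expanded.inst_keys):       # stable unique order
        sel = [i for i, k in enumerate(expanded.inst_keys) if k == key]
        comps = _beads_to_components(positions[sel], expanded.radii[sel],
                                     n_components_per_copy)
        for w, mu, cov in comps:
            weights.append(w)
            means.append(mu)
            covs.append(cov)
    return GaussianMixtureDensity(np.array(weights), np.array(means),
                                  np.array(covs))


# ---------------------------------------------------------------------------
# text interchange: one row per component


_COV_COLS = ["cxx", "cxy", "cxz", "cyy", "cyz", "czz"]


def write_density_csv(density: GaussianMixtureDensity, path) -> None:
    rows = []
    for w, mu, cov in zip(density.weights, density.means, density.covariances):
        rows.append({"weight": w, "mx": mu[0], "my": mu[1], "mz": mu[2],
                     "cxx": cov[0, 0], "cxy": cov[0, 1], "cxz": cov[0, 2],
                     "cyy": cov[1, 1], "cyz": cov[1, 2], "czz": cov[2, 2]})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_density_csv(path) -> GaussianMixtureDensity:
    df = pd.read_csv(path)
    covs = np.empty((len(df), 3, 3))
    for i, row in df.iterrows():
        c = row[_COV_COLS].to_numpy(float)
        covs[i] = [[c[0], c[1], c[2]], [c[1], c[3], c[4]], [c[2], c[4], c[5]]]
    return GaussianMixtureDensity(df["weight"].to_numpy(float),
                                  df[["mx", "my", "mz"]].to_numpy(float), covs)
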