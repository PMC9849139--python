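"""Scoring and ranking of candidate NPC assembly pathways (toy scale).

A candidate static structure at each time point is scored against the
kinetic copy-number data and a target protein density; static structures
are then chained into assembly pathways, which are valid when every
transition preserves the copies already present (monotone subcomplex
inclusion) and the last state is the mature pore.  Pathways are ranked by
the sum of their static-structure scores (transition scores are uniform
over allowed transitions and drop out of the ranking) and converted to
posterior shares by Boltzmann weighting at unit temperature.

Score terms (all additive; harmonic terms are 0 when unviolated):

copy_number       0.5 * ((copies - mu) / sigma)^2 per subcomplex type
                  (negative log of a Gaussian copy-number likelihood)
go                harmonic restraint toward mature-contact distances,
                  linearly scaled from 0 (first time point) to 1 (mature)
excluded_volume   harmonic overlap penalty between beads of different
                  copies
membrane          harmonic attraction of ALPS-flagged beads to the
                  envelope surface
envelope          harmonic repulsion of beads out of the membrane volume
density           weight * (1 - cc) with cc the model-to-target density
                  correlation
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .density import GaussianMixtureDensity, density_correlation, \
    structure_density
from .geometry import (EnvelopeToroid, Pose, StaticStructure, SubcomplexType,
                       rotation_about_axis)

__all__ = [
    "ScoreWeights", "CopyNumberRestraint", "ScoringContext", "ScoreBreakdown",
    "go_contacts", "score_static", "mc_refine", "enumerate_copy_combinations",
    "enumerate_pathways", "rank_pathways", "RankedPathway", "PathwayModel",
]


@dataclass(frozen=True)
class ScoreWeights:
    """Restraint strengths.

    Harmonic strengths are in score units per nm^2 (the published
    kcal/mol/Angstrom constants converted to nm with the score treated as
    an energy at unit Monte Carlo temperature); ``density`` multiplies
    ``(1 - cc)``.
    """

    go: float = 1.0                 # 0.01 kcal/mol/A -> per nm
    excluded_volume: float = 1.0
    membrane: float = 10.0          # 0.1 kcal/mol/A
    envelope: float = 1.0
    density: float = 100.0


@dataclass(frozen=True)
class CopyNumberRestraint:
    """Gaussian copy-number restraints for one time point."""

    means: Mapping[str, float]
    sds: Mapping[str, float]

    def penalty(self, copy_numbers: Mapping[str, int]) -> float:
        total = 0.0
        for type_id, mu in self.means.items():
            sd = self.sds[type_id]
            c = copy_numbers.get(type_id, 0)
            total += 0.5 * ((c - mu) / sd) ** 2
        return total


@dataclass(frozen=True)
class GoContact:
    bead_a: tuple                   # (instance key, bead index)
    bead_b: tuple
    distance: float                 # nm, in the mature structure


def go_contacts(mature: StaticStructure,
                types: Mapping[str, SubcomplexType],
                cutoff: float = 5.0) -> list[GoContact]:
    """Inter-copy bead contacts within ``cutoff`` nm of the mature pore."""
    exp = mature.expand(types)
    dists = squareform(pdist(exp.positions))
    contacts = []
    n = exp.positions.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if exp.inst_keys[i] == exp.inst_keys[j]:
                continue
            if dists[i, j] <= cutoff:
                contacts.append(GoContact(exp.bead_keys[i], exp.bead_keys[j],
                                          float(dists[i, j])))
    return contacts


@dataclass
class ScoringContext:
    """Everything needed to score static structures along the time series."""

    types: Mapping[str, SubcomplexType]
    mature: StaticStructure
    envelopes: Sequence[EnvelopeToroid]
    copy_restraints: Sequence[CopyNumberRestraint]
    target_densities: Sequence[GaussianMixtureDensity]
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    contacts: list[GoContact] | None = None
    go_cutoff: float = 5.0

    def __post_init__(self) -> None:
        if not (len(self.envelopes) == len(self.copy_restraints)
                == len(self.target_densities)):
            raise ValueError("per-time-point inputs must have equal length")
        if self.contacts is None:
            self.contacts = go_contacts(self.mature, self.types,
                                        self.go_cutoff)
        if not self.contacts:
            raise ValueError("mature reference yields no Go contacts; "
                             "check the contact cutoff")

    @property
    def n_timepoints(self) -> int:
        return len(self.envelopes)

    def time_scale(self, time_index: int) -> float:
        """Go-restraint ramp: 0 at the first time point, 1 at the mature."""
        if self.n_timepoints == 1:
            return 1.0
        return time_index / (self.n_timepoints - 1)


@dataclass(frozen=True)
class ScoreBreakdown:
    terms: dict[str, float]

    @property
    def total(self) -> float:
        return float(sum(self.terms.values()))


def score_static(structure: StaticStructure, ctx: ScoringContext,
                 time_index: int,
                 time_scale: float | None = None) -> ScoreBreakdown:
    """Additive score of one static structure at one time point."""
    w = ctx.weights
    if time_scale is None:
        time_scale = ctx.time_scale(time_index)
    exp = structure.expand(ctx.types)
    pos, radii = exp.positions, exp.radii
    inst = np.asarray([hash(k) for k in exp.inst_keys])

    copy_term = ctx.copy_restraints[time_index].penalty(
        structure.copy_numbers())

    # excluded volume between beads of different copies
    d = squareform(pdist(pos))
    rsum = radii[:, None] + radii[None, :]
    different = inst[:, None] != inst[None, :]
    overlap = np.triu(np.maximum(rsum - d, 0.0) * different, k=1)
    ev_term = 0.5 * w.excluded_volume * float(np.sum(overlap ** 2))

    # Go restraints toward mature distances, ramped in time
    index = {key: i for i, key in enumerate(exp.bead_keys)}
    dev2 = 0.0
    for contact in ctx.contacts:
        ia = index.get(contact.bead_a)
        ib = index.get(contact.bead_b)
        if ia is None or ib is None:
            continue
        dist = float(np.linalg.norm(pos[ia] - pos[ib]))
        dev2 += (dist - contact.distance) ** 2
    go_term = time_scale * 0.5 * w.go * dev2

    # envelope repulsion on bead centres inside the membrane volume
    env = ctx.envelopes[time_index]
    pen = env.penetration(pos)
    env_term = 0.5 * w.envelope * float(np.sum(pen ** 2))

    membrane_term = 0.0
    if exp.alps.any():
        gap = env.surface_distance(pos[exp.alps]) - radii[exp.alps]
        membrane_term = 0.5 * w.membrane * float(np.sum(np.maximum(gap, 0.0) ** 2))

    model_density = structure_density(structure, ctx.types)
    cc = density_correlation(model_density, ctx.target_densities[time_index])
    density_term = w.density * (1.0 - cc)

    return ScoreBreakdown(terms={
        "copy_number": float(copy_term), "go": float(go_term),
        "excluded_volume": ev_term, "membrane": membrane_term,
        "envelope": float(env_term), "density": float(density_term)})


# ---------------------------------------------------------------------------
# Monte Carlo refinement


def mc_refine(structure: StaticStructure, ctx: ScoringContext,
              time_index: int, n_moves: int, seed: int = 0,
              max_rotation: float = 0.04, max_translation: float = 0.4
              ) -> tuple[StaticStructure, ScoreBreakdown]:
    """Metropolis refinement of the asymmetric unit at unit temperature.

    Each move perturbs one copy's rigid-body pose (rotation about a random
    axis by a uniform angle in +/- ``max_rotation`` rad, translation
    uniform in a +/- ``max_translation`` nm cube); the C8 expansion is
    applied at scoring time, so symmetry is preserved by construction.
    Returns the best-scoring visited configuration (never worse than the
    start) deterministically for a given seed.
    """
    if n_moves < 1:
        raise ValueError("n_moves must be >= 1")
    rng = np.random.default_rng(seed)
    current = structure
    current_score = score_static(current, ctx, time_index)
    best, best_score = current, current_score
    ids = [inst.instance_id for inst in structure.instances]
    for _ in range(n_moves):
        pick = ids[rng.integers(len(ids))]
        angle = rng.uniform(-max_rotation, max_rotation)
        axis = rng.normal(size=3)
        shift = rng.uniform(-max_translation, max_translation, size=3)
        if max_rotation == 0.0:
            rot = np.eye(3)
        else:
            rot = rotation_about_axis(axis, angle)
        old_pose = next(i.pose for i in current.instances
                        if i.instance_id == pick)
        proposal = current.with_pose(pick, old_pose.perturbed(rot, shift))
        prop_score = score_static(proposal, ctx, time_index)
        delta = prop_score.total - current_score.total
        if delta <= 0 or rng.random() < np.exp(-delta):
            current, current_score = proposal, prop_score
            if current_score.total < best_score.total:
                best, best_score = current, current_score
    return best, best_score


# ---------------------------------------------------------------------------
# enumeration and ranking


def enumerate_copy_combinations(restraint: CopyNumberRestraint,
                                mature_copies: Mapping[str, int],
                                top_k: int = 20, step: int = 8
                                ) -> list[tuple[dict[str, int], float]]:
    """Top-scoring C8-compatible copy-number assignments at one time point.

    The admissible lattice per type is 0..mature in steps of 8; the full
    lattice is enumerated and ranked by the Gaussian copy-number penalty
    (ties broken by the assignment itself for determinism).
    """
    type_ids = sorted(mature_copies)
    if not type_ids:
        raise ValueError("no subcomplex types: admissible set is empty")
    grids = [range(0, mature_copies[t] + 1, step) for t in type_ids]
    scored = []
    for combo in itertools.product(*grids):
        assignment = dict(zip(type_ids, combo))
        scored.append((assignment, restraint.penalty(assignment)))
    scored.sort(key=lambda item: (item[1], tuple(sorted(item[0].items()))))
    return scored[:top_k]


def transition_allowed(first: StaticStructure, second: StaticStructure) -> bool:
    """Monotone subcomplex inclusion: every copy persists into the successor."""
    return first.instance_keys() <= second.instance_keys()


def enumerate_pathways(stages: Sequence[Sequence[StaticStructure]]
                       ) -> list[tuple[int, ...]]:
    """All index tuples through ``stages`` with valid transitions.

    ``stages`` is one candidate list per time point, the last stage being
    the mature endpoint (typically a single structure).  Returns an empty
    list if no valid chain exists.
    """
    if not stages or any(len(s) == 0 for s in stages):
        raise ValueError("every time point needs at least one candidate")
    paths: list[tuple[int, ...]] = [(i,) for i in range(len(stages[0]))]
    for stage_idx in range(1, len(stages)):
        new_paths = []
        for path in paths:
            prev = stages[stage_idx - 1][path[-1]]
            for j, cand in enumerate(stages[stage_idx]):
                if transition_allowed(prev, cand):
                    new_paths.append(path + (j,))
        paths = new_paths
        if not paths:
            return []
    return paths


@dataclass(frozen=True)
class RankedPathway:
    indices: tuple[int, ...]
    score: float
    share: float


@dataclass(frozen=True)
class PathwayModel:
    """Enumerated, scored and ranked assembly pathways."""

    stages: tuple
    ranked: tuple[RankedPathway, ...]

    @property
    def best(self) -> RankedPathway:
        return self.ranked[0]

    def structures(self, pathway: RankedPathway) -> list[StaticStructure]:
        return [self.stages[t][i] for t, i in enumerate(pathway.indices)]


def rank_pathways(stages: Sequence[Sequence[StaticStructure]],
                  stage_scores: Sequence[Sequence[float]],
                  transition_score: float = 0.0) -> PathwayModel:
    """Enumerate, score and rank all valid pathways.

    A pathway's score is the sum of its static scores plus a uniform
    ``transition_score`` per step (uniform over allowed transitions, so it
    shifts every total equally).  Posterior shares use Boltzmann weights
    ``exp(-(score - min))`` normalized over the enumerated set, making the
    ranking invariant under constant score offsets.
    """
    paths = enumerate_pathways(stages)
    if not paths:
        return PathwayModel(stages=tuple(tuple(s) for s in stages), ranked=())
    totals = np.array([
        sum(stage_scores[t][i] for t, i in enumerate(path))
        + transition_score * (len(path) - 1)
        for path in paths])
    weights = np.exp(-(totals - totals.min()))
    shares = weights / weights.sum()
    order = np.argsort(totals, kind="stable")
    ranked = tuple(RankedPathway(indices=paths[i], score=float(totals[i]),
                                 share=float(shares[i])) for i in order)
    return PathwayModel(stages=tuple(tuple(s) for s in stages), ranked=ranked)
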