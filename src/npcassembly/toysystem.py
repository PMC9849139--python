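"""Synthetic toy assembly systems with a planted ground-truth pathway.

A toy system stands in for the full-scale structural inputs of pathway
modelling: rigid subcomplexes are short bead arcs placed at the spoke
radius of a C8-symmetric pore, the nuclear envelope is the toroid series
of a dilating pore, and the per-time-point target densities are generated
*from the planted configurations by the same Gaussian-mixture forward
model used in scoring* (optionally jittered).  The planted copy-number
table obeys the monotone-inclusion transition rule and ends at the mature
structure, so the planted pathway is guaranteed to be among the
enumerable pathways; the generator returns the full ground-truth record
for recovery tests.

Geometry defaults are chosen so the mature configuration is overlap-free
(zero excluded-volume penalty) and sits outside the membrane volume, and
so that vertically stacked subcomplexes provide mature contacts within
the 5-nm Go cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .density import GaussianMixtureDensity, structure_density
from .geometry import (EnvelopeToroid, Pose, StaticStructure,
                       SubcomplexInstance, SubcomplexType, rotation_z)
from .pathway import (CopyNumberRestraint, PathwayModel, ScoreWeights,
                      ScoringContext, enumerate_copy_combinations,
                      rank_pathways, score_static)

__all__ = ["ToySubcomplexSpec", "ToyTimepoint", "ToySystemSpec",
           "ToyAssemblySystem", "InvalidSpecError", "make_toy_assembly_system",
           "model_toy_system", "planted_indices"]


class InvalidSpecError(ValueError):
    """The toy-system specification violates a structural invariant."""


@dataclass(frozen=True)
class ToySubcomplexSpec:
    """One rigid subcomplex type: a bead arc, possibly in several rings.

    ``placements`` lists the (z height nm, arc-centre angle deg) of each
    copy per spoke; mature copies = n_spokes * len(placements).
    """

    type_id: str
    bead_count: int = 4
    bead_radius: float = 1.8
    placements: tuple[tuple[float, float], ...] = ((0.0, 22.5),)
    bead_spacing: float = 4.0       # nm along the arc
    alps: bool = False


@dataclass(frozen=True)
class ToyTimepoint:
    minutes: float
    pore_diameter: float            # nm
    minor_radius: float             # nm


#: pore cross sections of the dilating postmitotic pore; last row = mature
DEFAULT_TIMEPOINTS: tuple[ToyTimepoint, ...] = (
    ToyTimepoint(5.0, 51.5, 21.4),
    ToyTimepoint(6.0, 58.4, 21.2),
    ToyTimepoint(8.0, 72.7, 21.5),
    ToyTimepoint(10.0, 84.6, 20.3),
    ToyTimepoint(15.0, 79.8, 17.1),
    ToyTimepoint(120.0, 87.0, 15.0),
)

DEFAULT_SUBCOMPLEXES: tuple[ToySubcomplexSpec, ...] = (
    ToySubcomplexSpec("Y", bead_count=4, bead_radius=1.8,
                      placements=((9.0, 20.0), (-9.0, 25.0))),
    ToySubcomplexSpec("IRC", bead_count=3, bead_radius=1.8,
                      placements=((-4.5, 25.0),)),
    ToySubcomplexSpec("CC", bead_count=3, bead_radius=1.5,
                      placements=((0.0, 25.0),)),
)

#: nuclear-ring-first assembly order: one Y ring, inner ring, second Y
#: ring, central channel, then maturation
DEFAULT_PLANTED: tuple[dict[str, int], ...] = (
    {"Y": 8, "IRC": 0, "CC": 0},
    {"Y": 8, "IRC": 8, "CC": 0},
    {"Y": 16, "IRC": 8, "CC": 0},
    {"Y": 16, "IRC": 8, "CC": 8},
    {"Y": 16, "IRC": 8, "CC": 8},
    {"Y": 16, "IRC": 8, "CC": 8},
)


@dataclass(frozen=True)
class ToySystemSpec:
    subcomplexes: tuple[ToySubcomplexSpec, ...] = DEFAULT_SUBCOMPLEXES
    n_spokes: int = 8
    timepoints: tuple[ToyTimepoint, ...] = DEFAULT_TIMEPOINTS
    planted_pathway: tuple[dict[str, int], ...] = DEFAULT_PLANTED
    density_noise: float = 0.0      # nm jitter on planted bead coordinates
    copy_sd: float = 4.0            # SD of the Gaussian copy restraints
    radial_fraction: float = 0.83   # arc radius as fraction of pore radius

    def mature_copies(self) -> dict[str, int]:
        return {sub.type_id: self.n_spokes * len(sub.placements)
                for sub in self.subcomplexes}


@dataclass(frozen=True)
class ToyAssemblySystem:
    """A generated toy system plus its ground-truth record."""

    spec: ToySystemSpec
    types: dict[str, SubcomplexType]
    mature: StaticStructure
    envelopes: tuple[EnvelopeToroid, ...]
    planted: tuple[StaticStructure, ...]        # ground truth per time point
    copy_restraints: tuple[CopyNumberRestraint, ...]
    target_densities: tuple[GaussianMixtureDensity, ...]

    def scoring_context(self, weights: ScoreWeights | None = None
                        ) -> ScoringContext:
        return ScoringContext(
            types=self.types, mature=self.mature, envelopes=self.envelopes,
            copy_restraints=self.copy_restraints,
            target_densities=self.target_densities,
            weights=weights or ScoreWeights())

    def reference_structure(self, time_index: int,
                            copies: dict[str, int]) -> StaticStructure:
        """Deterministic structure for a copy assignment at a time point.

        Copies fill each type's placements in order, so assignments that
        are monotone in copy number are automatically monotone in
        instance inclusion.
        """
        return _build_structure(self.spec, time_index, copies)


def _arc_type(spec: ToySystemSpec, sub: ToySubcomplexSpec,
              mature_pore_radius: float) -> SubcomplexType:
    r_ref = spec.radial_fraction * mature_pore_radius
    k = sub.bead_count
    dphi = sub.bead_spacing / r_ref
    phis = (np.arange(k) - (k - 1) / 2.0) * dphi
    offsets = np.column_stack([r_ref * np.cos(phis) - r_ref,
                               r_ref * np.sin(phis),
                               np.zeros(k)])
    return SubcomplexType(
        type_id=sub.type_id, bead_offsets=offsets,
        bead_radii=np.full(k, sub.bead_radius),
        alps_mask=np.full(k, sub.alps))


def _build_structure(spec: ToySystemSpec, time_index: int,
                     copies: dict[str, int]) -> StaticStructure:
    tp = spec.timepoints[time_index]
    mature_radius = 0.5 * spec.timepoints[-1].pore_diameter
    r_t = spec.radial_fraction * 0.5 * tp.pore_diameter
    instances = []
    for sub in spec.subcomplexes:
        count = copies.get(sub.type_id, 0) // spec.n_spokes
        for m in range(count):
            z, center_deg = sub.placements[m]
            theta = np.deg2rad(center_deg)
            translation = np.array([r_t * np.cos(theta),
                                    r_t * np.sin(theta), z])
            instances.append(SubcomplexInstance(
                type_id=sub.type_id, instance_id=f"{sub.type_id}/{m}",
                pose=Pose(rotation_z(theta), translation)))
    return StaticStructure(time_label=tp.minutes, instances=tuple(instances),
                           n_fold=spec.n_spokes)


def make_toy_assembly_system(spec: ToySystemSpec | None = None,
                             seed: int = 0) -> ToyAssemblySystem:
    """Generate subcomplex library, envelope series, target densities and
    the planted ground-truth pathway.

    Raises :class:`InvalidSpecError` if the planted table is not monotone
    non-decreasing per subcomplex, exceeds mature copy numbers, is not
    C-symmetric (multiples of ``n_spokes``) or does not end at the mature
    structure.
    """
    spec = spec or ToySystemSpec()
    mature_copies = spec.mature_copies()
    planted = spec.planted_pathway
    if len(planted) != len(spec.timepoints):
        raise InvalidSpecError("planted pathway must cover every time point")
    for t, copies in enumerate(planted):
        for type_id, c in copies.items():
            if type_id not in mature_copies:
                raise InvalidSpecError(f"unknown subcomplex {type_id!r}")
            if c % spec.n_spokes:
                raise InvalidSpecError(
                    f"copies must be multiples of {spec.n_spokes}, got {c}")
            if c > mature_copies[type_id]:
                raise InvalidSpecError(
                    f"planted copies of {type_id} exceed the mature count")
            if t > 0 and c < planted[t - 1].get(type_id, 0):
                raise InvalidSpecError(
                    f"planted copies of {type_id} decrease at step {t}")
    final = {t: planted[-1].get(t, 0) for t in mature_copies}
    if final != mature_copies:
        raise InvalidSpecError("final planted state must equal the mature "
                               "structure")

    mature_radius = 0.5 * spec.timepoints[-1].pore_diameter
    types = {sub.type_id: _arc_type(spec, sub, mature_radius)
             for sub in spec.subcomplexes}
    envelopes = tuple(EnvelopeToroid(tp.pore_diameter, tp.minor_radius)
                      for tp in spec.timepoints)
    planted_structures = tuple(_build_structure(spec, t, copies)
                               for t, copies in enumerate(planted))
    mature_structure = planted_structures[-1]
    restraints = tuple(
        CopyNumberRestraint(
            means={t: float(copies.get(t, 0)) for t in mature_copies},
            sds={t: spec.copy_sd for t in mature_copies})
        for copies in planted)
    rng = np.random.default_rng(seed)
    densities = tuple(
        structure_density(s, types, jitter_sd=spec.density_noise, rng=rng)
        for s in planted_structures)
    return ToyAssemblySystem(
        spec=spec, types=types, mature=mature_structure, envelopes=envelopes,
        planted=planted_structures, copy_restraints=restraints,
        target_densities=densities)


def model_toy_system(system: ToyAssemblySystem, top_k: int = 4,
                     weights: ScoreWeights | None = None) -> PathwayModel:
    """Enumerate, score and rank assembly pathways for a toy system.

    Candidates at each intermediate time point are the ``top_k``
    copy-number assignments by copy likelihood, built at the deterministic
    reference poses; the last stage is pinned to the mature structure.
    """
    ctx = system.scoring_context(weights)
    mature_copies = system.spec.mature_copies()
    stages: list[list[StaticStructure]] = []
    scores: list[list[float]] = []
    last = len(system.spec.timepoints) - 1
    for t in range(last + 1):
        if t == last:
            cands = [system.mature]
        else:
            combos = enumerate_copy_combinations(
                system.copy_restraints[t], mature_copies, top_k=top_k,
                step=system.spec.n_spokes)
            cands = [system.reference_structure(t, combo)
                     for combo, _ in combos if sum(combo.values()) > 0]
        stages.append(cands)
        scores.append([score_static(s, ctx, t).total for s in cands])
    return rank_pathways(stages, scores)


def planted_indices(system: ToyAssemblySystem,
                    model: PathwayModel) -> tuple[int, ...] | None:
    """Locate the planted pathway among a model's enumerated stages."""
    indices = []
    for t, planted in enumerate(system.planted):
        keys = planted.instance_keys()
        stage = model.stages[t]
        match = next((i for i, s in enumerate(stage)
                      if s.instance_keys() == keys), None)
        if match is None:
            return None
        indices.append(match)
    return tuple(indices)
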