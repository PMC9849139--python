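"""Coarse-grained rigid-body geometry for toy NPC structures.

Subcomplexes are rigid bodies of spherical beads (positions in nm in an
internal frame); a structure holds posed instances of them for one
asymmetric unit of a C8-symmetric pore and is expanded on demand by
rotating the unit about the pore (z) axis.  The nuclear envelope is a
fixed toroid embedded in two parallel planes: the membrane fills the solid
torus of minor radius ``r`` around the circle of radius
``R = pore_radius + r`` in the z = 0 plane, plus the slab ``|z| <= r`` at
cylindrical radii beyond ``R`` (the flat double membrane).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = ["SubcomplexType", "Pose", "SubcomplexInstance", "StaticStructure",
           "EnvelopeToroid", "ExpandedBeads", "rotation_z",
           "rotation_about_axis"]


@dataclass(frozen=True)
class SubcomplexType:
    """A rigid subcomplex: bead offsets (nm), radii (nm), ALPS flags."""

    type_id: str
    bead_offsets: np.ndarray        # (k, 3)
    bead_radii: np.ndarray          # (k,)
    alps_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        offsets = np.atleast_2d(np.asarray(self.bead_offsets, float))
        radii = np.atleast_1d(np.asarray(self.bead_radii, float))
        if offsets.shape[0] != radii.shape[0] or offsets.shape[1] != 3:
            raise ValueError("bead_offsets must be (k, 3) matching bead_radii")
        if offsets.shape[0] == 0:
            raise ValueError("a subcomplex needs at least one bead")
        if np.any(radii <= 0):
            raise ValueError("bead radii must be positive")
        mask = (np.zeros(radii.shape[0], bool) if self.alps_mask is None
                else np.asarray(self.alps_mask, bool))
        object.__setattr__(self, "bead_offsets", offsets)
        object.__setattr__(self, "bead_radii", radii)
        object.__setattr__(self, "alps_mask", mask)

    @property
    def n_beads(self) -> int:
        return self.bead_radii.size


def rotation_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (non-zero) axis."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


@dataclass(frozen=True)
class Pose:
    rotation: np.ndarray            # (3, 3)
    translation: np.ndarray         # (3,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, float))
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, float))

    @staticmethod
    def identity() -> "Pose":
        return Pose(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def perturbed(self, rot: np.ndarray, shift: np.ndarray) -> "Pose":
        return Pose(rot @ self.rotation, self.translation + shift)


@dataclass(frozen=True)
class SubcomplexInstance:
    """One posed copy of a subcomplex type within the asymmetric unit.

    ``instance_id`` is any hashable label that is stable across structures
    (substructures of a mature reference keep the mature ids), so that
    Go-contact bookkeeping and pathway-inclusion checks can identify the
    same copy in different structures.
    """

    type_id: str
    instance_id: object
    pose: Pose


@dataclass(frozen=True)
class ExpandedBeads:
    """Flat bead arrays of a (symmetry-expanded) structure."""

    positions: np.ndarray           # (B, 3)
    radii: np.ndarray               # (B,)
    alps: np.ndarray                # (B,) bool
    inst_keys: list                 # length B, hashable per-instance key
    bead_keys: list                 # length B, (inst_key, bead_index)
    type_ids: list                  # length B


@dataclass(frozen=True)
class StaticStructure:
    """C8-symmetric bead configuration at one time point.

    ``instances`` describe one asymmetric unit when ``n_fold > 1``; the
    full pore is the unit rotated by ``2*pi*k/n_fold`` about z.  A fully
    expanded structure uses ``n_fold = 1``.
    """

    time_label: float
    instances: tuple[SubcomplexInstance, ...]
    n_fold: int = 8

    def __post_init__(self) -> None:
        object.__setattr__(self, "instances", tuple(self.instances))
        ids = [inst.instance_id for inst in self.instances]
        if len(set(ids)) != len(ids):
            raise ValueError("instance ids must be unique within a structure")

    def copy_numbers(self) -> dict[str, int]:
        """Total copies per subcomplex type in the full pore."""
        counts: dict[str, int] = {}
        for inst in self.instances:
            counts[inst.type_id] = counts.get(inst.type_id, 0) + self.n_fold
        return counts

    def instance_keys(self) -> frozenset:
        """Identity of every copy in the full pore (for inclusion tests)."""
        if self.n_fold == 1:
            return frozenset(inst.instance_id for inst in self.instances)
        return frozenset((inst.instance_id, s)
                         for inst in self.instances
                         for s in range(self.n_fold))

    def expand(self, types: Mapping[str, SubcomplexType]) -> ExpandedBeads:
        positions, radii, alps = [], [], []
        inst_keys, bead_keys, type_ids = [], [], []
        spokes = range(self.n_fold)
        rots = [rotation_z(2.0 * np.pi * s / self.n_fold) for s in spokes]
        for inst in self.instances:
            sub = types[inst.type_id]
            local = inst.pose.apply(sub.bead_offsets)
            for s in spokes:
                key = inst.instance_id if self.n_fold == 1 \
                    else (inst.instance_id, s)
                pts = local @ rots[s].T
                positions.append(pts)
                radii.append(sub.bead_radii)
                alps.append(sub.alps_mask)
                inst_keys.extend([key] * sub.n_beads)
                bead_keys.extend((key, b) for b in range(sub.n_beads))
                type_ids.extend([inst.type_id] * sub.n_beads)
        return ExpandedBeads(positions=np.vstack(positions),
                             radii=np.concatenate(radii),
                             alps=np.concatenate(alps),
                             inst_keys=inst_keys, bead_keys=bead_keys,
                             type_ids=type_ids)

    def expanded_structure(self, types: Mapping[str, SubcomplexType]
                           ) -> "StaticStructure":
        """The same pore as an explicit ``n_fold = 1`` structure."""
        out = []
        for inst in self.instances:
            for s in range(self.n_fold):
                rot = rotation_z(2.0 * np.pi * s / self.n_fold)
                out.append(SubcomplexInstance(
                    type_id=inst.type_id,
                    instance_id=(inst.instance_id, s),
                    pose=Pose(rot @ inst.pose.rotation,
                              rot @ inst.pose.translation)))
        return StaticStructure(time_label=self.time_label,
                               instances=tuple(out), n_fold=1)

    def with_pose(self, instance_id, pose: Pose) -> "StaticStructure":
        out = [replace(inst, pose=pose) if inst.instance_id == instance_id
               else inst for inst in self.instances]
        return replace(self, instances=tuple(out))


@dataclass(frozen=True)
class EnvelopeToroid:
    """Nuclear envelope around one pore: toroid wall joining two planes."""

    pore_diameter: float            # nm, inner (channel) diameter
    minor_radius: float             # nm, tube radius (half membrane spacing)

    def __post_init__(self) -> None:
        if self.pore_diameter <= 0 or self.minor_radius <= 0:
            raise ValueError("pore diameter and minor radius must be positive")

    @property
    def pore_radius(self) -> float:
        return 0.5 * self.pore_diameter

    @property
    def major_radius(self) -> float:
        # centre circle of the membrane tube
        return self.pore_radius + self.minor_radius

    def penetration(self, points: np.ndarray) -> np.ndarray:
        """Depth (nm, >= 0) by which each point sits inside the membrane.

        0 for points outside the membrane volume; uses the analytic
        closest-surface distance of the torus-with-planes geometry.
        """
        points = np.atleast_2d(np.asarray(points, float))
        rho = np.hypot(points[:, 0], points[:, 1])
        z = points[:, 2]
        pen_torus = self.minor_radius - np.hypot(rho - self.major_radius, z)
        pen_slab = np.where(rho >= self.major_radius,
                            self.minor_radius - np.abs(z), -np.inf)
        return np.maximum(np.maximum(pen_torus, pen_slab), 0.0)

    def surface_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance to the membrane surface (negative inside)."""
        points = np.atleast_2d(np.asarray(points, float))
        rho = np.hypot(points[:, 0], points[:, 1])
        z = points[:, 2]
        d_torus = np.hypot(rho - self.major_radius, z) - self.minor_radius
        d_slab = np.where(rho >= self.major_radius,
                          np.abs(z) - self.minor_radius, np.inf)
        return np.minimum(d_torus, d_slab)
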