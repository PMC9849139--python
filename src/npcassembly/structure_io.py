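"""Loading mature reference structures from mmCIF/PDB files.

For users who want to score against a real mature NPC model (e.g. the
deposited partial pseudoatomic structures of the human pore) instead of a
toy system: each polymer chain is coarse-grained into beads of
``residues_per_bead`` consecutive residues at their atomic center of
mass, and returned as one rigid subcomplex instance.  Coordinates are
converted to nm.  The toy-scale tests do not depend on this loader.
"""

from __future__ import annotations

import numpy as np

from .geometry import (Pose, StaticStructure, SubcomplexInstance,
                       SubcomplexType)

__all__ = ["load_reference_structure"]


def load_reference_structure(path, residues_per_bead: int = 10,
                             bead_radius: float = 1.0,
                             n_fold: int = 1
                             ) -> tuple[dict[str, SubcomplexType],
                                        StaticStructure]:
    """Read an mmCIF/PDB file into coarse-grained rigid bodies.

    Each chain becomes its own subcomplex type (named after the chain id)
    with one posed instance; set ``n_fold=8`` if the file holds a single
    spoke to be expanded by C8 symmetry.  Returns ``(types, structure)``.
    """
    import gemmi

    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    model = structure[0]
    types: dict[str, SubcomplexType] = {}
    instances = []
    for chain in model:
        positions, weights = [], []
        for residue in chain:
            for atom in residue:
                positions.append([atom.pos.x, atom.pos.y, atom.pos.z])
                weights.append(atom.element.weight or 12.0)
        if not positions:
            continue
        positions = np.asarray(positions) / 10.0        # A -> nm
        weights = np.asarray(weights)
        # group consecutive residues' atoms approximately evenly
        n_res = sum(1 for _ in chain)
        n_beads = max(1, n_res // residues_per_bead)
        splits = np.array_split(np.arange(positions.shape[0]), n_beads)
        beads = np.array([
            np.average(positions[idx], axis=0, weights=weights[idx])
            for idx in splits])
        centroid = beads.mean(axis=0)
        types[chain.name] = SubcomplexType(
            type_id=chain.name, bead_offsets=beads - centroid,
            bead_radii=np.full(n_beads, bead_radius))
        instances.append(SubcomplexInstance(
            type_id=chain.name, instance_id=chain.name,
            pose=Pose(np.eye(3), centroid)))
    if not instances:
        raise ValueError(f"no polymer coordinates found in {path}")
    return types, StaticStructure(time_label=0.0, instances=tuple(instances),
                                  n_fold=n_fold)
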