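"""Pocket truncation, frozen/active region assignment, and pose rescoring.

The end-to-end refinement protocol for a docked pose:

1. **Truncate** the receptor to the residues within a radius
   (8–15 Å, default 12 Å) of the ligand's geometric center, keeping
   residues whole and hydrogen-capping severed backbone bonds.
2. **Assign regions**: receptor atoms within 2.5 Å of any ligand atom
   form the *active* part and move under a 5 kcal/mol/Å² harmonic
   positional restraint toward their input positions; all other
   receptor atoms are *frozen* (restraint weight −1) and stay static.
   Ligand atoms are fully unrestrained.
3. **Refine**: build the complex (pocket atoms then pose atoms),
   compose the potential with the restraints and frozen mask, minimize
   with CG-BS, and compute the binding energy

       ΔE_bind = E_com − E_rec − E_lig

   where E_rec and E_lig are single-point energies of the pocket and
   the ligand at their optimized in-complex coordinates (rigid
   decomposition; separate relaxation is available as an option).
4. **Rank** the pose set by ascending ΔE_bind (most negative first).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .optimizer import ConvergenceCriteria, OptimizerConfig, cgbs_minimize
from .potentials import EnergyModel, PositionalRestraint, compose
from .structures import FROZEN_SENTINEL, Atom, Structure, concatenate

__all__ = [
    "RegionAssignment",
    "PoseScore",
    "truncate_receptor",
    "assign_regions",
    "refine_pose",
    "binding_energy",
    "rank_poses",
]

# backbone linkage atoms whose bond may be severed by truncation:
# (atom in kept residue, atom in neighboring residue, neighbor offset)
_LINKAGE = [
    ("N", "C", -1),    # peptide bond to the previous amino acid
    ("C", "N", +1),    # peptide bond to the next amino acid
    ("P", "O3'", -1),  # phosphodiester bond to the previous nucleotide
    ("O3'", "P", +1),  # phosphodiester bond to the next nucleotide
]
_CAP_BOND_LENGTH = 1.09  # Å, standard X–H distance used for capping
_MAX_BOND_LENGTH = 2.0   # Å, sanity cutoff: farther pairs were never bonded


@dataclass
class RegionAssignment:
    """Frozen/active split of a pocket's atoms for restrained refinement."""

    frozen_indices: frozenset
    active_indices: frozenset
    weights: np.ndarray
    reference_coords: np.ndarray

    def __post_init__(self):
        if self.frozen_indices & self.active_indices:
            raise ValueError("an atom cannot be both frozen and active")

    @property
    def frozen_mask(self) -> np.ndarray:
        mask = np.zeros(len(self.weights), dtype=bool)
        mask[list(self.frozen_indices)] = True
        return mask


@dataclass
class PoseScore:
    """Energies and rank of one refined pose."""

    pose_id: str
    E_com: float
    E_rec: float
    E_lig: float
    delta_E_bind: float
    converged: bool
    rank: int = 0


def truncate_receptor(receptor: Structure, ligand: Structure, radius: float = 12.0) -> Structure:
    """Keep receptor residues with any atom within ``radius`` of the ligand center.

    Residues are kept or dropped whole.  Backbone bonds severed by the
    truncation (peptide N–C and nucleotide P–O3' linkages) are capped
    with a hydrogen placed 1.09 Å along the former bond vector, keeping
    valences closed without introducing new residues.
    """
    if len(receptor) == 0 or len(ligand) == 0:
        raise ValueError("receptor and ligand must be non-empty")
    if not (8.0 <= radius <= 15.0):
        warnings.warn(
            f"truncation radius {radius} Å is outside the usual 8–15 Å range",
            stacklevel=2,
        )
    center = ligand.centroid()
    coords = receptor.coords
    residues = receptor.residues()
    kept_keys = set()
    for key, idxs in residues:
        d = np.linalg.norm(coords[idxs] - center, axis=1)
        if d.min() <= radius:
            kept_keys.add(key)
    if not kept_keys:
        raise ValueError(f"no receptor residue within {radius} Å of the ligand center")

    atom_lookup = {}
    for i, a in enumerate(receptor.atoms):
        atom_lookup[(a.chain_id, a.residue_id, a.atom_name.strip())] = i

    atoms: list[Atom] = []
    caps: list[Atom] = []
    for key, idxs in residues:
        if key not in kept_keys:
            continue
        chain, res_id = key
        for i in idxs:
            atoms.append(receptor.atoms[i])
        for own_name, partner_name, offset in _LINKAGE:
            own_idx = atom_lookup.get((chain, res_id, own_name))
            partner_idx = atom_lookup.get((chain, res_id + offset, partner_name))
            if own_idx is None or partner_idx is None:
                continue
            if (chain, res_id + offset) in kept_keys:
                continue  # bond partner survives; nothing severed
            own = receptor.atoms[own_idx]
            bond = receptor.atoms[partner_idx].coords - own.coords
            bond_len = float(np.linalg.norm(bond))
            if bond_len == 0.0 or bond_len > _MAX_BOND_LENGTH:
                continue
            caps.append(
                Atom(
                    element="H",
                    coords=own.coords + _CAP_BOND_LENGTH * bond / bond_len,
                    residue_name=own.residue_name,
                    residue_id=own.residue_id,
                    chain_id=own.chain_id,
                    atom_name="HCP",
                    restraint_weight=0.0,
                )
            )
    return Structure(atoms + caps, label=f"{receptor.label}_pocket")


def assign_regions(
    pocket: Structure,
    ligand: Structure,
    boundary: float = 2.5,
    active_weight: float = 5.0,
    frozen_flag: float = FROZEN_SENTINEL,
) -> RegionAssignment:
    """Split pocket atoms into active (≤ ``boundary`` Å of any ligand atom) and frozen.

    The boundary comparison is inclusive and measured between atom
    centers, hydrogens included.  Active atoms get ``active_weight``
    (harmonic restraint toward their input positions); frozen atoms get
    the ``frozen_flag`` sentinel.
    """
    if len(pocket) == 0 or len(ligand) == 0:
        raise ValueError("pocket and ligand must be non-empty")
    tree = cKDTree(ligand.coords)
    dmin, _ = tree.query(pocket.coords, k=1)
    active = np.flatnonzero(dmin <= boundary)
    frozen = np.flatnonzero(dmin > boundary)
    weights = np.full(len(pocket), frozen_flag, dtype=float)
    weights[active] = active_weight
    return RegionAssignment(
        frozen_indices=frozenset(int(i) for i in frozen),
        active_indices=frozenset(int(i) for i in active),
        weights=weights,
        reference_coords=pocket.coords,
    )


def binding_energy(E_com: float, E_rec: float, E_lig: float) -> float:
    """ΔE_bind = E_com − E_rec − E_lig (kcal/mol)."""
    for name, v in (("E_com", E_com), ("E_rec", E_rec), ("E_lig", E_lig)):
        if not np.isfinite(v):
            raise ValueError(f"{name} is not finite: {v}")
    return float(E_com - E_rec - E_lig)


def refine_pose(
    pocket: Structure,
    pose: Structure,
    assignment: RegionAssignment,
    model: EnergyModel,
    criteria: ConvergenceCriteria = ConvergenceCriteria(),
    config: OptimizerConfig = OptimizerConfig(),
    relax_components: bool = False,
) -> tuple[Structure, PoseScore]:
    """Optimize the pocket+pose complex and score its binding energy.

    The complex is pocket atoms followed by pose atoms.  Active pocket
    atoms are restrained to their reference positions with the
    assignment's weights, frozen pocket atoms are masked static, and
    ligand atoms run free.  After minimization, E_com / E_rec / E_lig
    are energies of the *base* model (restraint terms excluded): E_com
    on the full optimized complex, E_rec and E_lig single points on the
    pocket and ligand at their optimized in-complex coordinates.  With
    ``relax_components=True`` the pocket and ligand are instead relaxed
    separately before their single-point energies.
    """
    if len(assignment.weights) != len(pocket):
        raise ValueError("assignment does not match the pocket atom count")
    complex_structure = concatenate([pocket, pose], label=pose.label or "complex")
    model.check_elements(complex_structure.elements)

    n_rec = len(pocket)
    frozen_mask = np.concatenate([assignment.frozen_mask, np.zeros(len(pose), dtype=bool)])

    restraints = []
    active = sorted(assignment.active_indices)
    if active:
        # group by weight so heterogeneous assignments stay exact
        by_weight: dict[float, list[int]] = {}
        for i in active:
            by_weight.setdefault(float(assignment.weights[i]), []).append(i)
        for w, idxs in by_weight.items():
            restraints.append(
                PositionalRestraint(
                    atom_indices=tuple(idxs),
                    reference_coords=assignment.reference_coords[idxs],
                    weight=w,
                )
            )

    composite = compose(model, restraints, frozen_mask)
    result = cgbs_minimize(composite, complex_structure.coords, frozen_mask, criteria, config)

    final = result.final_coords
    E_com = model.energy(final)
    if relax_components:
        rec_result = cgbs_minimize(
            compose(model, restraints, assignment.frozen_mask),
            final[:n_rec],
            assignment.frozen_mask,
            criteria,
            config,
        )
        lig_result = cgbs_minimize(model, final[n_rec:], None, criteria, config)
        E_rec = model.energy(rec_result.final_coords)
        E_lig = model.energy(lig_result.final_coords)
    else:
        E_rec = model.energy(final[:n_rec])
        E_lig = model.energy(final[n_rec:])

    score = PoseScore(
        pose_id=pose.label or "pose",
        E_com=E_com,
        E_rec=E_rec,
        E_lig=E_lig,
        delta_E_bind=binding_energy(E_com, E_rec, E_lig),
        converged=result.converged,
    )
    weights = np.concatenate([assignment.weights, np.zeros(len(pose))])
    optimized = complex_structure.with_coords(final).with_weights(weights)
    return optimized, score


def rank_poses(scores: Sequence[PoseScore]) -> list[PoseScore]:
    """Assign ranks by ascending ΔE_bind (rank 1 = most negative).

    Ties keep input order (stable sort).  Returns new PoseScore objects
    in the input order with the ``rank`` field set.
    """
    if not scores:
        raise ValueError("rank_poses requires at least one pose")
    order = sorted(range(len(scores)), key=lambda i: scores[i].delta_E_bind)
    ranks = [0] * len(scores)
    for rank, i in enumerate(order, start=1):
        ranks[i] = rank
    return [replace(s, rank=r) for s, r in zip(scores, ranks)]
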