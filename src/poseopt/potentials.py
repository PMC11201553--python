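"""Energy/force backends consumed by the optimizer.

Every backend satisfies the :class:`EnergyModel` contract: a callable
``evaluate(coords)`` mapping an (N, 3) coordinate array in Å to a tuple
``(energy, forces)`` with the energy in kcal/mol and forces (negative
gradient) in kcal/mol/Å.  Backends include analytic test potentials
(Lennard-Jones clusters, harmonic wells), harmonic positional and
torsional restraint terms, a composite that sums a base potential with
restraints and masks frozen atoms, and an adapter to the published
ANI-2x neural-network potential (optional dependency).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "EnergyModel",
    "LennardJonesModel",
    "HarmonicWellModel",
    "PositionalRestraint",
    "TorsionRestraint",
    "CompositePotential",
    "lj_pair_model",
    "harmonic_well_model",
    "compose",
    "ani2x_adapter",
    "ANI_SUPPORTED_ELEMENTS",
    "finite_difference_forces",
    "UnsupportedElementError",
]

#: elements the ANI-2x potential was trained on
ANI_SUPPORTED_ELEMENTS = frozenset({"H", "C", "N", "O", "S", "F", "Cl"})


class UnsupportedElementError(ValueError):
    """An element outside a backend's training/support domain."""


class EnergyModel:
    """Base contract: coordinates (Å) -> (energy kcal/mol, forces kcal/mol/Å)."""

    #: set of supported element symbols, or the string "any"
    supported_elements: frozenset | str = "any"

    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        raise NotImplementedError

    def energy(self, coords: np.ndarray) -> float:
        return self.evaluate(coords)[0]

    def check_elements(self, elements: Sequence[str]) -> None:
        if self.supported_elements == "any":
            return
        for e in elements:
            if e not in self.supported_elements:
                raise UnsupportedElementError(
                    f"element {e!r} is not supported by this potential "
                    f"(supported: {sorted(self.supported_elements)})"
                )


def _as_coords(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError(f"coordinates must be (N, 3), got shape {coords.shape}")
    return coords


class LennardJonesModel(EnergyModel):
    """Pairwise-additive 12-6 Lennard-Jones over all atom pairs.

    E = 4ε Σ_{i<j} [(σ/r_ij)^12 − (σ/r_ij)^6].  The dimer minimum sits at
    r = 2^(1/6) σ with depth −ε.  An optional plain truncation ``cutoff``
    zeroes pair contributions beyond that distance (used to build
    strictly non-interacting partitions in tests).
    """

    def __init__(self, epsilon: float = 1.0, sigma: float = 1.0, cutoff: float | None = None):
        if epsilon <= 0 or sigma <= 0:
            raise ValueError("epsilon and sigma must be positive")
        self.epsilon = float(epsilon)
        self.sigma = float(sigma)
        self.cutoff = None if cutoff is None else float(cutoff)

    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        coords = _as_coords(coords)
        n = len(coords)
        forces = np.zeros_like(coords)
        if n < 2:
            return 0.0, forces
        diff = coords[:, None, :] - coords[None, :, :]
        r2 = np.einsum("ijk,ijk->ij", diff, diff)
        iu = np.triu_indices(n, k=1)
        r2_pairs = r2[iu]
        if np.any(r2_pairs == 0.0):
            raise ValueError("coincident atoms: Lennard-Jones energy undefined at r = 0")
        mask = np.ones_like(r2_pairs, dtype=bool)
        if self.cutoff is not None:
            mask = r2_pairs <= self.cutoff**2
        s2 = self.sigma**2 / r2_pairs
        s6 = s2**3
        s12 = s6**2
        e_pairs = 4.0 * self.epsilon * (s12 - s6)
        energy = float(np.sum(e_pairs[mask]))
        # dE/dr2 per pair; force on i is -dE/dri = -(dE/dr2)*2*(ri-rj)
        de_dr2 = 4.0 * self.epsilon * (-6.0 * s12 + 3.0 * s6) / r2_pairs
        de_dr2 = np.where(mask, de_dr2, 0.0)
        fmat = np.zeros((n, n))
        fmat[iu] = de_dr2
        fmat = fmat + fmat.T
        forces = -2.0 * np.einsum("ij,ijk->ik", fmat, diff)
        return energy, forces

    def pair_energy(self, coords_a: np.ndarray, coords_b: np.ndarray) -> float:
        """Cross-interaction energy between two atom groups (no intra terms)."""
        coords_a = _as_coords(coords_a)
        coords_b = _as_coords(coords_b)
        diff = coords_a[:, None, :] - coords_b[None, :, :]
        r2 = np.einsum("ijk,ijk->ij", diff, diff)
        if np.any(r2 == 0.0):
            raise ValueError("coincident atoms across groups")
        if self.cutoff is not None:
            sel = r2 <= self.cutoff**2
        else:
            sel = np.ones_like(r2, dtype=bool)
        s6 = (self.sigma**2 / r2) ** 3
        return float(np.sum((4.0 * self.epsilon * (s6**2 - s6))[sel]))


class HarmonicWellModel(EnergyModel):
    """Isotropic harmonic well: E = k Σ_i |r_i − c|², F_i = −2k (r_i − c)."""

    def __init__(self, k: float = 1.0, center: Sequence[float] = (0.0, 0.0, 0.0)):
        if k <= 0:
            raise ValueError("k must be positive")
        self.k = float(k)
        self.center = np.asarray(center, dtype=float).reshape(3)

    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        coords = _as_coords(coords)
        d = coords - self.center
        energy = self.k * float(np.sum(d * d))
        forces = -2.0 * self.k * d
        return energy, forces


def lj_pair_model(epsilon: float, sigma: float, cutoff: float | None = None) -> LennardJonesModel:
    return LennardJonesModel(epsilon, sigma, cutoff)


def harmonic_well_model(k: float, center: Sequence[float] = (0.0, 0.0, 0.0)) -> HarmonicWellModel:
    return HarmonicWellModel(k, center)


# ---------------------------------------------------------------------------
# Restraints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PositionalRestraint:
    """Harmonic positional restraint E = w Σ_i |r_i − r_i⁰|².

    The functional form carries no ½ factor: a weight of w kcal/mol/Å²
    costs w kcal/mol per Å² of squared displacement, matching the
    convention the per-atom weights are quoted in.
    """

    atom_indices: tuple[int, ...]
    reference_coords: np.ndarray
    weight: float

    def __post_init__(self):
        object.__setattr__(self, "atom_indices", tuple(int(i) for i in self.atom_indices))
        ref = np.asarray(self.reference_coords, dtype=float).reshape(-1, 3)
        if ref.shape[0] != len(self.atom_indices):
            raise ValueError("reference_coords must match atom_indices length")
        object.__setattr__(self, "reference_coords", ref)
        if self.weight <= 0:
            raise ValueError("restraint weight must be positive")

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        coords = _as_coords(coords)
        idx = np.asarray(self.atom_indices, dtype=int)
        if len(idx) and idx.max() >= len(coords):
            raise IndexError("restraint index out of range for coordinate array")
        d = coords[idx] - self.reference_coords
        energy = self.weight * float(np.sum(d * d))
        forces = np.zeros_like(coords)
        forces[idx] = -2.0 * self.weight * d
        return energy, forces


def restraint_energy_forces(
    restraint: "PositionalRestraint", coords: np.ndarray
) -> tuple[float, np.ndarray]:
    return restraint.energy_forces(coords)


def _dihedral_and_gradient(p: np.ndarray) -> tuple[float, np.ndarray]:
    """Signed dihedral (radians) of four points and its analytic gradient.

    Uses the standard normal-vector formulation; raises on collinear
    consecutive triples where the dihedral is undefined.
    """
    b1 = p[1] - p[0]
    b2 = p[2] - p[1]
    b3 = p[3] - p[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1_sq = float(n1 @ n1)
    n2_sq = float(n2 @ n2)
    b2_len = float(np.linalg.norm(b2))
    if n1_sq < 1e-18 or n2_sq < 1e-18 or b2_len < 1e-12:
        raise ValueError("dihedral undefined: collinear consecutive atoms")
    phi = float(np.arctan2((np.cross(n1, n2) @ b2) / b2_len, n1 @ n2))
    dphi = np.zeros((4, 3))
    dphi[0] = -(b2_len / n1_sq) * n1
    dphi[3] = (b2_len / n2_sq) * n2
    f1 = float(b1 @ b2) / (b2_len**2)
    f3 = float(b3 @ b2) / (b2_len**2)
    dphi[1] = -(1.0 + f1) * dphi[0] + f3 * dphi[3]
    dphi[2] = f1 * dphi[0] - (1.0 + f3) * dphi[3]
    return phi, dphi


def _wrap_angle(delta: float) -> float:
    """Wrap an angle difference into (−π, π]."""
    wrapped = (delta + np.pi) % (2.0 * np.pi) - np.pi
    if wrapped == -np.pi:
        wrapped = np.pi
    return float(wrapped)


@dataclass(frozen=True)
class TorsionRestraint:
    """Harmonic torsional restraint E = w Δφ² on one dihedral.

    Δφ is the signed difference between the current dihedral and the
    target, wrapped into (−180°, 180°] so a target of 180° and a current
    value of −180° cost nothing.  Weight is kcal/mol/rad².
    """

    atom_quadruple: tuple[int, int, int, int]
    target_angle: float  # degrees, in (−180, 180]
    weight: float

    def __post_init__(self):
        quad = tuple(int(i) for i in self.atom_quadruple)
        if len(quad) != 4 or len(set(quad)) != 4:
            raise ValueError("atom_quadruple must contain four distinct indices")
        object.__setattr__(self, "atom_quadruple", quad)
        if not (-180.0 < self.target_angle <= 180.0):
            raise ValueError("target_angle must lie in (−180, 180] degrees")
        if self.weight <= 0:
            raise ValueError("restraint weight must be positive")

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        coords = _as_coords(coords)
        idx = np.asarray(self.atom_quadruple, dtype=int)
        if idx.max() >= len(coords):
            raise IndexError("torsion index out of range")
        phi, dphi = _dihedral_and_gradient(coords[idx])
        delta = _wrap_angle(phi - np.deg2rad(self.target_angle))
        energy = self.weight * delta**2
        forces = np.zeros_like(coords)
        forces[idx] = -2.0 * self.weight * delta * dphi
        return energy, forces


def torsion_restraint_energy_forces(
    restraint: TorsionRestraint, coords: np.ndarray
) -> tuple[float, np.ndarray]:
    return restraint.energy_forces(coords)


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

@dataclass
class CompositePotential(EnergyModel):
    """Base potential plus restraint terms, with frozen-atom force masking.

    Energy is exactly the sum of the parts.  Frozen atoms still feel —
    and exert — the base potential (they are a static environment); only
    the forces reported on them are zeroed after summation so no
    optimizer can move them.
    """

    base: EnergyModel
    restraints: tuple = field(default_factory=tuple)
    frozen_mask: np.ndarray | None = None

    def __post_init__(self):
        self.restraints = tuple(self.restraints)
        if self.frozen_mask is not None:
            self.frozen_mask = np.asarray(self.frozen_mask, dtype=bool)
        self.supported_elements = self.base.supported_elements

    def evaluate(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        coords = _as_coords(coords)
        if self.frozen_mask is not None and len(self.frozen_mask) != len(coords):
            raise ValueError(
                f"frozen mask length {len(self.frozen_mask)} != atom count {len(coords)}"
            )
        energy, forces = self.base.evaluate(coords)
        forces = forces.copy()
        for restraint in self.restraints:
            e_r, f_r = restraint.energy_forces(coords)
            energy += e_r
            forces += f_r
        if self.frozen_mask is not None:
            forces[self.frozen_mask] = 0.0
        return energy, forces


def compose(
    base: EnergyModel,
    restraints: Sequence = (),
    frozen_mask: np.ndarray | None = None,
) -> CompositePotential:
    return CompositePotential(base, tuple(restraints), frozen_mask)


# ---------------------------------------------------------------------------
# ANI-2x adapter (optional dependency)
# ---------------------------------------------------------------------------

def ani2x_adapter(elements: Sequence[str]) -> EnergyModel:
    """Adapter exposing the published ANI-2x potential as an EnergyModel.

    ``elements`` fixes the species vector, in atom order, of every
    coordinate array later passed to ``evaluate``.  Element support is
    checked up front (ANI-2x covers H, C, N, O, S, F, Cl only), before
    the torch stack is touched, so e.g. a bromine-containing ligand is
    rejected with a precise message whether or not torchani is present.
    Energies are converted from Hartree to kcal/mol and forces to
    kcal/mol/Å; evaluation is deterministic for fixed coordinates.
    """
    for e in elements:
        if e not in ANI_SUPPORTED_ELEMENTS:
            raise UnsupportedElementError(
                f"element {e!r} is not supported by the ANI-2x potential "
                f"(supported: {sorted(ANI_SUPPORTED_ELEMENTS)})"
            )
    try:
        import torch
        import torchani
    except ImportError as exc:
        raise ImportError(
            "the ANI-2x backend requires the optional dependencies "
            "'torch' and 'torchani'; install them with "
            "`pip install poseopt[ani]` or `pip install torch torchani`"
        ) from exc

    from .units import BOHR_TO_ANGSTROM, HARTREE_TO_KCALMOL  # noqa: F401

    class _ANI2xModel(EnergyModel):
        supported_elements = ANI_SUPPORTED_ELEMENTS

        def __init__(self, symbols):
            self._model = torchani.models.ANI2x(periodic_table_index=False)
            self._species = self._model.species_to_tensor("".join(symbols)).unsqueeze(0)
            self._symbols = list(symbols)

        def evaluate(self, coords):
            coords = _as_coords(coords)
            if len(coords) != len(self._symbols):
                raise ValueError("coordinate count does not match bound species")
            pos = torch.tensor(coords, dtype=torch.float64).unsqueeze(0)
            pos.requires_grad_(True)
            energy_h = self._model((self._species, pos)).energies
            (grad,) = torch.autograd.grad(energy_h.sum(), pos)
            energy = float(energy_h.item()) * HARTREE_TO_KCALMOL
            forces = -grad.squeeze(0).numpy() * HARTREE_TO_KCALMOL
            return energy, forces

    return _ANI2xModel(list(elements))


# ---------------------------------------------------------------------------
# Finite-difference oracle
# ---------------------------------------------------------------------------

def finite_difference_forces(
    model: EnergyModel, coords: np.ndarray, h: float = 1e-5
) -> np.ndarray:
    """Central-difference numerical forces, −∂E/∂x with step h (Å).

    The independent check every analytic backend is validated against.
    """
    coords = _as_coords(coords)
    forces = np.zeros_like(coords)
    for i in range(coords.shape[0]):
        for j in range(3):
            plus = coords.copy()
            minus = coords.copy()
            plus[i, j] += h
            minus[i, j] -= h
            forces[i, j] = -(model.energy(plus) - model.energy(minus)) / (2.0 * h)
    return forces
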