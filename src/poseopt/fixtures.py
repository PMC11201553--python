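"""Deterministic synthetic systems for exercising the whole pipeline.

Commercial docking engines and curated affinity databases cannot ship
with a library, so these generators produce the three inputs every
pipeline stage needs: toy receptor–ligand complexes on an analytic
Lennard-Jones surface, rigid-perturbation decoy pose sets standing in
for a docking engine's top-10 output, and synthetic screening tables
whose predicted scores are the exact affinity-derived energy plus
Gaussian noise.  A single explicit integer seed fixes all randomness;
no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import KI_TIER_BOUNDS, ScreeningRecord, ki_to_energy
from .units import GAS_CONSTANT_KCALMOL
from .structures import Atom, Structure

__all__ = [
    "ToyComplexSpec",
    "DecoySpec",
    "make_toy_complex",
    "make_decoys",
    "make_screening_table",
]


@dataclass(frozen=True)
class ToyComplexSpec:
    """Parameters of a Lennard-Jones toy complex."""

    n_receptor_atoms: int = 8
    n_ligand_atoms: int = 2
    potential: str = "lj"
    epsilon: float = 1.0
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_receptor_atoms < 1 or self.n_ligand_atoms < 1:
            raise ValueError("atom counts must be >= 1")
        if self.potential != "lj":
            raise ValueError("only the 'lj' toy potential is implemented")


@dataclass(frozen=True)
class DecoySpec:
    """Rigid-perturbation decoy generator parameters."""

    n_decoys: int = 10
    max_translation: float = 1.0  # Å
    max_rotation: float = 30.0  # degrees
    seed: int = 0
    include_native: bool = False

    def __post_init__(self):
        if self.n_decoys < 1:
            raise ValueError("n_decoys must be >= 1")
        if self.max_translation < 0 or self.max_rotation < 0:
            raise ValueError("perturbation magnitudes must be non-negative")


def make_toy_complex(spec: ToyComplexSpec) -> tuple[Structure, Structure]:
    """Build a jittered-lattice LJ receptor and a ligand at a favorable site.

    Receptor atoms sit on a cubic lattice with spacing 2^(1/6) σ (the LJ
    pair minimum), jittered by 2% of σ.  The ligand starts as a short
    chain outside the cluster along +x and is then relaxed against the
    static receptor, so the returned native pose sits at a genuine
    local minimum of the joint LJ surface.  For a 1+1 atom spec this
    reduces to a dimer at the analytic minimum separation 2^(1/6) σ.
    """
    rng = np.random.default_rng(spec.seed)
    r_min = 2.0 ** (1.0 / 6.0) * spec.sigma

    side = int(np.ceil(spec.n_receptor_atoms ** (1.0 / 3.0)))
    lattice = []
    for i in range(side):
        for j in range(side):
            for k in range(side):
                lattice.append((i, j, k))
    lattice = np.array(lattice[: spec.n_receptor_atoms], dtype=float) * r_min
    lattice -= lattice.mean(axis=0)
    jitter = rng.normal(0.0, 0.02 * spec.sigma, size=lattice.shape)
    rec_coords = lattice + jitter

    receptor = Structure(
        [
            Atom("C", c, residue_name="REC", residue_id=i + 1, chain_id="R", atom_name="C")
            for i, c in enumerate(rec_coords)
        ],
        label="toy_receptor",
    )

    # Place the ligand at the most favorable surface site: start a chain
    # outward from several candidate directions, relax each against the
    # static receptor, and keep the deepest minimum.  This makes the
    # native basin the deepest sampled one by construction, so decoy
    # ranking tests have a well-defined right answer.  (Deferred import:
    # fixtures sit above the optimizer in the layering only here.)
    from .optimizer import OptimizerConfig, cgbs_minimize
    from .potentials import LennardJonesModel

    model = LennardJonesModel(spec.epsilon, spec.sigma)
    centroid = rec_coords.mean(axis=0)
    extent = float(np.abs(rec_coords - centroid).max()) if len(rec_coords) > 1 else 0.0
    directions = [np.array(v, dtype=float) for v in
                  [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
                   (1, 1, 0), (1, -1, 0), (-1, 1, 0), (-1, -1, 0),
                   (1, 0, 1), (1, 0, -1), (-1, 0, 1), (-1, 0, -1),
                   (0, 1, 1), (0, 1, -1), (0, -1, 1), (0, -1, -1),
                   (1, 1, 1), (-1, -1, -1), (1, -1, 1), (-1, 1, -1)]]
    frozen = np.array([True] * len(rec_coords) + [False] * spec.n_ligand_atoms)
    candidates = []
    for direction in directions:
        u = direction / np.linalg.norm(direction)
        # exterior approach along this direction
        candidates.append(np.array(
            [centroid + (extent + r_min + n * r_min) * u for n in range(spec.n_ligand_atoms)]
        ))
        # interior cavity along the same axis (clusters often hide their
        # deepest site inside; start slightly off-center to break symmetry)
        candidates.append(np.array(
            [centroid + (0.1 + 0.3 * n) * r_min * u for n in range(spec.n_ligand_atoms)]
        ))
        # surface-hugging chain: anchor outside along u, extend tangentially
        if spec.n_ligand_atoms > 1:
            ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
            t = np.cross(u, ref)
            t /= np.linalg.norm(t)
            anchor = centroid + (extent + r_min) * u
            candidates.append(np.array(
                [anchor + n * r_min * t for n in range(spec.n_ligand_atoms)]
            ))
    best_energy, lig_coords = np.inf, None
    cfg = OptimizerConfig(max_iterations=500)
    for start in candidates:
        result = cgbs_minimize(model, np.vstack([rec_coords, start]), frozen, config=cfg)
        if result.final_energy < best_energy:
            best_energy = result.final_energy
            lig_coords = result.final_coords[len(rec_coords):]

    ligand = Structure(
        [
            Atom("C", c, residue_name="LIG", residue_id=1, chain_id="L", atom_name="C")
            for c in lig_coords
        ],
        label="toy_ligand",
    )
    return receptor, ligand


def _random_rotation_matrix(rng: np.random.Generator, max_angle_deg: float) -> np.ndarray:
    """Axis–angle rotation: uniform axis on the sphere, uniform angle in [0, max]."""
    axis = rng.normal(size=3)
    norm = np.linalg.norm(axis)
    axis = axis / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
    angle = np.deg2rad(rng.uniform(0.0, max_angle_deg))
    k = axis
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def make_decoys(native: Structure, spec: DecoySpec) -> list[Structure]:
    """Rigid perturbations of a native pose, standing in for docked decoys.

    Each decoy rotates the native pose about its centroid (axis uniform
    on the sphere, angle ≤ ``max_rotation``) and translates it by a
    vector of magnitude ≤ ``max_translation``.  With
    ``include_native=True`` the first pose is the unperturbed native.
    """
    if len(native) == 0:
        raise ValueError("native pose must be non-empty")
    rng = np.random.default_rng(spec.seed)
    centroid = native.centroid()
    coords = native.coords
    decoys: list[Structure] = []
    n_perturbed = spec.n_decoys - (1 if spec.include_native else 0)
    if spec.include_native:
        decoys.append(native.with_coords(coords.copy(), label="pose_01_native"))
    for d in range(n_perturbed):
        R = _random_rotation_matrix(rng, spec.max_rotation)
        direction = rng.normal(size=3)
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
        shift = rng.uniform(0.0, spec.max_translation) * direction
        new_coords = (coords - centroid) @ R.T + centroid + shift
        decoys.append(
            native.with_coords(new_coords, label=f"pose_{len(decoys) + 1:02d}")
        )
    return decoys


def make_screening_table(
    n: int, noise_sigma: float, seed: int = 0
) -> list[ScreeningRecord]:
    """Synthetic screening set: stratified Ki values plus a noisy score.

    Ki values are log-uniform within each of the four affinity tiers
    (<10 nM, 10 nM–1 µM, 1–100 µM, ≥100 µM), split as evenly as n
    allows; the strongest tier starts at 0.1 nM and the weakest tier is
    capped at the −4 kcal/mol weak-binder cutoff so every generated
    compound would survive the selection filters.  The predicted score
    is the exact RT·ln(Ki) energy plus Gaussian noise of standard
    deviation ``noise_sigma`` (kcal/mol) — the knob that sets how much
    a noiseless scoring function is attenuated.
    """
    if n < 4:
        raise ValueError("need n >= 4 to populate all four tiers")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    rng = np.random.default_rng(seed)
    cutoff_ki = float(np.exp(-4.0 / (GAS_CONSTANT_KCALMOL * 298.15)))
    edges = [1e-10, *KI_TIER_BOUNDS, cutoff_ki]
    per_tier = [n // 4] * 4
    for i in range(n % 4):
        per_tier[i] += 1
    records: list[ScreeningRecord] = []
    idx = 0
    for tier, count in enumerate(per_tier):
        lo, hi = np.log(edges[tier]), np.log(edges[tier + 1])
        for _ in range(count):
            ki = float(np.exp(rng.uniform(lo, hi)))
            energy = ki_to_energy(ki)
            records.append(
                ScreeningRecord(
                    compound_id=f"cmpd_{idx:04d}",
                    Ki=ki,
                    elements=frozenset({"C", "H", "O", "N"}),
                    experimental_energy=energy,
                    predicted_score=energy + rng.normal(0.0, noise_sigma),
                )
            )
            idx += 1
    return records
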