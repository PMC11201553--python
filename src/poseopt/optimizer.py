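"""Conjugate-gradient geometry minimizer with backtracking line search.

The minimizer (CG-BS) drives any :class:`~poseopt.potentials.EnergyModel`
to a local minimum of the potential-energy surface:

* search directions follow Polak–Ribière⁺ conjugate gradients,
  ``d_k = −g_k + β_k d_{k−1}`` with ``β_k = max(0, g_k·(g_k−g_{k−1}) /
  |g_{k−1}|²)``, restarted periodically and whenever a direction fails
  to descend;
* each step length comes from an Armijo backtracking line search
  (sufficient-decrease condition); the curvature (second Wolfe)
  condition is evaluated and recorded as a diagnostic but not enforced,
  since pure backtracking cannot guarantee it;
* frozen atoms never move — their gradient components are masked out of
  every direction, so their coordinates are bit-identical on exit;
* convergence uses the four quantum-chemistry–convention criteria
  (maximum force, RMS force, maximum displacement, RMS displacement),
  compared in atomic units with ``≤`` against thresholds of
  0.00045 / 0.0003 Hartree/Bohr and 0.0018 / 0.0012 Bohr.

Machine-learned potential-energy surfaces are less smooth than ab
initio ones; the combination of a short, capped trial step and a pure
backtracking search keeps each accepted step strictly downhill, which
is what makes this scheme robust on such surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .potentials import EnergyModel
from .structures import Structure
from .units import BOHR_TO_ANGSTROM, FORCE_AU_TO_KCALMOL_PER_A

__all__ = [
    "ConvergenceCriteria",
    "OptimizerConfig",
    "OptimizationResult",
    "LineSearchResult",
    "LineSearchFailure",
    "AscentDirectionError",
    "cgbs_minimize",
    "backtracking_search",
    "check_convergence",
]


@dataclass(frozen=True)
class ConvergenceCriteria:
    """Convergence thresholds in atomic units (Hartree/Bohr and Bohr)."""

    max_force: float = 0.00045
    rms_force: float = 0.0003
    max_displacement: float = 0.0018
    rms_displacement: float = 0.0012

    def __post_init__(self):
        for name in ("max_force", "rms_force", "max_displacement", "rms_displacement"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class OptimizerConfig:
    """Tunable optimizer parameters.

    ``initial_step`` is a geometric scale: the first trial step of each
    line search is chosen so the largest single-atom displacement is at
    most this many Å.  Subsequent line searches start from twice the
    last accepted step length, capped back at that geometric scale.
    ``restart_interval = None`` restarts conjugacy every 3·N_free
    coordinates.
    """

    armijo_c1: float = 1e-4
    curvature_c2: float = 0.9
    backtrack_factor: float = 0.5
    initial_step: float = 0.05  # Å, max per-atom displacement of first trial
    max_line_search_trials: int = 20
    restart_interval: int | None = None
    max_iterations: int = 5000

    def __post_init__(self):
        if not (0.0 < self.armijo_c1 < self.curvature_c2 < 1.0):
            raise ValueError("require 0 < c1 < c2 < 1")
        if not (0.0 < self.backtrack_factor < 1.0):
            raise ValueError("backtrack_factor must lie in (0, 1)")
        if self.initial_step <= 0 or self.max_line_search_trials < 1 or self.max_iterations < 1:
            raise ValueError("step/trial/iteration parameters must be positive")


@dataclass
class OptimizationResult:
    """Outcome of a CG-BS minimization."""

    final_coords: np.ndarray
    final_energy: float
    n_iterations: int
    converged: bool
    criteria_status: tuple[bool, bool, bool, bool]
    energy_trace: list[float] = field(default_factory=list)

    def summary(self) -> str:
        names = ("max force", "RMS force", "max displacement", "RMS displacement")
        lines = [
            f"CG-BS: {'converged' if self.converged else 'NOT converged'} "
            f"in {self.n_iterations} iterations",
            f"final energy: {self.final_energy:.6f} kcal/mol",
        ]
        for name, ok in zip(names, self.criteria_status):
            lines.append(f"  {name:<18s} {'YES' if ok else 'no'}")
        return "\n".join(lines)


@dataclass
class LineSearchResult:
    step_length: float
    new_coords: np.ndarray
    new_energy: float
    new_forces: np.ndarray
    curvature_satisfied: bool
    n_trials: int


class LineSearchFailure(RuntimeError):
    """Armijo condition not met within the trial budget."""


class AscentDirectionError(ValueError):
    """The supplied direction is not a descent direction."""


def check_convergence(
    forces: np.ndarray,
    displacement: np.ndarray | None,
    criteria: ConvergenceCriteria = ConvergenceCriteria(),
) -> tuple[bool, bool, bool, bool]:
    """Evaluate the four convergence criteria on the free atoms.

    ``forces`` (kcal/mol/Å) and ``displacement`` (Å, last accepted step)
    are arrays over free atoms only.  Both are converted to atomic units
    and the maximum and RMS of the per-atom vector norms are compared
    against the thresholds with ``≤``.  ``displacement=None`` (no step
    taken yet) leaves both displacement criteria unsatisfied.
    """
    forces = np.asarray(forces, dtype=float).reshape(-1, 3)
    if forces.size == 0:
        raise ValueError("convergence check requires at least one free atom")
    f_au = np.linalg.norm(forces, axis=1) / FORCE_AU_TO_KCALMOL_PER_A
    max_f_ok = bool(f_au.max() <= criteria.max_force)
    rms_f_ok = bool(np.sqrt(np.mean(f_au**2)) <= criteria.rms_force)
    if displacement is None:
        return (max_f_ok, rms_f_ok, False, False)
    disp = np.asarray(displacement, dtype=float).reshape(-1, 3)
    d_au = np.linalg.norm(disp, axis=1) / BOHR_TO_ANGSTROM
    max_d_ok = bool(d_au.max() <= criteria.max_displacement)
    rms_d_ok = bool(np.sqrt(np.mean(d_au**2)) <= criteria.rms_displacement)
    return (max_f_ok, rms_f_ok, max_d_ok, rms_d_ok)


def backtracking_search(
    model: EnergyModel,
    coords: np.ndarray,
    direction: np.ndarray,
    g0: np.ndarray,
    E0: float,
    config: OptimizerConfig = OptimizerConfig(),
    alpha0: float | None = None,
) -> LineSearchResult:
    """Armijo backtracking line search along ``direction``.

    Tries α ∈ {α₀, α₀ρ, α₀ρ², …} and accepts the first trial with
    ``E(x + αd) ≤ E0 + c1 α (g0·d)``.  The curvature condition
    ``g(x+αd)·d ≥ c2 g0·d`` is evaluated at the accepted point for
    diagnostics.  Raises :class:`AscentDirectionError` when ``g0·d ≥ 0``
    and :class:`LineSearchFailure` when no trial satisfies Armijo.
    """
    coords = np.asarray(coords, dtype=float)
    direction = np.asarray(direction, dtype=float)
    g0 = np.asarray(g0, dtype=float)
    slope = float(np.sum(g0 * direction))
    if slope >= 0.0:
        raise AscentDirectionError(f"g0·d = {slope:.3e} is not a descent direction")
    if alpha0 is None:
        max_disp = float(np.linalg.norm(direction.reshape(-1, 3), axis=1).max())
        if max_disp == 0.0:
            raise AscentDirectionError("zero direction")
        alpha0 = config.initial_step / max_disp
    alpha = float(alpha0)
    for trial in range(1, config.max_line_search_trials + 1):
        new_coords = coords + alpha * direction
        new_energy, new_forces = model.evaluate(new_coords)
        if not np.isfinite(new_energy):
            alpha *= config.backtrack_factor
            continue
        if new_energy <= E0 + config.armijo_c1 * alpha * slope:
            new_slope = float(np.sum(-new_forces * direction))
            curvature_ok = new_slope >= config.curvature_c2 * slope
            return LineSearchResult(alpha, new_coords, new_energy, new_forces, curvature_ok, trial)
        alpha *= config.backtrack_factor
    raise LineSearchFailure(
        f"Armijo condition not satisfied within {config.max_line_search_trials} trials"
    )


def _resolve_inputs(start, frozen_mask, n_atoms):
    if frozen_mask is None:
        frozen_mask = np.zeros(n_atoms, dtype=bool)
    frozen_mask = np.asarray(frozen_mask, dtype=bool)
    if len(frozen_mask) != n_atoms:
        raise ValueError(f"frozen mask length {len(frozen_mask)} != atom count {n_atoms}")
    return frozen_mask


def cgbs_minimize(
    model: EnergyModel,
    start: Structure | np.ndarray,
    frozen_mask: Sequence[bool] | np.ndarray | None = None,
    criteria: ConvergenceCriteria = ConvergenceCriteria(),
    config: OptimizerConfig = OptimizerConfig(),
) -> OptimizationResult:
    """Minimize ``model`` from ``start`` with CG-BS.

    ``start`` is a Structure or an (N, 3) coordinate array in Å.  When a
    Structure is given and ``frozen_mask`` is None, atoms flagged frozen
    (restraint weight −1) supply the mask.  Accepted-step energies are
    monotonically non-increasing; frozen coordinates are returned
    bit-identical to the input.
    """
    if isinstance(start, Structure):
        coords = start.coords
        if frozen_mask is None and np.any(start.frozen_mask):
            frozen_mask = start.frozen_mask
    else:
        coords = np.array(start, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
        raise ValueError("start coordinates must be a non-empty (N, 3) array")
    n = coords.shape[0]
    frozen_mask = _resolve_inputs(start, frozen_mask, n)
    free = ~frozen_mask
    if not np.any(free):
        raise ValueError("no free atoms: every atom is frozen")
    if isinstance(start, Structure):
        model.check_elements(start.elements)

    # default restart period: one sweep of the free coordinate count
    restart_every = config.restart_interval or max(1, 3 * int(free.sum()))

    energy, forces = model.evaluate(coords)
    if not np.isfinite(energy):
        raise ValueError("non-finite energy at the starting geometry")
    grad = -forces
    grad[frozen_mask] = 0.0
    trace = [float(energy)]

    # Degenerate start: exactly zero gradient on the free atoms.
    if float(np.linalg.norm(grad)) == 0.0:
        return OptimizationResult(coords, float(energy), 0, True, (True, True, True, True), trace)

    direction = -grad
    last_alpha: float | None = None
    since_restart = 0
    consecutive_failures = 0
    status = (False, False, False, False)

    for iteration in range(1, config.max_iterations + 1):
        if float(np.sum(grad * direction)) >= 0.0:
            direction = -grad
            since_restart = 0
        max_disp = float(np.linalg.norm(direction.reshape(-1, 3), axis=1).max())
        if max_disp == 0.0:
            # gradient vanished on free atoms mid-run
            status = check_convergence(forces[free], np.zeros((int(free.sum()), 3)), criteria)
            return OptimizationResult(
                coords, float(energy), iteration - 1, all(status), status, trace
            )
        alpha_cap = config.initial_step / max_disp
        alpha0 = alpha_cap if last_alpha is None else min(2.0 * last_alpha, alpha_cap)
        try:
            ls = backtracking_search(model, coords, direction, grad, energy, config, alpha0)
            consecutive_failures = 0
        except LineSearchFailure:
            consecutive_failures += 1
            if consecutive_failures >= 2:
                return OptimizationResult(
                    coords, float(energy), iteration, False, status, trace
                )
            direction = -grad
            last_alpha = None
            # retry from steepest descent with a reduced initial step
            try:
                ls = backtracking_search(
                    model, coords, direction, grad, energy, config,
                    config.backtrack_factor * config.initial_step / max(
                        float(np.linalg.norm(direction.reshape(-1, 3), axis=1).max()), 1e-300
                    ),
                )
                consecutive_failures = 0
            except LineSearchFailure:
                return OptimizationResult(
                    coords, float(energy), iteration, False, status, trace
                )

        displacement = ls.new_coords - coords
        frozen_snapshot = coords[frozen_mask]
        coords = ls.new_coords
        coords[frozen_mask] = frozen_snapshot  # bit-identical frozen coordinates
        new_energy, new_forces = ls.new_energy, ls.new_forces
        if not np.isfinite(new_energy):
            raise ValueError("non-finite energy during optimization")
        new_grad = -new_forces
        new_grad[frozen_mask] = 0.0
        trace.append(float(new_energy))
        last_alpha = ls.step_length

        status = check_convergence(new_forces[free], displacement[free], criteria)
        if all(status):
            return OptimizationResult(coords, float(new_energy), iteration, True, status, trace)

        since_restart += 1
        denom = float(np.sum(grad * grad))
        beta = max(0.0, float(np.sum(new_grad * (new_grad - grad))) / denom) if denom > 0 else 0.0
        if since_restart >= restart_every:
            beta = 0.0
            since_restart = 0
        direction = -new_grad + beta * direction
        direction[frozen_mask] = 0.0
        grad = new_grad
        energy = new_energy
        forces = new_forces

    return OptimizationResult(
        coords, float(energy), config.max_iterations, False, status, trace
    )
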