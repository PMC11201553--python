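"""Docking-, scoring- and ranking-power evaluation metrics.

* **Docking power** — receptor-anchored ligand RMSD: the superposition
  is computed on receptor atoms only and that transform is applied to
  the ligand, so translation/rotation of the ligand inside the pocket
  contributes fully to the value.  Per-system Top-1/3/5/10 minima,
  first-success category, success rates and category histograms follow.
* **Scoring power** — Pearson's R between predicted scores and
  experimental affinities.
* **Ranking power** — Spearman's ρ (Pearson on fractional ranks).
* **Affinity handling** — Ki→ΔG conversion (ΔG = RT ln Ki, 1 M
  reference state) and the compound-selection filters: allowed-element
  screen, weak-binder cutoff, and capped sampling from four Ki tiers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.transform import Rotation

from .structures import Structure
from .units import GAS_CONSTANT_KCALMOL

__all__ = [
    "TopCategorySummary",
    "ScreeningRecord",
    "receptor_anchored_rmsd",
    "top_category_minima",
    "first_success_category",
    "success_rate",
    "SuccessRate",
    "category_occurrence_counts",
    "pearson",
    "spearman",
    "ki_to_energy",
    "select_compounds",
    "KI_TIER_BOUNDS",
    "ALLOWED_ELEMENTS",
]

CATEGORIES = (1, 3, 5, 10)

#: Ki tier edges in molar: (<10 nM, 10 nM–1 µM, 1–100 µM, ≥100 µM)
KI_TIER_BOUNDS = (1e-8, 1e-6, 1e-4)

#: element domain of the screening sets (what the ML potential covers)
ALLOWED_ELEMENTS = frozenset({"C", "H", "O", "N", "S", "F", "Cl"})


# ---------------------------------------------------------------------------
# Receptor-anchored RMSD
# ---------------------------------------------------------------------------

def receptor_anchored_rmsd(
    reference_complex: Structure,
    predicted_complex: Structure,
    ligand_selection: Sequence[int] | np.ndarray,
) -> float:
    """Ligand RMSD after superposing the receptors only.

    ``ligand_selection`` indexes ligand atoms inside both complexes
    (matched atom order); the remaining atoms are the receptor.  The
    least-squares rigid transform (Kabsch) fitted on receptor atoms is
    applied to the predicted ligand, and the RMSD is computed over
    ligand heavy atoms with no further fitting — so a ligand sliding in
    a fixed pocket shows up at full magnitude.
    """
    if len(reference_complex) != len(predicted_complex):
        raise ValueError("reference and predicted complexes differ in atom count")
    n = len(reference_complex)
    lig_idx = np.asarray(sorted(int(i) for i in ligand_selection), dtype=int)
    if lig_idx.size == 0 or lig_idx.min() < 0 or lig_idx.max() >= n:
        raise ValueError("invalid ligand selection")
    rec_mask = np.ones(n, dtype=bool)
    rec_mask[lig_idx] = False
    if rec_mask.sum() < 3:
        raise ValueError("receptor anchoring requires at least 3 receptor atoms")

    ref = reference_complex.coords
    pred = predicted_complex.coords
    ref_rec, pred_rec = ref[rec_mask], pred[rec_mask]
    c_ref = ref_rec.mean(axis=0)
    c_pred = pred_rec.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_rec - c_ref, pred_rec - c_pred)

    heavy = [
        i for i in lig_idx if predicted_complex.atoms[i].element != "H"
    ]
    if not heavy:
        raise ValueError("ligand selection contains no heavy atoms")
    pred_lig = rot.apply(pred[heavy] - c_pred) + c_ref
    diff = pred_lig - ref[heavy]
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


# ---------------------------------------------------------------------------
# Top-N category analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TopCategorySummary:
    """Lowest RMSD within Top 1/3/5/10 and the first category reaching it."""

    minima: tuple[float, float, float, float]
    first_category: int
    success: bool

    def __post_init__(self):
        if any(b > a + 1e-12 for a, b in zip(self.minima, self.minima[1:])):
            raise ValueError("category minima must be non-increasing")


def top_category_minima(ranked_rmsds: Sequence[float]) -> TopCategorySummary:
    """Summarize a rank-ordered RMSD list (rank 1 first) into Top-N minima.

    Expects up to 10 values; with fewer, categories are capped at the
    available count (the Top-10 minimum then covers all poses given).
    """
    values = [float(v) for v in ranked_rmsds]
    if not values:
        raise ValueError("ranked_rmsds must be non-empty")
    if len(values) > 10:
        raise ValueError("at most 10 ranked poses are evaluated")
    minima = tuple(min(values[: min(nc, len(values))]) for nc in CATEGORIES)
    category, success = first_success_category(minima)
    return TopCategorySummary(minima=minima, first_category=category, success=success)


def first_success_category(
    minima: Sequence[float], tolerance: float = 1e-9
) -> tuple[int, bool]:
    """Smallest category whose minimum already equals the Top-10 minimum.

    Success means the overall best pose appears within the top three
    ranks (category ≤ 3).
    """
    m = [float(v) for v in minima]
    if len(m) != 4:
        raise ValueError("expected four category minima (Top 1/3/5/10)")
    if any(b > a + tolerance for a, b in zip(m, m[1:])):
        raise ValueError("category minima must be non-increasing")
    best = m[-1]
    for cat, v in zip(CATEGORIES, m):
        if abs(v - best) <= tolerance:
            return cat, cat <= 3
    return 10, False


class SuccessRate(NamedTuple):
    rounded: int
    exact: float


def success_rate(summaries: Sequence[TopCategorySummary]) -> SuccessRate:
    """Percentage of systems whose best pose sits within the top three ranks."""
    if not summaries:
        raise ValueError("success_rate requires at least one summary")
    exact = 100.0 * sum(s.success for s in summaries) / len(summaries)
    return SuccessRate(rounded=int(round(exact)), exact=exact)


def category_occurrence_counts(
    summaries: Sequence[TopCategorySummary],
) -> dict[int, int]:
    """Histogram of the first-success category over systems."""
    counts = {c: 0 for c in CATEGORIES}
    for s in summaries:
        counts[s.first_category] += 1
    return counts


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def _check_xy(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} observations")
    return x, y


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient R ∈ [−1, 1]."""
    x, y = _check_xy(x, y)
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("pearson undefined for a zero-variance variable")
    return float(stats.pearsonr(x, y).statistic)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Rank correlation ρ: Pearson on fractional (average) ranks."""
    x, y = _check_xy(x, y)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("spearman undefined for an all-tied variable")
    return float(stats.spearmanr(x, y).statistic)


# ---------------------------------------------------------------------------
# Affinity conversion and compound selection
# ---------------------------------------------------------------------------

def ki_to_energy(Ki: float, T: float = 298.15) -> float:
    """ΔG = RT ln(Ki) in kcal/mol, Ki in molar (1 M reference state)."""
    if Ki <= 0:
        raise ValueError("Ki must be positive")
    return GAS_CONSTANT_KCALMOL * T * math.log(Ki)


@dataclass(frozen=True)
class ScreeningRecord:
    """One screened compound: identity, affinity and prediction."""

    compound_id: str
    Ki: float  # molar (Kd accepted interchangeably)
    elements: frozenset
    experimental_energy: float  # kcal/mol
    predicted_score: float

    def __post_init__(self):
        if self.Ki <= 0:
            raise ValueError("Ki must be positive")
        object.__setattr__(self, "elements", frozenset(self.elements))


def ki_tier(Ki: float) -> int:
    """Tier index 1–4: <10 nM, 10 nM–1 µM, 1–100 µM, ≥100 µM."""
    if Ki <= 0:
        raise ValueError("Ki must be positive")
    for tier, bound in enumerate(KI_TIER_BOUNDS, start=1):
        if Ki < bound:
            return tier
    return 4


def select_compounds(
    records: Sequence[ScreeningRecord],
    per_tier_cap: int = 300,
    energy_cutoff: float = -4.0,
    allowed_elements: frozenset = ALLOWED_ELEMENTS,
    seed: int | None = None,
) -> list[ScreeningRecord]:
    """Apply the screening-set filters and per-tier caps.

    Drops compounds containing elements outside ``allowed_elements``
    and compounds weaker than the ``energy_cutoff`` (ΔG above the
    cutoff).  Survivors are stratified into the four Ki tiers; when a
    tier exceeds ``per_tier_cap``, a seeded uniform subsample is kept.
    Output preserves the input order.
    """
    allowed = frozenset(allowed_elements)
    eligible = [
        (i, r)
        for i, r in enumerate(records)
        if r.elements <= allowed and ki_to_energy(r.Ki) <= energy_cutoff
    ]
    rng = np.random.default_rng(seed)
    tiers: dict[int, list[int]] = {1: [], 2: [], 3: [], 4: []}
    for pos, (i, r) in enumerate(eligible):
        tiers[ki_tier(r.Ki)].append(pos)
    keep = set()
    for tier_positions in tiers.values():
        if len(tier_positions) <= per_tier_cap:
            keep.update(tier_positions)
        else:
            chosen = rng.choice(len(tier_positions), size=per_tier_cap, replace=False)
            keep.update(tier_positions[j] for j in chosen)
    return [eligible[pos][1] for pos in sorted(keep)]
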