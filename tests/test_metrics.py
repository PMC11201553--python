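import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poseopt.metrics import (
    ScreeningRecord,
    category_occurrence_counts,
    first_success_category,
    ki_tier,
    ki_to_energy,
    pearson,
    receptor_anchored_rmsd,
    select_compounds,
    spearman,
    success_rate,
    top_category_minima,
)
from poseopt.structures import Atom, Structure
from poseopt.units import GAS_CONSTANT_KCALMOL


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / math.sqrt(np.sum(xm**2) * np.sum(ym**2)))


def fractional_ranks(v):
    v = np.asarray(v, float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    return pearson_oracle(fractional_ranks(x), fractional_ranks(y))


def complex_of(coords, n_ligand):
    n = len(coords)
    atoms = []
    for i, c in enumerate(coords):
        if i < n - n_ligand:
            atoms.append(Atom("C", c, "REC", i + 1, "R", "C"))
        else:
            atoms.append(Atom("C", c, "LIG", 1, "L", "C"))
    return Structure(atoms)


def rigid_transform(coords, seed):
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0, np.pi)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    t = rng.uniform(-10, 10, 3)
    return coords @ R.T + t


class TestReceptorAnchoredRmsd:
    def setup_method(self):
        rng = np.random.default_rng(1)
        self.coords = rng.uniform(-8, 8, (12, 3))
        self.lig_idx = list(range(8, 12))
        self.ref = complex_of(self.coords, 4)

    def test_identical_complexes_give_zero(self):
        assert receptor_anchored_rmsd(self.ref, self.ref, self.lig_idx) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_joint_rigid_transform_removed(self, seed):
        moved = complex_of(rigid_transform(self.coords, seed), 4)
        assert receptor_anchored_rmsd(self.ref, moved, self.lig_idx) == pytest.approx(
            0.0, abs=1e-8
        )

    def test_ligand_translation_retained_in_full(self):
        shifted = self.coords.copy()
        shifted[8:] += np.array([1.0, 0.0, 0.0])
        moved = complex_of(shifted, 4)
        assert receptor_anchored_rmsd(self.ref, moved, self.lig_idx) == pytest.approx(
            1.0, abs=1e-8
        )

    def test_ligand_translation_survives_joint_transform(self):
        shifted = self.coords.copy()
        shifted[8:] += np.array([0.0, 2.5, 0.0])
        moved = complex_of(rigid_transform(shifted, 5), 4)
        assert receptor_anchored_rmsd(self.ref, moved, self.lig_idx) == pytest.approx(
            2.5, abs=1e-8
        )

    def test_hydrogens_excluded_from_ligand_rmsd(self):
        atoms = list(self.ref.atoms)
        atoms[11] = Atom("H", self.coords[11], "LIG", 1, "L", "H")
        ref_h = Structure(atoms)
        shifted = self.coords.copy()
        shifted[11] += 100.0  # only the hydrogen moves
        pred = Structure(
            atoms[:11] + [Atom("H", shifted[11], "LIG", 1, "L", "H")]
        )
        assert receptor_anchored_rmsd(ref_h, pred, self.lig_idx) == pytest.approx(0.0, abs=1e-8)

    def test_atom_count_mismatch(self):
        with pytest.raises(ValueError):
            receptor_anchored_rmsd(self.ref, complex_of(self.coords[:-1], 3), [8])

    def test_too_few_receptor_atoms(self):
        small = complex_of(self.coords[:4], 2)
        with pytest.raises(ValueError):
            receptor_anchored_rmsd(small, small, [2, 3])


class TestTopCategories:
    def test_worked_example(self):
        s = top_category_minima([3, 2, 1, 4, 4, 4, 4, 4, 4, 4])
        assert s.minima == (3, 1, 1, 1)
        assert s.first_category == 3
        assert s.success

    def test_strictly_decreasing_sequence_fails(self):
        s = top_category_minima(list(np.linspace(10, 1, 10)))
        assert s.first_category == 10
        assert not s.success

    def test_constant_sequence_is_top1(self):
        s = top_category_minima([2.0] * 10)
        assert s.minima == (2.0, 2.0, 2.0, 2.0)
        assert s.first_category == 1

    def test_short_pose_lists_are_capped(self):
        s = top_category_minima([3.0, 1.0])
        assert s.minima == (3.0, 1.0, 1.0, 1.0)

    @pytest.mark.parametrize(
        "minima,category,success",
        [
            ((2.96, 0.92, 0.92, 0.92), 3, True),
            ((0.47, 0.47, 0.47, 0.47), 1, True),
            ((8.55, 8.27, 1.47, 1.07), 10, False),
        ],
    )
    def test_first_success_category_on_published_rows(self, minima, category, success):
        cat, ok = first_success_category(minima)
        assert cat == category
        assert ok is success

    def test_increasing_minima_rejected(self):
        with pytest.raises(ValueError):
            first_success_category((1.0, 2.0, 2.0, 2.0))

    def test_success_rate_single_system(self):
        s = top_category_minima([1.0] * 10)
        assert success_rate([s]).rounded == 100

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.integers(0, 3), min_size=1, max_size=30),
           st.lists(st.integers(0, 3), min_size=1, max_size=30))
    def test_success_rate_of_concatenation_is_weighted_mean(self, a, b):
        cats = [1, 3, 5, 10]
        mk = lambda lst: [
            top_category_minima([0.5] * cats[i] + [5.0] * (10 - cats[i])) for i in lst
        ]
        sa, sb = mk(a), mk(b)
        combined = success_rate(sa + sb).exact
        weighted = (success_rate(sa).exact * len(sa) + success_rate(sb).exact * len(sb)) / (
            len(sa) + len(sb)
        )
        assert combined == pytest.approx(weighted, abs=1e-9)

    def test_category_counts_sum_to_n(self):
        summaries = [
            top_category_minima(list(np.random.default_rng(i).uniform(1, 9, 10)))
            for i in range(20)
        ]
        counts = category_occurrence_counts(summaries)
        assert sum(counts.values()) == 20


class TestCorrelations:
    def test_perfect_linear(self):
        x = np.arange(1.0, 9.0)
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_pearson_matches_bruteforce_oracle(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 5.0]
        assert pearson(x, y) == pytest.approx(pearson_oracle(x, y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_both_match_oracles_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=40)
        y = rng.normal(size=40) + 0.5 * x
        assert pearson(x, y) == pytest.approx(pearson_oracle(x, y), abs=1e-12)
        assert spearman(x, y) == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_spearman_with_ties_matches_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        y = [3.0, 1.0, 4.0, 4.0, 2.0, 5.0]
        assert spearman(x, y) == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_spearman_monotone_ymap_gives_one(self):
        x = np.array([0.3, 1.2, 2.7, 5.5, 9.1])
        assert spearman(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman(x, -np.sqrt(x)) == pytest.approx(-1.0)

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.integers(-5000, 5000), min_size=4, max_size=25, unique=True))
    def test_spearman_invariant_under_monotone_transform(self, ints):
        x = [v / 100.0 for v in ints]
        rng = np.random.default_rng(len(x))
        y = list(rng.normal(size=len(x)))
        base = spearman(x, y)
        transformed = spearman([math.exp(v / 25.0) for v in x], y)
        assert transformed == pytest.approx(base, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            spearman([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [1.0, 2.0])


class TestAffinityConversion:
    def test_reference_state(self):
        assert ki_to_energy(1.0) == 0.0

    def test_one_nanomolar(self):
        assert ki_to_energy(1e-9) == pytest.approx(-12.28, abs=0.01)

    def test_cutoff_inverse(self):
        ki_at_cutoff = math.exp(-4.0 / (GAS_CONSTANT_KCALMOL * 298.15))
        assert ki_at_cutoff == pytest.approx(1.17e-3, rel=0.01)
        assert ki_to_energy(ki_at_cutoff) == pytest.approx(-4.0, abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ki_to_energy(0.0)


def record(ki, elements=("C", "H", "O", "N"), cid="c"):
    return ScreeningRecord(cid, ki, frozenset(elements), ki_to_energy(ki), ki_to_energy(ki))


class TestCompoundSelection:
    def test_disallowed_element_excluded(self):
        out = select_compounds([record(1e-9, ("C", "H", "Br"))])
        assert out == []

    def test_weak_binder_excluded(self):
        ki_weak = math.exp(-3.5 / (GAS_CONSTANT_KCALMOL * 298.15))  # ΔG = −3.5
        assert select_compounds([record(ki_weak)]) == []

    @pytest.mark.parametrize(
        "ki,tier", [(5e-9, 1), (5e-7, 2), (5e-5, 3), (5e-4, 4), (1e-8, 2), (1e-6, 3)]
    )
    def test_tier_boundaries(self, ki, tier):
        assert ki_tier(ki) == tier

    def test_per_tier_cap_with_seeded_subsample(self):
        records = [record(10 ** np.random.default_rng(i).uniform(-9.5, -8.5), cid=f"c{i}")
                   for i in range(40)]
        out1 = select_compounds(records, per_tier_cap=10, seed=0)
        out2 = select_compounds(records, per_tier_cap=10, seed=0)
        out3 = select_compounds(records, per_tier_cap=10, seed=1)
        assert len(out1) == 10
        assert [r.compound_id for r in out1] == [r.compound_id for r in out2]
        assert [r.compound_id for r in out1] != [r.compound_id for r in out3]

    def test_output_preserves_input_order(self):
        records = [record(1e-9, cid="a"), record(2e-9, cid="b"), record(5e-7, cid="c")]
        out = select_compounds(records)
        assert [r.compound_id for r in out] == ["a", "b", "c"]
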