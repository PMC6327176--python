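"""Energy tables, symmetry folding, DEE pruning, and exact GMEC search."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from symprop import (CnSymmetry, DesignPosition, EnergyTables,
                     build_energy_tables, brute_force_gmec, dee_prune,
                     fold_symmetric_tables, make_random_design_problem,
                     make_symmetric_design_problem, score_assignment,
                     solve_gmec)
from symprop.design import (ROTAMER_LIBRARY, _SIDECHAIN, EnergyModelConfig,
                            _pair_atom_energy, build_rotamer_choices)


def tiny_tables(e1, e2=None):
    return EnergyTables(n_choices=[len(v) for v in e1],
                        e1=[np.array(v, dtype=float) for v in e1],
                        e2=e2 or {})


# ---------------------------------------------------------------------------
# energy tables
# ---------------------------------------------------------------------------

def test_pair_energy_symmetric_and_cutoff():
    positions = [DesignPosition(0, 1, allowed=("S", "V")),
                 DesignPosition(1, 2, allowed=("A", "T"))]
    anchors = [np.zeros(3), np.array([6.0, 0.0, 0.0])]
    backbone = [np.array([[0.0, 0, 3.8], [6.0, 0, 3.8], [3.0, 3.0, 3.8],
                          [3.0, -3.0, 3.8]])]
    tables = build_energy_tables(backbone, positions, anchors)
    for (i, j), entries in tables.e2.items():
        for (ci, cj), e in entries.items():
            assert tables.pair_energy(j, cj, i, ci) == pytest.approx(e)
    # far-apart positions produce no pair table
    far = build_energy_tables(backbone, positions,
                              [np.zeros(3), np.array([100.0, 0.0, 0.0])])
    assert not far.e2


def test_total_energy_matches_all_pairs_oracle():
    """Sum E1 + sum E2 of a full assignment equals a direct evaluation
    over every pseudo-atom pair plus backbone interactions."""
    cfg = EnergyModelConfig()
    positions = [DesignPosition(i, i + 1, allowed=("S", "V", "K"))
                 for i in range(3)]
    anchors = [np.array([0.0, 0, 0]), np.array([5.0, 0, 0]),
               np.array([2.5, 4.0, 0])]
    backbone = [np.array([[1.0, 1.0, 3.0], [4.0, -1.0, 3.0]])]
    tables = build_energy_tables(backbone, positions, anchors, None, cfg)
    assignment = (0, 2, 1)
    total = score_assignment(tables, assignment)

    # independent re-summation over pseudo-atoms
    def placed_atoms(i, c):
        ch = tables.choices[i][c]
        return [(lab, (p[0] + anchors[i][0], p[1] + anchors[i][1],
                       p[2] + anchors[i][2]), r, q)
                for lab, p, r, q in ch.pseudo_atoms]

    expected = 0.0
    for i, c in enumerate(assignment):
        ident = tables.choices[i][c].identity
        expected += _SIDECHAIN[ident][4] * cfg.reference_weight
        for atom in placed_atoms(i, c):
            for bpos in backbone[0]:
                expected += _pair_atom_energy(
                    atom, ("BB", tuple(bpos), 1.9, 0.0), cfg)
    for i in range(3):
        for j in range(i + 1, 3):
            for a in placed_atoms(i, assignment[i]):
                for b in placed_atoms(j, assignment[j]):
                    expected += _pair_atom_energy(a, b, cfg)
    assert total == pytest.approx(expected, abs=1e-9)


def test_fixed_position_restricts_choices():
    pos = DesignPosition(0, 11, fixed="H")
    assert pos.allowed == ("H",)
    assert {c.identity for c in build_rotamer_choices(pos)} == {"H"}


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def test_score_zero_tables():
    t = tiny_tables([[0.0, 0.0], [0.0]])
    assert score_assignment(t, (0, 0)) == 0.0


def test_score_single_position():
    t = tiny_tables([[-2.0, 1.0]])
    assert score_assignment(t, (0,)) == -2.0


def test_score_matches_resummation_oracle(rng):
    t = make_random_design_problem(5, 3, pair_density=0.8, seed=42)
    assignment = tuple(rng.integers(0, 3, size=5))
    expected = sum(t.e1[i][c] for i, c in enumerate(assignment))
    for (i, j), entries in t.e2.items():
        expected += entries.get((assignment[i], assignment[j]), 0.0)
    assert score_assignment(t, assignment) == pytest.approx(expected,
                                                            abs=1e-12)


def test_score_rejects_disallowed_choice():
    t = tiny_tables([[0.0, 1.0]])
    with pytest.raises(ValueError):
        score_assignment(t, (5,))


@given(shift=st.floats(-10, 10))
def test_constant_shift_moves_energy_not_argmin(shift):
    t = make_random_design_problem(4, 3, pair_density=0.5, seed=9)
    base = solve_gmec(t)
    shifted = EnergyTables(n_choices=t.n_choices,
                           e1=[t.e1[0] + shift] + [np.array(v)
                                                   for v in t.e1[1:]],
                           e2=t.e2)
    res = solve_gmec(shifted)
    assert res.assignment == base.assignment
    assert res.energy == pytest.approx(base.energy + shift, abs=1e-9)


# ---------------------------------------------------------------------------
# DEE
# ---------------------------------------------------------------------------

def test_dee_prunes_dominated_single():
    t = tiny_tables([[0.0, 5.0]])
    alive, pruned = dee_prune(t)
    assert alive == [[0]]
    assert pruned == 1


def test_dee_idempotent():
    t = make_random_design_problem(5, 4, pair_density=0.5, seed=3)
    alive1, n1 = dee_prune(t)
    alive2, n2 = dee_prune(t)
    assert alive1 == alive2 and n1 == n2


@pytest.mark.parametrize("seed", range(30))
def test_dee_never_prunes_the_gmec(seed):
    rng = np.random.default_rng(seed)
    n_pos = int(rng.integers(2, 6))
    n_cho = int(rng.integers(2, 5))
    t = make_random_design_problem(n_pos, n_cho,
                                   pair_density=float(rng.uniform(0, 1)),
                                   seed=seed + 1000)
    oracle = brute_force_gmec(t)
    alive, _ = dee_prune(t)
    for i, c in enumerate(oracle.assignment):
        assert c in alive[i]


# ---------------------------------------------------------------------------
# exact search
# ---------------------------------------------------------------------------

def test_single_position_argmin():
    t = tiny_tables([[3.0, -1.0, 2.0]])
    res = solve_gmec(t)
    assert res.assignment == (1,)
    assert res.energy == -1.0
    assert res.optimal


def test_brute_force_coupled_pair():
    # E2 favours the mixed assignment despite E1 preferring (0, 0)
    t = tiny_tables([[0.0, 0.1], [0.0, 0.1]],
                    {(0, 1): {(0, 0): 5.0, (0, 1): -3.0,
                              (1, 0): -3.0, (1, 1): 5.0}})
    res = brute_force_gmec(t)
    assert res.assignment == (0, 1)
    assert res.energy == pytest.approx(-2.9)


def test_brute_force_cap():
    t = tiny_tables([[0.0] * 10] * 7)
    with pytest.raises(ValueError):
        brute_force_gmec(t, cap=10 ** 6)


@pytest.mark.parametrize("seed", range(60))
def test_solver_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n_pos = int(rng.integers(2, 7))
    n_cho = int(rng.integers(2, 6))
    t = make_random_design_problem(n_pos, n_cho,
                                   pair_density=float(rng.uniform(0, 1)),
                                   seed=seed)
    exact = solve_gmec(t)
    oracle = brute_force_gmec(t)
    assert exact.energy == oracle.energy
    assert exact.assignment == oracle.assignment
    assert exact.optimal


def test_solver_respects_fixed_constraints():
    t = make_random_design_problem(4, 5, pair_density=0.6, seed=11)
    res = solve_gmec(t, fixed={0: 3, 2: 1})
    assert res.assignment[0] == 3 and res.assignment[2] == 1
    # optimal among assignments satisfying the constraint
    best = min(
        (score_assignment(t, (3, a, 1, b)), (3, a, 1, b))
        for a in range(5) for b in range(5))
    assert res.energy == pytest.approx(best[0], abs=1e-12)
    assert res.assignment == best[1]


def test_motif_identities_stay_fixed():
    """His/Ser/Asp/Trp motif positions pinned during design come back
    with exactly those identities in the optimum."""
    positions = [DesignPosition(0, 11, fixed="H"),
                 DesignPosition(1, 27, fixed="S"),
                 DesignPosition(2, 31, fixed="D"),
                 DesignPosition(3, 37, fixed="W"),
                 DesignPosition(4, 2, allowed=("A", "V", "K"))]
    anchors = [np.array([4.0 * k, 0.0, 0.0]) for k in range(5)]
    backbone = [np.array([[2.0, 2.0, 3.0], [10.0, -2.0, 3.0]])]
    tables = build_energy_tables(backbone, positions, anchors)
    res = solve_gmec(tables)
    assert res.identities[:4] == ("H", "S", "D", "W")


# ---------------------------------------------------------------------------
# symmetry folding
# ---------------------------------------------------------------------------

def test_fold_identity_order_one():
    t = make_random_design_problem(3, 3, pair_density=0.7, seed=5)
    folded = fold_symmetric_tables(t, CnSymmetry(order=1))
    for combo in itertools.product(range(3), repeat=3):
        assert score_assignment(folded, combo) == pytest.approx(
            score_assignment(t, combo), abs=1e-12)


def test_fold_c2_hand_computed():
    # one ASU position, two copies: E1 = a per copy, one cross-copy pair e
    a, e = 1.5, -0.7
    t = tiny_tables([[a, 2.0], [a, 2.0]],
                    {(0, 1): {(0, 0): e, (1, 1): 0.3}})
    folded = fold_symmetric_tables(t, CnSymmetry(order=2))
    assert score_assignment(folded, (0,)) == pytest.approx(2 * a + e,
                                                           abs=1e-12)
    assert folded.e_self[0][(0, 0)] == pytest.approx(e)


@pytest.mark.parametrize("order", [2, 4, 8])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_fold_replication_identity_exhaustive(order, seed):
    t = make_symmetric_design_problem(order, 2, 3, seed=seed)
    folded = fold_symmetric_tables(t, CnSymmetry(order=order))
    for combo in itertools.product(range(3), repeat=2):
        full = score_assignment(t, tuple(combo) * order)
        assert score_assignment(folded, combo) == pytest.approx(
            full, abs=1e-9)


def test_fold_rejects_asymmetric_tables():
    t = make_symmetric_design_problem(2, 2, 2, seed=0)
    t.e1[3] = t.e1[3] + 1.0  # break copy symmetry
    with pytest.raises(ValueError, match="not symmetric"):
        fold_symmetric_tables(t, CnSymmetry(order=2))


def test_fold_then_solve_matches_full_ring():
    order = 4
    t = make_symmetric_design_problem(order, 2, 3, seed=7)
    folded = fold_symmetric_tables(t, CnSymmetry(order=order))
    res = solve_gmec(folded)
    # exhaustive check over all symmetric assignments of the full ring
    best = min(score_assignment(t, combo * order)
               for combo in itertools.product(range(3), repeat=2))
    assert res.energy == pytest.approx(best, abs=1e-9)
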