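"""Exact fixed-backbone sequence design over pairwise-decomposable energies.

The design problem is a cost-function network: each design position carries
a set of choices (amino-acid identity x rotamer), one-body energies E1 and
sparse two-body energies E2 couple them, and the goal is the provably
optimal assignment — the global minimum energy conformation (GMEC).

The solver is exact: Goldstein dead-end elimination prunes choices that
provably cannot belong to the GMEC, then best-first branch and bound with
an admissible lower bound certifies the optimum. A brute-force enumerator
serves as the independent oracle on small instances.

For Cn-symmetric designs the full-ring energy matrix is folded onto the
design asymmetric unit (ASU): one-body terms aggregate across symmetry
copies and cross-copy pair terms become ASU pair (or self-pair) terms, so
that the ASU energy of any symmetric assignment equals the full-ring
energy exactly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .assembly import CnSymmetry, RingBackbone

__all__ = [
    "DesignPosition",
    "RotamerChoice",
    "EnergyTables",
    "FoldedEnergyTables",
    "GmecResult",
    "EnergyModelConfig",
    "ROTAMER_LIBRARY",
    "build_rotamer_choices",
    "build_energy_tables",
    "fold_symmetric_tables",
    "score_assignment",
    "dee_prune",
    "solve_gmec",
    "brute_force_gmec",
]

ENERGY_TOL = 1e-9
BRUTE_FORCE_CAP = 10 ** 6
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class DesignPosition:
    """One designable site: allowed identities, optionally fixed to one."""

    asu_index: int
    author_residue: int
    allowed: tuple[str, ...] = tuple(AMINO_ACIDS)
    fixed: str | None = None

    def __post_init__(self) -> None:
        if self.fixed is not None:
            if self.fixed not in self.allowed and self.allowed != (self.fixed,):
                self.allowed = (self.fixed,)
            else:
                self.allowed = (self.fixed,)


@dataclass(frozen=True)
class RotamerChoice:
    """An identity plus a discrete side-chain conformation.

    ``pseudo_atoms`` is a tuple of (label, position Å, radius Å, charge e)
    describing the reduced side-chain representation.
    """

    identity: str
    rotamer_index: int
    pseudo_atoms: tuple[tuple[str, tuple[float, float, float], float, float],
                        ...] = ()


@dataclass
class EnergyTables:
    """One-body and sparse two-body design energies.

    ``e1[i][c]`` is the one-body energy of choice c at position i;
    ``e2[(i, j)][(ci, cj)]`` (i < j) the pair energy, absent entries being
    zero (beyond the interaction cutoff).
    """

    n_choices: list[int]
    e1: list[np.ndarray]
    e2: dict[tuple[int, int], dict[tuple[int, int], float]]
    positions: list[DesignPosition] | None = None
    choices: list[list[RotamerChoice]] | None = None

    def __post_init__(self) -> None:
        if len(self.e1) != len(self.n_choices):
            raise ValueError("e1 length mismatch")
        for i, arr in enumerate(self.e1):
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.n_choices[i],):
                raise ValueError(f"e1[{i}] has wrong shape")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite energy at position {i}")
            self.e1[i] = arr
        for (i, j) in self.e2:
            if not i < j:
                raise ValueError("e2 keys must satisfy i < j")

    @property
    def n_positions(self) -> int:
        return len(self.n_choices)

    def pair_energy(self, i: int, ci: int, j: int, cj: int) -> float:
        if i > j:
            i, j, ci, cj = j, i, cj, ci
        return self.e2.get((i, j), {}).get((ci, cj), 0.0)


@dataclass
class FoldedEnergyTables(EnergyTables):
    """ASU-level tables; self-pair terms live in ``e_self[i][(ci, ci')]``.

    A self-pair term couples a position with its own symmetry copies: it
    contributes when the same ASU position takes choices ci in one copy and
    (necessarily the same) choice in another, so only diagonal (c, c)
    entries are ever scored for a symmetric assignment; the full (ci, cj)
    map is kept for validation.
    """

    order: int = 1
    e_self: list[dict[tuple[int, int], float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        super().__post_init__()
        if not self.e_self:
            self.e_self = [{} for _ in self.n_choices]


@dataclass
class GmecResult:
    assignment: tuple[int, ...]
    energy: float
    optimal: bool           # certified zero bound gap
    nodes_expanded: int = 0
    rotamers_pruned: int = 0
    identities: tuple[str, ...] | None = None


# ---------------------------------------------------------------------------
# Reduced rotamer library and energy model
# ---------------------------------------------------------------------------

# Per identity: (n pseudo-atoms, reach Å of the outermost pseudo-atom from
# CA, per-atom radius Å, net charge e, reference energy). The side chain is
# discretized at chi1 in 60° steps; small residues get a single rotamer.
_SIDECHAIN = {
    #        n  reach  rad   q     ref
    "G": (0, 0.0, 0.0,  0.0,  0.0),
    "A": (1, 1.5, 1.9,  0.0,  0.2),
    "S": (1, 1.9, 1.7,  0.0,  0.1),
    "C": (1, 2.0, 1.9,  0.0,  0.3),
    "T": (1, 1.9, 1.9,  0.0,  0.1),
    "V": (1, 2.0, 2.0,  0.0,  0.3),
    "P": (1, 1.9, 1.9,  0.0,  0.5),
    "D": (2, 2.5, 1.8, -1.0, -0.1),
    "N": (2, 2.5, 1.8,  0.0,  0.0),
    "L": (2, 2.6, 2.0,  0.0,  0.2),
    "I": (2, 2.6, 2.0,  0.0,  0.3),
    "M": (2, 3.0, 2.0,  0.0,  0.4),
    "E": (2, 3.1, 1.8, -1.0, -0.1),
    "Q": (2, 3.1, 1.8,  0.0,  0.0),
    "K": (3, 3.9, 1.8,  1.0,  0.0),
    "R": (3, 4.1, 1.8,  1.0,  0.1),
    "H": (2, 3.0, 1.9,  0.0,  0.2),
    "F": (2, 3.4, 2.1,  0.0,  0.4),
    "Y": (3, 3.6, 2.0,  0.0,  0.3),
    "W": (3, 3.7, 2.1,  0.0,  0.5),
}

CHI1_STEPS = (-60.0, 60.0, 180.0)


def _rotamer_pseudo_atoms(identity: str, chi1: float,
                          ) -> tuple[tuple[str, tuple[float, float, float],
                                           float, float], ...]:
    """Pseudo-atoms in a local CA frame for one identity/chi1 combination."""
    n, reach, rad, charge, _ref = _SIDECHAIN[identity]
    if n == 0:
        return ()
    # CB direction fixed (+x tilted off the backbone plane); chi1 swings the
    # distal pseudo-atoms around the CA-CB bond
    cb_dir = np.array([0.866, 0.0, 0.5])
    swing = np.radians(chi1)
    perp = np.array([-0.5 * math.sin(swing), math.cos(swing),
                     0.866 * math.sin(swing)])
    atoms = []
    for k in range(n):
        frac = (k + 1) / n
        pos = cb_dir * (1.5 + (reach - 1.5) * frac) \
            + perp * (reach - 1.5) * frac * 0.6
        q = charge if k == n - 1 else 0.0
        atoms.append((f"X{k + 1}", tuple(float(x) for x in pos), rad, q))
    return tuple(atoms)


def _library_for(identity: str) -> list[RotamerChoice]:
    n, _reach, _rad, _q, _ref = _SIDECHAIN[identity]
    if n <= 1:
        return [RotamerChoice(identity, 0,
                              _rotamer_pseudo_atoms(identity, CHI1_STEPS[1]))]
    return [RotamerChoice(identity, k, _rotamer_pseudo_atoms(identity, chi))
            for k, chi in enumerate(CHI1_STEPS)]


ROTAMER_LIBRARY: dict[str, list[RotamerChoice]] = {
    aa: _library_for(aa) for aa in AMINO_ACIDS}


@dataclass
class EnergyModelConfig:
    """Simplified pairwise-decomposable energy model.

    Soft 12-6 steric term with per-atom radii, screened Coulomb with a
    distance-dependent dielectric (eps = dielectric_slope * d), and
    per-identity reference energies. The same one-body/two-body
    decomposition as full-atom design scores; the parametrization is the
    toolkit's own and lives entirely here.
    """

    lj_epsilon: float = 0.15        # kcal/mol well depth
    lj_cap: float = 10.0            # clamp on the repulsive branch
    coulomb_constant: float = 332.0637  # kcal Å / (mol e^2)
    dielectric_slope: float = 4.0   # eps(d) = slope * d
    cutoff: float = 10.0            # Å, pair interactions beyond are zero
    reference_weight: float = 1.0


def build_rotamer_choices(position: DesignPosition,
                          library: dict[str, list[RotamerChoice]] | None = None,
                          ) -> list[RotamerChoice]:
    lib = library or ROTAMER_LIBRARY
    out: list[RotamerChoice] = []
    for aa in position.allowed:
        if aa not in lib or not lib[aa]:
            raise ValueError(f"rotamer library has no entries for {aa!r}")
        out.extend(lib[aa])
    return out


def _pair_atom_energy(a, b, cfg: EnergyModelConfig) -> float:
    (_la, pa, ra, qa) = a
    (_lb, pb, rb, qb) = b
    d = math.dist(pa, pb)
    if d > cfg.cutoff:
        return 0.0
    d = max(d, 0.3)
    sigma = ra + rb
    x6 = (sigma / d) ** 6
    lj = min(cfg.lj_epsilon * (x6 * x6 - 2.0 * x6), cfg.lj_cap)
    lj = min(lj, cfg.lj_cap)
    coul = 0.0
    if qa != 0.0 and qb != 0.0:
        coul = cfg.coulomb_constant * qa * qb / (cfg.dielectric_slope * d * d)
    return lj + coul


def _place(atoms, origin: np.ndarray):
    return tuple((lab, (pos[0] + origin[0], pos[1] + origin[1],
                        pos[2] + origin[2]), rad, q)
                 for lab, pos, rad, q in atoms)


def build_energy_tables(backbone: RingBackbone | list[np.ndarray],
                        positions: list[DesignPosition],
                        anchors: list[np.ndarray],
                        library: dict[str, list[RotamerChoice]] | None = None,
                        model_config: EnergyModelConfig | None = None,
                        ) -> EnergyTables:
    """Compute one- and two-body design energies on a fixed backbone.

    ``anchors`` gives the CA position of each design position; rotamer
    pseudo-atoms are placed in a local frame at each anchor. E1 combines
    the identity reference energy with the choice's interaction against all
    backbone atoms; E2 is the pseudo-atom pair energy between choices at
    two positions, omitted beyond the cutoff.
    """
    cfg = model_config or EnergyModelConfig()
    if len(anchors) != len(positions):
        raise ValueError("need one anchor per design position")
    if isinstance(backbone, RingBackbone):
        bb_atoms = np.vstack(backbone.blades)
    else:
        bb_atoms = np.vstack([np.asarray(b, dtype=float) for b in backbone])

    choices = [build_rotamer_choices(p, library) for p in positions]
    n_choices = [len(c) for c in choices]
    placed = [[_place(ch.pseudo_atoms, np.asarray(anchors[i], dtype=float))
               for ch in choices[i]] for i in range(len(positions))]

    e1: list[np.ndarray] = []
    for i, pos in enumerate(positions):
        arr = np.zeros(n_choices[i])
        for c, ch in enumerate(choices[i]):
            e = cfg.reference_weight * _SIDECHAIN[ch.identity][4]
            anchor = np.asarray(anchors[i], dtype=float)
            near = bb_atoms[np.linalg.norm(bb_atoms - anchor, axis=1)
                            < cfg.cutoff + 5.0]
            for atom in placed[i][c]:
                for bpos in near:
                    # backbone atoms: neutral, carbon-like radius
                    e += _pair_atom_energy(
                        atom, ("BB", tuple(bpos), 1.9, 0.0), cfg)
            arr[c] = e
        e1.append(arr)

    e2: dict[tuple[int, int], dict[tuple[int, int], float]] = {}
    anchors_arr = np.asarray(anchors, dtype=float)
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            if np.linalg.norm(anchors_arr[i] - anchors_arr[j]) \
                    > cfg.cutoff + 8.0:
                continue  # beyond any rotamer reach
            entries: dict[tuple[int, int], float] = {}
            for ci in range(n_choices[i]):
                for cj in range(n_choices[j]):
                    e = 0.0
                    for a in placed[i][ci]:
                        for b in placed[j][cj]:
                            e += _pair_atom_energy(a, b, cfg)
                    if abs(e) > 0.0:
                        entries[(ci, cj)] = e
            if entries:
                e2[(i, j)] = entries
    return EnergyTables(n_choices=n_choices, e1=e1, e2=e2,
                        positions=positions, choices=choices)


# ---------------------------------------------------------------------------
# Symmetry folding
# ---------------------------------------------------------------------------

def fold_symmetric_tables(tables: EnergyTables, sym: CnSymmetry,
                          asu_positions: list[int] | None = None,
                          ) -> FoldedEnergyTables:
    """Fold full-ring tables onto the design asymmetric unit.

    Full positions must be the ASU positions replicated ``sym.order`` times
    in copy-major order (copy 0's positions, then copy 1's, ...), with
    identical choice counts per copy. One-body terms sum across copies;
    each cross-copy pair term is assigned once to its ASU pair (or to the
    self-pair map when both ends are copies of the same ASU position). The
    defining contract is the replication identity: for every ASU assignment
    s, folded energy(s) = full energy of s replicated n times.

    Raises if the full tables are not invariant under the copy permutation.
    """
    n = sym.order
    total = tables.n_positions
    if total % n != 0:
        raise ValueError(f"{total} positions not divisible by order {n}")
    m = total // n
    if asu_positions is None:
        asu_positions = list(range(m))
    if len(asu_positions) != m:
        raise ValueError("ASU position list has wrong length")

    def asu_of(p: int) -> tuple[int, int]:
        return p % m, p // m  # (asu index, copy index)

    # verify symmetry of the full tables under the copy shift
    violations: list[str] = []
    for p in range(total):
        a, k = asu_of(p)
        if tables.n_choices[p] != tables.n_choices[a]:
            violations.append(f"choice count differs at position {p}")
            continue
        if not np.allclose(tables.e1[p], tables.e1[a], atol=ENERGY_TOL):
            violations.append(f"E1 differs between position {p} and its "
                              f"ASU representative {a}")
    for (i, j), entries in tables.e2.items():
        ai, ki = asu_of(i)
        aj, kj = asu_of(j)
        # the copy-shifted image of (i, j)
        si = ai + ((ki + 1) % n) * m
        sj = aj + ((kj + 1) % n) * m
        for (ci, cj), e in entries.items():
            es = tables.pair_energy(si, ci, sj, cj)
            if abs(es - e) > 1e-6:
                violations.append(
                    f"E2[{i},{j}][{ci},{cj}]={e:.6g} but its symmetry image "
                    f"E2[{si},{sj}]={es:.6g}")
                if len(violations) > 20:
                    break
    if violations:
        raise ValueError("full tables are not symmetric under the copy "
                         "permutation:\n" + "\n".join(violations[:20]))

    e1 = [np.array(tables.e1[a], dtype=float) * n for a in range(m)]
    e2: dict[tuple[int, int], dict[tuple[int, int], float]] = {}
    e_self: list[dict[tuple[int, int], float]] = [{} for _ in range(m)]
    for (i, j), entries in tables.e2.items():
        ai, _ki = asu_of(i)
        aj, _kj = asu_of(j)
        for (ci, cj), e in entries.items():
            if ai == aj:
                key = (ci, cj) if ci <= cj else (cj, ci)
                e_self[ai][key] = e_self[ai].get(key, 0.0) + e
            else:
                a, b = (ai, aj) if ai < aj else (aj, ai)
                ca, cb = ((ci, cj) if ai < aj else (cj, ci))
                e2.setdefault((a, b), {})
                e2[(a, b)][(ca, cb)] = e2[(a, b)].get((ca, cb), 0.0) + e

    folded = FoldedEnergyTables(
        n_choices=[tables.n_choices[a] for a in range(m)],
        e1=e1, e2=e2, order=n, e_self=e_self,
        positions=(tables.positions[:m] if tables.positions else None),
        choices=(tables.choices[:m] if tables.choices else None))
    return folded


def replicate_assignment(assignment: tuple[int, ...], order: int,
                         ) -> tuple[int, ...]:
    return tuple(assignment) * order


# ---------------------------------------------------------------------------
# Scoring and exact search
# ---------------------------------------------------------------------------

def score_assignment(tables: EnergyTables, assignment) -> float:
    """Total energy sum E1 + sum E2 (+ self-pair terms for folded tables)."""
    assignment = tuple(assignment)
    if len(assignment) != tables.n_positions:
        raise ValueError("assignment length mismatch")
    for i, c in enumerate(assignment):
        if not 0 <= c < tables.n_choices[i]:
            raise ValueError(f"choice {c} not allowed at position {i}")
    e = sum(tables.e1[i][c] for i, c in enumerate(assignment))
    for (i, j), entries in tables.e2.items():
        e += entries.get((assignment[i], assignment[j]), 0.0)
    if isinstance(tables, FoldedEnergyTables):
        for i, c in enumerate(assignment):
            e += tables.e_self[i].get((c, c), 0.0)
    return float(e)


def _self_energy(tables: EnergyTables, i: int, c: int) -> float:
    if isinstance(tables, FoldedEnergyTables):
        return tables.e_self[i].get((c, c), 0.0)
    return 0.0


def dee_prune(tables: EnergyTables,
              ) -> tuple[list[list[int]], int]:
    """Goldstein singles dead-end elimination, iterated to a fixpoint.

    Choice r at position i is pruned when some competitor r' satisfies
    E1(i,r) - E1(i,r') + sum_j min_s [E2(i,r,j,s) - E2(i,r',j,s)] > 0:
    every completion of r is then beaten by the same completion of r', so r
    cannot be in the GMEC. Returns the surviving choice lists per position
    and the number pruned. Exactness-preserving by construction.
    """
    return _dee_with_restriction(
        tables, [list(range(k)) for k in tables.n_choices])


def brute_force_gmec(tables: EnergyTables,
                     cap: int = BRUTE_FORCE_CAP) -> GmecResult:
    """Exhaustive GMEC by enumeration; ties broken lexicographically."""
    total = 1
    for k in tables.n_choices:
        total *= k
        if total > cap:
            raise ValueError(f"combination count exceeds cap {cap}")
    best_a, best_e = None, np.inf
    for combo in itertools.product(*(range(k) for k in tables.n_choices)):
        e = score_assignment(tables, combo)
        if e < best_e:  # strict: ties keep the lexicographically first
            best_a, best_e = combo, e
    assert best_a is not None
    return GmecResult(assignment=best_a, energy=float(best_e), optimal=True,
                      nodes_expanded=total,
                      identities=_identities(tables, best_a))


def _identities(tables: EnergyTables, assignment) -> tuple[str, ...] | None:
    if tables.choices is None:
        return None
    return tuple(tables.choices[i][c].identity
                 for i, c in enumerate(assignment))


def solve_gmec(tables: EnergyTables,
               fixed: dict[int, int] | None = None) -> GmecResult:
    """Exact GMEC by DEE preprocessing + best-first branch and bound.

    ``fixed`` pins positions to specific choice indices (e.g. conserved
    motif residues). The lower bound for a partial assignment is the exact
    energy of the decided part plus, for every undecided position, the
    minimum over surviving choices of its one-body energy and its pair
    energies against decided positions, plus the minimum pair energy over
    every undecided-undecided pair — admissible, so the first dequeued
    complete assignment is certified optimal. Ties are broken
    lexicographically by position then choice index.
    """
    import heapq

    n = tables.n_positions
    fixed = fixed or {}
    base_alive = [list(range(k)) for k in tables.n_choices]
    for i, c in fixed.items():
        if not 0 <= c < tables.n_choices[i]:
            raise ValueError(f"fixed choice {c} invalid at position {i}")
        base_alive[i] = [c]

    # DEE on the constrained problem: restrict then prune
    alive, pruned = _dee_with_restriction(tables, base_alive)

    # positions expanded in index order so the heap tie-break is
    # lexicographic by position then choice, matching brute force
    order = list(range(n))

    def pair(i: int, ci: int, j: int, cj: int) -> float:
        return tables.pair_energy(i, ci, j, cj)

    def lower_bound(assigned: dict[int, int]) -> float:
        e = 0.0
        done = list(assigned.items())
        for (i, ci) in done:
            e += tables.e1[i][ci] + _self_energy(tables, i, ci)
        for a in range(len(done)):
            for b in range(a + 1, len(done)):
                i, ci = done[a]
                j, cj = done[b]
                e += pair(i, ci, j, cj)
        undecided = [i for i in range(n) if i not in assigned]
        for i in undecided:
            e += min(tables.e1[i][c] + _self_energy(tables, i, c)
                     + sum(min(pair(i, c, j, cj) for cj in [assigned[j]])
                           for j in assigned)
                     for c in alive[i])
        for a in range(len(undecided)):
            for b in range(a + 1, len(undecided)):
                i, j = undecided[a], undecided[b]
                if (min(i, j), max(i, j)) not in tables.e2:
                    continue
                e += min(pair(i, ci, j, cj)
                         for ci in alive[i] for cj in alive[j])
        return e

    # best-first: (bound, partial assignment); partial doubles as tie-break
    heap: list[tuple[float, tuple[int, ...]]] = []
    heapq.heappush(heap, (lower_bound({}), ()))
    nodes = 0
    while heap:
        bound, partial = heapq.heappop(heap)
        depth = len(partial)
        nodes += 1
        assigned = dict(zip(order[:depth], partial))
        if depth == n:
            full = tuple(assigned[i] for i in range(n))
            energy = score_assignment(tables, full)
            return GmecResult(assignment=full, energy=energy, optimal=True,
                              nodes_expanded=nodes, rotamers_pruned=pruned,
                              identities=_identities(tables, full))
        pos = order[depth]
        for c in alive[pos]:
            child = dict(assigned)
            child[pos] = c
            heapq.heappush(heap, (lower_bound(child), partial + (c,)))
    raise RuntimeError("search exhausted without a complete assignment")


def _dee_with_restriction(tables: EnergyTables,
                          alive: list[list[int]],
                          ) -> tuple[list[list[int]], int]:
    """Goldstein DEE restricted to the given surviving-choice lists."""
    n = tables.n_positions
    alive = [list(a) for a in alive]
    for i, a in enumerate(alive):
        if not a:
            raise ValueError(f"position {i} has no allowed choices")
    pruned = 0
    changed = True
    while changed:
        changed = False
        for i in range(n):
            if len(alive[i]) <= 1:
                continue
            keep: list[int] = []
            for r in alive[i]:
                dominated = False
                for rp in alive[i]:
                    if rp == r:
                        continue
                    gap = (tables.e1[i][r] + _self_energy(tables, i, r)
                           - tables.e1[i][rp] - _self_energy(tables, i, rp))
                    for j in range(n):
                        if j == i:
                            continue
                        gap += min(tables.pair_energy(i, r, j, s)
                                   - tables.pair_energy(i, rp, j, s)
                                   for s in alive[j])
                    if gap > ENERGY_TOL:
                        dominated = True
                        break
                if dominated:
                    pruned += 1
                    changed = True
                else:
                    keep.append(r)
            if not keep:
                raise RuntimeError(f"position {i} lost all choices")
            alive[i] = keep
    return alive, pruned
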