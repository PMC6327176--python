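"""Synthetic fixtures: idealized Cn propellers and random design problems.

Every stage of the toolkit is testable offline with these generators. The
toy propeller is an idealized blade (a four-strand zigzag Cα trace with N
and C backbone atoms) replicated with exact Cn symmetry and geometrically
closed at the anchor threonine; it exercises geometry and bookkeeping, not
folding realism. The random design-problem generator draws bounded
one-/two-body energies for cross-validation of the exact solver against
brute force.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembly import CnSymmetry, cn_expand
from .design import EnergyTables
from .structure_io import AtomRecord, ResidueRecord, StructureModel

__all__ = [
    "ToyPropellerSpec",
    "make_toy_propeller",
    "toy_blade_ca",
    "make_random_design_problem",
    "make_symmetric_design_problem",
]


@dataclass
class ToyPropellerSpec:
    """Geometry of an idealized Cn toy propeller."""

    n_blades: int = 8
    residues_per_blade: int = 40
    strand_spacing: float = 4.8   # Å between the 4 zigzag strands
    rise: float = 3.5             # Å Cα step along a strand
    radius: float = 18.0          # Å blade centroid distance from the axis
    noise_sigma: float = 0.0      # Å isotropic Gaussian coordinate noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blades < 1:
            raise ValueError("need at least one blade")
        if self.residues_per_blade < 4:
            raise ValueError("need at least 4 residues per blade")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def _ideal_blade_local(spec: ToyPropellerSpec) -> np.ndarray:
    """Cα trace of one blade in its local frame, centred at the origin.

    Four antiparallel zigzag strands in the xz-plane, fanned slightly so
    consecutive blades do not collide at moderate radius.
    """
    n = spec.residues_per_blade
    per_strand = [n // 4] * 4
    for k in range(n % 4):
        per_strand[k] += 1
    pts = []
    y = 0.0
    for s, count in enumerate(per_strand):
        x0 = (s - 1.5) * spec.strand_spacing
        direction = 1.0 if s % 2 == 0 else -1.0
        z0 = 0.0 if direction > 0 else spec.rise * (count - 1)
        for t in range(count):
            z = z0 + direction * spec.rise * t
            zig = 0.6 * (1 if t % 2 == 0 else -1)
            pts.append([x0 + zig, y, z - spec.rise * (count - 1) / 2.0])
    arr = np.array(pts)
    return arr - arr.mean(axis=0)


def toy_blade_ca(spec: ToyPropellerSpec) -> np.ndarray:
    """One placed blade: the local blade moved out to the ring radius."""
    local = _ideal_blade_local(spec)
    # tilt the blade so its strands fan tangentially around the ring
    ang = np.pi / spec.n_blades
    R = np.array([[np.cos(ang), -np.sin(ang), 0.0],
                  [np.sin(ang), np.cos(ang), 0.0],
                  [0.0, 0.0, 1.0]])
    return local @ R.T + np.array([spec.radius, 0.0, 0.0])


def make_toy_propeller(spec: ToyPropellerSpec,
                       ) -> tuple[StructureModel, dict]:
    """Build an exactly Cn-symmetric toy propeller as a StructureModel.

    Residues are threonine at each blade start (the anchor) and alanine
    elsewhere; every residue carries N, CA and C backbone atoms. The ring
    is closed by construction: the carbonyl C of each blade's final
    residue sits exactly on the symmetry image of the next blade's anchor
    N, so the measured closure distance is zero at ``noise_sigma = 0``.
    Gaussian noise, when requested, is applied per atom after expansion
    (breaking the symmetry, as real coordinates do).

    Returns the model plus a metadata dict (symmetry, anchor positions,
    per-blade Cα blocks).
    """
    rng = np.random.default_rng(spec.seed)
    sym = CnSymmetry(order=spec.n_blades)
    ca = toy_blade_ca(spec)
    n = spec.residues_per_blade

    # backbone N and C flank each Cα along the local chain direction
    def flank(ca_block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        diffs = np.gradient(ca_block, axis=0)
        norm = np.linalg.norm(diffs, axis=1, keepdims=True)
        u = diffs / np.maximum(norm, 1e-9)
        return ca_block - 1.45 * u, ca_block + 1.52 * u

    npos, cpos = flank(ca)
    # exact closure: pin the final C onto the generator image of the first N
    cpos[-1] = sym.rotate(npos[0], 1)

    blades_ca = cn_expand(ca, sym)
    blades_n = cn_expand(npos, sym)
    blades_c = cn_expand(cpos, sym)

    if spec.noise_sigma > 0:
        for blk in (blades_ca, blades_n, blades_c):
            for b in blk:
                b += rng.normal(0.0, spec.noise_sigma, size=b.shape)

    model = StructureModel(title=f"toy C{spec.n_blades} propeller")
    residues: list[ResidueRecord] = []
    num = 1
    for k in range(spec.n_blades):
        for r in range(n):
            name3 = "THR" if r == 0 else "ALA"
            atoms = [
                AtomRecord("N", "N", blades_n[k][r]),
                AtomRecord("CA", "C", blades_ca[k][r]),
                AtomRecord("C", "C", blades_c[k][r]),
            ]
            residues.append(ResidueRecord(chain_id="A", number=num,
                                          name3=name3, atoms=atoms))
            num += 1
    model.chains["A"] = residues
    meta = {
        "symmetry": sym,
        "blades_ca": blades_ca,
        "junction_n": npos[0],
        "junction_c": cpos[-1],
        "anchor_residues": [1 + k * n for k in range(spec.n_blades)],
        "blade_ca": ca,
    }
    return model, meta


def make_random_design_problem(n_positions: int,
                               identities_per_position: int,
                               rotamers_per_identity: int = 1,
                               pair_density: float = 0.5,
                               energy_scale: float = 5.0,
                               seed: int = 0) -> EnergyTables:
    """Random bounded design instance, fully reproducible from the seed.

    One-body energies and (Bernoulli-included) pair tables are drawn
    uniformly in [-energy_scale, energy_scale].
    """
    if n_positions < 1 or identities_per_position < 1 \
            or rotamers_per_identity < 1:
        raise ValueError("counts must be >= 1")
    if not 0.0 <= pair_density <= 1.0:
        raise ValueError("pair density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    k = identities_per_position * rotamers_per_identity
    n_choices = [k] * n_positions
    e1 = [rng.uniform(-energy_scale, energy_scale, size=k)
          for _ in range(n_positions)]
    e2: dict[tuple[int, int], dict[tuple[int, int], float]] = {}
    for i in range(n_positions):
        for j in range(i + 1, n_positions):
            if rng.random() >= pair_density:
                continue
            block = rng.uniform(-energy_scale, energy_scale, size=(k, k))
            e2[(i, j)] = {(ci, cj): float(block[ci, cj])
                          for ci in range(k) for cj in range(k)}
    return EnergyTables(n_choices=n_choices, e1=e1, e2=e2)


def make_symmetric_design_problem(order: int, asu_positions: int,
                                  identities: int,
                                  pair_density: float = 0.7,
                                  energy_scale: float = 3.0,
                                  seed: int = 0) -> EnergyTables:
    """Random full-ring tables exactly invariant under the Cn copy shift.

    Positions are the ``asu_positions`` replicated ``order`` times in
    copy-major order. Interaction patterns are drawn once between copy 0
    and copy s (for every ASU pair and separation s) and replicated around
    the ring, so the tables are symmetric by construction and can be
    folded onto the ASU.
    """
    rng = np.random.default_rng(seed)
    m, n, k = asu_positions, order, identities
    e1_asu = [rng.uniform(-energy_scale, energy_scale, size=k)
              for _ in range(m)]
    e1 = [np.array(e1_asu[p % m]) for p in range(m * n)]
    e2: dict[tuple[int, int], dict[tuple[int, int], float]] = {}
    for a in range(m):
        for b in range(m):
            for s in range(n):
                if s == 0 and b <= a:
                    continue  # within-copy pairs once, no self pairs
                if rng.random() >= pair_density:
                    continue
                block = rng.uniform(-energy_scale, energy_scale, size=(k, k))
                for copy in range(n):
                    p = a + copy * m
                    q = b + ((copy + s) % n) * m
                    if p == q:
                        continue
                    i, j = (p, q) if p < q else (q, p)
                    entries = e2.setdefault((i, j), {})
                    for ca in range(k):
                        for cb in range(k):
                            key = (ca, cb) if p < q else (cb, ca)
                            entries[key] = entries.get(key, 0.0) \
                                + float(block[ca, cb])
    return EnergyTables(n_choices=[k] * (m * n), e1=e1, e2=e2)
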