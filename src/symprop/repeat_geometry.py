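"""Blade extraction, least-squares superposition and Cn-axis analysis.

Propeller repeats ("blades") are compared by Kabsch superposition of their
Cα traces: the rotation minimizing the RMSD over all proper rigid motions.
Per-position deviation profiles after superposition, pairwise RMSD matrices
over all blades, and rotational-symmetry order fitting build on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import StructureModel, ca_trace

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "RepeatSpan",
    "DeviationProfile",
    "kabsch_superpose",
    "extract_repeats",
    "pairwise_rmsd_matrix",
    "deviation_profile",
    "fit_cn_axis",
]

ORTHONORMALITY_TOL = 1e-9


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("improper rotation (reflection) rejected")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    deviations: np.ndarray
    n_pairs: int


@dataclass
class RepeatSpan:
    """Inclusive author-numbered residue range within one chain."""

    chain_id: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"span start {self.start} > end {self.end}")


@dataclass
class DeviationProfile:
    deviations: np.ndarray  # per aligned position, Å
    max_deviation: float


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     ) -> SuperpositionResult:
    """Optimal proper-rigid superposition of ``mobile`` onto ``reference``.

    Returns the transform, the minimized RMSD and the per-pair Cα
    deviations after applying it. Reflections are never returned: the
    rotation is constrained proper, preserving chirality.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError(f"point sets must both be (N, 3); got "
                         f"{mob.shape} and {ref.shape}")
    n = mob.shape[0]
    if n < 3:
        raise ValueError("need at least 3 point pairs")
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    if np.allclose(mob, mc, atol=1e-12) and np.allclose(ref, rc, atol=1e-12):
        raise ValueError("degenerate input: all points coincident")
    # align_vectors solves the orthogonal Procrustes problem over proper
    # rotations (Kabsch with reflection correction built in)
    rot, _ = Rotation.align_vectors(ref - rc, mob - mc)
    R = rot.as_matrix()
    t = rc - R @ mc
    transform = RigidTransform(R, t)
    devs = np.linalg.norm(transform.apply(mob) - ref, axis=1)
    rmsd = float(np.sqrt(np.mean(devs ** 2)))
    return SuperpositionResult(transform=transform, rmsd=rmsd,
                               deviations=devs, n_pairs=n)


# ---------------------------------------------------------------------------
# Blade extraction
# ---------------------------------------------------------------------------

def extract_repeats(model: StructureModel,
                    spans: list[RepeatSpan] | None = None,
                    chain_id: str | None = None,
                    anchor: str | None = None,
                    expected_count: int | None = None,
                    ) -> list[tuple[RepeatSpan, np.ndarray]]:
    """Cut a chain into repeat blades, by explicit spans or by anchor residue.

    Explicit mode: each span yields the Cα block of its residues; spans must
    not overlap. Anchor mode: the chain is split at successive occurrences
    of the anchor residue type (e.g. ``THR``, the conserved blade-start
    threonine); when more anchors exist than ``expected_count`` repeats, the
    subset of split points giving the most uniform repeat lengths is chosen
    deterministically.
    """
    if spans is not None:
        seen: list[RepeatSpan] = []
        out: list[tuple[RepeatSpan, np.ndarray]] = []
        for span in spans:
            for other in seen:
                if (span.chain_id == other.chain_id
                        and span.start <= other.end and other.start <= span.end):
                    raise ValueError(f"overlapping spans: {span} / {other}")
            seen.append(span)
            trace, _ = ca_trace(model, span.chain_id)
            block = [pos for num, _aa, pos in trace
                     if span.start <= num <= span.end]
            if not block:
                raise ValueError(f"span {span} resolves to no Cα atoms")
            out.append((span, np.array(block)))
        return out

    if anchor is None or expected_count is None or chain_id is None:
        raise ValueError("anchor mode requires chain_id, anchor and "
                         "expected_count")
    anchor1 = anchor if len(anchor) == 1 else \
        {"THR": "T"}.get(anchor.upper(), anchor[:1])
    from .structure_io import AA3_TO_1
    if len(anchor) == 3:
        anchor1 = AA3_TO_1.get(anchor.upper(), anchor1)
    trace, _ = ca_trace(model, chain_id)
    hits = [i for i, (_n, aa, _p) in enumerate(trace) if aa == anchor1]
    if len(hits) < expected_count:
        raise ValueError(f"found {len(hits)} {anchor} residues, need "
                         f">= {expected_count}")
    starts = _choose_uniform_splits(hits, expected_count, len(trace))
    bounds = starts + [starts[0] + len(trace)]  # wrap: final blade to ring end
    out = []
    for k in range(expected_count):
        lo, hi = bounds[k], bounds[k + 1]
        idx = [i % len(trace) for i in range(lo, hi)]
        block = np.array([trace[i][2] for i in idx])
        span = RepeatSpan(chain_id=chain_id, start=trace[lo][0],
                          end=trace[idx[-1]][0], label=f"repeat{k + 1}")
        out.append((span, block))
    return out


def _choose_uniform_splits(hits: list[int], k: int, total: int) -> list[int]:
    """Pick k anchor indices minimizing the variance of repeat lengths."""
    from itertools import combinations
    if len(hits) == k:
        return hits
    best, best_var = None, np.inf
    for combo in combinations(hits, k):
        lengths = np.diff(list(combo) + [combo[0] + total])
        var = float(np.var(lengths))
        if var < best_var - 1e-12:
            best, best_var = list(combo), var
    assert best is not None
    return best


def pairwise_rmsd_matrix(repeats: list[np.ndarray]) -> np.ndarray:
    """Symmetric matrix of Kabsch RMSDs between every pair of Cα blocks.

    Blocks of unequal length are trimmed to the common minimum length.
    """
    if len(repeats) < 2:
        raise ValueError("need at least 2 repeats")
    blocks = [np.asarray(r, dtype=float) for r in repeats]
    m = min(b.shape[0] for b in blocks)
    blocks = [b[:m] for b in blocks]
    n = len(blocks)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = kabsch_superpose(blocks[i], blocks[j]).rmsd
            mat[i, j] = mat[j, i] = r
    return mat


def deviation_profile(repeat_a: np.ndarray, repeat_b: np.ndarray,
                      pairing: list[tuple[int, int]] | None = None,
                      ) -> DeviationProfile:
    """Per-position Cα deviations of two blades after superposition.

    The default pairing is positional (i <-> i); a structure-guided pairing
    for blades of unequal length is supplied explicitly as (index_a,
    index_b) tuples. Superposition is computed on the paired set.
    """
    a = np.asarray(repeat_a, dtype=float)
    b = np.asarray(repeat_b, dtype=float)
    if pairing is None:
        if a.shape[0] != b.shape[0]:
            raise ValueError("positional pairing needs equal-length blocks")
        pairing = [(i, i) for i in range(a.shape[0])]
    if len(pairing) < 3:
        raise ValueError("pairing must cover at least 3 positions")
    ia = [p[0] for p in pairing]
    ib = [p[1] for p in pairing]
    sup = kabsch_superpose(a[ia], b[ib])
    return DeviationProfile(deviations=sup.deviations,
                            max_deviation=float(sup.deviations.max()))


# ---------------------------------------------------------------------------
# Cn symmetry-axis fitting
# ---------------------------------------------------------------------------

def _rotation_about_axis(axis: np.ndarray, point: np.ndarray,
                         angle_deg: float) -> RigidTransform:
    R = Rotation.from_rotvec(np.radians(angle_deg)
                             * axis / np.linalg.norm(axis)).as_matrix()
    return RigidTransform(R, point - R @ point)


def fit_cn_axis(repeats: list[np.ndarray],
                n_candidates: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8, 9, 10),
                ) -> tuple[np.ndarray, np.ndarray, int, float]:
    """Fit the cyclic symmetry axis of a set of blades and its best order.

    The axis direction is the least-squares normal of the plane through the
    blade centroids (smallest principal component); the axis passes through
    the centroid mean. For each candidate order n, the rotational RMSD is
    the mean plain (superposition-free) RMSD between blade k rotated by
    360/n about the axis and blade k+1; the order minimizing it wins.

    Returns (unit axis, axis point, best order, rotational rmsd in Å).
    """
    if len(repeats) < 3:
        raise ValueError("need at least 3 repeats to fit an axis")
    blocks = [np.asarray(r, dtype=float) for r in repeats]
    centroids = np.array([b.mean(axis=0) for b in blocks])
    center = centroids.mean(axis=0)
    centered = centroids - center
    # smallest singular direction = plane normal
    _u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9:
        raise ValueError("degenerate blade centroids (collinear)")
    axis = vt[2]
    # orient axis so successive blades advance by positive rotation
    cross = np.cross(centered[0], centered[1])
    if np.dot(cross, axis) < 0:
        axis = -axis

    best_n, best_rmsd = None, np.inf
    for n in n_candidates:
        tf = _rotation_about_axis(axis, center, 360.0 / n)
        vals = []
        for k in range(len(blocks) - 1):
            if blocks[k].shape != blocks[k + 1].shape:
                continue
            moved = tf.apply(blocks[k])
            vals.append(float(np.sqrt(np.mean(
                np.sum((moved - blocks[k + 1]) ** 2, axis=1)))))
        if not vals:
            continue
        r = float(np.mean(vals))
        if r < best_rmsd - 1e-12:
            best_n, best_rmsd = n, r
    if best_n is None:
        raise ValueError("no candidate order could be evaluated")
    return axis, center, best_n, best_rmsd
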