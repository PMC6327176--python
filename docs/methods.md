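# Methods

This note records the models, parameter choices and numerical conventions
behind `symprop`, and what the synthetic fixtures do and do not establish
about real structures.

## Structures and numbering

PDB fixed-width is the required dialect (ATOM/HETATM/CRYST1/TER/END; first
model only). Author residue numbering is authoritative throughout, because
conserved-motif positions in propeller design are always cited by author
numbers (His11, Ser27, Asp31, Trp37 within each blade); internal 0-based
indices are never serialized. Alternate locations default to the
highest-occupancy copy (ties to the earlier altloc); hetero residues are
parsed but excluded from Cα traces and RMSD work. Solvent content uses the
Matthews convention: V_m = V_cell/(MW × copies in cell) and solvent
fraction 1 − 1.23/V_m, with the protein constant 1.23 Å³/Da fixed in
`structure_io` and the result clamped to [0, 1].

## Superposition and symmetry geometry

Kabsch superposition is solved through the orthogonal Procrustes problem
restricted to proper rotations (reflections are never returned — protein
chirality must be preserved), via `scipy.spatial.transform`. Equality
tolerances: orthonormality 1e-9, RMSD comparisons 1e-6 Å. The independent
check in the test suite minimizes RMSD numerically over rotation vectors
from multiple starts, a deliberately different path from the closed form.

The Cn axis is fitted as the least-squares normal of the plane through
blade centroids (smallest principal component), passing through the
centroid mean; this is exact for an ideal ring and degrades gracefully
under noise. Candidate orders are scored by the mean superposition-free
RMSD between blade k rotated by 360/n about the axis and blade k+1; the
minimizing order wins. Collinear centroids are rejected as degenerate.

Anchor-mode blade extraction splits a chain at occurrences of the anchor
residue type; when more anchors exist than expected repeats, the split
minimizing the variance of repeat lengths is chosen (deterministic,
first-best on ties). Deviation profiles default to positional pairing;
structure-guided pairings for unequal blades are supplied by the caller —
no automatic coordinate alignment is attempted.

## Ancestral reconstruction

Repeat distances are p-distances (mismatches over pairwise gap-free
columns). UPGMA runs through average-linkage clustering and yields
ultrametric trees; neighbor joining is implemented directly and rooted at
the midpoint. Ancestral states use Fitch parsimony — bottom-up
intersection/union — with the gap as a 21st state that is stripped from
emitted sequences. All tie combinations are enumerated in lexicographic
order up to a cap (default 10,000). Parsimony with full tie enumeration
was chosen over ML/Bayesian reconstruction deliberately: it is exact,
assumption-light, enumerable, and the column-set output leaves room to
layer alternative weightings later. Trees are Bio.Phylo objects and
serialize as Newick.

## Symmetric assembly

The docking search space is five-dimensional — radius, z-offset, spin,
tilt, roll — with the symmetry axis fixed to +z. The score is the stated
functional form: a clash term Σ max(0, d_clash − d)² over inter-blade
heavy-atom pairs (d_clash = 3.2 Å, softer than van der Waals contact to
admit un-minimized backbones) minus w × (count of inter-blade Cα pairs in
the 4.5–8.0 Å contact shell), w = 0.1. Grid search keeps the minimum
(ties to earlier grid points), followed by deterministic coordinate
descent with a halving step schedule. An error with diagnostics is raised
when no clash-free placement exists on the grid.

Ring closure is measured, not rebuilt: the distance between the carbonyl C
that must bond to the next blade's anchor N and the symmetry image of that
N. The acceptance threshold defaults to 2.0 Å — relaxed from the ideal
1.33 Å peptide bond, again to admit un-minimized backbones — and is
configurable; a violation raises an error carrying the measured distance.

## Design energies and exact search

The energy model is pairwise-decomposable with the standard one-body /
two-body split: per-identity reference energies, a soft 12-6 steric term
with per-atom radii (well depth 0.15 kcal/mol, repulsion clamped at
10 kcal/mol), and screened Coulomb with a distance-dependent dielectric
ε(d) = 4d, cut off at 10 Å. The parametrization is the toolkit's own and
lives in one config object; the algorithmic machinery (folding, DEE,
branch-and-bound) is independent of it. Side chains use a reduced
representation of 1–3 pseudo-atoms per identity at chi1 discretized in 60°
steps — enough to make identities and rotamers energetically distinct,
not a physical rotamer library.

Symmetry folding aggregates one-body terms across the n copies and maps
every cross-copy pair term to its ASU pair — or to a self-pair term when
both ends are copies of the same ASU position, which contributes as a
diagonal one-body-like term under symmetric assignments. The defining
contract is the replication identity: folded energy equals full-ring
energy for *every* ASU assignment, enforced within 1e-9 and checked
exhaustively in tests. Tables that are not invariant under the copy
permutation are rejected with the violating entries listed.

The solver applies Goldstein singles DEE to a fixpoint (provably
GMEC-preserving), then best-first branch-and-bound with an admissible
bound: exact energy of the decided part, plus per-undecided-position
minima including their interactions with decided positions, plus pairwise
minima over undecided pairs. Positions are expanded in index order so the
heap tie-break is lexicographic by position then choice, matching the
brute-force enumerator's tie-break exactly; agreement on both energy and
assignment is therefore testable, and is tested on hundreds of seeded
instances. Energies are compared with absolute tolerance 1e-9; the
brute-force cap defaults to 10⁶ combinations.

## Threading, selection, DNA emission

Threading restricts each design position to the threaded identity's
rotamers and re-solves exactly, so a candidate's energy is the certified
optimum for its sequence. The optional relaxation is deliberately
lightweight — rigid-blade translation proposals accepted only when a
geometric score (deviation of consecutive Cα spacings from 3.8 Å) does not
worsen — standing in for full-atom minimization; the contracted metric is
the Kabsch Cα RMSD drift of the final trace against the input. Selection
takes the lowest-drift candidate within an energy window of the best
score (default 5 % above the best; the literature protocol filters "best
energy" candidates before taking lowest deviation but does not state the
cut, so the window is explicit and configurable), with ties to lower
energy then input order.

Reverse translation fills codons from a deterministic E. coli preference
table. Each requested restriction site is placed at the first repeat
junction where an exhaustive enumeration of synonymous codon combinations
yields the site spanning the junction boundary and the site is unique in
the whole construct; failure names the site and junctions. The
translate∘encode identity is asserted on every output.

## Two-state denaturation

The model and parameters are given in the README. The logistic is
evaluated through `scipy.special.expit` so extreme |ΔG° − mD|/RT never
overflows. Fitting is trust-region least squares with multi-start
initialization: baselines from the curve ends, C_m seeded at the
steepest-slope point, m started at 1, 2 and 4 kcal/mol/M; the best
residual norm wins, deterministically. A fit is flagged as "no detectable
transition" when the fitted midpoint leaves the measured range or the
baseline separation at the midpoint is under 3× the RMS residual.
R = 1.987×10⁻³ kcal/(mol·K) and T = 298.15 K by default, both
configurable. ΔΔG between proteins is exactly
(C_m,A − C_m,B)(m_A + m_B)/2.

## Synthetic fixtures

The toy propeller is an idealized blade — four antiparallel zigzag
Cα strands (4.8 Å strand spacing, 3.5 Å rise) with N and C backbone atoms
flanking each Cα — replicated with exact Cn symmetry at a default radius
of 18 Å, anchored by a threonine first residue per blade, and closed by
pinning the final carbonyl C onto the generator image of the first N.
Noise, when requested, is i.i.d. Gaussian per atom applied after
expansion, breaking the symmetry the way real coordinates do. The
generator is deterministic given its seed, which is always an explicit
argument.

These fixtures test geometry, bookkeeping and exactness — they are not
physically realistic β-sheets, carry no packing or hydrogen-bonding
structure, and say nothing about foldability. Passing the synthetic suite
demonstrates that the algorithms are correct on their stated contracts; it
does not demonstrate that a designed sequence folds, which in this
workflow is an experimental question.

## Problem sizes

The verification suite uses desk-scale sizes chosen to keep exhaustive
oracles exact: 300 random design instances of ≤ 6 positions × ≤ 5
choices (brute-force enumerable), C2/C4/C8 folding checks with 2 ASU
positions × 3 identities (9 symmetric assignments, checked exhaustively),
10-point superposition sets, toy propellers of 12–40 residues per blade,
and 100 noisy denaturation replicates at 0.2 M spacing over 0–7 M. Larger
problems run through exactly the same code paths; only the oracles stop
being enumerable.

## Known limitations

- No flexible or sequence-guided structural alignment; pairings are
  positional or user-supplied.
- No loop modelling or junction regularization — closure is checked, not
  rebuilt.
- The energy model is simplified and config-driven; absolute energies are
  not comparable to full-atom force fields, though the exactness
  guarantees are independent of the parametrization.
- No continuous rotamers, backbone flexibility during design, or
  partition-function calculations.
- No probabilistic ancestral reconstruction; alignments are inputs, never
  computed.
- The two-state module fits isothermal chemical denaturation only — no
  thermal-melt model or instrument signal processing.
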