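# symprop

A toolkit for designing and analysing **Cn-symmetric β-propeller
proteins**. β-propellers are toroidal folds of 4–10 structurally similar
"blades" arranged around a central pseudo-symmetry axis; natural WD40
propellers are only approximately symmetric. `symprop` implements the
computational workflow that turns such a natural repeat protein into a
perfectly symmetric designed one, and the analytics used to judge the
result:

- **Blade geometry** — isolate repeats at a common anchor residue
  (conventionally a threonine at each blade start), superpose them by the
  Kabsch algorithm, compute pairwise Cα-RMSD matrices and per-position
  deviation profiles, and fit the cyclic symmetry axis and its order.
- **Ancestral/consensus reconstruction** — build UPGMA or
  neighbor-joining guide trees over the repeat alignment (p-distances) and
  enumerate ancestral candidate sequences by Fitch parsimony with full tie
  enumeration.
- **Symmetric assembly** — replicate one blade under Cn symmetry,
  search rigid blade placements (radius, z-offset, spin, tilt, roll) for
  the minimum of a clash + contact score, and close the ring at the anchor
  residue with an explicit junction-distance check.
- **Exact sequence design (GMEC)** — pairwise-decomposable design
  energies over a reduced rotamer representation, folded onto the design
  asymmetric unit so that ASU energy equals full-ring energy exactly;
  Goldstein dead-end elimination plus best-first branch-and-bound returns
  the certified global minimum energy conformation, with conserved motif
  residues (e.g. His11/Ser27/Asp31/Trp37 per blade) held fixed.
- **Design selection and cloning output** — thread candidate sequences,
  repack exactly, relax lightly, select the candidate with the lowest
  backbone deviation within an energy window, and reverse-translate the
  final repeat sequence with silent restriction sites at repeat junctions.
- **Stability analysis** — fit the six-parameter two-state chemical
  denaturation model (linear extrapolation method) and compare proteins by
  ΔΔG = (C<sub>m,A</sub> − C<sub>m,B</sub>)(m<sub>A</sub> + m<sub>B</sub>)/2.

The design core is exact, not heuristic: on every instance small enough to
enumerate, the solver provably matches brute force, and the symmetry
folding satisfies a replication identity for *every* assignment, not just
the optimum.

## The models in brief

**GMEC design.** With positions *i*, choices *c* (amino-acid identity ×
rotamer), one-body energies *E₁(i,c)* and two-body energies
*E₂(i,c,j,c′)*, the design problem is

    min over assignments s:  Σᵢ E₁(i, sᵢ) + Σ_{i<j} E₂(i, sᵢ, j, sⱼ)

Under Cn symmetry every blade carries the same sequence, so the matrix is
folded onto the asymmetric unit: one-body terms aggregate over the n
copies and cross-copy pair terms become ASU pair (or self-pair) terms with
each physical interaction counted once.

**Two-state denaturation.** With denaturant concentration *D* at
temperature *T*,

    K(D) = exp(−(ΔG° − m·D)/RT),  f_U = K/(1+K)
    y(D) = (γ⁰_F + m_F·D)(1 − f_U) + (γ⁰_U + m_U·D)·f_U

with R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹ and the midpoint C_m = ΔG°/m.

## Worked example

```python
import numpy as np
from symprop import *

# 1. a C8 toy propeller with 0.1 A coordinate noise; recover its symmetry
spec = ToyPropellerSpec(n_blades=8, residues_per_blade=40,
                        noise_sigma=0.1, seed=7)
model, meta = make_toy_propeller(spec)
blades = [blk for _, blk in extract_repeats(model, chain_id="A",
                                            anchor="THR", expected_count=8)]
axis, origin, order, rot_rmsd = fit_cn_axis(blades, tuple(range(3, 11)))
print(f"symmetry order {order}, rotational rmsd {rot_rmsd:.3f} A, "
      f"axis {np.round(axis, 3)}")
mat = pairwise_rmsd_matrix(blades)
print(f"mean inter-blade Calpha rmsd {mat[np.triu_indices(8, 1)].mean():.3f} A")

# 2. exact symmetric sequence design on a random C4 problem
tables = make_symmetric_design_problem(order=4, asu_positions=2,
                                       identities=3, seed=7)
folded = fold_symmetric_tables(tables, CnSymmetry(order=4))
result = solve_gmec(folded)
print(f"GMEC assignment {result.assignment}, energy {result.energy:.3f}, "
      f"certified optimal: {result.optimal}")

# 3. two-state denaturation fit and stability difference
truth = TwoStateParams(dG0=8.0, m=2.0, g0F=1.0, g0U=0.2, mF=-0.01, mU=0.015)
conc = np.arange(0.0, 7.01, 0.2)
rng = np.random.default_rng(7)
signal = two_state_signal(truth, conc) + rng.normal(0, 0.008, conc.shape)
params, diag = fit_two_state(DenaturationCurve(conc, signal))
print(f"dG0 = {params.dG0:.2f} kcal/mol, m = {params.m:.2f} kcal/mol/M, "
      f"Cm = {params.cm:.2f} M")
ref = TwoStateParams(dG0=6.0, m=2.0, g0F=1.0, g0U=0.2)
print(f"ddG vs reference = {ddg_between(params, ref):.2f} kcal/mol")
```

Output:

```
symmetry order 8, rotational rmsd 0.228 A, axis [0. 0. 1.]
mean inter-blade Calpha rmsd 0.218 A
GMEC assignment (0, 2), energy -30.687, certified optimal: True
dG0 = 7.59 kcal/mol, m = 1.90 kcal/mol/M, Cm = 3.99 M
ddG vs reference = 1.93 kcal/mol
```

The axis fit recovers the construction order (8) and axis (+z) despite the
noise; the inter-blade RMSD (~0.2 Å) reflects the injected 0.1 Å per-atom
jitter. The folded C4 design problem is solved to certified optimality.
The denaturation fit recovers ΔG° = 8, m = 2 (C_m = 4 M) to within the
noise, and the ΔΔG against a ΔG° = 6 reference comes out near the true
2 kcal/mol.

A `symprop` command-line tool mirrors the library (`symprop info`,
`superpose`, `blades`, `axis`, `tree`, `ancestors`, `assemble`, `gmec`,
`select`, `revtrans`, `fit-ied`, `ddg`, `toy-propeller`, `toy-design`);
run `symprop --help`.

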