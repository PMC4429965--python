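# Methods

This note documents the models, parameter choices and numerical conventions
behind `ssdesign`, and what the synthetic fixtures do and do not establish
about real data.

## The design problem

An engineered disulfide bridge crosslinks two cysteines introduced by paired
substitutions. It stabilizes a fold mainly by reducing the conformational
entropy of the unfolded state, so a good site must (a) be geometrically able
to form the Sγ–Sγ bond without backbone strain, (b) not disturb existing
bridges, and (c) not sit close enough to the catalytic machinery to cost
activity. The package encodes this as geometric enumeration → consensus →
rule-based rejection → rigidity ranking.

## Geometric enumeration

Two independent criteria sets are applied, mirroring the two families of
public disulfide predictors, and only their consensus advances.

**Window grading (MODIP-like).** Residue pairs with sequence separation ≥ 2
are graded by nested windows on the Cα–Cα and Cβ–Cβ distances. Grade A is
the classical sterically ideal band, Cα–Cα ∈ [4.4, 6.8] Å and
Cβ–Cβ ∈ [3.4, 4.6] Å. The B–D windows are this package's own progressive
widenings (B: [4.0, 7.4]/[3.0, 5.1]; C: [3.6, 8.0]/[2.5, 5.5];
D: [3.2, 9.0]/[2.0, 6.2] Å): the exact grade boundaries used by the public
servers are not published, and nothing downstream depends on them beyond
"graded at all". Glycine gets a virtual Cβ built from N/Cα/C with ideal
tetrahedral geometry (1.521 Å bond, L-configuration dihedral +122.6°).

**Distance + torsion scoring (DbD-like).** Pairs inside a Cβ–Cβ window
(default [3.0, 5.1] Å) are scored

    score = w₁ (d_CβCβ − 3.85)²  +  w₂ (1 + cos 2χ3)/2 ,

both weights 1 by default. χ3 (the Cβ–Sγ–Sγ–Cβ torsion) is estimated by
placing an idealized Sγ on each residue at the most common side-chain
rotamer (χ1 = −60°, bond 1.808 Å, angle 114°). The torsion term is zero at
|χ3| = 90° and maximal for the strained planar geometries, reflecting the
tight clustering of real disulfides near |χ3| ≈ 87°. Lower scores are
better; i,i+1 pairs are excluded as sterically unreasonable.

Because the server algorithms themselves are unpublished, the enumeration is
validated by construction rather than by reproducing server pair counts: a
synthetically planted geometrically ideal pair must be proposed by both
enumerators (grade A, minimal score) and must survive filtering, and
widening a window must never remove a previously reported candidate.

## Rejection rules

Applied in order, each pair receiving exactly one auditable decision:

1. **native_pair** — the pair is itself a native bridge (detected as CYS
   pairs with Sγ–Sγ ≤ 2.3 Å, greedily matched shortest-first so each
   cysteine joins at most one bridge).
2. **near_native** — a member is a native-bridge cysteine or lies within ±2
   sequence positions of one on the same chain. The ±2 window is the
   smallest that captures the standard "could affect the conformation
   around an existing bridge" objection while leaving ordinary surface
   pairs untouched.
3. **triad_proximity** — a member sits within the exclusion radius
   (default 6 Å) of a catalytic-triad residue. With a structure in hand the
   minimum heavy-atom distance is measured; whether published exclusion
   distances were Cα- or all-atom-based is usually unstated, so the
   criterion is configurable and the measured distance is recorded. Without
   a structure (label-only candidate lists), a user-supplied annotation set
   of triad-proximal residues is honoured instead.

## Rigidity ranking

The study-scale arbiter of candidate quality — high-temperature MD and the
RMSD of each variant — is force-field- and seed-dependent and far beyond
desk scale, so the package takes a two-level approach:

- **Trajectory analytics** for trajectories produced elsewhere: Kabsch
  superposition (SVD form, reflections corrected to det +1), per-frame Cα
  RMSD against the first frame (the conventional reference), equilibration
  detection (first index whose trailing 20%-window mean is within 5% of the
  final window's mean — a heuristic, always reported next to full-series
  statistics), and the distribution mode on 0.05 Å bins with edges at
  multiples of the width, reported as the bin center. 0.05 Å is the natural
  grain for Cα RMSD histograms of stable proteins; ties take the lowest
  center and are flagged.
- **A Gaussian network model** as the desk-scale surrogate for "more
  rigid": Cα contact (Kirchhoff) matrix at 7.3 Å (the standard GNM cutoff),
  per-residue mean-square fluctuations from the diagonal of its
  pseudoinverse with the single zero mode of a connected network removed.
  A candidate bridge is one extra contact; candidates are ranked by the
  decrease in total fluctuation. Laplacian interlacing guarantees the
  decrease is never negative-to-positive, which the tests assert
  numerically. GNM is preferred over an anisotropic model because only the
  *relative* ranking is needed and the Gaussian model has an exact
  small-case oracle (the path-graph Laplacian pseudoinverse in closed
  form). Units are relative (unit spring constant): only differences and
  ratios are meaningful.

Most disulfide-compatible pairs are already within the contact cutoff, so
their GNM delta is zero; the pipeline therefore breaks ties by the
distance/torsion score (ascending), then label order. When per-variant
trajectories are available, ranking by measured post-equilibration RMSD
supersedes the surrogate.

B-factor profiling (per-residue mean heavy-atom B, centred 5-residue
smoothing, hotspots as maximal runs above the 0.8 quantile) supports the
complementary "stabilize the mobile regions" heuristic: a good candidate
joins a high-B segment to a rigid one.

## Mutagenesis

Structure mutations use a stub side-chain model: rename, truncate beyond
Cβ, and (for cysteine) optionally place an idealized Sγ at χ1 = −60° or
along an explicit direction. Primer design follows the whole-plasmid
(QuikChange) convention — fully complementary forward/reverse oligos, the
mutant codon centred within ±3 nt — growing flanks until length ≥ 25 nt and
the kit's published melting estimate Tm = 81.5 + 0.41·%GC − 675/N −
%mismatch reaches 78 °C (an external kit convention, not a
thermodynamic model). Validation checks exact reverse-complementarity,
codon placement, and gapless annealing to the gene with only the intended
mismatches; pairs supplied without a codon span (e.g. published primer
tables) are validated on complementarity and length alone.

## Assay calculations

- **Thiol titration.** Free thiol (mM) = (OD₄₁₀ − b)/m from the Ellman
  calibration line fitted by ordinary least squares; readings within 0.05
  OD below the intercept clamp to zero, lower readings are an error.
  Protein molarity = (mg/mL)/MW(kDa); with the nominal 36.0 kDa apparent MW
  this makes 2 mg/mL ≈ 0.0556 mM. The per-molecule ratio is rounded to the
  nearest integer but always reported raw for audit; bridges follow by
  difference, (total − free)/2, with an odd difference flagged as
  inconsistent accounting.
- **Kinetics.** v = V_max·S/(K_m+S) by nonlinear least squares seeded from
  a Hanes linearization (S/v vs S), exact on noiseless data.
  k_cat = V_max·MW (U·mg⁻¹ × kDa = min⁻¹) and efficiency k_cat/K_m held to
  the definition exactly after every fit. Published turnover numbers can
  differ slightly from V_max·(apparent MW) because the true molar mass is
  not the SDS-PAGE estimate; reported uncertainty bands cover this.
- **Inactivation.** Default log-linear fit of ln(A/A₀) vs t (closed-form,
  robust), t½ = ln 2/k; an independent monotone-interpolation estimate of
  the 50% crossing is reported whenever it disagrees by more than 10%.
  Flat series give an infinite-t½ flag; series that never reach 50% are
  flagged as extrapolated. Fold changes are reported to 1 decimal, so
  reciprocity of folds holds only to that rounding grain.
- **Temperature optimum.** Argmax of the measured profile normalized to
  max = 100% (ties: lowest temperature, flagged; boundary maxima flagged);
  optional 3-point parabolic refinement, off by default because published
  optima are conventionally grid values.

## Synthetic fixtures: what they show and what they don't

`synthetic_data` builds poly-Ala backbones by natural-extension chaining at
ideal bond geometry (helix φ/ψ = −57°/−47°; strands −139°/135°; a dumbbell
of two helical domains joined by an extended linker), then rigidly re-hinges
the chain so a chosen pair sits at an exact Cβ–Cβ distance with the
face-to-face tilt of real disulfides (the hinge roll is chosen so the
idealized χ3 lands near ±87°). Planted native bridges get real Sγ atoms at
2.05 Å separation. Trajectories are the reference plus iid Gaussian jitter,
optional random rigid motion, and an optional decaying per-atom displacement
field for equilibration tests. Assay tables come from the exact generative
models the fitters assume. All randomness is `numpy.random.default_rng`
(PCG64) with explicit seeds; fixed seed ⇒ bit-identical output.

Passing on these fixtures therefore demonstrates *algorithmic* correctness —
geometry, bookkeeping, estimator consistency at stated noise — not
robustness to the things real data add: correlated thermal motion, rotamer
heterogeneity, anharmonic unfolding, assay systematics, model misspecified
noise. In particular the jitter trajectories have no correlated dynamics,
so RMSD distribution modes on them say nothing about force-field MD; and
the generative assay models match the fitted models by construction.

## Problem sizes and determinism

Fixtures are ≤ 300 residues; default test trajectories are ≤ 200 frames of
≤ 30 residues; parameter-recovery studies use 50 replicates of 12-point
datasets. These sizes make every statistical check well-conditioned while
keeping the whole suite fast. Pipeline runs are deterministic given a
structure and config (reports carry a config snapshot and no timestamps);
the acceptance script derives all replicate seeds from its single `--seed`
argument.

## Known limitations

- PDB subset only: no mmCIF, gzip, insertion-code arithmetic beyond
  identity, or binary trajectory formats (extension point documented in
  `structure_io`).
- Sγ placement is rotamer-idealized, not rotamer-searched; no energy
  minimization or ΔΔG prediction of modelled bridges.
- The GNM surrogate cannot discriminate candidates that are both already
  within the contact cutoff (delta 0 for both) beyond the geometric
  tie-break.
- Numbering is treated as opaque author labels; construct offsets between
  homologous sequences are the user's responsibility (supply triad and
  native-bridge labels in the structure's own numbering).
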