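# Methods

This note records the models behind each analysis stage, the conventions
chosen where the field has no single standard, the defaults and their
units, what the synthetic generators do and do not emulate, and the known
limitations. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Structure model and PDB handling

Structures are a chain → residue → atom hierarchy with coordinates in Å.
Residue identity is the author key (chain id, author number, insertion
code), so positions keep the numbering used in the literature (e.g.
Thr85-style labels). Parsing is delegated to gemmi; writing emits
fixed-column ATOM/HETATM records with coordinates to 3 decimals, TER
between chains, END at the end. Only the PDB dialect is supported — every
structure relevant to this workflow is distributed as a 4-character PDB
entry — and mmCIF is out of scope.

Altloc duplicates are resolved at read time: default policy keeps the
highest-occupancy conformer, ties broken alphabetically by altloc id;
`keep-first` keeps file order. Hydrogens are parsed and retained but
excluded by the default heavy-atom selections, because docked and modelled
structures usually lack them and the contact criterion is conventionally
heavy-atom. MODEL-delimited files explode into separate structures in file
order. gemmi silently coerces malformed coordinate fields to zero, so a
cheap validation scan enforces the contract that a non-numeric coordinate
raises a parse error naming the line.

## Contact prevalence

A residue pair is in contact when the minimum distance between selected
atoms is ≤ the cutoff (default 3.0 Å, heavy atoms). Contact search uses a
k-d tree on the ligand atoms; the test suite proves exact equality with an
all-pairs distance scan on 1,000 random complexes, so the acceleration is
an implementation detail, not an approximation.

Prevalence is binary per pose: a residue touching the partner through four
atoms in one pose counts once. The denominator is all supplied poses.
Symmetry folding uses the union (OR) rule over the two subunit copies,
which requires per-pose membership, so profiles retain the pose index sets
rather than only marginal counts. Cross-ensemble averaging weights each
ensemble equally regardless of pose count and reports mean ± sample SD
(ddof = 1).

Domain localization ranks residues by mean prevalence (ties broken by
ascending chain, residue number — a determinism requirement), takes the
top k = 20, and reports each domain's share; the profile is "localized"
when the largest share reaches 0.8. Both constants are operational
defaults for the qualitative clustered-versus-scattered contrast and are
exposed in the configuration. The composite-site fraction calls a pose
composite when ≥ 3 contacting residues come from each of the two subunit
chains.

## Superposition, iRMSD, funnel, RMSF

Superposition is least-squares rigid (Kabsch) with reflections excluded;
the rotation comes from `scipy.spatial.transform.Rotation.align_vectors`
and the RMSD is recomputed from the transformed coordinates because the
solver's reported residual loses precision near zero. Degenerate
(collinear) point sets are rejected. The test suite checks agreement with
an independent closed-form quaternion (Horn) solver to 1e-6 Å.

The average complex superposes all poses onto pose 0 on receptor Cα
atoms and takes the per-atom coordinate mean. Mean structures can be
stereochemically unphysical, so the medoid pose (argmin of mean pairwise
RMSD over the superposed coordinates, no per-pair re-fitting) is reported
alongside as the robust representative.

Interface RMSD convention: interface residues are defined on the
*reference* as any residue with a heavy atom within 10 Å of the partner;
the pose is fitted to the reference on receptor Cα; the deviation is
measured over the union of receptor and ligand interface Cα atoms without
re-fitting on the interface set. This matches common docking-assessment
practice; cutoff, fit selection and measured selection are parameters.

Funnel criteria are deliberately operational: the cloud of (score, iRMSD)
points is a funnel iff the Spearman rank correlation is ≥ 0.4 *and* the
median iRMSD of the best-scoring decile lies below the global median.
Lower scores are better. Both thresholds are reported with the result and
configurable; they turn a visual judgement into a reproducible boolean.

RMSF aligns frames to the evolving mean structure by a 2-pass iterative
Kabsch fit on the selection (default Cα), then computes
RMSF_i = √⟨|x_i − x̄_i|²⟩. The fluctuation-alignment protocol is a choice,
not a standard; two passes are enough for the mean to stabilize on the
trajectories tested. The equilibration detector reports the earliest time
after which every sliding window (default 10 frames) of the RMSD trace
spans ≤ 0.5 Å; window and band are defaults for plateau-style language and
exposed as flags. The proximal-minus-distant RMSF delta maps each
interface residue of the partner-proximal subunit to its symmetry mate and
counts how many show lower fluctuation proximally.

## Interface evolution

Structure-to-alignment mapping is by gap skipping with strict sequence
agreement; the degapped alignment row must equal the structure sequence or
be a substring/superstring of it, and unmatched tails are reported rather
than dropped. If multiple placements are possible the first occurrence is
used.

A clade-specific call requires every clade row to share one non-gap,
non-X residue that occurs in *no* out-clade row; a gap in any clade row
disqualifies the column. A relaxed mode tolerates a configurable out-clade
frequency but is off by default — specificity claims should rest on the
strict rule.

Percent identity comes from a global (end-gap penalized) affine-gap
alignment implemented in-repo (Gotoh dynamic programming): BLOSUM62, gap
cost 10 + (k−1)·0.5 for a gap of length k. Identity = identical aligned
pairs / alignment columns, terminal gap columns excluded, X columns
excluded from numerator and denominator, reported to 1 decimal. Identity
values are convention-sensitive — different matrices, gap costs or
denominators shift the number by a few percent — so the convention is
fixed, declared, and cross-checked in the tests against an independent
aligner (Biopython `PairwiseAligner`) for the optimal score and against
exhaustive enumeration of all alignments on short sequences.

Isoelectric point: net charge Z(pH) over the free termini plus D, E, C, Y,
H, K, R side chains with the Bjellqvist pKa set (side chains K 10.0,
R 12.0, H 5.98, D 4.05, E 4.45, C 9.0, Y 10.0; residue-specific terminal
values), solved by bisection on [0, 14] to 1e-4 pH units. Cys is treated
as ionizable and disulfides are ignored; X contributes nothing. Z is
strictly decreasing in pH, so the root is unique.

## Binding kinetics

The single-site default is the exact ligand-depletion quadratic, not the
simple hyperbola, because the study conditions (probe 1 μM, K_D 13–23 μM)
put the probe concentration within an order of magnitude of K_D; the
depletion-free limit is verified to reduce to the hyperbola to < 0.1 % at
L = K_D/1000. Fits are nonlinear least squares from three deterministic
starts (midpoint K_D estimate ×{0.1, 1, 10}), keeping the lowest residual
sum of squares; no randomness enters any fit. Parameter standard errors
come from the Jacobian-based covariance at the optimum; the Monte-Carlo
tests check they agree with replicate scatter within a factor of 2. The
Hill coefficient is bounded to [0.2, 5] with a warning when pinned.

The displacement fit solves, per competitor concentration, the coupled
mass balance P = P_free + L·P_free/(K_L+P_free) + C·P_free/(K_C+P_free)
by bracketed root finding to 1e-9 μM, with the probe K_D fixed from a
prior direct titration, and fits the competitor K_D. EC50 is defined as
the competitor concentration at half-maximal bound-probe reduction,
obtained by bisection on the fitted model; a descending-logistic fallback
is available when no probe K_D exists.

Coupled-assay rates use NADH ε₃₄₀ = 6220 M⁻¹cm⁻¹ (standard constant) and a
user-selected linear window; automatic window detection is deliberately
out of scope. Rate (nmol/min) = |slope|/(ε·path) × volume, divided by
stoichiometry and enzyme mass for the specific activity. A positive slope
under the NADH-consumption convention triggers a warning, with a 1e-12
absolute tolerance so a flat trace does not.

## Synthetic data: what it does and does not show

The generators are pure functions of their arguments including the seed;
regeneration is byte-identical, and every planted truth is returned in a
sidecar record.

The structural generators use minimal residues — Cα plus one pseudo
side-chain atom per receptor residue, one atom per ligand residue — laid
out so that planted contact residues sit ≤ 2.6 Å from a ligand atom and
every other receptor residue ≥ 3.3 Å away, giving the 3.0 Å cutoff a
≥ 0.3 Å safety margin on both sides. The dimer's two chains are related by
an exact C2 rotation. Pose ensembles realize target frequencies as exact
counts (round(f·n) poses per residue, membership by seeded permutation),
so prevalence recovery is exact, with a Bernoulli mode for stochastic
tests. Trajectories add iid isotropic Gaussian displacements with
per-residue amplitude σ, for which the expected RMSF is σ√3; an optional
rigid drift exercises the alignment step. Alignments pin one out-clade row
to the column consensus so background substitution noise and gaps can
never fabricate a clade-specific column; planted columns satisfy the
strict call rule by construction. Titration curves come from the exact
forward models plus iid Gaussian noise.

Consequently, passing tests demonstrate that the *statistics* are computed
correctly, with calibrated recovery under the stated noise models. They do
not demonstrate robustness to the failure modes of real data: docking
decoys with correlated errors, anisotropic or multi-well protein dynamics,
alignment errors and paralog contamination, or instrument drift in
titrations. The generator parameters (30 poses per ensemble, 2 % titration
noise, 2,000-frame RMSF recovery, 200-replicate discrimination tests) are
fixed study conditions, not tuning knobs.

## Problem sizes

The shipped tests and the acceptance script run entirely on synthetic
inputs at these scales, chosen as the smallest sizes at which each
statistical claim is meaningful: 1,000 random complexes (≤ 500 atoms) for
contact-oracle equivalence; 30-pose ensembles for prevalence; 1,000 random
instances for superposition-oracle agreement; 2,000 frames for the RMSF
closed form; 200 seeded replicates each for funnel discrimination, noisy
K_D recovery, and lineage-call exactness.

## Known limitations

- No docking, MD, force-field, or free-energy computation: the package
  analyzes ensembles and trajectories produced elsewhere.
- PDB input only; no mmCIF, no compressed trajectory formats (ordered PDB
  frames stand in for trajectories).
- Percent identity and pI depend on declared conventions; comparisons
  against values computed under other conventions can differ by a few
  percent or a few tenths of a pH unit.
- The iRMSD convention (reference-defined interface, receptor-Cα fit) is
  one of several in use; numbers are not comparable across conventions.
- Sequence-mapping handles gaps but not rearrangements or chimeric rows.
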