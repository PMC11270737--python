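# Methods

## Scope and model of the data

The package analyses conformational ensembles of a short intrinsically
disordered peptide — the reference construct is the p53 C-terminal
regulatory region, residues 351–393 in author numbering (five
tetramerization-domain residues included at the N-terminal side), with up
to seven Ser/Thr phosphosites (366, 371, 376, 377, 378, 387, 392). An
ensemble is a sequence of frames (atoms × 3 coordinates, nm; times, ps);
the atom table carries author residue numbers, elements, and Bondi van der
Waals radii attached at read time. PDB files are in Å and are converted on
read/write; all internal units are nm, ps, degrees, kcal/mol (H-bond
energies) and kT (free energies). Ensembles are assumed whole: no periodic
boundary handling anywhere.

## Residue chemistry and charge accounting

Formal side-chain charges: K/R +1, D/E −1, phosphorylated S/T a
configurable integer, default −1. The monoanionic default reflects a
phosphate bearing one protic hydrogen and three oxygens of which one is
protonated; a −2 (dianionic) model is a parameter, not a code change.
Histidine is neutral by default at physiological pH. The construct's
43-residue sequence contains three histidines, and its conventional "+8"
net-charge bookkeeping is only reachable if they are protonated, while its
"15 charged species summing to +5" salt-bridge bookkeeping requires them
neutral; both conventions are therefore exposed (`his_protonation`) and
neither is guessed silently. Zwitterionic termini contribute net zero and
can optionally be included as two extra charged groups for contact
analysis. Charged-atom sets use standard PDB v3 naming (Lys NZ; Arg
NE/NH1/NH2; Asp OD1/OD2; Glu OE1/OE2; phospho-S/T O1P/O2P/O3P/OG(OG1);
N-terminus N; C-terminus O/OXT): the analyses only name charged species,
so the atom-level definition is a package choice.

## Synthetic ensembles: what they emulate and what they do not

Microsecond explicit-solvent trajectories are not reproducible at desk
scale, so the generators supply ensembles whose statistics are known
exactly; they are measurement standards, not simulations. They emulate
(i) a heteropolymer backbone with canonical Engh–Huber geometry (N–Cα
1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, ω = 180°), built from (φ, ψ) lists by
natural-extension (NeRF) placement, with amide H on the N-bisector at
1.0 Å and Cβ from the standard local-frame construction; (ii) dihedral
dynamics as a Markov chain over Ramachandran basins (one chain drives the
whole backbone; emitted angles are basin centers plus isotropic Gaussian
jitter, default 10–12°), giving exact stationary occupancies and a slowest
autocorrelation eigenvalue λ₂ known from the transition matrix; (iii)
ideal freely-jointed chains (⟨R²⟩ = Nb², ⟨Rg²⟩ = Nb²/6·(1 + 3/N) at finite
N), bond length defaulting to the Cα–Cα virtual bond 0.38 nm; (iv)
planted charged-pair contacts: exactly round(f·n_frames) frames place a
pair's groups below 0.8·cutoff and all other frames beyond 2·cutoff, in
staggered deterministic blocks, so recovered occupancy equals the plan
exactly. Default synthetic condition for the pipeline is a three-basin
model (PPII, α, β centers) with PPII-dominated transitions, the
qualitative regime expected for a disorder-promoting sequence.

What the generators do not emulate: sterics, solvent, realistic side-chain
packing (side chains beyond Cβ exist only for charged groups in the
contact scaffold), cooperative secondary-structure formation, or realistic
transition kinetics. Passing tests therefore demonstrate the estimators
are correct, not that MD observables are reproduced; headline MD ensemble
averages (mean EE_DIST, salt-bridge percentages, landscape shapes) are
outside what synthetic data can certify. A `pin_first` option fixes the
first residue across frames, emulating a terminally restrained chain;
otherwise frames receive random global rotations/translations so
orientation-dependent bugs cannot hide.

## Descriptors

R_G is mass-weighted by default (unweighted available); EE_DIST defaults
to the Cα atoms of the first and last residues — the literature rarely
names the end atoms, so the rule is configurable. RMSD uses the standard
3×3 covariance SVD with a determinant sign guard against reflections;
`superpose=False` gives the identity-alignment RMSD. Fewer than three
non-collinear atoms is rejected as ill-posed.

SASA is Shrake–Rupley with a deterministic golden-spiral point set
(default 960 points) on each expanded sphere (r + 0.14 nm probe);
neighbours are found with a k-d tree. On molecular totals, moving from 240
to 960 points changes results by well under 1%; pathological 5-atom
clusters with deep mutual overlap can differ a bit more, which is why
verification against the Monte-Carlo surface oracle uses a 2% band. The
phosphosite-excluding total (`total_sasa(..., exclude_sites=...)`)
implements the accounting in which condition comparisons are made over the
unmodified residues only; per-residue differencing aligns residues by
author number, deliberately comparing S against pS at the same position.

## Secondary structure

Hydrogen bonds use the classic electrostatic model,
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol (distances in
Å, energy clamped at −9.9), bond iff E < −0.5. The amide H is
reconstructed on the bisector of N→C(prev) and N→Cα at 1.0 Å when absent;
prolines and the N-terminal residue do not donate. Donor–acceptor pairs
separated by fewer than two residues are excluded, and pairs with
r_ON > 5.2 Å are skipped (the energy cannot reach the cutoff there).
Helices follow the n-turn patterns (two consecutive n-turns mark n
residues), priority H > G > I; strand residues come from parallel and
antiparallel bridge patterns, ladder-adjacent bridges scoring E and
isolated ones B; turns T from any n-turn interior; bends S from a Cα
pentapeptide kink > 70°. PPII (P) is assigned to runs of ≥ 2 consecutive
residues within ±29° of (φ, ψ) = (−75°, +145°) that are not already
helix/strand — P outranks T and S, since the PPII basin is a structural
state rather than a local irregularity. Phosphorylated residues are
reported as their own class X and never enter the structural classes:
this makes the phospho-class fraction exactly (#sites)/(#residues),
frame-independent, which is the arithmetic the composition table relies
on (1/43 = 2.33%, 7/43 = 16.3%). Whether a given MD tool's bend/turn
conventions match these defaults exactly cannot be settled from
composition tables alone; the defaults are the canonical ones.

## Ramachandran regions

The default priority-ordered table is P: φ∈[−110,−40), ψ∈[100,180];
β: φ∈[−180,−110), ψ∈[90,180]∪[−180,−160); α: φ∈[−120,−20), ψ∈[−80,30);
δ: φ∈[−180,−120), ψ∈[−90,60); L: φ∈[0,90), ψ∈[−30,90); γ: remaining
φ ≥ 0; other: remainder. Basin labels are conventional but their numeric
borders are not standardised, so the table is configuration, not code;
evaluation order guarantees a total, single-valued classification on
[−180,180)². Angles are degrees wrapped to [−180,180); terminal residues
carry undefined first-φ/last-ψ markers and are excluded from populations.

## Contacts

Group–group distance is the minimum over the two groups' atom pairs
(centroid mode optional); when a coarse synthetic chain lacks the charged
side-chain atoms the group falls back to Cβ, then Cα. Two cutoffs coexist
deliberately: 0.35 nm for salt-bridge statistics between oppositely
charged species, 0.30 nm for H-bond-style heatmaps; both configurable. No
angular criterion is applied. Because it is unstated whether an "average
occupancy" should run over all scored pairs or only pairs ever observed
bonded, `mean_occupancy(observed_only=...)` exports both reductions.

## Distribution summaries

Moments are population (bias-uncorrected) formulas; skew is Fisher's
moment coefficient and kurtosis is excess — near-Gaussian data then sit
near zero, which is how the reference tables read. FWHM defaults to the
Gaussian-equivalent 2√(2 ln 2)·σ: the reference tables' FWHM/variance
pairs satisfy this identity to printed precision on all rows, which is
what fixed the convention; a literal KDE half-maximum crossing width is
available (`fwhm_mode="kde"`). KDE bandwidth is Scott's rule. A constant
series has undefined shape moments; they are reported as 0.

## Landscapes

Features are (cos, sin) of every defined backbone dihedral, continuous
across the angular seam and bounded in [−1,1]. tICA solves
C(τ)v = λC(0)v with symmetrised (reversible) covariance estimates — a
choice made so eigenvalues are real, not a claim about the data's
reversibility — and an ε-ridge (default 1e−8) on C(0); a singular C(0)
without regularisation fails loudly. Components are C(0)-orthonormal, so
projections have unit instantaneous covariance. Implied timescales are
−τ/ln λ. Defaults: lag 100 frames for production data (tests use lag 1–5
at their frame counts), 2 retained components, matching a 2-D landscape.
The free-energy surface is −kT ln(ρ̂/ρ̂_max) from a 2-D Gaussian KDE on a
padded grid; the minimum is exactly 0 by normalisation and kT is a scale
parameter (298 K ≡ 1 kT unit). Clustering is Ward agglomerative (scipy
linkage) scanned over k ∈ [2,10]; silhouette and Davies–Bouldin are
computed in-package (cross-checked against scikit-learn in tests). When
the two metrics disagree on k, the silhouette wins and both are reported.
Clusters under 10 frames are dropped from the retained list but keep
their labels. Representatives are medoids in projected space, ties broken
by lowest frame index.

## Pipeline and reproducibility

`run_analysis` takes one JSON config (sequence, first residue, conditions
with phosphosite lists and trajectory sources, analysis parameters) with
exactly one control condition, and emits per-condition tables plus
condition-minus-control differences; a stage failure raises
`PipelineError` naming the stage and carrying partial results. All
randomness flows from explicit seeds; identical config and seed give
bit-identical bundles, and the report manifest records the config hash,
seed and package version. Default desk-scale problem sizes (tens to
hundreds of frames for full-coordinate analyses, 10⁵ frames for
angle-only spectral estimates, 240-point SASA spheres in the pipeline)
were chosen so each stage's estimator noise is far below its validation
tolerance. The crystal-check helper reports the construct end-to-end Cα
distance and a named Cα pair distance for any supplied single-frame
structure; it performs no fetching.

## Known limitations

- The DSSP-style assignment is a faithful re-derivation of the classic
  patterns but simplifies ladder/sheet bookkeeping (no sheet topology
  graphs, no π-helix beyond the I pattern).
- SASA supports atoms, not implicit hydrogens; synthetic chains carry only
  the atoms they declare.
- tICA assumes a single contiguous trajectory per condition; multiple
  replicates must be concatenated by the caller with care at the joins.
- The synthetic generators' realism limits are described above; no
  thermodynamic claim transfers from them to real MD data.
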