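# Methods

This note records the models, conventions and numerical choices behind
`tcrdockeval`, and what the synthetic verification does and does not
establish about real data.

## Evaluation model

A docking case consists of a bound reference TCR–pMHC complex, unbound
TCR and pMHC structures, and a rank-ordered set of docked models. The TCR
(chains D/E) is always the receptor and the pMHC (chains A/B/C) the
ligand. For MHC class I cases chain B holds β2-microglobulin; for class
II the A/B chains are the MHC α/β chains — one convention covers both.

For each model against the reference:

- **Contacts.** A residue pair is in contact when any heavy-atom distance
  is strictly below the cutoff. The native-contact cutoff defaults to
  5.0 Å (CAPRI convention). **F_nat** is the fraction of native
  receptor–ligand contacts reproduced; **F_non-nat** the fraction of the
  model's contacts absent from the native set (0 when the model has no
  contacts). Model contacts are computed over residues with a
  correspondence to the reference and compared in reference key space.
- **L-RMSD.** The model is superposed on the reference over the receptor
  backbone (N, CA, C, O) by least squares; the ligand backbone RMSD is
  then measured without re-fitting.
- **I-RMSD.** Interface residues are reference residues of either partner
  with any heavy atom within 10.0 Å of the other partner (CAPRI
  convention); the superposition and the RMSD both use those backbone
  atoms, and the reported value is the minimised one.
- **Quality classes** follow the standard CAPRI table (see README).
  Threshold comparisons are inclusive (≥ / ≤) exactly as tabulated;
  distance-based *selection* rules are strict (<).

Case **difficulty** superposes each unbound component onto its bound
counterpart over all mapped backbone atoms, measures the I-RMSD over the
bound interface backbone without re-fitting, and takes F_non-nat from the
contacts of the superposed-unbound pseudo-complex. Classes: rigid
(I-RMSD ≤ 1.5 Å and F_non-nat ≤ 0.4), medium (1.5 < I-RMSD ≤ 2.2 Å, or
I-RMSD ≤ 1.5 Å with F_non-nat > 0.4), difficult (I-RMSD > 2.2 Å).

## Superposition kernel

Rigid superposition is the SVD solution of the orthogonal Procrustes
problem with the determinant sign correction, so the returned rotation is
always proper (det +1 within 1e-8); no atom weighting is applied. Atom
correspondence is by (mapped residue key, atom name); atoms missing on
either side are dropped pairwise with a logged count. Fewer than three
pairs is an error; collinear point sets produce a warning (the rotation
about the line is undetermined) but a valid minimised RMSD.

## Correspondence and selection

Residue pairing uses global alignment with BLOSUM62, gap open −10,
extend −0.5 (configurable); identity is the fraction of aligned non-gap
columns that match, so residues unresolved in one structure do not
depress identity. Chain pairs below the identity floor (default 0.9)
raise an error naming the role. Among co-optimal alignments the aligner's
first traceback is taken, which is deterministic for fixed inputs.

CDR loops are fixed IMGT ranges 27–38 / 56–65 / 105–117; insertion-coded
residues inside a range belong to the loop. Framework = IMGT 1–128 minus
the CDR ranges; the constant domain (positions > 128) is excluded so
framework superposition is insensitive to TCR elbow-angle variation. Loop
RMSD superposes the frameworks of both TCR chains over backbone atoms and
measures the loop over all heavy atoms without re-fitting.

Structures are assumed IMGT-numbered; an optional TSV numbering map
(chain, author number, icode, IMGT number) renumbers structures that are
not.

## Clustering

FCC between two models is |A ∩ B| / |A| over their receptor–ligand
contact-pair sets — directional by construction. The pairwise similarity
is symmetrised as min(fcc(a,b), fcc(b,a)); this is the conservative
choice (both directions must agree) and can be switched to
either-direction. Greedy extraction picks the unassigned model with the
most unassigned neighbours (ties broken by better platform rank) as a
centroid; clusters below the minimum size (default 4) dissolve at the
end, so the output partitions the input and is deterministic. Cluster
ranking uses the mean of the best `top_k_for_score` (default 4) member
scores, lower-is-better, with ties broken by best single score then
lowest member rank.

## Synthetic generator

`make_reference` builds a toy complex from planar five-atom residues
(N, CA, C, O, CB; CB omitted for glycine) on a 3.8 Å CA lattice: an MHC
helix pair flanking the peptide at ±7 Å plus a groove floor deliberately
outside the 9 Å peptide shell (so scenario 2 has both selected and
unselected MHC residues), a β2m stand-in far below the groove, and two
TCR variable domains whose CDR3 tips sit directly above peptide residues
at the `interface_gap` distance (default 4.0 Å — below both the 4.5 Å
true-interface cutoff and the 5.0 Å contact cutoff, guaranteeing
non-empty scenario-4 selections and native contacts). Because all
intra-residue atom offsets are planar, the closest TCR–peptide approach
equals the gap exactly before jitter. A small seeded jitter (σ 0.08 Å)
makes different seeds genuinely different cases; sequences are drawn
uniformly from the twenty standard residues per seed.

`make_unbound` splits the reference, adds Gaussian noise (per coordinate)
to interface-residue atoms only, and re-poses each component with a
uniform random rotation (normalised-quaternion method) and translation.
σ = 0 reproduces the bound form (rigid); σ ≈ 1 Å lands in the medium
band; σ = 2.5 Å reliably exceeds the 2.2 Å difficult threshold.

`make_decoy` moves the ligand rigidly (rotation about a chosen axis
through the ligand interface centroid, then translation), leaving the
receptor untouched, so a pure translation of |t| gives L-RMSD = |t|
exactly. `make_decoy_set` realises an exact planted mixture of quality
classes by drawing per-class magnitudes from frozen ranges
(lateral shifts ≈ 0.2–0.6 Å for high, ≈ 2.3–3.2 Å for medium, twists of
≈ 28–45° for acceptable, ≥ 20 Å displacements for incorrect), verifying
each decoy with the full evaluation path and re-drawing on mismatch
(bounded retries); the verification loop makes the exact ranges
non-critical. Ranks are a seeded permutation and synthetic scores are
class-based means (−150/−120/−90/−40) with σ = 8 Gaussian noise, giving
the score–quality correlation that cluster ranking expects.

### What the synthetic data does not show

The toy geometry has no side chains, no secondary-structure realism, no
MHC–TCR contacts away from the peptide, and contact counts (~18 native
pairs) far below a real interface, so F_nat is much more granular than in
real cases. Passing tests therefore demonstrate correctness of the
metrics, selections, clustering and analytics — not docking realism, and
not the numerical values any real benchmark would produce. Published
success rates can only be reproduced by running the pipeline on the
actual benchmark structures and deposited model sets, which are external
downloads outside the test surface; because the exact F_nat/I-RMSD
cutoffs behind published figures are rarely stated, small per-case
deviations are expected even then.

## Problem sizes and runtime choices

Tests and the acceptance script use peptide length 9, helix length 12,
47-residue TCR domains, decoy sets of 8–50 models and cohorts of 10
cases — large enough that every code path (shells, gaps, dissolved
clusters, mixed mixtures) is exercised, small enough that brute-force
all-pairs oracles can verify every contact set and the whole suite runs
in seconds.

## Other numerical choices

- Altloc resolution keeps the highest-occupancy conformer, alphabetically
  first on ties; hydrogens and non-polymer heteroatoms are removed at
  clean time (all metrics are heavy-atom).
- Multi-model files contribute model 1 only.
- Random re-posing uses a 20 Å default translation bound — enough to
  scrub orientation bias; the magnitude is otherwise immaterial.
- Chain relabelling is two-phase (via private temporary IDs), so swapped
  source IDs (e.g. D/E reversed) cannot collide.
- Success percentages are reported to one decimal in tables; raw values
  are available from the functions.
- Cases with fewer than N models are evaluated over the models that
  exist rather than counted as automatic failures.
- Unique TCR/pMHC counting uses exact equality of concatenated chain
  sequences.
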