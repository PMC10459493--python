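# Methods

This note records the models, conventions and numerical choices behind
`peplib`, what the synthetic fixtures do and do not establish, and the design
decisions taken where the procedure was genuinely open.

## Library enumeration

A combinatorial library over an alphabet `A` (an ordered subset of the 20
canonical one-letter codes) at length `L` is the complete set of `|A|^L`
sequences.  Members are streamed in lexicographic order of the alphabet as
given; the ordering is a free choice (downstream statistics are
order-invariant) fixed for reproducible ranking tie-breaks.  Positions are
1-based, N→C.  For the canonical screen, `A = ACDEFGHIKLMNPQRSTVWY`, `L = 4`,
160,000 members, and every residue has frequency exactly 1/20 at every
position.

## Peptide molecules

Sequences become molecules as all-L free peptides: free N-terminal amine,
free C-terminal carboxylic acid, no capping — the display-library context
this models implies unmodified termini.  Glycine is achiral; everything else
is (S) at Cα.

**Ionization (pH 7.4)** is rule-based on dominant microstates: all
carboxylic acids deprotonated (C-terminus, Asp, Glu), all non-amide amines
protonated (N-terminus including N-terminal proline's secondary amine, Lys),
arginine guanidine protonated on the imine nitrogen; His (pKa ≈ 6), Cys,
Tyr, Ser, Thr neutral.  Net formal charge therefore equals
(#basic groups) − (#acidic groups).  This replaces a proprietary pKa-model
ionizer whose microstate choices (e.g. His tautomer) are not published; the
rules are the standard dominant species between roughly pH 5 and 9, and pH
enters only as a validity bound.

**Conformers** come from RDKit ETKDGv3 distance-geometry embedding with a
fixed random seed (identical seed ⇒ identical coordinates) followed by MMFF94
relaxation.  Invariants enforced: no two atoms closer than 0.7 Å, covalent
bonds within 0.8–2.0 Å.  Rotamer-library side-chain optimization used in the
original modelling chain is intentionally not reproduced; only the embedding
contract (one valid, reproducible low-energy conformer) is kept.

## Descriptors

* **Net charge** — Henderson–Hasselbalch sum over N-terminus, C-terminus and
  ionizable side chains (D, E, C, Y acidic; H, K, R basic):
  `z = Σ_b 1/(1+10^(pH−pKa_b)) − Σ_a 1/(1+10^(pKa_a−pH))`.
  The shipped default pKa table is the Lehninger-style free-amino-acid set
  (`src/peplib/data/pka_lehninger.csv`, versioned, swappable): N-term 9.69,
  C-term 2.34, D 3.65, E 4.25, C 8.30, Y 10.07, H 6.00, K 10.53, R 12.48.
  The complete-library mean at pH 7 with this table is 0.0068; published
  values near 0.006 depend on the (unpublished) table used, which is why the
  table is explicit data and the documented sensitivity source.
* **Molecular weight** — sum of standard average residue masses plus one
  water (Biopython); complete-library mean 493.55 g/mol.
* **Eisenberg hydrophobicity** — arithmetic mean over residues of the
  normalized consensus scale (Eisenberg et al. 1984, shipped as versioned
  data; the 20 values sum to 0.00, so the complete-library mean is exactly 0).
* **Crippen logP** — Wildman–Crippen atom-contribution sum on the neutral
  form (partition coefficients are defined for neutral species).
  Complete-library mean −1.608.
* **Rotatable bonds** — strict rotor definition: non-ring single bonds
  between two non-terminal heavy atoms, excluding amide C–N bonds and their
  amidine/guanidinium analogues (RDKit strict).  GGGG has 7 rotors (3 φ +
  4 Cα–C(O)); the complete-library mean is 14.25, matching the reported
  14.3 ± 2.4 for tetrapeptide libraries.  A definition that counts
  guanidinium C–N as rotatable (Arg 5 instead of 4 side-chain rotors) would
  give 15.0 and was rejected for that reason.
* **Panel extras** — TPSA, H-bond donors/acceptors, ring count (rings occur
  only in P, H, F, Y, W over the canonical alphabet; Trp contributes two)
  and heavy atoms, all on the neutral RDKit molecule.

**Positional additivity.** Every descriptor above is exactly additive in
per-position residue contributions — atom typing in the Crippen and rotor
definitions is local to each residue and unaffected by its neighbours (this
holds for proline contexts as well, verified numerically to 1e-14 at
machine precision over random tetrapeptides).  `library_mean_additive`
exploits this: the exact complete-library mean from `1 + L·|A|`
single-substitution evaluations instead of `|A|^L` molecules.  Tests always
re-validate additivity against brute force on a seeded sample before using
the shortcut; the acceptance script uses full brute force regardless.

**Streaming profiles** use Welford's one-pass mean/variance and fixed,
configurable histogram bin edges recorded in the output (the reference
histograms' binning is not published; defaults were chosen for comparable
granularity).  Out-of-range values are clipped into edge bins so counts sum
to n.

## Docking I/O

The docking engine itself (cavity mapping, GA/Monte-Carlo/simplex search,
SF3 scoring) is out of scope; the package emits its configuration and
consumes its output.

* **prm writer** — rDock/CmDock dialect with the `RbtLigandSiteMapper`
  section; defaults reproduce the published cavity: radius 4.0 Å around the
  reference ligand, small_sphere 1.0, min_volume 100, max_cavities 1,
  vol_incr 0.0, gridstep 0.5, RECEPTOR_FLEX 3.0, 100 runs.  Keys are written
  uppercase per the engine's own files; a round-trip parser ships with the
  module.
* **Scores** — lower is better (rDock convention); "highest-scored" peptides
  are the most negative.  Per peptide the best pose is the minimum score
  across runs — the engine's reported best; the aggregation is not stated in
  the reference protocol and minimum is the engine-faithful choice.  Ties
  break lexicographically by sequence, making rankings fully deterministic.
* **Convergence** — for each run budget r, the mean over sampled peptides of
  the best INTER score within the first r runs; pointwise a running minimum,
  hence monotone non-increasing.  The peptide sample (default fraction
  0.001) is drawn with a seeded generator.  No numeric convergence threshold
  is imposed; the curve is reported and the stopping criterion is the
  user's.
* **Surrogate scorer** — minus the weighted count of detected fingerprint
  interactions (H-bonds 1.0, hydrophobic 0.5, π-π 1.5, cation-π 1.0, salt
  bridge 2.0; weights arbitrary, documented, configurable).  It is **not**
  the SF3 scoring function and exists purely so the pipeline can run and be
  tested engine-free.  Poses outside an optional spherical cavity bound are
  flagged rejected.

## Interaction fingerprints

The fingerprint is a fixed-dimension vector over (receptor residue ×
interaction type) with six types.  The original analysis used a proprietary
fingerprint definition; here every criterion is explicit, configurable and
recorded with the output:

| type | criterion (defaults) |
|---|---|
| H-bond (either direction) | donor–acceptor heavy-atom distance ≤ 3.5 Å; D–H…A ≥ 120° when donor hydrogens have coordinates, distance-only otherwise |
| hydrophobic | apolar carbon (only C/H/S neighbours) pair ≤ 4.5 Å |
| π-π | ring-centroid distance ≤ 5.5 Å, interplanar angle ≤ 30° (parallel) or 60–90° (T-shaped) |
| cation-π | charged-group atom to ring centroid ≤ 6.0 Å, both directions |
| salt bridge | opposite formal-charge heavy atoms ≤ 4.0 Å, Asp/Glu/Lys/Arg side chains on the receptor side |

Receptor atoms are typed from residue/atom-name tables (backbone N donor
except proline, backbone O acceptor, side-chain donors/acceptors, apolar
carbons, aromatic rings of H/F/Y/W, charged side-chain groups at
physiological pH); ligand atoms from the RDKit connection table.  Crystal
structures usually lack hydrogens, so the receptor side runs in heavy-atom
fallback mode by default.  PDB author numbering is preserved verbatim and
alternate locations resolve to highest occupancy.  Detection is exhaustive
over atom pairs within cutoff and is tested against an independent
all-pairs nested-loop oracle, for rigid-body invariance, and for
monotonicity (tightening any cutoff never adds interactions).  The
fingerprint column universe is frozen at fit time as all residues with any
atom within 8 Å of any pose, so fingerprints align across a ligand set.
Water-mediated interactions, halogen bonds and metal coordination are not
modelled.

## Binding-mode clustering

Complete-linkage agglomerative clustering on Tanimoto (Jaccard) distance of
presence bits, cut at a threshold (default 0.6), was chosen because complete
linkage guarantees every intra-cluster pairwise distance is at or below the
threshold and makes outliers reproducible; the reference analysis clustered
binding modes partly by visual inspection, so its five-cluster partition is
a qualitative, not exact, reference.  Groups smaller than `min_size`
(default 2) are outliers — singleton binding modes mirror the screened
ligands that could not be assigned to any cluster.  Determinism: at equal
linkage distance the candidate pair with the lexicographically smallest
sorted member ids merges first, so the partition is independent of input
order; labels are assigned by decreasing cluster size.  Two all-zero
fingerprints have distance 0 by convention.  The implementation is
hand-rolled (~50 lines) because the tie rule is part of the contract;
scipy's complete linkage serves as the independent cross-check oracle on
tie-free data.

## Enrichment

Residue groups follow side-chain character: positive R/H/K, negative D/E,
polar uncharged S/T/N/Q, hydrophobic A/V/I/L/M/F/Y/W, and singleton groups
C, G, P — a partition of the alphabet, validated on construction.
Group-size normalization divides each group's positional frequency by its
member count (the substantive step) and then rescales to sum 1 per position
(a presentation choice; the reference bars do not state their rescaling).
Rest pooling is per position: residues occurring in fewer than `min_count`
(default 2) of the selected peptides pool into a "rest" key, conserving
total mass.  Descriptor comparison reports plain mean/sd shifts between
library, top-N and top-10 — deliberately no significance testing, matching
the descriptive character of the source analysis.  Motif containment is the
leftmost increasing index mapping of the query into the reference (greedy
scan, provably leftmost); it asserts subsequence structure, not binding.

## Synthetic fixtures — what green tests establish

The toy receptor is ten residue *fragments* (minimal atom sets) on a 14 Å
grid, each offering one interaction capability at an exclusive site, plus a
far-away decoy chain.  Poses are placed analytically: fragment geometries
(amine N–H at 2.9 Å/180°, formaldehyde O at 2.9 Å, methane C at 3.8 Å,
benzene stacked at 5.0 Å, quaternary N⁺ at 4.5 Å to centroids, charges at
3.8 Å) satisfy exactly the planted criteria and, by site isolation, nothing
else.  Scored SD files draw per-run scores from seeded `normal(true, 0.5)`
noise (sd arbitrary, documented) around planted values.  Green tests
therefore establish: geometric classification agrees with an independent
oracle, planted truths are recovered exactly, ranking/clustering machinery
is correct, and the pipeline is deterministic under a seed.  They do **not**
establish anything about real protein geometry, real docking scores, or the
specific top-100 composition of the published screen — those depend on a
stochastic 160k-ligand docking campaign and a proprietary fingerprint
definition, and reproducing them is explicitly out of scope.

## Numerical choices and degenerate inputs

Frequencies are fractions internally (percentages only at presentation);
raw positional frequencies sum to 1 within 1e-12.  Empty libraries, empty
streams, ragged sequence lengths, out-of-range positions/pH, non-partition
group schemes, unknown residues (reported with 1-based position), absent
chains (reported with available ones), malformed SD records (reported with
record index) and infeasible plants all raise early with specific messages.
Seeds are consumed through `numpy.random.default_rng` or explicit RDKit
seed parameters only; nothing reads global RNG state.

## Known limitations

* The ionizer is a two-state rule set: no tautomer or microstate
  populations, no pKa shifts from sequence context.
* Heavy-atom H-bond detection (no receptor hydrogens) cannot distinguish
  donor/acceptor ambiguity on His imidazole nitrogens.
* The surrogate scorer's scale is unrelated to binding free energy; only
  ordering within one fixture set is meaningful.
* Complete linkage is O(n³) as implemented — fine for the ≤ a few hundred
  ligands it is meant for, not for clustering whole libraries.
* The library-mean shortcut assumes positional additivity; it is validated
  at use, and brute force remains the fallback for any non-additive
  descriptor.
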