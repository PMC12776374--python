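# Methods

## Scope and model of the problem

The package evaluates predicted protein–ligand complexes against reference
(crystallographic) complexes, and predicted affinities/scores against
measured potencies. It does not generate predictions: co-folding models and
docking programs produce the structures, confidence vectors and scores this
pipeline consumes.

## Pose evaluation

**Template sanitization.** Predicted and reference ligand coordinates carry
no reliable chemistry, so both are validated against a template built from
the ligand's canonical SMILES: the SMILES is parsed, normalized (so e.g.
charged and uncharged nitro dialects collapse to one form), connectivity is
perceived from the coordinates, and bond orders/aromaticity are copied from
the template. An element-multiset mismatch is a template error; a perception
or valence failure is a sanitization error. Both are recorded per ligand and
never abort a batch, so batch accounting is exact:
sanitization failures + correspondence failures + evaluated = batch size.

**Correspondence and symmetry.** Both ligands are re-ordered into template
atom order, so the atom correspondence is the identity over template indices
and the template's graph automorphism group (enumerated with the molecule
matched onto itself, element- and bond-graph-preserving) applies to both
simultaneously. Enumeration is capped at 10,000 mappings; beyond the cap the
identity map is used with a warning. The cap is far above any drug-like
ligand's automorphism count.

**Superposition and RMSD.** Receptors are superposed over all common Cα
atoms, matched by (chain, author residue number); author numbering is the
canonical key throughout because binding-site residues are conventionally
cited that way (Phe156, Gly130). The fit is a proper-rotation Kabsch solve
(SVD with reflection correction). The ligand RMSD is then computed in the
receptor-aligned frame with **no ligand re-fitting** — the quantity measured
is where the predictor placed the ligand relative to the pocket, not whether
the ligand's internal geometry is right — minimized over the automorphism
group. Success requires both the center-of-mass gate (mass-weighted over
heavy atoms, threshold 2.5 Å) and RMSD < 2.0 Å. Geometric-centroid weighting
is available as config; mass weighting is the default reading of
"center of mass".

**Pocket states.** Two alternative binding-site conformations are called
geometrically. *Twisted*: after a local backbone superposition of residues
154–158, the angle between the residue-156 C=O vectors exceeds 90°.
*Open*: after global Cα superposition the Gly130 Cα is displaced by more
than 4 Å (half of the ~8 Å full loop motion). These thresholds are package
decisions — the underlying phenomena are described qualitatively in the
literature, and the 4 Å / 90° values sit far from both the ground-state noise
floor and the full-motion amplitude, so the calls are insensitive to small
threshold changes. Missing residues yield "unknown", never a silent guess.

**Hydrogen bonds.** A donor–acceptor pair (ligand N/O against backbone N as
donor and backbone O as acceptor, at residues 22, 23, 156, 157 by default) is
a hydrogen bond when the heavy-atom distance is ≤ 3.5 Å; a D–H···A angle
criterion (≥ 120°) applies only when explicit hydrogens exist. Heavy-atom
crystallographic and co-folded models are therefore handled in distance-only
mode, which is the common convention when protonation is not modeled.

## Confidence metrics

L-pLDDT is the unweighted arithmetic mean of per-atom pLDDT over ligand
atoms. L-PAE and mPAE average/minimize over "all PAE elements that involve a
ligand atom", read as the union of ligand rows and ligand columns with each
cell counted once (diagonal included). This union-once convention is
symmetric under PAE asymmetry and deterministic; a rows-only mode is provided
for sensitivity checks. Confidence files are validated at load time: a pLDDT
vector or PAE matrix whose length matches neither the heavy-atom count nor
the token count (one token per protein residue, then one per ligand heavy
atom — the co-folding convention) is an alignment error, never truncated.

## Chemical space

Fingerprints are Morgan radius-2, 2048-bit (the ECFP4 convention), with
Tanimoto similarity |A∩B|/|A∪B|. MCS uses element-exact atom comparison,
bond-order-insensitive bond comparison, and ring-atoms-match-ring-atoms;
MCS% divides the shared heavy-atom count by the larger molecule so the
measure is symmetric and bounded by 100. The per-pair timeout is 10 s with
the best-so-far reported on cancellation. Best-first clustering repeatedly
promotes the unassigned item with the most unassigned above-threshold
neighbors to cluster head (ties to the lowest index), which makes the
procedure deterministic and order-independent. The PCA embedding uses
concatenated rows of the MCS% and Tc pairwise matrices, column-standardized,
with the sign convention that each component's largest-magnitude loading is
positive. Training-set cutoff dates are explicit configuration; the default
cutoff for Boltz-2-style corpora is 2023-06-01 (where two published dates
disagree, the Methods-section date is taken, and the date is user-settable
precisely because of such ambiguities).

## Affinity evaluation

pIC50 = −log10(IC50 in molar). The pIC→kcal factor is ln(10)·R·T with
T = 298.15 K by default (≈1.364 kcal/mol per pIC unit), consistent with the
published 0.68 pIC ↔ 0.93 kcal pairing. Single-point displacement data are
converted to an apparent Ki through the one-site competitive interpolation
IC50 = C·(1−f)/f followed by Cheng–Prusoff division by (1+[S]/Km). The
[S]/Km defaults (0.5 for the σ2 assay at 1 μM probe; ≈2.846 for D4 at 10 μM)
are back-solved from the published 2.0 μM and 7.8 μM apparent-Ki cutoffs
because the assay constants themselves are not printed; they are explicit
per-target configuration and flagged as back-solved.

Calibration regresses measured on predicted (OLS), so calibrated predictions
live on the measured scale; in-sample RMSE cannot increase. The baseline MAE
is the mean absolute deviation about the dataset mean — identically the MAE
of a predict-the-mean predictor. False-positive affinity assignment supports
three schemes: drop inactives; assign all inactives 2× the threshold
concentration (optimistic bound); or draw inactive pKi uniformly between the
threshold pKi and 1.0 (100 mM), seeded and bit-reproducible.

Method comparison uses the tie-adjusted Friedman statistic on
within-compound ranks (complete cases only, dropped rows logged) and Conover
post-hoc pairwise t statistics on rank sums with the tie-adjusted pooled
variance and df = (n−1)(k−1). An all-tied matrix returns statistic 0 and
p = 1. Pairwise p-values are Holm–Bonferroni adjusted by default (plain
Bonferroni available). The Conover step is implemented in-package; the
omnibus statistic is cross-checked against scipy's Friedman test for k ≥ 3.

## Screen rescoring

Actives are labeled by strict inequality against the target's apparent-Ki
cutoff (records exactly at the cutoff are inactive, matching "<" cutoffs).
ROC AUC equals the normalized Mann–Whitney U with ties credited ½. KS
separation is the two-sample maximum ECDF gap with the asymptotic two-sided
p-value. Hit-rate curves sort the tested list best-first, slide a window
(defaults mirroring the published analyses: 100 for AmpC/σ2-sized lists,
50 for smaller ones) at stride 1, and report each window's active fraction
with a 95% Wilson interval at the pProp of the window-center rank. pProp is
computed within the tested list, not the full docked library. Stride 1 and
center anchoring are package decisions; the plateau behavior of such curves
is insensitive to either choice.

## Synthetic data: what it emulates, and what it does not

The generator provides every input the pipeline needs, with planted ground
truth:

* **Receptor** — an idealized helical backbone (N/CA/C/O) of 140 residues
  numbered from 20, with residues 22/23/129/130/156/157 named as in the Mac1
  convention, plus seeded 0.05 Å jitter. It exercises residue-keyed logic
  and superposition; it does not emulate real protein topology.
* **Ligand library** — four chemically disjoint cores (purine-like
  N-heteroaromatic, naphthalene, a cyclic sulfone ether, an acyclic amide)
  decorated with per-scaffold signature substituent elements (F/I, Cl/Br, O,
  N). Disjoint substituent alphabets keep between-scaffold MCS% below the
  35 threshold while the shared core keeps within-scaffold MCS% above it;
  the constraint is verified pair-by-pair at generation time and violators
  are regenerated. The default library is 40 ligands over 4 scaffolds, so
  best-first clustering has a known answer (exactly 4 chemotypes). The
  library matches the cluster statistics of a fragment-campaign dataset, not
  its pharmacophores or size distribution.
* **Poses** — perturbations with exact identity-map RMSD: `jitter`
  (rescaled i.i.d. Gaussian displacements), `translate` (rigid shift, COM
  distance equals the target exactly), and `rigid` (rotation about the
  centroid plus a translation solved in closed form, exploiting that
  centered-rotation and translation contributions to RMSD² are orthogonal).
  Rigid mode preserves internal geometry, so perturbed poses at any target
  RMSD still pass connectivity perception and template matching; it is the
  mode used for end-to-end recovery checks. The default pose ligand is
  asymmetric (trivial automorphism group) so the symmetry minimum equals the
  planted identity-map value. The predicted complex also receives a random
  global rigid motion that Cα superposition must undo.
* **Confidence** — scores = center + b·(−RMSD) + N(0, σ), with the slope b
  solved from the target correlation ρ given the fixed noise σ
  (b = ρ/√(1−ρ²)·σ/σ_RMSD); ρ and σ are not independent given a fixed
  slope, so the slope is the free parameter. Clipping to [0, 100] happens
  after correlation targeting and the clipped fraction is reported, keeping
  recovery tests honest.
* **Affinity** — predicted = slope·true + intercept + noise. The default
  scenario (slope 1, intercept +1.2, noise 0.3) mirrors a systematically
  over-potent predictor: raw MAE equals the bias, calibrated MAE falls to
  the noise level.
* **Hit lists** — actives ~ N(d, 1), inactives ~ N(0, 1), so the population
  AUC is Φ(d/√2); apparent Ki values are drawn log-uniformly on the correct
  side of the threshold. Real screen score distributions are neither Gaussian
  nor homoscedastic; the generator plants separation, not realism.

Passing tests on these fixtures demonstrates that the measurement machinery
is exact and unbiased under known ground truth. It does not demonstrate
anything about the accuracy of any particular predictor on real complexes,
nor about crystallographic noise, occupancy or alternate conformers, which
are deliberately not modeled.

## Numerical conventions and problem sizes

mmCIF output preserves coordinates to ~9 significant digits, so file-based
round trips of the pose pipeline are exact to well below 1e-6 Å; PDB output
is limited to the format's three decimals (~1e-3 Å) and is provided for
interoperability. Results CSVs encode missing values as empty cells and
round-trip numerics at 1e-9 (%.12g). All generators take explicit seeds and
are bit-reproducible; batch runs derive per-item seeds from the run seed.

Default verification sizes — 200 molecules for the symmetry-RMSD oracle,
300 (tests) / 100 (acceptance script) file-based pose pairs, 1,000 AUC
fixtures, 1,000 Wilson draws, n = 200 calibration, 5,000 + 5,000 screen
records — were chosen so each check's sampling error is far below its
assertion tolerance while the full suite stays fast on one CPU.

## Known limitations

* H-bond detection has no angular term without explicit hydrogens and no
  side-chain donors/acceptors beyond backbone atoms on the synthetic
  receptor; on real structures side-chain N/O of the residues of interest
  are compared by the same distance rule.
* The pocket-state calls are threshold classifiers, not conformational
  clustering; intermediate states map to "ground".
* MCS% depends on the matching parameterization; other choices (bond-order
  sensitivity, complete-rings-only) shift absolute percentages and are not
  exposed as defaults.
* The Conover post-hoc implementation assumes the Friedman rank model;
  for k = 2 it reduces to a sign-test-like comparison and the omnibus
  statistic is computed in-package rather than by scipy (which requires
  k ≥ 3).
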