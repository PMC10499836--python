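# Methods

## The rescoring model

The package operates on ensembles of rigid-body docking poses of an
antibody–antigen complex. The working assumptions are those of the underlying
approach: docking methods are good samplers and poor scorers, and a
structure-conditioned confidence model can re-assess pose plausibility
without co-evolutionary input.

Each pose is converted into a single-chain poly-alanine structure template.
Only backbone and Cβ atoms are retained (an inclusive atom mask over
N, CA, C, O, CB), every template residue is relabelled alanine, and the query
side carries the true merged sequence with a blanked single-row MSA. The
confidence metrics of the rebuilt model — mean pLDDT (local error) and
pTMscore (global fold) — are standardized within the ensemble of one system
and summed without weights:

    composite = z_pLDDT + z_pTMscore

Standardization makes the score system-independent; the unweighted sum
rewards models on which the two complementary metrics agree, which is the
regime associated with genuinely good poses. z-scores use the sample
(ddof = 1) standard deviation; this is a package choice (configurable), as
the convention is not fixed by the method description. A constant ensemble
maps to all-zero z-scores with a warning rather than an error so that pooling
never crashes on degenerate systems. Ensembles below 25 models trigger a
warning: standardized scores estimated from few models carry errors above
roughly one composite unit.

## Template preparation details

* **Chain merging.** Antibody chains first (heavy then light, as stored),
  antigen last; configurable. The linker strategy inserts 50 unknown (X)
  residues per boundary, carries no coordinates for them, and renumbers
  sequentially from 1 — which artificially joins the ends of unsolved loops;
  junction points are listed in a log warning. The gap strategy keeps only
  real residues and offsets each subsequent chain's numbering by 200; the gap
  is applied at **every** chain boundary (the alternative, a single gap, is a
  plausible reading — flagged here for anyone comparing against other
  implementations).
* **Poly-alanine mutation.** Residues keep exactly N, CA, C, O, CB. Glycines
  (and any residue lacking a Cβ but with a complete backbone) gain a
  constructed Cβ: the direction is the standard local-frame linear
  combination of the N→CA and CA→C vectors and their cross product
  (tetrahedral, L-chirality), renormalised to an exact 1.522 Å bond. Built
  from local difference vectors only, the construction is rigid-motion
  equivariant; backbone atoms are never moved (bitwise).
* **PDB output of merged templates.** ATOM records cannot represent atom-less
  residues, so linker residues are omitted from PDB output; their presence
  remains visible as a numbering gap. The feature bundle (JSON, schema
  version 1) is the lossless representation and the boundary of this
  package's responsibility — executing the network is out of scope.

## CAPRI evaluation

* Contacts are heavy-atom, cross-partner, at 5 Å, with ties at exactly the
  cutoff counted (closed interval). Hydrogens are dropped on read.
* The interface is defined on the reference structure only (10 Å heavy-atom
  criterion, both partners jointly); interface RMSD superposes the same atom
  selection it scores. The joint-partner fit is the implemented reading; a
  receptor-only fit would be a small variant.
* Ligand RMSD superposes the model antigen onto the reference antigen and
  reports antibody-atom RMSD without refitting.
* "Backbone" means N, CA, C, O; a CA-only mode exists for coarser analyses.
* Superposition is a Kabsch least-squares fit (SVD with proper-rotation
  correction); degenerate geometry (n < 3 or collinear points) is an error.
* Class thresholds (standard CAPRI criteria, not restated by the method
  description itself): High requires fnat ≥ 0.5 and (lRMSD ≤ 1.0 Å or
  iRMSD ≤ 1.0 Å); Medium fnat ≥ 0.3 and (lRMSD ≤ 5.0 or iRMSD ≤ 2.0);
  Acceptable fnat ≥ 0.1 and (lRMSD ≤ 10.0 or iRMSD ≤ 4.0); else Incorrect.
  Positive ⇔ at least Acceptable.
* Residue correspondence is by (chain, author number, insertion code); no
  sequence-alignment fallback, since model and reference share a sequence by
  construction.

## Enrichment analytics

* ROC AUC is the Mann–Whitney rank statistic (ties half-credit). A system
  with an empty class returns NaN — the "excluded" signal — so AUC sweeps
  filter rather than crash. Success curves, by contrast, include systems with
  no positives (they never succeed); this asymmetry is deliberate: AUC
  comparisons need both classes, success curves must show docking failures.
* Under the docking scheme, success labels come from the docking-generated
  model variant; under the composite scheme, from the rebuilt-model variant —
  each scheme is judged on the coordinates it would actually deliver.
* Separation is |median(pos) − median(neg)| divided by the pooled (all
  scores, ddof = 1) SD; a negatives-only SD denominator is available as an
  option since the choice of denominator is a convention.
* Precision curves smooth each class with a Gaussian KDE (Silverman
  bandwidth; default grid of 512 points over the data range ± 3 bandwidths)
  and form precision(t) = w⁺S⁺(t) / (w⁺S⁺(t) + w⁻S⁻(t)) from the survival
  masses above t weighted by class counts. The uncertainty band is the
  binomial standard error at the smoothed effective count above t; in sparse
  tails the band widens accordingly.
* Composition summaries report, per method and label variant, systems,
  models, positives with a 1-decimal percentage, negatives and the
  positives-per-system mean ± SD (1 decimal); a counts-only entry point
  (`summarize_counts`) performs the same arithmetic directly from published
  composition counts, where per-system SDs are not recoverable.

## Synthetic fixtures: what they emulate, and what they do not

Toy complexes are two ideal poly-alanine α-helices (φ = −57°, ψ = −47°,
standard bond lengths/angles, NeRF-built) placed in contact with at least
three 5 Å residue-contact pairs; the antigen orientation and approach vector
vary with the seed. Decoys perturb the antibody rigidly (antigen frame
fixed, mirroring the ligand-RMSD convention) along a frozen
rotation/translation ladder of 20 rungs calibrated once so that a default
50-model ensemble spans all four CAPRI classes while keeping positives
scarce (roughly 10–25%, in line with the positive-starved composition of
real docking decoy sets).

Mock confidence metrics use −log(1 + lRMSD) as the latent true-quality
score; each metric is `signal_strength × z(latent)` plus Gaussian noise, the
two noise components correlating at `agreement`, logistic-squashed into
(0, 1). Defaults — signal_strength 0.8, agreement 0.9, noise_sd 0.5 — were
chosen once as a plausible "informative but noisy confidence" regime and
frozen. The benchmark's docking scores are pure noise, an intentionally
information-free baseline.

What passing desk-scale tests therefore shows: the pipeline's plumbing,
metric definitions, standardization and ranking machinery behave correctly,
and a confidence signal correlated with true quality is provably recovered
by the composite score (and not fabricated when the signal is zero). What it
does not show: anything about real AF2 confidence behaviour on real
antibody–antigen interfaces — helical toy chains have no CDR loops, no
side-chain chemistry, no clash physics, and the synthetic "rebuild" step is
the identity, so the two quality-label variants coincide.

## Numerical choices and degenerate inputs

* Coordinates in Å; residue numbering 1-based; ranges closed.
* Altloc resolution: highest occupancy, ties by first altloc label
  alphabetically.
* Ranking is stable descending sort — equal scores keep input order,
  matching the cluster-size tie convention; NaN scores are an error.
* Pooling verifies that every method's scores are already standardized
  (mean ≈ 0 within tolerance 1e-8) and refuses otherwise; cluster sizes are
  standardized exactly like energies before pooling.
* pLDDT is accepted on the 0–1 or 0–100 convention and normalised on ingest
  (standardization makes this cosmetic).
* Generators are deterministic for fixed seeds (bitwise on one platform;
  coordinate tolerance 1e-9 across platforms).

## Known limitations

* No mmCIF input; no symmetry-unit reconstruction; no side-chain repacking.
* No DockQ continuous score; no symmetry correction of ligand RMSD for
  homo-oligomeric antigens.
* The feature bundle is this package's own schema, not any inference
  harness's internal layout; an adapter must map it (including the question
  of how X linker positions interact with residue-class bookkeeping, which
  is kept here as masked X positions).
* Acceptance-scale simulations use 20 systems × 50 decoys — small enough to
  run anywhere in seconds while leaving the signal/null contrast
  unambiguous.
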