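# Methods

`korscreen` re-implements, as an open and testable pipeline, a virtual-
screening strategy for discovering *nonbasic* kappa-opioid receptor (KOR)
agonists: ligands that, like the diterpene salvinorin A (SalA), carry no
protonatable amine and no formal charge, and therefore cannot form the
salt bridge to D138 that anchors classical opioids. The campaign modelled
here screens in two parallel arms — a structure-based 3D pharmacophore
match and a Gaussian shape/feature overlay, both seeded by a SalA binding
hypothesis — validates the queries against property-matched decoys by ROC
analysis, and triages the merged hit lists with charge/basicity and
physicochemical filters, fixed-frame pose re-scoring and binding-site
contact annotation.

## Pharmacophore model and matching

A query is a set of typed tolerance spheres (kinds HBA, HBD, HY, AR) plus
an exclusion-volume coat. Matching a ligand conformer proceeds by:

1. perceiving features on the conformer (rules below);
2. enumerating kind-compatible assignments of ligand features to query
   features, pruned by pairwise distance compatibility
   |d_query(i,j) − d_ligand(i,j)| ≤ r_i + r_j;
3. superposing matched ligand centers onto the query by closed-form
   least-squares rigid transforms (Kabsch; the reflection branch of the
   SVD is rejected so only proper rotations are returned);
4. accepting when every matched feature lies inside its tolerance sphere
   and no ligand heavy atom falls inside an exclusion sphere.

The fit score is

    S = 9·n_matched + Σ_f (1 − d_f / r_f)

The constant 9 dominates the fractional term (which is < 1 per feature),
so a match fulfilling more features always outranks a geometrically
tighter match fulfilling fewer; within equal cardinality, smaller
residuals win. This mirrors scoring-by-feature-fulfilment without claiming
to reproduce any proprietary formula. Full-match mode requires all
required features (all features when none are marked required); partial
mode maximizes S over subsets of size ≥ 1 and is what the score > 0
hit-retention rule operates on. Subsets are searched in decreasing
cardinality, which makes the search exact despite early termination: once
any subset of size k is feasible, no smaller subset can score higher.
Defaults: tolerance radius 1.5 Å for every kind, exclusion radius 1.0 Å —
conventional pharmacophore sphere sizes, both configurable. Acceptor
features are undirected spheres (no projected points). Pose re-scoring
reuses the matcher with the transform pinned to the identity, so residuals
are measured in the receptor frame.

## Feature perception

Perception is a declared convention (commercial toolkits do not publish
theirs), encoded as substructure rules:

* **HBA** — carbonyl O; hydroxyl O; aliphatic ether O *except* the sp3
  oxygen of an ester; nitrile N; aromatic N without H. Charged atoms never
  accept. Ester sp3 and aromatic ring oxygens are excluded because the
  SalA-derived query places its acceptors on carbonyl groups and the
  furan/ester ring oxygens are poor acceptors in practice.
* **HBD** — neutral N or O bearing at least one hydrogen.
* **HY** — "apolar" atoms are C, S and halogens not adjacent to a charged
  atom. Each ring whose atoms are all apolar contributes one feature at
  its centroid (a fused system yields one per ring, which prevents feature
  inflation); acyclic apolar atoms form bonded clusters, and clusters of
  ≥ 2 atoms contribute a centroid feature. A lone methane carbon is not a
  hydrophobic feature.
* **AR** — aromatic ring centroids.

Descriptors (MW, rotatable bonds with the amide C–N exclusion, Crippen
logP, net formal charge) come from RDKit, computed on the canonically
renumbered connection table so that atom input order cannot change any
value at the bit level; HBD/HBA *counts* reuse the perception rules above
so the decoy generator's windows and the 3D features agree on what counts
as an acceptor.

**Nonbasic filter.** A compound fails as *charged* if any atom carries a
formal charge, and as *basic* if it contains an aliphatic primary/
secondary/tertiary amine, an amidine or a guanidine — the classes
predicted protonated at pH 7 by structure alone. Amide, anilinic and
aromatic-ring nitrogens do not count. A pKa calculator is deliberately not
used: the filter is binary and structural, conformer-independent, and
easy to audit.

## Gaussian shape similarity

Each heavy atom contributes a spherical Gaussian of amplitude p = 2.70
and width α_i = π(3p/4π)^{2/3}/σ_i², σ_i its van der Waals radius (Bondi
table bundled), so an isolated atom's Gaussian volume equals its
hard-sphere volume. Overlap volumes are first-order (pairwise) only; the
second-order inclusion–exclusion correction is out of scope. Shape
Tanimoto is O_AB/(O_AA+O_BB−O_AB). Alignment initializes from centroid +
principal axes in all four proper sign combinations (plus any caller-
supplied transform, e.g. a pharmacophore alignment) and refines the six
rigid degrees of freedom with Nelder–Mead (rotation-vector parameterization
about the probe centroid, iteration cap 300, tolerance 1e-3); the result
is clamped to never fall below its best initialization. The "color" term
applies the same overlap formalism to same-kind perceived features (HBA,
HBD, AR, HY) as unit-width Gaussians (σ = 1.0 Å) under the shape-optimal
transform; combo = T_shape + T_color ∈ [0, 2]. Shape screening ranks by
combo and keeps the top 500 per library by default, matching common
practice for this screen type.

## Decoy generation

DUD-E-style selection without the web service: a universe candidate is
eligible for an active when it sits inside every property window
(MW ± 25 Da, logP ± 1.0, rotatable bonds ± 2, HBD ± 1, HBA ± 1, identical
net charge) and its Morgan fingerprint (radius 2, 2048 bits) Tanimoto to
that active is below 0.35. Each active draws k = 50 candidates without
replacement under a seeded RNG; a decoy claimed by an earlier active is
never reassigned, and an active with fewer than k eligible candidates
takes them all with a logged shortfall. The window sizes and cap are
declared defaults (the reference service's exact binning is version-
dependent) and all are configurable. Active-set curation implements the
stated rules: exact EC50 in nM, [35S]GTPγS functional assay, MW 300–500
Da, uncharged/nonbasic, de-duplicated by InChIKey, with per-stage counts
reported.

## Validation statistics

AUC uses the rank-sum (Mann–Whitney) estimator, ties counting one half —
identical to the trapezoidal ROC area, and cross-checked in the tests by
brute-force counting over all active–decoy pairs. The partially specified
validation rank list (82 actives vs 4100 decoys; decoys at ranks 59, 67,
74, 79, 83–86; straggler actives at 702, 848, 1476; 79 actives in the top
87) is materialized into a full label vector and its AUC computed exactly
with rational arithmetic: 0.9916, reported as 0.99 at the two-decimal
printing precision. The reconstruction is tie-free, on which the rank-sum
and trapezoidal estimators coincide, so the unstated choice between them
is immaterial. Sensitivity is reported at whole-percent rounding
(56/82 → 68%); enrichment factors use EF_f = (TP_f/n_f)/(P/N) at list
fractions 1% and 5%. The Cheng–Prusoff utility converts a competition
IC50 to Ki = IC50/(1 + L/K_d).

## Synthetic study set

No compound identities or coordinates are deposited for the original
campaign, so the generator *emulates the stated envelope* rather than any
real structure. Its defaults are the study conditions: 82 actives, 50
decoys per active, MW 300–500 Da, everything nonbasic.

* **Actives** are substituted 2-hydroxy-anthraquinones: a rigid tricyclic
  core carrying two ring carbonyl acceptors, one phenolic acceptor/donor
  and three ring hydrophobes, decorated at up to three positions with
  F/Cl/Br/I/CH₃/OCH₃ to spread molecular weight across the curation
  window. The set is an even stride over the canonical-SMILES-sorted
  enumeration, so it spans the property window instead of clustering.
  Because the feature-bearing core is rigid and shared, every active's
  embedded conformer satisfies the reference query — retrieval of 100% of
  constructed actives is a designed property, and the fixture ROC
  experiment separates actives from decoys essentially perfectly. Real
  screens face flexible molecules and imperfect queries; passing these
  tests demonstrates the machinery, not real-world enrichment.
* **The decoy universe** enumerates six different rigid oxygen-rich
  scaffold families (hydroxy-xanthones, -fluorenones, flavones,
  aroyl-coumarins, benzofuran ketones, hydroxy-benzophenones) with the
  same substituent chemistry, giving matched property ranges with
  different topology (anthraquinone–xanthone Morgan Tanimoto ≈ 0.26) and
  scrambled 3D feature geometry. At the default enumeration depth the
  universe (~12k compounds) supports 50 decoys per active for all 82
  actives with no shortfall across seeds.
* **The reference query** ("sala_kor_reduced") is built from the template
  active's embedded conformer: three HY ring features plus the acceptor
  triplet, labelled C1/C2/C4 by analogy to SalA's three substituent
  carbonyls; the reduced form drops C2, mirroring the query-reduction
  experiment, and carries two exclusion spheres 5 Å above and below the
  ring plane. Its coordinates are a geometric stand-in, not the published
  model, so absolute hit lists are not comparable to the original
  campaign's.
* **The pocket fixture** places invented but geometrically plausible side
  chains for Q115, V118, Y139, Y312, Y313 around the template pose, with
  one tyrosine hydroxyl at hydrogen-bond distance (2.8 Å) of a ligand
  carbonyl. It exercises contact detection only; it is not a receptor
  model.

Conformers are embedded with ETKDG using a per-molecule seed derived by
hashing (global seed, molecule id), then MMFF94-minimized; identical specs
give byte-identical fixtures.

## Triage

Hit lists merge by InChIKey, keeping each method's best score and
recording the origin (the overlap between arms is reported, never
assumed). Filters — charged, basic, MW > 500 Da, rotatable bonds > 10 —
are independent structural predicates, so they commute; boundary values
(MW = 500, RotB = 10) pass, matching the ≤ convention. Pose re-scoring is
the fixed-frame partial match with the score > 0 retention rule, flagging
whether the C2-analogue acceptor is fulfilled. Contacts are distance
criteria: hydrogen bond when a ligand acceptor/donor heavy atom is within
3.5 Å of a receptor N/O (distance-only, as no explicit hydrogens are
present in either partner; the 120° angle criterion would apply were they
available), hydrophobic when apolar carbons are within 4.5 Å. The final
"manual selection" of the original campaign is intentionally not
automated: the pipeline emits a ranked table with pose score, shape combo,
C2 flag, contact summary and descriptors as sortable columns.

## Problem sizes and numerical choices

The analysis drivers run at desk scale by choice: the decoy generation
runs at the full 82 × 50 study size; ROC screening uses a 300-decoy
subsample; the end-to-end pipeline demonstration uses 20 actives with a
capped shape arm (the shape optimizer, at a few seconds per molecule,
dominates runtime and its behaviour is size-independent). Degenerate
inputs are defined errors: empty queries, empty libraries, single-class
ROC input, zero-radius spheres and inconsistent rank lists all raise
validation errors rather than returning values. Ties in every ranking are
broken by molecule id ascending, so all outputs are deterministic under a
fixed seed.

## Known limitations

* No tautomer enumeration, pKa prediction, or stereo-aware conformer
  ranking; flexible (minimizing) pharmacophore matching is out of scope.
* Docking pose generation is external by design; poses arrive as SDF in
  the receptor frame.
* The campaign-scale hit counts (250/2000/1821/15), the pharmacophore-arm
  AUC of 0.85, and the discovered compounds' affinities depend on
  proprietary software, commercial libraries and wet-lab assays and are
  not reproducible here; the pipeline reproduces the reconstructable
  summaries (rank-list AUC 0.99, 79-in-87, 68% sensitivity/11 FP, the
  4100-decoy accounting, the 1.44% natural-product share) and the
  method-level properties.
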