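# Methods

## The screen

Some carbohydrate-binding modules of family 2 (CBM2), when tethered to
bacterial AA10 lytic polysaccharide monooxygenases (LPMOs), carry a
surface copper-binding site built from two methionines and a histidine
(the MMH motif; Met266/Met286/His288 in ScLPMO10C numbering). `cbmscreen`
implements the discovery screen for such sites and the quantitative-assay
analyses used to characterise them.

The screen runs in five stages:

1. **Sequence intake.** Protein FASTA plus a TSV domain table
   (`protein_id`, `family`, `start`, `end`, coordinates 1-based inclusive).
   Exact duplicate sequences are removed, keeping the first occurrence.
   Identity clustering below 100% is deliberately out of scope — it belongs
   to external tools — so "duplicate" means full-string equality of the
   uppercased sequence.
2. **Domain extraction.** Annotated CBM2 and AA10 ranges are sliced out of
   the full proteins; scanning never runs on whole sequences, only on
   domain subsequences.
3. **Motif grammar scan.** MMH in CBM2 domains: Met, any gap, Met, exactly
   one residue, His (regular expression `M.*M.H`). REF in AA10 domains:
   Arg, 3–10 residue gap, Glu, one residue, Phe (`RX(3,10)EXF`), the
   second-coordination-sphere signature of strict C1-oxidizing
   cellulose-active AA10s. Patterns are data (`MotifPattern`), so extended
   grammars can be supplied; the shipped four-anchor MMHH pattern (M, gap,
   M, one residue, H, one residue, H) is flagged experimental because no
   authoritative spacing exists for it. The scanner enumerates *all*
   anchor-position tuples; counting uses presence per domain, and the
   canonical hit (smallest last anchor, then smallest first anchor) is the
   deterministic representative used downstream. Non-canonical residues
   (X, B, Z) never match an anchor letter.
4. **Geometric confirmation.** A regex match is only sequence order; the
   copper site is a geometric claim. On a Cα-only model of the protein the
   verifier searches the CBM2 residue range for a Met/Met/His triplet with
   all three pairwise Cα–Cα distances ≤ 8.5 Å. Proteins without a model
   are *unverified*: excluded from confirmed counts and emitted on a review
   list, never auto-resolved.
5. **Co-occurrence, trees, accounting.** Reference residue positions are
   mapped through an MSA to columns, residue combinations at those columns
   are tallied (gaps render as `-`, unknowns as `X`), motif classes
   (`REF-MMH`, `MMH-only`, `REF-only`, `none`) are painted onto Newick tree
   tips, and the screen totals become a `ScreenReport` whose percentages
   are always recomputed from the integer counts (half-up rounding, one
   decimal or integer precision).

## Interpretation choices the data did not fix

* **"Within 8.5 Å"** is read in its strictest form: all three pairwise
  distances ≤ threshold (`geometry_mode="all_pairs"`). The weaker reading —
  each Met within threshold of the His only — is available as
  `pair_to_his` because the phrase is genuinely ambiguous.
* **Search space of the triplet.** The verifier defaults to the whole CBM2
  range (`anchor_mode="whole_domain"`): the geometric search is a fresh
  question, not a re-check of the regex anchors. `regex_anchors` restricts
  to the scanned positions for users who want the tighter coupling.
* **REF multiplicity** is treated as presence/absence per domain.
* **Second-order regression** keeps a free intercept; forcing through the
  origin is an option (`through_origin=True`). Under pure pseudo-first-order
  behaviour the intercept estimates 0 anyway.
* **Ambiguous denominators** (e.g. a clade fraction that can be read
  against all clade members or only the CBM2-carrying ones) are never
  resolved silently: the run report exposes the alternate
  numerator/denominator pairings side by side.

## Assay analyses

* **Linear calibration** (BCS copper standards 0–8 μM; A255 ascorbate
  standards): ordinary least squares, inverted for unknowns. No slope sign
  is assumed — a quenching probe fits a negative slope. Responses outside
  the standard range warn (extrapolation); negative concentrations clip to
  0 with a warning.
* **Copper stoichiometry**: bound = total − free, normalised per μM CBM
  (the 4 μM CBM / 8 μM Cu design). `free > total` within 0.5 μM is treated
  as calibration noise and clipped; beyond that it is a calibration fault
  and an error.
* **One-site binding** [P_bound] = B_max·[P_free]/(K_d + [P_free]):
  Levenberg–Marquardt least squares on (log K_d, log B_max) with an
  analytic Jacobian — the log parameterisation enforces positivity without
  bounds. Start values are derivative-free and deterministic: B_max from
  1.05× the largest observed bound value, K_d from the first concentration
  reaching half of that. A fit whose data never reach the fitted K_d sets
  a saturation warning.
* **Stopped-flow traces** y(t) = a·t + b + c·e^(−k_obs·t): same solver,
  k_obs in log space, amplitude sign free (rise for reduction, decay for
  oxidation). Initialisation: drift slope a from OLS on the last quartile,
  offset b from the drift-corrected last-quartile mean, amplitude c from
  the first sample, k_obs from a log-linear regression of the residual
  magnitude over the first half. A trace indistinguishable from pure drift
  (fitted |c| < 10⁻⁶ of the signal range) is rejected as degenerate rather
  than returning a meaningless rate. `drift=False` pins a = 0 for traces
  known to be drift-free.
* **Second-order constants**: k_app is the OLS slope of k_obs against
  reagent concentration in M. Standard errors for all nonlinear parameters
  come from the Jacobian at the optimum (delta method back from log scale);
  for OLS stages they are the closed-form regression errors.
* **Linear-phase rates**: OLS slope over a 0–120 min window by default; an
  automatic mode takes the longest series prefix keeping R² ≥ 0.98 (at
  least 3 points). The stop rule trails slightly past a sharp kink — the
  prefix R² degrades gradually — which is the expected behaviour of any
  prefix-R² criterion.
* **Depletion time**: first time the calibrated concentration falls below
  5% of its initial value, linearly interpolated between samples, requiring
  two consecutive sub-threshold samples so a single noise dip does not
  count. A flat control never "depletes".
* **Replicates**: fits run per replicate; reported values are mean ± SD
  across replicates (n = 3 convention).

Convergence contract for the nonlinear solver: relative parameter change
below 1e-10 or relative residual change below 1e-12, at most ~500
iterations; non-convergence raises, it never returns a silent best-effort.
On noiseless inputs all fitters recover generating parameters to better
than 1e-6 relative (asserted in the test suite).

## The synthetic benchmark

Every input has a generator that also writes a machine-readable truth
ledger; all pipeline-level tests compare against the ledger, never against
re-derived values. Generators are pure functions of their seed (default
20251124): reruns are byte-identical.

**Sequences.** Each protein is AA10 (200 aa) + linker (20 aa) + CBM2
(100 aa, mirroring the 102-residue ScCBM2 263–364 span). Background
residues are uniform over the 20 amino acids with Met/His/Arg/Glu/Phe
down-weighted ×0.5 — spurious regex hits are wanted (they exercise the
geometric filter) but kept rare. Planted MMH anchors sit at
domain-relative positions 4/24/26, the Met266/Met286/His288 layout of a
domain starting at 263. Domains not meant to carry a motif are scrubbed of
accidental regex matches, and a fraction of negatives carries near-miss
decoys (M..M without the trailing `.H`; REF spaced 2 or 11, just outside
the 3–10 bound).

**Structures.** Cα-only chains written as fixed-width PDB ATOM records.
Non-motif residues follow a self-avoiding random walk with 3.8 Å steps.
The planted triplet's triangle carries designed pairwise distances:
all U(4, 8) Å for geometry-consistent positives; one pair U(9.5, 15) Å for
violators, so violators fail at 8.5 Å but still pass at 20 Å. Every other
Met/His Cα inside the CBM2 range is parked on a ≥ 12 Å lattice, so no
spurious triplet can pass and the geometric verdict equals the planted
label by construction. This is the one place the generator is *not*
physically realistic: geometry is planted, not folded, and chain
continuity is broken around the relocated residues. Consequently a perfect
confusion matrix on this benchmark demonstrates the correctness of the
scanning and verification logic — not robustness to the messiness of real
predicted models (low-confidence regions, missing residues, alternative
conformations).

**Assays.** Isotherms use the published protein grid (0, 10, 25, 50, 75,
150, 300, 500 μg/mL) expressed in μM via an ScCBM2-like molar mass of
10.8 kDa (102 residues), giving free concentrations up to ≈ 46 μM around a
K_d of 3.7 μM; noise is Gaussian, 2% of B_max by convention. Stopped-flow
traces are generated per concentration (ascorbate 25–800 μM, H2O2
50–1600 μM after mixing) with k_obs = k_app·C, 200 points over six
half-lives, 1% amplitude Gaussian noise, three replicates. Depletion
series decay exponentially with the closed-form crossing time stored in
the truth. The generated traces carry no instrument drift; accordingly the
benchmark analyses fit them with `drift=False`, while the drift term stays
on by default for real traces.

## Problem sizes and known limitations

The shipped benchmark sizes — 200 proteins, 200-point traces, three
replicates, 200 random structures for the oracle comparison — keep a full
test run in the tens of seconds while leaving every estimate comfortably
identified; they are the package's own choice of a desk-scale experiment.

One statistical caveat is worth stating explicitly. In the stopped-flow
regression the k_obs estimation error grows proportionally with
concentration (each trace spans a fixed number of its own half-lives), so
the points with the largest leverage also carry the largest error. The
closed-form OLS slope SE does not account for this heteroscedasticity and
understates the seed-to-seed spread of the slope by roughly 1.5–2×; a
"within 2 SE" band around the generating constant therefore covers only
≈ 70–80% of seeds even though the estimator is unbiased (the slope itself
stays within ~1% of truth). This is a property of unweighted
pseudo-first-order designs generally, not of this implementation; weighted
regression would fix it but the unweighted fit is the field's standard
analysis and is what this package implements.

Other limitations: no mmCIF input, no sidechain-atom (SD/NE2) distance
criteria, no pLDDT filtering, no profile-HMM scanning, no global
multi-trace fitting, and no tree inference or graphics — tip annotations
are tables meant for external colouring tools.
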