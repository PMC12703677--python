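# cbmscreen

Discovery screen for copper-binding **MMH motifs** in family-2
carbohydrate-binding modules (CBM2) tethered to bacterial AA10 lytic
polysaccharide monooxygenases (LPMOs), plus the quantitative-assay
analyses used to characterise the sites. Built for protein
bioinformaticians and enzymologists who have domain-annotated sequence
sets, predicted structures and plate/stopped-flow data, and want a
reproducible, tested pipeline instead of a notebook.

## What it computes

**Screen.** CBM2 domains are scanned with the motif grammar
`M.*M.H` — Met, any gap, Met, exactly one residue, His (the
Met266/Met286/His288 site in ScLPMO10C numbering) — and AA10 catalytic
domains with `RX(3,10)EXF`, the second-sphere Arg–Glu–Phe signature of
strict C1-oxidizing cellulose-active LPMOs. Regex hits are then confirmed
geometrically: two methionines and a histidine whose pairwise Cα–Cα
distances are all ≤ 8.5 Å on a predicted model. Confirmed proteins are
classified by motif co-occurrence (`REF-MMH`, `MMH-only`, `REF-only`,
`none`), mapped onto alignments and phylogenetic trees, and totalled in a
screen report whose percentages are recomputed from counts.

**Assays.** One-site binding
`[P_bound] = B_max·[P_free]/(K_d + [P_free])` (nonlinear least squares,
log-parameterised for positivity); stopped-flow traces
`y(t) = a·t + b + c·e^(−k_obs·t)` per reagent concentration, with the
apparent second-order rate constant `k_app` as the OLS slope of `k_obs`
vs concentration (M⁻¹ s⁻¹); linear standard curves and their inversion;
copper-binding stoichiometry `(Cu_total − Cu_free)/[CBM]`; linear-phase
rates; reductant-depletion times.

**Synthetic benchmark.** Every input can be generated with a known truth
ledger (planted motifs with label-consistent 3-D geometry, isotherms,
traces, standards), so the whole pipeline is testable end to end without
any database downloads. See `docs/methods.md` for the model details and
design decisions.

## Worked example

Generate a 200-protein benchmark with 25% planted MMH sites (one fifth of
them geometry-violating decoys) and run the screen:

```python
import cbmscreen as cs

ds = cs.gen_domain_dataset(n_proteins=200, mmh_fraction=0.25,
                           ref_fraction=0.5, seed=20251124)
paths = ds.write("demo/input")
cs.gen_structures(ds, seed=20251124, out_dir="demo/structures")

res = cs.run_screen(cs.RunConfig(fasta=str(paths["fasta"]),
                                 domains=str(paths["domains"]),
                                 structures_dir="demo/structures",
                                 out_dir="demo/out"))
print(res.report.to_dict()["counts"])
```

```
{'retrieved': 200, 'unique': 200, 'regex_hits': 50, 'confirmed': 40,
 'aa10_linked': 40, 'cbm2_only': 0, 'ref_positive': 17}
```

50 proteins carry the sequence motif; the geometric filter removes the 10
planted decoys, leaving exactly the 40 truth-positive sites (precision and
recall 1.0 against the ledger), 17 of which co-occur with a REF-positive
AA10. The same pipeline is available from the shell
(`cbmscreen run --fasta … --domains … --structures-dir … --out-dir …`),
along with `scan`, `verify`, `cooccur`, `classify`, `report`,
`fit-binding`, `fit-kinetics`, `fit-calibration`, `depletion` and
`simulate` subcommands.

Screen accounting from explicit totals:

```bash
cbmscreen report --retrieved 26436 --unique 25466 --regex-hits 713 \
  --aa10-linked 649 --cbm2-only 34 --ref-positive 644
```

prints percentages recomputed from the counts — MMH occurrence 2.7%
(683/25,466), AA10 association 95.0% (649/683), REF fraction 99.2%
(644/649).

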