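# ecadscreen

Analysis pipeline for image-based, genome-wide siRNA screens of
**membrane-associated E-cadherin**, modelled on a high-content screen in
*APC*-mutant SW480 colorectal cancer cells. Loss of APC lowers E-cadherin at
adherens junctions; knocking down a gene that *represses* junctional
E-cadherin (such as *ZEB1*) raises it, and knocking down a gene *required*
for it (such as *CDH1* itself, or *CTNNA1*/*CTNND1*) lowers it. The package
is for screeners and image-analysis developers who want the complete,
tested decision cascade of such a screen - from raw two-channel field
images to validated regulator lists - plus a synthetic-data generator with
exact ground truth, so every stage can be exercised and benchmarked without
any proprietary screen data.

## The quantities and rules

* **Ecad score** - for each well, elongated "fibre-like" E-cadherin
  structures are detected inside a whole-cell mask (nuclei from the Hoechst
  channel, dilated by a ring) and counted; the score is
  `total fibres / total cells` over all fields of the well.
* **Acquisition rule** - fields are imaged until 3000 cells are reached, at
  most 25 fields, stopping early after a run of more than 6 consecutive
  sparse fields (< 14 cells). Mock wells average ~20 fields.
* **Normalization** - duplicate plates are averaged; each well is divided
  by its plate's mock-well mean (fold-to-mock); folds are standardized
  across the screen with a robust Z-score, `z = (x - median) / (1.4826 * MAD)`.
* **Viability bins** - cell-count fold >= 0.7 is CV1, 0.5-0.7 is CV2, and
  < 0.5 (i.e. < 1500 cells in 25 fields) is LC: pro-survival genes,
  excluded from E-cadherin candidacy. Genes reaching the cell target two
  SDs faster than mock (< 15 FOV) with an unchanged Ecad score are
  anti-proliferative.
* **Candidate bins** - Ecad fold >= 1.6 is High (siZEB1-like), <= 0.2 is
  Low (siCDH1-like); the equivalent robust-Z cutoffs (5.16 and 0.036) are
  reported for audit. Genes with RPKM < 1 in the assay line are removed.
* **miR-200 seed filter** - a duplex whose guide-strand positions 2-8 equal
  a miR-200-family seed (`AAUACUG` or `AACACUG`, miRBase v19) can mimic the
  family's E-cadherin induction off-target; seed-carrying Ecad-High pools
  are excluded, unless deconvolution later shows >= 2 active duplexes of
  which >= 1 is seed-free.
* **Deconvolution validation** - each candidate's four duplexes are tested
  individually: *active* means a one-tailed unpaired t-test against mock is
  significant (alpha 0.05) **and** the duplex mean fold clears the class
  threshold. A gene validates with >= 2 of 4 active duplexes; validated
  Ecad-High genes are negative regulators, Ecad-Low genes positive
  regulators.

## Worked example

```python
from ecadscreen import ScreenConfig, run_synthetic_screen
from ecadscreen.simulate import ecad_up_gene, ecad_down_gene, toxic_gene, null_gene

specs = (
    [ecad_up_gene(f"UP{i}", fold=2.0) for i in range(3)]    # Ecad raised 2x
    + [ecad_down_gene(f"DN{i}", fold=0.1) for i in range(3)]  # Ecad lost
    + [toxic_gene("TOX0")]                                   # kills cells
    + [null_gene(f"NULL{i}") for i in range(43)]
)
results, truth = run_synthetic_screen(specs, ScreenConfig(), noise_sd=0.1, seed=1)
print("negative regulators:", results.negative_regulators)
print("positive regulators:", results.positive_regulators)
f = results.funnel
print(f"funnel: {f['n_genes']} genes -> {f['n_lc_excluded']} LC-excluded, "
      f"{f['n_ecad_high']} Ecad-High, {f['n_ecad_low']} Ecad-Low, "
      f"{f['n_deconvolved']} deconvolved, {f['n_validated']} validated")
```

prints

```
negative regulators: ['UP0', 'UP1', 'UP2']
positive regulators: ['DN0', 'DN1', 'DN2']
funnel: 50 genes -> 1 LC-excluded, 3 Ecad-High, 3 Ecad-Low, 6 deconvolved, 6 validated
```

All three planted Ecad-raising genes come back as negative regulators and
all three Ecad-lowering genes as positive regulators; the toxic gene is the
one LC exclusion (flagged pro-survival), and no null gene validates.

The same stages are available from the shell:

```sh
ecadscreen simulate --seed 5 --genes 40 --out screen/
ecadscreen normalize --wells-a screen/wells_repA.csv --wells-b screen/wells_repB.csv --out scores.csv
ecadscreen call-hits --wells-a screen/wells_repA.csv --wells-b screen/wells_repB.csv \
    --expression screen/expression_rpkm.csv --out report.csv --report funnel.json
```

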