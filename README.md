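# utrtune

Design and quantification pipeline for synthetic 5′-UTR RNA hairpins
("regulation elements", RgEs) that tune protein translation in mammalian
cells. The package covers the full quantitative workflow around such
elements:

- **`utrtune.rge` / `utrtune.energy`** — hairpin domain model and its three
  design properties: fold free energy (nearest-neighbor model with an
  exhaustive-search verification oracle), stem GC content/class, and
  cap-relative placement with CAA spacers; plus a target-driven stem
  designer and FASTA/CSV I/O.
- **`utrtune.synth`** — synthetic-data generators with planted ground truth
  for every input the pipeline consumes: flow-cytometry event tables
  (bivariate lognormal reporters, debris/doublet/untransfected strata),
  qPCR CT tables, logistic batch cultures, SEC chromatograms, gel lanes,
  and saturating helper-factor dose responses.
- **`utrtune.flow`** — scatter/singlet/BFP-positivity gating and the
  per-cell RFP/BFP geometric-mean fold change versus an unregulated control.
- **`utrtune.qpcr`** — 2^−ΔΔCT relative mRNA quantification, reporter-ratio
  mRNA fold changes, RNA/protein fold-change ratios.
- **`utrtune.quality`** — SEC peak integration into HMW/mAb/LMW fractions,
  gel densitometry band ratios (full-size vs heavy-chain dimer), and the
  lysate+supernatant western-blot normalization for helper-factor levels.
- **`utrtune.bioprocess`** — cumulative cell days, specific productivity
  (qP), A280 protein concentration, and the chromogenic sulfatase activity
  assay.
- **`utrtune.dosemodel`** — linear and 4-parameter-logistic ΔG→FC fits,
  GC-pair differentials, cross-host correlations, segmented (plateau)
  dose-response with breakpoint estimation, and the Levene → ANOVA →
  Dunnett testing chain.
- **`utrtune.experiments` / `utrtune.cli`** — end-to-end orchestration of
  the three experiment chains (reporter panel, heavy-chain tuning,
  helper-factor/enzyme co-expression) with machine-readable reports.

## Command line

```sh
utrtune --help
utrtune design --target-dg -30 --gc-class high --seed 1
utrtune simulate --kind flow --dosage 0.35 --out flow.csv --seed 1
utrtune flow-quant --sample RgE3 flow.csv --sample CMV control.csv \
    --control CMV --ref untransfected.csv --out panel.csv
utrtune run --config experiment.yaml --out results/
utrtune fixtures --seed 1 --out fixtures/
```

An experiment config is a small YAML file, e.g.

```yaml
experiment: reporter_panel   # or igg_hc_tuning, sumf1_asa
seed: 1
n_events: 30000
```

`utrtune run` writes stage CSVs plus a versioned `report.json` with all
headline quantities (fold changes, R², peak fractions, qP, activities).
Event tables are read from CSV (`fsc_a,ssc_a,ssc_h,bfp,rfp`) or FCS
3.0/3.1 list-mode files.

## Notes

- The free-energy model embeds a published nearest-neighbor parameter
  subset (Watson-Crick + GU stacks, hairpin-loop initiation with
  log-extrapolation, AU/GU helix-end penalty). Absolute values
  approximate, but do not exactly equal, full folding servers —
  tetraloop bonuses and loop-sequence terms are deliberately excluded
  so every energy is reproducible by hand from the embedded tables.
- All simulators are deterministic given a config and seed; datasets
  written to disk carry a `.truth.json` sidecar with the planted truth.
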