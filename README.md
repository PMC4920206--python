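# proxymed

Metabolite-panel association scanning and proxy-based mediation testing
for a rare lipid variant.

## The problem

Rare loss-of-function variants in *APOC3* lower circulating triglycerides
and reshape the lipoprotein profile, and apoC-III is believed to act
largely by inhibiting lipoprotein lipase (LPL). Given a panel of ~225
NMR metabolomics measures scanned against (a) the rare *APOC3* focal
variant and (b) a common variant near *LPL* serving as a proxy of LPL
activity, the question is: **which of the rare variant's metabolite
effects are NOT explainable as LPL-mediated?**

`proxymed` implements the full analysis as a reusable, tested pipeline
for statistical geneticists and epidemiologists: genotype QC, the
per-metabolite association scan, cross-study pooling (fixed/random
effects meta-analysis and pedigree-aware mixed-model pooling),
Benjamini-Yekutieli FDR control, and the mediation test itself —
together with a synthetic multi-study cohort generator with known ground
truth, so the whole analysis runs and calibrates itself with no access
to restricted cohort data.

## The core statistic

If the focal variant acts only through LPL, its per-metabolite effects
are proportional to the proxy's: beta_A,m = k · beta_L,m for all m. The
pipeline estimates k as the **25% trimmed mean** (midmean) of the
per-metabolite effect ratios r_m = beta_A,m / beta_L,m — trimming
rejects metabolites that do not follow the proportional model — with a
standard error from **bootstrapping the ratio list 1000 times**. Each
metabolite's predicted pure-mediation effect k̂·beta_L,m gets a 95% CI
via the delta method (Var = k̂² se_L² + beta_L² se_k²); a metabolite is
flagged **proxy-independent** when this interval and the observed
effect's interval are strictly disjoint. Per-study results are combined
by a sample-size-weighted fixed-effects meta-analysis.

Details, assumptions and numerical conventions: [docs/methods.md](docs/methods.md).

## Worked example

The numbered scripts under `analysis/` walk through the full analysis on
a generated three-cohort dataset (n = 3000/2500/2000, 60 metabolites,
focal MAF 2%, proxy MAF 10%, true k = −2, and five metabolites given a
genuine proxy-independent effect):

```bash
cd analysis
python 01_simulate_cohorts.py
python 02_association_scan.py
python 03_meta_fdr.py
python 04_proxy_mediation_test.py
python 05_calibration_replicates.py
```

Stage 04 prints:

```
young   : k = -2.101 (bootstrap SE 0.072, 30/60 ratios kept), 5 flagged proxy-independent
          z-profile correlation r = -0.963, slope = -0.939
mothers : k = -2.039 (bootstrap SE 0.075, 30/60 ratios kept), 4 flagged proxy-independent
women   : k = -1.939 (bootstrap SE 0.090, 30/60 ratios kept), 4 flagged proxy-independent
combined: 5 measures flagged proxy-independent: met001, met013, met025, met037, met048
ground truth proxy-independent set: met001, met013, met025, met037, met048
-> 5/5 true positives recovered, 0 false positives
```

Each study's trimmed-mean ratio recovers the true mediation constant
(−2) within its bootstrap SE; the z-scaled effect profiles of the two
variants are near-perfectly (anti-)correlated, as proportionality
implies; and after the sample-size-weighted combination the flagged set
is exactly the five metabolites simulated with a real proxy-independent
effect.

The same machinery is available as a CLI (`proxymed simulate / scan /
pool / meta / fdr / proxytest / combine / run / report`) — `proxymed run`
executes the entire pipeline from a YAML config and writes every
intermediate as TSV plus a machine-readable summary, byte-identical
under rerun with the same config and seed.

## Layout

```
src/proxymed/       the library
  synthcohort.py    synthetic multi-study cohort generator (+ ground truth)
  assoc.py          QC, ln(x+1) transform, vectorized association scan
  metastat.py       fixed/random-effects meta, pedigree REML pooling, BY-FDR
  proxytest.py      ratios, trimmed mean, bootstrap, predictions, overlap
  calibration.py    replicate simulation studies
  pipeline.py       end-to-end orchestration with persisted intermediates
  cli.py            click CLI over all of the above
analysis/           numbered narrative drivers (the worked example)
scripts/            acceptance.py (calibration reproduction)
tests/              pytest suite incl. property-based checks
```
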