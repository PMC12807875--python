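# xiescape

Allele-specific analysis of how Xist RNA levels modulate escape from
X-chromosome inactivation (XCI).

In female cells one X chromosome is transcriptionally silenced, but a subset
of X-linked genes ("escapees") keeps expressing from the inactive X (Xi).
`xiescape` is a pipeline for haplotype-resolved RNA-seq experiments in which
Xist is upregulated from an inducible promoter over a multi-day time course
(with optional washout arms): it quantifies escape per gene, tests whether
induction shifts the allelic balance, models the kinetics of escapee
silencing, and classifies how reversible that silencing is. It is aimed at
computational biologists analysing allele-specific count tables from F1
hybrid lines (e.g. SNPsplit + featureCounts output).

## What it computes

For each gene *g* in sample *s*, the **allelic ratio** (d-score) is

    r = Xi / (Xi + Xa),

the fraction of haplotype-assigned reads from the inactive X. On top of this:

- **Escape calling** — a gene escapes when r > 0.1 in the untreated state
  (all replicates, or a configurable fraction of samples); ratios > 0.8 are
  excluded as strain/mapping artefacts, Xist itself is excluded, and genes
  with a mean allelic count < 10 are dropped.
- **Cross-study categories** — from a gene × study literature matrix:
  *constitutive* (detected in ≥ 3 studies, escaping in > 50% of them),
  *facultative* (escaping somewhere, not constitutive), *clone-specific*
  (escaping locally, never in the literature), *silenced*.
- **Differential allelic imbalance** — per gene, Xi counts k given totals n
  are modelled as a binomial GLM, logit(p) = β₀ + β₁·treatment, with a Wald
  test on β₁ and Holm (or Benjamini–Hochberg) adjustment; a gene is *silenced
  by Dox* when the adjusted test is significant and the allelic ratio drops
  by ≥ 50%.
- **Silencing kinetics** — each escapee's trajectory over Dox days t is fitted
  with the exponential decay r(t) = a·exp(−k·t) + b by bounded least squares;
  a nested fit with b = 0 is compared by BIC (genes with R² < 0.3 in both
  fits are discarded). The half-life is t½ = ln 2 / k, and a selected offset
  b > 0 indicates **residual escape**.
- **Gene groups** — escapees are chained into local groups whenever
  consecutive gene starts lie within 100 kb; a seeded permutation test asks
  whether neighbouring escapees share similar half-lives.
- **Reversibility** — after Dox washout, fold recovery = washout ratio /
  untreated ratio; genes are *reversible* (recovery ≥ 50% and washout ratio
  > 0.1), *partially irreversible* (10–50% and > 0.1) or *irreversible*.
- **Synthetic data** — a seeded generator emulating the full study design
  (379 informative genes, 133 escapees in three categories, time grid
  {0, 3, 7, 14, 21} days, washout arms, clustered gene coordinates, a
  19-study literature matrix) with the generating truth recorded, so every
  stage can be validated without any download.

## Worked example

```python
import xiescape as xe

data = xe.simulate_dataset(xe.SimulationConfig(seed=1))
out = xe.run_pipeline(data.counts, data.sheet, annotation=data.annotation,
                      study_matrix=data.study_matrix, seed=2)

print(out["escape_calls"]["status"].value_counts().to_dict())
print(out["categories"]["category"].value_counts().to_dict())

from xiescape.kinetics import DecayResults
print(DecayResults(out["kinetics"]).summary())
```

prints

```
{'silenced': 246, 'escapee': 129, 'excluded_high_ratio': 3, 'excluded_xist': 1}
{'silenced': 243, 'facultative': 84, 'clone_specific': 36, 'constitutive': 12, 'unclassified': 4}
Exponential-decay silencing kinetics
genes fitted:          129
reliable fits:         129
residual escape (BIC): 25
median half-life:      1.91 days
```

Of the 379 simulated genes, 129 are called escapees in the untreated state
(the generator planted 133; a few sit too close to the 0.1 threshold at this
sequencing depth), Xist and three high-ratio artefact genes are excluded, and
the literature matrix reproduces the planted 12/84 constitutive/facultative
split. All escapee trajectories yield reliable decay fits; 25 genes keep a
BIC-supported residual-escape offset. Downstream stages follow the same
pattern:

```python
model = xe.AllelicImbalanceModel(out["ratios"], data.sheet,
                                 ("untreated", "dox3d"))
print(model.fit().summary())
```

```
Allelic imbalance (binomial GLM, Wald test)
contrast: untreated vs dox3d
genes tested:        379
estimable fits:      364
significant (adj p < 0.05, holm): 96
```

and `out["reversibility"]` holds the per-gene washout classes, e.g. 89
reversible / 9 partially irreversible / 31 irreversible escapees after 7 days
of induction, shifting to 55 / 8 / 66 after 21 days — silencing becomes
increasingly locked in with longer induction.

The same stages are available on the command line
(`xiescape simulate`, `xiescape run-all`, plus one subcommand per stage):

```sh
xiescape --seed 11 simulate --outdir sim/
xiescape --seed 12 run-all --counts sim/counts.tsv --sheet sim/sample_sheet.tsv \
    --annotation sim/annotation.bed --annotation-format bed \
    --studies sim/study_matrix.tsv --outdir results/
```

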