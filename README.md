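# glytrome

Codon-resolved analysis of tRNA m⁵C loss and its translational
consequences, built for the question raised by neuronal Nsun2 knockout
models: when the methyltransferase that deposits 5-methylcytosine on the
tRNA variable loop is ablated, glycine tRNAs are destabilized — what does
that do to translation, the proteome, and free amino-acid pools?

The package links six assay layers behind one importable API:

| layer | module | core statistic |
|---|---|---|
| tRNA bisulfite amplicons | `glytrome.methylation` | per-cytosine C/(C+T) fraction, per-site t-test, BKY FDR |
| full-length tRNA / fragment counts | `glytrome.expression` | conditional NB exact test, CPM ≥ 20 filter, \|FC\| ≥ 1.5 |
| codon content vs translation | `glytrome.codon` | logTER = log₂FC(protein) − log₂FC(RNA); Pearson r; MI + permutation z |
| ribosome footprints | `glytrome.ribo` | P-site offsets, loess-capped codon counts, relative dwell time KO/WT |
| proteome strata | `glytrome.proteome` | Welch t + BKY strata; Mann–Whitney on amino-acid content |
| amino-acid metabolites | `glytrome.metabolomics` | heavy-standard normalization, y = α + βx calibration, Grubbs outlier |

A seeded generator (`glytrome.simulate`) produces every input with the
knockout effect structure — Nsun2-site methylation collapse, Gly-family
isodecoder depletion, a GGA-specific ribosome stall, a negative
glycine-content effect on translational efficiency, and a 2.46-fold
glycine increase — so the whole pipeline runs with no download.

## The statistics at the core

- **Mann–Whitney U**, exact by full enumeration of the U null
  distribution at n₁+n₂ ≤ 20 (two-sided p = doubled smaller tail); used
  for content and dwell-time contrasts.
- **NB exact test** for isodecoder counts: conditional on the feature
  total, group sums S₁, S₂ are negative binomial with sizes nᵢ/φ and a
  shared success probability that cancels, so
  P(S₁ = s | S₁+S₂ = t) ∝ C(s+r₁−1, s)·C(t−s+r₂−1, t−s).
  φ is a common method-of-moments dispersion; φ → 0 recovers the exact
  binomial conditional test.
- **Two-stage BKY FDR**: linear step-up at q/(1+q) estimates the number
  of true nulls m₀; the step-up is re-run with m₀. Never less powerful
  than Benjamini–Hochberg.
- **MI enrichment**: values binned into equal-frequency quantiles, mutual
  information with a binary gene set in bits, z-score and p from 10,000
  membership permutations, per-bin hypergeometric tails with Bonferroni.
- **Dwell time**: footprints are assigned to the codon holding the A-site
  nucleotide (P-site offset + 3 nt); per-transcript densities are
  normalized to the interior mean, stall excess is capped at 5× a robust
  loess prediction, and DT per codon is a 5% trimmed mean over instances;
  relative DT = DT_KO / DT_WT.

## Worked example

```
$ python examples/08_full_pipeline.py
min Nsun2 relative methylation deficit: 64.0%
Gly isodecoders with negative logFC: 9/10
glycine content vs logTER r = -0.542
GGA relative dwell time = 2.87 (max over codons: True)
glycine metabolite fold change = 3.01 (Grubbs outlier: True)
```

Reading the lines in order: every Nsun2-regulated cytosine loses more
than half of its baseline methylation in the knockout (the weakest site,
C39, drops 64% of a ~15% baseline); 9 of the 10 glycine isodecoders are
estimated down at n = 3/group; glycine codon content correlates
negatively with translational efficiency (r = −0.54); the GGA codon —
decoded by the depleted Gly-TCC tRNA — shows the largest relative
ribosome dwell time (2.87, against an injected 3× stall); and glycine is
the single Grubbs outlier among 19 amino-acid fold changes in this
cohort (3.0 here; the scenario's injected effect is 2.46, and a single
n = 4 cohort estimates it with ~11% sampling error).

`examples/01`–`07` run each capability on its own with a line of
interpretation per output; the `glytrome` CLI (`simulate`, `run`,
`methylation`, `tdiff`, `fragments`, `metabolome`) exposes the same
stages on files.

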