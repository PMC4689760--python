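# sterolflux

Heavy-water (²H₂O) mass-isotopomer analysis of sterol biosynthetic flux,
with companion multi-reference-gene qPCR expression analysis and
plate-viability statistics.

## The problem

Cells grown in media containing ²H₂O incorporate deuterium into every
molecule they synthesize during the labelling window. For a sterol such as
lanosterol (C₃₀H₅₀O, the first intermediate committed solely to cholesterol
biosynthesis) or cholesterol itself (C₂₇H₄₆O), the LC–MS isotopologue
envelope of the metabolite pool therefore becomes a mixture of the
pre-existing (natural-abundance) envelope and the shifted envelope of newly
made molecules. Reading the fraction of newly synthesized molecules out of
that mixture gives a direct measure of biosynthetic flux through the pool —
for instance to compare de novo sterol synthesis between a drug-sensitive
leukemia line (CEM) and its resistant daughter line (CEM/R2), with and
without cholesterol-pathway inhibitors.

`sterolflux` implements the full desk side of that experiment:

- **Isotope arithmetic** (`sterolflux.isotopes`): formula parsing,
  monoisotopic masses, APCI adduct m/z (sterols are monitored as the
  dehydrated protonated ion [M+H−H₂O]⁺), and natural-abundance
  isotopologue envelopes by per-element multinomial convolution,
  aggregated in unit-mass bins M+0…M+K.
- **Labelling forward model** (`sterolflux.labeling`): the envelope of a
  fully newly synthesized molecule is the convolution of the natural
  envelope of the non-exchangeable atoms with a Binomial(n_exch, p)
  deuterium-count distribution, where *p* is the water ²H enrichment
  (0.30 in the study design) and *n_exch* the number of hydrogens derived
  from water during biosynthesis. Pool envelope:
  `M(f) = (1 − f)·M_nat + f·M_lab`. Natural-abundance correction matrices
  and NNLS/triangular deconvolution live here too.
- **Inverse problem** (`sterolflux.enrichment`): least-squares estimation
  of the fraction new *f*, of the enrichment *p*, the model-free mean
  mass-shift index, relative quantification, and treated-vs-control flux
  comparisons (Welch t).
- **Targeted extraction** (`sterolflux.extraction`): centroided mzML (or
  CSV spectrum tables) → per-isotopologue areas by accurate mass (ppm
  tolerance) and retention time with apex re-anchoring.
- **qPCR** (`sterolflux.qpcr`): relative expression against the geometric
  mean of the reference genes RPL13A, RPS18, ACTB and GAPDH; log2 fold
  changes with Welch t-tests.
- **Viability statistics** (`sterolflux.viability`, `sterolflux.multcomp`):
  vehicle normalization, Welch t, one-way ANOVA with Dunnett's two-sided
  many-to-one comparisons (multivariate-t integration, written here and
  cross-checked against independent oracles).
- **Synthetic data** (`sterolflux.simulate`): generators for every input
  modality with ground-truth sidecars, used by the test-suite and the
  worked example below.
- **Pipeline + CLI** (`sterolflux.pipeline`, `sterolflux.cli`): one-command
  orchestration with a hashed run manifest.

## Worked example

```bash
sterolflux run --scenario paper-like --seed 1 --out results/demo
```

simulates paired H₂O / 30 % ²H₂O LC–MS runs (five replicates per cell line),
a Cq table and a viability plate table, then runs extraction, correction,
fitting and statistics. Mean fitted values from the flux table
(`results/demo/flux_estimates.csv`):

```
                        f_hat  shift_index
cholesterol CEM        0.0001       0.0003
            CEM_R2     0.0003       0.0008
lanosterol  CEM        0.1494       1.0048
            CEM_R2     0.3002       1.9888
```

The generator's truths were f = 0.15 / 0.30 for lanosterol in CEM / CEM_R2
and f = 0 for cholesterol: the fit recovers the doubled lanosterol flux in
the resistant line, and cholesterol shows essentially no label uptake
(`f_hat` flagged at the zero boundary). The `shift_index` column is the
model-free mean mass shift of the natural-abundance-corrected envelope —
at p = 0.30 and n_exch = 25 a fraction new of 0.15 corresponds to a mean
shift of about one mass unit. The qPCR table reproduces the expression
pattern encoded in the scenario (fold = 2^log2_fold):

```
gene,log2_fold,sem,p_value,...,stars
ABCA1,2.340972,0.095447,0.000000,***      # ~5.1x up
CYP51A1,2.113153,0.100018,0.000001,***    # ~4.3x up
HMGCR,-0.953130,0.142669,0.000068,***     # ~2.1x down
SQLE,1.545480,0.098018,0.000000,***       # ~2.9x up
```

and `viability_results.csv` carries Dunnett-adjusted p-values per treatment
with the star legend # ≤ 0.1, * ≤ 0.05, ** ≤ 0.01, *** ≤ 0.001.

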