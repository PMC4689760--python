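# Methods

## Isotopologue envelopes

Envelopes are aggregated by **nominal mass shift** (unit-mass bins M+0…M+K)
rather than isotope fine structure: unit-resolved Q-TOF envelopes of
~400 Da sterol ions do not resolve ¹³C from ²H, and the analysis only needs
bin fractions. The natural envelope of a formula is computed per element by
exponentiation-by-squaring of the single-atom shift distribution and
cross-element discrete convolution, then truncated at K and renormalized;
the discarded tail is logged when it exceeds 1e-6. The isotope masses and
abundances are pinned in `sterolflux/data/isotope_abundances.tsv`
(IUPAC/CIAAW 2013 representative values as commonly tabulated) so results
are bit-stable; the loader checks per-element normalization. A brute-force
oracle that enumerates every isotope assignment of every atom verifies the
convolution to 1e-12 on small formulas.

The default K is **8** for the sterols. At the study conditions
(p = 0.30, n_exch ≈ 25) the fully labelled envelope has mean shift
n_exch·p ≈ 7.5, so K = 8 truncates a substantial part of the *fully
labelled* envelope. This is deliberate: generator and estimator share the
same truncated basis, making the mixture fit exactly self-consistent (see
below), and real acquisitions window the same envelope region. K is
configurable per species.

## Ion bookkeeping

Under APCI in positive mode sterols are monitored as the dehydrated
protonated ion [M+H−H₂O]⁺; all envelope modelling therefore uses the **ion
composition** (lanosterol → C₃₀H₄₉), since the observed isotope pattern
belongs to the ion, not the neutral. Ion m/z uses proton-mass bookkeeping
(no electron-mass refinement); the isotopologue m/z grid uses the averaged
¹³C/²H spacing 1.00336 Th per charge, which is adequate at unit-bin
aggregation and 20 ppm tolerance.

## Labelling model

A molecule synthesized during the labelling window carries deuterium at
its n_exch water-derived hydrogen positions. We parameterize the water
enrichment **p as the excess over the natural deuterium background**: each
exchangeable site is ²H with probability `p + (1 − p)·a_nat(²H)`. The
labelled envelope is then

    M_lab = M_nat(formula − n_exch H) ⊛ Binomial(n_exch, p′),

which reduces *exactly* to the natural envelope at p = 0 (binomial
identity), and differs from using a raw site probability of 0.30 by ~8e-5
at the study's media composition. The pool envelope is the two-component
mixture `(1 − f)·M_nat + f·M_lab`.

Defaults for n_exch — lanosterol 25, cholesterol 26 — are biology-dependent
placeholders (the count of water-derived hydrogens is not measurable from
this experiment alone). Two safeguards keep conclusions from hinging on
them: the estimators can fit enrichment as the effective product n_exch·p
(joint (f, p) fit with an identifiability check on the Jacobian), and the
model-free **mass shift index** Σ i·(corrected_i − natural_i) is reported
alongside every fraction-new fit; it never consumes n_exch and is exactly
linear in f.

## Natural-abundance correction and where the fit happens

The correction matrix has column j equal to the natural envelope of the
monitored ion shifted up by j and truncated at K *without* renormalization
(column sums ≤ 1 reflect the true truncated mass). The default solver is
non-negative least squares; an exact triangular solve is available for
noiseless work (negative values clipped to zero under a warning). The
noiseless round trip `correct(M·x) = x` holds to 1e-9 and is
property-tested over random label distributions.

Fraction-new fitting uses **all K+1 bins with equal weight** via the
closed-form projection of the observed envelope onto the segment between
the natural and labelled envelopes, clipped to [0, 1]; fits within 1e-6 of
a boundary are flagged rather than silently reported. In the end-to-end
pipeline the fraction new is fitted on the **raw** envelope (the exact
inverse of the forward model, hence unbiased to float precision in the
noiseless limit), while the NNLS-corrected envelope feeds the shift index.
Fitting after correction is also supported (`corrected=True`); in that mode
the labelled basis is itself pushed through the correction operator so that
truncation is consistent on both sides. The pure deconvolve-then-fit
variant carries an inherent ~2 % relative distortion at these conditions
because NNLS deconvolution of a K-truncated envelope is lossy and mildly
nonlinear — one reason both routes are exposed.

Confidence intervals on f: percentile bootstrap (1999 resamples, fixed
seed 20151223) with ≥ 5 replicates, a t-interval with 3–4, a point interval
below that; bounds are clipped into [0, 1].

## Extraction

Targeted species are located by accurate mass (default 20 ppm, Q-TOF
appropriate) and retention time. RT windows are half-open [start, end) in
minutes. The elution apex is the maximum of a 3-point moving average of the
summed M+0…M+2 chromatogram (earliest RT on ties); the integration window
re-anchors at the apex so off-center elution does not bias bin areas, which
are trapezoid integrals over RT. Species with no apex signal are flagged
"not detected" rather than returning an envelope of zeros. MS/MS
confirmation, isobar deconvolution and vendor raw formats are out of scope.
The mzML subset read and written here is centroided MS1 with 32/64-bit
float arrays, zlib or no compression; the writer emits no timestamps, so
output is byte-reproducible.

## qPCR

Relative expression is `E_g^(−Cq_g)` over the **geometric mean** of
`E_r^(−Cq_r)` across the reference genes (RPL13A, RPS18, ACTB, GAPDH) —
the standard multi-reference combination rule; with all efficiencies at
the default 2.0 this is `2^−(Cq_g − mean Cq_refs)`. Group statistics are
computed on per-replicate log2 values (variance stabilizing, matching the
log2-fold presentation) with two-tailed Welch t-tests. No multiple-testing
correction is applied to the per-gene p-values; a Benjamini–Hochberg
q-value column is emitted as clearly supplementary output.

## Viability

Each record is normalized by its (cell line, experiment) vehicle mean, so
the vehicle group has mean 1 by construction and normalization is
idempotent. Technical replicates are averaged within experiment before
testing; n is the number of independent experiments. Many-to-one
comparisons use ordinary one-way ANOVA plus Dunnett's two-sided test. The
max-|t| tail probability is computed here by numerical quadrature:
conditioning on the shared control-mean deviate (Gauss–Hermite, 96 nodes)
and the pooled-SD scale factor (Gauss–Legendre, 128 nodes over the
chi-distribution support) factorizes the k statistics. The integrator
reproduces classical table values (k=3, ν=12, α=0.05 → 2.68), collapses to
the pooled t quantile at k=1, matches `scipy.stats.dunnett` p-values to
~1e-3 and the Monte-Carlo max-|t| null to < 0.01, and yields a family-wise
error of 0.05 ± 0.01 in null simulation. Unequal group sizes are handled
by the generalized correlation structure. Blocked (per-experiment) ANOVA is
not implemented. Significance stars follow # ≤ 0.1, * ≤ 0.05, ** ≤ 0.01,
*** ≤ 0.001.

## Synthetic-data generator

The generator is first-class, tested code and defines the study-like
conditions end to end; each artifact carries a JSON truth sidecar and
identical config + seed reproduce outputs byte for byte.

- **LC-MS**: one centroided mzML per (cell line, media, replicate);
  Gaussian elution peaks (σ = 2 s on a 0.5 s scan grid) at each species'
  isotopologue grid, envelope = mixture model at the scenario truth, with
  multiplicative log-normal noise (default CV 1 %) and an optional additive
  floor. Defaults: lanosterol f = 0.15 (CEM) / 0.30 (CEM_R2), cholesterol
  f = 0 in both lines, p = 0.30, five replicates — p is the study's stated
  media enrichment; the f values are scenario parameters chosen to
  reproduce the qualitative sensitive-vs-resistant contrast.
- **qPCR**: reference genes constant across conditions plus Gaussian Cq
  noise (SD 0.2); targets offset by −log2(true fold) cycles in the
  comparison line (HMGCR 0.5×, CYP51A1 and ABCA1 5×, SQLE 3×), n = 6.
- **Viability**: log-normal luminescence around baseline × effect
  (CV 10 %), 4 experiments × 3 technical replicates, with a per-experiment
  plate scale factor; vehicle effect 1 by definition.

What the generator does **not** emulate: chromatographic tailing and drift,
ion suppression, detector saturation, isobaric interference, qPCR
efficiency variation or technical-replicate structure, and plate edge
effects. Passing recovery tests therefore demonstrates the correctness and
calibration of the estimators under the stated noise model — not robustness
to every artifact of real acquisitions.

## Numerical choices

- Enrichment inversion: bounded scalar minimization (xatol 1e-12) with a
  short local grid polish, giving |p̂ − p| ≲ 1e-10 on noiseless input.
- NNLS failure and all-zero distributions raise; nothing degrades silently.
- Correction/bootstrap seeds are fixed (20151223) where randomness is
  internal to an estimator.
- Problem sizes in the test battery (e.g. 200 simulated qPCR experiments,
  500 null envelopes, 10⁴ Dunnett null simulations, 10⁵ Monte-Carlo max-|t|
  draws) were chosen to put Monte-Carlo error well inside the asserted
  tolerances while keeping the whole suite fast on a single CPU.

## Known limitations

Single-time-point labelling only (no turnover kinetics, no correction for
cell-division dilution); no multi-pool precursor–product modelling; charge
states above 1 and electron-mass corrections are not modelled; RT values
for the sterols on any particular gradient are configuration inputs, not
predictions.
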