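# Methods

## The screen and its data

A RASL-seq screen measures a targeted panel of 56 genes (261 ligation
probes, 3–7 per gene) across 9,216 wells: ~360 chemical entries × 4
concentrations (0.01, 0.1, 1, 10 µM) × 2 sexes × 3 biological replicates,
laid out on twenty-four 384-well plates (4 male + 4 female plates per
replicate) with interspersed DMSO-only vehicle wells. Every well carries a
unique (forward, reverse) barcode pair, a luciferase spike-in at fixed
input, and probes for four control genes (*Ascl3*, *Psmd4*, *Sdha*, *Tbp*)
and the sex markers *Xist* (chrX) and *Ddx3y* (chrY). The pipeline's unit
of analysis is the *chemical-concentration-sex* condition profile obtained
after collapsing replicates.

The packaged default panel reproduces this scale exactly (37 genes × 5
probes + 19 genes × 4 probes = 261, plus 3 spike probes). Only part of the
real gene list is public; the remainder of the default panel consists of
plausible genes from the same functional families (microglial/astrocytic
markers, cytoskeleton, oxidative/ER stress, immediate early genes, synaptic
function), which is sufficient because nothing downstream depends on gene
identity beyond the control/sex-marker/spike roles.

## Synthetic screen model

The generator produces counts with the statistical structure the analysis
assumes; it is the test bed for every downstream stage, with ground truth
recorded per chemical (template, dose model, toxicity), per well (sex,
viability, failure) and per probe (failure).

**Counts.** Per well, library size L ~ LogNormal(meanlog = ln 30 000,
sdlog = 0.4) — roughly what two HiSeq lanes spread over 9,216 wells yield.
Each gene g has a baseline weight w_g ~ LogNormal(0, 0.8) drawn once per
simulation; a chemical's effect multiplies it by 2^(β_g · a(dose)), where
β_g is the per-gene log2 fold-change of the chemical's template and
a(dose) ∈ [0, 1] its dose activity. Gene mass is split equally over the
gene's probes; probe-level heterogeneity enters only through sampling noise
because the pipeline collapses probes by median anyway. Counts are negative
binomial around the expected partition of L with shared dispersion
(size = 10, i.e. ~32% extra-Poisson CV at high counts) — the simplest
overdispersed model consistent with targeted sequencing.

**Dose models.** `flat` responds fully at every tested concentration;
`threshold` only at the top dose (10 µM); `monotone` scales linearly in
log-concentration from 4 decades below the top dose, so 10 nM retains 25%
activity. These mirror the two phenotypes the classification must resolve
(a bifenthrin-like threshold response versus a pyraclostrobin-like
concentration-independent response); no quantitative dose–response model is
fitted anywhere — that is explicitly out of scope.

**Spike-in coupling.** The spike competes with cellular transcripts for the
well's fixed read budget: with viability v and cellular mass M(v) = v·Σw,
the expected spike read share is f = I/(I + M(v)), with I calibrated so
f = 5% at full viability and no effect. Cell death therefore raises the
spike fraction — the cell-health proxy — without changing the well's total
reads (pooling normalizes plates to equal representation). Toxic chemicals
reduce viability by toxicity × a(dose), floored at 0.05.

**Sex markers.** Xist gets +s/2 log2 units in female wells and −s/2 in
male wells; Ddx3y the opposite (default separation s = 4 log2 units, i.e.
16-fold — Xist is essentially silent in male tissue, so recovery should be
error-free on unfailed wells, and is).

**Failures.** A failed well's library size is scaled by 10⁻³ (≈30 reads,
far below the 500-read QC bar); a failed probe is zeroed everywhere.
Defaults: 0.2% well failure, 0.4% probe failure.

**Signature templates.** The six cluster templates plus a JQ1-like `novel`
and an inert `null` template are a hand-authored synthetic fixture
(`data/templates.tsv`, gene × template log2 effects, amplitudes 1–2.5).
They encode the qualitative directions of the previously described chemical
clusters — e.g. the Cluster-2-like electron-transport-inhibitor signature
up-regulates *Hmox1*, *Fos*, *Cx3cr1*, *Gsta4* and down-regulates *Rbfox3*,
*Syt1*, *Nrxn1*; the JQ1-like signature down-regulates microglial and
astrocytic markers and up-regulates *Fos*, *Rest*, *Nrxn1* — with pairwise
correlations kept below ~0.4 so the 0.65 retention rule can separate them.
They are **not** reconstructions of measured signature values, which were
never published.

**What the generator does not emulate**, and hence what passing tests do
not show about real screens: sequencing error and barcode hopping, PCR
amplification bias, plate-position (edge) effects, batch effects between
replicates, cell-type composition shifts, and probe-specific efficiency
differences beyond the equal-split assumption. Recovery rates measured here
are upper bounds for real data.

## Processing pipeline

1. **QC.** Spike probes are separated first and never enter normalization.
   Probe totals are computed over *all* wells of the experiment, then
   probes with totals > 1000 are kept; wells whose full totals (including
   spike reads and reads on dropped probes) exceed 500 are kept. Both
   inequalities are strict, per the processing rule's wording ("exceeded");
   an inclusive variant is exposed as `--ge`. A control gene losing its
   last probe is a hard error. Filters are idempotent and conservation
   (dropped + kept = input) is tested.
2. **Log-ratio normalization.** Pseudocount 1, then per well the log2 ratio
   of each probe to the geometric mean of the control-gene probes, computed
   in log space. The control-probe column mean is exactly zero by
   construction (machine precision), and multiplying a well's counts by a
   constant leaves its ratios unchanged — controls absorb library size.
3. **Probe collapse.** Median over each gene's surviving probes.
4. **Median polish.** Tukey's two-way polish, rows first then columns,
   alternating, until the maximum residual change is < 1e-6 or 20 sweeps.
   The output keeps residuals *plus row (gene) effects*: column (sample)
   effects and the overall level are removed while gene-relative structure
   is preserved for display and correlation (`residual` output is also
   available). The implementation agrees with an independent sweep oracle
   (and with R's `stats::medpolish`) to 1e-12 on small tables. At full
   screen scale (54 × ~6,900) the 20-sweep cap is reached before 1e-6
   convergence; the run log records this, and results remain deterministic.
5. **Replicate collapse.** Median across a condition's replicate wells;
   columns are labelled `chemical@conc_uM@sex`.
6. **Centering.** Sex markers are removed, then each gene row is
   median-centered across conditions.

Missing data are never imputed: genes or conditions that lose every
probe/well are dropped and logged.

## Classification

Sex calls use the sign of Xist − Ddx3y (exact zero → unknown). Condition
profiles are correlated (Pearson) against each signature over the shared
gene set — at least 3 genes, optionally restricted further to a
commonly-assayed subset; zero-variance profiles give a missing value, not
zero, so flat vehicle profiles can never match a signature. Sexes are
averaged before classification by default (per-sex assignment is
available). A chemical is **classified** when exactly one signature is
exceeded (r > 0.65, strict) at any concentration; **unclassified_ambiguous**
when several signatures are exceeded — candidates and the cell-health
covariate are reported, and the ambiguity is deliberately never
auto-resolved in code; **unclassified_low** otherwise. Hierarchical
clustering of condition columns uses 1 − Pearson distance with average
linkage (configurable); columns are pre-sorted lexicographically so leaf
order is deterministic. Cross-platform concordance is a plain Pearson r
with a two-sided t-distribution p-value over the genes shared with an
external (e.g. RNA-seq) profile, plus the paired per-gene table.

## Numerical and design choices

- Geometric means and ratios are computed in log space; no division by raw
  counts occurs anywhere.
- Polish sweep order (rows first) follows the classical formulation; tol
  1e-6 / 20 sweeps are exact on small tables and bounded-cost at scale.
- Thresholds 500/1000/0.65 are strict comparisons; all are surfaced as
  options with these defaults.
- Barcodes: forward barcodes index plates, reverse barcodes index well
  positions, which guarantees pair uniqueness; the synthetic read layout
  `fwd + junction + rev` with exact matching is this package's own dialect
  for testing the demultiplexer, not a claim about real read structure.
- All randomness flows from explicit seeds; identical (seed, inputs) give
  byte-identical artifacts, verified by manifest checksums.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on small matrices (≤ 10 × 10) against
brute-force oracles (100 random matrices for normalization/filters, 50 for
median polish). Recovery experiments use a 60-chemical triplicate screen
(2,304 wells; 6 chemicals per active template plus hallmark chemicals,
remainder null). The spike/viability coupling is measured with 12 wells per
viability level across 5 levels (viability 0.2–1.0), enough replication for
stable medians. The end-to-end determinism check runs the full 9,216-well ×
261-probe screen twice (a few seconds each on one CPU).

## Known limitations

- Classification accuracy depends on template separation; signatures more
  correlated than ~0.5 would produce more ambiguous calls than reported
  here.
- The probe filter assumes the matrix passed in covers the whole
  experiment; filtering a subset changes probe totals and hence the kept
  set.
- `unclassified_ambiguous` chemicals require manual review by design.
- The median polish keeps row effects by default; analyses that require
  pure residuals must request them explicitly.
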