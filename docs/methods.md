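# Methods

This note documents the models, parameter choices and numerical decisions
behind `dcflow`, and what its synthetic-data tests do and do not show
about real cytometry data.

## The synthetic whole-blood model

Each simulated sample emulates an erythrocyte-lysed, stained whole-blood
acquisition on an 18-fluorescence-parameter panel (21 antibodies; the
CD3/CD19/CD20/CD56 FITC dump is one pooled "Lineage" parameter) plus
FSC-A/FSC-H/SSC-A.

**Composition.** Live single mononuclear events are a multinomial over
eleven populations. The healthy defaults encode the cohort means the
panel is expected to recover: pDC 0.44%, cDC1 0.02%, cDC2 0.49%, slanDC
0.07%, moDC 0.001% ("almost undetectable", so the gate is exercised but
near-empty), plus a CD141⁻/CD1c⁻ cDC remainder at 0.28% so that the
total-cDC gate (CD123⁻CD11c⁺ DC-lineage cells) sums to 0.79%. The filler
composition (T 60%, B 10%, NK 9%, monocytes 18%, other lin⁻HLA-DR⁻ cells
~1.7%) is a plausible fixed choice for lysed whole blood. On top of the
mononuclear events every sample carries 5% dead cells (viability-stain
bright), 2% doublets (two random singlets with summed areas and the
larger height, so an FSC-H/FSC-A ratio gate detects them), 1% residual
granulocytes (high SSC) and 2% debris (low FSC, CD45⁻).

**Expression.** Marker expression is two-state: "off" is normal
autofluorescence (mean 120, SD 55; negatives are possible and retained)
and "on" is log-normal with the target mean and CV 0.5. Absolute on-state
scales are free parameters — the source figures print no MFI axes values
that could be used — constrained only in ordering and direction: basal
CD40/CD86 lowest on pDCs, CD40 higher and CD86 lower on cDC1s than
cDC2s, slanDCs above cDC2s; CD80 negligible everywhere; PD-L1 low on
slanDCs only; ILT2 absent on cDC1s and highest on slanDCs; TIM-3 highest
on cDC1s, lowest on pDCs.

**Stimulation.** Conditions multiply the on-state means of the six
read-outs per subset. Defaults encode the reported directions: LPS fully
activates cDCs and slanDCs with marginal pDC activation; IMQ gives its
strongest CD40 induction on pDCs; CD80/CD86 upregulation is larger on
cDC2s than cDC1s; PD-L1 rises on all subsets (highest slanDC, lowest
cDC1); ILT2 rises on cDC2s but not cDC1s; TIM-3 is untouched. IL-10
alone is nearly inert; combined with a TLR ligand it halves the
costimulatory induction (multiplier `1 + 0.5(m−1)`) and enhances the
checkpoint induction (`1.5 m`). The magnitudes are documented free
parameters, chosen once; conclusions drawn from them are directional.

**Donor variability.** Population frequencies get per-donor log-normal
factors with subset-specific CVs (pDC 0.5, cDC1 0.8, cDC2 0.25, slanDC
0.8, others ≈ 0.1), calibrated so a 16-donor cohort SEM has the order of
magnitude of the reported ± values. The 16 factors per population are
quantile-balanced (permuted quantile midpoints of the log-normal,
normalized to unit mean) rather than i.i.d.: the cohort spread matches
the configured CV while the cohort-mean truth equals the configured
frequency, so frequency-recovery tests measure gating error, not the
luck of one cohort draw. Read-out expression means get i.i.d. per-donor
log-normal factors (CV 0.2) shared across conditions, which cancel in
fold changes.

**MDS mode.** The 10-donor MDS cohort multiplies all DC frequencies by
0.35, applies basal overrides (cDC2 CD86 ×1.6 and ILT2 ×1.5, mild pDC
activation, and the subverted cDC1 repertoire: ILT2 ×10, TIM-3 ×⅓,
CD141 ×1.6, CD86 ×2) and attenuates all TLR multipliers
(`m → 1 + 0.45(m−1)`, i.e. TLR hyporesponsiveness). All are directional
encodings of the reported patient contrasts, not fitted magnitudes.

**Spillover.** The ground-truth spillover matrix is identity plus sparse
off-diagonals (30% occupancy, uniform in [0, 0.2], per-row off-diagonal
sum capped at 0.8 for conditioning), fixed by the config seed. Real
fluorochrome overlap is similarly sparse; values up to 0.2 exercise the
compensation step hard.

**Determinism.** Every (population-block, channel) pair draws from its
own seeded RNG stream, so a sample is bit-reproducible from
`(config, donor, condition, seed)` and an FMO control differs from its
paired full-stain sample only in the omitted marker's pre-mixing signal.

**What the generator does not model:** acquisition-time drift, carryover,
non-linear detector response, autofluorescence spectra (spillover acts
only on stain signal), population substructure within subsets, and any
bone-marrow material. Passing tests therefore demonstrate correctness of
the analysis pipeline under the stated statistical model, not robustness
to every artifact of real acquisitions.

## Compensation

Spillover is estimated per single-stained bead file: positive/negative
bead populations are split by a deterministic 1-D 2-means on the asinh
scale, `S[i,j] = (median_j(pos) − median_j(neg)) / (median_i(pos) −
median_i(neg))`, diagonal normalized to 1, negatives clamped to 0.
Medians make the estimate robust to bead outliers. A configurable
signal-to-background minimum (default 10 robust SDs) rejects files whose
populations do not separate. Compensation solves `observed = true · S`
by right-multiplication with `S⁻¹` (LAPACK solve, no explicit inverse);
compensated values may be negative and are retained, as is standard —
the gating transform handles them. A metadata flag prevents double
compensation. The pipeline assumes uncompensated input.

## Gating

Fluorescence channels are asinh-transformed with cofactor 150 (scatter
stays linear). Thresholds are data-derived per sample: for each channel
the "internal negative" population is the lower cluster of a 1-D 2-means
split (the whole sample if the cluster centers are closer than 2 asinh
units, i.e. the channel is effectively unimodal), and the threshold is a
percentile of that negative distribution.

Two percentile choices matter:

- `derive_threshold` defaults to the 99.5th percentile — appropriate for
  FMO-based read-out thresholds, where the parent population is the
  gated subset itself.
- The gate tree uses the 99.95th percentile for identity markers. At
  99.5, the 0.5% false-positive tail of an abundant parent would swamp a
  rare child gate: monocytes are ~18% of mononuclear cells and sit inside
  the inflammatory parent gate, so 0.5% of them (+0.09 percentage
  points) would more than double the 0.07% slanDC gate. At 99.95 the
  contamination is ~0.01 points, an order of magnitude below the
  between-donor spread, while the extra loss of true cells in exclusion
  gates is only 0.05% per gate. The internal-negative floor is 100
  events (the percentile only needs the bulk of a well-separated
  distribution); FMO-derived thresholds keep the stricter 500-event
  floor.

Fixed geometric gates: the mononuclear scatter rectangle
(FSC-A ∈ [25 000, 120 000], SSC-A ∈ [1 000, 60 000]) is calibrated to
the generator's lymphocyte + monocyte clusters and excludes granulocytes
and debris; real-data use requires user-supplied vertices. The singlet
gate keeps FSC-H/FSC-A ≥ 0.75.

Tree logic and tie-breaks: pDC = CD123⁺CD11c⁻ and cDC = CD123⁻CD11c⁺ are
quadrant-exclusive; inside the cDC gate a CD141⁺CD1c⁺ double positive is
called cDC1 (bright CD141 defines cDC1s, cDC2s can express low CD141) —
configurable but CD141-first by default; in the inflammatory branch
M-DC8 takes precedence over CD1a; and DC-lineage labels take precedence
over inflammatory ones, so each event carries at most one terminal
label. Subset frequencies are percentages of the mononuclear (live,
singlet, scatter-gate) denominator. CD45 is deliberately not a tree
gate; it pre-filters the embedding input only.

## Net MFI, fold change, statistics

Net MFI is the arithmetic mean of compensated linear intensities over
subset events minus the same statistic in the matched FMO control
(median available as an option). The linear-scale mean is used because
the read-out is a *mean* fluorescence intensity; negative net MFI is
retained. Records with fewer than 30 gated events are flagged
unreliable — mirroring the practice of not phenotyping subsets that are
too rare (e.g. cDC1s and slanDCs in MDS blood). FMO controls are
simulated once per donor and marker under basal conditions and reused
across conditions, since the omitted marker's background is
condition-independent by construction.

Fold change divides a condition's net MFI by the same donor/subset/
marker basal net MFI; basal values at or below the positivity floor
(default 0) make the ratio undefined (NaN, excluded listwise with a
logged count) rather than exploding.

Paired and unpaired Student t statistics are implemented from the
textbook closed forms (`t = mean(d)/(sd(d)/√n)`; pooled-variance
unpaired) with two-sided p-values from the t distribution; SciPy's
implementations serve as independent oracles in the tests, never as the
implementation. Zero-variance paired differences return an undefined
statistic flagged `degenerate` instead of a silent p = 1. No
multiple-testing correction is applied — contrasts report raw two-sided
p-values, matching the analysis design; this is a documented limitation.

## Embedding

Samples are filtered to live, singlet, CD45⁺, lineage⁻, HLA-DR⁺ events,
barcoded, concatenated, and embedded with Barnes-Hut t-SNE (scikit-learn)
at the protocol hyperparameters: 800 iterations, perplexity 20, θ = 0.5,
learning rate 200, deterministic initialization realized as PCA initial
coordinates (the conventional deterministic choice). Features are the
asinh-transformed intensities of the 15 identity + read-out markers,
standardized per marker (the protocol is silent on scaling; standardizing
keeps bright lineage channels from dominating distances — conclusions
that depend on this choice are noted here). Scatter and viability never
enter the feature set. θ = 0 switches to the exact gradient, used by the
permutation-invariance property test. Coordinates are reproducible for
fixed input and seed.

Desk-scale runs down-sample to 10 000 events, stratified by gated label:
rare subsets are kept in full and abundant classes share the remaining
quota (balanced allocation). A uniform down-sample would carry only ~10
cDC1 events (0.02% of mononuclear cells), too few for any neighbor
statistic; stratification is the standard rare-population workaround and
changes class balance, not within-class geometry.

Two artifact statistics quantify the visual map comparisons:

- **k-NN label purity** (leave-one-out majority vote at k = 15, per
  subset, non-DC events voting with a background label) — a purity
  measure robust to extreme class imbalance.
- **region shift** between two groups of one subset's events: centroid
  displacement normalized by pooled within-group spread, and a
  chance-normalized cross-group k-NN mixing score (1 = exchangeable,
  0 = disjoint); a subset is flagged "shifted" when mixing < 0.5. The
  statistic is symmetric in the groups and requires ≥ 50 events per
  group. It is an addition to the visual analysis and labelled as such
  in reports.

The MDS-vs-healthy region comparison uses unstimulated samples only (the
concatenated patient cDC1 phenotyping is likewise done on unstimulated
files); pooling stimulated samples would entangle TLR hyporesponsiveness
with basal subset location. Under the default effect maps the
stimulated-vs-basal comparison flags cDC2 most strongly, but pDCs and
slanDCs also move (their checkpoint induction is real); the clean
negative control for the shift statistic is the MDS comparison, where
pDC/cDC2/slanDC remain unshifted.

## Problem sizes and numerical choices

Cohort-scale analyses run at 50 000 events/sample (16 + 10 donors),
bead estimation at 20 000 events/file, phenotyping at 20 000
events/sample with 15 000-event FMOs, and embeddings at 10 000
down-sampled events — sizes chosen so the statistical targets (2 cohort
SEM on frequencies, 5–10% on MFI/fold-change recovery) are met with
single-CPU runtimes of seconds to a couple of minutes per stage.
Degenerate inputs are surfaced, not silently absorbed: unknown
conditions, missing bead channels, non-separating bead populations,
missing thresholds, too-few control events, already-compensated input
and empty subsets all raise with named diagnostics.

## Known limitations

- Absolute MFI scales, stimulation magnitudes and MDS effect sizes are
  free parameters; only orderings and directions are grounded, so the
  package reproduces patterns, not printed figure values (which do not
  exist in printed form).
- The mononuclear scatter gate is generator-calibrated; real instruments
  need user-supplied vertices (and ideally a logicle rather than asinh
  transform for strongly negative compensated data).
- The t-SNE region-shift flag depends on feature scaling and the mixing
  cutoff; it is a reproducible surrogate for a visual judgement, not an
  inferential test.
- Net MFI assumes compensation residuals are population-independent;
  with heavily overlapping panels on real instruments, FMO placement
  interacts with compensation error in ways the generator does not
  model.
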