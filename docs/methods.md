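# Methods

This note records the models behind `senrev`, the defaults and why they were
chosen, what the synthetic data does and does not emulate, and the numerical
conventions a maintainer should know.

## Screen model and Z scoring

The unit of observation is the well of a 384-well plate. Per-cell features
(cell/nuclear area in µm², cell/nuclear elongation as an axis ratio ≥ 1,
cell/nuclear roundness in (0, 1]) are collapsed to the per-well median —
robust to segmentation outliers — while cell count is the raw number of
segmented cells. Z scores are anchored to the siGLO negative-control wells of
the *same plate*: Z = (value − control mean)/control SD with the unbiased
sample SD, so plate-to-plate shifts cancel by construction and control wells
self-normalise to sample mean 0 / SD 1 exactly. A robust variant
(median, MAD × 1.4826) is available for plates with control outliers.
Replicate wells collapse by the median of their Z values within an arm.
Degenerate cases: an empty well keeps its count of 0 but has undefined
morphology; a plate/feature with zero control SD yields undefined Z with a
warning rather than an error; fewer than two usable control wells on a plate
is an error.

Hit calling uses the directional reversal signature (cell count up; cell
area, nuclear area, nuclear elongation down; nuclear roundness, cell
elongation up; cell roundness is measured but not part of the signature).
Defaults: z_threshold = 2 and at least 3 of the 5 signature morphology
features, both configurable. |Z| ≥ 2 is the conventional high-content cut
and, with the cell-count requirement plus a 3-of-5 morphology consensus,
keeps the null false-positive rate well under 5% while leaving planted ±4 SD
effects near-certain hits. Dose dependence (30 vs 60 nM arms) requires both
Z past the threshold, a shared sign, and |Z(60)| ≥ |Z(30)|.

Arm classification gives Group 1 precedence: an siRNA that reverses
senescence on its own is `independent` even when it is also a hit with p16
or p21 co-depletion — the interesting biology is that it needs no helper —
and `multi-arm` is reserved for siRNAs hitting in both co-depletion arms but
not alone. Replicate concordance across independent screen runs is
reported but not required for a hit, since requiring it is a stricter rule
than the screens' stated design implies.

## Synthetic data: what it emulates and what it does not

Each morphology feature is a fixed monotone transform of a latent Gaussian —
areas `exp(g)`, elongations `1 + exp(g)`, roundness `logistic(g)` — with a
cell-level SD within wells and a well-level SD between wells; per-well cell
counts are negative binomial (dispersion 50) for realistic overdispersion.
Planted siRNA effects are expressed in control-SD units *of the well-level
aggregate*: a shift of e multiplies into the latent location as
e·√(τ² + πσ²/2n̄) (between-well SD plus the sampling noise of a median of n̄
cells), so the planted effect equals the expected downstream Z to first
order. The logistic transform for roundness (rather than a scaled beta) was
chosen precisely to keep this latent-shift scheme uniform across features;
at the default scales the transform nonlinearity biases a planted |e| = 4 by
roughly 10%, which is immaterial at a calling threshold of 2. Measured over
many seeds, a planted +4 cell-count shift recovers as Z ≈ 4.3 ± 1.3; about
2% of planted reversers fall below the threshold per screen, which is the
honest sampling behaviour of the design, not a bug.

Default phenotype locations put DS cells at roughly 2.3× the EP cell and
1.8× the nuclear area, half the EP well occupancy, more elongated and less
round nuclei and less elongated cell bodies — the senescent morphology
direction — and the reversed phenotype close to EP. One plate carries one
(arm, replicate) combination with 16 evenly spaced siGLO wells; all
generators derive per-plate RNG streams deterministically from the call's
seed.

Not emulated: spatial plate effects (edge wells, gradients), cell-level
feature correlations, segmentation errors, transfection-efficiency
variation, and batch effects between the two independent screen runs.
Passing recovery tests therefore show the statistics are implemented and
calibrated correctly, not that real screens are free of these artefacts —
on real data the robust Z variant and the replicate-concordance report are
the first knobs to reach for.

The expression generator plants genes whose DS mean rises by a chosen number
of residual-SD units and returns to the EP level on reversal
(`revert_fraction` = 1 by default); non-planted genes are exchangeable
across conditions. The promoter generator plants exact motif copies at
non-overlapping positions on random strands over i.i.d. background at a
chosen GC fraction; by default the background is untouched, so spurious
exact matches occur at the closed-form rate 2(L−m+1)(1/4)^m, and an
`ensure_motif_free` flag redraws backgrounds for constructions that need
exact planted counts. The network generator wires a requested number of
interactors to random seeds plus second-degree distractors that a depth-1
expansion must ignore.

## Statistics

* **Differential expression:** Welch two-sample t on log-scale values,
  two-sided; directionality is imposed on the effect sign, not the test
  tail. A gene with zero variance in both groups gets p = 1 at zero effect
  and p = 0 otherwise (documented convention, not an error). BH adjustment
  is applied per contrast; candidates must pass q < 0.05 in both contrasts
  with the right signs, ranked by ascending q in the DS-vs-EP contrast,
  ties by descending |effect|, then gene id. With 4 replicates per group a
  5-SD planted effect has P(p < 0.01) ≈ 0.97 but P(p < 0.001) only ≈ 0.57
  (df ≈ 6), while the selection stage still recovers ≥ 95% of planted genes
  — power claims in tests are stated at these derived levels.
* **Motif enrichment:** the statistic is the fraction of genes with ≥ 1
  promoter hit (presence/absence; robust to promoter-length artefacts), a
  total-count variant behind a flag. Backgrounds are size-matched samples
  without replacement from universe \ foreground; N_bg defaults to 1,000;
  the add-one empirical p never reaches 0. IUPAC codes other than N are
  rejected; N never matches.
* **Gating:** default method is reference-based (negative-control
  mean + 2·SD), mirroring standard immunofluorescence practice; Otsu and
  absolute thresholds are alternatives. Positivity is strictly above the
  threshold, making the positive fraction monotone non-increasing in the
  threshold.
* **Focus counts:** two-sided rank-sum test; with ≤ 10 nuclei per group the
  p-value comes from exhaustive permutation of midranks (tie-safe, and
  symmetric under swapping groups), otherwise from the asymptotic
  Mann–Whitney U with tie correction.

## Pipeline and reproducibility

`run_pipeline` writes every input it generates and every result table under
the output directory, then a `manifest.json` with all parameters and SHA-256
checksums. All randomness flows from the single config seed through
deterministic per-stage sub-seeds, so identical configs give byte-identical
tabular outputs. Floats in tables are written at fixed precision (4 decimal
places; 6 for expression) with deterministic row order. A stage failure
aborts the run, names the stage in the raised error, and leaves a manifest
marked `incomplete`. The pipeline's motif stage caps the foreground at half
the promoter universe (in candidate-rank order) so disjoint size-matched
background sampling is always possible.

Problem sizes used by the test suite and the acceptance script (190-siRNA
single-arm and 60-siRNA three-arm screens at 3 replicates, ~70 cells per
well, 1,000-gene expression matrices, 150–400-gene promoter universes,
N_bg = 1,000) were chosen to keep a full run interactive on a single CPU
while leaving every statistical property comfortably detectable.

## Known limitations

* Well aggregation is median-only; mean/trimmed-mean aggregators would need
  a small extension of `aggregate_wells`.
* Gene identifiers are opaque case-sensitive symbols; no alias resolution is
  attempted, so edge lists and annotation tables must share the screen's
  naming.
* The promoter windowing convention (2 kb upstream to +200 by default when
  promoters are extracted elsewhere) is a documented convention only — the
  pipeline consumes pre-extracted FASTA and never touches a genome.
* The enrichment test resamples gene sets, not sequence composition;
  GC-matched backgrounds are out of scope.
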