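# senrev

Analysis toolkit for **senescence-reversal high-content siRNA screens**: the
computational workflow used to find transcriptional regulators (such as EGR2)
whose knockdown pushes deeply senescent cells back toward a proliferating
phenotype.

It is written for groups running arrayed 384-well siRNA screens with
image-based per-cell readouts (cell count plus cellular/nuclear morphology),
and covers the downstream informatics: candidate selection from expression
data, control-anchored hit calling, marker gating, interaction-network
expansion and promoter motif enrichment. A synthetic-data generator with
planted ground truth makes every stage testable without access to raw screen
images.

## The method

**Candidate selection.** From a gene × sample log-intensity matrix over three
states — early proliferating (EP), deep senescence (DS) and reversed (R) —
genes are kept when they are significantly up in DS vs EP *and* down in R vs
DS (Welch *t* per contrast, Benjamini–Hochberg *q* < 0.05 in both), ranked,
and truncated to the top *N* (default 190).

**Control-anchored Z scores.** Per-cell features are collapsed to well
profiles (median per feature; raw cell count). For each plate and feature,

&nbsp;&nbsp;&nbsp;&nbsp;*Z* = (well value − mean of siGLO control wells) / SD of siGLO control wells,

with the unbiased sample SD (a median/MAD variant is available). Replicate
wells collapse to one Z row per (siRNA, arm) by the median.

**Reversal signature and hit calling.** Reversal means cell number **up**;
cell area, nuclear area, nuclear elongation **down**; nuclear roundness and
cell elongation **up**. An siRNA is a hit in an arm when *Z*(cell count) ≥ 2
and at least 3 of the 5 signature morphology features pass |*Z*| ≥ 2 with the
expected sign. Arms model the co-depletion design: siRNA alone at 30 nM
(Group 1) or 60 nM (Group 1B), with p16 siRNA (Group 2), or with p21 siRNA
(Group 3); arm patterns classify each siRNA as `independent`, `requires-p16`,
`requires-p21`, `multi-arm` or `non-hit`, and paired 30/60 nM arms yield a
dose-dependence flag.

**Downstream.** Screen hits seed a depth-1 expansion over a protein
interaction edge list with six functional categories; promoters are scanned
on both strands for the EGR2 consensus `ACGCCCACGCA`, and foreground gene
sets are tested for enrichment against size-matched background sets resampled
from the universe, with the add-one empirical p-value
*p* = (1 + #{background ≥ observed}) / (1 + *N*<sub>bg</sub>). Marker
analyses gate per-cell intensities (reference mean + *k*·SD, Otsu, or an
absolute cut), tabulate p16/p21 quadrants including the double-negative
"reversed" fraction, and compare nuclear-focus count distributions with a
tie-safe rank-sum test (exhaustive permutation at small *n*).

## Worked example

Simulate a 40-siRNA single-arm screen with one planted reverser shifted by
±4 control-SD along the signature, then score it:

```python
from senrev import (
    DEFAULT_PARAMS, EffectMap, LayoutSpec, aggregate_wells, call_hits,
    compute_zscores, generate_screen, reversal_effect, summarize_hits,
)

library = [f"si{i+1:03d}" for i in range(40)]
effects = EffectMap(shifts={"si001": reversal_effect(4.0)})
cells, layout, truth = generate_screen(
    library, LayoutSpec(arms=("Group1",), replicates=3),
    DEFAULT_PARAMS, effects, seed=1,
)
z = compute_zscores(aggregate_wells(cells, layout), layout)
print(z.values.loc[("si001", "Group1")].round(2))
hits = call_hits(z)
print(summarize_hits(hits))
```

```
cell_count            3.76
cell_area            -2.41
nuclear_area         -3.27
cell_elongation       1.89
nuclear_elongation   -2.54
cell_roundness       -0.41
nuclear_roundness     4.77
Name: (si001, Group1), dtype: float64
      arm  n_sirna  n_hits  hit_rate
0  Group1       40       1     0.025
```

The planted siRNA's Z row points the reversal way (more cells, smaller
cells/nuclei, rounder nuclei), it is the single hit called, and the screen
hit rate is 1/40. The full pipeline — generation, selection, scoring,
network, motif and marker stages with a checksum manifest — runs from one
YAML config:

```sh
senrev run-all --config config.yaml        # or: senrev generate / select /
                                           # score / network / motif / markers
```

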