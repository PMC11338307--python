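# tractofluency

Tractometry of speech-fluency pathways: a tested, reusable pipeline that
links white-matter microstructure along the cerebellar peduncles (SCP,
MCP, ICP) and the frontal aslant tract (FAT) to speech-fluency measures
in neurotypical adults.

## Who this is for

Researchers running brain–behavior tractometry analyses on diffusion MRI:
you have per-subject streamline bundles (TRK/TCK), scalar maps (FA, MD),
and behavioral scores, and you want node-wise along-tract statistics with
honest multiple-comparison control. The package also ships a synthetic
cohort generator that emulates the whole data-generating process, so
every stage — and its statistical calibration — can be exercised and
tested without any imaging data.

## What it computes

**Speech-fluency measures.** From utterance-annotated transcripts:
speaking rate = Σ syllables / Σ duration over all utterances (syllables/s);
articulation rate = the same ratio over fluent utterances only; phonemic
and semantic verbal fluency = correct unique responses summed over three
letter/category criteria (repetitions, flagged errors, and subcategory
words with produced exemplars are not counted); plus disfluency
statistics by type (I, R, PW, SS, PR, DP).

**Bundle segmentation.** Waypoint-ROI logical operations (keep a
streamline iff it has a point in every include ROI and none in any
exclude ROI; closed-interval box tests), iterative statistical outlier
cleaning (remove streamlines longer than mean + 4 SD of bundle length —
1 SD for the short ICP — or spatially deviating more than 4 SD from the
bundle core), and clipping to the core segment enclosed between the two
waypoint ROIs.

**Tract profiling.** Streamlines resampled to 30 equidistant nodes;
core = per-node mean position; node value = distance-weighted mean of
streamline scalars (Gaussian weights on Mahalanobis distance to the
core, or uniform); tract value = mean across nodes. FA and MD follow the
tensor-eigenvalue definitions MD = (λ₁+λ₂+λ₃)/3 and
FA = √(3/2)·√Σ(λᵢ−MD)² / √Σλᵢ².

**Statistics.** Two-tailed Spearman ρ (mid-ranks, t-approximation
p-values); mean-tract correlations with Benjamini–Hochberg FDR at
q = 0.05 across the 8-tract family (separate families per behavior and
metric); along-tract node-wise correlations with cluster-size
permutation control of familywise error — a cluster is significant when
every node has uncorrected p < 0.05 and the run is longer than the
critical size, the (1−α)-quantile of the maximum suprathreshold run
length over permutations of the behavioral vector; first-order partial
Spearman correlations; and the Meng–Rosenthal–Rubin Z test comparing two
dependent correlations sharing a variable.

## Worked example

`examples/04_along_tract_stats.py` embeds a Spearman ρ = −0.45
association between MD at nodes 17–22 and speaking rate into an
otherwise null 45-subject cohort and runs the cluster permutation test:

```
critical cluster size: 5 nodes
significant cluster: nodes 17-25, mean rho = -0.465
  partial rho controlling articulation rate: -0.512 (p = 0.0004)
```

The permutation null says chance alone produces suprathreshold runs of
up to 5 nodes; the observed 9-node run overlapping the planted window
survives, its mean correlation recovers the planted effect size, and the
association persists when articulation rate is held constant — the
follow-up that separates lexical from articulatory contributions.

The other examples cover the synthetic behavioral copula
(`01_synthetic_cohort.py`), transcript scoring (`02_speech_measures.py`),
segmentation + profiling (`03_segmentation_profiling.py`), and the whole
pipeline in one call (`05_full_pipeline.py`). The same stages are
available from the shell:

```bash
tractofluency run --seed 2 --out results/run1
tractofluency speech --transcripts results/run1/transcripts.tsv --out behavior.csv
```

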