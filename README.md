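# polarcell

Quantifying cell polarity and asymmetric division from single-cell
fluorescence microscopy.

Hematopoietic stem cells (HSCs) preparing to divide often redistribute
fate-relevant molecules — tubulin, CDC42, NUMB, activated signaling
proteins — into a pole of the cell, and an asymmetric division hands the
two daughters unequal amounts of such markers. `polarcell` implements the
two measurements used to score this behavior on multi-channel
immunofluorescence images of single cells and daughter-cell doublets,
together with the frequency statistics used to compare experimental
conditions, and a synthetic-image generator with programmable ground
truth so every step of the pipeline can be verified quantitatively
without access to microscope data.

## The measurements

**Polarity call (per channel).** For each cell: maximum-intensity
z-projection per channel; a cell mask from the across-channel composite;
per-channel background subtraction (median of outside-mask pixels);
within-mask intensities quantized into *k* = 5 bins by globally optimal
1D k-means; pixels of the brightest bin(s) grouped into 8-connected
components; speckles smaller than 5 px discarded. With the polarity
identification zone set 15 px inward from the cell boundary and an
exclusion area of radius 10 px at the cell centroid, the channel is
**polar** iff the convex hull of all surviving clusters does not overlap
the exclusion area. The cluster direction (mask centroid → intensity-
weighted cluster centroid) is reported against the cell's major axis,
and the **polarization angle** of a channel is the angle between its
cluster direction and that of the reference (tubulin) channel, folded
into [0°, 180°].

**Paired-daughter call (per marker).** For a doublet imaged after one
division, the sister ratio is

&nbsp;&nbsp;&nbsp;&nbsp;*r* = max(ΣI_A, ΣI_B) / min(ΣI_A, ΣI_B)

over background-subtracted pixel sums of the two daughter masks. A
marker is inherited **asymmetrically** when *r* > 1.5, **symmetrically**
when *r* < 1.2, and is left indeterminate in between. Two markers
co-segregate when both are asymmetric into the same daughter.

**Statistics.** Per-condition class frequencies are summarized as mean ±
sample SD over replicates and compared with a two-sided Fisher's exact
test on pooled counts (probability-mass rule) and a two-tailed pooled
Student's *t* test on replicate percentages.

## Worked example

Generate a labeled synthetic cohort (30 single cells at the default 60%
polar mixture, 20 doublets with a programmed sister ratio of 2.0), then
score it:

```sh
polarcell synthesize --outdir demo --n-cells 30 --n-pairs 20 --seed 7
polarcell polarity  --manifest demo/manifest.csv --outdir demo/polarity
polarcell pairs     --manifest demo/manifest.csv --outdir demo/pairs
```

which prints

```
wrote 50 images under demo
scored 30 cells: 36/60 channel calls polar
classified 20 pairs: 40/40 marker calls asymmetric
```

`demo/polarity/cells.csv` holds one row per cell per channel, e.g.

```
cell_id,condition,replicate,channel,is_polar,n_clusters,direction_deg,angle_to_axis_deg,...
CTRL_cell_0000,CTRL,rep1,tubulin,True,1,184.616,3.75146,...
```

— this cell's tubulin cluster points 184.6° from the +x axis, 3.8° off
the cell's major axis. `demo/polarity/polarity_summary.csv` aggregates
the calls per condition:

```
condition,polarity_class,mean_pct,sd_pct,n_replicates,n_items
CTRL,nonpolar,40,10,3,24
CTRL,polar,60,10,3,36
```

60% ± 10% of channel calls are polar across the three replicates —
matching the 60% polar mixture the cohort was generated with. The
paired-daughter summary (`demo/pairs/...csv`) likewise reports 100%
asymmetric divisions for the ratio-2.0 doublets. A self-contained
recovery benchmark against the generator's ground truth is available as

```sh
polarcell benchmark --outdir demo/bench --seed 7
# polar-call accuracy 1.000, direction RMSE 3.93 deg
```

Every command writes a `params.json` recording the effective parameter
set and seed; identical configuration and seed reproduce outputs
byte-for-byte. All thresholds (zone width, exclusion radius, bins,
minimum cluster size, ratio cutoffs) are exposed as CLI flags and in a
YAML config file, and the same functionality is available as a library
(`polarcell.score_cell`, `polarcell.score_pair`,
`polarcell.summarize_cohort`, ...).

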