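# fourcbricks

4C-seq (circularized chromosome conformation capture with sequencing)
measures how often one genomic locus — the *viewpoint* — physically contacts
every other region of the genome.  `fourcbricks` is a tested, reusable
pipeline for the analysis style used to study chromatin architecture around
large copy-number variants such as the Williams–Beuren syndrome deletion:
it takes per-fragment 4C read counts from a rearranged and a control
condition and produces multi-scale interaction calls ("Bricks"), condition
differences (signed ratio Bricks), and permutation-based enrichment of the
interacting regions in genomic feature sets.  A ground-truthed synthetic
data generator makes the whole pipeline exercisable offline.

## The method

Signal lives on the virtual library of BglII restriction fragments
(`digest_genome`).  Reads are assigned to fragments by 5′ position,
self-ligation artifacts at the viewpoint are masked, counts are normalized
to library size, smoothed with a 19-fragment running mean and averaged over
replicates.  The strong local background follows the polymer contact decay

    E[signal](d) = 10^a / d + b        (slope −1 in log–log space),

with intercept `a` fitted robustly (signal-weighted median) and `b` the
distance-independent random-ligation floor; subtracting it gives the
profile-corrected track.

Bricks are called with a domainogram: fragment scores are ranked per
chromosome and every window of width `w ≤ Wmax` is scored with

    z(i, w) = (mean rank − 1/2) · √(12 w),   p = 1 − Φ(z),

refined by the exact Irwin–Hall tail for extreme windows, so no single
window size is imposed.  Disjoint significant windows are selected
strongest-first under a Benjamini–Hochberg-type stopping bound, with a
relaxed FDR (0.1) inside the short-range window around the rearrangement
(HSA7:53,532,296–78,116,172 in the original design) and a stringent one
(0.001) elsewhere.  Consecutive Bricks merge into interacting regions.

For the two-condition contrast, the pipeline computes log2(case/control) of
the smoothed tracks (the decay background cancels, so a hemizygous deletion
appears directly as log2 ≈ −1), calls signed ratio Bricks by running the
domainogram on both orderings of the ratio, and filters them: cross-set
overlaps > 5 % removed, genome gaps subtracted, candidates anchored to a
Brick of at least one condition.  A Wilcoxon rank-sum test compares read
counts in selected regions against the remaining Bricks, and
`shuffleBed`-style permutation tests (n = 10 000) measure enrichment of the
interacting regions in genes or histone-mark islands.

## Worked example

Simulate a deletion study (one ~4.1 Mb chromosome, viewpoint at 500 kb, a
300 kb hemizygous deletion at 1.3–1.6 Mb containing two of four planted
interaction peaks, 10⁵ reads per replicate) and run the full analysis:

```python
import numpy as np
from fourcbricks import (SimulationConfig, simulate_counts, simulate_fragment_map,
                         ShortRangeWindow, interval_change_summary, ratio_bricks)
from fourcbricks.pipeline import process_condition, call_regions, condition_ratio

cfg = SimulationConfig(seed=0).with_deletion()
fmap = simulate_fragment_map(cfg)
ctrl_counts, truth = simulate_counts(cfg, "control", fmap)
case_counts, _ = simulate_counts(cfg, "case", fmap)

ctrl = process_condition(ctrl_counts)
case = process_condition(case_counts)
srw = ShortRangeWindow(cfg.chrom, 0, cfg.chrom_length)
ctrl_bricks, ctrl_regions = call_regions(ctrl.calling, short_range=srw)
case_bricks, _ = call_regions(case.calling, short_range=srw)
ratio = condition_ratio(case, ctrl)
rset = ratio_bricks(ratio, ctrl_bricks, case_bricks,
                    gaps=np.empty((0, 2)), short_range=srw)
med, lo, hi = interval_change_summary(ratio, cfg.deletion, seed=0)
```

This prints (via the obvious `print` statements):

```
990 fragments, mean length 4141 bp
background: intercept 8.536, floor 33.261, diagnostic slope -0.87
4 control Bricks in 4 regions:
  chrSim:1,338,933-1,395,494  p=4.32e-15
  chrSim:1,444,534-1,560,030  p=3.50e-27
  chrSim:2,499,698-2,599,791  p=8.10e-27
  chrSim:3,402,107-3,499,723  p=2.57e-22
negative ratio Bricks: chrSim:942,619-1,628,129
median log2(case/control) in deletion: -0.90 (95% CI -0.91 to -0.89)
```

All four planted peaks are recovered as control regions, the deletion shows
up as one negative ratio Brick spanning it, and the median interaction
change inside the deleted interval is the expected two-fold decrease
(log2 ≈ −1, shrunk slightly toward zero by the pseudocount and total-read
renormalization).

The same chain is available from the shell: `fourcbricks simulate`,
`digest`, `count`, `smooth`, `bricks`, `diff`, `enrich`, `coverage` and
`report` (see `fourcbricks --help`).

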