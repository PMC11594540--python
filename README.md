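# exmplate

Quantitative analysis for high-throughput expansion microscopy (ExM) in
96-well plates: ring-profile cytometry of Hoechst-stained nuclear
peripheries, and expansion-quality metrics (expansion factor and
registration-based distortion error curves), with a synthetic-image
generator providing ground truth for every stage.

## Who it is for

ExM physically enlarges fixed specimens ~4× in a swellable hydrogel, so a
standard confocal reaches effective nanoscale resolution. Run in a
96-well plate it becomes a screening tool — but two questions must then be
answered computationally:

1. **Did the biology change?** Drug-treated nuclei show an intensity peak
   of DNA stain at the nuclear periphery. Because nuclei are irregular,
   the intensity is profiled by *onion-peel ring decomposition*: the
   dilated nuclear mask is peeled into concentric rings by iteratively
   removing the 4-connected boundary layer, per-ring mean intensities are
   interpolated to a length-500 profile I(u) of relative intensity versus
   normalized edge-to-center position, and three derivative metrics
   summarize the peripheral peak — the outer slope max dI/du, the inner
   slope min dI/du on u ∈ [0, 0.4], and the peak curvature min d²I/du² on
   u ∈ [0, 0.4]. Conditions are compared to control per metric by
   independent two-sample t-tests (α = 0.05).

2. **Can you trust the geometry?** The expansion factor is the mean
   landmark-distance ratio post/pre. Distortion is the smooth displacement
   field d(x) left after similarity alignment of matched pre/post fields,
   summarized as an error curve — RMS of |d(p) − d(q)| versus measurement
   length ℓ = |p − q| — and as the *average percent error*:
   mean of rmse(ℓ)/ℓ × 100 over curve points up to ℓ = 40 µm
   (post-expansion scale).

See `docs/methods.md` for the full model, defaults and limitations.

## Worked example

Simulate a dose-series plate (4 replicates × 25 nuclei per condition,
peak SNR ≈ 10) and test each dose against control, with replicates as the
unit of replication:

```python
from exmplate import plateio

cfg = plateio.RunConfig(min_area=200.0, unit="replicate")
metrics = plateio.simulate_plate_metrics(seed=11, n_replicates=4, n_nuclei=25)
table = plateio.dose_response_from_metrics(metrics, cfg)
print(len(metrics), "nuclei analyzed")
print(table.to_string(index=False))
```

```
491 nuclei analyzed
condition         metric  t_statistic      p_value  significant
    100nM    outer_slope    10.156490 5.300820e-05         True
    100nM    inner_slope   -15.293373 4.936264e-06         True
    100nM peak_curvature    -4.496583 4.118899e-03         True
     10nM    outer_slope    14.287386 7.354433e-06         True
     10nM    inner_slope   -29.717922 9.626614e-08         True
     10nM peak_curvature    -1.748843 1.308999e-01        False
      1nM    outer_slope    -1.099363 3.137524e-01        False
      1nM    inner_slope    -0.303463 7.717844e-01        False
      1nM peak_curvature     1.391022 2.136108e-01        False
      1uM    outer_slope    23.739432 3.667811e-07         True
      1uM    inner_slope   -32.192995 5.972471e-08         True
      1uM peak_curvature    -2.619694 3.960245e-02         True
```

491 of 500 simulated nuclei pass quality control. The generator's dose
model leaves 1 nM at the control level and strengthens/sharpens the
peripheral peak from 10 nM upward, and the comparisons recover exactly
that: both edge slopes become steeper (positive t for the rising outer
slope, negative for the descending inner slope) at 10 nM and above, while
1 nM shows no significant change.

The same analysis runs from the shell on a directory of TIFF stacks plus a
plate-layout YAML (`exmplate simulate|mask|profile|metrics|compare|distort|volume`;
each stage writes tidy CSVs and a provenance record), e.g.

```bash
exmplate volume 2806            # per-post retained gel volume -> 234 (nL)
```

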