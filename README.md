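# cordmap

Spatial and temporal analysis of the developing mouse spinal cord dorsal
horn: landmark-based normalization of section cell coordinates onto an
idealized template, EdU pulse-chase cumulative birthdating with sigmoid
half-birthdate estimation, quantile-level 2D kernel-density cohort maps,
dorsoventral depth profiles, and genotype cell-composition comparison — plus
a synthetic-data generator with known ground truth so every stage is
testable without microscope or spatial-transcriptomics data.

## Who this is for

Developmental neurobiologists quantifying where and when neuron types settle
in spinal cord cross-sections. Individual sections differ in orientation,
size and shape; `cordmap` registers each section's cells into a common
template coordinate frame using ten manually placed anatomical anchor
points, after which positions, depth histograms and density maps are
comparable across sections, embryos, timepoints and genotypes.

## The core procedures

**Registration.** The two midline anchors (dorsal-columns base and
dorsal/ventral-horn junction) define a rotation that verticalizes the
midline, with the junction translated to (0, 0). Each hemisection is then
stretched onto the template: a monotone piecewise-linear map in y with knots

    ventral tip → −2000,  junction → 0,  lateral dorsal horn → zone target,
    dorsal-columns base → zone target,  dorsal tip → +2000

and a compartment-wise linear map in x sending the lateral dorsal-horn
anchor to ±2000 (dorsal compartment) and the ventral lateral anchor to its
zone target (ventral compartment). Anchors land exactly on their targets,
and any perturbation composed of rotation, translation and axis-aligned
scaling is inverted exactly.

**Birthdating.** One EdU pulse per litter at embryonic day t labels neurons
born in [t, t + w] (w = 0.5 d by default). Per family, litter-mean co-labeled
fractions m_t are normalized to p_t = 100·m_t/Σs m_s ("% born at t"), and
each litter's value at t gets the constant Σ_{s<t} p_s added, so the mean
cumulative curve ends at exactly 100%. A four-parameter logistic

    Y = Bottom + (Top − Bottom) / (1 + (EC50/X)^HillSlope)

is fitted to the litter-level cumulative points; EC50 is the family's
half-birthdate. Families already near-complete at the first pulses fall back
to the asymmetric five-parameter logistic, whose half-birthdate is the
numeric 50%-of-span crossing.

**Density maps.** 2D Gaussian product-kernel density estimates on a 100×100
grid with the normal-reference bandwidth 4·1.06·min(sd, IQR/1.34)·n^(−1/5)
per axis (kernel sd = h/4). Contour thresholds enclose the densest 50%,
25%, 15%, 5% and 2.5% of points, as empirical quantiles of interpolated
per-point densities.

**Depth profiles.** Per-row means of thresholded (optionally colocalized,
i.e. pixel-product) images are compressed to 80 bins, normalized per
replicate, displayed over the dorsal-most 56 bins; registered cell y's are
binned into 200 dorsoventral bins per family and smoothed.

**Composition.** Per-replicate cell-type counts from complete sections or
hemisections (weight 0.5), normalized to sections collected, compared across
genotypes with a two-way ANOVA (cell type × genotype) and Tukey tests within
each cell type; controls can be downsampled per type by round(ρ·n_k) to
match a mutant's total.

## Worked example

```python
import cordmap as cm

template = cm.make_template("brachial")
section = cm.perturb_section(template, seed=3, section_id="S1")
cells = cm.sample_family_cells(section, cm.synthetic.DEFAULT_FAMILY_DEPTHS,
                               200, seed=5)
reg = cm.register_section(cells, section.anchors_raw, template)

import numpy as np
rms = np.sqrt(np.mean((reg["x_norm"] - cells["true_x"])**2
                      + (reg["y_norm"] - cells["true_y"])**2))
print(f"RMS recovery error: {rms:.3g}")

panel = cm.simulate_pulse_panel(
    cm.BirthWaveModel(families=cm.synthetic.DEFAULT_WAVES), seed=1)
print(cm.half_birthdates(panel).to_string(index=False))
```

prints

```
RMS recovery error: 2.48e-13
family model  half_birthdate       rss  degenerate error
 dILB1   4pl       10.762338 28.042455       False
 dILB2   4pl       11.024019 15.993055       False
 dILB3   4pl       11.493306 17.753597       False
 dILB4   4pl       11.997857 25.526415       False
```

The registration error shows that the simulated section's rotation,
translation and scaling are inverted to machine precision. The
half-birthdates preserve the generating waves' half-day spacing and order
(dILB1 earliest, dILB4 latest); each sits roughly a quarter-day before its
wave's peak because a pulse at t labels everything born in [t, t + 0.5].

There is also a CLI over the same functions:

```
cordmap simulate --seed 1 --out demo/
cordmap register --anchors demo/anchors.csv --cells demo/cells.csv --out demo/registered.csv
cordmap birthdate --counts demo/pulse_counts.csv
cordmap run --seed 1 --out demo_full/   # full pipeline with manifest
```

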