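# fiberredox

Fiber-type-specific analysis of the skeletal muscle optical redox state from
multichannel immunofluorescence cross-sections.

Skeletal muscle mixes metabolically distinct myofiber types — slow-oxidative
(MHC I), fast-oxidative (MHC IIa) and fast-glycolytic (MHC IIx) — and the
balance between the autofluorescent cofactor pools NADH (reduced) and
FAD-containing flavoproteins (Fp, oxidized) differs between them and shifts
with exercise. `fiberredox` turns section images into per-fiber redox
measurements and section-level capillarization morphometry, and provides the
mixed-effects inference layer used to compare fiber types and timepoints
across a cohort. It is written for muscle physiologists working with
cryosection fluorescence imaging (e.g., vastus lateralis biopsies) and for
methodologists who want a fully simulatable test bed: a built-in synthetic
section generator plants complete ground truth, so every stage of the
pipeline is verifiable without any microscopy data.

## What it computes

**Optical redox ratio.** For each segmented fiber, background-subtracted mean
intensities NADH and Fp give the oxidation-to-reduction ratio

    redox ratio = Fp / (Fp + NADH)  ∈ [0, 1],

higher = more oxidized. The ratio is computed per fiber and only then
averaged within type (mean of ratios, not ratio of means).

**Fiber typing.** Fibers are segmented from the MHC I / MHC IIa stains (plus
an optional autofluorescence channel that lights up MHC-double-negative
fibers) by thresholding, hole filling and watershed splitting on the distance
transform. Typing follows the standard positivity rules: MHC I⁺/IIa⁻ → I,
I⁻/IIa⁺ → IIa, I⁻/IIa⁻ → IIx, I⁺/IIa⁺ → hybrid (excluded from all
downstream statistics).

**Capillarization.** From a capillary stain (PAS-style): capillary density
(CD, capillaries/mm²), capillary-to-fiber ratio (C:F), mean capillary
contacts per fiber (CC), sharing factor (SF = CC/C:F), contacts per fiber
area (CC/FA ×1,000), and geometric O₂ diffusion distances — the maximal
(average) diffusion distance is the radius within which 95% (50%) of fiber
area is served by its nearest capillary, computed from the Euclidean
distance transform.

**Inference.** A linear mixed model `value ~ time + fiber_type + (1|subject)`
(REML, statsmodels backend) with Tukey-adjusted pairwise contrasts of the
estimated marginal means, reported as percent differences with 95% CIs;
per-subject exercise deltas; Spearman rank correlations. Cohort screening
utilities implement Goldberg/Black EI:BMR dietary-plausibility cutoffs and
HOMA-IR.

## Worked example

```python
import fiberredox as fr

params = fr.SectionParams(seed=42)           # ~70 fibers, 896x896 px @ 0.65 µm/px
images, truth = fr.generate_section(params)  # 7 channels + planted truth

rois  = fr.segment_fibers(images["MHC1"], images["MHC2a"], images["Fp"])
calls = fr.classify_fibers(rois, images["MHC1"], images["MHC2a"])
table = fr.quantify_section(rois, calls, images["NADH"], images["Fp"])
print(table[table.included].groupby("type").redox_ratio.agg(["mean", "count"]))
```

prints

```
       mean  count
type
I     0.530     25
IIa   0.474     18
IIx   0.466      3
```

— the planted oxidative gradient (type I most oxidized, IIx least) recovered
from the images: with the default simulator intensities the planted ratios
are 0.529 (I), 0.472 (IIa) and 0.464 (IIx). Continuing with capillarization:

```python
caps  = fr.detect_capillaries(images["CAP"])
inc   = [r for r in rois if r.included]
cmap  = fr.build_contact_graph(inc, caps, contact_tolerance_um=1.5,
                               pixel_size=params.pixel_size)
panel = fr.capillary_panel(cmap, inc)
panel.max_dd, panel.avg_dd = fr.diffusion_distances_geometric(
    inc, caps, images["CAP"].shape, params.pixel_size)
```

gives `capillary_density=426.6/mm²`, `cf_ratio=2.23`, `cc=4.83`,
`sharing_factor=2.16`, `max_dd=39.1 µm`, `avg_dd=22.4 µm` for this seed:
about 427 capillaries per mm² of analyzed tissue, 2.2 capillaries per fiber,
and half of all fiber area within 22 µm of a capillary.

The cohort-level layer works the same way from a long table
(`subject_id, timepoint, fiber_type, value`):

```python
eff = fr.synthetic_section.default_cohort_effects()   # plants a 7.2% I-vs-IIa gap
data, _ = fr.generate_cohort(19, ("baseline", "post", "post3h"), eff, seed=5)
res = fr.RedoxMixedModel.from_dataframe(data).fit()
print(res.summary())            # fixed effects, variance components,
                                # Tukey contrasts with percent differences
```

A thin CLI mirrors the library: `fiberredox simulate | segment | quantify |
capillaries | stats | qc` (see `fiberredox --help`).

## Layout

- `src/fiberredox/synthetic_section.py` — section & cohort simulators with planted truth
- `src/fiberredox/fiber_typing.py` — segmentation, positivity thresholds, type calls
- `src/fiberredox/redox_quant.py` — background, per-fiber intensities, redox ratio, calibration, collagen
- `src/fiberredox/capillary_morphometry.py` — detection, contact graph, panel, diffusion distances
- `src/fiberredox/stats_inference.py` — mixed model, Tukey contrasts, deltas, Spearman
- `src/fiberredox/cohort_qc.py` — Goldberg/Black cutoffs, HOMA-IR
- `docs/methods.md` — models, assumptions, parameter choices and limitations
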