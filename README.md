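# discspect

Multivariate FTIR-imaging analysis of intervertebral disc degeneration.

## Scientific problem

Degeneration of the intervertebral disc begins with biochemical remodelling
of the nucleus pulposus (NP) and annulus fibrosus (AF): proteoglycan is lost
from the NP, its sulfation pattern shifts, and the collagen balance between
the fibrous outer AF (collagen I) and the gel-like NP (collagen II) changes.
Fourier-transform infrared (FTIR) imaging of thin, paraffin-embedded disc
sections measures an absorbance spectrum at every pixel, so the spatial
distribution of these constituents can in principle be mapped — but the raw
spectra are dominated by baseline drift, scattering and heavy band overlap,
and no pixel contains a pure constituent.

`discspect` implements the full analysis chain that turns transflectance
hyperspectral cubes into chemically resolved, regionally quantified disc
profiles:

1. **Preprocessing** — Savitzky–Golay second derivatives (window 15, cubic
   polynomial) remove additive and linear baselines and sharpen overlapping
   bands; tissue pixels are segmented by the amide II criterion (negative
   second derivative at 1554 cm⁻¹, i.e. positive in the working
   orientation).
2. **Unmixing** — multivariate curve resolution by alternating least
   squares (MCR-ALS) factorizes the masked pixel × wavenumber matrix into
   `D ≈ C·Sᵀ`: `k` spectral profiles `S` and their per-pixel contributions
   `C`. Initial estimates come from NIPALS principal factors rotated onto
   the purest observed pixels; ALS then refines them under soft
   non-negativity on `C`.
3. **Mapping** — resolved factors are assigned to reference constituents
   (collagen I, collagen II, two proteoglycan forms PG1/PG2, paraffin) by
   Hungarian matching of profile correlations; contribution maps are
   normalized by an amide III tissue map to remove thickness variation. The
   C–O–S stretching band position (≈1126 cm⁻¹ for PG1 vs ≈1124 cm⁻¹ for
   PG2) discriminates proteoglycan sulfation forms.
4. **Gradients** — a horizontal area of interest across the disc is reduced
   to width-normalized anterior→posterior profiles (percent of disc width),
   integrated over standard regional windows: anterior AF 10–20 %, NP
   51–61 %, posterior AF 85–95 %.
5. **Statistics** — regional parameters are associated with degeneration
   covariates (histological grade, glycosaminoglycan and hydroxyproline
   content, MRI T2* relaxation time) by Theil–Sen regression with Kendall
   rank-correlation significance (exact permutation null for small n).

Because real tissue has no ground truth, the package ships a synthetic disc
**phantom generator**: 2-D sections with realistic zonation (collagen I
outer AF, collagen II NP, proteoglycan gradients that trade PG1 for PG2
with increasing degeneration, paraffin background), mixed under the
bilinear Beer–Lambert model with baselines and noise, plus a cohort
simulator with linked covariates. Every stage of the chain is validated
against this ground truth.

## Worked example

```python
import numpy as np
from discspect import (
    PhantomConfig, ReferenceLibrary, generate_phantom, second_derivative,
    compute_mask, resolve, assign_factors, tissue_map, component_map,
    ratio_map, default_aoi, extract_aoi, width_normalized_profile,
    integrate_region, cos_peak_position, Spectrum,
)

config = PhantomConfig(degeneration_level=0.3, seed=7)
image, truth, covariates = generate_phantom(config)
print("cube:", image.cube.shape)
# cube: (60, 208, 426)          # rows x cols x wavenumbers (1800..950 cm-1)

deriv = second_derivative(image)           # Savitzky-Golay, window 15, order 3
mask = compute_mask(deriv)                 # amide II criterion at 1554 cm-1
print(f"tissue pixels: {mask.n_included}/{deriv.n_pixels}")
# tissue pixels: 11342/12480

model = resolve(deriv, mask, 5, region=(950.0, 1300.0))
print(f"lack of fit: {model.lack_of_fit:.2f}% after "
      f"{model.iterations_run} iterations")
# lack of fit: 3.09% after 285 iterations

refs = ReferenceLibrary([truth.true_spectra[n] for n in config.components])
assignment = assign_factors(model, refs, region=model.region)
for fidx, comp in sorted(assignment.mapping.items()):
    ridx = assignment.reference_names.index(comp)
    print(f"factor {fidx} -> {comp:11s} (r = {assignment.scores[fidx, ridx]:.3f})")
# factor 0 -> PG1         (r = 0.996)
# factor 1 -> collagen_I  (r = 0.993)
# factor 2 -> collagen_II (r = 0.992)
# factor 3 -> paraffin    (r = 0.971)
# factor 4 -> PG2         (r = 0.961)

tmap = tissue_map(deriv, mask)             # amide III thickness reference
aoi = default_aoi(mask)                    # 10-row band through the centroid
tissue_aoi = extract_aoi(mask.included, aoi)
for name in ("PG1", "PG2"):
    fidx = assignment.component_factor(name)
    cmap = component_map(model, fidx, (deriv.n_rows, deriv.n_cols), mask)
    prof = width_normalized_profile(
        extract_aoi(ratio_map(cmap, tmap).values, aoi), tissue_aoi)
    np_mean = integrate_region(prof, 51, 61).value / 10.0
    peak = cos_peak_position(
        Spectrum(model.axis, model.S[:, fidx], derivative_order=2))
    print(f"{name}: NP mean ratio {np_mean:.3f}, C-O-S peak {peak:.1f} cm-1")
# PG1: NP mean ratio 0.096, C-O-S peak 1126.0 cm-1
# PG2: NP mean ratio 0.329, C-O-S peak 1124.6 cm-1
```

At degeneration level 0.3 the phantom has already lost most of its NP PG1
in favour of PG2, and the recovered C–O–S band positions of the two
proteoglycan factors are separated by 1.4 cm⁻¹ — the spectroscopic handle
that distinguishes the two sulfation forms.

## Command-line interface

The `discspect` command exposes each stage and a one-shot cohort run:

```sh
discspect simulate   --config config.yaml --seed 7 --out cube.h5 --covariates cov.csv
discspect preprocess --config config.yaml --cube cube.h5 --out deriv.h5
discspect decompose  --config config.yaml --cube deriv.h5 --k 5 --out model.h5
discspect maps       --config config.yaml --cube deriv.h5 --model model.h5 --out-dir maps/
discspect gradients  --config config.yaml --cube deriv.h5 --maps-dir maps/ --out-dir grads/
discspect correlate  --config config.yaml --regional regional_parameters.csv \
                     --covariates cov.csv --out associations.csv
discspect run        --config config.yaml --seed 7 --out-dir run/
```

`discspect run` simulates a cohort, analyses every sample with a single
MCR-ALS model over the collated areas of interest, and writes profiles,
regional parameters, associations and a manifest with output checksums.
Runs with the same config and seed are byte-identical.

## Reproduction

`scripts/acceptance.py` runs the headline computations end to end —
preprocessing exactness, factor recovery on the default phantom, the
proteoglycan signature contrast between intact and degenerate discs,
regional closed forms, T2* inversion, and the calibration and power of the
association statistics — and writes every quantity to JSON:

```sh
python scripts/acceptance.py --seed 1 --out acceptance.json
```

This takes about 4 minutes on one CPU. All randomness derives from
`--seed`; the test suite (`pytest`, about 3 minutes) asserts the same
quantities against their tolerances.
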