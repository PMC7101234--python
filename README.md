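# spindlemorph

Quantitative 3D morphometry and live-imaging analytics for *C. elegans*
male meiotic (spermatocyte) spindles.

Spermatocyte meiosis I has two unusual features: the unpaired (univalent) X
chromosome lags between the segregating autosome bivalents, tethered to both
centrosomes by lengthening kinetochore microtubules, and chromosome-to-pole
shortening (anaphase A) happens *without* net kinetochore-microtubule
shortening. `spindlemorph` implements the analysis stack used to quantify
both phenomena:

* **Tomogram morphometry** — consumes segmented reconstructions
  (microtubules as 3D polylines, chromosomes as closed surface meshes,
  centrioles as axis segments; nanometer units) and computes the standard
  per-spindle statistics: KMT classification, per-class length and
  tortuosity distributions, staging distances, plus-end-to-centriole
  distances, attachment angles, chromosome-stretch FWHM, and the polymer
  content in 1 µm³ boxes flanking the X.
* **Live-cell dynamics** — consumes two-channel 4D stacks (γ/β-tubulin::GFP
  plus histone::mCherry), tracks poles and chromatin groups, aligns curves
  on anaphase onset, fits initial rates, builds spindle-axis kymographs, and
  measures the X shape coefficient and two-box fluorescence ratio.
* **Anaphase decomposition** — the anaphase A/B partition of autosome
  separation and the closed-form three-factor anaphase-A budget.
* **Synthetic data** — generators for ground-truth-labeled spindle
  geometries and rendered movies, so the whole pipeline is testable without
  any microscope data.

## The quantities at the core

A microtubule is a **kinetochore microtubule (KMT)** when any polyline point
lies within the 150 nm ribosome-free kinetochore zone of a chromosome
surface; candidates are tested against the X first, then the nearest
autosome. A KMT is **end-on** when the 150 nm extrapolation beyond its plus
end (chord over the final 100 nm) intersects the chromosome surface,
otherwise **lateral**.

Key per-spindle statistics, in the field's notation:

* tortuosity `= L_path / L_end-to-end` (1 for a straight microtubule);
* chromosome stretch: FWHM of the cross-sectional-area profile A(z)
  sampled every 10 nm along the spindle axis, read off a fitted sum of five
  Gaussian components;
* attachment angle α between the autosome-center → centrosome axis and the
  autosome-center → plus-end vector;
* shape coefficient `z / ((x + y)/2)` of the lagging X (>1 = stretched);
* anaphase partition: `ΔAA = ΔPP (anaphase B) + 2·mean ΔPA (anaphase A)`;
* attachment-angle contribution to anaphase A: `L·(cos α₁ − cos α₂)`.

## Worked example

```python
import numpy as np
from spindlemorph import synthetic as syn, classify as cls, morphometry as mo
from spindlemorph import dynamics as dyn, anaphase as ana

# a labeled synthetic metaphase reconstruction
recipe = syn.GeometryRecipe(seed=7, n_mts=80, x_end_on=8, x_lateral=8,
                            autosome_end_on=20, autosome_lateral=20)
model, truth = syn.simulate_geometry(recipe)
ann = cls.classify_all(model)
print(cls.count_table(model, ann).to_string())
sm = mo.stage_metrics(model)
print(f"A-A {sm.aa_distance:.2f} um   P-P {sm.pp_distance:.2f} um   "
      f"centriole split {sm.centriole_split:.2f} um")

# kinetics from a synthetic distance series
d, traj = syn.simulate_distance_series(syn.KineticsParams(seed=1))
dyn.detect_onset(d)
fit = dyn.fit_initial_rate(d, key="pp")
print(f"P-P initial rate {fit.initial_rate:.2f} um/min "
      f"({fit.initial_length:.1f} -> {fit.final_length:.1f} um)")
part = ana.partition_ab(d)
print(f"anaphase B {part.anaphase_B:.1f} um ({100*part.fraction_B:.0f}%), "
      f"anaphase A {part.anaphase_A:.1f} um ({100*part.fraction_A:.0f}%)")

# the closed-form anaphase-A budget
budget = ana.contribution_budget(
    ana.stretch_contribution(0.73, 0.56),
    ana.centrosome_contribution((0.99, 1.14), (0.78, 0.95)),
    ana.angle_contribution(0.63, 37, 59), total_um=1.0)
print(f"explained fraction of anaphase A: {budget.explained_fraction:.2f}")
```

prints

```
                       mts_total  kmts_total  end_on_x  lateral_x  end_on_autosomes  lateral_autosomes
synthetic_metaphase_7         80          56         8          8                20                 20
A-A 0.94 um   P-P 3.41 um   centriole split 0.21 um
P-P initial rate 1.25 um/min (4.1 -> 7.8 um)
anaphase B 3.7 um (69%), anaphase A 1.6 um (30%)
explained fraction of anaphase A: 0.72
```

The classification recovers the generator's designed counts exactly; the
staging distances equal the recipe's metaphase geometry; the recovered
pole-pole elongation rate is within noise of the generating 1.29 µm/min;
and roughly 70 % of the ~1 µm anaphase-A shortening is explained by the
three geometric factors (stretch release 0.34 µm, centrosome reshaping
0.20 µm, angle opening 0.18 µm).

## Command line

```sh
spindlemorph simulate geometry --seed 1 --out out/        # model.json + truth.csv
spindlemorph classify --model out/model.json --out cls/   # counts + annotations
spindlemorph morph --model out/model.json --out morph.csv --per-mt mts.csv
spindlemorph simulate movie --seed 1 --out mov/           # movie.tif + sidecar
spindlemorph dynamics --tiff mov/movie.tif --config mov/movie.yaml --out dyn/
spindlemorph anaphase --curves dyn/curves.csv --budget budget.json
spindlemorph run --seed 1 --out bundle/                   # end-to-end demo
```

Geometry interchange is a documented JSON schema (see
`spindlemorph.model`) with a flat CSV point-table alternative; movies are
multi-page TIFFs with a YAML sidecar giving axis order, voxel size, frame
interval and channel roles.

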