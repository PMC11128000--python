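# sevquant

Digital counting, sizing and cargo-miRNA profiling of single small
extracellular vesicles (sEVs) from plasmonic ratio images.

## The problem

Small extracellular vesicles (30–200 nm, including exosomes) are shed into
blood by living cells and carry the molecular signature of their parent
cell, which makes them attractive liquid-biopsy analytes — but they are far
below the diffraction limit and scatter too little light for conventional
imaging. One label-free route is a plasmonic metasurface: a vesicle that
binds near the surface locally red-shifts the plasmon resonance, increasing
transmitted light, so each captured particle appears as a bright
sub-resolution spot in the **intensity-ratio (IR) image** — a sample frame
divided by a target-free background frame. Particle-free pixels sit at
IR ≈ 1 with relative SD ≈ 0.005; a particle's **contrast** is
(IR − 1) · 100 % at its local maximum.

`sevquant` implements the full analysis that turns such image stacks into
cohort-level diagnostics, together with a synthetic-data generator that
produces image sets and cohort tables with complete ground truth, so every
stage is testable without any instrument data.

## What it computes

* **Detection** — frames are rigidly registered to the background (phase
  cross-correlation, subpixel), divided (label-free channel) or subtracted
  (fluorescence channels), then particles are found as strict
  8-neighborhood local maxima of a lightly smoothed map above the Gaussian
  threshold `mean + 3σ` (IR > 1.015, i.e. 1.5 % contrast; fluorescence
  > 30 DN), merged within a minimum separation so nothing is counted twice.
* **Sizing** — an empirical quadratic calibrated against nanoparticle
  tracking, `size_nm = 0.1531 x² + 7.096 x + 20.211` with `x` the contrast
  in %, fitted by quantile–quantile least squares and invertible in closed
  form. Particles with contrast ≤ 18 % (≈ 200 nm) are "sEV-like".
* **Cargo labels** — fluorescence detections (e.g. a Cy3 molecular beacon
  that lights up on intravesicular *miR-21*) are matched to label-free
  detections greedily nearest-first within 2 px; occurrence % is the
  fraction of retained vesicles carrying the label.
* **Digital counts** — settlement curves over the pre-wash time lapse,
  pre/post-wash accounting, retention %, and the absolute sEV count
  **ASC/µl** = post-wash count / assay volume (20 µl by default).
* **Cohort statistics** — confusion-matrix metrics at a count cutoff
  (positive call: count > cutoff), a swept-cutoff ROC (cutoffs 2…1682,
  step 2) with trapezoidal AUC, a one-proportion z-test
  `z = (p − p₀)/√(p₀(1−p₀)/n)`, Pearson correlation, caliper tumor volume
  `V = ½ L W²`, and the saturating power law
  `count = 101.7 |V − 3.48·10⁻⁷|^0.12013 + 5.42` linking post-wash counts
  to tumor volume (mm³).

## Worked example

Simulate a cancer-patient-like plasma assay, detect, colocalize and
summarize:

```bash
sevquant simulate   --preset cancer --seed 1 --out demo --sample-id cpp01
sevquant detect     --manifest demo/manifest.json --out demo/detections.csv
sevquant colocalize --manifest demo/manifest.json --detections demo/detections.csv --out demo
sevquant quantify   --detections demo/detections_labeled.csv --out demo/summary.csv --group-label cancer
```

which logs

```
INFO wrote demo/manifest.json (1600 particles)
INFO wrote demo/detections.csv (5333 detections)
INFO wrote colocalization results to demo
INFO wrote demo/summary.csv (pre 1506, sEV-like 1106, post 307, ASC/µl 15.3)
```

The summary row reads: 1506 particles had settled at the 60-min endpoint,
1106 of them vesicle-scale (contrast ≤ 18 %); 307 particles survived the
wash (retention 27.8 % of the sEV-like count), i.e. 15.35 ASC/µl for the
20 µl assay — an order of magnitude above the healthy steady state of
~1.5 ASC/µl; 6.8 % of retained vesicles were *miR-21*-positive by beacon
fluorescence. A healthy-preset run (`--preset healthy`) lands near 1.5–2
ASC/µl with 0 % *miR-21* occurrence.

Cohort-level classification from a table of post-wash counts:

```bash
sevquant cohort-roc --summaries cohort.csv --cutoff 70 --out roc/
```

writes `roc/roc.csv` (cutoff, TPR, FPR) and `roc/metrics.json` with the
AUC and the sensitivity/specificity at the named cutoff (70 counts =
3.5 ASC/µl).

From Python, the library mirrors the same stages:

```python
import sevquant as sq

images, truth = sq.simulate_frame_stack(sq.preset("cellline", seed=0))
ratio = sq.ratio_image(images.panorama.post_wash()[0], images.panorama.background)
dets = sq.find_particles(ratio)
sizes = sq.size_distribution(dets)          # mean/SD/histogram in nm
print(round(sq.size_from_contrast(12.54)))  # -> 133
```

## Layout

```
src/sevquant/
  simdata.py      synthetic image stacks, cohort tables, ground truth
  imaging.py      registration, ratio/difference images, particle detection
  calibrate.py    contrast→size quadratic, quantile fitting, distributions
  colocalize.py   particle-level channel matching, occurrence %
  quantify.py     settlement curves, retention, ASC/µl, sample summaries
  cohortstats.py  confusion metrics, ROC/AUC, z-test, tumor power law
  io.py, cli.py   TIFF/manifest/CSV/JSON formats and the CLI
docs/methods.md   model assumptions, parameter choices, limitations
```
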