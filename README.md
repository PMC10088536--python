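# ebusdepot

Quantitative analysis of drug-depot formation in endobronchial ultrasound
(EBUS) videos of transbronchial needle injections (TBNI).

When a drug such as cisplatin is injected through a needle into a lung
tumor under real-time EBUS guidance, the injectate appears as a growing
hyperechoic (bright) region — the **depot** — in the B-mode video. Those
videos are recorded as standard of care, and this package turns them into
numbers for interventional pulmonologists and researchers studying
intratumoral drug delivery:

* **Screening** — the normalized percent intensity variation in a
  1 cm x 1 cm region of interest at the needle tip,
  `dI(t) = 100 (I_t - I_0) / I_0`, smoothed with a 1-s moving average; a
  video is analyzed only if the smoothed trace rises above 20%.
* **Uptake kinetics** — the background-subtracted mean cone intensity is
  fit with the exponential-plateau law `mu(t) = c + a (1 - e^{-b t})`; the
  injection duration is `dt = ln(20) / b` (time to 95% of plateau) and the
  constant flow rate is `Q = injected volume / dt`.
* **Depot segmentation** — background removal, edge-preserving
  (Perona-Malik) despeckling, Otsu intensity-cluster thresholding and
  morphological refinement yield per-frame depot masks.
* **Shape and retention** — centroid paths and min/max Feret diameters in
  needle-centered coordinates; the retained drug volume is the solid of
  revolution of the final depot about the needle axis (two-sided Pappus:
  `V = sum of 2 pi |y_centroid| A` over the two half-planes), and retention
  is `100 V / injected volume`.
* **Physical mechanisms** — radial Darcy flow implies a hydraulic
  conductivity `K = Q / (4 pi R P_i)`; comparing it with literature tumor
  values, and comparing injection pressure (linear pressure-flow scaling)
  with the Hutchinson-Suo crack-tunneling threshold
  `sigma_th = sqrt(pi E Gamma / 2h)`, yields a plausibility verdict for
  porous flow vs. tissue fracture.

Clinical recordings are not redistributable, so the package includes a
phantom generator (`ebusdepot.simulate`) producing EBUS-like videos — fan
cone, multiplicative speckle, heartbeat modulation, needle artifact and a
depot with known kinetics and retention — against which every stage is
validated. See `docs/methods.md` for models, defaults and limitations.

## Worked example

Simulate a 30-s injection phantom (rate constant b = 0.15 /s, true
retention 12% of 8 mL) and run the full analysis in memory:

```python
from ebusdepot.simulate import SimulationConfig, simulate_video, annotation_for
from ebusdepot.pipeline import analyze_video

config = SimulationConfig(duration=30.0, b=0.15, true_retention=0.12, rng_seed=42)
video, truth = simulate_video(config)
result = analyze_video(video, annotation_for(config, "DEMO"))
```

which prints (via the fields of `result`):

```
included: True (max dI = 57.8%)
uptake fit: a=0.0299, b=0.145 /s, R^2=0.410
injection duration dt = 20.68 s  (truth 19.97 s)
flow rate Q = 0.387 mL/s
retention = 11.9%  (truth 12.0%), escaped 7.05 mL
porous flow plausible: False, fracture plausible: True
```

The smoothed intensity variation peaks well above the 20% inclusion
threshold, so the video is analyzed. The fitted rate constant (0.145 /s vs.
0.15 true) gives an injection duration of 20.7 s and a flow rate of
0.39 mL/s; the rotation volume of the final segmented depot recovers the
simulated 12% retention, with the remaining ~7 mL estimated to have escaped
the imaged plane. The mechanism layer rules out Darcy porous flow (the
implied conductivity exceeds literature tumor values by 4-5 orders of
magnitude) while the estimated injection pressure exceeds both
crack-tunneling thresholds, so tissue fracture is the plausible
accommodation mechanism.

The same workflow is available from a shell:

```bash
ebusdepot simulate --config sim.yaml --out phantom/ --seed 42
ebusdepot screen   --video phantom/video.tif --annotation ann.json
ebusdepot analyze  --video phantom/video.tif --annotation ann.json --out results/
ebusdepot cohort   --config cohort.yaml --out-csv summary.csv
ebusdepot mechanisms --out mechanism_report.json
```

`analyze` writes every intermediate artifact (trace CSVs, uptake-fit JSON,
depot masks as multi-page TIFF, mechanism report) plus a `result.json`
carrying a configuration hash, so identical configs reproduce identical
outputs.

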