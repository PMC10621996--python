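# lysotube

Quantitative image analysis of **tubular lysosomes** and their contacts with
the endoplasmic reticulum (ER), for cell biologists studying lysosome
morphology and trafficking in fluorescence time-lapse microscopy (e.g.
Lamp1/Lysotracker imaging of fibroblasts and neurons, with an ER marker such
as Sec61β in a second channel).

Lysosomes exist as round puncta and as elongated, highly motile tubules that
form and move in close apposition to the ER. Quantifying this behaviour
requires several linked measurements, all provided here as a tested library
with a thin CLI:

* **Detection & morphometry** — particles are binarized with a
  Laplacian-of-Gaussian spot detector and measured by image moments. A
  particle is classified *tubular* when

  `circularity < 0.5  AND  eccentricity > 0.9  AND  major/minor axis ratio > 4`

  with circularity `4πA/P²` (Crofton perimeter) and eccentricity from the
  ellipse of inertia. Tubule counts per μm² are rescaled to a **tubulation
  index** in [0, 1] between same-experiment knockout (0) and wild-type (1)
  control means.
* **ER–lysosome contacts** — per-particle area-overlap fraction with the ER
  mask, thresholded at 30%; the threshold is derived from a 1-D blur
  argument: a 500 nm lysosome 10 nm from a 50 nm ER tubule imaged at 120 nm
  pixels shows a 230 nm apparent overlap on a 740 nm apparent diameter
  (≈30%). A 90°-flip control estimates chance overlap, a distance-transform
  metric scores membrane proximity on EM-style masks (<30 nm), and a spot
  colocalization routine classifies PLA-style puncta against two masks.
* **Tracking** — displacement-bounded nearest-assignment linking
  (Crocker–Grier style): no link may exceed the size of one tubular lysosome
  (2.4 μm = 20 px at 120 nm/px). Per track: path length, mean speed, the
  *fast* flag (>0.3 μm/s, microtubule-dependent transport), the *motile*
  flag (>1.2 μm traveled per minute), and instant speeds around
  round↔tubular shape transitions.
* **Axonal transport** — kymographs sampled along an axon polyline (soma at
  the left), anterograde/retrograde/stationary classification by signed net
  axial displacement, and the fraction of lysosomes within half the maximum
  soma distance.
* **siRNA screen scoring** — each condition is scored by (1) the mean
  probability, under a trained classifier, that its images show the knockout
  phenotype and (2) its tubulation index; hits must be at least as
  knockout-like as the weakest of the positive-control siRNAs on **both**
  readouts. The classifier backend is pluggable; the built-in one is a
  logistic regression on morphometry features.
* **Synthetic scenes** — a ground-truth generator (discs + capsules moving
  over a Voronoi-edge ER network, Gaussian PSF and noise; straight-axon
  scenes with programmed transport fractions) that makes every stage
  testable without real data.

## Worked example

```python
import numpy as np
from lysotube import synthetic_scenes as ss, detection, morphometry, contacts, tracking

cfg = ss.SceneConfig(n_round=10, n_tubular=8, n_frames=20, noise_sd=0.02,
                     jitter_sd_um=0.0, contact_fraction=0.6, seed=42)
scene = ss.generate_scene(cfg)

records = detection.label_regions(
    detection.binarize_spots(scene.lysosome_stack[0]), cfg.pixel_size_nm)
verdicts = morphometry.classify_regions(records)
h_um, w_um = cfg.field_size_um
density = morphometry.tubule_density(verdicts, h_um * w_um)
print(f"frame 0: {len(records)} particles, "
      f"{sum(v.tubular for v in verdicts)} tubular ({density:.4f} tubules/um^2)")

idx = morphometry.tubulation_index(density, wt_mean=0.009, ko_mean=0.001)
print(f"tubulation index vs (wt=0.009, ko=0.001): {idx.index:.2f}")

lyso_mask = detection.binarize_spots(scene.lysosome_stack[0])
frac = np.mean([r.in_contact for r in contacts.overlap_fraction(lyso_mask, scene.er_mask)])
null = np.mean([r.in_contact for r in contacts.flip_control(lyso_mask, scene.er_mask)])
print(f"lysosomes with >30% ER overlap: {frac:.0%} (90-degree flip control: {null:.0%})")

pts = [[(r.x_um, r.y_um) for r in detection.label_regions(
        detection.binarize_spots(f), cfg.pixel_size_nm)]
       for f in scene.lysosome_stack]
tracks = tracking.link_particles(pts, max_disp=2.4)
metrics = [tracking.trajectory_metrics(t, cfg.frame_interval_s)
           for t in tracks if len(t) >= 2]
print(f"{len(tracks)} tracks; {sum(m.fast for m in metrics)} with mean speed > 0.3 um/s")
```

prints

```
frame 0: 18 particles, 8 tubular (0.0085 tubules/um^2)
tubulation index vs (wt=0.009, ko=0.001): 0.93
lysosomes with >30% ER overlap: 44% (90-degree flip control: 17%)
20 tracks; 7 with mean speed > 0.3 um/s
```

All 18 programmed objects and all 8 tubules are recovered on the first
frame. The structured ER-contact rate (44%) sits well above its
flip-control chance estimate (17%), and the tubulation index places this
scene near the wild-type end of the control range, as constructed.

The same steps are available from the shell:

```bash
lysotube simulate --out-dir scene --seed 3 --n-frames 3
lysotube detect scene/lysosome.tif --out regions.csv
lysotube shapes regions.csv --out shapes.csv
lysotube track regions.csv --out tracks.csv
lysotube contacts lyso_mask.tif er_mask.tif --out contacts.csv
lysotube kymo axon.tif path.csv --out kymo.tif
```

## Layout

```
src/lysotube/
  synthetic_scenes.py   ground-truth scene and axon simulators
  imaging_io.py         TIFF + sidecar JSON, CSV tables, screen manifests
  detection.py          LoG spot binarization, moment-based region records
  morphometry.py        tubular classification, densities, tubulation index
  contacts.py           overlap, apparent-overlap calculator, proximity, coloc
  tracking.py           displacement-bounded linking, motility, transitions
  axon_dynamics.py      kymographs, directionality, axial distribution
  screen.py             splits, baseline classifier, gates, hit calling
  cli.py                click command group over the above
```

See `docs/methods.md` for the models, parameter choices, and limitations.
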