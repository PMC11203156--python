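# octrack

Preprocessing, segmentation post-filtering and multi-timepoint tracking of
organoids in 3-D optical coherence tomography (OCT) volumes.

Organoids — self-organizing 3-D structures grown from stem or tumor
cells — appear in OCT as bright quasi-spherical blobs in a speckle-noise
background. Following individual organoids across an imaging series
(e.g. every other day for two weeks) turns label-free OCT into a
quantitative growth assay: per-organoid volume trajectories, growth rates,
and fusion events. `octrack` provides the classical stages of that
pipeline for anyone building such an assay:

- **Enhancement chain** for speckle-dominated volumes:
  reference-histogram normalization, percentile contrast stretching,
  square-root variance stabilization of Poisson noise, unsharp sharpening
  (`2V − U` at the default weight), cubic median filtering, and 8-bit
  conversion.
- **Mask handling**: ingestion of binary masks from any external
  segmenter (e.g. a per-slice CNN), plus a thresholding baseline for
  self-contained runs.
- **Instance post-filtering**: 3-D connected components and removal of
  objects smaller than a 25 um reference sphere, `(π/6)·25³ ≈ 8181 um³`.
- **Dual-branch probabilistic tracking**: a reference timepoint anchors
  ascending (forward) and descending (backward) branches; candidate pairs
  are gated on centroid distance and volume change, scored by

      S = w_c·(1−D_c) + w_v·(1−D_v) + w_p·(1−D_p) + w_IoU·IoU,
      P = 1 / (1 + e^(−S)),

  and assigned greedily and exclusively from the probability matrix.
- **Tuning and analytics**: grid search over gates and reference day,
  tracking-quality metrics against ground truth, Dice/accuracy/
  sensitivity/precision for masks, and growth curves (mean volume per day
  ± standard error, least-squares growth rate in mm³/day).
- **Synthetic phantom generator**: multi-timepoint volumes with Poisson
  speckle, growing organoids, rigid inter-day misregistration and optional
  fusion — with exact ground-truth labels and trajectories, so the whole
  pipeline is testable without any acquired data.

See `docs/methods.md` for the model, parameter meanings and limitations.

## Worked example

Track ten synthetic organoids over seven timepoints (days 1–13) and
recover their programmed growth (from `examples/03_track_timeseries.py`):

```python
from octrack import MatchConfig, PhantomConfig, generate_scene, growth_curve, track_timeseries
from octrack.features import extract_organoids

cfg = PhantomConfig(shape=(64, 128, 128), n_organoids=10, days=(1, 3, 5, 7, 9, 11, 13), seed=5)
scene = generate_scene(cfg)
records = {day: extract_organoids(lv) for day, lv in scene.labels.items()}
tracks = track_timeseries(records, MatchConfig(reference_day=1))
curve = growth_curve(tracks, records)
```

Output:

```
10 tracks found; 10 span all 7 timepoints
full-track recall: 1.00, link precision: 1.00 (1.00 means every identity was followed without error)
 day  mean_volume_mm3  sem_mm3  n
   1         0.000030 0.000003 10
   ...
  13         0.000048 0.000003 10
fitted growth rate: 1500.0 um^3/day (programmed: 1500.0 um^3/day)
```

Every organoid identity is followed across all seven timepoints
(recall/precision 1.00), and the least-squares slope of the mean-volume
curve recovers the generator's programmed volume-linear growth rate.

The other scripts in `examples/` each demonstrate one capability:
enhancement (`01`), segmentation + sphere filtering (`02`), gate tuning
under misregistration (`04`), and phantom export (`05`).

## Command line

The same stages are available as subcommands for shell pipelines over TIFF
stacks and CSV tables:

```bash
octrack config init > pipeline.yaml
octrack simulate --config pipeline.yaml --seed 1 --out scene/
octrack preprocess scene/day*.tif --ref ref.json --out pre/
octrack segment pre/*.tif --mode baseline --out masks/
octrack postprocess masks/*.tif --min-diameter 25 --out labels/
octrack track labels/*.tif --days 1,3,5,7,9,11,13 --reference-day auto --out tracks.csv
octrack evaluate --pred masks/day01.tif --gt scene/day01_labels.tif
```

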