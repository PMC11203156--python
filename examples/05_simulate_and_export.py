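"""Generate a synthetic OCT-like time series and export it to disk.

Writes per-day intensity TIFF stacks, ground-truth label stacks, the
trajectory table and the event log — the same artifacts the `octrack
simulate` CLI command produces — into a temporary directory.
"""

import json
import tempfile
from pathlib import Path

from octrack import PhantomConfig, generate_scene
from octrack.io import write_label_volume, write_volume

cfg = PhantomConfig(shape=(48, 80, 80), n_organoids=5, days=(1, 3, 5), seed=11)
scene = generate_scene(cfg)

out = Path(tempfile.mkdtemp(prefix="octrack_phantom_"))
for day, vol in scene.volumes.items():
    write_volume(vol, out / f"day{day:02d}.tif")
    write_label_volume(scene.labels[day], out / f"day{day:02d}_labels.tif")
scene.trajectories.to_csv(out / "trajectories.csv", index=False)
(out / "events.json").write_text(json.dumps(scene.events, indent=2))

print(f"wrote {len(scene.volumes)} timepoints to {out}")
print(f"trajectory table: {len(scene.trajectories)} rows "
      f"({scene.trajectories['id'].nunique()} organoids x {len(cfg.days)} days)")
print(scene.trajectories.head(5).to_string(index=False))
print("volumes are Poisson speckle (mean "
      f"{cfg.lambda_bg:g} background / {cfg.lambda_org:g} inside organoids); "
      "labels share the persistent ids of the trajectory table")
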