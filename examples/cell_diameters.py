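"""Cell-diameter dynamics of a migrating cell from a timelapse mask stack.

Builds a capsule-shaped cell whose width alternates between 3 µm and 5 µm
while it crawls at 1 µm/min, then measures per-frame diameters (skeleton ×
Euclidean distance map), the time spent at a minimum diameter of 2–4 µm
versus >4 µm, and the track speed.
"""

import numpy as np

from dcmorph import (
    CellTimelapseSpec,
    make_cell_timelapse,
    residence_fractions,
    stack_diameters,
    straight_path,
    track_cells,
    track_speed,
)

n_frames, interval = 21, 2.0  # 40 min of imaging at 2 min/frame
widths = [3.0 if (f // 3) % 2 == 0 else 5.0 for f in range(n_frames)]
spec = CellTimelapseSpec(
    n_frames=n_frames,
    frame_interval=interval,
    width_schedule=widths,
    length=18.0,
    centroid_path=straight_path((12.0, 20.0), step_um=2.0, n_frames=n_frames),
    pixel_size=0.25,
    image_shape=(160, 256),
)
stack, truth = make_cell_timelapse(spec)

per_frame = stack_diameters(stack, pixel_size=0.25)
res = residence_fractions(per_frame["min_diam_um"], interval)
tracks = track_cells(stack.astype(np.int32), 0.25, interval)
speed = track_speed(tracks[0], "median")

print(per_frame[["frame", "min_diam_um", "mean_diam_um", "max_diam_um"]]
      .head(6).to_string(index=False))
print(f"...\ntime-averaged min diameter : {per_frame['min_diam_um'].mean():.2f} µm")
print(f"fraction of time at 2-4 µm  : {res.fraction_2to4:.2f}")
print(f"fraction of time at >4 µm   : {res.fraction_gt4:.2f}")
print(f"median track speed          : {speed:.2f} µm/min")
print(
    "\nThe fractions recover the programmed 12/21 vs 9/21 width occupancy and"
    "\nthe speed equals the programmed 2 µm per 2-min step."
)
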