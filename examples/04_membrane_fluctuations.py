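"""Estimate a cell-membrane-fluctuation (CMF) map from an OPD time stack.

One hundred frames at 10 Hz are simulated with nanometre-scale membrane
flicker (ring and dimple regions fluctuate with different amplitudes) on
top of 2 nm background noise. The estimator takes the per-pixel temporal
standard deviation and removes the noise floor in quadrature:
CMF = sqrt(std^2 - std_bkgd^2). The printed amplitudes show how well the
generating values are recovered and that the ring/dimple contrast is
resolved.
"""

import numpy as np

from holocyte import phantom
from holocyte.extract import SegmentationConfig, segment_cells
from holocyte.fluctuations import analyze_stack

params = phantom.scenario_base_params(phantom.sealed_scenario())
cfg = phantom.SceneConfig(grid_size=128, pixel_pitch_um=0.2, n_cells=1,
                          n_frames=100, frame_rate_hz=10.0)
base = phantom.render_scene([params], cfg)
cells, bkgd = segment_cells(base, SegmentationConfig(threshold_nm=20.0), 0.2,
                            apply_qc=False)
cell = cells[0]
radius = np.sqrt(cell.area_px / np.pi)

ring_amp, dimple_amp, noise = 5.0, 3.0, 2.0
amp = phantom.fluctuation_amplitude_map(cell.mask, cell.centroid, radius,
                                        ring_amp, dimple_amp)
stack = phantom.generate_fluctuation_stack(base, amp, cfg.n_frames, seed=0,
                                           bkgd_noise_nm=noise)

record, cmf = analyze_stack(stack, cell.mask, bkgd)
print(f"frames: {record.n_frames}, background noise estimate: "
      f"{record.bkgd_std_nm:.2f} nm (true {noise:.1f})")
print(f"whole-cell CMF amplitude: {record.cmf_amplitude_nm:.2f} nm "
      f"(true mean {amp[cell.mask].mean():.2f})")
print(f"ring CMF  : {record.cmf_ring_nm:.2f} nm (true {ring_amp:.1f})")
print(f"dimple CMF: {record.cmf_dimple_nm:.2f} nm (true {dimple_amp:.1f})")
print(f"pixels clamped at the noise floor: {record.clamped_px}")
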