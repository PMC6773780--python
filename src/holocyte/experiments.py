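"""High-level wiring: simulate a temperature sweep and measure it back.

A cohort of cells is sampled once and the same cells are morphed across
every temperature (a paired design: the experiments re-image the same
cells while the stage temperature is elevated). Each temperature yields a
rendered OPD scene plus the analytic ground-truth table; the measurement
path segments the scene and computes per-cell morphometrics, matched back
to ground truth by centroid proximity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import phantom
from .extract import SegmentationConfig, segment_cells
from .morphometrics import analyze_cell

__all__ = ["ExperimentScene", "simulate_temperature_sweep", "measure_scene",
           "run_temperature_experiment"]


@dataclass
class ExperimentScene:
    """One temperature condition of a simulated sweep."""

    temperature_c: float
    opd_nm: np.ndarray
    cells: list[phantom.PhantomParams]
    ground_truth: pd.DataFrame
    scene_config: phantom.SceneConfig
    ring_amp_nm: float
    dimple_amp_nm: float
    bkgd_noise_nm: float


def simulate_temperature_sweep(
    scenario: phantom.TemperatureScenario,
    scene_config: phantom.SceneConfig,
    base_params: phantom.PhantomParams | None = None,
    radius_cv: float = 0.04,
    mass_cv: float = 0.065,
    sphericity_sd: float = 0.02,
) -> list[ExperimentScene]:
    """Render the same jittered cohort at every scenario temperature."""
    rng = np.random.default_rng(scene_config.seed)
    if base_params is None:
        base_params = phantom.scenario_base_params(scenario)
    cohort = phantom.sample_cohort(
        scene_config.n_cells, base_params, rng,
        radius_cv=radius_cv, mass_cv=mass_cv, sphericity_sd=sphericity_sd,
    )
    # placement slot size covers the largest radius over the whole sweep
    dpsa = scenario.psa_slope_um2_per_c * (
        scenario.temperatures_c[-1] - scenario.temperatures_c[0]
    )
    max_radius = max(
        max(
            c.cell_radius_um,
            float(np.sqrt(max(np.pi * c.cell_radius_um**2 + dpsa, 1e-6) / np.pi)),
        )
        for c in cohort
    )
    centers = phantom.place_cells(
        scene_config.n_cells, scene_config, float(max_radius), rng, margin_um=1.5
    )
    scenes = []
    for t_c in scenario.temperatures_c:
        morphed = [
            dataclasses.replace(
                phantom.morph_for_temperature(c, scenario, t_c), center_xy=xy
            )
            for c, xy in zip(cohort, centers)
        ]
        ring, dimple = scenario.amplitudes_at(t_c)
        gt = phantom.scene_ground_truth(
            morphed, scene_config, temperature_c=t_c,
            ring_amp_nm=ring, dimple_amp_nm=dimple,
        )
        scenes.append(
            ExperimentScene(
                temperature_c=t_c,
                opd_nm=phantom.render_scene(morphed, scene_config),
                cells=morphed,
                ground_truth=gt,
                scene_config=scene_config,
                ring_amp_nm=ring,
                dimple_amp_nm=dimple,
                bkgd_noise_nm=scenario.bkgd_noise_nm,
            )
        )
    return scenes


def measure_scene(
    opd_nm: np.ndarray,
    scene: ExperimentScene,
    seg_config: SegmentationConfig | None = None,
    match_tol_px: float = 10.0,
) -> pd.DataFrame:
    """Segment an OPD map and measure per-cell scalars, matched to ground truth.

    ``opd_nm`` may be the rendered scene itself or its holographic
    reconstruction. Rows carry both measured values and the matched
    ground-truth columns (suffix ``_true``).
    """
    if seg_config is None:
        seg_config = SegmentationConfig(threshold_nm=20.0)
    pitch = scene.scene_config.pixel_pitch_um
    cells, _ = segment_cells(opd_nm, seg_config, pitch, apply_qc=False)
    gt = scene.ground_truth
    rows = []
    for cell in cells:
        rec = analyze_cell(
            opd_nm, cell.mask, pitch, temperature_c=scene.temperature_c
        )
        d = np.hypot(
            gt["center_row_px"] - cell.centroid[0],
            gt["center_col_px"] - cell.centroid[1],
        )
        j = int(d.idxmin())
        if d[j] > match_tol_px:
            continue
        row = dict(
            cell_id=int(gt.loc[j, "cell_id"]),
            temperature_c=scene.temperature_c,
            psa_um2=rec.psa_um2,
            mean_opd_nm=rec.mean_opd_nm,
            mch_pg=rec.mch_pg,
            sphericity_k=rec.sphericity_k,
            radius_um=rec.radius_um,
            centroid_row=rec.centroid[0],
            centroid_col=rec.centroid[1],
        )
        for col in ("psa_um2", "mean_opd_nm", "mch_pg", "sphericity_k"):
            row[f"{col}_true"] = float(gt.loc[j, col])
        rows.append(row)
    return pd.DataFrame(rows)


def run_temperature_experiment(
    scenario: phantom.TemperatureScenario,
    n_cells: int,
    seed: int,
    grid_size: int = 512,
    pixel_pitch_um: float = 0.18,
    threshold_nm: float = 20.0,
) -> pd.DataFrame:
    """Simulate one sweep and return the concatenated per-cell records."""
    cfg = phantom.SceneConfig(
        grid_size=grid_size, pixel_pitch_um=pixel_pitch_um,
        n_cells=n_cells, seed=seed,
    )
    scenes = simulate_temperature_sweep(scenario, cfg)
    seg = SegmentationConfig(threshold_nm=threshold_nm)
    frames = [measure_scene(s.opd_nm, s, seg) for s in scenes]
    return pd.concat(frames, ignore_index=True)
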