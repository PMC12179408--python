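"""Labelled measurement benchmarks built from the synthetic generator.

Real training data for the qualification model is a table of visually
verified cells; the shipped stand-in renders each sampled cell in its own
small field, runs it through the actual segmentation and measurement stages,
and labels the resulting feature row from ground truth (intact rod -> 1,
touching pair / rounded / fragment -> 0).  The classifier therefore trains on
exactly the measurement pipeline it will be applied to.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .descriptors import FEATURE_COLUMNS, measure_all
from .segmentation import segment
from .synth import (DEFAULT_PIXEL_UM, CellSpec, render_scene,
                    sample_population)

#: Default benchmark composition: 70% qualified rods, 30% split evenly over
#: the three disqualified classes.
BENCHMARK_PROPORTIONS = {
    "intact_rod": 0.70,
    "touching_pair": 0.10,
    "rounded": 0.10,
    "fragment": 0.10,
}


def measure_single_cell(spec: CellSpec, pixel_size_um: float = DEFAULT_PIXEL_UM,
                        noise_sd: float = 0.05, seed: int = 0) -> dict | None:
    """Render one spec alone, segment and measure it; returns the
    measurement record of the (largest) detected particle or None if the
    object was missed entirely."""
    ext = spec.length_um / 2.0 + spec.width_um / 2.0
    if spec.cell_class == "touching_pair":
        ext += spec.length_um / 2.0 + (spec.pair_width_um or spec.width_um)
    side_px = max(int(np.ceil(2 * (ext + 5.0) / pixel_size_um)), 64)
    center = side_px * pixel_size_um / 2.0
    placed = dataclasses.replace(spec, center_um=(center, center))
    scene = render_scene((side_px, side_px), pixel_size_um, [placed],
                         noise_sd=noise_sd, seed=seed)
    particles = segment(scene.image, min_area_um2=100.0, max_area_um2=5e4)
    if particles.n_particles == 0:
        return None
    if particles.n_particles == 1:
        table = measure_all(particles)
    else:  # noise specks: keep the largest particle
        table = measure_all(particles).nlargest(1, "area_um2")
    return table.iloc[0].to_dict()


def labeled_benchmark_table(n_cells: int = 1000,
                            proportions: dict[str, float] | None = None,
                            group: str = "control",
                            pixel_size_um: float = DEFAULT_PIXEL_UM,
                            noise_sd: float = 0.05,
                            seed: int = 0) -> pd.DataFrame:
    """Measurement table of ``n_cells`` synthetic cells with ground-truth
    qualification labels, suitable for :func:`cardiomorph.qc.train_qc`.

    Class composition follows the largest-remainder rule, so e.g. a 70/30
    qualified/disqualified mix is exact.
    """
    proportions = proportions or BENCHMARK_PROPORTIONS
    specs = sample_population(group, n_cells, proportions, seed=seed)
    rng = np.random.default_rng(seed)
    render_seeds = rng.integers(0, 2 ** 31 - 1, len(specs))
    rows = []
    for spec, s in zip(specs, render_seeds):
        rec = measure_single_cell(spec, pixel_size_um, noise_sd, int(s))
        if rec is None:
            continue
        rec["label"] = 1 if spec.cell_class == "intact_rod" else 0
        rec["cell_class"] = spec.cell_class
        rows.append(rec)
    return pd.DataFrame(rows)[
        ["particle_id", *FEATURE_COLUMNS, "length_um", "width_um",
         "label", "cell_class"]]
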