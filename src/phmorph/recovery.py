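"""Parameter-recovery sweeps: measure synthetic bones against ground truth.

The grid spans the published min/mean/max of each parameter (head diameter
38.2-58.1 mm, head height 10.4-17.5 mm, neck-shaft angle 114.20-143.07 deg,
medial offset 1.1-11.2 mm): the full 3x3x3 product over (hhd, hhh, angle)
with the three offset levels cycled across it, 27 bones in total, so every
extreme of every parameter is exercised.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd

from .pipeline import MeasureConfig, measure
from .synthetic import AnatomyParams, generate_humerus

__all__ = ["recovery_grid", "run_recovery", "TABLE_RANGES"]

# Published (min, mean, max) per parameter.
TABLE_RANGES = {
    "hhd": (38.2, 44.86, 58.1),
    "hhh": (10.4, 14.31, 17.5),
    "neck_shaft_angle": (114.20, 131.25, 143.07),
    "medial_offset": (1.1, 6.25, 11.2),
}


def recovery_grid() -> list[AnatomyParams]:
    """27 parameter sets spanning the published min/mean/max ranges."""
    grid = []
    offsets = TABLE_RANGES["medial_offset"]
    for k, (hhd, hhh, angle) in enumerate(product(TABLE_RANGES["hhd"],
                                                  TABLE_RANGES["hhh"],
                                                  TABLE_RANGES["neck_shaft_angle"])):
        grid.append(AnatomyParams(hhd=hhd, hhh=hhh, neck_shaft_angle=angle,
                                  medial_offset=offsets[k % 3], seed=k))
    return grid


def run_recovery(param_sets, vertex_noise_sd: float = 0.0, seed: int = 0,
                 config: MeasureConfig | None = None) -> pd.DataFrame:
    """Generate, measure and compare each parameter set to its ground truth.

    Relative errors are reported for the length parameters (including the
    derived articular surface diameter) and the absolute error in degrees for
    the angle.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for base in param_sets:
        params = base
        if vertex_noise_sd > 0:
            params = AnatomyParams(
                hhd=base.hhd, hhh=base.hhh,
                neck_shaft_angle=base.neck_shaft_angle,
                medial_offset=base.medial_offset,
                shaft_radius=base.shaft_radius, shaft_length=base.shaft_length,
                mesh_resolution=base.mesh_resolution,
                vertex_noise_sd=vertex_noise_sd,
                landmark_jitter_sd=base.landmark_jitter_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        mesh, landmarks, truth = generate_humerus(params)
        result, _ = measure(mesh, landmarks, config)
        row = {
            "hhd_true": truth.hhd, "hhh_true": truth.hhh,
            "angle_true": truth.neck_shaft_angle,
            "offset_true": truth.medial_offset, "asd_true": truth.asd,
            "hhd": result.hhd, "hhh": result.hhh,
            "angle": result.neck_shaft_angle,
            "offset": result.medial_offset, "asd": result.asd,
            "err_angle_deg": result.neck_shaft_angle - truth.neck_shaft_angle,
        }
        for name, meas, true in (("hhd", result.hhd, truth.hhd),
                                 ("hhh", result.hhh, truth.hhh),
                                 ("asd", result.asd, truth.asd)):
            row[f"err_{name}_rel"] = (meas - true) / true
        # The offset can be configured to zero, where a relative error is
        # undefined; report it relative to the head diameter instead.
        denom = truth.medial_offset if truth.medial_offset > 1e-9 else truth.hhd
        row["err_offset_rel"] = (result.medial_offset - truth.medial_offset) / denom
        rows.append(row)
    return pd.DataFrame(rows)
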