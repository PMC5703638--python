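"""Demonstrate the toy tilt-projection / reconstruction path.

Projects a small disk phantom into a single-axis tilt series (±60° in 2°
steps, the standard collection scheme), reconstructs it with weighted back
projection and with SIRT, and quantifies the missing-wedge elongation along
the beam axis — the reason quantitative density work reads intensities from
object interiors rather than boundaries.

Writes results/reconstruction_demo.json.
"""

import json
from pathlib import Path

import numpy as np

from cstetquant.morphometry import VolumeGrid
from cstetquant.tomo import (
    project_tilt_series,
    reconstruct,
    sirt_residuals,
    tilt_angles,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def elongation(image: np.ndarray, level: float = 0.5) -> float:
    seg = image > level
    zi, xi = np.nonzero(seg)
    return (zi.max() - zi.min()) / (xi.max() - xi.min())


def main() -> None:
    n = 64
    zz, _, xx = np.mgrid[:n, :1, :n]
    c = n // 2
    data = np.zeros((n, 1, n))
    data[((zz - c) ** 2 + (xx - c) ** 2) <= 14**2] = 1.0
    vol = VolumeGrid(data, 1.0)

    wedge = project_tilt_series(vol, tilt_angles(60.0, 2.0))
    full = project_tilt_series(vol, np.arange(-89.0, 90.0, 1.0))

    rec_full = reconstruct(full, "wbp")
    rec_wedge_wbp = reconstruct(wedge, "wbp")
    rec_wedge_sirt = reconstruct(wedge, "sirt", iterations=25)
    residuals = sirt_residuals(wedge, 0, iterations=25)

    interior = ((zz - c) ** 2 + (xx - c) ** 2) <= 10**2
    payload = {
        "full_range_wbp_interior_mean": float(rec_full.data[interior].mean()),
        "missing_wedge_wbp_elongation": elongation(rec_wedge_wbp.data[:, 0, :]),
        "missing_wedge_sirt_elongation": elongation(rec_wedge_sirt.data[:, 0, :]),
        "sirt_residual_first": residuals[0],
        "sirt_residual_last": residuals[-1],
    }
    OUT.mkdir(exist_ok=True)
    (OUT / "reconstruction_demo.json").write_text(json.dumps(payload, indent=2))

    print(f"Full-range WBP recovers the disk interior at "
          f"{payload['full_range_wbp_interior_mean']:.3f} (true 1.0).")
    print(f"±60° missing wedge elongates the disk along the beam axis: "
          f"axis ratio {payload['missing_wedge_wbp_elongation']:.2f} (WBP), "
          f"{payload['missing_wedge_sirt_elongation']:.2f} (SIRT).")
    print(f"SIRT residual norm fell {payload['sirt_residual_first']:.1f} -> "
          f"{payload['sirt_residual_last']:.1f} over 25 iterations.")


if __name__ == "__main__":
    main()
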