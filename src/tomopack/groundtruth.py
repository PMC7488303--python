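"""Ground-truth annotation tables for simulated tomograms.

One row per packed structure: label, kind, final centroid, displacement
vector, ZYZ Euler angles (degrees; zero for deformables by convention) and
bounding radius.  The table is what picking and segmentation methods are
scored against; the schema is stable and carried in the JSON output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GroundTruthEntry", "truth_table", "write_truth"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class GroundTruthEntry:
    label: str
    kind: str
    centroid: np.ndarray  # final position, world units
    displacement: np.ndarray
    euler_deg: tuple[float, float, float]
    bounding_radius: float

    @property
    def deformable(self) -> bool:
        return self.kind != "rigid"


def truth_table(entries: list[GroundTruthEntry]) -> pd.DataFrame:
    rows = []
    for e in entries:
        rows.append(
            {
                "label": e.label,
                "kind": e.kind,
                "x": e.centroid[0],
                "y": e.centroid[1],
                "z": e.centroid[2],
                "dx": e.displacement[0],
                "dy": e.displacement[1],
                "dz": e.displacement[2],
                "alpha_deg": e.euler_deg[0],
                "beta_deg": e.euler_deg[1],
                "gamma_deg": e.euler_deg[2],
                "bounding_radius": e.bounding_radius,
                "deformable": e.deformable,
            }
        )
    return pd.DataFrame(rows)


def write_truth(entries: list[GroundTruthEntry], csv_path=None, json_path=None) -> None:
    df = truth_table(entries)
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if json_path is not None:
        payload = {"schema_version": SCHEMA_VERSION,
                   "particles": df.to_dict(orient="records")}
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1)
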