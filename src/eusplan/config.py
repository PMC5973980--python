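"""Run configuration: every tunable of the planning pipeline in one place.

Defaults follow standard clinical EUS transducer geometry (120 deg fan,
5 cm depth), the plane sampling grid (+/-60 deg, 125 planes per vertex),
the landmark noise model (2 mm organ SD, bounding-box rule for vessels,
0.4 mm / 0.36 deg tracking error), the 5 mm^2 feature-area filter, the
5.33 mm contact-mesh decimation and the 1000 single / 100 pair simulation
budgets.  The full consumed configuration is persisted in the run manifest
so a run can be reproduced bit for bit.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .anatomy import LabelInfo


@dataclass
class RunConfig:
    # label roles
    labels: dict[int, LabelInfo] = field(default_factory=dict)
    target_label: int | None = None
    # sector geometry
    fan_angle_deg: float = 120.0
    depth_mm: float = 50.0
    pixel_pitch_mm: float = 0.5
    tre_pitch_mm: float = 1.0
    # plane sampling
    grid_range_deg: float = 60.0
    grid_step_deg: float = 30.0
    max_vertices: int | None = None  # subsample contact vertices if set
    # feature filtering
    min_area_mm2: float = 5.0
    # anatomy extraction
    decimation_edge_mm: float = 5.33
    smoothing_sigma_voxels: float = 0.8
    # noise model
    organ_sigma_mm: float = 2.0
    tracking_sigma_pos_mm: float = 0.4
    tracking_sigma_rot_deg: float = 0.36
    # simulation budgets
    n_sims_single: int = 1000
    n_sims_pair: int = 100
    n_sims_reestimate: int = 1000
    n_starts: int = 10
    pairs: bool = True
    pair_budget_factor: float = 2.0  # pairs sampled = factor * n contact vertices
    seed: int = 0

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["labels"] = {int(k): {"name": v["name"], "kind": v["kind"]}
                       for k, v in d["labels"].items()}
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        labels = {int(k): LabelInfo(v["name"], v["kind"])
                  for k, v in raw.pop("labels", {}).items()}
        return cls(labels=labels, **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = self.to_manifest()
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
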