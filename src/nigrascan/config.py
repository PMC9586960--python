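"""Pipeline configuration with the study's published threshold defaults."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the end-to-end pipeline.

    Threshold defaults: neuromelanin volume counts normalized signal > 1;
    DAT VOIs keep ratio > 3 (striatum) / > 1.65 (brainstem); LR > 50 marks
    increased prodromal risk; PCA retains 85% explained variance; the FDR is
    controlled at q = 0.05.
    """

    out_dir: str = "nigrascan-out"
    echo_times: tuple = (7.91, 15.96, 24.0)  # ms
    voxel_size: tuple = (0.6, 0.6, 1.3)  # mm
    t2star_cap: float = 150.0  # ms
    nm_volume_threshold: float = 1.0
    dat_striatal_threshold: float = 3.0
    dat_brainstem_threshold: float = 1.65
    lr_cutoff: float = 50.0
    pca_variance: float = 0.85
    fdr_q: float = 0.05
    glcm_levels: int = 32
    glcm_distance: int = 1
    kmeans_k: int = 3
    min_component: int = 5
    n_folds: int = 5
    seed: int = 0
    n_per_group: dict = field(default_factory=lambda: {"PD": 8, "NMC": 4, "NMNC": 8})

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["echo_times"] = list(self.echo_times)
        d["voxel_size"] = list(self.voxel_size)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["echo_times"] = tuple(d["echo_times"])
        d["voxel_size"] = tuple(d["voxel_size"])
        return cls(**d)

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]
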