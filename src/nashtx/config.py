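"""Pipeline configuration: one serializable object holding paths,
thresholds and flags.  Defaults are the pipeline's standard criteria
(fold change 2 / 0.5, FDR 0.1, normalized UMI > 1.0, k = 8 clusters)."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # input paths (None disables the dependent stages)
    counts: str | None = None
    design: str | None = None
    sc_matrix: str | None = None   # directory with matrix.mtx + sidecars
    sc_labels: str | None = None   # optional precomputed cell labels TSV
    gmt: str | None = None
    outdir: str = "nashtx_out"

    # thresholds
    fc_up: float = 2.0
    fc_down: float = 0.5
    fdr_max: float = 0.1
    interaction_fdr: float = 0.1
    umi_min: float = 1.0
    min_log2fc: float = 1.0
    q_max: float = 0.05            # marker-screen FDR
    k: int = 8
    pseudocount: float = 1.0
    n_perm: int = 1000
    seed: int = 0

    # flags
    by_sex: bool = False
    standardize: bool = True
    unique_markers: bool = True
    denominator: str = "queried"
    cluster_stat: str = "median"
    sc_cluster_method: str = "graph"
    sc_resolution_or_k: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.fdr_max <= 1 and 0 < self.interaction_fdr <= 1
                and 0 < self.q_max <= 1):
            raise ValueError("FDR thresholds must lie in (0, 1]")
        if self.fc_up < 1 or not (0 < self.fc_down <= 1):
            raise ValueError("fold-change gates out of range (fc_up >= 1, 0 < fc_down <= 1)")
        if self.umi_min < 0 or self.k < 1 or self.pseudocount <= 0:
            raise ValueError("invalid threshold value")
        if self.denominator not in ("queried", "assigned"):
            raise ValueError("denominator must be 'queried' or 'assigned'")

    # presets -----------------------------------------------------------
    @classmethod
    def preset(cls, name: str, **overrides) -> "PipelineConfig":
        """Named presets; ``interaction_strict`` applies the 1% interaction
        FDR used for the merged early-late gene set."""
        presets = {
            "default": {},
            "interaction_strict": {"interaction_fdr": 0.01},
        }
        if name not in presets:
            raise ValueError(f"unknown preset {name!r}; have {sorted(presets)}")
        return cls(**{**presets[name], **overrides})

    # serialization -----------------------------------------------------
    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True),
                        encoding="utf-8")
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = cls.__dataclass_fields__
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
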