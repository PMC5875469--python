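"""Run configuration: every tunable numeric default in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class Config:
    """Engine parameters.

    isodose_fraction
        OAR clouds keep only points receiving at least this fraction of
        the prescription dose (0.8 = the 80 % isodose).
    max_point_spacing
        Arc-length resampling interval for contour polylines, mm.
    icp_max_iter, icp_tol
        ICP stopping rule: iteration cap and translation-update norm (mm).
    constraint_doses
        Dose levels (Gy) at which OAR DVH constraint suggestions are read.
    dvh_bin_width
        Cumulative DVH bin width, Gy.
    synonym_table
        Optional path to a tab-separated structure-name synonym table.
    """

    isodose_fraction: float = 0.8
    max_point_spacing: float = 2.0
    icp_max_iter: int = 50
    icp_tol: float = 0.01
    constraint_doses: tuple[float, ...] = (21.0, 42.0, 48.0, 66.0)
    dvh_bin_width: float = 0.1
    synonym_table: str | None = None
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.isodose_fraction <= 1:
            raise ValueError("isodose_fraction must be in (0, 1]")
        for name in ("max_point_spacing", "icp_tol", "dvh_bin_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.constraint_doses = tuple(float(d) for d in self.constraint_doses)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        d["constraint_doses"] = list(d["constraint_doses"])
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
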