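"""Run configuration: one validated record, round-trippable through YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import study
from .errors import ValidationError


@dataclass(frozen=True)
class RunConfig:
    """Everything a batch run needs, with study defaults.

    Every field can be overridden by a CLI flag; the config file is the
    base layer.  ``offsets`` is the grid scanned by the offset search;
    ``vi_offset`` is the single level used for VI profiling and
    classification.
    """

    annotation_color: tuple[int, int, int] = (0, 255, 0)
    tau: float = 0.0
    offsets: tuple[float, ...] = tuple(float(v) for v in study.OFFSET_LEVELS)
    offset_mode: str = "erosion"
    vi_offset: float = float(study.OPTIMUM_OFFSET)
    t_variant: str = "welch"
    alpha: float = 0.05
    peripheral_cut: float = study.DEFAULT_CUTOFFS[0]
    central_cut: float = study.DEFAULT_CUTOFFS[1]
    overall_cut: float = study.DEFAULT_CUTOFFS[2]
    seed: int = 0
    select_largest_outline: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.offset_mode not in ("erosion", "distance"):
            raise ValidationError(f"bad offset_mode {self.offset_mode!r}")
        if self.t_variant not in ("welch", "pooled"):
            raise ValidationError(f"bad t_variant {self.t_variant!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.tau < 0:
            raise ValidationError(f"tau must be >= 0, got {self.tau}")
        for pct in (*self.offsets, self.vi_offset):
            if not 0.0 <= pct <= 100.0:
                raise ValidationError(f"offset {pct} outside [0, 100]")
        object.__setattr__(
            self, "annotation_color", tuple(int(v) for v in self.annotation_color)
        )
        object.__setattr__(
            self, "offsets", tuple(float(v) for v in self.offsets)
        )

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["annotation_color"] = list(self.annotation_color)
        d["offsets"] = list(self.offsets)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        text = Path(source).read_text() if isinstance(source, Path) else source
        data = yaml.safe_load(text) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "annotation_color" in data:
            data["annotation_color"] = tuple(data["annotation_color"])
        if "offsets" in data:
            data["offsets"] = tuple(data["offsets"])
        return cls(**data)
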