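"""Run configuration: one YAML-serializable bundle of all stage parameters."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .centerline import CenterlineConfig
from .centromere import EqWidthParams
from .dosimetry import DoseCurve, DEFAULT_CURVE
from .segmentation import ClassifierConfig, KMeansParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs, round-trippable through YAML."""

    kmeans: KMeansParams = field(default_factory=KMeansParams)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    centerline: CenterlineConfig = field(default_factory=CenterlineConfig)
    eqwidth: EqWidthParams = field(default_factory=EqWidthParams)
    curve: DoseCurve = DEFAULT_CURVE
    input_glob: str = "*.png"
    out_dir: str = "out"
    log_level: str = "INFO"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = dict(d)
        for name, sub in (
            ("kmeans", KMeansParams),
            ("classifier", ClassifierConfig),
            ("centerline", CenterlineConfig),
            ("eqwidth", EqWidthParams),
            ("curve", DoseCurve),
        ):
            if name in kw and isinstance(kw[name], dict):
                kw[name] = sub(**kw[name])
        known = {f.name for f in fields(cls)}
        unknown = set(kw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
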