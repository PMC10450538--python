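"""Run configuration: a single validated YAML file drives the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .caseonly import DEFAULT_CODINGS, CharacteristicCoding

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Configuration for the ``simulate`` and ``analyze`` commands.

    ``codings`` may be given in YAML as a list of mappings with keys
    name, levels, reference; it defaults to the study's standard five
    characteristics.
    """

    tweets_csv: Optional[str] = None
    records_csv: Optional[str] = None
    percentile: float = 95.0
    denoise_window: int = 0
    lags: tuple = (3, 7)
    mode: str = "suicide"
    codings: tuple = DEFAULT_CODINGS
    outdir: str = "out"
    seed: int = 0

    def __post_init__(self) -> None:
        self.lags = tuple(int(x) for x in self.lags)
        if not self.lags or any(lag < 0 for lag in self.lags):
            raise ValueError("lags must be non-empty with each lag >= 0")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")
        if self.mode not in ("suicide", "unexpected"):
            raise ValueError("mode must be 'suicide' or 'unexpected'")
        if self.denoise_window < 0 or (
            self.denoise_window > 0 and self.denoise_window % 2 == 0
        ):
            raise ValueError("denoise_window must be 0 or an odd integer >= 1")
        self.codings = tuple(
            c if isinstance(c, CharacteristicCoding) else CharacteristicCoding(**c)
            for c in self.codings
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path}: expected a mapping at top level")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"config {path}: unknown keys {sorted(unknown)}")
        return cls(**raw)
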