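"""CSV and JSON round-tripping for the command-line workflow.

All CSVs are comma-separated UTF-8 with a mandatory header row and "."
decimal separator.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import KiwigradeError
from .image import PipelineConfig

MEASUREMENT_COLUMNS = (
    "image_id",
    "weight_g",
    "length_mm",
    "mades_mm",
    "pa_cm2",
    "ra",
    "threshold",
    "n_components_removed",
)

GRADE_INPUT_COLUMNS = ("weight_g", "length_mm", "mades_mm", "pa_cm2")


def read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise KiwigradeError(f"{path}: missing required columns {missing}")
    return frame


def write_csv(frame: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


def load_pipeline_config(path: str | Path | None) -> PipelineConfig:
    """Pipeline configuration from a JSON file; missing file -> defaults."""
    if path is None:
        return PipelineConfig()
    obj = json.loads(Path(path).read_text())
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(obj) - known
    if unknown:
        raise KiwigradeError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**obj)
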