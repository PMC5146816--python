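"""Dataset / results export, config files and the run manifest.

Datasets are written as plain delimited text with a header row
(``id time event snp [treatment]``), tab-separated on write; read-back
accepts any whitespace so files remain directly loadable in R with
``read.table(file, header=TRUE)``.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .config import AnalysisConfig, SimulationConfig
from .power import PowerResult
from .simdata import Dataset

__all__ = [
    "export_dataset",
    "read_dataset",
    "write_results_table",
    "write_power_summary",
    "RunManifest",
    "load_config_file",
    "split_config_mapping",
]

_SIM_FIELDS = set(SimulationConfig.__dataclass_fields__)
_ANALYSIS_FIELDS = set(AnalysisConfig.__dataclass_fields__)


def export_dataset(dataset: Dataset, path) -> Path:
    """Write one replicate as tab-delimited text (header + one row/subject).

    The treatment column is omitted when no treatment arm was simulated.
    Round-trips losslessly through :func:`read_dataset`.
    """
    path = Path(path)
    dataset.to_frame().to_csv(path, sep="\t", index=False)
    return path


def read_dataset(path) -> Dataset:
    """Read a dataset written by :func:`export_dataset` (or any
    whitespace-delimited file with the same header)."""
    df = pd.read_csv(path, sep=r"\s+")
    return Dataset.from_frame(df)


def write_results_table(result: PowerResult, path) -> Path:
    """Per-replicate results, one row per replicate, tab-delimited."""
    path = Path(path)
    result.table.to_csv(path, sep="\t", index=False)
    return path


def write_power_summary(result: PowerResult, text_path, json_path) -> None:
    """Power summary as a human-readable block and a JSON twin."""
    Path(text_path).write_text(result.format_summary())
    Path(json_path).write_text(json.dumps(result.to_json_dict(), indent=2) + "\n")


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-identically."""

    sim: SimulationConfig
    analysis: AnalysisConfig
    tool_version: str
    created: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))
    output_dir: Optional[str] = None

    def to_json_dict(self) -> dict:
        return {
            "sim": self.sim.to_dict(),
            "analysis": self.analysis.to_dict(),
            "master_seed": self.sim.seed,
            "tool_version": self.tool_version,
            "created": self.created,
            "output_dir": self.output_dir,
        }

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_json_dict(), indent=2) + "\n")
        return path

    @classmethod
    def read(cls, path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(
            sim=SimulationConfig(**d["sim"]),
            analysis=AnalysisConfig(**d["analysis"]),
            tool_version=d.get("tool_version", "unknown"),
            created=d.get("created", ""),
            output_dir=d.get("output_dir"),
        )


def split_config_mapping(mapping: dict):
    """Split a flat key-value mapping into (sim kwargs, analysis kwargs).

    Unknown keys raise, so typos in a config file fail loudly instead of
    silently running with defaults.
    """
    sim_kwargs, analysis_kwargs = {}, {}
    for key, value in mapping.items():
        if key in _SIM_FIELDS:
            sim_kwargs[key] = value
        elif key in _ANALYSIS_FIELDS:
            analysis_kwargs[key] = value
        else:
            raise ValueError(f"unknown configuration key {key!r}")
    return sim_kwargs, analysis_kwargs


def load_config_file(path):
    """Load a flat YAML config file into (sim kwargs, analysis kwargs)."""
    mapping = yaml.safe_load(Path(path).read_text())
    if not isinstance(mapping, dict):
        raise ValueError(f"config file {path} must contain a flat key: value mapping")
    return split_config_mapping(mapping)
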