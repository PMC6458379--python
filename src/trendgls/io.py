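"""Configuration, tabular input and report output."""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .data import Dataset, build_covariate_design, build_polynomial_design, colocation_groups
from .model import TrendModel


@dataclass
class AnalysisConfig:
    """Validated analysis configuration.

    Column roles select the time (or coordinate) columns and the single
    response column of the input CSV; the model is either a polynomial
    ``degree`` in time or an explicit ``covariates`` list.
    """

    input: str = ""
    response: str = "y"
    time: Optional[str] = None
    coords: Optional[list] = None
    group: Optional[str] = None
    degree: int = 1
    covariates: Optional[list] = None
    rho_method: str = "tadw"
    alpha: float = 0.05
    distance_metric: str = "euclidean"
    forecast: Optional[dict] = None  # {"from":, "to":, "step":}
    seed: int = 0
    output: Optional[str] = None

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if (self.time is None) == (self.coords is None):
            raise ValueError("configure exactly one of time or coords")
        if self.coords is not None and self.distance_metric == "great-circle" \
                and len(self.coords) != 2:
            raise ValueError("great-circle metric needs two (lon, lat) columns")

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def read_table(path: str, config: AnalysisConfig):
    """Load a CSV into a (Dataset, DesignMatrix) pair per the config.

    Rows with missing values in the selected columns are rejected with
    their row numbers.  Duplicated coordinates populate co-location
    groups on the dataset.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    pos = [config.time] if config.time is not None else list(config.coords)
    need = pos + [config.response] + (config.covariates or []) \
        + ([config.group] if config.group else [])
    missing_cols = [c for c in need if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    sub = df[need]
    bad = sub.isna().any(axis=1)
    if bad.any():
        rows = [int(i) + 2 for i in np.where(bad.to_numpy())[0]]  # 1-based + header
        raise ValueError(f"{path}: missing values on lines {rows}")
    ds = Dataset(coords=df[pos].to_numpy(dtype=float),
                 y=df[config.response].to_numpy(dtype=float),
                 group_ids=df[config.group].to_numpy() if config.group else None,
                 distance_metric=config.distance_metric)
    if ds.group_ids is None:
        labels = colocation_groups(ds.coords)
        if labels.max() + 1 < ds.n:
            ds.group_ids = labels
    if config.time is not None and config.covariates is None:
        design = build_polynomial_design(ds.coords[:, 0], config.degree)
    else:
        cols = config.covariates if config.covariates is not None else pos
        design = build_covariate_design(df[cols].to_numpy(dtype=float), names=cols)
    return ds, design


def load_model(config: AnalysisConfig) -> TrendModel:
    ds, design = read_table(config.input, config)
    return TrendModel(ds, design)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_report(summary_text: str, records: dict, path: str,
                 config: Optional[AnalysisConfig] = None) -> list:
    """Write a human-readable summary plus a machine-readable JSON twin.

    ``records`` must already contain every number worth re-using (it is
    written verbatim); the config echo and seed are included so the
    analysis can be reconstructed.  Returns the list of files written.
    """
    base, _ = os.path.splitext(path)
    txt = base + ".txt"
    js = base + ".json"
    # pre-flight: fail before any partial output
    for f in (txt, js):
        d = os.path.dirname(os.path.abspath(f))
        if not os.path.isdir(d) or not os.access(d, os.W_OK):
            raise ValueError(f"output directory not writable: {d}")
    payload = dict(records)
    if config is not None:
        payload["config"] = config.to_dict()
        payload["seed"] = config.seed
    with open(txt, "w") as fh:
        fh.write(summary_text + "\n")
    with open(js, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    return [txt, js]
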