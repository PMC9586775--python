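"""Plain-text I/O: censored samples as CSV, parameters as YAML/JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .censoring import CensoredSample
from .distributions import MixtureParams

__all__ = ["read_sample_csv", "write_sample_csv", "read_params", "write_params"]


def read_sample_csv(path) -> CensoredSample:
    """Read a censored sample from CSV.

    Accepts two columns (time, status) or three (time, status, label);
    status is 1 for an observed failure and 0 for a censored record.  A
    header row is optional and detected automatically.
    """
    df = pd.read_csv(path, header=None)
    if df.empty:
        raise ValueError(f"{path}: empty sample file")
    # drop a header row if the first cell is not numeric
    try:
        float(df.iloc[0, 0])
    except (TypeError, ValueError):
        df = pd.read_csv(path)
    if df.shape[1] not in (2, 3):
        raise ValueError(f"{path}: expected 2 or 3 columns, got {df.shape[1]}")
    try:
        times = df.iloc[:, 0].astype(float).to_numpy()
        status = df.iloc[:, 1].astype(int).to_numpy()
        labels = df.iloc[:, 2].astype(int).to_numpy() if df.shape[1] == 3 else None
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric entry ({exc})") from exc
    t_anchor = float(times[status == 1].max()) if (status == 1).any() else None
    return CensoredSample(times, status, labels, t_anchor=t_anchor)


def write_sample_csv(sample: CensoredSample, path) -> None:
    cols = {"time": sample.times, "status": sample.status}
    if sample.labels is not None:
        cols["label"] = sample.labels
    pd.DataFrame(cols).to_csv(path, index=False)


def read_params(path) -> MixtureParams:
    """Read mixture parameters from YAML or JSON with keys
    lambda1, theta1, lambda2, theta2, pi1."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return MixtureParams.from_dict(data)


def write_params(omega: MixtureParams, path) -> None:
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(omega.to_dict(), indent=2))
    else:
        p.write_text(yaml.safe_dump(omega.to_dict()))
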