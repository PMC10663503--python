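"""Trial-table, config and fit-result file plumbing.

Trial tables are UTF-8 comma-separated text with a header row using the
canonical TrialRecord field names; boolean flags are stored as 0/1 and
missing values as empty cells.  Session configs are YAML key-value files
mirroring :class:`tempwager.task.SessionConfig`.  Fit results are key-value
text files with the per-start NLL array inlined.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .task import TRIAL_COLUMNS, SessionConfig

_BOOL_COLS = ("is_catch", "is_violation", "opted_out", "rewarded")


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as CSV (flags as 0/1, missing as empty)."""
    out = trials.copy()
    for c in _BOOL_COLS:
        if c in out:
            out[c] = out[c].astype(int)
    out.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a trial-table CSV, validating the schema."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns and c in (
        "rat_id", "session_id", "trial_index", "block", "reward_offer",
        "is_catch", "is_violation",
    )]
    if missing:
        raise ValueError(f"trial table {path} is missing column(s): {missing}")
    for c in _BOOL_COLS:
        if c in df:
            df[c] = df[c].fillna(0).astype(bool)
    return df


def write_config(config: SessionConfig, path) -> None:
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_config(path) -> SessionConfig:
    d = yaml.safe_load(Path(path).read_text()) or {}
    if "reward_set" in d:
        d["reward_set"] = tuple(d["reward_set"])
    return SessionConfig(**d)


def write_fit_result(res, path, extra: dict | None = None) -> None:
    """Serialize a :class:`~tempwager.fitting.WaitTimeResults` as text."""
    lines = [
        f"model: {res.model.model}",
        f"n_obs: {res.nobs}",
        f"n_params: {res.k}",
        f"nll: {float(res.nll)!r}",
        f"bic: {float(res.bic)!r}",
        f"aic: {float(res.aic)!r}",
    ]
    for k, v in (extra or {}).items():
        lines.append(f"{k}: {v}")
    for name, val in res.params_dict.items():
        lines.append(f"param {name}: {float(val)!r}")
    lines.append("start_nlls: " + ",".join(repr(float(v)) for v in res.start_nlls))
    Path(path).write_text("\n".join(lines) + "\n")


def read_fit_result(path) -> dict:
    """Read a fit-result file back into a plain dict."""
    out: dict = {"params": {}}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, _, val = line.partition(":")
        key, val = key.strip(), val.strip()
        if key.startswith("param "):
            out["params"][key[6:]] = float(val)
        elif key == "start_nlls":
            out[key] = np.array([float(v) for v in val.split(",") if v])
        elif key in ("n_obs", "n_params"):
            out[key] = int(val)
        elif key in ("nll", "bic", "aic"):
            out[key] = float(val)
        else:
            out[key] = val
    return out
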