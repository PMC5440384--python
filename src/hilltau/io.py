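"""File formats, run configuration, and the packaged study design table.

Canonical CSV dialects (comma-separated, dot decimal, UTF-8, mandatory
header; hours and wt.% are the only accepted units):

* curve CSV — columns ``t_hours``, ``signal``;
* design CSV — one column per agent (header = agent name, values wt.%),
  plus ``tau_obs``, ``tau_sd``, ``n_rep`` and an optional leading ``sample``
  label column;
* isobole CSV — columns ``C_A``, ``C_B``.

Reports are JSON with a ``schema_version`` field and no timestamps, so a
given input + configuration + seed always produces byte-identical output.

The packaged design table (oxidation-induction times of a sunflower-ester
substrate dosed with three antioxidants, singly and in binary blends at a
0.25 wt.% total-dose cap) ships as ``data/table1.csv`` and is checksum-pinned
against silent edits.  Its ``tau_fitted_ref`` column carries the published
fitted values for reference and is never consumed by the estimators.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .fitting import CompositionRecord, ConductivityCurve

__all__ = [
    "RunConfig",
    "read_curve_csv",
    "write_curve_csv",
    "read_design_csv",
    "write_design_csv",
    "write_isobole_csv",
    "load_table1",
    "table1_fitted_reference",
    "write_report",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1

_DESIGN_META_COLS = ("sample", "tau_obs", "tau_sd", "n_rep", "tau_fitted_ref")
_TABLE1_SHA256 = "7e55f3f8dfdb0ef8fbc4afcd84ffdefd376f948853fa7c850d40bcba6a7905a4"


class RunConfig(BaseModel):
    """Validated run configuration shared by the command-line entry points."""

    theta_mode: float | Literal["shared", "free"] = "shared"
    synergy_pairs: list[tuple[str, str]] = Field(default_factory=list)
    lam: float = 2.0
    beta: float = -1.0
    seed: int = 0
    records_used: Literal["single", "all"] = "single"
    output_dir: Path | None = None

    @field_validator("theta_mode")
    @classmethod
    def _theta_positive(cls, v):
        if isinstance(v, float) and not v > 0:
            raise ValueError("fixed theta must be > 0")
        return v

    @field_validator("lam")
    @classmethod
    def _lam_positive(cls, v):
        if not v > 0:
            raise ValueError("lam must be > 0")
        return v

    @field_validator("beta")
    @classmethod
    def _beta_nonzero(cls, v):
        if v == 0:
            raise ValueError("beta must be nonzero")
        return v

    def validate_agents(self, agents: Sequence[str]) -> None:
        """Require every synergy-pair agent to appear in the design."""
        known = set(agents)
        for a, b in self.synergy_pairs:
            missing = {a, b} - known
            if missing:
                raise ValueError(
                    f"synergy pair ({a!r}, {b!r}) references agents absent "
                    f"from the design: {sorted(missing)}"
                )


def read_curve_csv(path: str | Path) -> ConductivityCurve:
    """Read a monitor curve (columns t_hours, signal)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty or unreadable curve CSV") from exc
    missing = {"t_hours", "signal"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: curve CSV lacks columns {sorted(missing)}")
    if df[["t_hours", "signal"]].isna().any().any():
        bad = int(df[["t_hours", "signal"]].isna().any(axis=1).idxmax()) + 2
        raise ValueError(f"{path}: malformed numeric value near line {bad}")
    return ConductivityCurve(
        times=df["t_hours"].to_numpy(float),
        signal=df["signal"].to_numpy(float),
        label=path.stem,
    )


def write_curve_csv(curve: ConductivityCurve, path: str | Path) -> None:
    pd.DataFrame({"t_hours": curve.times, "signal": curve.signal}).to_csv(
        path, index=False
    )


def read_design_csv(path: str | Path) -> list[CompositionRecord]:
    """Read a composition/response design table.

    Agent columns are every column not in the reserved set
    (sample, tau_obs, tau_sd, n_rep, tau_fitted_ref).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty or unreadable design CSV") from exc
    if "tau_obs" not in df.columns:
        raise ValueError(f"{path}: design CSV lacks a tau_obs column")
    agents = [c for c in df.columns if c not in _DESIGN_META_COLS]
    if not agents:
        raise ValueError(f"{path}: design CSV has no agent columns")
    records = []
    for i, row in df.iterrows():
        records.append(
            CompositionRecord(
                composition={a: float(row[a]) for a in agents},
                tau_obs=float(row["tau_obs"]),
                tau_sd=float(row.get("tau_sd", 0.0) or 0.0),
                n_rep=int(row.get("n_rep", 1) or 1),
                label=str(row["sample"]) if "sample" in df.columns else f"row-{i}",
            )
        )
    return records


def write_design_csv(records: Sequence[CompositionRecord], path: str | Path) -> None:
    agents = sorted({a for r in records for a in r.composition})
    rows = []
    for r in records:
        row = {"sample": r.label}
        row.update({a: r.composition.get(a, 0.0) for a in agents})
        row.update({"tau_obs": r.tau_obs, "tau_sd": r.tau_sd, "n_rep": r.n_rep})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_isobole_csv(C_A: np.ndarray, C_B: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"C_A": C_A, "C_B": C_B}).to_csv(path, index=False)


def _table1_bytes() -> bytes:
    return (resources.files("hilltau") / "data" / "table1.csv").read_bytes()


def load_table1() -> list[CompositionRecord]:
    """The packaged study design table as composition records.

    The file's checksum is verified on every load; a mismatch means the
    packaged fixture was altered and the published values can no longer be
    trusted.
    """
    raw = _table1_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE1_SHA256:
        raise RuntimeError(
            "packaged design table failed its integrity check "
            f"(sha256 {digest})"
        )
    import io as _io

    df = pd.read_csv(_io.BytesIO(raw))
    records = []
    agents = [c for c in df.columns if c not in _DESIGN_META_COLS]
    for _, row in df.iterrows():
        records.append(
            CompositionRecord(
                composition={a: float(row[a]) for a in agents},
                tau_obs=float(row["tau_obs"]),
                tau_sd=float(row["tau_sd"]),
                n_rep=int(row["n_rep"]),
                label=str(row["sample"]),
            )
        )
    return records


def table1_fitted_reference() -> dict[str, float]:
    """Published fitted tau per sample label (reference only, never fed to
    the estimators)."""
    import io as _io

    df = pd.read_csv(_io.BytesIO(_table1_bytes()))
    return dict(zip(df["sample"], df["tau_fitted_ref"].astype(float)))


def write_report(payload: dict, path: str | Path) -> None:
    """Write a JSON report with the schema version; deterministic layout."""
    doc = {"schema_version": SCHEMA_VERSION, **payload}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
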