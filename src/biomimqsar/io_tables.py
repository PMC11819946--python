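"""Tabular I/O and the canonical column vocabulary.

Every stage speaks the same schema:

* ``panel.csv`` — one row per compound with the in-silico descriptors
  (MW, TPSA, alpha, HBD, HBA, NRB, logP_ow, pKa), optional in-silico
  endpoints (logP_wpc, logKp, logP_wHSA, logBB) and, when available,
  chromatographic (logk_IAM, logk_BMC) and hemolysis (HC50) columns.
* ``retention.csv`` — compound_id, system (IAM|BMC), tr_rep1..3, t0 in
  minutes; replicate columns may be partially empty.
* ``hemolysis.csv`` — compound_id, conc_uM, abs_rep1..3, with reserved
  rows ``blank`` and ``control`` carrying the plate blank and the positive
  control absorbances.

Comma is the canonical delimiter; semicolon and tab dialects are accepted.
Missing cells are empty strings and parse as missing, never as zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError
from .hemolysis import HemolysisCurve
from .mlr import MlrModel
from .retention import RetentionRecord

__all__ = [
    "CompoundPanel",
    "DatasetBundle",
    "read_panel",
    "read_retention",
    "read_hemolysis",
    "write_model_report",
    "read_model_report",
    "attach_logk",
]

DIALECTS = {"comma": ",", "semicolon": ";", "tab": "\t"}

REQUIRED_PANEL_COLS = ["compound_id", "MW", "TPSA", "alpha", "HBD", "HBA", "NRB", "logP_ow"]
OPTIONAL_NUMERIC_COLS = [
    "pKa", "logP_wpc", "logKp", "logP_wHSA", "logBB", "logk_IAM", "logk_BMC", "HC50", "HBD_HBA",
]
INT_COLS = ["HBD", "HBA", "NRB"]
RESERVED_HEMOLYSIS_IDS = {"blank", "control"}


@dataclass
class CompoundPanel:
    """Descriptor + endpoint table keyed by compound_id.

    Validates uniqueness of compound ids, positivity of MW, nonnegativity of
    TPSA and the integer counts, and materializes the derived HBD_HBA column
    (sum of hydrogen-bond donors and acceptors) used by the models.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        f = self.frame
        if f.columns.duplicated().any():
            raise SchemaError(f"duplicated column names: {list(f.columns[f.columns.duplicated()])}")
        missing = [c for c in REQUIRED_PANEL_COLS if c not in f.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        if f["compound_id"].duplicated().any():
            dups = f.loc[f["compound_id"].duplicated(), "compound_id"].tolist()
            raise SchemaError(f"duplicated compound_id: {dups}")
        if len(f):
            if (f["MW"] <= 0).any():
                raise SchemaError("MW must be positive")
            if (f["TPSA"] < 0).any():
                raise SchemaError("TPSA must be nonnegative")
            for c in INT_COLS:
                vals = f[c].to_numpy(dtype=float)
                vals = vals[~np.isnan(vals)]
                if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
                    raise SchemaError(f"{c} must hold nonnegative integers")
        if "HBD_HBA" not in f.columns:
            f = f.copy()
            f["HBD_HBA"] = f["HBD"] + f["HBA"]
            self.frame = f
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def compound_ids(self) -> list[str]:
        return self.frame["compound_id"].tolist()

    def to_csv(self, path, dialect: str = "comma") -> None:
        # repr of a float is shortest-roundtrip, hence the write is lossless
        self.frame.to_csv(
            path, sep=DIALECTS[dialect], index=False, float_format=lambda v: repr(float(v))
        )


def _read_raw(path, dialect: str) -> pd.DataFrame:
    sep = DIALECTS.get(dialect)
    if sep is None:
        raise SchemaError(f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}")
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, skipinitialspace=True)


def _numeric(raw: pd.DataFrame, col: str) -> pd.Series:
    """Locale-independent numeric parsing with row/column error reporting."""
    s = raw[col].str.strip()
    probe = pd.to_numeric(s.mask(s == ""), errors="coerce")
    bad = probe.isna() & (s != "")
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ParseError(f"non-numeric value {s.iloc[row]!r} in column {col!r}, data row {row + 1}")
    # numpy's parser is correctly rounded, so repr-written floats round-trip
    return s.mask(s == "").astype(float)


def read_panel(path, dialect: str = "comma") -> CompoundPanel:
    """Read ``panel.csv``; header-name binding, column order irrelevant."""
    raw = _read_raw(path, dialect)
    missing = [c for c in REQUIRED_PANEL_COLS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if len(raw) == 0:
        warnings.warn(f"{path}: header present but no data rows; empty panel")
    frame = pd.DataFrame({"compound_id": raw["compound_id"].str.strip()})
    if "name" in raw.columns:
        frame["name"] = raw["name"]
    for col in raw.columns:
        if col in ("compound_id", "name"):
            continue
        if col in REQUIRED_PANEL_COLS or col in OPTIONAL_NUMERIC_COLS:
            frame[col] = _numeric(raw, col)
        else:
            frame[col] = _numeric(raw, col)  # extra columns are numeric by convention
    return CompoundPanel(frame)


def read_retention(path, dialect: str = "comma") -> list[RetentionRecord]:
    raw = _read_raw(path, dialect)
    required = ["compound_id", "system", "t0"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    rep_cols = [c for c in raw.columns if c.startswith("tr_rep")]
    if not rep_cols:
        raise SchemaError("no tr_rep* replicate columns found")
    reps = {c: _numeric(raw, c) for c in rep_cols}
    t0 = _numeric(raw, "t0")
    records = []
    for i in range(len(raw)):
        t_r = [float(reps[c].iloc[i]) for c in rep_cols if not np.isnan(reps[c].iloc[i])]
        records.append(
            RetentionRecord(
                compound_id=raw["compound_id"].iloc[i].strip(),
                system=raw["system"].iloc[i].strip(),
                t_r=t_r,
                t_0=float(t0.iloc[i]),
            )
        )
    return records


def attach_logk(panel: CompoundPanel, records: list[RetentionRecord]) -> CompoundPanel:
    """Merge derived log k values into the panel as logk_IAM / logk_BMC columns."""
    frame = panel.frame.copy()
    for system, col in (("IAM", "logk_IAM"), ("BMC", "logk_BMC")):
        values = {r.compound_id: r.log_k for r in records if r.system == system}
        if values:
            frame[col] = frame["compound_id"].map(values)
    return CompoundPanel(frame)


def read_hemolysis(path, dialect: str = "comma") -> list[HemolysisCurve]:
    """Read ``hemolysis.csv`` with reserved blank/control plate rows."""
    raw = _read_raw(path, dialect)
    required = ["compound_id", "conc_uM"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    rep_cols = [c for c in raw.columns if c.startswith("abs_rep")]
    if not rep_cols:
        raise SchemaError("no abs_rep* replicate columns found")
    reps = pd.DataFrame({c: _numeric(raw, c) for c in rep_cols})
    ids = raw["compound_id"].str.strip()
    low = ids.str.lower()
    plate = {}
    for key in RESERVED_HEMOLYSIS_IDS:
        mask = low == key
        if not mask.any():
            raise SchemaError(f"missing reserved plate row {key!r}")
        plate[key] = float(np.nanmean(reps.loc[mask].to_numpy()))
    conc = _numeric(raw, "conc_uM")
    curves = []
    for cid in ids[~low.isin(RESERVED_HEMOLYSIS_IDS)].unique():
        mask = ids == cid
        order = np.argsort(conc[mask].to_numpy())
        curves.append(
            HemolysisCurve(
                compound_id=cid,
                concentrations=conc[mask].to_numpy()[order],
                absorbances=reps.loc[mask].to_numpy()[order],
                abs_blank=plate["blank"],
                abs_control=plate["control"],
            )
        )
    return curves


@dataclass
class DatasetBundle:
    """All inputs for one study: panel, retention records, hemolysis curves."""

    panel: CompoundPanel
    retention: list[RetentionRecord] = field(default_factory=list)
    hemolysis: list[HemolysisCurve] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        known = set(self.panel.compound_ids)
        dangling = {r.compound_id for r in self.retention if r.compound_id not in known}
        dangling |= {c.compound_id for c in self.hemolysis if c.compound_id not in known}
        if dangling:
            raise SchemaError(f"compound_id(s) not in panel: {sorted(dangling)}")


def write_model_report(models: list[MlrModel], path) -> None:
    """Serialize fitted models to JSON (one record each), losslessly."""
    records = []
    for m in models:
        if not isinstance(m, MlrModel) or m.sd is None:
            raise SchemaError(f"unfitted or invalid model: {m!r}")
        records.append(m.to_record())
    Path(path).write_text(json.dumps(records, indent=1))


def read_model_report(path) -> list[dict]:
    """Companion reader for :func:`write_model_report`."""
    return json.loads(Path(path).read_text())
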