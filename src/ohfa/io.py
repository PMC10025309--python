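"""CSV interchange and packaged fixture tables.

Two schemas:

* **long format** (pipeline interchange): one row per
  strain x condition x replicate x compound, columns ``strain_id,
  condition_variable, condition_value, replicate_id, basis, fa_label,
  value, detected``. "n.d." or an empty value marks an undetected compound.
* **fixture format** (packaged ``table1`` .. ``table6``): wide mean/sd
  columns transcribing published aggregate tables, checksummed at build
  time and verified on load.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .profiles import (
    AggregateProfile,
    AggregateStat,
    Basis,
    ConditionVariable,
    ExperimentSeries,
    FattyAcidDescriptor,
    Measurement,
    SampleProfile,
    ValueKind,
    parse_fa_name,
)

__all__ = [
    "FIXTURE_NAMES",
    "FixtureTable",
    "IntegrityError",
    "SchemaError",
    "load_fixture",
    "read_long_csv",
    "write_long_csv",
    "series_to_frame",
]

FIXTURE_NAMES = ("table1", "table2", "table3", "table4", "table5", "table6")

LONG_COLUMNS = [
    "strain_id",
    "condition_variable",
    "condition_value",
    "replicate_id",
    "basis",
    "fa_label",
    "value",
    "detected",
]


class IntegrityError(RuntimeError):
    """A packaged fixture does not match its recorded checksum."""


class SchemaError(ValueError):
    """An input table is missing required columns or has bad values."""


def _normalize_text(s: str) -> str:
    # unicode minus / plus-minus normalized to ASCII at load
    return s.replace("−", "-").replace("±", "+/-")


# ---------------------------------------------------------------------------
# long-format interchange


def read_long_csv(path: str | Path) -> list[SampleProfile]:
    """Read a long-format measurement CSV into per-replicate profiles."""
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SchemaError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    profiles: dict[tuple, SampleProfile] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            cond_var = ConditionVariable(row.condition_variable)
            basis = Basis(row.basis)
            cond_val = float(row.condition_value)
            raw = _normalize_text(str(row.value)).strip()
            detected_col = str(row.detected).strip().lower()
            detected = detected_col not in ("false", "0", "no") and raw not in ("", "n.d.", "nd")
            value = float(raw) if detected else None
            kind = (
                ValueKind(row.value_kind)
                if "value_kind" in df.columns
                else ValueKind.RELATIVE_ABUNDANCE
            )
            desc = parse_fa_name(
                row.fa_label, hydroxylated_3=basis is Basis.TOTAL_3OH_FAS
            )
        except (ValueError, KeyError) as exc:
            raise SchemaError(f"{path}: row {row_no}: {exc}") from exc
        key = (row.strain_id, cond_var, cond_val, row.replicate_id, basis)
        profile = profiles.get(key)
        if profile is None:
            profile = SampleProfile(
                strain_id=row.strain_id,
                condition_variable=cond_var,
                condition_value=cond_val,
                replicate_id=row.replicate_id,
                basis=basis,
            )
            profiles[key] = profile
        profile.add(Measurement(desc, value, kind, detected))
    return list(profiles.values())


def series_to_frame(series: ExperimentSeries) -> pd.DataFrame:
    """Long-format frame of a series (inverse of :func:`read_long_csv`)."""
    rows = []
    for p in series.profiles:
        for desc, m in p.measurements.items():
            rows.append(
                {
                    "strain_id": p.strain_id,
                    "condition_variable": p.condition_variable.value,
                    "condition_value": p.condition_value,
                    "replicate_id": p.replicate_id,
                    "basis": p.basis.value,
                    "fa_label": desc.label,
                    "value": "" if m.value is None else f"{m.value:.6f}",
                    "detected": m.detected,
                }
            )
    return pd.DataFrame(rows, columns=LONG_COLUMNS)


def write_long_csv(series: ExperimentSeries, path: str | Path) -> None:
    series_to_frame(series).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# packaged fixtures

_CONDITION_LABELS = {"temperature_C": ConditionVariable.TEMPERATURE_C, "pH": ConditionVariable.PH}


@dataclass
class FixtureTable:
    """One packaged aggregate table with mean +/- sd cells.

    ``data`` is a tidy frame with one row per (label, condition block,
    level): columns ``label, kind, group, condition_variable, level, mean,
    sd, detected`` plus per-row ``r2``/``p`` regression columns repeated
    from the printed table.
    """

    name: str
    strain_id: str
    basis: Basis
    data: pd.DataFrame

    def levels(self, condition: ConditionVariable) -> list[float]:
        sel = self.data[self.data["condition_variable"] == condition.value]
        return sorted(sel["level"].unique())

    def cell(
        self, label: str, condition: ConditionVariable, level: float
    ) -> tuple[float, float | None] | None:
        """(mean, sd) of one printed cell, or ``None`` for "n.d."."""
        sel = self.data[
            (self.data["label"] == label)
            & (self.data["condition_variable"] == condition.value)
            & (self.data["level"] == level)
        ]
        if sel.empty:
            raise KeyError(f"{self.name}: no cell ({label!r}, {condition.value}, {level})")
        row = sel.iloc[0]
        if not row["detected"]:
            return None
        sd = None if pd.isna(row["sd"]) else float(row["sd"])
        return float(row["mean"]), sd

    def printed_stats(
        self, label: str, condition: ConditionVariable
    ) -> tuple[float | None, float | None]:
        """The printed per-row (R^2, p) regression columns."""
        sel = self.data[
            (self.data["label"] == label)
            & (self.data["condition_variable"] == condition.value)
        ]
        if sel.empty:
            raise KeyError(f"{self.name}: no row ({label!r}, {condition.value})")
        row = sel.iloc[0]
        r2 = None if pd.isna(row["r2"]) else float(row["r2"])
        p = None if pd.isna(row["p"]) else float(row["p"])
        return r2, p

    def fa_labels(self) -> list[str]:
        return list(self.data[self.data["kind"] == "fa"]["label"].unique())

    def aggregate_profile(
        self, condition: ConditionVariable, level: float, n_replicates: int = 3
    ) -> AggregateProfile:
        """Individual-compound rows of one column as an aggregate profile."""
        stats: dict[FattyAcidDescriptor, AggregateStat] = {}
        is_3oh = self.basis is Basis.TOTAL_3OH_FAS
        for label in self.fa_labels():
            cell = self.cell(label, condition, level)
            if cell is None:
                continue
            mean, sd = cell
            desc = parse_fa_name(label, hydroxylated_3=is_3oh)
            stats[desc] = AggregateStat(mean=mean, sd=sd, n_detected=n_replicates)
        return AggregateProfile(
            strain_id=self.strain_id,
            condition_variable=condition,
            condition_value=level,
            basis=self.basis,
            n_replicates=n_replicates,
            stats=stats,
        )


def _fixture_bytes(filename: str) -> bytes:
    ref = resources.files("ohfa.fixtures").joinpath(filename)
    return ref.read_bytes()


def load_fixture(name: str, *, verify_checksum: bool = True) -> FixtureTable:
    """Load a packaged aggregate table (``table1`` .. ``table6``)."""
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    raw = _fixture_bytes(f"{name}.csv")
    if verify_checksum:
        recorded = json.loads(_fixture_bytes("checksums.json"))
        digest = hashlib.sha256(raw).hexdigest()
        if recorded.get(f"{name}.csv") != digest:
            raise IntegrityError(
                f"fixture {name}.csv checksum mismatch (got {digest[:12]}...)"
            )
    import io as _io

    wide = pd.read_csv(_io.BytesIO(raw), dtype=str, keep_default_na=False)
    records = []
    for _, row in wide.iterrows():
        for i in range(1, 6):
            lev = row[f"level_{i}"]
            if lev == "":
                continue
            mean_raw = _normalize_text(row[f"mean_{i}"]).strip()
            detected = mean_raw not in ("", "n.d.")
            sd_raw = row[f"sd_{i}"].strip()
            records.append(
                {
                    "label": row["label"],
                    "kind": row["kind"],
                    "group": row["group"],
                    "condition_variable": row["condition_variable"],
                    "level": float(lev),
                    "mean": float(mean_raw) if detected else float("nan"),
                    "sd": float(sd_raw) if (detected and sd_raw) else float("nan"),
                    "detected": detected,
                    "r2": float(row["r2"]) if row["r2"] else float("nan"),
                    "p": float(row["p"]) if row["p"] else float("nan"),
                }
            )
    first = wide.iloc[0]
    return FixtureTable(
        name=name,
        strain_id=first["strain_id"],
        basis=Basis(first["basis"]),
        data=pd.DataFrame(records),
    )
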