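"""Domain types, unit conventions, and table I/O for permeation studies.

Everything downstream computes in a single unit system: mass in µg,
concentration in µg/mL, volume in mL (≡ cm³), area in cm², time in h.
Transmembranal water loss (TMWL) stays in g/(m²·h) and is never mixed
with the µg/cm² permeation system. Converters, where needed, live at the
I/O boundary only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class StudyDataError(ValueError):
    """Base class for study-data validation and I/O failures."""


class TableFormatError(StudyDataError):
    """A required column is missing or the table layout is unusable."""


class TableParseError(StudyDataError):
    """A cell value could not be parsed; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        super().__init__(message if row is None else f"row {row}: {message}")


class ValidationError(StudyDataError):
    """Data violate a domain invariant (e.g. no control row for a membrane)."""


class ConfigError(StudyDataError):
    """Bad configuration value (unknown policy label, malformed YAML, ...)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

#: Control label for untreated-membrane TMWL rows.
CONTROL_LABEL = "control"


@dataclass(frozen=True)
class FranzCellSpec:
    """Geometry and sampling protocol of a static Franz diffusion cell.

    Defaults are the study protocol: a 3 mL receptor compartment under a
    1.86 cm² orifice, 0.2 mL aliquots withdrawn (and replaced with fresh
    receptor fluid) at 0, 0.5, 1, 2 and 4 h.
    """

    receptor_volume_ml: float = 3.0
    sample_volume_ml: float = 0.2
    orifice_area_cm2: float = 1.86
    sampling_times_h: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0)

    def __post_init__(self):
        if self.receptor_volume_ml <= 0:
            raise ValidationError("receptor volume must be positive")
        if not (0 <= self.sample_volume_ml < self.receptor_volume_ml):
            raise ValidationError(
                "sample volume must satisfy 0 <= Vs < Vc "
                f"(got Vs={self.sample_volume_ml}, Vc={self.receptor_volume_ml})"
            )
        if self.orifice_area_cm2 <= 0:
            raise ValidationError("orifice area must be positive")
        t = np.asarray(self.sampling_times_h, dtype=float)
        if t.size and (t[0] < 0 or np.any(np.diff(t) <= 0)):
            raise ValidationError("sampling times must be strictly increasing, first >= 0")
        object.__setattr__(self, "sampling_times_h", tuple(float(x) for x in t))


@dataclass(frozen=True)
class DoseSpec:
    """Applied donor dose. Defaults: 300 µL of a 1% w/v solution."""

    applied_volume_ml: float = 0.3
    donor_concentration_ug_ml: float = 10_000.0

    def __post_init__(self):
        if self.donor_concentration_ug_ml <= 0:
            raise ValidationError("donor concentration C0 must be positive")
        if self.applied_volume_ml <= 0:
            raise ValidationError("applied volume must be positive")

    @property
    def applied_mass_ug(self) -> float:
        """Total applied mass = volume × C0 (µg)."""
        return self.applied_volume_ml * self.donor_concentration_ug_ml


@dataclass(frozen=True)
class AnalyteSpec:
    """An active compound with its lipophilicity, size and assay limits."""

    name: str
    log_kow: float = float("nan")
    molecular_weight: float = float("nan")
    lod_ug_ml: float = 0.0
    loq_ug_ml: float = 0.0

    def __post_init__(self):
        if self.lod_ug_ml > self.loq_ug_ml:
            raise ValidationError(
                f"{self.name}: LoD ({self.lod_ug_ml}) must not exceed LoQ ({self.loq_ug_ml})"
            )
        if not np.isnan(self.molecular_weight) and self.molecular_weight <= 0:
            raise ValidationError(f"{self.name}: molecular weight must be positive")


@dataclass
class ConcentrationSeries:
    """Measured receptor-compartment concentrations for one diffusion cell.

    ``concentrations_ug_ml[n]`` is the assayed concentration of the aliquot
    withdrawn at ``times_h[n]`` — the Cn (and, for earlier indices, Ci) of
    the cumulative-amount correction.
    """

    cell_id: str
    times_h: np.ndarray
    concentrations_ug_ml: np.ndarray
    membrane: str = ""
    formulation: str | None = None
    analyte: AnalyteSpec | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.concentrations_ug_ml = np.asarray(self.concentrations_ug_ml, dtype=float)
        if self.times_h.shape != self.concentrations_ug_ml.shape:
            raise ValidationError(
                f"{self.cell_id}: times and concentrations must align "
                f"({self.times_h.size} vs {self.concentrations_ug_ml.size})"
            )
        if self.times_h.size and np.any(np.diff(self.times_h) <= 0):
            raise ValidationError(f"{self.cell_id}: times must be strictly increasing")

    def __len__(self) -> int:
        return self.times_h.size

    def replace(self, **changes) -> "ConcentrationSeries":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class TMWLRecord:
    """One transmembranal water-loss measurement, g/(m²·h)."""

    membrane: str
    formulation: str
    tmwl: float
    replicate: int = 0

    def __post_init__(self):
        if self.tmwl < 0:
            raise ValidationError(
                f"TMWL must be non-negative ({self.membrane}/{self.formulation}: {self.tmwl})"
            )

    @property
    def is_control(self) -> bool:
        return self.formulation.strip().lower() == CONTROL_LABEL


# ---------------------------------------------------------------------------
# Time-course tables
# ---------------------------------------------------------------------------

TIMECOURSE_COLUMNS = ["cell_id", "membrane", "formulation", "analyte", "time_h", "conc_ug_ml"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def _numeric_column(df: pd.DataFrame, col: str, path) -> pd.Series:
    values = pd.to_numeric(df[col], errors="coerce")
    bad = values.isna() & df[col].notna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise TableParseError(f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column {col!r}", row=row)
    if values.isna().any():
        row = int(values.isna().idxmax()) + 2
        raise TableParseError(f"{path}: empty value in column {col!r}", row=row)
    return values.astype(float)


def read_timecourse_table(
    path: str | Path,
    config: FranzCellSpec | None = None,
    analytes: dict[str, AnalyteSpec] | None = None,
) -> list[ConcentrationSeries]:
    """Read a receptor-concentration time-course CSV into per-cell series.

    Expects header columns ``cell_id, membrane, formulation, analyte,
    time_h, conc_ug_ml``; any extra columns are preserved per series under
    ``metadata['extra_columns']``. Rows are sorted by time within each cell.
    Negative concentrations are rejected with a row-level error.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, TIMECOURSE_COLUMNS, path)
    df = df.reset_index(drop=True)
    times = _numeric_column(df, "time_h", path)
    concs = _numeric_column(df, "conc_ug_ml", path)
    neg = concs < 0
    if neg.any():
        row = int(neg.idxmax()) + 2
        raise TableParseError(
            f"{path}: negative concentration {concs[neg.idxmax()]} in column 'conc_ug_ml'", row=row
        )
    df = df.assign(time_h=times, conc_ug_ml=concs)
    extra_cols = [c for c in df.columns if c not in TIMECOURSE_COLUMNS]

    series: list[ConcentrationSeries] = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("time_h", kind="stable")
        formulation = grp["formulation"].iloc[0]
        formulation = None if pd.isna(formulation) or formulation == "" else str(formulation)
        name = str(grp["analyte"].iloc[0])
        analyte = (analytes or {}).get(name, AnalyteSpec(name=name))
        meta: dict = {}
        if extra_cols:
            meta["extra_columns"] = {c: grp[c].tolist() for c in extra_cols}
        series.append(
            ConcentrationSeries(
                cell_id=str(cell_id),
                membrane=str(grp["membrane"].iloc[0]),
                formulation=formulation,
                analyte=analyte,
                times_h=grp["time_h"].to_numpy(),
                concentrations_ug_ml=grp["conc_ug_ml"].to_numpy(),
                metadata=meta,
            )
        )
    if config is not None:
        schedule = set(config.sampling_times_h)
        for s in series:
            extra_times = set(s.times_h.tolist()) - schedule
            if extra_times:
                raise ValidationError(
                    f"{s.cell_id}: sampled times {sorted(extra_times)} are not in the "
                    f"configured schedule {list(config.sampling_times_h)}"
                )
    return series


def write_timecourse_table(series: Iterable[ConcentrationSeries], path: str | Path) -> None:
    """Write series back to the canonical time-course CSV layout."""
    rows = []
    for s in series:
        for t, c in zip(s.times_h, s.concentrations_ug_ml):
            rows.append(
                {
                    "cell_id": s.cell_id,
                    "membrane": s.membrane,
                    "formulation": "" if s.formulation is None else s.formulation,
                    "analyte": s.analyte.name if s.analyte else "",
                    "time_h": repr(float(t)),
                    "conc_ug_ml": repr(float(c)),
                }
            )
    pd.DataFrame(rows, columns=TIMECOURSE_COLUMNS).to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# TMWL tables
# ---------------------------------------------------------------------------

TMWL_COLUMNS = ["membrane", "formulation", "tmwl"]


def read_tmwl_table(path: str | Path, require_controls: bool = True) -> list[TMWLRecord]:
    """Read a TMWL panel CSV (columns membrane, formulation, tmwl).

    Duplicate (membrane, formulation) rows are kept as replicates, numbered
    in file order. With ``require_controls`` (default), every membrane that
    appears must have at least one 'control' row, since percent-reduction
    is undefined without a baseline.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, TMWL_COLUMNS, path)
    df = df.reset_index(drop=True)
    tmwl = _numeric_column(df, "tmwl", path)

    records: list[TMWLRecord] = []
    counter: dict[tuple[str, str], int] = {}
    for i in range(len(df)):
        membrane = str(df["membrane"].iloc[i])
        formulation = str(df["formulation"].iloc[i])
        key = (membrane, formulation)
        rep = counter.get(key, 0)
        counter[key] = rep + 1
        records.append(TMWLRecord(membrane=membrane, formulation=formulation,
                                  tmwl=float(tmwl.iloc[i]), replicate=rep))
    if require_controls and records:
        membranes = {r.membrane for r in records}
        with_control = {r.membrane for r in records if r.is_control}
        missing = sorted(membranes - with_control)
        if missing:
            raise ValidationError(f"{path}: no control row for membrane(s): {', '.join(missing)}")
    return records


def write_tmwl_table(records: Iterable[TMWLRecord], path: str | Path) -> None:
    rows = [
        {"membrane": r.membrane, "formulation": r.formulation, "tmwl": repr(float(r.tmwl))}
        for r in records
    ]
    pd.DataFrame(rows, columns=TMWL_COLUMNS).to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Derived-parameters tables
# ---------------------------------------------------------------------------

PARAMETERS_COLUMNS = [
    "cell_id", "analyte", "membrane", "formulation", "model",
    "flux_j_ug_cm2_h", "kp_cm_h", "lag_tl_h",
    "cmax_ug_ml", "qmax_ug_cm2", "tmax_h", "auc_ug_h_cm2",
    "r2", "r2_adj",
]


def write_parameters_table(params: Iterable, path: str | Path) -> None:
    """Write derived permeation parameters, one row per cell, full precision.

    ``params`` are :class:`~franzperm.kinetic_models.PermeationParameters`
    (duck-typed: any object with the documented attributes works).
    """
    rows = []
    for p in params:
        rows.append(
            {
                "cell_id": p.cell_id,
                "analyte": p.analyte,
                "membrane": p.membrane,
                "formulation": "" if p.formulation is None else p.formulation,
                "model": p.selected_model,
                "flux_j_ug_cm2_h": repr(float(p.flux_j)),
                "kp_cm_h": repr(float(p.kp)),
                "lag_tl_h": repr(float(p.lag_tl)),
                "cmax_ug_ml": repr(float(p.cmax_ug_ml)),
                "qmax_ug_cm2": repr(float(p.qmax_ug_cm2)),
                "tmax_h": repr(float(p.tmax_h)),
                "auc_ug_h_cm2": repr(float(p.auc)),
                "r2": repr(float(p.r2)),
                "r2_adj": repr(float(p.r2_adj)),
            }
        )
    pd.DataFrame(rows, columns=PARAMETERS_COLUMNS).to_csv(path, index=False, lineterminator="\n")


def read_parameters_table(path: str | Path) -> pd.DataFrame:
    """Read a parameters CSV back as a DataFrame (numeric columns coerced)."""
    df = pd.read_csv(path)
    return df


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> tuple[FranzCellSpec, DoseSpec, dict[str, AnalyteSpec]]:
    """Load cell/dose/analyte configuration from YAML.

    Schema::

        cell: {vc_ml, vs_ml, area_cm2, times_h: [..]}
        dose: {volume_ml, c0_ug_ml}
        analytes: [{name, log_kow, mw, lod, loq}, ...]

    Missing sections fall back to the study defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        cell_raw = raw.get("cell", {})
        cell = FranzCellSpec(
            receptor_volume_ml=float(cell_raw.get("vc_ml", 3.0)),
            sample_volume_ml=float(cell_raw.get("vs_ml", 0.2)),
            orifice_area_cm2=float(cell_raw.get("area_cm2", 1.86)),
            sampling_times_h=tuple(cell_raw.get("times_h", (0.0, 0.5, 1.0, 2.0, 4.0))),
        )
        dose_raw = raw.get("dose", {})
        dose = DoseSpec(
            applied_volume_ml=float(dose_raw.get("volume_ml", 0.3)),
            donor_concentration_ug_ml=float(dose_raw.get("c0_ug_ml", 10_000.0)),
        )
        analytes = {}
        for a in raw.get("analytes", []):
            spec = AnalyteSpec(
                name=str(a["name"]),
                log_kow=float(a.get("log_kow", float("nan"))),
                molecular_weight=float(a.get("mw", float("nan"))),
                lod_ug_ml=float(a.get("lod", 0.0)),
                loq_ug_ml=float(a.get("loq", 0.0)),
            )
            analytes[spec.name] = spec
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"{path}: malformed configuration ({exc})") from exc
    return cell, dose, analytes


def dump_config(cell: FranzCellSpec, dose: DoseSpec,
                analytes: Iterable[AnalyteSpec], path: str | Path) -> None:
    """Write configuration YAML in the schema :func:`load_config` reads."""
    doc = {
        "cell": {
            "vc_ml": cell.receptor_volume_ml,
            "vs_ml": cell.sample_volume_ml,
            "area_cm2": cell.orifice_area_cm2,
            "times_h": list(cell.sampling_times_h),
        },
        "dose": {
            "volume_ml": dose.applied_volume_ml,
            "c0_ug_ml": dose.donor_concentration_ug_ml,
        },
        "analytes": [
            {
                "name": a.name,
                "log_kow": float(a.log_kow),
                "mw": float(a.molecular_weight),
                "lod": float(a.lod_ug_ml),
                "loq": float(a.loq_ug_ml),
            }
            for a in analytes
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True, default_flow_style=False)
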