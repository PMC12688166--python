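"""Canonical data model for a longitudinal ctDNA monitoring cohort.

A cohort bundles four long-format tables sharing a per-patient day-zero time
axis (day zero = the patient's first CT scan):

* ``patients`` -- one row per patient with ER/Her2 status and, optionally, the
  overall-survival endpoint (``death_day``, ``death_event``).
* ``treatments`` -- treatment intervals with a regimen label and a coarse
  treatment class.
* ``samples`` -- plasma samples with the ichorCNA tumour fraction (stored as a
  fraction in [0, 1]) and optional CA15-3 and NG-TAS max-VAF values.
* ``scans`` -- CT scans with the RECIST progression flag (PD = 1, anything
  else = 0). The flag may switch between 0 and 1 repeatedly over follow-up.

The intrinsic breast-cancer subtype is derived from receptor status:
Her2+ regardless of ER, otherwise ER+Her2- or TN (triple negative).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUBTYPE_ER_HER2_NEG = "ER+Her2-"
SUBTYPE_HER2_POS = "Her2+"
SUBTYPE_TN = "TN"

TREATMENT_CLASSES = ("endocrine", "targeted", "chemotherapy", "targeted+chemotherapy")

#: canonical column sets per table (optional columns may be absent / NaN)
PATIENT_COLUMNS = ("patient_id", "er_status", "her2_status", "death_day", "death_event")
TREATMENT_COLUMNS = ("patient_id", "regimen", "treatment_class", "start_day", "end_day")
SAMPLE_COLUMNS = ("patient_id", "day", "tumour_fraction", "ca15_3", "max_vaf")
SCAN_COLUMNS = ("patient_id", "day", "progression", "response_category")

_OPTIONAL = {
    "patients": ("death_day", "death_event"),
    "treatments": ("treatment_class", "end_day"),
    "samples": ("ca15_3", "max_vaf"),
    "scans": ("response_category",),
}
_TABLE_COLUMNS = {
    "patients": PATIENT_COLUMNS,
    "treatments": TREATMENT_COLUMNS,
    "samples": SAMPLE_COLUMNS,
    "scans": SCAN_COLUMNS,
}


def derive_subtype(er_status, her2_status):
    """Map (ER, Her2) to the subtype label; NaN inputs give ``None``.

    Her2+ takes precedence over ER status; TN requires both negative.
    """
    if pd.isna(er_status) or pd.isna(her2_status):
        return None
    if int(her2_status) == 1:
        return SUBTYPE_HER2_POS
    return SUBTYPE_ER_HER2_NEG if int(er_status) == 1 else SUBTYPE_TN


@dataclasses.dataclass
class Cohort:
    """In-memory cohort: four pandas tables plus provenance metadata."""

    patients: pd.DataFrame
    treatments: pd.DataFrame
    samples: pd.DataFrame
    scans: pd.DataFrame
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        for name in _TABLE_COLUMNS:
            df = getattr(self, name).copy()
            for col in _TABLE_COLUMNS[name]:
                if col not in df.columns:
                    if col in _OPTIONAL.get(name, ()):
                        df[col] = np.nan
                    else:
                        raise ValueError(f"{name} table missing required column {col!r}")
            df["patient_id"] = df["patient_id"].astype(str)
            setattr(self, name, df.reset_index(drop=True))
        if "subtype" not in self.patients.columns:
            self.patients["subtype"] = [
                derive_subtype(e, h)
                for e, h in zip(self.patients["er_status"], self.patients["her2_status"])
            ]
        self._check_referential_integrity()

    def _check_referential_integrity(self):
        known = set(self.patients["patient_id"])
        for name in ("treatments", "samples", "scans"):
            ids = set(getattr(self, name)["patient_id"])
            orphans = sorted(ids - known)
            if orphans:
                raise ValueError(
                    f"{name} table references unknown patient IDs: {', '.join(orphans)}"
                )

    # ------------------------------------------------------------------
    def patient_ids(self) -> list[str]:
        return list(self.patients["patient_id"])

    def n_patients(self) -> int:
        return len(self.patients)

    def for_patient(self, patient_id: str) -> dict[str, pd.DataFrame]:
        pid = str(patient_id)
        return {
            name: getattr(self, name)[getattr(self, name)["patient_id"] == pid]
            for name in ("patients", "treatments", "samples", "scans")
        }

    def subset(self, patient_ids: Sequence[str]) -> "Cohort":
        keep = set(str(p) for p in patient_ids)
        return Cohort(
            patients=self.patients[self.patients["patient_id"].isin(keep)].copy(),
            treatments=self.treatments[self.treatments["patient_id"].isin(keep)].copy(),
            samples=self.samples[self.samples["patient_id"].isin(keep)].copy(),
            scans=self.scans[self.scans["patient_id"].isin(keep)].copy(),
            provenance=dict(self.provenance, subset_of=self.provenance.get("source")),
        )

    def copy(self) -> "Cohort":
        return Cohort(
            patients=self.patients.copy(),
            treatments=self.treatments.copy(),
            samples=self.samples.copy(),
            scans=self.scans.copy(),
            provenance=dict(self.provenance),
        )


# ----------------------------------------------------------------------
# column-mapping dialect


def parse_dialect(path: str | None) -> dict:
    """Parse a plain-text ``key = value`` column-mapping config.

    Keys are ``<table>.<canonical_field>`` (e.g. ``samples.day = Date.rel``)
    plus the global ``date_mode`` (``days`` or ``date``). Lines starting with
    ``#`` are ignored.
    """
    dialect: dict = {"date_mode": "days"}
    if path is None:
        return dialect
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            dialect[key] = value
    if dialect["date_mode"] not in ("days", "date"):
        raise ValueError(f"date_mode must be 'days' or 'date', got {dialect['date_mode']!r}")
    return dialect


def _read_table(path: str, table: str, dialect: Mapping) -> pd.DataFrame:
    sep = "\t" if os.path.splitext(path)[1].lower() in (".tsv", ".tab", ".txt") else ","
    raw = pd.read_csv(path, sep=sep)
    out = pd.DataFrame(index=raw.index)
    for canon in _TABLE_COLUMNS[table]:
        source = dialect.get(f"{table}.{canon}", canon)
        if source in raw.columns:
            out[canon] = raw[source]
        elif canon in _OPTIONAL.get(table, ()):
            out[canon] = np.nan
        else:
            raise ValueError(
                f"{path}: missing required column {source!r} (canonical {table}.{canon})"
            )
    return out


def _days_from_dates(cohort_tables: dict[str, pd.DataFrame], date_cols: dict) -> None:
    """Convert calendar-date columns to integer days from each patient's first scan."""
    scans = cohort_tables["scans"]
    scans["day"] = pd.to_datetime(scans["day"])
    first_scan = scans.groupby("patient_id")["day"].min()
    for table, cols in date_cols.items():
        df = cohort_tables[table]
        for col in cols:
            if col not in df.columns:
                continue
            parsed = pd.to_datetime(df[col], errors="coerce")
            base = df["patient_id"].map(first_scan)
            df[col] = (parsed - base).dt.days


def dedupe_same_day_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Keep the higher tumour fraction among same-day samples of a patient."""
    n0 = len(samples)
    samples = (
        samples.sort_values(["patient_id", "day", "tumour_fraction"])
        .groupby(["patient_id", "day"], as_index=False)
        .last()
    )
    if len(samples) < n0:
        logger.warning(
            "dropped %d same-day duplicate plasma samples (kept highest tumour fraction)",
            n0 - len(samples),
        )
    return samples[list(SAMPLE_COLUMNS)]


def read_cohort(
    clinical: str,
    treatments: str,
    samples: str,
    scans: str,
    dialect: str | Mapping | None = None,
    align: bool = True,
) -> Cohort:
    """Read a cohort from four delimited text tables.

    ``dialect`` maps canonical fields to source columns (path to a plain-text
    config, or a pre-parsed mapping). Times are converted to integer days from
    each patient's first CT scan; calendar dates are accepted when the dialect
    declares ``date_mode = date``.
    """
    dia = parse_dialect(dialect) if (dialect is None or isinstance(dialect, str)) else dict(dialect)
    dia.setdefault("date_mode", "days")
    tables = {
        "patients": _read_table(clinical, "patients", dia),
        "treatments": _read_table(treatments, "treatments", dia),
        "samples": _read_table(samples, "samples", dia),
        "scans": _read_table(scans, "scans", dia),
    }
    for name in tables:
        tables[name]["patient_id"] = tables[name]["patient_id"].astype(str)
    if dia["date_mode"] == "date":
        _days_from_dates(
            tables,
            {"scans": ["day"], "samples": ["day"],
             "treatments": ["start_day", "end_day"], "patients": ["death_day"]},
        )
    tables["samples"] = dedupe_same_day_samples(tables["samples"])
    cohort = Cohort(
        patients=tables["patients"],
        treatments=tables["treatments"],
        samples=tables["samples"],
        scans=tables["scans"],
        provenance={
            "source": {"clinical": clinical, "treatments": treatments,
                       "samples": samples, "scans": scans},
            "date_mode": dia["date_mode"],
        },
    )
    return align_times(cohort) if align else cohort


def write_cohort(cohort: Cohort, out_dir: str) -> dict[str, str]:
    """Write the four cohort tables (CSV) plus a provenance sidecar."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name in ("patients", "treatments", "samples", "scans"):
        path = os.path.join(out_dir, f"{name}.csv")
        df = getattr(cohort, name)
        df.to_csv(path, index=False)
        paths[name] = path
    with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
        json.dump(cohort.provenance, fh, indent=2, default=str)
    return paths


def read_cohort_dir(in_dir: str) -> Cohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    return read_cohort(
        clinical=os.path.join(in_dir, "patients.csv"),
        treatments=os.path.join(in_dir, "treatments.csv"),
        samples=os.path.join(in_dir, "samples.csv"),
        scans=os.path.join(in_dir, "scans.csv"),
    )


# ----------------------------------------------------------------------
# time alignment


def align_times(cohort: Cohort) -> Cohort:
    """Re-express all day fields relative to each patient's first CT scan.

    Day zero is the first scan; plasma samples drawn earlier carry negative
    days. Samples taken after the last scan are flagged ``post_followup`` (they
    are excluded from the Bayesian model fit). Idempotent.
    """
    cohort = cohort.copy()
    scans = cohort.scans
    if scans.empty:
        raise ValueError("cannot align times: cohort has no CT scans")
    no_scan = set(cohort.patients["patient_id"]) - set(scans["patient_id"])
    if no_scan:
        logger.warning("%d patients have no CT scan; their times are left unchanged", len(no_scan))
    if scans["day"].isna().any():
        bad = scans.loc[scans["day"].isna(), "patient_id"].unique()
        raise ValueError(f"scans with unparseable dates for patients: {', '.join(map(str, bad))}")
    offset = scans.groupby("patient_id")["day"].min()
    last = scans.groupby("patient_id")["day"].max()

    def shift(df, col):
        shifts = df["patient_id"].map(offset)
        df[col] = df[col] - shifts.fillna(0.0)

    shift(cohort.scans, "day")
    shift(cohort.samples, "day")
    shift(cohort.treatments, "start_day")
    shift(cohort.treatments, "end_day")
    shift(cohort.patients, "death_day")
    last_aligned = (last - offset).reindex(cohort.samples["patient_id"]).to_numpy()
    cohort.samples["post_followup"] = cohort.samples["day"].to_numpy() > last_aligned
    cohort.provenance["aligned"] = True
    return cohort


# ----------------------------------------------------------------------
# validation


def validate_cohort(cohort: Cohort) -> list[dict]:
    """Check cohort invariants; returns a list of violations (empty = clean).

    Checked: tumour fractions within [0, 1], sample/scan days sortable,
    treatment intervals per patient closed-before-open and non-overlapping,
    progression flags binary, patients with at least one sample and one scan.
    """
    report: list[dict] = []

    tf = cohort.samples["tumour_fraction"]
    bad = cohort.samples[(tf < 0) | (tf > 1)]
    for _, row in bad.iterrows():
        report.append({
            "rule": "tumour_fraction_range",
            "patient_id": row["patient_id"],
            "message": f"tumour fraction {row['tumour_fraction']} out of [0,1] "
                       f"at day {row['day']}",
        })

    prog = cohort.scans["progression"]
    for _, row in cohort.scans[~prog.isin([0, 1])].iterrows():
        report.append({
            "rule": "progression_binary",
            "patient_id": row["patient_id"],
            "message": f"progression flag {row['progression']!r} not in {{0,1}}",
        })

    for pid, group in cohort.treatments.groupby("patient_id"):
        rows = group.sort_values("start_day").reset_index(drop=True)
        for i in range(len(rows)):
            start_i, end_i = rows.loc[i, "start_day"], rows.loc[i, "end_day"]
            if pd.notna(end_i) and not start_i < end_i:
                report.append({
                    "rule": "interval_order",
                    "patient_id": pid,
                    "message": f"treatment {rows.loc[i, 'regimen']!r} has start_day "
                               f"{start_i} >= end_day {end_i}",
                })
            for j in range(i + 1, len(rows)):
                start_j, end_j = rows.loc[j, "start_day"], rows.loc[j, "end_day"]
                ei = np.inf if pd.isna(end_i) else end_i
                ej = np.inf if pd.isna(end_j) else end_j
                if max(start_i, start_j) < min(ei, ej):
                    report.append({
                        "rule": "treatment_overlap",
                        "patient_id": pid,
                        "message": f"overlapping treatments {rows.loc[i, 'regimen']!r} "
                                   f"and {rows.loc[j, 'regimen']!r}",
                    })

    with_sample = set(cohort.samples["patient_id"])
    with_scan = set(cohort.scans["patient_id"])
    for pid in cohort.patients["patient_id"]:
        if pid not in with_sample or pid not in with_scan:
            report.append({
                "rule": "min_records",
                "patient_id": pid,
                "message": "patient lacks at least one plasma sample and one CT scan",
            })

    if cohort.provenance.get("aligned"):
        first = cohort.scans.groupby("patient_id")["day"].min()
        for pid, day0 in first.items():
            if day0 != 0:
                report.append({
                    "rule": "first_scan_day_zero",
                    "patient_id": pid,
                    "message": f"first scan at day {day0}, expected 0 after alignment",
                })
    return report


def analysis_subset(cohort: Cohort, require_subtype: bool = False) -> Cohort:
    """Patients with >=1 sample and >=1 scan (and ER/Her2 when required)."""
    with_sample = set(cohort.samples["patient_id"])
    with_scan = set(cohort.scans["patient_id"])
    keep = [
        pid for pid, sub in zip(cohort.patients["patient_id"], cohort.patients["subtype"])
        if pid in with_sample and pid in with_scan and (not require_subtype or sub is not None)
    ]
    return cohort.subset(keep)
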