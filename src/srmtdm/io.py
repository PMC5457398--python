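"""Readers and writers for the pipeline's file formats.

Formats are deliberately plain: a long-format chromatogram CSV (one row
per acquired point), a sample manifest CSV, a patient cohort CSV, and
JSON reports.  mzML chromatogram lists (as deposited in SRM repositories)
can be ingested through a small built-in reader.  Concentrations are
always µg/mL and times always minutes at these boundaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .assay import PeptideAssay
from .chromatogram import Chromatogram
from .tdm import CohortRecord

__all__ = [
    "write_chromatograms_csv",
    "read_chromatograms",
    "write_manifest",
    "read_manifest",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_report",
]

log = logging.getLogger("srmtdm")

CHROM_COLUMNS = ["sample_id", "peptide", "channel", "product_mz", "time_min", "intensity"]
MANIFEST_COLUMNS = ["sample_id", "role", "nominal_conc", "day", "draw_type",
                    "outcome", "patient_id"]
COHORT_COLUMNS = ["patient_id", "cmin", "cmax", "outcome", "severe_toxicity"]

MZ_MATCH_TOL = 0.1


class SchemaError(ValueError):
    """A file does not carry the columns the pipeline requires."""


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


# ---------------------------------------------------------------------------
# chromatograms

def write_chromatograms_csv(chroms: Mapping[str, list[Chromatogram]], path) -> None:
    """Write all traces to one long-format CSV."""
    frames = []
    for sample_id in chroms:
        for ch in chroms[sample_id]:
            t = ch.transition
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": sample_id,
                        "peptide": t.peptide_id,
                        "channel": t.channel,
                        "product_mz": t.product_mz,
                        "time_min": ch.times,
                        "intensity": ch.intensities,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def _match_transition(assay, peptide, channel, product_mz):
    for pep in assay:
        if pep.peptide_id != peptide:
            continue
        for t in pep.transitions:
            if t.channel == channel and abs(t.product_mz - product_mz) <= MZ_MATCH_TOL:
                return t
    return None


def read_chromatograms(
    path, format: str = "csv", assay: list[PeptideAssay] | None = None
) -> dict[str, list[Chromatogram]]:
    """Read traces and match each to an assay transition (m/z within 0.1).

    Unmatched traces are logged and skipped; a file yielding zero matched
    traces is an error.
    """
    if assay is None:
        raise ValueError("an assay definition is required to match traces")
    if format == "csv":
        return _read_chromatograms_csv(path, assay)
    if format == "mzml":
        return _read_chromatograms_mzml(path, assay)
    raise ValueError(f"unknown chromatogram format {format!r}")


def _read_chromatograms_csv(path, assay) -> dict[str, list[Chromatogram]]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, CHROM_COLUMNS, f"chromatogram file {path}")
    out: dict[str, list[Chromatogram]] = {}
    for (sid, peptide, channel, pmz), grp in df.groupby(
        ["sample_id", "peptide", "channel", "product_mz"], sort=False
    ):
        tdef = _match_transition(assay, peptide, channel, float(pmz))
        if tdef is None:
            log.warning(
                "skipping unmatched trace %s/%s/%s/%s", sid, peptide, channel, pmz
            )
            continue
        grp = grp.sort_values("time_min")
        out.setdefault(str(sid), []).append(
            Chromatogram(
                str(sid), tdef,
                grp["time_min"].to_numpy(float),
                grp["intensity"].to_numpy(float),
            )
        )
    if not out:
        raise ValueError(f"no traces in {path} matched the assay")
    return out


def _decode_binary_array(node, ns) -> tuple[np.ndarray | None, str | None, str]:
    """Decode one <binaryDataArray>: (values, kind, unit).

    Supports 64/32-bit floats, uncompressed or zlib, time and intensity
    arrays — the subset SRM chromatogram deposits use.
    """
    import base64
    import zlib

    dtype, compressed, kind, unit = None, False, None, ""
    for cv in node.findall(f"{ns}cvParam"):
        acc = cv.get("accession")
        if acc == "MS:1000523":
            dtype = "<f8"
        elif acc == "MS:1000521":
            dtype = "<f4"
        elif acc == "MS:1000574":
            compressed = True
        elif acc == "MS:1000595":
            kind, unit = "time", cv.get("unitName", "minute")
        elif acc == "MS:1000515":
            kind = "intensity"
    binary = node.find(f"{ns}binary")
    if binary is None or dtype is None or kind is None:
        return None, None, unit
    raw = base64.b64decode((binary.text or "").strip())
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float), kind, unit


def _read_chromatograms_mzml(path, assay) -> dict[str, list[Chromatogram]]:
    """Minimal mzML chromatogram-list reader (SRM SIC traces only).

    Parses <chromatogram> entries with precursor/product isolation-window
    target m/z values and base64 time/intensity arrays; seconds are
    converted to minutes.  Spectrum data and vendor extensions are out of
    scope.
    """
    import xml.etree.ElementTree as ET

    ns = "{http://psi.hupo.org/ms/mzml}"
    sample_id = Path(path).stem
    out: dict[str, list[Chromatogram]] = {}
    root = ET.parse(str(path)).getroot()
    for chrom in root.iter(f"{ns}chromatogram"):
        def _target(tag):
            iso = chrom.find(f"{ns}{tag}/{ns}isolationWindow")
            if iso is None:
                return None
            for cv in iso.findall(f"{ns}cvParam"):
                if cv.get("accession") == "MS:1000827":
                    return float(cv.get("value"))
            return None

        prec, prod = _target("precursor"), _target("product")
        if prec is None or prod is None:
            log.warning("skipping chromatogram %r without SRM windows",
                        chrom.get("id"))
            continue
        tdef = None
        for pep in assay:
            for t in pep.transitions:
                if (
                    abs(t.precursor_mz - prec) <= MZ_MATCH_TOL
                    and abs(t.product_mz - prod) <= MZ_MATCH_TOL
                ):
                    tdef = t
                    break
            if tdef:
                break
        if tdef is None:
            log.warning("skipping unmatched SRM trace %s -> %s", prec, prod)
            continue
        times = intens = None
        for arr in chrom.iter(f"{ns}binaryDataArray"):
            vals, kind, unit = _decode_binary_array(arr, ns)
            if kind == "time":
                times = vals / 60.0 if unit == "second" else vals
            elif kind == "intensity":
                intens = vals
        if times is None or intens is None:
            log.warning("skipping chromatogram %r without data arrays",
                        chrom.get("id"))
            continue
        out.setdefault(sample_id, []).append(
            Chromatogram(sample_id, tdef, times, intens)
        )
    if not out:
        raise ValueError(f"no traces in {path} matched the assay")
    return out


# ---------------------------------------------------------------------------
# manifest and cohort tables

def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, index=False, float_format="%.17g")


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""],
                     float_precision="round_trip")
    _require_columns(df, ["sample_id", "role"], f"manifest {path}")
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col in ("draw_type", "outcome", "patient_id") else np.nan
    for col in ("draw_type", "outcome", "patient_id"):
        df[col] = df[col].fillna("")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].unique()
        raise SchemaError(f"duplicate sample_id(s) in manifest: {list(dupes)}")
    standards = df[df["role"] == "standard"]
    if standards["nominal_conc"].isna().any():
        raise SchemaError("every standard needs a nominal_conc")
    patients = df[df["role"] == "patient"]
    if (patients["draw_type"].astype(str) == "").any():
        raise SchemaError("every patient sample needs a draw_type (cmin/cmax)")
    return df


def write_cohort_csv(cohort: list[CohortRecord], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in cohort])[COHORT_COLUMNS].to_csv(
        path, index=False, float_format="%.17g"
    )


def read_cohort_csv(path) -> list[CohortRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["patient_id", "cmin", "cmax", "outcome"], f"cohort {path}")
    records = []
    for _, row in df.iterrows():
        records.append(
            CohortRecord(
                patient_id=str(row["patient_id"]),
                cmin=float(row["cmin"]),
                cmax=float(row["cmax"]),
                outcome=str(row["outcome"]),
                severe_toxicity=bool(row.get("severe_toxicity", False)),
            )
        )
    return records


# ---------------------------------------------------------------------------
# reports

def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, set):
        return sorted(_jsonify(v) for v in obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    return obj


def write_report(report: dict, path) -> None:
    """Serialize a run report deterministically (sorted keys, fixed floats)."""
    with open(path, "w") as fh:
        json.dump(_jsonify(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
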