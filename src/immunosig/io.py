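"""Readers and writers for the package's text formats.

All tabular files are comma-separated UTF-8 with "." decimals; blank cells
mean missing (never zero).  The fitted model travels as a JSON document
with a versioned schema, a recorded quantile convention and band
parameters, and a payload checksum so truncation or corruption is caught
on read.  Every pipeline output directory carries a run manifest with
input digests and seeds.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import zlib
from dataclasses import asdict

import pandas as pd

from .errors import DataError, ModelFormatError
from .profiles import GROUP_HC, GROUP_SLE, LongitudinalRecord, SubjectProfile
from .reference import ReferenceStats
from .signature import ReferenceModel, SignatureResult, SubsetModel, ZeroZone

MODEL_SCHEMA_VERSION = "1.0"
_META_COLS = ("subject_id", "group", "sex", "age")


# ---------------------------------------------------------------------------
# subject x subset tables
# ---------------------------------------------------------------------------

def write_subject_table(profiles: list[SubjectProfile], path) -> None:
    rows = []
    for p in profiles:
        row = {"subject_id": p.subject_id, "group": p.group, "sex": p.sex, "age": p.age}
        row.update(p.values)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_subject_table(path) -> list[SubjectProfile]:
    """Parse a subject x subset table with cell-level error reporting.

    Percentages must lie in [0, 100]; group labels are case-normalized to
    SLE/HC; duplicate subject ids, unknown groups and out-of-range values
    raise a :class:`DataError` naming the row and column.
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except FileNotFoundError:
        raise DataError(f"input file not found: {path}") from None
    except Exception as exc:
        raise DataError(f"cannot parse table {path}: {exc}") from exc
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise DataError(f"table {path}: missing required column {col!r}")
    subset_cols = [c for c in df.columns if c not in _META_COLS]
    profiles: list[SubjectProfile] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        sid = row["subject_id"]
        if pd.isna(sid) or not str(sid).strip():
            raise DataError(f"table {path}, row {i + 2}: empty subject_id")
        sid = str(sid).strip()
        if sid in seen:
            raise DataError(f"table {path}, row {i + 2}: duplicate subject_id {sid!r}")
        seen.add(sid)
        group = str(row["group"]).strip().upper()
        if group not in (GROUP_SLE, GROUP_HC):
            raise DataError(
                f"table {path}, row {i + 2}, column 'group': unknown label {row['group']!r}"
            )
        sex = None if "sex" not in df.columns or pd.isna(row.get("sex")) else str(row["sex"])
        age = None
        if "age" in df.columns and not pd.isna(row.get("age")):
            age = float(row["age"])
        values: dict[str, float | None] = {}
        for col in subset_cols:
            raw = row[col]
            if pd.isna(raw) or str(raw).strip() == "":
                values[col] = None
                continue
            try:
                v = float(raw)
            except ValueError:
                raise DataError(
                    f"table {path}, row {i + 2}, column {col!r}: not a number ({raw!r})"
                ) from None
            if not 0.0 <= v <= 100.0:
                raise DataError(
                    f"table {path}, row {i + 2}, column {col!r}: value {v} outside [0, 100]"
                )
            values[col] = v
        profiles.append(SubjectProfile(subject_id=sid, group=group, sex=sex, age=age, values=values))
    return profiles


# ---------------------------------------------------------------------------
# fitted-model serialization
# ---------------------------------------------------------------------------

def _model_payload(model: ReferenceModel) -> dict:
    return {
        "n_max": model.n_max,
        "band_steps": model.band_steps,
        "rank_floor": model.rank_floor,
        "quantile_convention": model.quantile_convention,
        "cover_on_cleaned": model.cover_on_cleaned,
        "outlier_policy": "one_pass_strict_fences",
        "skipped": model.skipped,
        "subsets": {
            name: {"stats": asdict(sm.stats), "zone": asdict(sm.zone)}
            for name, sm in model.subsets.items()
        },
    }


def _checksum(payload: dict) -> int:
    canon = json.dumps(payload, sort_keys=True).encode("utf-8")
    return zlib.crc32(canon)


def write_model(model: ReferenceModel, path) -> None:
    payload = _model_payload(model)
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "checksum": _checksum(payload),
        "model": payload,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def read_model(path) -> ReferenceModel:
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except FileNotFoundError:
        raise DataError(f"model file not found: {path}") from None
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"model file {path} is corrupted or truncated: {exc}") from exc
    if not isinstance(doc, dict) or "model" not in doc or "schema_version" not in doc:
        raise ModelFormatError(f"model file {path}: missing schema envelope")
    major = str(doc["schema_version"]).split(".")[0]
    if major != MODEL_SCHEMA_VERSION.split(".")[0]:
        raise ModelFormatError(
            f"model file {path}: schema version {doc['schema_version']} is newer than "
            f"supported {MODEL_SCHEMA_VERSION}"
        )
    payload = doc["model"]
    if _checksum(payload) != doc.get("checksum"):
        raise ModelFormatError(f"model file {path}: checksum mismatch (corrupted content)")
    subsets = {
        name: SubsetModel(
            stats=ReferenceStats(**entry["stats"]), zone=ZeroZone(**entry["zone"])
        )
        for name, entry in payload["subsets"].items()
    }
    return ReferenceModel(
        subsets=subsets,
        skipped=dict(payload.get("skipped", {})),
        n_max=int(payload["n_max"]),
        band_steps=int(payload["band_steps"]),
        rank_floor=int(payload["rank_floor"]),
        quantile_convention=payload["quantile_convention"],
        cover_on_cleaned=bool(payload.get("cover_on_cleaned", False)),
    )


# ---------------------------------------------------------------------------
# scores, longitudinal tables, manifest
# ---------------------------------------------------------------------------

def write_scores(results: list[SignatureResult], path) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "score": r.score,
                "n_subsets_used": r.n_subsets_used,
                "n_subsets_skipped": r.n_subsets_skipped,
            }
            for r in results
        ]
    ).to_csv(path, index=False)


def write_rank_matrix(results: list[SignatureResult], path) -> None:
    pd.DataFrame(
        [{"subject_id": r.subject_id, **r.ranks} for r in results]
    ).to_csv(path, index=False)


def write_longitudinal_table(records: list[LongitudinalRecord], path) -> None:
    """Long format: one row per (patient, week, subset)."""
    rows = []
    for r in records:
        for subset, pct in sorted(r.values.items()):
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "week": r.week,
                    "sledai2k": r.sledai2k,
                    "leucocyte_count": r.leucocyte_count,
                    "subset": subset,
                    "percentage": pct,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_longitudinal_table(path) -> list[LongitudinalRecord]:
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise DataError(f"input file not found: {path}") from None
    for col in ("patient_id", "week", "sledai2k", "subset", "percentage"):
        if col not in df.columns:
            raise DataError(f"table {path}: missing required column {col!r}")
    records: dict[tuple[str, int], LongitudinalRecord] = {}
    for _, row in df.iterrows():
        key = (str(row["patient_id"]), int(row["week"]))
        if key not in records:
            sledai = int(row["sledai2k"])
            if sledai < 0:
                raise DataError(f"table {path}: negative SLEDAI-2K for {key}")
            leu = row.get("leucocyte_count")
            records[key] = LongitudinalRecord(
                patient_id=key[0],
                week=key[1],
                sledai2k=sledai,
                leucocyte_count=None if pd.isna(leu) else float(leu),
            )
        records[key].values[str(row["subset"])] = float(row["percentage"])
    return list(records.values())


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(
    command: str,
    config: dict | None,
    inputs: dict[str, str],
    seeds: dict[str, int],
    warnings: list[str],
) -> dict:
    from . import __version__

    cfg_hash = None
    if config is not None:
        cfg_hash = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()
    return {
        "command": command,
        "config_sha256": cfg_hash,
        "input_sha256": dict(inputs),
        "seeds": dict(seeds),
        "package_version": __version__,
        "timestamp_utc": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "warnings": list(warnings),
    }


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
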