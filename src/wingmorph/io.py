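"""Read, validate and write landmark datasets in TPS and wide-CSV form.

TPS follows the tpsDIG conventions: records start with ``LM=<k>`` followed by
k whitespace-separated ``x y`` lines, then optional ``KEY=value`` lines
(``ID=``, ``IMAGE=``, ``SCALE=``).  This writer additionally emits
``SPECIES=``, ``SEX=``, ``OBSERVER=``, ``SITE=`` and ``REPLICATE=`` keys so
that metadata survives a round trip; unknown keys are ignored with a warning,
so plain third-party TPS files read fine.

Coordinates are stored exactly as read; no y-axis flip is applied.  Alignment
downstream is reflection-free, so a dataset must be digitized with a single
chirality (e.g. all left wings); validate_dataset warns when the signed area
of the landmark polygon changes sign across records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import LandmarkConfiguration, LandmarkDataset, Sex, Species

logger = logging.getLogger(__name__)

_COORD_FMT = "{:.9f}"

_META_COLUMNS = ["id", "species", "sex", "observer", "site", "replicate"]


class TpsParseError(ValueError):
    """Malformed TPS input."""


class CsvSchemaError(ValueError):
    """CSV input does not match the expected wide-landmark schema."""


@dataclass
class ValidationIssue:
    level: str  # "error" | "warning"
    record: str | None  # specimen key or None for dataset-level issues
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.level == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.level == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:
        if not self.issues:
            return "validation: no issues"
        lines = [
            f"[{i.level}] {i.record or '<dataset>'}: {i.message}"
            for i in self.issues
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------

_KNOWN_TPS_KEYS = {
    "LM", "ID", "IMAGE", "SCALE",
    "SPECIES", "SEX", "OBSERVER", "SITE", "REPLICATE",
}


def read_tps(path: str | Path) -> LandmarkDataset:
    """Parse a TPS landmark file into a dataset.

    Raises TpsParseError on malformed records, non-numeric coordinate tokens
    (with line numbers) or mixed LM= counts across records.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()

    records: list[LandmarkConfiguration] = []
    ks: set[int] = set()
    i = 0
    n_lines = len(lines)
    record_index = 0
    while i < n_lines:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TpsParseError(
                f"{path}:{i + 1}: expected 'LM=' record start, got {line!r}"
            )
        record_index += 1
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TpsParseError(
                f"{path}:{i + 1}: non-integer landmark count in {line!r}"
            ) from exc
        i += 1
        coords = []
        while i < n_lines and len(coords) < k:
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            if "=" in row and not _looks_numeric(row.split()[0]):
                break  # metadata started before k coordinates were read
            tokens = row.split()
            if len(tokens) != 2:
                raise TpsParseError(
                    f"{path}:{i + 1}: expected 'x y' coordinate pair, "
                    f"got {row!r}"
                )
            try:
                coords.append((float(tokens[0]), float(tokens[1])))
            except ValueError as exc:
                raise TpsParseError(
                    f"{path}:{i + 1}: non-numeric coordinate token in {row!r}"
                ) from exc
            i += 1
        if len(coords) != k:
            raise TpsParseError(
                f"{path}: record {record_index} declares LM={k} but has "
                f"{len(coords)} coordinate lines"
            )
        meta: dict[str, str] = {}
        while i < n_lines:
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            if row.upper().startswith("LM="):
                break
            if "=" not in row:
                raise TpsParseError(
                    f"{path}:{i + 1}: unexpected line {row!r} "
                    "(extra coordinate beyond LM count?)"
                )
            key, value = row.split("=", 1)
            key = key.strip().upper()
            if key not in _KNOWN_TPS_KEYS:
                logger.warning("%s:%d: ignoring unknown TPS key %s", path, i + 1, key)
            else:
                meta[key] = value.strip()
            i += 1

        arr = np.array(coords, dtype=float)
        if "SCALE" in meta:
            try:
                scale = float(meta["SCALE"])
            except ValueError as exc:
                raise TpsParseError(
                    f"{path}: record {record_index}: non-numeric SCALE "
                    f"{meta['SCALE']!r}"
                ) from exc
            arr = arr * scale
        specimen_id = meta.get("ID") or _image_basename(meta.get("IMAGE")) or (
            f"record_{record_index}"
        )
        records.append(
            LandmarkConfiguration(
                specimen_id=specimen_id,
                coords=arr,
                species=Species.parse(meta.get("SPECIES", "unknown")),
                sex=Sex.parse(meta.get("SEX", "unknown")),
                observer=meta.get("OBSERVER", "obs1"),
                site=meta.get("SITE") or None,
                replicate=int(meta.get("REPLICATE", 1)),
            )
        )
        ks.add(k)

    if not records:
        raise TpsParseError(f"{path}: no TPS records found")
    if len(ks) > 1:
        raise TpsParseError(
            f"{path}: heterogeneous landmark counts across records: {sorted(ks)}"
        )
    return LandmarkDataset(records, provenance=f"tps:{path}")


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _image_basename(image: str | None) -> str | None:
    if not image:
        return None
    return Path(image).stem


def write_tps(dataset: LandmarkDataset, path: str | Path) -> None:
    """Write a dataset as TPS with metadata keys; deterministic byte output."""
    _check_writable_dataset(dataset)
    path = Path(path)
    chunks: list[str] = []
    for c in dataset:
        lines = [f"LM={c.k}"]
        lines += [
            f"{_COORD_FMT.format(x)} {_COORD_FMT.format(y)}" for x, y in c.coords
        ]
        lines.append(f"ID={c.specimen_id}")
        lines.append(f"SPECIES={c.species.value}")
        lines.append(f"SEX={c.sex.value}")
        lines.append(f"OBSERVER={c.observer}")
        if c.site is not None:
            lines.append(f"SITE={c.site}")
        lines.append(f"REPLICATE={c.replicate}")
        chunks.append("\n".join(lines))
    path.write_text("\n".join(chunks) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# CSV (wide format: id, species, sex, observer, site, replicate, x1..yk)
# ---------------------------------------------------------------------------

def read_csv(path: str | Path) -> LandmarkDataset:
    """Read the wide CSV landmark format.

    The header must contain the metadata columns and x1,y1,...,xk,yk; k is
    inferred from the header.  Unrecognized species/sex strings map to
    'unknown' with a logged warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"id": str, "observer": str, "site": str})
    except pd.errors.ParserError as exc:
        raise CsvSchemaError(f"{path}: ragged or malformed CSV: {exc}") from exc

    missing_meta = [c for c in _META_COLUMNS if c not in df.columns]
    if missing_meta:
        raise CsvSchemaError(
            f"{path}: missing metadata column(s): {', '.join(missing_meta)}"
        )
    k = 0
    while f"x{k + 1}" in df.columns and f"y{k + 1}" in df.columns:
        k += 1
    if k == 0:
        raise CsvSchemaError(f"{path}: no coordinate columns (x1, y1, ...) found")
    expected_pairs = [(f"x{j}", f"y{j}") for j in range(1, k + 1)]
    stray = [
        c for c in df.columns
        if (c.startswith("x") or c.startswith("y"))
        and c[1:].isdigit()
        and c not in {name for pair in expected_pairs for name in pair}
    ]
    if stray:
        raise CsvSchemaError(
            f"{path}: incomplete coordinate pair(s); unexpected column(s) {stray}"
        )

    coord_cols = [name for pair in expected_pairs for name in pair]
    coord_values = df[coord_cols].to_numpy(dtype=float)
    if np.isnan(coord_values).any():
        bad = int(np.where(np.isnan(coord_values).any(axis=1))[0][0])
        raise CsvSchemaError(
            f"{path}: row {bad + 2}: missing or non-numeric coordinate value"
        )

    records = []
    for row_idx, row in df.iterrows():
        species = Species.parse(row["species"])
        if species is Species.UNKNOWN and str(row["species"]).strip().lower() != "unknown":
            logger.warning(
                "%s: row %d: unknown species label %r mapped to 'unknown'",
                path, row_idx + 2, row["species"],
            )
        sex = Sex.parse(row["sex"])
        if sex is Sex.UNKNOWN and str(row["sex"]).strip().lower() != "unknown":
            logger.warning(
                "%s: row %d: unknown sex label %r mapped to 'unknown'",
                path, row_idx + 2, row["sex"],
            )
        site = row["site"]
        if pd.isna(site) or str(site) == "":
            site = None
        records.append(
            LandmarkConfiguration(
                specimen_id=str(row["id"]),
                coords=coord_values[row_idx].reshape(k, 2),
                species=species,
                sex=sex,
                observer=str(row["observer"]),
                site=site,
                replicate=int(row["replicate"]),
            )
        )
    return LandmarkDataset(records, provenance=f"csv:{path}")


def write_csv(dataset: LandmarkDataset, path: str | Path) -> None:
    """Write the wide CSV format; deterministic byte output, '.' decimals."""
    _check_writable_dataset(dataset)
    path = Path(path)
    k = dataset.landmark_count
    header = _META_COLUMNS + [
        name for j in range(1, k + 1) for name in (f"x{j}", f"y{j}")
    ]
    rows = [",".join(header)]
    for c in dataset:
        cells = [
            c.specimen_id,
            c.species.value,
            c.sex.value,
            c.observer,
            c.site if c.site is not None else "",
            str(c.replicate),
        ]
        cells += [_COORD_FMT.format(v) for v in c.coords.ravel()]
        rows.append(",".join(cells))
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")


def _check_writable_dataset(dataset: LandmarkDataset) -> None:
    if not isinstance(dataset, LandmarkDataset):
        raise TypeError("expected a LandmarkDataset")
    for c in dataset:
        if c.coords.size == 0:
            raise ValueError(
                f"configuration {c.specimen_id!r} has no coordinates"
            )
        if not np.isfinite(c.coords).all():
            raise ValueError(
                f"configuration {c.specimen_id!r} has non-finite coordinates"
            )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_dataset(dataset: LandmarkDataset) -> ValidationReport:
    """Pure QC pass over a dataset; reports issues, mutates nothing.

    Checks: finite coordinates, coincident landmarks within a record,
    duplicate (id, observer, replicate) keys, missing species/sex metadata,
    and mixed polygon orientation (a proxy for mixed wing chirality, which
    reflection-free alignment cannot absorb).
    """
    report = ValidationReport()
    seen: dict[tuple, str] = {}
    orientations: set[int] = set()
    for c in dataset:
        label = f"{c.specimen_id}/{c.observer}/r{c.replicate}"
        if not np.isfinite(c.coords).all():
            report.issues.append(
                ValidationIssue("error", label, "non-finite coordinates")
            )
            continue
        # coincident landmark pairs
        d = np.linalg.norm(c.coords[:, None, :] - c.coords[None, :, :], axis=-1)
        iu = np.triu_indices(c.k, k=1)
        coincident = np.argwhere(d[iu] == 0.0)
        for (flat,) in coincident:
            a, b = iu[0][flat], iu[1][flat]
            report.issues.append(
                ValidationIssue(
                    "error", label,
                    f"coincident landmarks {a + 1} and {b + 1}",
                )
            )
        if c.key in seen:
            report.issues.append(
                ValidationIssue(
                    "error", label,
                    "duplicate (specimen_id, observer, replicate) key",
                )
            )
        seen[c.key] = label
        if c.species is Species.UNKNOWN:
            report.issues.append(
                ValidationIssue("warning", label, "species is unknown")
            )
        if c.sex is Sex.UNKNOWN:
            report.issues.append(
                ValidationIssue("warning", label, "sex is unknown")
            )
        orientations.add(int(np.sign(_signed_area(c.coords))) or 1)
    if len(orientations) > 1:
        report.issues.append(
            ValidationIssue(
                "warning", None,
                "mixed landmark polygon orientation across records "
                "(possible mixed wing chirality; alignment is reflection-free)",
            )
        )
    return report


def _signed_area(coords: np.ndarray) -> float:
    """Shoelace signed area of the landmark polygon in file order."""
    x, y = coords[:, 0], coords[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
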