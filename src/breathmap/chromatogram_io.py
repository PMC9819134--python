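"""Strict readers and writers for the pipeline's plain-text formats.

Chromatograms are two-column CSV (``rt,intensity``); every multi-column
table (peaks, profiles, labels, compounds, covariates) is TSV, because
compound names routinely contain commas and brackets.  Readers are
strict and total: a malformed file raises before any partially built
object escapes.  Numeric round-trips are exact to full repr precision.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .chromatogram import MIN_POINTS, Chromatogram
from .peak_detection import Peak, PeakTable
from .profiling import FEATURE_NAMES, ProfileMatrix

__all__ = [
    "BreathmapIOError",
    "FormatError",
    "ParseError",
    "OrderingError",
    "SizeError",
    "IntegrityError",
    "read_chromatogram",
    "write_chromatogram",
    "read_peak_table",
    "write_peak_table",
    "read_profiles",
    "write_profiles",
    "read_labels",
    "write_labels",
    "read_compounds",
    "write_compounds",
    "read_covariates",
    "write_covariates",
]


class BreathmapIOError(ValueError):
    """Base class for file-format failures."""


class FormatError(BreathmapIOError):
    """Header or column structure is wrong."""


class ParseError(BreathmapIOError):
    """A cell failed to parse; the message carries the line number."""


class OrderingError(BreathmapIOError):
    """Retention times are not strictly increasing."""


class SizeError(BreathmapIOError):
    """Too few data points."""


class IntegrityError(BreathmapIOError):
    """Duplicate keys or inconsistent rows."""


# ---------------------------------------------------------------------------
# Chromatograms (CSV)
# ---------------------------------------------------------------------------

_CHROM_HEADER = "rt,intensity"


def read_chromatogram(path: str | Path, sample_id: str | None = None) -> Chromatogram:
    """Read a two-column ``rt,intensity`` CSV into a :class:`Chromatogram`.

    ``sample_id`` defaults to the file stem.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != _CHROM_HEADER:
        raise FormatError(
            f"{path.name}: first line must be '{_CHROM_HEADER}'"
        )
    rt, intensity = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ParseError(f"{path.name}, line {lineno}: expected 2 fields")
        try:
            rt.append(float(parts[0]))
            intensity.append(float(parts[1]))
        except ValueError as exc:
            raise ParseError(
                f"{path.name}, line {lineno}: non-numeric cell ({line!r})"
            ) from exc
    if len(rt) < MIN_POINTS:
        raise SizeError(
            f"{path.name}: need at least {MIN_POINTS} points, got {len(rt)}"
        )
    rt_arr = np.asarray(rt)
    if np.any(np.diff(rt_arr) <= 0):
        raise OrderingError(f"{path.name}: rt must be strictly increasing")
    return Chromatogram(
        sample_id=sample_id if sample_id is not None else path.stem,
        rt=rt_arr,
        intensity=np.asarray(intensity),
    )


def write_chromatogram(chromatogram: Chromatogram, path: str | Path) -> None:
    """Write a chromatogram as CSV at full repr precision."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_CHROM_HEADER + "\n")
        for t, y in zip(chromatogram.rt, chromatogram.intensity):
            fh.write(f"{float(t)!r},{float(y)!r}\n")


# ---------------------------------------------------------------------------
# Peak tables (TSV)
# ---------------------------------------------------------------------------

_PEAK_COLUMNS = (
    "sample_id",
    "rt",
    "height",
    "prominence",
    "width",
    "left_rt",
    "right_rt",
    "area",
    "ratio",
    "confirmed",
)


def write_peak_table(
    peak_tables: PeakTable | list[PeakTable], path: str | Path
) -> None:
    """Write one or more per-sample peak tables into a single TSV."""
    if isinstance(peak_tables, PeakTable):
        peak_tables = [peak_tables]
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_PEAK_COLUMNS) + "\n")
        for table in peak_tables:
            for p in table:
                fields = [
                    table.sample_id,
                    repr(float(p.rt)),
                    repr(float(p.height)),
                    repr(float(p.prominence)),
                    repr(float(p.width)),
                    repr(float(p.left_rt)),
                    repr(float(p.right_rt)),
                    repr(float(p.area)),
                    repr(float(p.ratio)),
                    str(bool(p.confirmed)),
                ]
                fh.write("\t".join(fields) + "\n")


def read_peak_table(path: str | Path) -> list[PeakTable]:
    """Read a peak TSV back into per-sample :class:`PeakTable` objects.

    Sample order follows first appearance in the file.  Grid indices are
    not stored in the file, so the returned peaks carry ``index=None``.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path.name}: empty file")
    header = tuple(lines[0].split("\t"))
    if header != _PEAK_COLUMNS:
        unknown = set(header) - set(_PEAK_COLUMNS)
        raise FormatError(
            f"{path.name}: bad header"
            + (f" (unknown columns {sorted(unknown)})" if unknown else "")
        )
    grouped: dict[str, list[Peak]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(_PEAK_COLUMNS):
            raise ParseError(
                f"{path.name}, line {lineno}: expected "
                f"{len(_PEAK_COLUMNS)} fields"
            )
        sample_id = parts[0]
        try:
            numbers = [float(v) for v in parts[1:9]]
        except ValueError as exc:
            raise ParseError(
                f"{path.name}, line {lineno}: non-numeric cell"
            ) from exc
        if parts[9] not in ("True", "False"):
            raise ParseError(
                f"{path.name}, line {lineno}: confirmed must be "
                f"True or False, got {parts[9]!r}"
            )
        grouped.setdefault(sample_id, []).append(
            Peak(
                rt=numbers[0],
                height=numbers[1],
                prominence=numbers[2],
                width=numbers[3],
                left_rt=numbers[4],
                right_rt=numbers[5],
                area=numbers[6],
                ratio=numbers[7],
                confirmed=parts[9] == "True",
            )
        )
    return [PeakTable(sid, peaks) for sid, peaks in grouped.items()]


# ---------------------------------------------------------------------------
# Profile matrices (TSV)
# ---------------------------------------------------------------------------


def write_profiles(matrix: ProfileMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("sample_id\t" + "\t".join(FEATURE_NAMES) + "\n")
        for sid, row in zip(matrix.sample_ids, matrix.values):
            fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_profiles(path: str | Path) -> ProfileMatrix:
    path = Path(path)
    table = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str}, float_precision="round_trip"
    )
    expected = ["sample_id", *FEATURE_NAMES]
    if list(table.columns) != expected:
        raise FormatError(f"{path.name}: columns must be {expected}")
    values = table[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
    return ProfileMatrix(table["sample_id"].tolist(), values)


# ---------------------------------------------------------------------------
# Labels, compounds, covariates (TSV)
# ---------------------------------------------------------------------------


def write_labels(
    sample_ids: list[str], labels: np.ndarray, path: str | Path
) -> None:
    if len(sample_ids) != len(labels):
        raise IntegrityError("sample_ids and labels must align")
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("sample_id\tlabel\n")
        for sid, lab in zip(sample_ids, labels):
            fh.write(f"{sid}\t{int(lab)}\n")


def read_labels(path: str | Path) -> dict[str, int]:
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "label": int})
    if list(table.columns) != ["sample_id", "label"]:
        raise FormatError(f"{path.name}: columns must be sample_id, label")
    if table["sample_id"].duplicated().any():
        raise IntegrityError(f"{path.name}: duplicate sample ids")
    return dict(zip(table["sample_id"], table["label"].astype(int)))


def write_compounds(compounds: pd.DataFrame, path: str | Path) -> None:
    expected = ["sample_id", "compound", "rt"]
    if list(compounds.columns) != expected:
        raise FormatError(f"compound table columns must be {expected}")
    compounds.to_csv(path, sep="\t", index=False)


def read_compounds(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    table = pd.read_csv(
        path,
        sep="\t",
        dtype={"sample_id": str, "compound": str},
        float_precision="round_trip",
    )
    if list(table.columns) != ["sample_id", "compound", "rt"]:
        raise FormatError(
            f"{path.name}: columns must be sample_id, compound, rt"
        )
    return table


def write_covariates(covariates: pd.DataFrame, path: str | Path) -> None:
    expected = ["sample_id", "covariate", "value"]
    if list(covariates.columns) != expected:
        raise FormatError(f"covariate table columns must be {expected}")
    covariates.to_csv(path, sep="\t", index=False)


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Long-format covariates; numeric strings become floats, the rest
    stay categorical.  Duplicate (sample_id, covariate) pairs are
    rejected.
    """
    path = Path(path)
    table = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "covariate": str, "value": str}
    )
    if list(table.columns) != ["sample_id", "covariate", "value"]:
        raise FormatError(
            f"{path.name}: columns must be sample_id, covariate, value"
        )
    if table.duplicated(subset=["sample_id", "covariate"]).any():
        dupes = table[table.duplicated(subset=["sample_id", "covariate"])]
        raise IntegrityError(
            f"{path.name}: duplicate (sample_id, covariate) pairs, e.g. "
            f"{dupes.iloc[0]['sample_id']}/{dupes.iloc[0]['covariate']}"
        )

    def coerce(v):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return np.nan
        try:
            return float(v)
        except (TypeError, ValueError):
            return v

    table = table.copy()
    table["value"] = table["value"].map(coerce)
    return table
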