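"""Reading and writing focus-position tables and result summaries.

The canonical focus table is delimited text (CSV or TSV) with header

    nucleus_id, genotype, bivalent_rank, axis_length_um,
    segment_start_um, segment_end_um, focus_position_um

and one row per focus.  A segment without any focus is represented by a
sentinel row with an empty ``focus_position_um`` cell, so that bivalents with
zero crossovers are representable (they matter for the E0 class).  Decimal
commas are accepted and normalised on read.  ``bivalent_rank`` may be left
empty, in which case ranks are recomputed from descending axis lengths.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import os
from collections import OrderedDict

import numpy as np
import openpyxl
import pandas as pd

from .errors import CocountError, SchemaError, ValidationError
from .model import Cohort, FocusTrack, Nucleus, assign_ranks

FOCUS_TABLE_COLUMNS = (
    "nucleus_id",
    "genotype",
    "bivalent_rank",
    "axis_length_um",
    "segment_start_um",
    "segment_end_um",
    "focus_position_um",
)

#: float format guaranteeing exact round-trip of IEEE doubles through text
FLOAT_FMT = "%.17g"


def _parse_float(cell, column: str, row_number: int) -> float | None:
    """Parse a numeric cell, accepting decimal commas; None for empty cells."""
    if cell is None:
        return None
    text = str(cell).strip()
    if text == "" or text.lower() == "nan":
        return None
    try:
        return float(text.replace(",", "."))
    except ValueError:
        raise ValidationError(
            f"row {row_number}: cannot parse {column}={text!r} as a number"
        ) from None


def _sniff_delimiter(path: str) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else (";" if ";" in header else ",")


def read_focus_table(path: str, delimiter: str | None = None) -> Cohort:
    """Read a focus-position table into a validated single-genotype Cohort.

    Raises :class:`SchemaError` for a missing column, :class:`ValidationError`
    for out-of-range values (citing the offending row), and
    :class:`ValidationError` if the file mixes genotypes (use
    :func:`read_cohorts` for multi-genotype files).
    """
    cohorts = read_cohorts(path, delimiter=delimiter)
    if len(cohorts) == 0:
        return Cohort(genotype="", nuclei=(), provenance=str(path))
    if len(cohorts) > 1:
        raise ValidationError(
            f"{path} mixes genotypes {sorted(cohorts)}; use read_cohorts()"
        )
    return next(iter(cohorts.values()))


def read_cohorts(path: str, delimiter: str | None = None) -> dict[str, Cohort]:
    """Read a focus table possibly holding several genotypes, keyed by genotype."""
    if delimiter is None:
        delimiter = _sniff_delimiter(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for col in FOCUS_TABLE_COLUMNS:
            if col not in header:
                raise SchemaError(f"{path}: missing required column {col!r}")
        rows = list(reader)

    # rows grouped per (genotype, nucleus, bivalent); insertion order kept
    tracks_raw: "OrderedDict[tuple, dict]" = OrderedDict()
    for idx, row in enumerate(rows, start=2):  # header is line 1
        nucleus_id = (row["nucleus_id"] or "").strip()
        genotype = (row["genotype"] or "").strip()
        rank_val = _parse_float(row["bivalent_rank"], "bivalent_rank", idx)
        axis_length = _parse_float(row["axis_length_um"], "axis_length_um", idx)
        seg_start = _parse_float(row["segment_start_um"], "segment_start_um", idx)
        seg_end = _parse_float(row["segment_end_um"], "segment_end_um", idx)
        focus = _parse_float(row["focus_position_um"], "focus_position_um", idx)
        if axis_length is None or axis_length <= 0:
            raise ValidationError(f"row {idx}: axis_length_um must be a positive number")
        if seg_start is None or seg_end is None:
            raise ValidationError(f"row {idx}: segment bounds are required")
        if seg_start < 0 or seg_end > axis_length or seg_end <= seg_start:
            raise ValidationError(
                f"row {idx}: segment ({seg_start}, {seg_end}) invalid for "
                f"axis_length {axis_length}"
            )
        if focus is not None and not (seg_start <= focus <= seg_end):
            raise ValidationError(
                f"row {idx}: focus_position_um={focus} outside its segment "
                f"({seg_start}, {seg_end})"
            )
        key = (genotype, nucleus_id, None if rank_val is None else int(rank_val), axis_length)
        entry = tracks_raw.setdefault(
            key, {"segments": set(), "foci": [], "rows": []}
        )
        entry["segments"].add((seg_start, seg_end))
        entry["rows"].append(idx)
        if focus is not None:
            entry["foci"].append(focus)

    # assemble nuclei per genotype
    nuclei_raw: "OrderedDict[tuple, list]" = OrderedDict()
    for (genotype, nucleus_id, rank, axis_length), entry in tracks_raw.items():
        nuclei_raw.setdefault((genotype, nucleus_id), []).append(
            (rank, axis_length, entry)
        )

    cohorts: "OrderedDict[str, list[Nucleus]]" = OrderedDict()
    for (genotype, nucleus_id), items in nuclei_raw.items():
        if any(rank is None for rank, _, _ in items):
            ranks = assign_ranks([axis_length for _, axis_length, _ in items])
        else:
            ranks = [rank for rank, _, _ in items]
        tracks = []
        for rank, (orig_rank, axis_length, entry) in zip(ranks, items):
            try:
                tracks.append(
                    FocusTrack(
                        nucleus_id=nucleus_id,
                        genotype=genotype,
                        bivalent_rank=int(rank),
                        axis_length=axis_length,
                        segments=tuple(sorted(entry["segments"])),
                        focus_positions=tuple(sorted(entry["foci"])),
                    )
                )
            except ValidationError as err:
                raise ValidationError(f"rows {entry['rows']}: {err}") from None
        tracks.sort(key=lambda t: t.bivalent_rank)
        cohorts.setdefault(genotype, []).append(
            Nucleus(nucleus_id, genotype, tuple(tracks))
        )

    return {
        genotype: Cohort(genotype=genotype, nuclei=tuple(nuclei), provenance=str(path))
        for genotype, nuclei in cohorts.items()
    }


def write_focus_table(cohort: Cohort, path: str, delimiter: str = ",") -> None:
    """Write a Cohort back to the canonical focus-table format.

    Focus-free segments get a sentinel row with an empty focus cell, so
    reading the file back reproduces the cohort exactly.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(FOCUS_TABLE_COLUMNS)
        for nuc in cohort.nuclei:
            for track in nuc.tracks:
                for seg in track.segments:
                    foci = [p for p in track.focus_positions
                            if seg[0] <= p <= seg[1]]
                    if not foci:
                        writer.writerow(_focus_row(track, seg, None))
                    for p in foci:
                        writer.writerow(_focus_row(track, seg, p))


def _focus_row(track: FocusTrack, seg: tuple[float, float], focus: float | None):
    return [
        track.nucleus_id,
        track.genotype,
        track.bivalent_rank,
        FLOAT_FMT % track.axis_length,
        FLOAT_FMT % seg[0],
        FLOAT_FMT % seg[1],
        "" if focus is None else FLOAT_FMT % focus,
    ]


# ---------------------------------------------------------------------------
# supplementary workbook ingestion


def read_supplementary_workbook(path: str, sheet_map: dict) -> dict[str, pd.DataFrame]:
    """Read figure-panel tables from a supplementary spreadsheet workbook.

    ``sheet_map`` maps panel labels to worksheet names (or to
    ``{"sheet": name, "columns": [...]}`` to select/rename columns).  The
    first row of each sheet is taken as the header.  Tables are returned
    untransformed; conversion to a Cohort is the caller's job via an
    explicit column mapping.  A missing sheet raises :class:`SchemaError`
    listing the available sheets; a non-numeric cell below the header raises
    :class:`ValidationError` with its cell address.
    """
    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    available = wb.sheetnames
    out: dict[str, pd.DataFrame] = {}
    for panel, spec in sheet_map.items():
        if isinstance(spec, str):
            sheet_name, columns = spec, None
        else:
            sheet_name, columns = spec["sheet"], spec.get("columns")
        if sheet_name not in available:
            raise SchemaError(
                f"sheet {sheet_name!r} not in workbook; available sheets: {available}"
            )
        ws = wb[sheet_name]
        rows = list(ws.iter_rows())
        if not rows:
            out[panel] = pd.DataFrame()
            continue
        header = [str(c.value) if c.value is not None else f"col{i}"
                  for i, c in enumerate(rows[0])]
        data = {name: [] for name in header}
        for row in rows[1:]:
            for name, cell in zip(header, row):
                value = cell.value
                if value is None or (isinstance(value, str) and value.strip() == ""):
                    data[name].append(np.nan)
                    continue
                if isinstance(value, str):
                    try:
                        value = float(value.replace(",", "."))
                    except ValueError:
                        raise ValidationError(
                            f"non-numeric cell {cell.coordinate} in sheet "
                            f"{sheet_name!r}: {value!r}"
                        ) from None
                data[name].append(float(value))
        frame = pd.DataFrame(data)
        if columns is not None:
            missing = [c for c in columns if c not in frame.columns]
            if missing:
                raise SchemaError(
                    f"sheet {sheet_name!r}: missing columns {missing}; "
                    f"has {list(frame.columns)}"
                )
            frame = frame[list(columns)]
        out[panel] = frame
    wb.close()
    return out


# ---------------------------------------------------------------------------
# result serialisation


def _to_plain(obj):
    """Recursively convert results (dataclasses, arrays) to plain JSON types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _flatten(obj, prefix=""):
    plain = _to_plain(obj)
    flat: "OrderedDict[str, object]" = OrderedDict()

    def walk(node, key):
        if isinstance(node, dict):
            for k, v in node.items():
                walk(v, f"{key}.{k}" if key else str(k))
        elif isinstance(node, list):
            for i, v in enumerate(node):
                walk(v, f"{key}[{i}]")
        else:
            flat[key] = node

    walk(plain, prefix)
    return flat


def write_results(results, path: str, format: str = "csv") -> None:
    """Serialise a result object (dataclass / dict / nested) to disk.

    ``csv`` writes flattened ``key,value`` rows with 17-significant-digit
    floats so re-reading reproduces every number bit-identically; ``json``
    writes the nested structure.
    """
    directory = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(directory):
        raise IOError(f"directory does not exist: {directory}")
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_to_plain(results), fh, indent=2)
            fh.write("\n")
    elif format == "csv":
        flat = _flatten(results)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["key", "value"])
            for key, value in flat.items():
                if isinstance(value, float):
                    value = FLOAT_FMT % value
                writer.writerow([key, value])
    else:
        raise CocountError(f"unknown results format {format!r}; use 'csv' or 'json'")


def read_results(path: str, format: str = "csv"):
    """Re-read a results file written by :func:`write_results`.

    The csv path returns a flat ``{key: value}`` dict with numeric strings
    converted back to float/int; json returns the nested structure.
    """
    if format == "json":
        with open(path, "r", encoding="utf-8") as fh:
            return json.load(fh)
    flat: "OrderedDict[str, object]" = OrderedDict()
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        next(reader)  # header
        for key, value in reader:
            flat[key] = _coerce(value)
    return flat


def _coerce(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    if text == "True":
        return True
    if text == "False":
        return False
    if text == "":
        return None
    return text
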