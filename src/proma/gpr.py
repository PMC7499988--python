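"""Reading, validating and writing GenePix Results (GPR) files.

GPR files are the tab-separated ATF (Axon Text File) exports of microarray
scanners: a version line (``ATF<tab>1.0``), a line with the number of
optional header records and the number of data columns, that many
``Key=Value`` header records, a column-name row, and one data row per spot.
Each spot carries its 1-based geometry (``Block``, ``Column``, ``Row``),
``Name`` and ``ID`` annotations, and per-channel intensity statistics such
as ``F635 Median`` (foreground) and ``B635 Median`` (local background).

Real exports vary: both CRLF and LF line endings are accepted, and any text
field may be wrapped in double quotes (with ``""`` escaping an embedded
quote). Empty intensity cells parse to NaN, never to zero — zero is a legal
intensity.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, TextIO

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    GPRFormatError,
    GPRParseError,
    IntegrityError,
    SelectionError,
)

#: Columns every GPR spot table must provide, in canonical order.
GEOMETRY_COLUMNS = ("Block", "Column", "Row")
ANNOTATION_COLUMNS = ("Name", "ID")
REQUIRED_COLUMNS = GEOMETRY_COLUMNS + ANNOTATION_COLUMNS


@dataclass
class GPRFile:
    """One parsed GPR file: header metadata plus the spot table.

    The spot table is a :class:`pandas.DataFrame` with one row per spot.
    Geometry columns are integers, ``Name``/``ID`` are strings, every other
    column is a float intensity column (NaN marks a missing cell).
    """

    source_name: str
    atf_version: str
    header_records: dict[str, str]
    column_names: list[str]
    spots: pd.DataFrame

    @property
    def intensity_columns(self) -> list[str]:
        return [c for c in self.column_names if c not in REQUIRED_COLUMNS]

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    def layout_key(self) -> pd.DataFrame:
        """(Block, Column, Row, ID) table identifying the spot layout."""
        return self.spots[["Block", "Column", "Row", "ID"]]

    def equals(self, other: "GPRFile", rtol: float = 1e-6) -> bool:
        """Field-by-field equality with relative tolerance on intensities."""
        if (
            self.source_name != other.source_name
            or self.atf_version != other.atf_version
            or self.header_records != other.header_records
            or self.column_names != other.column_names
            or len(self.spots) != len(other.spots)
        ):
            return False
        for col in REQUIRED_COLUMNS:
            if not self.spots[col].tolist() == other.spots[col].tolist():
                return False
        for col in self.intensity_columns:
            a = self.spots[col].to_numpy(dtype=float)
            b = other.spots[col].to_numpy(dtype=float)
            if not np.array_equal(np.isnan(a), np.isnan(b)):
                return False
            m = ~np.isnan(a)
            if not np.allclose(a[m], b[m], rtol=rtol, atol=0.0):
                return False
        return True


@dataclass
class ColumnCatalog:
    """Intensity columns shared by all files and the chosen channels."""

    shared_columns: list[str]
    foreground: Optional[str] = None
    background: Optional[str] = None
    auto_detected: bool = False


_HEADER_RECORD_RE = re.compile(r"^(?P<key>[^=]+)=(?P<value>.*)$", re.S)


def _split_fields(line: str) -> list[str]:
    """Split one tab-separated line, honouring double-quoted fields."""
    return next(csv.reader([line], delimiter="\t", quotechar='"'))


def _unquote(text: str) -> str:
    text = text.strip()
    if len(text) >= 2 and text[0] == '"' and text[-1] == '"':
        return text[1:-1].replace('""', '"')
    return text


def parse_gpr(stream: TextIO | str, source_name: str) -> GPRFile:
    """Parse ATF-dialect GPR text into a :class:`GPRFile`.

    Parameters
    ----------
    stream
        Text stream or string containing the whole file.
    source_name
        Label for the sample (conventionally the filename stem).

    Raises
    ------
    GPRFormatError
        Malformed preamble (version line, counts line, short file), naming
        the offending line.
    GPRParseError
        Non-numeric value in a numeric column (reports the 1-based data row).
    IntegrityError
        Duplicate (Block, Column, Row) coordinates.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    raw_lines = stream.read().splitlines()
    if len(raw_lines) < 3:
        raise GPRFormatError(f"{source_name}: file too short to be ATF text")

    version_fields = [_unquote(f) for f in raw_lines[0].split("\t")]
    if not version_fields or version_fields[0].upper() != "ATF":
        raise GPRFormatError(
            f"{source_name}: line 1 must start with 'ATF', got {raw_lines[0]!r}"
        )
    atf_version = version_fields[1] if len(version_fields) > 1 else ""

    counts = raw_lines[1].split("\t")
    try:
        n_headers, n_columns = int(_unquote(counts[0])), int(_unquote(counts[1]))
    except (IndexError, ValueError):
        raise GPRFormatError(
            f"{source_name}: line 2 must hold two integers "
            f"(header count, column count), got {raw_lines[1]!r}"
        ) from None

    if len(raw_lines) < 2 + n_headers + 1:
        raise GPRFormatError(
            f"{source_name}: declares {n_headers} header records but the "
            f"file ends at line {len(raw_lines)}"
        )

    header_records: dict[str, str] = {}
    for i in range(n_headers):
        record = _unquote(raw_lines[2 + i])
        m = _HEADER_RECORD_RE.match(record)
        if m is None:
            raise GPRFormatError(
                f"{source_name}: header record on line {3 + i} is not "
                f"'Key=Value': {record!r}"
            )
        header_records[m.group("key")] = m.group("value")

    column_line_idx = 2 + n_headers
    column_names = [c for c in _split_fields(raw_lines[column_line_idx])]
    if len(column_names) != n_columns:
        raise GPRFormatError(
            f"{source_name}: line 2 declares {n_columns} columns but the "
            f"column row has {len(column_names)}"
        )
    missing = [c for c in REQUIRED_COLUMNS if c not in column_names]
    if missing:
        raise GPRFormatError(
            f"{source_name}: required columns missing: {', '.join(missing)}"
        )

    data_lines = [ln for ln in raw_lines[column_line_idx + 1 :] if ln.strip() != ""]
    rows: list[list] = []
    int_cols = set(GEOMETRY_COLUMNS)
    text_cols = set(ANNOTATION_COLUMNS)
    for row_idx, line in enumerate(data_lines, start=1):
        fields = _split_fields(line)
        if len(fields) != n_columns:
            raise GPRParseError(
                f"{source_name}: data row {row_idx} has {len(fields)} fields, "
                f"expected {n_columns}"
            )
        parsed: list = []
        for col, value in zip(column_names, fields):
            if col in text_cols:
                parsed.append(value)
            elif col in int_cols:
                try:
                    parsed.append(int(value))
                except ValueError:
                    raise GPRParseError(
                        f"{source_name}: data row {row_idx}, column {col!r}: "
                        f"expected integer, got {value!r}"
                    ) from None
            else:
                if value.strip() == "":
                    parsed.append(np.nan)
                else:
                    try:
                        parsed.append(float(value))
                    except ValueError:
                        raise GPRParseError(
                            f"{source_name}: data row {row_idx}, column "
                            f"{col!r}: expected number, got {value!r}"
                        ) from None
        rows.append(parsed)

    spots = pd.DataFrame(rows, columns=column_names)
    if len(spots) == 0:
        spots = pd.DataFrame({c: pd.Series(dtype=float) for c in column_names})
        for c in GEOMETRY_COLUMNS:
            spots[c] = spots[c].astype(int)
        for c in ANNOTATION_COLUMNS:
            spots[c] = spots[c].astype(str)
    else:
        for c in GEOMETRY_COLUMNS:
            if (spots[c] < 1).any():
                bad = int(spots.index[spots[c] < 1][0]) + 1
                raise IntegrityError(
                    f"{source_name}: {c} < 1 at data row {bad} (GPR geometry "
                    f"is 1-based)"
                )
        dup = spots.duplicated(subset=list(GEOMETRY_COLUMNS))
        if dup.any():
            b, c, r = spots.loc[dup.idxmax(), list(GEOMETRY_COLUMNS)]
            raise IntegrityError(
                f"{source_name}: duplicate spot coordinates "
                f"(block={b}, column={c}, row={r})"
            )

    return GPRFile(
        source_name=source_name,
        atf_version=atf_version,
        header_records=header_records,
        column_names=column_names,
        spots=spots,
    )


def _format_field(value, is_text: bool) -> str:
    if is_text:
        return '"' + str(value).replace('"', '""') + '"'
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    v = float(value)
    if np.isnan(v):
        return ""
    return format(v, ".10g")


def write_gpr(gpr: GPRFile, sink: TextIO) -> None:
    """Serialize a :class:`GPRFile` as ATF text.

    The output re-parses to a file equal to the input (text fields exactly,
    intensities to better than 1e-6 relative). Text fields are quoted;
    embedded quotes are escaped by doubling.
    """
    sink.write(f"ATF\t{gpr.atf_version}\n")
    sink.write(f"{len(gpr.header_records)}\t{len(gpr.column_names)}\n")
    for key, value in gpr.header_records.items():
        sink.write(f'"{key}={value}"\n')
    sink.write("\t".join(f'"{c}"' for c in gpr.column_names) + "\n")
    text_cols = set(ANNOTATION_COLUMNS)
    for row in gpr.spots.itertuples(index=False):
        fields = [
            _format_field(v, col in text_cols)
            for col, v in zip(gpr.column_names, row)
        ]
        sink.write("\t".join(fields) + "\n")


def validate_consistency(files: Sequence[GPRFile]) -> ColumnCatalog:
    """Check that all files share columns and spot layout.

    All files must have identical column-name lists and identical
    (Block, Column, Row, ID) spot layouts, in the same order — downstream
    replicate averaging assumes aligned layouts. Returns the catalog of the
    shared intensity columns with foreground/background unset.

    Raises
    ------
    ConsistencyError
        Naming the differing files and columns, or the first divergent spot.
    """
    if len(files) == 0:
        raise ConsistencyError("no files given")
    reference = files[0]
    ref_cols = reference.column_names
    mismatches = []
    for f in files[1:]:
        if f.column_names != ref_cols:
            missing = sorted(set(ref_cols) - set(f.column_names))
            extra = sorted(set(f.column_names) - set(ref_cols))
            detail = []
            if missing:
                detail.append(f"missing {missing}")
            if extra:
                detail.append(f"extra {extra}")
            if not detail:
                detail.append("same columns in different order")
            mismatches.append(f"{f.source_name} vs {reference.source_name}: "
                              + "; ".join(detail))
    if mismatches:
        raise ConsistencyError(
            "column headers differ between files: " + " | ".join(mismatches)
        )

    # Layout equality is order-insensitive: assembly aligns spots by their
    # (Block, Column, Row, ID) key, so a permuted export is still consistent.
    ref_layout = sorted(map(tuple, reference.layout_key().itertuples(index=False)))
    for f in files[1:]:
        layout = sorted(map(tuple, f.layout_key().itertuples(index=False)))
        if len(layout) != len(ref_layout):
            raise ConsistencyError(
                f"spot count differs: {reference.source_name} has "
                f"{len(ref_layout)}, {f.source_name} has {len(layout)}"
            )
        for a, b in zip(ref_layout, layout):
            if a != b:
                raise ConsistencyError(
                    f"spot layout diverges: {reference.source_name} has "
                    f"(block, column, row, id)={a} where {f.source_name} "
                    f"has {b}"
                )

    return ColumnCatalog(shared_columns=list(reference.intensity_columns))


#: Platform-specific channel choices tried before the generic pattern; the
#: table is config-editable so new platforms can be added without code.
PLATFORM_CHANNELS: dict[str, tuple[str, str]] = {
    "protoarray": ("F635 Median", "B635 Median"),
    "huprot": ("F635 Median", "B635 Median"),
}

#: Generic fallback: a foreground "F<wavelength> Median"-style column paired
#: with the matching "B<wavelength>"-style background column.
FOREGROUND_RE = re.compile(r"^F(?P<wl>\d+)(?: Median)?$")


def _match_background(columns: Iterable[str], wavelength: str) -> Optional[str]:
    for candidate in (f"B{wavelength} Median", f"B{wavelength}",
                      f"B{wavelength} Mean"):
        if candidate in columns:
            return candidate
    return None


def select_channels(
    catalog: ColumnCatalog,
    platform_hint: Optional[str] = None,
    foreground: Optional[str] = None,
    background: Optional[str] = None,
    platform_channels: Optional[dict[str, tuple[str, str]]] = None,
) -> ColumnCatalog:
    """Choose foreground/background intensity columns.

    Explicit choices always win. Otherwise the platform hint is looked up in
    the platform table (ProtoArray and HuProt ship by default), then the
    generic wavelength pattern is tried: the first ``F<wl> Median`` column
    paired with its ``B<wl>``-style counterpart.

    Raises
    ------
    SelectionError
        If no channel can be chosen; the message lists candidate columns so
        the caller can pick explicitly.
    """
    cols = catalog.shared_columns
    if platform_channels is None:
        platform_channels = PLATFORM_CHANNELS

    for name, role in ((foreground, "foreground"), (background, "background")):
        if name is not None and name not in cols:
            raise SelectionError(
                f"requested {role} column {name!r} is not shared by all "
                f"files; shared intensity columns: {cols}"
            )

    fg, bg = foreground, background
    auto = False
    if fg is not None and bg is None:
        # pair the explicit foreground with its own wavelength's background
        m = FOREGROUND_RE.match(fg)
        if m is not None:
            bg = _match_background(cols, m.group("wl"))
            auto = bg is not None
    if fg is None or bg is None:
        auto_fg = auto_bg = None
        if platform_hint is not None:
            key = platform_hint.strip().lower()
            if key in platform_channels:
                cand_fg, cand_bg = platform_channels[key]
                if cand_fg in cols and cand_bg in cols:
                    auto_fg, auto_bg = cand_fg, cand_bg
        if auto_fg is None:
            # prefer "F<wl> Median" over bare "F<wl>"
            candidates = sorted(
                (c for c in cols if FOREGROUND_RE.match(c)),
                key=lambda c: (0 if c.endswith("Median") else 1, c),
            )
            for c in candidates:
                wl = FOREGROUND_RE.match(c).group("wl")
                b = _match_background(cols, wl)
                if b is not None and b != c:
                    auto_fg, auto_bg = c, b
                    break
        if fg is None:
            fg = auto_fg
        if bg is None:
            bg = auto_bg
        auto = True

    if fg is None or bg is None:
        raise SelectionError(
            "could not auto-detect foreground/background channels; choose "
            f"explicitly from the shared intensity columns: {cols}"
        )
    if fg == bg:
        raise SelectionError(
            f"foreground and background must differ (both {fg!r})"
        )
    return replace(catalog, foreground=fg, background=bg, auto_detected=auto)
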