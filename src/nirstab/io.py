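"""Reading and writing spectra.

Two on-disk formats are supported:

* a canonical CSV dialect — UTF-8, comma separated, header
  ``sample_id,brand,batch_id,role,cup,pair_id,date_index,<w1>,<w2>,...``
  with one spectrum per row and wavenumbers as decimal column labels;
* a strict subset of JCAMP-DX: ``##XYDATA=(X++(Y..Y))`` with AFFN numerals
  and uniform ``DELTAX``.  Anything else (SQZ/DIF/DUP compression, PEAK
  TABLE, non-uniform X) raises rather than misparsing.

Values round-trip bit-exactly through the CSV writer/reader.  Spectra are
stored ascending in wavenumber; JCAMP files with negative DELTAX are
reversed on read.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import FormatError
from .spectra import Cup, Role, Spectrum, SpectrumMeta, SpectrumSet, WavenumberGrid

__all__ = ["read_csv_spectra", "write_csv_spectra", "read_jcamp", "META_COLUMNS"]

META_COLUMNS = ("sample_id", "brand", "batch_id", "role", "cup", "pair_id", "date_index")

#: relative tolerance on wavenumber spacing uniformity
_GRID_RTOL = 1e-9


def _grid_from_header(wavenumbers: Sequence[str], path: Path) -> WavenumberGrid:
    try:
        w = np.array([float(x) for x in wavenumbers])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric wavenumber column label: {exc}") from exc
    if w.size < 2:
        raise FormatError(f"{path}: need at least 2 wavenumber columns, got {w.size}")
    steps = np.diff(w)
    step = steps[0]
    if step <= 0:
        raise FormatError(f"{path}: wavenumber columns must be strictly increasing")
    if np.any(np.abs(steps - step) > _GRID_RTOL * abs(step)):
        bad = int(np.argmax(np.abs(steps - step) > _GRID_RTOL * abs(step)))
        raise FormatError(
            f"{path}: non-uniform wavenumber spacing at column {bad + 1}: "
            f"step {steps[bad]!r} vs {step!r}"
        )
    return WavenumberGrid(start=float(w[0]), step=float(step), n_points=int(w.size))


def read_csv_spectra(path: str | Path, delimiter: str = ",") -> SpectrumSet:
    """Read a SpectrumSet from the canonical CSV dialect.

    The grid is inferred from the wavenumber header columns; spacing that is
    non-uniform beyond 1e-9 of the step is rejected.  Errors name the
    offending column, row or cell.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        for i, col in enumerate(META_COLUMNS):
            if i >= len(header) or header[i] != col:
                raise FormatError(
                    f"{path}: missing or misplaced metadata column {col!r} "
                    f"(header position {i})"
                )
        grid = _grid_from_header(header[len(META_COLUMNS):], path)
        n_cols = len(header)
        spectra: list[Spectrum] = []
        for row_idx, row in enumerate(reader, start=2):
            if len(row) != n_cols:
                raise FormatError(
                    f"{path}: ragged row {row_idx}: expected {n_cols} fields, got {len(row)}"
                )
            sample_id, brand, batch_id, role, cup, pair_id, date_index = row[:7]
            vals = np.empty(grid.n_points)
            for j, cell in enumerate(row[7:]):
                try:
                    vals[j] = float(cell)
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric absorbance at row {row_idx}, "
                        f"column {header[7 + j]!r}: {cell!r}"
                    ) from None
            meta = SpectrumMeta(
                sample_id=sample_id,
                brand=brand or None,
                batch_id=batch_id or None,
                role=Role(role) if role else Role.PRODUCT,
                cup=Cup(cup) if cup else Cup.CLASSICAL,
                pair_id=pair_id or None,
                date_index=int(date_index) if date_index else 0,
            )
            spectra.append(Spectrum(meta=meta, grid=grid, values=vals))
    return SpectrumSet(grid=grid, spectra=spectra)


def write_csv_spectra(spectrum_set: SpectrumSet, path: str | Path) -> Path:
    """Write the canonical dialect; floats use shortest round-trip repr."""
    path = Path(path)
    grid = spectrum_set.grid
    header = list(META_COLUMNS) + [f"{w:.10g}" for w in grid.values]
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for s in spectrum_set:
            m = s.meta
            writer.writerow(
                [
                    m.sample_id,
                    m.brand or "",
                    m.batch_id or "",
                    m.role.value,
                    m.cup.value,
                    m.pair_id or "",
                    str(m.date_index),
                ]
                + [repr(float(v)) for v in s.values]
            )
    return path


# --- JCAMP-DX subset -------------------------------------------------------

_LDR_RE = re.compile(r"^##([^=]+)=\s*(.*)$")
_AFFN_LINE_RE = re.compile(r"^[\s+\-.0-9eE,;]*$")


def read_jcamp(path: str | Path, sample_id: str | None = None) -> Spectrum:
    """Read one spectrum from a JCAMP-DX file (``(X++(Y..Y))``, AFFN only).

    The grid comes from FIRSTX/DELTAX/NPOINTS and Y values are scaled by
    YFACTOR.  Metadata JCAMP cannot represent defaults to role=product,
    cup=classical; callers attach real provenance afterwards via
    :meth:`Spectrum.with_meta`.
    """
    path = Path(path)
    labels: dict[str, str] = {}
    y_raw: list[float] = []
    in_xydata = False
    expected_x = None
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            m = _LDR_RE.match(line)
            if m:
                key = m.group(1).strip().upper().replace(" ", "")
                val = m.group(2).strip()
                if key == "XYDATA":
                    variant = val.replace(" ", "")
                    if variant != "(X++(Y..Y))":
                        raise FormatError(
                            f"{path}: unsupported JCAMP variant XYDATA={val!r}; "
                            "only (X++(Y..Y)) is supported"
                        )
                    in_xydata = True
                elif key == "END":
                    in_xydata = False
                else:
                    if in_xydata:
                        in_xydata = False
                    labels[key] = val
                continue
            if in_xydata:
                if not _AFFN_LINE_RE.match(line):
                    raise FormatError(
                        f"{path}: unsupported JCAMP variant: non-AFFN data line {line!r} "
                        "(SQZ/DIF/DUP compression is not supported)"
                    )
                parts = [p for p in re.split(r"[,;\s]+", line) if p]
                try:
                    nums = [float(p) for p in parts]
                except ValueError as exc:
                    raise FormatError(f"{path}: bad numeral in data line {line!r}") from exc
                if not nums:
                    continue
                x, ys = nums[0], nums[1:]
                if expected_x is not None and abs(x - expected_x) > 1e-6 * max(
                    1.0, abs(expected_x)
                ):
                    raise FormatError(
                        f"{path}: X check failed: expected {expected_x}, line starts at {x}"
                    )
                y_raw.extend(ys)
                deltax = float(labels.get("DELTAX", "0") or 0)
                expected_x = x + deltax * len(ys)

    for required in ("FIRSTX", "DELTAX", "NPOINTS"):
        if required not in labels:
            raise FormatError(f"{path}: missing required JCAMP label ##{required}=")
    firstx = float(labels["FIRSTX"])
    deltax = float(labels["DELTAX"])
    npoints = int(float(labels["NPOINTS"]))
    yfactor = float(labels.get("YFACTOR", "1") or 1)
    if deltax == 0:
        raise FormatError(f"{path}: DELTAX must be non-zero and uniform")
    if len(y_raw) != npoints:
        raise FormatError(
            f"{path}: NPOINTS={npoints} but data table holds {len(y_raw)} Y values"
        )
    values = np.asarray(y_raw) * yfactor
    if deltax < 0:
        values = values[::-1]
        firstx = firstx + deltax * (npoints - 1)
        deltax = -deltax
    grid = WavenumberGrid(start=firstx, step=deltax, n_points=npoints)
    sid = sample_id or labels.get("TITLE", path.stem) or path.stem
    # JCAMP has no brand/batch fields; placeholders satisfy the product-role
    # invariant and are replaced by the caller via with_meta().
    meta = SpectrumMeta(
        sample_id=sid, role=Role.PRODUCT, cup=Cup.CLASSICAL,
        brand=labels.get("BRAND") or "unknown", batch_id=labels.get("BATCH") or "unknown",
    )
    return Spectrum(meta=meta, grid=grid, values=values)
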