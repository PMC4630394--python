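"""Readers and writers for the package's plain-text formats.

Three formats are supported:

* spectra CSV — first column the wavenumber axis (cm^-1), one column per
  sample; canonical orientation is descending (4000 -> 650), ascending
  files are accepted and reversed with a logged notice;
* composition CSV — ``sample_id`` column plus one percent-w/w column per
  constituent from the fixed vocabulary;
* band-assignment TSV — columns ``constituent``, ``center_cm1``,
  ``functional_group``, ``literature_ref`` (optional ``width_cm1``,
  ``amplitude``).

All values round-trip at full float precision (repr round-trip).  A
minimal JCAMP-DX import (single-spectrum AFFN ``(X++(Y..Y))`` data) is
provided as an optional convenience; it is not used by the pipeline.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CONSTITUENTS,
    FormatError,
    SpectraSet,
    WavenumberGrid,
    validate_band_table,
    validate_composition,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_spectra_csv",
    "write_spectra_csv",
    "read_composition_csv",
    "write_composition_csv",
    "read_band_table_tsv",
    "write_band_table_tsv",
    "read_jcamp",
]


def read_spectra_csv(path: str | Path) -> SpectraSet:
    """Read a spectra CSV (wavenumber column first, one column per sample).

    The grid is validated as strictly monotone with uniform spacing;
    ascending files are reversed to the canonical descending order.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    ids = header[1:]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise FormatError(f"duplicated sample id(s) in {path.name}: {dupes}")
    df = pd.read_csv(path)
    if df.isna().any().any():
        raise FormatError(f"missing values in {path.name}")
    wn = df.iloc[:, 0].to_numpy(dtype=float)
    d = np.diff(wn)
    if np.all(d > 0):
        logger.info("ascending wavenumber axis in %s; reversing to descending", path.name)
        df = df.iloc[::-1].reset_index(drop=True)
        wn = wn[::-1]
    elif not np.all(d < 0):
        bad = int(np.argmax(~(d < 0))) + 1 if np.any(d < 0) else 1
        raise FormatError(f"non-monotone wavenumber axis in {path.name} at row {bad + 1}")
    grid = WavenumberGrid(wn)  # raises FormatError on non-uniform spacing
    absorbance = df.iloc[:, 1:].to_numpy(dtype=float).T
    return SpectraSet(grid, absorbance, ids)


def write_spectra_csv(spectra: SpectraSet, path: str | Path) -> None:
    """Write a SpectraSet in the spectra CSV layout at full precision."""
    df = pd.DataFrame({"wavenumber_cm1": spectra.grid.values})
    for i, sid in enumerate(spectra.sample_ids):
        df[sid] = spectra.absorbance[i, :]
    df.to_csv(path, index=False)


def read_composition_csv(path: str | Path) -> pd.DataFrame:
    """Read a composition CSV into a DataFrame indexed by sample id."""
    df = pd.read_csv(path)
    if df.columns[0] != "sample_id":
        raise FormatError(
            f"first column of {Path(path).name} must be 'sample_id', got {df.columns[0]!r}"
        )
    df = df.set_index("sample_id")
    return validate_composition(df)


def write_composition_csv(table: pd.DataFrame, path: str | Path) -> None:
    validate_composition(table)
    table.to_csv(path, index=True, index_label="sample_id")


def read_band_table_tsv(path: str | Path) -> pd.DataFrame:
    """Read and validate a band-assignment TSV."""
    return validate_band_table(pd.read_csv(path, sep="\t"))


def write_band_table_tsv(table: pd.DataFrame, path: str | Path) -> None:
    validate_band_table(table)
    table.to_csv(path, sep="\t", index=False)


def read_jcamp(path: str | Path) -> SpectraSet:
    """Minimal JCAMP-DX reader: single spectrum, AFFN ``(X++(Y..Y))`` only.

    Supports the tabular layout where each data line starts with an X
    value followed by whitespace-separated Y values; Y values are scaled
    by ``##YFACTOR`` and the X axis is rebuilt from ``##FIRSTX``,
    ``##LASTX`` and ``##NPOINTS``.  Compressed (SQZ/DIF/DUP) forms are
    not supported.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    ys: list[float] = []
    in_data = False
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key in ("XYDATA", "DATATABLE"):
                if "(X++(Y..Y))" not in value.replace(" ", ""):
                    raise FormatError(f"unsupported JCAMP data form {value!r}")
                in_data = True
                continue
            if key == "END":
                in_data = False
            meta[key] = value
            continue
        if in_data:
            parts = line.replace(",", " ").split()
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise FormatError(f"non-AFFN JCAMP data line {line!r}") from exc
            ys.extend(vals[1:])  # first entry is the X of the line
    if not ys:
        raise FormatError(f"no XYDATA found in {path.name}")
    try:
        firstx = float(meta["FIRSTX"])
        lastx = float(meta["LASTX"])
    except KeyError as exc:
        raise FormatError("JCAMP file lacks FIRSTX/LASTX") from exc
    npoints = int(float(meta.get("NPOINTS", len(ys))))
    if npoints != len(ys):
        raise FormatError(f"NPOINTS={npoints} but {len(ys)} Y values read")
    yfactor = float(meta.get("YFACTOR", 1.0))
    x = np.linspace(firstx, lastx, npoints)
    y = np.asarray(ys) * yfactor
    if x[0] < x[-1]:  # normalise to descending
        x, y = x[::-1], y[::-1]
    title = meta.get("TITLE", path.stem) or path.stem
    return SpectraSet(WavenumberGrid(x), y[None, :], [title])
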