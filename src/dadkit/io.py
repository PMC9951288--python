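"""Reading and writing HPLC-DAD absorbance matrices.

The package's single in-memory currency is the :class:`Chromatogram`: a
time x wavelength absorbance matrix (mAU) on strictly increasing grids,
plus run metadata.  On disk the canonical interchange format is a plain
CSV with header ``time,<wl1>,<wl2>,...`` and one row per time point
(UTF-8, ``.`` decimal, LF line ends).  Two vendor-style ASCII dialects
are supported as documented stand-ins for common control-software
exports: a comma-separated matrix export with absorbance in AU
(``chemstation_csv``) and a tab-separated block preceded by key:value
metadata lines and a ``[PDA 3D]`` section marker (``shimadzu_txt``).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "RunMeta",
    "Chromatogram",
    "GridError",
    "ParseError",
    "ShapeError",
    "read_vendor_export",
    "write_canonical_csv",
    "write_chemstation_csv",
    "write_shimadzu_txt",
    "validate_grid",
]

RUN_TYPES = ("calibration", "sample", "blank", "simulation")

#: relative tolerance on time-grid spacing before resampling kicks in
GRID_SPACING_TOL = 0.01
#: minimum number of time points for a usable chromatogram
MIN_TIME_POINTS = 8


class ParseError(ValueError):
    """Raised when a vendor export cannot be parsed; names the offending line."""


class GridError(ValueError):
    """Raised for non-monotone or otherwise unusable time/wavelength grids."""


class ShapeError(ValueError):
    """Raised for ragged or inconsistent matrix shapes."""


@dataclass
class RunMeta:
    """Metadata attached to one chromatographic run."""

    run_id: str = ""
    run_type: str = "sample"
    compound: Optional[str] = None
    concentration: Optional[float] = None
    istd: bool = False
    istd_concentration: Optional[float] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.run_type not in RUN_TYPES:
            raise ValueError(
                f"run_type must be one of {RUN_TYPES}, got {self.run_type!r}"
            )


@dataclass
class Chromatogram:
    """One run's time x wavelength absorbance matrix.

    Parameters
    ----------
    time : ndarray
        Retention times in minutes, strictly increasing, near-uniform.
    wavelength : ndarray
        Detection wavelengths in nm, strictly increasing.
    absorbance : ndarray, shape (n_time, n_wavelength)
        Absorbance in mAU.
    meta : RunMeta
        Run identity and campaign role.
    """

    time: np.ndarray
    wavelength: np.ndarray
    absorbance: np.ndarray
    meta: RunMeta = field(default_factory=RunMeta)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ShapeError("absorbance must be a 2-D matrix")
        nt, nw = self.absorbance.shape
        if nt != self.time.size:
            raise ShapeError(
                f"matrix has {nt} rows but time grid has {self.time.size} points"
            )
        if nw != self.wavelength.size:
            raise ShapeError(
                f"matrix has {nw} columns but wavelength grid has "
                f"{self.wavelength.size} points"
            )
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise GridError("time grid is not strictly increasing")
        if self.wavelength.size > 1 and not np.all(np.diff(self.wavelength) > 0):
            raise GridError("wavelength grid is not strictly increasing")
        if not (
            np.all(np.isfinite(self.time))
            and np.all(np.isfinite(self.wavelength))
            and np.all(np.isfinite(self.absorbance))
        ):
            raise ValueError("chromatogram contains non-finite values")

    @property
    def n_time(self) -> int:
        return self.time.size

    @property
    def n_wavelength(self) -> int:
        return self.wavelength.size

    @property
    def dt(self) -> float:
        """Median time spacing in minutes."""
        return float(np.median(np.diff(self.time)))

    def copy_with(self, **kwargs) -> "Chromatogram":
        """Return a copy with some fields replaced (arrays are not copied)."""
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# parsing


def _parse_float(token: str, lineno: int, path: str) -> float:
    try:
        return float(token)
    except ValueError as exc:
        raise ParseError(
            f"{path}: line {lineno}: cannot parse {token!r} as a number"
        ) from exc


def _read_matrix_lines(lines, sep, path, start_lineno):
    """Parse ``time<sep>a1<sep>a2...`` rows into (time, matrix)."""
    times = []
    rows = []
    width = None
    for off, line in enumerate(lines):
        lineno = start_lineno + off
        line = line.strip()
        if not line:
            continue
        tokens = line.split(sep)
        if width is None:
            width = len(tokens)
        elif len(tokens) != width:
            raise ShapeError(
                f"{path}: line {lineno}: ragged row ({len(tokens)} fields, "
                f"expected {width})"
            )
        values = [_parse_float(t, lineno, path) for t in tokens]
        times.append(values[0])
        rows.append(values[1:])
    if not rows:
        raise ParseError(f"{path}: no data rows found")
    return np.asarray(times), np.asarray(rows)


def _parse_header_wavelengths(header: str, sep: str, path: str) -> np.ndarray:
    tokens = [t.strip() for t in header.strip().split(sep)]
    if len(tokens) < 2:
        raise ParseError(f"{path}: line 1: header has no wavelength columns")
    return np.asarray([_parse_float(t, 1, path) for t in tokens[1:]])


def _read_canonical_csv(path: Path, meta: RunMeta) -> Chromatogram:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.lower().startswith("time"):
            raise ParseError(f"{path}: line 1: expected header starting with 'time'")
        wl = _parse_header_wavelengths(header, ",", str(path))
        time, matrix = _read_matrix_lines(fh, ",", str(path), 2)
    return Chromatogram(time, wl, matrix, meta)


def _read_chemstation_csv(path: Path, meta: RunMeta) -> Chromatogram:
    """Comma-separated matrix export; absorbance stored in AU -> x1000."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        wl = _parse_header_wavelengths(header, ",", str(path))
        time, matrix = _read_matrix_lines(fh, ",", str(path), 2)
    return Chromatogram(time, wl, matrix * 1000.0, meta)


def _read_shimadzu_txt(path: Path, meta: RunMeta) -> Chromatogram:
    """Tab-separated PDA block preceded by ``key: value`` metadata lines."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    marker = None
    for i, line in enumerate(lines):
        if line.strip().startswith("[PDA 3D]"):
            marker = i
            break
    if marker is None:
        raise ParseError(f"{path}: no '[PDA 3D]' section marker found")
    for line in lines[:marker]:
        if ":" in line:
            key, _, value = line.partition(":")
            meta.extras.setdefault(key.strip(), value.strip())
    body = lines[marker + 1 :]
    if not body:
        raise ParseError(f"{path}: line {marker + 2}: empty PDA block")
    wl = _parse_header_wavelengths(body[0], "\t", str(path))
    time, matrix = _read_matrix_lines(body[1:], "\t", str(path), marker + 3)
    return Chromatogram(time, wl, matrix, meta)


_DIALECTS = {
    "canonical_csv": _read_canonical_csv,
    "chemstation_csv": _read_chemstation_csv,
    "shimadzu_txt": _read_shimadzu_txt,
}


def read_vendor_export(
    path, dialect: str = "canonical_csv", meta: Optional[RunMeta] = None
) -> Chromatogram:
    """Parse a vendor ASCII/CSV export into a :class:`Chromatogram`.

    Parameters
    ----------
    path : path-like
        File to read.
    dialect : {"canonical_csv", "chemstation_csv", "shimadzu_txt"}
        Export layout.  ``chemstation_csv`` stores absorbance in AU and is
        converted to mAU on read; the other dialects store mAU.
    meta : RunMeta, optional
        Metadata attached to the parsed run (defaults to an anonymous
        sample run named after the file stem).
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    if meta is None:
        meta = RunMeta(run_id=path.stem)
    return _DIALECTS[dialect](path, meta)


# ---------------------------------------------------------------------------
# writing


def write_canonical_csv(chrom: Chromatogram, path) -> None:
    """Write the canonical open CSV; lossless to >= 9 significant digits."""
    path = Path(path)
    buf = _io.StringIO()
    buf.write("time," + ",".join(f"{w:.12g}" for w in chrom.wavelength) + "\n")
    for t, row in zip(chrom.time, chrom.absorbance):
        buf.write(f"{t:.12g}," + ",".join(f"{v:.12g}" for v in row) + "\n")
    path.write_text(buf.getvalue(), encoding="utf-8", newline="\n")


def write_chemstation_csv(chrom: Chromatogram, path) -> None:
    """Write the ChemStation-style dialect (absorbance in AU)."""
    path = Path(path)
    buf = _io.StringIO()
    buf.write(
        "Time (min)," + ",".join(f"{w:.12g}" for w in chrom.wavelength) + "\n"
    )
    for t, row in zip(chrom.time, chrom.absorbance):
        buf.write(f"{t:.12g}," + ",".join(f"{v / 1000.0:.12g}" for v in row) + "\n")
    path.write_text(buf.getvalue(), encoding="utf-8", newline="\n")


def write_shimadzu_txt(chrom: Chromatogram, path) -> None:
    """Write the LabSolutions-style dialect (tab-separated PDA block)."""
    path = Path(path)
    buf = _io.StringIO()
    buf.write(f"Sample Name: {chrom.meta.run_id}\n")
    buf.write("Detector: PDA\n")
    buf.write("[PDA 3D]\n")
    buf.write("R.Time (min)\t" + "\t".join(f"{w:.12g}" for w in chrom.wavelength) + "\n")
    for t, row in zip(chrom.time, chrom.absorbance):
        buf.write(f"{t:.12g}\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")
    path.write_text(buf.getvalue(), encoding="utf-8", newline="\n")


# ---------------------------------------------------------------------------
# grid validation


def validate_grid(chrom: Chromatogram) -> Chromatogram:
    """Check time-grid uniformity; resample by linear interpolation if needed.

    The time grid is accepted as-is when every successive spacing deviates
    from the median spacing by at most 1%.  Otherwise the matrix is
    resampled column-wise onto a uniform grid spanning the same interval,
    and ``meta.extras['resampled']`` is set.
    """
    if chrom.n_time < MIN_TIME_POINTS:
        raise GridError(
            f"time grid too short ({chrom.n_time} points, need >= {MIN_TIME_POINTS})"
        )
    spacing = np.diff(chrom.time)
    med = np.median(spacing)
    if np.max(np.abs(spacing - med)) <= GRID_SPACING_TOL * med:
        return chrom
    uniform = np.linspace(chrom.time[0], chrom.time[-1], chrom.n_time)
    resampled = np.empty_like(chrom.absorbance)
    for j in range(chrom.n_wavelength):
        resampled[:, j] = np.interp(uniform, chrom.time, chrom.absorbance[:, j])
    meta = replace(chrom.meta, extras={**chrom.meta.extras, "resampled": True})
    return Chromatogram(uniform, chrom.wavelength.copy(), resampled, meta)
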