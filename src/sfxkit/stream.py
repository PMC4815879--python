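"""Reading and writing the per-crystal text "stream" dialect and hkl tables.

The stream dialect is a documented subset of the text format produced by
serial-crystallography indexing pipelines: chunks delimited by
``----- Begin chunk -----`` / ``----- End chunk -----``, one optional peak
list and zero or more crystals per chunk, each crystal carrying its unit
cell, oriented reciprocal basis, profile radius, optional resolution
estimate and a reflection table.  Basis vectors are stored in nm^-1 and
cell lengths in nm (converted to SI on read).  Unknown lines are preserved
verbatim so that streams can be passed through without information loss.

Intensities may legitimately be negative (background subtraction); the
parser never clamps them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .core import Crystal, Peaks, Reflections, UnitCell
from .symmetry import SymmetryGroup, get_pointgroup

log = logging.getLogger(__name__)

CHUNK_BEGIN = "----- Begin chunk -----"
CHUNK_END = "----- End chunk -----"
CRYSTAL_BEGIN = "--- Begin crystal"
CRYSTAL_END = "--- End crystal"
PEAKS_BEGIN = "Peaks from peak search"
PEAKS_END = "End of peak list"
REFL_BEGIN = "Reflections measured after indexing"
REFL_END = "End of reflections"

_REFL_HEADER = ("   h    k    l          I   sigma(I)       peak "
                "background   fs/px   ss/px panel")
_PEAK_HEADER = "   fs/px   ss/px    intensity panel"


class StreamParseError(ValueError):
    """Malformed stream or hkl file; message carries the line number."""


@dataclass
class Chunk:
    """One detector frame: peaks plus zero or more indexed crystals."""

    frame_id: str
    peaks: Optional[Peaks] = None
    crystals: List[Crystal] = field(default_factory=list)
    extra_lines: List[str] = field(default_factory=list)


@dataclass
class Stream:
    chunks: List[Chunk] = field(default_factory=list)
    header_lines: List[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.chunks)

    @property
    def crystals(self) -> List[Crystal]:
        return [cr for ch in self.chunks for cr in ch.crystals]


def _default_header() -> List[str]:
    from . import __version__
    return [f"Stream written by sfxkit {__version__}"]


def geometry_header_line(geom) -> str:
    """One self-contained header line carrying the detector geometry."""
    return ("geometry: wavelength = %.6e m; camera_length = %.6e m; "
            "pixel_size = %.6e m; beam_centre = %.4f %.4f px; "
            "panel = %d %d px"
            % (geom.wavelength, geom.camera_length, geom.pixel_size,
               geom.beam_centre[0], geom.beam_centre[1],
               geom.panel_shape[0], geom.panel_shape[1]))


def geometry_from_stream(stream: "Stream"):
    """Recover the Geometry from a stream header; None if absent."""
    from .core import Geometry
    for line in stream.header_lines:
        if line.startswith("geometry:"):
            fields = dict(part.split("=") for part in line[9:].split(";"))
            vals = {k.strip(): v.split()[: -1] for k, v in fields.items()}
            return Geometry(
                wavelength=float(vals["wavelength"][0]),
                camera_length=float(vals["camera_length"][0]),
                pixel_size=float(vals["pixel_size"][0]),
                beam_centre=(float(vals["beam_centre"][0]),
                             float(vals["beam_centre"][1])),
                panel_shape=(int(vals["panel"][0]), int(vals["panel"][1])))
    return None


# ---------------------------------------------------------------------------
# stream reading


class _Lines:
    def __init__(self, path):
        with open(path, "r", encoding="utf-8") as fh:
            self.lines = fh.read().splitlines()
        self.i = 0

    def next(self):
        if self.i >= len(self.lines):
            return None
        line = self.lines[self.i]
        self.i += 1
        return line

    @property
    def lineno(self) -> int:
        return self.i


def read_stream(path) -> Stream:
    """Parse a stream file; crystals without a cell or basis are skipped."""
    src = _Lines(path)
    stream = Stream()
    in_header = True
    while True:
        line = src.next()
        if line is None:
            break
        if line.strip() == CHUNK_END:
            raise StreamParseError(f"line {src.lineno}: chunk end without begin")
        if line.strip() == CHUNK_BEGIN:
            in_header = False
            stream.chunks.append(_read_chunk(src))
        elif in_header:
            stream.header_lines.append(line)
        elif line.strip():
            raise StreamParseError(f"line {src.lineno}: unexpected content "
                                   f"between chunks: {line!r}")
    return stream


def _read_chunk(src: _Lines) -> Chunk:
    chunk = Chunk(frame_id="")
    while True:
        line = src.next()
        if line is None:
            raise StreamParseError(f"line {src.lineno}: unterminated chunk")
        stripped = line.strip()
        if stripped == CHUNK_END:
            return chunk
        if stripped == CHUNK_BEGIN:
            raise StreamParseError(f"line {src.lineno}: nested chunk begin")
        if stripped.startswith("Image filename:"):
            chunk.frame_id = stripped.split(":", 1)[1].strip()
        elif stripped == PEAKS_BEGIN:
            chunk.peaks = _read_peaks(src)
        elif stripped == CRYSTAL_BEGIN:
            crystal = _read_crystal(src, chunk.frame_id)
            if crystal is not None:
                chunk.crystals.append(crystal)
        else:
            chunk.extra_lines.append(line)


def _read_peaks(src: _Lines) -> Peaks:
    fs, ss, inten, panel = [], [], [], []
    first = True
    while True:
        line = src.next()
        if line is None:
            raise StreamParseError(f"line {src.lineno}: unterminated peak list")
        if line.strip() == PEAKS_END:
            break
        if first:  # column header
            first = False
            continue
        parts = line.split()
        if len(parts) < 3:
            raise StreamParseError(f"line {src.lineno}: bad peak line {line!r}")
        fs.append(float(parts[0]))
        ss.append(float(parts[1]))
        inten.append(float(parts[2]))
        panel.append(parts[3] if len(parts) > 3 else "p0")
    return Peaks(np.array(fs), np.array(ss), np.array(inten), panel)


def _parse_vec(line: str, lineno: int) -> np.ndarray:
    # "astar = +0.1234567 +0.0000000 +0.0000000 nm^-1"
    try:
        parts = line.split("=", 1)[1].split()
        return np.array([float(x) for x in parts[:3]]) * 1e9  # nm^-1 -> m^-1
    except (IndexError, ValueError) as exc:
        raise StreamParseError(f"line {lineno}: bad basis vector {line!r}") from exc


def _read_crystal(src: _Lines, frame_id: str) -> Optional[Crystal]:
    cell = None
    centring = "P"
    vecs: Dict[str, np.ndarray] = {}
    profile_radius = None
    resolution_estimate = None
    refl: Optional[Reflections] = None
    extra: List[str] = []
    cell_params = None
    while True:
        line = src.next()
        if line is None:
            raise StreamParseError(f"line {src.lineno}: unterminated crystal")
        stripped = line.strip()
        if stripped.startswith(CRYSTAL_END):
            break
        if stripped.startswith("Cell parameters"):
            parts = stripped.replace(",", " ").split()
            try:
                a, b, c = (float(x) * 10.0 for x in parts[2:5])  # nm -> A
                al, be, ga = (float(x) for x in parts[6:9])
            except (IndexError, ValueError) as exc:
                raise StreamParseError(
                    f"line {src.lineno}: bad cell line {line!r}") from exc
            cell_params = (a, b, c, al, be, ga)
        elif stripped.startswith("centering ="):
            centring = stripped.split("=", 1)[1].strip()
        elif stripped.startswith(("astar =", "bstar =", "cstar =")):
            vecs[stripped[:5]] = _parse_vec(stripped, src.lineno)
        elif stripped.startswith("profile_radius ="):
            profile_radius = float(stripped.split("=")[1].split()[0]) * 1e9
        elif stripped.startswith("diffraction_resolution_limit ="):
            resolution_estimate = float(stripped.split("=")[1].split()[0]) * 1e9
        elif stripped == REFL_BEGIN:
            refl = _read_reflections(src)
        else:
            extra.append(line)

    if cell_params is None or len(vecs) != 3:
        log.warning("crystal in frame %r lacks cell or basis; skipped", frame_id)
        return None
    cell = UnitCell(*cell_params, centring=centring)
    basis = np.vstack([vecs["astar"], vecs["bstar"], vecs["cstar"]])
    if refl is None:
        refl = Reflections(np.empty((0, 3), dtype=int), [], [])
    return Crystal(cell=cell, basis=basis, reflections=refl,
                   profile_radius=profile_radius if profile_radius else 2e7,
                   resolution_estimate=resolution_estimate,
                   frame_id=frame_id, extra_lines=extra)


def _read_reflections(src: _Lines) -> Reflections:
    rows = []
    panels = []
    first = True
    while True:
        line = src.next()
        if line is None:
            raise StreamParseError(f"line {src.lineno}: unterminated reflection list")
        if line.strip() == REFL_END:
            break
        if first:
            first = False
            continue
        parts = line.split()
        if len(parts) < 9:
            raise StreamParseError(f"line {src.lineno}: bad reflection {line!r}")
        try:
            rows.append([float(x) for x in parts[:9]])
        except ValueError as exc:
            raise StreamParseError(f"line {src.lineno}: bad reflection {line!r}") from exc
        panels.append(parts[9] if len(parts) > 9 else "p0")
    if not rows:
        return Reflections(np.empty((0, 3), dtype=int), [], [])
    arr = np.array(rows)
    return Reflections(arr[:, :3].astype(int), arr[:, 3], arr[:, 4],
                       peak=arr[:, 5], background=arr[:, 6],
                       fs=arr[:, 7], ss=arr[:, 8], panel=panels)


# ---------------------------------------------------------------------------
# stream writing


def _write_crystal(out, cr: Crystal) -> None:
    out.append(CRYSTAL_BEGIN)
    c = cr.cell
    out.append("Cell parameters %.5f %.5f %.5f nm, %.5f %.5f %.5f deg"
               % (c.a / 10, c.b / 10, c.c / 10, c.alpha, c.beta, c.gamma))
    out.append("centering = %s" % c.centring)
    for name, vec in zip(("astar", "bstar", "cstar"), cr.basis):
        out.append("%s = %+.7f %+.7f %+.7f nm^-1"
                   % (name, vec[0] / 1e9, vec[1] / 1e9, vec[2] / 1e9))
    out.append("profile_radius = %.5f nm^-1" % (cr.profile_radius / 1e9))
    if cr.resolution_estimate is not None:
        out.append("diffraction_resolution_limit = %.5f nm^-1"
                   % (cr.resolution_estimate / 1e9))
    out.extend(cr.extra_lines)
    refl = cr.reflections
    out.append(REFL_BEGIN)
    out.append(_REFL_HEADER)
    n = len(refl)
    peak = refl.peak if refl.peak is not None else np.zeros(n)
    background = refl.background if refl.background is not None else np.zeros(n)
    fs = refl.fs if refl.fs is not None else np.zeros(n)
    ss = refl.ss if refl.ss is not None else np.zeros(n)
    panel = refl.panel if refl.panel is not None else ["p0"] * n
    for i in range(n):
        h, k, l = refl.hkl[i]
        out.append("%4d %4d %4d %10.2f %10.2f %10.2f %10.2f %8.2f %8.2f %s"
                   % (h, k, l, refl.I[i], refl.sigma[i], peak[i],
                      background[i], fs[i], ss[i], panel[i]))
    out.append(REFL_END)
    out.append(CRYSTAL_END)


def write_stream(stream: Stream, path) -> None:
    """Write a stream with deterministic formatting (round-trip stable)."""
    out: List[str] = []
    out.extend(stream.header_lines if stream.header_lines else _default_header())
    for chunk in stream.chunks:
        out.append(CHUNK_BEGIN)
        out.append("Image filename: %s" % chunk.frame_id)
        out.extend(chunk.extra_lines)
        if chunk.peaks is not None:
            out.append(PEAKS_BEGIN)
            out.append(_PEAK_HEADER)
            for i in range(len(chunk.peaks)):
                out.append("%8.2f %8.2f %12.2f %s"
                           % (chunk.peaks.fs[i], chunk.peaks.ss[i],
                              chunk.peaks.intensity[i], chunk.peaks.panel[i]))
            out.append(PEAKS_END)
        for cr in chunk.crystals:
            _write_crystal(out, cr)
        out.append(CHUNK_END)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# merged hkl tables


@dataclass
class MergedDataset:
    """Symmetry-unique reflections with merged intensities.

    ``table`` maps canonical (h, k, l) to (I_mean, sigma_mean, n_meas).
    """

    table: Dict[tuple, tuple]
    symmetry: SymmetryGroup
    cell: Optional[UnitCell] = None

    def __len__(self) -> int:
        return len(self.table)

    def arrays(self):
        """(hkl (N,3) int, I, sigma, nmeas) in deterministic (sorted) order."""
        keys = sorted(self.table)
        hkl = np.array(keys, dtype=int).reshape(-1, 3)
        vals = np.array([self.table[k] for k in keys], dtype=float).reshape(-1, 3)
        return hkl, vals[:, 0], vals[:, 1], vals[:, 2].astype(int)


def write_hkl(dataset: MergedDataset, path) -> None:
    out = ["Reflection list: merged intensities",
           "Symmetry: %s" % dataset.symmetry.label,
           "   h    k    l          I    phase   sigma(I)   nmeas"]
    hkl, I, sigma, nmeas = dataset.arrays()
    for i in range(len(hkl)):
        out.append("%4d %4d %4d %10.2f        - %10.2f %7d"
                   % (hkl[i, 0], hkl[i, 1], hkl[i, 2], I[i], sigma[i], nmeas[i]))
    out.append(REFL_END)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(out) + "\n")


def read_hkl(path, cell: Optional[UnitCell] = None) -> MergedDataset:
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    symmetry = get_pointgroup("1")
    table: Dict[tuple, tuple] = {}
    seen_end = False
    for lineno, line in enumerate(lines, 1):
        stripped = line.strip()
        if not stripped or stripped.startswith("Reflection list"):
            continue
        if stripped.startswith("Symmetry:"):
            label = stripped.split(":", 1)[1].strip()
            try:
                symmetry = get_pointgroup(label)
            except KeyError:
                log.warning("unknown symmetry %r in %s; using '1'", label, path)
            continue
        if stripped.split()[0] == "h":
            continue
        if stripped == REFL_END:
            seen_end = True
            break
        parts = stripped.split()
        if len(parts) < 7:
            raise StreamParseError(f"line {lineno}: bad hkl row {line!r}")
        key = (int(parts[0]), int(parts[1]), int(parts[2]))
        if key in table:
            raise StreamParseError(f"line {lineno}: duplicate reflection {key}")
        table[key] = (float(parts[3]), float(parts[5]), int(parts[6]))
    if not seen_end:
        raise StreamParseError("hkl file missing 'End of reflections' marker")
    return MergedDataset(table, symmetry, cell)


# ---------------------------------------------------------------------------
# dataset-identifier split lists


def read_split_list(path) -> Dict[str, str]:
    """Map frame_id -> dataset label; duplicate conflicting entries are errors."""
    mapping: Dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 2:
                raise StreamParseError(
                    f"line {lineno}: expected 'frame_id label', got {line!r}")
            frame_id, label = parts
            if frame_id in mapping and mapping[frame_id] != label:
                raise StreamParseError(
                    f"line {lineno}: conflicting labels for {frame_id!r}")
            mapping[frame_id] = label
    return mapping
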