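"""Core crystallographic types and reciprocal-space geometry.

Conventions used throughout the package:

* reciprocal vectors follow the crystallographic ``1/d`` convention (no
  factor of 2*pi); ``|q| = 1/d`` and ``s = sin(theta)/lambda = |q|/2``,
* all internal lengths are SI (metres and reciprocal metres); unit-cell
  parameters are expressed in Angstroms and degrees at the API surface
  because that is what crystallographers read,
* the incident beam travels along +z and the (single-panel) detector is
  perpendicular to it at distance ``camera_length``,
* pixel coordinates are 0-based with pixel centres at integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

ANGSTROM = 1e-10  # m

CENTRINGS = frozenset("PABCIFHR")


class DegenerateCellError(ValueError):
    """Raised when unit-cell parameters do not define a positive volume."""


@dataclass(frozen=True)
class UnitCell:
    """Real-space unit cell: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    centring: str = "P"

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise DegenerateCellError(
                f"cell lengths must be positive, got {(self.a, self.b, self.c)}"
            )
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise DegenerateCellError(f"{name}={ang} deg outside (0, 180)")
        if self.centring not in CENTRINGS:
            raise DegenerateCellError(f"unknown centring {self.centring!r}")
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        disc = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if disc <= 0.0:
            raise DegenerateCellError(
                "cell angles do not define a positive volume "
                f"({self.alpha}, {self.beta}, {self.gamma})"
            )

    @property
    def volume(self) -> float:
        """Cell volume in cubic Angstrom."""
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        disc = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        return self.a * self.b * self.c * float(np.sqrt(disc))

    def direct_matrix(self) -> np.ndarray:
        """3x3 matrix whose rows are the real-space basis vectors in metres."""
        a, b, c = self.a * ANGSTROM, self.b * ANGSTROM, self.c * ANGSTROM
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = np.sin(np.radians(self.gamma))
        av = np.array([a, 0.0, 0.0])
        bv = np.array([b * cg, b * sg, 0.0])
        cx = c * cb
        cy = c * (ca - cb * cg) / sg
        cz2 = c * c - cx * cx - cy * cy
        if cz2 <= 0:
            raise DegenerateCellError("cell angles incompatible with a real c axis")
        cv = np.array([cx, cy, np.sqrt(cz2)])
        return np.vstack([av, bv, cv])


def reciprocal_from_cell(cell: UnitCell, orientation: Optional[np.ndarray] = None) -> np.ndarray:
    """Oriented reciprocal basis of a crystal.

    Returns a 3x3 array whose *rows* are a*, b*, c* in reciprocal metres
    (1/d convention).  ``orientation`` is a proper rotation matrix applied
    to every basis vector; identity if omitted.
    """
    A = cell.direct_matrix()
    B = np.linalg.inv(A).T  # rows satisfy  b_i . a_j = delta_ij
    if orientation is not None:
        R = np.asarray(orientation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-9) \
                or np.linalg.det(R) < 0:
            raise ValueError("orientation must be a proper rotation matrix")
        B = B @ R.T  # rotate each row vector
    return B


def cell_from_reciprocal(basis: np.ndarray, centring: str = "P") -> UnitCell:
    """Recover unit-cell parameters from an (arbitrarily oriented) reciprocal basis."""
    B = np.asarray(basis, dtype=float)
    if B.shape != (3, 3) or abs(np.linalg.det(B)) < 1e-40:
        raise DegenerateCellError("reciprocal basis is singular")
    A = np.linalg.inv(B.T)  # rows are the real-space vectors (m)
    lengths = np.linalg.norm(A, axis=1)
    a, b, c = lengths / ANGSTROM

    def angle(u, v):
        return float(np.degrees(np.arccos(np.clip(
            np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0))))

    return UnitCell(a, b, c,
                    angle(A[1], A[2]), angle(A[0], A[2]), angle(A[0], A[1]),
                    centring)


def resolution_1_over_d(hkl, basis_or_cell) -> np.ndarray:
    """|q| = 1/d in reciprocal metres for one or many Miller index triples."""
    if isinstance(basis_or_cell, UnitCell):
        B = reciprocal_from_cell(basis_or_cell)
    else:
        B = np.asarray(basis_or_cell, dtype=float)
    hkl = np.asarray(hkl, dtype=float)
    q = hkl @ B  # rows of B are a*,b*,c*
    return np.linalg.norm(q, axis=-1)


def excitation_error(q, wavelength: float) -> np.ndarray:
    """Signed distance of reciprocal point(s) q from the Ewald sphere.

    With k = 1/lambda and the beam along +z the sphere is centred at
    -k z-hat; the value is |q + k z| - k: negative inside the sphere,
    positive outside, zero exactly at the Bragg condition.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    k = 1.0 / wavelength
    q = np.asarray(q, dtype=float)
    shifted = q.copy()
    shifted[..., 2] += k
    return np.linalg.norm(shifted, axis=-1) - k


@dataclass(frozen=True)
class Geometry:
    """Single flat detector panel perpendicular to the beam."""

    wavelength: float          # m
    camera_length: float       # m
    pixel_size: float          # m
    beam_centre: tuple = (0.0, 0.0)   # (cx, cy) pixels
    panel_shape: tuple = (2048, 2048)  # (nfs, nss) pixels

    def __post_init__(self):
        for name in ("wavelength", "camera_length", "pixel_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def detector_position(q, geometry: Geometry):
    """Project reciprocal point(s) onto the detector.

    Gnomonic projection of the scattered direction q + k z-hat onto the
    plane z = camera_length.  Returns (fs, ss, valid); rays with
    non-positive z-component are unpredictable and flagged invalid.
    """
    k = 1.0 / geometry.wavelength
    q = np.asarray(q, dtype=float)
    s = q.copy()
    s[..., 2] += k
    sz = s[..., 2]
    valid = sz > 1e-12 * k
    with np.errstate(divide="ignore", invalid="ignore"):
        x = geometry.camera_length * s[..., 0] / sz
        y = geometry.camera_length * s[..., 1] / sz
    fs = geometry.beam_centre[0] + x / geometry.pixel_size
    ss = geometry.beam_centre[1] + y / geometry.pixel_size
    return fs, ss, valid


def back_project(fs, ss, geometry: Geometry) -> np.ndarray:
    """Reciprocal-space position of detector coordinates (inverse of projection)."""
    fs = np.asarray(fs, dtype=float)
    ss = np.asarray(ss, dtype=float)
    x = (fs - geometry.beam_centre[0]) * geometry.pixel_size
    y = (ss - geometry.beam_centre[1]) * geometry.pixel_size
    d = np.stack([x, y, np.broadcast_to(geometry.camera_length, x.shape)], axis=-1)
    d = d / np.linalg.norm(d, axis=-1, keepdims=True)
    k = 1.0 / geometry.wavelength
    q = k * d
    q[..., 2] -= k
    return q


# ---------------------------------------------------------------------------
# Reflection containers


@dataclass
class Reflections:
    """Column-oriented list of reflection observations for one crystal."""

    hkl: np.ndarray                      # (N, 3) int
    I: np.ndarray                        # intensities (may be negative)
    sigma: np.ndarray
    p: Optional[np.ndarray] = None       # partiality in [0, 1]
    r: Optional[np.ndarray] = None       # excitation error, m^-1
    fs: Optional[np.ndarray] = None
    ss: Optional[np.ndarray] = None
    peak: Optional[np.ndarray] = None    # pass-through stream columns
    background: Optional[np.ndarray] = None
    panel: Optional[list] = None
    free: Optional[np.ndarray] = None    # bool: held out of scaling fits
    saturated: Optional[np.ndarray] = None

    def __post_init__(self):
        self.hkl = np.atleast_2d(np.asarray(self.hkl, dtype=int))
        n = len(self.hkl)
        self.I = np.asarray(self.I, dtype=float).reshape(n)
        self.sigma = np.asarray(self.sigma, dtype=float).reshape(n)
        for name in ("p", "r", "fs", "ss", "peak", "background"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float).reshape(n))
        for name in ("free", "saturated"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=bool).reshape(n))

    def __len__(self) -> int:
        return len(self.hkl)

    def select(self, mask) -> "Reflections":
        kw = {}
        for name in ("p", "r", "fs", "ss", "peak", "background", "free", "saturated"):
            v = getattr(self, name)
            if v is not None:
                kw[name] = v[mask]
        panel = None
        if self.panel is not None:
            panel = [x for x, m in zip(self.panel, np.asarray(mask).tolist()) if m] \
                if np.asarray(mask).dtype == bool else [self.panel[i] for i in mask]
        return Reflections(self.hkl[mask], self.I[mask], self.sigma[mask],
                           panel=panel, **kw)

    def copy(self) -> "Reflections":
        return self.select(np.ones(len(self), dtype=bool))


@dataclass
class Peaks:
    """Unindexed detector spots found by the peak search."""

    fs: np.ndarray
    ss: np.ndarray
    intensity: np.ndarray
    panel: list = field(default_factory=list)

    def __post_init__(self):
        self.fs = np.atleast_1d(np.asarray(self.fs, dtype=float))
        self.ss = np.atleast_1d(np.asarray(self.ss, dtype=float))
        self.intensity = np.atleast_1d(np.asarray(self.intensity, dtype=float))
        if not self.panel:
            self.panel = ["p0"] * len(self.fs)

    def __len__(self) -> int:
        return len(self.fs)


@dataclass
class Crystal:
    """One indexed crystal: oriented basis plus its reflection list."""

    cell: UnitCell
    basis: np.ndarray                       # rows a*, b*, c* in m^-1
    reflections: Reflections
    profile_radius: float = 2e7             # m^-1
    resolution_estimate: Optional[float] = None  # m^-1
    G: float = 1.0                          # linear scale
    B: float = 0.0                          # Debye-Waller term, A^2
    assignment: int = 0                     # indexing-ambiguity label
    frame_id: str = ""
    extra_lines: list = field(default_factory=list)  # pass-through stream lines

    def __post_init__(self):
        self.basis = np.asarray(self.basis, dtype=float).reshape(3, 3)
        if self.profile_radius <= 0:
            raise ValueError("profile_radius must be positive")

    def copy(self) -> "Crystal":
        return replace(self, basis=self.basis.copy(),
                       reflections=self.reflections.copy(),
                       extra_lines=list(self.extra_lines))


def enumerate_hkl_sphere(basis: np.ndarray, q_max: float) -> np.ndarray:
    """All integer Miller triples (excluding 000) with 1/d <= q_max."""
    B = np.asarray(basis, dtype=float)
    # safe index bounds from the real-space vector lengths: |h| <= |a| * q_max
    A = np.linalg.inv(B.T)
    lim = np.floor(np.linalg.norm(A, axis=1) * q_max).astype(int) + 1
    h = np.arange(-lim[0], lim[0] + 1)
    k = np.arange(-lim[1], lim[1] + 1)
    l = np.arange(-lim[2], lim[2] + 1)
    grid = np.stack(np.meshgrid(h, k, l, indexing="ij"), axis=-1).reshape(-1, 3)
    qn = np.linalg.norm(grid @ B, axis=1)
    keep = (qn <= q_max) & (qn > 0)
    return grid[keep]
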