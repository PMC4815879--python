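"""Synthetic serial-crystallography datasets with geometric partialities.

Generates streams of still-diffraction snapshots that have the structure
the downstream algorithms assume: each crystal carries a random
orientation, a per-crystal linear scale G and Debye-Waller factor B, a
reciprocal-space profile radius, optionally a mis-indexed (ambiguity
flipped) reflection list, and Gaussian measurement noise.  Partialities
follow a spherical-cap model: the recorded fraction of a reflection is
the volume fraction of a sphere of radius R around the reciprocal lattice
point that lies inside the Ewald sphere.

Ground truth for every randomised quantity is recorded so that each
estimator in the package can be scored against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import (ANGSTROM, Crystal, Geometry, Peaks, Reflections, UnitCell,
                   detector_position, enumerate_hkl_sphere, excitation_error,
                   reciprocal_from_cell)
from .stream import Chunk, Stream
from .symmetry import AmbiguityOperator, SymmetryGroup, canonical_hkl, get_pointgroup


def random_orientation(rng: np.random.Generator) -> np.ndarray:
    """Rotation matrix drawn uniformly from SO(3) (Shoemake quaternion method)."""
    u1, u2, u3 = rng.random(3)
    q = np.array([
        np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
        np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
        np.sqrt(u1) * np.sin(2 * np.pi * u3),
        np.sqrt(u1) * np.cos(2 * np.pi * u3),
    ])
    x, y, z, w = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def partiality_sphere(r, R: float):
    """Spherical-cap partiality: fraction of the profile sphere inside the Ewald sphere.

    ``r`` is the signed excitation error of the reflection centre and ``R``
    the profile radius; p(-R) = 1, p(0) = 1/2, p(+R) = 0.
    """
    if R <= 0:
        raise ValueError("profile radius must be positive")
    t = np.clip((R - np.asarray(r, dtype=float)) / (2.0 * R), 0.0, 1.0)
    return 3.0 * t * t - 2.0 * t ** 3


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic dataset.

    Defaults describe a tetragonal crystal whose lattice metric supports a
    merohedral indexing ambiguity (point group 4/m, metric 4/mmm, operator
    k,h,-l), about 1000 symmetry-unique reflections to the resolution
    limit and a 2e7 m^-1 profile radius, giving on the order of a hundred
    recorded reflections per still snapshot.
    """

    cell: UnitCell = field(default_factory=lambda: UnitCell(40.0, 40.0, 60.0,
                                                            90.0, 90.0, 90.0))
    symmetry: str = "4/m"
    n_crystals: int = 100
    d_min: float = 3.7                     # A; extent of the reference table
    wavelength: float = 1.3e-10            # m
    bandwidth: float = 1e-3                # fractional; recorded, not used (monochromatic model)
    profile_radius: float = 2e7            # m^-1
    radius_jitter: float = 0.1             # lognormal sigma of per-crystal R
    apply_partiality: bool = True          # False: record full intensities (p = 1)
    g_mu: float = 0.0                      # ln-scale mean of lognormal G
    g_sigma: float = 0.3
    b_mu: float = 5.0                      # A^2
    b_sigma: float = 3.0
    sigma_floor: float = 2.0               # detector units
    noise_c: float = 1.0                   # sigma = max(floor, c*sqrt(I))
    wilson_b: float = 20.0                 # A^2 decay of the reference intensities
    i0: float = 1000.0                     # reference intensity scale at s = 0
    ambiguity_operator: Optional[str] = "k,h,-l"
    flip_probability: float = 0.5
    beam_centre_offset: Tuple[float, float] = (0.0, 0.0)   # px, injected truth
    camera_length: float = 0.08            # m
    pixel_size: float = 100e-6             # m
    beam_centre: Tuple[float, float] = (500.0, 500.0)      # px, nominal
    panel_shape: Tuple[int, int] = (1000, 1000)
    seed: int = 0

    def geometry(self, true_centre: bool = False) -> Geometry:
        cx, cy = self.beam_centre
        if true_centre:
            cx += self.beam_centre_offset[0]
            cy += self.beam_centre_offset[1]
        return Geometry(self.wavelength, self.camera_length, self.pixel_size,
                        (cx, cy), self.panel_shape)

    @property
    def group(self) -> SymmetryGroup:
        return get_pointgroup(self.symmetry)

    @property
    def operator(self) -> Optional[AmbiguityOperator]:
        if self.ambiguity_operator is None:
            return None
        return AmbiguityOperator.from_string(self.ambiguity_operator)


@dataclass
class GroundTruth:
    """Everything randomised by the simulator, for scoring estimators."""

    reference: Dict[tuple, float]
    orientations: List[np.ndarray] = field(default_factory=list)
    G: List[float] = field(default_factory=list)
    B: List[float] = field(default_factory=list)
    profile_radius: List[float] = field(default_factory=list)
    flipped: List[bool] = field(default_factory=list)
    beam_centre_offset: Tuple[float, float] = (0.0, 0.0)
    frame_ids: List[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        doc = {
            "reference": [[*k, v] for k, v in sorted(self.reference.items())],
            "orientations": [np.asarray(o).tolist() for o in self.orientations],
            "G": list(map(float, self.G)),
            "B": list(map(float, self.B)),
            "profile_radius": list(map(float, self.profile_radius)),
            "flipped": list(map(bool, self.flipped)),
            "beam_centre_offset": list(self.beam_centre_offset),
            "frame_ids": list(self.frame_ids),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(
            reference={(int(h), int(k), int(l)): float(v)
                       for h, k, l, v in doc["reference"]},
            orientations=[np.array(o) for o in doc["orientations"]],
            G=doc["G"], B=doc["B"], profile_radius=doc["profile_radius"],
            flipped=doc["flipped"],
            beam_centre_offset=tuple(doc["beam_centre_offset"]),
            frame_ids=doc["frame_ids"],
        )


def generate_reference(cell: UnitCell, symmetry: SymmetryGroup, d_min: float,
                       rng: np.random.Generator, wilson_b: float = 20.0,
                       i0: float = 1000.0) -> Dict[tuple, float]:
    """Wilson-like reference intensities for every unique hkl to d_min.

    Intensities are exponential draws whose mean decays as
    exp(-2 * wilson_b * s^2), s = (1/d)/2 in 1/A.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    basis = reciprocal_from_cell(cell)
    hkl = enumerate_hkl_sphere(basis, 1.0 / (d_min * ANGSTROM))
    uniq = np.unique(canonical_hkl(hkl, symmetry), axis=0)
    q = np.linalg.norm(uniq @ basis, axis=1)
    s2 = (q * ANGSTROM / 2.0) ** 2                    # A^-2
    means = i0 * np.exp(-2.0 * wilson_b * s2)
    vals = rng.exponential(means)
    vals = np.maximum(vals, 1e-6 * i0)  # strictly positive
    return {tuple(int(x) for x in row): float(v) for row, v in zip(uniq, vals)}


def simulate_crystal(config: SimulationConfig, reference: Dict[tuple, float],
                     rng: np.random.Generator, truth: Optional[GroundTruth] = None,
                     frame_id: str = "") -> Crystal:
    """One still snapshot: orientation, scales, flip, noise; truth appended."""
    group = config.group
    operator = config.operator
    orientation = random_orientation(rng)
    basis = reciprocal_from_cell(config.cell, orientation)
    R_c = config.profile_radius * np.exp(config.radius_jitter * rng.standard_normal())
    G = float(np.exp(rng.normal(config.g_mu, config.g_sigma)))
    B = float(rng.normal(config.b_mu, config.b_sigma))
    flipped = bool(operator is not None and rng.random() < config.flip_probability)

    q_max = 1.0 / (config.d_min * ANGSTROM)
    hkl = enumerate_hkl_sphere(basis, q_max)
    q = hkl @ basis
    r = excitation_error(q, config.wavelength)
    keep = np.abs(r) < R_c
    hkl, q, r = hkl[keep], q[keep], r[keep]

    # intensity index: a mis-indexed crystal records indices that map to the
    # true ones through the ambiguity operation
    lookup_hkl = operator.apply(hkl) if flipped else hkl
    lookup = canonical_hkl(lookup_hkl, group)
    i_ref = np.array([reference.get(tuple(int(x) for x in row), np.nan)
                      for row in lookup])
    ok = np.isfinite(i_ref)
    hkl, q, r, i_ref = hkl[ok], q[ok], r[ok], i_ref[ok]

    p = partiality_sphere(r, R_c) if config.apply_partiality else np.ones(len(r))
    s2 = (np.linalg.norm(q, axis=1) * ANGSTROM / 2.0) ** 2
    i_true = G * np.exp(-2.0 * B * s2) * p * i_ref
    sigma = np.maximum(config.sigma_floor,
                       config.noise_c * np.sqrt(np.maximum(i_true, 0.0)))
    intensity = i_true + sigma * rng.standard_normal(len(i_true))

    geom = config.geometry(true_centre=True)
    fs, ss, valid = detector_position(q, geom)
    on_panel = (valid & (fs >= 0) & (ss >= 0)
                & (fs <= geom.panel_shape[0] - 1) & (ss <= geom.panel_shape[1] - 1))
    refl = Reflections(hkl[on_panel], intensity[on_panel], sigma[on_panel],
                       p=p[on_panel], r=r[on_panel],
                       fs=fs[on_panel], ss=ss[on_panel])
    crystal = Crystal(cell=config.cell, basis=basis, reflections=refl,
                      profile_radius=R_c, frame_id=frame_id)
    if truth is not None:
        truth.orientations.append(orientation)
        truth.G.append(G)
        truth.B.append(B)
        truth.profile_radius.append(R_c)
        truth.flipped.append(flipped)
        truth.frame_ids.append(frame_id)
    return crystal


def simulate_dataset(config: SimulationConfig) -> Tuple[Stream, GroundTruth]:
    """A full synthetic stream of ``n_crystals`` snapshots plus ground truth."""
    rng = np.random.default_rng(config.seed)
    reference = generate_reference(config.cell, config.group, config.d_min, rng,
                                   config.wilson_b, config.i0)
    truth = GroundTruth(reference=reference,
                        beam_centre_offset=config.beam_centre_offset)
    from .stream import _default_header, geometry_header_line
    stream = Stream(header_lines=_default_header()
                    + [geometry_header_line(config.geometry())])
    for i in range(config.n_crystals):
        frame_id = f"sim-{i:05d}.h5"
        crystal = simulate_crystal(config, reference, rng, truth, frame_id)
        stream.chunks.append(Chunk(frame_id=frame_id, crystals=[crystal]))
    return stream, truth


def simulate_peaks(crystal: Crystal, geometry: Geometry, jitter_px: float = 0.0,
                   outlier_fraction: float = 0.0,
                   rng: Optional[np.random.Generator] = None) -> Peaks:
    """Detector spots for a crystal: jittered predictions plus spurious peaks.

    Each predicted reflection yields a peak with isotropic Gaussian
    positional jitter; a fraction ``outlier_fraction`` of the peaks is
    replaced by spurious spots placed uniformly on the panel.
    """
    if jitter_px < 0:
        raise ValueError("jitter must be non-negative")
    if not 0.0 <= outlier_fraction <= 1.0:
        raise ValueError("outlier_fraction must be in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    refl = crystal.reflections
    n = len(refl)
    fs = refl.fs + jitter_px * rng.standard_normal(n)
    ss = refl.ss + jitter_px * rng.standard_normal(n)
    inten = refl.I.copy()
    n_out = int(round(outlier_fraction * n))
    if n_out:
        idx = rng.choice(n, size=n_out, replace=False)
        fs[idx] = rng.uniform(0, geometry.panel_shape[0] - 1, n_out)
        ss[idx] = rng.uniform(0, geometry.panel_shape[1] - 1, n_out)
        inten[idx] = rng.uniform(0.5, 1.0, n_out) * max(inten.max(initial=1.0), 1.0)
    return Peaks(fs, ss, inten)
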