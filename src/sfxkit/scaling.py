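"""Scaling and merging of still-snapshot reflection intensities.

Two strategies are provided:

* simple Monte Carlo merging (mean of all measurements per unique
  reflection) with an optional two-pass linear scale against the first
  merge, and
* iterative log-residual scaling: per crystal the model

      ln I_i = ln G - 2 B s_i^2 + ln p_i + ln L + ln I_ref,i

  (L = 1 and p = 1 here; s = sin(theta)/lambda in 1/A) is fitted by
  linear least squares in (ln G, B) against a reference obtained by
  merging all surviving crystals, and the merge/fit cycle repeats.  The
  logarithmic residual guarantees G > 0, weights reflections roughly
  evenly across resolution, and requires I > 0 and I_ref > 0; crystals
  with |B| above a threshold or with too few usable reflections are
  excluded from all further processing.

A seeded 5% "free" set of reflections is excluded from the fits and used
to report a cross-validation residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import ANGSTROM, Crystal, Geometry
from .stream import MergedDataset
from .symmetry import SymmetryGroup, canonical_hkl

log = logging.getLogger(__name__)


class ScalingError(RuntimeError):
    pass


@dataclass
class ScalingConfig:
    n_iterations: int = 3
    max_b: float = 100.0          # A^2; |B| above this rejects the crystal
    free_fraction: float = 0.05
    seed: int = 0
    polarization_fraction: float = 1.0   # 1 = fully horizontal
    push_res: Optional[float] = None     # m^-1 above the resolution estimate

    def __post_init__(self):
        if not 0.0 <= self.free_fraction < 0.5:
            raise ValueError("free fraction must be in [0, 0.5)")


@dataclass
class CrystalScale:
    G: float = 1.0
    B: float = 0.0
    n_used: int = 0
    residual: float = float("nan")
    free_residual: float = float("nan")
    rejected: Optional[str] = None       # rejection reason or None


@dataclass
class ScaleReport:
    crystals: List[CrystalScale] = field(default_factory=list)
    iteration_residuals: List[float] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return sum(1 for c in self.crystals if c.rejected)


# ---------------------------------------------------------------------------
# polarization


def polarization_factor(q, geometry: Geometry, fraction: float = 1.0):
    """Thomson polarization factor P for reciprocal point(s) q.

    P = f (1 - sin^2(2theta) cos^2(phi)) + (1-f)(1 - sin^2(2theta) sin^2(phi)),
    phi the detector azimuth; intensities are divided by P.
    """
    q = np.asarray(q, dtype=float)
    k = 1.0 / geometry.wavelength
    s = q.copy()
    s[..., 2] += k
    sn = np.linalg.norm(s, axis=-1)
    cos2t = np.clip(s[..., 2] / sn, -1.0, 1.0)
    sin2_2t = 1.0 - cos2t ** 2
    phi = np.arctan2(q[..., 1], q[..., 0])
    return (fraction * (1.0 - sin2_2t * np.cos(phi) ** 2)
            + (1.0 - fraction) * (1.0 - sin2_2t * np.sin(phi) ** 2))


def polarization_correct(crystal: Crystal, geometry: Geometry,
                         fraction: float = 1.0, min_p: float = 0.01) -> Crystal:
    """Divide intensities and sigmas by the polarization factor.

    Reflections with P below ``min_p`` are excluded (flagged and dropped).
    """
    out = crystal.copy()
    q = out.reflections.hkl @ out.basis
    P = polarization_factor(q, geometry, fraction)
    ok = P >= min_p
    out.reflections = out.reflections.select(ok)
    out.reflections.I = out.reflections.I / P[ok]
    out.reflections.sigma = out.reflections.sigma / P[ok]
    return out


# ---------------------------------------------------------------------------
# merging


def _s2_A(crystal: Crystal, hkl=None) -> np.ndarray:
    """s^2 = (sin(theta)/lambda)^2 in 1/A^2 for the crystal's reflections."""
    hkl = crystal.reflections.hkl if hkl is None else hkl
    q = np.linalg.norm(hkl @ crystal.basis, axis=1)
    return (q * ANGSTROM / 2.0) ** 2


def _crystal_observations(crystal: Crystal, symmetry: SymmetryGroup,
                          config: Optional[ScalingConfig], scaled: bool):
    """(canonical hkl, I, sigma) after cutoff/saturation/scaling filters."""
    refl = crystal.reflections
    keep = np.ones(len(refl), dtype=bool)
    if refl.saturated is not None:
        keep &= ~refl.saturated
    if (config is not None and config.push_res is not None
            and crystal.resolution_estimate is not None):
        q = np.linalg.norm(refl.hkl @ crystal.basis, axis=1)
        keep &= q <= crystal.resolution_estimate + config.push_res
    hkl = refl.hkl[keep]
    I = refl.I[keep]
    sigma = refl.sigma[keep]
    if scaled:
        scale = crystal.G * np.exp(-2.0 * crystal.B * _s2_A(crystal, hkl))
        I = I / scale
        sigma = sigma / scale
    return canonical_hkl(hkl, symmetry), I, sigma


def merge_simple(crystals: Sequence[Crystal], symmetry: SymmetryGroup,
                 config: Optional[ScalingConfig] = None,
                 scaled: bool = False,
                 extra_scales: Optional[Sequence[float]] = None,
                 cell=None) -> MergedDataset:
    """Mean of the individual measurements per symmetry-unique reflection.

    With ``scaled=True`` each observation is divided by the crystal's
    G * exp(-2 B s^2) first; ``extra_scales`` multiplies each crystal's
    intensities by a per-crystal constant (used by the two-pass scaling).
    The merged sigma is the standard error of the mean (sample sd / sqrt n)
    for n >= 2, or the observation's own sigma for n = 1.
    """
    if len(crystals) == 0:
        raise ScalingError("no crystals to merge")
    all_hkl, all_I, all_sigma = [], [], []
    for ci, crystal in enumerate(crystals):
        canon, I, sigma = _crystal_observations(crystal, symmetry, config, scaled)
        if extra_scales is not None:
            I = I * extra_scales[ci]
            sigma = sigma * extra_scales[ci]
        all_hkl.append(canon)
        all_I.append(I)
        all_sigma.append(sigma)
    hkl = np.concatenate(all_hkl, axis=0)
    I = np.concatenate(all_I)
    sigma = np.concatenate(all_sigma)
    if len(hkl) == 0:
        raise ScalingError("no reflections to merge")
    uniq, inverse, counts = np.unique(hkl, axis=0, return_inverse=True,
                                      return_counts=True)
    sums = np.bincount(inverse, weights=I, minlength=len(uniq))
    means = sums / counts
    sq = np.bincount(inverse, weights=I * I, minlength=len(uniq))
    table: Dict[tuple, tuple] = {}
    first_sigma = np.zeros(len(uniq))
    # singleton sigma: the observation's own sigma
    order = np.argsort(inverse, kind="stable")
    firsts = order[np.searchsorted(np.sort(inverse), np.arange(len(uniq)))]
    first_sigma = sigma[firsts]
    for u in range(len(uniq)):
        n = int(counts[u])
        if n >= 2:
            var = (sq[u] - n * means[u] ** 2) / (n - 1)
            sig = float(np.sqrt(max(var, 0.0) / n))
        else:
            sig = float(first_sigma[u])
        table[tuple(int(x) for x in uniq[u])] = (float(means[u]), sig, n)
    if cell is None:
        cell = crystals[0].cell
    return MergedDataset(table, symmetry, cell)


def two_pass_scale_merge(crystals: Sequence[Crystal], symmetry: SymmetryGroup,
                         config: Optional[ScalingConfig] = None
                         ) -> Tuple[MergedDataset, np.ndarray]:
    """Merge twice; the second pass applies per-crystal linear scales.

    The scale k for each crystal is the least-squares fit through the
    origin of its intensities to the first-pass merged intensities,
    k = sum(I * I_ref) / sum(I^2).  Returns (merged, scales).
    """
    if len(crystals) < 2:
        raise ScalingError("two-pass scaling needs at least two crystals")
    reference = merge_simple(crystals, symmetry, config)
    scales = np.ones(len(crystals))
    for ci, crystal in enumerate(crystals):
        canon, I, _ = _crystal_observations(crystal, symmetry, config, False)
        iref = np.array([reference.table.get(tuple(int(x) for x in row),
                                             (np.nan,))[0] for row in canon])
        ok = np.isfinite(iref)
        denom = float(np.sum(I[ok] ** 2))
        if not ok.any() or denom == 0.0:
            log.warning("crystal %r has no overlap with reference; scale 1",
                        crystal.frame_id)
            continue
        scales[ci] = float(np.sum(I[ok] * iref[ok]) / denom)
    merged = merge_simple(crystals, symmetry, config, extra_scales=scales)
    return merged, scales


# ---------------------------------------------------------------------------
# log-residual scaling


def assign_free_flags(crystals: Sequence[Crystal], fraction: float = 0.05,
                      seed: int = 0) -> None:
    """Seeded random free set per crystal, in place; ~fraction of reflections."""
    rng = np.random.default_rng(seed)
    for crystal in crystals:
        n = len(crystal.reflections)
        crystal.reflections.free = rng.random(n) < fraction


def fit_crystal_scale(crystal: Crystal, reference: MergedDataset,
                      config: Optional[ScalingConfig] = None) -> CrystalScale:
    """Closed-form least squares of (ln G, B) on the logarithmic residual.

    Only reflections with I > 0 and I_ref > 0 enter (the logarithm demands
    it); free-flagged reflections are excluded from the fit and pooled
    into the free residual.  The crystal is rejected when |B| exceeds the
    threshold or the usable reflections do not outnumber the two
    parameters.
    """
    config = config or ScalingConfig()
    refl = crystal.reflections
    canon = canonical_hkl(refl.hkl, reference.symmetry)
    iref = np.array([reference.table.get(tuple(int(x) for x in row),
                                         (np.nan,))[0] for row in canon])
    usable = np.isfinite(iref) & (iref > 0) & (refl.I > 0)
    free = refl.free if refl.free is not None else np.zeros(len(refl), dtype=bool)
    work = usable & ~free
    n_used = int(work.sum())
    if n_used <= 2:
        return CrystalScale(rejected="too few reflections", n_used=n_used)
    s2 = _s2_A(crystal)
    y = np.log(refl.I[work]) - np.log(iref[work])
    u = s2[work]
    # y = alpha - 2 B u with alpha = ln G
    um, ym = u.mean(), y.mean()
    du = u - um
    denom = float(du @ du)
    if denom == 0.0:
        return CrystalScale(rejected="degenerate resolution distribution",
                            n_used=n_used)
    beta = float(du @ (y - ym)) / denom
    B = -beta / 2.0
    alpha = ym - beta * um
    G = float(np.exp(alpha))
    model = alpha + beta * s2
    residual = float(np.sum((np.log(refl.I[work]) - np.log(iref[work])
                             - model[work]) ** 2))
    free_mask = usable & free
    free_residual = float(np.sum((np.log(refl.I[free_mask])
                                  - np.log(iref[free_mask])
                                  - model[free_mask]) ** 2)) \
        if free_mask.any() else float("nan")
    if abs(B) > config.max_b:
        return CrystalScale(G=G, B=B, n_used=n_used, residual=residual,
                            free_residual=free_residual, rejected="B too large")
    return CrystalScale(G=G, B=B, n_used=n_used, residual=residual,
                        free_residual=free_residual)


def iterative_scale(crystals: Sequence[Crystal], symmetry: SymmetryGroup,
                    config: Optional[ScalingConfig] = None
                    ) -> Tuple[List[Crystal], MergedDataset, ScaleReport]:
    """Reference-merge / per-crystal-fit cycles of log-residual scaling.

    Returns the surviving crystals (with G and B set), the final merged
    dataset of scaled intensities, and a per-crystal report.  Rejected
    crystals are excluded from all further iterations.
    """
    config = config or ScalingConfig()
    if len(crystals) < 2:
        raise ScalingError("iterative scaling needs at least two crystals")
    work = [c.copy() for c in crystals]
    if any(c.reflections.free is None for c in work):
        assign_free_flags(work, config.free_fraction, config.seed)
    report = ScaleReport(crystals=[CrystalScale() for _ in work])
    active = list(range(len(work)))
    for _ in range(config.n_iterations):
        if not active:
            raise ScalingError("all crystals rejected during scaling")
        reference = merge_simple([work[i] for i in active], symmetry, config,
                                 scaled=True)
        total = 0.0
        still_active = []
        for i in active:
            result = fit_crystal_scale(work[i], reference, config)
            report.crystals[i] = result
            if result.rejected:
                continue
            work[i].G = result.G
            work[i].B = result.B
            total += result.residual
            still_active.append(i)
        active = still_active
        report.iteration_residuals.append(total)
    if not active:
        raise ScalingError("all crystals rejected during scaling")
    survivors = [work[i] for i in active]
    merged = merge_simple(survivors, symmetry, config, scaled=True)
    return survivors, merged, report


# ---------------------------------------------------------------------------
# dataset splitting


def split_halves(crystals: Sequence[Crystal], symmetry: SymmetryGroup,
                 seed: int = 0, config: Optional[ScalingConfig] = None,
                 scaled: bool = False) -> Tuple[MergedDataset, MergedDataset]:
    """Random half-dataset split (crystal-wise, sizes differing by <= 1)."""
    if len(crystals) < 2:
        raise ScalingError("need at least two crystals to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(crystals))
    half = (len(crystals) + 1) // 2
    a = [crystals[i] for i in order[:half]]
    b = [crystals[i] for i in order[half:]]
    return (merge_simple(a, symmetry, config, scaled=scaled),
            merge_simple(b, symmetry, config, scaled=scaled))


def merge_by_identifier(crystals: Sequence[Crystal], split_map: Dict[str, str],
                        symmetry: SymmetryGroup,
                        config: Optional[ScalingConfig] = None,
                        scaled: bool = False, seed: int = 0):
    """Per-label merges (with half splits) after joint scaling.

    ``split_map`` maps frame_id to a dataset label (a time delay,
    "native"/"derivative", ...).  Crystals absent from the map enter only
    the overall merge.  Scaling is not redone per group, so all groups
    stay on a common scale.  Returns (overall, {label: (full, halfA, halfB)}).
    """
    overall = (merge_simple(crystals, symmetry, config, scaled=scaled),
               *split_halves(crystals, symmetry, seed, config, scaled=scaled))
    groups: Dict[str, List[Crystal]] = {}
    for crystal in crystals:
        label = split_map.get(crystal.frame_id)
        if label is not None:
            groups.setdefault(label, []).append(crystal)
    out = {}
    for label in sorted(set(split_map.values())):
        members = groups.get(label, [])
        if not members:
            log.warning("dataset label %r matches no crystals; omitted", label)
            continue
        full = merge_simple(members, symmetry, config, scaled=scaled)
        if len(members) >= 2:
            ha, hb = split_halves(members, symmetry, seed, config, scaled=scaled)
        else:
            ha = hb = full
        out[label] = (full, ha, hb)
    return overall, out
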