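"""Prediction refinement: spot-reflection pairing, outlier truncation,
least-squares refinement of the lattice basis and beam centre, and the
profile-radius / resolution-limit estimates.

The refinement minimises, over the nine reciprocal-basis components and
the two beam-centre coordinates,

    sum_i  I_hat_i * [ w * r_i^2 + (x_obs,i - x_calc,i)^2 + (y_obs,i - y_calc,i)^2 ]

where r_i is the excitation error of reflection i under the current
basis, (x, y) are detector positions in metres in the lab frame, and
I_hat_i is the spot intensity divided by the strongest spot in the
pattern.  The weight w (default 1e-22 m^4) brings excitation errors
(~1e7 m^-1) and position errors (~1e-4 m) onto a comparable scale.
Minimisation uses a Levenberg-Marquardt loop with a finite-difference
Jacobian; damping guarantees a monotonically non-increasing residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .core import (Crystal, Geometry, Peaks, Reflections, back_project,
                   detector_position, excitation_error, enumerate_hkl_sphere)
from .simulate import partiality_sphere

PAIRING_CUT_PX = 10.0       # spot-prediction distance cut
MIN_PAIRS = 10              # crystals with fewer paired spots are rejected
INDEX_TOLERANCE = 0.25      # fractional-index window for "accounted" spots


class CrystalRejected(RuntimeError):
    """Crystal cannot be refined (too few paired spots or singular system)."""


@dataclass
class SpotPairing:
    """Peak-reflection pairs retained for refinement."""

    hkl: np.ndarray            # (N, 3) nearest-integer indices
    fs_obs: np.ndarray
    ss_obs: np.ndarray
    fs_calc: np.ndarray
    ss_calc: np.ndarray
    r: np.ndarray              # excitation error, m^-1
    i_rel: np.ndarray          # spot intensity / max intensity in pattern
    misfit: np.ndarray         # max |fractional index - integer|

    def __len__(self) -> int:
        return len(self.r)

    def select(self, idx) -> "SpotPairing":
        return SpotPairing(self.hkl[idx], self.fs_obs[idx], self.ss_obs[idx],
                           self.fs_calc[idx], self.ss_calc[idx], self.r[idx],
                           self.i_rel[idx], self.misfit[idx])


@dataclass
class RefinementResult:
    crystal: Crystal                       # with refined basis
    beam_shift_px: tuple                   # (dfs, dss)
    beam_shift_m: tuple
    residual_before: float
    residual_after: float
    n_pairs: int
    profile_radius_before: float
    profile_radius_after: float
    cost_history: List[float] = field(default_factory=list)


def pair_spots(peaks: Peaks, crystal: Crystal, geometry: Geometry,
               max_dist_px: float = PAIRING_CUT_PX) -> SpotPairing:
    """Assign each observed spot the nearest integer Miller indices.

    Fractional indices come from back-projecting the spot onto the Ewald
    sphere and solving against the lattice basis; indices are rounded
    regardless of how far from integral they are, and the pair is kept
    only if the predicted position falls within ``max_dist_px`` pixels of
    the observed spot.
    """
    n = len(peaks)
    if n == 0:
        e = np.empty(0)
        return SpotPairing(np.empty((0, 3), dtype=int), e, e, e, e, e, e, e)
    q_obs = back_project(peaks.fs, peaks.ss, geometry)
    frac = q_obs @ np.linalg.inv(crystal.basis)
    hkl = np.rint(frac).astype(int)
    misfit = np.abs(frac - hkl).max(axis=1)
    q_pred = hkl @ crystal.basis
    fs_c, ss_c, valid = detector_position(q_pred, geometry)
    dist = np.hypot(fs_c - peaks.fs, ss_c - peaks.ss)
    keep = valid & (dist <= max_dist_px)
    i_max = peaks.intensity.max()
    # weights: negative (noise-dominated) spot intensities get zero weight
    i_rel = np.clip(peaks.intensity / i_max, 0.0, None) if i_max > 0 \
        else np.ones(n)
    r = excitation_error(q_pred, geometry.wavelength)
    return SpotPairing(hkl[keep], peaks.fs[keep], peaks.ss[keep],
                       fs_c[keep], ss_c[keep], r[keep], i_rel[keep],
                       misfit[keep])


def truncate_outliers(pairing: SpotPairing, k: float = 5.0) -> SpotPairing:
    """Drop the tail of the pairing after the first abrupt increase of |r|.

    Pairs are sorted by increasing |r|; the gap g_j between consecutive
    values is compared with the median of the preceding gaps, starting at
    position max(4, ceil(N/4)); the list is truncated immediately before
    the first position whose gap exceeds k times that median.  Fewer than
    four pairs are returned unchanged.
    """
    n = len(pairing)
    if n < 4:
        return pairing
    order = np.argsort(np.abs(pairing.r), kind="stable")
    sorted_pairing = pairing.select(order)
    rs = np.abs(sorted_pairing.r)
    gaps = np.diff(rs)                      # gaps[j-1] = g_j (1-based j)
    start = max(4, int(np.ceil(n / 4)))
    for j in range(start, n):               # j = 1-based gap index
        prior = gaps[:j - 1]
        med = np.median(prior) if len(prior) else 0.0
        if med > 0 and gaps[j - 1] > k * med:
            return sorted_pairing.select(np.arange(j))
    return sorted_pairing


def _pack(basis: np.ndarray, shift_m: np.ndarray) -> np.ndarray:
    return np.concatenate([basis.ravel() * 1e-9, shift_m * 1e4])


def _unpack(params: np.ndarray):
    return params[:9].reshape(3, 3) * 1e9, params[9:] * 1e-4


def _residual_vector(params, pairing, geometry, weight):
    basis, shift = _unpack(params)
    q = pairing.hkl @ basis
    r = excitation_error(q, geometry.wavelength)
    fs_c, ss_c, _ = detector_position(q, geometry)
    pix = geometry.pixel_size
    dx = (pairing.fs_obs - fs_c) * pix - shift[0]
    dy = (pairing.ss_obs - ss_c) * pix - shift[1]
    w = np.sqrt(pairing.i_rel)
    return np.concatenate([w * np.sqrt(weight) * r, w * dx, w * dy])


def refine_prediction(crystal: Crystal, pairing: SpotPairing,
                      geometry: Geometry, weight: float = 1e-22,
                      max_iter: int = 100, tol: float = 1e-6
                      ) -> RefinementResult:
    """Levenberg-Marquardt refinement of basis vectors and beam centre."""
    if len(pairing) < MIN_PAIRS:
        raise CrystalRejected(
            f"only {len(pairing)} spots assigned indices (need {MIN_PAIRS})")
    params = _pack(crystal.basis, np.zeros(2))
    res = _residual_vector(params, pairing, geometry, weight)
    cost = float(res @ res)
    history = [cost]
    lam = 1e-3
    for _ in range(max_iter):
        # forward-difference Jacobian over the 11 scaled parameters
        J = np.empty((len(res), len(params)))
        for p in range(len(params)):
            step = 1e-7 * max(abs(params[p]), 1e-3)
            trial = params.copy()
            trial[p] += step
            J[:, p] = (_residual_vector(trial, pairing, geometry, weight) - res) / step
        JtJ = J.T @ J
        g = J.T @ res
        improved = False
        for _ in range(25):
            try:
                delta = np.linalg.solve(JtJ + lam * np.diag(np.diag(JtJ))
                                        + 1e-30 * np.eye(len(params)), -g)
            except np.linalg.LinAlgError as exc:
                raise CrystalRejected("singular normal matrix") from exc
            trial = params + delta
            trial_res = _residual_vector(trial, pairing, geometry, weight)
            trial_cost = float(trial_res @ trial_res)
            if trial_cost <= cost:
                improved = True
                break
            lam *= 10.0
            if lam > 1e12:
                break
        if not improved:
            break
        lam = max(lam / 10.0, 1e-12)
        rel_change = (cost - trial_cost) / max(cost, 1e-300)
        params, res, cost = trial, trial_res, trial_cost
        history.append(cost)
        if rel_change < tol:
            break

    basis, shift = _unpack(params)
    refined = crystal.copy()
    refined.basis = basis
    q = pairing.hkl @ basis
    r_after = excitation_error(q, geometry.wavelength)
    radius_before = estimate_profile_radius(np.abs(pairing.r))
    radius_after = estimate_profile_radius(np.abs(r_after))
    refined.profile_radius = radius_after
    pix = geometry.pixel_size
    return RefinementResult(
        crystal=refined,
        beam_shift_px=(shift[0] / pix, shift[1] / pix),
        beam_shift_m=(float(shift[0]), float(shift[1])),
        residual_before=history[0], residual_after=cost,
        n_pairs=len(pairing),
        profile_radius_before=radius_before,
        profile_radius_after=radius_after,
        cost_history=history)


def nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: the ceil(p*n)-th smallest value."""
    vals = np.sort(np.asarray(values, dtype=float))
    if len(vals) == 0:
        raise ValueError("empty sample")
    rank = int(np.ceil(percentile / 100.0 * len(vals)))
    return float(vals[max(rank, 1) - 1])


def estimate_profile_radius(r_values, percentile: float = 98.0) -> float:
    """Profile radius such that the given fraction of paired spots is predicted.

    Set to the nearest-rank 98th percentile of |r| over the retained
    pairs; reflections with |r| < R are then "predicted".
    """
    r_abs = np.abs(np.asarray(r_values, dtype=float))
    if len(r_abs) == 0:
        raise ValueError("no pairs to estimate profile radius from")
    return nearest_rank_percentile(r_abs, percentile)


def estimate_resolution_limit(peaks: Peaks, crystal: Crystal,
                              geometry: Geometry,
                              tolerance: float = INDEX_TOLERANCE,
                              percentile: float = 98.0) -> Optional[float]:
    """Conservative per-crystal resolution estimate in m^-1.

    A spot is accounted for by the lattice if all three fractional Miller
    indices are within ``tolerance`` of integers; the estimate is the
    nearest-rank 98th percentile of 1/d over accounted spots.  Returns
    None when no spot is accounted for.
    """
    if len(peaks) == 0:
        return None
    q_obs = back_project(peaks.fs, peaks.ss, geometry)
    frac = q_obs @ np.linalg.inv(crystal.basis)
    accounted = np.all(np.abs(frac - np.rint(frac)) <= tolerance, axis=1)
    if not accounted.any():
        return None
    one_over_d = np.linalg.norm(q_obs[accounted], axis=1)
    return nearest_rank_percentile(one_over_d, percentile)


def predict_reflections(crystal: Crystal, geometry: Geometry,
                        push_res: float = np.inf) -> Reflections:
    """Reflections predicted by the diffraction model, from scratch.

    All hkl with |r| < profile radius and 1/d <= resolution estimate +
    push_res (no cutoff when the estimate is unset or push_res infinite);
    each carries its excitation error, spherical-cap partiality and
    predicted detector position.
    """
    limit = np.inf
    if crystal.resolution_estimate is not None and np.isfinite(push_res):
        limit = crystal.resolution_estimate + push_res
    # enumeration bound: detector corner sets the observable resolution
    cx, cy = geometry.beam_centre
    nfs, nss = geometry.panel_shape
    corners_fs = np.array([0.0, nfs - 1.0, 0.0, nfs - 1.0])
    corners_ss = np.array([0.0, 0.0, nss - 1.0, nss - 1.0])
    q_corner = np.linalg.norm(back_project(corners_fs, corners_ss, geometry),
                              axis=-1).max()
    q_max = min(limit, q_corner)
    if q_max <= 0:
        return Reflections(np.empty((0, 3), dtype=int), [], [])
    hkl = enumerate_hkl_sphere(crystal.basis, q_max)
    q = hkl @ crystal.basis
    r = excitation_error(q, geometry.wavelength)
    keep = np.abs(r) < crystal.profile_radius
    hkl, q, r = hkl[keep], q[keep], r[keep]
    fs, ss, valid = detector_position(q, geometry)
    hkl, q, r, fs, ss = hkl[valid], q[valid], r[valid], fs[valid], ss[valid]
    p = partiality_sphere(r, crystal.profile_radius)
    n = len(hkl)
    return Reflections(hkl, np.zeros(n), np.zeros(n), p=p, r=r, fs=fs, ss=ss)
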