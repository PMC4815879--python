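"""Indexing-ambiguity resolution by one-dimensional correlation clustering.

When the lattice metric symmetry exceeds the true intensity symmetry,
each crystal of a serial dataset may be indexed in two (or more)
inequivalent ways; merging without resolving the ambiguity yields a
perfectly twinned dataset.  The resolver sorts crystals into two groups
with high intra-group intensity correlation:

1. a random indexing assignment is made for each crystal;
2. Pearson correlation coefficients between the intensity lists of
   crystal pairs are computed over a restricted resolution window;
3. for each crystal in turn, f = mean CC against crystals with the same
   assignment and g = mean CC against the others; the assignment is
   swapped if g > f (strictly);
4. passes over the dataset repeat until no assignment changes.

When the reindexing operator is known, f additionally includes the CCs
against opposite-assignment crystals after reindexing them, which
improves the contrast; g symmetrically includes the reindexed CCs
against same-assignment crystals, so that f and g compare the two
labelling hypotheses over the same partner set (this also lets a
dataset without genuine flips collapse into a single class).  Restricting the resolution window (default
40-4 A) removes the trivially positive correlation between any two
crystals caused by the overall intensity falloff with resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import ANGSTROM, Crystal
from .symmetry import AmbiguityOperator, SymmetryGroup, canonical_hkl

MIN_COMMON = 3  # fewer common reflections -> CC undefined


class AmbiguityError(RuntimeError):
    pass


@dataclass
class AmbiguityConfig:
    """Resolution window in Angstrom (low d > high d), partner budget, seed."""

    lowres: float = 40.0        # A, low-resolution (large d) edge
    highres: float = 4.0        # A, high-resolution (small d) edge
    ncorr: int = 0              # max partner CCs per crystal; 0 = all pairs
    max_passes: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.lowres <= self.highres:
            raise ValueError("low-resolution d-spacing bound must exceed the "
                             "high-resolution bound (both in Angstrom)")

    @property
    def q_window(self) -> Tuple[float, float]:
        """(q_min, q_max) in m^-1 for the CC window."""
        return 1.0 / (self.lowres * ANGSTROM), 1.0 / (self.highres * ANGSTROM)


@dataclass
class AmbiguityTrace:
    """Per-visit f/g record of the clustering run."""

    records: List[tuple] = field(default_factory=list)  # (pass, crystal, f, g, assignment)
    n_passes: int = 0
    converged: bool = False
    assignments: Optional[np.ndarray] = None

    def fg_arrays(self):
        arr = np.array([(r[2], r[3]) for r in self.records], dtype=float)
        return arr[:, 0], arr[:, 1]


def _merged_window_intensities(crystal: Crystal, symmetry: SymmetryGroup,
                               q_window: Tuple[float, float],
                               operator: Optional[AmbiguityOperator] = None
                               ) -> Dict[tuple, float]:
    """Symmetry-merged (mean) intensities restricted to the resolution window."""
    refl = crystal.reflections
    if len(refl) == 0:
        return {}
    q = np.linalg.norm(refl.hkl @ crystal.basis, axis=1)
    keep = (q >= q_window[0]) & (q <= q_window[1])
    hkl = refl.hkl[keep]
    if operator is not None:
        hkl = operator.apply(hkl)
    canon = canonical_hkl(hkl, symmetry)
    out: Dict[tuple, list] = {}
    for key, I in zip(map(tuple, canon.tolist()), refl.I[keep]):
        out.setdefault(key, []).append(I)
    return {k: float(np.mean(v)) for k, v in out.items()}


def restricted_correlation(a: Crystal, b: Crystal, symmetry: SymmetryGroup,
                           config: Optional[AmbiguityConfig] = None,
                           operator_applied_to_b: Optional[AmbiguityOperator] = None
                           ) -> float:
    """Pearson CC of two crystals' merged intensities in the window.

    Returns NaN (undefined) when fewer than three symmetry-unique
    reflections are common or either side has zero variance.
    """
    config = config or AmbiguityConfig()
    da = _merged_window_intensities(a, symmetry, config.q_window)
    db = _merged_window_intensities(b, symmetry, config.q_window,
                                    operator_applied_to_b)
    common = sorted(set(da) & set(db))
    if len(common) < MIN_COMMON:
        return float("nan")
    x = np.array([da[k] for k in common])
    y = np.array([db[k] for k in common])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _intensity_matrix(crystals: Sequence[Crystal], symmetry: SymmetryGroup,
                      q_window, operator=None, index=None):
    """(N, U) matrix of window intensities over the union index set; NaN absent.

    ``index`` fixes the column ordering so that matrices built with and
    without the reindexing operator share one column space.
    """
    dicts = [_merged_window_intensities(c, symmetry, q_window, operator)
             for c in crystals]
    if index is None:
        keys = sorted(set().union(*dicts) if dicts else set())
        index = {k: i for i, k in enumerate(keys)}
    M = np.full((len(crystals), len(index)), np.nan)
    for i, d in enumerate(dicts):
        for k, v in d.items():
            col = index.get(k)
            if col is not None:
                M[i, col] = v
    return M, index


def _pairwise_cc(MA: np.ndarray, MB: np.ndarray) -> np.ndarray:
    """CC[i, j] between rows of MA and MB over jointly observed columns.

    Implemented with zero-filled matrix products so that the whole matrix
    costs a handful of GEMMs; entries with fewer than MIN_COMMON common
    reflections or zero variance are NaN.
    """
    WA = np.isfinite(MA).astype(float)
    WB = np.isfinite(MB).astype(float)
    ZA = np.where(np.isfinite(MA), MA, 0.0)
    ZB = np.where(np.isfinite(MB), MB, 0.0)
    n = WA @ WB.T
    sx = ZA @ WB.T
    sy = WA @ ZB.T
    sxx = (ZA * ZA) @ WB.T
    syy = WA @ (ZB * ZB).T
    sxy = ZA @ ZB.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        cc = cov / np.sqrt(varx * vary)
    cc[(n < MIN_COMMON) | (varx <= 0) | (vary <= 0)] = np.nan
    return cc


def cc_matrices(crystals: Sequence[Crystal], symmetry: SymmetryGroup,
                config: AmbiguityConfig,
                operator: Optional[AmbiguityOperator] = None):
    """(C, C_reind): all-pairs CC as indexed, and crystal-i vs reindexed-j."""
    M, index = _intensity_matrix(crystals, symmetry, config.q_window)
    C = _pairwise_cc(M, M)
    C_re = None
    if operator is not None:
        # shared column space: reindexed keys outside the plain union cannot
        # intersect any plain row, so the plain index suffices
        M_op, _ = _intensity_matrix(crystals, symmetry, config.q_window,
                                    operator, index)
        C_re = _pairwise_cc(M, M_op)
    return C, C_re


def _mean_defined(values: np.ndarray) -> float:
    vals = values[np.isfinite(values)]
    return float(vals.mean()) if len(vals) else 0.0


def resolve_ambiguity(crystals: Sequence[Crystal], symmetry: SymmetryGroup,
                      operator: Optional[AmbiguityOperator] = None,
                      config: Optional[AmbiguityConfig] = None
                      ) -> Tuple[np.ndarray, AmbiguityTrace]:
    """Cluster crystals into two indexing-assignment groups.

    Returns (assignments in {0, 1} up to a global flip, trace).  Raises
    :class:`AmbiguityError` when no crystal pair shares enough reflections
    in the window to define a correlation coefficient.
    """
    if len(crystals) < 2:
        raise AmbiguityError("need at least two crystals")
    config = config or AmbiguityConfig()
    rng = np.random.default_rng(config.seed)
    n = len(crystals)
    C, C_re = cc_matrices(crystals, symmetry, config, operator)
    off = ~np.eye(n, dtype=bool)
    if not np.isfinite(C[off]).any():
        raise AmbiguityError(
            "no crystal pair shares enough reflections in the resolution "
            "window; widen the --lowres/--highres range")

    # optional complexity reduction: a fixed, seeded partner subset per crystal
    partner_mask = off
    if config.ncorr and config.ncorr < n - 1:
        partner_mask = np.zeros((n, n), dtype=bool)
        for i in range(n):
            others = np.delete(np.arange(n), i)
            partner_mask[i, rng.choice(others, size=config.ncorr, replace=False)] = True

    assignments = rng.integers(0, 2, size=n)
    trace = AmbiguityTrace()
    for pass_no in range(1, config.max_passes + 1):
        swaps = 0
        for i in range(n):
            partners = partner_mask[i]
            same = partners & (assignments == assignments[i])
            diff = partners & (assignments != assignments[i])
            f_vals = [C[i, same]]
            g_vals = [C[i, diff]]
            if C_re is not None:
                # known operator: f gains the reindexed opposite-assignment
                # CCs ("my label is right"); symmetrically, g gains the
                # reindexed same-assignment CCs ("my label is wrong")
                f_vals.append(C_re[i, diff])
                g_vals.append(C_re[i, same])
            f = _mean_defined(np.concatenate(f_vals))
            g = _mean_defined(np.concatenate(g_vals))
            if g > f:
                assignments[i] ^= 1
                swaps += 1
            trace.records.append((pass_no, i, f, g, int(assignments[i])))
        trace.n_passes = pass_no
        if swaps == 0:
            trace.converged = True
            break
    trace.assignments = assignments.copy()
    return assignments, trace


def reindex_crystal(crystal: Crystal, operator: AmbiguityOperator) -> Crystal:
    """Map every Miller index of a crystal through the ambiguity operator."""
    out = crystal.copy()
    out.reflections.hkl = operator.apply(out.reflections.hkl)
    return out


def reindex_resolved(crystals: Sequence[Crystal], assignments,
                     operator: AmbiguityOperator, flip_class: int = 1
                     ) -> List[Crystal]:
    """Apply the operator to every crystal in the given assignment class."""
    return [reindex_crystal(c, operator) if a == flip_class else c.copy()
            for c, a in zip(crystals, assignments)]


def resolve_double_ambiguity(crystals: Sequence[Crystal], symmetry: SymmetryGroup,
                             op1: AmbiguityOperator, op2: AmbiguityOperator,
                             config: Optional[AmbiguityConfig] = None):
    """Two-pass strategy for systems with two independent ambiguities.

    Resolves op1 first, reindexes accordingly, then resolves op2 on the
    result; the composite label (pass1, pass2) distinguishes the four
    indexing classes up to global relabelling.
    """
    for a, b in ((op1.mat, op2.mat), (op1.mat, op1.mat @ op2.mat),
                 (op2.mat, op1.mat @ op2.mat)):
        if np.array_equal(a, b):
            raise ValueError("op1, op2 and op1*op2 must be distinct")
    config = config or AmbiguityConfig()
    a1, trace1 = resolve_ambiguity(crystals, symmetry, op1, config)
    fixed = reindex_resolved(crystals, a1, op1)
    a2, trace2 = resolve_ambiguity(fixed, symmetry, op2, config)
    labels = np.array([2 * x + y for x, y in zip(a1, a2)])
    return labels, (trace1, trace2)


def export_cc_matrix(crystals: Sequence[Crystal], symmetry: SymmetryGroup,
                     path, config: Optional[AmbiguityConfig] = None) -> None:
    """Write the full symmetric CC matrix and frame ids to an HDF5 file."""
    import h5py

    config = config or AmbiguityConfig()
    C, _ = cc_matrices(crystals, symmetry, config)
    np.fill_diagonal(C, 1.0)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("cc", data=C)
        fh.create_dataset(
            "frame_ids",
            data=np.array([c.frame_id for c in crystals], dtype=object),
            dtype=h5py.string_dtype())
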