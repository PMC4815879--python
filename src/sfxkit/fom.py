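"""Figures of merit on merged reflection datasets.

CC1/2 is the Pearson correlation between the merged intensities of two
half-datasets; Rsplit is the normalised mean absolute half-dataset
difference,

    Rsplit = (1/sqrt(2)) * sum |I_A - I_B|  /  (0.5 * sum (I_A + I_B)).

Statistics are reported overall and in resolution shells holding (by
default) equal numbers of unique reflections; overall values are pooled
over all common reflections, not averaged over shells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .core import UnitCell, enumerate_hkl_sphere, reciprocal_from_cell, \
    resolution_1_over_d
from .stream import MergedDataset
from .symmetry import canonical_hkl


class FomError(RuntimeError):
    pass


@dataclass
class ShellScheme:
    """Half-open 1/d bins [low, high) (m^-1); the last bin is closed."""

    edges: np.ndarray

    @classmethod
    def equal_count(cls, one_over_d: np.ndarray, n_shells: int) -> "ShellScheme":
        vals = np.sort(np.asarray(one_over_d, dtype=float))
        if len(vals) == 0:
            raise FomError("no reflections to build shells from")
        n_shells = max(1, min(n_shells, len(vals)))
        qs = np.quantile(vals, np.linspace(0, 1, n_shells + 1))
        qs[0] -= 1e-9 * max(qs[-1], 1.0)
        qs[-1] += 1e-9 * max(qs[-1], 1.0)
        return cls(np.asarray(qs))

    @property
    def n_shells(self) -> int:
        return len(self.edges) - 1

    def assign(self, one_over_d: np.ndarray) -> np.ndarray:
        """Shell index per value; -1 for out-of-range."""
        idx = np.searchsorted(self.edges, one_over_d, side="right") - 1
        idx[one_over_d == self.edges[-1]] = self.n_shells - 1
        idx[(one_over_d < self.edges[0]) | (one_over_d > self.edges[-1])] = -1
        return idx


def _common_arrays(a: MergedDataset, b: MergedDataset, cell: Optional[UnitCell]):
    keys = sorted(set(a.table) & set(b.table))
    if not keys:
        raise FomError("datasets share no reflections")
    hkl = np.array(keys, dtype=int).reshape(-1, 3)
    ia = np.array([a.table[k][0] for k in keys])
    ib = np.array([b.table[k][0] for k in keys])
    cell = cell or a.cell or b.cell
    if cell is None:
        raise FomError("a unit cell is required for resolution shells")
    q = resolution_1_over_d(hkl, cell)
    return hkl, ia, ib, q


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def cc_half(a: MergedDataset, b: MergedDataset,
            shells: "int | ShellScheme" = 10,
            cell: Optional[UnitCell] = None):
    """Per-shell and overall Pearson CC of two merged datasets.

    Returns (overall, shell_table) where shell_table rows are
    (1/d low, 1/d high, n_common, CC); shells with fewer than three
    common reflections are NaN.
    """
    hkl, ia, ib, q = _common_arrays(a, b, cell)
    scheme = shells if isinstance(shells, ShellScheme) \
        else ShellScheme.equal_count(q, shells)
    idx = scheme.assign(q)
    rows = []
    for s in range(scheme.n_shells):
        sel = idx == s
        rows.append((float(scheme.edges[s]), float(scheme.edges[s + 1]),
                     int(sel.sum()), _pearson(ia[sel], ib[sel])))
    return _pearson(ia, ib), rows


def rsplit(a: MergedDataset, b: MergedDataset,
           shells: "int | ShellScheme" = 10,
           cell: Optional[UnitCell] = None):
    """Per-shell and overall Rsplit; NaN where the denominator vanishes."""
    hkl, ia, ib, q = _common_arrays(a, b, cell)
    scheme = shells if isinstance(shells, ShellScheme) \
        else ShellScheme.equal_count(q, shells)
    idx = scheme.assign(q)

    def _rs(x, y):
        denom = 0.5 * float(np.sum(x + y))
        if denom == 0 or len(x) == 0:
            return float("nan")
        return float(np.sum(np.abs(x - y)) / denom / np.sqrt(2.0))

    rows = []
    for s in range(scheme.n_shells):
        sel = idx == s
        rows.append((float(scheme.edges[s]), float(scheme.edges[s + 1]),
                     int(sel.sum()), _rs(ia[sel], ib[sel])))
    return _rs(ia, ib), rows


def count_possible_unique(cell: UnitCell, symmetry, q_low: float,
                          q_high: float) -> np.ndarray:
    """All symmetry-unique hkl with q_low < 1/d <= q_high (canonical form)."""
    basis = reciprocal_from_cell(cell)
    hkl = enumerate_hkl_sphere(basis, q_high)
    q = np.linalg.norm(hkl @ basis, axis=1)
    hkl = hkl[q > q_low]
    if len(hkl) == 0:
        return np.empty((0, 3), dtype=int)
    return np.unique(canonical_hkl(hkl, symmetry), axis=0)


def check_stats(a: MergedDataset, cell: Optional[UnitCell] = None,
                d_range: Optional[Tuple[float, float]] = None,
                shells: "int | ShellScheme" = 10):
    """Single-dataset statistics per shell and overall.

    Returns (overall, shell_rows); each row is a dict with 1/d bounds,
    n_unique, n_possible, completeness (%), redundancy and mean I/sigma.
    ``d_range`` is (d_low, d_high) in Angstrom; defaults to the dataset's
    own extent.
    """
    cell = cell or a.cell
    if cell is None:
        raise FomError("a unit cell is required")
    hkl, I, sigma, nmeas = a.arrays()
    if len(hkl) == 0:
        raise FomError("empty dataset")
    q = resolution_1_over_d(hkl, cell)
    if d_range is not None:
        q_low, q_high = 1e10 / d_range[0], 1e10 / d_range[1]
    else:
        q_low, q_high = 0.0, float(q.max())
    scheme = shells if isinstance(shells, ShellScheme) else \
        ShellScheme.equal_count(q[(q > q_low) & (q <= q_high)], shells)
    possible = count_possible_unique(cell, a.symmetry, q_low, q_high)
    q_poss = resolution_1_over_d(possible, cell)
    idx_obs = scheme.assign(q)
    idx_poss = scheme.assign(q_poss)

    def shell_row(sel_obs, sel_poss, lo, hi):
        n_u = int(sel_obs.sum())
        n_p = int(sel_poss.sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            isig = I[sel_obs] / sigma[sel_obs]
        isig = isig[np.isfinite(isig)]
        return {
            "q_low": lo, "q_high": hi,
            "n_unique": n_u, "n_possible": n_p,
            "completeness": 100.0 * n_u / n_p if n_p else float("nan"),
            "redundancy": float(nmeas[sel_obs].mean()) if n_u else float("nan"),
            "mean_i_over_sigma": float(isig.mean()) if len(isig) else float("nan"),
        }

    rows = []
    for s in range(scheme.n_shells):
        rows.append(shell_row(idx_obs == s, idx_poss == s,
                              float(scheme.edges[s]), float(scheme.edges[s + 1])))
    overall = shell_row(idx_obs >= 0, idx_poss >= 0,
                        float(scheme.edges[0]), float(scheme.edges[-1]))
    return overall, rows
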