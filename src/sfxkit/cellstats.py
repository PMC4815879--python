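"""Headless unit-cell statistics across a stream.

Collects the per-crystal cell parameters determined independently for
each diffraction pattern, filters them with rectangular windows on any
parameter, and fits a Gaussian (maximum-likelihood normal fit on the
windowed values, i.e. sample mean and sd, not a curve fit to histogram
bars) so that quantitative cell parameters with error estimates can be
extracted even from contaminated distributions.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .stream import Stream

PARAMS = ("a", "b", "c", "alpha", "beta", "gamma")


def collect_cells(stream: Stream) -> pd.DataFrame:
    """One row of cell parameters (A / deg) per crystal, centring preserved."""
    rows = []
    for chunk in stream.chunks:
        for crystal in chunk.crystals:
            cell = crystal.cell
            rows.append({"a": cell.a, "b": cell.b, "c": cell.c,
                         "alpha": cell.alpha, "beta": cell.beta,
                         "gamma": cell.gamma, "centring": cell.centring,
                         "frame_id": crystal.frame_id})
    return pd.DataFrame(rows, columns=[*PARAMS, "centring", "frame_id"])


def fit_gaussian(values, window: Tuple[float, float]) -> Tuple[float, float, int]:
    """(mu, sigma, n) of the values inside [lo, hi]; needs at least three."""
    lo, hi = window
    vals = np.asarray(values, dtype=float)
    vals = vals[(vals >= lo) & (vals <= hi)]
    if len(vals) < 3:
        raise ValueError(
            f"only {len(vals)} values in window [{lo}, {hi}]; need >= 3")
    return float(vals.mean()), float(vals.std(ddof=1)), int(len(vals))


def conditional_filter(table: pd.DataFrame,
                       constraints: Dict[str, Tuple[float, float]]
                       ) -> pd.DataFrame:
    """Rows satisfying every [lo, hi] constraint (linked-histogram behaviour)."""
    mask = np.ones(len(table), dtype=bool)
    for param, (lo, hi) in constraints.items():
        mask &= (table[param] >= lo).to_numpy() & (table[param] <= hi).to_numpy()
    return table[mask]


def histogram(values, bins: int = 50, window=None):
    """(bin_centres, counts) for writing a text histogram."""
    vals = np.asarray(values, dtype=float)
    if window is not None:
        vals = vals[(vals >= window[0]) & (vals <= window[1])]
    counts, edges = np.histogram(vals, bins=bins)
    return 0.5 * (edges[:-1] + edges[1:]), counts
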