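"""Point-group symmetry on Miller indices and indexing-ambiguity operators.

Only the rotational/Laue point groups needed to define "symmetrically
unique reflection" for merging, and to express merohedral indexing
ambiguities, are built in.  Arbitrary groups can be constructed from an
explicit operator list.  Operators are 3x3 integer matrices acting on the
column vector (h, k, l).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

_I3 = np.eye(3, dtype=int)


def _closure(generators: Iterable[np.ndarray]) -> list:
    """Close a set of integer matrices under multiplication."""
    ops = {tuple(_I3.ravel())}
    frontier = [np.asarray(g, dtype=int) for g in generators]
    for g in frontier:
        ops.add(tuple(g.ravel()))
    changed = True
    while changed:
        changed = False
        current = [np.array(o, dtype=int).reshape(3, 3) for o in ops]
        for a in current:
            for b in current:
                t = tuple((a @ b).ravel())
                if t not in ops:
                    ops.add(t)
                    changed = True
                    if len(ops) > 192:
                        raise ValueError("operator set does not close (group too large)")
    return sorted(ops)


@dataclass(frozen=True)
class SymmetryGroup:
    """Finite group of integer matrices acting on (h, k, l)."""

    label: str
    _ops: tuple  # tuple of 9-tuples, canonical sorted order

    @classmethod
    def from_operators(cls, label: str, operators: Sequence) -> "SymmetryGroup":
        mats = [np.asarray(op, dtype=int).reshape(3, 3) for op in operators]
        return cls(label, tuple(_closure(mats)))

    @property
    def operators(self) -> np.ndarray:
        """(n_ops, 3, 3) integer array, identity included."""
        return np.array(self._ops, dtype=int).reshape(-1, 3, 3)

    def __len__(self) -> int:
        return len(self._ops)

    def __contains__(self, matrix) -> bool:
        m = np.asarray(matrix, dtype=int).reshape(3, 3)
        return tuple(m.ravel()) in set(self._ops)


# generators per point group; axes follow conventional settings
# (monoclinic unique b, trigonal/hexagonal c axis, hexagonal indices for "3")
_INV = -_I3
_GEN = {
    "1": [],
    "-1": [_INV],
    "2/m": [np.array([[-1, 0, 0], [0, 1, 0], [0, 0, -1]]), _INV],
    "mmm": [np.array([[-1, 0, 0], [0, -1, 0], [0, 0, 1]]),
            np.array([[1, 0, 0], [0, -1, 0], [0, 0, -1]]), _INV],
    "4/m": [np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]]), _INV],
    "4/mmm": [np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]]),
              np.array([[1, 0, 0], [0, -1, 0], [0, 0, -1]]), _INV],
    "3": [np.array([[0, 1, 0], [-1, -1, 0], [0, 0, 1]])],
    "-3": [np.array([[0, 1, 0], [-1, -1, 0], [0, 0, 1]]), _INV],
    "6/m": [np.array([[0, -1, 0], [1, 1, 0], [0, 0, 1]]), _INV],
    "6/mmm": [np.array([[0, -1, 0], [1, 1, 0], [0, 0, 1]]),
              np.array([[0, 1, 0], [1, 0, 0], [0, 0, -1]]), _INV],
    "m-3": [np.array([[0, 0, 1], [1, 0, 0], [0, 1, 0]]),
            np.array([[-1, 0, 0], [0, -1, 0], [0, 0, 1]]), _INV],
}

_CACHE: dict = {}


def get_pointgroup(label: str) -> SymmetryGroup:
    """Look up a built-in point group by its Hermann-Mauguin label."""
    if label not in _GEN:
        raise KeyError(
            f"unknown point group {label!r}; available: {sorted(_GEN)}")
    if label not in _CACHE:
        _CACHE[label] = SymmetryGroup.from_operators(label, _GEN[label])
    return _CACHE[label]


def _lex_key(images: np.ndarray) -> np.ndarray:
    # images: (..., 3) with |index| < 512; scalar key preserving lex order
    im = images.astype(np.int64)
    return ((im[..., 0] + 512) << 20) + ((im[..., 1] + 512) << 10) + (im[..., 2] + 512)


def canonical_hkl(hkl, group: SymmetryGroup):
    """Deterministic symmetry-unique representative of Miller indices.

    The representative is the lexicographically greatest image of (h,k,l)
    under all group operations; idempotent by construction.  Accepts a
    single triple or an (N, 3) array.
    """
    arr = np.asarray(hkl, dtype=int)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if np.abs(arr).max(initial=0) >= 512:
        raise ValueError("Miller indices out of supported range (|index| < 512)")
    ops = group.operators                       # (m, 3, 3)
    images = np.einsum("mij,nj->mni", ops, arr)  # (m, N, 3)
    best = np.argmax(_lex_key(images), axis=0)   # (N,)
    out = images[best, np.arange(arr.shape[0])]
    return tuple(int(x) for x in out[0]) if single else out


@dataclass(frozen=True)
class AmbiguityOperator:
    """Reindexing operation for a merohedral indexing ambiguity."""

    matrix: tuple  # 9-tuple of ints

    def __init__(self, matrix):
        m = np.asarray(matrix, dtype=int).reshape(3, 3)
        if abs(round(float(np.linalg.det(m)))) != 1:
            raise ValueError("ambiguity operator must have determinant +/-1")
        object.__setattr__(self, "matrix", tuple(int(x) for x in m.ravel()))

    @property
    def mat(self) -> np.ndarray:
        return np.array(self.matrix, dtype=int).reshape(3, 3)

    @property
    def inverse(self) -> "AmbiguityOperator":
        inv = np.linalg.inv(self.mat)
        ri = np.rint(inv).astype(int)
        if not np.allclose(inv, ri):
            raise ValueError("operator inverse is not integral")
        return AmbiguityOperator(ri)

    def apply(self, hkl):
        """Map one triple or an (N, 3) array of triples through the operator."""
        arr = np.asarray(hkl, dtype=int)
        single = arr.ndim == 1
        out = np.atleast_2d(arr) @ self.mat.T
        return tuple(int(x) for x in out[0]) if single else out

    @classmethod
    def from_string(cls, text: str) -> "AmbiguityOperator":
        """Parse an operator like ``"k,h,-l"`` or ``"-h-k,k,-l"``.

        Each comma-separated component is a signed sum of h, k and l.
        """
        parts = text.replace(" ", "").split(",")
        if len(parts) != 3:
            raise ValueError(f"operator must have three components: {text!r}")
        cols = {"h": 0, "k": 1, "l": 2}
        m = np.zeros((3, 3), dtype=int)
        for row, part in enumerate(parts):
            if not part:
                raise ValueError(f"empty component in operator {text!r}")
            sign = 1
            for ch in part:
                if ch == "+":
                    sign = 1
                elif ch == "-":
                    sign = -1
                elif ch in cols:
                    m[row, cols[ch]] += sign
                    sign = 1
                else:
                    raise ValueError(f"bad character {ch!r} in operator {text!r}")
        return cls(m)

    def __str__(self) -> str:
        names = ["h", "k", "l"]
        rows = []
        for row in self.mat:
            terms = ""
            for coef, name in zip(row, names):
                for _ in range(abs(int(coef))):
                    terms += ("-" if coef < 0 else ("+" if terms else "")) + name
            rows.append(terms or "0")
        return ",".join(rows)
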