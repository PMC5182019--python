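"""Unit-cell metrics, point-group symmetry and asymmetric-unit mapping.

The merging and statistics machinery needs four crystallographic
primitives: d-spacings from a (possibly triclinic) metric tensor,
mapping of Miller indices to a canonical asymmetric-unit representative
while keeping Friedel (Bijvoet) mates distinguishable, centric-reflection
detection, and equal-volume resolution shells.

Only point groups ``"1"`` and ``"222"`` ship built in — the study system
is a primitive orthorhombic protein crystal — but :class:`PointGroup`
accepts any user-supplied list of integer rotation matrices that forms a
group.

Conventions
-----------
* Rotation matrices act on Miller-index column vectors, ``h' = R @ h``.
* The canonical ASU representative of a reflection is the
  lexicographically greatest triple in the combined orbit
  ``{R h} ∪ {R (−h)}``.  If that representative lies in the orbit of
  ``+h`` the Friedel sign is ``+1``, otherwise ``−1``.  Centric
  reflections (orbits containing both signs) are assigned ``+1``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "UnitCell",
    "PointGroup",
    "UniqueReflection",
    "d_spacing",
    "map_to_asu",
    "asu_map",
    "is_centric",
    "centric_flags",
    "assign_shells",
    "shell_edges",
    "unique_reflections",
]


@dataclasses.dataclass(frozen=True)
class UnitCell:
    """Crystal unit cell: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if np.linalg.det(self.metric) <= 0:
            raise ValueError("cell metric tensor is not positive definite")

    @property
    def metric(self) -> np.ndarray:
        """Direct-space metric tensor G (3x3, Å²)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    @property
    def reciprocal_metric(self) -> np.ndarray:
        """Reciprocal-space metric tensor G* = G⁻¹ (Å⁻²)."""
        return np.linalg.inv(self.metric)

    @property
    def volume(self) -> float:
        """Cell volume in Å³."""
        return float(math.sqrt(np.linalg.det(self.metric)))

    @property
    def orthogonalization(self) -> np.ndarray:
        """Matrix O taking fractional to Cartesian coordinates (Å)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = math.sqrt(1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg)
        return np.array(
            [
                [a, b * cg, c * cb],
                [0.0, b * sg, c * (ca - cb * cg) / sg],
                [0.0, 0.0, c * v / sg],
            ]
        )

    @property
    def b_matrix(self) -> np.ndarray:
        """Matrix B taking Miller indices to Cartesian reciprocal vectors (Å⁻¹).

        ``|B @ h| = 1/d(h)``; columns are the reciprocal basis vectors in
        the crystal-fixed Cartesian frame.
        """
        return np.linalg.inv(self.orthogonalization).T


def _as_index_array(hkl) -> np.ndarray:
    arr = np.asarray(hkl)
    scalar = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[-1] != 3:
        raise ValueError("Miller indices must be triples")
    return arr, scalar


def d_spacing(hkl, cell: UnitCell):
    """Resolution d = 1/|h·a* + k·b* + l·c*| in Å.

    Accepts a single triple or an (N, 3) array.  Raises ``ValueError``
    for the (0,0,0) triple.
    """
    arr, scalar = _as_index_array(hkl)
    gstar = cell.reciprocal_metric
    inv_d2 = np.einsum("ni,ij,nj->n", arr, gstar, arr)
    if np.any(inv_d2 <= 0):
        raise ValueError("d-spacing undefined for the zero index triple")
    d = 1.0 / np.sqrt(inv_d2)
    return float(d[0]) if scalar else d


_BUILTIN_OPS = {
    "1": [np.eye(3, dtype=int)],
    # 222: identity plus the three two-fold rotations along a, b, c.
    "222": [
        np.diag([1, 1, 1]),
        np.diag([1, -1, -1]),
        np.diag([-1, 1, -1]),
        np.diag([-1, -1, 1]),
    ],
}


@dataclasses.dataclass(frozen=True)
class PointGroup:
    """A point group acting on Miller indices by integer rotation matrices."""

    name: str
    ops: tuple = ()

    def __post_init__(self) -> None:
        ops = self.ops or tuple(np.array(m, dtype=int) for m in _BUILTIN_OPS.get(self.name, ()))
        if not ops:
            raise ValueError(f"unknown point group {self.name!r} and no ops supplied")
        ops = tuple(np.asarray(m, dtype=int).reshape(3, 3) for m in ops)
        keys = {m.tobytes() for m in ops}
        if np.eye(3, dtype=int).tobytes() not in keys:
            raise ValueError("point group must contain the identity")
        for m in ops:
            if abs(round(np.linalg.det(m))) != 1:
                raise ValueError("point-group ops must have determinant ±1")
            for n in ops:
                if (m @ n).tobytes() not in keys:
                    raise ValueError("point-group ops are not closed under composition")
        object.__setattr__(self, "ops", ops)

    @property
    def op_array(self) -> np.ndarray:
        """All ops stacked as an (m, 3, 3) integer array."""
        return np.stack(self.ops)

    @classmethod
    def from_matrices(cls, name: str, matrices: Iterable[Sequence[int]]) -> "PointGroup":
        """Build a custom group from nine-integer row-major matrices."""
        ops = tuple(np.array(m, dtype=int).reshape(3, 3) for m in matrices)
        return cls(name=name, ops=ops)


@dataclasses.dataclass(frozen=True)
class UniqueReflection:
    """Canonical ASU triple plus the Friedel sign (+1 or −1)."""

    hkl_asu: tuple
    friedel: int

    def __post_init__(self) -> None:
        if self.friedel not in (-1, 1):
            raise ValueError("friedel sign must be +1 or -1")


def _lex_key(H: np.ndarray, scale: int) -> np.ndarray:
    # Composite integer key realising lexicographic order on triples.
    return (H[..., 0] * scale + H[..., 1]) * scale + H[..., 2]


def asu_map(hkl, pg: PointGroup):
    """Vectorised ASU mapping.

    Parameters
    ----------
    hkl : (N, 3) array-like of integer Miller indices (no zero triple).
    pg : point group.

    Returns
    -------
    (H_asu, friedel) : ``H_asu`` is (N, 3) int, ``friedel`` is (N,) int
    with values ±1.
    """
    H, scalar = _as_index_array(hkl)
    H = H.astype(np.int64)
    if np.any(np.all(H == 0, axis=1)):
        raise ValueError("ASU mapping undefined for the zero index triple")
    R = pg.op_array  # (m,3,3)
    plus = np.einsum("mij,nj->mni", R, H)  # orbit of +h
    minus = -plus  # orbit of -h (R(-h) = -(Rh))
    scale = 2 * int(np.abs(H).max()) + 3
    kp = _lex_key(plus, scale)  # (m, n)
    km = _lex_key(minus, scale)
    best_p = kp.max(axis=0)
    best_m = km.max(axis=0)
    take_plus = best_p >= best_m  # centric ties resolve to +
    idx_p = kp.argmax(axis=0)
    idx_m = km.argmax(axis=0)
    n = H.shape[0]
    cols = np.arange(n)
    H_asu = np.where(
        take_plus[:, None], plus[idx_p, cols], minus[idx_m, cols]
    )
    friedel = np.where(take_plus, 1, -1)
    if scalar:
        return H_asu[0], int(friedel[0])
    return H_asu, friedel


def map_to_asu(hkl, pg: PointGroup) -> UniqueReflection:
    """Map one Miller triple to its canonical :class:`UniqueReflection`."""
    h_asu, sign = asu_map(np.asarray(hkl), pg)
    return UniqueReflection(hkl_asu=tuple(int(x) for x in h_asu), friedel=sign)


def centric_flags(hkl, pg: PointGroup):
    """True where some symmetry op maps hkl onto −hkl (vectorised)."""
    H, scalar = _as_index_array(hkl)
    H = H.astype(np.int64)
    if np.any(np.all(H == 0, axis=1)):
        raise ValueError("centricity undefined for the zero index triple")
    R = pg.op_array
    orbit = np.einsum("mij,nj->mni", R, H)
    flags = np.any(np.all(orbit == -H[None, :, :], axis=-1), axis=0)
    return bool(flags[0]) if scalar else flags


def is_centric(hkl, pg: PointGroup) -> bool:
    """True iff the reflection is phase restricted in this point group."""
    return bool(centric_flags(np.asarray(hkl), pg))


def shell_edges(n_shells: int, d_min: float, d_max: float) -> np.ndarray:
    """Shell boundaries in d (Å), equally spaced in 1/d³.

    Returns ``n_shells + 1`` descending d values from ``d_max`` to
    ``d_min`` so that each shell spans the same reciprocal volume.
    """
    if n_shells < 1:
        raise ValueError("need at least one shell")
    if not d_min < d_max:
        raise ValueError("d_min must be smaller than d_max")
    s3 = np.linspace(d_max**-3, d_min**-3, n_shells + 1)
    return s3 ** (-1.0 / 3.0)


def assign_shells(hkl, cell: UnitCell, n_shells: int, d_min: float, d_max: float):
    """Assign each reflection an equal-reciprocal-volume shell index.

    Returns an (N,) int array; in-range reflections get 0..n_shells−1
    (0 is the lowest-resolution shell), out-of-range reflections get −1.
    Empty input yields an empty array.
    """
    H = np.atleast_2d(np.asarray(hkl))
    if H.size == 0:
        return np.empty(0, dtype=int)
    d = np.atleast_1d(d_spacing(H, cell))
    return assign_shells_d(d, n_shells, d_min, d_max)


def assign_shells_d(d, n_shells: int, d_min: float, d_max: float):
    """Shell assignment from precomputed d-spacings (same contract)."""
    d = np.asarray(d, dtype=float)
    edges = shell_edges(n_shells, d_min, d_max)  # descending d
    s3 = d**-3
    idx = np.searchsorted(edges**-3, s3, side="right") - 1
    idx[idx == n_shells] = n_shells - 1  # d == d_min boundary
    out_of_range = (d > d_max) | (d < d_min)
    idx[out_of_range] = -1
    return idx


def unique_reflections(cell: UnitCell, pg: PointGroup, d_min: float, d_max: float = np.inf):
    """Enumerate canonical ASU representatives with d in [d_min, d_max].

    Returns (H_asu, centric) where ``H_asu`` is (n, 3) int and
    ``centric`` the matching boolean flags.  Friedel mates are *not*
    listed separately; each row is the ``friedel=+1`` representative.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    hmax = int(cell.a / d_min) + 1
    kmax = int(cell.b / d_min) + 1
    lmax = int(cell.c / d_min) + 1
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    H = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    H = H[np.any(H != 0, axis=1)]
    d = d_spacing(H, cell)
    H = H[(d >= d_min) & (d <= d_max)]
    H_asu, _ = asu_map(H, pg)
    H_asu = np.unique(H_asu, axis=0)
    return H_asu, centric_flags(H_asu, pg)
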