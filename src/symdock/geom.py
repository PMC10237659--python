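"""Rigid-body transform algebra, backbone stub frames, and hierarchical samplers.

Transforms are represented as 4x4 homogeneous matrices (``numpy.ndarray``),
the convention used throughout structural-bioinformatics code: the upper-left
3x3 block is a proper rotation, the last column the translation in Angstroms.

The orientation sampler partitions rotation space by the cells of a
bitruncated 24-cell on the quaternion 3-sphere: the 48 cell-center unit
quaternions (the binary octahedral group) collapse to 24 rotation cells under
antipodal identification.  Each cell carries a local cubic grid that is halved
per hierarchy level, mirroring the binary nesting of the Cartesian dimensions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

# Empirical covering radius of the 24-cell orientation lattice: the largest
# rotation angle from any rotation to its nearest cell center.  Measured once
# by Monte-Carlo (2e5 uniform rotations -> 62.63 deg) and frozen with margin.
ORI_TOP_COVERAGE_DEG = 62.8

# Half-width of the per-cell gnomonic cube, tan(coverage/2).
ORI_CELL_HALFWIDTH = math.tan(math.radians(ORI_TOP_COVERAGE_DEG / 2.0))

DEFAULT_CART_RESL = 10.0  # Angstrom, top search level
DEFAULT_ORI_RESL = 30.0  # degrees, top search level


class DegenerateGeometryError(ValueError):
    """Raised when backbone atoms are collinear/coincident and no frame exists."""


# ---------------------------------------------------------------------------
# homogeneous transform helpers
# ---------------------------------------------------------------------------

def htrans(v) -> np.ndarray:
    """Pure translation by 3-vector ``v``."""
    X = np.eye(4)
    X[:3, 3] = np.asarray(v, dtype=float)
    return X


def hrot(axis, angle_deg: float, center=None) -> np.ndarray:
    """Rotation of ``angle_deg`` degrees about ``axis`` (through ``center``)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    R = Rotation.from_rotvec(axis * math.radians(angle_deg)).as_matrix()
    X = np.eye(4)
    X[:3, :3] = R
    if center is not None:
        c = np.asarray(center, dtype=float)
        X[:3, 3] = c - R @ c
    return X


def hinv(X: np.ndarray) -> np.ndarray:
    """Inverse of a rigid transform (exploits orthonormality)."""
    X = np.asarray(X)
    out = np.eye(4)
    R = X[:3, :3]
    out[:3, :3] = R.T
    out[:3, 3] = -R.T @ X[:3, 3]
    return out


def rot_of(X: np.ndarray) -> np.ndarray:
    return np.asarray(X)[..., :3, :3]


def trans_of(X: np.ndarray) -> np.ndarray:
    return np.asarray(X)[..., :3, 3]


def is_rigid_xform(X: np.ndarray, tol: float = 1e-8) -> bool:
    """Check orthonormality and det +1 of the rotation block."""
    R = rot_of(X)
    return (
        np.allclose(R @ R.T, np.eye(3), atol=tol)
        and abs(np.linalg.det(R) - 1.0) < tol
        and np.allclose(np.asarray(X)[3], [0, 0, 0, 1], atol=tol)
    )


def align_vector(a, b) -> np.ndarray:
    """Minimal rotation carrying direction ``a`` onto direction ``b``."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    X = np.eye(4)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return X
        # antiparallel: rotate 180 deg about any axis orthogonal to a
        ortho = np.eye(3)[np.argmin(np.abs(a))]
        axis = np.cross(a, ortho)
        return hrot(axis, 180.0)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    X[:3, :3] = np.eye(3) + K + K @ K / (1.0 + c)
    return X


def xform_points(X: np.ndarray, pts: np.ndarray) -> np.ndarray:
    pts = np.asarray(pts, float)
    return pts @ rot_of(X).T + trans_of(X)


def stub_from_backbone(n_xyz, ca_xyz, c_xyz, residue=None) -> np.ndarray:
    """Orthonormal residue frame from backbone N, CA, C coordinates.

    Convention (fixed, Gram-Schmidt on the two backbone bond vectors):
    origin at CA; x along the unit bisector-orthogonalized pair, concretely
    e1 = unit(N-CA), e2 = unit((C-CA) - ((C-CA).e1) e1), e3 = e1 x e2.
    Any consistent convention works because scores depend only on relative
    transforms binned the same way on both sides of the lookup.
    """
    n = np.asarray(n_xyz, float)
    ca = np.asarray(ca_xyz, float)
    c = np.asarray(c_xyz, float)
    a = n - ca
    b = c - ca
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-6 or nb < 1e-6 or np.linalg.norm(np.cross(a, b)) / (na * nb) < 1e-6:
        where = f" at residue {residue}" if residue is not None else ""
        raise DegenerateGeometryError(
            f"collinear or coincident backbone atoms{where}: cannot build stub frame"
        )
    e1 = a / na
    e2 = b - np.dot(b, e1) * e1
    e2 = e2 / np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    X = np.eye(4)
    X[:3, 0] = e1
    X[:3, 1] = e2
    X[:3, 2] = e3
    X[:3, 3] = ca
    return X


def stubs_from_backbone_arrays(n, ca, c) -> np.ndarray:
    """Vectorized stub construction for (nres,3) N/CA/C arrays."""
    n = np.asarray(n, float)
    ca = np.asarray(ca, float)
    c = np.asarray(c, float)
    a = n - ca
    b = c - ca
    e1 = a / np.linalg.norm(a, axis=-1, keepdims=True)
    e2 = b - np.sum(b * e1, axis=-1, keepdims=True) * e1
    e2 = e2 / np.linalg.norm(e2, axis=-1, keepdims=True)
    e3 = np.cross(e1, e2)
    X = np.zeros((len(ca), 4, 4))
    X[:, 3, 3] = 1.0
    X[:, :3, 0] = e1
    X[:, :3, 1] = e2
    X[:, :3, 2] = e3
    X[:, :3, 3] = ca
    return X


# ---------------------------------------------------------------------------
# orientation cell lattice
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrientationCellLattice:
    """24 rotation cells from the bitruncated 24-cell, antipodally identified."""

    top_cells: np.ndarray  # (24, 4) unit quaternions (w, x, y, z)

    def assign(self, quats: np.ndarray) -> np.ndarray:
        """Cell index by maximum |q . c| over cell centers."""
        quats = np.atleast_2d(np.asarray(quats, float))
        return np.argmax(np.abs(quats @ self.top_cells.T), axis=-1)


def _canonical_half(q: np.ndarray) -> np.ndarray:
    """Pick the representative with first nonzero component positive."""
    q = np.asarray(q, float)
    for x in q:
        if abs(x) > 1e-12:
            return q if x > 0 else -q
    return q


def orientation_top_cells() -> OrientationCellLattice:
    """The 24 top-level rotation cells.

    Cell centers are the 48 unit quaternions of the binary octahedral group
    (vertices of the 24-cell plus its dual), reduced to 24 representatives by
    antipodal identification q ~ -q.
    """
    cells = []
    for i in range(4):
        v = np.zeros(4)
        v[i] = 1.0
        cells.append(v)
    for signs in itertools.product([1.0, -1.0], repeat=3):
        cells.append(np.array([1.0, *signs]) / 2.0)
    for i, j in itertools.combinations(range(4), 2):
        for s in (1.0, -1.0):
            v = np.zeros(4)
            v[i] = 1.0
            v[j] = s
            cells.append(v / math.sqrt(2.0))
    cells = np.array([_canonical_half(c) for c in cells])
    assert cells.shape == (24, 4)
    return OrientationCellLattice(top_cells=cells)


_TOP_CELLS = orientation_top_cells()


def quat_angular_distance(q1, q2) -> float:
    """Rotation angle (degrees) between two unit quaternions, mod antipodes."""
    d = abs(float(np.dot(q1, q2)))
    return 2.0 * math.degrees(math.acos(min(1.0, d)))


def rotation_to_quat(R: np.ndarray) -> np.ndarray:
    """3x3 rotation -> unit quaternion (w, x, y, z)."""
    q = Rotation.from_matrix(R).as_quat()  # (x, y, z, w)
    return np.array([q[3], q[0], q[1], q[2]])


def quat_to_rotation(q: np.ndarray) -> np.ndarray:
    return Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()


def quat_multiply(a, b):
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ]
    )


# ---------------------------------------------------------------------------
# hierarchical sampler dimensions
# ---------------------------------------------------------------------------

class CartDim:
    """1D Cartesian dimension with binary nesting.

    Level-0 cells have width ``resl``; level L has ``ceil((hi-lo)/resl) * 2**L``
    cells of width ``resl / 2**L``, covering [lo, lo + n0*resl).
    """

    kind = "cartesian"

    def __init__(self, lo: float, hi: float, resl: float):
        if hi <= lo or resl <= 0:
            raise ValueError("need hi > lo and resl > 0")
        self.lo, self.hi, self.resl = float(lo), float(hi), float(resl)
        self.n0 = int(math.ceil((hi - lo) / resl))

    def ncells(self, level: int) -> int:
        return self.n0 * 2**level

    def nchild(self) -> int:
        return 2

    def children(self, index: int) -> list[int]:
        return [2 * index, 2 * index + 1]

    def parent(self, index: int) -> int:
        return index // 2

    def value(self, level: int, index: int) -> float:
        w = self.resl / 2**level
        return self.lo + (index + 0.5) * w

    def values(self, level: int, indices: np.ndarray) -> np.ndarray:
        w = self.resl / 2**level
        return self.lo + (np.asarray(indices) + 0.5) * w

    def cell_width(self, level: int) -> float:
        return self.resl / 2**level


class AngleDim(CartDim):
    """Rotation-about-axis dimension in degrees, half-open [lo, hi)."""

    kind = "rotation-about-axis"


class DiscreteDim:
    """Fixed discrete choices (e.g. flip on/off); never subdivided."""

    kind = "discrete"

    def __init__(self, choices):
        self.choices = list(choices)

    def ncells(self, level: int) -> int:
        return len(self.choices)

    def nchild(self) -> int:
        return 1

    def children(self, index: int) -> list[int]:
        return [index]

    def parent(self, index: int) -> int:
        return index

    def value(self, level: int, index: int):
        return self.choices[index]

    def values(self, level: int, indices):
        return [self.choices[i] for i in np.asarray(indices)]


class OriDim:
    """3D orientation dimension over the 24-cell lattice.

    Each top cell carries an ``n0 x n0 x n0`` gnomonic grid, with
    ``n0 = max(1, round(coverage / resl))``; each level doubles the per-axis
    count, so an orientation index has 8 children per level.
    """

    kind = "orientation"

    def __init__(self, resl: float = DEFAULT_ORI_RESL):
        self.resl = float(resl)
        self.n0 = max(1, round(ORI_TOP_COVERAGE_DEG / self.resl))
        self.lattice = _TOP_CELLS

    def nside(self, level: int) -> int:
        return self.n0 * 2**level

    def ncells(self, level: int) -> int:
        return 24 * self.nside(level) ** 3

    def nchild(self) -> int:
        return 8

    def children_at(self, level: int, index: int) -> list[int]:
        s = self.nside(level)
        cell, rem = divmod(index, s**3)
        i, rem = divmod(rem, s**2)
        j, k = divmod(rem, s)
        s2 = 2 * s
        out = []
        for di, dj, dk in itertools.product((0, 1), repeat=3):
            ii, jj, kk = 2 * i + di, 2 * j + dj, 2 * k + dk
            out.append(cell * s2**3 + ii * s2**2 + jj * s2 + kk)
        return out

    def parent_at(self, level: int, index: int) -> int:
        s = self.nside(level)
        cell, rem = divmod(index, s**3)
        i, rem = divmod(rem, s**2)
        j, k = divmod(rem, s)
        sp = s // 2
        return cell * sp**3 + (i // 2) * sp**2 + (j // 2) * sp + (k // 2)

    def quat(self, level: int, index: int) -> np.ndarray:
        s = self.nside(level)
        cell, rem = divmod(int(index), s**3)
        i, rem = divmod(rem, s**2)
        j, k = divmod(rem, s)
        w = 2.0 * ORI_CELL_HALFWIDTH / s
        p = np.array(
            [
                -ORI_CELL_HALFWIDTH + (i + 0.5) * w,
                -ORI_CELL_HALFWIDTH + (j + 0.5) * w,
                -ORI_CELL_HALFWIDTH + (k + 0.5) * w,
            ]
        )
        c = self.lattice.top_cells[cell]
        q = quat_multiply(c, np.array([1.0, *p]))
        return q / np.linalg.norm(q)

    def value(self, level: int, index: int) -> np.ndarray:
        return quat_to_rotation(self.quat(level, index))

    def values(self, level: int, indices) -> np.ndarray:
        return np.array([self.value(level, i) for i in np.asarray(indices)])

    def cell_width(self, level: int) -> float:
        """Approximate angular width (deg) of one sub-cell at this level."""
        return ORI_TOP_COVERAGE_DEG / self.nside(level)


# ---------------------------------------------------------------------------
# HierSampler: mixed-radix product of dimensions
# ---------------------------------------------------------------------------

@dataclass
class HierSampler:
    """Nested multi-resolution index space over a product of DOF dimensions.

    Indices at each level are mixed-radix encodings of per-dimension cell
    indices (last dimension fastest).  ``children``/``parent`` map indices
    between consecutive levels; ``expand`` maps indices to DOF value tuples.
    """

    dims: list
    n_levels: int = 5
    transform_fn: object = None  # optional: DOF tuple -> transform tuple

    def size(self, level: int) -> int:
        n = 1
        for d in self.dims:
            n *= d.ncells(level)
        return n

    def branching(self) -> int:
        n = 1
        for d in self.dims:
            n *= d.nchild()
        return n

    def _radices(self, level: int) -> list[int]:
        return [d.ncells(level) for d in self.dims]

    def decode(self, level: int, index: int) -> list[int]:
        out = []
        for r in reversed(self._radices(level)):
            index, digit = divmod(index, r)
            out.append(digit)
        return list(reversed(out))

    def encode(self, level: int, digits) -> int:
        index = 0
        for digit, r in zip(digits, self._radices(level)):
            index = index * r + digit
        return index

    def check_index(self, level: int, index: int) -> None:
        n = self.size(level)
        if not 0 <= index < n:
            raise IndexError(
                f"index {index} out of range at level {level} (max {n - 1})"
            )

    def children(self, level: int, index: int) -> list[int]:
        if level >= self.n_levels - 1:
            raise ValueError(f"level {level} is the finest level; no children")
        self.check_index(level, index)
        digits = self.decode(level, index)
        per_dim = []
        for d, digit in zip(self.dims, digits):
            if isinstance(d, OriDim):
                per_dim.append(d.children_at(level, digit))
            else:
                per_dim.append(d.children(digit))
        return [
            self.encode(level + 1, combo)
            for combo in itertools.product(*per_dim)
        ]

    def parent(self, level: int, index: int) -> int:
        """Parent index at level-1 of ``index`` at ``level`` (level >= 1)."""
        if level < 1:
            raise ValueError("level 0 has no parent")
        self.check_index(level, index)
        digits = self.decode(level, index)
        pdigits = []
        for d, digit in zip(self.dims, digits):
            if isinstance(d, OriDim):
                pdigits.append(d.parent_at(level, digit))
            else:
                pdigits.append(d.parent(digit))
        return self.encode(level - 1, pdigits)

    def expand(self, level: int, indices) -> list[tuple]:
        """Map indices to DOF value tuples (floats / rotation matrices / choices)."""
        out = []
        for index in np.atleast_1d(np.asarray(indices, dtype=np.int64)):
            self.check_index(level, int(index))
            digits = self.decode(level, int(index))
            out.append(
                tuple(d.value(level, dig) for d, dig in zip(self.dims, digits))
            )
        return out


def hier_expand(sampler: HierSampler, level: int, indices):
    """Expand indices to transforms via the sampler's transform_fn (or DOF tuples)."""
    vals = sampler.expand(level, indices)
    if sampler.transform_fn is None:
        return vals
    return [sampler.transform_fn(v) for v in vals]


def hier_children(sampler: HierSampler, level: int, index: int) -> list[int]:
    return sampler.children(level, index)


def enumeration_size(top_level_samples: int, subdivisions: int, ndim: int) -> int:
    """Total transforms in an enumerative search: top samples x subdiv^ndim."""
    return int(top_level_samples) * int(subdivisions) ** int(ndim)
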