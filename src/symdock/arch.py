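"""Symmetric architecture definitions: keywords, symmetry frames, kinematics.

An architecture fixes, for each building-block component, the global symmetry
axis its internal cyclic axis is aligned to, the one or more rigid-body DOFs
it may sample (rotation about and translation along that axis, plus an
optional 180-degree flip), and the global symmetry frames that regenerate the
full assembly from the asymmetric unit.

Canonical axis conventions (frozen constants, tested via inter-axis angles):

* T: 2-fold on z, 3-folds on the cube body diagonals (1,1,1)/sqrt3 and
  (1,1,-1)/sqrt3 (adjacent pair, 70.53 deg apart)
* O: 4-fold on z, 3-fold on (1,1,1)/sqrt3, 2-fold on (1,1,0)/sqrt2
* I: 2-folds on the coordinate axes; 5-fold through the icosahedron vertex
  (0, 1, phi), 3-fold through the face center (1/phi, 0, phi), adjacent to
  both (37.38 deg from the 5-fold, 20.91 deg from the z 2-fold)
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

from . import geom

PHI = (1.0 + math.sqrt(5.0)) / 2.0

_Z = np.array([0.0, 0.0, 1.0])

AXES = {
    "T": {
        2: _Z,
        3: np.array([1.0, 1.0, 1.0]) / math.sqrt(3.0),
        33: np.array([1.0, 1.0, -1.0]) / math.sqrt(3.0),  # second 3-fold (T33)
    },
    "O": {
        4: _Z,
        3: np.array([1.0, 1.0, 1.0]) / math.sqrt(3.0),
        2: np.array([1.0, 1.0, 0.0]) / math.sqrt(2.0),
    },
    "I": {
        2: _Z,
        3: np.array([1.0 / PHI, 0.0, PHI]) / math.sqrt(3.0),
        5: np.array([0.0, 1.0, PHI]) / math.sqrt(1.0 + PHI**2),
    },
}

GROUP_ORDER = {"T": 12, "O": 24, "I": 60}

# wallpaper site tables: plane group -> {cyclic order: fractional (u, v) site}
# (conventional Wyckoff rotation sites of p4, p3, p6)
WALLPAPER_SITES = {
    "P4": {4: [(0.0, 0.0), (0.5, 0.5)], 2: [(0.5, 0.0)]},
    "P3": {3: [(0.0, 0.0), (1.0 / 3.0, 2.0 / 3.0), (2.0 / 3.0, 1.0 / 3.0)]},
    "P6": {6: [(0.0, 0.0)], 3: [(1.0 / 3.0, 2.0 / 3.0)], 2: [(0.5, 0.0)]},
}

SUPPORTED_KEYWORDS = (
    "ASYM, C[n], D[n] / D[n]_[n] / D[n]_2, AXLE_[n] / AXLE_1_[m]_[n], "
    "T2 T3 O2 O3 O4 I2 I3 I5, T32 T33 O32 O42 O43 I32 I52 I53, "
    "T332 O432 I532, P6_632 P6_63 P6_62 P6_32 P3_33 P4_42 P4_44"
)


class ArchitectureError(ValueError):
    pass


@dataclass
class ArchSpec:
    """A docking architecture: components, axes, DOFs, and symmetry frames."""

    name: str
    n_components: int
    comp_nfold: list  # cyclic order of each component
    comp_axis: list  # global unit axis each component's internal z aligns to
    frames: np.ndarray  # (nframe, 4, 4) global symmetry operations
    kind: str = "point"  # point | cyclic | dihedral | stack | wallpaper | asym
    lattice: np.ndarray = None  # (2, 3) lattice vectors for wallpaper groups
    wallpaper_sites: list = None  # per-component fractional (u, v) site

    def angular_bound(self, comp: int) -> float:
        """Default upper angular sampling bound: 360 / nfold (half-open)."""
        return 360.0 / self.comp_nfold[comp]


# ---------------------------------------------------------------------------
# symmetry frame generation
# ---------------------------------------------------------------------------

def _cyclic_frames(n: int, axis=_Z) -> np.ndarray:
    return np.array([geom.hrot(axis, 360.0 * i / n) for i in range(n)])


def _closure(generators, order: int, tol: float = 1e-6) -> np.ndarray:
    """Generate a finite rotation group from generators by closure."""
    frames = [np.eye(4)]

    def seen(X):
        return any(np.allclose(X, F, atol=tol) for F in frames)

    added = True
    while added:
        added = False
        for F in list(frames):
            for G in generators:
                H = G @ F
                if not seen(H):
                    frames.append(H)
                    added = True
        if len(frames) > order:
            raise ArchitectureError("group closure exceeded expected order")
    if len(frames) != order:
        raise ArchitectureError(
            f"group closure gave {len(frames)} elements, expected {order}"
        )
    return np.array(frames)


_POINT_CACHE: dict = {}


def sym_frames(group: str) -> np.ndarray:
    """Symmetry frames of Cn, Dn, T, O, I as 4x4 transforms (identity first)."""
    group = group.upper()
    if group in _POINT_CACHE:
        return _POINT_CACHE[group]
    m = re.fullmatch(r"C(\d+)", group)
    if m:
        out = _cyclic_frames(int(m.group(1)))
    elif re.fullmatch(r"D(\d+)", group):
        n = int(group[1:])
        cyc = _cyclic_frames(n)
        flip = geom.hrot([1.0, 0.0, 0.0], 180.0)
        out = np.concatenate([cyc, np.array([F @ flip for F in cyc])])
    elif group == "T":
        out = _closure(
            [geom.hrot(AXES["T"][2], 180.0), geom.hrot(AXES["T"][3], 120.0)], 12
        )
    elif group == "O":
        out = _closure(
            [geom.hrot(_Z, 90.0), geom.hrot(AXES["O"][3], 120.0)], 24
        )
    elif group == "I":
        out = _closure(
            [geom.hrot(AXES["I"][5], 72.0), geom.hrot(AXES["I"][2], 180.0)], 60
        )
    else:
        raise ArchitectureError(
            f"unsupported symmetry group {group!r}; supported: Cn, Dn, T, O, I"
        )
    _POINT_CACHE[group] = out
    return out


# ---------------------------------------------------------------------------
# architecture parsing
# ---------------------------------------------------------------------------

def parse_architecture(keyword: str) -> ArchSpec:
    """Parse an architecture keyword (case-insensitive) into an ArchSpec."""
    kw = keyword.strip().upper()
    if kw == "ASYM":
        return ArchSpec(
            name="ASYM", n_components=2, comp_nfold=[1, 1],
            comp_axis=[_Z.copy(), _Z.copy()],
            frames=np.eye(4)[None], kind="asym",
        )
    m = re.fullmatch(r"C(\d+)", kw)
    if m:
        n = int(m.group(1))
        return ArchSpec(
            name=kw, n_components=1, comp_nfold=[n], comp_axis=[_Z.copy()],
            frames=sym_frames(kw), kind="cyclic",
        )
    m = re.fullmatch(r"D(\d+)(?:_(\d+))?", kw)
    if m:
        n = int(m.group(1))
        sub = int(m.group(2)) if m.group(2) else n
        if sub == n:
            axis, nfold = _Z.copy(), n
        elif sub == 2:
            # dimer aligned to an in-plane dihedral 2-fold (the x axis)
            axis, nfold = np.array([1.0, 0.0, 0.0]), 2
        else:
            raise ArchitectureError(
                f"dihedral keyword {keyword!r}: suffix must be the n-fold ({n}) or 2"
            )
        return ArchSpec(
            name=kw, n_components=1, comp_nfold=[nfold], comp_axis=[axis],
            frames=sym_frames(f"D{n}"), kind="dihedral",
        )
    m = re.fullmatch(r"AXLE_(\d+)", kw) or re.fullmatch(r"AXLE_1_(\d+)_(\d+)", kw)
    if m:
        if len(m.groups()) == 1:
            m1 = n1 = int(m.group(1))
        else:
            m1, n1 = int(m.group(1)), int(m.group(2))
            if m1 == n1:
                raise ArchitectureError("AXLE_1_[m]_[n] requires m != n")
            if m1 > 5 or n1 > 6:
                raise ArchitectureError("AXLE supports up to m=5 and n=6")
        g = math.gcd(m1, n1)
        return ArchSpec(
            name=kw, n_components=2, comp_nfold=[m1, n1],
            comp_axis=[_Z.copy(), _Z.copy()],
            frames=sym_frames(f"C{g}"), kind="stack",
        )
    m = re.fullmatch(r"([TOI])(\d)(\d)?(\d)?", kw)
    if m:
        grp = m.group(1)
        nfolds = [int(x) for x in m.groups()[1:] if x]
        axes = []
        seen3 = 0
        for nf in nfolds:
            if grp == "T" and nf == 3 and seen3 == 1:
                axes.append(AXES["T"][33].copy())
            elif nf in AXES[grp]:
                axes.append(AXES[grp][nf].copy())
            else:
                raise ArchitectureError(
                    f"{grp} has no {nf}-fold axis (keyword {keyword!r})"
                )
            if nf == 3:
                seen3 += 1
        valid = {
            "T": {(2,), (3,), (3, 2), (3, 3), (3, 3, 2)},
            "O": {(2,), (3,), (4,), (3, 2), (4, 2), (4, 3), (4, 3, 2)},
            "I": {(2,), (3,), (5,), (3, 2), (5, 2), (5, 3), (5, 3, 2)},
        }
        if tuple(nfolds) not in valid[grp]:
            raise ArchitectureError(
                f"unsupported polyhedral keyword {keyword!r}; supported: {SUPPORTED_KEYWORDS}"
            )
        return ArchSpec(
            name=kw, n_components=len(nfolds), comp_nfold=nfolds,
            comp_axis=axes, frames=sym_frames(grp), kind="point",
        )
    m = re.fullmatch(r"P(\d)_(\d+)", kw)
    if m:
        return _parse_wallpaper(kw, int(m.group(1)), m.group(2))
    raise ArchitectureError(
        f"unknown architecture keyword {keyword!r}; supported: {SUPPORTED_KEYWORDS}"
    )


def _parse_wallpaper(kw: str, lat: int, folds: str) -> ArchSpec:
    nfolds = [int(c) for c in folds]
    pg = f"P{lat}"
    if pg not in WALLPAPER_SITES:
        raise ArchitectureError(f"unsupported wallpaper lattice in {kw!r}")
    sites = []
    used: dict = {}
    for nf in nfolds:
        table = WALLPAPER_SITES[pg].get(nf)
        if not table:
            raise ArchitectureError(
                f"wallpaper group {pg} has no {nf}-fold site (keyword {kw!r})"
            )
        k = used.get(nf, 0)
        if k >= len(table):
            raise ArchitectureError(
                f"wallpaper group {pg} has only {len(table)} distinct {nf}-fold sites"
            )
        sites.append(table[k])
        used[nf] = k + 1
    # unit lattice vectors (lattice scale is a runtime DOF)
    if lat == 4:
        a, b = np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])
    else:  # hexagonal for P3 / P6
        a = np.array([1.0, 0.0, 0.0])
        b = np.array([-0.5, math.sqrt(3.0) / 2.0, 0.0])
    frames = _cyclic_frames(lat)  # site point-group rotations about z
    return ArchSpec(
        name=kw, n_components=len(nfolds), comp_nfold=nfolds,
        comp_axis=[_Z.copy() for _ in nfolds], frames=frames,
        kind="wallpaper", lattice=np.array([a, b]), wallpaper_sites=sites,
    )


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def place_component(
    spec: ArchSpec, comp: int, rot_deg: float, disp: float, flipped: bool = False
) -> np.ndarray:
    """Rigid placement of component ``comp`` at DOF values (rot, disp, flip).

    The component is assumed pre-aligned with its internal cyclic axis on z
    and center of mass near the origin.  Operation order (fixed):
    align(z -> comp_axis) . translate(disp * z) . rotz(rot_deg) . flip,
    where flip is a 180-degree rotation about x.
    """
    X = geom.align_vector(_Z, spec.comp_axis[comp])
    X = X @ geom.htrans([0.0, 0.0, disp])
    X = X @ geom.hrot(_Z, rot_deg)
    if flipped:
        X = X @ geom.hrot([1.0, 0.0, 0.0], 180.0)
    return X


def wallpaper_frames(spec: ArchSpec, n_cells: int, lattice_scale: float = 100.0) -> np.ndarray:
    """Frames for an n_cells x n_cells wallpaper patch at a given lattice scale.

    Point-group rotations about z composed with the lattice translations of
    the patch.  The lattice scale (Angstrom per unit cell) is a DOF sampled
    alongside the component DOFs during wallpaper docking.
    """
    if spec.kind != "wallpaper":
        raise ArchitectureError(f"{spec.name} is not a wallpaper architecture")
    a = spec.lattice[0] * lattice_scale
    b = spec.lattice[1] * lattice_scale
    out = []
    for i in range(n_cells):
        for j in range(n_cells):
            T = geom.htrans(i * a + j * b)
            for F in spec.frames:
                out.append(T @ F)
    return np.array(out)


def assembly_coords(
    spec: ArchSpec, bodies: list, placements: list, frames: np.ndarray = None
) -> list:
    """CA coordinate blocks for every chain of the expanded assembly."""
    frames = spec.frames if frames is None else frames
    chains = []
    for F in frames:
        for bd, X in zip(bodies, placements):
            chains.append(geom.xform_points(F @ X, bd.ca_coords))
    return chains
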