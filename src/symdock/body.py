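"""Structure ingestion, secondary structure, and sphere-BVH geometry queries.

A :class:`Body` holds one rigid building block: backbone coordinates, residue
stub frames, a secondary-structure string, and two sphere bounding-volume
hierarchies (all backbone atoms for clash/slide, CA atoms for contact-pair
collection).  Sphere BVHs are used instead of axis-aligned boxes because a
sphere tree is invariant under rigid motion: the same tree answers queries for
any placement of the body by transforming sphere centers on the fly.

Conventions (documented here because the queries and scores depend on them):

* center of mass = mean of CA coordinates
* long axis = unit principal eigenvector of the CA coordinate covariance
* contact definition = CA-CA distance <= maxdist
* clash definition = any backbone-atom pair closer than mindist (default 3 A)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import geom

log = logging.getLogger(__name__)

CLASH_DIST_DEFAULT = 3.0  # Angstrom, non-hydrogen backbone atoms

_BACKBONE = ("N", "CA", "C")

NO_CONTACT = math.inf  # sentinel returned by slide when no contact is possible


# ---------------------------------------------------------------------------
# sphere bounding volume hierarchy
# ---------------------------------------------------------------------------

class SphereBVH:
    """Binary sphere tree over a point set, median-split on the widest axis.

    Leaves hold single points (zero-radius spheres); internal nodes hold the
    smallest enclosing sphere of their children (center = midpoint bound).
    Queries take the rigid placements of both trees and are exact: they prune
    with sphere bounds but test leaf pairs with true distances, so any valid
    tree gives brute-force-identical answers.
    """

    def __init__(self, points: np.ndarray):
        pts = np.asarray(points, float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) == 0:
            raise ValueError("SphereBVH needs an (n,3) nonempty point array")
        self.points = pts
        # arrays: center (nnode,3), radius (nnode,), left/right (-1 leaf), leaf id
        centers, radii, lefts, rights, leaf_ids = [], [], [], [], []

        def build(idx: np.ndarray) -> int:
            node = len(centers)
            centers.append(np.zeros(3))
            radii.append(0.0)
            lefts.append(-1)
            rights.append(-1)
            leaf_ids.append(-1)
            if len(idx) == 1:
                centers[node] = pts[idx[0]]
                leaf_ids[node] = int(idx[0])
                return node
            sub = pts[idx]
            lo, hi = sub.min(axis=0), sub.max(axis=0)
            axis = int(np.argmax(hi - lo))
            order = np.argsort(sub[:, axis], kind="stable")
            half = len(idx) // 2
            li = build(idx[order[:half]])
            ri = build(idx[order[half:]])
            # enclosing sphere of the two child spheres
            c1, r1 = centers[li], radii[li]
            c2, r2 = centers[ri], radii[ri]
            d = float(np.linalg.norm(c2 - c1))
            if d < 1e-12:
                c, r = c1.copy(), max(r1, r2)
            elif d + r2 <= r1:
                c, r = c1.copy(), r1
            elif d + r1 <= r2:
                c, r = c2.copy(), r2
            else:
                r = (d + r1 + r2) / 2.0
                c = c1 + (c2 - c1) * ((r - r1) / d)
            centers[node] = c
            radii[node] = r
            lefts[node] = li
            rights[node] = ri
            return node

        build(np.arange(len(pts)))
        self.center = np.array(centers)
        self.radius = np.array(radii)
        self.left = np.array(lefts)
        self.right = np.array(rights)
        self.leaf_id = np.array(leaf_ids)

    # -- queries ------------------------------------------------------------

    def isect(self, other: "SphereBVH", Xa, Xb, mindist: float) -> bool:
        """True iff some cross-tree point pair is closer than ``mindist``."""
        ca = geom.xform_points(Xa, self.center)
        cb = geom.xform_points(Xb, other.center)

        def recurse(i: int, j: int) -> bool:
            d = np.linalg.norm(ca[i] - cb[j])
            if d - self.radius[i] - other.radius[j] >= mindist:
                return False
            ileaf = self.left[i] < 0
            jleaf = other.left[j] < 0
            if ileaf and jleaf:
                return d < mindist
            if jleaf or (not ileaf and self.radius[i] >= other.radius[j]):
                return recurse(self.left[i], j) or recurse(self.right[i], j)
            return recurse(i, other.left[j]) or recurse(i, other.right[j])

        return recurse(0, 0)

    def slide(self, other: "SphereBVH", Xa, Xb, direction, mindist: float) -> float:
        """Minimal translation of ``other`` along ``direction`` reaching contact.

        Returns the signed translation t such that after moving the second
        tree by t*direction the closest cross pair is exactly ``mindist``
        apart, or :data:`NO_CONTACT` if no pair can come within ``mindist``.
        """
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        pa = geom.xform_points(Xa, self.center)
        pb = geom.xform_points(Xb, other.center)
        best = [NO_CONTACT]

        def pair_t(p, q, m) -> float:
            # |q + t d - p| = m ; first-touch root
            w = q - p
            b = float(np.dot(d, w))
            cc = float(np.dot(w, w)) - m * m
            disc = b * b - cc
            if disc < 0:
                return NO_CONTACT
            return -b - math.sqrt(disc)

        def recurse(i: int, j: int) -> None:
            bound = pair_t(
                pa[i], pb[j], mindist + self.radius[i] + other.radius[j]
            )
            if bound >= best[0]:
                return
            ileaf = self.left[i] < 0
            jleaf = other.left[j] < 0
            if ileaf and jleaf:
                t = pair_t(pa[i], pb[j], mindist)
                if t < best[0]:
                    best[0] = t
                return
            if jleaf or (not ileaf and self.radius[i] >= other.radius[j]):
                recurse(self.left[i], j)
                recurse(self.right[i], j)
            else:
                recurse(i, other.left[j])
                recurse(i, other.right[j])

        recurse(0, 0)
        return best[0]

    def collect_pairs(self, other: "SphereBVH", Xa, Xb, maxdist: float) -> list:
        """All cross-tree point-id pairs within ``maxdist`` (inclusive)."""
        ca = geom.xform_points(Xa, self.center)
        cb = geom.xform_points(Xb, other.center)
        out = []

        def recurse(i: int, j: int) -> None:
            d = np.linalg.norm(ca[i] - cb[j])
            if d - self.radius[i] - other.radius[j] > maxdist:
                return
            ileaf = self.left[i] < 0
            jleaf = other.left[j] < 0
            if ileaf and jleaf:
                if d <= maxdist:
                    out.append((int(self.leaf_id[i]), int(other.leaf_id[j])))
                return
            if jleaf or (not ileaf and self.radius[i] >= other.radius[j]):
                recurse(self.left[i], j)
                recurse(self.right[i], j)
            else:
                recurse(i, other.left[j])
                recurse(i, other.right[j])

        recurse(0, 0)
        return out


# ---------------------------------------------------------------------------
# Body
# ---------------------------------------------------------------------------

@dataclass
class Body:
    """A rigid building block: coordinates, stubs, SS, and query structures."""

    coords: np.ndarray  # (natom, 3) backbone atoms, grouped N,CA,C per residue
    atom_names: list
    bb_index: np.ndarray  # (nres, 3) atom indices of N, CA, C
    ss: str = ""
    stubs: np.ndarray = None  # (nres, 4, 4)
    chain_breaks: list = field(default_factory=list)  # residue index after which a break occurs
    allowed_mask: np.ndarray = None  # (nres,) bool, True = contributes to score
    label: str = "body"
    probe_coords: np.ndarray = None  # optional termini-access helix atoms (clash only)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        self.bb_index = np.asarray(self.bb_index, int)
        n, ca, c = (self.coords[self.bb_index[:, i]] for i in range(3))
        if self.stubs is None:
            self.stubs = geom.stubs_from_backbone_arrays(n, ca, c)
        if not self.ss:
            self.ss = assign_ss(self)
        if self.allowed_mask is None:
            self.allowed_mask = np.ones(self.nres, dtype=bool)
        self._bvh_all = None
        self._bvh_ca = None

    # -- basic geometry -----------------------------------------------------

    @property
    def nres(self) -> int:
        return len(self.bb_index)

    @property
    def ca_coords(self) -> np.ndarray:
        return self.coords[self.bb_index[:, 1]]

    @property
    def com(self) -> np.ndarray:
        """Center of mass: mean CA coordinate (documented convention)."""
        return self.ca_coords.mean(axis=0)

    @property
    def long_axis(self) -> np.ndarray:
        """Unit principal eigenvector of the CA coordinate covariance."""
        ca = self.ca_coords - self.com
        cov = ca.T @ ca / len(ca)
        w, v = np.linalg.eigh(cov)
        axis = v[:, -1]
        return axis if axis[2] >= 0 else -axis

    @property
    def radius(self) -> float:
        """Bounding-sphere radius about the CA center of mass (incl. probe)."""
        r = float(np.linalg.norm(self.clash_coords - self.com, axis=1).max())
        return r

    @property
    def lever_radius(self) -> float:
        """Largest atom distance from either the com or the internal z axis.

        Used to bound how far interface atoms can move under one sampling
        cell's worth of rotation about the sampled axes.
        """
        r_axis = float(np.linalg.norm(self.clash_coords[:, :2], axis=1).max())
        return max(self.radius, r_axis)

    @property
    def clash_coords(self) -> np.ndarray:
        """Backbone atoms plus any termini-access probe atoms."""
        if self.probe_coords is not None and len(self.probe_coords):
            return np.vstack([self.coords, self.probe_coords])
        return self.coords

    @property
    def bvh_all(self) -> SphereBVH:
        if self._bvh_all is None:
            self._bvh_all = SphereBVH(self.clash_coords)
        return self._bvh_all

    @property
    def bvh_ca(self) -> SphereBVH:
        if self._bvh_ca is None:
            self._bvh_ca = SphereBVH(self.ca_coords)
        return self._bvh_ca

    def transformed(self, X: np.ndarray) -> "Body":
        """A new Body with every coordinate (and stub) moved by X."""
        b = Body(
            coords=geom.xform_points(X, self.coords),
            atom_names=list(self.atom_names),
            bb_index=self.bb_index.copy(),
            ss=self.ss,
            stubs=np.asarray(X) @ self.stubs,
            chain_breaks=list(self.chain_breaks),
            allowed_mask=self.allowed_mask.copy(),
            label=self.label,
            probe_coords=None
            if self.probe_coords is None
            else geom.xform_points(X, self.probe_coords),
        )
        return b

    # -- ss elements --------------------------------------------------------

    def ss_elements(self) -> np.ndarray:
        """Per-residue id of its secondary-structure element (-1 for loops).

        An element is a maximal run of H or of E not crossing a chain break.
        """
        ids = np.full(self.nres, -1, dtype=int)
        cur = -1
        breaks = set(self.chain_breaks)
        for i, s in enumerate(self.ss):
            if s in "HE" and i > 0 and self.ss[i - 1] == s and (i - 1) not in breaks:
                ids[i] = cur
            elif s in "HE":
                cur += 1
                ids[i] = cur
        return ids

    # -- PDB ----------------------------------------------------------------

    def to_pdb_string(self, chain: str = "A") -> str:
        return _write_pdb_records(self, chain)


# ---------------------------------------------------------------------------
# query functions (spec surface)
# ---------------------------------------------------------------------------

def bvh_isect(a: Body, xa, b: Body, xb, mindist: float) -> bool:
    """True iff some cross-body backbone-atom pair is closer than ``mindist``."""
    return a.bvh_all.isect(b.bvh_all, xa, xb, mindist)


def bvh_slide(a: Body, b: Body, direction, mindist: float, xa=None, xb=None) -> float:
    """Signed translation of ``b`` along ``direction`` to exact ``mindist`` contact."""
    xa = np.eye(4) if xa is None else xa
    xb = np.eye(4) if xb is None else xb
    return a.bvh_all.slide(b.bvh_all, xa, xb, direction, mindist)


def collect_pairs(a: Body, xa, b: Body, xb, maxdist: float) -> list:
    """Residue index pairs with CA-CA distance <= maxdist, no duplicates."""
    if maxdist <= 0:
        return []
    return a.bvh_ca.collect_pairs(b.bvh_ca, xa, xb, maxdist)


def collect_pairs_brute(a: Body, xa, b: Body, xb, maxdist: float) -> list:
    """Brute-force oracle for collect_pairs (used by tests and batch scoring)."""
    if maxdist <= 0:
        return []
    ca = geom.xform_points(xa, a.ca_coords)
    cb = geom.xform_points(xb, b.ca_coords)
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    ii, jj = np.nonzero(d <= maxdist)
    return list(zip(ii.tolist(), jj.tolist()))


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

def backbone_dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral (degrees), standard biomolecular convention."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    return math.degrees(math.atan2(y, x))


def assign_ss(body: Body, min_helix: int = 4, min_strand: int = 3) -> str:
    """Assign {H,E,L} from backbone phi/psi with minimum run lengths.

    A deliberately lightweight dihedral heuristic: a residue is helix-like if
    (phi, psi) falls in the alpha basin (-120<phi<-30, -100<psi<0), strand-like
    in the beta basin (-180<phi<-40, 90<psi<=180 or psi<-150).  Terminal
    residues missing one dihedral inherit the classification of the available
    one.  Runs shorter than the minimum become loops.
    """
    n, ca, c = (body.coords[body.bb_index[:, i]] for i in range(3))
    nres = body.nres
    breaks = set(body.chain_breaks)
    cls = []
    for i in range(nres):
        phi = psi = None
        if i > 0 and (i - 1) not in breaks:
            phi = backbone_dihedral(c[i - 1], n[i], ca[i], c[i])
        if i < nres - 1 and i not in breaks:
            psi = backbone_dihedral(n[i], ca[i], c[i], n[i + 1])
        h = e = True
        if phi is not None:
            h &= -120 < phi < -30
            e &= -180 <= phi < -40
        if psi is not None:
            h &= -100 < psi < 0
            e &= (90 < psi <= 180) or (psi < -150)
        if phi is None and psi is None:
            h = e = False
        cls.append("H" if h else ("E" if e and not h else "L"))
    # enforce run lengths
    out = list(cls)
    i = 0
    while i < nres:
        j = i
        while j < nres and cls[j] == cls[i] and not (j > i and (j - 1) in breaks):
            j += 1
        run = j - i
        if cls[i] == "H" and run < min_helix:
            out[i:j] = ["L"] * run
        if cls[i] == "E" and run < min_strand:
            out[i:j] = ["L"] * run
        i = j
    return "".join(out)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def load_body(pdb_source: str, recenter: bool = False, label: str = "body") -> Body:
    """Build a Body from PDB-format text (or a path to a .pdb file).

    Residues are renumbered sequentially from 1 ignoring numeric gaps; chains
    are concatenated with a recorded chain break; residues missing any of
    N/CA/C are skipped with a warning; only the first MODEL is read and for
    altLocs the highest-occupancy copy is kept.
    """
    import gemmi

    text = pdb_source
    if "\n" not in pdb_source and pdb_source.endswith(".pdb"):
        with open(pdb_source) as fh:
            text = fh.read()
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise ValueError("empty structure: no models in PDB input")
    st.remove_alternative_conformations()  # keeps highest-occupancy altLoc
    model = st[0]
    coords, names, bb_index, breaks = [], [], [], []
    nres = 0
    for chain in model:
        chain_start = nres
        for res in chain:
            atoms = {}
            for at in res:
                if at.name in _BACKBONE and at.name not in atoms:
                    atoms[at.name] = [at.pos.x, at.pos.y, at.pos.z]
            if len(atoms) < 3:
                log.warning(
                    "skipping residue %s %s in chain %s: incomplete backbone",
                    res.name, res.seqid.num, chain.name,
                )
                continue
            idx = []
            for nm in _BACKBONE:
                idx.append(len(coords))
                coords.append(atoms[nm])
                names.append(nm)
            bb_index.append(idx)
            nres += 1
        if chain_start < nres:
            breaks.append(nres - 1)  # provisional break after each chain
    if nres == 0:
        raise ValueError("empty structure: no residues with complete N/CA/C backbone")
    breaks = [b for b in breaks if b < nres - 1]  # last chain ends the body
    body = Body(
        coords=np.array(coords),
        atom_names=names,
        bb_index=np.array(bb_index),
        chain_breaks=breaks,
        label=label,
    )
    if recenter:
        body = body.transformed(geom.htrans(-body.com))
    return body


def _write_pdb_records(body: Body, chain: str, start_serial: int = 1, start_res: int = 1) -> str:
    lines = []
    serial = start_serial
    for ires in range(body.nres):
        for k, nm in enumerate(_BACKBONE):
            x, y, z = body.coords[body.bb_index[ires, k]]
            lines.append(
                f"ATOM  {serial:5d}  {nm:<3s}{'GLY':>4s} {chain:1s}"
                f"{start_res + ires:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}           {nm[0]:>2s}"
            )
            serial += 1
    return "\n".join(lines) + "\n"
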