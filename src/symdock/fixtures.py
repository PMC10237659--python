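"""Deterministic toy structures and synthetic hscore tables.

Everything other modules need for testing is generated here from seeds and
ideal geometry: canonical alpha-helix backbones (built residue-by-residue
from ideal bond lengths/angles and helical phi/psi), clash-free cyclic rings
of helices as stand-ins for oligomeric building blocks, and synthetic
multi-resolution hscore tables whose coarse levels are constructed to
upper-bound their refinements so hierarchical pruning is admissible by
construction.  Synthetic tables are anchored on helix-pair packing
geometries, qualitatively emulating a helix-only motif subset; their scores
are invented favorability values, not energies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import body as _body
from . import geom, rpxscore

# ideal backbone internal coordinates (lengths A, angles deg)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
HELIX_PHI = -57.0
HELIX_PSI = -47.0
OMEGA = 180.0

IDEAL_HELIX_LEN = 21  # the termini probe helix length


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the deterministic fixture generators."""

    seed: int = 0
    helix_len: int = 21
    oligomer_nfold: int = 3
    radius: float = 12.0
    hscore_n_keys: int = 50
    hscore_score_range: tuple = (1.0, 10.0)


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Next atom position from three predecessors and internal coordinates."""
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-math.cos(theta), math.sin(theta) * math.cos(chi), math.sin(theta) * math.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def backbone_from_dihedrals(phi_psi: list) -> np.ndarray:
    """Backbone N/CA/C coordinates from a (phi, psi) list, ideal geometry."""
    nres = len(phi_psi)
    coords = np.zeros((nres * 3, 3))
    coords[0] = [0.0, 0.0, 0.0]  # N0
    coords[1] = [BOND_N_CA, 0.0, 0.0]  # CA0
    th = math.radians(ANGLE_N_CA_C)
    coords[2] = coords[1] + BOND_CA_C * np.array([-math.cos(th), math.sin(th), 0.0])
    for i in range(1, nres):
        _, psi_prev = phi_psi[i - 1]
        phi_i, _ = phi_psi[i]
        nprev, caprev, cprev = coords[3 * i - 3], coords[3 * i - 2], coords[3 * i - 1]
        ni = _place_atom(nprev, caprev, cprev, BOND_C_N, ANGLE_CA_C_N, psi_prev)
        cai = _place_atom(caprev, cprev, ni, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        ci = _place_atom(cprev, ni, cai, BOND_CA_C, ANGLE_N_CA_C, phi_i)
        coords[3 * i : 3 * i + 3] = [ni, cai, ci]
    return coords


def _body_from_backbone(coords: np.ndarray, label: str) -> _body.Body:
    nres = len(coords) // 3
    return _body.Body(
        coords=coords,
        atom_names=["N", "CA", "C"] * nres,
        bb_index=np.arange(nres * 3).reshape(nres, 3),
        label=label,
    )


def make_ideal_helix(n: int) -> _body.Body:
    """Canonical alpha helix of ``n`` residues, axis on z, com at the origin.

    Built from ideal internal coordinates with phi/psi = (-57, -47); the
    resulting rise is ~1.5 A per residue with ~100 degrees of turn.
    """
    if n < 4:
        raise ValueError(f"need at least 4 residues for a helix, got {n}")
    coords = backbone_from_dihedrals([(HELIX_PHI, HELIX_PSI)] * n)
    bd = _body_from_backbone(coords, label=f"helix{n}")
    # align the helix axis (principal CA axis) to +z, N->C toward +z
    axis = bd.long_axis
    ca = bd.ca_coords
    if np.dot(ca[-1] - ca[0], axis) < 0:
        axis = -axis
    X = geom.align_vector(axis, [0.0, 0.0, 1.0]) @ geom.htrans(-bd.com)
    return bd.transformed(X)


def make_toy_oligomer(monomer: _body.Body, nfold: int, radius: float) -> _body.Body:
    """Asymmetric unit of a clash-free Cn ring: the monomer at +x offset.

    The returned Body is pre-aligned per the docking input conventions: the
    ring's cyclic axis is z, the ring center of mass is on the axis, and the
    asu sits at the given radius.  Raises if the requested radius leaves
    symmetry neighbors clashing.
    """
    if nfold < 2:
        raise ValueError("oligomer nfold must be >= 2")
    asu = monomer.transformed(geom.htrans([radius, 0.0, 0.0]))
    F = geom.hrot([0.0, 0.0, 1.0], 360.0 / nfold)
    if _body.bvh_isect(asu, np.eye(4), asu, F, _body.CLASH_DIST_DEFAULT):
        raise ValueError(
            f"C{nfold} ring at radius {radius} A clashes; use a larger radius"
        )
    return asu


# ---------------------------------------------------------------------------
# synthetic hscore tables
# ---------------------------------------------------------------------------

def helix_pair_anchor_xforms(gap: float = 9.0, crossing: float = -35.0) -> list:
    """Relative stub transforms of a canonical packed helix pair.

    A second ideal helix is placed ``gap`` A away with the classic packing
    crossing angle; the relative transforms of all contacting residue pairs
    anchor the synthetic tables on realistic helix-packing geometry.
    """
    h = make_ideal_helix(14)
    X2 = geom.htrans([gap, 0.0, 0.0]) @ geom.hrot([1.0, 0.0, 0.0], crossing)
    pairs = _body.collect_pairs_brute(h, np.eye(4), h, X2, 8.0)
    out = []
    for i, j in pairs:
        out.append(geom.hinv(h.stubs[i]) @ X2 @ h.stubs[j])
    return out


def build_table_from_entries(
    entries: list,
    n_levels: int = 4,
    cart_resl: float = geom.DEFAULT_CART_RESL,
    ori_resl: float = geom.DEFAULT_ORI_RESL,
    subset_tag: str = "SYNTH_H",
    level_extras: dict = None,
) -> rpxscore.HScoreTable:
    """Build an admissible multi-resolution table from (xform, score) entries.

    The finest level bins each entry (and its inverse) directly.  Each coarse
    level re-bins every entry after perturbing it across the span of one
    coarse cell (translation offsets in half-steps of the cell width, small
    rotations about each axis), taking the max into every key touched: the
    spreading guarantees that any transform whose fine bin carries a score
    finds at least that score in its coarse bin, the admissibility needed for
    safe beam pruning.
    """
    xforms = []
    scores = []
    for X, v in entries:
        for Y in (np.asarray(X, float), geom.hinv(X)):
            xforms.append(Y)
            scores.append(float(v))
    xforms = np.array(xforms)
    scores = np.array(scores)
    levels = [dict() for _ in range(n_levels)]
    fine = n_levels - 1

    keys = rpxscore.bin_xforms(xforms, cart_resl, ori_resl, fine)
    _max_update(levels[fine], keys, scores)

    axes = np.eye(3)
    nx = len(xforms)
    for lvl in range(fine - 1, -1, -1):
        w, ores = rpxscore.level_resls(cart_resl, ori_resl, lvl)
        t_offsets = np.array(
            [
                (i, j, k)
                for i in (-1.0, -0.5, 0.0, 0.5, 1.0)
                for j in (-1.0, -0.5, 0.0, 0.5, 1.0)
                for k in (-1.0, -0.5, 0.0, 0.5, 1.0)
            ]
        ) * w
        rots = [np.eye(3)]
        for ax in range(3):
            for sgn in (1.0, -1.0):
                rots.append(geom.hrot(axes[ax], sgn * 0.5 * ores)[:3, :3])
        rots = np.array(rots)
        # one big (nrot * noff * nx) batch per level
        R = np.einsum("rij,njk->rnik", rots, xforms[:, :3, :3])
        R = np.broadcast_to(
            R[:, None], (len(rots), len(t_offsets), nx, 3, 3)
        )
        T = xforms[None, None, :, :3, 3] + t_offsets[None, :, None, :]
        T = np.broadcast_to(T, (len(rots), len(t_offsets), nx, 3))
        Xp = np.zeros((len(rots), len(t_offsets), nx, 4, 4))
        Xp[..., 3, 3] = 1.0
        Xp[..., :3, :3] = R
        Xp[..., :3, 3] = T
        Xp = Xp.reshape(-1, 4, 4)
        keys = rpxscore.bin_xforms(Xp, cart_resl, ori_resl, lvl)
        _max_update(levels[lvl], keys, np.tile(scores, len(rots) * len(t_offsets)))
    # extra per-level entries (e.g. a planted configuration's ancestor-cell
    # interfaces) binned directly at their level with a +-1 cell pad
    for lvl, extra in (level_extras or {}).items():
        if not extra:
            continue
        w, _ = rpxscore.level_resls(cart_resl, ori_resl, lvl)
        ex_x, ex_s = [], []
        for X, v in extra:
            for Y in (np.asarray(X, float), geom.hinv(X)):
                for off in itertools_product3((-w, 0.0, w)):
                    P = Y.copy()
                    P[:3, 3] = Y[:3, 3] + np.asarray(off)
                    ex_x.append(P)
                    ex_s.append(float(v))
        keys = rpxscore.bin_xforms(np.array(ex_x), cart_resl, ori_resl, lvl)
        _max_update(levels[lvl], keys, np.array(ex_s))
    return rpxscore.HScoreTable(
        cart_resl=cart_resl, ori_resl=ori_resl, levels=levels,
        subset_tag=subset_tag,
        provenance={"generator": "synthetic", "n_entries": len(entries)},
    )


def _max_update(table: dict, keys: np.ndarray, scores: np.ndarray) -> None:
    for k, v in zip(keys, scores):
        k = int(k)
        if k < 0:
            continue
        if v > table.get(k, 0.0):
            table[k] = float(v)


def make_synthetic_hscore(
    spec: FixtureSpec = FixtureSpec(),
    n_levels: int = 4,
    cart_resl: float = geom.DEFAULT_CART_RESL,
    ori_resl: float = geom.DEFAULT_ORI_RESL,
    anchor_xforms: list = None,
) -> rpxscore.HScoreTable:
    """Seeded synthetic hscore table concentrated around favorable geometry.

    Anchors default to ideal helix-pair packing transforms; ``hscore_n_keys``
    additional jittered copies with seeded scores broaden the landscape.
    """
    rng = np.random.default_rng(spec.seed)
    anchors = (
        helix_pair_anchor_xforms() if anchor_xforms is None else list(anchor_xforms)
    )
    lo, hi = spec.hscore_score_range
    entries = [(X, hi) for X in anchors]
    for _ in range(spec.hscore_n_keys):
        base = anchors[rng.integers(len(anchors))]
        jitter = geom.htrans(rng.normal(scale=2.0, size=3)) @ np.asarray(base)
        jitter = jitter @ geom.hrot(rng.normal(size=3), rng.normal(scale=15.0))
        entries.append((jitter, float(rng.uniform(lo, hi))))
    return build_table_from_entries(
        entries, n_levels=n_levels, cart_resl=cart_resl, ori_resl=ori_resl,
    )


def itertools_product3(vals):
    return [(a, b, c) for a in vals for b in vals for c in vals]


def _config_pair_entries(bodies, spec, placements, maxdist, score):
    """(relative stub transform, score) for every interface pair of a config.

    ``maxdist`` may be a float or a callable (comp_i, comp_j) -> float.
    """
    from . import search as _search

    out = []
    for ci, cj, F in _search.interface_terms(spec):
        Xi = placements[ci]
        Xj = np.asarray(F) @ placements[cj]
        md = maxdist(ci, cj) if callable(maxdist) else maxdist
        pairs = _body.collect_pairs_brute(
            bodies[ci], Xi, bodies[cj], Xj, md
        )
        for i, j in pairs:
            rel = geom.hinv(Xi @ bodies[ci].stubs[i]) @ (Xj @ bodies[cj].stubs[j])
            out.append((rel, score))
    return out


def _ancestor_dofs(sampler, dofs, level):
    """Cell-center DOFs of the ancestor cell containing ``dofs`` at a level."""
    fine = sampler.n_levels - 1
    out = []
    for dim, v in zip(sampler.dims, dofs):
        if not isinstance(dim, (geom.CartDim,)):
            out.append(v)
            continue
        wf = dim.cell_width(fine)
        i_f = int(np.clip(np.floor((v - dim.lo) / wf), 0, dim.ncells(fine) - 1))
        i_l = i_f >> (fine - level)
        out.append(dim.lo + (i_l + 0.5) * dim.cell_width(level))
    return tuple(out)


def hscore_from_dock(
    bodies,
    spec,
    layout,
    dof_tuple,
    n_levels: int = 3,
    cart_resl: float = geom.DEFAULT_CART_RESL,
    ori_resl: float = geom.DEFAULT_ORI_RESL,
    score: float = 10.0,
    max_pair_dist: float = 8.0,
    noise_entries: list = (),
    sampler=None,
) -> rpxscore.HScoreTable:
    """Table whose high-score keys are planted at one docked configuration.

    Places the bodies at the given DOFs, collects every cross-interface
    residue pair, and assigns the planted score to their relative-transform
    bins; optional noise entries add distractor keys.  When a sampler is
    given, the interfaces of the planted cell's ancestor-cell centers are
    additionally scored at each coarse level, so the planted configuration's
    entire refinement lineage carries an admissible upper bound even where
    component lever arms defeat the generic neighborhood spreading.
    """
    placements = layout.placements(dof_tuple)
    entries = list(noise_entries)
    entries += _config_pair_entries(bodies, spec, placements, max_pair_dist, score)
    if len(entries) == len(noise_entries):
        raise ValueError(
            "planted configuration has no interface contacts; move the "
            "components closer before building the table"
        )
    level_extras = {}
    if sampler is not None:
        from . import search as _search

        levers = [bd.lever_radius for bd in bodies]
        for lvl in range(n_levels - 1):
            adofs = _ancestor_dofs(sampler, dof_tuple, lvl)
            apl = layout.placements(adofs)
            maxd = lambda ci, cj, lvl=lvl: max_pair_dist + _search.interface_margin(
                cart_resl, ori_resl, lvl, levers[ci], levers[cj]
            )
            level_extras[lvl] = _config_pair_entries(
                bodies, spec, apl, maxd, score
            )
    return build_table_from_entries(
        entries, n_levels=n_levels, cart_resl=cart_resl, ori_resl=ori_resl,
        subset_tag="PLANTED", level_extras=level_extras,
    )


# ---------------------------------------------------------------------------
# exhaustive docking oracle
# ---------------------------------------------------------------------------

def brute_force_dock_oracle(bodies, spec, resolutions, table, params, cfg=None):
    """Exhaustive enumeration at a single resolution: the search oracle.

    Enumerates every sampler cell at the stated (cart, ori) resolution,
    clash-filters, scores, and returns the full ranked StageResult.  Shares
    the scoring definition with grid_search by construction.
    """
    from . import search as _search

    cfg = cfg or _search.SearchConfig()
    stage, sampler, layout = _search.grid_search(
        bodies, spec, resolutions, table, params, cfg
    )
    return stage, sampler, layout
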