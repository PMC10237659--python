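"""Hierarchical beam search and enumerative grid search over architecture DOFs.

The hierarchical search evaluates the full top-level sampling grid, keeps the
``beam_size`` best non-clashing configurations, expands each kept cell into
its children at double resolution, and repeats to the finest level.  Pruning
is admissible when the hscore table's coarse levels upper-bound their
refinements and the geometric checks are loosened with the cell size:

* clash distance is reduced by half the Cartesian cell width at coarse levels
* the contact cutoff is enlarged by the same amount (in ScoreParams)
* flatness / delta-h constraints get a resolution-dependent margin

so that no configuration whose finest-level refinement would survive is
discarded early.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from . import arch as _arch
from . import body as _body
from . import geom, rpxscore

log = logging.getLogger(__name__)

MAX_GRID_CELLS = 2_000_000


@dataclass
class SearchConfig:
    """Options controlling the search (defaults mirror the CLI defaults)."""

    method: str = "hier"  # hier | grid
    beam_size: int = 100_000
    n_levels: int = 5
    ori_resl: float = geom.DEFAULT_ORI_RESL  # degrees, top level
    cart_resl: float = geom.DEFAULT_CART_RESL  # Angstrom, top level
    grid_resolution_cart: float = 1.0  # A (grid method)
    grid_resolution_ori: float = 1.0  # degrees (grid method)
    cart_bounds: tuple = None  # (d1, d2) A; default depends on architecture
    flip_components: tuple = None  # per-component bool, default all True
    fixed_rot: tuple = ()  # 0-based component indices
    fixed_trans: tuple = ()
    fixed_components: tuple = ()
    fixed_wiggle: tuple = ()
    fw_rot_lb: float = 0.0
    fw_rot_ub: float = 0.0
    fw_trans_lb: float = 0.0
    fw_trans_ub: float = 0.0
    max_longaxis_dot_z: float = 1.0
    max_delta_h: float = None
    clash_dist: float = _body.CLASH_DIST_DEFAULT
    termini_dir: tuple = None  # per component (N, C) in {"in","out",None}
    term_access: tuple = None  # per component (N, C) booleans

    def __post_init__(self):
        if self.beam_size < 1:
            raise ValueError("beam_size must be >= 1")
        if self.cart_resl <= 0 or self.ori_resl <= 0:
            raise ValueError("resolutions must be positive")
        if not 0.0 <= self.max_longaxis_dot_z <= 1.0:
            raise ValueError("max_longaxis_dot_z must lie in [0, 1]")
        if self.fixed_wiggle:
            if self.fw_rot_ub == self.fw_rot_lb or self.fw_trans_ub == self.fw_trans_lb:
                raise ValueError(
                    "fixed_wiggle needs unequal lower/upper bounds "
                    "(fw_rot_lb/ub, fw_trans_lb/ub)"
                )

    def clash_dist_at(self, level: int) -> float:
        """Clash tolerance loosened at coarse levels (never below 0.05 A)."""
        return max(0.05, self.clash_dist - self.cart_resl / 2**level / 2.0)


@dataclass
class StageResult:
    """One stage of a search: surviving indices, scores, diagnostics."""

    level: int
    indices: np.ndarray  # sorted by (score desc, index asc)
    scores: np.ndarray
    extras: dict  # per-surviving-index arrays: ncontact, rpx_sum, rpx_mean
    n_evaluated: int
    n_pruned_clash: int
    n_pruned_constraints: int


# ---------------------------------------------------------------------------
# sampler construction per architecture
# ---------------------------------------------------------------------------

@dataclass
class DofLayout:
    """Maps a sampler DOF tuple back to per-component placements."""

    spec: object
    entries: list  # (comp, kind) per sampler dim; kind in rot|disp|flip|x|y|z|ori
    fixed: dict  # (comp, kind) -> fixed value for unsampled DOFs

    def __post_init__(self):
        # per-component placement cache: symmetric architectures revisit the
        # same few hundred (rot, disp, flip) values across a whole level
        self._cache: dict = {}

    def placements(self, dofs: tuple) -> list:
        spec = self.spec
        vals = dict(zip(self.entries, dofs))
        if spec.kind == "asym":
            X = geom.htrans([vals[(1, "x")], vals[(1, "y")], vals[(1, "z")]])
            X[:3, :3] = vals[(1, "ori")]
            return [np.eye(4), X]
        if spec.kind == "cyclic":
            # monomer: full orientation plus radial offset from the axis
            X = geom.htrans([vals[(0, "radius")], 0.0, 0.0])
            X[:3, :3] = vals[(0, "ori")]
            return [X]
        per = []
        for comp in range(spec.n_components):
            get = lambda kind: vals.get(
                (comp, kind), self.fixed.get((comp, kind), 0.0)
            )
            key = (comp, float(get("rot")), float(get("disp")), bool(get("flip")))
            X = self._cache.get(key)
            if X is None:
                X = _arch.place_component(spec, comp, key[1], key[2], key[3])
                if len(self._cache) < 200_000:
                    self._cache[key] = X
            per.append(X)
        return per

    def dof_dict(self, dofs: tuple) -> dict:
        d = dict(self.fixed)
        d.update(zip(self.entries, dofs))
        return d


def default_cart_bounds(spec) -> tuple:
    """[0, 500] for symmetric architectures (flip covers the negative branch);
    [-500, 500] for ASYM."""
    return (-500.0, 500.0) if spec.kind == "asym" else (0.0, 500.0)


def make_sampler(spec, cfg: SearchConfig, bodies=None, level0_resl=None):
    """Build the hierarchical sampler and DOF layout for an architecture."""
    cart_resl = cfg.cart_resl if level0_resl is None else level0_resl[0]
    ori_resl = cfg.ori_resl if level0_resl is None else level0_resl[1]
    bounds = cfg.cart_bounds or default_cart_bounds(spec)
    d1, d2 = bounds
    dims, entries, fixed = [], [], {}
    if spec.kind == "asym":
        for kind in ("x", "y", "z"):
            dims.append(geom.CartDim(d1, d2, cart_resl))
            entries.append((1, kind))
        dims.append(geom.OriDim(ori_resl))
        entries.append((1, "ori"))
        layout = DofLayout(spec, entries, fixed)
        return geom.HierSampler(dims, cfg.n_levels), layout
    if spec.kind == "cyclic":
        # 4 DOFs: 3 rotational + the radius; axial translation and rotation
        # about the cyclic axis produce identical assemblies and are skipped
        dims.append(geom.OriDim(ori_resl))
        entries.append((0, "ori"))
        dims.append(geom.CartDim(max(0.0, d1), d2, cart_resl))
        entries.append((0, "radius"))
        layout = DofLayout(spec, entries, fixed)
        return geom.HierSampler(dims, cfg.n_levels), layout

    flip_default = cfg.flip_components
    for comp in range(spec.n_components):
        comp_fixed = comp in cfg.fixed_components
        wiggle = comp in cfg.fixed_wiggle
        # flip dimension
        allowed_flips = [False, True]
        if flip_default is not None and not flip_default[comp]:
            allowed_flips = [False]
        if cfg.termini_dir is not None and cfg.termini_dir[comp] is not None:
            allowed_flips = _restrict_flips_for_termini(
                bodies[comp] if bodies else None,
                cfg.termini_dir[comp],
                allowed_flips,
            )
        if comp_fixed:
            allowed_flips = [False]
        if len(allowed_flips) > 1:
            dims.append(geom.DiscreteDim(allowed_flips))
            entries.append((comp, "flip"))
        else:
            fixed[(comp, "flip")] = allowed_flips[0]
        # rotation about the component axis
        if comp_fixed or comp in cfg.fixed_rot:
            fixed[(comp, "rot")] = 0.0
        elif wiggle:
            dims.append(geom.AngleDim(cfg.fw_rot_lb, cfg.fw_rot_ub, ori_resl))
            entries.append((comp, "rot"))
        else:
            dims.append(geom.AngleDim(0.0, spec.angular_bound(comp), ori_resl))
            entries.append((comp, "rot"))
        # translation along the component axis
        if comp_fixed or comp in cfg.fixed_trans:
            fixed[(comp, "disp")] = 0.0
        elif wiggle:
            dims.append(geom.CartDim(cfg.fw_trans_lb, cfg.fw_trans_ub, cart_resl))
            entries.append((comp, "disp"))
        else:
            dims.append(geom.CartDim(d1, d2, cart_resl))
            entries.append((comp, "disp"))
    layout = DofLayout(spec, entries, fixed)
    return geom.HierSampler(dims, cfg.n_levels), layout


def _restrict_flips_for_termini(bd, want: tuple, allowed: list) -> list:
    """Intersect allowed flips with the termini-direction requirement."""
    if bd is None:
        return allowed
    out = []
    for flip in allowed:
        ok = True
        for term, desired in zip("NC", want):
            if desired in (None, "none", "None"):
                continue
            native = termini_direction(bd, term)
            actual = native if not flip else ("in" if native == "out" else "out")
            ok &= actual == desired
        if ok:
            out.append(flip)
    if not out:
        raise ValueError(
            "termini_dir constraints eliminate both flip states; "
            "check --termini_dir against --flip_components"
        )
    return out


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------

def check_flatness_cyclic(bd, placement, max_longaxis_dot_z: float, margin: float = 0.0) -> bool:
    """|cos(angle(placed long axis, z))| <= threshold (+ optional margin)."""
    axis = geom.rot_of(placement) @ bd.long_axis
    return abs(float(axis[2])) <= min(1.0, max_longaxis_dot_z + margin) + 1e-9


def check_delta_h(displacements, max_delta_h: float, margin: float = 0.0) -> bool:
    """Max pairwise |axial offset difference| <= bound (+ margin)."""
    d = np.asarray(displacements, float)
    if len(d) < 2 or max_delta_h is None or not math.isfinite(max_delta_h):
        return True
    return float(d.max() - d.min()) <= max_delta_h + margin


# ---------------------------------------------------------------------------
# termini direction / accessibility
# ---------------------------------------------------------------------------

def _kabsch(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Rigid transform superposing point set P onto Q (least squares)."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    X = np.eye(4)
    X[:3, :3] = R
    X[:3, 3] = cq - R @ cp
    return X


def _aligned_probe_helix(bd, terminus: str):
    """Ideal 21-residue helix least-squares aligned to 7 terminal residues.

    N terminus: helix residues 15-21 onto body residues 1-7 (the helix
    extension continues past the N terminus); C terminus: helix residues 1-7
    onto the last 7 body residues.
    """
    from . import fixtures

    if terminus not in ("N", "C"):
        raise ValueError("terminus must be 'N' or 'C'")
    if bd.nres < 7:
        raise ValueError(f"terminus {terminus}: need >= 7 residues, have {bd.nres}")
    helix = fixtures.make_ideal_helix(21)
    if terminus == "N":
        h_idx = np.arange(14, 21)
        b_idx = np.arange(0, 7)
    else:
        h_idx = np.arange(0, 7)
        b_idx = np.arange(bd.nres - 7, bd.nres)
    hp = helix.coords[helix.bb_index[h_idx].ravel()]
    bp = bd.coords[bd.bb_index[b_idx].ravel()]
    X = _kabsch(hp, bp)
    placed = helix.transformed(X)
    return placed


def termini_direction(bd, terminus: str) -> str:
    """Classify a terminus as pointing "in" or "out".

    The body is assumed in its docking frame (internal axis on z, displaced
    toward +z at assembly time): a terminus whose free helix extension points
    toward -z points at the architecture center, i.e. "in".
    """
    placed = _aligned_probe_helix(bd, terminus)
    ca = placed.ca_coords
    com_start = ca[0:3].mean(axis=0)
    com_end = ca[18:21].mean(axis=0)
    if terminus == "N":
        v = com_start - com_end  # toward the free N-terminal extension
    else:
        v = com_end - com_start  # toward the free C-terminal extension
    return "in" if v[2] < 0 else "out"


def term_access_probe(bd, terminus: str):
    """Return a copy of the body carrying the aligned probe helix.

    Probe atoms join the clash geometry only: they are excluded from contact
    collection, scoring, and any dumped output.
    """
    placed = _aligned_probe_helix(bd, terminus)
    probe = placed.coords
    existing = bd.probe_coords
    if existing is not None and len(existing):
        probe = np.vstack([existing, probe])
    out = _body.Body(
        coords=bd.coords.copy(),
        atom_names=list(bd.atom_names),
        bb_index=bd.bb_index.copy(),
        ss=bd.ss,
        stubs=bd.stubs.copy(),
        chain_breaks=list(bd.chain_breaks),
        allowed_mask=bd.allowed_mask.copy(),
        label=bd.label,
        probe_coords=probe,
    )
    return out


# ---------------------------------------------------------------------------
# interface enumeration and batch evaluation
# ---------------------------------------------------------------------------

def interface_margin(
    cart_resl: float, ori_resl: float, level: int, r_i: float, r_j: float
) -> float:
    """Conservative bound on interface displacement within one sampling cell.

    Within a level-L cell each component can translate up to half the cell
    width and rotate up to half the angular cell width about its axis, moving
    interface atoms by up to the rotational lever (body radius x chord).
    Contact cutoffs are enlarged and clash distances reduced by this margin
    so that no configuration whose refinement would survive is pruned early.
    """
    w = cart_resl / 2**level
    half = math.radians(min(178.0, ori_resl / 2**level)) / 2.0
    lever = (r_i + r_j) * math.sin(min(math.pi / 2.0, half / 2.0)) * 2.0
    return w + lever


def _frame_inverse_index(frames: np.ndarray) -> np.ndarray:
    inv = np.empty(len(frames), dtype=int)
    for i, F in enumerate(frames):
        Fi = geom.hinv(F)
        for j, G in enumerate(frames):
            if np.allclose(Fi, G, atol=1e-6):
                inv[i] = j
                break
        else:
            raise ValueError("frames not closed under inversion")
    return inv


def interface_terms(spec) -> list:
    """Distinct two-body interface terms as (comp_i, comp_j, frame).

    Same-component terms use non-identity frames, one per {F, F^-1} pair;
    cross-component terms use every frame.  Interfaces with a component's own
    internal-axis images are constant in the component DOFs but included for
    consistency (they cancel in ranking).
    """
    frames = spec.frames
    inv = _frame_inverse_index(frames)
    terms = []
    for i in range(spec.n_components):
        for k in range(1, len(frames)):
            if k <= inv[k]:
                terms.append((i, i, frames[k]))
        for j in range(i + 1, spec.n_components):
            for k in range(len(frames)):
                terms.append((i, j, frames[k]))
    return terms


def _batched_min_dist_mask(
    coords_a: np.ndarray, coords_b: np.ndarray, cutoff: float, chunk: int = 2048
) -> np.ndarray:
    """Per-candidate boolean: any cross pair closer than cutoff."""
    n = len(coords_a)
    out = np.zeros(n, dtype=bool)
    for s in range(0, n, chunk):
        d2 = np.sum(
            (coords_a[s : s + chunk, :, None, :] - coords_b[s : s + chunk, None, :, :])
            ** 2,
            axis=-1,
        )
        out[s : s + chunk] = d2.min(axis=(1, 2)) < cutoff**2
    return out


def _place_coords(X: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """(n,4,4) transforms applied to (m,3) points -> (n,m,3)."""
    return np.einsum("nij,mj->nmi", X[:, :3, :3], pts) + X[:, :3, None, 3].transpose(0, 2, 1)


def evaluate_configs(
    bodies, spec, layout, table, params, cfg, level, dof_tuples, table_level=None
):
    """Score a batch of configurations; returns per-candidate arrays.

    scores are -inf for clash, NaN-free; also returns masks and metrics.
    """
    n = len(dof_tuples)
    placements = [layout.placements(d) for d in dof_tuples]
    Xs = [
        np.array([p[c] for p in placements]) for c in range(spec.n_components)
    ]
    ok = np.ones(n, dtype=bool)
    # -- constraints ------------------------------------------------------
    n_constraint = 0
    ori_margin = math.sin(math.radians(min(90.0, cfg.ori_resl / 2**level)))
    if spec.kind == "cyclic" and cfg.max_longaxis_dot_z < 1.0:
        for i in range(n):
            if not check_flatness_cyclic(
                bodies[0], placements[i][0], cfg.max_longaxis_dot_z, ori_margin
            ):
                ok[i] = False
    if spec.n_components >= 2 and cfg.max_delta_h is not None:
        margin = cfg.cart_resl / 2**level
        for i in range(n):
            disps = [
                layout.dof_dict(dof_tuples[i]).get((c, "disp"), 0.0)
                for c in range(spec.n_components)
            ]
            if not check_delta_h(disps, cfg.max_delta_h, margin):
                ok[i] = False
    n_constraint = int(n - ok.sum())
    # -- clash ------------------------------------------------------------
    clash = np.zeros(n, dtype=bool)
    terms = interface_terms(spec)
    radii = [bd.radius for bd in bodies]
    levers = [bd.lever_radius for bd in bodies]
    coms = [bd.com for bd in bodies]
    for ci, cj, F in terms:
        margin = interface_margin(
            cfg.cart_resl, cfg.ori_resl, level, levers[ci], levers[cj]
        )
        mindist = max(0.05, cfg.clash_dist - margin)
        Xi = Xs[ci]
        Xj = np.asarray(F) @ Xs[cj]
        live = ok & ~clash
        if not live.any():
            break
        com_i = np.einsum("nij,j->ni", Xi[live, :3, :3], coms[ci]) + Xi[live, :3, 3]
        com_j = np.einsum("nij,j->ni", Xj[live, :3, :3], coms[cj]) + Xj[live, :3, 3]
        near = (
            np.linalg.norm(com_i - com_j, axis=1)
            < radii[ci] + radii[cj] + mindist
        )
        if not near.any():
            continue
        idx = np.flatnonzero(live)[near]
        ca = _place_coords(Xi[idx], bodies[ci].clash_coords)
        cb = _place_coords(Xj[idx], bodies[cj].clash_coords)
        hit = _batched_min_dist_mask(ca, cb, mindist)
        clash[idx[hit]] = True
    n_clash = int(clash[ok].sum())
    valid = ok & ~clash
    # -- scoring ----------------------------------------------------------
    ncontact = np.zeros(n, dtype=int)
    rpx_sum = np.zeros(n)
    tlevel = min(level, table.n_levels - 1) if table_level is None else table_level
    pair_vals = {} if params.function == "median" else None
    for ci, cj, F in terms:
        margin = interface_margin(
            cfg.cart_resl, cfg.ori_resl, level, levers[ci], levers[cj]
        )
        maxdist = params.max_pair_dist + margin
        live = np.flatnonzero(valid)
        if len(live) == 0:
            break
        Xi = Xs[ci][live]
        Xj = np.asarray(F) @ Xs[cj][live]
        com_i = np.einsum("nij,j->ni", Xi[:, :3, :3], coms[ci]) + Xi[:, :3, 3]
        com_j = np.einsum("nij,j->ni", Xj[:, :3, :3], coms[cj]) + Xj[:, :3, 3]
        near = (
            np.linalg.norm(com_i - com_j, axis=1)
            < radii[ci] + radii[cj] + maxdist
        )
        if not near.any():
            continue
        sel = live[near]
        Xi, Xj = Xi[near], Xj[near]
        ca = _place_coords(Xi, bodies[ci].ca_coords)
        cb = _place_coords(Xj, bodies[cj].ca_coords)
        # contact pairs per candidate (chunked)
        chunk = max(1, int(2_000_000 // max(1, ca.shape[1] * cb.shape[1])))
        for s in range(0, len(sel), chunk):
            d2 = np.sum(
                (ca[s : s + chunk, :, None, :] - cb[s : s + chunk, None, :, :]) ** 2,
                axis=-1,
            )
            cand, ia, jb = np.nonzero(d2 <= maxdist**2)
            if len(cand) == 0:
                continue
            gidx = sel[s + cand]
            np.add.at(ncontact, gidx, 1)
            stubs_i = Xi[s + cand] @ bodies[ci].stubs[ia]
            stubs_j = Xj[s + cand] @ bodies[cj].stubs[jb]
            vals = rpxscore.pair_rpx_batch(table, stubs_i, stubs_j, tlevel)
            mask = (
                bodies[ci].allowed_mask[ia] & bodies[cj].allowed_mask[jb]
            )
            if params.score_only_ss:
                ss_i = np.array(
                    [bodies[ci].ss[k] in params.score_only_ss for k in ia]
                )
                ss_j = np.array(
                    [bodies[cj].ss[k] in params.score_only_ss for k in jb]
                )
                mask &= (
                    (ss_i & ss_j) if params.score_only_sspair else (ss_i | ss_j)
                )
            vals = np.where(mask, vals, 0.0)
            np.add.at(rpx_sum, gidx, vals)
            if pair_vals is not None:
                for g, v in zip(gidx, vals):
                    pair_vals.setdefault(int(g), []).append(float(v))
    rpx_mean = np.where(ncontact > 0, rpx_sum / np.maximum(ncontact, 1), 0.0)
    scores = np.full(n, -np.inf)
    for i in np.flatnonzero(valid):
        if params.function == "stnd":
            scores[i] = rpxscore.score_stnd(
                rpx_sum[i], ncontact[i], params.weight_rpx, params.weight_ncontact
            )
        elif params.function == "sasa_priority":
            scores[i] = rpxscore.score_sasa_priority(
                rpx_mean[i], int(ncontact[i]), params.weight_rpx,
                params.weight_ncontact, params.weight_sasa,
                params.weight_error, params.sasa_per_contact,
            )
        elif params.function == "mean":
            scores[i] = rpx_mean[i]
        elif params.function == "median":
            vals = pair_vals.get(int(i), [])
            scores[i] = float(np.median(vals)) if vals else 0.0
        elif params.function == "exp":
            scores[i] = rpx_sum[i] - 4.6679 * ncontact[i] ** 0.588
        elif params.function == "lin":
            scores[i] = rpx_sum[i] - 0.7514 * ncontact[i]
    return {
        "scores": scores,
        "valid": valid,
        "ncontact": ncontact,
        "rpx_sum": rpx_sum,
        "rpx_mean": rpx_mean,
        "n_pruned_clash": n_clash,
        "n_pruned_constraints": n_constraint,
    }


# ---------------------------------------------------------------------------
# search drivers
# ---------------------------------------------------------------------------

def _sorted_survivors(indices: np.ndarray, ev: dict):
    valid = ev["valid"]
    idx = np.asarray(indices)[valid]
    sc = ev["scores"][valid]
    order = np.lexsort((idx, -sc))  # score desc, index asc
    extras = {
        k: ev[k][valid][order] for k in ("ncontact", "rpx_sum", "rpx_mean")
    }
    return idx[order], sc[order], extras


def hier_search(bodies, spec, sampler, table, params, cfg: SearchConfig, layout=None):
    """Hierarchical beam search; returns one StageResult per level."""
    if layout is None:
        sampler_built, layout = make_sampler(spec, cfg, bodies)
        if sampler is None:
            sampler = sampler_built
    stages = []
    indices = np.arange(sampler.size(0), dtype=np.int64)
    for level in range(sampler.n_levels):
        if level > 0:
            kept = stages[-1].indices[: cfg.beam_size]
            if len(kept) == 0:
                stages.append(
                    StageResult(level, np.array([], np.int64), np.array([]),
                                {}, 0, 0, 0)
                )
                continue
            indices = np.concatenate(
                [sampler.children(level - 1, int(i)) for i in kept]
            ).astype(np.int64)
        dof_tuples = sampler.expand(level, indices)
        ev = evaluate_configs(
            bodies, spec, layout, table, params, cfg, level, dof_tuples
        )
        sidx, ssc, extras = _sorted_survivors(indices, ev)
        stages.append(
            StageResult(
                level=level, indices=sidx, scores=ssc, extras=extras,
                n_evaluated=len(indices),
                n_pruned_clash=ev["n_pruned_clash"],
                n_pruned_constraints=ev["n_pruned_constraints"],
            )
        )
        log.info(
            "stage %d: evaluated %d, clash %d, constraints %d, kept %d",
            level, len(indices), ev["n_pruned_clash"],
            ev["n_pruned_constraints"], min(len(sidx), cfg.beam_size),
        )
    return stages


def grid_search(bodies, spec, resolutions, table, params, cfg: SearchConfig):
    """Exhaustive single-resolution enumeration (debugging / oracle).

    ``resolutions`` is (cart_resl_A, ori_resl_deg).  All cells are evaluated
    at level 0 of a one-level sampler; results sorted by score.
    """
    gcfg = SearchConfig(
        **{
            **cfg.__dict__,
            "n_levels": 1,
            "cart_resl": float(resolutions[0]),
            "ori_resl": float(resolutions[1]),
        }
    )
    sampler, layout = make_sampler(spec, gcfg, bodies)
    ncells = sampler.size(0)
    if ncells > MAX_GRID_CELLS:
        raise ValueError(
            f"grid search would enumerate {ncells} cells (> {MAX_GRID_CELLS}); "
            "use the hierarchical method instead"
        )
    indices = np.arange(ncells, dtype=np.int64)
    dof_tuples = sampler.expand(0, indices)
    ev = evaluate_configs(
        bodies, spec, layout, table, params, gcfg, 0, dof_tuples,
        table_level=table.n_levels - 1,
    )
    sidx, ssc, extras = _sorted_survivors(indices, ev)
    return StageResult(
        level=0, indices=sidx, scores=ssc, extras=extras,
        n_evaluated=ncells,
        n_pruned_clash=ev["n_pruned_clash"],
        n_pruned_constraints=ev["n_pruned_constraints"],
    ), sampler, layout


def final_placements(spec, layout, sampler, stage: StageResult, max_n=None):
    """Per-component transforms for the survivors of the final stage."""
    idx = stage.indices if max_n is None else stage.indices[:max_n]
    dof_tuples = sampler.expand(stage.level, idx)
    return [layout.placements(d) for d in dof_tuples], idx
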