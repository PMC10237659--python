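"""Residue-pair-transform (RPX) scoring: 6D binning, hscore tables, score functions.

The interaction of two residues is summarized by the rigid transform between
their backbone stub frames.  That transform is binned into a six-dimensional
body-centered-cubic (BCC) lattice -- three translation dimensions on an
interleaved pair of cubic lattices (a parity bit selects the sublattice), and
three rotation dimensions on a per-cell gnomonic grid inside the 24 rotation
cells of the quaternion 24-cell partition.  An *hscore* table maps bin keys to
nonnegative pair scores at several resolutions; coarse levels store upper
bounds over their refinements, which is what makes beam pruning admissible.

Scores here follow a "higher is better" convention: synthetic tables store
nonnegative favorability values, and a missing key scores zero.
"""

from __future__ import annotations

import io
import json
import math
import pickle
import tarfile
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from . import geom
from .geom import ORI_CELL_HALFWIDTH, ORI_TOP_COVERAGE_DEG

HSCORE_FORMAT_VERSION = 1

# translation lattice extent: integer coords must fit in +-512 bins
# (at the default finest resolution 0.625 A that is +-320 A, far beyond any
# residue-pair transform; transforms outside the extent are flagged unscored)
_EXTENT_BINS = 512

_TOP = geom.orientation_top_cells().top_cells  # (24, 4)


def ori_nside(ori_resl: float, level: int = 0) -> int:
    """Per-axis sub-grid count inside one rotation cell at a given level."""
    n0 = max(1, round(ORI_TOP_COVERAGE_DEG / ori_resl))
    return n0 * 2**level


def level_resls(cart_resl: float, ori_resl: float, level: int) -> tuple:
    """Resolution halves per level: (cart_resl/2^L, ori_resl/2^L)."""
    return cart_resl / 2**level, ori_resl / 2**level


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_xforms(X: np.ndarray, cart_resl: float, ori_resl: float, level: int = 0) -> np.ndarray:
    """Vectorized 6D bin keys for an (n,4,4) transform array.

    Returns int64 keys (-1 for transforms beyond the table extent).  The key
    packs (parity, rotation cell, 3 rotation sub-coords, 3 translation
    coords); keys are only comparable within one (cart_resl, ori_resl, level).
    """
    X = np.asarray(X, float)
    single = X.ndim == 2
    if single:
        X = X[None]
    w, _ = level_resls(cart_resl, ori_resl, level)
    t = X[:, :3, 3] / w
    # BCC: nearest point of the even (integer) and odd (integer+1/2) lattices
    c_even = np.round(t)
    c_odd = np.floor(t) + 0.5
    d_even = np.sum((t - c_even) ** 2, axis=1)
    d_odd = np.sum((t - c_odd) ** 2, axis=1)
    odd = d_odd < d_even
    coords = np.where(odd[:, None], np.floor(t), c_even).astype(np.int64)
    parity = odd.astype(np.int64)

    q = Rotation.from_matrix(X[:, :3, :3]).as_quat()  # (x,y,z,w)
    q = np.concatenate([q[:, 3:4], q[:, :3]], axis=1)  # (w,x,y,z)
    dots = q @ _TOP.T
    cell = np.argmax(np.abs(dots), axis=1)
    cq = _TOP[cell]
    sign = np.sign(np.take_along_axis(dots, cell[:, None], axis=1)[:, 0])
    q = q * sign[:, None]
    # local rotation r = conj(c) * q, gnomonic coords p = r_vec / r_w
    r = _quat_multiply_conj(cq, q)
    p = r[:, 1:4] / r[:, 0:1]
    n = ori_nside(ori_resl, level)
    step = 2.0 * ORI_CELL_HALFWIDTH / n
    sub = np.floor((p + ORI_CELL_HALFWIDTH) / step).astype(np.int64)
    sub = np.clip(sub, 0, n - 1)

    bad = np.any(np.abs(coords) >= _EXTENT_BINS, axis=1)
    # pack: parity(1) | cell(5) | sub xyz (8 each) | trans xyz (10 each) = 60 bits
    key = (
        parity
        | (cell.astype(np.int64) << 1)
        | (sub[:, 0] << 6)
        | (sub[:, 1] << 14)
        | (sub[:, 2] << 22)
        | ((coords[:, 0] + _EXTENT_BINS) << 30)
        | ((coords[:, 1] + _EXTENT_BINS) << 40)
        | ((coords[:, 2] + _EXTENT_BINS) << 50)
    )
    key[bad] = -1
    if single:
        return key[0]
    return key


def _quat_multiply_conj(c: np.ndarray, q: np.ndarray) -> np.ndarray:
    """conj(c) * q for (n,4) quaternion arrays in (w,x,y,z) order."""
    cw, cx, cy, cz = c[:, 0], -c[:, 1], -c[:, 2], -c[:, 3]
    qw, qx, qy, qz = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    return np.stack(
        [
            cw * qw - cx * qx - cy * qy - cz * qz,
            cw * qx + cx * qw + cy * qz - cz * qy,
            cw * qy - cx * qz + cy * qw + cz * qx,
            cw * qz + cx * qy - cy * qx + cz * qw,
        ],
        axis=1,
    )


def bin_xform(x: np.ndarray, cart_resl: float, ori_resl: float, level: int = 0) -> int:
    """Scalar convenience wrapper around :func:`bin_xforms`."""
    return int(bin_xforms(x, cart_resl, ori_resl, level))


# ---------------------------------------------------------------------------
# hscore table
# ---------------------------------------------------------------------------

@dataclass
class HScoreTable:
    """Multi-resolution map from 6D transform-bin keys to nonnegative scores.

    ``levels[L]`` is a dict for resolution (cart_resl/2^L, ori_resl/2^L);
    level 0 is coarsest.  Missing keys score zero.  Coarse levels are expected
    to upper-bound their refinements (the generator enforces this).
    """

    cart_resl: float
    ori_resl: float
    levels: list  # list of dict[int, float], coarse -> fine
    subset_tag: str = "SYNTH_H"
    provenance: dict = field(default_factory=dict)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def lookup(self, level: int, keys) -> np.ndarray:
        """Scores for int64 keys at a level; missing or out-of-range keys -> 0."""
        table = self.levels[min(level, self.n_levels - 1)]
        keys = np.atleast_1d(np.asarray(keys, np.int64))
        return np.array([table.get(int(k), 0.0) if k >= 0 else 0.0 for k in keys])

    def resls(self, level: int) -> tuple:
        return level_resls(self.cart_resl, self.ori_resl, level)


def pair_rpx(table: HScoreTable, stub_i, stub_j, level: int) -> float:
    """RPX score of one stub pair at a hierarchy level (0 if unknown bin)."""
    X = geom.hinv(stub_i) @ np.asarray(stub_j)
    key = bin_xform(X, table.cart_resl, table.ori_resl, level)
    return float(table.lookup(level, key)[0])


def pair_rpx_batch(table: HScoreTable, stubs_i: np.ndarray, stubs_j: np.ndarray, level: int) -> np.ndarray:
    """Vectorized RPX lookup for (n,4,4) stub arrays."""
    if len(stubs_i) == 0:
        return np.zeros(0)
    inv = np.swapaxes(stubs_i[:, :3, :3], 1, 2)
    X = np.zeros((len(stubs_i), 4, 4))
    X[:, 3, 3] = 1.0
    X[:, :3, :3] = inv @ stubs_j[:, :3, :3]
    X[:, :3, 3] = np.einsum(
        "nij,nj->ni", inv, stubs_j[:, :3, 3] - stubs_i[:, :3, 3]
    )
    keys = bin_xforms(X, table.cart_resl, table.ori_resl, level)
    return table.lookup(level, keys)


# ---------------------------------------------------------------------------
# score parameters and functions
# ---------------------------------------------------------------------------

SCORE_FUNCTIONS = ("stnd", "sasa_priority", "mean", "median", "exp", "lin")

# A^2 of interface area buried per contacting residue pair: the empirical
# ncontact<->SASA conversion constant.  24 A^2/contact puts the default
# sasa_priority target (1152 A^2) at 48 contacts.
SASA_PER_CONTACT = 24.0


@dataclass
class ScoreParams:
    """Weights and restrictions for ranking docked configurations."""

    function: str = "stnd"
    weight_rpx: float = 1.0  # a
    weight_ncontact: float = 0.001  # b (5 recommended for sasa_priority)
    weight_sasa: float = 1152.0  # mu, target buried area (A^2)
    weight_error: float = 4.0  # sigma, tolerance of the area prior
    max_pair_dist: float = 8.0  # A, CA-CA contact cutoff at finest level
    score_only_ss: str = ""  # subset of "EHL"; empty = no restriction
    score_only_sspair: bool = False  # require *both* residues on allowed SS
    sasa_per_contact: float = SASA_PER_CONTACT

    def __post_init__(self):
        if self.function not in SCORE_FUNCTIONS:
            raise ValueError(
                f"unknown score function {self.function!r}; choose from {SCORE_FUNCTIONS}"
            )
        if self.max_pair_dist <= 0:
            raise ValueError("max_pair_dist must be positive")

    def maxdist_at(self, cart_resl: float, level: int) -> float:
        """Contact cutoff loosened at coarse levels: + cart_resl(level)/2."""
        return self.max_pair_dist + cart_resl / 2**level / 2.0


def score_stnd(rpx_sum: float, ncontact: float, a: float = 1.0, b: float = 0.001) -> float:
    """Default score: a * RPX + b * ncontact."""
    return a * rpx_sum + b * ncontact


def lognormal_contact_term(ncontact, mu: float, sigma: float, c: float = SASA_PER_CONTACT):
    """ln of a log-normal density over estimated buried area c * ncontact.

    Parameterized so the density *mode* sits exactly at area mu: with shape
    s = sigma / 4 (s = 1 at the default tolerance), the log-scale location is
    m = ln(mu) + s^2, since the mode of LogNormal(m, s) is exp(m - s^2).
    """
    area = c * np.asarray(ncontact, float)
    s = sigma / 4.0
    m = math.log(mu) + s * s
    return (
        -np.log(area)
        - math.log(s * math.sqrt(2.0 * math.pi))
        - (np.log(area) - m) ** 2 / (2.0 * s * s)
    )


def score_sasa_priority(
    rpx_mean: float,
    ncontact: int,
    a: float = 1.0,
    b: float = 5.0,
    mu: float = 1152.0,
    sigma: float = 4.0,
    c: float = SASA_PER_CONTACT,
) -> float:
    """Interface-size-targeted score: a * mean(RPX) + b * ln LogNormal(c*N).

    Zero contacts score zero; otherwise the contact term peaks where the
    estimated buried area c*N equals the target mu.
    """
    if ncontact < 1:
        return 0.0
    return a * rpx_mean + b * float(lognormal_contact_term(ncontact, mu, sigma, c))


def score_variants(rpx_values, ncontact: int, function: str) -> float:
    """Aggregation variants over the per-pair max motif scores.

    mean / median replace the sum; exp and lin subtract empirical
    contact-count baselines: RPX - 4.6679 * N^0.588 and RPX - 0.7514 * N.
    """
    vals = np.asarray(rpx_values, float)
    rpx_sum = float(vals.sum())
    if function == "mean":
        return float(vals.mean()) if len(vals) else 0.0
    if function == "median":
        return float(np.median(vals)) if len(vals) else 0.0
    if function == "exp":
        return rpx_sum - 4.6679 * ncontact**0.588
    if function == "lin":
        return rpx_sum - 0.7514 * ncontact
    raise ValueError(
        f"unknown score function {function!r}; variants: mean, median, exp, lin"
    )


def combine_scores(rpx_values, ncontact: int, params: ScoreParams) -> float:
    """Apply the configured score function to per-pair RPX values."""
    vals = np.asarray(rpx_values, float)
    rpx_sum = float(vals.sum())
    if params.function == "stnd":
        return score_stnd(rpx_sum, ncontact, params.weight_rpx, params.weight_ncontact)
    if params.function == "sasa_priority":
        rpx_mean = float(vals.mean()) if len(vals) else 0.0
        return score_sasa_priority(
            rpx_mean, ncontact, params.weight_rpx, params.weight_ncontact,
            params.weight_sasa, params.weight_error, params.sasa_per_contact,
        )
    return score_variants(vals, ncontact, params.function)


def score_interface(a_body, xa, b_body, xb, table: HScoreTable, params: ScoreParams, level: int):
    """Score one two-body interface.

    Returns (score, ncontact, rpx_sum, rpx_mean).  Every CA-CA pair within
    the (level-loosened) cutoff counts as a contact; pairs masked out by
    allowed_residues or secondary-structure restrictions contribute zero RPX
    but still count as contacts.
    """
    from . import body as _body

    maxdist = params.maxdist_at(table.cart_resl, level)
    pairs = _body.collect_pairs_brute(a_body, xa, b_body, xb, maxdist)
    ncontact = len(pairs)
    if ncontact == 0:
        return 0.0, 0, 0.0, 0.0
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    stubs_i = np.asarray(xa) @ a_body.stubs[ii]
    stubs_j = np.asarray(xb) @ b_body.stubs[jj]
    vals = pair_rpx_batch(table, stubs_i, stubs_j, level)
    mask = a_body.allowed_mask[ii] & b_body.allowed_mask[jj]
    if params.score_only_ss:
        in_i = np.array([a_body.ss[i] in params.score_only_ss for i in ii])
        in_j = np.array([b_body.ss[j] in params.score_only_ss for j in jj])
        mask &= (in_i & in_j) if params.score_only_sspair else (in_i | in_j)
    vals = np.where(mask, vals, 0.0)
    rpx_sum = float(vals.sum())
    rpx_mean = rpx_sum / ncontact
    score = combine_scores(vals, ncontact, params)
    return score, ncontact, rpx_sum, rpx_mean


# ---------------------------------------------------------------------------
# serialization: portable .txz (text schema) and native .pickle
# ---------------------------------------------------------------------------

def save_hscore(table: HScoreTable, path: str) -> None:
    """Write an hscore table; format chosen by extension (.txz or .pickle)."""
    path = str(path)
    if path.endswith(".txz"):
        meta = {
            "format_version": HSCORE_FORMAT_VERSION,
            "cart_resl": table.cart_resl,
            "ori_resl": table.ori_resl,
            "n_levels": table.n_levels,
            "subset_tag": table.subset_tag,
            "provenance": table.provenance,
        }
        with tarfile.open(path, "w:xz") as tf:
            _add_text(tf, "meta.json", json.dumps(meta, indent=1))
            for lvl, d in enumerate(table.levels):
                lines = [f"{k}\t{v:.17g}" for k, v in sorted(d.items())]
                _add_text(tf, f"level{lvl}.tsv", "\n".join(lines) + "\n")
    elif path.endswith(".pickle"):
        with open(path, "wb") as fh:
            pickle.dump(
                {"format_version": HSCORE_FORMAT_VERSION, "table": table}, fh
            )
    else:
        raise ValueError(f"unknown hscore extension for {path!r}; use .txz or .pickle")


def load_hscore(path: str) -> HScoreTable:
    """Load an hscore table saved by :func:`save_hscore`."""
    import os

    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"hscore file not found: {path}")
    if path.endswith(".txz"):
        with tarfile.open(path, "r:xz") as tf:
            meta = json.loads(_read_text(tf, "meta.json"))
            if meta.get("format_version") != HSCORE_FORMAT_VERSION:
                raise ValueError(
                    f"hscore schema mismatch in {path}: expected format_version "
                    f"{HSCORE_FORMAT_VERSION}, found {meta.get('format_version')}"
                )
            levels = []
            for lvl in range(meta["n_levels"]):
                d = {}
                for line in _read_text(tf, f"level{lvl}.tsv").splitlines():
                    if line.strip():
                        k, v = line.split("\t")
                        d[int(k)] = float(v)
                levels.append(d)
        return HScoreTable(
            cart_resl=meta["cart_resl"], ori_resl=meta["ori_resl"], levels=levels,
            subset_tag=meta["subset_tag"], provenance=meta.get("provenance", {}),
        )
    if path.endswith(".pickle"):
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format_version") != HSCORE_FORMAT_VERSION:
            raise ValueError(
                f"hscore schema mismatch in {path}: expected format_version "
                f"{HSCORE_FORMAT_VERSION}"
            )
        return payload["table"]
    raise ValueError(f"unknown hscore extension for {path!r}; use .txz or .pickle")


def _add_text(tf: tarfile.TarFile, name: str, text: str) -> None:
    data = text.encode()
    info = tarfile.TarInfo(name)
    info.size = len(data)
    tf.addfile(info, io.BytesIO(data))


def _read_text(tf: tarfile.TarFile, name: str) -> str:
    member = tf.extractfile(name)
    if member is None:
        raise ValueError(f"hscore archive missing member {name}")
    return member.read().decode()
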