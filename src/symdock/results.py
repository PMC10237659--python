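"""Dock results: filtering, persistence, and symmetric-assembly PDB output.

A :class:`DockResult` stores the per-component transforms of the ranked
docked configurations in an xarray Dataset together with scores, contact
metrics, and any filter values, plus the bodies and architecture needed to
regenerate full coordinates.  Everything reported under a filter label is
recomputable from the stored transforms and bodies.
"""

from __future__ import annotations

import json
import logging
import math
import os
import pickle
import tarfile
from dataclasses import dataclass, field

import numpy as np
import xarray as xr
import yaml

from . import arch as _arch
from . import body as _body
from . import geom, rpxscore, search

log = logging.getLogger(__name__)

RESULT_FORMAT_VERSION = 1

# deterministic chain id cycle: single characters only (PDB column width)
CHAIN_IDS = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZ" "abcdefghijklmnopqrstuvwxyz" "0123456789"
)


@dataclass
class DockResult:
    """Ranked docked configurations for one architecture."""

    spec: object  # ArchSpec
    bodies: list  # per-component Body (default body set)
    data: xr.Dataset  # dims: model, comp; vars: xforms, scores, ...
    config: dict = field(default_factory=dict)
    body_sets: list = None  # optional per-batch body lists (multi-input runs)

    @property
    def n_docks(self) -> int:
        return int(self.data.sizes.get("model", 0))

    def xform(self, rank: int, comp: int) -> np.ndarray:
        return np.asarray(self.data["xforms"][rank, comp].values)

    def placements(self, rank: int) -> list:
        return [self.xform(rank, c) for c in range(self.spec.n_components)]

    def bodies_for(self, rank: int) -> list:
        """Bodies of one model (batched multi-input runs track provenance)."""
        if self.body_sets is not None and "body_set" in self.data:
            return self.body_sets[int(self.data["body_set"][rank])]
        return self.bodies

    def subset(self, indices) -> "DockResult":
        return DockResult(
            spec=self.spec, bodies=self.bodies,
            data=self.data.isel(model=np.asarray(indices, int)),
            config=dict(self.config), body_sets=self.body_sets,
        )


def result_from_search(
    bodies, spec, sampler, layout, stage, cfg, params, max_models: int = None
) -> DockResult:
    """Build a DockResult from a final search stage (already score-sorted)."""
    idx = stage.indices if max_models is None else stage.indices[:max_models]
    placements, idx = search.final_placements(
        spec, layout, sampler, stage, max_n=len(idx)
    )
    n = len(idx)
    xforms = np.array(placements) if n else np.zeros((0, spec.n_components, 4, 4))
    take = slice(0, n)
    data = xr.Dataset(
        {
            "xforms": (("model", "comp", "hrow", "hcol"), xforms),
            "scores": (("model",), np.asarray(stage.scores[take], float)),
            "ncontact": (("model",), np.asarray(stage.extras["ncontact"][take], int)),
            "rpx_sum": (("model",), np.asarray(stage.extras["rpx_sum"][take], float)),
            "rpx_mean": (("model",), np.asarray(stage.extras["rpx_mean"][take], float)),
            "level": (("model",), np.full(n, stage.level, int)),
            "sample_index": (("model",), np.asarray(idx, np.int64)),
        },
        attrs={
            "architecture": spec.name,
            "format_version": RESULT_FORMAT_VERSION,
        },
    )
    return DockResult(
        spec=spec, bodies=list(bodies), data=data,
        config={k: _jsonable(v) for k, v in cfg.__dict__.items()}
        | {"score_params": {k: _jsonable(v) for k, v in params.__dict__.items()}},
    )


def _jsonable(v):
    if isinstance(v, (np.ndarray, tuple)):
        return list(np.asarray(v).tolist())
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_redundancy(
    result: DockResult, max_bb_redundancy: float = 3.0, max_cluster: int = None
) -> np.ndarray:
    """Greedy best-first clustering on transformed-backbone RMSD.

    Walks docks in score order and keeps a dock iff its distance to every
    kept dock exceeds the cutoff, so only the highest-scoring member of each
    cluster survives.  Distance = max over components of the CA RMSD between
    the two placements without re-superposition (an unaligned-RMSD proxy).
    """
    kept: list = []
    placed: list = []
    for m in range(result.n_docks):
        pl = result.placements(m)
        bset = (
            int(result.data["body_set"][m]) if "body_set" in result.data else 0
        )
        cas = [bd.ca_coords for bd in result.bodies_for(m)]
        pts = [geom.xform_points(pl[c], cas[c]) for c in range(len(cas))]
        ok = True
        for kset, kpts in placed:
            if kset != bset:
                continue  # docks of different inputs are never redundant
            d = max(
                float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
                for a, b in zip(pts, kpts)
            )
            if d < max_bb_redundancy:
                ok = False
                break
        if ok:
            kept.append(m)
            placed.append((bset, pts))
            if max_cluster is not None and len(kept) >= max_cluster:
                break
    return np.asarray(kept, int)


def _interface_element_tags(result: DockResult, rank: int, max_pair_dist: float = 8.0):
    """Distinct SS elements in the docked interface, one tag per chain copy.

    A tag is (frame index, component, element id): the same helix contacting
    as the asu chain and again as a symmetry image counts once per copy,
    matching the assembly-level view of the interface.
    """
    spec = result.spec
    bodies = result.bodies_for(rank)
    pl = result.placements(rank)
    frames = spec.frames
    inv = search._frame_inverse_index(frames)
    elem_ids = [bd.ss_elements() for bd in bodies]
    tags: set = set()

    def add(f_idx: int, comp: int, residues) -> None:
        for r in residues:
            e = int(elem_ids[comp][r])
            if e >= 0:
                tags.add((f_idx, comp, e))

    for ci in range(spec.n_components):
        for k in range(1, len(frames)):
            if k > inv[k]:
                continue
            pairs = _body.collect_pairs_brute(
                bodies[ci], pl[ci], bodies[ci],
                np.asarray(frames[k]) @ pl[ci], max_pair_dist,
            )
            aa = {a for a, _ in pairs}
            bb = {b for _, b in pairs}
            add(0, ci, aa | bb)
            add(k, ci, bb)
            add(int(inv[k]), ci, aa)
        for cj in range(ci + 1, spec.n_components):
            for k in range(len(frames)):
                pairs = _body.collect_pairs_brute(
                    bodies[ci], pl[ci], bodies[cj],
                    np.asarray(frames[k]) @ pl[cj], max_pair_dist,
                )
                add(0, ci, {a for a, _ in pairs})
                add(k, cj, {b for _, b in pairs})
                add(0, cj, {b for _, b in pairs})
                add(int(inv[k]), ci, {a for a, _ in pairs})
    return tags


def filter_sscount(
    result: DockResult,
    min_ss_elements: int = 0,
    confidence: bool = True,
    max_pair_dist: float = 8.0,
):
    """Count distinct secondary-structure elements in the docked interface.

    An element is a maximal helix or strand run contributing at least one
    interface residue; each contacting chain copy contributes its own
    elements.  With confidence False the counts are reported for every dock
    and nothing is removed.
    """
    values = np.zeros(result.n_docks, int)
    for m in range(result.n_docks):
        values[m] = len(_interface_element_tags(result, m, max_pair_dist))
    if confidence:
        keep = np.flatnonzero(values >= min_ss_elements)
    else:
        keep = np.arange(result.n_docks)
    return keep, values


def filter_sasa(
    result: DockResult,
    min_sasa: float = 0.0,
    max_sasa: float = math.inf,
    confidence: bool = True,
    sasa_per_contact: float = rpxscore.SASA_PER_CONTACT,
):
    """Estimate buried interface area as c * ncontact and bound it.

    Uses the same contact-to-area conversion constant as the sasa_priority
    score function.
    """
    if min_sasa > max_sasa:
        raise ValueError(
            f"filter_sasa: min_sasa ({min_sasa}) exceeds max_sasa ({max_sasa})"
        )
    values = sasa_per_contact * np.asarray(result.data["ncontact"].values, float)
    if confidence:
        keep = np.flatnonzero((values >= min_sasa) & (values <= max_sasa))
    else:
        keep = np.arange(result.n_docks)
    return keep, values


FILTER_REGISTRY = {
    "filter_sscount": filter_sscount,
    "filter_sasa": filter_sasa,
}


def parse_filter_config(source) -> dict:
    """Parse a YAML filter configuration (text, path, or dict).

    Each entry is ``label: {type: <registered filter>, confidence: bool,
    <filter-specific params>}``; labels are arbitrary whitespace-free
    strings and order is preserved.
    """
    if isinstance(source, dict):
        cfgd = source
    else:
        text = source
        if isinstance(source, str) and os.path.exists(source):
            with open(source) as fh:
                text = fh.read()
        cfgd = yaml.safe_load(text)
    if not isinstance(cfgd, dict):
        raise ValueError("filter config must be a mapping of label -> settings")
    out = {}
    for label, settings in cfgd.items():
        if not isinstance(settings, dict) or "type" not in settings:
            raise ValueError(f"filter {label!r}: missing required 'type' key")
        ftype = settings["type"]
        if ftype not in FILTER_REGISTRY:
            raise ValueError(
                f"filter {label!r}: unknown type {ftype!r}; available: "
                f"{sorted(FILTER_REGISTRY)}"
            )
        if any(ch.isspace() for ch in str(label)):
            raise ValueError(f"filter label {label!r} must not contain whitespace")
        out[str(label)] = dict(settings)
    return out


def apply_filters(result: DockResult, filter_config) -> DockResult:
    """Apply configured filters in order, annotating values for every dock."""
    cfgd = parse_filter_config(filter_config)
    current = result
    for label, settings in cfgd.items():
        settings = dict(settings)
        ftype = settings.pop("type")
        confidence = bool(settings.pop("confidence", True))
        fn = FILTER_REGISTRY[ftype]
        keep, values = fn(current, confidence=confidence, **settings)
        current.data[label] = ("model", np.asarray(values))
        before = current.n_docks
        current = current.subset(keep)
        # re-attach annotation sliced to survivors happens via subset
        log.info("filter %s (%s): %d -> %d docks", label, ftype, before, current.n_docks)
    return current


# ---------------------------------------------------------------------------
# PDB output
# ---------------------------------------------------------------------------

def _closest_frames(result: DockResult, rank: int, maxdist: float = 8.0):
    """Per-component frames putting the asu chains at the densest interface."""
    spec = result.spec
    bodies = result.bodies_for(rank)
    pl = result.placements(rank)
    if spec.n_components < 2:
        return [np.eye(4)] * spec.n_components
    best, best_n = None, -1
    for F in spec.frames:
        n = len(
            _body.collect_pairs_brute(
                bodies[0], pl[0], bodies[1], np.asarray(F) @ pl[1], maxdist
            )
        )
        if n > best_n:
            best, best_n = F, n
    frames = [np.eye(4), np.asarray(best)]
    frames += [np.eye(4)] * (spec.n_components - 2)
    return frames


def dump_pdb(
    result: DockResult,
    rank: int,
    asym_only: bool = False,
    closest_subunits: bool = False,
) -> str:
    """PDB text of a docked model: the asu or the fully expanded assembly.

    Chains are labeled deterministically (A-Z, a-z, 0-9 in frame-major
    order).  Probe helices used for termini accessibility are never written.
    """
    if not 0 <= rank < result.n_docks:
        raise IndexError(
            f"model rank {rank} out of range (have {result.n_docks} docks)"
        )
    spec = result.spec
    pl = result.placements(rank)
    if asym_only:
        if closest_subunits:
            frames = _closest_frames(result, rank)
            chains = [
                (c, np.asarray(frames[c]) @ pl[c])
                for c in range(spec.n_components)
            ]
        else:
            chains = [(c, pl[c]) for c in range(spec.n_components)]
    else:
        chains = [
            (c, np.asarray(F) @ pl[c])
            for F in spec.frames
            for c in range(spec.n_components)
        ]
    lines = []
    serial = 1
    for k, (comp, X) in enumerate(chains):
        cid = CHAIN_IDS[k % len(CHAIN_IDS)]
        moved = result.bodies_for(rank)[comp].transformed(X)
        txt = _body._write_pdb_records(moved, cid, start_serial=serial)
        lines.append(txt)
        serial += moved.nres * 3
        lines.append("TER\n")
    lines.append("END\n")
    return "".join(lines)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_result(result: DockResult, path: str, overwrite: bool = False) -> None:
    """Write a result archive (.txz portable text or .pickle native)."""
    path = str(path)
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(
            f"{path} exists; pass --overwrite_existing_results to replace it"
        )
    if path.endswith(".txz"):
        meta = {
            "format_version": RESULT_FORMAT_VERSION,
            "architecture": result.spec.name,
            "config": result.config,
            "n_docks": result.n_docks,
            "body_labels": [bd.label for bd in result.bodies],
        }
        table = {
            name: np.asarray(result.data[name].values).tolist()
            for name in result.data.data_vars
            if name != "xforms"
        }
        with tarfile.open(path, "w:xz") as tf:
            _add = rpxscore._add_text
            _add(tf, "meta.json", json.dumps(meta, indent=1))
            _add(tf, "metrics.json", json.dumps(table))
            _add(
                tf,
                "xforms.json",
                json.dumps(np.asarray(result.data["xforms"].values).tolist()),
            )
            for c, bd in enumerate(result.bodies):
                _add(tf, f"bodies/comp{c}.pdb", bd.to_pdb_string())
    elif path.endswith(".pickle"):
        with open(path, "wb") as fh:
            pickle.dump(
                {"format_version": RESULT_FORMAT_VERSION, "result": result}, fh
            )
    else:
        raise ValueError(f"unknown result extension for {path!r}; use .txz or .pickle")


def load_result(path: str) -> DockResult:
    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"result file not found: {path}")
    if path.endswith(".pickle"):
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        return payload["result"]
    if not path.endswith(".txz"):
        raise ValueError(f"unknown result extension for {path!r}; use .txz or .pickle")
    with tarfile.open(path, "r:xz") as tf:
        meta = json.loads(rpxscore._read_text(tf, "meta.json"))
        if meta.get("format_version") != RESULT_FORMAT_VERSION:
            raise ValueError(
                f"result schema mismatch in {path}: expected format_version "
                f"{RESULT_FORMAT_VERSION}"
            )
        metrics = json.loads(rpxscore._read_text(tf, "metrics.json"))
        xforms = np.asarray(json.loads(rpxscore._read_text(tf, "xforms.json")))
        bodies = []
        for c, lbl in enumerate(meta["body_labels"]):
            pdb = rpxscore._read_text(tf, f"bodies/comp{c}.pdb")
            bodies.append(_body.load_body(pdb, label=lbl))
    spec = _arch.parse_architecture(meta["architecture"])
    n = meta["n_docks"]
    if xforms.size == 0:
        xforms = np.zeros((0, spec.n_components, 4, 4))
    data_vars = {
        "xforms": (("model", "comp", "hrow", "hcol"), xforms),
    }
    for name, vals in metrics.items():
        data_vars[name] = (("model",), np.asarray(vals))
    data = xr.Dataset(
        data_vars,
        attrs={"architecture": spec.name, "format_version": RESULT_FORMAT_VERSION},
    )
    return DockResult(spec=spec, bodies=bodies, data=data, config=meta["config"])


# ---------------------------------------------------------------------------
# allowed-residue list parsing
# ---------------------------------------------------------------------------

def parse_allowed_residues(text: str, nres: int) -> np.ndarray:
    """Parse a whitespace/newline-delimited residue list into a boolean mask.

    Entries are 1-based residue numbers or Python-style ranges ``a:b`` with
    negative-index semantics, inclusive of both endpoints ("80:-1" selects
    residue 80 through the last).
    """
    mask = np.zeros(nres, dtype=bool)

    def resolve(tok: str) -> int:
        v = int(tok)
        if v < 0:
            v = nres + 1 + v  # -1 -> last residue (1-based)
        if not 1 <= v <= nres:
            raise ValueError(f"residue index {tok} out of range 1..{nres}")
        return v

    for token in text.split():
        if ":" in token:
            a, b = token.split(":")
            lo, hi = resolve(a), resolve(b)
            if lo > hi:
                raise ValueError(f"empty residue range {token!r}")
            mask[lo - 1 : hi] = True
        else:
            v = resolve(token)
            mask[v - 1] = True
    return mask


def run_cli(argv=None) -> int:
    """Entry point for the command-line application (thin wrapper)."""
    from . import cli

    return cli.main(argv)
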