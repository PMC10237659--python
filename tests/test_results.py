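"""Filters, PDB emission, result persistence, and CLI plumbing."""

import math
import os

import numpy as np
import pytest
import xarray as xr

from symdock import arch, body, cli, fixtures, geom, results, rpxscore, search


def make_result(spec, bodies, placements, scores, **extra):
    """Assemble a DockResult directly from placements (test helper)."""
    n = len(placements)
    xforms = np.array(placements)
    data = {
        "xforms": (("model", "comp", "hrow", "hcol"), xforms),
        "scores": (("model",), np.asarray(scores, float)),
        "ncontact": (("model",), np.asarray(extra.get("ncontact", np.zeros(n)), int)),
        "rpx_sum": (("model",), np.zeros(n)),
        "rpx_mean": (("model",), np.zeros(n)),
    }
    return results.DockResult(
        spec=spec, bodies=bodies, data=xr.Dataset(data), config={}
    )


@pytest.fixture()
def d3_result(trimer):
    """A small ranked D3 result with known near-duplicate structure."""
    spec = arch.parse_architecture("D3")
    placements, scores = [], []
    rng = np.random.default_rng(42)
    for cluster, (rot, disp) in enumerate([(20.0, 12.0), (75.0, 18.0), (110.0, 9.0)]):
        for k in range(3):  # jitter << cutoff << inter-cluster distance
            jr = rot + rng.uniform(-0.5, 0.5)
            jd = disp + rng.uniform(-0.2, 0.2)
            placements.append([arch.place_component(spec, 0, jr, jd, False)])
            scores.append(30.0 - cluster * 5 - k)
    order = np.argsort(-np.asarray(scores))
    placements = [placements[i] for i in order]
    scores = [scores[i] for i in order]
    return make_result(spec, [trimer], placements, scores)


class TestFilterRedundancy:
    def test_exact_duplicates_keep_first(self, trimer):
        spec = arch.parse_architecture("D3")
        X = arch.place_component(spec, 0, 30.0, 10.0, False)
        res = make_result(spec, [trimer], [[X]] * 4, [9.0, 8.0, 7.0, 6.0])
        keep = results.filter_redundancy(res, 3.0)
        assert list(keep) == [0]

    def test_zero_cutoff_keeps_everything(self, d3_result):
        keep = results.filter_redundancy(d3_result, 0.0)
        assert len(keep) == d3_result.n_docks

    def test_one_survivor_per_cluster_best_scoring(self, d3_result):
        keep = results.filter_redundancy(d3_result, 3.0)
        assert len(keep) == 3
        # survivors must be the top-scoring member of each cluster: as docks
        # are walked best-first, each kept score exceeds later cluster members
        kept_scores = d3_result.data["scores"].values[keep]
        assert list(kept_scores) == [30.0, 25.0, 20.0]

    def test_max_cluster_truncates(self, d3_result):
        keep = results.filter_redundancy(d3_result, 3.0, max_cluster=2)
        assert len(keep) == 2


class TestFilterSSCount:
    def test_all_loop_interface_counts_zero(self):
        rng = np.random.default_rng(9)
        phi_psi = [(rng.uniform(-180, 180), rng.uniform(-180, 180)) for _ in range(8)]
        coil = fixtures._body_from_backbone(
            fixtures.backbone_from_dihedrals(phi_psi), "coil"
        )
        if "H" in coil.ss or "E" in coil.ss:
            pytest.skip("seeded coil unexpectedly structured")
        spec = arch.parse_architecture("C2")
        res = make_result(
            spec, [coil], [[geom.htrans([3.0, 0, 0])]], [1.0]
        )
        _, values = results.filter_sscount(res, confidence=False)
        assert values[0] == 0

    def test_helix_interfaces_count_elements(self, trimer):
        """Contacting helices on both sides are separate SS elements."""
        spec = arch.parse_architecture("D3")
        X = arch.place_component(spec, 0, 40.0, 9.0, False)
        res = make_result(spec, [trimer], [[X]], [1.0])
        keep, values = results.filter_sscount(res, min_ss_elements=2, confidence=True)
        assert values[0] >= 2
        assert list(keep) == [0]
        keep5, _ = results.filter_sscount(res, min_ss_elements=99, confidence=True)
        assert len(keep5) == 0

    def test_confidence_false_annotates_without_removing(self, d3_result):
        keep, values = results.filter_sscount(
            d3_result, min_ss_elements=99, confidence=False
        )
        assert len(keep) == d3_result.n_docks
        assert len(values) == d3_result.n_docks


class TestFilterSasa:
    def test_unbounded_removes_nothing(self, d3_result):
        keep, _ = results.filter_sasa(d3_result, 0.0, math.inf)
        assert len(keep) == d3_result.n_docks

    def test_zero_contact_docks_removed_by_min(self, d3_result):
        keep, values = results.filter_sasa(d3_result, min_sasa=1.0)
        assert len(keep) == 0  # helper result has ncontact 0 everywhere
        assert np.all(values == 0)

    def test_monotone_in_min_sasa(self, trimer):
        spec = arch.parse_architecture("D3")
        rng = np.random.default_rng(3)
        placements = [
            [arch.place_component(spec, 0, r, d, False)]
            for r, d in zip(rng.uniform(0, 120, 8), rng.uniform(8.5, 12, 8))
        ]
        res = make_result(
            spec, [trimer], placements, np.arange(8)[::-1],
            ncontact=rng.integers(0, 60, 8),
        )
        survivors = [
            len(results.filter_sasa(res, min_sasa=m)[0])
            for m in (0, 200, 400, 800, 1600)
        ]
        assert survivors == sorted(survivors, reverse=True)

    def test_min_above_max_is_config_error(self, d3_result):
        with pytest.raises(ValueError, match="min_sasa"):
            results.filter_sasa(d3_result, 500.0, 100.0)


class TestFilterConfig:
    def test_yaml_ordered_application(self, d3_result):
        yaml_text = """
keep_all:
  type: filter_sasa
  confidence: false
drop_small:
  type: filter_sscount
  min_ss_elements: 0
  confidence: true
"""
        out = results.apply_filters(d3_result, yaml_text)
        assert "keep_all" in out.data
        assert "drop_small" in out.data

    def test_unknown_type_rejected_at_parse(self):
        with pytest.raises(ValueError, match="unknown type"):
            results.parse_filter_config({"x": {"type": "filter_bogus"}})

    def test_whitespace_label_rejected(self):
        with pytest.raises(ValueError, match="whitespace"):
            results.parse_filter_config({"bad label": {"type": "filter_sasa"}})


class TestDumpPdb:
    @pytest.fixture()
    def o43_result(self, tetramer, trimer):
        spec = arch.parse_architecture("O43")
        pl = [
            arch.place_component(spec, 0, 10.0, 30.0, False),
            arch.place_component(spec, 1, 20.0, 28.0, False),
        ]
        return make_result(spec, [tetramer, trimer], [pl], [5.0])

    def test_full_octahedral_dump_has_48_chains(self, o43_result):
        txt = results.dump_pdb(o43_result, 0)
        assert txt.count("TER") == 48
        chains = {line[21] for line in txt.splitlines() if line.startswith("ATOM")}
        assert len(chains) == 48

    def test_asym_only_has_component_count_chains(self, o43_result):
        txt = results.dump_pdb(o43_result, 0, asym_only=True)
        chains = {line[21] for line in txt.splitlines() if line.startswith("ATOM")}
        assert len(chains) == o43_result.spec.n_components

    def test_asu_plus_frames_matches_full_dump(self, o43_result):
        """Re-expanding the dumped asu with the frames recreates the assembly."""
        spec = o43_result.spec
        asu = body.load_body(results.dump_pdb(o43_result, 0, asym_only=True))
        # asu loaded as one concatenated 24-residue body; re-apply all frames
        expanded = np.vstack(
            [geom.xform_points(F, asu.coords) for F in spec.frames]
        )
        full = body.load_body(results.dump_pdb(o43_result, 0))
        a = np.sort(expanded.round(3), axis=0)
        b = np.sort(full.coords.round(3), axis=0)
        assert np.abs(a - b).max() <= 2e-3

    def test_rank_out_of_range(self, o43_result):
        with pytest.raises(IndexError, match="rank"):
            results.dump_pdb(o43_result, 5)

    def test_closest_subunits_maximize_contacts(self, o43_result):
        spec = o43_result.spec
        txt = results.dump_pdb(
            o43_result, 0, asym_only=True, closest_subunits=True
        )
        bd = body.load_body(txt)
        # the two chains in the closest-subunit output are nearer than the
        # default asu placement
        chains_default = body.load_body(results.dump_pdb(o43_result, 0, asym_only=True))
        def chain_gap(b):
            brk = b.chain_breaks[0] + 1
            ca = b.ca_coords
            d = np.linalg.norm(ca[:brk, None] - ca[None, brk:], axis=-1)
            return d.min()
        assert chain_gap(bd) <= chain_gap(chains_default) + 1e-9


class TestPersistence:
    @pytest.fixture()
    def small_result(self, trimer):
        spec = arch.parse_architecture("D3")
        pl = [[arch.place_component(spec, 0, 30.0, 10.0, False)]]
        return make_result(spec, [trimer], pl, [3.5])

    def test_txz_round_trip_stable(self, small_result, tmp_path):
        p1 = tmp_path / "r1.txz"
        p2 = tmp_path / "r2.txz"
        results.save_result(small_result, p1)
        back = results.load_result(str(p1))
        results.save_result(back, p2)
        import tarfile

        def members(p):
            with tarfile.open(p) as tf:
                return {
                    m.name: tf.extractfile(m).read() for m in tf.getmembers()
                }

        assert members(p1) == members(p2)

    def test_pickle_round_trip(self, small_result, tmp_path):
        p = tmp_path / "r.pickle"
        results.save_result(small_result, p)
        back = results.load_result(str(p))
        assert back.n_docks == small_result.n_docks
        assert np.allclose(
            back.data["xforms"].values, small_result.data["xforms"].values
        )

    def test_overwrite_refused_by_default(self, small_result, tmp_path):
        p = tmp_path / "r.txz"
        results.save_result(small_result, p)
        with pytest.raises(FileExistsError, match="overwrite_existing_results"):
            results.save_result(small_result, p)
        results.save_result(small_result, p, overwrite=True)


class TestAllowedResidues:
    def test_numbers_and_ranges(self):
        mask = results.parse_allowed_residues("1 2 3 4 5\n7:12\n80:-1", 100)
        expected = np.zeros(100, bool)
        expected[0:5] = True
        expected[6:12] = True
        expected[79:100] = True
        assert np.array_equal(mask, expected)

    def test_negative_index_semantics(self):
        mask = results.parse_allowed_residues("-3:-1", 10)
        assert np.array_equal(np.flatnonzero(mask) + 1, [8, 9, 10])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            results.parse_allowed_residues("101", 100)


class TestCli:
    def test_help_lists_documented_options(self, capsys):
        with pytest.raises(SystemExit):
            cli.main(["--help"])
        out = capsys.readouterr().out
        for flag in (
            "--architecture", "--beam_size", "--cart_bounds", "--flip_components",
            "--max_longaxis_dot_z", "--termini_dir1", "--hscore_files",
            "--weight_sasa", "--max_bb_redundancy", "--nout_top",
        ):
            assert flag in out

    def test_nout_top_defaults_to_ten(self):
        args = cli.build_parser().parse_args(["--architecture", "C3"])
        assert args.nout_top == 10
        assert args.max_bb_redundancy == 3.0
        assert args.beam_size == 100_000

    def test_component_count_mismatch_rejected(self, tmp_path, helix12):
        pdb = tmp_path / "m.pdb"
        pdb.write_text(helix12.to_pdb_string())
        with pytest.raises(SystemExit, match="input list"):
            cli.main(
                ["--inputs1", str(pdb), "--inputs2", str(pdb),
                 "--architecture", "C3", "--output_prefix", str(tmp_path / "x")]
            )

    def test_asym_two_monomer_smoke(self, tmp_path, helix12, synth_table):
        """Tiny 6-DOF asymmetric dock runs end to end."""
        pdb = tmp_path / "m.pdb"
        pdb.write_text(helix12.to_pdb_string())
        table = tmp_path / "t.txz"
        rpxscore.save_hscore(synth_table, table)
        rc = cli.main(
            [
                "--inputs1", str(pdb), "--inputs2", str(pdb),
                "--architecture", "ASYM",
                "--hscore_files", str(table),
                "--cart_bounds", "-10", "10",
                "--n_levels", "2", "--beam_size", "100",
                "--max_models", "20",
                "--output_prefix", str(tmp_path / "asym"),
                "--dump_pdbs", "--nout_top", "1",
            ]
        )
        assert rc == 0
        assert (tmp_path / "asym_result.txz").exists()
        assert (tmp_path / "asym_000.pdb").exists()
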