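"""6D transform binning, hscore tables, and score-function closed forms."""

import math

import numpy as np
import pytest

from symdock import body, fixtures, geom, rpxscore


def random_xform(rng, scale=5.0):
    return geom.htrans(rng.normal(scale=scale, size=3)) @ geom.hrot(
        rng.normal(size=3), rng.uniform(0, 360)
    )


class TestBinXform:
    def test_identity_key_is_stable(self):
        k1 = rpxscore.bin_xform(np.eye(4), 10.0, 30.0, 0)
        k2 = rpxscore.bin_xform(np.eye(4), 10.0, 30.0, 0)
        assert k1 == k2 >= 0

    def test_well_separated_rotations_never_share_rotation_bins(self, rng):
        """Rotations > 2*ori_resl apart must fall in different rotation bins."""
        ori_resl = 30.0
        rot_mask = (1 << 30) - 1  # rotation cell + sub-coords bits
        for _ in range(300):
            X1 = np.eye(4)
            X1[:3, :3] = geom.hrot(rng.normal(size=3), rng.uniform(0, 360))[:3, :3]
            axis = rng.normal(size=3)
            X2 = X1.copy()
            ang = rng.uniform(2 * ori_resl + 1, 175.0)
            X2[:3, :3] = geom.hrot(axis, ang)[:3, :3] @ X1[:3, :3]
            k1 = rpxscore.bin_xform(X1, 10.0, ori_resl, 0)
            k2 = rpxscore.bin_xform(X2, 10.0, ori_resl, 0)
            assert (k1 & rot_mask) != (k2 & rot_mask)

    def test_bcc_covering_radius(self, rng):
        """Nearest BCC lattice point is within the closed-form sqrt(5)/4 * w."""
        w = 10.0
        pts = rng.uniform(-50, 50, size=(5000, 3))
        u = pts / w
        d_even = np.linalg.norm(u - np.round(u), axis=1)
        d_odd = np.linalg.norm(u - (np.floor(u) + 0.5), axis=1)
        nearest = np.minimum(d_even, d_odd) * w
        assert nearest.max() <= math.sqrt(5.0) / 4.0 * w + 1e-9

    def test_beyond_extent_flagged_unscored(self):
        X = geom.htrans([1e6, 0, 0])
        key = rpxscore.bin_xform(X, 10.0, 30.0, 0)
        assert key == -1
        table = rpxscore.HScoreTable(10.0, 30.0, [{}])
        assert table.lookup(0, key)[0] == 0.0

    def test_nearby_transforms_share_keys_more_often(self, rng):
        """Key-sharing probability rises as the separation shrinks."""
        shares = []
        for eps in (0.01, 2.0):
            hits = 0
            for _ in range(200):
                X = random_xform(rng)
                P = geom.htrans(rng.normal(scale=eps, size=3)) @ X
                hits += rpxscore.bin_xform(X, 10, 30, 0) == rpxscore.bin_xform(
                    P, 10, 30, 0
                )
            shares.append(hits / 200)
        assert shares[0] > shares[1]


class TestPairRpx:
    def test_empty_table_scores_zero(self, rng):
        table = rpxscore.HScoreTable(10.0, 30.0, [{}, {}])
        for _ in range(10):
            assert rpxscore.pair_rpx(table, random_xform(rng), random_xform(rng), 1) == 0.0

    def test_single_key_direct_lookup(self):
        X = geom.htrans([3.0, 1.0, -2.0]) @ geom.hrot([1, 1, 0], 40.0)
        key = rpxscore.bin_xform(X, 10.0, 30.0, 0)
        table = rpxscore.HScoreTable(10.0, 30.0, [{key: 7.5}])
        stub_i = geom.htrans([4.0, 4.0, 4.0]) @ geom.hrot([1, 2, 3], 25.0)
        stub_j = stub_i @ X
        assert rpxscore.pair_rpx(table, stub_i, stub_j, 0) == 7.5

    def test_coarse_bounds_fine_on_synthetic_table(self, synth_table, rng):
        """Hierarchical admissibility: coarse lookup >= fine lookup."""
        anchors = fixtures.helix_pair_anchor_xforms()
        checked = 0
        for _ in range(100):
            X = np.asarray(anchors[rng.integers(len(anchors))])
            X = geom.htrans(rng.normal(scale=0.5, size=3)) @ X
            vals = [
                rpxscore.pair_rpx(synth_table, np.eye(4), X, lvl)
                for lvl in range(synth_table.n_levels)
            ]
            for coarse, fine in zip(vals, vals[1:]):
                assert coarse >= fine - 1e-9
            checked += vals[-1] > 0
        assert checked > 10  # the planted region is actually exercised


class TestScoreFunctions:
    def test_stnd_closed_forms(self):
        assert rpxscore.score_stnd(0.0, 20, 1.0, 0.001) == pytest.approx(0.02)
        assert rpxscore.score_stnd(7.0, 0, 2.0, 0.5) == pytest.approx(14.0)
        assert rpxscore.score_stnd(10.0, 20, 1.0, 0.001) == pytest.approx(10.02)

    def test_variants_closed_forms(self):
        assert rpxscore.score_variants([5.0], 0, "exp") == pytest.approx(5.0)
        assert rpxscore.score_variants([0.7514], 1, "lin") == pytest.approx(0.0)
        assert rpxscore.score_variants([3.0, 3.0, 3.0], 3, "median") == pytest.approx(3.0)
        assert rpxscore.score_variants([1.0, 2.0, 6.0], 3, "mean") == pytest.approx(3.0)
        assert rpxscore.score_variants(
            [10.0, 10.0], 2, "exp"
        ) == pytest.approx(20.0 - 4.6679 * 2**0.588)
        with pytest.raises(ValueError, match="mean, median"):
            rpxscore.score_variants([1.0], 1, "bogus")

    @pytest.mark.parametrize("sigma", [2.0, 4.0, 8.0])
    def test_sasa_priority_mode_at_target_area(self, sigma):
        """The contact-density term peaks where c*N equals weight_sasa."""
        mu, c = 1152.0, rpxscore.SASA_PER_CONTACT
        target = int(mu / c)
        vals = {
            n: rpxscore.lognormal_contact_term(n, mu, sigma, c)
            for n in range(1, 200)
        }
        assert max(vals, key=vals.get) == target

    @pytest.mark.parametrize("sigma", [2.0, 4.0, 8.0])
    def test_sasa_priority_monotone_away_from_mode(self, sigma):
        mu, c = 1152.0, rpxscore.SASA_PER_CONTACT
        target = int(mu / c)
        vals = [
            float(rpxscore.lognormal_contact_term(n, mu, sigma, c))
            for n in range(1, 200)
        ]
        before = vals[: target - 1]
        after = vals[target - 1 :]
        assert all(a < b for a, b in zip(before, before[1:]))
        assert all(a > b for a, b in zip(after, after[1:]))

    def test_sasa_priority_b_zero_is_mean_rpx(self):
        assert rpxscore.score_sasa_priority(3.7, 55, a=1.0, b=0.0) == pytest.approx(3.7)

    def test_sasa_priority_zero_contacts_scores_zero(self):
        assert rpxscore.score_sasa_priority(5.0, 0) == 0.0

    def test_unknown_function_rejected(self):
        with pytest.raises(ValueError, match="unknown score function"):
            rpxscore.ScoreParams(function="best")


class TestScoreInterface:
    def test_no_contacts_scores_zero(self, helix12, synth_table):
        far = geom.htrans([500.0, 0, 0])
        out = rpxscore.score_interface(
            helix12, np.eye(4), helix12, far, synth_table,
            rpxscore.ScoreParams(), synth_table.n_levels - 1,
        )
        assert out == (0.0, 0, 0.0, 0.0)

    def test_single_pair_value_plus_contact_term(self, helix12):
        """One contacting pair with table value v scores v + b under stnd."""
        X = geom.htrans([9.0, 0.0, 0.0])
        params = rpxscore.ScoreParams()
        pairs = body.collect_pairs_brute(
            helix12, np.eye(4), helix12, X,
            params.maxdist_at(10.0, 0),
        )
        # populate exactly one pair's bin
        i, j = pairs[0]
        rel = geom.hinv(helix12.stubs[i]) @ X @ helix12.stubs[j]
        key = rpxscore.bin_xform(rel, 10.0, 30.0, 0)
        table = rpxscore.HScoreTable(10.0, 30.0, [{key: 4.0}])
        score, ncontact, rpx_sum, rpx_mean = rpxscore.score_interface(
            helix12, np.eye(4), helix12, X, table, params, 0
        )
        assert ncontact == len(pairs)
        assert rpx_sum >= 4.0  # other pairs may alias into the same bin
        assert score == pytest.approx(rpx_sum + 0.001 * ncontact)

    def test_ss_restriction_keeps_contacts_but_drops_rpx(self, synth_table):
        """Loop-only pairs count as contacts but contribute no motif score."""
        h = fixtures.make_ideal_helix(12)
        X = geom.htrans([9.0, 0.0, 0.0])
        params_h = rpxscore.ScoreParams(score_only_ss="E")  # helix body has no E
        score, ncontact, rpx_sum, _ = rpxscore.score_interface(
            h, np.eye(4), h, X, synth_table, params_h, synth_table.n_levels - 1
        )
        assert ncontact > 0
        assert rpx_sum == 0.0
        assert score == pytest.approx(0.001 * ncontact)

    def test_masked_residues_count_as_contacts_only(self, synth_table):
        h = fixtures.make_ideal_helix(12)
        X = geom.htrans([9.0, 0.0, 0.0])
        lvl = synth_table.n_levels - 1
        params = rpxscore.ScoreParams()
        _, n0, r0, _ = rpxscore.score_interface(
            h, np.eye(4), h, X, synth_table, params, lvl
        )
        masked = fixtures.make_ideal_helix(12)
        masked.allowed_mask[:] = False
        _, n1, r1, _ = rpxscore.score_interface(
            masked, np.eye(4), masked, X, synth_table, params, lvl
        )
        assert n1 == n0
        assert r1 == 0.0

    def test_invariant_under_common_rigid_motion(self, helix12, synth_table, rng):
        X = geom.htrans([9.0, 0.5, 1.0])
        lvl = synth_table.n_levels - 1
        params = rpxscore.ScoreParams()
        base = rpxscore.score_interface(
            helix12, np.eye(4), helix12, X, synth_table, params, lvl
        )
        for _ in range(5):
            G = random_xform(rng, scale=20.0)
            moved = rpxscore.score_interface(
                helix12, G, helix12, G @ X, synth_table, params, lvl
            )
            assert moved[1] == base[1]
            assert moved[2] == pytest.approx(base[2], abs=1e-9)


class TestHScoreIO:
    def _table(self):
        return fixtures.make_synthetic_hscore(
            fixtures.FixtureSpec(seed=3, hscore_n_keys=5), n_levels=2
        )

    @pytest.mark.parametrize("ext", ["txz", "pickle"])
    def test_round_trip_lossless(self, tmp_path, ext):
        table = self._table()
        path = tmp_path / f"table.{ext}"
        rpxscore.save_hscore(table, path)
        back = rpxscore.load_hscore(str(path))
        assert back.cart_resl == table.cart_resl
        assert back.ori_resl == table.ori_resl
        assert back.subset_tag == table.subset_tag
        assert len(back.levels) == len(table.levels)
        for a, b in zip(back.levels, table.levels):
            assert a == b

    def test_subset_tag_provenance_recorded(self, tmp_path):
        table = self._table()
        table.subset_tag = "ILV_H"
        path = tmp_path / "ilv.txz"
        rpxscore.save_hscore(table, path)
        assert rpxscore.load_hscore(str(path)).subset_tag == "ILV_H"

    def test_missing_file_clear_error(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="not found"):
            rpxscore.load_hscore(str(tmp_path / "nope.txz"))

    def test_schema_mismatch_cites_version(self, tmp_path):
        import json
        import tarfile

        path = tmp_path / "bad.txz"
        with tarfile.open(path, "w:xz") as tf:
            rpxscore._add_text(
                tf, "meta.json",
                json.dumps({"format_version": 999, "n_levels": 0}),
            )
        with pytest.raises(ValueError, match="format_version"):
            rpxscore.load_hscore(str(path))
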