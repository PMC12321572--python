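"""Generator contracts: determinism, statistical law, geometry of the truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from arraytomo.pairing import attach_tau_flags, enrichment_ratio, find_pairs
from arraytomo.synthetic import (
    OpticsParams,
    SceneParams,
    generate_fret_set,
    generate_scene,
    objects_from_truth,
    render_stacks,
)


class TestSceneParams:
    @pytest.mark.parametrize(
        "field, value",
        [
            ("p_pre", 1.5),
            ("q1", -0.1),
            ("paired_fraction", 2.0),
            ("pre_density", -1.0),
            ("pixel_size", 0.0),
            ("tau_scale", 1.0),
            ("pair_offset_range", (0.2, 0.7)),  # max beyond pairing radius
            ("pair_offset_range", (0.0, 0.3)),
        ],
    )
    def test_invalid_parameters_name_the_field(self, field, value):
        with pytest.raises(ValueError, match=field.split("_")[0]):
            SceneParams(**{field: value})

    def test_engulfment_requires_astro_volume(self):
        with pytest.raises(ValueError, match="engulf_fraction"):
            SceneParams(astro_fraction_of_volume=0.0, engulf_fraction=0.2)

    def test_implied_enrichment_closed_form(self):
        p = SceneParams(p_pre=0.3, q1=0.6, q0=0.02)
        expected = 0.6 / (0.3 * 0.6 + 0.7 * 0.02)
        assert p.implied_true_enrichment == pytest.approx(expected, rel=1e-12)


class TestGenerateScene:
    def test_seeded_determinism_bit_identical(self):
        params = SceneParams(field_x=15, field_y=15, n_sections=12, seed=7)
        a = generate_scene(params)
        b = generate_scene(params)
        pd.testing.assert_frame_equal(a.puncta, b.puncta)
        pd.testing.assert_frame_equal(a.pairing, b.pairing)
        assert np.array_equal(a.astro_mask, b.astro_mask)

    def test_different_seeds_differ(self):
        a = generate_scene(SceneParams(field_x=15, field_y=15, seed=1))
        b = generate_scene(SceneParams(field_x=15, field_y=15, seed=2))
        assert len(a.puncta) != len(b.puncta) or not np.allclose(
            a.puncta[["cx", "cy"]].to_numpy(), b.puncta[["cx", "cy"]].to_numpy()
        )

    def test_degenerate_probabilities(self):
        truth = generate_scene(
            SceneParams(field_x=15, field_y=15, seed=3, p_pre=1.0, q1=1.0, q0=0.0)
        )
        pre = truth.role("pre")
        assert pre["tau"].all()
        paired_posts = truth.puncta.set_index("id").loc[truth.pairing["post_id"]]
        assert paired_posts["tau"].all()
        # orphan posts draw tau at q0 = 0
        orphan = truth.role("post")[~truth.role("post")["id"].isin(truth.pairing["post_id"])]
        assert not orphan["tau"].any()

    def test_pre_count_poisson_interval(self):
        # mean = 0.5 / um^3 * (50 * 50 * 1.4 um^3) = 1750; central 99.9% interval
        truth = generate_scene(
            SceneParams(field_x=50, field_y=50, n_sections=20, pre_density=0.5, seed=11)
        )
        n_pre = len(truth.role("pre"))
        lo = stats.poisson.ppf(0.0005, 1750)
        hi = stats.poisson.ppf(0.9995, 1750)
        assert lo <= n_pre <= hi

    def test_pair_offsets_within_range(self, small_scene):
        lo, hi = small_scene.params.pair_offset_range
        off = small_scene.pairing["offset_um"]
        assert ((off >= lo - 1e-12) & (off <= hi + 1e-12)).all()

    def test_partner_is_nearest_pre(self, small_scene):
        """The generator guarantees identifiable pairs: each paired post's
        true partner is its nearest presynapse."""
        pre = small_scene.role("pre").set_index("id")
        posts = small_scene.role("post").set_index("id")
        from scipy.spatial import cKDTree

        tree = cKDTree(pre[["cx", "cy", "cz"]].to_numpy())
        p = posts.loc[small_scene.pairing["post_id"], ["cx", "cy", "cz"]].to_numpy()
        _, idx = tree.query(p, k=1)
        nearest_ids = pre.index.to_numpy()[idx]
        assert np.array_equal(nearest_ids, small_scene.pairing["pre_id"].to_numpy())

    def test_orphans_have_no_pre_within_radius(self, small_scene):
        from scipy.spatial import cKDTree

        pre = small_scene.role("pre")
        posts = small_scene.role("post")
        orphan = posts[~posts["id"].isin(small_scene.pairing["post_id"])]
        if len(orphan) == 0:
            pytest.skip("no orphans drawn at this seed")
        tree = cKDTree(pre[["cx", "cy", "cz"]].to_numpy())
        d, _ = tree.query(orphan[["cx", "cy", "cz"]].to_numpy(), k=1)
        assert (d > 0.5).all()

    def test_tau_puncta_fully_inside_hosts(self, small_scene):
        tau = small_scene.role("tau")
        hosts = small_scene.puncta.set_index("id")
        for row in tau.itertuples():
            h = hosts.loc[row.host_id]
            # support function check for axis-aligned ellipsoid containment:
            # scaled centre offset norm + tau/host axis ratio <= 1
            off = np.array([row.cx - h.cx, row.cy - h.cy, row.cz - h.cz])
            scaled = np.linalg.norm(off / np.array([h.rx, h.ry, h.rz]))
            assert scaled + row.rx / h.rx <= 1.0 + 1e-9

    def test_engulfed_centroids_inside_astro_mask(self, small_scene):
        g = small_scene.params.geometry
        eng = small_scene.puncta[small_scene.puncta["engulfed"]]
        assert len(eng) > 0
        idx = np.rint(
            eng[["cz", "cy", "cx"]].to_numpy() / np.array([g.dz, g.dy, g.dx])
        ).astype(int)
        idx = np.minimum(idx, np.array(small_scene.astro_mask.shape) - 1)
        assert small_scene.astro_mask[idx[:, 0], idx[:, 1], idx[:, 2]].all()

    def test_astro_mask_hits_target_fraction(self, small_scene):
        target = small_scene.params.astro_fraction_of_volume
        assert small_scene.astro_mask.mean() == pytest.approx(target, rel=0.02)

    def test_generator_law_conditional_tau_rate(self):
        """Across many seeds the tau rate of posts paired to tau+ pres
        converges to q1 (within 3 binomial standard errors)."""
        q1, q0 = 0.6, 0.05
        hits = trials = 0
        for seed in range(200):
            truth = generate_scene(
                SceneParams(
                    field_x=10, field_y=10, n_sections=10, seed=seed,
                    q1=q1, q0=q0, astro_fraction_of_volume=0.0, engulf_fraction=0.0,
                )
            )
            flags = truth.puncta.set_index("id")["tau"]
            pre_tau = flags.loc[truth.pairing["pre_id"]].to_numpy()
            post_tau = flags.loc[truth.pairing["post_id"]].to_numpy()
            hits += int((pre_tau & post_tau).sum())
            trials += int(pre_tau.sum())
        rate = hits / trials
        se = np.sqrt(q1 * (1 - q1) / trials)
        assert abs(rate - q1) <= 3 * se


class TestRenderStacks:
    def test_identity_optics_maxima_at_centres(self, small_scene):
        stack = render_stacks(
            small_scene,
            OpticsParams(
                psf_sigma_xy=0.0, gaussian_noise_sd=0.0, photon_noise=False,
                jitter_translation_max=0.0, jitter_rotation_max=0.0,
                speckle_rate=0.0, bit_depth=None,
            ),
        )
        g = small_scene.params.geometry
        arr = stack.channels["SYO"]
        pre = small_scene.role("pre")
        inside = pre[~pre["clipped"]]
        for row in inside.sample(20, random_state=0).itertuples():
            k = int(round(row.cz / g.dz))
            i = int(round(row.cy / g.dy))
            j = int(round(row.cx / g.dx))
            assert arr[k, i, j] >= 200.0

    def test_render_deterministic(self, small_scene):
        opt = OpticsParams(speckle_rate=2.0)
        a = render_stacks(small_scene, opt)
        b = render_stacks(small_scene, opt)
        for name in a.channel_names:
            assert np.array_equal(a.channels[name], b.channels[name])

    def test_jitter_within_bounds_and_recorded(self, small_scene):
        opt = OpticsParams(jitter_translation_max=3.0, jitter_rotation_max=1.0)
        render_stacks(small_scene, opt)
        t = small_scene.transforms
        assert (t[["dx", "dy"]].abs().to_numpy() <= 3.0).all()
        assert (t["theta"].abs() <= 1.0).all()
        assert t.iloc[0][["dx", "dy", "theta"]].eq(0).all()  # anchor section

    def test_noise_substream_does_not_move_geometry(self):
        params = SceneParams(field_x=12, field_y=12, n_sections=10, seed=9)
        a = generate_scene(params)
        b = generate_scene(params)
        render_stacks(a, OpticsParams(gaussian_noise_sd=0.0, photon_noise=False))
        render_stacks(b, OpticsParams(gaussian_noise_sd=5.0, photon_noise=True))
        pd.testing.assert_frame_equal(a.transforms, b.transforms)

    def test_speckles_span_one_section_in_truth(self, small_scene):
        opt = OpticsParams(speckle_rate=5.0)
        render_stacks(small_scene, opt)
        sp = small_scene.speckles
        assert len(sp) > 0
        assert sp.groupby("id")["section"].nunique().eq(1).all()


class TestFretSet:
    def test_donor_only_exact_ratio(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[8:20, 8:20] = True
        s = generate_fret_set(0.2, 0.1, mask, seed=0)
        don = s["donor_only"]
        pos = don.i_dd > 0
        assert np.allclose(don.i_da[pos] / don.i_dd[pos], 0.2, atol=1e-12)

    def test_double_label_is_exact_linear_mixture(self):
        mask = np.zeros((24, 24), dtype=bool)
        mask[4:12, 4:12] = True
        s = generate_fret_set(0.15, 0.30, mask, seed=1, f_true=40.0)
        d = s["double_label"]
        recon = 0.15 * d.i_dd + 0.30 * d.i_aa + d.f_true
        assert np.allclose(d.i_da, recon, atol=1e-12)
        assert (d.f_true[~mask] == 0).all()

    def test_negative_coefficients_rejected(self):
        with pytest.raises(ValueError, match="coefficients"):
            generate_fret_set(-0.1, 0.2, np.ones((8, 8), dtype=bool))
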