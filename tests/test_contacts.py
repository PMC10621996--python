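"""ER-lysosome overlap, apparent-overlap calculator, proximity, colocalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lysotube import contacts, detection, synthetic_scenes as ss
from lysotube.contacts import ApparentOverlapInputs


class TestOverlapFraction:
    def test_full_er_coverage_gives_fraction_one(self):
        lyso = np.zeros((20, 20), bool)
        lyso[2:6, 2:6] = True
        lyso[10:14, 10:14] = True
        records = contacts.overlap_fraction(lyso, np.ones((20, 20), bool))
        assert len(records) == 2
        assert all(r.overlap_fraction == 1.0 and r.in_contact for r in records)

    def test_disjoint_masks_give_zero(self):
        lyso = np.zeros((20, 20), bool)
        lyso[2:6, 2:6] = True
        er = np.zeros((20, 20), bool)
        er[15:18, 15:18] = True
        (rec,) = contacts.overlap_fraction(lyso, er)
        assert rec.overlap_fraction == 0.0 and not rec.in_contact

    def test_half_covered_square_gives_half(self):
        lyso = np.zeros((20, 20), bool)
        lyso[5:15, 5:15] = True  # 10x10 square
        er = np.zeros((20, 20), bool)
        er[:, 5:10] = True  # strip over 5 of its 10 columns
        (rec,) = contacts.overlap_fraction(lyso, er)
        assert rec.overlap_fraction == pytest.approx(0.5)
        assert rec.in_contact  # 0.5 > 0.30

    def test_empty_lysosome_mask_gives_empty_list(self):
        assert contacts.overlap_fraction(
            np.zeros((8, 8), bool), np.ones((8, 8), bool)
        ) == []

    def test_invariant_under_common_rigid_transform(self, contact_scene):
        lyso = detection.binarize_spots(contact_scene.lysosome_stack[0])
        er = contact_scene.er_mask
        base = sorted(
            r.overlap_fraction for r in contacts.overlap_fraction(lyso, er)
        )
        moved = sorted(
            r.overlap_fraction
            for r in contacts.overlap_fraction(np.rot90(lyso), np.rot90(er))
        )
        assert np.allclose(base, moved)


class TestApparentOverlap:
    def test_reference_geometry_reproduced(self):
        result = contacts.apparent_overlap()
        assert result.overlap_nm == 230.0
        assert result.apparent_lysosome_diameter_nm == 740.0
        # "about 30%" of the apparent diameter
        assert round(result.percent_of_diameter, -1) == 30.0

    def test_gap_of_two_pixels_gives_zero_overlap(self):
        result = contacts.apparent_overlap(
            ApparentOverlapInputs(edge_gap_nm=240.0)
        )
        assert result.overlap_nm == 0.0

    @given(
        gap=st.floats(0, 300),
        gap_delta=st.floats(0, 100),
        pixel=st.floats(50, 300),
        pixel_delta=st.floats(0, 100),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_monotone_in_gap_and_pixel_size(self, gap, gap_delta, pixel,
                                            pixel_delta):
        base = contacts.apparent_overlap(
            ApparentOverlapInputs(edge_gap_nm=gap, pixel_size_nm=pixel)
        ).overlap_nm
        wider_gap = contacts.apparent_overlap(
            ApparentOverlapInputs(edge_gap_nm=gap + gap_delta,
                                  pixel_size_nm=pixel)
        ).overlap_nm
        bigger_pixel = contacts.apparent_overlap(
            ApparentOverlapInputs(edge_gap_nm=gap,
                                  pixel_size_nm=pixel + pixel_delta)
        ).overlap_nm
        assert wider_gap <= base
        assert bigger_pixel >= base


class TestFlipControl:
    def test_full_coverage_unaffected_by_flip(self):
        lyso = np.zeros((20, 20), bool)
        lyso[8:12, 8:12] = True
        records = contacts.flip_control(lyso, np.ones((20, 20), bool))
        assert all(r.overlap_fraction == 1.0 for r in records)

    def test_vertical_stripe_contacts_destroyed_by_flip(self):
        # lysosomes sitting exactly on a vertical ER stripe; after a 90
        # degree rotation they lie on a horizontal line and miss the stripe
        er = np.zeros((40, 40), bool)
        er[:, 18:22] = True
        lyso = np.zeros((40, 40), bool)
        for cy in (5, 15, 25, 35):
            lyso[cy - 1 : cy + 2, 19 : 21] = True
        structured = [r.overlap_fraction for r in
                      contacts.overlap_fraction(lyso, er)]
        flipped = contacts.flip_control(lyso, er)
        assert all(f == 1.0 for f in structured)
        off_stripe = [r for r in flipped if r.overlap_fraction == 0.0]
        assert len(off_stripe) >= 2

    def test_flip_null_below_structured_overlap(self, contact_scene):
        lyso = detection.binarize_spots(contact_scene.lysosome_stack[0])
        er = contact_scene.er_mask
        structured = np.mean(
            [r.overlap_fraction for r in contacts.overlap_fraction(lyso, er)]
        )
        null = np.mean(
            [r.overlap_fraction for r in contacts.flip_control(lyso, er)]
        )
        assert null < structured

    def test_contact_call_rate_monotone_in_contact_fraction(self):
        rates = []
        for cf in (0.0, 0.5, 1.0):
            cfg = ss.SceneConfig(
                n_round=10, n_tubular=5, n_frames=1, noise_sd=0.0,
                jitter_sd_um=0.0, contact_fraction=cf, seed=7,
            )
            scene = ss.generate_scene(cfg)
            lyso = detection.binarize_spots(scene.lysosome_stack[0])
            records = contacts.overlap_fraction(lyso, scene.er_mask)
            rates.append(np.mean([r.in_contact for r in records]))
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > rates[0]


class TestMembraneProximity:
    def test_touching_masks_are_near(self):
        lyso = np.zeros((20, 20), bool)
        lyso[5:10, 5:10] = True
        er = np.zeros((20, 20), bool)
        er[5:10, 10:15] = True  # shares an edge with the lysosome
        (rec,) = contacts.membrane_proximity(lyso, er, pixel_size_nm=5.0,
                                             cutoff_nm=30.0)
        assert rec.is_near
        assert rec.fraction_of_boundary_near > 0

    def test_distant_masks_are_not_near(self):
        lyso = np.zeros((30, 30), bool)
        lyso[2:6, 2:6] = True
        er = np.zeros((30, 30), bool)
        er[20:25, 20:25] = True
        (rec,) = contacts.membrane_proximity(lyso, er, pixel_size_nm=5.0,
                                             cutoff_nm=30.0)
        assert not rec.is_near

    def test_boundary_fraction_matches_constructed_geometry(self):
        # 10x10 square lysosome; ER slab 2 px away (10 nm at 5 nm/px).
        # Only the facing edge of the lysosome boundary is within 30 nm:
        # boundary pixels at distance <= 6 px of the ER membrane.
        lyso = np.zeros((30, 40), bool)
        lyso[10:20, 5:15] = True
        er = np.zeros((30, 40), bool)
        er[10:20, 17:25] = True
        (rec,) = contacts.membrane_proximity(lyso, er, pixel_size_nm=5.0,
                                             cutoff_nm=30.0)
        # lysosome boundary: 36 pixels; near set: facing column (10 px,
        # at 3 px -> 15 nm) plus the two corners-adjacent columns within
        # sqrt(3^2+...)  -- count analytically from pixel distances
        ys, xs = np.nonzero(_boundary(lyso))
        er_ys, er_xs = np.nonzero(_boundary(er))
        d = np.sqrt(
            (ys[:, None] - er_ys[None, :]) ** 2
            + (xs[:, None] - er_xs[None, :]) ** 2
        ).min(1)
        expected = (d * 5.0 <= 30.0).mean()
        assert rec.fraction_of_boundary_near == pytest.approx(expected)
        assert rec.is_near

    def test_warns_when_cutoff_below_pixel(self, caplog):
        lyso = np.zeros((10, 10), bool)
        lyso[2:4, 2:4] = True
        er = np.zeros((10, 10), bool)
        er[2:4, 5:7] = True
        import logging

        with caplog.at_level(logging.WARNING):
            contacts.membrane_proximity(lyso, er, pixel_size_nm=120.0,
                                        cutoff_nm=30.0)
        assert any("quantized" in r.message for r in caplog.records)


def _boundary(mask):
    from scipy import ndimage

    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return mask & ~eroded


class TestSpotColocalization:
    def test_spot_classes(self):
        a = np.zeros((10, 10), bool)
        a[0:5, :] = True
        b = np.zeros((10, 10), bool)
        b[:, 0:5] = True
        pts = np.array([[2.0, 2.0], [8.0, 2.0], [2.0, 8.0], [8.0, 8.0]])
        classes, props = contacts.spot_colocalization(pts, a, b)
        assert [c.coloc for c in classes] == [
            "both", "mask_a_only", "mask_b_only", "neither"
        ]

    def test_constructed_proportions(self):
        a = np.zeros((20, 20), bool)
        a[:10, :] = True
        b = np.zeros((20, 20), bool)
        b[:, :10] = True
        pts = (
            [[2.0, 2.0]] * 4  # both
            + [[15.0, 2.0]] * 3  # a only
            + [[2.0, 15.0]] * 2  # b only
            + [[15.0, 15.0]] * 1  # neither
        )
        _, props = contacts.spot_colocalization(np.array(pts), a, b)
        assert props == {
            "mask_a_only": 0.3, "mask_b_only": 0.2,
            "both": 0.4, "neither": 0.1,
        }

    def test_zero_spots_warns_and_returns_empty(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            classes, props = contacts.spot_colocalization(
                np.empty((0, 2)), np.zeros((5, 5), bool), np.zeros((5, 5), bool)
            )
        assert classes == [] and props == {}
        assert any("zero spots" in r.message for r in caplog.records)

    def test_out_of_bounds_spot_rejected(self):
        with pytest.raises(ValueError, match="out of bounds"):
            contacts.spot_colocalization(
                np.array([[50.0, 2.0]]),
                np.zeros((10, 10), bool),
                np.zeros((10, 10), bool),
            )
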