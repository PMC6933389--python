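"""Mirror-map comparison: flip, registration, ROI detection, homologous
matching, chemotopy and concentration consistency."""

import numpy as np
import pytest

from glomap.activity import ActivityMap
from glomap.symmetry import (
    GlomerulusSet,
    Roi,
    chemotopy_shift,
    concentration_response,
    detect_glomeruli,
    flip_medial,
    match_ensembles,
    register_ap_offset,
    Registration,
)
from glomap.synthetic import Glomerulus, MapSpec, generate_map_pair, render_activity_map

PANEL = ["3CHO", "4CHO", "5CHO", "6CHO", "7CHO"]
MAP_NOISE = 3e-4  # map-level ΔF/F0 noise from default acquisition settings


def _amap(values, view="medial", odorant="5CHO"):
    return ActivityMap(np.asarray(values, float), odorant, 0.2, 4, 700, 200,
                       (1.4, 0.4), view=view)


@pytest.fixture(scope="module")
def map_pair():
    return generate_map_pair(8, PANEL, seed=7, ap_offset_px=12)


def rendered_views(map_pair, noise_sd=0.0, seed0=0):
    """Dorsal maps and flipped medial maps for the whole panel."""
    dorsal_spec, medial_spec = map_pair
    dmaps = [render_activity_map(dorsal_spec, o, noise_sd=noise_sd,
                                 seed=seed0 + i) for i, o in enumerate(PANEL)]
    mmaps = [render_activity_map(medial_spec, o, noise_sd=noise_sd,
                                 seed=seed0 + 50 + i)[::-1].copy()
             for i, o in enumerate(PANEL)]
    return dmaps, mmaps


class TestFlip:
    def test_flip_is_involution_on_values(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0, 1, (16, 16))
        flipped = flip_medial(_amap(values))
        assert np.array_equal(flipped.values[::-1], values)

    def test_single_pixel_moves_to_mirror_row(self):
        values = np.zeros((16, 16))
        values[3, 11] = 1.0
        flipped = flip_medial(_amap(values))
        assert flipped.values[16 - 1 - 3, 11] == 1.0
        assert flipped.values.sum() == 1.0

    def test_double_flip_guard(self):
        flipped = flip_medial(_amap(np.zeros((8, 8))))
        with pytest.raises(ValueError, match="already flipped"):
            flip_medial(flipped)

    def test_flipped_medial_correlates_with_dorsal(self, map_pair):
        dmaps, mmaps = rendered_views(map_pair)
        reg = register_ap_offset(np.max(np.stack(dmaps), 0),
                                 np.max(np.stack(mmaps), 0))
        assert reg.score > 0.9


class TestRegistration:
    def test_identical_maps_zero_shift_unit_score(self):
        values = np.random.default_rng(1).normal(0, 1, (32, 32))
        reg = register_ap_offset(values, values.copy(), max_shift_px=10)
        assert reg.ap_shift_px == 0
        assert reg.score == pytest.approx(1.0)

    def test_true_offset_recovered_noiseless(self, map_pair):
        dmaps, mmaps = rendered_views(map_pair)
        reg = register_ap_offset(np.max(np.stack(dmaps), 0),
                                 np.max(np.stack(mmaps), 0))
        # shift applied to the flipped medial map = minus the prism offset
        assert abs(reg.ap_shift_px + 12) <= 1

    def test_true_offset_recovered_default_noise(self, map_pair):
        dmaps, mmaps = rendered_views(map_pair, noise_sd=MAP_NOISE, seed0=3)
        reg = register_ap_offset(np.max(np.stack(dmaps), 0),
                                 np.max(np.stack(mmaps), 0))
        assert abs(reg.ap_shift_px + 12) <= 2

    def test_additive_offset_invariance(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, (32, 32))
        b = np.roll(a, 5, axis=1)
        r1 = register_ap_offset(a, b, max_shift_px=10)
        r2 = register_ap_offset(a, b + 3.14, max_shift_px=10)
        assert r1.ap_shift_px == r2.ap_shift_px
        assert r1.score == pytest.approx(r2.score)

    def test_zero_variance_overlap_raises(self):
        with pytest.raises(ValueError, match="overlap"):
            register_ap_offset(np.zeros((8, 8)), np.zeros((8, 8)),
                               max_shift_px=2)


class TestDetection:
    def test_all_zero_maps_give_empty_set(self):
        gset = detect_glomeruli([np.zeros((32, 32))])
        assert gset.rois == []

    def test_separated_blobs_found_with_subpixel_centroids(self, map_pair):
        dorsal_spec, _ = map_pair
        dmaps = [render_activity_map(dorsal_spec, o, noise_sd=MAP_NOISE,
                                     seed=i) for i, o in enumerate(PANEL)]
        gset = detect_glomeruli(dmaps, labels=PANEL)
        assert len(gset.rois) == 8
        true_centers = np.array(
            [(g.center_y_px, g.center_x_px) for g in dorsal_spec.glomeruli]
        )
        found = np.array([r.centroid_px for r in gset.rois])
        d = np.sqrt(((true_centers[:, None] - found[None]) ** 2).sum(-1))
        assert d.min(axis=1).max() <= 1.0

    def test_adjacent_peaks_merge_to_stronger(self):
        values = np.zeros((32, 32))
        yy, xx = np.mgrid[0:32, 0:32]
        values += 0.06 * np.exp(-((xx - 15) ** 2 + (yy - 15) ** 2) / 4.0)
        values += 0.04 * np.exp(-((xx - 17) ** 2 + (yy - 15) ** 2) / 4.0)
        gset = detect_glomeruli([values])
        assert len(gset.rois) == 1

    def test_masks_disjoint(self, map_pair):
        dmaps, _ = rendered_views(map_pair, noise_sd=MAP_NOISE)
        gset = detect_glomeruli(dmaps, labels=PANEL)
        total = np.zeros((128, 128), dtype=int)
        for roi in gset.rois:
            total += roi.mask
        assert total.max() <= 1


class TestMatching:
    def test_identical_sets_identity_registration(self, map_pair):
        dmaps, _ = rendered_views(map_pair, noise_sd=MAP_NOISE)
        gset = detect_glomeruli(dmaps, labels=PANEL)
        pairs = match_ensembles(gset, gset,
                                Registration("horizontal", 0, 1.0))
        assert len(pairs) == len(gset.rois)
        assert pairs.distance_px.max() == 0.0
        assert pairs.tuning_correlation.min() == pytest.approx(1.0)

    def test_homologous_pairs_recovered(self, map_pair):
        """>= 95% of ground-truth homologous pairs matched at default noise,
        with near-identical tuning."""
        dorsal_spec, _ = map_pair
        dmaps, mmaps = rendered_views(map_pair, noise_sd=MAP_NOISE, seed0=7)
        reg = register_ap_offset(np.max(np.stack(dmaps), 0),
                                 np.max(np.stack(mmaps), 0))
        dset = detect_glomeruli(dmaps, labels=PANEL)
        mset = detect_glomeruli(mmaps, labels=PANEL, view="medial_flipped")
        pairs = match_ensembles(dset, mset, reg)
        assert len(pairs) >= 0.95 * len(dorsal_spec.glomeruli)
        assert pairs.distance_px.max() <= 2.0
        assert pairs.tuning_correlation.min() > 0.9

    def test_spurious_roi_stays_unmatched(self, map_pair):
        dmaps, mmaps = rendered_views(map_pair, noise_sd=MAP_NOISE, seed0=11)
        reg = register_ap_offset(np.max(np.stack(dmaps), 0),
                                 np.max(np.stack(mmaps), 0))
        dset = detect_glomeruli(dmaps, labels=PANEL)
        mset = detect_glomeruli(mmaps, labels=PANEL, view="medial_flipped")
        far_corner = np.zeros(mset.frame_shape, dtype=bool)
        far_corner[2, 2] = True
        mset.rois.append(Roi(999, (2.0, 2.0), far_corner,
                             {o: 0.05 for o in PANEL}))
        pairs = match_ensembles(dset, mset, reg)
        assert 999 not in set(pairs.medial_id)

    def test_empty_sets_empty_table(self):
        empty = GlomerulusSet([], frame_shape=(32, 32))
        pairs = match_ensembles(empty, empty, Registration("horizontal", 0, 1.0))
        assert len(pairs) == 0


class TestChemotopy:
    def test_gradient_panels_monotone_in_both_views(self, map_pair):
        dmaps, mmaps = rendered_views(map_pair, noise_sd=MAP_NOISE, seed0=23)
        for maps, view in ((dmaps, "dorsal"), (mmaps, "medial_flipped")):
            gset = detect_glomeruli(maps, labels=PANEL, view=view)
            _, flag = chemotopy_shift(gset, PANEL)
            assert flag

    def test_shuffled_tuning_rarely_monotone(self):
        """Permuting tuning across glomeruli destroys the gradient: the
        monotonicity flag holds in fewer than half of random shuffles."""
        dorsal_spec, _ = generate_map_pair(8, PANEL, seed=7, ap_offset_px=12)
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            perm = rng.permutation(len(dorsal_spec.glomeruli))
            glomeruli = tuple(
                Glomerulus(g.center_x_px, g.center_y_px, g.radius_px,
                           dorsal_spec.glomeruli[p].tuning)
                for g, p in zip(dorsal_spec.glomeruli, perm)
            )
            spec = MapSpec(glomeruli, frame_shape=dorsal_spec.frame_shape)
            maps = [render_activity_map(spec, o) for o in PANEL]
            gset = detect_glomeruli(maps, labels=PANEL)
            _, flag = chemotopy_shift(gset, PANEL)
            hits += flag
        assert hits / n_seeds < 0.5

    def test_short_panel_raises(self):
        gset = GlomerulusSet([], frame_shape=(8, 8))
        with pytest.raises(ValueError, match="at least 3"):
            chemotopy_shift(gset, ["3CHO", "4CHO"])

    def test_unresponsive_odorant_marked_absent(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[4, 4] = True
        roi = Roi(0, (4.0, 4.0), mask, {"3CHO": 0.05, "4CHO": 0.04, "5CHO": 0.0})
        table, _ = chemotopy_shift(GlomerulusSet([roi], frame_shape=(8, 8)),
                                   ["3CHO", "4CHO", "5CHO"])
        assert bool(table.loc[table.odorant == "5CHO", "absent"].iloc[0])


class TestConcentrationResponse:
    def _set(self, amps, shape=(16, 16)):
        rois = []
        for i, a in enumerate(amps):
            mask = np.zeros(shape, dtype=bool)
            mask[i, i] = True
            rois.append(Roi(i, (float(i), float(i)), mask, {"PB": a}))
        return GlomerulusSet(rois, frame_shape=shape)

    def test_saturating_amplitudes_consistent_counts(self):
        """With saturating tuning, the responding-glomerulus count is the
        same at 0.02%, 0.2% and 2% nominal concentration."""
        c50 = 0.005
        base = [0.05, 0.04, 0.03]
        sets = {
            c: self._set([a * c / (c + c50) for a in base])
            for c in (0.02, 0.2, 2.0)
        }
        table = concentration_response(sets, response_floor=0.01)
        assert table.n_responding.nunique() == 1
        assert table.n_responding.iloc[0] == 3

    def test_floor_zero_counts_all(self):
        sets = {0.2: self._set([0.05, 0.0, 0.01])}
        table = concentration_response(sets, response_floor=0.0)
        assert table.n_responding.iloc[0] == 3

    def test_all_below_floor_counts_zero(self):
        sets = {0.2: self._set([0.001, 0.002])}
        table = concentration_response(sets, response_floor=0.01)
        assert table.n_responding.iloc[0] == 0

    def test_mismatched_fov_raises(self):
        sets = {0.2: self._set([0.05]), 2.0: self._set([0.05], shape=(8, 8))}
        with pytest.raises(ValueError, match="fields of view"):
            concentration_response(sets, response_floor=0.01)
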