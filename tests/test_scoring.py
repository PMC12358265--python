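"""ROI-Based Glaucoma Score: identities, oracle agreement, monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glaucroi.scoring import LeakageError, gls, healthy_reference, model_scores
from glaucroi.texture import annulus_mask
from glaucroi.types import GLSResult, ROIMap, TextureEnfaceMap, ThicknessMap


def _map(values, mm=6.0):
    values = np.asarray(values, dtype=float)
    h, w = values.shape
    return TextureEnfaceMap(
        values=values, onh_center=((h - 1) / 2.0, (w - 1) / 2.0), mm_per_px=(mm / h, mm / w)
    )


def _roi(mask):
    return ROIMap(labels=np.asarray(mask, dtype=np.int8), energy=0.0, converged=True)


def brute_force_gls(roi_mask, enface_values, dom_mask, ref):
    """Independent re-statement of the score: 0.5*area fraction plus
    0.5*clamped relative intensity reduction, on the domain pixels."""
    sel = roi_mask & dom_mask
    if sel.sum() == 0:
        return 0.0
    frac = sel.sum() / dom_mask.sum()
    mean_roi = enface_values[sel].mean()
    term = min(max(1.0 - mean_roi / ref, 0.0), 1.0)
    return 0.5 * frac + 0.5 * term


class TestHealthyReference:
    def test_constant_maps_return_constant(self):
        maps = [_map(np.full((16, 16), 0.42)) for _ in range(3)]
        assert healthy_reference(maps) == pytest.approx(0.42)

    def test_mean_of_two_annulus_means(self):
        maps = [_map(np.full((16, 16), 0.4)), _map(np.full((16, 16), 0.6))]
        assert healthy_reference(maps) == pytest.approx(0.5)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            healthy_reference([])


class TestGLS:
    def test_empty_roi_scores_zero(self, rng):
        res = gls(_roi(np.zeros((16, 16))), _map(rng.random((16, 16))), 0.5)
        assert res.gls == 0.0
        assert res.roi_fraction == 0.0
        assert res.intensity_term == 0.0

    def test_full_domain_roi_at_reference_intensity_scores_half(self):
        enface = _map(np.full((16, 16), 0.5))
        res = gls(_roi(np.ones((16, 16))), enface, 0.5)
        assert res.gls == pytest.approx(0.5)

    def test_printed_formula_example(self):
        """quarter-domain ROI at 60 vs reference 80 -> 0.5*0.25 + 0.5*0.25."""
        enface = _map(np.full((16, 16), 60.0))
        dom = annulus_mask(enface)
        mask = np.zeros((16, 16), dtype=bool)
        idx = np.argwhere(dom)
        take = idx[: int(round(0.25 * dom.sum()))]
        mask[take[:, 0], take[:, 1]] = True
        res = gls(_roi(mask), enface, 80.0)
        assert res.roi_fraction == pytest.approx(mask.sum() / dom.sum())
        assert res.intensity_term == pytest.approx(0.25)
        assert res.gls == pytest.approx(0.5 * res.roi_fraction + 0.125)

    def test_brighter_than_reference_roi_clamped_to_zero_term(self, rng):
        enface = _map(np.full((16, 16), 0.9))
        mask = annulus_mask(enface)
        res = gls(_roi(mask), enface, 0.5)
        assert res.intensity_term == 0.0
        assert 0.0 <= res.gls <= 1.0

    def test_agrees_with_bruteforce_on_random_fixtures(self, rng):
        """Exact agreement with an independent implementation, 100 draws."""
        enface = _map(rng.random((20, 20)))
        dom = annulus_mask(enface)
        for _ in range(100):
            mask = rng.random((20, 20)) < rng.uniform(0.0, 0.5)
            ref = rng.uniform(0.2, 0.9)
            expected = brute_force_gls(mask, enface.values, dom, ref)
            assert gls(_roi(mask), enface, ref).gls == expected

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_adding_dim_pixels_never_decreases_score(self, seed):
        """Growing the ROI by pixels dimmer than the reference cannot lower
        the score (both terms are non-decreasing under such growth)."""
        r = np.random.default_rng(seed)
        vals = r.random((16, 16))
        enface = _map(vals)
        dom = annulus_mask(enface)
        ref = 0.95
        mask = (r.random((16, 16)) < 0.2) & dom & (vals < ref)
        extra = (r.random((16, 16)) < 0.2) & dom & (vals < ref) & ~mask
        # only grow with pixels at or below the current ROI mean to keep the
        # intensity term monotone as well
        if mask.any():
            extra &= vals <= vals[mask].min()
        before = gls(_roi(mask), enface, ref).gls
        after = gls(_roi(mask | extra), enface, ref).gls
        assert after >= before - 1e-12

    def test_bounds_always_hold(self, rng):
        enface = _map(rng.random((16, 16)) * 2)
        for _ in range(50):
            mask = rng.random((16, 16)) < 0.3
            res = gls(_roi(mask), enface, rng.uniform(0.1, 1.5))
            assert 0.0 <= res.gls <= 1.0

    def test_bad_reference_rejected(self, rng):
        with pytest.raises(ValueError):
            gls(_roi(np.ones((8, 8))), _map(rng.random((8, 8))), 0.0)


class TestModelScores:
    def _geo_maps(self, rng):
        enface = _map(rng.random((32, 32)))
        thickness = ThicknessMap(
            values=rng.random((32, 32)) * 100,
            onh_center=enface.onh_center,
            mm_per_px=enface.mm_per_px,
        )
        return enface, thickness

    def test_all_four_modes_finite(self, small_cohort, trained_models):
        from glaucroi.mrf import MRFConfig

        c = small_cohort
        h_model, g_model = trained_models
        r = c.records[0]
        fold_models = {
            "h_model": h_model,
            "g_model": g_model,
            "mrf_cfg": MRFConfig(),
            "mean_healthy_ref": 0.5,
            "train_patients": set(),
        }
        for mode in ("dual_ae", "single_ae", "rnfl_global", "texture_global"):
            s = model_scores(
                c.enface[r.eye_id], c.thickness[r.eye_id], mode, fold_models=fold_models, patient_id=r.patient_id
            )
            assert np.isfinite(s)

    def test_leakage_is_hard_error(self, small_cohort, trained_models):
        from glaucroi.mrf import MRFConfig

        c = small_cohort
        h_model, g_model = trained_models
        r = c.records[0]
        fold_models = {
            "h_model": h_model,
            "g_model": g_model,
            "mrf_cfg": MRFConfig(),
            "mean_healthy_ref": 0.5,
            "train_patients": {r.patient_id},
        }
        with pytest.raises(LeakageError):
            model_scores(c.enface[r.eye_id], c.thickness[r.eye_id], "dual_ae", fold_models=fold_models, patient_id=r.patient_id)

    def test_deep_defect_scores_above_defect_free(self, small_cohort, trained_models):
        """Paired phantom check: a glaucoma eye with a real wedge gets a
        higher dual-AE score than a defect-free healthy eye."""
        from glaucroi.mrf import MRFConfig
        from glaucroi.scoring import healthy_reference

        c = small_cohort
        h_model, g_model = trained_models
        ref = healthy_reference([c.enface[r.eye_id] for r in c.records if r.diagnosis == "healthy"])
        fold_models = {
            "h_model": h_model,
            "g_model": g_model,
            "mrf_cfg": MRFConfig(),
            "mean_healthy_ref": ref,
            "train_patients": set(),
        }
        glaucoma = [r for r in c.records if r.diagnosis == "glaucoma" and c.truth[r.eye_id].defect_mask.mean() > 0.05]
        healthy = [r for r in c.records if r.diagnosis == "healthy"]
        s_g = np.mean([
            model_scores(c.enface[r.eye_id], c.thickness[r.eye_id], "dual_ae", fold_models=fold_models)
            for r in glaucoma
        ])
        s_h = np.mean([
            model_scores(c.enface[r.eye_id], c.thickness[r.eye_id], "dual_ae", fold_models=fold_models)
            for r in healthy
        ])
        assert s_g > s_h

    def test_rnfl_mode_ranks_thin_above_thick(self, rng):
        enface, _ = self._geo_maps(rng)
        geo = dict(onh_center=enface.onh_center, mm_per_px=enface.mm_per_px)
        thin = ThicknessMap(values=np.full((32, 32), 60.0), **geo)
        thick = ThicknessMap(values=np.full((32, 32), 110.0), **geo)
        assert model_scores(enface, thin, "rnfl_global") > model_scores(enface, thick, "rnfl_global")

    def test_unknown_mode_rejected(self, rng):
        enface, thickness = self._geo_maps(rng)
        with pytest.raises(ValueError):
            model_scores(enface, thickness, "banana")
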