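"""Phantom generator: determinism, glyph discriminability, gold-annotation
consistency, and case persistence."""

import json

import numpy as np
import pytest

from dentalchart import matching, phantom
from dentalchart.phantom import (PhantomConfig, generate_phantom_case,
                                 generate_tooth_glyph, read_case, write_case)
from dentalchart.repository import VALID_FDI


class TestGlyphs:
    def test_same_inputs_identical_patch(self):
        a = generate_tooth_glyph(11, 1.0, 42)
        b = generate_tooth_glyph(11, 1.0, 42)
        assert np.array_equal(a.patch, b.patch)
        assert np.array_equal(a.mask, b.mask)

    def test_left_right_quadrants_are_mirror_images(self):
        right = generate_tooth_glyph(11, 1.0, 3)
        left = generate_tooth_glyph(21, 1.0, 3)
        assert np.array_equal(right.patch, left.patch[:, ::-1])
        lower_r = generate_tooth_glyph(44, 1.0, 3)
        lower_l = generate_tooth_glyph(34, 1.0, 3)
        assert np.array_equal(lower_r.patch, lower_l.patch[:, ::-1])

    def test_invalid_fdi_rejected(self):
        with pytest.raises(ValueError, match="19"):
            generate_tooth_glyph(19, 1.0, 0)
        with pytest.raises(ValueError, match="scale"):
            generate_tooth_glyph(11, 0.0, 0)

    def test_match_score_diagonal_dominates_all_pairs(self):
        """Every glyph scores itself strictly above every other FDI class,
        so normalized cross-correlation can discriminate all 32 teeth."""
        fdis = sorted(VALID_FDI)
        glyphs = {f: generate_tooth_glyph(f, 1.0, 0) for f in fdis}
        scores = np.array([[matching.match_score(glyphs[a].patch,
                                                 glyphs[b].patch).score
                            for b in fdis] for a in fdis])
        for i in range(len(fdis)):
            off_diag = np.delete(scores[i], i)
            assert scores[i, i] > off_diag.max(), fdis[i]

    def test_scaled_glyph_dimensions(self):
        g1 = generate_tooth_glyph(16, 1.0, 0)
        g2 = generate_tooth_glyph(16, 0.5, 0)
        assert g2.patch.shape[0] == round(g1.patch.shape[0] * 0.5)


class TestCaseGeneration:
    def test_complete_case_composition(self, no_jitter_case):
        case = no_jitter_case
        assert len(case.periapicals) == 14
        assert sum(p.position == "maxilla" for p in case.periapicals) == 7
        assert sum(p.position == "mandible" for p in case.periapicals) == 7
        assert len(case.bitewings) == 4
        assert len(case.panoramic.teeth) == 32
        assert sum(st.present for st in case.gold_chart.values()) == 32

    def test_missing_tooth_absent_everywhere(self):
        case = generate_phantom_case(PhantomConfig(seed=3, missing_fdi={36}))
        assert all(t.fdi != 36 for t in case.panoramic.teeth)
        for pi in case.intraoral:
            assert all(t.fdi != 36 for t in pi.teeth)
        assert not case.gold_chart[36].present
        assert case.gold_chart[35].present

    def test_intraoral_teeth_also_in_panoramic(self, no_jitter_case):
        pan_fdis = {t.fdi for t in no_jitter_case.panoramic.teeth}
        for pi in no_jitter_case.intraoral:
            assert {t.fdi for t in pi.teeth} <= pan_fdis

    def test_gold_boxes_valid_and_consistent(self, no_jitter_case):
        """Boxes lie in bounds; the panoramic box of each tooth contains all
        of its glyph pixels, intraoral boxes contain the root-side pixels."""
        for pi in [no_jitter_case.panoramic, *no_jitter_case.intraoral]:
            h, w = pi.image.shape
            for t in pi.teeth:
                x0, y0, x1, y1 = t.box
                assert 0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h
                assert t.fdi in VALID_FDI
        pan = no_jitter_case.panoramic
        # panoramic glyphs don't overlap, so box interiors partition the mask
        inside = sum(pan.tooth_mask[y0:y1, x0:x1].sum()
                     for x0, y0, x1, y1 in (t.box for t in pan.teeth))
        assert inside >= 0.90 * pan.tooth_mask.sum()

    def test_bitewing_has_two_cej_rows(self, no_jitter_case):
        for bw in no_jitter_case.bitewings:
            assert len(bw.cej_rows) == 2
        for pa in no_jitter_case.periapicals:
            assert len(pa.cej_rows) == 1

    def test_seeded_determinism(self):
        c1 = generate_phantom_case(PhantomConfig(seed=5, scale_jitter=0.1,
                                                 position_jitter=2,
                                                 noise_sigma=3.0))
        c2 = generate_phantom_case(PhantomConfig(seed=5, scale_jitter=0.1,
                                                 position_jitter=2,
                                                 noise_sigma=3.0))
        assert np.array_equal(c1.panoramic.image, c2.panoramic.image)
        for a, b in zip(c1.intraoral, c2.intraoral):
            assert a.image_id == b.image_id
            assert np.array_equal(a.image, b.image)
            assert [t.box for t in a.teeth] == [t.box for t in b.teeth]

    def test_empty_quadrants_give_no_intraoral_images(self):
        case = generate_phantom_case(PhantomConfig(seed=1,
                                                   quadrants_present=frozenset()))
        assert case.intraoral == []
        assert len(case.panoramic.teeth) == 0
        assert not any(st.present for st in case.gold_chart.values())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PhantomConfig(missing_fdi={19})
        with pytest.raises(ValueError):
            PhantomConfig(scale_jitter=0.9)
        with pytest.raises(ValueError):
            PhantomConfig(bone_level_fraction=1.5)


class TestPersistence:
    def test_round_trip_preserves_gold_annotations(self, tmp_path, no_jitter_case):
        write_case(no_jitter_case, tmp_path)
        loaded = read_case(tmp_path)
        assert loaded.config == no_jitter_case.config
        assert np.array_equal(loaded.panoramic.image, no_jitter_case.panoramic.image)
        assert np.array_equal(loaded.panoramic.tooth_mask,
                              no_jitter_case.panoramic.tooth_mask)
        for a, b in zip(loaded.intraoral, no_jitter_case.intraoral):
            assert a.image_id == b.image_id and a.position == b.position
            assert np.array_equal(a.image, b.image)
            assert np.array_equal(a.bone_mask, b.bone_mask)
            assert np.array_equal(a.cej_mask, b.cej_mask)
            assert [(t.fdi, t.box, t.bone_level_fraction) for t in a.teeth] == \
                   [(t.fdi, t.box, t.bone_level_fraction) for t in b.teeth]
        assert loaded.gold_chart == no_jitter_case.gold_chart

    def test_write_twice_identical_manifest_and_pngs(self, tmp_path):
        case = generate_phantom_case(PhantomConfig(seed=9))
        p1 = write_case(case, tmp_path / "a")
        p2 = write_case(case, tmp_path / "b")
        assert p1.read_bytes() == p2.read_bytes()
        img = case.periapicals[0].image_id + ".png"
        assert (tmp_path / "a" / img).read_bytes() == \
               (tmp_path / "b" / img).read_bytes()

    def test_regenerated_case_writes_identical_pngs(self, tmp_path):
        cfg = PhantomConfig(seed=13, noise_sigma=2.0)
        write_case(generate_phantom_case(cfg), tmp_path / "a")
        write_case(generate_phantom_case(cfg), tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name

    def test_empty_case_valid_manifest(self, tmp_path):
        case = generate_phantom_case(PhantomConfig(seed=1,
                                                   quadrants_present=frozenset()))
        path = write_case(case, tmp_path)
        manifest = json.loads(path.read_text())
        assert manifest["periapicals"] == [] and manifest["bitewings"] == []
        assert read_case(tmp_path).intraoral == []
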