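"""Texture-matrix features against exhaustive brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

import radiomaps as rm
from radiomaps.features import (
    ExtractionSettings,
    discretize,
    extract_all,
    gldm_features,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

import oracles

GENERIC_TO_GLRLM = {
    "SmallEmphasis": "ShortRunEmphasis",
    "LargeEmphasis": "LongRunEmphasis",
    "GLN": "GrayLevelNonUniformity",
    "GLNN": "GrayLevelNonUniformityNormalized",
    "SizeNonUniformity": "RunLengthNonUniformity",
    "SizeNonUniformityNormalized": "RunLengthNonUniformityNormalized",
    "Percentage": "RunPercentage",
    "GLVariance": "GrayLevelVariance",
    "SizeVariance": "RunVariance",
    "Entropy": "RunEntropy",
    "LowGL": "LowGrayLevelRunEmphasis",
    "HighGL": "HighGrayLevelRunEmphasis",
    "SmallLow": "ShortRunLowGrayLevelEmphasis",
    "SmallHigh": "ShortRunHighGrayLevelEmphasis",
    "LargeLow": "LongRunLowGrayLevelEmphasis",
    "LargeHigh": "LongRunHighGrayLevelEmphasis",
}
GENERIC_TO_GLSZM = {
    "SmallEmphasis": "SmallAreaEmphasis",
    "LargeEmphasis": "LargeAreaEmphasis",
    "GLN": "GrayLevelNonUniformity",
    "GLNN": "GrayLevelNonUniformityNormalized",
    "SizeNonUniformity": "SizeZoneNonUniformity",
    "SizeNonUniformityNormalized": "SizeZoneNonUniformityNormalized",
    "Percentage": "ZonePercentage",
    "GLVariance": "GrayLevelVariance",
    "SizeVariance": "ZoneVariance",
    "Entropy": "ZoneEntropy",
    "LowGL": "LowGrayLevelZoneEmphasis",
    "HighGL": "HighGrayLevelZoneEmphasis",
    "SmallLow": "SmallAreaLowGrayLevelEmphasis",
    "SmallHigh": "SmallAreaHighGrayLevelEmphasis",
    "LargeLow": "LargeAreaLowGrayLevelEmphasis",
    "LargeHigh": "LargeAreaHighGrayLevelEmphasis",
}
GENERIC_TO_GLDM = {
    "SmallEmphasis": "SmallDependenceEmphasis",
    "LargeEmphasis": "LargeDependenceEmphasis",
    "GLN": "GrayLevelNonUniformity",
    "GLNN": "GrayLevelNonUniformityNormalized",
    "SizeNonUniformity": "DependenceNonUniformity",
    "SizeNonUniformityNormalized": "DependenceNonUniformityNormalized",
    "GLVariance": "GrayLevelVariance",
    "SizeVariance": "DependenceVariance",
    "Entropy": "DependenceEntropy",
    "LowGL": "LowGrayLevelEmphasis",
    "HighGL": "HighGrayLevelEmphasis",
    "SmallLow": "SmallDependenceLowGrayLevelEmphasis",
    "SmallHigh": "SmallDependenceHighGrayLevelEmphasis",
    "LargeLow": "LargeDependenceLowGrayLevelEmphasis",
    "LargeHigh": "LargeDependenceHighGrayLevelEmphasis",
}


def make_region(values, mask, spacing=(1.0, 1.0)):
    img = rm.ImageSlice(np.asarray(values, dtype=float), spacing)
    m = rm.SegmentationMask.like(img, np.asarray(mask, dtype=bool))
    return img, m


def _compare(expected: dict, actual: dict, prefix: str, rename=None, rtol=1e-8):
    for key, exp in expected.items():
        name = f"{prefix}_{(rename or {}).get(key, key)}"
        act = actual[name]
        if exp is None:
            assert math.isnan(act), f"{name}: expected undefined, got {act}"
        else:
            assert act == pytest.approx(exp, rel=rtol, abs=1e-12), name


class TestOracleEquivalence:
    """Every matrix feature equals its exhaustive enumeration on 100 seeded
    random 8x8 masked regions with Ng <= 6."""

    def test_all_matrix_classes(self, random_regions):
        settings = ExtractionSettings()
        for values, mask in random_regions:
            img, m = make_region(values, mask)
            reg = discretize(img, m, settings)
            lv, ng = oracles.bf_discretize(values, mask, settings.bin_width)
            np.testing.assert_array_equal(reg.levels, lv)
            assert reg.ng == ng
            npx = int(mask.sum())

            _compare(oracles.bf_glcm(lv, ng), glcm_features(reg, settings), "glcm")
            _compare(
                oracles.bf_glrlm(lv, ng, npx),
                glrlm_features(reg, settings),
                "glrlm",
                GENERIC_TO_GLRLM,
            )
            _compare(
                oracles.bf_glszm(lv, ng, npx),
                glszm_features(reg, settings),
                "glszm",
                GENERIC_TO_GLSZM,
            )
            _compare(
                oracles.bf_gldm(lv, ng, npx),
                gldm_features(reg, settings),
                "gldm",
                GENERIC_TO_GLDM,
            )
            ntg = oracles.bf_ngtdm(lv, ng)
            if ntg is not None:
                _compare(ntg, ngtdm_features(reg, settings), "ngtdm")


class TestHandExamples:
    def test_glcm_two_column_grid(self):
        # [[1,2],[1,2]] at angle 0: p(1,2)=p(2,1)=0.5 after symmetrization
        img, m = make_region([[0.0, 25.0], [0.0, 25.0]], np.ones((2, 2)))
        s = ExtractionSettings(angles_2d=((0, 1),))
        g = glcm_features(discretize(img, m, s), s)
        assert g["glcm_JointEntropy"] == pytest.approx(1.0)  # 1 bit
        assert g["glcm_Contrast"] == pytest.approx(1.0)
        assert g["glcm_MaximumProbability"] == pytest.approx(0.5)

    def test_glrlm_single_row_runs(self):
        # [1,1,2,2,2]: runs (1,len2),(2,len3); SRE=(1/4+1/9)/2; RP=2/5
        img, m = make_region([[0.0, 0.0, 25.0, 25.0, 25.0]], np.ones((1, 5)))
        s = ExtractionSettings(angles_2d=((0, 1),))
        rl = glrlm_features(discretize(img, m, s), s)
        assert rl["glrlm_ShortRunEmphasis"] == pytest.approx((0.25 + 1 / 9) / 2)
        assert rl["glrlm_RunPercentage"] == pytest.approx(0.4)

    def test_glrlm_constant_row_long_run(self):
        img, m = make_region([[7.0] * 6], np.ones((1, 6)))
        s = ExtractionSettings(angles_2d=((0, 1),))
        rl = glrlm_features(discretize(img, m, s), s)
        assert rl["glrlm_LongRunEmphasis"] == pytest.approx(36.0)

    def test_glszm_checkerboard_connectivity(self):
        # 8-connectivity joins the diagonal cells: two zones of size 2.
        img, m = make_region([[0.0, 25.0], [25.0, 0.0]], np.ones((2, 2)))
        sz8 = glszm_features(discretize(img, m, None), ExtractionSettings())
        assert sz8["glszm_SmallAreaEmphasis"] == pytest.approx(0.25)
        assert sz8["glszm_LargeAreaEmphasis"] == pytest.approx(4.0)
        # 4-connectivity splits them into four singleton zones.
        s4 = ExtractionSettings(connectivity=4)
        sz4 = glszm_features(discretize(img, m, s4), s4)
        assert sz4["glszm_SmallAreaEmphasis"] == pytest.approx(1.0)

    def test_glszm_constant_region_single_zone(self):
        img, m = make_region(np.full((3, 4), 9.0), np.ones((3, 4)))
        sz = glszm_features(discretize(img, m, None), ExtractionSettings())
        assert sz["glszm_ZonePercentage"] == pytest.approx(1.0 / 12.0)
        assert sz["glszm_LargeAreaEmphasis"] == pytest.approx(144.0)

    def test_gldm_neighbor_counts_on_constant_grid(self):
        # constant 3x3: dependence 8 center, 5 edges, 3 corners -> sizes j=dep+1
        img, m = make_region(np.full((3, 3), 1.0), np.ones((3, 3)))
        reg = discretize(img, m, None)
        gd = gldm_features(reg, ExtractionSettings())
        # LargeDependenceEmphasis = mean of (dep+1)^2 = (4*16 + 4*36 + 81)/9
        assert gd["gldm_LargeDependenceEmphasis"] == pytest.approx(
            (4 * 16 + 4 * 36 + 81) / 9
        )

    def test_ngtdm_constant_and_degenerate(self):
        img, m = make_region(np.full((3, 3), 5.0), np.ones((3, 3)))
        nt = ngtdm_features(discretize(img, m, None), ExtractionSettings())
        assert nt["ngtdm_Coarseness"] == pytest.approx(1e6)
        assert nt["ngtdm_Contrast"] == 0.0

        mask1 = np.zeros((3, 3), bool)
        mask1[1, 1] = True
        img1, m1 = make_region(np.full((3, 3), 5.0), mask1)
        fv = extract_all(img1, m1)
        for name in ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength"):
            assert not fv.valid[f"ngtdm_{name}"]

    def test_glcm_no_pairs_is_undefined(self):
        mask = np.zeros((3, 3), bool)
        mask[0, 0] = mask[2, 2] = True  # no pair at distance 1
        img, m = make_region(np.arange(9.0).reshape(3, 3) * 25, mask)
        fv = extract_all(img, m)
        assert not fv.valid["glcm_Contrast"]


class TestRangeInvariants:
    def test_bounded_and_signed_features(self, random_regions):
        for values, mask in random_regions[:25]:
            img, m = make_region(values, mask)
            fv = extract_all(img, m)
            assert 0 < fv["firstorder_Uniformity"] <= 1.0
            assert fv["firstorder_Entropy"] >= 0.0
            if fv.valid["glcm_Contrast"]:
                assert fv["glcm_Contrast"] >= 0.0
            assert 0 < fv["glrlm_RunPercentage"] <= 1.0
            assert 0 < fv["glszm_ZonePercentage"] <= 1.0
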