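"""Evaluation metrics against brute-force set-arithmetic oracles."""

import math

import numpy as np
import pytest

from maffresunet.metrics import (
    BinaryMaskPair, binarize, boundary_pixels, dsc, evaluate_pair,
    evaluate_set, hausdorff, iou, ppv, sensitivity,
)


# ---------------------------------------------------------------------------
# independent oracles: explicit pixel-set arithmetic and double loops
# ---------------------------------------------------------------------------

def pixel_set(mask):
    return {tuple(ix) for ix in np.argwhere(np.asarray(mask, dtype=bool))}


def oracle_counts(p_mask, g_mask):
    p, g = pixel_set(p_mask), pixel_set(g_mask)
    return len(p & g), len(p | g), len(p), len(g)


def oracle_boundary(mask):
    """Pixels of the mask with at least one 4-neighbour outside it."""
    pixels = pixel_set(mask)
    h, w = np.asarray(mask).shape
    out = set()
    for (r, c) in pixels:
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if not (0 <= rr < h and 0 <= cc < w) or (rr, cc) not in pixels:
                out.add((r, c))
                break
    return out


def oracle_hausdorff(p_mask, g_mask, spacing=(1.0, 1.0)):
    """Exhaustive O(|P|·|G|) double loop over boundary pixels."""
    bp = oracle_boundary(p_mask)
    bg = oracle_boundary(g_mask)
    sy, sx = spacing

    def directed(a_set, b_set):
        worst = 0.0
        for a in a_set:
            best = math.inf
            for b in b_set:
                d = math.hypot((a[0] - b[0]) * sy, (a[1] - b[1]) * sx)
                best = min(best, d)
            worst = max(worst, best)
        return worst

    return max(directed(bp, bg), directed(bg, bp))


def random_mask(rng, shape=(16, 16), p=0.3):
    return rng.random(shape) < p


# ---------------------------------------------------------------------------
# hand-derived examples
# ---------------------------------------------------------------------------

def two_pixel_pair():
    p = np.zeros((2, 2), dtype=bool)
    g = np.zeros((2, 2), dtype=bool)
    p[0, 0] = p[0, 1] = True
    g[0, 1] = g[1, 1] = True
    return BinaryMaskPair(p, g)


class TestExamples:
    def test_overlap_example_iou_third(self):
        assert iou(two_pixel_pair()) == pytest.approx(1 / 3)

    def test_overlap_example_sen_ppv_dsc_half(self):
        pair = two_pixel_pair()
        assert sensitivity(pair) == pytest.approx(0.5)
        assert ppv(pair) == pytest.approx(0.5)
        assert dsc(pair) == pytest.approx(0.5)

    def test_identical_masks_are_perfect(self, rng):
        m = random_mask(rng)
        m[0, 0] = True
        pair = BinaryMaskPair(m, m)
        assert iou(pair) == sensitivity(pair) == ppv(pair) == dsc(pair) == 1.0
        assert hausdorff(pair) == 0.0

    def test_disjoint_masks_are_zero(self):
        p = np.zeros((4, 4), dtype=bool)
        g = np.zeros((4, 4), dtype=bool)
        p[0, 0] = True
        g[3, 3] = True
        pair = BinaryMaskPair(p, g)
        assert iou(pair) == dsc(pair) == 0.0
        assert sensitivity(pair) == 0.0 and ppv(pair) == 0.0

    def test_hausdorff_3_4_5_triangle(self):
        p = np.zeros((8, 8), dtype=bool)
        g = np.zeros((8, 8), dtype=bool)
        p[0, 0] = True
        g[3, 4] = True
        assert hausdorff(BinaryMaskPair(p, g)) == pytest.approx(5.0)

    def test_hausdorff_respects_pixel_spacing(self):
        p = np.zeros((4, 4), dtype=bool)
        g = np.zeros((4, 4), dtype=bool)
        p[0, 0] = True
        g[1, 0] = True
        pair = BinaryMaskPair(p, g, pixel_spacing=(2.5, 1.0))
        assert hausdorff(pair) == pytest.approx(2.5)

    def test_both_empty_convention(self):
        z = np.zeros((3, 3), dtype=bool)
        pair = BinaryMaskPair(z, z)
        assert iou(pair) == 1.0 and dsc(pair) == 1.0

    def test_undefined_cases_raise(self):
        z = np.zeros((3, 3), dtype=bool)
        m = ~z
        with pytest.raises(ValueError):
            sensitivity(BinaryMaskPair(m, z))
        with pytest.raises(ValueError):
            ppv(BinaryMaskPair(z, m))
        with pytest.raises(ValueError):
            hausdorff(BinaryMaskPair(z, m))


class TestBinarize:
    def test_boundary_value_included(self):
        assert binarize(np.array([0.5, 0.4999]), 0.5).tolist() == [True, False]

    def test_threshold_bounds_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.array([0.4]), 0.0)
        with pytest.raises(ValueError):
            binarize(np.array([0.4]), 1.0)


class TestAgainstOracles:
    """All five metrics agree with brute-force oracles on random masks."""

    def test_count_metrics_on_200_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            p = random_mask(rng)
            g = random_mask(rng)
            inter, union, n_p, n_g = oracle_counts(p, g)
            pair = BinaryMaskPair(p, g)
            assert iou(pair) == pytest.approx(
                inter / union if union else 1.0, abs=0)
            assert dsc(pair) == pytest.approx(
                2 * inter / (n_p + n_g) if n_p + n_g else 1.0, abs=0)
            if n_g:
                assert sensitivity(pair) == pytest.approx(inter / n_g, abs=0)
            if n_p:
                assert ppv(pair) == pytest.approx(inter / n_p, abs=0)

    def test_hausdorff_on_random_pairs_matches_double_loop(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 50:
            p = random_mask(rng, p=0.2)
            g = random_mask(rng, p=0.2)
            if not p.any() or not g.any():
                continue
            got = hausdorff(BinaryMaskPair(p, g))
            assert got == pytest.approx(oracle_hausdorff(p, g), abs=1e-12)
            checked += 1

    def test_boundary_extraction_matches_neighbour_definition(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            m = random_mask(rng, p=0.4)
            assert pixel_set_from_coords(boundary_pixels(m)) == \
                oracle_boundary(m)


def pixel_set_from_coords(coords):
    return {tuple(c) for c in coords}


class TestIdentities:
    def test_dsc_equals_2iou_over_1_plus_iou(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            pair = BinaryMaskPair(random_mask(rng), random_mask(rng))
            i = iou(pair)
            assert dsc(pair) == pytest.approx(2 * i / (1 + i), abs=1e-9)

    def test_dsc_is_harmonic_mean_of_sen_and_ppv(self):
        rng = np.random.default_rng(12)
        checked = 0
        while checked < 200:
            pair = BinaryMaskPair(random_mask(rng), random_mask(rng))
            if not pair.P.any() or not pair.G.any():
                continue
            s, v = sensitivity(pair), ppv(pair)
            if s + v == 0:
                assert dsc(pair) == 0.0
            else:
                assert dsc(pair) == pytest.approx(2 * s * v / (s + v),
                                                  abs=1e-9)
            checked += 1

    def test_hausdorff_symmetry_and_identity(self):
        rng = np.random.default_rng(13)
        checked = 0
        while checked < 50:
            p, g = random_mask(rng), random_mask(rng)
            if not p.any() or not g.any():
                continue
            assert hausdorff(BinaryMaskPair(p, g)) == pytest.approx(
                hausdorff(BinaryMaskPair(g, p)), abs=1e-12)
            checked += 1
        m = random_mask(rng, p=0.5)
        m[0, 0] = True
        assert hausdorff(BinaryMaskPair(m, m)) == 0.0

    def test_adding_a_correct_pixel_never_decreases_sensitivity(self):
        rng = np.random.default_rng(14)
        for _ in range(50):
            g = random_mask(rng)
            if not g.any():
                continue
            p = random_mask(rng)
            missing = np.argwhere(g & ~p)
            if missing.size == 0:
                continue
            before = sensitivity(BinaryMaskPair(p, g))
            p2 = p.copy()
            p2[tuple(missing[0])] = True
            assert sensitivity(BinaryMaskPair(p2, g)) >= before


class TestEvaluateSet:
    def _nested_target(self, rng):
        t = np.zeros((3, 16, 16))
        t[0, 4:12, 4:12] = 1   # WT
        t[1, 6:10, 6:10] = 1   # TC
        t[2, 7:9, 7:9] = 1     # ET
        return t

    def test_perfect_predictions_give_ones_and_zero_hd(self, rng):
        targets = [self._nested_target(rng) for _ in range(3)]
        report = evaluate_set([t.astype(float) for t in targets], targets)
        for region in ("WT", "TC", "ET"):
            for metric in ("iou", "sen", "ppv", "dsc"):
                assert report.mean[region][metric] == 1.0
                assert report.sd[region][metric] == 0.0
            assert report.mean[region]["hd"] == 0.0
        assert report.n_slices_evaluated == 3

    def test_single_slice_sd_is_zero(self, rng):
        t = self._nested_target(rng)
        report = evaluate_set([t.astype(float)], [t])
        assert all(v == 0.0 for m in report.sd.values() for v in m.values())

    def test_two_slice_mean_matches_hand_average(self):
        t = np.zeros((3, 8, 8))
        t[:, 2:6, 2:6] = 1
        # slice A: perfect; slice B: half-covered prediction
        pred_a = t.astype(float)
        pred_b = t.astype(float).copy()
        pred_b[:, :, 4:] = 0.0
        per_slice_dsc = []
        for pred in (pred_a, pred_b):
            pair = BinaryMaskPair(pred[0] >= 0.5, t[0].astype(bool))
            per_slice_dsc.append(dsc(pair))
        report = evaluate_set([pred_a, pred_b], [t, t])
        assert report.mean["WT"]["dsc"] == pytest.approx(
            np.mean(per_slice_dsc))
        assert report.sd["WT"]["dsc"] == pytest.approx(
            np.std(per_slice_dsc))

    def test_skip_counts_surface_in_report(self):
        t_empty_et = np.zeros((3, 8, 8))
        t_empty_et[0, 2:6, 2:6] = 1
        t_empty_et[1, 3:5, 3:5] = 1  # ET channel empty
        pred = t_empty_et.astype(float)
        report = evaluate_set([pred], [t_empty_et])
        assert report.n_skipped["ET"]["sen"] == 1
        assert report.n_skipped["ET"]["hd"] == 1
        # both-empty ET still counts for IoU/DSC with value 1
        assert report.mean["ET"]["iou"] == 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate_set([], [])

    def test_csv_and_json_serialization(self, tmp_path, rng):
        t = self._nested_target(rng)
        report = evaluate_set([t.astype(float)], [t])
        report.to_csv(tmp_path / "report.csv")
        report.to_json(tmp_path / "report.json")
        assert (tmp_path / "report.csv").read_text().startswith("subregion")
        assert "n_slices_evaluated" in (tmp_path / "report.json").read_text()
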