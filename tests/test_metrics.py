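"""Metric correctness against exhaustive brute-force oracles."""

import itertools

import numpy as np
import pytest

from neolesion.errors import GridMismatchError
from neolesion.metrics import (CONNECTIVITY_26, EvalReport, aggregate_reports,
                               confusion_counts, dsc, evaluate_case,
                               label_lesions, lesion_detection,
                               mean_surface_distance, no_lesion_metrics,
                               overlap_rates, surface_voxels)

from conftest import make_mask


def _random_mask(rng, shape=(6, 6, 6), density=0.2, spacing=(1.0, 1.0, 1.0)):
    return make_mask((rng.random(shape) < density).astype(np.uint8),
                     spacing=spacing)


# ------------------------------------------------------------------- oracles

def _oracle_confusion(a, g):
    tp = fp = fn = tn = 0
    for av, gv in zip(a.data.ravel(), g.data.ravel()):
        if av and gv:
            tp += 1
        elif av:
            fp += 1
        elif gv:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def _oracle_components(mask):
    """Flood-fill component count under 26-connectivity."""
    data = mask.data.astype(bool)
    seen = np.zeros_like(data)
    count = 0
    offsets = [d for d in itertools.product((-1, 0, 1), repeat=3)
               if d != (0, 0, 0)]
    labels = np.zeros(data.shape, dtype=int)
    for start in np.argwhere(data):
        start = tuple(start)
        if seen[start]:
            continue
        count += 1
        stack = [start]
        seen[start] = True
        while stack:
            v = stack.pop()
            labels[v] = count
            for d in offsets:
                nb = tuple(np.add(v, d))
                if all(0 <= nb[i] < data.shape[i] for i in range(3)):
                    if data[nb] and not seen[nb]:
                        seen[nb] = True
                        stack.append(nb)
    return labels, count


def _oracle_msd(a, g):
    """All-pairs exhaustive symmetric mean surface distance."""
    spacing = np.asarray(a.spacing)
    pa = np.argwhere(surface_voxels(a)) * spacing
    pg = np.argwhere(surface_voxels(g)) * spacing
    d_ag = [min(np.linalg.norm(p - q) for q in pg) for p in pa]
    d_ga = [min(np.linalg.norm(p - q) for q in pa) for p in pg]
    return (sum(d_ag) + sum(d_ga)) / (len(pa) + len(pg))


def _oracle_detection(a, g):
    la, na = _oracle_components(a)
    lg, mg = _oracle_components(g)
    if mg == 0:
        return None, None, None
    hit_g = {lg[tuple(v)] for v in np.argwhere(g.data.astype(bool))
             if a.data[tuple(v)]}
    s = len(hit_g) / mg
    if na == 0:
        p = 0.0
    else:
        hit_a = {la[tuple(v)] for v in np.argwhere(a.data.astype(bool))
                 if g.data[tuple(v)]}
        p = len(hit_a) / na
    f1 = 2 * s * p / (s + p) if s + p else 0.0
    return s, p, f1


# ----------------------------------------------------------------- randomized

def test_confusion_counts_match_voxel_loop_oracle(rng):
    for _ in range(50):
        a, g = _random_mask(rng), _random_mask(rng)
        got = confusion_counts(a, g)
        assert got == _oracle_confusion(a, g)
        assert sum(got) == a.data.size


def test_dsc_matches_oracle_and_conventions(rng):
    for _ in range(50):
        a, g = _random_mask(rng), _random_mask(rng)
        tp, fp, fn, _ = _oracle_confusion(a, g)
        if 2 * tp + fp + fn == 0:
            assert dsc(a, g) is None
        else:
            assert dsc(a, g) == pytest.approx(2 * tp / (2 * tp + fp + fn))
    m = _random_mask(rng, density=0.3)
    assert dsc(m, m) == 1.0
    empty = make_mask(np.zeros((6, 6, 6), dtype=np.uint8))
    assert dsc(empty, empty) is None


def test_component_count_matches_flood_fill_oracle(rng):
    for _ in range(40):
        mask = _random_mask(rng, density=0.15)
        _, count = label_lesions(mask)
        _, expected = _oracle_components(mask)
        assert count == expected


def test_corner_touching_voxels_are_one_component_under_26():
    data = np.zeros((4, 4, 4), dtype=np.uint8)
    data[0, 0, 0] = 1
    data[1, 1, 1] = 1
    _, count = label_lesions(make_mask(data))
    assert count == 1
    separated = np.zeros((5, 5, 5), dtype=np.uint8)
    separated[0, 0, 0] = 1
    separated[4, 4, 4] = 1
    _, count = label_lesions(make_mask(separated))
    assert count == 2


def test_lesion_detection_matches_component_oracle(rng):
    for _ in range(40):
        a = _random_mask(rng, density=0.1)
        g = _random_mask(rng, density=0.1)
        got = lesion_detection(a, g)
        expected = _oracle_detection(a, g)
        for gv, ev in zip(got, expected):
            if ev is None:
                assert gv is None
            else:
                assert gv == pytest.approx(ev)


def test_lesion_detection_worked_example():
    """2 GT lesions, 3 predicted, one hit each way: S=1/2, P=1/3, F1=0.4."""
    g = np.zeros((10, 10, 10), dtype=np.uint8)
    g[1, 1, 1] = 1          # GT lesion 1 (detected)
    g[8, 8, 8] = 1          # GT lesion 2 (missed)
    a = np.zeros((10, 10, 10), dtype=np.uint8)
    a[1, 1, 1] = 1          # hits GT lesion 1
    a[5, 5, 5] = 1          # false positive
    a[1, 8, 1] = 1          # false positive
    s, p, f1 = lesion_detection(make_mask(a), make_mask(g))
    assert (s, p) == (0.5, pytest.approx(1 / 3))
    assert f1 == pytest.approx(0.4)


def test_lesion_detection_conventions(rng):
    m = _random_mask(rng, density=0.1)
    if m.data.any():
        s, p, f1 = lesion_detection(m, m)
        assert (s, p, f1) == (1.0, 1.0, 1.0)
    empty = make_mask(np.zeros((6, 6, 6), dtype=np.uint8))
    g = _random_mask(rng, density=0.2)
    s, p, f1 = lesion_detection(empty, g)
    assert (s, p, f1) == (0.0, 0.0, 0.0)
    assert lesion_detection(g, empty) == (None, None, None)


def test_no_lesion_metrics_volume_scaling():
    # 10 voxels at 1.2 mm isotropic spacing -> 10 * 1.728 = 17.28 mm^3
    data = np.zeros((8, 8, 8), dtype=np.uint8)
    data[0, 0, :] = 1          # a 8-voxel line
    data[5, 5, 5:7] = 1        # a separate 2-voxel lesion
    mask = make_mask(data, spacing=(1.2, 1.2, 1.2))
    n, vol = no_lesion_metrics(mask)
    assert n == 2
    assert vol == pytest.approx(17.28)
    empty = make_mask(np.zeros((4, 4, 4), dtype=np.uint8))
    assert no_lesion_metrics(empty) == (0, 0.0)


def test_single_cube_lesion_volume():
    data = np.zeros((9, 9, 9), dtype=np.uint8)
    data[3:6, 3:6, 3:6] = 1
    n, vol = no_lesion_metrics(make_mask(data, spacing=(0.5, 0.5, 0.5)))
    assert n == 1
    assert vol == pytest.approx(27 * 0.125)


def test_overlap_rates_match_oracle(rng):
    for _ in range(50):
        a, g = _random_mask(rng), _random_mask(rng)
        tp, fp, fn, tn = _oracle_confusion(a, g)
        ppv, se, sp = overlap_rates(a, g)
        assert ppv == (pytest.approx(tp / (tp + fp)) if tp + fp else None)
        assert se == (pytest.approx(tp / (tp + fn)) if tp + fn else None)
        assert sp == (pytest.approx(tn / (tn + fp)) if tn + fp else None)


def test_overlap_rates_are_asymmetric():
    g = np.zeros((6, 6, 6), dtype=np.uint8)
    g[0:2, 0, 0] = 1
    a = np.zeros((6, 6, 6), dtype=np.uint8)
    a[0, 0, 0] = 1  # half of G, no FP
    ppv, se, _ = overlap_rates(make_mask(a), make_mask(g))
    assert (ppv, se) == (1.0, 0.5)
    ppv_r, se_r, _ = overlap_rates(make_mask(g), make_mask(a))
    assert (ppv_r, se_r) == (0.5, 1.0)


def test_msd_identical_masks_zero(rng):
    m = _random_mask(rng, density=0.3)
    assert mean_surface_distance(m, m) == 0.0


def test_msd_two_point_masks_is_their_distance():
    a = np.zeros((8, 8, 8), dtype=np.uint8)
    g = np.zeros((8, 8, 8), dtype=np.uint8)
    a[2, 2, 2] = 1
    g[2, 2, 5] = 1
    assert mean_surface_distance(make_mask(a), make_mask(g)) == pytest.approx(3.0)
    # anisotropic spacing scales the physical distance
    am = make_mask(a, spacing=(1.0, 1.0, 0.5))
    gm = make_mask(g, spacing=(1.0, 1.0, 0.5))
    assert mean_surface_distance(am, gm) == pytest.approx(1.5)


def test_msd_matches_all_pairs_oracle(rng):
    for _ in range(20):
        a = _random_mask(rng, density=0.25, spacing=(1.0, 1.2, 0.7))
        g = _random_mask(rng, density=0.25, spacing=(1.0, 1.2, 0.7))
        if not a.data.any() or not g.data.any():
            continue
        assert mean_surface_distance(a, g) == pytest.approx(_oracle_msd(a, g))


def test_msd_symmetric_and_empty_flagged(rng):
    a = _random_mask(rng, density=0.3)
    g = _random_mask(rng, density=0.3)
    assert mean_surface_distance(a, g) == pytest.approx(
        mean_surface_distance(g, a))
    empty = make_mask(np.zeros((6, 6, 6), dtype=np.uint8))
    assert mean_surface_distance(a, empty) is None


def test_component_count_invariant_under_flips_and_permutations(rng):
    mask = _random_mask(rng, density=0.15)
    _, base = label_lesions(mask)
    for perm in itertools.permutations(range(3)):
        transposed = make_mask(np.transpose(mask.data, perm))
        assert label_lesions(transposed)[1] == base
    flipped = make_mask(mask.data[::-1, :, ::-1].copy())
    assert label_lesions(flipped)[1] == base


def test_grid_mismatch_raises(rng):
    a = _random_mask(rng, shape=(5, 5, 5))
    g = _random_mask(rng, shape=(6, 6, 6))
    with pytest.raises(GridMismatchError):
        confusion_counts(a, g)


def test_evaluate_case_flags_and_aggregation(rng):
    lesion_pred = _random_mask(rng, density=0.1)
    lesion_gt = _random_mask(rng, density=0.1)
    empty = make_mask(np.zeros((6, 6, 6), dtype=np.uint8))
    rep_normal = evaluate_case(lesion_pred, lesion_gt)
    rep_nolesion = evaluate_case(lesion_pred, empty)
    assert rep_nolesion.f1 is None
    assert "f1" in rep_nolesion.flags
    means = aggregate_reports({"a": rep_normal, "b": rep_nolesion})
    # the flagged case is skipped, so the cohort F1 equals the defined one
    assert means["f1"] == pytest.approx(rep_normal.f1)
    assert means["n_lesions_pred"] == pytest.approx(
        (rep_normal.n_lesions_pred + rep_nolesion.n_lesions_pred) / 2)


def test_f1_consistency_invariant(rng):
    for _ in range(20):
        a, g = _random_mask(rng, density=0.1), _random_mask(rng, density=0.1)
        s, p, f1 = lesion_detection(a, g)
        if s is None or s + p == 0:
            continue
        assert f1 == pytest.approx(2 * s * p / (s + p))
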