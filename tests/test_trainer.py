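import numpy as np
import pytest

from neolesion.errors import NeolesionError
from neolesion.model import NetworkConfig, build_network
from neolesion.phantom import PhantomConfig, generate_cohort
from neolesion.slicer import extract_plane_slices, select_lesion_positive
from neolesion.trainer import TrainConfig, augment, fit, split_by_patient


@pytest.fixture(scope="module")
def tiny_pool():
    """Lesion-positive axial slices from two 32^3 phantoms, 32-canvas."""
    cfg = PhantomConfig(shape=(32, 32, 32), n_stable_lesions=1,
                        n_new_lesions=2, lesion_radius_range=(2, 3))
    cases = generate_cohort(2, cfg, seed=3)
    pool = []
    for case in cases:
        pool.extend(select_lesion_positive(
            extract_plane_slices(case, "axial", canvas=32)))
    return pool


def _tiny_model(seed=0):
    cfg = NetworkConfig(in_channels=2, input_size=32, filters=(4, 8))
    return build_network(cfg, np.random.default_rng(seed))


def test_split_by_patient_disjoint_and_sized():
    cfg = PhantomConfig(shape=(8, 8, 8), n_stable_lesions=0, n_new_lesions=0)
    cases = generate_cohort(29, cfg, seed=0)
    train, val = split_by_patient(cases, 24, 5, seed=42)
    assert len(train) == 24 and len(val) == 5
    train_ids = {c.patient_id for c in train}
    val_ids = {c.patient_id for c in val}
    assert train_ids.isdisjoint(val_ids)


def test_split_deterministic_given_seed():
    cfg = PhantomConfig(shape=(8, 8, 8), n_stable_lesions=0, n_new_lesions=0)
    cases = generate_cohort(10, cfg, seed=0)
    a = split_by_patient(cases, 6, 2, seed=7)
    b = split_by_patient(cases, 6, 2, seed=7)
    assert [c.patient_id for c in a[0]] == [c.patient_id for c in b[0]]
    assert [c.patient_id for c in a[1]] == [c.patient_id for c in b[1]]


def test_split_insufficient_cases():
    cfg = PhantomConfig(shape=(8, 8, 8), n_stable_lesions=0, n_new_lesions=0)
    cases = generate_cohort(10, cfg, seed=0)
    with pytest.raises(NeolesionError):
        split_by_patient(cases, 24, 5, seed=0)


def test_augment_flip_consistent_across_channels_and_label(tiny_pool):
    rec = tiny_pool[0]
    rng = np.random.default_rng(0)
    # force a pure horizontal flip
    out = augment(rec, rng, rotation_deg=0.0, shift_frac=0.0, flip_prob=1.0)
    np.testing.assert_array_equal(out.image, rec.image[::-1, ::-1])
    np.testing.assert_array_equal(out.label, rec.label[::-1, ::-1])
    assert set(np.unique(out.label)) <= {0, 1}
    assert out.label.sum() == rec.label.sum()  # flips are permutations


def test_augment_identity_draw_returns_record_unchanged(tiny_pool):
    rec = tiny_pool[0]
    rng = np.random.default_rng(0)
    out = augment(rec, rng, rotation_deg=0.0, shift_frac=0.0, flip_prob=0.0)
    np.testing.assert_array_equal(out.image, rec.image)
    np.testing.assert_array_equal(out.label, rec.label)


def test_augment_label_stays_binary_under_rotation(tiny_pool):
    rec = tiny_pool[0]
    rng = np.random.default_rng(5)
    out = augment(rec, rng, rotation_deg=10.0, shift_frac=0.1, flip_prob=0.5)
    assert set(np.unique(out.label)) <= {0, 1}
    assert out.image.shape == rec.image.shape


def test_fit_early_stops_with_frozen_model(tiny_pool):
    model = _tiny_model()
    cfg = TrainConfig(learning_rate=0.0, max_epochs=50, early_stop_patience=1,
                      augment=False, seed=0)
    _, history = fit(model, tiny_pool, tiny_pool, cfg)
    assert len(history) == 2  # epoch 1 sets the best; epoch 2 stalls, stops


def test_fit_deterministic_first_epoch(tiny_pool):
    histories = []
    for _ in range(2):
        model = _tiny_model(seed=9)
        cfg = TrainConfig(max_epochs=1, seed=11)
        _, hist = fit(model, tiny_pool, tiny_pool, cfg)
        histories.append(hist[0]["train_loss"])
    assert histories[0] == histories[1]


def test_fit_history_finite_and_lr_schedule(tiny_pool):
    model = _tiny_model()
    cfg = TrainConfig(learning_rate=0.0, max_epochs=25, plateau_patience=10,
                      plateau_factor=0.1, early_stop_patience=100,
                      augment=False, seed=0)
    _, history = fit(model, tiny_pool, tiny_pool, cfg)
    losses = [h["train_loss"] for h in history]
    assert np.isfinite(losses).all()
    # frozen model: plateau fires every 10 stalled epochs after epoch 1
    # epochs 1-11 at lr0, 12-21 at lr0*f, 22-25 at lr0*f^2
    assert history[0]["lr"] == 0.0
    lrs = [h["lr"] for h in history]
    assert len(set(lrs)) == 1  # lr 0 stays 0 under multiplication


def test_plateau_halves_learning_rate_by_factor(tiny_pool):
    model = _tiny_model()
    cfg = TrainConfig(learning_rate=1e-4, max_epochs=24, plateau_patience=5,
                      plateau_factor=0.1, early_stop_patience=100,
                      min_delta=10.0,  # every epoch counts as stalled
                      augment=False, seed=0)
    _, history = fit(model, tiny_pool, tiny_pool, cfg)
    lrs = sorted({round(h["lr"], 12) for h in history}, reverse=True)
    # after k plateau events the rate is lr * factor^k
    expected = [1e-4 * 0.1 ** k for k in range(len(lrs))]
    assert lrs == pytest.approx(expected)


def test_fit_requires_nonempty_labelled_pools(tiny_pool):
    model = _tiny_model()
    cfg = TrainConfig(max_epochs=1)
    with pytest.raises(NeolesionError):
        fit(model, [], tiny_pool, cfg)
    unlabelled = [
        type(tiny_pool[0])(image=tiny_pool[0].image, label=None,
                           plane="axial", index=0, orig_shape=(32, 32),
                           pad_offsets=(0, 0))
    ]
    with pytest.raises(NeolesionError):
        fit(model, unlabelled, tiny_pool, cfg)


def test_fit_writes_run_artifacts(tiny_pool, tmp_path):
    model = _tiny_model()
    cfg = TrainConfig(max_epochs=2, augment=False, seed=0)
    fit(model, tiny_pool, tiny_pool, cfg, run_dir=tmp_path / "run")
    assert (tmp_path / "run" / "history.csv").exists()
    assert (tmp_path / "run" / "train_config.json").exists()
    assert (tmp_path / "run" / "best_model.npz").exists()
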