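"""Synthetic longitudinal FLAIR phantoms.

Each phantom is an ellipsoidal "brain" on a zero background whose voxels are
drawn from a two-mode intensity mixture (emulating the two dominant tissue
peaks of a skull-stripped FLAIR histogram). Hyperintense spherical lesions
with smooth radial falloff are planted: stable lesions appear in both time
points, new lesions only in the follow-up, and exactly the new lesions form
the ground-truth mask. Independent Gaussian noise is added per time point.
Everything is deterministic given the seed.

This generator exists to exercise the full pipeline — normalization,
slicing, training, reconstruction, metrics — without external data. It does
not model MR physics, bias fields, or registration error.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .errors import PlacementError
from .volio import BinaryMask, LongitudinalCase, Volume, write_case

MAX_PLACEMENT_TRIES = 200


@dataclasses.dataclass(frozen=True)
class PhantomConfig:
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    #: (mean, sd) of the darker and brighter tissue modes
    tissue_modes: tuple[tuple[float, float], tuple[float, float]] = (
        (100.0, 5.0), (200.0, 8.0))
    #: mixing weights of the two modes (sum to 1); brighter mode dominant
    mode_weights: tuple[float, float] = (0.4, 0.6)
    n_stable_lesions: int = 3
    n_new_lesions: int = 2
    lesion_radius_range: tuple[int, int] = (2, 5)
    #: lesion peak intensity = boost x brighter mode mean
    lesion_intensity_boost: float = 1.6
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_stable_lesions < 0 or self.n_new_lesions < 0:
            raise ValueError("lesion counts must be >= 0")
        if self.lesion_radius_range[0] < 1:
            raise ValueError("lesion radii must be >= 1 voxel")
        if self.lesion_intensity_boost <= 1:
            raise ValueError("lesion_intensity_boost must exceed 1")
        if abs(sum(self.mode_weights) - 1.0) > 1e-9:
            raise ValueError("mode weights must sum to 1")


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    center = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) * 0.42
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return r2 <= 1.0


def _place_lesions(brain: np.ndarray, occupied: np.ndarray, n: int,
                   radius_range: tuple[int, int],
                   rng: np.random.Generator) -> list[tuple[np.ndarray, int]]:
    """Choose lesion centers inside the brain, avoiding prior lesions."""
    shape = np.asarray(brain.shape)
    lesions = []
    for _ in range(n):
        for _attempt in range(MAX_PLACEMENT_TRIES):
            radius = int(rng.integers(radius_range[0], radius_range[1] + 1))
            center = np.array([rng.integers(radius + 1, s - radius - 1)
                               for s in shape])
            lo = center - radius
            hi = center + radius + 1
            box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
            # the sphere must sit fully inside the brain, clear of others
            grids = np.ogrid[box]
            r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
            sphere = r2 <= radius ** 2
            if brain[box][sphere].all() and not occupied[box][sphere].any():
                occupied[box][sphere] = True
                lesions.append((center, radius))
                break
        else:
            raise PlacementError(
                f"could not place lesion {len(lesions)} after "
                f"{MAX_PLACEMENT_TRIES} tries")
    return lesions


def _paint_lesions(data: np.ndarray, lesions: list[tuple[np.ndarray, int]],
                   peak: float, mask_out: np.ndarray | None = None) -> None:
    """Set lesion voxels to peak x smooth falloff (1 -> 0.7 at the rim)."""
    for center, radius in lesions:
        lo = center - radius
        hi = center + radius + 1
        box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        grids = np.ogrid[box]
        r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        sphere = r2 <= radius ** 2
        falloff = 1.0 - 0.3 * (r2 / radius ** 2)
        region = data[box]
        region[sphere] = (peak * falloff)[sphere]
        data[box] = region
        if mask_out is not None:
            sub = mask_out[box]
            sub[sphere] = 1
            mask_out[box] = sub


def generate_case(cfg: PhantomConfig,
                  patient_id: str | None = None) -> LongitudinalCase:
    """One deterministic longitudinal phantom case."""
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(cfg.shape)
    brain = _ellipsoid_mask(shape)

    (m1, s1), (m2, s2) = cfg.tissue_modes
    w1, _ = cfg.mode_weights
    mode_pick = rng.random(shape) < w1
    tissue = np.where(mode_pick, rng.normal(m1, s1, shape),
                      rng.normal(m2, s2, shape))
    tissue = np.clip(tissue, 1.0, None) * brain

    occupied = np.zeros(shape, dtype=bool)
    stable = _place_lesions(brain, occupied, cfg.n_stable_lesions,
                            cfg.lesion_radius_range, rng)
    new = _place_lesions(brain, occupied, cfg.n_new_lesions,
                         cfg.lesion_radius_range, rng)

    brighter_mean = max(m1, m2)
    peak = cfg.lesion_intensity_boost * brighter_mean
    baseline = tissue.copy()
    followup = tissue.copy()
    gt = np.zeros(shape, dtype=np.uint8)
    _paint_lesions(baseline, stable, peak)
    _paint_lesions(followup, stable, peak)
    _paint_lesions(followup, new, peak, mask_out=gt)

    baseline += rng.normal(0.0, cfg.noise_sd, shape) * brain
    followup += rng.normal(0.0, cfg.noise_sd, shape) * brain
    baseline = np.clip(baseline, 0.0, None) * brain
    followup = np.clip(followup, 0.0, None) * brain

    affine = np.diag(list(cfg.spacing) + [1.0])
    pid = patient_id or f"phantom_{cfg.seed:05d}"
    return LongitudinalCase(
        patient_id=pid,
        baseline=Volume(baseline.astype(np.float32), cfg.spacing, affine),
        followup=Volume(followup.astype(np.float32), cfg.spacing, affine),
        gt_new_lesions=BinaryMask(gt, cfg.spacing, affine))


def generate_cohort(n_cases: int, cfg: PhantomConfig, seed: int,
                    no_lesion_fraction: float = 0.0
                    ) -> list[LongitudinalCase]:
    """A cohort of phantoms with per-case derived seeds.

    ``no_lesion_fraction`` of the cases (rounded to the nearest count,
    positions chosen deterministically from the seed) are generated with
    zero new lesions, emulating longitudinal cohorts in which many patients
    show no lesion activity between scans.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(seed)
    case_seeds = rng.integers(0, 2 ** 31 - 1, size=n_cases)
    n_empty = int(round(no_lesion_fraction * n_cases))
    empty_idx = set(rng.permutation(n_cases)[:n_empty].tolist())
    cases = []
    for i in range(n_cases):
        case_cfg = dataclasses.replace(
            cfg, seed=int(case_seeds[i]),
            n_new_lesions=0 if i in empty_idx else cfg.n_new_lesions)
        cases.append(generate_case(case_cfg, patient_id=f"patient_{i:03d}"))
    return cases


def write_cohort(cases: list[LongitudinalCase], out_dir) -> list[Path]:
    """Write cases as MSSEG-2-style patient directories."""
    return [write_case(case, out_dir) for case in cases]
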