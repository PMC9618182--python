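"""Synthetic cohorts, image stacks and validation panels.

These generators produce inputs with the statistical structure the
analysis assumes — log-normal pooled reporter intensities, a planted
fraction of proteins with fold changes beyond the +/-20% thresholds,
unique-peptide counts, missing values, and two-channel punctate image
stacks with a controlled colocalized fraction — together with ground
truth, so every downstream stage can be exercised and scored without any
external data.

All randomness in a call flows from a single integer seed through one
:class:`numpy.random.Generator` instance; identical seeds and configs
yield identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .design import ComparisonDesign
from .errors import ConfigError, PlacementError
from .imaging import ImageStack
from .transform import DOWN, UNCHANGED, UP

__all__ = [
    "EffectConfig",
    "generate_pool_table",
    "generate_image_stack",
    "generate_validation_panel",
]

# Baseline reporter intensities: log10-normal, mean 6, sd 0.5 — a realistic
# dynamic range; exact values are immaterial to ratiometric analysis.
BASELINE_LOG10_MEAN = 6.0
BASELINE_LOG10_SD = 0.5
PEPTIDE_POISSON_MEAN = 4.0

TRUTH_COLUMNS = ["accession", "comparison", "true_ratio", "true_class"]


@dataclass(frozen=True)
class EffectConfig:
    """Configuration of a synthetic pooled cohort.

    Parameters
    ----------
    n_proteins
        Number of simulated proteins.
    frac_altered_per_comparison
        Fraction of proteins planted with a fold change in each
        comparison (split evenly between UP and DOWN).
    fold_change_range_up, fold_change_range_down
        Uniform sampling intervals for planted case/control ratios;
        the UP interval must lie above 1, the DOWN interval below 1.
    noise_cv
        Coefficient of variation of multiplicative log-normal noise
        applied to every measured intensity.
    frac_missing
        Fraction of non-control-pool cells set to missing.
    frac_low_peptide
        Fraction of proteins forced to a unique-peptide count of 1
        (to exercise the identification filter).
    pool_loading_sd
        SD (in log10 units) of per-pool loading factors; 0 disables
        loading variation so raw ratios equal planted ratios exactly.
    seed
        Integer seed for the single random generator.
    """

    n_proteins: int = 1000
    frac_altered_per_comparison: float = 0.1
    fold_change_range_up: tuple[float, float] = (1.3, 2.5)
    fold_change_range_down: tuple[float, float] = (0.4, 0.77)
    noise_cv: float = 0.0
    frac_missing: float = 0.0
    frac_low_peptide: float = 0.0
    pool_loading_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError(f"n_proteins must be >= 1, got {self.n_proteins}")
        if not 0 <= self.frac_altered_per_comparison <= 1:
            raise ConfigError("frac_altered_per_comparison must be in [0, 1]")
        lo_up, hi_up = self.fold_change_range_up
        if not 1 < lo_up <= hi_up:
            raise ConfigError("fold_change_range_up must satisfy 1 < lo <= hi")
        lo_dn, hi_dn = self.fold_change_range_down
        if not 0 < lo_dn <= hi_dn < 1:
            raise ConfigError("fold_change_range_down must satisfy 0 < lo <= hi < 1")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        for name in ("frac_missing", "frac_low_peptide"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ConfigError(f"{name} must be in [0, 1), got {v}")
        if self.pool_loading_sd < 0:
            raise ConfigError("pool_loading_sd must be >= 0")


def generate_pool_table(
    design: ComparisonDesign, cfg: EffectConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a pooled quantification table with planted fold changes.

    Every comparison's planted effects are applied multiplicatively to
    its case pool before noise; the truth table records the planted
    class and ratio per protein per comparison.  To keep planted ratios
    well-defined, each case pool may serve as the case of exactly one
    comparison and must not double as a control pool.

    Returns
    -------
    (table, truth)
        ``table`` follows the :mod:`synprot.io` schema (accession index,
        ``symbol``, ``unique_peptides``, one column per pool); ``truth``
        is tidy with columns ``accession, comparison, true_ratio,
        true_class``.
    """
    case_pools = [c.case_pool for c in design]
    control_pools = {c.control_pool for c in design}
    if len(set(case_pools)) != len(case_pools):
        raise ConfigError("each pool may be the case of at most one comparison")
    if set(case_pools) & control_pools:
        raise ConfigError("a case pool may not also serve as a control pool")

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    accessions = np.array([f"P{i:05d}" for i in range(n)])
    symbols = np.array([f"GENE{i}" for i in range(n)])
    baseline = 10.0 ** rng.normal(BASELINE_LOG10_MEAN, BASELINE_LOG10_SD, n)

    pools = list(design.pool_ids)
    intensity = {p: baseline.copy() for p in pools}

    # Plant per-comparison effects on the case pool.
    n_altered = int(round(cfg.frac_altered_per_comparison * n))
    truth_frames = []
    for comp in design:
        chosen = rng.choice(n, size=n_altered, replace=False)
        n_up = n_altered // 2 + (n_altered % 2) * int(rng.integers(2))
        up_idx = chosen[:n_up]
        down_idx = chosen[n_up:]
        ratios = np.ones(n)
        ratios[up_idx] = rng.uniform(*cfg.fold_change_range_up, size=len(up_idx))
        ratios[down_idx] = rng.uniform(*cfg.fold_change_range_down, size=len(down_idx))
        classes = np.full(n, UNCHANGED, dtype=object)
        classes[up_idx] = UP
        classes[down_idx] = DOWN
        intensity[comp.case_pool] = intensity[comp.case_pool] * ratios
        truth_frames.append(
            pd.DataFrame(
                {
                    "accession": accessions,
                    "comparison": comp.name,
                    "true_ratio": ratios,
                    "true_class": classes,
                }
            )
        )
    truth = pd.concat(truth_frames, ignore_index=True)[TRUTH_COLUMNS]

    # Per-pool loading factors (log10-normal), removed downstream by the
    # 1/median correction.
    if cfg.pool_loading_sd > 0:
        for p in pools:
            intensity[p] = intensity[p] * 10.0 ** rng.normal(0.0, cfg.pool_loading_sd)

    # Multiplicative log-normal measurement noise per cell.
    if cfg.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + cfg.noise_cv**2))
        for p in pools:
            intensity[p] = intensity[p] * np.exp(rng.normal(0.0, sigma, n))

    # Unique-peptide counts, with a forced low-count subset.
    peptides = 1 + rng.poisson(PEPTIDE_POISSON_MEAN, n)
    n_low = int(round(cfg.frac_low_peptide * n))
    if n_low:
        peptides[rng.choice(n, size=n_low, replace=False)] = 1

    table = pd.DataFrame({"symbol": symbols, "unique_peptides": peptides})
    table.index = pd.Index(accessions, name="accession")
    for p in pools:
        table[p] = intensity[p]

    # Missing values only in non-control pools, so ratio denominators exist.
    if cfg.frac_missing > 0:
        target_pools = [p for p in pools if p not in control_pools]
        for p in target_pools:
            n_miss = int(round(cfg.frac_missing * n))
            if n_miss:
                miss_idx = rng.choice(n, size=n_miss, replace=False)
                col = table[p].to_numpy()
                col[miss_idx] = np.nan
                table[p] = col

    return table, truth


def _place_centers(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int, int],
    margin: int,
    min_sep_vox: int,
    existing: list[tuple[int, int, int]] | None = None,
    forbidden_nm: tuple[list[tuple[float, float, float]], float] | None = None,
    voxel_size_nm: tuple[float, float, float] | None = None,
    max_tries: int = 2000,
) -> list[tuple[int, int, int]]:
    """Rejection-sample punctum origins with Chebyshev separation.

    ``forbidden_nm`` excludes origins whose physical position falls
    within a radius of any listed point (used to keep non-colocalized
    puncta away from the other channel).
    """
    centers: list[tuple[int, int, int]] = list(existing or [])
    placed: list[tuple[int, int, int]] = []
    for _ in range(n):
        for attempt in range(max_tries):
            z = int(rng.integers(margin, shape[0] - margin - 1))
            y = int(rng.integers(margin, shape[1] - margin - 1))
            x = int(rng.integers(margin, shape[2] - margin - 1))
            if any(
                max(abs(z - cz), abs(y - cy), abs(x - cx)) < min_sep_vox
                for cz, cy, cx in centers
            ):
                continue
            if forbidden_nm is not None:
                points, radius = forbidden_nm
                dz, dy, dx = voxel_size_nm
                pos = (z * dz, y * dy, x * dx)
                if any(
                    math.dist(pos, q) <= radius for q in points
                ):
                    continue
            centers.append((z, y, x))
            placed.append((z, y, x))
            break
        else:
            raise PlacementError(
                f"could not place punctum {len(placed) + 1}/{n} after {max_tries} tries"
            )
    return placed


def generate_image_stack(
    shape: tuple[int, int, int] = (20, 128, 128),
    voxel_size_nm: tuple[float, float, float] = (70.0, 100.0, 100.0),
    n_puncta: tuple[int, int] = (30, 30),
    coloc_fraction: float = 0.5,
    psf_sigma_nm: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    opposition_nm: float = 280.0,
    exclusion_nm: float = 600.0,
    amplitude: float = 100.0,
) -> tuple[dict[str, ImageStack], pd.DataFrame]:
    """Simulate a two-channel serial-section stack with planted puncta.

    Each punctum is a 2x2x2-voxel cube of intensity ``amplitude``.  A
    fraction ``coloc_fraction`` of channel-B puncta is placed at physical
    distance ``opposition_nm`` from a distinct channel-A punctum (the
    opposed pre/post arrangement); the remaining B puncta are placed
    uniformly at random but kept at least ``exclusion_nm`` from every A
    punctum, so the planted colocalized fraction is exact under any
    cutoff between ``opposition_nm`` plus one voxel diagonal and
    ``exclusion_nm``.  Optional Gaussian blur (``psf_sigma_nm``) and
    additive Gaussian noise (``noise_sd``) follow placement.

    Returns
    -------
    (stacks, truth)
        ``stacks`` maps channel name ("A", "B") to :class:`ImageStack`;
        ``truth`` lists planted puncta with columns ``channel, z_nm,
        y_nm, x_nm, colocalized``.
    """
    if shape[0] < 3 or min(shape) < 1:
        raise ConfigError(f"stack needs >= 3 slices, got shape {shape}")
    margin = 3
    if any(dim <= 2 * margin + 1 for dim in shape):
        raise ConfigError(
            f"stack shape {shape} too small for punctum placement margin {margin}"
        )
    n_a, n_b = n_puncta
    if n_a < 0 or n_b < 0:
        raise ConfigError("puncta counts must be >= 0")
    if not 0 <= coloc_fraction <= 1:
        raise ConfigError("coloc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    min_sep_vox = 5  # cube size 2 + >=3 empty voxels: components never merge

    centers_a = _place_centers(rng, n_a, shape, margin, min_sep_vox)

    n_coloc = int(round(coloc_fraction * n_b))
    if n_coloc > n_a and n_coloc > 0:
        raise ConfigError(
            f"{n_coloc} colocalized B puncta requested but only {n_a} A puncta"
        )
    dzyx = np.asarray(voxel_size_nm, dtype=float)
    centers_b: list[tuple[int, int, int]] = []
    partners = rng.choice(n_a, size=n_coloc, replace=False) if n_coloc else []
    for a_idx in partners:
        az, ay, ax = centers_a[a_idx]
        for attempt in range(2000):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            offset_vox = np.round(direction * opposition_nm / dzyx).astype(int)
            cand = (az + offset_vox[0], ay + offset_vox[1], ax + offset_vox[2])
            if not (
                margin <= cand[0] < shape[0] - margin - 1
                and margin <= cand[1] < shape[1] - margin - 1
                and margin <= cand[2] < shape[2] - margin - 1
            ):
                continue
            if any(
                max(abs(cand[0] - z), abs(cand[1] - y), abs(cand[2] - x)) < min_sep_vox
                for z, y, x in centers_b
            ):
                continue
            centers_b.append(cand)
            break
        else:
            raise PlacementError("could not place an opposed channel-B punctum")

    a_points_nm = [tuple(np.asarray(c) * dzyx) for c in centers_a]
    free_b = _place_centers(
        rng,
        n_b - n_coloc,
        shape,
        margin,
        min_sep_vox,
        existing=centers_b,
        forbidden_nm=(a_points_nm, exclusion_nm),
        voxel_size_nm=tuple(dzyx),
    )
    coloc_flags = [True] * n_coloc + [False] * len(free_b)
    centers_b = centers_b + free_b

    stacks = {}
    truth_rows = []
    for channel, centers, flags in (
        ("A", centers_a, [False] * n_a),
        ("B", centers_b, coloc_flags),
    ):
        arr = np.zeros(shape, dtype=float)
        for z, y, x in centers:
            arr[z : z + 2, y : y + 2, x : x + 2] = amplitude
        if psf_sigma_nm > 0:
            arr = gaussian_filter(arr, sigma=tuple(psf_sigma_nm / dzyx))
        if noise_sd > 0:
            arr = arr + rng.normal(0.0, noise_sd, shape)
        stacks[channel] = ImageStack(data=arr, voxel_size_nm=tuple(dzyx))
        for (z, y, x), flag in zip(centers, flags):
            # ground-truth centroid of the 2x2x2 cube, in nm
            truth_rows.append(
                {
                    "channel": channel,
                    "z_nm": (z + 0.5) * dzyx[0],
                    "y_nm": (y + 0.5) * dzyx[1],
                    "x_nm": (x + 0.5) * dzyx[2],
                    "colocalized": flag,
                }
            )
    truth = pd.DataFrame(
        truth_rows, columns=["channel", "z_nm", "y_nm", "x_nm", "colocalized"]
    )
    return stacks, truth


def generate_validation_panel(
    n_proteins: int = 6,
    slope: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Paired orthogonal-method vs proteomics ratios with a known linear
    relation plus Gaussian noise on the proteomics axis.

    The orthogonal ratios cycle through increased (~1.4-2.0), decreased
    (~0.4-0.7) and unchanged (~0.9-1.1) proteins, emulating a validation
    panel chosen to span the range of alterations.

    Raises
    ------
    ConfigError
        If ``n_proteins`` < 3 (the regression would be degenerate).
    """
    if n_proteins < 3:
        raise ConfigError(f"validation panel needs >= 3 proteins, got {n_proteins}")
    rng = np.random.default_rng(seed)
    bands = [(1.4, 2.0), (0.4, 0.7), (0.9, 1.1)]
    x = np.array(
        [rng.uniform(*bands[i % 3]) for i in range(n_proteins)], dtype=float
    )
    y = slope * x + rng.normal(0.0, noise_sd, n_proteins)
    return list(zip(x.tolist(), y.tolist()))
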