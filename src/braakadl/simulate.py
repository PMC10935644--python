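"""Synthetic cohorts, young reference samples and toy image sets.

The generator emulates the statistical structure the analysis modules
assume, so the whole pipeline is testable without any data download:

* a young (age < 26) cognitively-unimpaired reference sample drawn from
  the stage-0 SUVR distribution, for threshold estimation;
* a cohort (default n = 291 split 112/78/35/66 across stage groups
  0 / I–II / III–IV / V–VI) whose regional tau-PET SUVR profiles are
  abnormal exactly through each participant's true top stage;
* stage-graded baseline functional scores — effects (in latent SD units)
  emerge at III–IV for FAQ/ECog and only at V–VI for CDR-SB-F — realised
  as item-level responses so the scoring operators are exercised
  end-to-end;
* elevated annual functional decline confined to stages V–VI, with a
  follow-up visit for a subset of participants (default 188/291) after a
  truncated-normal interval (mean 1.97 y, SD 0.66, range 0.8–3.6);
* covariates (age, sex, amyloid SUVR, MMSE, diagnosis) with
  stage-group-dependent distributions;
* toy 3D image sets with signal injected inside Braak-like masks and
  coupled to the functional score, for the voxelwise module.

All generators are deterministic under a fixed config seed. True group
labels are stored under a separate ``truth_`` column namespace that the
analysis modules never read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter

from .cohort import (
    BRAAK_SUVR_COLS,
    CDRF_COLS,
    ECOG_COLS,
    FAQ_COLS,
    CohortTable,
    derive_scores,
)
from .voxelwise import VoxelImageSet

__all__ = [
    "SyntheticConfig",
    "generate_reference",
    "generate_cohort",
    "generate_images",
    "make_braak_toy_masks",
    "items_for_faq_total",
    "items_for_ecog_mean",
    "boxes_for_cdrsbf_total",
]

INSTRUMENTS = ("faq", "ecog", "cdrsbf")
_GROUPS = ("0", "I-II", "III-IV", "V-VI")
_GROUP_STAGES = {"0": (0,), "I-II": (1, 2), "III-IV": (3, 4), "V-VI": (5, 6)}

# All valid CDR-SB-F totals and the box triples realising them.
_CDR_TRIPLES: dict[float, list[tuple[float, float, float]]] = {}
for _t in product((0.0, 0.5, 1.0, 2.0, 3.0), repeat=3):
    _CDR_TRIPLES.setdefault(round(sum(_t), 1), []).append(_t)
_CDR_TOTALS = np.array(sorted(_CDR_TRIPLES))


@dataclass
class SyntheticConfig:
    """Generating parameters of the synthetic study (defaults = study conditions)."""

    seed: int = 0
    n_total: int = 291
    group_fractions: tuple = (112 / 291, 78 / 291, 35 / 291, 66 / 291)
    young_reference_n: int = 30
    young_age_range: tuple = (18.0, 25.9)

    # regional tau-PET SUVR model
    roi_ref_mean: tuple = (1.0,) * 6
    roi_ref_sd: float = 0.05
    abnormal_delta: float = 0.5

    # baseline score effects per stage group, in latent SD units
    baseline_effects: dict = field(
        default_factory=lambda: {
            "faq": (0.0, 0.0, 0.45, 1.2),
            "ecog": (0.0, 0.0, 0.45, 1.2),
            "cdrsbf": (0.0, 0.0, 0.0, 1.2),
        }
    )
    # annual-decline effects per stage group, in latent SD units
    decline_effects: dict = field(
        default_factory=lambda: {
            "faq": (0.0, 0.0, 0.0, 1.69),
            "ecog": (0.0, 0.0, 0.0, 1.05),
            "cdrsbf": (0.0, 0.0, 0.0, 1.29),
        }
    )
    score_noise_sd: float = 0.45
    rate_noise_sd: float = 0.7
    instrument_corr: float = 0.7
    # latent -> raw score mapping: (base, raw units per latent SD)
    score_scale: dict = field(
        default_factory=lambda: {"faq": (4.0, 5.0), "ecog": (1.7, 0.45), "cdrsbf": (0.2, 1.5)}
    )
    rate_scale: dict = field(
        default_factory=lambda: {"faq": (0.1, 1.2), "ecog": (0.02, 0.15), "cdrsbf": (0.05, 0.6)}
    )

    followup_fraction: float = 188 / 291
    followup_years_mean: float = 1.97
    followup_years_sd: float = 0.66
    followup_years_bounds: tuple = (0.8, 3.6)

    # covariates
    age_mean: float = 70.60
    age_sd: float = 7.48
    female_fraction: float = 0.628
    education_mean: float = 15.3
    education_sd: float = 3.8
    abeta_group_means: tuple = (1.38, 1.75, 2.01, 2.64)
    abeta_group_sds: tuple = (0.3, 0.5, 0.6, 0.5)
    mmse_group_means: tuple = (29.07, 28.76, 28.03, 22.00)
    mmse_group_sds: tuple = (1.1, 1.7, 3.1, 6.2)
    diagnosis_probs: tuple = (
        (0.964, 0.036, 0.0),
        (0.718, 0.244, 0.038),
        (0.486, 0.314, 0.200),
        (0.0, 0.333, 0.667),
    )

    def group_counts(self) -> np.ndarray:
        """Integer group sizes by largest-remainder apportionment."""
        f = np.asarray(self.group_fractions, dtype=float)
        if not np.isclose(f.sum(), 1.0):
            raise ValueError("group_fractions must sum to 1")
        raw = f * self.n_total
        counts = np.floor(raw).astype(int)
        for i in np.argsort(-(raw - counts))[: self.n_total - counts.sum()]:
            counts[i] += 1
        return counts


def items_for_faq_total(total: int, rng: np.random.Generator) -> np.ndarray:
    """Random 10-item FAQ response with the given total (uniform composition)."""
    if not 0 <= total <= 30:
        raise ValueError(f"infeasible FAQ total {total} (range 0..30)")
    return rng.multivariate_hypergeometric([3] * 10, int(total))


def items_for_ecog_mean(mean_score: float, rng: np.random.Generator) -> np.ndarray:
    """Random 39-item ECog response whose mean is as close as the item grid allows."""
    if not 1.0 <= mean_score <= 4.0:
        raise ValueError(f"infeasible ECog mean {mean_score} (range 1..4)")
    units = int(round((mean_score - 1.0) * 39))
    return 1 + rng.multivariate_hypergeometric([3] * 39, units)


def boxes_for_cdrsbf_total(total: float, rng: np.random.Generator) -> tuple:
    """Random valid CDR functional-box triple summing to the nearest achievable total."""
    if not 0.0 <= total <= 9.0:
        raise ValueError(f"infeasible CDR-SB-F total {total} (range 0..9)")
    snapped = _CDR_TOTALS[np.argmin(np.abs(_CDR_TOTALS - total))]
    options = _CDR_TRIPLES[round(float(snapped), 1)]
    return options[rng.integers(len(options))]


def _correlated_noise(rng, n, sd, corr):
    cov = sd**2 * (np.full((3, 3), corr) + (1 - corr) * np.eye(3))
    return rng.multivariate_normal(np.zeros(3), cov, size=n)


def generate_reference(config: SyntheticConfig) -> pd.DataFrame:
    """Young cognitively-unimpaired reference sample for threshold estimation."""
    if config.young_reference_n < 2:
        raise ValueError("young_reference_n must be >= 2")
    rng = np.random.default_rng([config.seed, 0])
    n = config.young_reference_n
    df = pd.DataFrame({"id": [f"y{i:03d}" for i in range(n)]})
    df["age"] = rng.uniform(*config.young_age_range, size=n)
    for j, col in enumerate(BRAAK_SUVR_COLS):
        df[col] = rng.normal(config.roi_ref_mean[j], config.roi_ref_sd, size=n)
    return df


def _quantize_scores(raw: dict[str, np.ndarray], rng) -> dict[str, list]:
    """Map continuous raw scores to item-level responses."""
    out = {"faq": [], "ecog": [], "cdrsbf": []}
    n = len(raw["faq"])
    for i in range(n):
        out["faq"].append(
            items_for_faq_total(int(round(float(np.clip(raw["faq"][i], 0, 30)))), rng)
        )
        out["ecog"].append(
            items_for_ecog_mean(float(np.clip(raw["ecog"][i], 1.0, 4.0)), rng)
        )
        out["cdrsbf"].append(
            boxes_for_cdrsbf_total(float(np.clip(raw["cdrsbf"][i], 0.0, 9.0)), rng)
        )
    return out


def generate_cohort(config: SyntheticConfig | None = None) -> CohortTable:
    """Generate a full synthetic cohort with true stage labels attached.

    Returns a :class:`CohortTable` whose ``data`` has baseline rows for all
    participants and follow-up rows for the configured fraction. True
    labels live in ``truth_group`` / ``truth_stage``.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng([cfg.seed, 1])
    counts = cfg.group_counts()
    n = int(counts.sum())

    group_idx = np.repeat(np.arange(4), counts)
    rng.shuffle(group_idx)
    groups = np.array(_GROUPS)[group_idx]
    stages = np.array(
        [_GROUP_STAGES[g][rng.integers(len(_GROUP_STAGES[g]))] for g in groups]
    )

    ids = [f"p{i:04d}" for i in range(n)]
    base = pd.DataFrame({"id": ids, "visit": "baseline", "time_years": 0.0})
    base["age"] = rng.normal(cfg.age_mean, cfg.age_sd, size=n)
    base["sex"] = np.where(rng.random(n) < cfg.female_fraction, "female", "male")
    base["education"] = np.clip(rng.normal(cfg.education_mean, cfg.education_sd, n), 6, 24)
    base["diagnosis"] = [
        ("CU", "MCI", "AD")[rng.choice(3, p=np.asarray(cfg.diagnosis_probs[g]) /
                                       np.sum(cfg.diagnosis_probs[g]))]
        for g in group_idx
    ]
    base["mmse"] = np.clip(
        np.round(
            rng.normal(
                np.asarray(cfg.mmse_group_means)[group_idx],
                np.asarray(cfg.mmse_group_sds)[group_idx],
            )
        ),
        0,
        30,
    ).astype(int)
    base["abeta_suvr"] = np.clip(
        rng.normal(
            np.asarray(cfg.abeta_group_means)[group_idx],
            np.asarray(cfg.abeta_group_sds)[group_idx],
        ),
        0.5,
        None,
    )

    # ROI SUVRs: abnormal exactly through the participant's true top stage
    for j, col in enumerate(BRAAK_SUVR_COLS):
        mean = cfg.roi_ref_mean[j] + cfg.abnormal_delta * (stages >= j + 1)
        base[col] = np.clip(rng.normal(mean, cfg.roi_ref_sd), 0.05, None)

    # baseline functional scores via correlated latents
    noise = _correlated_noise(rng, n, cfg.score_noise_sd, cfg.instrument_corr)
    raw = {}
    for k, instr in enumerate(INSTRUMENTS):
        z = np.asarray(cfg.baseline_effects[instr])[group_idx] + noise[:, k]
        b0, scale = cfg.score_scale[instr]
        raw[instr] = b0 + scale * z
    items = _quantize_scores(raw, rng)
    base[FAQ_COLS] = np.array(items["faq"])
    base[ECOG_COLS] = np.array(items["ecog"])
    base[CDRF_COLS] = np.array(items["cdrsbf"])
    base["truth_group"] = groups
    base["truth_stage"] = stages

    frames = [base]
    n_fu = int(round(cfg.followup_fraction * n))
    if n_fu > 0:
        fu_pos = np.sort(rng.choice(n, size=n_fu, replace=False))
        lo, hi = cfg.followup_years_bounds
        a = (lo - cfg.followup_years_mean) / cfg.followup_years_sd
        b = (hi - cfg.followup_years_mean) / cfg.followup_years_sd
        years = stats.truncnorm.rvs(
            a, b, loc=cfg.followup_years_mean, scale=cfg.followup_years_sd,
            size=n_fu, random_state=rng,
        )
        rnoise = _correlated_noise(rng, n_fu, cfg.rate_noise_sd, cfg.instrument_corr)
        scored = derive_scores(base)
        baseline_observed = {
            "faq": scored["faq_total"].to_numpy(dtype=float)[fu_pos],
            "ecog": scored["ecog_mean"].to_numpy(dtype=float)[fu_pos],
            "cdrsbf": scored["cdrsbf_total"].to_numpy(dtype=float)[fu_pos],
        }
        raw_fu = {}
        for k, instr in enumerate(INSTRUMENTS):
            rz = np.asarray(cfg.decline_effects[instr])[group_idx[fu_pos]] + rnoise[:, k]
            r0, rscale = cfg.rate_scale[instr]
            rate_raw = r0 + rscale * rz
            raw_fu[instr] = baseline_observed[instr] + rate_raw * years
        items_fu = _quantize_scores(raw_fu, rng)
        fu = pd.DataFrame(
            {"id": [ids[i] for i in fu_pos], "visit": "followup", "time_years": years}
        )
        fu["age"] = base["age"].to_numpy()[fu_pos] + years
        fu["sex"] = base["sex"].to_numpy()[fu_pos]
        fu[FAQ_COLS] = np.array(items_fu["faq"])
        fu[ECOG_COLS] = np.array(items_fu["ecog"])
        fu[CDRF_COLS] = np.array(items_fu["cdrsbf"])
        fu["truth_group"] = groups[fu_pos]
        fu["truth_stage"] = stages[fu_pos]
        frames.append(fu)

    data = pd.concat(frames, ignore_index=True)
    data = derive_scores(data)
    return CohortTable(data=data)


def make_braak_toy_masks(shape: tuple[int, int, int]) -> dict[str, np.ndarray]:
    """Three disjoint box masks standing in for Braak I–II / III–IV / V–VI ROIs."""
    nx, ny, nz = shape
    ys, ye = ny // 4, 3 * ny // 4
    zs, ze = nz // 4, 3 * nz // 4
    seg = nx // 6
    masks = {}
    for i, name in enumerate(("I-II", "III-IV", "V-VI")):
        m = np.zeros(shape, dtype=bool)
        x0 = (2 * i + 1) * seg - seg // 2
        m[x0 : x0 + seg, ys:ye, zs:ze] = True
        masks[name] = m
    return masks


def generate_images(
    score,
    shape: tuple[int, int, int] = (16, 16, 16),
    roi_masks: dict[str, np.ndarray] | None = None,
    amplitude: float = 1.0,
    noise_sd: float = 1.0,
    noise_fwhm_vox: float = 2.0,
    baseline: float = 1.0,
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
    seed: int = 0,
) -> tuple[VoxelImageSet, dict[str, np.ndarray]]:
    """Per-subject toy volumes with score-coupled signal inside Braak masks.

    Each subject's volume is ``baseline + amplitude * z(score) * union(masks)``
    plus stationary smooth Gaussian noise (periodic smoothing at
    ``noise_fwhm_vox`` FWHM, renormalised so the marginal SD is ``noise_sd``).
    """
    score = np.asarray(score, dtype=float)
    n = len(score)
    if roi_masks is None:
        roi_masks = make_braak_toy_masks(shape)
    for name, m in roi_masks.items():
        if m.shape != tuple(shape):
            raise ValueError(f"ROI mask {name!r} does not fit the grid {shape}")
    union = np.zeros(shape, dtype=bool)
    for m in roi_masks.values():
        union |= m

    rng = np.random.default_rng([seed, 2])
    sigma = noise_fwhm_vox / np.sqrt(8.0 * np.log(2.0))
    # energy of the periodic smoothing kernel, for exact renormalisation
    impulse = np.zeros(shape)
    impulse[0, 0, 0] = 1.0
    kernel = gaussian_filter(impulse, sigma, mode="wrap")
    energy = np.sqrt(np.sum(kernel**2))

    s = score - score.mean()
    sd = s.std(ddof=1)
    z = s / sd if sd > 0 else s
    vols = np.empty((n, *shape))
    for j in range(n):
        noise = gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
        vols[j] = baseline + amplitude * z[j] * union + noise_sd * noise / energy
    return VoxelImageSet(vols, voxel_size=voxel_size), roi_masks
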