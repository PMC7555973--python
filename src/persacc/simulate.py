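"""Synthetic judge x target x trait rating studies.

The generative model mirrors the assumptions the accuracy indices rest on.
Targets carry a criterion profile equal to a shared normative trait profile
plus target-specific distinctive deviations; judges observe the normative
profile perfectly and pick up a fraction of each target's distinctive
deviation proportional to their latent ability, corrupted by rating noise,
Likert rounding and rare acquaintance-driven missingness:

    criterion(t, a) = clip(normative(a) + delta(t, a), 1, 5)
    rating(j, t, a) = normative(a) + w_j * m(t) * delta(t, a) + eps
    w_j             = w0 + (1 - w0) * theta_j

where ``delta ~ N(0, sigma_distinctive^2)``, ``theta_j`` is the judge's
ability on [0, 1] (truncated normal), ``w0`` the baseline distinctive
pickup, ``m(t)`` the target's exposure-modality multiplier and ``eps ~
N(0, noise_sd^2)``.  Setting ability and ``w0`` to zero with a flat
normative profile yields an exact null in which every accuracy index has
expectation zero.

Latent truth (theta, delta) is returned alongside the observable tables so
recovery tests can correlate estimated accuracy with true ability; it is
never an input to scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import (
    MODALITIES,
    CriterionMatrix,
    JudgeRecord,
    RatingScale,
    RatingsCube,
)

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "generate_targets",
    "generate_judges",
    "generate_ratings",
    "simulate_study",
]

DEFAULT_TRAITS = (
    "openness",
    "conscientiousness",
    "extraversion",
    "agreeableness",
    "neuroticism",
    "cooperativeness",
    "empathy",
    "intelligence",
)

#: typical self-report profile on a 1-5 scale: agreeable/cooperative high,
#: neuroticism low — the normative component profile accuracy can exploit
DEFAULT_NORMATIVE = (3.4, 3.45, 3.35, 3.5, 3.25, 3.55, 3.5, 3.4)


@dataclass(frozen=True)
class SimulationConfig:
    """All generator parameters; the defaults emulate the reference design
    (121 judges, 30 targets in three modality blocks of 10, 8 traits)."""

    n_judges: int = 121
    traits: tuple[str, ...] = DEFAULT_TRAITS
    modalities: tuple[str, ...] = MODALITIES
    targets_per_modality: int = 10
    normative_criterion: tuple[float, ...] = DEFAULT_NORMATIVE
    sigma_distinctive: float = 0.7
    ability_mean: float = 0.12
    ability_sd: float = 0.15
    gender_ability_gap: float = 0.1  # added to female judges' ability mean
    prop_female_judges: float = 0.61
    modality_multipliers: tuple[float, ...] = (0.5, 1.0, 1.1)
    normative_bias_weight: float = 0.03  # w0: baseline distinctive pickup
    noise_sd: float = 1.2
    discretize: bool = True
    p_known: float = 34.0 / 3630.0
    era_mean: float = 65.0
    era_slope: float = 40.0  # percent-correct points per unit ability
    era_noise_sd: float = 8.0
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if len(self.normative_criterion) != len(self.traits):
            raise ValueError("normative_criterion length must match traits")
        if len(self.modality_multipliers) != len(self.modalities):
            raise ValueError("one modality multiplier per modality required")
        for name in ("sigma_distinctive", "ability_sd", "noise_sd", "era_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(m < 0 for m in self.modality_multipliers):
            raise ValueError("modality multipliers must be >= 0")
        for name in ("p_known", "prop_female_judges"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def n_targets(self) -> int:
        return self.targets_per_modality * len(self.modalities)

    def null(self) -> "SimulationConfig":
        """Signal-free variant: no distinctive pickup, flat normative profile.

        Under it every accuracy index has expectation zero.
        """
        return replace(
            self,
            ability_mean=0.0,
            ability_sd=0.0,
            gender_ability_gap=0.0,
            normative_bias_weight=0.0,
            normative_criterion=tuple(3.0 for _ in self.traits),
        )

    @classmethod
    def from_mapping(cls, d: Mapping, seed: int | None = None) -> "SimulationConfig":
        """Build from a plain dict (YAML/JSON config); lists become tuples."""
        kw = dict(d)
        for key in ("traits", "modalities", "normative_criterion", "modality_multipliers"):
            if key in kw and kw[key] is not None:
                kw[key] = tuple(kw[key])
        if seed is not None:
            kw["seed"] = seed
        unknown = set(kw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**kw)


@dataclass
class SimulatedStudy:
    """Observable tables plus the latent truth that produced them."""

    cube: RatingsCube
    criteria: CriterionMatrix
    judges: list[JudgeRecord]
    theta: pd.Series  # latent judge ability
    delta: pd.DataFrame  # latent target x trait distinctive deviations


def _rngs(cfg: SimulationConfig) -> tuple[np.random.Generator, ...]:
    # named substreams: adding judges must not perturb target draws
    kids = np.random.SeedSequence(cfg.seed).spawn(3)
    return tuple(np.random.default_rng(k) for k in kids)


def generate_targets(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[CriterionMatrix, pd.DataFrame]:
    """Draw target criterion profiles: normative base + distinctive deviation.

    Modality and gender are assigned in balanced blocks (half male, half
    female within each modality block).
    """
    if rng is None:
        rng = _rngs(cfg)[0]
    T, A = cfg.n_targets, len(cfg.traits)
    ids = [f"t{i:03d}" for i in range(T)]
    delta = rng.normal(0.0, cfg.sigma_distinctive, size=(T, A))
    base = np.asarray(cfg.normative_criterion)
    values = np.clip(base[None, :] + delta, 1.0, 5.0)
    modality = np.repeat(list(cfg.modalities), cfg.targets_per_modality)
    half = cfg.targets_per_modality // 2
    block = ["male"] * half + ["female"] * (cfg.targets_per_modality - half)
    gender = np.tile(block, len(cfg.modalities))
    idx = pd.Index(ids, name="target_id")
    crit = CriterionMatrix(
        pd.DataFrame(values, index=idx, columns=list(cfg.traits)),
        pd.Series(modality, index=idx),
        pd.Series(gender, index=idx),
    )
    return crit, pd.DataFrame(delta, index=idx, columns=list(cfg.traits))


def _truncnorm(rng, means, sd, lo, hi):
    means = np.asarray(means, dtype=float)
    if sd == 0:
        return np.clip(means, lo, hi)
    a, b = (lo - means) / sd, (hi - means) / sd
    return sps.truncnorm.rvs(
        a, b, loc=means, scale=sd, size=means.shape, random_state=rng
    )


def generate_judges(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[JudgeRecord], pd.Series]:
    """Draw judges: gender, latent ability theta, and external test scores.

    Female judges get a ``gender_ability_gap`` shift in mean ability.  The
    emotion-recognition score is a noisy linear readout of ability (clipped
    to the 0-100 percent scale); the understanding and trait-EI scores are
    drawn independently of ability.
    """
    if rng is None:
        rng = _rngs(cfg)[1]
    J = cfg.n_judges
    ids = [f"j{i:03d}" for i in range(J)]
    female = rng.random(J) < cfg.prop_female_judges
    means = np.where(female, cfg.ability_mean + cfg.gender_ability_gap, cfg.ability_mean)
    theta = _truncnorm(rng, means, cfg.ability_sd, 0.0, 1.0)
    era = cfg.era_mean + cfg.era_slope * (theta - theta.mean())
    era = np.clip(era + rng.normal(0.0, cfg.era_noise_sd, J), 0.0, 100.0)
    steu = np.clip(np.round(rng.normal(17.0, 3.0, J)), 0, 25)
    teique = np.clip(rng.normal(150.0, 20.0, J), 30, 210)
    judges = [
        JudgeRecord(
            judge_id=ids[i],
            gender="female" if female[i] else "male",
            era_score=float(era[i]),
            understanding_score=float(steu[i]),
            trait_ei_score=float(teique[i]),
        )
        for i in range(J)
    ]
    return judges, pd.Series(theta, index=ids, name="theta")


def generate_ratings(
    cfg: SimulationConfig,
    criteria: CriterionMatrix,
    judges: Sequence[JudgeRecord],
    theta: pd.Series,
    delta: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> RatingsCube:
    """Draw the ratings cube from the latent study state."""
    if rng is None:
        rng = _rngs(cfg)[2]
    J = len(judges)
    T, A = delta.shape
    base = np.asarray(cfg.normative_criterion)
    mult = dict(zip(cfg.modalities, cfg.modality_multipliers))
    m = criteria.modality.map(mult).to_numpy()  # (T,)
    w = cfg.normative_bias_weight + (1.0 - cfg.normative_bias_weight) * theta.to_numpy()
    raw = (
        base[None, None, :]
        + w[:, None, None] * m[None, :, None] * delta.to_numpy()[None, :, :]
        + rng.normal(0.0, cfg.noise_sd, size=(J, T, A))
    )
    raw = np.clip(raw, 1.0, 5.0)
    if cfg.discretize:
        raw = np.clip(np.round(raw), 1.0, 5.0)
    known = rng.random((J, T)) < cfg.p_known
    scale = RatingScale(1.0, 5.0, integer_grid=cfg.discretize)
    return RatingsCube(
        [j.judge_id for j in judges],
        list(delta.index),
        list(delta.columns),
        raw,
        known,
        scale,
    )


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Compose the three generators; identical seed => identical study."""
    r_targets, r_judges, r_ratings = _rngs(cfg)
    criteria, delta = generate_targets(cfg, r_targets)
    judges, theta = generate_judges(cfg, r_judges)
    cube = generate_ratings(cfg, criteria, judges, theta, delta, r_ratings)
    return SimulatedStudy(cube, criteria, judges, theta, delta)
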