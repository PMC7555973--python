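"""Reliability of the accuracy indices and disattenuated correlations.

Trait accuracy treats the 24 trait x modality Fisher-z cells as items of a
24-item scale and reports Cronbach's alpha across judges.  The profile
indices use a repeated random split-half of the targets: within each split
the per-target Fisher-z values are averaged per half, the two half-scores
are correlated across judges, stepped up with Spearman-Brown, and the mean
over splits is reported.  Reliabilities of the external ability tests are
user inputs (item-level data are outside this package's scope).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import JudgeRecord
from .scoring import AccuracyResult, CellCorrelations
from .stats import DEFAULT_CLIP, disattenuate, pearson_r, spearman_rho

__all__ = [
    "ReliabilityEstimate",
    "CorrectedCorrelation",
    "trait_accuracy_reliability",
    "profile_replicability",
    "corrected_correlation_table",
    "study_reliabilities",
]


@dataclass(frozen=True)
class ReliabilityEstimate:
    index: str
    method: str  # "alpha_over_components" | "split_half_spearman_brown"
    value: float
    n_components: int


@dataclass(frozen=True)
class CorrectedCorrelation:
    ability: str
    index: str
    raw_r: float
    rel_x: float
    rel_y: float
    corrected_r: float
    warning: bool  # |corrected_r| > 1


def trait_accuracy_reliability(
    cells: CellCorrelations, clip: float = DEFAULT_CLIP
) -> ReliabilityEstimate:
    """Cronbach's alpha over the judge x cell Fisher-z matrix (complete-case)."""
    from .stats import cronbach_alpha

    z = cells.z_matrix(clip=clip)
    if z.dropna().shape[0] < 2:
        raise ValueError("need at least 2 judges with complete cells")
    return ReliabilityEstimate(
        "trait", "alpha_over_components", cronbach_alpha(z.to_numpy()), z.shape[1]
    )


def profile_replicability(
    profile_z: pd.DataFrame,
    n_splits: int = 200,
    seed: int | None = None,
    index: str = "profile",
) -> ReliabilityEstimate:
    """Repeated split-half reliability of a judge x target Fisher-z matrix.

    Each split partitions the targets into two random halves; a judge's
    score in a half is the mean z over that half's defined entries.  The
    two half-scores are correlated across judges and stepped up with
    Spearman-Brown (2r / (1 + r)); the estimate is the mean over splits.
    A fixed seed makes the estimate deterministic.
    """
    if seed is None:
        raise ValueError("seed is mandatory for replicability")
    z = profile_z.to_numpy(dtype=float)
    J, T = z.shape
    if T < 4 or J < 3:
        raise ValueError("need at least 4 targets and 3 judges")
    rng = np.random.default_rng(seed)
    half = T // 2
    if half < 2:
        raise ValueError("fewer than 2 targets per half")
    vals = []
    for _ in range(n_splits):
        perm = rng.permutation(T)
        a, b = perm[:half], perm[half:]
        with np.errstate(invalid="ignore"):
            sa = np.nanmean(z[:, a], axis=1)
            sb = np.nanmean(z[:, b], axis=1)
        r = pearson_r(sa, sb).r
        if not math.isnan(r):
            vals.append(2.0 * r / (1.0 + r))
    value = float(np.mean(vals)) if vals else math.nan
    return ReliabilityEstimate(index, "split_half_spearman_brown", value, T)


def study_reliabilities(
    result: AccuracyResult, n_splits: int = 200, seed: int | None = None
) -> dict[str, ReliabilityEstimate]:
    """Reliability of each index: alpha for trait, split-half for profiles."""
    out = {"trait": trait_accuracy_reliability(result.cells)}
    for mode in ("overall", "distinctive"):
        out[mode] = profile_replicability(
            result.profiles[mode].z_matrix(), n_splits=n_splits, seed=seed, index=mode
        )
    return out


def corrected_correlation_table(
    result: AccuracyResult,
    judges: Sequence[JudgeRecord],
    index_reliabilities: Mapping[str, float],
    ability_reliabilities: Mapping[str, float],
) -> list[CorrectedCorrelation]:
    """Spearman correlations of index totals with ability scores, disattenuated.

    Abilities are the external test scores carried on :class:`JudgeRecord`
    (``era``, ``steu``, ``teique``).  Pairs lacking a reliability on either
    side are skipped.  Corrected values above 1 in magnitude are reported
    as-is with ``warning=True``.
    """
    ability_cols = {
        "era": [j.era_score for j in judges],
        "steu": [j.understanding_score for j in judges],
        "teique": [j.trait_ei_score for j in judges],
    }
    jid = [j.judge_id for j in judges]
    rows: list[CorrectedCorrelation] = []
    for ability, scores in ability_cols.items():
        rel_x = ability_reliabilities.get(ability)
        if rel_x is None:
            continue
        a = pd.Series(scores, index=jid, dtype=float)
        for index, ix in result.indices.items():
            rel_y = index_reliabilities.get(index)
            if rel_y is None:
                continue
            joined = pd.concat([a, ix.total], axis=1, join="inner").dropna()
            raw = spearman_rho(joined.iloc[:, 0], joined.iloc[:, 1]).r
            if math.isnan(raw):
                continue
            corrected = disattenuate(raw, rel_x, rel_y)
            rows.append(
                CorrectedCorrelation(
                    ability, index, raw, rel_x, rel_y, corrected, abs(corrected) > 1.0
                )
            )
    return rows
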