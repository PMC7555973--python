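"""Per-judge personality-judgment-accuracy indices.

Three indices are computed for every judge from a ratings cube and a
criterion matrix:

* **trait accuracy** — for each trait x modality cell, the Pearson
  correlation across that modality's targets between the judge's ratings
  and the targets' criterion scores; the cells (8 traits x 3 modalities =
  24 in the reference design) are Fisher-z averaged into one total.
* **overall profile accuracy** — for each target, the correlation across
  traits between the judge's rating profile and the target's criterion
  profile; the per-target correlations are Fisher-z averaged.
* **distinctive profile accuracy** — the same after subtracting the
  normative rating profile (grand mean rating per trait over all judges
  and targets) from ratings and the normative criterion profile (mean per
  trait over all targets) from criteria, isolating sensitivity to each
  target's unique trait pattern.

Aggregates are missing unless at least ``min_prop`` (default 80%) of their
component correlations are defined; undefined components (zero variance or
fewer than 3 pairs) count against availability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import CriterionMatrix, JudgeRecord, RatingsCube
from .stats import (
    DEFAULT_CLIP,
    DEFAULT_MIN_PROP,
    AggregateScore,
    CorrelationValue,
    aggregate_z,
    pearson_r,
)

__all__ = [
    "CellCorrelations",
    "ProfileCorrelations",
    "NormativeProfiles",
    "IndexScores",
    "AccuracyResult",
    "cell_correlations",
    "trait_accuracy",
    "normative_profiles",
    "profile_accuracy",
    "gender_pairing_accuracy",
    "score_study",
]

INDEX_NAMES = ("trait", "overall", "distinctive")


@dataclass
class CellCorrelations:
    """Per-judge trait x modality correlations (r nan where undefined)."""

    judges: list[str]
    traits: list[str]
    modalities: list[str]
    r: np.ndarray  # (J, A, M)
    n: np.ndarray  # (J, A, M) pair counts

    def judge_cells(self, i: int) -> list[CorrelationValue]:
        """The judge's cells flattened trait-major (24 in the full design)."""
        return [
            CorrelationValue(float(self.r[i, a, m]), int(self.n[i, a, m]))
            for a in range(len(self.traits))
            for m in range(len(self.modalities))
        ]

    def z_matrix(self, clip: float = DEFAULT_CLIP) -> pd.DataFrame:
        """Judges x cells Fisher-z matrix (nan for undefined cells)."""
        with np.errstate(invalid="ignore"):
            z = np.arctanh(np.clip(self.r, -clip, clip))
        cols = [f"{a}:{m}" for a in self.traits for m in self.modalities]
        J = len(self.judges)
        return pd.DataFrame(z.reshape(J, -1), index=self.judges, columns=cols)


@dataclass
class ProfileCorrelations:
    """Per-judge, per-target profile correlations across traits."""

    judges: list[str]
    targets: list[str]
    mode: str  # "overall" or "distinctive"
    r: np.ndarray  # (J, T)
    n: np.ndarray  # (J, T)

    def z_matrix(self, clip: float = DEFAULT_CLIP) -> pd.DataFrame:
        with np.errstate(invalid="ignore"):
            z = np.arctanh(np.clip(self.r, -clip, clip))
        return pd.DataFrame(z, index=self.judges, columns=self.targets)


@dataclass
class NormativeProfiles:
    """Mean trait profiles: of ratings (all judges x targets) and criteria."""

    normative_rating: pd.Series
    normative_criterion: pd.Series


@dataclass
class IndexScores:
    """One accuracy index: per-judge totals plus subscores.

    ``total`` holds the back-transformed score (nan where the availability
    rule failed); ``total_z`` the mean Fisher z; ``subscores`` columns are
    ``trait:<name>`` and/or ``modality:<name>`` back-transformed aggregates.
    """

    name: str
    total: pd.Series
    total_z: pd.Series
    n_available: pd.Series
    n_components: int
    subscores: pd.DataFrame


@dataclass
class AccuracyResult:
    """All indices, subscores and audit detail for one scored dataset."""

    indices: dict[str, IndexScores]
    cells: CellCorrelations
    profiles: dict[str, ProfileCorrelations]
    normative: NormativeProfiles
    by_target_gender: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def per_judge(self) -> pd.DataFrame:
        """Wide per-judge table: totals, availability, subscores."""
        frames = {}
        for name, ix in self.indices.items():
            frames[f"{name}_accuracy"] = ix.total
            frames[f"{name}_accuracy_z"] = ix.total_z
            frames[f"{name}_n_available"] = ix.n_available
        out = pd.DataFrame(frames)
        for name, ix in self.indices.items():
            sub = ix.subscores.add_prefix(f"{name}_accuracy/")
            out = out.join(sub)
        if not self.by_target_gender.empty:
            out = out.join(self.by_target_gender)
        return out


def _agg(cells: Sequence[CorrelationValue], min_prop, clip) -> AggregateScore | None:
    return aggregate_z(cells, min_prop=min_prop, clip=clip)


def _unpack(agg: AggregateScore | None) -> tuple[float, float, int]:
    if agg is None:
        return math.nan, math.nan, 0
    return agg.r_back, agg.mean_z, agg.n_available


def cell_correlations(
    cube: RatingsCube,
    crit: CriterionMatrix,
    target_mask: np.ndarray | None = None,
) -> CellCorrelations:
    """Correlate each judge's ratings with criteria per trait x modality.

    ``target_mask`` optionally restricts to a subset of targets (used for
    gender-pairing subscores).  Cells with fewer than 3 usable targets or
    a constant rating vector are undefined.
    """
    vals = cube.values()
    J, T, A = vals.shape
    modalities = [m for m in pd.unique(crit.modality) if True]
    mod_arr = crit.modality.to_numpy()
    if target_mask is None:
        target_mask = np.ones(T, dtype=bool)
    critv = crit.values.to_numpy()
    r = np.full((J, A, len(modalities)), np.nan)
    n = np.zeros((J, A, len(modalities)), dtype=int)
    for mi, mod in enumerate(modalities):
        tsel = (mod_arr == mod) & target_mask
        cv = critv[tsel]  # (Tm, A)
        for j in range(J):
            rv = vals[j][tsel]  # (Tm, A)
            for a in range(A):
                c = pearson_r(rv[:, a], cv[:, a])
                r[j, a, mi] = c.r
                n[j, a, mi] = c.n
    return CellCorrelations(list(cube.judges), list(cube.traits), modalities, r, n)


def trait_accuracy(
    cells: CellCorrelations,
    min_prop: float = DEFAULT_MIN_PROP,
    clip: float = DEFAULT_CLIP,
) -> IndexScores:
    """Aggregate trait x modality cells into totals and subscores.

    The total averages all cells; per-trait subscores average that trait's
    modality cells; per-modality subscores average that modality's trait
    cells.  Every aggregate applies the same availability rule.
    """
    J = len(cells.judges)
    A, M = len(cells.traits), len(cells.modalities)
    total = np.full(J, np.nan)
    total_z = np.full(J, np.nan)
    avail = np.zeros(J, dtype=int)
    sub_cols = [f"trait:{a}" for a in cells.traits] + [
        f"modality:{m}" for m in cells.modalities
    ]
    subs = np.full((J, A + M), np.nan)
    for j in range(J):
        cv = cells.judge_cells(j)
        total[j], total_z[j], avail[j] = _unpack(_agg(cv, min_prop, clip))
        for a in range(A):
            sel = [cv[a * M + m] for m in range(M)]
            subs[j, a], _, _ = _unpack(_agg(sel, min_prop, clip))
        for m in range(M):
            sel = [cv[a * M + m] for a in range(A)]
            subs[j, A + m], _, _ = _unpack(_agg(sel, min_prop, clip))
    ix = cells.judges
    return IndexScores(
        "trait",
        pd.Series(total, index=ix),
        pd.Series(total_z, index=ix),
        pd.Series(avail, index=ix),
        A * M,
        pd.DataFrame(subs, index=ix, columns=sub_cols),
    )


def normative_profiles(
    cube: RatingsCube, crit: CriterionMatrix, exclude_judge: str | None = None
) -> NormativeProfiles:
    """Grand-mean trait profiles over the *full* target set.

    The normative rating profile is the mean present rating per trait over
    all judges and all targets (optionally leaving one judge out); the
    normative criterion profile is the mean criterion per trait over all
    targets.  Both always use every target, never a modality or gender
    subset.
    """
    vals = cube.values()
    if exclude_judge is not None:
        keep = [i for i, j in enumerate(cube.judges) if j != exclude_judge]
        vals = vals[keep]
    with np.errstate(invalid="ignore"):
        mean_rating = np.nanmean(vals.reshape(-1, vals.shape[2]), axis=0)
    if np.isnan(mean_rating).any():
        bad = cube.traits[int(np.isnan(mean_rating).argmax())]
        raise ValueError(f"trait {bad!r} has no present ratings")
    return NormativeProfiles(
        pd.Series(mean_rating, index=cube.traits),
        crit.values.mean(axis=0),
    )


def _profile_corrs(
    vals: np.ndarray,
    critv: np.ndarray,
    judges: list[str],
    targets: list[str],
    mode: str,
    rating_offset: np.ndarray,
    criterion_offset: np.ndarray,
) -> ProfileCorrelations:
    J, T, A = vals.shape
    r = np.full((J, T), np.nan)
    n = np.zeros((J, T), dtype=int)
    cmat = critv - criterion_offset  # (T, A)
    for j in range(J):
        rmat = vals[j] - rating_offset
        for t in range(T):
            c = pearson_r(rmat[t], cmat[t])
            r[j, t] = c.r
            n[j, t] = c.n
    return ProfileCorrelations(judges, targets, mode, r, n)


def profile_accuracy(
    cube: RatingsCube,
    crit: CriterionMatrix,
    mode: str,
    min_prop: float = DEFAULT_MIN_PROP,
    clip: float = DEFAULT_CLIP,
    normative: NormativeProfiles | None = None,
    target_mask: np.ndarray | None = None,
    exclude_self: bool = False,
) -> tuple[IndexScores, ProfileCorrelations]:
    """Per-target profile correlations aggregated per judge.

    ``mode`` is ``"overall"`` (raw profiles) or ``"distinctive"`` (normative
    profiles subtracted from both sides).  The distinctive mode uses
    full-sample normative profiles even when ``target_mask`` restricts the
    targets being scored.  ``exclude_self`` recomputes the normative rating
    profile leaving out the judge being scored.
    """
    if mode not in ("overall", "distinctive"):
        raise ValueError(f"unknown mode {mode!r}")
    vals = cube.values()
    J, T, A = vals.shape
    critv = crit.values.to_numpy()
    zero = np.zeros(A)
    if mode == "distinctive":
        if normative is None:
            normative = normative_profiles(cube, crit)
        crit_off = normative.normative_criterion.to_numpy()
    else:
        crit_off = zero

    if mode == "distinctive" and exclude_self:
        parts = []
        for j in cube.judges:
            np_j = normative_profiles(cube, crit, exclude_judge=j)
            idx = cube.judges.index(j)
            parts.append(
                _profile_corrs(
                    vals[idx : idx + 1],
                    critv,
                    [j],
                    list(cube.targets),
                    mode,
                    np_j.normative_rating.to_numpy(),
                    crit_off,
                )
            )
        profiles = ProfileCorrelations(
            list(cube.judges),
            list(cube.targets),
            mode,
            np.vstack([p.r for p in parts]),
            np.vstack([p.n for p in parts]),
        )
    else:
        rating_off = (
            normative.normative_rating.to_numpy() if mode == "distinctive" else zero
        )
        profiles = _profile_corrs(
            vals, critv, list(cube.judges), list(cube.targets), mode, rating_off, crit_off
        )

    if target_mask is None:
        target_mask = np.ones(T, dtype=bool)
    mod_arr = crit.modality.to_numpy()
    modalities = list(pd.unique(crit.modality))
    sub_cols = [f"modality:{m}" for m in modalities]
    total = np.full(J, np.nan)
    total_z = np.full(J, np.nan)
    avail = np.zeros(J, dtype=int)
    subs = np.full((J, len(modalities)), np.nan)
    tsel_all = np.nonzero(target_mask)[0]
    for j in range(J):
        comps = [
            CorrelationValue(float(profiles.r[j, t]), int(profiles.n[j, t]))
            for t in tsel_all
        ]
        total[j], total_z[j], avail[j] = _unpack(_agg(comps, min_prop, clip))
        for mi, mod in enumerate(modalities):
            sel = [
                CorrelationValue(float(profiles.r[j, t]), int(profiles.n[j, t]))
                for t in tsel_all
                if mod_arr[t] == mod
            ]
            if sel:
                subs[j, mi], _, _ = _unpack(_agg(sel, min_prop, clip))
    ix = list(cube.judges)
    scores = IndexScores(
        mode,
        pd.Series(total, index=ix),
        pd.Series(total_z, index=ix),
        pd.Series(avail, index=ix),
        int(target_mask.sum()),
        pd.DataFrame(subs, index=ix, columns=sub_cols),
    )
    return scores, profiles


def _restricted_totals(
    cube: RatingsCube,
    crit: CriterionMatrix,
    normative: NormativeProfiles,
    target_mask: np.ndarray,
    min_prop: float,
    clip: float,
) -> pd.DataFrame:
    """Totals for the three indices over a target subset (per judge)."""
    cells = cell_correlations(cube, crit, target_mask=target_mask)
    ta = trait_accuracy(cells, min_prop, clip)
    ov, _ = profile_accuracy(
        cube, crit, "overall", min_prop, clip, target_mask=target_mask
    )
    di, _ = profile_accuracy(
        cube,
        crit,
        "distinctive",
        min_prop,
        clip,
        normative=normative,
        target_mask=target_mask,
    )
    return pd.DataFrame(
        {"trait": ta.total, "overall": ov.total, "distinctive": di.total}
    )


def gender_pairing_accuracy(
    cube: RatingsCube,
    crit: CriterionMatrix,
    judges: Sequence[JudgeRecord],
    min_prop: float = DEFAULT_MIN_PROP,
    clip: float = DEFAULT_CLIP,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Accuracy recomputed per target gender, summarized by judge gender.

    Returns ``(per_judge, summary)``: per-judge totals restricted to male
    and to female targets (columns ``<index>/targets_<gender>``), and the
    judge-gender x target-gender table of means, SDs and Ns for each index.
    Distinctive scoring keeps the full-sample normative profiles.
    """
    normative = normative_profiles(cube, crit)
    gend = crit.gender.to_numpy()
    frames = []
    for tg in pd.unique(crit.gender):
        mask = gend == tg
        tot = _restricted_totals(cube, crit, normative, mask, min_prop, clip)
        tot.columns = [f"{c}/targets_{tg}" for c in tot.columns]
        frames.append(tot)
    per_judge = pd.concat(frames, axis=1)

    jg = pd.Series({j.judge_id: j.gender for j in judges}).reindex(per_judge.index)
    rows = []
    for judge_gender in jg.dropna().unique():
        members = per_judge.index[jg == judge_gender]
        for tg in pd.unique(crit.gender):
            for index in INDEX_NAMES:
                col = f"{index}/targets_{tg}"
                v = per_judge.loc[members, col].dropna()
                rows.append(
                    {
                        "judge_gender": judge_gender,
                        "target_gender": tg,
                        "index": index,
                        "mean": v.mean() if len(v) else math.nan,
                        "sd": v.std(ddof=1) if len(v) > 1 else math.nan,
                        "n": len(v),
                    }
                )
    return per_judge, pd.DataFrame(rows)


def score_study(
    cube: RatingsCube,
    crit: CriterionMatrix,
    judges: Sequence[JudgeRecord] | None = None,
    min_prop: float = DEFAULT_MIN_PROP,
    clip: float = DEFAULT_CLIP,
    exclude_self: bool = False,
) -> AccuracyResult:
    """Compute every accuracy index and subscore for a dataset."""
    cells = cell_correlations(cube, crit)
    normative = normative_profiles(cube, crit)
    ta = trait_accuracy(cells, min_prop, clip)
    ov, ov_prof = profile_accuracy(cube, crit, "overall", min_prop, clip)
    di, di_prof = profile_accuracy(
        cube,
        crit,
        "distinctive",
        min_prop,
        clip,
        normative=normative,
        exclude_self=exclude_self,
    )
    by_tg = pd.DataFrame(index=pd.Index(cube.judges))
    if judges is not None and crit.gender.nunique() > 1:
        by_tg, _ = gender_pairing_accuracy(cube, crit, judges, min_prop, clip)
        by_tg.columns = [c.replace("/", "_accuracy/", 1) for c in by_tg.columns]
    return AccuracyResult(
        {"trait": ta, "overall": ov, "distinctive": di},
        cells,
        {"overall": ov_prof, "distinctive": di_prof},
        normative,
        by_tg,
    )
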