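"""Domain types and tabular I/O for judge x target x trait rating studies.

The study design: each judge rates every target on a fixed ordered set of
traits using a Likert scale (1-5 by default).  Targets carry criterion
("true") scores on the same traits, standardized to the rating scale, plus
an exposure modality (photo, mute video, audio video) and a gender label.
Judges may be acquainted with some targets; such ratings are flagged and
treated as missing by every scoring operation.

External CSV contracts (fixed column names):

* ratings: ``judge_id,target_id,trait,rating,known``
* criteria: ``target_id,trait,raw_value``
* target metadata: ``target_id,modality,gender``
* judges: ``judge_id,gender,era,steu,teique``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import math

import numpy as np
import pandas as pd

MODALITIES = ("photo", "mute_video", "audio_video")


class DataError(ValueError):
    """Base class for dataset construction/validation failures."""


class FormatError(DataError):
    """Malformed value in an input table (non-numeric, off the rating grid)."""


class DuplicationError(DataError):
    """Duplicate (judge, target, trait) key in a ratings table."""


class SchemaError(DataError):
    """Label or column mismatch between tables."""


@dataclass(frozen=True)
class TraitScale:
    """Theoretical range of the instrument a criterion trait was measured on."""

    name: str
    raw_min: float
    raw_max: float

    def __post_init__(self):
        if not self.raw_max > self.raw_min:
            raise ValueError(f"raw_max must exceed raw_min for {self.name!r}")


@dataclass(frozen=True)
class RatingScale:
    """Judges' response scale; default a 5-point integer Likert grid."""

    minimum: float = 1.0
    maximum: float = 5.0
    integer_grid: bool = True

    def valid(self, v: float) -> bool:
        if not np.isfinite(v) or not (self.minimum <= v <= self.maximum):
            return False
        if self.integer_grid and float(v) != int(v):
            return False
        return True


@dataclass
class RatingsCube:
    """Judges x targets x traits ratings with explicit missingness.

    ``ratings[j, t, a]`` is nan where absent; ``known[j, t]`` marks judge-
    target acquaintance.  ``values()`` returns ratings with acquainted
    targets masked out — the only view scoring code should consume.
    """

    judges: list[str]
    targets: list[str]
    traits: list[str]
    ratings: np.ndarray  # (J, T, A) float, nan = missing
    known: np.ndarray  # (J, T) bool
    scale: RatingScale = field(default_factory=RatingScale)

    def __post_init__(self):
        J, T, A = len(self.judges), len(self.targets), len(self.traits)
        if self.ratings.shape != (J, T, A):
            raise SchemaError(f"ratings shape {self.ratings.shape} != {(J, T, A)}")
        if self.known.shape != (J, T):
            raise SchemaError(f"known shape {self.known.shape} != {(J, T)}")

    def values(self) -> np.ndarray:
        """Ratings with known (acquainted) judge-target pairs set to nan."""
        out = self.ratings.copy()
        out[self.known, :] = np.nan
        return out

    def to_long(self) -> pd.DataFrame:
        """Long-format table of present cells (before the known-filter)."""
        j, t, a = np.nonzero(~np.isnan(self.ratings))
        return pd.DataFrame(
            {
                "judge_id": np.asarray(self.judges, dtype=object)[j],
                "target_id": np.asarray(self.targets, dtype=object)[t],
                "trait": np.asarray(self.traits, dtype=object)[a],
                "rating": self.ratings[j, t, a],
                "known": self.known[j, t],
            }
        )


@dataclass
class CriterionMatrix:
    """Targets x traits criterion scores on the rating scale, plus metadata."""

    values: pd.DataFrame  # index = target_id, columns = traits, no missing
    modality: pd.Series  # per target, in MODALITIES
    gender: pd.Series  # per target, e.g. male/female

    def __post_init__(self):
        if self.values.isna().any().any():
            raise DataError("criterion matrix contains missing values")
        for s in (self.modality, self.gender):
            if not s.index.equals(self.values.index):
                raise SchemaError("metadata index does not match criterion targets")
        bad = set(self.modality) - set(MODALITIES)
        if bad:
            raise SchemaError(f"unknown modality labels: {sorted(bad)}")

    @property
    def targets(self) -> list[str]:
        return list(self.values.index)

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class JudgeRecord:
    """Per-judge metadata and external ability-test scores (may be missing)."""

    judge_id: str
    gender: str = "unknown"
    era_score: float = math.nan  # percent correct, 0-100
    understanding_score: float = math.nan  # count correct
    trait_ei_score: float = math.nan  # questionnaire sum

    def __post_init__(self):
        e = self.era_score
        if not math.isnan(e) and not (0.0 <= e <= 100.0):
            raise DataError(f"era_score out of [0, 100] for {self.judge_id}: {e}")


@dataclass
class ValidationReport:
    passed: bool
    issues: list[str]
    missing_cells_per_judge: dict[str, int]
    uncovered_targets: list[str]

    def __str__(self) -> str:
        head = "PASS" if self.passed else "FAIL"
        lines = [f"dataset validation: {head}"] + [f"  - {i}" for i in self.issues]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path, delimiter: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=delimiter, dtype={"judge_id": str, "target_id": str})


def read_ratings_table(
    path,
    schema: Mapping[str, str] | None = None,
    scale: RatingScale | None = None,
    delimiter: str = ",",
) -> RatingsCube:
    """Read a long-format ratings CSV into a :class:`RatingsCube`.

    ``schema`` maps the canonical column names (judge_id, target_id, trait,
    rating, known) to the file's actual columns.  The ``known`` column is
    optional.  Absent (judge, target, trait) rows become missing cells;
    duplicate keys are an error.
    """
    scale = scale or RatingScale()
    df = _read_table(path, delimiter)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    required = {"judge_id", "target_id", "trait", "rating"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise SchemaError(f"ratings table lacks columns: {sorted(missing_cols)}")
    if "known" not in df.columns:
        df["known"] = False
    df["known"] = df["known"].fillna(False).astype(bool)

    dup = df.duplicated(subset=["judge_id", "target_id", "trait"])
    if dup.any():
        row = df[dup].iloc[0]
        raise DuplicationError(
            f"duplicate (judge,target,trait) key: "
            f"({row.judge_id}, {row.target_id}, {row.trait})"
        )
    ratings_num = pd.to_numeric(df["rating"], errors="coerce")
    for i, (raw, v) in enumerate(zip(df["rating"], ratings_num)):
        if pd.isna(v) or not scale.valid(float(v)):
            raise FormatError(f"row {i}: invalid rating {raw!r} for scale {scale}")
    df["rating"] = ratings_num.astype(float)

    judges = sorted(df["judge_id"].unique())
    targets = sorted(df["target_id"].unique())
    traits = sorted(df["trait"].unique())
    jix = {v: i for i, v in enumerate(judges)}
    tix = {v: i for i, v in enumerate(targets)}
    aix = {v: i for i, v in enumerate(traits)}
    cube = np.full((len(judges), len(targets), len(traits)), np.nan)
    known = np.zeros((len(judges), len(targets)), dtype=bool)
    j = df["judge_id"].map(jix).to_numpy()
    t = df["target_id"].map(tix).to_numpy()
    a = df["trait"].map(aix).to_numpy()
    cube[j, t, a] = df["rating"].to_numpy()
    known[j[df["known"].to_numpy()], t[df["known"].to_numpy()]] = True
    return RatingsCube(judges, targets, traits, cube, known, scale)


def write_ratings_table(cube: RatingsCube, path) -> None:
    cube.to_long().to_csv(path, index=False)


def read_criteria_tables(
    criteria_path, target_meta_path, delimiter: str = ","
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read raw criteria (long) and target metadata; returns (wide raw, meta)."""
    crit = _read_table(criteria_path, delimiter)
    meta = _read_table(target_meta_path, delimiter)
    for col in ("target_id", "trait", "raw_value"):
        if col not in crit.columns:
            raise SchemaError(f"criteria table lacks column {col!r}")
    for col in ("target_id", "modality", "gender"):
        if col not in meta.columns:
            raise SchemaError(f"target metadata lacks column {col!r}")
    wide = crit.pivot(index="target_id", columns="trait", values="raw_value")
    if wide.isna().any().any():
        raise DataError("criteria table has missing target x trait entries")
    return wide, meta.set_index("target_id")


def standardize_criteria(
    raw: pd.DataFrame,
    scales: Mapping[str, TraitScale],
    modality: pd.Series | None = None,
    gender: pd.Series | None = None,
) -> CriterionMatrix:
    """Affine-map raw instrument scores onto the common 1-5 scale.

    Each trait column is mapped by ``1 + 4 * (x - raw_min) / (raw_max -
    raw_min)`` using the instrument's *theoretical* range, so the mapping
    does not depend on which targets were sampled.  Raw values outside the
    instrument range are an error.
    """
    out = {}
    for trait in raw.columns:
        if trait not in scales:
            raise SchemaError(f"no TraitScale supplied for trait {trait!r}")
        sc = scales[trait]
        x = raw[trait].astype(float)
        if ((x < sc.raw_min) | (x > sc.raw_max)).any():
            bad = raw.index[(x < sc.raw_min) | (x > sc.raw_max)][0]
            raise DataError(
                f"raw value for {trait!r} outside [{sc.raw_min}, {sc.raw_max}] "
                f"at target {bad}"
            )
        out[trait] = 1.0 + 4.0 * (x - sc.raw_min) / (sc.raw_max - sc.raw_min)
    values = pd.DataFrame(out, index=raw.index)
    if modality is None:
        modality = pd.Series("photo", index=values.index)
    if gender is None:
        gender = pd.Series("unknown", index=values.index)
    return CriterionMatrix(values, modality.loc[values.index], gender.loc[values.index])


def read_judges_table(path, delimiter: str = ",") -> list[JudgeRecord]:
    df = _read_table(path, delimiter)
    if "judge_id" not in df.columns:
        raise SchemaError("judges table lacks column 'judge_id'")

    def get(row, col):
        v = row.get(col, math.nan)
        return float(v) if pd.notna(v) else math.nan

    return [
        JudgeRecord(
            judge_id=str(row["judge_id"]),
            gender=str(row.get("gender", "unknown")),
            era_score=get(row, "era"),
            understanding_score=get(row, "steu"),
            trait_ei_score=get(row, "teique"),
        )
        for _, row in df.iterrows()
    ]


def write_judges_table(judges: Sequence[JudgeRecord], path) -> None:
    pd.DataFrame(
        {
            "judge_id": [j.judge_id for j in judges],
            "gender": [j.gender for j in judges],
            "era": [j.era_score for j in judges],
            "steu": [j.understanding_score for j in judges],
            "teique": [j.trait_ei_score for j in judges],
        }
    ).to_csv(path, index=False)


def write_criteria_tables(crit: CriterionMatrix, criteria_path, meta_path) -> None:
    long = crit.values.reset_index(names="target_id").melt(
        id_vars="target_id", var_name="trait", value_name="raw_value"
    )
    long.to_csv(criteria_path, index=False)
    pd.DataFrame(
        {
            "target_id": crit.targets,
            "modality": crit.modality.values,
            "gender": crit.gender.values,
        }
    ).to_csv(meta_path, index=False)


# ---------------------------------------------------------------------------
# validation


def validate_dataset(
    cube: RatingsCube,
    crit: CriterionMatrix,
    judges: Sequence[JudgeRecord] | None = None,
) -> ValidationReport:
    """Cross-check labels and coverage between ratings, criteria and judges.

    The dataset passes iff trait/target labels align between cube and
    criteria and every judge has at least one usable rating after the
    known-target filter.  Missing-cell counts include cells excluded by
    the acquaintance filter.
    """
    issues: list[str] = []
    if list(cube.traits) != list(crit.traits):
        raise SchemaError(
            f"trait labels differ: cube {cube.traits} vs criteria {crit.traits}"
        )
    if list(cube.targets) != list(crit.targets):
        raise SchemaError("target labels differ between cube and criteria")
    if judges is not None:
        cube_j = set(cube.judges)
        meta_j = {j.judge_id for j in judges}
        extra = cube_j - meta_j
        if extra:
            issues.append(f"{len(extra)} judges in cube without metadata")

    vals = cube.values()
    present = ~np.isnan(vals)
    n_cells = len(cube.targets) * len(cube.traits)
    missing_per_judge = {
        j: int(n_cells - present[i].sum()) for i, j in enumerate(cube.judges)
    }
    uncovered = [
        t for i, t in enumerate(cube.targets) if not present[:, i, :].any()
    ]
    for t in uncovered:
        issues.append(f"target {t} has zero coverage")
    no_data = [j for i, j in enumerate(cube.judges) if not present[i].any()]
    for j in no_data:
        issues.append(f"judge {j} has no usable ratings")
    passed = not uncovered and not no_data
    return ValidationReport(passed, issues, missing_per_judge, uncovered)
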