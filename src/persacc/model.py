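"""Model/Results interface over the scoring, reliability and test layers.

:class:`JudgmentAccuracyModel` is constructed from the study tables
(ratings cube, criterion matrix, judge records); ``fit()`` runs the whole
analysis — indices and subscores per judge, one-sample t tests against
chance, Spearman intercorrelations with the external ability measures and
judge gender, gender-pairing means with pooled t tests, reliabilities, and
attenuation-corrected correlations — and returns a
:class:`JudgmentAccuracyResults` whose ``summary()`` renders the report
tables and whose ``report()`` is a full-precision JSON-serializable dict.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import data_model as dm
from .data_model import CriterionMatrix, JudgeRecord, RatingsCube, TraitScale
from .reliability import (
    CorrectedCorrelation,
    corrected_correlation_table,
    study_reliabilities,
)
from .scoring import INDEX_NAMES, AccuracyResult, gender_pairing_accuracy, score_study
from .stats import (
    DEFAULT_CLIP,
    DEFAULT_MIN_PROP,
    one_sample_t,
    pooled_two_sample_t,
    spearman_rho,
)

__all__ = ["JudgmentAccuracyModel", "JudgmentAccuracyResults", "render_report"]

#: published internal consistencies of the external instruments; these are
#: inputs to disattenuation, never recomputed here (no item-level data)
DEFAULT_ABILITY_RELIABILITIES = {"era": 0.89, "steu": 0.78, "teique": 0.93}

ABILITY_FIELDS = {
    "era": "era_score",
    "steu": "understanding_score",
    "teique": "trait_ei_score",
}


class JudgmentAccuracyModel:
    """Personality-judgment-accuracy analysis of one rating study.

    Parameters
    ----------
    cube : RatingsCube
        Judges x targets x traits Likert ratings (acquainted targets flagged).
    criteria : CriterionMatrix
        Targets x traits criterion scores on the rating scale, with
        modality and target-gender metadata.
    judges : sequence of JudgeRecord, optional
        Judge metadata and external ability scores; without it the gender
        and ability blocks of the report are skipped.
    min_prop : float
        Minimum proportion of defined component correlations an aggregate
        needs (default 0.8: at least 20 of 24 cells, 24 of 30 profiles).
    clip : float
        |r| clip before the Fisher transform.
    exclude_self : bool
        Leave the scored judge out of the normative rating profile.
    """

    def __init__(
        self,
        cube: RatingsCube,
        criteria: CriterionMatrix,
        judges: Sequence[JudgeRecord] | None = None,
        min_prop: float = DEFAULT_MIN_PROP,
        clip: float = DEFAULT_CLIP,
        exclude_self: bool = False,
    ):
        report = dm.validate_dataset(cube, criteria, judges)
        if not report.passed:
            raise dm.DataError(str(report))
        self.cube = cube
        self.criteria = criteria
        self.judges = list(judges) if judges is not None else None
        self.min_prop = min_prop
        self.clip = clip
        self.exclude_self = exclude_self
        self.validation = report

    @classmethod
    def from_csv(
        cls,
        ratings_path,
        criteria_path,
        target_meta_path,
        judges_path=None,
        scales: Mapping[str, TraitScale] | None = None,
        **kwargs,
    ) -> "JudgmentAccuracyModel":
        """Build the model from the four CSV contracts.

        ``scales`` gives each trait's instrument range for criterion
        standardization; by default raw values are assumed to be on the
        1-5 rating scale already (identity mapping).
        """
        cube = dm.read_ratings_table(ratings_path)
        raw, meta = dm.read_criteria_tables(criteria_path, target_meta_path)
        missing_t = set(cube.targets) - set(raw.index)
        if missing_t:
            raise dm.SchemaError(
                f"{len(missing_t)} rated targets absent from criteria"
            )
        missing_a = set(cube.traits) - set(raw.columns)
        if missing_a:
            raise dm.SchemaError(f"traits absent from criteria: {sorted(missing_a)}")
        if scales is None:
            scales = {t: TraitScale(t, 1.0, 5.0) for t in raw.columns}
        crit = dm.standardize_criteria(
            raw, scales, modality=meta["modality"], gender=meta["gender"]
        )
        # align axis order with the cube
        crit = CriterionMatrix(
            crit.values.loc[cube.targets, cube.traits],
            crit.modality.loc[cube.targets],
            crit.gender.loc[cube.targets],
        )
        judges = dm.read_judges_table(judges_path) if judges_path else None
        return cls(cube, crit, judges, **kwargs)

    def fit(
        self,
        reliability_splits: int = 200,
        reliability_seed: int = 0,
        ability_reliabilities: Mapping[str, float] | None = None,
    ) -> "JudgmentAccuracyResults":
        """Run the full analysis and return the results object."""
        warnings: list[str] = []
        acc = score_study(
            self.cube,
            self.criteria,
            judges=self.judges,
            min_prop=self.min_prop,
            clip=self.clip,
            exclude_self=self.exclude_self,
        )
        measures = self._measure_table(acc, warnings)
        ttests = {
            name: one_sample_t(acc.indices[name].total, 0.0)
            for name in INDEX_NAMES
            if acc.indices[name].total.notna().sum() >= 2
        }
        spearman = self._spearman_matrix(measures)
        pairing_summary, gender_tests = self._gender_blocks(acc, warnings)
        reliabilities = study_reliabilities(
            acc, n_splits=reliability_splits, seed=reliability_seed
        )
        corrected = self._corrected(acc, reliabilities, ability_reliabilities, warnings)
        return JudgmentAccuracyResults(
            model=self,
            accuracy=acc,
            measures=measures,
            ttests=ttests,
            spearman=spearman,
            gender_pairing=pairing_summary,
            gender_tests=gender_tests,
            reliabilities=reliabilities,
            corrected=corrected,
            warnings=warnings,
        )

    # -- helpers ----------------------------------------------------------

    def _measure_table(self, acc: AccuracyResult, warnings: list[str]) -> pd.DataFrame:
        cols = {f"{n}_accuracy": acc.indices[n].total for n in INDEX_NAMES}
        if self.judges is not None:
            jid = [j.judge_id for j in self.judges]
            for name, attr in ABILITY_FIELDS.items():
                s = pd.Series(
                    [getattr(j, attr) for j in self.judges], index=jid, dtype=float
                )
                if s.notna().sum() == 0:
                    warnings.append(f"ability measure {name!r} absent; skipped")
                    continue
                cols[name] = s
            gender = pd.Series([j.gender for j in self.judges], index=jid)
            if gender.isin(["male", "female"]).any():
                cols["gender_female"] = gender.map({"male": 0.0, "female": 1.0})
        df = pd.DataFrame(cols)
        df.index.name = "judge_id"
        return df

    def _spearman_matrix(self, measures: pd.DataFrame) -> pd.DataFrame:
        cols = list(measures.columns)
        out = pd.DataFrame(np.nan, index=cols, columns=cols)
        for i, a in enumerate(cols):
            out.loc[a, a] = 1.0
            for b in cols[i + 1 :]:
                pair = measures[[a, b]].dropna()
                r = spearman_rho(pair[a], pair[b]).r
                out.loc[a, b] = out.loc[b, a] = r
        return out

    def _gender_blocks(self, acc: AccuracyResult, warnings: list[str]):
        if self.judges is None or self.criteria.gender.nunique() < 2:
            if self.judges is None:
                warnings.append("no judge metadata; gender blocks skipped")
            return pd.DataFrame(), {}
        per_judge, summary = gender_pairing_accuracy(
            self.cube, self.criteria, self.judges, self.min_prop, self.clip
        )
        jg = pd.Series({j.judge_id: j.gender for j in self.judges}).reindex(
            per_judge.index
        )
        tests = {}
        for index in INDEX_NAMES:
            mm = per_judge.loc[jg == "male", f"{index}/targets_male"].dropna()
            ff = per_judge.loc[jg == "female", f"{index}/targets_female"].dropna()
            if len(mm) >= 2 and len(ff) >= 2:
                tests[index] = pooled_two_sample_t(mm, ff)
        return summary, tests

    def _corrected(
        self,
        acc: AccuracyResult,
        reliabilities,
        ability_reliabilities: Mapping[str, float] | None,
        warnings: list[str],
    ) -> list[CorrectedCorrelation]:
        if self.judges is None:
            return []
        if ability_reliabilities is None:
            ability_reliabilities = DEFAULT_ABILITY_RELIABILITIES
        index_rel = {}
        for name, est in reliabilities.items():
            if 0.0 < est.value <= 1.0:
                index_rel[name] = est.value
            else:
                warnings.append(
                    f"reliability of {name} accuracy ({est.value:.3f}) outside (0, 1];"
                    " disattenuation skipped for it"
                )
        return corrected_correlation_table(
            acc, self.judges, index_rel, ability_reliabilities
        )


@dataclass
class JudgmentAccuracyResults:
    """Fitted results: estimates, tests, reliabilities and report rendering."""

    model: JudgmentAccuracyModel
    accuracy: AccuracyResult
    measures: pd.DataFrame
    ttests: dict
    spearman: pd.DataFrame
    gender_pairing: pd.DataFrame
    gender_tests: dict
    reliabilities: dict
    corrected: list[CorrectedCorrelation]
    warnings: list[str] = field(default_factory=list)

    @property
    def scores(self) -> pd.DataFrame:
        """Per-judge totals, availability counts and subscores."""
        return self.accuracy.per_judge

    def report(self) -> dict:
        """Full-precision, JSON-serializable report of every block."""
        acc = self.accuracy

        def desc(s: pd.Series) -> dict:
            v = s.dropna()
            return {
                "mean": float(v.mean()) if len(v) else None,
                "sd": float(v.std(ddof=1)) if len(v) > 1 else None,
                "n": int(len(v)),
            }

        def tres(t) -> dict:
            return {
                "t": None if math.isnan(t.statistic) else float(t.statistic),
                "df": float(t.df),
                "p": None if math.isnan(t.p_two_sided) else float(t.p_two_sided),
            }

        def sub_block(series: pd.Series) -> dict:
            d = desc(series)
            v = series.dropna()
            if len(v) >= 2 and v.std(ddof=1) > 0:
                d.update(tres(one_sample_t(v, 0.0)))
            return d

        trait_subs = {}
        for trait in acc.cells.traits:
            trait_subs[trait] = sub_block(
                acc.indices["trait"].subscores[f"trait:{trait}"]
            )
        modality_subs = {}
        for name in INDEX_NAMES:
            modality_subs[name] = {
                col.split(":", 1)[1]: sub_block(acc.indices[name].subscores[col])
                for col in acc.indices[name].subscores.columns
                if col.startswith("modality:")
            }
        spearman = {
            "measures": list(self.spearman.columns),
            "matrix": [
                [None if math.isnan(v) else float(v) for v in row]
                for row in self.spearman.to_numpy()
            ],
        }
        pairing = []
        if not self.gender_pairing.empty:
            for _, row in self.gender_pairing.iterrows():
                pairing.append(
                    {
                        "judge_gender": row["judge_gender"],
                        "target_gender": row["target_gender"],
                        "index": row["index"],
                        "mean": None if pd.isna(row["mean"]) else float(row["mean"]),
                        "sd": None if pd.isna(row["sd"]) else float(row["sd"]),
                        "n": int(row["n"]),
                    }
                )
        return {
            "design": {
                "n_judges": len(self.model.cube.judges),
                "n_targets": len(self.model.cube.targets),
                "n_traits": len(self.model.cube.traits),
            },
            "parameters": {
                "min_prop": self.model.min_prop,
                "clip": self.model.clip,
                "exclude_self": self.model.exclude_self,
            },
            "descriptives": {c: desc(self.measures[c]) for c in self.measures},
            "one_sample_t": {k: tres(v) for k, v in self.ttests.items()},
            "spearman": spearman,
            "trait_subscores": trait_subs,
            "modality_subscores": modality_subs,
            "gender_pairing": pairing,
            "gender_tests": {k: tres(v) for k, v in self.gender_tests.items()},
            "reliability": {
                k: {
                    "method": est.method,
                    "value": None if math.isnan(est.value) else float(est.value),
                    "n_components": est.n_components,
                }
                for k, est in self.reliabilities.items()
            },
            "corrected_correlations": [asdict(c) for c in self.corrected],
            "warnings": list(self.warnings),
        }

    def summary(self) -> str:
        """Human-readable report tables (2-decimal rounding)."""
        return render_report(self.report())


# ---------------------------------------------------------------------------
# report rendering (pure function of the JSON report, so that a report read
# back from disk renders identically)


def _fmt(v, nd=2, width=8):
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return " " * (width - 2) + "--"
    return f"{v:{width}.{nd}f}"


def render_report(rep: dict) -> str:
    d = rep["design"]
    lines = [
        "Personality judgment accuracy report",
        "=" * 68,
        f"judges: {d['n_judges']}   targets: {d['n_targets']}   "
        f"traits: {d['n_traits']}   min_prop: {rep['parameters']['min_prop']}",
        "",
        "Descriptives",
        "-" * 68,
        f"{'measure':<24}{'mean':>8}{'sd':>8}{'n':>6}",
    ]
    for name, ds in rep["descriptives"].items():
        lines.append(
            f"{name:<24}{_fmt(ds['mean'])}{_fmt(ds['sd'])}{ds['n']:>6d}"
        )
    lines += ["", "One-sample t tests against zero", "-" * 68]
    for name, t in rep["one_sample_t"].items():
        lines.append(
            f"{name:<24}t({t['df']:.0f}) = {_fmt(t['t'], 3, 8).strip()},"
            f" p = {_fmt(t['p'], 4, 7).strip()}"
        )
    sp = rep["spearman"]
    if sp["measures"]:
        lines += ["", "Spearman rank correlations", "-" * 68]
        head = f"{'':<24}" + "".join(f"{m[:7]:>8}" for m in sp["measures"])
        lines.append(head)
        for m, row in zip(sp["measures"], sp["matrix"]):
            lines.append(f"{m:<24}" + "".join(_fmt(v) for v in row))
    lines += ["", "Trait subscores (trait accuracy)", "-" * 68,
              f"{'trait':<24}{'mean':>8}{'sd':>8}{'n':>6}{'t':>8}{'p':>8}"]
    for trait, ds in rep["trait_subscores"].items():
        lines.append(
            f"{trait:<24}{_fmt(ds['mean'])}{_fmt(ds['sd'])}{ds['n']:>6d}"
            f"{_fmt(ds.get('t'))}{_fmt(ds.get('p'), 3)}"
        )
    lines += ["", "Modality subscores", "-" * 68,
              f"{'index / modality':<24}{'mean':>8}{'sd':>8}{'n':>6}{'t':>8}{'p':>8}"]
    for index, mods in rep["modality_subscores"].items():
        for mod, ds in mods.items():
            lines.append(
                f"{index + ' / ' + mod:<24}{_fmt(ds['mean'])}{_fmt(ds['sd'])}"
                f"{ds['n']:>6d}{_fmt(ds.get('t'))}{_fmt(ds.get('p'), 3)}"
            )
    if rep["gender_pairing"]:
        lines += ["", "Gender pairings (judge gender x target gender)", "-" * 68,
                  f"{'pairing / index':<32}{'mean':>8}{'sd':>8}{'n':>6}"]
        for row in rep["gender_pairing"]:
            label = f"{row['judge_gender']}->{row['target_gender']} / {row['index']}"
            lines.append(
                f"{label:<32}{_fmt(row['mean'])}{_fmt(row['sd'])}{row['n']:>6d}"
            )
    if rep["gender_tests"]:
        lines += ["", "Same-gender comparisons (male-male vs female-female)", "-" * 68]
        for index, t in rep["gender_tests"].items():
            lines.append(
                f"{index:<24}t({t['df']:.0f}) = {_fmt(t['t'], 3, 8).strip()},"
                f" p = {_fmt(t['p'], 4, 7).strip()}"
            )
    lines += ["", "Reliability", "-" * 68]
    for index, r in rep["reliability"].items():
        lines.append(
            f"{index:<24}{_fmt(r['value'])}  ({r['method']},"
            f" {r['n_components']} components)"
        )
    if rep["corrected_correlations"]:
        lines += ["", "Attenuation-corrected correlations", "-" * 68,
                  f"{'ability x index':<28}{'raw r':>8}{'rel_x':>8}{'rel_y':>8}"
                  f"{'corrected':>10}"]
        for c in rep["corrected_correlations"]:
            flag = " !" if c["warning"] else ""
            lines.append(
                f"{c['ability'] + ' x ' + c['index']:<28}{_fmt(c['raw_r'])}"
                f"{_fmt(c['rel_x'])}{_fmt(c['rel_y'])}{_fmt(c['corrected_r'], 2, 10)}"
                f"{flag}"
            )
    if rep["warnings"]:
        lines += ["", "Warnings", "-" * 68]
        lines += [f"  - {w}" for w in rep["warnings"]]
    return "\n".join(lines) + "\n"
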