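"""End-to-end analyses: accuracy, complexity, interaction summaries, chi-square.

The drivers here take production/trial tables (real-format CSVs or frames
from the simulators), run the scoring and conditioning-complexity stages,
and emit tidy summary tables.  Inference is deliberately descriptive —
estimates with confidence intervals — except for the one 2x2 Pearson
chi-square on post-test regularization by dyad type.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import conditioning, scoring
from .languages import LanguageSpec


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; rows are dyad types, columns regularized-in-posttest
    yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def chi2_2x2(t: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction.

    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); p from the chi-square
    distribution with 1 df.  Any zero margin leaves the statistic undefined
    and raises.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("zero margin: chi-square statistic undefined")
    chi2 = t.n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), 1, p


def _binom_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    if n == 0:
        return float("nan"), float("nan")
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=level, method="wilson")
    return float(ci.low), float(ci.high)


def regularization_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Proportion of irregular-cell productions using the regularized form,
    by director role x dyad type x round, with Wilson 95% CIs."""
    irr = trials[trials["item_type"] == "irregular"]
    if irr.empty:
        warnings.warn("no irregular-cell productions in input")
        return pd.DataFrame(
            columns=["dyad_type", "director_role", "round", "numerator", "denominator", "proportion", "ci_low", "ci_high"]
        )
    rows = []
    for (dt, role, rnd), grp in irr.groupby(["dyad_type", "director_role", "round"]):
        k = int(grp["regularized"].sum())
        n = len(grp)
        lo, hi = _binom_ci(k, n)
        rows.append({
            "dyad_type": dt, "director_role": role, "round": rnd,
            "numerator": k, "denominator": n, "proportion": k / n,
            "ci_low": lo, "ci_high": hi,
        })
    return pd.DataFrame(rows)


def communicative_success_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Matched proportion by round x dyad type x item type, plus pooled
    rows (round = 'all')."""
    if trials.empty:
        raise ValueError("empty trial input")
    if "matched_correctly" not in trials.columns:
        raise ValueError("trials carry no matched_correctly column")
    rows = []
    groups = list(trials.groupby(["dyad_type", "item_type", "round"]))
    groups += [((dt, it, "all"), grp) for (dt, it), grp in trials.groupby(["dyad_type", "item_type"])]
    for (dt, it, rnd), grp in groups:
        k = int(grp["matched_correctly"].sum())
        n = len(grp)
        lo, hi = _binom_ci(k, n)
        rows.append({
            "dyad_type": dt, "item_type": it, "round": rnd,
            "numerator": k, "denominator": n, "proportion": k / n,
            "ci_low": lo, "ci_high": hi,
        })
    return pd.DataFrame(rows)


# --- experiment drivers -------------------------------------------------------


def _segment_suffixes(df: pd.DataFrame, target: LanguageSpec) -> pd.DataFrame:
    """Segment every produced word against the target stems; one row per
    word class with the suffix token (NULL for zero-marked)."""
    word_cols = [c for c in ("word1", "word2", "word3") if c in df.columns]
    rows = []
    for rec in df.itertuples(index=False):
        number = rec.number if rec.number not in ("", "NA") else None
        scene = scoring.Scene(number, rec.animal, rec.motion)
        target_words = target.words_for(scene)
        for i, tw in enumerate(target_words):
            word = getattr(rec, word_cols[i]) if i < len(word_cols) else ""
            if not word:
                suffix, method = scoring.NULL, "missing"
            else:
                seg = scoring.segment_word(word, target.stems(tw.word_class))
                suffix, method = seg.suffix, seg.method
            rows.append({
                "participant_id": rec.participant_id,
                "phase": int(rec.phase),
                "number": number,
                "animal": rec.animal,
                "motion": rec.motion,
                "word_class": tw.word_class,
                "suffix": suffix,
                "segmentation_method": method,
            })
    return pd.DataFrame(rows)


def _write(df: pd.DataFrame, out_dir, name: str) -> None:
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(out_dir) / name, index=False, float_format="%.6f")


def run_exp1(
    productions: pd.DataFrame, target: LanguageSpec, out_dir=None
) -> dict[str, pd.DataFrame]:
    """Learning-study analysis: accuracy by round and conditioning
    complexity per participant x round x word class."""
    scored = scoring.score_table(productions, target)
    accuracy = scoring.aggregate_accuracy(scored)
    suffixes = _segment_suffixes(productions, target)
    complexity = conditioning.complexity_table(suffixes)
    _write(accuracy, out_dir, "exp1_accuracy.csv")
    _write(complexity, out_dir, "exp1_complexity.csv")
    return {"scored": scored, "accuracy": accuracy, "suffixes": suffixes, "complexity": complexity}


def run_exp2(
    productions: pd.DataFrame, target: LanguageSpec, phase: int = 8, out_dir=None
) -> dict[str, pd.DataFrame]:
    """Mixing-study analysis: round-``phase`` complexity by input condition
    (condition column required), as estimates with CIs."""
    if "condition" not in productions.columns:
        raise ValueError("exp2 productions need a condition column")
    sub = productions[productions["phase"].astype(int) == phase]
    suffixes = _segment_suffixes(sub, target)
    cond_of = sub.drop_duplicates("participant_id").set_index("participant_id")["condition"]
    complexity = conditioning.complexity_table(suffixes)
    complexity = complexity.assign(condition=complexity["participant_id"].map(cond_of))
    rows = []
    for (cond, wc), grp in complexity.groupby(["condition", "word_class"]):
        vals = grp["complexity"].to_numpy(dtype=float)
        mean, hw = scoring._mean_ci(vals)
        rows.append({
            "condition": cond, "word_class": wc, "mean_complexity": mean,
            "ci_low": mean - hw, "ci_high": mean + hw, "n": len(vals),
        })
    summary = pd.DataFrame(rows)
    _write(complexity, out_dir, "exp2_complexity.csv")
    _write(summary, out_dir, "exp2_complexity_by_condition.csv")
    return {"complexity": complexity, "summary": summary}


def posttest_contingency(posttest: pd.DataFrame) -> ContingencyTable:
    """Complex speakers by dyad type x whether they produced at least one
    regularized irregular in the solo post-test.  Row order: mixed first."""
    cpx = posttest[(posttest["director_role"] == "complex") & (posttest["item_type"] == "irregular")]
    per_speaker = cpx.groupby(["dyad_type", "director_id"])["regularized"].any()
    counts = {}
    for dt in ("mixed", "complex"):
        grp = per_speaker.loc[dt] if dt in per_speaker.index.get_level_values(0) else pd.Series(dtype=bool)
        counts[dt] = (int(grp.sum()), int((~grp).sum()))
    return ContingencyTable(counts["mixed"][0], counts["mixed"][1], counts["complex"][0], counts["complex"][1])


def run_exp3(
    trials: pd.DataFrame, posttest: pd.DataFrame, out_dir=None
) -> dict:
    """Interaction-study analysis: communicative success, regularization
    proportions, and the post-test 2x2 chi-square (reported as refused when
    a margin is zero)."""
    success = communicative_success_summary(trials)
    regular = regularization_summary(trials)
    post_reg = regularization_summary(posttest.assign(round="posttest"))
    table = posttest_contingency(posttest)
    try:
        chi2, df, p = chi2_2x2(table)
        chi2_result = {"chi2": chi2, "df": df, "p": p, "refused": False}
    except ValueError as err:
        chi2_result = {"chi2": None, "df": 1, "p": None, "refused": True, "reason": str(err)}
    _write(success, out_dir, "exp3_communicative_success.csv")
    _write(regular, out_dir, "exp3_regularization.csv")
    _write(post_reg, out_dir, "exp3_posttest_regularization.csv")
    if out_dir is not None:
        with open(Path(out_dir) / "exp3_chi2.json", "w") as fh:
            json.dump({**chi2_result, "table": [table.a, table.b, table.c, table.d]}, fh, indent=2)
    return {
        "success": success,
        "regularization": regular,
        "posttest_regularization": post_reg,
        "contingency": table,
        "chi2": chi2_result,
    }


def write_manifest(out_dir, seed: int, config: dict) -> None:
    """A single JSON run manifest: inputs, config, seed, versions."""
    import morphocomplex

    Path(out_dir).mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": morphocomplex.__version__,
        "seed": seed,
        "config": config,
    }
    with open(Path(out_dir) / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
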