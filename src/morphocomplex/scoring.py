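"""Production scoring: segmentation, normalized-Levenshtein accuracy, aggregation.

Produced words are split into stem + suffix against the candidate stems of
the target language (exact-prefix match where possible, closest-stem split
otherwise).  Accuracy of a produced stem or suffix is 1 minus the
normalized Levenshtein distance to the target form, so it lives in [0, 1].
Zero-marked (absent) suffixes are coded with the literal token "NULL" and
scored as the empty string.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from .languages import LanguageSpec, Scene

NULL = "NULL"


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    return edlib.align(a, b, task="distance")["editDistance"]


def normalized_levenshtein(a: str, b: str) -> float:
    """Edit distance divided by the length of the longer string; 0 for two
    empty strings."""
    n = max(len(a), len(b))
    if n == 0:
        return 0.0
    return levenshtein(a, b) / n


@dataclass(frozen=True)
class SegmentedWord:
    stem: str
    suffix: str  # "NULL" when zero-marked
    method: str  # exact_prefix | best_edit | manual

    @property
    def needs_review(self) -> bool:
        return self.method == "best_edit"

    @property
    def surface(self) -> str:
        return self.stem if self.suffix == NULL else self.stem + self.suffix


def segment_word(word: str, candidate_stems: set[str]) -> SegmentedWord:
    """Split a produced word into stem + suffix.

    If some candidate stem is an exact prefix of the word, split there
    (longest such stem on ties; method ``exact_prefix``).  Otherwise pick
    the split point and stem minimizing the edit distance between the
    word's prefix and any candidate stem (method ``best_edit``, flagged for
    manual review); ties go to the longer stem, then lexicographically
    earlier stem, then the longer prefix.  An empty remainder yields the
    suffix code "NULL".
    """
    if not word:
        raise ValueError("cannot segment an empty word")
    if not candidate_stems:
        raise ValueError("candidate_stems must be non-empty")

    exact = [s for s in candidate_stems if word.startswith(s)]
    if exact:
        stem = max(exact, key=len)
        rest = word[len(stem):]
        return SegmentedWord(stem, rest if rest else NULL, "exact_prefix")

    best = None
    for i in range(1, len(word) + 1):
        prefix = word[:i]
        for stem in candidate_stems:
            key = (levenshtein(prefix, stem), -len(stem), stem, -i)
            if best is None or key < best[0]:
                best = (key, prefix, stem, word[i:])
    _, prefix, stem, rest = best
    # The produced stem is the word's prefix (what the learner wrote), the
    # matched candidate identifies which lexeme it was aimed at.
    return SegmentedWord(prefix, rest if rest else NULL, "best_edit")


@dataclass
class AccuracyRecord:
    word_class: str
    stem_accuracy: float
    suffix_accuracy: float


def _suffix_to_string(suffix: str) -> str:
    return "" if suffix == NULL else suffix


def score_production(
    produced: list[str], scene: Scene, target: LanguageSpec
) -> list[AccuracyRecord]:
    """Per-word-class stem and suffix accuracy of one production.

    Produced words are matched to word classes positionally; a missing word
    scores 0 on both stem and suffix.  Target segmentations come from the
    language spec's own stem/suffix index, never re-derived.
    """
    target_words = target.words_for(scene)  # raises on unknown scene
    out = []
    for i, tw in enumerate(target_words):
        if i >= len(produced) or not produced[i]:
            out.append(AccuracyRecord(tw.word_class, 0.0, 0.0))
            continue
        seg = segment_word(produced[i], target.stems(tw.word_class))
        stem_acc = 1.0 - normalized_levenshtein(seg.stem, tw.stem)
        suffix_acc = 1.0 - normalized_levenshtein(
            _suffix_to_string(seg.suffix), tw.suffix
        )
        out.append(AccuracyRecord(tw.word_class, stem_acc, suffix_acc))
    return out


# --- tabular interface --------------------------------------------------------

PRODUCTION_COLUMNS = [
    "participant_id", "phase", "number", "animal", "motion",
    "word1", "word2", "word3", "condition",
]


def read_productions(path) -> pd.DataFrame:
    """Read a production CSV, stripping any word-internal hyphens."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PRODUCTION_COLUMNS if c not in df.columns and c != "condition"]
    if missing:
        raise ValueError(f"production CSV missing columns: {missing}")
    for col in ("word1", "word2", "word3"):
        df[col] = df[col].str.replace("-", "", regex=False).str.replace("‐", "", regex=False)
    return df


def score_table(df: pd.DataFrame, target: LanguageSpec) -> pd.DataFrame:
    """Score every production row; returns one row per word class with
    stem and suffix accuracy."""
    word_cols = [c for c in ("word1", "word2", "word3") if c in df.columns]
    rows = []
    for rec in df.itertuples(index=False):
        number = rec.number if rec.number not in ("", "NA") else None
        scene = Scene(number, rec.animal, rec.motion)
        produced = [getattr(rec, c) for c in word_cols]
        produced = [w for w in produced]
        for acc in score_production(produced, scene, target):
            rows.append({
                "participant_id": rec.participant_id,
                "phase": rec.phase,
                "number": number,
                "animal": rec.animal,
                "motion": rec.motion,
                "word_class": acc.word_class,
                "stem_accuracy": acc.stem_accuracy,
                "suffix_accuracy": acc.suffix_accuracy,
            })
    return pd.DataFrame(rows)


def _mean_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Mean and half-width of the CI on the mean: t-based below n=30,
    normal above; width 0 for a single observation (degenerate)."""
    n = len(values)
    mean = float(np.mean(values))
    if n < 2:
        return mean, 0.0
    se = float(np.std(values, ddof=1)) / np.sqrt(n)
    if n < 30:
        crit = stats.t.ppf(0.5 + level / 2, df=n - 1)
    else:
        crit = stats.norm.ppf(0.5 + level / 2)
    return mean, float(crit * se)


def aggregate_accuracy(scored: pd.DataFrame) -> pd.DataFrame:
    """Mean of by-participant mean accuracy per round, for stems and suffixes.

    Averages first within participant x round (over scenes and word
    classes), then across participants; the 95% CI is on the mean of the
    participant means.
    """
    if scored.empty:
        raise ValueError("no scored records to aggregate")
    per_participant = scored.groupby(["phase", "participant_id"])[
        ["stem_accuracy", "suffix_accuracy"]
    ].mean()
    rows = []
    for phase, grp in per_participant.groupby(level="phase"):
        for measure in ("stem", "suffix"):
            vals = grp[f"{measure}_accuracy"].to_numpy()
            mean, hw = _mean_ci(vals)
            rows.append({
                "round": phase,
                "measure": measure,
                "mean": mean,
                "ci_low": mean - hw,
                "ci_high": mean + hw,
                "n": len(vals),
            })
    return pd.DataFrame(rows)


def exact_stem_match_proportion(df: pd.DataFrame, target: LanguageSpec) -> pd.Series:
    """Per participant: proportion of produced words whose stem exactly
    matches the target stem (segmentation by exact prefix only)."""
    word_cols = [c for c in ("word1", "word2", "word3") if c in df.columns]
    out: dict[str, list[bool]] = {}
    for rec in df.itertuples(index=False):
        number = rec.number if rec.number not in ("", "NA") else None
        scene = Scene(number, rec.animal, rec.motion)
        target_words = target.words_for(scene)
        for i, tw in enumerate(target_words):
            word = getattr(rec, word_cols[i]) if i < len(word_cols) else ""
            out.setdefault(rec.participant_id, []).append(
                bool(word) and word.startswith(tw.stem)
            )
    return pd.Series({p: float(np.mean(v)) for p, v in out.items()}, name="exact_stem_match")
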