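"""Built-in reference data: one learner's suffix productions.

The study's worked example is a single learner's quantifier, noun, and verb
suffix choices for all 18 scenes, recorded after two rounds of training
(stems mastered, suffixes still simplified) and after eight rounds (the
target language fully acquired).  These suffix sets are the canonical input
for demonstrating the conditioning-complexity statistic: the round-2 system
conditions each suffix on fewer semantic features than the round-8 system.
"""

from __future__ import annotations

import pandas as pd

from .languages import Scene, exp1_scenes

# (number, animal, motion) -> (Q, N, V) suffix, by round.  Scene order is
# duck one/two x straight/bounce/loop, then bird, then crocodile.
_ROUND2 = {
    ("one", "duck", "straight"): ("a", "o", "esp"),
    ("two", "duck", "straight"): ("ak", "op", "esp"),
    ("one", "duck", "bounce"): ("a", "o", "esp"),
    ("two", "duck", "bounce"): ("ak", "op", "esp"),
    ("one", "duck", "loop"): ("a", "o", "an"),
    ("two", "duck", "loop"): ("ak", "op", "an"),
    ("one", "bird", "straight"): ("a", "o", "esp"),
    ("two", "bird", "straight"): ("ak", "op", "esp"),
    ("one", "bird", "bounce"): ("a", "o", "esp"),
    ("two", "bird", "bounce"): ("ak", "o", "asp"),
    ("one", "bird", "loop"): ("a", "o", "an"),
    ("two", "bird", "loop"): ("ak", "op", "an"),
    ("one", "crocodile", "straight"): ("a", "o", "esp"),
    ("two", "crocodile", "straight"): ("ak", "op", "esp"),
    ("one", "crocodile", "bounce"): ("a", "o", "esp"),
    ("two", "crocodile", "bounce"): ("ak", "op", "esp"),
    ("one", "crocodile", "loop"): ("a", "o", "an"),
    ("two", "crocodile", "loop"): ("ak", "op", "an"),
}

_ROUND8 = {
    ("one", "duck", "straight"): ("a", "o", "an"),
    ("two", "duck", "straight"): ("ak", "op", "asp"),
    ("one", "duck", "bounce"): ("a", "o", "an"),
    ("two", "duck", "bounce"): ("ak", "op", "asp"),
    ("one", "duck", "loop"): ("a", "o", "an"),
    ("two", "duck", "loop"): ("ak", "op", "onk"),
    ("one", "bird", "straight"): ("a", "o", "an"),
    ("two", "bird", "straight"): ("ak", "o", "asp"),
    ("one", "bird", "bounce"): ("a", "o", "an"),
    ("two", "bird", "bounce"): ("ak", "o", "asp"),
    ("one", "bird", "loop"): ("a", "o", "an"),
    ("two", "bird", "loop"): ("ak", "o", "onk"),
    ("one", "crocodile", "straight"): ("u", "o", "en"),
    ("two", "crocodile", "straight"): ("uk", "op", "esp"),
    ("one", "crocodile", "bounce"): ("u", "o", "en"),
    ("two", "crocodile", "bounce"): ("uk", "op", "esp"),
    ("one", "crocodile", "loop"): ("u", "o", "en"),
    ("two", "crocodile", "loop"): ("uk", "op", "onk"),
}


def example_learner_suffixes() -> pd.DataFrame:
    """Long-format suffix data for the example learner.

    Columns: participant_id, phase (2 or 8), number, animal, motion,
    word_class (Q/N/V), suffix.  108 rows (18 scenes x 3 classes x 2
    rounds).
    """
    rows = []
    for phase, table in ((2, _ROUND2), (8, _ROUND8)):
        for scene in exp1_scenes():
            q, n, v = table[(scene.number, scene.animal, scene.motion)]
            for wc, suf in zip(("Q", "N", "V"), (q, n, v)):
                rows.append({
                    "participant_id": "example",
                    "phase": phase,
                    "number": scene.number,
                    "animal": scene.animal,
                    "motion": scene.motion,
                    "word_class": wc,
                    "suffix": suf,
                })
    return pd.DataFrame(rows)


def example_learner_scene_suffixes(phase: int, word_class: str) -> tuple[list[Scene], list[str]]:
    """The (scenes, suffixes) pair for one round and word class."""
    table = {2: _ROUND2, 8: _ROUND8}[phase]
    idx = {"Q": 0, "N": 1, "V": 2}[word_class]
    scenes = exp1_scenes()
    return scenes, [table[(s.number, s.animal, s.motion)][idx] for s in scenes]
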