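#!/usr/bin/env python
"""Conditioning complexity of the example learner's suffix systems.

Runs the exhaustive multinomial-model AIC selection on the example
learner's round-2 and round-8 suffix data for quantifiers, nouns, and
verbs, and on the target language itself.  The early system should come
out simpler (fewer conditioning features) than the late one, which matches
the target's complexity.

Writes results/worked_example_complexity.csv.
"""

from pathlib import Path

import pandas as pd

from morphocomplex.conditioning import best_model, complexity_table, suffix_entropy
from morphocomplex.datasets import example_learner_suffixes
from morphocomplex.languages import build_exp1_target

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    table = complexity_table(example_learner_suffixes())
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "worked_example_complexity.csv", index=False, float_format="%.6f")

    print("Example learner, conditioning complexity by round and word class:")
    print(table[["phase", "word_class", "best_model_formula", "complexity", "entropy_bits"]]
          .to_string(index=False))

    target = build_exp1_target()
    scenes = target.scenes
    print("\nTarget language complexity per word class:")
    for wc in ("Q", "N", "V"):
        suffixes = [next(w.suffix for w in target.entries[s] if w.word_class == wc) or "NULL"
                    for s in scenes]
        score = best_model(scenes, suffixes)
        print(f"  {wc}: {score.best.model.formula}  complexity {score.complexity}  "
              f"entropy {suffix_entropy(suffixes):.3f} bits")

    r2 = table[table.phase == 2]["complexity"].sum()
    r8 = table[table.phase == 8]["complexity"].sum()
    print(f"\nTotal complexity rises from {r2} (round 2) to {r8} (round 8): "
          "the early-learning system conditions suffix choice on fewer semantic features.")


if __name__ == "__main__":
    main()
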