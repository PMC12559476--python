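"""Rank alignment positions by their association with substrate activity.

Builds a single enzyme family in which activity on a substrate is
determined solely by the residue at one planted column, then shows that
grouped permutation importance recovers that column as rank 1.
"""

import pandas as pd

from t3pks.importance import rank_positions
from t3pks.synthetic import SyntheticSpec, generate_families

PLANTED = 12

members = generate_families(SyntheticSpec(
    seed=21, n_families=1, family_sizes=30, seq_length=40,
    within_family_mutation_rate=0.3, frozen_positions={},
    motif_column=PLANTED, family_motifs=("V",),
))

rows, labels = {}, {}
for k, rec in enumerate(members):
    residues = list(rec.residues)
    active = k % 2 == 0
    residues[PLANTED - 1] = "V" if active else "L"  # the determining residue
    rows[rec.id] = dict(zip(range(1, 41), residues))
    labels[rec.id] = int(active)
profiles = pd.DataFrame.from_dict(rows, orient="index")

table = rank_positions(profiles, labels, seed=0, n_boot=10)
print(table.head(5).to_string(index=False))
top = table.iloc[0]
print(f"\ntop-ranked position: {int(top['ref_position'])} "
      f"(planted determinant was {PLANTED}); "
      f"stability {top['stability']:.0%} of bootstrap replicates")
# The planted column dominates the ranking; unrelated columns score near
# zero because shuffling them does not change the fitted model's accuracy.
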