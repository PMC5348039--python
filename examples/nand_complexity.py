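"""Derive the per-task NAND complexities by exhaustive circuit search.

Each Boolean task's complexity is the minimum number of NAND gate
executions needed to compute it, found by breadth-first search over
straight-line NAND programs starting from the two input projections.
The complexity of a whole phenotype is the sum over its tasks, normalized
by the all-task maximum of 25."""

from avidalite import bitstring_to_mask, phenotype_complexity
from avidalite.nandcount import task_nand_complexities

print("task  min NAND gates")
for task, gates in task_nand_complexities().items():
    print(f"{task:6s} {gates}")

mask = bitstring_to_mask("101010000")  # NOT, AND, OR
score = phenotype_complexity(mask)
print(f"\nphenotype {{NOT, AND, OR}}: raw complexity {score.raw}, "
      f"normalized {score.normalized:.2f}")
print("The sum (1+2+3=6) over 25 ranks this phenotype a quarter of the way "
      "to the most complex (all-nine-task) phenotype.")
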