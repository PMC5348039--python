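"""Evaluate self-replicating digital organisms in the test environment.

Builds the canonical copy-loop replicator at L=100 and its NAND-performing
variant, runs each in isolation, and prints viability, gestation time and
phenotype.  A faithful replicator divides well inside the 20xL execution
budget; the NAND variant additionally emits the bitwise NAND of its two
buffered environment inputs, which the task detector credits as the NAND
trait (phenotype id 2)."""

from avidalite import mask_tasks, run_test
from avidalite.micro import copy_loop_replicator, nand_replicator

for genome in (copy_loop_replicator(100), nand_replicator(100)):
    r = run_test(genome, env=42)
    print(f"genome       {genome[:32]}... (L={len(genome)})")
    print(f"  viable={r.viable} faithful={r.faithful} gestation={r.gestation} "
          f"executed={r.executed}")
    print(f"  fraction of genome executed: {r.fraction_executed:.2f}")
    print(f"  phenotype id {r.phenotype} -> tasks {mask_tasks(r.phenotype) or '(merely viable)'}")
    print()

print("Gestation is the number of instructions executed before division;")
print("an organism that never divides within 20*L instructions is inviable.")
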