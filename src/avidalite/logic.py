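"""The nine Boolean logic tasks and the 512-element phenotype space.

An organism's phenotype is the set of logic operations it computes on the
input words it has taken from the environment, encoded as a 9-bit mask in
the fixed task order NOT, NAND, AND, OR_N, OR, AND_N, NOR, XOR, EQU
(NOT = bit 0, EQU = bit 8).  Mask 0 is the merely-viable (no-trait)
phenotype.  Each task has an integer complexity: the minimum number of NAND
gate executions needed to compute it (see :mod:`avidalite.nandcount`, which
re-derives these values by exhaustive search).
"""

from __future__ import annotations

from dataclasses import dataclass

TASK_NAMES = ("NOT", "NAND", "AND", "OR_N", "OR", "AND_N", "NOR", "XOR", "EQU")

TASK_COMPLEXITY = {
    "NOT": 1,
    "NAND": 1,
    "AND": 2,
    "OR_N": 2,
    "OR": 3,
    "AND_N": 3,
    "NOR": 4,
    "XOR": 4,
    "EQU": 5,
}

TASK_ARITY = {name: (1 if name == "NOT" else 2) for name in TASK_NAMES}

TASK_BIT = {name: i for i, name in enumerate(TASK_NAMES)}

N_TASKS = 9
N_PHENOTYPES = 1 << N_TASKS  # 512

#: Sum of all nine per-task complexities; the all-task phenotype scores 1.0.
MAX_COMPLEXITY = sum(TASK_COMPLEXITY.values())  # 25


def apply_op(op: str, x: int, y: int | None = None, width: int = 32) -> int:
    """Bitwise evaluation of one logic task at the given word width.

    Unary NOT takes one argument; all other tasks take two.  The *_N tasks
    negate the second argument (``x OP ~y``); detection treats operand order
    as immaterial.
    """
    mask = (1 << width) - 1
    if TASK_ARITY[op] == 1:
        if y is not None:
            raise ValueError(f"{op} is unary")
        return ~x & mask
    if y is None:
        raise ValueError(f"{op} needs two arguments")
    if op == "NAND":
        return ~(x & y) & mask
    if op == "AND":
        return x & y & mask
    if op == "OR_N":
        return (x | (~y & mask)) & mask
    if op == "OR":
        return (x | y) & mask
    if op == "AND_N":
        return x & (~y & mask)
    if op == "NOR":
        return ~(x | y) & mask
    if op == "XOR":
        return (x ^ y) & mask
    if op == "EQU":
        return ~(x ^ y) & mask
    raise ValueError(f"unknown op {op!r}")


def detect_ops(output: int, inputs: tuple[int, int], width: int = 32) -> int:
    """Mask of every task whose result on the buffered inputs equals the
    emitted output.

    Unary NOT is tried on each input separately; the order-sensitive *_N
    tasks are accepted in either operand order.  Degenerate inputs may match
    several tasks at once; all matches are credited.
    """
    in1, in2 = inputs
    mask = 0
    for op in TASK_NAMES:
        if TASK_ARITY[op] == 1:
            hit = output in (apply_op(op, in1, width=width), apply_op(op, in2, width=width))
        else:
            hit = output == apply_op(op, in1, in2, width=width)
            if not hit and op in ("OR_N", "AND_N"):
                hit = output == apply_op(op, in2, in1, width=width)
        if hit:
            mask |= 1 << TASK_BIT[op]
    return mask


@dataclass(frozen=True)
class ComplexityScore:
    raw: int
    normalized: float


def mask_tasks(mask: int) -> tuple[str, ...]:
    """Task names present in a phenotype mask."""
    return tuple(name for name in TASK_NAMES if mask & (1 << TASK_BIT[name]))


def phenotype_complexity(mask: int) -> ComplexityScore:
    """Sum of per-task complexities, normalized by the all-task score (25)."""
    if not 0 <= mask < N_PHENOTYPES:
        raise ValueError(f"phenotype id must be in 0..{N_PHENOTYPES - 1}")
    raw = sum(TASK_COMPLEXITY[name] for name in mask_tasks(mask))
    return ComplexityScore(raw=raw, normalized=raw / MAX_COMPLEXITY)


def mask_to_bitstring(mask: int) -> str:
    """9-character bitstring in task order NOT,NAND,AND,OR_N,OR,AND_N,NOR,XOR,EQU."""
    return "".join("1" if mask & (1 << i) else "0" for i in range(N_TASKS))


def bitstring_to_mask(bits: str) -> int:
    if len(bits) != N_TASKS or set(bits) - {"0", "1"}:
        raise ValueError("expected a 9-character 0/1 string")
    return sum(1 << i for i, b in enumerate(bits) if b == "1")
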