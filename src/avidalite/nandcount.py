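"""Minimum NAND-gate counts for two-input Boolean functions.

A two-input Boolean function is a 4-row truth table encoded as a 4-bit
integer: bit ``r`` (``r = 2*x + y``) holds ``f(x, y)``.  Starting from the
two projections x and y, a breadth-first search adds one NAND gate per
level; gate outputs are reusable (straight-line programs, not trees), which
is what makes AND cost 2 gates rather than 3.  The first level at which a
table appears is its NAND complexity; projections cost 0.
"""

from __future__ import annotations

from functools import lru_cache

TABLE_X = 0b1100  # rows 10,11 -> f=1
TABLE_Y = 0b1010  # rows 01,11 -> f=1
ALL_TABLES = range(16)

#: Truth tables of the nine logic tasks (NOT taken as NOT(x); the task's
#: complexity is independent of which input is negated).
TASK_TABLES = {
    "NOT": ~TABLE_X & 0xF,
    "NAND": ~(TABLE_X & TABLE_Y) & 0xF,
    "AND": TABLE_X & TABLE_Y,
    "OR_N": TABLE_X | (~TABLE_Y & 0xF),
    "OR": TABLE_X | TABLE_Y,
    "AND_N": TABLE_X & (~TABLE_Y & 0xF),
    "NOR": ~(TABLE_X | TABLE_Y) & 0xF,
    "XOR": TABLE_X ^ TABLE_Y,
    "EQU": ~(TABLE_X ^ TABLE_Y) & 0xF,
}


def nand_table(a: int, b: int) -> int:
    return ~(a & b) & 0xF


@lru_cache(maxsize=1)
def min_gates_table() -> dict[int, int]:
    """First BFS level at which each of the 16 truth tables appears.

    States are frozensets of available tables; each transition executes one
    NAND on any two available tables (the same table may feed both inputs)
    and adds the result.  BFS over states therefore finds, for every table,
    the minimum number of NAND executions in any straight-line program.
    """
    start = frozenset({TABLE_X, TABLE_Y})
    first_seen = {TABLE_X: 0, TABLE_Y: 0}
    frontier = {start}
    seen_states = {start}
    depth = 0
    while frontier and len(first_seen) < 16:
        depth += 1
        nxt = set()
        for avail in frontier:
            for a in avail:
                for b in avail:
                    t = nand_table(a, b)
                    if t in avail:
                        continue
                    state = avail | {t}
                    first_seen.setdefault(t, depth)
                    if state not in seen_states:
                        seen_states.add(state)
                        nxt.add(state)
        frontier = nxt
        if depth > 16:  # pragma: no cover - NAND is universal
            raise RuntimeError("BFS failed to reach all tables")
    return dict(first_seen)


def min_nand_gates(table: int) -> int:
    """Minimum number of NAND executions needed to compute ``table``."""
    if not 0 <= table < 16:
        raise ValueError("truth table must be a 4-bit integer")
    levels = min_gates_table()
    if table not in levels:  # pragma: no cover - NAND is universal
        raise ValueError(f"table {table:#06b} unreachable")
    return levels[table]


def task_nand_complexities() -> dict[str, int]:
    """NAND complexity of each of the nine logic tasks, by exhaustive search."""
    return {name: min_nand_gates(t) for name, t in TASK_TABLES.items()}
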