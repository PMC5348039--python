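"""Minimal Avida-style virtual CPU.

A digital organism is a circular sequence of instructions (its genome)
executed by a virtual CPU with three registers (AX, BX, CX), two stacks,
four heads (instruction pointer, read, write, flow) and a pair of input
buffers.  The organism replicates by allocating child memory (``h-alloc``),
copying itself instruction by instruction (``h-copy``) and splitting off the
copy (``h-divide``).  Logic tasks are performed on random input words taken
from the environment through the ``IO`` instruction and detected on every
emitted output word.

The test environment (:func:`run_test`) runs one organism in isolation, with
no mutations, until it divides or until it has executed ``limit_factor * L``
instructions.  Viability and phenotype are pure functions of the genome for a
fixed environment seed.

Differences from stock Avida are deliberate and documented in
``docs/instruction_set.md``; the main one is that ``h-alloc`` parks the write
head at the first allocated position, which lets compact replicators exist in
very small instruction alphabets.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from . import instructions as ins
from .instructions import AX, BX, CX, FLOW, IP, READ, WRITE
from .logic import detect_ops

MAX_LABEL = 10


@dataclass(frozen=True)
class VMConfig:
    """Execution parameters of the virtual CPU.

    word_width
        Width of the machine word in bits (32 in the standard configuration;
        micro configurations may use less so that degenerate task matches are
        easy to enumerate).
    limit_factor
        An organism may execute at most ``limit_factor * L`` instructions in
        the test environment before it is declared inviable.
    fidelity
        ``"exact"``: a divided organism is viable only if the offspring is a
        letter-perfect copy of the parent (the test protocol applies no
        mutations, so self-replication must be faithful).  ``"copied"``:
        any structurally legal division counts as viable.
    alphabet
        Letters available to *generators* (random genomes, mutations,
        neighbor enumeration).  Execution always understands all 26 letters.
    """

    word_width: int = 32
    limit_factor: int = 20
    fidelity: str = "exact"
    alphabet: str = ins.LETTERS
    fill_code: int = 0  # allocated child memory is filled with nop-a

    def __post_init__(self):
        if self.fidelity not in ("exact", "copied"):
            raise ValueError(f"unknown fidelity mode {self.fidelity!r}")
        if not (1 <= self.word_width <= 32):
            raise ValueError("word_width must be in 1..32")
        if self.limit_factor < 1:
            raise ValueError("limit_factor must be >= 1")

    @property
    def mask(self) -> int:
        return (1 << self.word_width) - 1


class EnvironmentStream:
    """Deterministic stream of random input words.

    The served word sequence is a pure function of ``seed`` (and the word
    width), so an organism's phenotype is a pure function of its genotype for
    a fixed environment seed.
    """

    def __init__(self, seed: int, word_width: int = 32):
        self.seed = seed
        self.word_width = word_width
        self._rng = random.Random(seed)
        self.served: list[int] = []

    def next_word(self) -> int:
        word = self._rng.getrandbits(self.word_width)
        self.served.append(word)
        return word


@dataclass
class CpuState:
    """Mutable CPU state of one executing organism."""

    memory: list[int]
    parent_length: int
    regs: list[int] = field(default_factory=lambda: [0, 0, 0])
    stacks: tuple[list[int], list[int]] = field(default_factory=lambda: ([], []))
    active_stack: int = 0
    heads: list[int] = field(default_factory=lambda: [0, 0, 0, 0])
    input1: int | None = None
    input2: int | None = None
    outputs: list[tuple[int, int | None, int | None]] = field(default_factory=list)
    allocated: bool = False
    copied: set[int] = field(default_factory=set)
    copy_history: list[int] = field(default_factory=list)
    executed: int = 0
    visited: set[int] = field(default_factory=set)
    offspring: list[int] | None = None
    gestation: int | None = None

    @property
    def memlen(self) -> int:
        return len(self.memory)


@dataclass(frozen=True)
class TestResult:
    """Outcome of evaluating one genome in the isolated test environment."""

    genome: str
    viable: bool
    executed: int
    gestation: int | None
    offspring: str | None
    faithful: bool
    phenotype: int  # 9-bit task mask; 0 = merely viable (or inviable)
    fraction_executed: float


def initial_state(codes: list[int]) -> CpuState:
    if len(codes) < 1:
        raise ValueError("genome must contain at least one instruction")
    return CpuState(memory=list(codes), parent_length=len(codes))


def _consume_nop(state: CpuState) -> int | None:
    """Peek at the next instruction; if it is a nop, consume it as an
    argument of the current instruction (the IP skips it) and return its
    opcode."""
    pos = state.heads[IP] % state.memlen
    code = state.memory[pos]
    if ins.is_nop(code):
        state.visited.add(pos)
        state.heads[IP] = (pos + 1) % state.memlen
        return code
    return None


def _read_label(state: CpuState) -> list[int]:
    """Consume the run of nops following the current instruction (at most
    MAX_LABEL, so an all-nop genome cannot trap the reader)."""
    label: list[int] = []
    while len(label) < MAX_LABEL:
        code = _consume_nop(state)
        if code is None:
            break
        label.append(code)
    return label


def _skip_next(state: CpuState) -> None:
    state.heads[IP] = (state.heads[IP] + 1) % state.memlen


def _modified_register(state: CpuState, default: int) -> int:
    code = _consume_nop(state)
    return ins.NOP_REGISTER[code] if code is not None else default


def _modified_head(state: CpuState, default: int = IP) -> int:
    code = _consume_nop(state)
    return ins.NOP_HEAD[code] if code is not None else default


def _find_label(state: CpuState, target: list[int]) -> int | None:
    """Circular scan for ``target`` (a run of specific nops) starting at the
    current IP; returns the offset to the start of the first match."""
    mem, n, k = state.memory, state.memlen, len(target)
    start = state.heads[IP] % n
    for off in range(n):
        s = start + off
        if all(mem[(s + j) % n] == target[j] for j in range(k)):
            return off
    return None


def _attempt_divide(state: CpuState) -> bool:
    """Structural division legality: an allocation exists, the offspring
    region (read head up to write head, circularly) is nonempty, and every
    position in it was written by h-copy."""
    if not state.allocated:
        return False
    n = state.memlen
    r = state.heads[READ] % n
    w = state.heads[WRITE] % n
    length = (w - r) % n
    if length == 0:
        return False
    region = [(r + j) % n for j in range(length)]
    if any(p not in state.copied for p in region):
        return False
    state.offspring = [state.memory[p] for p in region]
    state.gestation = state.executed
    return True


def step(state: CpuState, cfg: VMConfig, env: EnvironmentStream) -> CpuState:
    """Execute exactly one instruction (mutating and returning ``state``).

    A nop argument consumed by the executed instruction does not count as an
    executed instruction itself, but its position counts as visited for the
    execution profile.
    """
    n = state.memlen
    pos = state.heads[IP] % n
    code = state.memory[pos]
    state.visited.add(pos)
    state.heads[IP] = (pos + 1) % n
    state.executed += 1
    mask = cfg.mask
    regs = state.regs

    if code < 3:  # nop-a / nop-b / nop-c
        pass
    elif code == 3:  # if-n-equ: execute next iff ?BX? != complement
        reg = _modified_register(state, BX)
        if regs[reg] == regs[ins.complement_register(reg)]:
            _skip_next(state)
    elif code == 4:  # if-less: execute next iff ?BX? < complement
        reg = _modified_register(state, BX)
        if not regs[reg] < regs[ins.complement_register(reg)]:
            _skip_next(state)
    elif code == 5:  # if-label
        label = _read_label(state)
        target = [ins.complement_nop(c) for c in label]
        ok = bool(label) and state.copy_history[-len(target):] == target
        if not ok:
            _skip_next(state)
    elif code == 6:  # mov-head: move ?IP? to the flow head
        head = _modified_head(state)
        state.heads[head] = state.heads[FLOW] % n
    elif code == 7:  # jmp-head: move ?IP? by CX positions
        head = _modified_head(state)
        state.heads[head] = (state.heads[head] + regs[CX]) % n
    elif code == 8:  # get-head: CX = position of ?IP?
        head = _modified_head(state)
        regs[CX] = state.heads[head] % n
    elif code == 9:  # set-flow: flow head = value of ?CX?
        reg = _modified_register(state, CX)
        state.heads[FLOW] = regs[reg] % n
    elif code == 10:  # shift-r
        reg = _modified_register(state, BX)
        regs[reg] >>= 1
    elif code == 11:  # shift-l
        reg = _modified_register(state, BX)
        regs[reg] = (regs[reg] << 1) & mask
    elif code == 12:  # inc
        reg = _modified_register(state, BX)
        regs[reg] = (regs[reg] + 1) & mask
    elif code == 13:  # dec
        reg = _modified_register(state, BX)
        regs[reg] = (regs[reg] - 1) & mask
    elif code == 14:  # push
        reg = _modified_register(state, BX)
        state.stacks[state.active_stack].append(regs[reg])
    elif code == 15:  # pop (empty stack yields 0)
        reg = _modified_register(state, BX)
        stack = state.stacks[state.active_stack]
        regs[reg] = stack.pop() if stack else 0
    elif code == 16:  # swap-stk
        state.active_stack ^= 1
    elif code == 17:  # swap ?BX? with its complement
        reg = _modified_register(state, BX)
        comp = ins.complement_register(reg)
        regs[reg], regs[comp] = regs[comp], regs[reg]
    elif code == 18:  # add: ?BX? = BX + CX
        reg = _modified_register(state, BX)
        regs[reg] = (regs[BX] + regs[CX]) & mask
    elif code == 19:  # sub: ?BX? = BX - CX
        reg = _modified_register(state, BX)
        regs[reg] = (regs[BX] - regs[CX]) & mask
    elif code == 20:  # nand: ?BX? = ~(BX & CX)
        reg = _modified_register(state, BX)
        regs[reg] = ~(regs[BX] & regs[CX]) & mask
    elif code == 21:  # h-copy
        r = state.heads[READ] % n
        w = state.heads[WRITE] % n
        state.memory[w] = state.memory[r]
        state.copy_history.append(state.memory[r])
        state.copied.add(w)
        state.heads[READ] = (r + 1) % n
        state.heads[WRITE] = (w + 1) % n
    elif code == 22:  # h-alloc
        if not state.allocated:
            old = state.memlen
            state.memory.extend([cfg.fill_code] * state.parent_length)
            state.allocated = True
            # Park the write head at the start of the child region (see
            # docs/instruction_set.md for why this differs from stock Avida).
            state.heads[WRITE] = old
    elif code == 23:  # h-divide
        _attempt_divide(state)
    elif code == 24:  # IO
        reg = _modified_register(state, BX)
        state.outputs.append((regs[reg], state.input1, state.input2))
        word = env.next_word()
        regs[reg] = word
        state.input2 = state.input1
        state.input1 = word
    elif code == 25:  # h-search
        label = _read_label(state)
        if not label:
            state.heads[FLOW] = state.heads[IP] % n
            regs[BX] = 0
            regs[CX] = 0
        else:
            target = [ins.complement_nop(c) for c in label]
            off = _find_label(state, target)
            if off is None:
                state.heads[FLOW] = state.heads[IP] % n
                regs[BX] = 0
                regs[CX] = 0
            else:
                start = (state.heads[IP] + off) % n
                state.heads[FLOW] = (start + len(target)) % n
                regs[BX] = off
                regs[CX] = len(target)
    else:  # pragma: no cover
        raise ValueError(f"unknown opcode {code}")
    return state


def run_test(
    genome: str,
    env: EnvironmentStream | int = 42,
    cfg: VMConfig | None = None,
    limit_factor: int | None = None,
) -> TestResult:
    """Evaluate one genome in the isolated test environment.

    Executes at most ``limit_factor * L`` instructions or until the organism
    divides, whichever comes first.  The result is bit-identical across runs
    for a fixed environment seed.
    """
    cfg = cfg or VMConfig()
    if limit_factor is None:
        limit_factor = cfg.limit_factor
    if isinstance(env, int):
        env = EnvironmentStream(env, cfg.word_width)
    codes = ins.to_codes(genome)
    state = initial_state(codes)
    limit = limit_factor * len(codes)
    while state.executed < limit and state.offspring is None:
        step(state, cfg, env)

    divided = state.offspring is not None
    faithful = divided and state.offspring == codes
    viable = divided and (faithful or cfg.fidelity == "copied")
    mask = 0
    if viable:
        for out, in1, in2 in state.outputs:
            if in1 is not None and in2 is not None:
                mask |= detect_ops(out, (in1, in2), cfg.word_width)
    L = state.parent_length
    fraction = len([p for p in state.visited if p < L]) / L
    return TestResult(
        genome=genome,
        viable=viable,
        executed=state.executed,
        gestation=state.gestation if viable else None,
        offspring=ins.to_letters(state.offspring) if viable else None,
        faithful=faithful,
        phenotype=mask,
        fraction_executed=fraction,
    )


def execution_profile(result: TestResult) -> tuple[float, int]:
    """(fraction of distinct genome positions executed, instructions executed)."""
    return result.fraction_executed, result.executed
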