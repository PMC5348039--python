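"""The 26-letter "heads" instruction alphabet.

Each instruction is a single lower-case letter; the letter <-> opcode bijection
is fixed and position 0-25 in :data:`NAMES` is the opcode.  Full execution
semantics live in :mod:`avidalite.vm` and are documented instruction by
instruction in ``docs/instruction_set.md``.
"""

from __future__ import annotations

LETTERS = "abcdefghijklmnopqrstuvwxyz"

#: Instruction names in opcode order (a=0 ... z=25).
NAMES = (
    "nop-a",      # a
    "nop-b",      # b
    "nop-c",      # c
    "if-n-equ",   # d
    "if-less",    # e
    "if-label",   # f
    "mov-head",   # g
    "jmp-head",   # h
    "get-head",   # i
    "set-flow",   # j
    "shift-r",    # k
    "shift-l",    # l
    "inc",        # m
    "dec",        # n
    "push",       # o
    "pop",        # p
    "swap-stk",   # q
    "swap",       # r
    "add",        # s
    "sub",        # t
    "nand",       # u
    "h-copy",     # v
    "h-alloc",    # w
    "h-divide",   # x
    "IO",         # y
    "h-search",   # z
)

ALPHABET_SIZE = 26

CODE_OF = {name: i for i, name in enumerate(NAMES)}
LETTER_OF_CODE = {i: LETTERS[i] for i in range(ALPHABET_SIZE)}
CODE_OF_LETTER = {LETTERS[i]: i for i in range(ALPHABET_SIZE)}

#: Opcodes of the three no-operation instructions; they double as arguments
#: (register / head selectors and labels) for the instruction that precedes
#: them.
NOP_CODES = (0, 1, 2)

# Register indices.
AX, BX, CX = 0, 1, 2
REGISTER_NAMES = ("AX", "BX", "CX")

# Head indices.
IP, READ, WRITE, FLOW = 0, 1, 2, 3
HEAD_NAMES = ("IP", "READ", "WRITE", "FLOW")

#: nop-a/b/c select AX/BX/CX when an instruction expects a register argument,
#: and IP/READ/WRITE when it expects a head argument.
NOP_REGISTER = {0: AX, 1: BX, 2: CX}
NOP_HEAD = {0: IP, 1: READ, 2: WRITE}


def is_nop(code: int) -> bool:
    return code < 3


def complement_nop(code: int) -> int:
    """Complement cycle used by labels: nop-a -> nop-b -> nop-c -> nop-a."""
    return (code + 1) % 3


def complement_register(reg: int) -> int:
    """Complement cycle for registers: AX -> BX -> CX -> AX."""
    return (reg + 1) % 3


def to_codes(genome: str) -> list[int]:
    return [CODE_OF_LETTER[ch] for ch in genome]


def to_letters(codes) -> str:
    return "".join(LETTERS[c] for c in codes)
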