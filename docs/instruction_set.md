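# Instruction set reference

Genomes are circular sequences over a 26-letter alphabet, one instruction per
letter.  The CPU holds three word registers (AX, BX, CX), two stacks with one
active-stack flag, four heads into memory (instruction pointer IP, read head,
write head, flow head), a pair of input buffers (input-1 = most recent,
input-2 = previous), and an output log.  Words are unsigned with wraparound
arithmetic at the configured width (32 bits by default).  Head positions are
always reduced modulo the current memory length.

## Nop arguments

`nop-a`, `nop-b`, `nop-c` do nothing when executed.  Their second role is as
*arguments*: an instruction that expects a register or head operand peeks at
the instruction following it; if it is a nop, the nop is consumed (the IP
skips past it, and the consumed position counts as visited for the execution
profile but not as an executed instruction) and selects the operand:

| nop    | register | head  |
|--------|----------|-------|
| nop-a  | AX       | IP    |
| nop-b  | BX       | READ  |
| nop-c  | CX       | WRITE |

`?BX?` below means "BX unless modified by a following nop".  Labels are
maximal runs of nops (capped at 10) read the same way; label matching always
uses the *complement* label under the cycle nop-a → nop-b → nop-c → nop-a.
The register complement cycle is AX → BX → CX → AX.

## Instructions

| letter | name | effect |
|---|---|---|
| a,b,c | nop-a/b/c | no effect |
| d | if-n-equ | execute the next instruction iff `?BX?` ≠ its complement register, else skip exactly one instruction |
| e | if-less  | execute the next instruction iff `?BX?` < its complement register (unsigned), else skip one |
| f | if-label | read the following label; execute the next instruction iff the most recently copied instructions end with the complement label (empty label: never) |
| g | mov-head | move head `?IP?` to the flow head's position |
| h | jmp-head | move head `?IP?` by CX positions |
| i | get-head | CX = position of head `?IP?` |
| j | set-flow | flow head = value of `?CX?` mod memory length |
| k | shift-r  | `?BX?` >>= 1 |
| l | shift-l  | `?BX?` <<= 1 (masked to the word width) |
| m | inc      | `?BX?` += 1 |
| n | dec      | `?BX?` -= 1 |
| o | push     | push `?BX?` onto the active stack |
| p | pop      | `?BX?` = pop from the active stack (empty stack yields 0) |
| q | swap-stk | toggle the active stack |
| r | swap     | exchange `?BX?` with its complement register |
| s | add      | `?BX?` = BX + CX |
| t | sub      | `?BX?` = BX - CX |
| u | nand     | `?BX?` = ~(BX & CX): returns 0 at a bit position iff both inputs are 1 |
| v | h-copy   | memory[write] = memory[read]; record the copied instruction (for if-label); mark the written position as copied; advance both heads |
| w | h-alloc  | once per gestation: extend memory by the parent length (filled with nop-a) and park the write head at the first allocated position; registers unchanged |
| x | h-divide | attempt division (below); a failed attempt is a no-op |
| y | IO       | append (`?BX?`, input-1, input-2) to the output log and check it for logic tasks; then load a fresh random word into `?BX?`, shift input-1 to input-2 and store the new word in input-1 |
| z | h-search | read the following label; scan memory circularly for the complement label; on a hit set flow = position after the found label, BX = distance, CX = label length; with no label (or no hit) set flow = next position, BX = CX = 0 |

## Division and viability

`h-divide` succeeds iff an allocation exists, the offspring region — from the
read head up to (but excluding) the write head, circularly — is nonempty, and
every position in it was written by `h-copy`.  The offspring is the contents
of that region.  In the test environment the first successful division ends
the run; the organism is viable iff it divided within `20 * L` executed
instructions and (in the default `exact` fidelity mode) the offspring is a
letter-perfect copy of the parent.  The `copied` mode accepts any legal
division — useful in evolving populations, where mutations are applied to
the offspring, and in micro spaces where rotated self-copies are common.

## Deviations from stock Avida

* **h-alloc parks the write head at the child region.**  Stock Avida leaves
  all heads untouched; the canonical copy-loop ancestor positions the write
  head itself via `h-search` + `mov-head nop-c`, and that path behaves
  identically here.  Parking the head additionally lets compact replicators
  (e.g. `wvx`, `wvvx`) exist in tiny alphabets without head-movement
  instructions, which keeps exhaustively enumerable micro spaces non-trivial.
* **h-alloc leaves registers unchanged** (stock Avida reports the old memory
  size in a register; nothing here depends on it).
* Conditionals skip exactly one instruction; a skipped instruction's own nop
  arguments are then executed as plain nops.
* Labels are capped at 10 nops; `h-search` with an absent label degrades to
  "mark the next position".

## A worked replication cycle

`wzcag` + `c`\*k + `zvfcaxgab` (any L ≥ 15): `h-alloc` doubles memory;
`h-search ca` finds the complement label `ab` at the genome's tail and places
the flow head just past it (= the child region); `mov-head nop-c` parks the
write head there; the filler nops fall through to `h-search` (no label),
which marks the loop start; then `h-copy` / `if-label ca` / `h-divide` /
`mov-head nop-a` copy one instruction per pass and divide exactly when the
trailing `ab` has been copied — a faithful offspring after ~3 executed
instructions per copied position.
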