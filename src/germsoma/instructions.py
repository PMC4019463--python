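"""Instruction set and circular genomes for the digital cells.

The instruction set is a reduced Avida-style "heads" set: three no-op/label
instructions, conditionals, head movement, the self-replication machinery
(h-alloc / h-copy / h-divide), stack and arithmetic operations, the ``nand``
primitive from which all nine rewarded Boolean logic functions are composable,
an ``io`` instruction that couples a cell to its environment, facing rotation,
and the seven coordination/differentiation instructions (``get_xy``,
``send_message``, ``broadcast_message``, ``retrieve_message``,
``block_propagation``, ``if_propagule_eligible``, ``if_propagule_ineligible``).

Opcodes are small integers, stable across runs; genomes are stored as int8
arrays indexed modularly (position L is position 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "Instruction",
    "InstructionSet",
    "Genome",
    "INSTRUCTION_SET",
    "NEUTRAL_INSTRUCTION",
]


@dataclass(frozen=True)
class Instruction:
    """A named executable with a unique small-integer opcode."""

    name: str
    opcode: int


_NAMES = [
    "nop-a",                   # 0  label no-op
    "nop-b",                   # 1  label no-op
    "nop-c",                   # 2  label no-op; designated neutral knockout filler
    "if-less",                 # 3  execute next iff BX < CX
    "if-n-equ",                # 4  execute next iff BX != CX
    "if-label",                # 5  execute next iff complement label just copied
    "mov-head",                # 6  IP <- FLOW
    "jmp-head",                # 7  IP <- IP + signed(CX)
    "h-search",                # 8  FLOW <- after complement of trailing label
    "h-alloc",                 # 9  allocate offspring memory, reset copy state
    "h-copy",                  # 10 copy one instruction parent -> offspring
    "h-divide",                # 11 finish division if the copy is complete
    "push",                    # 12 push BX
    "pop",                     # 13 BX <- pop (0 if empty)
    "swap",                    # 14 BX <-> CX
    "inc",                     # 15 BX += 1
    "dec",                     # 16 BX -= 1
    "add",                     # 17 BX += CX
    "sub",                     # 18 BX -= CX
    "nand",                    # 19 BX <- ~(BX & CX)
    "io",                      # 20 output BX (logic evaluation), BX <- next input
    "rotate-l",                # 21 facing one step counter-clockwise
    "rotate-r",                # 22 facing one step clockwise
    "get_xy",                  # 23 BX <- x, CX <- y
    "send_message",            # 24 send (BX, CX) to the faced neighbour
    "broadcast_message",       # 25 send (BX, CX) to all occupied neighbours
    "retrieve_message",        # 26 (BX, CX) <- oldest inbox message
    "block_propagation",       # 27 eligible <- False (absorbing)
    "if_propagule_eligible",   # 28 execute next iff eligible
    "if_propagule_ineligible", # 29 execute next iff not eligible
]

# opcode aliases used by the execution kernel
NOP_A, NOP_B, NOP_C = 0, 1, 2
IF_LESS, IF_N_EQU, IF_LABEL = 3, 4, 5
MOV_HEAD, JMP_HEAD, H_SEARCH = 6, 7, 8
H_ALLOC, H_COPY, H_DIVIDE = 9, 10, 11
PUSH, POP, SWAP, INC, DEC, ADD, SUB, NAND = 12, 13, 14, 15, 16, 17, 18, 19
IO, ROTATE_L, ROTATE_R = 20, 21, 22
GET_XY, SEND_MSG, BCAST_MSG, RETRIEVE_MSG = 23, 24, 25, 26
BLOCK_PROPAGATION, IF_ELIGIBLE, IF_INELIGIBLE = 27, 28, 29

NEUTRAL_INSTRUCTION = "nop-c"


class InstructionSet:
    """Ordered collection of instructions with unique names and opcodes."""

    def __init__(self, names: Iterable[str] = _NAMES):
        names = list(names)
        if len(set(names)) != len(names):
            raise ValueError("instruction names must be unique")
        self.instructions = [Instruction(n, i) for i, n in enumerate(names)]
        self._by_name = {ins.name: ins for ins in self.instructions}

    def __len__(self) -> int:
        return len(self.instructions)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, key: int | str) -> Instruction:
        if isinstance(key, str):
            return self._by_name[key]
        return self.instructions[key]

    def opcode(self, name: str) -> int:
        try:
            return self._by_name[name].opcode
        except KeyError:
            raise KeyError(f"unknown instruction {name!r}") from None

    def name(self, opcode: int) -> str:
        return self.instructions[opcode].name

    @property
    def neutral_opcode(self) -> int:
        return self.opcode(NEUTRAL_INSTRUCTION)


INSTRUCTION_SET = InstructionSet()


class Genome:
    """A circular sequence of instructions; the unit of heredity and mutation.

    Indexing is modular: ``genome[L]`` is ``genome[0]``.
    """

    def __init__(self, ops, iset: InstructionSet = INSTRUCTION_SET):
        if isinstance(ops, Genome):
            ops = ops.ops
        arr = []
        for op in ops:
            if isinstance(op, str):
                arr.append(iset.opcode(op))
            else:
                op = int(op)
                if not 0 <= op < len(iset):
                    raise ValueError(f"opcode {op} outside instruction set")
                arr.append(op)
        if len(arr) < 1:
            raise ValueError("genome must contain at least one instruction")
        self.ops = np.asarray(arr, dtype=np.int8)
        self.iset = iset

    def __len__(self) -> int:
        return len(self.ops)

    def __getitem__(self, i: int) -> str:
        return self.iset.name(int(self.ops[i % len(self.ops)]))

    def __iter__(self) -> Iterator[str]:
        return (self.iset.name(int(o)) for o in self.ops)

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and np.array_equal(self.ops, other.ops)

    def __hash__(self):
        return hash(self.ops.tobytes())

    def __repr__(self) -> str:
        return f"Genome(length={len(self)})"

    @property
    def names(self) -> list[str]:
        return list(self)

    def count(self, name: str) -> int:
        return int(np.sum(self.ops == self.iset.opcode(name)))

    def replaced(self, target: str, replacement: str) -> "Genome":
        """Return a copy with every ``target`` replaced by ``replacement``."""
        ops = self.ops.copy()
        ops[ops == self.iset.opcode(target)] = self.iset.opcode(replacement)
        return Genome(ops, self.iset)
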