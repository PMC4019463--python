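"""Hand-authored genomes: the ancestor and differentiating reference cells.

The ancestor encodes self-replication plus the non-mutagenic logic function
NOT, in the classic layout: a short functional core, a long neutral nop
cassette (raw material for evolution), and a heads-style copy loop terminated
by a copied-label check.

The differentiated genomes are engineered examples of the two phenotypic-
plasticity mechanisms observed to evolve: conditional ``block_propagation``
driven by location information (``get_xy`` + ``if-less``) or by communicated
signals (``retrieve_message`` + ``if-less``).  In both, blocked (soma) cells
settle into a work loop performing mutagenic logic functions while eligible
(germ) cells only replicate, so the propagule workload difference is positive.
"""

from __future__ import annotations

from .instructions import Genome

__all__ = [
    "build_ancestor",
    "build_differentiated_fixture",
    "build_mutagenic_fixture",
]

_REPLICATION_LOOP = [
    # allocate offspring memory, then copy until the end label (nop-a nop-b,
    # the complement of nop-c nop-a) has just been copied, then divide
    "h-alloc",
    "h-search",          # no label: FLOW <- the h-copy below
    "h-copy",
    "if-label", "nop-c", "nop-a",
    "h-divide",
    "mov-head",          # back to h-copy
    "nop-a", "nop-b",    # end label
]


def build_ancestor(padding: int = 34) -> Genome:
    """Self-replicating NOT performer; all cells remain propagule-eligible.

    NOT(a) is composed as NAND(a, a): the input is duplicated into BX and CX
    through the stack, ``nand`` inverts it, and ``io`` outputs the result.
    """
    return Genome(
        ["io",              # BX <- input a
         "push",            # save a
         "swap",            # CX <- 0 juggling; see pop
         "pop",             # BX <- a  (now BX = CX's complement source)
         "nand",            # BX <- ~(a & a) = NOT a
         "io"]              # output NOT a (credited), BX <- next input
        + ["nop-c"] * padding
        + _REPLICATION_LOOP
    )


def _location_fixture() -> Genome:
    """Cells at grid positions with x < y block propagation and loop over
    NAND work; all other cells stay eligible and replicate."""
    return Genome([
        "h-search", "nop-b", "nop-a",   # FLOW <- soma entry (after nop-c nop-b)
        "get_xy",                       # BX <- x, CX <- y
        "if-less",                      # x < y ?
        "mov-head",                     # -> soma
        # germ: replicate
        "h-alloc",
        "h-search",
        "h-copy",
        "if-label", "nop-c", "nop-a",
        "h-divide",
        "mov-head",
        # soma section
        "nop-c", "nop-b",               # marker (complement of nop-b nop-a)
        "block_propagation",
        "io", "swap", "io", "nand", "io",   # NAND work loop
        "mov-head",
        "nop-a", "nop-b",               # copy end label
    ])


def _messaging_fixture() -> Genome:
    """Message-recruited soma on top of location-seeded soma.

    Location-differentiated soma (x < y) perform NAND and continually send
    their coordinates to the one neighbour they face; a cell that retrieves
    such a message (payload BX < CX) blocks propagation too and settles into
    an AND work loop.  Without ``retrieve_message`` the second soma caste
    never forms and the AND resource stream is lost.
    """
    return Genome([
        "h-search", "nop-a", "nop-a",   # FLOW <- message-soma entry
        "push", "swap", "pop",          # BX <- CX == BX (equal: fail-safe default)
        "retrieve_message",             # payload (x, y) of a sender, if any
        "if-less",                      # got a recruit message (BX < CX) ?
        "get_xy",                       # ... then consider own position
        "swap",                         # BX <- y, CX <- x
        "if-less",                      # y < x: recruitable half of the grid
        "mov-head",                     # -> message soma
        "h-search", "nop-b", "nop-a",   # FLOW <- location-soma entry
        "get_xy",
        "if-less",                      # x < y ?
        "mov-head",                     # -> location soma
        # germ (the x == y diagonal, or unrecruited): replicate
        "h-alloc",
        "h-search",
        "h-copy",
        "if-label", "nop-c", "nop-a",
        "h-divide",
        "mov-head",
        # location soma: NAND work + recruiting
        "nop-c", "nop-b",               # marker
        "block_propagation",
        "get_xy",
        "send_message",                 # recruit the faced neighbour with (x, y)
        "io", "swap", "io", "nand", "io",
        "mov-head",
        # message soma: AND work
        "nop-b", "nop-b",               # marker
        "block_propagation",
        "io", "swap", "io", "nand",
        "push", "swap", "pop", "nand",  # AND = NAND(NAND(a,b), NAND(a,b))
        "io",
        "mov-head",
        "nop-a", "nop-b",               # copy end label
    ])


def build_differentiated_fixture(kind: str = "location") -> Genome:
    """Hand-built differentiating genome (``kind``: 'location' | 'messaging')."""
    if kind == "location":
        return _location_fixture()
    if kind == "messaging":
        return _messaging_fixture()
    raise ValueError("kind must be 'location' or 'messaging'")


def build_mutagenic_fixture() -> Genome:
    """Undifferentiated self-replicator whose every cell performs the
    mutagenic function NAND each cycle — ages under any nonzero FML."""
    return Genome(
        ["io",              # BX <- a
         "swap",            # CX <- a
         "io",              # BX <- b
         "nand",            # BX <- NAND(a, b)
         "io"]              # output (credited)
        + _REPLICATION_LOOP
    )
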