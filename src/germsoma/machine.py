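"""Virtual-CPU execution kernel.

Each digital cell owns a circular genome, three 32-bit registers (AX, BX, CX;
wraparound arithmetic), two depth-10 stacks (the reduced instruction set uses
stack 0), four heads (IP, READ, WRITE, FLOW), a two-slot input buffer, a facing
direction on the Moore neighbourhood of its 5x5 toroidal grid, and a bounded
FIFO inbox.  One *update* is the standard unit of time: every cell executes 30
instructions.

The whole population state lives in flat numpy arrays (one slot per grid
position of every multicell) so the inner loop can be compiled with numba;
the object layer in :mod:`germsoma.multicell` and :mod:`germsoma.world` is a
thin view over these arrays.  Randomness is explicit and replayable: one
splitmix64 stream per multicell (mutagenesis, tie-breaks, offspring facing)
and one per cell (the environment input stream), all derived from the run
seed, so identical (genome, state, seed) always yields identical behaviour.
"""

from __future__ import annotations

from collections import namedtuple

import numpy as np
from numba import njit


__all__ = [
    "State",
    "Config",
    "make_state",
    "make_config",
    "seed_cell",
    "clear_multicell",
    "run_update",
    "step_cell",
    "evaluate_logic",
    "FUNCTION_NAMES",
    "N_FUNCTIONS",
]

# The nine rewarded Boolean logic functions, in canonical order.
FUNCTION_NAMES = ["NOT", "NAND", "AND", "ORNOT", "OR", "ANDNOT", "NOR", "XOR", "EQUALS"]
N_FUNCTIONS = 9

INBOX_CAPACITY = 16
STACK_DEPTH = 10
BLOCKLOG_CAPACITY = 8192

# Moore neighbourhood, facing index 0..7 (E, SE, S, SW, W, NW, N, NE)
DX = np.array([1, 1, 0, -1, -1, -1, 0, 1], dtype=np.int64)
DY = np.array([0, 1, 1, 1, 0, -1, -1, -1], dtype=np.int64)

M32 = np.uint64(0xFFFFFFFF)
_SM_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_SM_M1 = np.uint64(0xBF58476D1CE4E5B9)
_SM_M2 = np.uint64(0x94D049BB133111EB)
_INV53 = 1.0 / 9007199254740992.0

State = namedtuple(
    "State",
    [
        "grid",        # (2,) int64: width, height
        "glen",        # (M, C) int32 genome length (0 = empty slot)
        "genome",      # (M, C, G) int8
        "alive",       # (M, C) bool
        "eligible",    # (M, C) bool
        "born",        # (M, C) int64 update of birth
        "regs",        # (M, C, 3) uint64, masked to 32 bits (AX, BX, CX)
        "stack",       # (M, C, 2, STACK_DEPTH) uint64
        "sp",          # (M, C, 2) int8
        "heads",       # (M, C, 4) int32 (IP, READ, WRITE, FLOW)
        "inputs",      # (M, C, 2) uint64 (older, newer)
        "ninputs",     # (M, C) int32
        "facing",      # (M, C) int8
        "childbuf",    # (M, C, G) int8 offspring memory
        "copied",      # (M, C) int32
        "allocated",   # (M, C) bool
        "lastcopied",  # (M, C, 3) int8 most recently copied opcodes (-1 empty)
        "counts",      # (M, C, 9) int64 per-function performance tallies
        "inbox",       # (M, C, INBOX_CAPACITY, 2) uint64
        "inbox_n",     # (M, C) int8
        "inbox_head",  # (M, C) int8
        "ledger",      # (M, C) float64 accrued expected mutagenesis
        "tag",         # (M, C) bool lineage tag (defector assays)
        "cell_id",     # (M, C) int64
        "cell_parent", # (M, C) int64
        "cellrng",     # (M, C) uint64 per-cell input stream state
        "mcrng",       # (M,) uint64 per-multicell event stream state
        "pools",       # (M, 9) float64 resource pools
        "tally",       # (M,) float64 resources amassed toward replication
        "age",         # (M,) int64 updates since founding
        "next_cell_id",# (1,) int64
        "blocklog",    # (BLOCKLOG_CAPACITY, 2) int64 (m, c) of block transitions
        "blocklog_id", # (BLOCKLOG_CAPACITY,) int64 cell id
        "blocklog_n",  # (1,) int64
    ],
)

Config = namedtuple(
    "Config",
    [
        "fml",              # (9,) float64 per-function mutagen level
        "consumption",      # float64, fraction of pool acquired per performance
        "unlimited",        # (9,) bool, unlimited-resource functions
        "unlimited_amount", # float64 reward per performance when unlimited
        "redistribute",     # bool, redistribute eligible-cell mutagenesis
        "block_allowed",    # bool, block_propagation active
        "ipu",              # int64 instructions per update
        "gmax",             # int64 maximum genome / offspring length
    ],
)


def make_config(
    fml,
    consumption=0.05,
    unlimited=None,
    unlimited_amount=5.0,
    redistribute=False,
    block_allowed=True,
    ipu=30,
    gmax=125,
) -> Config:
    fml = np.asarray(fml, dtype=np.float64)
    if fml.shape != (N_FUNCTIONS,):
        raise ValueError("fml table must have 9 entries")
    if unlimited is None:
        unlimited = np.zeros(N_FUNCTIONS, dtype=np.bool_)
    else:
        unlimited = np.asarray(unlimited, dtype=np.bool_)
    return Config(
        fml=fml,
        consumption=float(consumption),
        unlimited=unlimited,
        unlimited_amount=float(unlimited_amount),
        redistribute=bool(redistribute),
        block_allowed=bool(block_allowed),
        ipu=int(ipu),
        gmax=int(gmax),
    )


def make_state(n_multicells: int, gmax: int, seed_seq: np.random.SeedSequence,
               width: int = 5, height: int = 5) -> State:
    M, C, G = int(n_multicells), int(width * height), int(gmax)
    seeds = seed_seq.generate_state(M + M * C, dtype=np.uint64)
    return State(
        grid=np.array([width, height], dtype=np.int64),
        glen=np.zeros((M, C), dtype=np.int32),
        genome=np.zeros((M, C, G), dtype=np.int8),
        alive=np.zeros((M, C), dtype=np.bool_),
        eligible=np.zeros((M, C), dtype=np.bool_),
        born=np.full((M, C), -1, dtype=np.int64),
        regs=np.zeros((M, C, 3), dtype=np.uint64),
        stack=np.zeros((M, C, 2, STACK_DEPTH), dtype=np.uint64),
        sp=np.zeros((M, C, 2), dtype=np.int8),
        heads=np.zeros((M, C, 4), dtype=np.int32),
        inputs=np.zeros((M, C, 2), dtype=np.uint64),
        ninputs=np.zeros((M, C), dtype=np.int32),
        facing=np.zeros((M, C), dtype=np.int8),
        childbuf=np.zeros((M, C, G), dtype=np.int8),
        copied=np.zeros((M, C), dtype=np.int32),
        allocated=np.zeros((M, C), dtype=np.bool_),
        lastcopied=np.full((M, C, 3), -1, dtype=np.int8),
        counts=np.zeros((M, C, N_FUNCTIONS), dtype=np.int64),
        inbox=np.zeros((M, C, INBOX_CAPACITY, 2), dtype=np.uint64),
        inbox_n=np.zeros((M, C), dtype=np.int8),
        inbox_head=np.zeros((M, C), dtype=np.int8),
        ledger=np.zeros((M, C), dtype=np.float64),
        tag=np.zeros((M, C), dtype=np.bool_),
        cell_id=np.full((M, C), -1, dtype=np.int64),
        cell_parent=np.full((M, C), -1, dtype=np.int64),
        cellrng=seeds[M:].reshape(M, C).copy(),
        mcrng=seeds[:M].copy(),
        pools=np.zeros((M, N_FUNCTIONS), dtype=np.float64),
        tally=np.zeros(M, dtype=np.float64),
        age=np.zeros(M, dtype=np.int64),
        next_cell_id=np.zeros(1, dtype=np.int64),
        blocklog=np.zeros((BLOCKLOG_CAPACITY, 2), dtype=np.int64),
        blocklog_id=np.zeros(BLOCKLOG_CAPACITY, dtype=np.int64),
        blocklog_n=np.zeros(1, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# random streams (splitmix64)

@njit(inline="always")
def _rng_u64(arr, i):
    s = arr[i] + _SM_GAMMA
    arr[i] = s
    z = (s ^ (s >> np.uint64(30))) * _SM_M1
    z = (z ^ (z >> np.uint64(27))) * _SM_M2
    return z ^ (z >> np.uint64(31))


@njit(inline="always")
def _rng_f64(arr, i):
    return float(_rng_u64(arr, i) >> np.uint64(11)) * _INV53


@njit(inline="always")
def _rng_below(arr, i, n):
    return int(_rng_u64(arr, i) % np.uint64(n))


# ---------------------------------------------------------------------------
# logic-function evaluation

@njit(inline="always")
def _eval_logic_mask(a, b, n, out):
    """Bitmask of the nine functions whose bitwise result equals ``out``.

    ``a`` is the older and ``b`` the newer of the two most recent 32-bit
    inputs; with a single input consumed only NOT is evaluable.  Asymmetric
    two-input functions (ORNOT, ANDNOT) match in either input order.
    """
    mask = 0
    if n < 1:
        return mask
    a = a & M32
    b = b & M32
    out = out & M32
    nb = (~b) & M32
    if n == 1:
        if out == nb:
            mask |= 1  # NOT
        return mask
    na = (~a) & M32
    if out == na or out == nb:
        mask |= 1 << 0                      # NOT
    if out == ((~(a & b)) & M32):
        mask |= 1 << 1                      # NAND
    if out == (a & b):
        mask |= 1 << 2                      # AND
    if out == ((a | nb) & M32) or out == ((b | na) & M32):
        mask |= 1 << 3                      # ORNOT
    if out == (a | b):
        mask |= 1 << 4                      # OR
    if out == (a & nb) or out == (b & na):
        mask |= 1 << 5                      # ANDNOT
    if out == ((~(a | b)) & M32):
        mask |= 1 << 6                      # NOR
    if out == (a ^ b):
        mask |= 1 << 7                      # XOR
    if out == ((~(a ^ b)) & M32):
        mask |= 1 << 8                      # EQUALS
    return mask


def evaluate_logic(last_inputs, output, n_inputs=2):
    """Set of function names matched by ``output`` on the most recent inputs."""
    a, b = (np.uint64(int(v) & 0xFFFFFFFF) for v in last_inputs)
    mask = _eval_logic_mask(a, b, int(n_inputs), np.uint64(int(output) & 0xFFFFFFFF))
    return {FUNCTION_NAMES[j] for j in range(N_FUNCTIONS) if mask >> j & 1}


# ---------------------------------------------------------------------------
# rewards and mutagenesis

@njit(inline="always")
def _mutate_sites(S, m, c, rate):
    """Per-site substitution at probability ``rate``; returns sites changed."""
    L = S.glen[m, c]
    n = 0
    for i in range(L):
        if _rng_f64(S.mcrng, m) < rate:
            cur = S.genome[m, c, i]
            r = _rng_below(S.mcrng, m, 29)  # 30 instructions, exclude current
            if r >= cur:
                r += 1
            S.genome[m, c, i] = np.int8(r)
            n += 1
    return n


@njit(inline="always")
def _least_loaded_eligible(S, m):
    """Index of the eligible cell with minimal mutagenesis ledger (ties random)."""
    C = S.alive.shape[1]
    best = -1
    best_load = 0.0
    ties = 0
    for c in range(C):
        if S.alive[m, c] and S.eligible[m, c]:
            load = S.ledger[m, c]
            if best < 0 or load < best_load:
                best = c
                best_load = load
                ties = 1
            elif load == best_load:
                ties += 1
                if _rng_below(S.mcrng, m, ties) == 0:
                    best = c
    return best


@njit(inline="always")
def _apply_fml(S, cfg, m, c, j):
    """Mutagenic side effect of one performance of function ``j`` by cell ``c``.

    In redistributed mode, performances by propagule-eligible cells degrade
    the eligible cell with the smallest accrued mutagenic workload instead of
    the performer; ineligible performers always degrade themselves.
    """
    mj = cfg.fml[j]
    if mj <= 0.0:
        return 0
    target = c
    if cfg.redistribute and S.eligible[m, c]:
        t = _least_loaded_eligible(S, m)
        if t >= 0:
            target = t
    n = _mutate_sites(S, m, target, mj)
    S.ledger[m, target] += mj * S.glen[m, target]
    return n


@njit(inline="always")
def _reward_only(S, cfg, m, c, j):
    """Resource acquisition for one performance of ``j`` (no mutagenesis)."""
    if cfg.unlimited[j]:
        gain = cfg.unlimited_amount
    else:
        gain = cfg.consumption * S.pools[m, j]
        S.pools[m, j] -= gain
    S.tally[m] += gain
    S.counts[m, c, j] += 1
    return gain


@njit(inline="always")
def _reward(S, cfg, m, c, j):
    """Credit one performance of function ``j``: resource gain plus FML."""
    gain = _reward_only(S, cfg, m, c, j)
    _apply_fml(S, cfg, m, c, j)
    return gain


# ---------------------------------------------------------------------------
# instruction semantics

@njit(inline="always")
def _read_label(S, m, c, ip, L):
    """Collect up to 3 trailing no-op labels after ``ip``.

    Returns ``k | lab0 << 2 | lab1 << 4 | lab2 << 6`` (k in bits 0-1)."""
    k = 0
    packed = 0
    pos = (ip + 1) % L
    while k < 3:
        op = S.genome[m, c, pos]
        if op > 2:  # not a nop
            break
        packed |= int(op) << (2 + 2 * k)
        k += 1
        pos = (pos + 1) % L
    return packed | k


@njit(inline="always")
def _inbox_push(S, m, c, v0, v1):
    if S.inbox_n[m, c] == INBOX_CAPACITY:  # drop oldest
        S.inbox_head[m, c] = (S.inbox_head[m, c] + 1) % INBOX_CAPACITY
        S.inbox_n[m, c] -= 1
    slot = (S.inbox_head[m, c] + S.inbox_n[m, c]) % INBOX_CAPACITY
    S.inbox[m, c, slot, 0] = v0
    S.inbox[m, c, slot, 1] = v1
    S.inbox_n[m, c] += 1


@njit(inline="always")
def _reset_cpu(S, m, c):
    for r in range(3):
        S.regs[m, c, r] = np.uint64(0)
    S.sp[m, c, 0] = 0
    S.sp[m, c, 1] = 0
    for h in range(4):
        S.heads[m, c, h] = 0
    S.inputs[m, c, 0] = np.uint64(0)
    S.inputs[m, c, 1] = np.uint64(0)
    S.ninputs[m, c] = 0
    S.allocated[m, c] = False
    S.copied[m, c] = 0
    for i in range(3):
        S.lastcopied[m, c, i] = -1


@njit(inline="always")
def _init_offspring(S, m, parent, target, length, upd):
    """Place a new cell at slot ``target`` (replacing any occupant)."""
    S.glen[m, target] = length
    for i in range(length):
        S.genome[m, target, i] = S.childbuf[m, parent, i]
    S.alive[m, target] = True
    S.eligible[m, target] = S.eligible[m, parent]
    S.tag[m, target] = S.tag[m, parent]
    S.born[m, target] = upd
    _reset_cpu(S, m, target)
    for j in range(N_FUNCTIONS):
        S.counts[m, target, j] = 0
    S.inbox_n[m, target] = 0
    S.inbox_head[m, target] = 0
    S.ledger[m, target] = 0.0
    S.facing[m, target] = np.int8(_rng_below(S.mcrng, m, 8))
    S.cellrng[m, target] = _rng_u64(S.mcrng, m)
    S.cell_id[m, target] = S.next_cell_id[0]
    S.cell_parent[m, target] = S.cell_id[m, parent]
    S.next_cell_id[0] += 1


@njit(inline="always")
def _neighbour(S, c, direction):
    W = S.grid[0]
    H = S.grid[1]
    x = (c % W + DX[direction]) % W
    y = (c // W + DY[direction]) % H
    return y * W + x


@njit
def _exec(S, cfg, upd, m0, m1, c0, c1, nsteps, respect_born):
    """Execute ``nsteps`` instructions for every living cell in the slot
    ranges [m0, m1) x [c0, c1), in fixed grid order.

    This is the single implementation of the instruction semantics; the body
    is written inline because a per-instruction function boundary carrying
    the full state is prohibitively expensive to cross.  With
    ``respect_born``, cells born during update ``upd`` do not execute (they
    start at the next update).
    """
    for m in range(m0, m1):
        for c in range(c0, c1):
            if not S.alive[m, c]:
                continue
            if respect_born and S.born[m, c] >= upd:
                continue
            for _k in range(nsteps):
                L = S.glen[m, c]
                if L <= 0:
                    break  # inert cell
                ip = S.heads[m, c, 0] % L
                op = S.genome[m, c, ip]
                bx = S.regs[m, c, 1]
                cx = S.regs[m, c, 2]
                nip = (ip + 1) % L

                if op <= 2:
                    pass  # nop-a / nop-b / nop-c
                elif op == 3:  # if-less
                    if not (bx < cx):
                        nip = (ip + 2) % L
                elif op == 4:  # if-n-equ
                    if not (bx != cx):
                        nip = (ip + 2) % L
                elif op == 5:  # if-label
                    k = 0
                    lab0 = 0
                    lab1 = 0
                    lab2 = 0
                    pos = nip
                    while k < 3:
                        lo = S.genome[m, c, pos]
                        if lo > 2:
                            break
                        if k == 0:
                            lab0 = lo
                        elif k == 1:
                            lab1 = lo
                        else:
                            lab2 = lo
                        k += 1
                        pos = (pos + 1) % L
                    after = (ip + 1 + k) % L
                    ok = k > 0
                    if k >= 1 and S.lastcopied[m, c, 3 - k] != (lab0 + 1) % 3:
                        ok = False
                    if k >= 2 and S.lastcopied[m, c, 4 - k] != (lab1 + 1) % 3:
                        ok = False
                    if k >= 3 and S.lastcopied[m, c, 2] != (lab2 + 1) % 3:
                        ok = False
                    if ok:
                        nip = after
                    else:
                        nip = (after + 1) % L
                elif op == 6:  # mov-head
                    nip = S.heads[m, c, 3] % L
                elif op == 7:  # jmp-head
                    off = np.int64(cx & M32)
                    if off >= 2147483648:
                        off -= 4294967296
                    nip = (ip + off) % L
                    if nip < 0:
                        nip += L
                elif op == 8:  # h-search
                    k = 0
                    comp0 = 0
                    comp1 = 0
                    comp2 = 0
                    pos = nip
                    while k < 3:
                        lo = S.genome[m, c, pos]
                        if lo > 2:
                            break
                        if k == 0:
                            comp0 = (lo + 1) % 3
                        elif k == 1:
                            comp1 = (lo + 1) % 3
                        else:
                            comp2 = (lo + 1) % 3
                        k += 1
                        pos = (pos + 1) % L
                    after = (ip + 1 + k) % L
                    if k == 0:
                        S.heads[m, c, 3] = after
                        S.regs[m, c, 1] = np.uint64(0)
                        S.regs[m, c, 2] = np.uint64(0)
                    else:
                        found = -1
                        for offset in range(L):
                            s = (after + offset) % L
                            if S.genome[m, c, s] != comp0:
                                continue
                            if k >= 2 and S.genome[m, c, (s + 1) % L] != comp1:
                                continue
                            if k >= 3 and S.genome[m, c, (s + 2) % L] != comp2:
                                continue
                            found = s
                            S.regs[m, c, 1] = np.uint64(offset) & M32
                            break
                        if found >= 0:
                            S.heads[m, c, 3] = (found + k) % L
                        else:
                            S.heads[m, c, 3] = after
                            S.regs[m, c, 1] = np.uint64(0)
                        S.regs[m, c, 2] = np.uint64(k)
                    nip = after
                elif op == 9:  # h-alloc
                    S.allocated[m, c] = True
                    S.copied[m, c] = 0
                    S.heads[m, c, 1] = 0
                    S.heads[m, c, 2] = 0
                    for i in range(3):
                        S.lastcopied[m, c, i] = -1
                elif op == 10:  # h-copy
                    if S.allocated[m, c] and S.copied[m, c] < cfg.gmax:
                        rd = S.heads[m, c, 1] % L
                        opc = S.genome[m, c, rd]
                        S.childbuf[m, c, S.copied[m, c]] = opc
                        S.lastcopied[m, c, 0] = S.lastcopied[m, c, 1]
                        S.lastcopied[m, c, 1] = S.lastcopied[m, c, 2]
                        S.lastcopied[m, c, 2] = opc
                        S.heads[m, c, 1] = (rd + 1) % L
                        S.heads[m, c, 2] += 1
                        S.copied[m, c] += 1
                elif op == 11:  # h-divide
                    if S.allocated[m, c] and S.copied[m, c] >= L:
                        target = _neighbour(S, c, S.facing[m, c])
                        _init_offspring(S, m, c, target, S.copied[m, c], upd)
                        _reset_cpu(S, m, c)
                        # the parent is reborn: its facing re-randomises like
                        # a fresh cell's, so repeated divisions spread over
                        # the neighbourhood
                        S.facing[m, c] = np.int8(_rng_below(S.mcrng, m, 8))
                        continue  # IP was reset to 0
                elif op == 12:  # push
                    if S.sp[m, c, 0] < STACK_DEPTH:
                        S.stack[m, c, 0, S.sp[m, c, 0]] = bx
                        S.sp[m, c, 0] += 1
                elif op == 13:  # pop
                    if S.sp[m, c, 0] > 0:
                        S.sp[m, c, 0] -= 1
                        S.regs[m, c, 1] = S.stack[m, c, 0, S.sp[m, c, 0]]
                    else:
                        S.regs[m, c, 1] = np.uint64(0)
                elif op == 14:  # swap
                    S.regs[m, c, 1] = cx
                    S.regs[m, c, 2] = bx
                elif op == 15:  # inc
                    S.regs[m, c, 1] = (bx + np.uint64(1)) & M32
                elif op == 16:  # dec
                    S.regs[m, c, 1] = (bx - np.uint64(1)) & M32
                elif op == 17:  # add
                    S.regs[m, c, 1] = (bx + cx) & M32
                elif op == 18:  # sub
                    S.regs[m, c, 1] = (bx - cx) & M32
                elif op == 19:  # nand
                    S.regs[m, c, 1] = (~(bx & cx)) & M32
                elif op == 20:  # io
                    mask = _eval_logic_mask(S.inputs[m, c, 0], S.inputs[m, c, 1],
                                            S.ninputs[m, c], bx)
                    if mask != 0:
                        for j in range(N_FUNCTIONS):
                            if mask >> j & 1:
                                _reward(S, cfg, m, c, j)
                    newin = _rng_u64(S.cellrng[m], c) & M32
                    S.inputs[m, c, 0] = S.inputs[m, c, 1]
                    S.inputs[m, c, 1] = newin
                    if S.ninputs[m, c] < 2:
                        S.ninputs[m, c] += 1
                    S.regs[m, c, 1] = newin
                elif op == 21:  # rotate-l
                    S.facing[m, c] = (S.facing[m, c] + 7) % 8
                elif op == 22:  # rotate-r
                    S.facing[m, c] = (S.facing[m, c] + 1) % 8
                elif op == 23:  # get_xy
                    S.regs[m, c, 1] = np.uint64(c % S.grid[0])
                    S.regs[m, c, 2] = np.uint64(c // S.grid[0])
                elif op == 24:  # send_message
                    t = _neighbour(S, c, S.facing[m, c])
                    if S.alive[m, t]:
                        _inbox_push(S, m, t, bx, cx)
                elif op == 25:  # broadcast_message
                    for d in range(8):
                        t = _neighbour(S, c, d)
                        if S.alive[m, t]:
                            _inbox_push(S, m, t, bx, cx)
                elif op == 26:  # retrieve_message
                    if S.inbox_n[m, c] > 0:
                        h = S.inbox_head[m, c]
                        S.regs[m, c, 1] = S.inbox[m, c, h, 0]
                        S.regs[m, c, 2] = S.inbox[m, c, h, 1]
                        S.inbox_head[m, c] = (h + 1) % INBOX_CAPACITY
                        S.inbox_n[m, c] -= 1
                elif op == 27:  # block_propagation
                    if cfg.block_allowed and S.eligible[m, c]:
                        S.eligible[m, c] = False
                        n = S.blocklog_n[0]
                        if n < BLOCKLOG_CAPACITY:
                            S.blocklog[n, 0] = m
                            S.blocklog[n, 1] = c
                            S.blocklog_id[n] = S.cell_id[m, c]
                            S.blocklog_n[0] = n + 1
                elif op == 28:  # if_propagule_eligible
                    if not S.eligible[m, c]:
                        nip = (ip + 2) % L
                elif op == 29:  # if_propagule_ineligible
                    if S.eligible[m, c]:
                        nip = (ip + 2) % L

                S.heads[m, c, 0] = nip


@njit
def _run_update(S, cfg, upd):
    M, C = S.alive.shape
    _exec(S, cfg, upd, 0, M, 0, C, cfg.ipu, True)
    for m in range(M):
        S.age[m] += 1


# ---------------------------------------------------------------------------
# Python-facing wrappers

def step_cell(state: State, cfg: Config, m: int, c: int, update: int = 0) -> None:
    """Execute one instruction of cell ``(m, c)`` (exactly one slot consumed)."""
    _exec(state, cfg, update, m, m + 1, c, c + 1, 1, False)


def run_cell_update(state: State, cfg: Config, m: int, c: int, update: int = 0) -> None:
    """Execute one full update (30 instructions) for a single cell."""
    _exec(state, cfg, update, m, m + 1, c, c + 1, cfg.ipu, False)


def run_update(state: State, cfg: Config, update: int) -> None:
    """Execute one update for every established cell, in fixed grid order.

    Cells born during the current update begin executing at the next one.
    """
    _run_update(state, cfg, update)


def seed_cell(state: State, m: int, c: int, genome_ops, *, eligible: bool = True,
              born: int = -1, tag: bool = False, parent_id: int = -1) -> int:
    """Install a fresh cell with the given genome at slot ``(m, c)``."""
    ops = np.asarray(genome_ops, dtype=np.int8)
    L = len(ops)
    if L < 1 or L > state.genome.shape[2]:
        raise ValueError("genome length outside [1, gmax]")
    state.glen[m, c] = L
    state.genome[m, c, :L] = ops
    state.alive[m, c] = True
    state.eligible[m, c] = eligible
    state.tag[m, c] = tag
    state.born[m, c] = born
    _reset_cpu(state, m, c)
    state.counts[m, c, :] = 0
    state.inbox_n[m, c] = 0
    state.inbox_head[m, c] = 0
    state.ledger[m, c] = 0.0
    state.facing[m, c] = np.int8(_rng_below(state.mcrng, m, 8))
    state.cellrng[m, c] = _rng_u64(state.mcrng, m)
    cid = int(state.next_cell_id[0])
    state.cell_id[m, c] = cid
    state.cell_parent[m, c] = parent_id
    state.next_cell_id[0] += 1
    return cid


def clear_multicell(state: State, m: int) -> None:
    """Empty slot ``m``: no cells, zero pools and tally, age zero."""
    state.alive[m, :] = False
    state.eligible[m, :] = False
    state.glen[m, :] = 0
    state.pools[m, :] = 0.0
    state.tally[m] = 0.0
    state.age[m] = 0


def drain_blocklog(state: State):
    """Return and clear the (m, c, cell_id) block-transition records."""
    n = int(state.blocklog_n[0])
    out = [(int(state.blocklog[i, 0]), int(state.blocklog[i, 1]),
            int(state.blocklog_id[i])) for i in range(n)]
    state.blocklog_n[0] = 0
    return out
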