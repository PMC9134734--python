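"""Signed gene-order permutations and inversion inference.

A sample's collapsed gene order is encoded against a reference as a signed
permutation; large inversions are recovered as a minimum-length sequence of
reversals sorting that permutation to the identity.  Plastome event counts
per lineage are small, so the search is exact: maximal colinear runs are
collapsed into blocks first, then an A*/iterative-deepening search over
reversal space with the breakpoint lower bound (each reversal removes at
most two breakpoints) finds a provably minimal scenario.  Among co-optimal
scenarios the one whose successive reversals are lexicographically
leftmost is reported, for determinism.

Reversal breakpoints are taken to fall between genes (in intergenic
spacers), which matches every large plastome inversion reported for ferns.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

from .plastome_io import GeneSymbol, GenomeRecord, SignedGeneOrder

__all__ = [
    "SignedPermutation",
    "InversionEvent",
    "to_signed_permutation",
    "breakpoint_distance",
    "infer_inversions",
    "estimate_inversion_size",
    "apply_reversal",
]


@dataclass
class SignedPermutation:
    """Sample gene order encoded as signed reference indices (1..n)."""

    taxon: str
    reference: str
    perm: list[int]
    shared_genes: list[GeneSymbol]  # reference order: shared_genes[i] has index i+1
    dropped_sample: set[GeneSymbol] = field(default_factory=set)
    dropped_reference: set[GeneSymbol] = field(default_factory=set)

    @property
    def is_identity(self) -> bool:
        return self.perm == list(range(1, len(self.perm) + 1))


@dataclass
class InversionEvent:
    """One inferred reversal, reported with reference-side flank genes."""

    left_flank: GeneSymbol
    right_flank: GeneSymbol
    span_genes: list[GeneSymbol]
    approx_size: int = 0
    label: str = ""


def to_signed_permutation(
    sample: SignedGeneOrder, reference: SignedGeneOrder
) -> SignedPermutation:
    """Encode ``sample``'s order relative to ``reference``.

    Both orders must be canonicalized on the same anchor.  Genes absent
    from either order are dropped and reported; the sign of each entry is
    the sample's orientation relative to the reference's.
    """
    if sample.anchor != reference.anchor:
        raise ValueError("orders are canonicalized on different anchors")
    ref_syms = reference.symbols()
    smp_syms = sample.symbols()
    shared = [s for s in ref_syms if s in set(smp_syms)]
    if not shared:
        raise ValueError("no shared genes between sample and reference")
    dropped_ref = set(ref_syms) - set(shared)
    dropped_smp = set(smp_syms) - set(shared)
    index = {}
    ref_sign = {}
    for i, (sym, sign) in enumerate(
        [(s, g) for s, g in reference.order if s in set(shared)], start=1
    ):
        index[sym] = i
        ref_sign[sym] = sign
    perm = []
    for sym, sign in sample.order:
        if sym not in index:
            continue
        v = index[sym]
        perm.append(v if sign == ref_sign[sym] else -v)
    return SignedPermutation(
        taxon=sample.taxon, reference=reference.taxon, perm=perm,
        shared_genes=shared, dropped_sample=dropped_ref,
        dropped_reference=dropped_smp,
    )


def breakpoint_distance(perm_or_list) -> int:
    """Number of non-conserved adjacencies under linear framing 0..n+1.

    An adjacency (a, b) is conserved iff b == a + 1 in signed terms.
    """
    perm = perm_or_list.perm if isinstance(perm_or_list, SignedPermutation) else list(perm_or_list)
    if not perm:
        raise ValueError("empty permutation")
    framed = [0] + perm + [len(perm) + 1]
    return sum(1 for a, b in zip(framed, framed[1:]) if b - a != 1)


def apply_reversal(perm: tuple[int, ...], i: int, j: int) -> tuple[int, ...]:
    """Reverse the closed slice [i, j] (0-based) negating its entries."""
    return perm[:i] + tuple(-v for v in perm[i : j + 1][::-1]) + perm[j + 1 :]


def _collapse_blocks(perm: list[int]):
    """Collapse maximal colinear runs (i, i+1, ... or -(i+1), -i, ...) into
    single signed blocks and renumber to a reduced permutation.

    Returns (reduced_perm, block_spans) where block_spans[k] = (lo, hi)
    gives the original 0-based index range covered by reduced position k.
    """
    if not perm:
        return [], []
    runs = []
    start = 0
    for k in range(1, len(perm) + 1):
        if k < len(perm) and perm[k] == perm[k - 1] + 1 and (
            (perm[k - 1] > 0) == (perm[k] > 0)
        ):
            continue
        runs.append((start, k - 1))
        start = k
    # each run is one block; sign = sign of its first element; order blocks
    # by the reference index of their smallest |value|
    reps = []
    for lo, hi in runs:
        vals = perm[lo : hi + 1]
        key = min(abs(v) for v in vals)
        sign = 1 if vals[0] > 0 else -1
        reps.append((key, sign, (lo, hi)))
    order = sorted(range(len(reps)), key=lambda t: reps[t][0])
    rank = {t: r + 1 for r, t in enumerate(order)}
    reduced = [rank[t] * reps[t][1] for t in range(len(reps))]
    # drop leading/trailing blocks already in place so the frame stays tight
    return reduced, [reps[t][2] for t in range(len(reps))]


def _cycle_bound(p: tuple[int, ...]) -> int:
    """Admissible lower bound on reversal distance: n + 1 - c, the cycle
    count of the breakpoint graph (a reversal changes c by at most one)."""
    n = len(p)
    pos = {0: 0, 2 * n + 1: 2 * n + 1}
    for i, v in enumerate(p):
        a = abs(v)
        head, tail = (2 * a - 1, 2 * a) if v > 0 else (2 * a, 2 * a - 1)
        pos[head] = 2 * i + 1
        pos[tail] = 2 * i + 2
    val_at = [0] * (2 * n + 2)
    for v, i in pos.items():
        val_at[i] = v
    seen = [False] * (2 * n + 2)
    c = 0
    for start in range(0, 2 * n + 2, 2):
        if seen[start]:
            continue
        c += 1
        i = start
        while not seen[i]:
            seen[i] = True
            j = i + 1 if i % 2 == 0 else i - 1  # black edge between positions
            seen[j] = True
            v = val_at[j]
            w = v + 1 if v % 2 == 0 else v - 1  # gray edge between values
            i = pos[w]
    return n + 1 - c


def _reversal_distance_astar(perm: tuple[int, ...], cap: int | None = None) -> int | None:
    """Exact reversal distance by A* (cycle-count lower bound, admissible)."""
    n = len(perm)
    goal = tuple(range(1, n + 1))
    if perm == goal:
        return 0

    h = _cycle_bound

    open_heap = [(h(perm), 0, perm)]
    gbest = {perm: 0}
    while open_heap:
        f, g, p = heapq.heappop(open_heap)
        if p == goal:
            return g
        if g > gbest.get(p, g):
            continue
        if cap is not None and g >= cap:
            continue
        for i in range(n):
            for j in range(i, n):
                q = apply_reversal(p, i, j)
                g2 = g + 1
                if g2 < gbest.get(q, 1 << 30):
                    gbest[q] = g2
                    heapq.heappush(open_heap, (g2 + h(q), g2, q))
    return None


def _lexicographic_scenario(perm: tuple[int, ...], dist: int):
    """Depth-first search for the (i, j)-lexicographically first minimal
    reversal scenario, pruned by the breakpoint bound."""
    n = len(perm)
    goal = tuple(range(1, n + 1))
    h = _cycle_bound
    path: list[tuple[int, int]] = []

    def dfs(p, remaining):
        if p == goal:
            return remaining == 0
        if remaining == 0 or h(p) > remaining:
            return False
        for i in range(n):
            for j in range(i, n):
                q = apply_reversal(p, i, j)
                if q == p:
                    continue
                path.append((i, j))
                if dfs(q, remaining - 1):
                    return True
                path.pop()
        return False

    return path if dfs(perm, dist) else None


def infer_inversions(
    perm: SignedPermutation,
    max_events: int = 6,
    max_blocks: int = 14,
    record: GenomeRecord | None = None,
):
    """Infer a minimum-length inversion scenario sorting ``perm``.

    Returns ``(events, status)`` where status is "resolved", "identity" or
    "unresolved".  Unresolved (reduced permutation larger than
    ``max_blocks``, or distance above ``max_events``) returns an empty
    event list; callers can fall back on :func:`breakpoint_distance`.
    Every returned scenario is verified to sort the permutation.
    """
    if max_events < 0:
        raise ValueError("max_events must be >= 0")
    p = list(perm.perm)
    if perm.is_identity:
        return [], "identity"
    reduced, spans = _collapse_blocks(p)
    if len(reduced) > max_blocks:
        return [], "unresolved"
    rt = tuple(reduced)
    dist = _reversal_distance_astar(rt, cap=max_events + 1)
    if dist is None or dist > max_events:
        return [], "unresolved"
    moves = _lexicographic_scenario(rt, dist)
    assert moves is not None
    # replay on the un-collapsed permutation to name genes per event
    state = list(p)
    block_spans = list(spans)  # current 0-based spans per reduced position
    events = []
    cur = list(rt)
    for (i, j) in moves:
        lo = block_spans[i][0]
        hi = block_spans[j][1]
        seg = state[lo : hi + 1]
        genes = [perm.shared_genes[abs(v) - 1] for v in seg]
        ref_sorted = sorted(genes, key=lambda s: perm.shared_genes.index(s))
        ev = InversionEvent(left_flank=ref_sorted[0], right_flank=ref_sorted[-1],
                            span_genes=genes)
        if record is not None:
            try:
                ev.approx_size = estimate_inversion_size(ev, record)
            except ValueError:
                pass
        events.append(ev)
        state[lo : hi + 1] = [-v for v in seg[::-1]]
        block_spans[i : j + 1] = [
            (block_spans[k][0] + 0, block_spans[k][1]) for k in range(j, i - 1, -1)
        ]
        # recompute spans positionally after the flip
        widths = [s[1] - s[0] + 1 for s in block_spans]
        pos = 0
        rebuilt = []
        for w in widths:
            rebuilt.append((pos, pos + w - 1))
            pos += w
        # widths are relative to the full order; anchor at original offsets
        offset = 0
        rebuilt = []
        for w in widths:
            rebuilt.append((offset, offset + w - 1))
            offset += w
        block_spans = rebuilt
        cur = list(apply_reversal(tuple(cur), i, j))
    assert state == sorted(state, key=abs) and all(v > 0 for v in state), (
        "scenario replay must sort the permutation"
    )
    return events, "resolved"


def estimate_inversion_size(event: InversionEvent, record: GenomeRecord) -> int:
    """Genomic span of an inversion, from left-flank start to right-flank
    end on the circle, in bp."""
    left = record.find(event.left_flank)
    right = record.find(event.right_flank)
    if not left or not right:
        missing = event.left_flank if not left else event.right_flank
        raise ValueError(f"flank gene {missing} missing from record {record.id}")
    ls = left[0].start
    re_ = max(e for s, e, _ in right[0].parts)
    if re_ >= ls:
        return re_ - ls + 1
    return record.length - ls + 1 + re_
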