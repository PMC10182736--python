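"""Maximal-unique-match (MUM) detection between two genomes and clustering
of parallel, consecutive, neighboring MUMs into synteny blocks.

A MUM is a substring that occurs exactly once in each genome (on the stated
orientation) and cannot be extended on either side without breaking the
match.  MUMs are found with a suffix array + LCP array over the concatenated
sequences: a cross-genome adjacent suffix pair whose common prefix is longer
than both flanking LCP values is unique in the combined text, hence in each
genome.  Blocks chain same-orientation MUMs that are consecutive in both
genomes with gaps of at most ``max_gap`` bases on each side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._codon import revcomp

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class MUM:
    start_a: int  # half-open 0-based, on genome A forward strand
    start_b: int  # on genome B forward strand (for reverse MUMs: the interval
    # of B whose reverse complement matches A)
    length: int
    orientation: str = FORWARD

    @property
    def end_a(self) -> int:
        return self.start_a + self.length

    @property
    def end_b(self) -> int:
        return self.start_b + self.length


@dataclass
class SyntenyBlock:
    members: list[MUM]
    orientation: str = FORWARD

    @property
    def span_a(self) -> tuple[int, int]:
        return (min(m.start_a for m in self.members), max(m.end_a for m in self.members))

    @property
    def span_b(self) -> tuple[int, int]:
        return (min(m.start_b for m in self.members), max(m.end_b for m in self.members))


# --------------------------------------------------------------------------
# suffix array machinery
# --------------------------------------------------------------------------


def _suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), vectorized)."""
    n = len(codes)
    rank = np.unique(codes, return_inverse=True)[1].astype(np.int64)
    k = 1
    idx = np.arange(n)
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        shifted = idx + k
        valid = shifted < n
        key2[valid] = rank[shifted[valid]]
        order = np.lexsort((key2, rank))
        pair = np.stack([rank[order], key2[order]], axis=1)
        new_rank = np.empty(n, dtype=np.int64)
        changed = np.any(pair[1:] != pair[:-1], axis=1)
        ranks_sorted = np.concatenate([[0], np.cumsum(changed)])
        new_rank[order] = ranks_sorted
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order
        k *= 2


def _lcp_array(codes: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """Kasai LCP: lcp[i] = longest common prefix of suffixes sa[i], sa[i+1]."""
    n = len(codes)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(max(n - 1, 0), dtype=np.int64)
    h = 0
    for i in range(n):
        r = rank[i]
        if r < n - 1:
            j = sa[r + 1]
            while i + h < n and j + h < n and codes[i + h] == codes[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


_BASE_CODE = {"A": 1, "C": 2, "G": 3, "T": 4}


def _encode(seq: str, start_code: int) -> tuple[np.ndarray, int]:
    """Integer codes; each N gets a unique code so it never matches anything."""
    codes = np.empty(len(seq), dtype=np.int64)
    nxt = start_code
    for i, ch in enumerate(seq):
        base = _BASE_CODE.get(ch)
        if base is not None:
            codes[i] = base
        else:
            codes[i] = nxt
            nxt += 1
    return codes, nxt


def _forward_mums(a: str, b: str, min_len: int) -> list[tuple[int, int, int]]:
    """(start_a, start_b, length) of all forward-orientation MUMs."""
    code_a, nxt = _encode(a, 10)
    code_b, nxt = _encode(b, nxt)
    sep = np.array([nxt], dtype=np.int64)
    s = np.concatenate([code_a, sep, code_b])
    n = len(s)
    na = len(a)
    sa = _suffix_array(s)
    lcp = _lcp_array(s, sa)

    out = []
    for i in range(n - 1):
        l = lcp[i]
        if l < min_len:
            continue
        p, q = int(sa[i]), int(sa[i + 1])
        in_a_p, in_a_q = p < na, q < na
        if in_a_p == in_a_q:
            continue  # same genome: the prefix is repeated within one genome
        # unique in the combined text (hence in each genome)
        if i > 0 and lcp[i - 1] >= l:
            continue
        if i < n - 2 and lcp[i + 1] >= l:
            continue
        pa, pb = (p, q - na - 1) if in_a_p else (q, p - na - 1)
        # left-maximality: preceding characters must differ (separator/edge ok)
        if pa > 0 and pb > 0 and a[pa - 1] == b[pb - 1] and a[pa - 1] in _BASE_CODE:
            continue
        out.append((pa, pb, int(l)))
    return out


def find_mums(
    genome_a: str,
    genome_b: str,
    min_len: int = 20,
    both_strands: bool = True,
) -> list[MUM]:
    """All MUMs of length ≥ min_len between two genomes.

    Forward-orientation MUMs always; reverse-orientation MUMs (genome A vs
    the reverse complement of genome B, with ``start_b`` reported on B's
    forward strand) when ``both_strands``.  N never matches.
    """
    a, b = genome_a.upper(), genome_b.upper()
    if not a or not b:
        raise ValueError("genomes must be nonempty")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    mums = [MUM(pa, pb, l, FORWARD) for pa, pb, l in _forward_mums(a, b, min_len)]
    if both_strands:
        rb = revcomp(b)
        for pa, prb, l in _forward_mums(a, rb, min_len):
            mums.append(MUM(pa, len(b) - prb - l, l, REVERSE))
    mums.sort(key=lambda m: (m.orientation, m.start_a, m.start_b))
    return mums


# --------------------------------------------------------------------------
# clustering
# --------------------------------------------------------------------------


def _linked(prev: MUM, cur: MUM, max_gap: int) -> bool:
    """Parallel (same orientation), consecutive (consistent order in both
    genomes) and neighboring (gap ≤ max_gap on both sides)."""
    if prev.orientation != cur.orientation:
        return False
    gap_a = cur.start_a - prev.end_a
    if prev.orientation == FORWARD:
        if cur.start_b < prev.start_b:
            return False  # crossing
        gap_b = cur.start_b - prev.end_b
    else:
        if cur.start_b > prev.start_b:
            return False
        gap_b = prev.start_b - cur.end_b
    return gap_a <= max_gap and gap_b <= max_gap


def cluster_mums(mums: list[MUM], max_gap: int = 100) -> list[SyntenyBlock]:
    """Chain MUMs (sorted by genome-A position, per orientation) into blocks."""
    blocks: list[SyntenyBlock] = []
    for orientation in (FORWARD, REVERSE):
        chain: list[MUM] = []
        for m in sorted(
            (m for m in mums if m.orientation == orientation),
            key=lambda m: (m.start_a, m.start_b),
        ):
            if chain and _linked(chain[-1], m, max_gap):
                chain.append(m)
            else:
                if chain:
                    blocks.append(SyntenyBlock(chain, orientation))
                chain = [m]
        if chain:
            blocks.append(SyntenyBlock(chain, orientation))
    return blocks


def gene_in_block(
    gene_interval: tuple[int, int],
    blocks: list[SyntenyBlock],
    genome_side: str = "a",
    min_fraction: float = 0.0,
) -> bool:
    """True iff the (half-open) gene interval overlaps any block span by at
    least 1 bp and at least ``min_fraction`` of the gene length."""
    start, end = gene_interval
    if genome_side not in ("a", "b"):
        raise ValueError("genome_side must be 'a' or 'b'")
    length = max(end - start, 1)
    for block in blocks:
        s, e = block.span_a if genome_side == "a" else block.span_b
        overlap = min(end, e) - max(start, s)
        if overlap >= 1 and overlap / length >= min_fraction:
            return True
    return False


def blocks_frame(blocks: list[SyntenyBlock]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "block": i,
                "orientation": b.orientation,
                "start_a": b.span_a[0],
                "end_a": b.span_a[1],
                "start_b": b.span_b[0],
                "end_b": b.span_b[1],
                "n_mums": len(b.members),
            }
            for i, b in enumerate(blocks)
        ],
        columns=["block", "orientation", "start_a", "end_a", "start_b", "end_b", "n_mums"],
    )
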