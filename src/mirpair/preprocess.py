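"""Read preprocessing: 3' quality trimming, adapter clipping, collapsing,
and mismatch-bounded ungapped genome mapping.

Trimming removes the maximal 3' suffix in which every base is below the
Phred threshold (strict ``< min_q``); internal low-quality bases 5' of a
high-quality base are retained.  Adapter clipping removes the read suffix
from the leftmost position where a prefix of the adapter matches with at
most 1 mismatch per 10 nt of overlap.  Mapping is full-length and ungapped
(miR-length queries) and reports *all* equally-best genomic positions, as
the downstream multi-assignment rule needs the complete hit set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from ._seq import encode, revcomp
from .types import GenomeAlignment, SequencedRead, UniqueSequence


def trim_quality(read: SequencedRead, min_q: int = 30) -> SequencedRead:
    """Trim the maximal all-low-quality 3' suffix (Phred < ``min_q``)."""
    keep = len(read.qual)
    while keep > 0 and read.qual[keep - 1] < min_q:
        keep -= 1
    if keep == len(read.seq):
        return read
    return SequencedRead(id=read.id, seq=read.seq[:keep], qual=read.qual[:keep])


def _suffix_matches(read_suffix: str, adapter_prefix: str) -> bool:
    allowed = len(read_suffix) // 10
    mm = sum(1 for a, b in zip(read_suffix, adapter_prefix) if a != b)
    return mm <= allowed


def clip_adapter(read: SequencedRead, adapter: str, min_overlap: int = 6) -> SequencedRead:
    """Clip the 3' adapter; leftmost qualifying match wins.

    An overlap shorter than the adapter must span >= ``min_overlap`` bases;
    a full-adapter occurrence qualifies at any position (bases 3' of it are
    clipped with it).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    n, la = len(read.seq), len(adapter)
    for i in range(n):
        ov = n - i
        if ov >= la:
            if _suffix_matches(read.seq[i : i + la], adapter):
                return SequencedRead(id=read.id, seq=read.seq[:i], qual=read.qual[:i])
        elif ov >= min_overlap:
            if _suffix_matches(read.seq[i:], adapter[:ov]):
                return SequencedRead(id=read.id, seq=read.seq[:i], qual=read.qual[:i])
    return read


def collapse(seqs) -> list[UniqueSequence]:
    """Collapse identical sequences to (seq, count); empty reads dropped.

    Output is ordered by decreasing count, ties lexicographic, so collapsing
    is deterministic.
    """
    counter = Counter(s for s in seqs if s)
    return [
        UniqueSequence(seq=s, count=c)
        for s, c in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


@dataclass
class RetentionStats:
    raw: int = 0
    retained: int = 0

    @property
    def fraction(self) -> float:
        return self.retained / self.raw if self.raw else 0.0


def preprocess_reads(
    reads,
    adapter: str,
    min_q: int = 30,
    min_overlap: int = 6,
) -> tuple[list[UniqueSequence], RetentionStats]:
    """Quality-trim, adapter-clip and collapse an iterable of reads."""
    stats = RetentionStats()
    cleaned = []
    for read in reads:
        stats.raw += 1
        read = trim_quality(read, min_q=min_q)
        read = clip_adapter(read, adapter, min_overlap=min_overlap)
        if read.seq:
            stats.retained += 1
            cleaned.append(read.seq)
    return collapse(cleaned), stats


class GenomeIndex:
    """Seed-and-verify ungapped mapper over a mini-genome.

    Pigeonhole seeding: a query aligned with <= ``max_mm`` mismatches must
    contain at least one exact seed among ``max_mm + 1`` disjoint chunks, so
    exact k-mer lookups of those chunks enumerate every candidate placement.
    """

    def __init__(self, genome: dict[str, str], seed_len: int = 6):
        self.seed_len = seed_len
        self.chroms = list(genome)
        self._enc = {c: encode(genome[c]) for c in self.chroms}
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.items():
            for i in range(len(seq) - seed_len + 1):
                self._index.setdefault(seq[i : i + seed_len], []).append((chrom, i))

    def _candidates(self, seq: str, max_mm: int):
        k = self.seed_len
        n_seeds = max_mm + 1
        L = len(seq)
        # disjoint seeds spread across the query
        offsets = [round(j * (L - k) / max(n_seeds - 1, 1)) for j in range(n_seeds)]
        offsets = sorted(set(min(o, L - k) for o in offsets))
        cands = set()
        for o in offsets:
            for chrom, pos in self._index.get(seq[o : o + k], ()):
                cands.add((chrom, pos - o))
        return cands

    def map(self, seq: str, max_mm: int = 2, min_len: int = 18) -> list[GenomeAlignment]:
        """All equally-best full-length placements with <= ``max_mm`` mismatches."""
        if len(seq) < min_len:
            return []
        q_fwd = encode(seq)
        q_rev = encode(revcomp(seq))
        hits: list[tuple[str, int, str, int]] = []
        for strand, q, query_seq in (("+", q_fwd, seq), ("-", q_rev, revcomp(seq))):
            for chrom, start in self._candidates(query_seq, max_mm):
                ref = self._enc[chrom]
                if start < 0 or start + len(q) > len(ref):
                    continue
                mm = int(np.count_nonzero(ref[start : start + len(q)] != q))
                if mm <= max_mm:
                    hits.append((chrom, start, strand, mm))
        if not hits:
            return []
        best = min(h[3] for h in hits)
        tier = sorted(set(h for h in hits if h[3] == best))
        return [
            GenomeAlignment(seq=seq, chrom=c, pos=p, strand=s, mismatches=mm, n_hits=len(tier))
            for c, p, s, mm in tier
        ]


def map_genome(
    u: UniqueSequence,
    index: GenomeIndex,
    max_mm: int = 2,
    min_len: int = 18,
) -> list[GenomeAlignment]:
    """Map a collapsed sequence against an indexed genome."""
    return index.map(u.seq, max_mm=max_mm, min_len=min_len)
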