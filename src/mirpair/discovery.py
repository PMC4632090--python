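"""Simplified hairpin-based novel miR candidate discovery.

The discovery stage mirrors the classic read-signature approach: each
unexplained genomic read locus is excised with two asymmetric flank windows
(70 nt upstream / 20 nt downstream, and the mirror), each window is folded
by a maximum base-pairing dynamic program, and candidates are scored on the
read signature expected of Drosha/Dicer processing — abundant mature reads,
presence of the star strand, presence of loop reads, and a well-paired
stem.  Candidates from repetitive loci (> 5 genomic copies) or overlapping
annotated non-miR ncRNA/coding intervals are excluded, and the final score
cutoff is calibrated by permutation to a target signal-to-noise ratio
(default 5:1).

Folding is deliberately a Nussinov maximum-pairing model (Watson-Crick plus
G·U wobble, minimum loop 3 nt, helices shorter than 2 bp pruned) rather
than a thermodynamic nearest-neighbour model; cross-species conservation is
not used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp
from .types import GenomeAlignment

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}

DEFAULT_WEIGHTS = {"w_mature": 1.0, "w_star": 2.0, "w_loop": 1.0, "w_pairing": 2.0, "penalty": 2.0}


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


# ------------------------------------------------------------------ folding

def fold_hairpin(seq: str, min_loop: int = 3, min_helix: int = 2) -> tuple[str, float]:
    """Maximum base-pairing fold; returns (dot-bracket, pairing fraction).

    Watson-Crick and G·U pairs; hairpin loops must span at least
    ``min_loop`` unpaired bases; helices shorter than ``min_helix`` stacked
    pairs are pruned from the traceback before the pairing fraction is
    computed.
    """
    s = seq.upper().replace("U", "T")
    if any(b not in "ACGT" for b in s):
        raise ValueError("sequence contains non-ACGU(T) symbols")
    n = len(s)
    if n < 40:
        raise ValueError("sequence shorter than 40 nt")

    pair_ok = np.zeros((n, n), dtype=bool)
    codes = {"A": 0, "C": 1, "G": 2, "T": 3}
    enc = np.array([codes[b] for b in s])
    comp = {(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)}
    for a, b in comp:
        pair_ok |= np.outer(enc == a, enc == b)

    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        i_idx = np.arange(0, n - span)
        j_idx = i_idx + span
        best = np.maximum(dp[i_idx + 1, j_idx], dp[i_idx, j_idx - 1])
        paired = dp[i_idx + 1, j_idx - 1] + 1
        best = np.maximum(best, np.where(pair_ok[i_idx, j_idx], paired, -1))
        # bifurcation: max_k dp[i,k] + dp[k+1,j]
        for off, (i, j) in enumerate(zip(i_idx, j_idx)):
            if span >= 2:
                k = np.arange(i, j)
                m = int(np.max(dp[i, k] + dp[k + 1, j]))
                if m > best[off]:
                    best[off] = m
        dp[i_idx, j_idx] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        v = dp[i, j]
        if v == dp[i + 1, j]:
            stack.append((i + 1, j))
        elif v == dp[i, j - 1]:
            stack.append((i, j - 1))
        elif pair_ok[i, j] and v == dp[i + 1, j - 1] + 1:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
        else:
            for k in range(i, j):
                if dp[i, k] + dp[k + 1, j] == v:
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break

    # prune helices shorter than min_helix stacked pairs
    pairs.sort()
    pair_set = set(pairs)
    kept: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for p in pairs:
        if p in seen:
            continue
        helix = [p]
        q = (p[0] + 1, p[1] - 1)
        while q in pair_set:
            helix.append(q)
            q = (q[0] + 1, q[1] - 1)
        seen.update(helix)
        if len(helix) >= min_helix:
            kept.extend(helix)

    struct = ["."] * n
    for i, j in kept:
        struct[i], struct[j] = "(", ")"
    return "".join(struct), 2 * len(kept) / n


# ------------------------------------------------------------------ excision

def excise_precursors(
    aln: GenomeAlignment,
    genome: dict[str, str],
    flank_long: int = 70,
    flank_short: int = 20,
) -> list[tuple[str, int, int, str, str]]:
    """Two candidate precursor windows around a read alignment.

    Flanks are applied in transcript orientation (upstream = genomic right
    for minus-strand reads) and clipped at contig ends.  Returns
    ``(chrom, start, end, strand, window_kind)`` tuples.
    """
    n = len(genome[aln.chrom])
    read_len = len(aln.seq)
    out = []
    for kind, (up, down) in (("up70_down20", (flank_long, flank_short)),
                             ("up20_down70", (flank_short, flank_long))):
        if aln.strand == "+":
            start, end = aln.pos - up, aln.pos + read_len + down
        else:
            start, end = aln.pos - down, aln.pos + read_len + up
        out.append((aln.chrom, max(0, start), min(n, end), aln.strand, kind))
    return out


def window_sequence(genome: dict[str, str], window: tuple[str, int, int, str, str]) -> str:
    chrom, start, end, strand, _ = window
    seq = genome[chrom][start:end]
    return revcomp(seq) if strand == "-" else seq


# ------------------------------------------------------------------ candidates

@dataclass
class HairpinCandidate:
    locus: tuple[str, int, int, str]
    window_kind: str
    precursor_seq: str
    structure: str
    pairing_fraction: float
    mature_arm: str
    mature_offset: int  # precursor-local start of the defining (mature) read
    mature_len: int
    read_support: dict[str, float] = field(default_factory=dict)
    score: float = 0.0
    n_hits: int = 1
    name: str = ""


@dataclass
class CandidateSet:
    candidates: list[HairpinCandidate]
    cutoff: float = float("-inf")
    snr: float = float("inf")
    n_false_estimate: float = 0.0
    achieved: bool = True

    def retained(self) -> list[HairpinCandidate]:
        return [c for c in self.candidates if c.score >= self.cutoff]


def _support_counts(
    starts_counts: list[tuple[int, float]],
    mature_start: int,
    mature_len: int,
    structure: str,
    slop: int = 3,
) -> dict[str, float]:
    """Partition locus read mass into mature / star / loop / outside.

    The star start is located via the pairing partner of the mature arm in
    the predicted structure (3' 2-nt overhang convention); when the arm is
    unpaired the mirrored position is used.
    """
    n = len(structure)
    partner = {}
    stack = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            partner[i], partner[j] = j, i
    m_end = min(mature_start + mature_len, n) - 1
    star_start = None
    for k in range(m_end, mature_start - 1, -1):
        if k in partner:
            star_start = max(0, partner[k] - 2)  # 2-nt 3' overhang
            break
    if star_start is None:
        star_start = max(0, n - mature_start - mature_len)

    support = {"mature": 0.0, "star": 0.0, "loop": 0.0, "outside": 0.0}
    lo_m, hi_m = mature_start - slop, mature_start + slop
    lo_s, hi_s = star_start - slop, star_start + slop
    for start, cnt in starts_counts:
        if lo_m <= start <= hi_m:
            support["mature"] += cnt
        elif lo_s <= start <= hi_s:
            support["star"] += cnt
        elif min(mature_start, star_start) < start < max(mature_start, star_start):
            support["loop"] += cnt
        else:
            support["outside"] += cnt
    return support


def score_candidate(
    support: dict[str, float],
    pairing_fraction: float,
    weights: dict[str, float] | None = None,
) -> float:
    """Read-signature score; a locus with no reads scores 0 by convention."""
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)
    total = sum(support.get(k, 0.0) for k in ("mature", "star", "loop", "outside"))
    if total == 0:
        return 0.0
    frac_out = support.get("outside", 0.0) / total
    return (
        w["w_mature"] * float(np.log1p(support.get("mature", 0.0)))
        + w["w_star"] * (support.get("star", 0.0) > 0)
        + w["w_loop"] * (support.get("loop", 0.0) > 0)
        + w["w_pairing"] * pairing_fraction
        - w["penalty"] * frac_out
    )


def _overlaps(locus: tuple[str, int, int], intervals) -> bool:
    c, s, e = locus
    for iv in intervals:
        if iv[0] == c and s < iv[2] and iv[1] < e:
            return True
    return False


def filter_candidates(
    candidates: list[HairpinCandidate],
    max_loci: int = 5,
    annotations=(),
) -> list[HairpinCandidate]:
    """Drop candidates from repetitive loci (> ``max_loci`` genomic copies)
    or overlapping annotated non-miR intervals (ncRNA/coding)."""
    out = []
    for c in candidates:
        if c.n_hits > max_loci:
            continue
        if _overlaps(c.locus[:3], annotations):
            continue
        out.append(c)
    return out


@dataclass
class CutoffResult:
    cutoff: float
    snr: float
    n_false_estimate: float
    achieved: bool


def calibrate_cutoff(
    scores,
    permuted_scores_fn,
    known_count: int,
    target_snr: float = 5.0,
    n_perm: int = 100,
    seed: int = 0,
) -> CutoffResult:
    """Lowest observed-score cutoff whose signal-to-noise ratio meets target.

    SNR(c) = (number of candidates scoring >= c, plus known miRs) divided by
    the permutation-estimated expected number of false positives >= c.  If
    no cutoff qualifies, the best-SNR cutoff is returned flagged.
    """
    scores = np.asarray(list(scores), dtype=float)
    rng = np.random.default_rng(seed)
    perms = [np.asarray(permuted_scores_fn(rng), dtype=float) for _ in range(n_perm)]
    grid = np.unique(scores)
    best = CutoffResult(cutoff=float("nan"), snr=-np.inf, n_false_estimate=np.nan, achieved=False)
    for c in grid:
        signal = int(np.sum(scores >= c)) + known_count
        noise = float(np.mean([np.sum(p >= c) for p in perms]))
        snr = signal / noise if noise > 0 else float("inf")
        if snr > best.snr:
            best = CutoffResult(cutoff=float(c), snr=snr, n_false_estimate=noise, achieved=False)
        if snr >= target_snr:
            return CutoffResult(cutoff=float(c), snr=snr, n_false_estimate=noise, achieved=True)
    return best


# ------------------------------------------------------------------ orchestrator

def _cluster_loci(alignments: list[tuple[GenomeAlignment, float]], merge_dist: int = 30):
    """Group read alignments into loci per (chrom, strand); returns lists of
    (alignment, count) sorted by position."""
    by_key: dict[tuple[str, str], list[tuple[GenomeAlignment, float]]] = {}
    for aln, cnt in alignments:
        by_key.setdefault((aln.chrom, aln.strand), []).append((aln, cnt))
    loci = []
    for key in sorted(by_key):
        group = sorted(by_key[key], key=lambda ac: ac[0].pos)
        current: list[tuple[GenomeAlignment, float]] = []
        last_end = None
        for aln, cnt in group:
            end = aln.pos + len(aln.seq)
            if last_end is not None and aln.pos - last_end > merge_dist:
                loci.append(current)
                current = []
            current.append((aln, cnt))
            last_end = end if last_end is None else max(last_end, end)
        if current:
            loci.append(current)
    return loci


def discover_candidates(
    unique_seqs,
    genome_index,
    known_intervals=(),
    exclusion_intervals=(),
    max_mm: int = 2,
    min_len: int = 18,
    max_loci: int = 5,
    target_snr: float = 5.0,
    n_perm: int = 100,
    min_pairing: float = 0.55,
    weights: dict[str, float] | None = None,
    seed: int = 0,
) -> CandidateSet:
    """End-to-end novel candidate discovery from collapsed reads.

    Reads are mapped to the mini-genome; reads at more than ``max_loci``
    positions are excluded up front; remaining alignments are clustered into
    loci, loci overlapping known precursors are skipped (they count toward
    the known-miR tally of the SNR), each remaining locus is excised, folded
    and scored, and the cutoff is permutation-calibrated.
    """
    genome = {c: "".join("ACGTN"[b] for b in genome_index._enc[c]) for c in genome_index.chroms}

    mapped: list[tuple[GenomeAlignment, float]] = []
    for u in unique_seqs:
        hits = genome_index.map(u.seq, max_mm=max_mm, min_len=min_len)
        if not hits or hits[0].n_hits > max_loci:
            continue
        for h in hits:
            mapped.append((h, u.count))

    known_loci = 0
    candidates: list[HairpinCandidate] = []
    locus_reads: list[list[tuple[int, float, int]]] = []  # per candidate: (local start, count, len)
    for locus in _cluster_loci(mapped):
        chrom, strand = locus[0][0].chrom, locus[0][0].strand
        lo = min(a.pos for a, _ in locus)
        hi = max(a.pos + len(a.seq) for a, _ in locus)
        if _overlaps((chrom, lo, hi), known_intervals):
            known_loci += 1
            continue
        defining = max(locus, key=lambda ac: (ac[1], -ac[0].pos))[0]
        windows = excise_precursors(defining, genome)
        best = None
        for w in windows:
            seq = window_sequence(genome, w)
            if len(seq) < 40:
                continue
            struct, pf = fold_hairpin(seq)
            if best is None or pf > best[2]:
                best = (w, struct, pf, seq)
        if best is None or best[2] < min_pairing:
            continue
        w, struct, pf, seq = best
        chrom_w, start_w, end_w, strand_w, kind = w
        if strand == "+":
            local = [(a.pos - start_w, cnt, len(a.seq)) for a, cnt in locus]
        else:
            local = [(end_w - (a.pos + len(a.seq)), cnt, len(a.seq)) for a, cnt in locus]
        local = [(p, cnt, ln) for p, cnt, ln in local if 0 <= p < len(seq)]
        if not local:
            continue
        def_start = max(local, key=lambda t: t[1])[0]
        def_len = max(local, key=lambda t: t[1])[2]
        support = _support_counts([(p, cnt) for p, cnt, _ in local], def_start, def_len, struct)
        arm = "5p" if def_start + def_len / 2 < len(seq) / 2 else "3p"
        cand = HairpinCandidate(
            locus=(chrom_w, start_w, end_w, strand_w),
            window_kind=kind,
            precursor_seq=seq,
            structure=struct,
            pairing_fraction=pf,
            mature_arm=arm,
            mature_offset=def_start,
            mature_len=def_len,
            read_support=support,
            score=score_candidate(support, pf, weights),
            n_hits=defining.n_hits,
            name=f"cand_{chrom_w}_{start_w}",
        )
        candidates.append(cand)
        locus_reads.append(local)

    candidates_kept = filter_candidates(candidates, max_loci=max_loci, annotations=exclusion_intervals)
    kept_idx = [i for i, c in enumerate(candidates) if c in candidates_kept]

    def permuted_scores(rng: np.random.Generator):
        out = []
        for i in kept_idx:
            c = candidates[i]
            n = len(c.precursor_seq)
            reads = locus_reads[i]
            starts = rng.integers(0, n, size=len(reads))
            perm = [(int(s), cnt) for s, (_, cnt, _) in zip(starts, reads)]
            def_start = int(starts[int(np.argmax([cnt for _, cnt, _ in reads]))])
            support = _support_counts(perm, def_start, c.mature_len, c.structure)
            out.append(score_candidate(support, c.pairing_fraction, weights))
        return out

    cut = calibrate_cutoff(
        [c.score for c in candidates_kept],
        permuted_scores,
        known_count=known_loci,
        target_snr=target_snr,
        n_perm=n_perm,
        seed=seed,
    )
    return CandidateSet(
        candidates=candidates_kept,
        cutoff=cut.cutoff if np.isfinite(cut.cutoff) else float("-inf"),
        snr=cut.snr,
        n_false_estimate=cut.n_false_estimate,
        achieved=cut.achieved,
    )
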