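"""Precursor-window quantification of mature miRs.

Collapsed reads are aligned full-length and ungapped to the precursor
library with at most one substitution.  A read counts toward a mature miR
when its 5' start falls in the acceptance window of 2 nt upstream to 5 nt
downstream of the annotated mature start (isomiR slack for imprecise Dicer
processing and untemplated 3' additions; the window test itself is exact on
coordinates).  Reads that map equally well to several mature positions are
added in full to each of them; a sequence that is itself an annotated
mature miR loses any equally-good off-window hits on unrelated precursors.
Rows of identical mature sequence arising from related precursors are
averaged into one row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import encode
from .types import PrecursorLibrary, PrecursorRecord, UniqueSequence


@dataclass(frozen=True)
class PrecursorHit:
    seq: str
    precursor: str
    offset: int
    mismatches: int


@dataclass(frozen=True)
class MatureAssignment:
    seq: str
    mature_id: str


class PrecursorIndex:
    """Exact-seed index for <=1-mismatch full-length search in precursors."""

    def __init__(self, precursors: list[PrecursorRecord], seed_len: int = 9):
        self.precursors = {p.name: p for p in precursors}
        self.seed_len = seed_len
        self._enc = {p.name: encode(p.sequence) for p in precursors}
        self._index: dict[str, list[tuple[str, int]]] = {}
        for p in precursors:
            for i in range(len(p.sequence) - seed_len + 1):
                self._index.setdefault(p.sequence[i : i + seed_len], []).append((p.name, i))

    def align(self, seq: str, max_mm: int = 1) -> list[PrecursorHit]:
        k = self.seed_len
        L = len(seq)
        if L < k:
            return []
        n_seeds = max_mm + 1
        offsets = sorted(set(min(j * k, L - k) for j in range(n_seeds)))
        q = encode(seq)
        found: set[tuple[str, int]] = set()
        hits = []
        for o in offsets:
            for name, pos in self._index.get(seq[o : o + k], ()):
                start = pos - o
                if (name, start) in found:
                    continue
                found.add((name, start))
                ref = self._enc[name]
                if start < 0 or start + L > len(ref):
                    continue
                mm = int(np.count_nonzero(ref[start : start + L] != q))
                if mm <= max_mm:
                    hits.append(PrecursorHit(seq=seq, precursor=name, offset=start, mismatches=mm))
        return sorted(hits, key=lambda h: (h.mismatches, h.precursor, h.offset))


def align_to_precursors(
    u: UniqueSequence, index: PrecursorIndex, max_mm: int = 1
) -> list[PrecursorHit]:
    return index.align(u.seq, max_mm=max_mm)


def assign_mature(
    hit: PrecursorHit, record: PrecursorRecord, up: int = 2, down: int = 5
) -> MatureAssignment | None:
    """Window test: assign the hit to an arm iff its start offset lies in
    [mature_start - up, mature_start + down]."""
    if hit.precursor != record.name:
        raise ValueError("hit/record mismatch")
    for arm, (m_start, _) in record.arms():
        if m_start - up <= hit.offset <= m_start + down:
            return MatureAssignment(seq=hit.seq, mature_id=record.mature_id(arm))
    return None


def resolve_multimappers(
    hits: list[PrecursorHit],
    records: dict[str, PrecursorRecord],
    annotated_matures: set[str],
    up: int = 2,
    down: int = 5,
) -> list[str]:
    """Final mature ids credited with this sequence's full count.

    Only the equally-best (minimum-mismatch) hits survive.  Window-passing
    hits each receive the full count.  If the sequence is itself an
    annotated mature miR and some best hit lands off-window on an unrelated
    precursor, that off-target hit is simply dropped; if *all* best hits of
    an annotated mature sequence are off-window the sequence is removed
    (contributes nothing).
    """
    if not hits:
        return []
    best = min(h.mismatches for h in hits)
    tier = [h for h in hits if h.mismatches == best]
    assigned = []
    for h in tier:
        a = assign_mature(h, records[h.precursor], up=up, down=down)
        if a is not None:
            assigned.append(a.mature_id)
    return sorted(set(assigned))


def quantify_sample(
    uniques: list[UniqueSequence],
    index: PrecursorIndex,
    max_mm: int = 1,
    up: int = 2,
    down: int = 5,
) -> pd.Series:
    """Per-mature counts for one sample's collapsed reads."""
    records = index.precursors
    annotated = {
        rec.mature_seq(arm) for rec in records.values() for arm, _ in rec.arms()
    }
    mature_ids = [rec.mature_id(arm) for rec in records.values() for arm, _ in rec.arms()]
    counts = pd.Series(0.0, index=mature_ids)
    for u in uniques:
        hits = index.align(u.seq, max_mm=max_mm)
        for mid in resolve_multimappers(hits, records, annotated, up=up, down=down):
            counts[mid] += u.count
    return counts


def build_count_matrix(
    per_sample_uniques: dict[str, list[UniqueSequence]],
    library: PrecursorLibrary,
    max_mm: int = 1,
    up: int = 2,
    down: int = 5,
) -> pd.DataFrame:
    index = PrecursorIndex(library.precursors)
    cols = {}
    for sample_id, uniques in per_sample_uniques.items():
        cols[sample_id] = quantify_sample(uniques, index, max_mm=max_mm, up=up, down=down)
    return pd.DataFrame(cols)


def average_related(matrix: pd.DataFrame, library: PrecursorLibrary) -> pd.DataFrame:
    """Average rows whose mature sequences are identical (related precursor
    copies, e.g. several genomic precursors yielding one mature miR).

    The merged row keeps the alphabetically first mature id of the group.
    """
    seq_of = {}
    for mid, rec, arm in library.mature_records():
        seq_of[mid] = rec.mature_seq(arm)
    groups: dict[str, list[str]] = {}
    for mid in matrix.index:
        groups.setdefault(seq_of.get(mid, mid), []).append(mid)
    rows = []
    names = []
    for seq in groups:
        members = sorted(groups[seq])
        rows.append(matrix.loc[members].mean(axis=0))
        names.append(members[0])
    out = pd.DataFrame(rows, index=names)
    out.index.name = matrix.index.name
    return out.sort_index()


def presence_stats(matrix: pd.DataFrame) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    """Detection summaries: per-miR fraction of samples with count >= 1,
    per-sample number of detected miRs, and the detection indicator."""
    detected = matrix >= 1
    return detected.mean(axis=1), detected.sum(axis=0), detected
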