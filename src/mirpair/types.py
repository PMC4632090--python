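"""Core domain types for the paired small RNA-seq pipeline.

The objects here mirror the data the pipeline moves between stages: hairpin
precursor annotations with their mature -5p/-3p arms, the paired cohort
design (primary colorectal cancer pCRC, metastasis M, paired normal mucosa
PN and paired normal extra-colonic tissue MN), the planted-effect
specification used by the synthetic cohort generator, and light containers
for reads and collapsed sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._seq import revcomp

TISSUE_CLASSES = ("pCRC", "M", "PN", "MN")
TUMOR_CLASSES = ("pCRC", "M")

MIN_ARM_LEN = 18
MAX_ARM_LEN = 26


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass
class PrecursorRecord:
    """A hairpin precursor with genomic placement and mature-arm coordinates.

    ``start``/``end`` are 0-based half-open genomic coordinates; the mature
    arm intervals are precursor-local 0-based half-open.  Either arm may be
    absent (``None``).
    """

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    mature5p: tuple[int, int] | None = None
    mature3p: tuple[int, int] | None = None
    known: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.name}: strand must be + or -")
        if self.end - self.start != len(self.sequence):
            raise ValidationError(f"{self.name}: interval/sequence length mismatch")
        n = len(self.sequence)
        for arm, iv in (("5p", self.mature5p), ("3p", self.mature3p)):
            if iv is None:
                continue
            s, e = iv
            if not (0 <= s < e <= n):
                raise ValidationError(f"{self.name}-{arm}: arm outside precursor")
            if not (MIN_ARM_LEN <= e - s <= MAX_ARM_LEN):
                raise ValidationError(f"{self.name}-{arm}: arm length {e - s} outside 18..26")
        if self.mature5p and self.mature3p:
            if self.mature5p[1] > self.mature3p[0]:
                raise ValidationError(f"{self.name}: mature arms overlap")

    def arms(self):
        """Yield ``(arm_label, (start, end))`` for each annotated arm."""
        if self.mature5p is not None:
            yield "5p", self.mature5p
        if self.mature3p is not None:
            yield "3p", self.mature3p

    def mature_id(self, arm: str) -> str:
        return f"{self.name}-{arm}"

    def mature_seq(self, arm: str) -> str:
        iv = self.mature5p if arm == "5p" else self.mature3p
        if iv is None:
            raise KeyError(f"{self.name} has no {arm} arm")
        return self.sequence[iv[0] : iv[1]]


@dataclass
class PrecursorLibrary:
    """Mini-genome plus precursor annotations, decoy ncRNA and repeat loci."""

    genome: dict[str, str]
    precursors: list[PrecursorRecord]
    decoy_ncrna: list[tuple[str, int, int, str]] = field(default_factory=list)
    repeat_loci: list[tuple[str, int, int]] = field(default_factory=list)

    def validate(self) -> None:
        for rec in self.precursors:
            sub = self.genome[rec.chrom][rec.start : rec.end]
            if rec.strand == "-":
                sub = revcomp(sub)
            if sub != rec.sequence:
                raise ValidationError(f"{rec.name}: sequence does not match genome interval")

    def mature_ids(self) -> list[str]:
        out = []
        for rec in self.precursors:
            for arm, _ in rec.arms():
                out.append(rec.mature_id(arm))
        return out

    def mature_records(self):
        """Yield ``(mature_id, precursor, arm)`` for every annotated arm."""
        for rec in self.precursors:
            for arm, _ in rec.arms():
                yield rec.mature_id(arm), rec, arm


@dataclass
class Sample:
    sample_id: str
    patient_id: str
    tissue_class: str
    organ: str
    resection_day: int
    chemo_between: bool = False
    replicate_group: str | None = None
    tumor_cell_pct: int = 0

    def __post_init__(self) -> None:
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValidationError(f"unknown tissue class {self.tissue_class!r}")


@dataclass
class SampleDesign:
    """Paired cohort design: one row per sequenced sample."""

    samples: list[Sample]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample ids")
        by_patient: dict[str, set[str]] = {}
        for s in self.samples:
            by_patient.setdefault(s.patient_id, set()).add(s.tissue_class)
        for s in self.samples:
            if s.tissue_class == "M" and "pCRC" not in by_patient[s.patient_id]:
                raise ValidationError(f"metastasis {s.sample_id} has no paired pCRC")
        groups: dict[str, set[tuple[str, str]]] = {}
        for s in self.samples:
            if s.replicate_group:
                groups.setdefault(s.replicate_group, set()).add(
                    (s.patient_id, s.tissue_class)
                )
        for g, keys in groups.items():
            if len(keys) != 1:
                raise ValidationError(f"replicate group {g} mixes patients/tissues")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "patient_id": [s.patient_id for s in self.samples],
                "tissue_class": [s.tissue_class for s in self.samples],
                "organ": [s.organ for s in self.samples],
                "resection_day": [s.resection_day for s in self.samples],
                "chemo_between": [s.chemo_between for s in self.samples],
                "replicate_group": [s.replicate_group or "" for s in self.samples],
                "tumor_cell_pct": [s.tumor_cell_pct for s in self.samples],
            }
        ).set_index("sample_id", drop=False)

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def of_class(self, tissue_class: str) -> list[Sample]:
        return [s for s in self.samples if s.tissue_class == tissue_class]

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class EffectSpec:
    """Planted-truth specification for the synthetic cohort.

    Effects are natural-log fold changes.  ``tumor_up``/``tumor_down`` act on
    tumor samples (pCRC and M) versus matched normals; ``met_specific`` acts
    on M versus pCRC; ``tissue_specific`` acts on extra-colonic samples
    (M and MN alike), so the M-pCRC difference it creates is mirrored in
    MN-PN — the decoy pattern the tissue-specificity correction must reject.
    """

    n_mirs: int
    tumor_up: dict[int, float] = field(default_factory=dict)
    tumor_down: dict[int, float] = field(default_factory=dict)
    met_specific: dict[int, float] = field(default_factory=dict)
    tissue_specific: dict[int, float] = field(default_factory=dict)
    baseline_log_mean: tuple[float, float] = (-10.4, 1.5)
    dispersion: float = 0.15
    patient_sd: float = 0.2
    libsize_range: tuple[float, float] = (5e5, 2e6)

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if set(self.met_specific) & set(self.tissue_specific):
            raise ValidationError("met_specific and tissue_specific overlap")
        for d in (self.tumor_up, self.tumor_down, self.met_specific, self.tissue_specific):
            for i in d:
                if not (0 <= i < self.n_mirs):
                    raise ValidationError(f"effect index {i} out of range")


@dataclass
class TrueCounts:
    """miR x sample matrix of simulated true molecule counts."""

    counts: pd.DataFrame
    effects: EffectSpec
    seed: int


@dataclass
class SequencedRead:
    id: str
    seq: str
    qual: list[int]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValidationError(f"{self.id}: seq/qual length mismatch")


@dataclass(frozen=True)
class UniqueSequence:
    seq: str
    count: int


@dataclass(frozen=True)
class GenomeAlignment:
    seq: str
    chrom: str
    pos: int
    strand: str
    mismatches: int
    n_hits: int
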