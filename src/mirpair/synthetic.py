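"""Seeded synthetic small RNA-seq cohort generator.

Everything downstream is testable against this module's planted truth: a
mini-genome carrying hairpin precursors (known and novel), decoy ncRNA and
a repetitive family; a paired cohort design shaped like a 38-patient
primary-CRC/metastasis series (every patient one pCRC and at least one
metastasis; normal mucosa and extra-colonic normals on subsets; liver
overrepresented among metastatic sites); negative-binomial counts with a
patient random intercept and planted tumor-specific, metastasis-specific
and tissue-specific natural-log effects; and FASTQ reads with imprecise
Dicer 5' ends, untemplated 3' additions, a 3' sequencing adapter,
substitution errors and decaying 3' quality tails.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import revcomp
from .discovery import fold_hairpin
from .io import write_fastq
from .types import (
    EffectSpec,
    PrecursorLibrary,
    PrecursorRecord,
    Sample,
    SampleDesign,
    SequencedRead,
    TrueCounts,
    ValidationError,
)

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # TruSeq small RNA 3' adapter

# metastatic-site frequencies with liver overrepresented
_ORGANS = ("liver", "lymph_node", "ovary", "peritoneum", "lung", "stomach", "thoracic_wall")
_ORGAN_P = (0.45, 0.17, 0.13, 0.11, 0.08, 0.03, 0.03)

# 5' jitter over {-2..+5}: truncated geometric centered at 0, >= 0.9 mass at 0
JITTER_OFFSETS = np.arange(-2, 6)


def jitter_weights(decay: float = 0.04) -> np.ndarray:
    w = decay ** np.abs(JITTER_OFFSETS.astype(float))
    return w / w.sum()


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _make_hairpin(rng: np.random.Generator, min_pairing: float = 0.55, drop_arm_p: float = 0.1):
    """One hairpin precursor sequence with annotated arms; retries until the
    maximum-pairing fold reaches the required stem fraction."""
    for _ in range(50):
        arm_len = int(rng.integers(20, 25))
        loop = _random_seq(rng, int(rng.integers(8, 16)))
        arm5 = _random_seq(rng, arm_len)
        arm3 = list(revcomp(arm5))
        for i in rng.choice(arm_len, size=int(rng.integers(0, 3)), replace=False):
            arm3[i] = _random_seq(rng, 1)
        arm3 = "".join(arm3)
        f5 = _random_seq(rng, int(rng.integers(5, 16)))
        f3 = _random_seq(rng, int(rng.integers(5, 16)))
        seq = f5 + arm5 + loop + arm3 + f3
        try:
            _, pf = fold_hairpin(seq)
        except ValueError:
            continue
        if pf < min_pairing:
            continue
        m5 = (len(f5), len(f5) + arm_len)
        m3 = (len(f5) + arm_len + len(loop), len(f5) + arm_len + len(loop) + arm_len)
        u = rng.random()
        if u < drop_arm_p / 2:
            m5 = None
        elif u < drop_arm_p:
            m3 = None
        return seq, m5, m3
    raise ValidationError("failed to generate a well-paired hairpin")


def make_precursor_library(
    n_known: int,
    n_novel: int = 0,
    n_decoys: int = 4,
    seed: int = 0,
    spacer_len: int = 150,
    chrom_size_cap: int = 400_000,
) -> PrecursorLibrary:
    """Mini-genome with hairpin precursors, one >5-copy repeat family and
    decoy ncRNA loci.

    Precursors are placed non-overlapping with at least 100 nt of random
    flank on each side so the 70/20 excision windows stay in bounds.
    """
    if n_known + n_novel < 1:
        raise ValidationError("need at least one precursor")
    rng = np.random.default_rng(seed)
    features: list[tuple[str, object]] = []
    for i in range(n_known):
        features.append((f"mir-{i + 1:03d}", _make_hairpin(rng)))
    for i in range(n_novel):
        features.append((f"novel-{i + 1:03d}", _make_hairpin(rng, drop_arm_p=0.0)))

    repeat_unit = _random_seq(rng, 30)
    n_repeat_copies = 7
    decoy_seqs = [(f"decoy_ncRNA_{i + 1}", _random_seq(rng, 72)) for i in range(n_decoys)]

    # interleave features across chromosomes deterministically
    slots: list[tuple[str, object]] = list(features)
    slots += [("__repeat__", repeat_unit)] * n_repeat_copies
    slots += [("__decoy__", d) for d in decoy_seqs]
    order = rng.permutation(len(slots))

    genome: dict[str, list[str]] = {}
    precursors: list[PrecursorRecord] = []
    decoys: list[tuple[str, int, int, str]] = []
    repeats: list[tuple[str, int, int]] = []

    chrom_i = 1
    chrom = f"chr{chrom_i}"
    parts: list[str] = []
    pos = 0

    def new_chrom():
        nonlocal chrom_i, chrom, parts, pos
        genome[chrom] = parts
        chrom_i += 1
        chrom = f"chr{chrom_i}"
        parts = []
        pos = 0

    for idx in order:
        kind, payload = slots[idx]
        spacer = _random_seq(rng, spacer_len)
        parts.append(spacer)
        pos += len(spacer)
        if kind == "__repeat__":
            parts.append(repeat_unit)
            repeats.append((chrom, pos, pos + len(repeat_unit)))
            pos += len(repeat_unit)
        elif kind == "__decoy__":
            name, seq = payload
            parts.append(seq)
            decoys.append((chrom, pos, pos + len(seq), name))
            pos += len(seq)
        else:
            seq, m5, m3 = payload
            strand = "+" if rng.random() < 0.5 else "-"
            placed = seq if strand == "+" else revcomp(seq)
            parts.append(placed)
            precursors.append(
                PrecursorRecord(
                    name=kind,
                    chrom=chrom,
                    start=pos,
                    end=pos + len(seq),
                    strand=strand,
                    sequence=seq,
                    mature5p=m5,
                    mature3p=m3,
                    known=not kind.startswith("novel"),
                )
            )
            pos += len(seq)
        if pos > chrom_size_cap:
            tail = _random_seq(rng, spacer_len)
            parts.append(tail)
            new_chrom()
    parts.append(_random_seq(rng, spacer_len))
    genome[chrom] = parts

    lib = PrecursorLibrary(
        genome={c: "".join(p) for c, p in genome.items() if p},
        precursors=sorted(precursors, key=lambda r: r.name),
        decoy_ncrna=decoys,
        repeat_loci=repeats,
    )
    if sum(len(s) for s in lib.genome.values()) > 2_000_000:
        raise ValidationError("mini-genome exceeds 2 Mb; reduce feature counts")
    lib.validate()
    return lib


def make_design(
    n_patients: int,
    pn_fraction: float = 0.6,
    mn_fraction: float = 0.45,
    seed: int = 0,
    extra_met_fraction: float = 0.18,
    chemo_p: float = 0.32,
) -> SampleDesign:
    """Paired cohort: every patient one pCRC (two patients contribute a
    second pCRC-class sample, emulating a double primary and a local
    recurrence) and >= 1 metastasis; PN/MN attached to the stated patient
    fractions; resection gaps straddle the 90-day synchronicity threshold;
    two replicate groups (a biological triplicate and a technical
    duplicate)."""
    if n_patients < 2:
        raise ValidationError("need at least 2 patients")
    for f in (pn_fraction, mn_fraction):
        if not 0.0 <= f <= 1.0:
            raise ValidationError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    samples: list[Sample] = []
    patients = [f"P{i + 1:02d}" for i in range(n_patients)]
    n_extra_m = int(round(extra_met_fraction * n_patients))
    extra_m_patients = set(rng.choice(patients, size=n_extra_m, replace=False))
    pn_patients = set(rng.choice(patients, size=int(round(pn_fraction * n_patients)), replace=False))
    # normal-tissue sampling co-occurs: MN patients are drawn from the PN
    # patients first so the paired MN-PN comparison exists at cohort scale
    n_mn = int(round(mn_fraction * n_patients))
    pn_sorted = sorted(pn_patients)
    if n_mn <= len(pn_sorted):
        mn_patients = set(rng.choice(pn_sorted, size=n_mn, replace=False))
    else:
        rest = sorted(set(patients) - pn_patients)
        mn_patients = pn_patients | set(rng.choice(rest, size=n_mn - len(pn_sorted), replace=False))
    double_primary = set(patients[: min(2, n_patients)]) if n_patients >= 4 else set()

    def tumor_pct() -> int:
        return int(np.clip(rng.normal(80, 12), 35, 98))

    for p in patients:
        day0 = int(rng.integers(0, 200))
        samples.append(Sample(f"{p}-pCRC", p, "pCRC", "colon", day0, tumor_cell_pct=tumor_pct()))
        if p in double_primary:
            samples.append(
                Sample(f"{p}-pCRC2", p, "pCRC", "colon", day0 + int(rng.integers(10, 120)),
                       tumor_cell_pct=tumor_pct())
            )
        n_m = 2 if p in extra_m_patients else 1
        for k in range(n_m):
            organ = str(rng.choice(_ORGANS, p=_ORGAN_P))
            # half the pairs synchronous (gap < 90 d, occasionally metastasis
            # first), half metachronous
            if rng.random() < 0.5:
                gap = int(rng.integers(-40, 90))
            else:
                gap = int(rng.integers(90, 1500))
            chemo = bool(rng.random() < chemo_p) and gap >= 90
            samples.append(
                Sample(f"{p}-M{k + 1}", p, "M", organ, day0 + gap,
                       chemo_between=chemo, tumor_cell_pct=tumor_pct())
            )
        if p in pn_patients:
            samples.append(Sample(f"{p}-PN", p, "PN", "colon", day0))
        if p in mn_patients:
            organ_mn = next(s.organ for s in samples if s.patient_id == p and s.tissue_class == "M")
            samples.append(Sample(f"{p}-MN", p, "MN", organ_mn, day0 + int(rng.integers(0, 400))))

    # replicate groups: biological triplicate of one pCRC, technical duplicate
    # of one metastasis
    rep_src = samples[0]
    for r in range(2):
        samples.append(
            Sample(f"{rep_src.sample_id}-rep{r + 2}", rep_src.patient_id, rep_src.tissue_class,
                   rep_src.organ, rep_src.resection_day, replicate_group="bio_triplicate",
                   tumor_cell_pct=rep_src.tumor_cell_pct)
        )
    m_src = next(s for s in samples if s.tissue_class == "M")
    samples.append(
        Sample(f"{m_src.sample_id}-rep2", m_src.patient_id, "M", m_src.organ,
               m_src.resection_day, replicate_group="tech_duplicate",
               tumor_cell_pct=m_src.tumor_cell_pct)
    )
    rep_src.replicate_group = "bio_triplicate"
    m_src.replicate_group = "tech_duplicate"
    return SampleDesign(samples)


def plan_effects(
    n_mirs: int,
    n_met: int = 8,
    n_tissue: int = 29,
    n_tumor_up: int = 135,
    n_tumor_down: int = 87,
    seed: int = 0,
    met_mag: tuple[float, float] = (1.3, 0.25),
    tissue_mag: tuple[float, float] = (1.0, 0.2),
    tumor_mag: tuple[float, float] = (0.9, 0.4),
    **kwargs,
) -> EffectSpec:
    """Planted effect sets shaped like the study's selection counts.

    Magnitudes are natural-log fold changes.  Metastasis-specific effects
    are drawn |N(1.3, 0.25)| clipped to [0.9, 2.0] — the scale of the
    reported tissue-corrected contrast magnitudes (0.80-2.32) and the
    scale a 17-pair normal-normal arm can actually resolve (the
    one-sided |M-pCRC| vs |MN-PN| comparison has standard error ~0.2 at
    this cohort size, so planted contrasts below ~1 are undetectable by
    any test).  Tissue-specific decoys are |N(1.0, 0.2)| clipped to
    [0.8, 1.6] and tumor effects follow the reported tumor-vs-normal
    range, |N(0.9, 0.4)| clipped to [0.4, 2.7].
    """
    rng = np.random.default_rng(seed)
    total = n_met + n_tissue + n_tumor_up + n_tumor_down
    if total > n_mirs:
        raise ValidationError("more planted effects than miRs")
    idx = rng.choice(n_mirs, size=total, replace=False)
    i_met = idx[:n_met]
    i_tis = idx[n_met : n_met + n_tissue]
    i_up = idx[n_met + n_tissue : n_met + n_tissue + n_tumor_up]
    i_down = idx[n_met + n_tissue + n_tumor_up :]

    def mags(n, mu, sd, lo, hi):
        return np.clip(np.abs(rng.normal(mu, sd, size=n)), lo, hi)

    met_sign = rng.choice([-1.0, 1.0], size=n_met)
    tis_sign = rng.choice([-1.0, 1.0], size=n_tissue)
    return EffectSpec(
        n_mirs=n_mirs,
        met_specific={int(i): float(s * m) for i, s, m in
                      zip(i_met, met_sign, mags(n_met, *met_mag, 0.9, 2.0))},
        tissue_specific={int(i): float(s * m) for i, s, m in
                         zip(i_tis, tis_sign, mags(n_tissue, *tissue_mag, 0.8, 1.6))},
        tumor_up={int(i): float(m) for i, m in
                  zip(i_up, mags(n_tumor_up, *tumor_mag, 0.4, 2.7))},
        tumor_down={int(i): float(-m) for i, m in
                    zip(i_down, mags(n_tumor_down, *tumor_mag, 0.4, 2.7))},
        **kwargs,
    )


def simulate_counts(
    library_or_ids,
    design: SampleDesign,
    effects: EffectSpec,
    seed: int = 0,
) -> TrueCounts:
    """Negative-binomial counts over the paired design.

    mean_{i,s} = libsize_s * exp(baseline_i + patient_intercept_{p(s),i}
    + planted effects applicable to sample s); variance mu + disp * mu^2
    (gamma-Poisson; exactly Poisson at dispersion 0).
    """
    if isinstance(library_or_ids, PrecursorLibrary):
        mature_ids = library_or_ids.mature_ids()
    else:
        mature_ids = list(library_or_ids)
    n = len(mature_ids)
    if effects.n_mirs != n:
        raise ValidationError(f"effects.n_mirs={effects.n_mirs} but library has {n} matures")
    rng = np.random.default_rng(seed)
    mu0, sd0 = effects.baseline_log_mean
    baseline = rng.normal(mu0, sd0, size=n)
    lo, hi = effects.libsize_range
    sample_ids = design.sample_ids()
    libsize = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(sample_ids)))
    patients = sorted({s.patient_id for s in design.samples})
    b = {p: rng.normal(0.0, effects.patient_sd, size=n) for p in patients}

    eta = np.tile(baseline, (len(sample_ids), 1))
    for j, s in enumerate(design.samples):
        eta[j] += b[s.patient_id]
        if s.tissue_class in ("pCRC", "M"):
            for i, d in effects.tumor_up.items():
                eta[j, i] += d
            for i, d in effects.tumor_down.items():
                eta[j, i] += d
        if s.tissue_class == "M":
            for i, d in effects.met_specific.items():
                eta[j, i] += d
        if s.tissue_class in ("M", "MN"):
            for i, d in effects.tissue_specific.items():
                eta[j, i] += d
    mu = libsize[:, None] * np.exp(eta)
    if effects.dispersion > 0:
        shape = 1.0 / effects.dispersion
        lam = rng.gamma(shape, mu / shape)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)
    df = pd.DataFrame(counts.T, index=mature_ids, columns=sample_ids)
    return TrueCounts(counts=df, effects=effects, seed=seed)


def emit_reads(
    true_counts: TrueCounts,
    library: PrecursorLibrary,
    adapter: str = DEFAULT_ADAPTER,
    error_rate: float = 0.001,
    seed: int = 0,
    p_ua: float = 0.05,
    jitter_decay: float = 0.04,
    lowq_tail_fraction: float = 0.2,
    decoy_rate: float = 0.01,
    dimer_rate: float = 0.005,
    out_dir: str | Path | None = None,
) -> dict[str, object]:
    """Emit per-sample FASTQ reads for every counted mature molecule.

    Each molecule becomes one read: precursor sequence from the (possibly
    jittered) mature 5' start to the mature 3' end, optionally one
    untemplated 3' A/U, then the adapter; substitution errors at
    ``error_rate``; plateau Q37 qualities with a sub-Q30 3' tail in
    ``lowq_tail_fraction`` of reads.  Decoy-ncRNA and repeat-locus reads
    are added at ``decoy_rate`` of the miR read total, and adapter-dimer
    reads (empty insert, lost at preprocessing) at ``dimer_rate``.  Returns
    ``{sample_id: list[SequencedRead] | Path}`` plus a ``counts`` entry
    with per-sample totals.
    """
    if len(adapter) < 10:
        raise ValidationError("adapter must be at least 10 nt")
    rng = np.random.default_rng(seed)
    jw = jitter_weights(jitter_decay)
    matures = []
    for mid, rec, arm in library.mature_records():
        iv = rec.mature5p if arm == "5p" else rec.mature3p
        matures.append((mid, rec.sequence, iv[0], iv[1]))
    mature_map = {m[0]: m for m in matures}

    decoy_pool = [library.genome[c][s:e] for c, s, e, _ in library.decoy_ncrna]
    decoy_pool += [library.genome[c][s:e] for c, s, e in library.repeat_loci]

    bases = np.array(list("ACGT"))
    out: dict[str, object] = {}
    totals = {}
    for sample_id in true_counts.counts.columns:
        col = true_counts.counts[sample_id]
        reads: list[SequencedRead] = []
        ridx = 0
        for mid, cnt in col.items():
            cnt = int(cnt)
            if cnt == 0:
                continue
            _, prec_seq, m_start, m_end = mature_map[mid]
            offs = rng.choice(JITTER_OFFSETS, size=cnt, p=jw)
            for off in offs:
                start = max(0, m_start + int(off))
                insert = prec_seq[start:m_end]
                if p_ua > 0 and rng.random() < p_ua:
                    insert += str(rng.choice(["A", "T"]))
                seq = insert + adapter
                if error_rate > 0:
                    arr = np.array(list(seq))
                    hit = rng.random(len(arr)) < error_rate
                    if hit.any():
                        arr[hit] = bases[rng.integers(0, 4, size=int(hit.sum()))]
                    seq = "".join(arr)
                qual = [37] * len(seq)
                if lowq_tail_fraction > 0 and rng.random() < lowq_tail_fraction:
                    t = int(rng.integers(3, 9))
                    for k in range(max(0, len(seq) - t), len(seq)):
                        qual[k] = int(rng.integers(2, 30))
                reads.append(SequencedRead(
                    id=f"{sample_id}_r{ridx} mature={mid};off={int(off)}",
                    seq=seq, qual=qual))
                ridx += 1
        n_mir_reads = len(reads)
        n_decoy = rng.poisson(decoy_rate * n_mir_reads) if decoy_pool and decoy_rate > 0 else 0
        for _ in range(int(n_decoy)):
            src = decoy_pool[int(rng.integers(0, len(decoy_pool)))]
            ln = int(rng.integers(19, min(31, len(src) + 1)))
            s0 = int(rng.integers(0, len(src) - ln + 1))
            seq = src[s0 : s0 + ln] + adapter
            reads.append(SequencedRead(id=f"{sample_id}_r{ridx} decoy", seq=seq,
                                       qual=[37] * len(seq)))
            ridx += 1
        n_dimer = rng.poisson(dimer_rate * n_mir_reads) if dimer_rate > 0 else 0
        for _ in range(int(n_dimer)):
            seq = adapter + _random_seq(rng, 8)
            reads.append(SequencedRead(id=f"{sample_id}_r{ridx} dimer", seq=seq,
                                       qual=[37] * len(seq)))
            ridx += 1
        totals[sample_id] = {"mir_reads": n_mir_reads, "decoy_reads": int(n_decoy),
                             "dimer_reads": int(n_dimer), "total": len(reads)}
        if out_dir is not None:
            path = Path(out_dir) / f"{sample_id}.fastq"
            path.parent.mkdir(parents=True, exist_ok=True)
            write_fastq(reads, path)
            out[sample_id] = path
        else:
            out[sample_id] = reads
    out["counts"] = totals
    return out
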