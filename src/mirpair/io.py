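"""Readers/writers for the pipeline's on-disk formats.

FASTA/FASTQ go through Biopython; BED6, sample sheets and count matrices are
plain TSV via pandas.  Collapsed reads use the conventional
``>seq_<i>_x<count>`` FASTA headers.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .types import PrecursorLibrary, PrecursorRecord, Sample, SampleDesign, SequencedRead, UniqueSequence

PHRED_OFFSET = 33


# ---------------------------------------------------------------- FASTA

def write_fasta(records: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_collapsed_fasta(uniques: list[UniqueSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, u in enumerate(uniques):
            fh.write(f">seq_{i}_x{u.count}\n{u.seq}\n")


def read_collapsed_fasta(path: str | Path) -> list[UniqueSequence]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        count = int(rec.id.rsplit("_x", 1)[1])
        out.append(UniqueSequence(seq=str(rec.seq).upper(), count=count))
    return out


# ---------------------------------------------------------------- FASTQ

def write_fastq(reads, path: str | Path) -> None:
    """Write an iterable of SequencedRead as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + PHRED_OFFSET) for q in r.qual)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def iter_fastq(path: str | Path):
    """Yield SequencedRead records from a Phred+33 FASTQ file."""
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield SequencedRead(
                id=title.split()[0],
                seq=seq.upper(),
                qual=[ord(c) - PHRED_OFFSET for c in qual],
            )


# ---------------------------------------------------------------- BED6

def write_bed6(rows: list[tuple], path: str | Path) -> None:
    """rows: (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_bed6(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )


def library_bed_rows(library: PrecursorLibrary) -> list[tuple]:
    """BED6 rows for precursors and their mature arms (genome coordinates)."""
    rows = []
    for rec in library.precursors:
        rows.append((rec.chrom, rec.start, rec.end, rec.name, 0, rec.strand))
        for arm, (s, e) in rec.arms():
            if rec.strand == "+":
                gs, ge = rec.start + s, rec.start + e
            else:
                gs, ge = rec.end - e, rec.end - s
            rows.append((rec.chrom, gs, ge, rec.mature_id(arm), 0, rec.strand))
    return rows


def write_library(library: PrecursorLibrary, out_dir: str | Path) -> dict[str, Path]:
    """Write genome FASTA, precursor FASTA and annotation BED6; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "precursors": out / "precursors.fa",
        "annotations": out / "annotations.bed",
    }
    write_fasta(library.genome, paths["genome"])
    write_fasta({p.name: p.sequence for p in library.precursors}, paths["precursors"])
    rows = library_bed_rows(library)
    rows += [(c, s, e, name, 0, "+") for c, s, e, name in library.decoy_ncrna]
    rows += [(c, s, e, "repeat", 0, "+") for c, s, e in library.repeat_loci]
    write_bed6(rows, paths["annotations"])
    return paths


# ---------------------------------------------------------------- sample sheet

def write_sample_sheet(design: SampleDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype={"replicate_group": str}, keep_default_na=False)
    samples = [
        Sample(
            sample_id=row.sample_id,
            patient_id=row.patient_id,
            tissue_class=row.tissue_class,
            organ=row.organ,
            resection_day=int(row.resection_day),
            chemo_between=bool(row.chemo_between) and str(row.chemo_between) != "False",
            replicate_group=row.replicate_group or None,
            tumor_cell_pct=int(row.tumor_cell_pct),
        )
        for row in df.itertuples()
    ]
    return SampleDesign(samples)


# ---------------------------------------------------------------- matrices / config

def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_mtx(df: pd.DataFrame, path: str | Path) -> None:
    """Sparse MatrixMarket coordinate export of a count matrix."""
    from scipy import io as spio
    from scipy import sparse

    spio.mmwrite(str(path), sparse.csr_matrix(df.to_numpy()))


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
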