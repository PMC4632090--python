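"""End-to-end orchestration: synthesize -> preprocess -> discover ->
quantify -> stats -> profiles, with versioned artifacts and a run log.

All randomness flows from the single config seed; stage seeds are derived
from it with fixed offsets so stages can be re-run independently.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import discovery, io, profiles, quantify, stats, synthetic
from .config import AnalysisConfig
from .preprocess import GenomeIndex, preprocess_reads
from .types import PrecursorLibrary, SampleDesign


class RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.parent.mkdir(parents=True, exist_ok=True)

    def event(self, stage: str, **fields) -> None:
        rec = {"stage": stage, **fields}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")


def _stage_seed(seed: int, offset: int) -> int:
    return int((seed * 1000 + offset) % (2**31 - 1))


def stage_synthesize(cfg: AnalysisConfig, out: Path, log: RunLog):
    t0 = time.perf_counter()
    lib = synthetic.make_precursor_library(
        cfg.n_known, cfg.n_novel, cfg.n_decoys, seed=_stage_seed(cfg.seed, 1)
    )
    design = synthetic.make_design(
        cfg.n_patients, cfg.pn_fraction, cfg.mn_fraction, seed=_stage_seed(cfg.seed, 2)
    )
    n_mirs = len(lib.mature_ids())
    effects = synthetic.plan_effects(
        n_mirs,
        n_met=min(8, max(1, n_mirs // 20)),
        n_tissue=min(29, max(1, n_mirs // 8)),
        n_tumor_up=min(135, max(1, n_mirs // 6)),
        n_tumor_down=min(87, max(1, n_mirs // 8)),
        seed=_stage_seed(cfg.seed, 3),
        libsize_range=(cfg.libsize_lo, cfg.libsize_hi),
    )
    truth = synthetic.simulate_counts(lib, design, effects, seed=_stage_seed(cfg.seed, 4))
    reads = synthetic.emit_reads(
        truth, lib, adapter=cfg.adapter, error_rate=cfg.error_rate,
        p_ua=cfg.p_ua, seed=_stage_seed(cfg.seed, 5), out_dir=out / "fastq",
    )
    io.write_library(lib, out / "library")
    io.write_sample_sheet(design, out / "samples.tsv")
    io.write_matrix(truth.counts, out / "true_counts.tsv")
    log.event("synthesize", seed=cfg.seed, n_precursors=len(lib.precursors),
              n_samples=len(design), wall_s=round(time.perf_counter() - t0, 2))
    return lib, design, truth, reads


def stage_preprocess(cfg: AnalysisConfig, out: Path, log: RunLog, design: SampleDesign):
    t0 = time.perf_counter()
    collapsed = {}
    retention = {}
    (out / "collapsed").mkdir(parents=True, exist_ok=True)
    for sample_id in design.sample_ids():
        fq = out / "fastq" / f"{sample_id}.fastq"
        uniques, st = preprocess_reads(
            io.iter_fastq(fq), cfg.adapter, min_q=cfg.phred_min,
            min_overlap=cfg.adapter_min_overlap,
        )
        collapsed[sample_id] = uniques
        retention[sample_id] = {"raw": st.raw, "retained": st.retained}
        io.write_collapsed_fasta(uniques, out / "collapsed" / f"{sample_id}.fa")
    raw = sum(v["raw"] for v in retention.values())
    kept = sum(v["retained"] for v in retention.values())
    pct = profiles.percent(kept, raw, 1) if raw else "0.0%"
    with open(out / "retention.json", "w") as fh:
        json.dump({"per_sample": retention, "total_raw": raw, "total_retained": kept,
                   "retained_pct": pct}, fh, indent=1, sort_keys=True)
    log.event("preprocess", raw_reads=raw, retained=kept, retained_pct=pct,
              wall_s=round(time.perf_counter() - t0, 2))
    return collapsed, retention


def stage_discover(cfg: AnalysisConfig, out: Path, log: RunLog,
                   lib: PrecursorLibrary, collapsed: dict):
    t0 = time.perf_counter()
    pooled: dict[str, int] = {}
    for uniques in collapsed.values():
        for u in uniques:
            pooled[u.seq] = pooled.get(u.seq, 0) + u.count
    from .types import UniqueSequence

    pooled_u = [UniqueSequence(seq=s, count=c) for s, c in
                sorted(pooled.items(), key=lambda kv: (-kv[1], kv[0]))]
    gidx = GenomeIndex(lib.genome)
    known_iv = [(p.chrom, p.start, p.end) for p in lib.precursors if p.known]
    excl = [(c, s, e) for c, s, e, _ in lib.decoy_ncrna]
    cset = discovery.discover_candidates(
        pooled_u, gidx, known_intervals=known_iv, exclusion_intervals=excl,
        max_mm=cfg.max_mm_genome, min_len=cfg.min_len, max_loci=cfg.max_loci,
        target_snr=cfg.snr_target, n_perm=cfg.n_perm_discovery,
        min_pairing=cfg.min_pairing, seed=_stage_seed(cfg.seed, 6),
    )
    retained = cset.retained()
    rows = [(c.locus[0], c.locus[1], c.locus[2], c.name, round(c.score, 3), c.locus[3])
            for c in retained]
    io.write_bed6(rows, out / "novel_candidates.bed")
    io.write_fasta({c.name: c.precursor_seq for c in retained}, out / "novel_candidates.fa")
    pd.DataFrame(
        [{"name": c.name, "score": c.score, "pairing_fraction": c.pairing_fraction,
          "mature_arm": c.mature_arm, **{f"reads_{k}": v for k, v in c.read_support.items()}}
         for c in retained]
    ).to_csv(out / "novel_candidates.tsv", sep="\t", index=False)
    log.event("discover", n_candidates=len(retained), cutoff=cset.cutoff,
              snr=cset.snr, achieved=cset.achieved,
              wall_s=round(time.perf_counter() - t0, 2))
    return cset


def stage_quantify(cfg: AnalysisConfig, out: Path, log: RunLog,
                   lib: PrecursorLibrary, collapsed: dict):
    t0 = time.perf_counter()
    raw_matrix = quantify.build_count_matrix(
        collapsed, lib, max_mm=cfg.max_mm_precursor, up=cfg.window_up, down=cfg.window_down
    )
    matrix = quantify.average_related(raw_matrix, lib)
    io.write_matrix(matrix, out / "counts.tsv")
    io.write_mtx(matrix, out / "counts.mtx")
    frac, per_sample, _ = quantify.presence_stats(matrix)
    log.event("quantify", n_mirs=int((matrix.sum(axis=1) > 0).sum()),
              mean_mirs_per_sample=float(per_sample.mean()),
              wall_s=round(time.perf_counter() - t0, 2))
    return matrix


def stage_stats(cfg: AnalysisConfig, out: Path, log: RunLog,
                matrix: pd.DataFrame, design: SampleDesign):
    t0 = time.perf_counter()
    filtered = stats.presence_filter(matrix, cfg.min_present_samples)
    norm = stats.normalize(filtered)
    results = {}
    deltas = {}
    for contrast in stats.CONTRASTS:
        spec = stats.ContrastSpec(contrast, sync_days=cfg.sync_days)
        try:
            deltas[contrast], _ = stats.paired_deltas(norm.ln, design, spec)
        except ValueError:
            continue
        try:
            fit = stats.paired_contrast(norm.ln, design, spec)
        except ValueError:
            continue
        results[contrast] = stats.moderate_and_fdr(fit)
        results[contrast].table.to_csv(out / f"contrast_{contrast}.tsv", sep="\t")
    tissue = None
    selection = {}
    if "M_vs_pCRC" in results and "MN_vs_PN" in deltas:
        tissue = stats.tissue_specific_test(
            deltas["M_vs_pCRC"], deltas["MN_vs_PN"],
            n_perm=cfg.n_perm_tissue, seed=_stage_seed(cfg.seed, 7),
        )
        tissue.table.to_csv(out / "tissue_specific_test.tsv", sep="\t")
        sel = stats.select_metastasis_specific(
            results["M_vs_pCRC"], tissue, q=cfg.q_meta, q_tissue=cfg.q_tissue
        )
        selection["metastasis_specific"] = sel.metastasis_specific
        selection["tissue_specific_excluded"] = sel.tissue_specific_excluded
        selection["stage1"] = sel.stage1
    if "M_vs_MN" in results and "pCRC_vs_PN" in results:
        gm_all = pd.Series(
            {m: stats.geometric_mean(norm.normalized.loc[m])[0] for m in norm.normalized.index}
        )
        sel2 = stats.select_tumor_specific(
            results["M_vs_MN"], results["pCRC_vs_PN"], gm_all,
            q=cfg.q_tumor, expr_cut=cfg.expr_shortlist_cut,
        )
        selection["tumor_specific_up"] = sel2.tumor_specific_up
        selection["tumor_specific_down"] = sel2.tumor_specific_down
        selection["high_expression_shortlist"] = sel2.high_expression_shortlist
    with open(out / "selection.json", "w") as fh:
        json.dump(selection, fh, indent=1, sort_keys=True)
    io.write_matrix(norm.log2, out / "log2_normalized.tsv")
    norm.tmm.to_csv(out / "tmm_factors.tsv", sep="\t")
    log.event("stats", n_testable=filtered.shape[0],
              **{k: len(v) for k, v in selection.items()},
              wall_s=round(time.perf_counter() - t0, 2))
    return norm, results, tissue, selection


def stage_profiles(cfg: AnalysisConfig, out: Path, log: RunLog,
                   norm: stats.NormalizedMatrix, design: SampleDesign,
                   matrix: pd.DataFrame, retention: dict, selection: dict):
    t0 = time.perf_counter()
    df = design.to_frame()
    report: dict[str, object] = {}
    # clustering of tumor vs normal mucosa, and pCRC vs M
    for name, classes in (("pCRC_vs_PN", ("pCRC", "PN")), ("pCRC_vs_M", ("pCRC", "M"))):
        ids = [s for s in norm.log2.columns
               if df.loc[s, "tissue_class"] in classes and not df.loc[s, "replicate_group"]]
        if len(ids) < 4:
            continue
        res = profiles.ward_cluster(norm.log2[ids])
        (out / f"dendrogram_{name}.nwk").write_text(res.to_newick())
        agreement = profiles.cluster_class_agreement(
            res.cut(2), df.loc[ids, "tissue_class"])
        report[f"cluster_agreement_{name}"] = agreement
    # replicate concordance
    conc = profiles.replicate_concordance(matrix, design)
    report["replicate_spearman"] = {f"{a}|{b}": (None if np.isnan(r) else round(r, 4))
                                    for (a, b), r in conc.items()}
    # retention and selection arithmetic
    raw = sum(v["raw"] for v in retention.values())
    kept = sum(v["retained"] for v in retention.values())
    entries = [("retained_reads", kept, raw, 1)]
    n_testable = selection.get("n_testable")
    report["percentages"] = profiles.summary_report(entries)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    log.event("profiles", wall_s=round(time.perf_counter() - t0, 2))
    return report


def run_pipeline(cfg: AnalysisConfig, out_dir: str | Path) -> Path:
    """Execute every stage; returns the artifact directory."""
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog(out / "run.log")
    log.event("start", config=cfg.to_dict())
    lib, design, truth, _ = stage_synthesize(cfg, out, log)
    collapsed, retention = stage_preprocess(cfg, out, log, design)
    stage_discover(cfg, out, log, lib, collapsed)
    matrix = stage_quantify(cfg, out, log, lib, collapsed)
    norm, results, tissue, selection = stage_stats(cfg, out, log, matrix, design)
    stage_profiles(cfg, out, log, norm, design, matrix, retention, selection)
    log.event("done")
    return out
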