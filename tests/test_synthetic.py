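"""Synthetic cohort generator: library, design, counts, reads."""

import numpy as np
import pytest

from mirpair import io, synthetic
from mirpair.discovery import fold_hairpin
from mirpair.preprocess import clip_adapter, preprocess_reads, trim_quality
from mirpair.quantify import PrecursorIndex, assign_mature
from mirpair.types import EffectSpec, ValidationError


class TestPrecursorLibrary:
    def test_minimal_library_unique_placement(self):
        lib = synthetic.make_precursor_library(1, 0, 0, seed=1)
        assert len(lib.precursors) == 1
        rec = lib.precursors[0]
        genome = "".join(lib.genome.values())
        placed = rec.sequence if rec.strand == "+" else None
        from mirpair._seq import revcomp

        placed = rec.sequence if rec.strand == "+" else revcomp(rec.sequence)
        assert genome.count(placed) == 1

    def test_all_precursors_fold_and_validate(self, small_library):
        small_library.validate()
        for rec in small_library.precursors:
            _, pf = fold_hairpin(rec.sequence)
            assert pf >= 0.55

    def test_repeat_family_has_more_than_five_copies(self, small_library):
        c, s, e = small_library.repeat_loci[0]
        unit = small_library.genome[c][s:e]
        total = sum(g.count(unit) for g in small_library.genome.values())
        assert total > 5
        assert len(small_library.repeat_loci) > 5

    def test_deterministic_byte_identical_output(self, tmp_path):
        for d in ("a", "b"):
            lib = synthetic.make_precursor_library(6, 2, 2, seed=42)
            io.write_library(lib, tmp_path / d)
        for name in ("genome.fa", "precursors.fa", "annotations.bed"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


class TestDesign:
    def test_cohort_shape(self, cohort_design):
        df = cohort_design.to_frame()
        assert df.patient_id.nunique() == 38
        assert (df.tissue_class == "PN").sum() == 23
        assert (df.tissue_class == "MN").sum() == 17
        # every metastasis patient has a paired pCRC
        by_patient = df.groupby("patient_id")["tissue_class"].agg(set)
        assert all("pCRC" in s for s in by_patient[by_patient.apply(lambda s: "M" in s)].values)
        assert df.replicate_group.replace("", np.nan).dropna().nunique() == 2

    def test_full_pairing_two_patients(self, quad_design):
        df = quad_design.to_frame()
        by_patient = df.groupby("patient_id")["tissue_class"].agg(set)
        assert all(s >= {"pCRC", "M", "PN", "MN"} for s in by_patient)

    def test_fraction_validation(self):
        with pytest.raises(ValidationError):
            synthetic.make_design(4, 1.5, 0.5, seed=0)

    def test_synchronicity_straddles_90_days(self, cohort_design):
        from mirpair.stats import ContrastSpec, paired_deltas
        import pandas as pd

        ids = [f"m{i}" for i in range(4)]
        eff = EffectSpec(n_mirs=4)
        tc = synthetic.simulate_counts(ids, cohort_design, eff, seed=0)
        ln = np.log(tc.counts + 1.0)
        _, covs = paired_deltas(ln, cohort_design, ContrastSpec("M_vs_pCRC"))
        assert (covs.time_days == 0).any() and (covs.time_days >= 90).any()
        assert not ((covs.time_days > 0) & (covs.time_days < 90)).any()


class TestSimulateCounts:
    def test_null_model_classes_exchangeable(self):
        design = synthetic.make_design(6, 1.0, 1.0, seed=1)
        ids = [f"m{i}" for i in range(30)]
        eff = EffectSpec(n_mirs=30, patient_sd=0.0, libsize_range=(1e6, 1e6))
        df = design.to_frame()
        diffs = []
        for seed in range(20):
            tc = synthetic.simulate_counts(ids, design, eff, seed=seed)
            m_cols = df.index[df.tissue_class == "M"]
            p_cols = df.index[df.tissue_class == "pCRC"]
            diffs.append(tc.counts[m_cols].mean(axis=1) - tc.counts[p_cols].mean(axis=1))
        mean_diff = np.mean([d.mean() for d in diffs])
        se = np.std([d.mean() for d in diffs], ddof=1) / np.sqrt(20)
        assert abs(mean_diff) <= 3 * max(se, 1e-9)

    def test_planted_met_effect_recovers_ratio(self):
        design = synthetic.make_design(10, 1.0, 1.0, seed=2)
        ids = [f"m{i}" for i in range(40)]
        df = design.to_frame()
        ratios = []
        for seed in range(20):
            eff = EffectSpec(n_mirs=40, met_specific={0: 0.84}, patient_sd=0.0,
                             baseline_log_mean=(-6.0, 0.3), dispersion=0.05,
                             libsize_range=(1e5, 1e5))
            tc = synthetic.simulate_counts(ids, design, eff, seed=100 + seed)
            m = tc.counts.loc["m0", df.index[df.tissue_class == "M"]].mean()
            p = tc.counts.loc["m0", df.index[df.tissue_class == "pCRC"]].mean()
            ratios.append(m / p)
        mc_se = np.std(ratios, ddof=1) / np.sqrt(20)
        assert np.mean(ratios) == pytest.approx(np.exp(0.84), abs=3 * mc_se + 0.05)

    def test_zero_dispersion_is_poisson(self):
        design = synthetic.make_design(20, 0.0, 0.0, seed=3)
        ids = [f"m{i}" for i in range(100)]
        eff = EffectSpec(n_mirs=100, dispersion=0.0, patient_sd=0.0,
                         baseline_log_mean=(-7.0, 0.0), libsize_range=(1e5, 1e5))
        tc = synthetic.simulate_counts(ids, design, eff, seed=4)
        ratio = (tc.counts.var(axis=1, ddof=1) / tc.counts.mean(axis=1)).mean()
        n = tc.counts.shape[1]
        assert ratio == pytest.approx(1.0, abs=4 * np.sqrt(2.0 / (n - 1)) / 10 + 0.05)


class TestEmitReads:
    @pytest.fixture(scope="class")
    def noiseless(self, small_library):
        design = synthetic.make_design(2, 1.0, 1.0, seed=5)
        eff = synthetic.plan_effects(len(small_library.mature_ids()), 1, 1, 2, 1,
                                     seed=0, libsize_range=(1e4, 2e4))
        tc = synthetic.simulate_counts(small_library, design, eff, seed=6)
        reads = synthetic.emit_reads(tc, small_library, error_rate=0.0, p_ua=0.0,
                                     jitter_decay=0.0, lowq_tail_fraction=0.0,
                                     decoy_rate=0.0, dimer_rate=0.0, seed=7)
        return tc, reads

    def test_noiseless_reads_clip_to_mature_exactly(self, small_library, noiseless):
        tc, reads = noiseless
        matures = {rec.mature_seq(arm) for _, rec, arm in small_library.mature_records()}
        sid = tc.counts.columns[0]
        for r in reads[sid][:200]:
            clipped = clip_adapter(trim_quality(r), synthetic.DEFAULT_ADAPTER)
            assert clipped.seq in matures

    def test_read_conservation(self, small_library):
        design = synthetic.make_design(2, 0.5, 0.5, seed=8)
        eff = synthetic.plan_effects(len(small_library.mature_ids()), 1, 1, 1, 1,
                                     seed=1, libsize_range=(1e4, 2e4))
        tc = synthetic.simulate_counts(small_library, design, eff, seed=9)
        reads = synthetic.emit_reads(tc, small_library, seed=10)
        for sid in tc.counts.columns:
            t = reads["counts"][sid]
            assert t["mir_reads"] == int(tc.counts[sid].sum())
            assert len(reads[sid]) == t["total"] == (
                t["mir_reads"] + t["decoy_reads"] + t["dimer_reads"]
            )

    def test_out_of_window_jitter_unassigned(self, small_library):
        rec = next(r for r in small_library.precursors if r.mature5p is not None)
        m_start, m_end = rec.mature5p
        insert = rec.sequence[m_start - 3 : m_end]  # jitter -3: outside window
        idx = PrecursorIndex(small_library.precursors)
        hits = [h for h in idx.align(insert) if h.precursor == rec.name]
        assert hits, "read still aligns to its precursor"
        assert all(assign_mature(h, rec) is None or
                   h.offset != m_start - 3 for h in hits)
        at_minus3 = [h for h in hits if h.offset == m_start - 3]
        assert at_minus3 and all(assign_mature(h, rec) is None for h in at_minus3)

    def test_deterministic_fastq_bytes(self, small_library, tmp_path):
        design = synthetic.make_design(2, 0.0, 0.0, seed=11)
        eff = synthetic.plan_effects(len(small_library.mature_ids()), 1, 1, 1, 1,
                                     seed=2, libsize_range=(5e3, 1e4))
        tc = synthetic.simulate_counts(small_library, design, eff, seed=12)
        for d in ("a", "b"):
            synthetic.emit_reads(tc, small_library, seed=13, out_dir=tmp_path / d)
        sid = tc.counts.columns[0]
        assert (tmp_path / "a" / f"{sid}.fastq").read_bytes() == \
               (tmp_path / "b" / f"{sid}.fastq").read_bytes()

    def test_lowq_tail_exercises_trimmer(self, small_library):
        design = synthetic.make_design(2, 0.0, 0.0, seed=14)
        eff = synthetic.plan_effects(len(small_library.mature_ids()), 1, 1, 1, 1,
                                     seed=3, libsize_range=(1e4, 2e4))
        tc = synthetic.simulate_counts(small_library, design, eff, seed=15)
        reads = synthetic.emit_reads(tc, small_library, seed=16, lowq_tail_fraction=0.2)
        sid = tc.counts.columns[0]
        frac_tail = np.mean([min(r.qual[-3:]) < 30 for r in reads[sid]])
        assert 0.1 < frac_tail < 0.35
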