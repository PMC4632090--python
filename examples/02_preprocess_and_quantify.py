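"""Noiseless round-trip: emit reads, preprocess, quantify, and compare the
recovered count matrix to the planted truth.

With sequencing errors, 5' jitter and untemplated additions switched off,
quality trimming + adapter clipping + precursor-window assignment must
reproduce the true molecule counts exactly — an end-to-end consistency
check of the whole read path.
"""

from mirpair import synthetic
from mirpair.preprocess import preprocess_reads
from mirpair.quantify import build_count_matrix, presence_stats

library = synthetic.make_precursor_library(25, 5, 0, seed=7)
design = synthetic.make_design(4, 1.0, 1.0, seed=8)
effects = synthetic.plan_effects(
    len(library.mature_ids()), 2, 2, 4, 3, seed=9, libsize_range=(3e4, 6e4))
truth = synthetic.simulate_counts(library, design, effects, seed=10)
reads = synthetic.emit_reads(
    truth, library, error_rate=0.0, p_ua=0.0, jitter_decay=0.0,
    lowq_tail_fraction=0.0, decoy_rate=0.0, dimer_rate=0.0, seed=11,
)

collapsed = {}
for sample_id in truth.counts.columns:
    collapsed[sample_id], stats_ = preprocess_reads(
        reads[sample_id], synthetic.DEFAULT_ADAPTER)
    assert stats_.retained == stats_.raw

matrix = build_count_matrix(collapsed, library)
matrix = matrix.loc[truth.counts.index, truth.counts.columns]
exact = (matrix == truth.counts).to_numpy().mean()
frac, per_sample, _ = presence_stats(matrix)

print(f"count matrix: {matrix.shape[0]} mature miRs x {matrix.shape[1]} samples")
print(f"cells equal to planted truth: {100 * exact:.1f}%")
print(f"mean miRs detected per sample: {per_sample.mean():.0f}")
# 100% equality means no read was lost, misassigned or double-counted
# anywhere in trim -> clip -> collapse -> align -> window-assign.
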