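"""Unsupervised clustering, saturation, replicate concordance and report
arithmetic.

Clustering is Ward's minimum-variance linkage on Euclidean distances
between sample columns of the log2 normalized matrix (per-miR row scaling
is a display convention only and is not applied before clustering).
Saturation curves subsample reads without replacement, nested across
depths so each replicate's curve is monotone.  Report percentages are
rounded half-up at the requested precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import spearmanr

from .types import SampleDesign


# ------------------------------------------------------------------ clustering

@dataclass
class ClusterResult:
    linkage: np.ndarray
    sample_ids: list[str]
    order: list[str]

    def cut(self, k: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids, name="cluster")

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.sample_ids[node.id]
            left, right = rec(node.get_left()), rec(node.get_right())
            return f"({left}:{node.dist:.6g},{right}:{node.dist:.6g})"

        return rec(tree) + ";"


def ward_cluster(log2_matrix: pd.DataFrame) -> ClusterResult:
    """Ward linkage over sample columns (Euclidean distance)."""
    if log2_matrix.shape[1] < 2:
        raise ValueError("clustering needs at least 2 samples")
    X = log2_matrix.to_numpy(dtype=float).T
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    order = [log2_matrix.columns[i] for i in hierarchy.leaves_list(Z)]
    return ClusterResult(linkage=Z, sample_ids=list(log2_matrix.columns), order=order)


def cluster_class_agreement(labels: pd.Series, classes: pd.Series) -> float:
    """Best-relabeling agreement between a 2-cut and a binary class label."""
    a = labels.to_numpy()
    c = classes.loc[labels.index].to_numpy()
    cls = np.unique(c)
    if len(cls) != 2:
        raise ValueError("expected exactly two classes")
    match1 = np.mean((a == a.min()) == (c == cls[0]))
    return float(max(match1, 1.0 - match1))


# ------------------------------------------------------------------ saturation

@dataclass
class SaturationCurve:
    depths: list[int]
    unique_mirs: pd.DataFrame  # replicate x depth
    marginal_rates: pd.DataFrame  # replicate x (depth interval)

    def mean_unique(self) -> pd.Series:
        return self.unique_mirs.mean(axis=0)


def marginal_rate(delta_unique: float, delta_reads: float) -> float:
    """Additional unique miRs per million additional reads."""
    return delta_unique / (delta_reads / 1e6)


def saturation_curve(
    read_labels,
    depths,
    n_rep: int = 3,
    seed: int = 0,
) -> SaturationCurve:
    """Unique detected miRs at nested subsampled depths.

    ``read_labels`` is the per-read mature-miR assignment for one sample
    (``None`` for unassigned reads); each replicate draws one permutation
    and reuses its prefixes across depths, so curves are monotone.
    """
    labels = np.asarray(
        ["" if v is None else str(v) for v in read_labels], dtype=object
    )
    depths = sorted(int(d) for d in depths)
    if depths and depths[-1] > len(labels):
        raise ValueError("depth exceeds available reads")
    rng = np.random.default_rng(seed)
    uniq = np.zeros((n_rep, len(depths)), dtype=int)
    for r in range(n_rep):
        perm = rng.permutation(len(labels))
        for j, d in enumerate(depths):
            sub = labels[perm[:d]]
            uniq[r, j] = len(set(sub[sub != ""]))
    cols = [f"{d}" for d in depths]
    udf = pd.DataFrame(uniq, columns=cols)
    rates = {}
    for j in range(1, len(depths)):
        key = f"{depths[j-1]}-{depths[j]}"
        rates[key] = [
            marginal_rate(uniq[r, j] - uniq[r, j - 1], depths[j] - depths[j - 1])
            for r in range(n_rep)
        ]
    return SaturationCurve(depths=depths, unique_mirs=udf, marginal_rates=pd.DataFrame(rates))


# ------------------------------------------------------------------ concordance

def replicate_concordance(
    matrix: pd.DataFrame, design: SampleDesign
) -> dict[tuple[str, str], float]:
    """Spearman correlation for every within-replicate-group sample pair,
    computed on miRs detected (count >= 1) in both samples."""
    groups: dict[str, list[str]] = {}
    for s in design.samples:
        if s.replicate_group:
            groups.setdefault(s.replicate_group, []).append(s.sample_id)
    out = {}
    for g in sorted(groups):
        ids = [i for i in groups[g] if i in matrix.columns]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = matrix[ids[i]], matrix[ids[j]]
                shared = (a >= 1) & (b >= 1)
                if shared.sum() < 3:
                    rho = np.nan
                else:
                    rho = float(spearmanr(a[shared], b[shared]).statistic)
                out[(ids[i], ids[j])] = rho
    return out


def pairwise_spearman(a, b) -> float:
    """Spearman rho between two expression vectors on jointly detected miRs."""
    a = pd.Series(a)
    b = pd.Series(b)
    shared = (a >= 1) & (b >= 1)
    return float(spearmanr(a[shared], b[shared]).statistic)


# ------------------------------------------------------------------ report

def percent(numerator: float, denominator: float, decimals: int = 1) -> str:
    """100*num/den rounded half-up, formatted with a trailing percent sign."""
    if denominator == 0:
        raise ZeroDivisionError("zero denominator in report percentage")
    value = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    q = Decimal(1).scaleb(-decimals)
    return f"{value.quantize(q, rounding=ROUND_HALF_UP)}%"


def round_half_up(value: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def summary_report(entries: list[tuple[str, float, float, int]]) -> dict[str, str]:
    """Formatted ratio lines: entries are (label, numerator, denominator,
    decimals)."""
    return {label: percent(num, den, dec) for label, num, den, dec in entries}
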