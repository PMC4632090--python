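"""Normalization and paired differential expression with Bayesian FDR.

The statistical workflow mirrors standard paired count-seq practice:

* **TMM normalization** (trimmed mean of M-values) computed from its
  definition: a reference sample is the one whose upper-quartile /
  library-size ratio is closest to the cohort mean; per sample, log2
  ratios (M) and average log2 abundances (A) over genes positive in both
  sample and reference are doubly trimmed (30% on M, 5% on A, by average
  ranks) and combined in a precision-weighted mean, exponentiated to a
  factor; factors are rescaled so the reference's factor is 1.
* **Paired contrasts** on the natural-log scale: per-patient differences
  are regressed on an intercept plus mean-centered covariates (organ of
  metastasis for the M-pCRC contrast only, time between resections with
  the < 90-day synchronicity rule, chemotherapy between resections); the
  intercept is the reported effect.
* **Empirical-Bayes moderation**: squared standard errors are shrunk
  toward a scaled-inverse-chi-square prior fitted by marginal maximum
  likelihood across miRs; moderated t statistics are probit-transformed to
  z scores and fed to a two-groups local-fdr fit (theoretical N(0,1) null,
  marginal density by Lindsey's Poisson-spline histogram method).
* **Bayesian FDR**: the running mean of local fdr values over the
  rejection set, i.e. BFDR(i) = mean of the i smallest lfdr values.
* **Tissue-specificity correction**: the one-sided test of whether
  |M-pCRC| exceeds |MN-PN| per miR, by permutation of pair labels between
  the two pair collections.

Selection reproduces the two-stage logic: metastasis-specific miRs are
those significant for M-pCRC (BFDR <= 0.10) whose difference is also
significantly larger than the matched normal-tissue difference; tumor-
specific miRs are those concordantly significant (BFDR <= 0.05, same
sign) in both tumor-versus-normal contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps
from scipy.interpolate import BSpline

from .types import SampleDesign

CONTRASTS = ("M_vs_pCRC", "MN_vs_PN", "M_vs_MN", "pCRC_vs_PN")
_CONTRAST_CLASSES = {
    "M_vs_pCRC": ("M", "pCRC"),
    "MN_vs_PN": ("MN", "PN"),
    "M_vs_MN": ("M", "MN"),
    "pCRC_vs_PN": ("pCRC", "PN"),
}


# ------------------------------------------------------------------ TMM

def _avg_ranks(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based), ties averaged."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, reference factor 1."""
    X = counts.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = X.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("all-zero sample in count matrix")
    uq = np.array([np.quantile(X[:, s], 0.75) for s in range(X.shape[1])]) / lib
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(X.shape[1])
    for s in range(X.shape[1]):
        if s == ref:
            continue
        mask = (X[:, s] > 0) & (X[:, ref] > 0)
        if not mask.any():
            raise ValueError(
                f"sample {counts.columns[s]!r} shares no positive genes with reference"
            )
        ys, yr = X[mask, s], X[mask, ref]
        ps, pr = ys / lib[s], yr / lib[ref]
        M = np.log2(ps / pr)
        A = 0.5 * np.log2(ps * pr)
        # asymptotic (delta-method) variance of M
        v = (lib[s] - ys) / (lib[s] * ys) + (lib[ref] - yr) / (lib[ref] * yr)
        n = len(M)
        loM = int(np.floor(n * logratio_trim)) + 1
        hiM = n + 1 - loM
        loA = int(np.floor(n * sum_trim)) + 1
        hiA = n + 1 - loA
        rM, rA = _avg_ranks(M), _avg_ranks(A)
        keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        if not keep.any():
            factors[s] = 1.0
            continue
        with np.errstate(divide="ignore"):
            f = np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep])
        factors[s] = 2.0 ** f
    factors = factors / factors[ref]
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


@dataclass
class NormalizedMatrix:
    """Count matrix with TMM factors and the derived transforms."""

    counts: pd.DataFrame
    tmm: pd.Series
    effective_libsize: pd.Series
    normalized: pd.DataFrame
    log2: pd.DataFrame
    ln: pd.DataFrame


def normalize(counts: pd.DataFrame, **tmm_kwargs) -> NormalizedMatrix:
    """TMM-normalize to a common scale (counts-per-mean-effective-libsize)."""
    tmm = tmm_factors(counts, **tmm_kwargs)
    lib = counts.sum(axis=0)
    eff = lib * tmm
    norm = counts / eff * eff.mean()
    return NormalizedMatrix(
        counts=counts,
        tmm=tmm,
        effective_libsize=eff,
        normalized=norm,
        log2=log_transform(norm),
        ln=np.log(norm + 1.0),
    )


def log_transform(normalized: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1) elementwise."""
    if (normalized.to_numpy() < 0).any():
        raise ValueError("negative values in normalized matrix")
    return np.log2(normalized + 1.0)


def presence_filter(matrix: pd.DataFrame, min_samples: int = 3) -> pd.DataFrame:
    """Keep miRs with count >= 1 in at least ``min_samples`` samples."""
    keep = (matrix >= 1).sum(axis=1) >= min_samples
    return matrix.loc[keep]


def geometric_mean(values) -> tuple[float, float]:
    """(exp(mean(ln(x+1))) - 1, percent of samples with x >= 1)."""
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        return 0.0, 0.0
    gm = float(np.expm1(np.mean(np.log1p(x))))
    return gm, float(100.0 * np.mean(x >= 1))


# ------------------------------------------------------------------ pairing

@dataclass
class ContrastSpec:
    contrast: str
    use_organ: bool | None = None
    sync_days: int = 90

    def __post_init__(self) -> None:
        if self.contrast not in CONTRASTS:
            raise ValueError(f"unknown contrast {self.contrast!r}")
        if self.use_organ is None:
            # organ of metastasis is a covariate for the M-pCRC comparison only
            self.use_organ = self.contrast == "M_vs_pCRC"


def paired_deltas(
    ln_matrix: pd.DataFrame, design: SampleDesign, spec: ContrastSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pair natural-log differences and the pair covariate table.

    Pairs are (numerator sample, patient's denominator samples averaged).
    A patient with two metastases contributes both pairs; a patient with
    two pCRCs contributes the mean expression and mean resection time of
    the two.  The time covariate is 0 for synchronous pairs (gap below the
    synchronicity threshold, or metastasis resected first).
    """
    num_class, den_class = _CONTRAST_CLASSES[spec.contrast]
    # within a replicate group only the first sample (by id) enters pairing
    secondary_reps: set[str] = set()
    groups: dict[str, list[str]] = {}
    for s in design.samples:
        if s.replicate_group:
            groups.setdefault(s.replicate_group, []).append(s.sample_id)
    for ids in groups.values():
        secondary_reps.update(sorted(ids)[1:])
    by_patient_den: dict[str, list] = {}
    for s in design.samples:
        if s.tissue_class == den_class and s.sample_id not in secondary_reps:
            by_patient_den.setdefault(s.patient_id, []).append(s)
    deltas = {}
    covs = []
    for s in design.samples:
        if s.tissue_class != num_class or s.sample_id in secondary_reps:
            continue
        dens = by_patient_den.get(s.patient_id)
        if not dens:
            continue
        den_expr = ln_matrix[[d.sample_id for d in dens]].mean(axis=1)
        pair_id = f"{s.sample_id}|{den_class}"
        deltas[pair_id] = ln_matrix[s.sample_id] - den_expr
        den_day = float(np.mean([d.resection_day for d in dens]))
        gap = s.resection_day - den_day
        time_days = 0.0 if gap < spec.sync_days else float(gap)
        covs.append(
            {
                "pair_id": pair_id,
                "patient_id": s.patient_id,
                "organ": s.organ,
                "time_days": time_days,
                "chemo": float(s.chemo_between),
            }
        )
    if not deltas:
        raise ValueError(f"no complete pairs for contrast {spec.contrast}")
    return pd.DataFrame(deltas), pd.DataFrame(covs).set_index("pair_id")


def _design_matrix(covs: pd.DataFrame, use_organ: bool) -> np.ndarray:
    """Intercept + mean-centered covariates (so the intercept is the
    covariate-adjusted mean difference)."""
    cols = [np.ones(len(covs))]
    for name in ("time_days", "chemo"):
        x = covs[name].to_numpy(dtype=float)
        if np.ptp(x) > 0:
            cols.append(x - x.mean())
    if use_organ:
        organs = sorted(covs["organ"].unique())
        for org in organs[1:]:
            x = (covs["organ"] == org).to_numpy(dtype=float)
            if 0 < x.sum() < len(x):
                cols.append(x - x.mean())
    return np.column_stack(cols)


def paired_contrast(
    ln_matrix: pd.DataFrame, design: SampleDesign, spec: ContrastSpec
) -> pd.DataFrame:
    """Per-miR effect (natural-log FC), standard error and residual df."""
    D, covs = paired_deltas(ln_matrix, design, spec)
    if D.shape[1] < 3:
        raise ValueError(f"contrast {spec.contrast}: fewer than 3 complete pairs")
    X = _design_matrix(covs, spec.use_organ)
    n, p = X.shape
    if n <= p:
        X = X[:, :1]
        p = 1
    Y = D.to_numpy(dtype=float).T  # pairs x miRs
    XtX_inv = np.linalg.pinv(X.T @ X)
    B = XtX_inv @ X.T @ Y
    resid = Y - X @ B
    dof = n - p
    s2 = (resid ** 2).sum(axis=0) / dof if dof > 0 else np.zeros(Y.shape[1])
    se = np.sqrt(s2 * XtX_inv[0, 0])
    return pd.DataFrame(
        {"effect": B[0], "se": se, "df": dof, "n_pairs": n}, index=D.index
    )


# ------------------------------------------------------------------ moderation & fdr

def fit_scaled_invchisq(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Fit (prior df d0, prior scale s0^2) by marginal ML across features.

    Under the hierarchical model  s_g^2 | sigma_g^2 ~ sigma_g^2 chi2_d/d
    with a scaled-inverse-chi-square prior on sigma_g^2, the marginal law
    of s_g^2 / s0^2 is F(d, d0).
    """
    pos = s2 > 0
    if pos.sum() < 10:
        return np.inf, float(np.median(s2[pos])) if pos.any() else 0.0
    x = s2[pos]
    d = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)[pos]

    def nll(theta):
        log_s02, log_d0 = theta
        s02, d0 = np.exp(log_s02), np.exp(log_d0)
        with np.errstate(all="ignore"):
            ll = np.sum(sps.f.logpdf(x / s02, d, d0) - log_s02)
        return -ll if np.isfinite(ll) else 1e12

    x0 = np.array([np.log(np.median(x)), np.log(4.0)])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-6, "maxiter": 2000})
    log_s02, log_d0 = res.x
    d0 = float(np.exp(log_d0))
    return (np.inf if d0 > 1e6 else d0), float(np.exp(log_s02))


def _probit_from_t(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    """Numerically safe probit transform of t statistics to z scores."""
    t = np.asarray(t, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), t.shape)
    z = np.empty_like(t)
    with np.errstate(over="ignore"):
        logsf = sps.t.logsf(np.abs(t), df)
    z = -special.ndtri_exp(logsf)
    z = np.clip(z, 0.0, 38.0)
    return np.sign(t) * z


def lindsey_density(z: np.ndarray, n_bins: int = 120, knot_spacing: float = 1.2):
    """Marginal density estimate of z by Lindsey's method (Poisson GLM on
    histogram counts over a B-spline basis).  Returns a callable log-density.

    Interior knots are evenly spaced (about ``knot_spacing`` z-units apart)
    so the fit can follow a deep valley between the null bulk and a
    well-separated alternative cluster instead of bridging it.
    """
    lo, hi = z.min() - 1.0, z.max() + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    counts, _ = np.histogram(z, bins=edges)
    width = edges[1] - edges[0]

    n_inner = max(5, int(np.ceil((hi - lo) / knot_spacing)))
    inner = np.linspace(lo, hi, n_inner + 2)[1:-1]
    knots = np.concatenate([[lo] * 4, inner, [hi] * 4])
    degree = 3

    def basis(x):
        return BSpline.design_matrix(np.clip(x, lo, hi), knots, degree).toarray()

    X = basis(mids)
    beta = _poisson_irls(X, counts.astype(float))
    ok = beta is not None
    if ok:
        # sanity: the fit must track the histogram where there is mass
        eta = X @ beta
        heavy = counts >= 5
        if heavy.any() and np.max(np.abs(eta[heavy] - np.log(counts[heavy]))) > 2.0:
            ok = False
    if ok:
        def log_density(x):
            return basis(np.atleast_1d(x)) @ beta - np.log(len(z) * width)

        return log_density

    kde = sps.gaussian_kde(z, bw_method=0.2)

    def log_density(x):
        return np.log(np.maximum(kde(np.atleast_1d(x)), 1e-300))

    return log_density


def _poisson_irls(X: np.ndarray, y: np.ndarray, ridge: float = 1e-4,
                  max_iter: int = 200) -> np.ndarray | None:
    """Ridge-stabilized Poisson IRLS (log link).

    The tiny L2 penalty keeps coefficients of basis columns supported only
    by empty histogram bins finite (their unpenalized MLE is -infinity,
    which makes off-the-shelf IRLS diverge silently).
    """
    p = X.shape[1]
    beta = np.linalg.lstsq(X.T @ X + ridge * np.eye(p), X.T @ np.log(y + 0.5),
                           rcond=None)[0]
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu
        zwork = eta + (y - mu) / np.maximum(mu, 1e-10)
        A = X.T @ (W[:, None] * X) + ridge * np.eye(p)
        try:
            beta_new = np.linalg.solve(A, X.T @ (W * zwork))
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(beta_new)):
            return None
        if np.max(np.abs(beta_new - beta)) < 1e-8:
            beta = beta_new
            break
        beta = beta_new
    return beta


def local_fdr_from_z(z: np.ndarray, n_bins: int = 120, empirical_null: bool = True) -> np.ndarray:
    """Two-groups local fdr.

    The null is N(mu0, sd0^2) estimated by central matching (a quadratic
    fit to the log marginal density around its central mode, the locfdr
    convention) — moderated statistics on correlated paired designs are
    often mildly over- or under-dispersed relative to the theoretical
    N(0,1), which a theoretical null turns into badly miscalibrated fdrs.
    ``empirical_null=False`` forces the theoretical N(0,1) null.
    """
    z = np.asarray(z, dtype=float)
    log_f = lindsey_density(z, n_bins=n_bins)
    mu0, sd0 = 0.0, 1.0
    if empirical_null and len(z) >= 200:
        center = float(np.median(z))
        grid = np.linspace(center - 1.8, center + 1.8, 41)
        y = log_f(grid)
        X = np.column_stack([np.ones_like(grid), grid, grid ** 2])
        a, b, c = np.linalg.lstsq(X, y, rcond=None)[0]
        if c < -1e-6:
            sd0 = float(np.clip(np.sqrt(-1.0 / (2.0 * c)), 0.7, 1.6))
            mu0 = float(np.clip(-b / (2.0 * c), center - 1.0, center + 1.0))
    log_f0 = sps.norm.logpdf(z, loc=mu0, scale=sd0)
    # pi0 by matching the null and marginal densities at the null center
    pi0 = float(np.exp(np.clip(
        log_f(mu0)[0] - sps.norm.logpdf(mu0, loc=mu0, scale=sd0), None, 0.0)))
    lfdr = np.exp(np.log(max(pi0, 1e-12)) + log_f0 - log_f(z))
    return np.clip(lfdr, 0.0, 1.0)


def bayes_fdr(lfdr: np.ndarray) -> np.ndarray:
    """Running mean of sorted local fdrs: BFDR for the rejection set that
    includes each feature and everything more significant."""
    lfdr = np.asarray(lfdr, dtype=float)
    order = np.argsort(lfdr, kind="mergesort")
    cum = np.cumsum(lfdr[order]) / np.arange(1, len(lfdr) + 1)
    out = np.empty_like(cum)
    out[order] = cum
    return out


@dataclass
class ContrastResult:
    table: pd.DataFrame  # effect, se, df, t_mod, lfdr, bayes_fdr
    d0: float = np.inf
    s02: float = 0.0
    moderated: bool = True

    def significant(self, q: float) -> pd.Index:
        return self.table.index[self.table["bayes_fdr"] <= q]


def moderate_and_fdr(contrast_df: pd.DataFrame) -> ContrastResult:
    """Empirical-Bayes moderation + two-groups local fdr + Bayesian FDR.

    Expects columns ``effect``, ``se``, ``df`` (as from paired_contrast).
    """
    eff = contrast_df["effect"].to_numpy(dtype=float)
    se = contrast_df["se"].to_numpy(dtype=float)
    df = contrast_df["df"].to_numpy(dtype=float)
    if len(eff) < 50:
        warnings.warn("fewer than 50 miRs; hyperparameter estimates may be unstable")
    s2 = se ** 2
    moderated = True
    if np.allclose(s2, s2[0] if len(s2) else 0.0):
        warnings.warn("degenerate variances; falling back to unmoderated statistics")
        moderated = False
        d0, s02 = 0.0, 0.0
        s2_post = s2.copy()
        df_post = df
    else:
        d0, s02 = fit_scaled_invchisq(s2, df)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s02)
            df_post = np.full_like(df, 1e6)
        else:
            s2_post = (df * s2 + d0 * s02) / (df + d0)
            df_post = df + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(s2_post > 0, eff / np.sqrt(np.where(s2_post > 0, s2_post, 1.0)), 0.0)
        t = np.where((s2_post == 0) & (eff != 0), np.sign(eff) * 38.0, t)
    z = _probit_from_t(t, np.minimum(df_post, 1e6))
    lfdr = local_fdr_from_z(z)
    table = contrast_df.copy()
    table["t_mod"] = t
    table["z"] = z
    table["lfdr"] = lfdr
    table["bayes_fdr"] = bayes_fdr(lfdr)
    return ContrastResult(table=table, d0=d0, s02=s02, moderated=moderated)


def group_summaries(
    normalized: pd.DataFrame, design: SampleDesign
) -> dict[str, pd.DataFrame]:
    """Geometric mean and percent-expressed per tissue class per miR."""
    out = {}
    df = design.to_frame()
    for cls in ("pCRC", "M", "PN", "MN"):
        ids = [s for s in df.index[df["tissue_class"] == cls] if s in normalized.columns]
        if not ids:
            continue
        sub = normalized[ids].to_numpy(dtype=float)
        gm = np.expm1(np.mean(np.log1p(sub), axis=1))
        pct = 100.0 * np.mean(sub >= 1, axis=1)
        out[cls] = pd.DataFrame({"geometric_mean": gm, "pct_expressed": pct},
                                index=normalized.index)
    return out


# ------------------------------------------------------------------ tissue specificity

@dataclass
class TissueTestResult:
    table: pd.DataFrame  # T, p_perm, z, lfdr, bayes_fdr
    n_perm: int = 0
    testable: bool = True


def tissue_specific_test(
    delta_tumor: pd.DataFrame,
    delta_normal: pd.DataFrame,
    n_perm: int = 1999,
    seed: int = 0,
) -> TissueTestResult:
    """One-sided test of T = |effect M-pCRC| - |effect MN-PN| > 0.

    ``delta_tumor`` and ``delta_normal`` are miR x pair matrices of
    natural-log per-pair differences.  Pair labels are permuted between the
    two collections (the same permutation across miRs, preserving the
    pair-level exchangeability of the null).  Empirical one-sided p-values
    are reported; for the local-fdr input the observed T is studentized
    against the moments of its own permutation null, which extends
    resolution beyond 1/(n_perm+1) in the far tail.
    """
    if delta_normal.shape[1] == 0:
        table = pd.DataFrame(
            {"T": np.nan, "p_perm": np.nan, "z": np.nan, "lfdr": np.nan, "bayes_fdr": np.nan},
            index=delta_tumor.index,
        )
        return TissueTestResult(table=table, n_perm=0, testable=False)
    common = delta_tumor.index.intersection(delta_normal.index)
    A = delta_tumor.loc[common].to_numpy(dtype=float)
    B = delta_normal.loc[common].to_numpy(dtype=float)
    n1, n2 = A.shape[1], B.shape[1]
    pooled = np.hstack([A, B])
    T_obs = np.abs(A.mean(axis=1)) - np.abs(B.mean(axis=1))

    rng = np.random.default_rng(seed)
    n_tot = n1 + n2
    sel = np.zeros((n_tot, n_perm))
    for k in range(n_perm):
        idx = rng.permutation(n_tot)[:n1]
        sel[idx, k] = 1.0
    sum1 = pooled @ sel                       # miR x perm sums of group-1 deltas
    tot = pooled.sum(axis=1, keepdims=True)
    m1 = sum1 / n1
    m2 = (tot - sum1) / n2
    T_perm = np.abs(m1) - np.abs(m2)

    exceed = (T_perm >= T_obs[:, None]).sum(axis=1)
    p_emp = (1.0 + exceed) / (n_perm + 1.0)
    mu = T_perm.mean(axis=1)
    sd = T_perm.std(axis=1, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    z = (T_obs - mu) / sd
    lfdr = local_fdr_from_z(z)
    table = pd.DataFrame(
        {"T": T_obs, "p_perm": p_emp, "z": z, "lfdr": lfdr, "bayes_fdr": bayes_fdr(lfdr)},
        index=common,
    )
    return TissueTestResult(table=table, n_perm=n_perm, testable=True)


# ------------------------------------------------------------------ selection

@dataclass
class SelectionResult:
    metastasis_specific: list[str] = field(default_factory=list)
    tissue_specific_excluded: list[str] = field(default_factory=list)
    stage1: list[str] = field(default_factory=list)
    tumor_specific_up: list[str] = field(default_factory=list)
    tumor_specific_down: list[str] = field(default_factory=list)
    high_expression_shortlist: list[str] = field(default_factory=list)


def select_metastasis_specific(
    result_m_pcrc: ContrastResult,
    tissue_test: TissueTestResult,
    q: float = 0.10,
    q_tissue: float = 0.05,
) -> SelectionResult:
    """Stage 1: BFDR <= q in the M-pCRC contrast; stage 2: keep only miRs
    whose |M-pCRC| is significantly larger than |MN-PN|."""
    stage1 = list(result_m_pcrc.significant(q))
    if not tissue_test.testable:
        return SelectionResult(metastasis_specific=[], tissue_specific_excluded=stage1,
                               stage1=stage1)
    sig_tissue = set(tissue_test.table.index[tissue_test.table["bayes_fdr"] <= q_tissue])
    final = [m for m in stage1 if m in sig_tissue]
    excluded = [m for m in stage1 if m not in sig_tissue]
    return SelectionResult(
        metastasis_specific=final, tissue_specific_excluded=excluded, stage1=stage1
    )


def select_tumor_specific(
    result_m_mn: ContrastResult,
    result_pcrc_pn: ContrastResult,
    overall_geometric_mean: pd.Series,
    q: float = 0.05,
    expr_cut: float = 1000.0,
) -> SelectionResult:
    """Concordant tumor-vs-normal selection (both contrasts tumor-minus-
    normal on the natural-log scale): BFDR <= q in both and same sign."""
    a, b = result_m_mn.table, result_pcrc_pn.table
    common = a.index.intersection(b.index)
    sig = (
        (a.loc[common, "bayes_fdr"] <= q)
        & (b.loc[common, "bayes_fdr"] <= q)
        & (np.sign(a.loc[common, "effect"]) == np.sign(b.loc[common, "effect"]))
        & (a.loc[common, "effect"] != 0)
    )
    hits = common[sig]
    up = [m for m in hits if a.loc[m, "effect"] > 0]
    down = [m for m in hits if a.loc[m, "effect"] < 0]
    shortlist = [m for m in up if overall_geometric_mean.get(m, 0.0) > expr_cut]
    return SelectionResult(
        tumor_specific_up=up, tumor_specific_down=down, high_expression_shortlist=shortlist
    )
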