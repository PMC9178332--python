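"""Negative-binomial differential expression and transcriptome-level QC.

A self-contained two-group NB Wald test in the DESeq2 mould: median-of-ratios
size factors, method-of-moments per-gene dispersions shrunk toward a fitted
phi(mu) = a0 + a1/mu trend, a log-link NB fit per group (Newton iterations,
vectorized over genes) and a Wald statistic on the log fold change with the
asymptotic normal reference.  Calls are trichotomous: +1/-1 when
|log2FC| > 1.5 and BH-adjusted p < 0.05, else 0.

Also here: PCA of scaled expression, hierarchical-clustering outlier flagging
(average linkage, Euclidean) and the relative distance plasticity index
(RDPI), the mean per-gene relative distance between all control/treatment
replicate pairs, used as a transcriptome inducibility measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .io_core import logger

LFC_THRESHOLD = 1.5
ALPHA = 0.05
MIN_MEAN_COUNT = 10.0
DISPERSION_FLOOR = 1e-8


@dataclass
class ContrastResult:
    """Per-gene DE statistics for one (reference, test) treatment pair.

    ``table`` columns: base_mean, log2fc, p, padj, call, converged.
    Genes failing the mean-count filter are absent.
    """

    reference: str
    test: str
    table: pd.DataFrame

    @property
    def calls(self) -> pd.Series:
        return self.table["call"]


@dataclass
class RdpiResult:
    treatment: str
    control: str
    pair_values: pd.Series  # index: (control sample, treatment sample)


# ---------------------------------------------------------------------------
# filters and size factors


def filter_min_count(counts: pd.DataFrame, min_mean: float = MIN_MEAN_COUNT) -> pd.DataFrame:
    """Keep genes whose mean count across the given samples is >= min_mean."""
    if min_mean < 0:
        raise ValueError("min_mean must be >= 0")
    return counts.loc[counts.mean(axis=1) >= min_mean]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors.

    Uses genes with all-positive counts for the geometric-mean reference;
    falls back to library-size ratios if none exist.
    """
    values = counts.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if positive.sum() == 0:
        logger.warning("no all-positive genes; size factors from library totals")
        totals = values.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(totals)))
    else:
        logref = np.log(values[positive]).mean(axis=1)
        ratios = np.log(values[positive]) - logref[:, None]
        sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# dispersion estimation


def estimate_dispersions(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    sf: pd.Series | None = None,
    shrink_weight: float = 0.5,
) -> pd.Series:
    """Per-gene NB dispersion by method of moments with trend shrinkage.

    Raw estimate from within-group residuals on size-factor-normalized counts:
    phi_hat = max(0, (s^2 - xbar) / xbar^2), pooled across groups.  A trend
    phi(mu) = a0 + a1/mu is least-squares fitted to the positive raw estimates
    and each gene is shrunk toward it: phi = (1-w) * phi_hat + w * trend.
    """
    groups = samples.groupby("treatment")["sample_id"].apply(list)
    for t, ids in groups.items():
        if len(ids) < 2:
            raise ValueError(f"treatment {t!r} has fewer than 2 replicates")
    if sf is None:
        sf = size_factors(counts)
    norm = counts.to_numpy(dtype=float) / sf.loc[counts.columns].to_numpy()[None, :]

    G = counts.shape[0]
    ss = np.zeros(G)  # pooled within-group sum of squares
    dof = 0
    mean_acc = np.zeros(G)
    n_total = 0
    for ids in groups:
        cols = [counts.columns.get_loc(s) for s in ids]
        sub = norm[:, cols]
        m = sub.mean(axis=1)
        ss += ((sub - m[:, None]) ** 2).sum(axis=1)
        dof += len(cols) - 1
        mean_acc += m * len(cols)
        n_total += len(cols)
    s2 = ss / dof
    xbar = mean_acc / n_total
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(xbar > 0, np.maximum(0.0, (s2 - xbar) / xbar**2), 0.0)

    # least-squares fit of phi = a0 + a1/mu over genes with positive estimates
    mask = (raw > 0) & (xbar > 0)
    if mask.sum() >= 10:
        X = np.column_stack([np.ones(mask.sum()), 1.0 / xbar[mask]])
        coef, *_ = np.linalg.lstsq(X, raw[mask], rcond=None)
        a0, a1 = max(coef[0], DISPERSION_FLOOR), max(coef[1], 0.0)
    else:
        a0, a1 = 0.05, 5.0
        logger.warning("too few genes for a dispersion trend; using defaults")
    with np.errstate(divide="ignore"):
        trend = np.where(xbar > 0, a0 + a1 / xbar, a0)
    phi = (1 - shrink_weight) * raw + shrink_weight * trend
    phi = np.maximum(phi, DISPERSION_FLOOR)
    return pd.Series(phi, index=counts.index, name="dispersion")


# ---------------------------------------------------------------------------
# NB group fit and Wald test


def _fit_group_mean(y: np.ndarray, s: np.ndarray, phi: np.ndarray, n_iter: int = 50):
    """MLE of the per-gene group abundance q under NB(mu_i = s_i q, phi).

    Solves sum_i (y_i - s_i q) / (1 + phi s_i q) = 0 by Newton iterations on
    beta = log q, vectorized over genes.  Returns (q, fisher_info, converged);
    the Fisher information of beta is sum_i mu_i / (1 + phi mu_i).
    """
    G = y.shape[0]
    q = y.sum(axis=1) / s.sum()  # moment start (exact for phi -> 0)
    zero = q <= 0
    q = np.where(zero, 1e-8, q)
    beta = np.log(q)
    converged = np.zeros(G, dtype=bool)
    phi_col = phi[:, None]
    for _ in range(n_iter):
        mu = np.exp(beta)[:, None] * s[None, :]
        denom = 1.0 + phi_col * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)  # expected information in beta
        step = np.where(info > 0, score / np.maximum(info, 1e-12), 0.0)
        step = np.clip(step, -5, 5)
        beta = beta + np.where(converged, 0.0, step)
        newly = np.abs(step) < 1e-10
        converged |= newly
        if converged.all():
            break
    q = np.exp(beta)
    mu = q[:, None] * s[None, :]
    info = (mu / (1.0 + phi_col * mu)).sum(axis=1)
    # all-zero groups: q -> 0 boundary, treat as converged with tiny info
    converged |= zero & (y.sum(axis=1) == 0)
    return q, info, converged


def nb_wald_test(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    reference: str,
    test: str,
    min_mean: float = MIN_MEAN_COUNT,
    lfc_threshold: float = LFC_THRESHOLD,
    alpha: float = ALPHA,
    shrink_weight: float = 0.5,
) -> ContrastResult:
    """Two-group NB Wald differential-expression test.

    Genes are pre-filtered on mean count over the two groups' samples; size
    factors are computed on those samples (median of ratios); per-gene
    dispersions come from :func:`estimate_dispersions`.  log2fc is the
    difference of fitted log-abundances / ln 2; the two-sided p uses the
    normal reference; BH is applied over tested genes; calls follow the
    |log2FC| > ``lfc_threshold`` and padj < ``alpha`` rule.
    """
    for label in (reference, test):
        n = (samples["treatment"] == label).sum()
        if n < 2:
            raise ValueError(f"treatment {label!r} needs >= 2 replicates (has {n})")
    ref_ids = samples.loc[samples["treatment"] == reference, "sample_id"].tolist()
    test_ids = samples.loc[samples["treatment"] == test, "sample_id"].tolist()
    sub = counts[ref_ids + test_ids]
    sub = filter_min_count(sub, min_mean)
    if sub.empty:
        raise ValueError("no genes pass the mean-count filter")

    sf = size_factors(sub)
    pair_samples = samples[samples["treatment"].isin([reference, test])]
    phi = estimate_dispersions(sub, pair_samples, sf=sf, shrink_weight=shrink_weight)

    y = sub.to_numpy(dtype=float)
    s = sf.to_numpy()
    phi_arr = phi.to_numpy()
    n_ref = len(ref_ids)
    q_ref, info_ref, conv_ref = _fit_group_mean(y[:, :n_ref], s[:n_ref], phi_arr)
    q_test, info_test, conv_test = _fit_group_mean(y[:, n_ref:], s[n_ref:], phi_arr)
    converged = conv_ref & conv_test

    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = (np.log(q_test) - np.log(q_ref)) / np.log(2)
        se = np.sqrt(1.0 / np.maximum(info_ref, 1e-12) + 1.0 / np.maximum(info_test, 1e-12))
        z = (np.log(q_test) - np.log(q_ref)) / se
    from scipy.stats import norm as _norm

    p = 2.0 * _norm.sf(np.abs(z))
    bad = ~np.isfinite(p) | ~converged | ~np.isfinite(log2fc)
    p = np.where(bad, 1.0, p)
    log2fc = np.where(np.isfinite(log2fc), log2fc, 0.0)

    padj = benjamini_hochberg(p)
    call = np.zeros(len(p), dtype=int)
    call[(log2fc > lfc_threshold) & (padj < alpha)] = 1
    call[(log2fc < -lfc_threshold) & (padj < alpha)] = -1
    call[bad] = 0

    base_mean = (y / s[None, :]).mean(axis=1)
    table = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "p": p,
            "padj": padj,
            "call": call,
            "converged": converged,
        },
        index=sub.index,
    )
    return ContrastResult(reference=reference, test=test, table=table)


def benjamini_hochberg(p) -> np.ndarray:
    """Step-up BH adjustment; original order restored.

    padj_(i) = min_{j >= i} min(1, m p_(j) / j) over the sorted p-values.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# PCA, outliers, RDPI


def pca_projection(expr: pd.DataFrame):
    """PCA of samples on per-gene centered, unit-variance scaled expression.

    Constant genes are dropped before scaling.  Returns ``(scores, fractions)``
    where scores is a samples x components DataFrame (columns PC1, PC2, ...)
    and fractions the per-component explained-variance fractions (sum <= 1).
    """
    if expr.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-constant genes")
    X = (values[keep] - values[keep].mean(axis=1)[:, None]) / sd[keep][:, None]
    X = X.T  # samples x genes
    X = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    scores = U * S
    var = S**2 / max(X.shape[0] - 1, 1)
    fractions = var / (X.shape[1])  # total variance = n scaled genes
    k = min(X.shape) if min(X.shape) > 0 else 0
    cols = [f"PC{i+1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=expr.columns, columns=cols),
        pd.Series(fractions, index=cols, name="explained_variance_fraction"),
    )


def detect_outliers(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    c: float = 2.0,
):
    """Flag outlying replicates by average-linkage clustering distances.

    An average-linkage dendrogram (Euclidean distance over all genes) is
    computed for the record; the flagging rule is per treatment: a replicate
    is flagged when its mean Euclidean distance to the other same-treatment
    replicates exceeds ``c`` times the median of those means.  Treatments
    with < 3 replicates are skipped with a warning.  Returns
    ``(flagged_ids, linkage_matrix)``.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples overall")
    X = expr.to_numpy(dtype=float).T  # samples x genes
    Z = linkage(X, method="average", metric="euclidean")
    D = squareform(pdist(X))
    ids = list(expr.columns)
    pos = {s: i for i, s in enumerate(ids)}

    flagged: list[str] = []
    for t, sub in samples.groupby("treatment"):
        members = [s for s in sub["sample_id"] if s in pos]
        if len(members) < 3:
            logger.warning("treatment %r has < 3 replicates; outlier check skipped", t)
            continue
        idx = [pos[s] for s in members]
        dsub = D[np.ix_(idx, idx)]
        mean_d = (dsub.sum(axis=1)) / (len(idx) - 1)
        med = np.median(mean_d)
        if med == 0:
            continue  # identical replicates
        for s_id, md in zip(members, mean_d):
            if md > c * med:
                flagged.append(s_id)
    return flagged, Z


def rdpi(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    control: str,
    treatment: str,
) -> RdpiResult:
    """Relative distance plasticity index over all control/treatment pairs.

    For each (control replicate i, treatment replicate j):
    RDPI_ij = mean over genes g with x_gi + x_gj > 0 of
    |x_gj - x_gi| / (x_gj + x_gi).  Values lie in [0, 1].
    """
    ctrl_ids = samples.loc[samples["treatment"] == control, "sample_id"].tolist()
    trt_ids = samples.loc[samples["treatment"] == treatment, "sample_id"].tolist()
    if not ctrl_ids or not trt_ids:
        raise ValueError("both groups must be non-empty")
    if (expr[ctrl_ids + trt_ids].to_numpy() < 0).any():
        raise ValueError("expression values must be >= 0")
    values: dict[tuple[str, str], float] = {}
    for i in ctrl_ids:
        xi = expr[i].to_numpy(dtype=float)
        for j in trt_ids:
            xj = expr[j].to_numpy(dtype=float)
            tot = xi + xj
            mask = tot > 0
            if not mask.any():
                raise ValueError(f"no expressed genes for pair ({i}, {j})")
            values[(i, j)] = float(np.mean(np.abs(xj[mask] - xi[mask]) / tot[mask]))
    idx = pd.MultiIndex.from_tuples(values.keys(), names=["control_sample", "treatment_sample"])
    return RdpiResult(
        treatment=treatment,
        control=control,
        pair_values=pd.Series(list(values.values()), index=idx, name="rdpi"),
    )
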