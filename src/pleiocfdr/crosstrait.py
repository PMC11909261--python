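"""Cross-trait enrichment, genomic Spearman correlation, robust trend fits and
conditional Q-Q diagnostics for P-value-only GWAS pairs.

The central quantity is the cross-trait fold enrichment: the proportion of
variants associated with the target trait (P_target < alpha) among variants
associated with an auxiliary trait (P_aux < alpha), relative to that
proportion among all variants::

    fold = Prob(P_t < a | P_a < a) / Prob(P_t < a)

By Bayes' theorem this ratio is reciprocal between the two traits, a property
used here as a numerical self-check. Stratified enrichment applies the same
ratio within an annotation (TF binding sites, ATAC peaks), and interval-level
bootstrap gives its standard error.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._rng import substream
from .errors import (
    ConsistencyError,
    ConvergenceError,
    DegenerateDistributionError,
    InstabilityError,
    InsufficientDataError,
    UndefinedEnrichmentError,
)
from .io import AnnotationSet, normalize_chrom, trait_columns

logger = logging.getLogger(__name__)


def _pair_columns(joined: pd.DataFrame, target: str | None, aux: str | None) -> tuple[str, str]:
    cols = trait_columns(joined)
    t = target if target is not None else cols[0]
    a = aux if aux is not None else cols[1]
    if t not in joined.columns or a not in joined.columns:
        raise KeyError(f"trait columns {t!r}/{a!r} not in table (have {cols})")
    return t, a


@dataclass
class EnrichmentResult:
    """Fold enrichment with the counts that define it."""

    fold: float
    alpha_target: float
    alpha_other: float
    n_subset: int
    n_subset_hits: int
    n_all: int
    n_all_hits: int
    se: float | None = None
    stratum_name: str | None = None


def _fold_from_masks(
    hit_t: np.ndarray, hit_a: np.ndarray, alpha_t: float, alpha_a: float,
    stratum: str | None = None,
) -> EnrichmentResult:
    n_all = hit_t.size
    n_subset = int(hit_a.sum())
    n_all_hits = int(hit_t.sum())
    if n_subset == 0 or n_all_hits == 0 or n_all == 0:
        raise UndefinedEnrichmentError(
            f"enrichment undefined: n_subset={n_subset}, n_all_hits={n_all_hits}"
            + (f" (stratum {stratum!r})" if stratum else "")
        )
    n_subset_hits = int((hit_t & hit_a).sum())
    fold = (n_subset_hits / n_subset) / (n_all_hits / n_all)
    return EnrichmentResult(
        fold, alpha_t, alpha_a, n_subset, n_subset_hits, n_all, n_all_hits,
        stratum_name=stratum,
    )


def fold_enrichment(
    joined: pd.DataFrame,
    alpha: float = 0.05,
    target: str | None = None,
    aux: str | None = None,
) -> EnrichmentResult:
    """Genome-wide cross-trait fold enrichment at threshold ``alpha`` (both traits)."""
    t, a = _pair_columns(joined, target, aux)
    hit_t = joined[t].to_numpy() < alpha
    hit_a = joined[a].to_numpy() < alpha
    return _fold_from_masks(hit_t, hit_a, alpha, alpha)


def stratified_enrichment(
    joined: pd.DataFrame,
    annotation: AnnotationSet,
    alpha: float = 0.05,
    target: str | None = None,
    aux: str | None = None,
) -> EnrichmentResult:
    """Fold enrichment restricted to variants inside the annotation's intervals."""
    t, a = _pair_columns(joined, target, aux)
    member = annotation.contains(joined["chrom"], joined["pos"])
    if not member.any():
        raise UndefinedEnrichmentError(f"no variants in annotation {annotation.name!r}")
    sub = joined.loc[member]
    hit_t = sub[t].to_numpy() < alpha
    hit_a = sub[a].to_numpy() < alpha
    return _fold_from_masks(hit_t, hit_a, alpha, alpha, stratum=annotation.name)


def enrichment_reciprocity_check(
    joined: pd.DataFrame,
    alpha: float = 0.05,
    target: str | None = None,
    aux: str | None = None,
) -> tuple[float, float]:
    """Both directional folds; by Bayes' theorem they must agree to 1e-12."""
    t, a = _pair_columns(joined, target, aux)
    fold_xy = fold_enrichment(joined, alpha, target=t, aux=a).fold
    fold_yx = fold_enrichment(joined, alpha, target=a, aux=t).fold
    denom = max(abs(fold_xy), abs(fold_yx), 1.0)
    if abs(fold_xy - fold_yx) / denom > 1e-12:
        raise ConsistencyError(
            f"reciprocity violated: {fold_xy!r} vs {fold_yx!r}"
        )
    return fold_xy, fold_yx


# ---------------------------------------------------------------------------
# interval bootstrap


def _interval_members(
    joined: pd.DataFrame, annotation: AnnotationSet
) -> list[np.ndarray]:
    """Row indices of ``joined`` inside each (unmerged) interval."""
    chrom = normalize_chrom(joined["chrom"]).to_numpy()
    pos0 = joined["pos"].to_numpy(dtype=np.int64) - 1
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in np.unique(chrom):
        sel = np.flatnonzero(chrom == c)
        order = np.argsort(pos0[sel], kind="stable")
        by_chrom[c] = (pos0[sel][order], sel[order])
    members = []
    iv = annotation.intervals
    ivc = normalize_chrom(iv["chrom"]).to_numpy()
    for c, s, e in zip(ivc, iv["start"].to_numpy(), iv["end"].to_numpy()):
        if c not in by_chrom:
            members.append(np.empty(0, dtype=np.int64))
            continue
        posn, idx = by_chrom[c]
        lo = np.searchsorted(posn, s, side="left")
        hi = np.searchsorted(posn, e, side="left")
        members.append(idx[lo:hi])
    return members


def bootstrap_stratified_se(
    joined: pd.DataFrame,
    annotation: AnnotationSet,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
    target: str | None = None,
    aux: str | None = None,
) -> EnrichmentResult:
    """Stratified enrichment with an SE from resampling intervals with replacement.

    Replicates where the fold is undefined (empty conditioning subset) are
    dropped and counted; more than 50% undefined raises
    :class:`InstabilityError`.
    """
    if len(annotation) < 2:
        raise InsufficientDataError("bootstrap needs at least 2 intervals")
    t, a = _pair_columns(joined, target, aux)
    point = stratified_enrichment(joined, annotation, alpha, target=t, aux=a)
    hit_t = joined[t].to_numpy() < alpha
    hit_a = joined[a].to_numpy() < alpha
    members = _interval_members(joined, annotation)
    rng = substream(seed, "bootstrap")
    n_iv = len(members)
    folds = []
    n_undefined = 0
    n = len(joined)
    for _ in range(n_boot):
        draw = rng.integers(0, n_iv, size=n_iv)
        member = np.zeros(n, dtype=bool)
        for j in draw:
            member[members[j]] = True
        ht, ha = hit_t[member], hit_a[member]
        n_subset = int(ha.sum())
        n_all_hits = int(ht.sum())
        if n_subset == 0 or n_all_hits == 0 or member.sum() == 0:
            n_undefined += 1
            continue
        folds.append((int((ht & ha).sum()) / n_subset) / (n_all_hits / member.sum()))
    if n_undefined > n_boot / 2:
        raise InstabilityError(
            f"{n_undefined}/{n_boot} bootstrap replicates had undefined enrichment"
        )
    if len(folds) <= 1:
        warnings.warn("bootstrap SE over <= 1 replicate is 0 by definition")
        point.se = 0.0
    else:
        point.se = float(np.std(folds, ddof=1))
    if n_undefined:
        logger.info("bootstrap: %d/%d undefined replicates dropped", n_undefined, n_boot)
    return point


# ---------------------------------------------------------------------------
# genomic Spearman correlation over LD blocks


def block_means(
    joined: pd.DataFrame,
    blocks: AnnotationSet,
    exclusions: AnnotationSet | None = None,
    target: str | None = None,
    aux: str | None = None,
) -> pd.DataFrame:
    """Per-block mean of -log10 P for each trait, blocks with no variants dropped."""
    t, a = _pair_columns(joined, target, aux)
    df = joined
    if exclusions is not None and len(exclusions):
        inside = exclusions.contains(df["chrom"], df["pos"])
        df = df.loc[~inside]
    members = _interval_members(df.reset_index(drop=True), blocks)
    rows = []
    lt = -np.log10(df[t].to_numpy())
    la = -np.log10(df[a].to_numpy())
    for i, idx in enumerate(members):
        if len(idx):
            rows.append((i, float(lt[idx].mean()), float(la[idx].mean())))
    return pd.DataFrame(rows, columns=["block", "mean_target", "mean_aux"])


def genomic_spearman(
    joined: pd.DataFrame,
    blocks: AnnotationSet,
    exclusions: AnnotationSet | None = None,
    target: str | None = None,
    aux: str | None = None,
    literal_formula: bool = False,
) -> float:
    """Rank correlation of LD-block-averaged -log10 P between two traits.

    This is the genomic correlation usable when signed effects are not
    available. ``literal_formula=True`` evaluates 1 - 6*sum(d_i)/(n(n^2-1))
    with unsquared rank differences; with average ranks the rank differences
    sum to zero, so that variant degenerates to 1 — it is retained only to
    document the difference from standard Spearman (which squares d_i).
    """
    bm = block_means(joined, blocks, exclusions, target, aux)
    n = len(bm)
    if n < 3:
        raise InsufficientDataError(f"genomic_spearman needs >= 3 usable blocks, got {n}")
    if literal_formula:
        rx = stats.rankdata(bm["mean_target"])
        ry = stats.rankdata(bm["mean_aux"])
        d = rx - ry
        return float(1.0 - 6.0 * d.sum() / (n * (n * n - 1.0)))
    rho, _ = stats.spearmanr(bm["mean_target"], bm["mean_aux"])
    return float(rho)


# ---------------------------------------------------------------------------
# robust trend fit (enrichment vs genomic correlation)


@dataclass
class TrendFit:
    """Robust linear trend with a 95% confidence band."""

    slope: float
    intercept: float
    slope_se: float
    slope_ci: tuple[float, float]
    p_value: float
    cov: np.ndarray  # 2x2 covariance of (intercept, slope)

    def band(self, x: Sequence[float]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Fitted line with pointwise 95% CI at ``x``."""
        x = np.asarray(x, dtype=float)
        yhat = self.intercept + self.slope * x
        X = np.column_stack([np.ones_like(x), x])
        var = np.einsum("ij,jk,ik->i", X, self.cov, X)
        half = stats.norm.ppf(0.975) * np.sqrt(var)
        return yhat, yhat - half, yhat + half


def irls_trend(
    x: Sequence[float],
    y: Sequence[float],
    tol: float = 1e-8,
    maxiter: int = 100,
) -> TrendFit:
    """Iteratively reweighted least squares with Tukey bisquare weights (c=4.685).

    Used for the trend of cross-trait enrichment against genomic correlation;
    the bisquare loss discounts gross outliers while retaining ~95% Gaussian
    efficiency.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise InsufficientDataError(f"irls_trend needs >= 4 points, got {len(x)}")
    X = sm.add_constant(x)
    model = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685))
    res = model.fit(maxiter=maxiter, tol=tol, conv="coefs")
    hist = res.fit_history.get("params", [])
    if len(hist) >= 2:
        delta = float(
            np.max(np.abs(np.asarray(hist[-1], float) - np.asarray(hist[-2], float)))
        )
        if len(hist) >= maxiter and delta > tol:
            raise ConvergenceError(
                f"IRLS did not converge in {maxiter} iterations (last delta {delta:.3g})"
            )
    intercept, slope = res.params
    cov = np.asarray(res.cov_params())
    slope_se = float(np.sqrt(cov[1, 1]))
    zq = stats.norm.ppf(0.975)
    pval = float(2.0 * stats.norm.sf(abs(slope) / slope_se)) if slope_se > 0 else 0.0
    return TrendFit(
        slope=float(slope),
        intercept=float(intercept),
        slope_se=slope_se,
        slope_ci=(float(slope - zq * slope_se), float(slope + zq * slope_se)),
        p_value=pval,
        cov=cov,
    )


# ---------------------------------------------------------------------------
# outlier test for one annotation against a background of annotations


def tf_outlier_test(fold_target: float, folds_background: Sequence[float]) -> float:
    """One-tailed upper-tail P for one annotation's fold against a background.

    The target fold is standardized against the background sample mean and SD
    and referred to a Student t with n-1 degrees of freedom; small P means the
    annotation's enrichment is an outlier above the background of comparable
    annotations (e.g. one TF's binding sites versus all other TFs').
    """
    bg = np.asarray(folds_background, dtype=float)
    if len(bg) < 10:
        raise InsufficientDataError(f"need >= 10 background folds, got {len(bg)}")
    sd = float(np.std(bg, ddof=1))
    if sd == 0:
        raise DegenerateDistributionError("background folds have zero spread")
    z = (float(fold_target) - float(np.mean(bg))) / sd
    return float(stats.t.sf(z, df=len(bg) - 1))


# ---------------------------------------------------------------------------
# conditional Q-Q curves


@dataclass
class QQCurve:
    """Observed vs expected -log10 P within one auxiliary-P stratum."""

    stratum_threshold: float
    expected_quantiles: np.ndarray
    observed_quantiles: np.ndarray
    n: int


def conditional_qq(
    joined: pd.DataFrame,
    strata_thresholds: Sequence[float] = (1.0, 0.1, 0.01, 0.001),
    max_points: int = 1000,
    target: str | None = None,
    aux: str | None = None,
) -> list[QQCurve]:
    """Q-Q curves of target P values within nested auxiliary-P strata.

    A leftward/upward shift of stricter strata relative to the unconditional
    curve is the visual signature of cross-trait enrichment. Expected
    quantiles are -log10 of uniform order statistics i/(n+1); curves are
    thinned to ``max_points`` by quantile subsampling. Empty strata are
    skipped with a warning.
    """
    t, a = _pair_columns(joined, target, aux)
    p_t = joined[t].to_numpy()
    p_a = joined[a].to_numpy()
    curves = []
    for q in strata_thresholds:
        sel = p_a <= q
        n = int(sel.sum())
        if n == 0:
            warnings.warn(f"conditional_qq: stratum P_aux <= {q} is empty; skipped")
            continue
        obs = np.sort(-np.log10(p_t[sel]))
        exp = -np.log10(np.arange(n, 0, -1) / (n + 1.0))
        if n > max_points:
            idx = np.unique(np.round(np.linspace(0, n - 1, max_points)).astype(int))
            obs, exp = obs[idx], exp[idx]
        curves.append(QQCurve(float(q), exp, obs, n))
    return curves


def qq_table(curves: Sequence[QQCurve]) -> pd.DataFrame:
    """Long-format table of Q-Q curves for serialization/plotting."""
    frames = [
        pd.DataFrame(
            {
                "stratum_threshold": c.stratum_threshold,
                "expected": c.expected_quantiles,
                "observed": c.observed_quantiles,
            }
        )
        for c in curves
    ]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["stratum_threshold", "expected", "observed"]
    )
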