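"""Ploidy-aware population summaries: allele frequencies, F_ST, PCA, clines.

Genotype calls are transformed into within-individual allele frequencies
(copy number / ploidy) so diploids and tetraploids enter the same analyses;
only biallelic loci can be represented this way. F_ST defaults to a
Nei-style ratio-of-averages 1 - mean(H_S)/mean(H_T'), with the small-
sample-of-populations correction H_T' = H_S + s/(s-1) (H_T - H_S) (Nei &
Chesser), which makes the estimator consistent for the Balding-Nichols
divergence parameter; a frequency-based Weir-Cockerham variant is
selectable. The latitudinal cline in admixture is fit as a linear mixed
model on arcsine-square-root-transformed Q values with a population random
intercept (REML).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .types import GenotypeMatrix

__all__ = [
    "FreqMatrix",
    "AdmixtureRecord",
    "ClineFit",
    "freq_matrix",
    "impute_missing",
    "fst",
    "fst_outliers",
    "pca_scores",
    "cline_fit",
]


@dataclass
class FreqMatrix:
    """Samples x loci within-individual frequencies of the counted allele.

    Non-missing entries are exact multiples of 1/ploidy for the row's
    sample; missing entries are NaN.
    """

    frame: pd.DataFrame  # samples x loci, NaN = missing
    counted_allele: pd.Series  # locus -> allele whose frequency is stored
    ploidy: pd.Series  # sample -> ploidy
    n_excluded_loci: int = 0

    @property
    def is_complete(self) -> bool:
        return not self.frame.isna().any().any()


def freq_matrix(matrix: GenotypeMatrix, biallelic_only: bool = True) -> FreqMatrix:
    """Within-individual allele frequencies, normalized for ploidy.

    For each retained locus the counted allele is the lexicographically
    second of its observed alleles (the alternate at a ref/alt SNV); a
    tetraploid A:3,T:1 call yields 0.25, a diploid A:1,T:1 yields 0.5.
    Multi-allelic loci are excluded (and counted) when ``biallelic_only``.
    """
    keep = []
    counted: Dict[str, str] = {}
    n_excluded = 0
    for l in matrix.loci:
        alleles = matrix.alleles_at(l)
        if len(alleles) < 2:
            n_excluded += 1
            continue
        if biallelic_only and len(alleles) != 2:
            n_excluded += 1
            continue
        keep.append(l)
        counted[l] = alleles[1]
    data = np.full((len(matrix.samples), len(keep)), np.nan)
    for i, s in enumerate(matrix.samples):
        k = matrix.ploidy[s]
        for j, l in enumerate(keep):
            call = matrix.get_call(s, l)
            if call is not None:
                data[i, j] = call.get(counted[l], 0) / k
    frame = pd.DataFrame(data, index=list(matrix.samples), columns=keep)
    return FreqMatrix(
        frame=frame,
        counted_allele=pd.Series(counted, dtype=object),
        ploidy=pd.Series({s: matrix.ploidy[s] for s in matrix.samples}),
        n_excluded_loci=n_excluded,
    )


def impute_missing(
    freqs: FreqMatrix,
    method: str = "mean",
    rank: int = 2,
    tol: float = 1e-6,
    max_iter: int = 100,
    seed: Optional[int] = None,
) -> FreqMatrix:
    """Replace missing frequencies so downstream PCA can run.

    ``mean`` fills each missing entry with its locus mean. ``iterative-
    lowrank`` starts from the mean fill and alternates a rank-``rank``
    SVD reconstruction with re-imputation of the missing cells until the
    largest change is below ``tol`` or ``max_iter`` iterations (an EM-PCA
    scheme in the spirit of missMDA). ``seed`` is accepted for interface
    stability; the algorithm is deterministic.
    """
    X = freqs.frame.to_numpy(dtype=float, copy=True)
    if X.size == 0:
        return FreqMatrix(freqs.frame.copy(), freqs.counted_allele, freqs.ploidy,
                          freqs.n_excluded_loci)
    nan_mask = np.isnan(X)
    all_missing_loci = freqs.frame.columns[nan_mask.all(axis=0)].tolist()
    all_missing_samples = freqs.frame.index[nan_mask.all(axis=1)].tolist()
    if all_missing_loci or all_missing_samples:
        raise ValueError(
            f"cannot impute: all-missing loci {all_missing_loci}, "
            f"all-missing samples {all_missing_samples}"
        )
    col_means = np.nanmean(X, axis=0)
    X[nan_mask] = np.take(col_means, np.where(nan_mask)[1])
    if method == "mean":
        pass
    elif method == "iterative-lowrank":
        r = min(rank, min(X.shape) - 1) if min(X.shape) > 1 else 0
        for _ in range(max_iter):
            mu = X.mean(axis=0)
            Xc = X - mu
            U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
            S_r = np.zeros_like(S)
            S_r[:r] = S[:r]
            recon = (U * S_r) @ Vt + mu
            delta = np.max(np.abs(recon[nan_mask] - X[nan_mask])) if nan_mask.any() else 0.0
            X[nan_mask] = recon[nan_mask]
            if delta < tol:
                break
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    frame = pd.DataFrame(X, index=freqs.frame.index, columns=freqs.frame.columns)
    return FreqMatrix(frame, freqs.counted_allele, freqs.ploidy, freqs.n_excluded_loci)


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------


def _group_arrays(
    freqs: FreqMatrix, groups: Mapping[str, object]
) -> Tuple[list, np.ndarray, np.ndarray]:
    """Per-group non-missing counts and mean frequencies, per locus."""
    frame = freqs.frame
    labels = sorted({groups[s] for s in frame.index}, key=str)
    counts = []
    means = []
    for g in labels:
        sub = frame.loc[[s for s in frame.index if groups[s] == g]]
        if sub.empty or sub.notna().sum().sum() == 0:
            raise ValueError(f"group {g!r} has no non-missing data")
        counts.append(sub.notna().sum(axis=0).to_numpy(dtype=float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means.append(np.nanmean(sub.to_numpy(dtype=float), axis=0))
    return labels, np.stack(counts), np.stack(means)


def _nei_components(n_g: np.ndarray, p_g: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-locus (H_S, H_T') with the s/(s-1) among-group correction."""
    have = (n_g > 0) & np.isfinite(p_g)
    s = have.sum(axis=0).astype(float)
    n = np.where(have, n_g, 0.0)
    p = np.where(have, p_g, 0.0)
    n_tot = n.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = (n * p).sum(axis=0) / n_tot
        hs = (n * 2.0 * p * (1.0 - p)).sum(axis=0) / n_tot
        ht = 2.0 * pbar * (1.0 - pbar)
        ht_corr = hs + np.where(s > 1, s / (s - 1.0), np.nan) * (ht - hs)
    valid = s > 1
    return np.where(valid, hs, np.nan), np.where(valid, ht_corr, np.nan)


def _wc_theta(n_g: np.ndarray, p_g: np.ndarray, ploidy_weight: np.ndarray) -> float:
    """Frequency-based Weir-Cockerham theta (no within-individual term)."""
    n_chrom = n_g * ploidy_weight[:, None] if ploidy_weight is not None else n_g
    have = (n_chrom > 0) & np.isfinite(p_g)
    r = have.sum(axis=0).astype(float)
    n = np.where(have, n_chrom, 0.0)
    p = np.where(have, p_g, 0.0)
    ok = r > 1
    n, p, r = n[:, ok], p[:, ok], r[ok]
    nbar = n.sum(axis=0) / r
    n2 = (n**2).sum(axis=0)
    nc = (r * nbar - n2 / (r * nbar)) / (r - 1.0)
    pbar = (n * p).sum(axis=0) / (r * nbar)
    s2 = (n * (p - pbar[None, :]) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
    pq = pbar * (1.0 - pbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (s2 - (pq - s2 * (r - 1.0) / r) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pq - s2 * (r - 1.0) / r)
    good = np.isfinite(a) & np.isfinite(b)
    denom = (a[good] + b[good]).sum()
    return float(a[good].sum() / denom) if denom != 0 else float("nan")


def fst(
    freqs: FreqMatrix,
    groups: Union[Mapping[str, object], pd.Series],
    mode: str = "global",
    estimator: str = "nei",
    clip: bool = False,
) -> Union[float, pd.Series, pd.DataFrame]:
    """F_ST from within-individual allele frequencies.

    ``mode='global'`` returns the multi-group estimate over all loci
    (ratio of per-locus averages); ``'per_locus'`` the per-locus values;
    ``'pairwise'`` a symmetric group x group table of global estimates.
    Small negative estimates are possible; ``clip`` truncates to [0, 1].
    """
    if isinstance(groups, pd.Series):
        groups = groups.to_dict()
    labels, n_g, p_g = _group_arrays(freqs, groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")

    def _global(idx: Sequence[int]) -> float:
        if estimator == "nei":
            hs, ht = _nei_components(n_g[idx], p_g[idx])
            ok = np.isfinite(ht) & (ht > 0)
            if not ok.any():
                return float("nan")
            val = 1.0 - hs[ok].mean() / ht[ok].mean()
        elif estimator == "weir-cockerham":
            pw = np.array(
                [
                    np.mean([freqs.ploidy[s] for s in freqs.frame.index
                             if groups[s] == labels[i]])
                    for i in idx
                ]
            )
            val = _wc_theta(n_g[idx], p_g[idx], pw)
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
        return float(np.clip(val, 0.0, 1.0)) if clip else float(val)

    all_idx = list(range(len(labels)))
    if mode == "global":
        return _global(all_idx)
    if mode == "per_locus":
        if estimator != "nei":
            raise ValueError("per-locus mode is defined for the nei estimator")
        hs, ht = _nei_components(n_g, p_g)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = 1.0 - hs / ht
        vals = np.where(np.isfinite(ht) & (ht > 0), vals, np.nan)
        if clip:
            vals = np.clip(vals, 0.0, 1.0)
        return pd.Series(vals, index=freqs.frame.columns, name="fst")
    if mode == "pairwise":
        out = pd.DataFrame(np.nan, index=labels, columns=labels)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                v = _global([i, j])
                out.iloc[i, j] = out.iloc[j, i] = v
            out.iloc[i, i] = 0.0
        return out
    raise ValueError(f"unknown mode {mode!r}")


def fst_outliers(per_locus: pd.Series, quantile: float = 0.99) -> pd.Index:
    """Loci whose per-locus F_ST exceeds the given quantile of the distribution."""
    threshold = per_locus.quantile(quantile)
    return per_locus.index[per_locus > threshold]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def pca_scores(
    freqs: FreqMatrix, n_components: int = 2
) -> Tuple[pd.DataFrame, pd.Series]:
    """Column-centered SVD scores and explained-variance fractions.

    Deterministic up to sign; the sign convention makes the largest-
    magnitude loading of each component positive.
    """
    X = freqs.frame.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("frequency matrix has missing entries; impute first")
    if n_components > min(X.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(matrix dims)={min(X.shape)}"
        )
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for j in range(n_components):
        i_max = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U[:, :n_components] * S[:n_components]
    total = float((S**2).sum())
    # a numerically zero matrix (identical rows) has no variance to explain
    degenerate = S[0] <= 1e-12 * max(1.0, float(np.abs(X).max()))
    if degenerate or total == 0.0:
        scores = np.zeros_like(scores)
        explained = np.zeros(n_components)
    else:
        explained = S[:n_components] ** 2 / total
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=freqs.frame.index, columns=cols),
        pd.Series(explained, index=cols, name="explained_variance_fraction"),
    )


# ---------------------------------------------------------------------------
# Latitudinal cline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdmixtureRecord:
    """Per-sample admixture proportion toward a source cluster."""

    sample_id: str
    Q: float
    population_id: str
    latitude: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.Q <= 1.0):
            raise ValueError(f"{self.sample_id}: Q={self.Q} outside [0, 1]")


@dataclass
class ClineFit:
    """REML mixed-model fit of arcsine-transformed admixture on latitude."""

    slope: float
    slope_se: float
    p_value: float
    intercept: float
    population_effects: Dict[str, float]
    population_means: Dict[str, float]
    variance_components: Tuple[float, float]  # (sigma2_pop, sigma2_resid)
    n_obs: int
    method: str = "MixedLM-REML"


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    needed = {"sample_id", "Q", "population_id", "latitude"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"admixture records missing fields: {sorted(missing)}")
    if ((df["Q"] < 0) | (df["Q"] > 1)).any():
        raise ValueError("Q values outside [0, 1]")
    return df


def cline_fit(records) -> ClineFit:
    """Fit y = arcsin(sqrt(Q)) ~ latitude with a population random intercept.

    Restricted maximum likelihood via statsmodels MixedLM; the slope
    p-value is a Wald test against a t reference with between-population
    degrees of freedom (n_populations - 2), since the slope's information
    comes from the population means when latitude is shared within
    populations; a normal reference would be anticonservative. If the
    mixed model cannot be fit (degenerate, e.g. noise-free data), an OLS
    fallback with zero population variance is returned and flagged in
    ``method``.
    """
    import statsmodels.api as sm

    df = _records_frame(records)
    if df["population_id"].nunique() < 3:
        raise ValueError("need at least 3 populations for the mixed model")
    if df["latitude"].nunique() < 2:
        raise ValueError("degenerate design: latitude does not vary")
    y = np.arcsin(np.sqrt(df["Q"].to_numpy(dtype=float)))
    X = sm.add_constant(df["latitude"].to_numpy(dtype=float))
    pops = df["population_id"].to_numpy()
    ddf = max(df["population_id"].nunique() - 2, 1)

    def _wald_p(beta: float, se: float) -> float:
        if se == 0 or not np.isfinite(se):
            return 0.0 if beta != 0 else 1.0
        return float(2.0 * t_dist.sf(abs(beta) / se, ddf))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=pops)
            res = model.fit(reml=True)
        slope = float(res.params[1])
        se = float(res.bse[1])
        intercept = float(res.params[0])
        sigma2_pop = float(np.asarray(res.cov_re)[0, 0])
        sigma2_resid = float(res.scale)
        effects = {str(g): float(np.asarray(v)[0]) for g, v in res.random_effects.items()}
        method = "MixedLM-REML"
    except Exception:
        ols = sm.OLS(y, X).fit()
        slope = float(ols.params[1])
        se = float(ols.bse[1])
        intercept = float(ols.params[0])
        sigma2_pop, sigma2_resid = 0.0, float(ols.mse_resid)
        effects = {str(g): 0.0 for g in pd.unique(pops)}
        method = "OLS-fallback"
    lat_means = df.groupby("population_id")["latitude"].mean()
    pop_means = {
        str(g): intercept + slope * float(lat_means[g]) + effects.get(str(g), 0.0)
        for g in lat_means.index
    }
    return ClineFit(
        slope=slope,
        slope_se=se,
        p_value=_wald_p(slope, se),
        intercept=intercept,
        population_effects=effects,
        population_means=pop_means,
        variance_components=(max(sigma2_pop, 0.0), max(sigma2_resid, 0.0)),
        n_obs=len(df),
    )
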