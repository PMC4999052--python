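"""Ploidy inference from allele read-count ratios at heterozygous sites.

At a heterozygous locus in an individual with ``k`` haploid chromosome sets,
the expected fraction of reads carrying an allele is one of
``{1/k, ..., (k-1)/k}`` (e.g. {0.25, 0.5, 0.75} for a tetraploid, the single
value 0.5 for a diploid). Observed read fractions are overdispersed relative
to the binomial -- library preparation and sequencing introduce a per-locus
bias -- so each component is modelled as a beta-binomial with expectation
``p`` and correlation ``rho``. Observations are censored to ratios in
[0.1, 0.9] to exclude homozygous loci that appear heterozygous through
sequencing error, and the density is renormalized over the censored support.

The per-individual log-likelihood is

    L = sum_l log( sum_p m_p * BBc(x_l; n_l, p, rho) )

with mixture weights ``m_p`` over the dosage classes and a single shared
``rho``. Candidate ploidies are compared with AIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import betaln, gammaln, logsumexp

from .types import AlleleCounts

__all__ = [
    "RatioObservation",
    "RatioResult",
    "PloidyModelSpec",
    "PloidyFit",
    "PloidyClassification",
    "expected_het_fractions",
    "heterozygous_ratios",
    "censored_betabinom_logpmf",
    "mixture_loglik",
    "fit_ploidy_model",
    "classify_ploidy",
]

_EPS = 1e-9  # tolerance for ratio-window boundary tests (0.1*30 != 3.0 in floats)

# chi-square(1) 95% quantile / 2, for profile-likelihood intervals
_CHI2_1_95_HALF = 1.9207294


def expected_het_fractions(k: int) -> List[float]:
    """Expected focal-read fractions {1/k, ..., (k-1)/k} for ploidy ``k``."""
    if k < 2:
        raise ValueError("ploidy must be >= 2")
    return [i / k for i in range(1, k)]


@dataclass(frozen=True)
class RatioObservation:
    """Focal-allele count ``x`` out of ``n`` total reads at one het locus."""

    x: int
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.x <= self.n:
            raise ValueError(f"need 0 <= x <= n, got x={self.x}, n={self.n}")

    @property
    def ratio(self) -> float:
        return self.x / self.n


@dataclass
class RatioResult:
    """Outcome of collecting allele-ratio observations for one sample."""

    observations: List[RatioObservation]
    status: str  # "ok" | "insufficient_heterozygous_sites"
    n_input: int = 0
    n_not_biallelic: int = 0
    n_low_coverage: int = 0
    n_censored: int = 0


@dataclass(frozen=True)
class PloidyModelSpec:
    """Candidate-ploidy model: component grid and censoring window."""

    k: int
    p_grid: Tuple[float, ...]
    censor_lo: float = 0.1
    censor_hi: float = 0.9

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("ploidy must be >= 2")
        grid = self.p_grid
        if any(not (0.0 < p < 1.0) for p in grid):
            raise ValueError("p_grid values must be in (0, 1)")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("p_grid must be strictly increasing")
        if not (0.0 <= self.censor_lo < self.censor_hi <= 1.0):
            raise ValueError("invalid censoring window")

    @classmethod
    def for_ploidy(
        cls, k: int, censor_lo: float = 0.1, censor_hi: float = 0.9
    ) -> "PloidyModelSpec":
        return cls(
            k=k,
            p_grid=tuple(expected_het_fractions(k)),
            censor_lo=censor_lo,
            censor_hi=censor_hi,
        )

    @property
    def n_free_params(self) -> int:
        # (|p_grid| - 1) mixture weights + rho
        return (len(self.p_grid) - 1) + 1


@dataclass
class PloidyFit:
    """Maximum-likelihood fit of the censored mixture for one candidate ploidy."""

    k: int
    m: np.ndarray
    rho: float
    loglik: float
    n_free_params: int
    aic: float
    n_obs: int
    rho_ci: Optional[Tuple[float, float]] = None
    ci_method: str = "profile_likelihood"
    status: str = "converged"


@dataclass
class PloidyClassification:
    """AIC comparison across candidate ploidies for one sample."""

    best_k: Optional[int]
    fits: Dict[int, PloidyFit]
    delta_aic: Dict[int, float]
    status: str  # "ok" | "undetermined"


# ---------------------------------------------------------------------------
# Ratio collection
# ---------------------------------------------------------------------------


def heterozygous_ratios(
    counts: Iterable[AlleleCounts],
    min_cov: int = 30,
    censor: Tuple[float, float] = (0.1, 0.9),
) -> RatioResult:
    """Collect focal-allele read ratios at apparent heterozygous sites.

    A site enters if exactly two alleles have at least one read each
    (multi-allelic sites are excluded from ploidy estimation), total coverage
    is at least ``min_cov``, and the focal-allele ratio lies inside the
    (inclusive) censoring window. The focal allele is the second-listed
    observed allele, i.e. the non-reference allele at a biallelic site.
    """
    lo, hi = censor
    obs: List[RatioObservation] = []
    res = RatioResult(observations=obs, status="ok")
    for rec in counts:
        res.n_input += 1
        observed = rec.observed()
        if len(observed) != 2:
            res.n_not_biallelic += 1
            continue
        n = rec.total
        if n < min_cov:
            res.n_low_coverage += 1
            continue
        x = observed[1][1]
        if x < lo * n - _EPS or x > hi * n + _EPS:
            res.n_censored += 1
            continue
        obs.append(RatioObservation(x=x, n=n))
    if not obs:
        res.status = "insufficient_heterozygous_sites"
    return res


# ---------------------------------------------------------------------------
# Censored beta-binomial density
# ---------------------------------------------------------------------------


def _bb_logpmf(x, n, a: float, b: float):
    """Log pmf of the beta-binomial via log-gamma; vectorized over x, n."""
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    return (
        gammaln(n + 1)
        - gammaln(x + 1)
        - gammaln(n - x + 1)
        + betaln(x + a, n - x + b)
        - betaln(a, b)
    )


def _ab_from_p_rho(p: float, rho: float) -> Tuple[float, float]:
    return p * (1.0 - rho) / rho, (1.0 - p) * (1.0 - rho) / rho


def _window_bounds(n: int, lo: float, hi: float) -> Tuple[int, int]:
    """Smallest/largest integer count whose ratio lies in [lo, hi]."""
    y_lo = int(math.ceil(lo * n - _EPS))
    y_hi = int(math.floor(hi * n + _EPS))
    return y_lo, y_hi


def censored_betabinom_logpmf(
    x: int,
    n: int,
    p: float,
    rho: float,
    censor: Tuple[float, float] = (0.1, 0.9),
) -> float:
    """Log density of the beta-binomial renormalized over the censored support.

    The density is divided by the total beta-binomial mass on counts ``y``
    with ``lo <= y/n <= hi`` (inclusive), so it sums to one over the window.
    """
    lo, hi = censor
    if not (0.0 < p < 1.0):
        raise ValueError("p must be in (0, 1)")
    if not (0.0 < rho < 1.0):
        raise ValueError("rho must be in (0, 1)")
    y_lo, y_hi = _window_bounds(n, lo, hi)
    if not (y_lo <= x <= y_hi):
        raise ValueError(
            f"x/n = {x}/{n} lies outside the censoring window [{lo}, {hi}]"
        )
    a, b = _ab_from_p_rho(p, rho)
    y = np.arange(y_lo, y_hi + 1)
    log_all = _bb_logpmf(y, n, a, b)
    return float(log_all[x - y_lo] - logsumexp(log_all))


class _CensoredMixtureWorkspace:
    """Precomputed grids for fast repeated evaluation of the censored mixture.

    Groups observations by their total count ``n`` so that the normalization
    sum over each censored support is computed once per (n, p, rho) on a
    padded 2-D grid. Because all count arguments are small integers, the
    log-gamma terms that depend on (a, b) are served from two lookup tables
    of size max(n)+1 per evaluation, making one likelihood evaluation a few
    hundred gammaln calls regardless of the number of observations.
    """

    def __init__(
        self, obs: Sequence[RatioObservation], censor: Tuple[float, float]
    ) -> None:
        if not obs:
            raise ValueError("no observations")
        self.lo, self.hi = censor
        xs = np.array([o.x for o in obs], dtype=int)
        ns = np.array([o.n for o in obs], dtype=int)
        for o in obs:
            y_lo, y_hi = _window_bounds(o.n, self.lo, self.hi)
            if not (y_lo <= o.x <= y_hi):
                raise ValueError(
                    f"observation {o.x}/{o.n} outside censoring window "
                    f"[{self.lo}, {self.hi}]"
                )
        self.unique_n, self.inverse = np.unique(ns, return_inverse=True)
        self._max_n = int(self.unique_n.max())
        self._obs_x = xs
        self._obs_nx = ns - xs
        # x-only part of log C(n, x), rho-independent
        lg = gammaln(np.arange(self._max_n + 2, dtype=float))
        self._comb_obs = lg[ns + 1] - lg[xs + 1] - lg[ns - xs + 1]

        bounds = [_window_bounds(int(n), self.lo, self.hi) for n in self.unique_n]
        widths = [hi_ - lo_ + 1 for lo_, hi_ in bounds]
        w = max(widths)
        U = len(self.unique_n)
        grid_y = np.zeros((U, w), dtype=int)
        grid_n = np.zeros((U, w), dtype=int)
        mask = np.zeros((U, w), dtype=bool)
        for i, ((lo_, hi_), n) in enumerate(zip(bounds, self.unique_n)):
            k = hi_ - lo_ + 1
            grid_y[i, :k] = np.arange(lo_, hi_ + 1)
            grid_n[i, :] = n
            mask[i, :k] = True
        self._grid_y = grid_y
        self._grid_ny = grid_n - grid_y
        self._grid_mask = mask
        self._comb_grid = np.where(
            mask, lg[grid_n + 1] - lg[grid_y + 1] - lg[self._grid_ny + 1], 0.0
        )
        self._row_of_obs = self.inverse

    def component_logdens(self, p: float, rho: float) -> np.ndarray:
        """Censored log density of every observation under component p."""
        a, b = _ab_from_p_rho(p, rho)
        v = np.arange(self._max_n + 1, dtype=float)
        ta = gammaln(v + a)
        tb = gammaln(v + b)
        t_nab = gammaln(self.unique_n + a + b)
        log_bab = gammaln(a) + gammaln(b) - gammaln(a + b)
        # betaln(y+a, n-y+b) - betaln(a, b), via the tables
        grid = (
            self._comb_grid
            + ta[self._grid_y]
            + tb[self._grid_ny]
            - t_nab[:, None]
            - log_bab
        )
        grid = np.where(self._grid_mask, grid, -np.inf)
        lognorm = logsumexp(grid, axis=1)
        obs = (
            self._comb_obs
            + ta[self._obs_x]
            + tb[self._obs_nx]
            - t_nab[self._row_of_obs]
            - log_bab
        )
        return obs - lognorm[self._row_of_obs]

    def logdens_matrix(self, p_grid: Sequence[float], rho: float) -> np.ndarray:
        return np.column_stack([self.component_logdens(p, rho) for p in p_grid])


def mixture_loglik(
    obs: Sequence[RatioObservation],
    spec: PloidyModelSpec,
    m: Sequence[float],
    rho: float,
) -> float:
    """Censored beta-binomial mixture log-likelihood at fixed weights and rho."""
    m = np.asarray(m, dtype=float)
    if m.shape != (len(spec.p_grid),):
        raise ValueError("weight vector length must match the component grid")
    if np.any(m < -1e-8) or abs(m.sum() - 1.0) > 1e-8:
        raise ValueError("weights must lie on the probability simplex")
    ws = _CensoredMixtureWorkspace(obs, (spec.censor_lo, spec.censor_hi))
    D = ws.logdens_matrix(spec.p_grid, rho)
    with np.errstate(divide="ignore"):
        log_m = np.log(np.clip(m, 0.0, None))
    return float(logsumexp(D + log_m[None, :], axis=1).sum())


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------


def _em_weights(
    D: np.ndarray, tol: float = 1e-10, max_iter: int = 400
) -> Tuple[float, np.ndarray]:
    """Maximize the mixture log-likelihood over weights for fixed components.

    The log-likelihood is concave in the weights, so EM converges to the
    global optimum of this subproblem.
    """
    n, P = D.shape
    if P == 1:
        return float(D.sum()), np.ones(1)
    m = np.full(P, 1.0 / P)
    log_m = np.log(m)
    mx = D.max(axis=1, keepdims=True)
    E = np.exp(D - mx)  # scaled densities, reused every iteration
    base = float(mx.sum())
    prev = -np.inf
    for _ in range(max_iter):
        num = E * m[None, :]
        row = num.sum(axis=1)
        ll = base + float(np.log(row).sum())
        if ll - prev < tol * (abs(ll) + 1.0):
            break
        prev = ll
        m = (num / row[:, None]).mean(axis=0)
        m = np.clip(m, 1e-300, None)
        m /= m.sum()
    row = (E * m[None, :]).sum(axis=1)
    ll = base + float(np.log(row).sum())
    return ll, m


_RHO_MIN, _RHO_MAX = 1e-6, 0.8
_DEFAULT_RHO_GRID = np.geomspace(5e-4, 0.5, 13)


def fit_ploidy_model(
    obs: Sequence[RatioObservation],
    spec: PloidyModelSpec,
    min_obs: int = 50,
    compute_ci: bool = True,
) -> PloidyFit:
    """Maximum-likelihood fit of the censored mixture for one candidate ploidy.

    The weights are profiled out by EM (a concave subproblem with a global
    optimum), and the profile likelihood is maximized over ``rho`` by a
    coarse grid followed by Brent refinement. A 95% profile-likelihood
    interval for ``rho`` is reported.
    """
    if len(obs) < min_obs:
        raise ValueError(
            f"need at least {min_obs} ratio observations, got {len(obs)}"
        )
    ws = _CensoredMixtureWorkspace(obs, (spec.censor_lo, spec.censor_hi))
    cache: Dict[float, Tuple[float, np.ndarray]] = {}

    def profile(rho: float) -> Tuple[float, np.ndarray]:
        rho = float(np.clip(rho, _RHO_MIN, _RHO_MAX))
        if rho not in cache:
            cache[rho] = _em_weights(ws.logdens_matrix(spec.p_grid, rho))
        return cache[rho]

    status = "converged"
    grid = _DEFAULT_RHO_GRID
    grid_ll = np.array([profile(r)[0] for r in grid])
    i = int(np.argmax(grid_ll))
    lo_b = grid[max(i - 1, 0)]
    hi_b = grid[min(i + 1, len(grid) - 1)]
    try:
        res = minimize_scalar(
            lambda t: -profile(math.exp(t))[0],
            bounds=(math.log(lo_b), math.log(hi_b)),
            method="bounded",
            options={"xatol": 1e-5},
        )
        rho_hat = float(np.clip(math.exp(res.x), _RHO_MIN, _RHO_MAX))
    except Exception:  # pragma: no cover - defensive
        status = "unconverged"
        rho_hat = float(grid[i])
    ll_hat, m_hat = profile(rho_hat)
    if grid_ll[i] > ll_hat:  # keep the best point seen
        rho_hat = float(grid[i])
        ll_hat, m_hat = profile(rho_hat)

    rho_ci: Optional[Tuple[float, float]] = None
    if compute_ci:
        target = ll_hat - _CHI2_1_95_HALF

        def gap(r: float) -> float:
            return profile(r)[0] - target

        ci_lo, ci_hi = _RHO_MIN, _RHO_MAX
        try:
            if gap(_RHO_MIN) < 0:
                ci_lo = brentq(gap, _RHO_MIN, rho_hat, xtol=1e-8)
            if gap(_RHO_MAX) < 0:
                ci_hi = brentq(gap, rho_hat, _RHO_MAX, xtol=1e-8)
            rho_ci = (float(ci_lo), float(ci_hi))
        except ValueError:  # pragma: no cover - degenerate profiles
            rho_ci = None

    aic = 2.0 * spec.n_free_params - 2.0 * ll_hat
    return PloidyFit(
        k=spec.k,
        m=m_hat,
        rho=rho_hat,
        loglik=ll_hat,
        n_free_params=spec.n_free_params,
        aic=aic,
        n_obs=len(obs),
        rho_ci=rho_ci,
        status=status,
    )


def classify_ploidy(
    obs: Sequence[RatioObservation],
    candidate_ks: Iterable[int] = (2, 3, 4),
    min_obs: int = 50,
    censor: Tuple[float, float] = (0.1, 0.9),
    compute_ci: bool = False,
) -> PloidyClassification:
    """Fit every candidate ploidy and pick the minimum-AIC model.

    Samples with fewer than ``min_obs`` usable ratio observations are
    reported as undetermined rather than classified (very small numbers of
    variable sites are known to produce unstable assignments). AIC ties are
    broken toward the lower ploidy.
    """
    ks = sorted(set(int(k) for k in candidate_ks))
    if not ks:
        raise ValueError("no candidate ploidies supplied")
    if len(obs) < min_obs:
        return PloidyClassification(best_k=None, fits={}, delta_aic={}, status="undetermined")
    fits: Dict[int, PloidyFit] = {}
    for k in ks:
        spec = PloidyModelSpec.for_ploidy(k, censor_lo=censor[0], censor_hi=censor[1])
        fits[k] = fit_ploidy_model(obs, spec, min_obs=min_obs, compute_ci=compute_ci)
    converged = {k: f for k, f in fits.items() if f.status != "unconverged"}
    if not converged:
        return PloidyClassification(best_k=None, fits=fits, delta_aic={}, status="undetermined")
    best_k = min(converged, key=lambda k: (converged[k].aic, k))
    aic_min = fits[best_k].aic
    delta = {k: f.aic - aic_min for k, f in fits.items()}
    return PloidyClassification(best_k=best_k, fits=fits, delta_aic=delta, status="ok")
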