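"""Allele-dosage genotype calling for a sample of known ploidy.

Every possible dosage model at a ploidy ``n`` is an integer partition of
``n`` (for a tetraploid: 4:0:0:0, 3:1:0:0, 2:2:0:0, 2:1:1:0, 1:1:1:1). Read
counts ``x`` are sorted in descending order with their mean phred qualities
``q`` carried along, and each model is scored with a two-part likelihood:

* L1, multinomial: where the model expects reads, counts follow a
  multinomial with class probabilities ``m_i / n``;
* L2, error: where reads are observed but the model expects none, each read
  is a sequencing error with probability ``p = 10^(-q/10)``.

The total is ``L = L1 * L2`` (computed in log space with log-gamma), and the
best-fitting model is chosen by BIC with sample size N = total reads at the
locus and model dimension = number of distinct alleles in the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammaln

from .types import AlleleCounts

__all__ = [
    "DosageModel",
    "GenotypeCall",
    "enumerate_dosage_models",
    "prepare_counts",
    "model_loglik",
    "call_genotype",
    "genotype_sample",
]

logger = logging.getLogger(__name__)

_LN10_OVER_10 = np.log(10.0) / 10.0

#: Placeholder label for a copy assigned to an allele that was not observed
#: (possible only when the winning model names more alleles than were seen).
UNOBSERVED_ALLELE = "N"


@dataclass(frozen=True)
class DosageModel:
    """An integer partition of the ploidy across up to ``n`` alleles."""

    n: int
    m: Tuple[int, ...]

    def __post_init__(self) -> None:
        if sum(self.m) != self.n:
            raise ValueError(f"dosages {self.m} do not sum to ploidy {self.n}")
        if len(self.m) != self.n:
            raise ValueError(f"model vector must be zero-padded to length {self.n}")
        if any(a < b for a, b in zip(self.m, self.m[1:])):
            raise ValueError(f"dosages {self.m} not sorted descending")

    @property
    def n_alleles(self) -> int:
        """Number of distinct alleles the model expects (non-zero entries)."""
        return sum(1 for v in self.m if v > 0)

    def __str__(self) -> str:
        return ":".join(str(v) for v in self.m)


def enumerate_dosage_models(n: int) -> List[DosageModel]:
    """All dosage models for ploidy ``n``, in lexicographically decreasing order.

    n=2 -> [2:0, 1:1]; n=3 -> [3:0:0, 2:1:0, 1:1:1];
    n=4 -> [4:0:0:0, 3:1:0:0, 2:2:0:0, 2:1:1:0, 1:1:1:1].
    """
    if n < 1:
        raise ValueError("ploidy must be >= 1")

    parts: List[Tuple[int, ...]] = []

    def rec(remaining: int, max_part: int, prefix: List[int]) -> None:
        if remaining == 0:
            parts.append(tuple(prefix + [0] * (n - len(prefix))))
            return
        for v in range(min(max_part, remaining), 0, -1):
            rec(remaining - v, v, prefix + [v])

    rec(n, n, [])
    parts.sort(reverse=True)
    return [DosageModel(n=n, m=p) for p in parts]


def prepare_counts(
    rec: AlleleCounts, n: int
) -> Tuple[Tuple[int, ...], Tuple[float, ...], Tuple[str, ...]]:
    """Sort counts descending (qualities permuted along) and truncate to ``n``.

    If more than ``n`` alleles are recorded, only the ``n`` most frequent are
    kept (truncation on the right). Ties in counts are broken by allele label
    order, so results do not depend on input ordering.
    """
    if sum(rec.counts) == 0:
        raise ValueError(f"{rec.locus_id}: record with all-zero counts")
    order = sorted(
        range(len(rec.alleles)), key=lambda i: (-rec.counts[i], rec.alleles[i])
    )
    order = order[:n]
    x = tuple(rec.counts[i] for i in order)
    q = tuple(rec.mean_phred[i] for i in order)
    alleles = tuple(rec.alleles[i] for i in order)
    return x, q, alleles


def model_loglik(
    x: Sequence[int], q: Sequence[float], model: DosageModel
) -> float:
    """Log likelihood log(L1) + log(L2) of a dosage model for sorted counts.

    ``x`` and ``q`` may be shorter than the ploidy; they are zero-padded to
    the model length (a model may expect an allele that was never observed;
    such positions contribute no mass to either term).
    """
    n = model.n
    if len(x) > n:
        raise ValueError("count vector longer than ploidy; run prepare_counts first")
    xs = np.zeros(n)
    qs = np.zeros(n)
    xs[: len(x)] = x
    qs[: len(q)] = q
    m = np.asarray(model.m, dtype=float)
    expected = m > 0

    xe = xs[expected]
    # multinomial in log space: log(sum(xe)!) - sum(log xe!) + sum(xe*log(m/n))
    l1 = gammaln(xe.sum() + 1.0) - gammaln(xe + 1.0).sum()
    pos = xe > 0
    l1 += float((xe[pos] * np.log(m[expected][pos] / n)).sum())

    xu = xs[~expected]
    qu = qs[~expected]
    # per-read error probability p = 10^(-q/10) => log p = -q*ln(10)/10
    l2 = float(-(xu * qu).sum() * _LN10_OVER_10)
    return float(l1 + l2)


@dataclass
class GenotypeCall:
    """Best-fitting dosage model for one locus in one sample."""

    locus_id: str
    allele_dosages: Dict[str, int]
    model: Optional[DosageModel]
    loglik: float
    bic: float
    delta_bic_runnerup: float
    status: str  # called | missing_low_cov | missing_high_cov | ambiguous

    @property
    def is_called(self) -> bool:
        return self.status == "called"


def _missing_call(locus_id: str, status: str) -> GenotypeCall:
    return GenotypeCall(
        locus_id=locus_id,
        allele_dosages={},
        model=None,
        loglik=np.nan,
        bic=np.nan,
        delta_bic_runnerup=np.nan,
        status=status,
    )


def _preference_key(model: DosageModel) -> Tuple:
    # fewer distinct alleles first; then larger leading dosage (more
    # homozygous), i.e. lexicographically larger partition
    return (model.n_alleles, tuple(-v for v in model.m))


def call_genotype(
    rec: AlleleCounts,
    n: int,
    cov_min: Optional[int] = None,
    cov_max: int = 200,
    ambiguous_delta: float = 0.0,
) -> GenotypeCall:
    """Score every dosage model for one record and select by BIC.

    Coverage gating is inclusive: loci with fewer than ``cov_min`` reads
    (default five per ploidy level, i.e. 10 for diploids, 20 for tetraploids)
    or more than ``cov_max`` reads are reported missing. BIC uses the total
    read count as sample size and the number of distinct alleles in the model
    as its dimension; ties are broken toward fewer distinct alleles, then
    toward the more homozygous model. If ``ambiguous_delta`` > 0, calls whose
    BIC margin over the runner-up is below it are flagged ambiguous.
    """
    if n < 1:
        raise ValueError("ploidy must be >= 1")
    if cov_min is None:
        cov_min = 5 * n
    total = rec.total
    if total < cov_min:
        return _missing_call(rec.locus_id, "missing_low_cov")
    if total > cov_max:
        return _missing_call(rec.locus_id, "missing_high_cov")

    x, q, alleles = prepare_counts(rec, n)
    n_total = float(sum(x))
    log_n_total = np.log(n_total)
    scored: List[Tuple[float, DosageModel, float]] = []
    for model in enumerate_dosage_models(n):
        ll = model_loglik(x, q, model)
        bic = model.n_alleles * log_n_total - 2.0 * ll
        scored.append((bic, model, ll))
    scored.sort(key=lambda t: (t[0], _preference_key(t[1])))
    best_bic, best_model, best_ll = scored[0]
    delta = scored[1][0] - best_bic if len(scored) > 1 else np.inf

    dosages: Dict[str, int] = {}
    for i, copies in enumerate(best_model.m):
        if copies == 0:
            continue
        label = alleles[i] if i < len(alleles) else UNOBSERVED_ALLELE
        dosages[label] = dosages.get(label, 0) + copies

    status = "called"
    if ambiguous_delta > 0 and delta < ambiguous_delta:
        status = "ambiguous"
    return GenotypeCall(
        locus_id=rec.locus_id,
        allele_dosages=dosages,
        model=best_model,
        loglik=best_ll,
        bic=best_bic,
        delta_bic_runnerup=float(delta),
        status=status,
    )


def genotype_sample(
    recs: Iterable[AlleleCounts],
    n: int,
    cov_min: Optional[int] = None,
    cov_max: int = 200,
    ambiguous_delta: float = 0.0,
) -> List[GenotypeCall]:
    """Call every locus of one sample; logs a called/missing summary."""
    calls = [
        call_genotype(rec, n, cov_min=cov_min, cov_max=cov_max,
                      ambiguous_delta=ambiguous_delta)
        for rec in recs
    ]
    n_called = sum(1 for c in calls if c.is_called)
    logger.info(
        "genotyped %d loci at ploidy %d: %d called, %d missing/ambiguous",
        len(calls), n, n_called, len(calls) - n_called,
    )
    return calls
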