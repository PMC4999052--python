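"""Synthetic allele read-count data with known ground truth.

The generator emulates the statistical structure of RAD-seq read counts in a
mixed-ploidy cohort: per-locus population allele frequencies, Hardy-Weinberg
dosage genotypes at the sample's ploidy, skewed per-locus coverage (negative
binomial), beta-binomially overdispersed allele sampling at heterozygous
sites (correlation ``rho``), and phred-calibrated sequencing errors that land
on non-genotype alleles. Everything is driven by a mandatory seed and is
byte-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import AlleleCounts, GenotypeMatrix

__all__ = [
    "SimConfig",
    "LocusDef",
    "SimTruth",
    "CohortSim",
    "simulate_individual",
    "simulate_cohort",
    "simulate_admixture_records",
    "truth_compare",
    "AccuracyReport",
]

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulated cohort.

    ``n_samples`` maps ploidy -> number of individuals. Coverage defaults to
    a negative binomial with mean 60 and dispersion 5 (truncated to >= 1),
    mirroring RAD coverage skew; ``rho`` = 0.02 matches the overdispersion
    regime of real libraries; ``error_rate`` is the per-read miscall
    probability, with phred qualities set consistently
    (q = -10 log10(error_rate) when constant).
    """

    n_samples: Mapping[int, int]
    n_loci: int
    seed: int
    coverage_law: Tuple[str, Mapping[str, float]] = (
        "negative-binomial",
        {"mean": 60.0, "dispersion": 5.0},
    )
    rho: float = 0.02
    error_rate: float = 0.005
    phred: Optional[float] = None
    allele_freq_law: Tuple[str, Mapping[str, float]] = (
        "uniform",
        {"low": 0.05, "high": 0.95},
    )
    group_divergence: Optional[float] = None
    n_groups: int = 1
    extra_allelic: Mapping[int, int] = field(default_factory=dict)
    #: condition every genotype on being heterozygous (used to realize
    #: "N heterozygous sites per individual" study conditions)
    condition_het: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_loci < 1 or any(v < 1 for v in self.n_samples.values()):
            raise ValueError("n_loci and sample counts must be >= 1")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0, 1)")
        if self.group_divergence is not None and not (0.0 < self.group_divergence < 1.0):
            raise ValueError("group_divergence F must be in (0, 1)")
        name, _ = self.coverage_law
        if name not in ("negative-binomial", "constant"):
            raise ValueError(f"unknown coverage law {name!r}")

    @property
    def phred_value(self) -> float:
        if self.phred is not None:
            return float(self.phred)
        if self.error_rate > 0:
            return -10.0 * math.log10(self.error_rate)
        return 40.0


@dataclass(frozen=True)
class LocusDef:
    """Cohort-level definition of one simulated locus."""

    locus_id: str
    alleles: Tuple[str, ...]  # ref first
    freqs: Tuple[Tuple[float, ...], ...]  # per group, aligned with alleles


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    ploidy: Dict[str, int]
    genotypes: Dict[str, Dict[str, Dict[str, int]]]  # sample -> locus -> dosage
    groups: Dict[str, int]
    locus_defs: List[LocusDef]

    def matrix(self) -> GenotypeMatrix:
        """The true genotypes as a GenotypeMatrix."""
        loci = [ld.locus_id for ld in self.locus_defs]
        samples = list(self.ploidy)
        gm = GenotypeMatrix(samples, loci, self.ploidy)
        for s in samples:
            for l, d in self.genotypes[s].items():
                gm.set_call(s, l, d)
        return gm


def _draw_coverage(cfg: SimConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    name, params = cfg.coverage_law
    if name == "constant":
        return np.full(size, int(params["value"]), dtype=int)
    mean, disp = float(params["mean"]), float(params["dispersion"])
    p = disp / (disp + mean)
    cov = rng.negative_binomial(disp, p, size=size)
    return np.maximum(cov, 1)


def _draw_base_freqs(cfg: SimConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    name, params = cfg.allele_freq_law
    if name == "uniform":
        return rng.uniform(params["low"], params["high"], size=size)
    if name == "beta":
        return rng.beta(params["a"], params["b"], size=size)
    raise ValueError(f"unknown allele frequency law {name!r}")


def _balding_nichols(
    p: np.ndarray, F: float, n_groups: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-group frequencies drawn around ancestral ``p`` with divergence F."""
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return np.stack([rng.beta(a, b) for _ in range(n_groups)], axis=0)


def _make_locus_defs(cfg: SimConfig, rng: np.random.Generator) -> List[LocusDef]:
    n_extra = sum(cfg.extra_allelic.values())
    if n_extra > cfg.n_loci:
        raise ValueError("more extra-allelic loci requested than n_loci")
    base_p = _draw_base_freqs(cfg, rng, cfg.n_loci)
    if cfg.group_divergence is not None and cfg.n_groups > 1:
        group_p = _balding_nichols(base_p, cfg.group_divergence, cfg.n_groups, rng)
    else:
        group_p = base_p[None, :].repeat(max(cfg.n_groups, 1), axis=0)

    # positions of planted multi-allelic loci (spread deterministically)
    allelicity = np.full(cfg.n_loci, 2, dtype=int)
    extra_positions = iter(range(cfg.n_loci))
    for n_alleles, count in sorted(cfg.extra_allelic.items()):
        if n_alleles not in (3, 4):
            raise ValueError("extra_allelic keys must be 3 or 4")
        taken = 0
        for pos in extra_positions:
            allelicity[pos] = n_alleles
            taken += 1
            if taken == count:
                break
        if taken < count:
            raise ValueError("not enough loci to plant extra-allelic sites")

    defs: List[LocusDef] = []
    for j in range(cfg.n_loci):
        na = int(allelicity[j])
        order = rng.permutation(4)[:na]
        alleles = tuple(_BASES[i] for i in order)
        if na == 2:
            freqs = tuple(
                (1.0 - group_p[g, j], group_p[g, j]) for g in range(group_p.shape[0])
            )
        else:
            # balanced-ish frequencies so every planted allele segregates
            freqs = tuple(
                tuple(rng.dirichlet(np.full(na, 8.0)))
                for _ in range(group_p.shape[0])
            )
        defs.append(LocusDef(locus_id=f"ctg1:{100 * (j + 1)}", alleles=alleles, freqs=freqs))
    return defs


def _simulate_counts_for_sample(
    cfg: SimConfig,
    locus_defs: Sequence[LocusDef],
    ploidy: int,
    group: int,
    sample_id: str,
    rng: np.random.Generator,
) -> Tuple[List[AlleleCounts], Dict[str, Dict[str, int]]]:
    L = len(locus_defs)
    cov = _draw_coverage(cfg, rng, L)
    q = cfg.phred_value
    e = cfg.error_rate
    records: List[AlleleCounts] = []
    genotypes: Dict[str, Dict[str, int]] = {}
    for j, ld in enumerate(locus_defs):
        freqs = np.asarray(ld.freqs[group if group < len(ld.freqs) else 0])
        dosage = rng.multinomial(ploidy, freqs)
        if cfg.condition_het:
            while dosage.max() == ploidy:  # rejection-sample a het genotype
                dosage = rng.multinomial(ploidy, freqs)
        c = int(cov[j])
        # allocate reads to genotype alleles: Dirichlet-multinomial with
        # concentration d/ploidy * (1-rho)/rho == beta-binomial when biallelic
        carriers = np.flatnonzero(dosage)
        counts = np.zeros(len(ld.alleles), dtype=int)
        if len(carriers) == 1:
            counts[carriers[0]] = c
        else:
            props = dosage[carriers] / ploidy
            if cfg.rho > 0:
                alpha = props * (1.0 - cfg.rho) / cfg.rho
                props = rng.dirichlet(alpha)
            counts[carriers] = rng.multinomial(c, props)
        # sequencing errors: each read miscalls with prob e onto a uniformly
        # random non-genotype allele
        allele_labels = list(ld.alleles)
        extra: Dict[str, int] = {}
        if e > 0:
            non_genotype = [b for b in _BASES if b not in {ld.alleles[i] for i in carriers}]
            if non_genotype:
                errs = rng.binomial(counts, e)
                n_err = int(errs.sum())
                if n_err > 0:
                    counts -= errs
                    split = rng.multinomial(n_err, np.full(len(non_genotype), 1.0 / len(non_genotype)))
                    for lab, k in zip(non_genotype, split):
                        if k > 0:
                            extra[lab] = extra.get(lab, 0) + int(k)
        out_alleles = allele_labels + [lab for lab in sorted(extra) if lab not in allele_labels]
        out_counts = [int(counts[i]) for i in range(len(allele_labels))]
        for lab in out_alleles[len(allele_labels):]:
            out_counts.append(extra[lab])
        # merge errors that landed on defined alleles (possible when a
        # defined allele is not in this sample's genotype)
        for lab, k in extra.items():
            if lab in allele_labels:
                out_counts[allele_labels.index(lab)] += k
        records.append(
            AlleleCounts(
                sample_id=sample_id,
                locus_id=ld.locus_id,
                alleles=tuple(out_alleles),
                counts=tuple(out_counts),
                mean_phred=tuple(q for _ in out_alleles),
            )
        )
        genotypes[ld.locus_id] = {
            ld.alleles[i]: int(dosage[i]) for i in np.flatnonzero(dosage)
        }
    return records, genotypes


def simulate_individual(
    cfg: SimConfig,
    ploidy: int,
    seed: int,
    locus_defs: Optional[Sequence[LocusDef]] = None,
    group: int = 0,
    sample_id: str = "S0",
) -> Tuple[List[AlleleCounts], Dict[str, Dict[str, int]]]:
    """Simulate one individual; returns (records, true dosage per locus)."""
    rng = np.random.default_rng(seed)
    if locus_defs is None:
        locus_defs = _make_locus_defs(cfg, rng)
    return _simulate_counts_for_sample(cfg, locus_defs, ploidy, group, sample_id, rng)


@dataclass
class CohortSim:
    """A simulated multi-sample data set plus its ground truth."""

    config: SimConfig
    counts: Dict[str, List[AlleleCounts]]
    truth: SimTruth
    meta: pd.DataFrame

    # -- on-disk formats --------------------------------------------------
    def write_vcf(self, path) -> None:
        from .io_counts import write_vcf_allele_depths

        write_vcf_allele_depths(self.counts, self.truth.locus_defs, path)

    def write_tables(self, directory) -> List[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for sample, recs in self.counts.items():
            p = directory / f"{sample}.tsv"
            with open(p, "w") as fh:
                fh.write("locus\tallele\tcount\tmean_qual\n")
                for rec in recs:
                    for a, c, qv in zip(rec.alleles, rec.counts, rec.mean_phred):
                        fh.write(f"{rec.locus_id}\t{a}\t{c}\t{qv:g}\n")
            paths.append(p)
        return paths

    def write_truth_json(self, path) -> None:
        payload = {
            "ploidy": self.truth.ploidy,
            "groups": self.truth.groups,
            "genotypes": self.truth.genotypes,
            "loci": [
                {"locus_id": ld.locus_id, "alleles": list(ld.alleles)}
                for ld in self.truth.locus_defs
            ],
            "seed": self.config.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)


def simulate_cohort(cfg: SimConfig) -> CohortSim:
    """Simulate a mixed-ploidy cohort under one set of locus definitions.

    Samples are spread round-robin over ``cfg.n_groups`` groups; with
    ``group_divergence`` set, group frequencies follow the Balding-Nichols
    model around the ancestral frequency.
    """
    ss = np.random.SeedSequence(cfg.seed)
    locus_rng = np.random.default_rng(ss.spawn(1)[0])
    locus_defs = _make_locus_defs(cfg, locus_rng)

    sample_plan: List[Tuple[str, int]] = []
    for ploidy in sorted(cfg.n_samples):
        for i in range(cfg.n_samples[ploidy]):
            sample_plan.append((f"S{ploidy}x_{i:03d}", ploidy))
    child_seeds = ss.spawn(len(sample_plan) + 1)[1:]

    counts: Dict[str, List[AlleleCounts]] = {}
    genotypes: Dict[str, Dict[str, Dict[str, int]]] = {}
    ploidy_map: Dict[str, int] = {}
    groups: Dict[str, int] = {}
    rows = []
    for idx, ((sample_id, ploidy), child) in enumerate(zip(sample_plan, child_seeds)):
        group = idx % max(cfg.n_groups, 1)
        rng = np.random.default_rng(child)
        recs, geno = _simulate_counts_for_sample(
            cfg, locus_defs, ploidy, group, sample_id, rng
        )
        counts[sample_id] = recs
        genotypes[sample_id] = geno
        ploidy_map[sample_id] = ploidy
        groups[sample_id] = group
        rows.append(
            {
                "sample_id": sample_id,
                "species_label": f"ploidy{ploidy}",
                "population_id": f"pop{group}",
                "latitude": 55.0,
                "raw_read_count": 5_000_000,
            }
        )
    truth = SimTruth(
        ploidy=ploidy_map, genotypes=genotypes, groups=groups, locus_defs=locus_defs
    )
    return CohortSim(config=cfg, counts=counts, truth=truth, meta=pd.DataFrame(rows))


def simulate_admixture_records(
    n_populations: int = 20,
    n_per_population: int = 6,
    slope: float = -0.01,
    intercept: float = 0.9,
    sigma_pop: float = 0.05,
    sigma_resid: float = 0.05,
    latitude_range: Tuple[float, float] = (50.0, 60.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a latitudinal admixture gradient for cline-fit tests.

    The linear model holds on the arcsine scale: y = intercept + slope*lat +
    population effect + noise, with Q = sin(y)^2 (clipped into [0, pi/2]
    before back-transform so Q stays in [0, 1]).
    """
    rng = np.random.default_rng(seed)
    lats = rng.uniform(*latitude_range, size=n_populations)
    rows = []
    for p in range(n_populations):
        u = rng.normal(0.0, sigma_pop)
        for i in range(n_per_population):
            y = intercept + slope * lats[p] + u + rng.normal(0.0, sigma_resid)
            y = float(np.clip(y, 0.0, math.pi / 2))
            rows.append(
                {
                    "sample_id": f"P{p:02d}_I{i}",
                    "Q": math.sin(y) ** 2,
                    "population_id": f"P{p:02d}",
                    "latitude": float(lats[p]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Truth comparison
# ---------------------------------------------------------------------------


def _partition_string(dosage: Mapping[str, int], ploidy: int) -> str:
    vals = sorted((v for v in dosage.values() if v > 0), reverse=True)
    vals += [0] * (ploidy - len(vals))
    return ":".join(str(v) for v in vals)


@dataclass
class AccuracyReport:
    """Per-ploidy genotype accuracy and dosage confusion of a call set."""

    accuracy_by_ploidy: Dict[int, float]
    n_compared_by_ploidy: Dict[int, int]
    confusion: pd.DataFrame  # true partition x called partition counts
    ploidy_accuracy: Optional[float] = None


def truth_compare(
    calls: GenotypeMatrix,
    truth: SimTruth,
    ploidy_calls: Optional[Mapping[str, int]] = None,
) -> AccuracyReport:
    """Compare called genotypes (and optionally ploidies) against truth.

    Accuracy is over non-missing calls; a call is correct only if the full
    allele -> copy-number map matches. The confusion matrix is keyed by
    dosage partition strings (e.g. "3:1:0:0" vs "2:2:0:0").
    """
    truth_loci = {ld.locus_id for ld in truth.locus_defs}
    if not set(calls.loci) <= truth_loci:
        raise ValueError("call matrix contains loci unknown to the simulation truth")
    correct: Dict[int, int] = {}
    total: Dict[int, int] = {}
    pairs: Dict[Tuple[str, str], int] = {}
    for s in calls.samples:
        k = truth.ploidy[s]
        for l in calls.loci:
            called = calls.get_call(s, l)
            if called is None:
                continue
            true = truth.genotypes[s][l]
            total[k] = total.get(k, 0) + 1
            if called == true:
                correct[k] = correct.get(k, 0) + 1
            key = (_partition_string(true, k), _partition_string(called, k))
            pairs[key] = pairs.get(key, 0) + 1
    acc = {k: correct.get(k, 0) / total[k] for k in total}
    if pairs:
        idx = sorted({a for a, _ in pairs})
        cols = sorted({b for _, b in pairs})
        confusion = pd.DataFrame(0, index=idx, columns=cols)
        for (a, b), n in pairs.items():
            confusion.loc[a, b] = n
    else:
        confusion = pd.DataFrame()
    ploidy_acc = None
    if ploidy_calls is not None:
        hits = [int(ploidy_calls.get(s) == truth.ploidy[s]) for s in ploidy_calls]
        ploidy_acc = float(np.mean(hits)) if hits else None
    return AccuracyReport(
        accuracy_by_ploidy=acc,
        n_compared_by_ploidy=total,
        confusion=confusion,
        ploidy_accuracy=ploidy_acc,
    )
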