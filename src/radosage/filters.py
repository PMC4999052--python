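"""The filtering cascade from raw variant records to the analysis matrix.

Canonical order (frozen in :func:`run_filter_cascade`): variant-type filter
and sample raw-read filter act upstream of genotyping; genotype-level
coverage gating (five reads per ploidy level to 200) happens inside the
genotyper and appears here only as missing calls. On the genotype matrix:
locus presence (>= 80% of samples) -> sample missingness (> 50% removed,
computed on that locus set) -> locus presence re-applied -> monomorphic
removal. Boundary conventions: "fewer than one million" strict, "> 50%
missing" strict, "at least 80% present" inclusive.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd

from .types import AlleleCounts, FilterReport, GenotypeMatrix, is_single_base_allele

__all__ = [
    "filter_variant_type",
    "filter_samples_raw_reads",
    "filter_sample_missingness",
    "filter_locus_presence",
    "drop_monomorphic",
    "classify_allelicity",
    "run_filter_cascade",
]


def filter_variant_type(
    records: Iterable[AlleleCounts],
) -> Tuple[List[AlleleCounts], FilterReport]:
    """Keep loci whose alleles are all single bases or the single-base deletion.

    The allele set of a locus is the union over all samples' records; a
    locus with any multi-base allele is dropped everywhere.
    """
    records = list(records)
    bad_loci = set()
    loci_seen: Dict[str, None] = {}
    for rec in records:
        loci_seen.setdefault(rec.locus_id, None)
        if not all(is_single_base_allele(a) for a in rec.alleles):
            bad_loci.add(rec.locus_id)
    kept = [r for r in records if r.locus_id not in bad_loci]
    report = FilterReport(
        stage="variant_type",
        items_in=len(loci_seen),
        items_out=len(loci_seen) - len(bad_loci),
        dropped_ids=sorted(bad_loci),
    )
    return kept, report


def filter_samples_raw_reads(
    meta: pd.DataFrame, min_reads: int = 1_000_000
) -> Tuple[List[str], FilterReport]:
    """Drop samples with fewer than ``min_reads`` raw reads (strict bound)."""
    if "raw_read_count" not in meta.columns or meta["raw_read_count"].isna().any():
        bad = (
            meta.loc[meta["raw_read_count"].isna(), "sample_id"].tolist()
            if "raw_read_count" in meta.columns
            else list(meta.get("sample_id", []))
        )
        raise ValueError(f"raw_read_count missing for samples: {bad}")
    keep_mask = meta["raw_read_count"] >= min_reads
    kept = meta.loc[keep_mask, "sample_id"].tolist()
    dropped = meta.loc[~keep_mask, "sample_id"].tolist()
    report = FilterReport(
        stage="sample_raw_reads",
        items_in=len(meta),
        items_out=len(kept),
        dropped_ids=dropped,
    )
    return kept, report


def filter_sample_missingness(
    matrix: GenotypeMatrix, max_missing: float = 0.5
) -> Tuple[GenotypeMatrix, FilterReport]:
    """Drop samples whose missing fraction is strictly above ``max_missing``.

    Missingness is computed on the locus set of the matrix passed in; in the
    canonical cascade that is the set of loci present in at least 80% of
    samples.
    """
    frac = matrix.missing_fraction_by_sample()
    keep = [s for s in matrix.samples if frac[s] <= max_missing]
    dropped = [s for s in matrix.samples if s not in set(keep)]
    out = matrix.subset(samples=keep)
    report = FilterReport(
        stage="sample_missingness",
        items_in=len(matrix.samples),
        items_out=len(keep),
        dropped_ids=dropped,
    )
    return out, report


def filter_locus_presence(
    matrix: GenotypeMatrix, min_presence: float = 0.8
) -> Tuple[GenotypeMatrix, FilterReport]:
    """Keep loci with non-missing calls in >= ``min_presence`` of samples (inclusive)."""
    frac = matrix.presence_fraction_by_locus()
    # tolerate float representation of e.g. 160/200 vs 0.8
    keep = [l for l in matrix.loci if frac[l] >= min_presence - 1e-12]
    dropped = [l for l in matrix.loci if frac[l] < min_presence - 1e-12]
    out = matrix.subset(loci=keep)
    report = FilterReport(
        stage="locus_presence",
        items_in=len(matrix.loci),
        items_out=len(keep),
        dropped_ids=dropped,
    )
    return out, report


def drop_monomorphic(matrix: GenotypeMatrix) -> Tuple[GenotypeMatrix, FilterReport]:
    """Remove loci where all non-missing calls carry a single allele."""
    dropped = [l for l in matrix.loci if len(matrix.alleles_at(l)) <= 1]
    keep = [l for l in matrix.loci if len(matrix.alleles_at(l)) > 1]
    out = matrix.subset(loci=keep)
    report = FilterReport(
        stage="monomorphic",
        items_in=len(matrix.loci),
        items_out=len(keep),
        dropped_ids=dropped,
    )
    return out, report


_ALLELICITY_NAMES = {1: "monomorphic", 2: "biallelic", 3: "triallelic", 4: "tetra-allelic"}


def classify_allelicity(matrix: GenotypeMatrix) -> Tuple[pd.Series, Dict[str, int]]:
    """Per-locus allelicity category and category counts.

    The category is the number of distinct alleles across all non-missing
    calls at the locus.
    """
    cats = {}
    for l in matrix.loci:
        n = len(matrix.alleles_at(l))
        cats[l] = _ALLELICITY_NAMES.get(n, f"{n}-allelic")
    series = pd.Series(cats, name="allelicity")
    counts: Dict[str, int] = series.value_counts().to_dict()
    return series, counts


def run_filter_cascade(
    matrix: GenotypeMatrix,
    min_presence: float = 0.8,
    max_missing: float = 0.5,
) -> Tuple[GenotypeMatrix, List[FilterReport]]:
    """Apply the canonical matrix-level cascade and report every stage.

    Order: locus presence -> sample missingness (on that locus set) -> locus
    presence re-applied on the reduced sample set -> monomorphic removal.
    """
    reports: List[FilterReport] = []
    matrix, rep = filter_locus_presence(matrix, min_presence)
    reports.append(rep)
    matrix, rep = filter_sample_missingness(matrix, max_missing)
    reports.append(rep)
    matrix, rep = filter_locus_presence(matrix, min_presence)
    rep.stage = "locus_presence_reapplied"
    reports.append(rep)
    matrix, rep = drop_monomorphic(matrix)
    reports.append(rep)
    return matrix, reports
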