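"""Core containers shared across the toolkit.

The central objects are :class:`AlleleCounts` (one sample at one variant
position: which alleles were seen, how many reads support each, and the mean
phred base quality of those reads) and :class:`GenotypeMatrix` (the samples x
loci collection of allele-dosage calls with per-sample ploidy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

#: Missing-data code used in STRUCTURE exports.
STRUCTURE_MISSING = -9

#: Symbol used for a single-base deletion allele.
DELETION = "-"

_VALID_ALLELES = frozenset("ACGT") | {DELETION}


def is_single_base_allele(label: str) -> bool:
    """True for A/C/G/T or the single-base deletion symbol ``-``."""
    return label in _VALID_ALLELES


@dataclass(frozen=True)
class AlleleCounts:
    """Observed allele read counts for one sample at one locus.

    Parameters
    ----------
    sample_id, locus_id
        Identifiers; ``locus_id`` is ``contig:pos`` with a 1-based position.
    alleles
        Ordered allele labels (reference first when known). Single bases or
        ``-`` for a single-base deletion.
    counts
        Read count per allele, aligned with ``alleles``. Zero counts are kept
        (they matter for downstream sorting).
    mean_phred
        Mean phred base quality of the reads supporting each allele.
    """

    sample_id: str
    locus_id: str
    alleles: Tuple[str, ...]
    counts: Tuple[int, ...]
    mean_phred: Tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.alleles) == len(self.counts) == len(self.mean_phred)):
            raise ValueError(
                f"{self.locus_id}: alleles, counts and mean_phred must have equal length"
            )
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"{self.locus_id}: duplicate allele labels")
        if any(c < 0 for c in self.counts):
            raise ValueError(f"{self.locus_id}: negative read count")
        if any(q < 0 for q in self.mean_phred):
            raise ValueError(f"{self.locus_id}: negative phred quality")
        if sum(self.counts) == 0:
            raise ValueError(f"{self.locus_id}: record with no supporting reads")

    @property
    def total(self) -> int:
        """Total read depth at the locus."""
        return int(sum(self.counts))

    def observed(self) -> List[Tuple[str, int, float]]:
        """(allele, count, phred) triples for alleles with at least one read,
        in the original listed order."""
        return [
            (a, c, q)
            for a, c, q in zip(self.alleles, self.counts, self.mean_phred)
            if c > 0
        ]


def make_allele_counts(
    sample_id: str,
    locus_id: str,
    alleles: Sequence[str],
    counts: Sequence[int],
    mean_phred: Sequence[float],
) -> AlleleCounts:
    return AlleleCounts(
        sample_id=sample_id,
        locus_id=locus_id,
        alleles=tuple(str(a) for a in alleles),
        counts=tuple(int(c) for c in counts),
        mean_phred=tuple(float(q) for q in mean_phred),
    )


REQUIRED_META_COLUMNS = (
    "sample_id",
    "species_label",
    "population_id",
    "latitude",
    "raw_read_count",
)


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample metadata table.

    Requires columns sample_id, species_label, population_id, latitude and
    raw_read_count; sample ids must be unique and latitudes within ±90.
    """
    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata is missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    lat = meta["latitude"].astype(float)
    if ((lat < -90) | (lat > 90)).any():
        raise ValueError("latitude outside [-90, 90]")
    return meta


Dosage = Dict[str, int]  # allele label -> copy number


class GenotypeMatrix:
    """Samples x loci collection of allele-dosage genotype calls.

    Each non-missing cell is a mapping ``allele -> copy number`` whose copy
    numbers sum to the sample's ploidy. Missing cells are ``None``.
    """

    def __init__(
        self,
        samples: Sequence[str],
        loci: Sequence[str],
        ploidy: Mapping[str, int],
        calls: Optional[Mapping[str, Mapping[str, Dosage]]] = None,
    ) -> None:
        self.samples: List[str] = list(samples)
        self.loci: List[str] = list(loci)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate locus ids")
        self.ploidy: Dict[str, int] = {s: int(ploidy[s]) for s in self.samples}
        self._calls: Dict[str, Dict[str, Dosage]] = {s: {} for s in self.samples}
        if calls:
            for s, per_locus in calls.items():
                for l, dosage in per_locus.items():
                    self.set_call(s, l, dosage)

    # -- mutation ---------------------------------------------------------
    def set_call(self, sample: str, locus: str, dosage: Optional[Dosage]) -> None:
        if sample not in self._calls:
            raise KeyError(f"unknown sample {sample!r}")
        if locus not in self._locus_set():
            raise KeyError(f"unknown locus {locus!r}")
        if dosage is None:
            self._calls[sample].pop(locus, None)
            return
        total = sum(dosage.values())
        if total != self.ploidy[sample]:
            raise ValueError(
                f"{sample}@{locus}: dosage sums to {total}, ploidy is {self.ploidy[sample]}"
            )
        self._calls[sample][locus] = {str(a): int(c) for a, c in dosage.items() if c > 0}

    def _locus_set(self) -> set:
        cached = getattr(self, "_locus_set_cache", None)
        if cached is None or len(cached) != len(self.loci):
            cached = set(self.loci)
            self._locus_set_cache = cached
        return cached

    # -- access -----------------------------------------------------------
    def get_call(self, sample: str, locus: str) -> Optional[Dosage]:
        return self._calls[sample].get(locus)

    def is_missing(self, sample: str, locus: str) -> bool:
        return locus not in self._calls[sample]

    def missing_fraction_by_sample(self) -> pd.Series:
        n = len(self.loci)
        return pd.Series(
            {s: 1.0 - len(self._calls[s]) / n if n else np.nan for s in self.samples},
            name="missing_fraction",
        )

    def missing_fraction_by_locus(self) -> pd.Series:
        present = {l: 0 for l in self.loci}
        for s in self.samples:
            for l in self._calls[s]:
                present[l] += 1
        n = len(self.samples)
        return pd.Series(
            {l: 1.0 - present[l] / n if n else np.nan for l in self.loci},
            name="missing_fraction",
        )

    def presence_fraction_by_locus(self) -> pd.Series:
        return (1.0 - self.missing_fraction_by_locus()).rename("presence_fraction")

    def alleles_at(self, locus: str) -> List[str]:
        """Sorted distinct alleles with copy number >= 1 across non-missing calls."""
        seen = set()
        for s in self.samples:
            call = self._calls[s].get(locus)
            if call:
                seen.update(call.keys())
        return sorted(seen)

    def subset(
        self,
        samples: Optional[Iterable[str]] = None,
        loci: Optional[Iterable[str]] = None,
    ) -> "GenotypeMatrix":
        keep_s = list(samples) if samples is not None else list(self.samples)
        keep_l = list(loci) if loci is not None else list(self.loci)
        keep_l_set = set(keep_l)
        out = GenotypeMatrix(keep_s, keep_l, {s: self.ploidy[s] for s in keep_s})
        for s in keep_s:
            for l, d in self._calls[s].items():
                if l in keep_l_set:
                    out._calls[s][l] = dict(d)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.loci == other.loci
            and self.ploidy == other.ploidy
            and self._calls == other._calls
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix({len(self.samples)} samples x {len(self.loci)} loci, "
            f"ploidies {sorted(set(self.ploidy.values()))})"
        )


@dataclass
class FilterReport:
    """Bookkeeping for one stage of the filtering cascade."""

    stage: str
    items_in: int
    items_out: int
    dropped_ids: Optional[List[str]] = None

    def __post_init__(self) -> None:
        if self.items_out > self.items_in:
            raise ValueError(f"{self.stage}: items_out > items_in")

    @property
    def n_dropped(self) -> int:
        return self.items_in - self.items_out

    def to_dict(self) -> dict:
        d = {"stage": self.stage, "items_in": self.items_in, "items_out": self.items_out}
        if self.dropped_ids is not None:
            d["dropped_ids"] = list(self.dropped_ids)
        return d
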