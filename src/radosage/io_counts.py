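"""Reading and writing allele read-count data and genotype matrices.

Inputs are VCF files carrying per-sample allele depths (``AD``; optional
per-allele mean qualities ``AQ``) or per-sample tab-separated variant tables
(one row per locus/allele pair). Outputs are an internal genotype-matrix TSV
with a per-sample ploidy header, and STRUCTURE-format exports with the
mixed-ploidy coding (every individual occupies four rows; a diploid's last
two rows carry the missing code).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import (
    DELETION,
    STRUCTURE_MISSING,
    AlleleCounts,
    GenotypeMatrix,
    is_single_base_allele,
    validate_sample_meta,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TableDialect",
    "read_vcf_allele_depths",
    "read_variant_table",
    "read_sample_metadata",
    "write_structure_file",
    "write_genotype_matrix",
    "read_genotype_matrix",
    "write_vcf_allele_depths",
]

DEFAULT_PHRED = 30.0  # typical Illumina base quality, used when AQ is absent

_MATRIX_MAGIC = "#radosage-genotype-matrix"
_MATRIX_VERSION = "v1"


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------


def _vcf_allele_labels(ref: str, alts: Sequence[str]) -> Optional[List[str]]:
    """Map VCF REF/ALT to single-character allele labels.

    SNVs map to their base; a single-base deletion (REF ``XY`` -> ALT ``X``)
    maps the reference allele to its polymorphic base and the deletion to
    ``-``. Insertions and multi-base events are not representable and return
    None (the site is skipped and counted by the caller).
    """
    if len(ref) == 1:
        labels = [ref]
        for alt in alts:
            if len(alt) == 1 and is_single_base_allele(alt):
                labels.append(alt)
            else:
                return None
        return labels
    if len(ref) == 2 and all(a == ref[0] for a in alts) and len(alts) >= 1:
        if all(len(a) == 1 for a in alts):
            return [ref[1]] + [DELETION] * len(alts)
    return None


def read_vcf_allele_depths(
    path,
    sample_subset: Optional[Sequence[str]] = None,
    default_phred: float = DEFAULT_PHRED,
) -> Iterator[AlleleCounts]:
    """Stream AlleleCounts from a VCF with per-sample AD annotations.

    One record is yielded per sample x variant site. Sites without usable
    depth information, and sites with alleles that cannot be expressed as a
    single base or single-base deletion, are skipped (counts are logged).
    Per-allele mean phred qualities are taken from an ``AQ`` FORMAT field
    when present, otherwise ``default_phred`` is used.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if sample_subset is not None:
        unknown = [s for s in sample_subset if s not in samples]
        if unknown:
            raise LookupError(f"samples not present in VCF: {unknown}")
        keep_idx = [samples.index(s) for s in sample_subset]
    else:
        keep_idx = list(range(len(samples)))

    n_bad_allele = 0
    n_no_depth = 0
    for variant in vcf:
        labels = _vcf_allele_labels(variant.REF, variant.ALT)
        if labels is None:
            n_bad_allele += 1
            continue
        ad = variant.format("AD")
        if ad is None:
            n_no_depth += 1
            continue
        try:
            aq = variant.format("AQ")
        except KeyError:  # AQ not declared in the header
            aq = None
        locus_id = f"{variant.CHROM}:{variant.POS}"
        for i in keep_idx:
            row = np.asarray(ad[i]).ravel()
            counts = np.where(row < 0, 0, row).astype(int)
            if counts.sum() == 0:
                continue
            if aq is not None:
                qrow = np.asarray(aq[i], dtype=float).ravel()
                phreds = np.where(np.isfinite(qrow) & (qrow >= 0), qrow, default_phred)
            else:
                phreds = np.full(len(labels), default_phred)
            yield AlleleCounts(
                sample_id=samples[i],
                locus_id=locus_id,
                alleles=tuple(labels),
                counts=tuple(int(c) for c in counts[: len(labels)]),
                mean_phred=tuple(float(q) for q in phreds[: len(labels)]),
            )
    if n_bad_allele:
        logger.warning("skipped %d sites with non-SNV/non-single-base-deletion alleles", n_bad_allele)
    if n_no_depth:
        logger.warning("skipped %d sites without AD depth information", n_no_depth)


# ---------------------------------------------------------------------------
# Tabular input (CLC-style per-sample variant tables)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TableDialect:
    """Column names and coordinate convention of a per-sample variant table."""

    locus_col: str = "locus"
    allele_col: str = "allele"
    count_col: str = "count"
    qual_col: str = "mean_qual"
    base: str = "1-based"  # or "0-based": positions converted on read

    def __post_init__(self) -> None:
        if self.base not in ("1-based", "0-based"):
            raise ValueError("base must be '1-based' or '0-based'")


def _convert_locus(locus: str, base: str) -> str:
    if base == "1-based":
        return locus
    contig, _, pos = locus.rpartition(":")
    return f"{contig}:{int(pos) + 1}"


def read_variant_table(
    path,
    dialect: TableDialect = TableDialect(),
    sample_id: Optional[str] = None,
) -> Iterator[AlleleCounts]:
    """Stream AlleleCounts from a tab-separated per-sample variant table.

    Rows are grouped by locus, preserving allele order as read. The sample
    id defaults to the file stem. Missing mandatory columns raise a schema
    error; negative counts a validation error.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    df = pd.read_csv(path, sep="\t", dtype={dialect.allele_col: str})
    needed = [dialect.locus_col, dialect.allele_col, dialect.count_col, dialect.qual_col]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: variant table is missing columns {missing}")
    if df.empty:
        return
    if (df[dialect.count_col] < 0).any():
        raise ValueError(f"{path}: negative read counts in table")
    n_bad_allele = 0
    for locus, group in df.groupby(dialect.locus_col, sort=False):
        alleles = [str(a) for a in group[dialect.allele_col]]
        if not all(is_single_base_allele(a) for a in alleles):
            n_bad_allele += 1
            continue
        counts = [int(c) for c in group[dialect.count_col]]
        if sum(counts) == 0:
            continue
        yield AlleleCounts(
            sample_id=sample_id,
            locus_id=_convert_locus(str(locus), dialect.base),
            alleles=tuple(alleles),
            counts=tuple(counts),
            mean_phred=tuple(float(q) for q in group[dialect.qual_col]),
        )
    if n_bad_allele:
        logger.warning("%s: skipped %d loci with multi-base alleles", path, n_bad_allele)


def read_sample_metadata(path) -> pd.DataFrame:
    """Read and validate a tab-separated sample metadata table."""
    return validate_sample_meta(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# STRUCTURE export
# ---------------------------------------------------------------------------


def write_structure_file(
    matrix: GenotypeMatrix,
    meta: Optional[pd.DataFrame] = None,
    path=None,
) -> None:
    """Write a STRUCTURE input file with mixed-ploidy coding.

    Every individual occupies exactly four rows: a tetraploid's four allele
    copies fill all rows, a triploid fills rows 1-3, and a diploid's two
    copies fill rows 1-2 with rows 3-4 carrying the missing code (-9), so
    diploids are coded as if tetraploid. Missing calls are -9 in all rows.
    Allele codes are 1-based integers assigned by allele sort order per
    locus; multi-allelic loci are recoded the same way.
    """
    if any(k > 4 for k in matrix.ploidy.values()):
        bad = [s for s, k in matrix.ploidy.items() if k > 4]
        raise ValueError(f"STRUCTURE export supports ploidy <= 4; offending samples: {bad}")
    codes: Dict[str, Dict[str, int]] = {
        l: {a: i + 1 for i, a in enumerate(matrix.alleles_at(l))} for l in matrix.loci
    }
    pop_of: Dict[str, str] = {}
    if meta is not None:
        pop_of = dict(zip(meta["sample_id"], meta["population_id"].astype(str)))
    with open(path, "w") as fh:
        fh.write("\t".join(matrix.loci) + "\n")
        for s in matrix.samples:
            rows: List[List[int]] = [[], [], [], []]
            for l in matrix.loci:
                call = matrix.get_call(s, l)
                if call is None:
                    col = [STRUCTURE_MISSING] * 4
                else:
                    col = []
                    for a in sorted(call):
                        col.extend([codes[l][a]] * call[a])
                    col += [STRUCTURE_MISSING] * (4 - len(col))
                for r in range(4):
                    rows[r].append(col[r])
            pop = pop_of.get(s, "1")
            for r in range(4):
                fh.write("\t".join([s, pop] + [str(v) for v in rows[r]]) + "\n")


# ---------------------------------------------------------------------------
# Genotype matrix TSV
# ---------------------------------------------------------------------------


def _format_dosage(dosage: Optional[Mapping[str, int]]) -> str:
    if dosage is None:
        return "."
    return ",".join(f"{a}:{dosage[a]}" for a in sorted(dosage))


def _parse_dosage(cell: str) -> Optional[Dict[str, int]]:
    if cell == ".":
        return None
    out: Dict[str, int] = {}
    for part in cell.split(","):
        a, _, c = part.partition(":")
        out[a] = int(c)
    return out


def write_genotype_matrix(matrix: GenotypeMatrix, path) -> None:
    """Write the internal genotype-matrix TSV (loci as rows, samples as columns)."""
    with open(path, "w") as fh:
        fh.write(f"{_MATRIX_MAGIC}\t{_MATRIX_VERSION}\n")
        fh.write("#ploidy\t" + "\t".join(f"{s}={matrix.ploidy[s]}" for s in matrix.samples) + "\n")
        fh.write("locus\t" + "\t".join(matrix.samples) + "\n")
        for l in matrix.loci:
            cells = [_format_dosage(matrix.get_call(s, l)) for s in matrix.samples]
            fh.write("\t".join([l] + cells) + "\n")


def read_genotype_matrix(path) -> GenotypeMatrix:
    """Read a genotype-matrix TSV written by :func:`write_genotype_matrix`."""
    with open(path) as fh:
        magic = fh.readline().rstrip("\n").split("\t")
        if len(magic) != 2 or magic[0] != _MATRIX_MAGIC or magic[1] != _MATRIX_VERSION:
            raise ValueError(
                f"{path}: not a {_MATRIX_MAGIC} {_MATRIX_VERSION} file (got {magic})"
            )
        ploidy_line = fh.readline().rstrip("\n").split("\t")
        if ploidy_line[0] != "#ploidy":
            raise ValueError(f"{path}: missing #ploidy header line")
        ploidy: Dict[str, int] = {}
        for item in ploidy_line[1:]:
            s, _, k = item.partition("=")
            ploidy[s] = int(k)
        header = fh.readline().rstrip("\n").split("\t")
        samples = header[1:]
        loci: List[str] = []
        cells: List[List[str]] = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            loci.append(parts[0])
            cells.append(parts[1:])
    matrix = GenotypeMatrix(samples, loci, ploidy)
    for row, l in zip(cells, loci):
        for s, cell in zip(samples, row):
            matrix.set_call(s, l, _parse_dosage(cell))
    return matrix


# ---------------------------------------------------------------------------
# VCF output (for the simulator and format conversion)
# ---------------------------------------------------------------------------


def write_vcf_allele_depths(
    counts: Mapping[str, Sequence[AlleleCounts]],
    locus_defs,
    path,
) -> None:
    """Write a multi-sample VCF with AD (depths) and AQ (mean phred) fields.

    ``counts`` maps sample -> records; ``locus_defs`` fixes the reference
    allele and locus order. Site ALT alleles are the union of non-reference
    alleles observed in any sample.
    """
    import pysam

    samples = list(counts)
    by_sample: Dict[str, Dict[str, AlleleCounts]] = {
        s: {r.locus_id: r for r in recs} for s, recs in counts.items()
    }
    contigs: Dict[str, int] = {}
    for ld in locus_defs:
        contig, _, pos = ld.locus_id.rpartition(":")
        contigs[contig] = max(contigs.get(contig, 0), int(pos))

    header = pysam.VariantHeader()
    for contig, length in contigs.items():
        header.contigs.add(contig, length=length + 1)
    header.formats.add("AD", "R", "Integer", "Read depth for each allele")
    header.formats.add("AQ", "R", "Float", "Mean phred base quality for each allele")
    for s in samples:
        header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for ld in locus_defs:
            contig, _, pos = ld.locus_id.rpartition(":")
            ref = ld.alleles[0]
            site_alleles = list(ld.alleles)
            for s in samples:
                rec = by_sample[s].get(ld.locus_id)
                if rec is None:
                    continue
                for a in rec.alleles:
                    if a not in site_alleles:
                        site_alleles.append(a)
            out = vf.new_record(
                contig=contig, start=int(pos) - 1, alleles=tuple(site_alleles)
            )
            for s in samples:
                rec = by_sample[s].get(ld.locus_id)
                ad = [0] * len(site_alleles)
                aq = [DEFAULT_PHRED] * len(site_alleles)
                if rec is not None:
                    for a, c, q in zip(rec.alleles, rec.counts, rec.mean_phred):
                        j = site_alleles.index(a)
                        ad[j] = int(c)
                        aq[j] = float(q)
                out.samples[s]["AD"] = tuple(ad)
                out.samples[s]["AQ"] = tuple(aq)
            vf.write(out)
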