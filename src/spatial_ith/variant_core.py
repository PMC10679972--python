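"""Multi-region somatic mutation tables: I/O, filtering and genomic biomarkers.

A *mutation key* is the tuple (chrom, pos, ref, alt).  A *sample* is one
(patient, region) pair; the three tumour regions profiled per patient are
the superficial primary (PT_sup), deep primary (PT_deep) and lymph-node
metastasis (LN_met), with the matched normal serving only as the
phylogenetic outgroup.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

REGIONS = ("PT_sup", "PT_deep", "LN_met")
OUTGROUP = "normal"

VARIANT_CLASSES = (
    "missense",
    "nonsense",
    "frameshift",
    "splice",
    "silent",
    "inframe_indel",
    "other",
)

#: non-silent convention: every class except silent counts toward gene
#: frequencies and burden
NON_SILENT = tuple(c for c in VARIANT_CLASSES if c != "silent")

_REQUIRED_COLUMNS = (
    "patient_id",
    "region",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "variant_class",
    "vaf",
    "depth",
)
_OPTIONAL_COLUMNS = ("tri_context", "sift", "polyphen")


class FormatError(ValueError):
    """A table does not conform to the expected layout."""


class ValidationError(ValueError):
    """A field value violates its invariant."""


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant observed in one region of one patient."""

    patient_id: str
    region: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    variant_class: str
    vaf: float
    depth: int
    tri_context: Optional[str] = None
    sift: Optional[float] = None
    polyphen: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValidationError(f"vaf {self.vaf} outside [0, 1]")
        if self.depth < 0:
            raise ValidationError(f"depth {self.depth} negative")
        if self.pos < 1:
            raise ValidationError(f"pos {self.pos} must be 1-based")
        if self.ref == self.alt:
            raise ValidationError("ref equals alt")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValidationError(f"unknown variant_class {self.variant_class!r}")
        if (
            self.tri_context is not None
            and self.is_snv
            and (len(self.tri_context) != 3 or self.tri_context[1] != self.ref)
        ):
            raise ValidationError(
                f"tri_context {self.tri_context!r} middle base must equal ref {self.ref!r}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_silent(self) -> bool:
        return self.variant_class == "silent"


@dataclass
class BinaryCharacterMatrix:
    """Regions x mutations presence matrix plus an all-zero outgroup row.

    Rows (taxa) are region labels with ``normal`` last; columns are
    mutation keys; entries are 0/1 presence calls.
    """

    taxa: list[str]
    characters: list[tuple[str, int, str, str]]
    values: np.ndarray  # taxa x characters, dtype uint8

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.taxa), len(self.characters)):
            raise ValueError("matrix shape does not match taxa/characters")
        if OUTGROUP in self.taxa:
            if self.values[self.taxa.index(OUTGROUP)].any():
                raise ValueError("outgroup row must be all zeros")
        if self.characters and (self.values.sum(axis=0) == 0).any():
            raise ValueError("all-zero character column")

    @property
    def tumor_taxa(self) -> list[str]:
        return [t for t in self.taxa if t != OUTGROUP]

    def presence(self, key: tuple[str, int, str, str]) -> frozenset[str]:
        j = self.characters.index(key)
        return frozenset(
            t for i, t in enumerate(self.taxa) if self.values[i, j] and t != OUTGROUP
        )


@dataclass
class RegionPartition:
    """Counts of mutation keys by the exact region subset carrying them."""

    subset_counts: dict[frozenset[str], int]
    total: int

    @property
    def unique_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for subset, n in self.subset_counts.items():
            if len(subset) == 1:
                (r,) = subset
                out[r] = n
        return out

    @property
    def unique_fractions(self) -> dict[str, float]:
        return {r: n / self.total for r, n in self.unique_counts.items()}


@dataclass
class BiomarkerProfile:
    """TMB / TNB / MSI values with their categorical grades."""

    tmb: Optional[float] = None
    tmb_class: Optional[str] = None
    tnb: Optional[float] = None
    tnb_class: Optional[str] = None
    msi_score: Optional[float] = None
    msi_class: Optional[str] = None


@dataclass
class FilterReport:
    """Bookkeeping for filter_somatic: records removed per reason."""

    n_input: int
    n_retained: int
    n_low_vaf: int
    n_low_depth: int


# ---------------------------------------------------------------------------
# I/O


def _record_from_row(row: Mapping, line: int) -> MutationRecord:
    def _opt_float(v):
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
            return None
        return float(v)

    tri = row.get("tri_context")
    if tri is not None and (tri == "" or (isinstance(tri, float) and np.isnan(tri))):
        tri = None
    vaf = float(row["vaf"])
    if not 0.0 <= vaf <= 1.0:
        raise ValidationError(f"line {line}: VAF {vaf} outside [0, 1]")
    return MutationRecord(
        patient_id=str(row["patient_id"]),
        region=str(row["region"]),
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        ref=str(row["ref"]),
        alt=str(row["alt"]),
        gene=str(row["gene"]),
        variant_class=str(row["variant_class"]),
        vaf=vaf,
        depth=int(row["depth"]),
        tri_context=None if tri is None else str(tri),
        sift=_opt_float(row.get("sift")),
        polyphen=_opt_float(row.get("polyphen")),
    )


def read_mutation_table(path: str | Path, dialect: str = "tsv") -> list[MutationRecord]:
    """Read a mutation table (TSV or VCF) into MutationRecords.

    The TSV dialect is a UTF-8 headered table with the columns
    patient_id, region, chrom, pos, ref, alt, gene, variant_class, vaf,
    depth and optional tri_context/sift/polyphen.  The VCF dialect maps
    per-sample ``AF``->vaf and ``DP``->depth, takes gene/class from the
    ``GENE``/``CLASS`` INFO fields and patient/region from the sample name
    ``<patient>:<region>``.  Output order is deterministic (file order).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        return [
            _record_from_row(row, line=i + 2)  # +2: header + 1-based
            for i, row in enumerate(df.to_dict("records"))
        ]
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_vcf(path: Path) -> list[MutationRecord]:
    import pysam

    records: list[MutationRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            gene = rec.info.get("GENE", "NA")
            vclass = rec.info.get("CLASS", "other")
            if isinstance(gene, tuple):
                gene = gene[0]
            if isinstance(vclass, tuple):
                vclass = vclass[0]
            for sample_name, sample in rec.samples.items():
                af = sample.get("AF")
                dp = sample.get("DP")
                if af is None or dp is None:
                    continue
                if isinstance(af, tuple):
                    af = af[0]
                patient, _, region = sample_name.partition(":")
                for alt in rec.alts or ():
                    records.append(
                        MutationRecord(
                            patient_id=patient,
                            region=region or patient,
                            chrom=str(rec.chrom),
                            pos=int(rec.pos),
                            ref=str(rec.ref),
                            alt=str(alt),
                            gene=str(gene),
                            variant_class=str(vclass),
                            vaf=float(af),
                            depth=int(dp),
                        )
                    )
    return records


def records_to_frame(records: Iterable[MutationRecord]) -> pd.DataFrame:
    """Tabular view of records (column order = TSV dialect)."""
    rows = [
        {
            "patient_id": r.patient_id,
            "region": r.region,
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "gene": r.gene,
            "variant_class": r.variant_class,
            "vaf": r.vaf,
            "depth": r.depth,
            "tri_context": r.tri_context,
            "sift": r.sift,
            "polyphen": r.polyphen,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS) + list(_OPTIONAL_COLUMNS))


# ---------------------------------------------------------------------------
# Filtering and partitioning


def filter_somatic(
    records: Sequence[MutationRecord],
    min_vaf: float = 0.02,
    min_depth: int = 10,
) -> tuple[list[MutationRecord], FilterReport]:
    """Apply the somatic quality gates: VAF and total read coverage.

    Exclusion is strict-less on both gates: a record is removed iff
    vaf < min_vaf or depth < min_depth, so records sitting exactly on a
    threshold are retained.
    """
    if min_vaf < 0 or min_depth < 0:
        raise ValueError("thresholds must be nonnegative")
    kept: list[MutationRecord] = []
    n_low_vaf = n_low_depth = 0
    for r in records:
        low_vaf = r.vaf < min_vaf
        low_depth = r.depth < min_depth
        if low_vaf:
            n_low_vaf += 1
        if low_depth:
            n_low_depth += 1
        if not (low_vaf or low_depth):
            kept.append(r)
    report = FilterReport(
        n_input=len(records),
        n_retained=len(kept),
        n_low_vaf=n_low_vaf,
        n_low_depth=n_low_depth,
    )
    return kept, report


def build_presence_matrix(
    records: Sequence[MutationRecord], key: str = "variant"
) -> BinaryCharacterMatrix:
    """Region x mutation presence matrix for one patient, plus outgroup.

    ``key='variant'`` (default) identifies mutations by (chrom, pos, ref,
    alt) as the phylogeny requires; ``key='gene'`` collapses to gene
    symbols for gene-level Venn summaries.  Duplicate observations of one
    key within a region are deduplicated with a warning.
    """
    if not records:
        raise ValueError("no mutations")
    patients = {r.patient_id for r in records}
    if len(patients) > 1:
        raise ValueError(f"records span multiple patients: {sorted(patients)}")
    if key not in ("variant", "gene"):
        raise ValueError("key must be 'variant' or 'gene'")

    regions = [r for r in REGIONS if any(m.region == r for m in records)]
    extra = sorted({m.region for m in records} - set(regions) - {OUTGROUP})
    regions += extra

    seen: set[tuple] = set()
    keys: list = []
    presence: dict[tuple, set[str]] = {}
    dup = 0
    for m in records:
        k = m.key if key == "variant" else (m.gene,)
        if (k, m.region) in seen:
            dup += 1
        seen.add((k, m.region))
        if k not in presence:
            presence[k] = set()
            keys.append(k)
        presence[k].add(m.region)
    if dup:
        warnings.warn(f"{dup} duplicate key/region observation(s) deduplicated")

    taxa = regions + [OUTGROUP]
    values = np.zeros((len(taxa), len(keys)), dtype=np.uint8)
    for j, k in enumerate(keys):
        for r in presence[k]:
            values[taxa.index(r), j] = 1
    chars = keys if key == "variant" else [(g, 0, "", "gene") for (g,) in keys]
    return BinaryCharacterMatrix(taxa=taxa, characters=chars, values=values)


def partition_regions(matrix: BinaryCharacterMatrix) -> RegionPartition:
    """Tabulate mutation keys by the exact subset of regions carrying them."""
    tumor = matrix.tumor_taxa
    if len(tumor) < 2:
        raise ValueError("partition requires at least 2 tumor regions")
    idx = [matrix.taxa.index(t) for t in tumor]
    sub = matrix.values[idx, :]
    if (sub.sum(axis=0) == 0).any():
        raise ValueError("cannot partition an absent mutation (all-zero row)")
    counts: dict[frozenset[str], int] = {}
    for j in range(sub.shape[1]):
        subset = frozenset(t for i, t in enumerate(tumor) if sub[i, j])
        counts[subset] = counts.get(subset, 0) + 1
    return RegionPartition(subset_counts=counts, total=sub.shape[1])


def gene_frequency(
    records: Sequence[MutationRecord], top_n: int
) -> pd.DataFrame:
    """Fraction of (patient, region) samples with >= 1 non-silent mutation per gene.

    Sorted by descending frequency, ties broken alphabetically, truncated
    to ``top_n`` genes.  Columns: gene, n_samples, fraction.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    samples = {(r.patient_id, r.region) for r in records}
    n_samples = len(samples)
    carriers: dict[str, set] = {}
    for r in records:
        if r.variant_class in NON_SILENT:
            carriers.setdefault(r.gene, set()).add((r.patient_id, r.region))
    rows = [
        {"gene": g, "n_samples": len(s), "fraction": len(s) / n_samples}
        for g, s in carriers.items()
    ]
    df = pd.DataFrame(rows, columns=["gene", "n_samples", "fraction"])
    df = df.sort_values(
        ["fraction", "gene"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return df.head(top_n)


# ---------------------------------------------------------------------------
# Genomic biomarker grading


def classify_tmb(n_nonsynonymous: int, capture_mb: float = 40.0) -> BiomarkerProfile:
    """Tumour mutational burden per Mb, graded H (> 10) / M ([2.5, 10]) / L (< 2.5)."""
    if capture_mb <= 0:
        raise ValueError("capture_mb must be positive")
    tmb = n_nonsynonymous / capture_mb
    if tmb > 10:
        cls = "TMB-H"
    elif tmb >= 2.5:
        cls = "TMB-M"
    else:
        cls = "TMB-L"
    return BiomarkerProfile(tmb=tmb, tmb_class=cls)


def classify_tnb(n_neoantigenic: int, capture_mb: float = 40.0) -> BiomarkerProfile:
    """Tumour neoantigen burden per Mb, graded H (> 4.5) / M ([.5, 4.5]) / L (< .5)."""
    if capture_mb <= 0:
        raise ValueError("capture_mb must be positive")
    tnb = n_neoantigenic / capture_mb
    if tnb > 4.5:
        cls = "TNB-H"
    elif tnb >= 0.5:
        cls = "TNB-M"
    else:
        cls = "TNB-L"
    return BiomarkerProfile(tnb=tnb, tnb_class=cls)


def classify_msi(msi_score: float) -> str:
    """MSI grade from the percentage of unstable loci: MSI-H iff score >= 20."""
    if not 0 <= msi_score <= 100:
        raise ValidationError(f"MSI score {msi_score} outside [0, 100]")
    return "MSI-H" if msi_score >= 20 else "MSS"
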