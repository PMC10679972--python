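"""Rule-based putative driver mutation calling.

A non-silent variant in a curated driver gene is a putative driver if
either of two criteria holds:

(a) catalogue evidence — the exact mutation, the identical genomic site,
    or at least three catalogue entries within a closed +/- 15 bp window
    on the same chromosome;
(b) deleteriousness — the gene is annotated recessive, the variant is a
    truncating class (nonsense / frameshift / splice) and SIFT < .05 or
    PolyPhen > .995.

Criterion (a) takes precedence when both fire.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .variant_core import MutationRecord

__all__ = [
    "CosmicCatalogue",
    "DriverCall",
    "match_catalogue",
    "classify_driver",
    "classify_drivers",
    "read_catalogue",
    "read_gene_list",
]

WINDOW_BP = 15
MIN_WINDOW_HITS = 3
SIFT_MAX = 0.05
POLYPHEN_MIN = 0.995
TRUNCATING_CLASSES = frozenset({"nonsense", "frameshift", "splice"})


@dataclass
class CosmicCatalogue:
    """COSMIC-style catalogue of known somatic mutations with gene roles."""

    entries: list[tuple[str, str, int, str, str]]  # (gene, chrom, pos, ref, alt)
    gene_roles: dict[str, str]  # gene -> recessive | dominant | unknown

    def __post_init__(self) -> None:
        if len(set(self.entries)) != len(self.entries):
            raise ValueError("catalogue entries must be unique")
        self._exact = {(c, p, r, a) for (_, c, p, r, a) in self.entries}
        self._sites = {(c, p) for (_, c, p, _, _) in self.entries}
        self._by_chrom: dict[str, list[int]] = {}
        for (_, c, p, _, _) in self.entries:
            self._by_chrom.setdefault(c, []).append(p)
        for positions in self._by_chrom.values():
            positions.sort()

    def role(self, gene: str) -> str:
        return self.gene_roles.get(gene, "unknown")


@dataclass(frozen=True)
class DriverCall:
    key: tuple[str, int, str, str]
    is_driver: bool
    criterion: str  # A_exact | A_site | A_window | B_deleterious | none

    def __post_init__(self) -> None:
        if self.is_driver != (self.criterion != "none"):
            raise ValueError("is_driver inconsistent with criterion")


def match_catalogue(m: MutationRecord, cat: CosmicCatalogue) -> str:
    """Catalogue evidence tier for one variant: A_exact, A_site, A_window or none."""
    if (m.chrom, m.pos, m.ref, m.alt) in cat._exact:
        return "A_exact"
    if (m.chrom, m.pos) in cat._sites:
        return "A_site"
    import bisect

    positions = cat._by_chrom.get(m.chrom, [])
    lo = bisect.bisect_left(positions, m.pos - WINDOW_BP)
    hi = bisect.bisect_right(positions, m.pos + WINDOW_BP)
    if hi - lo >= MIN_WINDOW_HITS:
        return "A_window"
    return "none"


def classify_driver(
    m: MutationRecord, cat: CosmicCatalogue, driver_genes: Iterable[str]
) -> DriverCall:
    """Apply the two-criterion driver rule to one mutation."""
    genes = set(driver_genes)
    if m.is_silent or m.gene not in genes:
        return DriverCall(key=m.key, is_driver=False, criterion="none")
    tier = match_catalogue(m, cat)
    if tier != "none":
        return DriverCall(key=m.key, is_driver=True, criterion=tier)
    role = cat.role(m.gene)
    if m.gene not in cat.gene_roles:
        warnings.warn(f"gene {m.gene} missing from role map; treated as unknown")
    if (
        role == "recessive"
        and m.variant_class in TRUNCATING_CLASSES
        and (
            (m.sift is not None and m.sift < SIFT_MAX)
            or (m.polyphen is not None and m.polyphen > POLYPHEN_MIN)
        )
    ):
        return DriverCall(key=m.key, is_driver=True, criterion="B_deleterious")
    return DriverCall(key=m.key, is_driver=False, criterion="none")


def classify_drivers(
    records: Sequence[MutationRecord],
    cat: CosmicCatalogue,
    driver_genes: Iterable[str],
) -> dict[tuple, DriverCall]:
    """Driver calls per distinct mutation key.

    A key observed in several regions is a driver if any of its
    observations satisfies a criterion (annotations are per-variant and
    should agree across regions).
    """
    genes = set(driver_genes)
    calls: dict[tuple, DriverCall] = {}
    for m in records:
        call = classify_driver(m, cat, genes)
        prev = calls.get(m.key)
        if prev is None or (call.is_driver and not prev.is_driver):
            calls[m.key] = call
    return calls


def read_catalogue(path: str | Path) -> CosmicCatalogue:
    """Catalogue TSV: gene, chrom, pos, ref, alt, role."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["gene", "chrom", "pos", "ref", "alt", "role"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    entries = [
        (str(r.gene), str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in df.itertuples()
    ]
    roles = {str(r.gene): str(r.role) for r in df.itertuples()}
    return CosmicCatalogue(entries=entries, gene_roles=roles)


def read_gene_list(path: str | Path) -> set[str]:
    """Driver gene list, one symbol per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
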