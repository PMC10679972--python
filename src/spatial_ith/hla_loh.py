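"""HLA class-I loss-of-heterozygosity grading and region association.

An allele is lost when its estimated copy number falls below 0.5 AND the
allelic imbalance between the two allele-specific coverage tracks is
significant at p < .01 (paired t-test); a sample is graded LOH when any
of its HLA-A/B/C alleles is lost, and a patient when any region-sample
is.  Association between region and LOH grade is tested with an exact
Fisher test over the regions x grade table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .stats import fisher_exact_rx2, paired_t_test

__all__ = [
    "HLAAlleleObservation",
    "paired_t_test",
    "call_allele_loh",
    "grade_sample",
    "grade_patients",
    "loh_region_association",
]

CN_CUTOFF = 0.5
P_CUTOFF = 0.01
LOCI = ("HLA-A", "HLA-B", "HLA-C")


@dataclass
class HLAAlleleObservation:
    """One HLA allele in one region-sample of one patient."""

    patient_id: str
    region: str
    locus: str
    allele: str
    copy_number: float
    imbalance_p: Optional[float] = None
    support_a: Optional[Sequence[float]] = None  # per-window coverage, allele 1
    support_b: Optional[Sequence[float]] = None  # per-window coverage, allele 2

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        if (self.support_a is None) != (self.support_b is None):
            raise ValueError("paired support tracks must both be present")
        if self.support_a is not None:
            if len(self.support_a) != len(self.support_b) or len(self.support_a) < 2:
                raise ValueError("paired tracks must be equal length >= 2")


def call_allele_loh(
    obs: HLAAlleleObservation,
    cn_cutoff: float = CN_CUTOFF,
    p_cutoff: float = P_CUTOFF,
) -> bool:
    """LOH iff copy number < cn_cutoff AND imbalance p < p_cutoff (both strict)."""
    if obs.imbalance_p is not None:
        p = obs.imbalance_p
    elif obs.support_a is not None:
        p = paired_t_test(obs.support_a, obs.support_b)
    else:
        raise ValueError(
            f"{obs.patient_id}/{obs.region}/{obs.allele}: no imbalance p-value "
            "and no paired support tracks"
        )
    return obs.copy_number < cn_cutoff and p < p_cutoff


def grade_sample(calls: Sequence[bool]) -> str:
    """'LOH' iff LOH was called for at least one allele of the sample."""
    if not calls:
        raise ValueError("need >= 1 allele call")
    return "LOH" if any(calls) else "non-LOH"


def grade_patients(grades: Mapping[tuple[str, str], str]) -> dict[str, str]:
    """Patient-level grade: LOH iff any region-sample of the patient is LOH."""
    out: dict[str, str] = {}
    for (patient, _region), grade in grades.items():
        if grade == "LOH" or patient not in out:
            out[patient] = grade if grade == "LOH" else out.get(patient, "non-LOH")
    return out


def loh_region_association(grades: Mapping[tuple[str, str], str]) -> float:
    """Exact Fisher p for the regions x {LOH, non-LOH} contingency table."""
    regions = sorted({r for (_, r) in grades})
    if len(regions) < 2:
        raise ValueError("need >= 2 regions")
    table = np.zeros((len(regions), 2), dtype=int)
    for (_, region), grade in grades.items():
        table[regions.index(region), 0 if grade == "LOH" else 1] += 1
    return fisher_exact_rx2(table)


def read_hla_table(path) -> list[HLAAlleleObservation]:
    """HLA observation TSV: patient_id, region, locus, allele, copy_number, imbalance_p."""
    df = pd.read_csv(path, sep="\t")
    required = ["patient_id", "region", "locus", "allele", "copy_number"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    obs = []
    for r in df.itertuples():
        p = getattr(r, "imbalance_p", None)
        if p is not None and pd.isna(p):
            p = None
        obs.append(
            HLAAlleleObservation(
                patient_id=str(r.patient_id),
                region=str(r.region),
                locus=str(r.locus),
                allele=str(r.allele),
                copy_number=float(r.copy_number),
                imbalance_p=None if p is None else float(p),
            )
        )
    return obs
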