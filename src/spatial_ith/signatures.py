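"""96-class trinucleotide mutation spectra and signature refitting.

SNVs are binned into the canonical 96 single-base-substitution classes:
six pyrimidine-centred substitutions (C>A, C>G, C>T, T>A, T>C, T>G) by
16 flanking-base contexts, with purine-reference mutations
reverse-complemented onto the pyrimidine strand.  Exposures to a given
signature matrix are refit by forward selection with non-negative
least-squares refinement, the convention used by refitting tools:
signatures enter one at a time while they reduce the squared
reconstruction error, weights below ``min_weight`` are dropped, and the
remainder renormalised to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .variant_core import MutationRecord

__all__ = [
    "SUBSTITUTIONS",
    "CONTEXT_LABELS",
    "Spectrum96",
    "SignatureMatrix",
    "ExposureVector",
    "build_spectrum",
    "fit_exposures",
    "dominant_signature",
    "read_signature_matrix",
]

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: canonical COSMIC ordering: substitution-major, then 5' flank, then 3' flank
CONTEXT_LABELS = tuple(
    f"{f5}[{sub}]{f3}" for sub in SUBSTITUTIONS for f5 in _BASES for f3 in _BASES
)
_LABEL_INDEX = {lab: i for i, lab in enumerate(CONTEXT_LABELS)}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def snv_class(ref: str, alt: str, tri_context: str) -> str:
    """Map one SNV to its pyrimidine-centred 96-class label."""
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError("not an SNV")
    if len(tri_context) != 3 or tri_context[1] != ref:
        raise ValueError(f"malformed tri_context {tri_context!r} for ref {ref!r}")
    if any(b not in _BASES for b in tri_context + alt):
        raise ValueError(f"non-ACGT base in {tri_context!r}>{alt!r}")
    if ref in "AG":  # purine reference: reverse-complement both strands
        tri_context = _revcomp(tri_context)
        ref = _COMPLEMENT[ref]
        alt = _COMPLEMENT[alt]
    label = f"{tri_context[0]}[{ref}>{alt}]{tri_context[2]}"
    return label


@dataclass
class Spectrum96:
    """Counts over the 96 trinucleotide substitution classes."""

    counts: np.ndarray  # length 96
    n_skipped: int = 0  # non-SNV records passed in and skipped

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have exactly 96 bins")
        if (self.counts < 0).any():
            raise ValueError("negative spectrum counts")

    @property
    def proportions(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("zero spectrum")
        return self.counts / total

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CONTEXT_LABELS))


@dataclass
class SignatureMatrix:
    """96 x S matrix of signature profiles; columns sum to one."""

    profiles: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.ndim != 2 or self.profiles.shape[0] != 96:
            raise ValueError("profiles must be 96 x S")
        if self.profiles.shape[1] != len(self.names):
            raise ValueError("names do not match columns")
        if (self.profiles < 0).any():
            raise ValueError("negative signature entries")
        sums = self.profiles.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("signature columns must sum to 1")


@dataclass
class ExposureVector:
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if self.weights:
            total = sum(self.weights.values())
            if abs(total - 1.0) > 1e-8 or any(w < 0 for w in self.weights.values()):
                raise ValueError("weights must be >= 0 and sum to 1")

    @property
    def dominant(self) -> str:
        return dominant_signature(self)


def build_spectrum(snvs: Sequence[MutationRecord]) -> Spectrum96:
    """Bin SNVs (with trinucleotide context) into the 96-class spectrum.

    Indels are skipped and counted in ``n_skipped``; SNVs lacking a
    context or with a malformed context raise.
    """
    counts = np.zeros(96)
    skipped = 0
    for m in snvs:
        if not m.is_snv:
            skipped += 1
            continue
        if m.tri_context is None:
            raise ValueError(f"SNV {m.key} lacks tri_context")
        counts[_LABEL_INDEX[snv_class(m.ref, m.alt, m.tri_context)]] += 1
    return Spectrum96(counts=counts, n_skipped=skipped)


def fit_exposures(
    spectrum: Spectrum96,
    sigs: SignatureMatrix,
    min_weight: float = 0.06,
    tol: float = 1e-4,
) -> ExposureVector:
    """Refit signature exposures by forward selection + NNLS refinement.

    Starting from the single best-fitting signature, signatures are added
    greedily while the non-negative least-squares reconstruction error of
    the selected subset improves by more than ``tol`` (relative).  Final
    weights below ``min_weight`` are dropped and the rest renormalised.
    Deterministic given its inputs.
    """
    target = spectrum.proportions  # raises on zero spectrum
    S = sigs.profiles.shape[1]
    selected: list[int] = []
    remaining = list(range(S))
    coef = np.zeros(0)
    best_err = float(np.sum(target**2))  # error of the empty model
    while remaining:
        trial_errs = []
        for j in remaining:
            cols = selected + [j]
            c, err = nnls(sigs.profiles[:, cols], target)
            trial_errs.append((err**2, j, c))
        err2, j, c = min(trial_errs, key=lambda t: (t[0], t[1]))
        if best_err - err2 <= tol * max(best_err, 1e-12):
            break
        selected.append(j)
        remaining.remove(j)
        coef = c
        best_err = err2
    if not selected:
        raise ValueError("no signature improves on the empty model")
    w = coef / coef.sum()
    keep = w >= min_weight
    if not keep.any():
        keep = w == w.max()
    w = np.where(keep, w, 0.0)
    w = w / w.sum()
    # weights keyed in signature-matrix column order so that the dominant
    # tie-break follows the canonical signature order
    pairs = sorted(
        ((sel, float(w[i])) for i, sel in enumerate(selected) if w[i] > 0)
    )
    weights = {sigs.names[sel]: wt for sel, wt in pairs}
    return ExposureVector(weights=weights)


def dominant_signature(exposures: ExposureVector) -> str:
    """Signature with the highest contribution; ties broken by insertion order."""
    if not exposures.weights:
        raise ValueError("empty exposure vector")
    best_name, best_w = None, -1.0
    for name, w in exposures.weights.items():
        if w > best_w + 1e-15:
            best_name, best_w = name, w
    return best_name


def read_signature_matrix(path: str | Path) -> SignatureMatrix:
    """Signature TSV: first column = 96 context labels (COSMIC order), then signatures."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(CONTEXT_LABELS):
        # accept any row order as long as the label set is complete
        if set(df.index) != set(CONTEXT_LABELS):
            raise ValueError("signature matrix must index all 96 context labels")
        df = df.loc[list(CONTEXT_LABELS)]
    return SignatureMatrix(profiles=df.to_numpy(), names=[str(c) for c in df.columns])
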