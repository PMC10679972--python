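"""GeoMx-style digital spatial profiling of protein counts.

Pipeline: AOI-level QC gating on scan metrics, technical normalisation
to the geometric mean of the three positive-control probes, conversion
to signal-to-background against the three IgG isotype controls,
simulated-bulk aggregation per sample, rank-sum differential testing
with BH correction, and marker-panel cell-abundance scores (mean log2
of the marker signals per cell type).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .stats import bh_adjust

__all__ = [
    "AOIRecord",
    "ProbePanel",
    "QCReport",
    "qc_filter",
    "control_normalize",
    "background_normalize",
    "simulated_bulk",
    "differential_proteins",
    "cell_abundance",
    "read_aoi_table",
    "read_panel",
]

FOV_MIN = 75.0  # AOIs with FOV detection <= 75% are eliminated
BD_MIN, BD_MAX = 0.1, 2.25  # binding density retained range (closed)
NUCLEI_MIN = 20  # nuclei > 20 ...
AREA_MIN = 1600.0  # ... or surface area > 1600 um^2

FC_CUTOFF = 1.5
FDR_CUTOFF = 0.05

_META_COLUMNS = (
    "patient_id",
    "region",
    "roi_id",
    "compartment",
    "fov_pct",
    "binding_density",
    "nuclei",
    "area_um2",
)


@dataclass
class AOIRecord:
    """One segmented area of interest with scan QC metrics and probe counts."""

    patient_id: str
    region: str
    roi_id: str
    compartment: str  # tumour | stroma
    fov_pct: float
    binding_density: float
    nuclei: int
    area_um2: float
    counts: dict[str, float]

    def __post_init__(self) -> None:
        if self.compartment not in ("tumour", "stroma"):
            raise ValueError(f"invalid compartment {self.compartment!r}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative probe count")
        for f in ("fov_pct", "binding_density", "nuclei", "area_um2"):
            v = getattr(self, f)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise ValueError(f"AOI {self.aoi_id}: missing QC field {f}")

    @property
    def aoi_id(self) -> str:
        return f"{self.patient_id}|{self.region}|{self.roi_id}|{self.compartment}"


@dataclass
class ProbePanel:
    """Target probes, control probes and the marker map for cell scoring."""

    targets: list[str]
    positive_controls: tuple[str, str, str] = ("S6", "Histone H3", "GAPDH")
    negative_controls: tuple[str, str, str] = ("Ms IgG1", "Ms IgG2a", "Rb IgG")
    marker_map: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        controls = set(self.positive_controls) | set(self.negative_controls)
        if controls & set(self.targets):
            raise ValueError("control probes must be disjoint from targets")
        for cell, probes in self.marker_map.items():
            unknown = set(probes) - set(self.targets)
            if unknown:
                raise ValueError(
                    f"marker map for {cell!r} references unknown probe(s): "
                    f"{sorted(unknown)}"
                )


@dataclass
class QCReport:
    n_input: int
    n_passed: int
    n_fail_fov: int
    n_fail_binding_density: int
    n_fail_nuclei_area: int


def _gm(values: Iterable[float]) -> float:
    arr = np.asarray(list(values), dtype=float)
    return float(np.exp(np.mean(np.log(arr))))


def qc_filter(aois: Sequence[AOIRecord]) -> tuple[list[AOIRecord], QCReport]:
    """Gate AOIs on scan quality.

    Pass iff FOV detection > 75% AND binding density in [.1, 2.25] AND
    (nuclei > 20 OR area > 1600 um^2).  The per-rule counts may sum to
    more than the number rejected: an AOI can fail several rules.
    """
    passed: list[AOIRecord] = []
    n_fov = n_bd = n_na = 0
    for a in aois:
        fail_fov = a.fov_pct <= FOV_MIN
        fail_bd = not (BD_MIN <= a.binding_density <= BD_MAX)
        fail_na = not (a.nuclei > NUCLEI_MIN or a.area_um2 > AREA_MIN)
        n_fov += fail_fov
        n_bd += fail_bd
        n_na += fail_na
        if not (fail_fov or fail_bd or fail_na):
            passed.append(a)
    report = QCReport(
        n_input=len(aois),
        n_passed=len(passed),
        n_fail_fov=n_fov,
        n_fail_binding_density=n_bd,
        n_fail_nuclei_area=n_na,
    )
    return passed, report


def _counts_frame(aois: Sequence[AOIRecord], probes: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(
        [[a.counts[p] for p in probes] for a in aois],
        index=[a.aoi_id for a in aois],
        columns=list(probes),
    )


def control_normalize(
    aois: Sequence[AOIRecord],
    panel: ProbePanel,
    reference: Optional[float] = None,
) -> pd.DataFrame:
    """Scale each AOI so positive-control geometric means are equal.

    The per-AOI factor is its positive-control geometric mean divided by
    a reference level — by default the cohort geometric mean of those
    per-AOI geometric means, or a fixed ``reference`` value; every
    target count is divided by its AOI's factor.  Returns an AOI x probe
    frame of normalised counts (controls included, equally scaled).
    With the cohort reference, relative expression between AOIs is what
    is preserved; a fixed reference additionally pins the absolute scale.
    """
    for a in aois:
        for c in panel.positive_controls:
            if a.counts.get(c, 0) <= 0:
                raise ValueError(f"AOI {a.aoi_id}: nonpositive control {c!r}")
    gms = np.array([_gm(a.counts[c] for c in panel.positive_controls) for a in aois])
    cohort = _gm(gms) if reference is None else float(reference)
    factors = gms / cohort
    probes = list(panel.targets) + list(panel.positive_controls) + list(
        panel.negative_controls
    )
    frame = _counts_frame(aois, probes)
    return frame.div(factors, axis=0)


def background_normalize(
    aois: Sequence[AOIRecord] | pd.DataFrame, panel: ProbePanel
) -> pd.DataFrame:
    """Signal-to-background: each target divided by the IgG geometric mean.

    Accepts raw AOIRecords or an already control-normalised frame.
    Returns an AOI x target frame of unitless signal-to-background
    ratios (log2 of which is the conventional SNR display scale).
    """
    if isinstance(aois, pd.DataFrame):
        frame = aois
    else:
        probes = list(panel.targets) + list(panel.negative_controls)
        frame = _counts_frame(aois, probes)
    igg = frame[list(panel.negative_controls)]
    if (igg <= 0).any().any():
        bad = igg.index[(igg <= 0).any(axis=1)][0]
        raise ValueError(f"AOI {bad}: nonpositive IgG count")
    gm = np.exp(np.log(igg).mean(axis=1))
    return frame[list(panel.targets)].div(gm, axis=0)


def simulated_bulk(
    values: pd.DataFrame,
    aois: Sequence[AOIRecord],
    compartment: Optional[str] = None,
) -> pd.DataFrame:
    """Arithmetic per-target mean over each sample's AOIs (simulated bulk).

    ``values`` is an AOI x target frame indexed by aoi_id; a sample is a
    (patient, region) pair; ``compartment`` restricts the stratum to
    tumour or stroma AOIs (default: all).  Samples with no AOI in the
    stratum are omitted with a warning.
    """
    by_id = {a.aoi_id: a for a in aois}
    rows = []
    index = []
    samples: dict[tuple[str, str], list[str]] = {}
    for aoi_id in values.index:
        a = by_id[aoi_id]
        if compartment is not None and a.compartment != compartment:
            continue
        samples.setdefault((a.patient_id, a.region), []).append(aoi_id)
    seen_samples = {(a.patient_id, a.region) for a in aois}
    empty = seen_samples - set(samples)
    if empty and compartment is not None:
        warnings.warn(
            f"{len(empty)} sample(s) have no {compartment} AOI; omitted"
        )
    for (patient, region), ids in samples.items():
        rows.append(values.loc[ids].mean(axis=0))
        index.append((patient, region))
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["patient_id", "region"])
    )


def differential_proteins(
    group_a: pd.DataFrame, group_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-protein differential expression between two observation groups.

    Fold change is mean(A)/mean(B) on the linear normalised scale,
    reported as log2 FC; p-values from the two-sided Wilcoxon rank-sum
    test, adjusted with Benjamini-Hochberg across proteins.  Significant
    iff FDR <= .05 and FC > 1.5 or FC < 1/1.5.  Columns: log2_fc, p,
    fdr, significant.
    """
    proteins = [p for p in group_a.columns if p in set(group_b.columns)]
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 observations")
    log2_fc = np.empty(len(proteins))
    pvals = np.empty(len(proteins))
    for i, prot in enumerate(proteins):
        a = group_a[prot].to_numpy(dtype=float)
        b = group_b[prot].to_numpy(dtype=float)
        log2_fc[i] = np.log2(a.mean() / b.mean())
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            pvals[i] = 1.0
        else:
            pvals[i] = _sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
    fdr = bh_adjust(pvals)
    fc = 2.0**log2_fc
    significant = (fdr <= FDR_CUTOFF) & ((fc > FC_CUTOFF) | (fc < 1.0 / FC_CUTOFF))
    return pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "p": pvals,
            "fdr": fdr,
            "significant": significant,
        },
        index=pd.Index(proteins, name="protein"),
    )


def cell_abundance(values: pd.DataFrame, panel: ProbePanel) -> pd.DataFrame:
    """Marker-panel cell-abundance scores: mean log2 of marker signals.

    ``values`` is an AOI x target frame of (background-normalised)
    signals; the score for a cell type is the mean of log2 marker values
    over its marker probes, per AOI.  Scores are translation-equivariant
    in log space: scaling all markers by c shifts the score by log2 c.
    """
    scores = {}
    for cell, probes in panel.marker_map.items():
        missing = [p for p in probes if p not in values.columns]
        if missing:
            raise ValueError(f"missing marker probe(s) for {cell!r}: {missing}")
        sub = values[probes]
        if (sub <= 0).any().any():
            raise ValueError(f"nonpositive marker value for {cell!r}")
        scores[cell] = np.log2(sub).mean(axis=1)
    return pd.DataFrame(scores)


def read_aoi_table_from_frame(df: pd.DataFrame) -> list[AOIRecord]:
    """Build AOIRecords from a table laid out like the AOI TSV."""
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    probe_cols = [c for c in df.columns if c not in _META_COLUMNS]
    records = []
    for _, row in df.iterrows():
        records.append(
            AOIRecord(
                patient_id=str(row["patient_id"]),
                region=str(row["region"]),
                roi_id=str(row["roi_id"]),
                compartment=str(row["compartment"]),
                fov_pct=float(row["fov_pct"]),
                binding_density=float(row["binding_density"]),
                nuclei=int(row["nuclei"]),
                area_um2=float(row["area_um2"]),
                counts={p: float(row[p]) for p in probe_cols},
            )
        )
    return records


def read_aoi_table(path: str | Path) -> list[AOIRecord]:
    """AOI TSV: metadata columns then one column per probe."""
    return read_aoi_table_from_frame(pd.read_csv(path, sep="\t"))


def read_panel(path: str | Path) -> ProbePanel:
    """Panel YAML: targets, positive_controls, negative_controls, marker_map."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return ProbePanel(
        targets=list(cfg["targets"]),
        positive_controls=tuple(cfg.get("positive_controls", ("S6", "Histone H3", "GAPDH"))),
        negative_controls=tuple(cfg.get("negative_controls", ("Ms IgG1", "Ms IgG2a", "Rb IgG"))),
        marker_map={k: list(v) for k, v in cfg.get("marker_map", {}).items()},
    )
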