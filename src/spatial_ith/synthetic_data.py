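"""Ground-truthed synthetic multi-region fixtures.

Emulates the study design the pipeline targets: per patient, three
tumour subregions (superficial primary PT_sup, deep primary PT_deep and
lymph-node metastasis LN_met) plus a matched normal used only as the
phylogenetic outgroup.  Mutations are planted as truncal (all regions),
shared (two-region subsets in a fixed rotation) or private (one region,
allocated across regions in proportion to the unique-mutation make-up
the design emulates), observed VAFs are binomial reads given purity,
depth and CCF under a diploid heterozygous model (vaf = purity * ccf / 2),
and driver mutations are planted with a truncal bias together with a
catalogue and deleteriousness scores that satisfy the driver rules.

DSP fixtures place lognormal probe counts in tumour/stroma AOIs with
positive-control and IgG probes, planted group effects and injected QC
failures; DE fixtures emit per-contrast statistic tables whose
thresholded DEG sets equal the planted sets, parameterisable to an
arbitrary directional overlap structure.

Every generator is bit-deterministic for a fixed seed (one
``numpy.random.default_rng`` stream per generator call).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .variant_core import REGIONS
from .dsp_profiling import ProbePanel

__all__ = [
    "GenomicsConfig",
    "DSPConfig",
    "DEConfig",
    "SimulationConfig",
    "GenomicsResult",
    "DSPResult",
    "DEResult",
    "simulate_genomics",
    "simulate_dsp",
    "simulate_de",
    "simulate_hla",
    "key_to_str",
]

_BASES = "ACGT"

DRIVER_GENES = (
    "TP53",
    "TTN",
    "ZNF429",
    "NOTCH1",
    "KMT2D",
    "EP300",
    "NFE2L2",
    "FAT1",
    "PIK3CA",
    "CDKN2A",
)

#: NanoString-style immune profiling panel targets used by the DSP generator
DSP_TARGETS = (
    "PanCK", "Ki-67", "CD45", "CD3", "CD4", "CD8", "CD20", "CD56",
    "CD68", "CD11c", "CD14", "CD40", "CD44", "CD127", "CTLA4", "PD-1",
    "PD-L1", "GZMB", "HLA-DR", "ICOS", "CD25", "FOXP3", "SMA",
    "Fibronectin",
)

DSP_MARKER_MAP = {
    "T cells": ["CD3"],
    "CD8 T cells": ["CD8"],
    "B cells": ["CD20"],
    "NK cells": ["CD56"],
    "Macrophages": ["CD68", "CD14"],
    "Dendritic cells": ["CD11c", "HLA-DR"],
    "Regulatory T cells": ["CD25", "FOXP3"],
    "Cytotoxic cells": ["GZMB"],
    "Fibroblasts": ["SMA", "Fibronectin"],
}

NON_SILENT_CLASSES = ("missense", "nonsense", "frameshift", "splice", "inframe_indel")
TRUNCATING = ("nonsense", "frameshift", "splice")


def key_to_str(key: tuple) -> str:
    return f"{key[0]}:{key[1]}:{key[2]}:{key[3]}"


def _largest_remainder(total: int, weights: Sequence[float]) -> list[int]:
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    raw = w * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return base.tolist()


# ---------------------------------------------------------------------------
# Genomics


@dataclass
class GenomicsConfig:
    """Study-design parameters for the multi-region mutation generator.

    Defaults emulate the target study: 15 WES patients with three tumour
    subregions, ~300x tumour coverage, and private mutations allocated
    across PT_sup / PT_deep / LN_met in proportion to the unique-mutation
    shares the design is built around.
    """

    seed: int = 0
    n_patients: int = 15
    regions: tuple[str, ...] = REGIONS
    n_trunk: int = 40
    n_shared: int = 25
    n_private: int = 35
    private_weights: tuple[float, ...] = (15.72, 5.02, 32.00)
    subclonal_fraction: float = 0.35
    subclonal_ccf: tuple[float, float] = (0.30, 0.50)
    clonal_ccf: tuple[float, float] = (0.85, 1.00)
    purity: dict = field(
        default_factory=lambda: {"PT_sup": 0.6, "PT_deep": 0.7, "LN_met": 0.5}
    )
    mean_depth: int = 300
    driver_fraction: float = 0.10
    trunk_bias_odds: float = 2.0
    silent_fraction: float = 0.20
    low_quality_rate: float = 0.10

    def validate(self) -> None:
        if min(self.n_trunk, self.n_shared, self.n_private) < 0:
            raise ValueError("mutation counts must be >= 0")
        if not 0 <= self.subclonal_fraction < 1:
            raise ValueError(
                "subclonal fraction must be in [0, 1): a main cluster is required"
            )
        for r in self.regions:
            if not 0.2 <= self.purity[r] <= 1:
                raise ValueError(f"purity for {r} outside [0.2, 1]")
        if len(self.regions) < 2:
            raise ValueError("need >= 2 regions")


@dataclass
class GenomicsResult:
    mutations: pd.DataFrame  # mutation-table TSV layout
    ccf: pd.DataFrame  # CCF-table TSV layout
    catalogue: pd.DataFrame  # driver catalogue TSV layout
    driver_genes: set[str]
    truth: dict


def _region_subsets(regions: Sequence[str]) -> list[tuple[str, ...]]:
    """Two-region subsets in a fixed rotation (shared-mutation placement)."""
    out = []
    n = len(regions)
    for i in range(n):
        for j in range(i + 1, n):
            out.append((regions[i], regions[j]))
    return out


def simulate_genomics(config: GenomicsConfig) -> GenomicsResult:
    """Generate the mutation table, CCF table, driver catalogue and truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    regions = list(config.regions)
    background_genes = [f"GENE{i:04d}" for i in range(200)]

    mut_rows: list[dict] = []
    ccf_rows: list[dict] = []
    cat_rows: list[dict] = []
    truth: dict = {
        "branch_class": {},
        "driver": {},
        "ith": {},
        "low_quality": {},
        "gene_carriers": {},
        "planted_counts": {
            "trunk": config.n_trunk,
            "shared": config.n_shared,
            "private": config.n_private,
        },
    }
    gene_carriers: dict[str, set] = {}

    subsets = _region_subsets(regions)
    shared_alloc = _largest_remainder(config.n_shared, [1.0] * len(subsets))
    private_alloc = _largest_remainder(config.n_private, config.private_weights)

    for pi in range(config.n_patients):
        patient = f"P{pi:03d}"
        total = config.n_trunk + config.n_shared + config.n_private
        n_lowq = int(round(config.low_quality_rate * total))
        n_all = total + n_lowq

        chroms = rng.integers(1, 23, size=n_all).astype(str)
        positions = rng.choice(1_000_000, size=n_all, replace=False) + 1
        refs = np.array(list(_BASES))[rng.integers(0, 4, size=n_all)]
        alts = np.array(
            [rng.choice([b for b in _BASES if b != r]) for r in refs]
        )
        tri = np.array(
            [
                rng.choice(list(_BASES)) + r + rng.choice(list(_BASES))
                for r in refs
            ]
        )
        keys = [
            (chroms[i], int(positions[i]), refs[i], alts[i]) for i in range(n_all)
        ]

        # presence pattern per key: trunk, then shared subsets, then private
        carrying: list[tuple[str, ...]] = []
        classes: list[str] = []
        k = 0
        for _ in range(config.n_trunk):
            carrying.append(tuple(regions))
            classes.append("trunk")
            k += 1
        for subset, n_sub in zip(subsets, shared_alloc):
            for _ in range(n_sub):
                carrying.append(subset)
                classes.append("shared")
                k += 1
        for region, n_priv in zip(regions, private_alloc):
            for _ in range(n_priv):
                carrying.append((region,))
                classes.append("private")
                k += 1

        # variant classes; drivers must be non-silent
        vclasses = [
            "silent"
            if rng.random() < config.silent_fraction
            else NON_SILENT_CLASSES[rng.integers(0, len(NON_SILENT_CLASSES))]
            for _ in range(total)
        ]

        # driver selection with truncal bias
        n_drivers = int(round(config.driver_fraction * total))
        weights = np.array(
            [
                (config.trunk_bias_odds if classes[i] == "trunk" else 1.0)
                * (0.0 if vclasses[i] == "silent" else 1.0)
                for i in range(total)
            ]
        )
        driver_idx = set(
            rng.choice(
                total, size=n_drivers, replace=False, p=weights / weights.sum()
            ).tolist()
        )

        sift = np.full(total, np.nan)
        polyphen = np.full(total, np.nan)
        genes: list[str] = []
        for i in range(total):
            if i in driver_idx:
                gene = DRIVER_GENES[rng.integers(0, len(DRIVER_GENES))]
                # every driver gene is annotated recessive so criterion (b)
                # plants stay valid regardless of other catalogue rows
                if rng.random() < 1 / 3:  # criterion (b): deleterious truncating
                    vclasses[i] = TRUNCATING[rng.integers(0, len(TRUNCATING))]
                    sift[i] = rng.uniform(0.0, 0.049)
                    polyphen[i] = rng.uniform(0.996, 1.0)
                    cat_rows.append(
                        {
                            "gene": gene,
                            "chrom": "0",  # placeholder row carrying the role only
                            "pos": 1 + len(cat_rows),
                            "ref": "A",
                            "alt": "C",
                            "role": "recessive",
                        }
                    )
                else:  # criterion (a): exact catalogue entry
                    cat_rows.append(
                        {
                            "gene": gene,
                            "chrom": keys[i][0],
                            "pos": keys[i][1],
                            "ref": keys[i][2],
                            "alt": keys[i][3],
                            "role": "recessive",
                        }
                    )
                    sift[i] = rng.uniform(0.2, 1.0)
                    polyphen[i] = rng.uniform(0.0, 0.9)
            else:
                gene = background_genes[rng.integers(0, len(background_genes))]
                sift[i] = rng.uniform(0.2, 1.0)
                polyphen[i] = rng.uniform(0.0, 0.9)
            genes.append(gene)

        for i in range(total):
            kstr = key_to_str(keys[i])
            truth["branch_class"].setdefault(patient, {})[kstr] = classes[i]
            truth["driver"].setdefault(patient, {})[kstr] = i in driver_idx
            if vclasses[i] != "silent":
                for region in carrying[i]:
                    gene_carriers.setdefault(genes[i], set()).add(
                        (patient, region)
                    )

        # per-region CCF assignment and observed VAF
        for region in regions:
            present = [i for i in range(total) if region in carrying[i]]
            n_present = len(present)
            n_sub = int(round(config.subclonal_fraction * n_present))
            sub_set = set(
                rng.choice(n_present, size=n_sub, replace=False).tolist()
            )
            truth["ith"][f"{patient}|{region}"] = {
                "n_main": n_present - n_sub,
                "n_sub": n_sub,
                "ith": n_sub / n_present,
            }
            for local_j, i in enumerate(present):
                subclonal = local_j in sub_set
                if subclonal:
                    ccf = rng.uniform(*config.subclonal_ccf)
                    cluster = 1
                else:
                    ccf = rng.uniform(*config.clonal_ccf)
                    cluster = 0
                depth = max(30, int(rng.poisson(config.mean_depth)))
                p = config.purity[region] * ccf / 2
                vaf = 0.0
                for _ in range(100):  # detected variants pass calling gates
                    vaf = rng.binomial(depth, p) / depth
                    if vaf >= 0.02:
                        break
                mut_rows.append(
                    {
                        "patient_id": patient,
                        "region": region,
                        "chrom": keys[i][0],
                        "pos": keys[i][1],
                        "ref": keys[i][2],
                        "alt": keys[i][3],
                        "gene": genes[i],
                        "variant_class": vclasses[i],
                        "vaf": round(vaf, 6),
                        "depth": depth,
                        "tri_context": tri[i],
                        "sift": round(float(sift[i]), 4),
                        "polyphen": round(float(polyphen[i]), 4),
                    }
                )
                ccf_rows.append(
                    {
                        "patient_id": patient,
                        "region": region,
                        "chrom": keys[i][0],
                        "pos": keys[i][1],
                        "ref": keys[i][2],
                        "alt": keys[i][3],
                        "ccf": round(float(ccf), 6),
                        "cluster_id": cluster,
                    }
                )

        # low-quality plants: fail exactly one gate each
        for j in range(n_lowq):
            i = total + j
            region = regions[int(rng.integers(0, len(regions)))]
            if rng.random() < 0.5:
                vaf, depth = float(rng.uniform(0.0, 0.019)), int(
                    rng.integers(50, 400)
                )
                reason = "low_vaf"
            else:
                vaf, depth = float(rng.uniform(0.05, 0.4)), int(
                    rng.integers(0, 10)
                )
                reason = "low_depth"
            truth["low_quality"].setdefault(patient, {})[
                key_to_str(keys[i])
            ] = reason
            mut_rows.append(
                {
                    "patient_id": patient,
                    "region": region,
                    "chrom": keys[i][0],
                    "pos": keys[i][1],
                    "ref": keys[i][2],
                    "alt": keys[i][3],
                    "gene": background_genes[
                        int(rng.integers(0, len(background_genes)))
                    ],
                    "variant_class": "missense",
                    "vaf": round(vaf, 6),
                    "depth": depth,
                    "tri_context": tri[i],
                    "sift": round(float(rng.uniform(0.2, 1.0)), 4),
                    "polyphen": round(float(rng.uniform(0.0, 0.9)), 4),
                }
            )

    n_samples = config.n_patients * len(regions)
    truth["gene_frequency"] = {
        g: len(s) / n_samples for g, s in gene_carriers.items()
    }
    return GenomicsResult(
        mutations=pd.DataFrame(mut_rows),
        ccf=pd.DataFrame(ccf_rows),
        catalogue=pd.DataFrame(cat_rows).drop_duplicates(
            subset=["gene", "chrom", "pos", "ref", "alt"]
        ),
        driver_genes=set(DRIVER_GENES),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# DSP


@dataclass
class DSPConfig:
    """DSP cohort design: 21 patients, 3 regions x 2 compartments, 2 AOIs each."""

    seed: int = 0
    n_patients: int = 21
    regions: tuple[str, ...] = REGIONS
    aois_per_stratum: int = 2
    igg_level: float = 20.0
    base_expression: tuple[float, float] = (50.0, 400.0)
    aoi_scale_sigma: float = 0.3  # lognormal sd of the per-AOI technical factor
    noise_sigma_log2: float = 0.5
    control_base: tuple[float, float, float] = (800.0, 1200.0, 1000.0)
    planted_effects: tuple = (
        ("CD8", "LN_met", "stroma", 2.0),
        ("CD20", "LN_met", "stroma", 2.0),
        ("SMA", "LN_met", "stroma", 0.5),
    )
    qc_fail_rate: float = 0.08

    def validate(self) -> None:
        if self.aois_per_stratum < 1 or self.n_patients < 2:
            raise ValueError("need >= 2 patients and >= 1 AOI per stratum")
        if not 0 <= self.qc_fail_rate < 1:
            raise ValueError("qc_fail_rate must be in [0, 1)")
        for probe, region, compartment, fold in self.planted_effects:
            if probe not in DSP_TARGETS or region not in self.regions:
                raise ValueError(f"invalid planted effect {probe}/{region}")
            if compartment not in ("tumour", "stroma") or fold <= 0:
                raise ValueError("invalid planted effect stratum or fold")


@dataclass
class DSPResult:
    aoi_frame: pd.DataFrame  # AOI TSV layout (metadata + probe columns)
    panel: ProbePanel
    truth: dict


def simulate_dsp(config: DSPConfig) -> DSPResult:
    """Generate AOI probe counts with planted effects and QC failures."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel = ProbePanel(
        targets=list(DSP_TARGETS), marker_map={k: list(v) for k, v in DSP_MARKER_MAP.items()}
    )
    sigma_ln = config.noise_sigma_log2 * np.log(2)
    base = {
        t: float(rng.uniform(*config.base_expression)) for t in DSP_TARGETS
    }
    effects = {
        (probe, region, compartment): fold
        for probe, region, compartment, fold in config.planted_effects
    }

    rows = []
    truth: dict = {
        "qc_fail": {},
        "planted_effects": [list(e) for e in config.planted_effects],
        "affected_cell_types": sorted(
            {
                cell
                for cell, probes in DSP_MARKER_MAP.items()
                for probe, *_ in config.planted_effects
                if probe in probes
            }
        ),
    }
    for pi in range(config.n_patients):
        patient = f"P{pi:03d}"
        for region in config.regions:
            for compartment in ("tumour", "stroma"):
                for a in range(config.aois_per_stratum):
                    roi = f"ROI{a + 1}"
                    aoi_id = f"{patient}|{region}|{roi}|{compartment}"
                    scale = float(
                        rng.lognormal(mean=0.0, sigma=config.aoi_scale_sigma)
                    )
                    counts = {}
                    for t in DSP_TARGETS:
                        fold = effects.get((t, region, compartment), 1.0)
                        noise = float(rng.lognormal(0.0, sigma_ln))
                        counts[t] = scale * base[t] * fold * noise
                    for c, cb in zip(
                        ("S6", "Histone H3", "GAPDH"), config.control_base
                    ):
                        counts[c] = scale * cb * float(rng.lognormal(0.0, 0.05))
                    for c in ("Ms IgG1", "Ms IgG2a", "Rb IgG"):
                        counts[c] = (
                            scale
                            * config.igg_level
                            * float(rng.lognormal(0.0, sigma_ln / 2))
                        )
                    fail = rng.random() < config.qc_fail_rate
                    if fail:
                        rule = ("fov", "binding_density", "nuclei_area")[
                            int(rng.integers(0, 3))
                        ]
                        truth["qc_fail"][aoi_id] = rule
                    else:
                        rule = None
                    fov = (
                        float(rng.uniform(50, 75))
                        if rule == "fov"
                        else float(rng.uniform(80, 100))
                    )
                    bd = (
                        float(rng.choice([0.05, 2.5]))
                        if rule == "binding_density"
                        else float(rng.uniform(0.5, 2.0))
                    )
                    if rule == "nuclei_area":
                        nuclei = int(rng.integers(1, 21))
                        area = float(rng.uniform(200, 1600))
                    else:
                        nuclei = int(rng.integers(50, 400))
                        area = float(rng.uniform(2000, 20000))
                    rows.append(
                        {
                            "patient_id": patient,
                            "region": region,
                            "roi_id": roi,
                            "compartment": compartment,
                            "fov_pct": round(fov, 3),
                            "binding_density": round(bd, 4),
                            "nuclei": nuclei,
                            "area_um2": round(area, 1),
                            **{p: round(v, 4) for p, v in counts.items()},
                        }
                    )
    return DSPResult(aoi_frame=pd.DataFrame(rows), panel=panel, truth=truth)


# ---------------------------------------------------------------------------
# Differential expression tables


@dataclass
class DEConfig:
    """Directional DEG overlap structure for two contrasts sharing a reference.

    Defaults reproduce the design's printed partition: contrast A has 715
    up / 126 down, contrast B 221 up / 152 down, with 177 up and 58 down
    overlapping (no discordant genes).
    """

    seed: int = 0
    n_genes: int = 5000
    contrast_a: str = "LN_met:PT_sup"
    contrast_b: str = "LN_met:PT_deep"
    up_a: int = 715
    down_a: int = 126
    up_b: int = 221
    down_b: int = 152
    overlap_up: int = 177
    overlap_down: int = 58

    def validate(self) -> None:
        if self.overlap_up > min(self.up_a, self.up_b):
            raise ValueError("overlap_up exceeds a directional total")
        if self.overlap_down > min(self.down_a, self.down_b):
            raise ValueError("overlap_down exceeds a directional total")
        n_deg = (
            self.up_a + self.down_a + self.up_b + self.down_b
            - self.overlap_up - self.overlap_down
        )
        if n_deg > self.n_genes:
            raise ValueError("planted DEGs exceed n_genes")


@dataclass
class DEResult:
    tables: dict  # contrast -> DataFrame (gene, log2fc, pvalue, fdr)
    truth: dict


def _de_rows(rng, genes, direction: dict, n_genes: int):
    rows = []
    for g in genes:
        d = direction.get(g, 0)
        if d != 0:
            fdr = float(rng.uniform(1e-6, 0.049))
            l2fc = d * float(rng.uniform(1.1, 5.0))
        elif rng.random() < 0.5:  # null: not significant by FDR
            fdr = float(rng.uniform(0.051, 1.0))
            l2fc = float(rng.uniform(-3.0, 3.0))
        else:  # null: significant FDR but small fold change
            fdr = float(rng.uniform(1e-4, 1.0))
            l2fc = float(rng.uniform(-0.99, 0.99))
        rows.append(
            {
                "gene": g,
                "log2fc": round(l2fc, 4),
                "pvalue": round(min(1.0, fdr * 0.5), 8),
                "fdr": round(fdr, 8),
            }
        )
    return rows


def simulate_de(config: DEConfig) -> DEResult:
    """Emit DE statistic tables whose thresholded DEG sets match the plant."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    pool = list(genes)

    # carve disjoint blocks: shared up/down, then unique per contrast
    shared_up = pool[: config.overlap_up]
    pool = pool[config.overlap_up:]
    shared_down = pool[: config.overlap_down]
    pool = pool[config.overlap_down:]
    ua = config.up_a - config.overlap_up
    da = config.down_a - config.overlap_down
    ub = config.up_b - config.overlap_up
    db = config.down_b - config.overlap_down
    uniq_up_a, pool = pool[:ua], pool[ua:]
    uniq_down_a, pool = pool[:da], pool[da:]
    uniq_up_b, pool = pool[:ub], pool[ub:]
    uniq_down_b, pool = pool[:db], pool[db:]

    dir_a = {g: 1 for g in shared_up + uniq_up_a}
    dir_a.update({g: -1 for g in shared_down + uniq_down_a})
    dir_b = {g: 1 for g in shared_up + uniq_up_b}
    dir_b.update({g: -1 for g in shared_down + uniq_down_b})

    tables = {
        config.contrast_a: pd.DataFrame(
            _de_rows(rng, genes, dir_a, config.n_genes)
        ),
        config.contrast_b: pd.DataFrame(
            _de_rows(rng, genes, dir_b, config.n_genes)
        ),
    }
    truth = {
        config.contrast_a: {
            "up": sorted(shared_up + uniq_up_a),
            "down": sorted(shared_down + uniq_down_a),
        },
        config.contrast_b: {
            "up": sorted(shared_up + uniq_up_b),
            "down": sorted(shared_down + uniq_down_b),
        },
        "overlap_up": sorted(shared_up),
        "overlap_down": sorted(shared_down),
    }
    return DEResult(tables=tables, truth=truth)


# ---------------------------------------------------------------------------
# HLA


def simulate_hla(
    seed: int = 0,
    n_patients: int = 15,
    n_loh_patients: int = 12,
    regions: Sequence[str] = REGIONS,
) -> tuple[pd.DataFrame, dict]:
    """HLA allele observation table with a planted patient-level LOH set.

    ``n_loh_patients`` of ``n_patients`` carry LOH in at least one
    region-sample (copy number < .5 with imbalance p < .01 on one
    allele); the rest are clean in every region.
    """
    rng = np.random.default_rng(seed)
    rows = []
    loh_patients = [f"P{i:03d}" for i in range(n_loh_patients)]
    truth = {"loh_patients": loh_patients}
    for pi in range(n_patients):
        patient = f"P{pi:03d}"
        loh_region = (
            regions[int(rng.integers(0, len(regions)))]
            if patient in loh_patients
            else None
        )
        for region in regions:
            lost_allele = None
            if region == loh_region:
                locus = ("HLA-A", "HLA-B", "HLA-C")[int(rng.integers(0, 3))]
                lost_allele = (locus, 1)
            for locus in ("HLA-A", "HLA-B", "HLA-C"):
                for allele_i in (1, 2):
                    lost = lost_allele == (locus, allele_i)
                    cn = (
                        float(rng.uniform(0.05, 0.45))
                        if lost
                        else float(rng.uniform(0.7, 1.4))
                    )
                    p = (
                        float(rng.uniform(1e-6, 0.009))
                        if lost
                        else float(rng.uniform(0.05, 1.0))
                    )
                    rows.append(
                        {
                            "patient_id": patient,
                            "region": region,
                            "locus": locus,
                            "allele": f"{locus}*{allele_i:02d}",
                            "copy_number": round(cn, 4),
                            "imbalance_p": round(p, 6),
                        }
                    )
    return pd.DataFrame(rows), truth


@dataclass
class SimulationConfig:
    """Aggregate configuration for the full synthetic cohort."""

    seed: int = 0
    genomics: GenomicsConfig = field(default_factory=GenomicsConfig)
    dsp: DSPConfig = field(default_factory=DSPConfig)
    de: DEConfig = field(default_factory=DEConfig)

    def __post_init__(self) -> None:
        # one master seed fans out to stream-specific seeds
        self.genomics.seed = self.seed * 3 + 1
        self.dsp.seed = self.seed * 3 + 2
        self.de.seed = self.seed * 3 + 3


def write_fixtures(config: SimulationConfig, out_dir) -> None:
    """Write all fixture TSVs plus the ground-truth JSON to a directory."""
    from pathlib import Path
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g = simulate_genomics(config.genomics)
    d = simulate_dsp(config.dsp)
    e = simulate_de(config.de)
    hla_frame, hla_truth = simulate_hla(seed=config.seed * 3 + 4)
    g.mutations.to_csv(out / "mutations.tsv", sep="\t", index=False)
    g.ccf.to_csv(out / "ccf.tsv", sep="\t", index=False)
    g.catalogue.to_csv(out / "catalogue.tsv", sep="\t", index=False)
    (out / "driver_genes.txt").write_text(
        "\n".join(sorted(g.driver_genes)) + "\n"
    )
    d.aoi_frame.to_csv(out / "aois.tsv", sep="\t", index=False)
    with open(out / "panel.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "targets": list(d.panel.targets),
                "positive_controls": list(d.panel.positive_controls),
                "negative_controls": list(d.panel.negative_controls),
                "marker_map": d.panel.marker_map,
            },
            fh,
        )
    for contrast, table in e.tables.items():
        table.to_csv(
            out / f"de_{contrast.replace(':', '_vs_')}.tsv", sep="\t", index=False
        )
    hla_frame.to_csv(out / "hla.tsv", sep="\t", index=False)
    truth = {
        "genomics": g.truth,
        "dsp": d.truth,
        "de": e.truth,
        "hla": hla_truth,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
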