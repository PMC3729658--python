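"""Methylation-expression integration: quadrant classification of per-probe
beta differences against per-gene expression log fold changes, genomic
region attribution, count tables and cross-platform concordance."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import AnalysisConfig, Manifest, ProbeAnnotation

QUADRANTS = ("Q1", "Q2", "Q3", "Q4", "none")

TSS_TAGS = frozenset({"TSS200", "TSS1500"})
UPSTREAM_TAGS = frozenset({"UTR5", "FirstExon"})
BODY_TAGS = frozenset({"Body", "UTR3"})


class RegionGroup(str, Enum):
    """Exclusive genomic-region assignment for a probe."""

    PROMOTER_ASSOCIATED = "PromoterAssociated"
    ENHANCER = "Enhancer"
    TSS_ONLY = "TSS_only"
    UPSTREAM_5P_FIRST_EXON = "Upstream5pFirstExon"
    GENE_BODY_ONLY = "GeneBodyOnly"
    INTERGENIC = "Intergenic"


#: precedence used by :func:`assign_region`; overridable via its argument
DEFAULT_REGION_PRECEDENCE = (
    RegionGroup.PROMOTER_ASSOCIATED,
    RegionGroup.ENHANCER,
    RegionGroup.TSS_ONLY,
    RegionGroup.UPSTREAM_5P_FIRST_EXON,
    RegionGroup.GENE_BODY_ONLY,
)


def assign_region(
    probe: ProbeAnnotation,
    precedence: tuple[RegionGroup, ...] = DEFAULT_REGION_PRECEDENCE,
) -> RegionGroup:
    """Map a probe to exactly one region group.

    Checked in precedence order: promoter flag, enhancer flag, any TSS tag,
    any 5'UTR/first-exon tag, any body/3'UTR tag; otherwise intergenic.
    """
    tags = set(probe.gene_region_tags)
    matches = {
        RegionGroup.PROMOTER_ASSOCIATED: probe.promoter_associated,
        RegionGroup.ENHANCER: probe.enhancer,
        RegionGroup.TSS_ONLY: bool(tags & TSS_TAGS),
        RegionGroup.UPSTREAM_5P_FIRST_EXON: bool(tags & UPSTREAM_TAGS),
        RegionGroup.GENE_BODY_ONLY: bool(tags & BODY_TAGS),
    }
    for group in precedence:
        if matches[group]:
            return group
    return RegionGroup.INTERGENIC


def classify_quadrant(
    delta_beta: float, logfc: float, config: AnalysisConfig
) -> str:
    """Quadrant of the (delta beta, logFC) plane, with strict gates.

    Both gates are exceeded strictly (boundary values are inside the
    technical-noise box and classify as 'none'):

    * Q1: delta_beta < -t_m and logfc > +t_e  (hypomethylated & up in arterial)
    * Q2: delta_beta > +t_m and logfc > +t_e
    * Q3: delta_beta > +t_m and logfc < -t_e  (hypomethylated & up in venous)
    * Q4: delta_beta < -t_m and logfc < -t_e

    where t_m = config.delta_beta_cutoff and t_e = config.logfc_cutoff.
    Q1 and Q3 are the reciprocal (anti-correlated) quadrants.
    """
    if not (np.isfinite(delta_beta) and np.isfinite(logfc)):
        raise ValueError("delta_beta and logfc must be finite")
    t_m = config.delta_beta_cutoff
    t_e = config.logfc_cutoff
    if delta_beta < -t_m and logfc > t_e:
        return "Q1"
    if delta_beta > t_m and logfc > t_e:
        return "Q2"
    if delta_beta > t_m and logfc < -t_e:
        return "Q3"
    if delta_beta < -t_m and logfc < -t_e:
        return "Q4"
    return "none"


@dataclass
class IntegrationRecord:
    """One gene's joined methylation/expression evidence."""

    gene: str
    logfc: float
    probe_rows: pd.DataFrame  # probe_id, delta_beta, quadrant, region_group
    promoter_probe_count: int
    total_probe_count: int

    @property
    def promoter_probe_fraction(self) -> tuple[int, int]:
        return (self.promoter_probe_count, self.total_probe_count)


def integrate_genes(
    dmps: pd.DataFrame,
    de: pd.DataFrame,
    annotation: Manifest,
    config: AnalysisConfig,
) -> tuple[list[IntegrationRecord], dict]:
    """Join per-probe beta differences with per-gene expression changes.

    Every analysable probe of a gene (not only called DMPs) receives the
    gene's single logFC; the quadrant is computed per probe.  The promoter
    fraction counts probes whose region tags for this gene include
    TSS200/TSS1500.  A probe annotated to several genes contributes one row
    per gene.  Genes without an expression record are skipped and counted.
    """
    if de["gene"].duplicated().any():
        dup = de["gene"][de["gene"].duplicated()].iloc[0]
        raise ValueError(f"duplicate gene symbol in expression results: {dup!r}")
    delta_by_probe = dmps["delta_beta"]
    gene_probes: dict[str, list[ProbeAnnotation]] = {}
    for pid in dmps["probe_id"]:
        if pid not in annotation:
            continue
        probe = annotation[pid]
        for gene in probe.gene_symbols:
            gene_probes.setdefault(gene, []).append(probe)

    records: list[IntegrationRecord] = []
    skipped_no_expression = 0
    logfc_by_gene = de.set_index("gene")["logfc"] if de.index.name != "gene" else de["logfc"]
    for gene in sorted(gene_probes):
        if gene not in logfc_by_gene.index:
            skipped_no_expression += 1
            continue
        logfc = float(logfc_by_gene[gene])
        rows = []
        n_promoter = 0
        for probe in gene_probes[gene]:
            delta = float(delta_by_probe[probe.probe_id])
            tags_for_gene = {
                tag
                for sym, tag in zip(probe.gene_symbols, probe.gene_region_tags)
                if sym == gene
            }
            if tags_for_gene & TSS_TAGS:
                n_promoter += 1
            rows.append(
                {
                    "probe_id": probe.probe_id,
                    "delta_beta": delta,
                    "quadrant": classify_quadrant(delta, logfc, config),
                    "region_group": assign_region(probe).value,
                }
            )
        probe_rows = pd.DataFrame(
            rows, columns=["probe_id", "delta_beta", "quadrant", "region_group"]
        )
        records.append(
            IntegrationRecord(
                gene=gene,
                logfc=logfc,
                probe_rows=probe_rows,
                promoter_probe_count=n_promoter,
                total_probe_count=len(rows),
            )
        )
    log = {
        "n_genes_integrated": len(records),
        "n_genes_skipped_no_expression": skipped_no_expression,
    }
    return records, log


def records_to_frame(records: list[IntegrationRecord]) -> pd.DataFrame:
    """Flatten integration records to one row per (gene, probe)."""
    frames = []
    for rec in records:
        df = rec.probe_rows.copy()
        df.insert(0, "gene", rec.gene)
        df.insert(1, "logfc", rec.logfc)
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["gene", "logfc", "probe_id", "delta_beta", "quadrant", "region_group"]
        )
    return pd.concat(frames, ignore_index=True)


def gene_summary_table(records: list[IntegrationRecord]) -> pd.DataFrame:
    """Per-gene summary: logfc, mean delta beta, promoter fraction, quadrants."""
    rows = []
    for rec in records:
        quads = rec.probe_rows["quadrant"].value_counts()
        dominant = "none"
        non_none = quads.drop("none", errors="ignore")
        if len(non_none):
            dominant = non_none.idxmax()
        frac = (
            f"{rec.promoter_probe_count}/{rec.total_probe_count} "
            f"({round(100 * rec.promoter_probe_count / rec.total_probe_count)}%)"
        )
        rows.append(
            {
                "gene": rec.gene,
                "logfc": rec.logfc,
                "mean_delta_beta": float(rec.probe_rows["delta_beta"].mean()),
                "n_probes": rec.total_probe_count,
                "n_promoter_probes": rec.promoter_probe_count,
                "promoter_fraction": frac,
                "dominant_quadrant": dominant,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "logfc",
            "mean_delta_beta",
            "n_probes",
            "n_promoter_probes",
            "promoter_fraction",
            "dominant_quadrant",
        ],
    )


#: overlapping probe families used by the count table (a probe can belong to
#: several; totals count each probe once per family)
REGION_FAMILIES = (
    "All",
    "Upstream1500_5pUTR_1stExon",
    "TSS_excluding_5pUTR_1stExon",
    "Enhancer",
    "PromoterAssociated",
    "GeneBodyOnly",
)


def _probe_families(probe: ProbeAnnotation) -> list[str]:
    tags = set(probe.gene_region_tags)
    families = ["All"]
    if tags & (TSS_TAGS | UPSTREAM_TAGS):
        families.append("Upstream1500_5pUTR_1stExon")
    if (tags & TSS_TAGS) and not (tags & UPSTREAM_TAGS):
        families.append("TSS_excluding_5pUTR_1stExon")
    if probe.enhancer:
        families.append("Enhancer")
    if probe.promoter_associated:
        families.append("PromoterAssociated")
    if (tags & BODY_TAGS) and not (tags & (TSS_TAGS | UPSTREAM_TAGS)):
        families.append("GeneBodyOnly")
    return families


@dataclass
class QuadrantRegionTable:
    """Probe counts per region family x quadrant, plus within-family proportions."""

    counts: pd.DataFrame  # families x (all, Q1..Q4)
    proportions: pd.DataFrame


def quadrant_region_table(
    records: list[IntegrationRecord], annotation: Manifest
) -> QuadrantRegionTable:
    """Count probes per overlapping region family and quadrant.

    Families are computed directly from tags and flags, independently of the
    exclusive :func:`assign_region` map (the two views answer different
    questions and are both emitted by the pipeline).  Each probe counts once
    per family even when annotated to multiple genes; a probe's quadrant is
    its strongest (non-'none' if any) label across gene contexts.
    """
    flat = records_to_frame(records)
    quad_by_probe: dict[str, str] = {}
    for probe_id, quad in zip(flat["probe_id"], flat["quadrant"]):
        prev = quad_by_probe.get(probe_id)
        if prev is None or (prev == "none" and quad != "none"):
            quad_by_probe[probe_id] = quad
    counts = pd.DataFrame(
        0, index=list(REGION_FAMILIES), columns=["all", "Q1", "Q2", "Q3", "Q4"]
    )
    for probe_id, quad in quad_by_probe.items():
        if probe_id not in annotation:
            continue
        for family in _probe_families(annotation[probe_id]):
            counts.loc[family, "all"] += 1
            if quad != "none":
                counts.loc[family, quad] += 1
    totals = counts["all"].replace(0, np.nan)
    proportions = counts.div(totals, axis=0).fillna(0.0)
    return QuadrantRegionTable(counts=counts, proportions=proportions)


def platform_concordance(
    array_beta: pd.Series | np.ndarray, second_platform_beta: pd.Series | np.ndarray
) -> tuple[float, float, int]:
    """Pearson r and mean absolute difference between matched measurements."""
    x = np.asarray(array_beta, dtype=float)
    y = np.asarray(second_platform_beta, dtype=float)
    if x.shape != y.shape:
        raise ValueError("platforms must supply matched measurement vectors")
    if x.size < 3:
        raise ValueError("need >= 3 matched measurements")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input vector: correlation undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r), float(np.mean(np.abs(x - y))), int(x.size)
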