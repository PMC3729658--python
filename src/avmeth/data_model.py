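"""Domain types and text-format readers/writers.

All tabular interchange is plain text: manifests and sample sheets are CSV,
matrices are TSV with a ``probe_id`` (or ``gene``) label column, genomic
exports are UCSC-dialect BED.  Matrix values are written with 6 significant
digits, so write-then-read round-trips are exact for values representable at
that precision.

Coordinate conventions: manifest positions are 1-based (array-manifest
convention); all BED exports are 0-based half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

GENE_REGION_TAGS = ("TSS200", "TSS1500", "UTR5", "FirstExon", "Body", "UTR3")
ISLAND_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")
SEX_CHROMOSOMES = frozenset({"X", "Y", "chrX", "chrY"})

ARTERIAL = "arterial"
VENOUS = "venous"
GROUPS = (ARTERIAL, VENOUS)

#: significant digits used for all text matrix output
MATRIX_SIG_DIGITS = 6
_MATRIX_FLOAT_FMT = "%.6g"


class DesignType(str, Enum):
    """Infinium probe chemistry."""

    I = "I"
    II = "II"


@dataclass(frozen=True)
class ProbeAnnotation:
    """One manifest row.

    ``gene_region_tags`` is parallel to ``gene_symbols``: tag *i* describes
    the probe's location relative to gene *i*.
    """

    probe_id: str
    chromosome: str
    position: int
    design_type: str = "II"
    gene_symbols: tuple[str, ...] = ()
    gene_region_tags: tuple[str, ...] = ()
    enhancer: bool = False
    promoter_associated: bool = False
    island_relation: str = "OpenSea"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(
                f"probe {self.probe_id}: position must be >= 1, got {self.position}"
            )
        if len(self.gene_symbols) != len(self.gene_region_tags):
            raise ValueError(
                f"probe {self.probe_id}: gene_symbols and gene_region_tags "
                f"must be parallel ({len(self.gene_symbols)} vs "
                f"{len(self.gene_region_tags)})"
            )
        for tag in self.gene_region_tags:
            if tag not in GENE_REGION_TAGS:
                raise ValueError(f"probe {self.probe_id}: unknown region tag {tag!r}")

    @property
    def is_sex_chromosome(self) -> bool:
        return self.chromosome in SEX_CHROMOSOMES

    @property
    def primary_gene(self) -> str:
        """First annotated gene symbol, or '' for intergenic probes."""
        return self.gene_symbols[0] if self.gene_symbols else ""


class Manifest:
    """An ordered collection of :class:`ProbeAnnotation` with unique ids."""

    def __init__(self, probes: Iterable[ProbeAnnotation]):
        self.probes: list[ProbeAnnotation] = list(probes)
        self._by_id: dict[str, ProbeAnnotation] = {}
        for p in self.probes:
            if p.probe_id in self._by_id:
                raise ValueError(f"duplicate probe_id in manifest: {p.probe_id!r}")
            self._by_id[p.probe_id] = p

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self._by_id

    def __getitem__(self, probe_id: str) -> ProbeAnnotation:
        return self._by_id[probe_id]

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    def subset(self, probe_ids: Iterable[str]) -> "Manifest":
        ids = set(probe_ids)
        return Manifest(p for p in self.probes if p.probe_id in ids)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "probe_id": p.probe_id,
                "chromosome": p.chromosome,
                "position": p.position,
                "design_type": p.design_type,
                "gene_symbols": ";".join(p.gene_symbols),
                "gene_region_tags": ";".join(p.gene_region_tags),
                "enhancer": p.enhancer,
                "promoter_associated": p.promoter_associated,
                "island_relation": p.island_relation,
            }
            for p in self.probes
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "probe_id",
                "chromosome",
                "position",
                "design_type",
                "gene_symbols",
                "gene_region_tags",
                "enhancer",
                "promoter_associated",
                "island_relation",
            ],
        )


@dataclass
class SampleSheet:
    """Sample metadata: id, group (arterial/venous) and placenta-of-origin pair id."""

    frame: pd.DataFrame  # columns: sample_id, group, pair_id

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "pair_id"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        self.frame = self.frame.reset_index(drop=True)
        ids = self.frame["sample_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate sample_id in sample sheet: {dup!r}")
        bad = set(self.frame["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}; expected {GROUPS}")
        per_group = self.frame.groupby("group")["pair_id"]
        for group, pairs in per_group:
            if pairs.duplicated().any():
                dup = pairs[pairs.duplicated()].iloc[0]
                raise ValueError(
                    f"pair_id {dup!r} appears more than once in group {group!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def group_samples(self, group: str) -> list[str]:
        return self.frame.loc[self.frame["group"] == group, "sample_id"].tolist()

    def pairs(self) -> pd.DataFrame:
        """One row per complete pair: pair_id, arterial sample, venous sample."""
        wide = self.frame.pivot(index="pair_id", columns="group", values="sample_id")
        wide = wide.dropna(subset=[g for g in GROUPS if g in wide.columns])
        wide = wide.rename(columns={ARTERIAL: "arterial", VENOUS: "venous"})
        return wide.reset_index()

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        keep = set(sample_ids)
        return SampleSheet(
            self.frame[self.frame["sample_id"].isin(keep)].reset_index(drop=True)
        )


@dataclass
class ArrayDataset:
    """Two-channel intensities plus detection p-values for one experiment."""

    annotation: Manifest
    meth: pd.DataFrame  # probes x samples
    unmeth: pd.DataFrame
    detection_p: pd.DataFrame | None
    samples: SampleSheet
    negctrl: pd.DataFrame | None = None  # controls x samples
    qc_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.meth.index.equals(self.unmeth.index) or not self.meth.columns.equals(
            self.unmeth.columns
        ):
            raise ValueError("meth and unmeth matrices must share probe/sample axes")
        if self.detection_p is not None:
            if not self.meth.index.equals(self.detection_p.index) or not (
                self.meth.columns.equals(self.detection_p.columns)
            ):
                raise ValueError("detection_p must share axes with intensities")
        for name, mat in (("meth", self.meth), ("unmeth", self.unmeth)):
            if (mat.to_numpy() < 0).any():
                raise ValueError(f"negative intensity found in {name} matrix")
        sheet_ids = self.samples.sample_ids
        if list(self.meth.columns) != sheet_ids:
            raise ValueError("sample axis must match the sample sheet order")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.meth.index)

    def subset_probes(self, probe_ids: Iterable[str]) -> "ArrayDataset":
        ids = [p for p in self.probe_ids if p in set(probe_ids)]
        return ArrayDataset(
            annotation=self.annotation.subset(ids),
            meth=self.meth.loc[ids],
            unmeth=self.unmeth.loc[ids],
            detection_p=None if self.detection_p is None else self.detection_p.loc[ids],
            samples=self.samples,
            negctrl=self.negctrl,
            qc_meta=dict(self.qc_meta),
        )


@dataclass
class MethylationMatrices:
    """Post-QC beta and M-value matrices plus the QC provenance log."""

    beta: pd.DataFrame
    mvalue: pd.DataFrame
    kept_probe_ids: list[str]
    qc_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        b = self.beta.to_numpy(dtype=float)
        finite = np.isfinite(b)
        if ((b[finite] < 0) | (b[finite] > 1)).any():
            raise ValueError("beta values must lie in [0, 1]")
        if not self.beta.index.equals(self.mvalue.index) or not (
            self.beta.columns.equals(self.mvalue.columns)
        ):
            raise ValueError("beta and mvalue must share axes")


@dataclass
class AnalysisConfig:
    """Thresholds and modelling switches for the whole pipeline."""

    detection_p_cutoff: float = 0.05
    fdr_cutoff: float = 0.05
    delta_beta_cutoff: float = 0.10
    logfc_cutoff: float = 0.5
    cv_cutoff: float = 0.4
    top_n_variable: int = 1000
    use_moderated_t: bool = True
    paired_design: bool = False
    dmr_min_probes: int = 3
    dmr_max_gap: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "detection_p_cutoff",
            "fdr_cutoff",
            "delta_beta_cutoff",
            "logfc_cutoff",
            "cv_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.top_n_variable < 2:
            raise ValueError("top_n_variable must be >= 2")


@dataclass
class ExpressionMatrix:
    """Gene-level log2 expression, genes x samples."""

    values: pd.DataFrame
    samples: SampleSheet

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene symbol in expression matrix: {dup!r}")
        if list(self.values.columns) != self.samples.sample_ids:
            raise ValueError("expression sample axis must match the sample sheet order")

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.values.index)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_MANIFEST_ALIASES = {
    "probe_id": ("probe_id", "ilmnid", "name", "probeid"),
    "chromosome": ("chromosome", "chr", "chrom"),
    "position": ("position", "mapinfo", "pos"),
    "design_type": ("design_type", "infinium_design_type", "type"),
    "gene_symbols": ("gene_symbols", "ucsc_refgene_name", "gene"),
    "gene_region_tags": ("gene_region_tags", "ucsc_refgene_group", "region"),
    "enhancer": ("enhancer", "enhancer_associated"),
    "promoter_associated": ("promoter_associated", "regulatory_feature_group"),
    "island_relation": ("island_relation", "relation_to_ucsc_cpg_island"),
}


def _resolve_columns(columns: Iterable[str]) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    resolved = {}
    for canonical, aliases in _MANIFEST_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                resolved[canonical] = lower[alias]
                break
    return resolved


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return False
    return str(value).strip().lower() in {"true", "1", "yes", "y", "t"}


def _split_multi(value) -> tuple[str, ...]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ()
    text = str(value).strip()
    if not text:
        return ()
    return tuple(part for part in text.split(";") if part)


def read_manifest(path: str | Path) -> Manifest:
    """Read a probe annotation manifest CSV.

    Required columns (case-insensitive, common array-manifest aliases
    accepted): probe id, chromosome, position, design type.  Region tag,
    gene, enhancer, promoter and island columns are optional and default to
    empty/false/OpenSea.

    Raises
    ------
    ValueError
        On duplicate probe ids or an unparseable position (with row number).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = _resolve_columns(df.columns)
    for required in ("probe_id", "chromosome", "position", "design_type"):
        if required not in cols:
            raise ValueError(f"manifest {path} is missing a {required} column")
    probes = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        # itertuples mangles column names; index positionally instead
        values = {canonical: row[df.columns.get_loc(col)] for canonical, col in cols.items()}
        try:
            position = int(str(values["position"]).strip())
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"manifest {path} line {i}: unparseable position "
                f"{values['position']!r}"
            ) from exc
        chrom = str(values["chromosome"]).strip()
        probes.append(
            ProbeAnnotation(
                probe_id=str(values["probe_id"]).strip(),
                chromosome=chrom[3:] if chrom.lower().startswith("chr") else chrom,
                position=position,
                design_type=str(values["design_type"]).strip(),
                gene_symbols=_split_multi(values.get("gene_symbols")),
                gene_region_tags=_split_multi(values.get("gene_region_tags")),
                enhancer=_parse_bool(values.get("enhancer")),
                promoter_associated=_parse_bool(values.get("promoter_associated")),
                island_relation=str(values.get("island_relation") or "OpenSea").strip()
                or "OpenSea",
            )
        )
    return Manifest(probes)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    manifest.to_frame().to_csv(path, index=False)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    return SampleSheet(df[["sample_id", "group", "pair_id"]])


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.frame.to_csv(path, index=False)


def read_matrix(path: str | Path, label: str = "probe_id") -> pd.DataFrame:
    """Read a labelled TSV matrix (rows: probes/genes, columns: samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = label
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, label: str = "probe_id") -> None:
    out = df.copy()
    out.index.name = label
    out.to_csv(path, sep="\t", float_format=_MATRIX_FLOAT_FMT)


def read_array_dataset(
    meth_path: str | Path,
    unmeth_path: str | Path,
    detp_path: str | Path | None,
    sheet_path: str | Path,
    manifest: Manifest,
    negctrl_path: str | Path | None = None,
) -> ArrayDataset:
    """Assemble an :class:`ArrayDataset` from its on-disk parts.

    Axes are aligned by label intersection (never positionally); probes or
    samples missing from any matrix are dropped and recorded in
    ``qc_meta``.  A sample listed on the sheet but absent from the
    intensity matrices is a hard error.
    """
    meth = read_matrix(meth_path)
    unmeth = read_matrix(unmeth_path)
    detp = read_matrix(detp_path) if detp_path is not None else None
    sheet = read_sample_sheet(sheet_path)

    missing_samples = [s for s in sheet.sample_ids if s not in meth.columns]
    if missing_samples:
        raise ValueError(
            f"sample sheet lists samples absent from intensity matrices: "
            f"{missing_samples}"
        )

    probe_sets = [set(meth.index), set(unmeth.index), set(manifest.probe_ids)]
    if detp is not None:
        probe_sets.append(set(detp.index))
    common = set.intersection(*probe_sets)
    dropped = sorted(set(meth.index) - common)
    probes = [p for p in meth.index if p in common]

    samples = [s for s in sheet.sample_ids if s in meth.columns]
    if not samples:
        raise ValueError("no overlapping samples between sheet and matrices")
    sheet = sheet.subset(samples)

    qc_meta = {"probes_dropped_on_alignment": dropped, "n_probes_aligned": len(probes)}
    negctrl = read_matrix(negctrl_path)[samples] if negctrl_path is not None else None
    return ArrayDataset(
        annotation=manifest.subset(probes),
        meth=meth.loc[probes, samples],
        unmeth=unmeth.loc[probes, samples],
        detection_p=None if detp is None else detp.loc[probes, samples],
        samples=sheet,
        negctrl=negctrl,
        qc_meta=qc_meta,
    )


# ---------------------------------------------------------------------------
# result writers
# ---------------------------------------------------------------------------

DMP_COLUMNS = [
    "probe_id",
    "mean_beta_arterial",
    "mean_beta_venous",
    "delta_beta",
    "t_stat",
    "df",
    "p_value",
    "adj_p",
    "is_dmp",
    "direction",
]


def write_dmp_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write per-probe differential methylation results as TSV."""
    out = records.reset_index() if records.index.name == "probe_id" else records.copy()
    out = out[[c for c in DMP_COLUMNS if c in out.columns]]
    out.to_csv(path, sep="\t", index=False, float_format=_MATRIX_FLOAT_FMT)


def write_dmp_bed(
    records: pd.DataFrame, manifest: Manifest, path: str | Path
) -> dict:
    """Write probes as single-bp BED intervals (0-based half-open).

    Score is ``round(1000 * |delta_beta|)``; name is the probe id.  Probes
    without manifest coordinates are skipped and counted in the returned log.
    """
    out = records.reset_index() if records.index.name == "probe_id" else records
    skipped = 0
    lines = []
    for row in out.itertuples(index=False):
        pid = row.probe_id
        if pid not in manifest:
            skipped += 1
            continue
        probe = manifest[pid]
        chrom = probe.chromosome
        if not chrom.startswith("chr"):
            chrom = f"chr{chrom}"
        score = int(round(1000 * abs(row.delta_beta)))
        lines.append(
            f"{chrom}\t{probe.position - 1}\t{probe.position}\t{pid}\t{score}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    return {"written": len(lines), "skipped_no_coordinates": skipped}


def write_json(obj: Mapping, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
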