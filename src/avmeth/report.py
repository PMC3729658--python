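"""Publication-style figures rendered from pipeline output files.

Figures are views over the TSVs already in the run directory; they never
contain information that is not re-readable from those files.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .data_model import read_manifest, read_matrix, read_sample_sheet


def plot_outputs(run_dir: str | Path, fmt: str = "png") -> list[Path]:
    """Render heatmap, starburst scatter and a per-gene probe profile."""
    run_dir = Path(run_dir)
    written = []
    written.append(_plot_heatmap(run_dir, fmt))
    written.append(_plot_starburst(run_dir, fmt))
    profile = _plot_gene_profile(run_dir, fmt)
    if profile is not None:
        written.append(profile)
    return [p for p in written if p is not None]


def _plot_heatmap(run_dir: Path, fmt: str) -> Path:
    beta = read_matrix(run_dir / "beta.tsv")
    merges = pd.read_csv(run_dir / "clustering_merges.tsv", sep="\t")
    sample_order = (
        (run_dir / "clustering_sample_order.txt").read_text().strip().splitlines()
    )
    # restrict to the clustered (most variable) probes if the run recorded them
    mval = read_matrix(run_dir / "mvalue.tsv")
    cv = beta.std(axis=1, ddof=1) / beta.mean(axis=1)
    top = cv.sort_values(ascending=False).head(min(1000, len(cv))).index
    data = beta.loc[top, sample_order]
    # order probes by their own dendrogram for a readable heatmap
    if len(top) > 2:
        z = hierarchy.linkage(pdist(mval.loc[top].to_numpy()), method="average")
        data = data.iloc[hierarchy.leaves_list(z)]

    fig, (ax_d, ax_h) = plt.subplots(
        2, 1, figsize=(8, 8), gridspec_kw={"height_ratios": [1, 5]}
    )
    link = merges[["left", "right", "height", "size"]].to_numpy()
    hierarchy.dendrogram(link, labels=sample_order_from_linkage(link, sample_order), ax=ax_d, color_threshold=0)
    ax_d.set_ylabel("height")
    im = ax_h.imshow(data.to_numpy(), aspect="auto", cmap="RdYlBu_r", vmin=0, vmax=1)
    ax_h.set_xticks(range(len(sample_order)), sample_order, rotation=90, fontsize=6)
    ax_h.set_yticks([])
    ax_h.set_ylabel(f"{len(data)} most variable probes")
    fig.colorbar(im, ax=ax_h, label="beta")
    out = run_dir / f"heatmap.{fmt}"
    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out


def sample_order_from_linkage(link: np.ndarray, leaf_order: list[str]) -> list[str]:
    # dendrogram() labels leaves by original index; our order file already
    # stores the leaf sequence, so label positions 0..n-1 accordingly
    n = link.shape[0] + 1
    order = hierarchy.leaves_list(link)
    labels = [""] * n
    for pos, leaf in enumerate(order):
        labels[leaf] = leaf_order[pos]
    return labels


def _plot_starburst(run_dir: Path, fmt: str) -> Path:
    flat = pd.read_csv(run_dir / "probe_quadrants.tsv", sep="\t")
    cfg = json.loads((run_dir / "run_record.json").read_text())["config"]
    analysis = cfg.get("analysis", {})
    t_m = analysis.get("delta_beta_cutoff", 0.10)
    t_e = analysis.get("logfc_cutoff", 0.5)
    fig, ax = plt.subplots(figsize=(6, 6))
    if len(flat):
        hot = flat["quadrant"] != "none"
        ax.scatter(
            flat.loc[~hot, "delta_beta"], flat.loc[~hot, "logfc"], s=4, c="0.7", lw=0
        )
        ax.scatter(
            flat.loc[hot, "delta_beta"], flat.loc[hot, "logfc"], s=6, c="crimson", lw=0
        )
    for x in (-t_m, t_m):
        ax.axvline(x, color="k", ls="--", lw=0.8)
    for y in (-t_e, t_e):
        ax.axhline(y, color="k", ls="--", lw=0.8)
    ax.set_xlabel("delta beta (arterial - venous)")
    ax.set_ylabel("expression log2 FC (arterial - venous)")
    out = run_dir / f"starburst.{fmt}"
    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out


def _plot_gene_profile(run_dir: Path, fmt: str, gene: str | None = None) -> Path | None:
    """Per-probe group means with 95% CIs along a gene, ordered by position."""
    manifest_path = run_dir / "manifest.csv"
    if not manifest_path.exists():
        return None
    manifest = read_manifest(manifest_path)
    beta = read_matrix(run_dir / "beta.tsv")
    sheet = read_sample_sheet(run_dir / "samples.csv")
    if gene is None:
        dmr_path = run_dir / "dmr.tsv"
        if dmr_path.exists():
            dmrs = pd.read_csv(dmr_path, sep="\t")
            if len(dmrs):
                gene = str(dmrs.sort_values("n_probes", ascending=False)["gene"].iloc[0])
    if not gene:
        return None
    probes = [p for p in manifest if p.primary_gene == gene and p.probe_id in beta.index]
    probes.sort(key=lambda p: p.position)
    if not probes:
        return None
    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(1, len(probes) + 1)
    for group, marker in (("arterial", "^"), ("venous", "s")):
        members = sheet.group_samples(group)
        values = beta.loc[[p.probe_id for p in probes], members]
        mean = values.mean(axis=1)
        ci = 1.96 * values.std(axis=1, ddof=1) / np.sqrt(len(members))
        ax.errorbar(x, mean, yerr=ci, marker=marker, capsize=3, label=group)
    ax.set_ylim(0, 1)
    ax.set_xticks(x)
    ax.set_xlabel(f"{gene} probes (5' to 3')")
    ax.set_ylabel("mean beta")
    ax.legend()
    out = run_dir / f"gene_profile_{gene}.{fmt}"
    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out
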