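"""QC filtering, beta/M computation, probe-type normalization, global
methylation summaries and variability-based clustering."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .data_model import (
    AnalysisConfig,
    ArrayDataset,
    Manifest,
    MethylationMatrices,
    SampleSheet,
)

log = logging.getLogger(__name__)

MIN_NEGCTRL = 10


def compute_detection_p(dataset: ArrayDataset) -> pd.DataFrame:
    """Detection p-values from negative-control probes.

    Per sample, a Normal(mu, sigma) is fitted to the negative-control total
    intensities; a probe's detection p is the upper-tail probability of its
    total (meth + unmeth) under that background model.  If the dataset
    already carries detection p-values this step is unnecessary — use
    :func:`ensure_detection_p`.
    """
    if dataset.negctrl is None or dataset.negctrl.shape[0] < MIN_NEGCTRL:
        raise ValueError(
            f"need >= {MIN_NEGCTRL} negative-control probes to estimate detection "
            "p-values; supply a detection_p matrix instead"
        )
    total = dataset.meth + dataset.unmeth
    mu = dataset.negctrl.mean(axis=0)
    sigma = dataset.negctrl.std(axis=0, ddof=1)
    z = (total - mu) / sigma
    p = pd.DataFrame(
        stats.norm.sf(z.to_numpy()), index=total.index, columns=total.columns
    )
    return p


def ensure_detection_p(dataset: ArrayDataset) -> ArrayDataset:
    """Return a dataset that definitely carries detection p-values."""
    if dataset.detection_p is not None:
        return dataset
    detp = compute_detection_p(dataset)
    return ArrayDataset(
        annotation=dataset.annotation,
        meth=dataset.meth,
        unmeth=dataset.unmeth,
        detection_p=detp,
        samples=dataset.samples,
        negctrl=dataset.negctrl,
        qc_meta=dict(dataset.qc_meta),
    )


def qc_filter(dataset: ArrayDataset, config: AnalysisConfig) -> ArrayDataset:
    """Drop poor-performing and sex-chromosome probes.

    A probe is removed if its detection p exceeds the cutoff in *any*
    sample, or if it maps to chromosome X or Y.  Both counts are logged
    separately in ``qc_meta['qc_log']``; surviving probe order is preserved.
    """
    dataset = ensure_detection_p(dataset)
    detp = dataset.detection_p
    fails_detection = (detp > config.detection_p_cutoff).any(axis=1)
    sex = pd.Series(
        [dataset.annotation[p].is_sex_chromosome for p in dataset.probe_ids],
        index=dataset.meth.index,
    )
    keep = ~(fails_detection | sex)
    if not keep.any():
        raise ValueError("QC removed every probe; check detection p-values")
    kept_ids = list(dataset.meth.index[keep])
    out = dataset.subset_probes(kept_ids)
    out.qc_meta["qc_log"] = {
        "n_input": len(keep),
        "n_failed_detection": int(fails_detection.sum()),
        "n_sex_chromosome": int(sex.sum()),
        "n_failed_both": int((fails_detection & sex).sum()),
        "n_kept": len(kept_ids),
        "detection_p_cutoff": config.detection_p_cutoff,
    }
    return out


def compute_beta_m(
    dataset: ArrayDataset, alpha_beta: float = 0.0, alpha_m: float = 1.0
) -> MethylationMatrices:
    """Methylation fraction and log-ratio matrices.

    beta = (M + a_b) / (M + U + 2 a_b);  mvalue = log2((M + a_m) / (U + a_m)).

    With both offsets zero the identity mvalue = log2(beta / (1 - beta))
    holds exactly.  Cells with zero total intensity and alpha_beta = 0 get a
    missing beta, recorded in the qc log.
    """
    meth = dataset.meth.to_numpy(dtype=float)
    unmeth = dataset.unmeth.to_numpy(dtype=float)
    denom = meth + unmeth + 2 * alpha_beta
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (meth + alpha_beta) / denom
        mval = np.log2((meth + alpha_m) / (unmeth + alpha_m))
    n_zero_total = int((denom == 0).sum())
    beta = np.where(denom == 0, np.nan, beta)
    qc_log = dict(dataset.qc_meta.get("qc_log", {}))
    qc_log["n_zero_intensity_cells"] = n_zero_total
    return MethylationMatrices(
        beta=pd.DataFrame(beta, index=dataset.meth.index, columns=dataset.meth.columns),
        mvalue=pd.DataFrame(mval, index=dataset.meth.index, columns=dataset.meth.columns),
        kept_probe_ids=list(dataset.meth.index),
        qc_log=qc_log,
    )


MIN_PROBES_PER_TYPE = 100


def normalize_type2(
    matrices: MethylationMatrices, annotation: Manifest
) -> MethylationMatrices:
    """Map type-II beta values onto the type-I distribution, per sample.

    A monotone empirical-quantile map (linear interpolation between type-I
    order statistics) replaces each type-II beta with the type-I value of
    equal rank.  M-values are recomputed from the normalized beta via the
    logit2 identity.  This is a deliberately simple stand-in for published
    within-array probe-type normalization methods; ``qc_log`` records that
    the substitute was applied.

    Skips (with a warning) when either design type has fewer than
    ``MIN_PROBES_PER_TYPE`` probes.
    """
    is_type2 = np.array(
        [annotation[p].design_type == "II" for p in matrices.beta.index]
    )
    n1, n2 = int((~is_type2).sum()), int(is_type2.sum())
    if min(n1, n2) < MIN_PROBES_PER_TYPE:
        warnings.warn(
            f"skipping type-II normalization: only {n1} type-I / {n2} type-II probes",
            stacklevel=2,
        )
        out = MethylationMatrices(
            beta=matrices.beta.copy(),
            mvalue=matrices.mvalue.copy(),
            kept_probe_ids=list(matrices.kept_probe_ids),
            qc_log={**matrices.qc_log, "type2_normalization": "skipped"},
        )
        return out

    beta = matrices.beta.to_numpy(dtype=float).copy()
    for j in range(beta.shape[1]):
        col = beta[:, j]
        ref = np.sort(col[~is_type2 & np.isfinite(col)])
        target_mask = is_type2 & np.isfinite(col)
        target = col[target_mask]
        # mid-ranks -> plotting positions in (0, 1), ties averaged
        ranks = stats.rankdata(target, method="average")
        q = (ranks - 0.5) / len(target)
        grid = (np.arange(len(ref)) + 0.5) / len(ref)
        mapped = np.interp(q, grid, ref)
        col[target_mask] = mapped
        beta[:, j] = col
    beta = np.clip(beta, 0.0, 1.0)
    eps = 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        mval = np.log2(np.clip(beta, eps, 1 - eps) / np.clip(1 - beta, eps, 1 - eps))
    return MethylationMatrices(
        beta=pd.DataFrame(beta, index=matrices.beta.index, columns=matrices.beta.columns),
        mvalue=pd.DataFrame(mval, index=matrices.beta.index, columns=matrices.beta.columns),
        kept_probe_ids=list(matrices.kept_probe_ids),
        qc_log={**matrices.qc_log, "type2_normalization": "quantile_substitute"},
    )


@dataclass
class GlobalMethylationSummary:
    """Mean beta per sample and per group, as a global-methylation proxy."""

    per_sample_mean_beta: dict[str, float]
    per_group_mean_beta: dict[str, float]


def global_methylation(
    matrices: MethylationMatrices, sheet: SampleSheet
) -> GlobalMethylationSummary:
    if matrices.beta.size == 0:
        raise ValueError("empty beta matrix")
    per_sample = matrices.beta.mean(axis=0, skipna=True)
    per_group = {}
    for group in sheet.frame["group"].unique():
        members = sheet.group_samples(group)
        per_group[group] = float(per_sample[members].mean())
    return GlobalMethylationSummary(
        per_sample_mean_beta={k: float(v) for k, v in per_sample.items()},
        per_group_mean_beta=per_group,
    )


def probe_cv(matrices: MethylationMatrices) -> pd.Series:
    """Coefficient of variation (sample SD / sample mean) of beta per probe.

    Computed on beta, not M-values — M-values can be negative, which makes
    SD/mean meaningless.  Probes with mean beta 0 are returned as NaN.
    """
    if matrices.beta.shape[1] < 2:
        raise ValueError("need >= 2 samples to compute variability")
    mean = matrices.beta.mean(axis=1)
    sd = matrices.beta.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    cv[mean == 0] = np.nan
    return cv


def select_variable_probes(
    matrices: MethylationMatrices, config: AnalysisConfig
) -> list[str]:
    """Probes whose beta CV exceeds ``config.cv_cutoff``."""
    cv = probe_cv(matrices)
    return list(cv.index[cv > config.cv_cutoff])


def top_variable(matrices: MethylationMatrices, n: int) -> list[str]:
    """The n probes of largest CV; ties broken by probe id."""
    cv = probe_cv(matrices).dropna()
    if n >= len(cv):
        if n > len(cv):
            warnings.warn(
                f"requested top {n} probes but only {len(cv)} available", stacklevel=2
            )
        n = len(cv)
    order = sorted(cv.index, key=lambda pid: (-cv[pid], pid))
    return order[:n]


@dataclass
class ClusteringResult:
    selected_probe_ids: list[str]
    linkage: np.ndarray  # scipy linkage matrix, (n_samples - 1) x 4
    sample_order: list[str]
    k2_labels: dict[str, int]

    def merge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage, columns=["left", "right", "height", "size"]
        )


def hierarchical_cluster(
    matrices: MethylationMatrices,
    probe_ids: list[str] | None = None,
    metric: str = "euclidean",
    method: str = "average",
) -> ClusteringResult:
    """Agglomerative clustering of samples on M-values.

    Euclidean distance with average linkage by default (both overridable).
    ``k2_labels`` come from cutting the dendrogram into two clusters.
    """
    values = matrices.mvalue if probe_ids is None else matrices.mvalue.loc[probe_ids]
    if values.shape[1] < 2 or values.shape[0] < 2:
        raise ValueError("need >= 2 samples and >= 2 probes to cluster")
    x = values.to_numpy(dtype=float).T  # samples x probes
    dist = pdist(x, metric=metric)
    z = hierarchy.linkage(dist, method=method)
    order = hierarchy.leaves_list(z)
    samples = list(values.columns)
    labels = hierarchy.fcluster(z, t=2, criterion="maxclust")
    return ClusteringResult(
        selected_probe_ids=list(values.index),
        linkage=z,
        sample_order=[samples[i] for i in order],
        k2_labels={s: int(l) for s, l in zip(samples, labels)},
    )
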