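"""Per-probe two-group inference with empirical-Bayes variance moderation,
step-up FDR adjustment, DMP calling, DMR chaining and expression log-fold
changes.

The moderated test shrinks each probe's variance toward a prior (d0, s0^2)
estimated across probes by matching the first two moments of log s^2 to a
scaled-F prior (digamma/trigamma moment equations).  Tests are run on
M-values; effect sizes and the effect-size gate are on the beta scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .data_model import (
    ARTERIAL,
    VENOUS,
    AnalysisConfig,
    ExpressionMatrix,
    Manifest,
    SampleSheet,
)

HYPER_IN_ARTERIAL = "hyper_in_arterial"
HYPER_IN_VENOUS = "hyper_in_venous"
NO_DIRECTION = "none"


@dataclass(frozen=True)
class EbayesHyperparams:
    """Prior degrees of freedom (may be +inf) and prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be > 0")
        if not (np.isfinite(self.s0_sq) and self.s0_sq > 0):
            raise ValueError("s0_sq must be finite and > 0")


def group_stats(
    values: pd.DataFrame, sheet: SampleSheet, paired: bool = False
) -> pd.DataFrame:
    """Per-row group means, difference variance and residual df.

    Unpaired: pooled within-group variance with df = n_A + n_V - 2.
    Paired: variance of the per-pair (arterial - venous) differences with
    df = n_pairs - 1.

    Returns a DataFrame with columns mean_a, mean_v, s2, df, n_a, n_v.
    """
    a_ids = sheet.group_samples(ARTERIAL)
    v_ids = sheet.group_samples(VENOUS)
    if len(a_ids) < 2 or len(v_ids) < 2:
        raise ValueError("need >= 2 samples in each group")
    a = values[a_ids].to_numpy(dtype=float)
    v = values[v_ids].to_numpy(dtype=float)
    mean_a = a.mean(axis=1)
    mean_v = v.mean(axis=1)
    if paired:
        pairs = sheet.pairs()
        if len(pairs) < 2:
            raise ValueError("paired design requires >= 2 complete pairs")
        diffs = (
            values[pairs["arterial"].tolist()].to_numpy(dtype=float)
            - values[pairs["venous"].tolist()].to_numpy(dtype=float)
        )
        s2 = diffs.var(axis=1, ddof=1)
        df = float(len(pairs) - 1)
    else:
        ss_a = ((a - mean_a[:, None]) ** 2).sum(axis=1)
        ss_v = ((v - mean_v[:, None]) ** 2).sum(axis=1)
        df = float(len(a_ids) + len(v_ids) - 2)
        s2 = (ss_a + ss_v) / df
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_v": mean_v,
            "s2": s2,
            "df": df,
            "n_a": len(a_ids),
            "n_v": len(v_ids),
        },
        index=values.index,
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def eb_fit(s_sq: np.ndarray | pd.Series, d_g: float) -> EbayesHyperparams:
    """Estimate the variance prior from the observed probe variances.

    With e = log(s^2) - digamma(d_g/2) + log(d_g/2):

    * d0 solves trigamma(d0/2) = var(e) - trigamma(d_g/2);
    * s0^2 = exp(mean(e) + digamma(d0/2) - log(d0/2)).

    When var(e) <= trigamma(d_g/2) the data are consistent with a common
    variance: d0 = +inf and s0^2 = exp(mean(e)).
    """
    s = np.asarray(s_sq, dtype=float)
    s = s[np.isfinite(s)]
    positive = s[s > 0]
    if positive.size == 0:
        raise ValueError("all probe variances are zero; cannot fit a variance prior")
    if positive.size < 50:
        raise ValueError(f"need >= 50 positive variances, got {positive.size}")
    e = np.log(positive) - special.digamma(d_g / 2.0) + math.log(d_g / 2.0)
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, d_g / 2.0))
    if excess <= 0:
        return EbayesHyperparams(d0=math.inf, s0_sq=float(np.exp(np.mean(e))))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(
        np.exp(np.mean(e) + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    )
    return EbayesHyperparams(d0=d0, s0_sq=s0_sq)


def moderated_t(
    group: pd.DataFrame,
    hyper: EbayesHyperparams | None,
    paired: bool = False,
) -> pd.DataFrame:
    """Moderated (or plain) two-group t-statistics per row.

    s~^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g); the standard error is
    s~ * sqrt(1/n_A + 1/n_V) (unpaired) or s~ / sqrt(n_pairs) (paired, where
    s~^2 moderates the variance of pair differences).  Total df = d0 + d_g,
    with d0 = +inf handled as a Normal reference.  Pass ``hyper=None`` (or
    d0 = 0 conceptually) for the classical unmoderated test.

    Returns columns t_stat, df, p_value.
    """
    s2 = group["s2"].to_numpy(dtype=float)
    dg = group["df"].to_numpy(dtype=float)
    if hyper is None:
        s2_post = s2
        df_total = dg
    elif math.isinf(hyper.d0):
        s2_post = np.full_like(s2, hyper.s0_sq)
        df_total = np.full_like(dg, np.inf)
    else:
        s2_post = (hyper.d0 * hyper.s0_sq + dg * s2) / (hyper.d0 + dg)
        df_total = dg + hyper.d0
    diff = (group["mean_a"] - group["mean_v"]).to_numpy(dtype=float)
    if paired:
        n_pairs = group["n_a"].to_numpy(dtype=float)  # complete pairs == n_a
        se = np.sqrt(s2_post / n_pairs)
    else:
        n_a = group["n_a"].to_numpy(dtype=float)
        n_v = group["n_v"].to_numpy(dtype=float)
        se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_v))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    t = np.where((diff == 0) & (se == 0), 0.0, t)
    finite_df = np.isfinite(df_total)
    p = np.empty_like(t)
    p[finite_df] = 2.0 * stats.t.sf(np.abs(t[finite_df]), df_total[finite_df])
    p[~finite_df] = 2.0 * stats.norm.sf(np.abs(t[~finite_df]))
    p = np.where(np.isnan(t), np.nan, p)
    return pd.DataFrame(
        {"t_stat": t, "df": df_total, "p_value": np.clip(p, 0.0, 1.0)},
        index=group.index,
    )


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Step-up false-discovery-rate adjustment.

    adj_(i) = min_{j >= i} (m * p_(j) / j), capped at 1, returned in the
    input order.  Ties are handled stably.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = arr.size
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m, dtype=float)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def call_dmps(
    beta_group: pd.DataFrame,
    m_test: pd.DataFrame,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Combine beta-scale effect sizes with M-value tests into DMP calls.

    is_dmp requires adj_p <= fdr_cutoff (inclusive) and
    |delta_beta| >= delta_beta_cutoff (inclusive); direction follows the
    sign of delta_beta (arterial minus venous).
    """
    if not beta_group.index.equals(m_test.index):
        raise ValueError("beta and M-value results must cover identical probes")
    delta = beta_group["mean_a"] - beta_group["mean_v"]
    adj = bh_adjust(m_test["p_value"].to_numpy())
    is_dmp = (adj <= config.fdr_cutoff) & (delta.abs() >= config.delta_beta_cutoff)
    direction = np.where(
        ~is_dmp, NO_DIRECTION, np.where(delta > 0, HYPER_IN_ARTERIAL, HYPER_IN_VENOUS)
    )
    out = pd.DataFrame(
        {
            "probe_id": beta_group.index,
            "mean_beta_arterial": beta_group["mean_a"].to_numpy(),
            "mean_beta_venous": beta_group["mean_v"].to_numpy(),
            "delta_beta": delta.to_numpy(),
            "t_stat": m_test["t_stat"].to_numpy(),
            "df": m_test["df"].to_numpy(),
            "p_value": m_test["p_value"].to_numpy(),
            "adj_p": adj,
            "is_dmp": is_dmp.to_numpy(),
            "direction": direction,
        }
    ).set_index("probe_id", drop=False)
    out.index.name = None
    return out


def aggregate_dmrs(
    dmps: pd.DataFrame,
    annotation: Manifest,
    min_probes: int = 3,
    max_gap: int = 1000,
) -> pd.DataFrame:
    """Chain consecutive same-direction DMPs into regions.

    Within each chromosome, DMPs are sorted by position and greedily chained
    while direction and primary gene stay constant and the inter-probe gap
    is <= ``max_gap``.  Chains with >= ``min_probes`` members become regions.

    Returns a DataFrame: gene, chromosome, start, end (1-based inclusive),
    n_probes, probe_ids (';' joined), direction, mean_delta_beta.
    """
    called = dmps[dmps["is_dmp"]]
    rows = []
    for pid, delta, direction in zip(
        called["probe_id"], called["delta_beta"], called["direction"]
    ):
        if pid not in annotation:
            continue
        probe = annotation[pid]
        rows.append(
            (probe.chromosome, probe.position, pid, delta, direction, probe.primary_gene)
        )
    rows.sort(key=lambda r: (r[0], r[1]))

    regions = []

    def flush(chain):
        if len(chain) >= min_probes:
            regions.append(
                {
                    "gene": chain[0][5],
                    "chromosome": chain[0][0],
                    "start": chain[0][1],
                    "end": chain[-1][1],
                    "n_probes": len(chain),
                    "probe_ids": ";".join(c[2] for c in chain),
                    "direction": chain[0][4],
                    "mean_delta_beta": float(np.mean([c[3] for c in chain])),
                }
            )

    chain: list = []
    for row in rows:
        if chain and (
            row[0] != chain[-1][0]
            or row[4] != chain[-1][4]
            or row[5] != chain[-1][5]
            or row[1] - chain[-1][1] > max_gap
        ):
            flush(chain)
            chain = []
        chain.append(row)
    flush(chain)
    return pd.DataFrame(
        regions,
        columns=[
            "gene",
            "chromosome",
            "start",
            "end",
            "n_probes",
            "probe_ids",
            "direction",
            "mean_delta_beta",
        ],
    )


def expression_logfc(
    expr: ExpressionMatrix, config: AnalysisConfig
) -> pd.DataFrame:
    """Per-gene log2 fold change (arterial minus venous) with moderated tests.

    Returns a DataFrame indexed by gene: logfc, t_stat, df, p_value, adj_p.
    """
    group = group_stats(expr.values, expr.samples, paired=config.paired_design)
    hyper = None
    if config.use_moderated_t and (group["s2"] > 0).sum() >= 50:
        hyper = eb_fit(group["s2"].to_numpy(), float(group["df"].iloc[0]))
    test = moderated_t(group, hyper, paired=config.paired_design)
    out = pd.DataFrame(
        {
            "gene": group.index,
            "logfc": (group["mean_a"] - group["mean_v"]).to_numpy(),
            "t_stat": test["t_stat"].to_numpy(),
            "df": test["df"].to_numpy(),
            "p_value": test["p_value"].to_numpy(),
            "adj_p": bh_adjust(test["p_value"].to_numpy()),
        }
    ).set_index("gene", drop=False)
    out.index.name = None
    return out


def differential_analysis(
    matrices,
    sheet: SampleSheet,
    config: AnalysisConfig,
) -> tuple[pd.DataFrame, EbayesHyperparams | None]:
    """Full per-probe pipeline: beta means + moderated M-value tests -> DMPs."""
    beta_group = group_stats(matrices.beta, sheet, paired=config.paired_design)
    m_group = group_stats(matrices.mvalue, sheet, paired=config.paired_design)
    hyper = None
    if config.use_moderated_t:
        hyper = eb_fit(m_group["s2"].to_numpy(), float(m_group["df"].iloc[0]))
    m_test = moderated_t(m_group, hyper, paired=config.paired_design)
    dmps = call_dmps(beta_group, m_test, config)
    return dmps, hyper
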