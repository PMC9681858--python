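"""Cluster-specific differentially methylated region (DMR) calling.

One-vs-rest contrasts over classifiable samples: per-CpG Welch t-tests with
Benjamini-Hochberg FDR control, greedy grouping of significant same-direction
CpGs along each chromosome (gap <= 1 kb, >= 2 CpGs), retention of regions
whose mean beta difference exceeds 0.30 in absolute value, and nearest-gene
linkage within 20 kb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .genome import CHROM_ORDER

__all__ = ["DMRParams", "cpg_stats", "call_dmrs", "link_genes", "cluster_dmrs", "write_bed"]


@dataclass
class DMRParams:
    fdr_alpha: float = 0.05
    max_gap_bp: int = 1000
    min_cpgs: int = 2
    min_abs_delta: float = 0.30
    gene_max_dist_bp: int = 20_000

    def __post_init__(self):
        if min(self.fdr_alpha, self.max_gap_bp, self.min_cpgs, self.gene_max_dist_bp) <= 0:
            raise ValueError("all parameters must be positive")
        if not 0 < self.min_abs_delta < 1:
            raise ValueError("min_abs_delta must lie in (0, 1)")


def cpg_stats(beta: pd.DataFrame, labels: pd.Series, cluster) -> pd.DataFrame:
    """Per-CpG one-vs-rest statistics for ``cluster``.

    delta = mean beta(cluster) − mean beta(rest); p from Welch's two-sample
    t-test; FDR by Benjamini-Hochberg over tested CpGs. CpGs constant in both
    groups are flagged (``tested`` False) and excluded from the FDR.
    """
    labels = labels.loc[beta.columns]
    in_c = (labels == cluster).to_numpy()
    if in_c.sum() < 3 or (~in_c).sum() < 3:
        raise ValueError("need >= 3 samples in the cluster and >= 3 in the rest")
    A = beta.to_numpy(dtype=float)[:, in_c]
    B = beta.to_numpy(dtype=float)[:, ~in_c]
    delta = A.mean(axis=1) - B.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(A, B, axis=1, equal_var=False)
    tested = np.isfinite(p)
    fdr = np.full(p.shape, np.nan)
    if tested.any():
        fdr[tested] = multipletests(p[tested], method="fdr_bh")[1]
    return pd.DataFrame(
        {"delta": delta, "t": t, "p": p, "fdr": fdr, "tested": tested},
        index=beta.index,
    )


def call_dmrs(
    stats: pd.DataFrame, manifest: pd.DataFrame, params: DMRParams | None = None,
    cluster=None,
) -> pd.DataFrame:
    """Group significant CpGs into regions and apply the |mean delta| filter.

    Significant CpGs (FDR < fdr_alpha) sharing a delta sign are grouped
    greedily along each chromosome while consecutive gaps stay <= max_gap_bp;
    groups with >= min_cpgs CpGs become candidate regions (1-based inclusive,
    first to last member CpG); regions are kept when |mean delta over member
    CpGs| > min_abs_delta (strict).
    """
    params = params or DMRParams()
    man = manifest.loc[stats.index]
    sig = stats[(stats["tested"]) & (stats["fdr"] < params.fdr_alpha)]
    records = []
    for chrom, probes in sig.groupby(man.loc[sig.index, "chrom"], sort=False):
        sub = man.loc[probes.index].sort_values("pos")
        pos = sub["pos"].to_numpy()
        delta = probes.loc[sub.index, "delta"].to_numpy()
        fdr = probes.loc[sub.index, "fdr"].to_numpy()
        sign = np.sign(delta)
        new_group = np.ones(pos.size, dtype=bool)
        if pos.size > 1:
            new_group[1:] = (np.diff(pos) > params.max_gap_bp) | (sign[1:] != sign[:-1])
        group_id = np.cumsum(new_group)
        for g in np.unique(group_id):
            m = group_id == g
            if m.sum() < params.min_cpgs:
                continue
            mean_delta = float(delta[m].mean())
            if abs(mean_delta) <= params.min_abs_delta:
                continue
            records.append(
                {
                    "cluster": cluster,
                    "chrom": chrom,
                    "start": int(pos[m][0]),
                    "end": int(pos[m][-1]),
                    "n_cpgs": int(m.sum()),
                    "mean_delta_beta": mean_delta,
                    "direction": "hyper" if mean_delta > 0 else "hypo",
                    "min_fdr": float(fdr[m].min()),
                }
            )
    cols = ["cluster", "chrom", "start", "end", "n_cpgs", "mean_delta_beta", "direction", "min_fdr"]
    out = pd.DataFrame(records, columns=cols)
    if len(out):
        out = out.sort_values(
            ["chrom", "start"], key=lambda s: s.map(CHROM_ORDER) if s.name == "chrom" else s
        ).reset_index(drop=True)
    return out


def link_genes(
    dmrs: pd.DataFrame, genes: pd.DataFrame, max_dist: int = 20_000
) -> pd.DataFrame:
    """Annotate each DMR with its nearest gene (minimal interval distance,
    0 when overlapping; ties break to the lexicographically smallest name).
    DMRs farther than ``max_dist`` from every gene get nearest_gene = None."""
    out = dmrs.copy()
    out["nearest_gene"] = None
    out["gene_distance"] = np.nan
    if genes is None or len(genes) == 0:
        return out
    for i, d in dmrs.iterrows():
        cand = genes[genes["chrom"] == str(d["chrom"])]
        if cand.empty:
            continue
        dist = np.maximum(
            0,
            np.maximum(cand["start"] - d["end"], d["start"] - cand["end"]),
        ).to_numpy()
        best = np.min(dist)
        if best > max_dist:
            continue
        names = sorted(cand.loc[dist == best, "gene"])
        out.at[i, "nearest_gene"] = names[0]
        out.at[i, "gene_distance"] = float(best)
    return out


def cluster_dmrs(
    beta: pd.DataFrame,
    labels: pd.Series,
    manifest: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    params: DMRParams | None = None,
) -> pd.DataFrame:
    """One-vs-rest DMRs for every cluster label, gene-linked if ``genes``."""
    params = params or DMRParams()
    frames = []
    for c in sorted(pd.unique(labels)):
        stats = cpg_stats(beta, labels, c)
        frames.append(call_dmrs(stats, manifest, params, cluster=c))
    dmrs = pd.concat(frames, ignore_index=True)
    if genes is not None:
        dmrs = link_genes(dmrs, genes, params.gene_max_dist_bp)
    return dmrs


def write_bed(dmrs: pd.DataFrame, path) -> None:
    """BED output (0-based half-open) with name = cluster:direction."""
    bed = pd.DataFrame(
        {
            "chrom": dmrs["chrom"],
            "start": dmrs["start"] - 1,
            "end": dmrs["end"],
            "name": dmrs["cluster"].astype(str) + ":" + dmrs["direction"],
            "score": (1000 * dmrs["mean_delta_beta"].abs()).astype(int),
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)
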