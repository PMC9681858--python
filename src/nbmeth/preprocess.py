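"""Probe-level QC filtering, beta-value computation and variance selection.

The filter chain reproduces standard Infinium practice for tumour subgrouping:
drop probes that fail detection in at least half the cohort, cross-reactive
probes, sex-chromosome probes, and probes with a proximal common SNP
(distance <= 2 bp from the CpG, minor allele frequency >= 5%); then keep the
most variable probes by standard deviation for clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "PreprocessParams",
    "FilterReport",
    "compute_beta",
    "filter_probes",
    "select_top_variable",
]


@dataclass
class PreprocessParams:
    beta_offset: float = 100.0
    det_alpha: float = 0.01
    det_frac: float = 0.5
    snp_maf_min: float = 0.05
    snp_dist_max: int = 2
    drop_sex_chroms: bool = True
    drop_cross_reactive: bool = True
    top_k: int = 10_000

    def __post_init__(self):
        if not 0 < self.det_alpha < 1 or not 0 < self.det_frac <= 1:
            raise ValueError("detection thresholds out of range")
        if self.top_k < 2:
            raise ValueError("top_k must be >= 2")


@dataclass
class FilterReport:
    """Removal counts per rule, in application order. A probe removed by an
    earlier rule is not re-counted by a later one."""

    n_input: int
    n_detection: int = 0
    n_cross_reactive: int = 0
    n_sex_chrom: int = 0
    n_snp: int = 0

    @property
    def n_removed(self) -> int:
        return self.n_detection + self.n_cross_reactive + self.n_sex_chrom + self.n_snp

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed


def compute_beta(M: pd.DataFrame, U: pd.DataFrame, offset: float = 100.0) -> pd.DataFrame:
    """beta = M / (M + U + offset), elementwise; values lie in [0, 1]."""
    if M.shape != U.shape:
        raise ValueError(f"M and U shapes differ: {M.shape} vs {U.shape}")
    if (M.to_numpy() < 0).any() or (U.to_numpy() < 0).any():
        raise ValueError("negative intensities")
    return M / (M + U + offset)


def filter_probes(
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    detp: pd.DataFrame | None = None,
    params: PreprocessParams | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the probe QC filters in order; returns the retained beta matrix
    and a per-rule removal report.

    Rules, in order: (1) detection failure — p > det_alpha in >= det_frac of
    samples (requires ``detp``); (2) cross-reactive; (3) sex chromosome;
    (4) SNP-proximal — snp_dist_bp <= snp_dist_max AND snp_maf >= snp_maf_min
    (both boundaries inclusive).
    """
    params = params or PreprocessParams()
    man = manifest.loc[beta.index]
    report = FilterReport(n_input=len(beta))
    removed = pd.Series(False, index=beta.index)

    if detp is not None:
        fail_frac = (detp.loc[beta.index] > params.det_alpha).mean(axis=1)
        hit = fail_frac >= params.det_frac
        report.n_detection = int(hit.sum())
        removed |= hit

    if params.drop_cross_reactive:
        hit = man["cross_reactive"].astype(bool) & ~removed
        report.n_cross_reactive = int(hit.sum())
        removed |= hit

    if params.drop_sex_chroms:
        hit = man["chrom"].isin(["X", "Y"]) & ~removed
        report.n_sex_chrom = int(hit.sum())
        removed |= hit

    snp_hit = (
        (man["snp_dist_bp"] <= params.snp_dist_max)
        & (man["snp_maf"] >= params.snp_maf_min)
    ).fillna(False) & ~removed
    report.n_snp = int(snp_hit.sum())
    removed |= snp_hit

    return beta.loc[~removed], report


def select_top_variable(beta: pd.DataFrame, k: int) -> pd.DataFrame:
    """Keep the k probes with the largest sample standard deviation (ddof=1).

    Original probe order is preserved within the selection; ties in SD break
    by lexicographic probe id.
    """
    if k > len(beta):
        raise ValueError(f"k={k} exceeds number of probes ({len(beta)})")
    sd = beta.std(axis=1, ddof=1)
    order = sorted(beta.index, key=lambda p: (-sd[p], p))
    keep = set(order[:k])
    return beta.loc[[p for p in beta.index if p in keep]]
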