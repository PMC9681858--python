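"""Methylation-derived copy-number calling.

Combined methylated + unmethylated probe intensities are normalised against a
panel of copy-neutral reference samples, binned along each chromosome arm
into windows satisfying both a minimum span (50 kb) and a minimum probe count
(15), and summarised as per-bin median log2 ratios. From the bins the caller
derives arm-level gain/loss calls, whole-chromosome aberrations (WCA, both
arms moving in the same direction), segmental aberrations (SCA, sub-arm runs
of shifted bins on chromosomes without a WCA) and focal amplification /
homozygous-deletion calls over a supplied gene table. Sex chromosomes are
retained here — the clustering path drops them, the copy-number path does not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import CHROM_ORDER

log = logging.getLogger(__name__)

__all__ = [
    "CNAParams",
    "CNAProfile",
    "normalize_to_reference",
    "bin_genome",
    "call_events",
    "profile_samples",
    "write_seg",
]


@dataclass
class CNAParams:
    min_bin_bases: int = 50_000
    min_bin_probes: int = 15
    call_threshold: float = 0.1
    amp_threshold: float = 1.0
    homdel_threshold: float = -1.0
    min_seg_bins: int = 3

    def __post_init__(self):
        if not (self.homdel_threshold < -self.call_threshold < 0 < self.call_threshold < self.amp_threshold):
            raise ValueError("thresholds must satisfy homdel < -call < 0 < call < amp")


@dataclass
class CNAProfile:
    sample: str
    bins: pd.DataFrame  # chrom, arm, start, end, n_probes, log2_ratio
    arm_calls: dict[tuple[str, str], str]  # (chrom, arm) -> gain|loss|neutral
    wca: list[tuple[str, str]]  # (chrom, direction)
    sca: list[dict]  # chrom, arm, start, end, direction, n_bins
    focal: list[dict]  # gene, direction, log2
    n_wca: int = 0
    has_sca: bool = False

    def arm_event_labels(self) -> set[str]:
        """e.g. {'1p-', '17q+'} for non-neutral arm calls."""
        out = set()
        for (chrom, arm), call in self.arm_calls.items():
            if call != "neutral":
                out.add(f"{chrom}{arm}{'+' if call == 'gain' else '-'}")
        return out


def normalize_to_reference(
    sample_totals: pd.DataFrame, reference_totals: pd.DataFrame
) -> pd.DataFrame:
    """Per-probe log2 ratios of combined intensities against a reference panel.

    The per-probe reference profile is the median across reference samples.
    Each query sample is globally rescaled so its median total intensity
    matches the reference profile's median, then log2(sample / reference) is
    taken per probe.
    """
    if reference_totals.shape[1] < 1:
        raise ValueError("need at least one reference sample")
    S = sample_totals.to_numpy(dtype=float)
    R = reference_totals.loc[sample_totals.index].to_numpy(dtype=float)
    if (S <= 0).any() or (R <= 0).any():
        raise ValueError("intensities must be positive")
    ref_profile = np.median(R, axis=1)
    scale = np.median(ref_profile) / np.median(S, axis=0)
    ratios = np.log2(S * scale[None, :] / ref_profile[:, None])
    return pd.DataFrame(ratios, index=sample_totals.index, columns=sample_totals.columns)


def bin_genome(
    ratios: pd.Series, manifest: pd.DataFrame, params: CNAParams | None = None
) -> pd.DataFrame:
    """Greedy left-to-right binning of per-probe log2 ratios within each arm.

    A bin is closed once it spans >= min_bin_bases AND holds >= min_bin_probes
    probes; a trailing bin failing either minimum is merged into its left
    neighbour, or dropped when the arm produced none. Bin value = median probe
    ratio. Arms with fewer than min_bin_probes probes yield no bins.
    """
    params = params or CNAParams()
    man = manifest.loc[ratios.index]
    rows = []
    order = sorted(
        man.groupby(["chrom", "arm"], sort=False).groups.items(),
        key=lambda kv: (CHROM_ORDER[kv[0][0]], kv[0][1]),
    )
    for (chrom, arm), idx in order:
        sub = man.loc[idx].sort_values("pos")
        pos = sub["pos"].to_numpy()
        vals = ratios.loc[sub.index].to_numpy(dtype=float)
        if pos.size < params.min_bin_probes:
            log.debug("arm %s%s has %d probes (<%d): no bins", chrom, arm, pos.size, params.min_bin_probes)
            continue
        arm_bins = []
        start_i = 0
        for i in range(pos.size):
            n_in = i - start_i + 1
            span = pos[i] - pos[start_i] + 1
            if span >= params.min_bin_bases and n_in >= params.min_bin_probes:
                arm_bins.append((start_i, i))
                start_i = i + 1
        if start_i < pos.size:  # trailing incomplete bin
            if arm_bins:
                lo, _ = arm_bins.pop()
                arm_bins.append((lo, pos.size - 1))
            # else: arm cannot satisfy the minima at all — no bins
        for lo, hi in arm_bins:
            rows.append(
                {
                    "chrom": chrom,
                    "arm": arm,
                    "start": int(pos[lo]),
                    "end": int(pos[hi]),
                    "n_probes": hi - lo + 1,
                    "log2_ratio": float(np.median(vals[lo : hi + 1])),
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "arm", "start", "end", "n_probes", "log2_ratio"]
    )


def call_events(
    bins: pd.DataFrame,
    params: CNAParams | None = None,
    gene_map: pd.DataFrame | None = None,
    sample: str = "",
) -> CNAProfile:
    """Derive arm, whole-chromosome, segmental and focal calls from bins.

    Arm call: median bin value vs ±call_threshold. WCA: both arms of a
    chromosome non-neutral in the same direction (single-armed chromosomes,
    e.g. acrocentrics, are called on the available arm alone). SCA: a run of
    >= min_seg_bins consecutive same-direction out-of-threshold bins on an
    arm of a chromosome without a WCA. Focal: any bin overlapping a gene in
    ``gene_map`` beyond the amplification / homozygous-deletion thresholds.
    """
    params = params or CNAParams()
    arm_calls: dict[tuple[str, str], str] = {}
    for (chrom, arm), sub in bins.groupby(["chrom", "arm"], sort=False):
        med = float(sub["log2_ratio"].median())
        call = "gain" if med > params.call_threshold else (
            "loss" if med < -params.call_threshold else "neutral"
        )
        arm_calls[(chrom, arm)] = call

    wca: list[tuple[str, str]] = []
    by_chrom: dict[str, list[str]] = {}
    for (chrom, arm), call in arm_calls.items():
        by_chrom.setdefault(chrom, []).append(call)
    for chrom, calls in by_chrom.items():
        if len(set(calls)) == 1 and calls[0] != "neutral":
            if len(calls) == 1:
                log.debug("chromosome %s: single-arm WCA call (%s)", chrom, calls[0])
            wca.append((chrom, calls[0]))
    wca_chroms = {c for c, _ in wca}

    sca: list[dict] = []
    for (chrom, arm), sub in bins.groupby(["chrom", "arm"], sort=False):
        if chrom in wca_chroms:
            continue
        vals = sub.sort_values("start")
        direc = np.where(
            vals["log2_ratio"] > params.call_threshold, 1,
            np.where(vals["log2_ratio"] < -params.call_threshold, -1, 0),
        )
        starts = vals["start"].to_numpy()
        ends = vals["end"].to_numpy()
        i = 0
        while i < len(direc):
            if direc[i] == 0:
                i += 1
                continue
            j = i
            while j + 1 < len(direc) and direc[j + 1] == direc[i]:
                j += 1
            if j - i + 1 >= params.min_seg_bins:
                sca.append(
                    {
                        "chrom": chrom,
                        "arm": arm,
                        "start": int(starts[i]),
                        "end": int(ends[j]),
                        "direction": "gain" if direc[i] > 0 else "loss",
                        "n_bins": int(j - i + 1),
                    }
                )
            i = j + 1

    focal: list[dict] = []
    if gene_map is not None and len(bins):
        for _, g in gene_map.iterrows():
            hit = bins[
                (bins["chrom"] == str(g["chrom"]))
                & (bins["start"] <= g["end"])
                & (bins["end"] >= g["start"])
            ]
            if hit.empty:
                continue
            top = float(hit["log2_ratio"].max())
            bot = float(hit["log2_ratio"].min())
            if top >= params.amp_threshold:
                focal.append({"gene": g["gene"], "direction": "amplification", "log2": top})
            elif bot <= params.homdel_threshold:
                focal.append({"gene": g["gene"], "direction": "deletion", "log2": bot})

    return CNAProfile(
        sample=sample,
        bins=bins,
        arm_calls=arm_calls,
        wca=wca,
        sca=sca,
        focal=focal,
        n_wca=len(wca),
        has_sca=bool(sca),
    )


def profile_samples(
    totals: pd.DataFrame,
    reference_totals: pd.DataFrame,
    manifest: pd.DataFrame,
    params: CNAParams | None = None,
    gene_map: pd.DataFrame | None = None,
) -> dict[str, CNAProfile]:
    """Normalise, bin and call every sample column of ``totals``."""
    params = params or CNAParams()
    ratios = normalize_to_reference(totals, reference_totals)
    profiles = {}
    for s in ratios.columns:
        bins = bin_genome(ratios[s], manifest, params)
        profiles[s] = call_events(bins, params, gene_map, sample=s)
    return profiles


def write_seg(profiles: dict[str, CNAProfile], path) -> None:
    """SEG-style TSV: sample, chrom, start, end (1-based inclusive),
    n_probes, log2."""
    rows = []
    for s, prof in profiles.items():
        for _, b in prof.bins.iterrows():
            rows.append(
                {
                    "sample": s,
                    "chrom": b["chrom"],
                    "start": b["start"],
                    "end": b["end"],
                    "n_probes": b["n_probes"],
                    "log2": b["log2_ratio"],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.4f")
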