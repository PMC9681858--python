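"""Synthetic Infinium-style methylation cohorts with known ground truth.

The generator emulates the data a 450k-style methylation array produces for a
neuroblastoma-like cohort: a CpG-island-clustered probe manifest, bimodal
beta-value distributions, a configurable number of planted methylation
subgroups that differ in block-shaped differentially methylated regions
(DMRs), copy-number events expressed as multiplicative shifts of combined
probe intensity, cluster-correlated clinical covariates, and cluster-dependent
exponential survival with independent censoring.

Every output is a deterministic function of (config, seed). The emitted
beta matrix is recomputed from the emitted intensities as M/(M+U+offset), so
the intensity and beta views of a cohort are exactly consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nbio
from .genome import ACROCENTRIC, AUTOSOMES, CHROMOSOMES, SEX_CHROMS

__all__ = [
    "ConfigError",
    "CNAEvent",
    "SimConfig",
    "GroundTruth",
    "Cohort",
    "default_cna_events",
    "default_clinical_model",
    "default_gene_map",
    "generate_manifest",
    "generate_cohort",
    "generate_survival",
    "write_cohort",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# hg19 coordinates of loci recurrently altered in neuroblastoma
GENE_COORDS: dict[str, tuple[str, int, int]] = {
    "MYCN": ("2", 16_080_683, 16_087_129),
    "TERT": ("5", 1_253_287, 1_295_162),
    "PTPRD": ("9", 8_314_246, 10_612_723),
    "CDKN2A": ("9", 21_967_751, 21_995_300),
}


@dataclass(frozen=True)
class CNAEvent:
    """A planted copy-number event.

    ``log2_shift`` is the magnitude of the log2 intensity shift; its sign is
    taken from ``direction``. Gains/losses are sub-integer shifts, focal
    amplifications/deletions are >= 1.
    """

    kind: str  # whole | arm | segment | focal
    chrom: str
    direction: str  # gain | loss | amplification | deletion
    log2_shift: float
    carrier_clusters: frozenset[int]
    penetrance: float = 1.0
    arm: str | None = None  # for kind == "arm"
    start: int | None = None  # for kind in {"segment", "focal"}
    end: int | None = None
    gene: str | None = None  # for kind == "focal"

    def __post_init__(self):
        if self.kind not in {"whole", "arm", "segment", "focal"}:
            raise ConfigError(f"unknown CNA kind {self.kind!r}")
        if self.direction not in {"gain", "loss", "amplification", "deletion"}:
            raise ConfigError(f"unknown CNA direction {self.direction!r}")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ConfigError("penetrance must lie in [0, 1]")
        if self.direction in {"amplification", "deletion"}:
            if self.log2_shift < 1.0:
                raise ConfigError("amplification/deletion shift must be >= 1.0")
        elif not 0.0 < self.log2_shift < 1.0:
            raise ConfigError("gain/loss shift must lie in (0, 1)")
        if self.kind == "arm" and self.arm not in {"p", "q"}:
            raise ConfigError("arm events need arm 'p' or 'q'")
        if self.kind in {"segment", "focal"} and not (
            self.start and self.end and self.start <= self.end
        ):
            raise ConfigError("segment/focal events need start <= end")

    @property
    def signed_shift(self) -> float:
        sign = 1.0 if self.direction in {"gain", "amplification"} else -1.0
        return sign * self.log2_shift

    def label(self) -> str:
        if self.kind == "focal":
            return f"{self.gene}:{self.direction}"
        where = f"{self.chrom}{self.arm or ''}" if self.kind != "segment" else (
            f"{self.chrom}:{self.start}-{self.end}"
        )
        return f"{where}:{self.direction}"


def default_cna_events() -> list[CNAEvent]:
    """Event panel emulating the recurrent aberrations of the five
    neuroblastoma methylation subgroups: 1p-/17q+/MYCN-amp in the
    MYCN-amplified cluster (1), 11q-/3p-/4p-/whole-7 gain in the 11q-deleted
    cluster (2), numeric whole-chromosome gains in the infant cluster (3) and
    the WCA-rich cluster (0), and a milder 11q-/17q+ burden in cluster 4."""
    f = frozenset
    return [
        CNAEvent("arm", "1", "loss", 0.4, f({1}), 0.88, arm="p"),
        CNAEvent("arm", "17", "gain", 0.4, f({1, 2, 4}), 0.72, arm="q"),
        CNAEvent("arm", "11", "loss", 0.4, f({2}), 0.95, arm="q"),
        CNAEvent("arm", "11", "loss", 0.35, f({4}), 0.51, arm="q"),
        CNAEvent("arm", "3", "loss", 0.4, f({2}), 0.69, arm="p"),
        CNAEvent("arm", "4", "loss", 0.4, f({2}), 0.50, arm="p"),
        CNAEvent("whole", "7", "gain", 0.4, f({2}), 0.48),
        CNAEvent("whole", "18", "gain", 0.4, f({0, 3}), 0.60),
        CNAEvent("whole", "6", "gain", 0.4, f({0, 3}), 0.50),
        CNAEvent(
            "focal", "2", "amplification", 1.5, f({1}), 0.91,
            start=GENE_COORDS["MYCN"][1], end=GENE_COORDS["MYCN"][2], gene="MYCN",
        ),
        CNAEvent(
            "focal", "9", "deletion", 1.5, f({1}), 0.28,
            start=GENE_COORDS["CDKN2A"][1], end=GENE_COORDS["CDKN2A"][2], gene="CDKN2A",
        ),
    ]


def default_clinical_model(n_clusters: int) -> dict[int, dict]:
    """Cluster -> clinical covariate distributions.

    For five clusters this mirrors the structure of the cohort the pipeline
    targets: one predominantly infant, low/intermediate-risk cluster (index 3),
    one MYCN-amplified high-risk cluster (index 1), and three high-risk,
    stage-4 clusters. Other cluster counts get a generic high-risk model.
    """
    high = {
        "infant_p": 0.08,
        "mycn_p": 0.05,
        "cog": {"high": 0.94, "intermediate": 0.04, "low": 0.02},
        "inss": {"4": 0.94, "3": 0.03, "1": 0.03},
    }
    model = {c: dict(high) for c in range(n_clusters)}
    if n_clusters >= 5:
        model[0] = {**high, "infant_p": 0.19, "mycn_p": 0.16}
        model[1] = {**high, "infant_p": 0.05, "mycn_p": 0.91}
        model[2] = {**high, "infant_p": 0.01, "mycn_p": 0.01}
        model[3] = {
            "infant_p": 0.90,
            "mycn_p": 0.01,
            "cog": {"low": 0.64, "intermediate": 0.23, "high": 0.13},
            "inss": {"4s": 0.59, "1": 0.28, "4": 0.13},
        }
        model[4] = {**high, "infant_p": 0.09, "mycn_p": 0.06}
    return model


def default_gene_map() -> pd.DataFrame:
    """BED-like table of the focal loci tracked by the CNA caller."""
    rows = [
        {"gene": g, "chrom": c, "start": s, "end": e}
        for g, (c, s, e) in GENE_COORDS.items()
    ]
    return pd.DataFrame(rows)[["chrom", "start", "end", "gene"]]


def _default_hazards(n_clusters: int) -> tuple[float, ...]:
    # ~0.2/yr gives 5-year event-free survival ~37%; the infant-like cluster
    # (index 3 of five) gets ~0.06/yr (~74% at 5 years)
    h = [0.2] * n_clusters
    if n_clusters >= 5:
        h[3] = 0.06
    return tuple(h)


@dataclass
class SimConfig:
    n_samples: int = 150
    n_probes: int = 8000
    n_clusters: int = 5
    cluster_proportions: tuple[float, ...] | None = None
    n_dmr_blocks_per_cluster: int = 25
    dmr_block_size: int = 8
    dmr_delta: float = 0.35
    beta_precision: float = 60.0
    cna_events: list[CNAEvent] = field(default_factory=default_cna_events)
    clinical_model: dict[int, dict] | None = None
    hazard_per_cluster: tuple[float, ...] | None = None
    censor_rate: float = 0.08
    ambiguous_fraction: float = 0.0
    # manifest knobs
    sex_fraction: float = 0.0
    cross_reactive_fraction: float = 0.02
    snp_fraction: float = 0.02
    island_mean_size: float = 7.0
    # intensity / detection knobs
    beta_offset: float = 100.0
    baseline_intensity: float = 4000.0
    intensity_sigma: float = 0.2
    intensity_noise_sigma: float = 0.15
    n_reference: int = 10
    failed_probe_fraction: float = 0.002
    failed_sample_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.n_probes < 100:
            raise ConfigError("n_probes must be >= 100")
        if self.n_samples < 1 or self.n_clusters < 1:
            raise ConfigError("n_samples and n_clusters must be positive")
        if self.cluster_proportions is None:
            self.cluster_proportions = tuple([1.0 / self.n_clusters] * self.n_clusters)
        props = np.asarray(self.cluster_proportions, dtype=float)
        if len(props) != self.n_clusters:
            raise ConfigError("cluster_proportions length must equal n_clusters")
        if not np.isclose(props.sum(), 1.0):
            raise ConfigError("cluster_proportions must sum to 1")
        if not 0.0 <= self.dmr_delta < 1.0:
            raise ConfigError("dmr_delta must lie in [0, 1)")
        if self.beta_precision <= 0 or self.censor_rate <= 0:
            raise ConfigError("beta_precision and censor_rate must be > 0")
        if not 0.0 <= self.ambiguous_fraction < 1.0:
            raise ConfigError("ambiguous_fraction must lie in [0, 1)")
        if self.hazard_per_cluster is None:
            self.hazard_per_cluster = _default_hazards(self.n_clusters)
        if len(self.hazard_per_cluster) != self.n_clusters:
            raise ConfigError("hazard_per_cluster length must equal n_clusters")
        if any(h <= 0 for h in self.hazard_per_cluster):
            raise ConfigError("hazards must be > 0")
        if self.clinical_model is None:
            self.clinical_model = default_clinical_model(self.n_clusters)


@dataclass
class GroundTruth:
    true_cluster: pd.Series
    planted_dmrs: pd.DataFrame  # cluster, chrom, start, end, delta, n_cpgs
    cna_events: list[CNAEvent]
    cna_carriers: pd.DataFrame  # samples x events (bool), columns = event labels
    true_hazard: pd.Series
    ambiguous_flag: pd.Series


@dataclass
class Cohort:
    manifest: pd.DataFrame
    M: pd.DataFrame
    U: pd.DataFrame
    detp: pd.DataFrame
    beta: pd.DataFrame
    samples: pd.DataFrame
    truth: GroundTruth
    ref_M: pd.DataFrame
    ref_U: pd.DataFrame

    @property
    def total_intensity(self) -> pd.DataFrame:
        return self.M + self.U

    @property
    def ref_total_intensity(self) -> pd.DataFrame:
        return self.ref_M + self.ref_U


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, stage)))


# ---------------------------------------------------------------------------
# manifest


def generate_manifest(config: SimConfig) -> pd.DataFrame:
    """Generate a 450k-like probe manifest.

    Probes are laid out in CpG-island-like clusters (geometric cluster sizes,
    30-300 bp spacing) spread over the autosomes proportionally to chromosome
    length; acrocentric p arms carry no probes. A fixed fraction is flagged
    cross-reactive and a fraction carries a proximal-SNP annotation
    (distance <= 2 bp, MAF >= 0.05). Focal loci referenced by configured CNA
    events always receive a dense probe cluster so copy-number bins cover them.
    """
    rng = _rng(config, 0)
    n_sex = int(round(config.sex_fraction * config.n_probes))
    n_auto = config.n_probes - n_sex

    chroms = list(AUTOSOMES)
    lengths = np.array([CHROMOSOMES[c][0] for c in chroms], dtype=float)
    counts = _largest_remainder(n_auto, lengths / lengths.sum())
    per_chrom = dict(zip(chroms, counts))
    if n_sex:
        sex_len = np.array([CHROMOSOMES[c][0] for c in SEX_CHROMS], dtype=float)
        for c, k in zip(SEX_CHROMS, _largest_remainder(n_sex, sex_len / sex_len.sum())):
            per_chrom[c] = k

    # reserve dense probe clusters over focal CNA loci
    focal = [ev for ev in config.cna_events if ev.kind == "focal"]
    records: dict[str, list[int]] = {c: [] for c in per_chrom}
    for ev in focal:
        if ev.chrom not in records or per_chrom.get(ev.chrom, 0) < 25:
            continue
        span = max(ev.end - ev.start, 25)
        pos = ev.start + np.unique((np.arange(25) * span // 25)).astype(int)[:25]
        records[ev.chrom].extend(int(p) for p in pos)
        per_chrom[ev.chrom] -= len(pos)

    for chrom, budget in per_chrom.items():
        length, cen = CHROMOSOMES[chrom]
        lo = cen if chrom in ACROCENTRIC else 1
        remaining = budget
        while remaining > 0:
            size = int(min(remaining, 1 + rng.poisson(config.island_mean_size)))
            start = int(rng.integers(lo, length - size * 300))
            gaps = rng.integers(30, 301, size=size)
            pos = start + np.cumsum(gaps)
            records[chrom].extend(int(p) for p in pos)
            remaining -= size

    frames = []
    for chrom in list(AUTOSOMES) + (SEX_CHROMS if n_sex else []):
        pos = np.sort(np.asarray(records.get(chrom, []), dtype=np.int64))
        # enforce strictly increasing positions where islands collide
        for _ in range(10):
            dup = np.flatnonzero(np.diff(pos) <= 0)
            if not dup.size:
                break
            pos[dup + 1] = pos[dup] + 1
        cen = CHROMOSOMES[chrom][1]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "arm": np.where(pos < cen, "p", "q"),
                }
            )
        )
    man = pd.concat(frames, ignore_index=True)
    man.index = pd.Index(
        [f"cg{i:08d}" for i in range(len(man))], name="probe_id"
    )

    n = len(man)
    man["cross_reactive"] = False
    n_xr = int(round(config.cross_reactive_fraction * n))
    man.iloc[rng.choice(n, size=n_xr, replace=False), man.columns.get_loc("cross_reactive")] = True

    man["snp_dist_bp"] = np.nan
    man["snp_maf"] = np.nan
    n_snp = int(round(config.snp_fraction * n))
    snp_idx = rng.choice(n, size=n_snp, replace=False)
    man.iloc[snp_idx, man.columns.get_loc("snp_dist_bp")] = rng.integers(0, 3, size=n_snp)
    man.iloc[snp_idx, man.columns.get_loc("snp_maf")] = rng.uniform(0.05, 0.5, size=n_snp)
    return man


def _largest_remainder(total: int, props: np.ndarray) -> np.ndarray:
    raw = props * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


# ---------------------------------------------------------------------------
# DMR slots


def _dmr_slots(manifest: pd.DataFrame, config: SimConfig) -> list[np.ndarray]:
    """Deterministically pick runs of consecutive tightly spaced probes (gap
    <= 500 bp, autosomal, not overlapping a focal CNA locus) to host planted
    DMR blocks. Returns positional index arrays into the manifest."""
    rng = _rng(config, 7)
    need = config.n_clusters * config.n_dmr_blocks_per_cluster
    size = config.dmr_block_size
    focal_spans = [
        (ev.chrom, ev.start, ev.end)
        for ev in config.cna_events
        if ev.kind == "focal"
    ]
    candidates: list[np.ndarray] = []
    positions = manifest["pos"].to_numpy()
    chrom_codes = manifest["chrom"].to_numpy()
    for chrom in AUTOSOMES:
        idx = np.flatnonzero(chrom_codes == chrom)
        if idx.size < size:
            continue
        pos = positions[idx]
        breaks = np.flatnonzero(np.diff(pos) > 500)
        for run in np.split(np.arange(idx.size), breaks + 1):
            if run.size < size:
                continue
            lo, hi = pos[run[0]], pos[run[-1]]
            if any(c == chrom and lo <= e and s <= hi for c, s, e in focal_spans):
                continue
            candidates.append(idx[run[:size]])
    if len(candidates) < need:
        raise ConfigError(
            f"manifest has only {len(candidates)} candidate DMR blocks; "
            f"{need} required — increase n_probes or island_mean_size"
        )
    picked = rng.choice(len(candidates), size=need, replace=False)
    return [candidates[i] for i in picked]


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(config: SimConfig, manifest: pd.DataFrame | None = None) -> Cohort:
    """Generate a full synthetic cohort (intensities, detection p-values,
    beta matrix, sample sheet, ground truth and reference samples)."""
    if manifest is None:
        manifest = generate_manifest(config)
    n_probes, n = len(manifest), config.n_samples
    k = config.n_clusters

    # --- cluster assignment (largest-remainder composition, shuffled)
    rng_s = _rng(config, 2)
    counts = _largest_remainder(n, np.asarray(config.cluster_proportions))
    labels = np.repeat(np.arange(k), counts)
    rng_s.shuffle(labels)
    sample_ids = [f"S{i:04d}" for i in range(n)]

    # --- archetypes: bimodal baseline + per-cluster DMR shifts
    rng_a = _rng(config, 1)
    state = rng_a.choice(3, size=n_probes, p=[0.55, 0.35, 0.10])
    base = np.empty(n_probes)
    base[state == 0] = rng_a.uniform(0.04, 0.12, size=(state == 0).sum())
    base[state == 1] = rng_a.uniform(0.82, 0.95, size=(state == 1).sum())
    base[state == 2] = rng_a.uniform(0.25, 0.75, size=(state == 2).sum())

    dmr_rows = []
    slots: list = []
    slot_meta: list[tuple[int, float]] = []
    if config.dmr_delta > 0 and config.n_dmr_blocks_per_cluster > 0:
        slots = _dmr_slots(manifest, config)
        # DMR blocks sit on coherently methylated islands: harmonise the
        # baseline of each block so the planted shift never clips
        for j, block in enumerate(slots):
            direction = 1.0 if rng_a.random() < 0.5 else -1.0
            if direction > 0:  # hyper in the carrier cluster
                base[block] = rng_a.uniform(0.05, 0.55 - config.dmr_delta, size=block.size)
            else:
                base[block] = rng_a.uniform(0.45 + config.dmr_delta, 0.95, size=block.size)
            slot_meta.append((j % k, direction))
    arch = np.tile(base, (k, 1))
    if slots:
        positions = manifest["pos"].to_numpy()
        chroms = manifest["chrom"].to_numpy()
        for block, (c, direction) in zip(slots, slot_meta):
            arch[c, block] = np.clip(
                base[block] + direction * config.dmr_delta, 0.02, 0.98
            )
            dmr_rows.append(
                {
                    "cluster": c,
                    "chrom": chroms[block[0]],
                    "start": int(positions[block[0]]),
                    "end": int(positions[block[-1]]),
                    "delta": direction * config.dmr_delta,
                    "n_cpgs": int(block.size),
                }
            )
    planted_dmrs = pd.DataFrame(
        dmr_rows, columns=["cluster", "chrom", "start", "end", "delta", "n_cpgs"]
    )

    # --- per-sample mean profiles (ambiguous samples mix two archetypes)
    n_amb = int(round(config.ambiguous_fraction * n))
    amb_idx = rng_s.choice(n, size=n_amb, replace=False)
    ambiguous = np.zeros(n, dtype=bool)
    ambiguous[amb_idx] = True
    means = arch[labels].copy()  # n x probes
    for i in amb_idx:
        other = int(rng_s.choice([c for c in range(k) if c != labels[i]])) if k > 1 else labels[i]
        w = rng_s.uniform(0.35, 0.65)
        means[i] = w * arch[labels[i]] + (1 - w) * arch[other]

    prec = config.beta_precision
    means = np.clip(means, 0.02, 0.98)
    beta_raw = rng_s.beta(means * prec, (1 - means) * prec).T  # probes x samples

    # --- intensities: shared per-probe baseline, CNA multiplicative shifts
    rng_i = _rng(config, 3)
    t0 = config.baseline_intensity * np.exp(
        rng_i.normal(0.0, config.intensity_sigma, size=n_probes)
    )
    noise = np.exp(rng_i.normal(0.0, config.intensity_noise_sigma, size=(n_probes, n)))
    total = t0[:, None] * noise

    carriers = np.zeros((n, len(config.cna_events)), dtype=bool)
    for e_idx, ev in enumerate(config.cna_events):
        eligible = np.isin(labels, list(ev.carrier_clusters))
        hit = eligible & (rng_i.random(n) < ev.penetrance)
        carriers[:, e_idx] = hit
        if hit.any():
            mask = _event_probe_mask(manifest, ev)
            total[np.ix_(mask, hit)] *= 2.0 ** ev.signed_shift

    M = beta_raw * total
    U = total - M
    offset = config.beta_offset
    beta = M / (M + U + offset)

    # --- reference (copy-neutral, baseline methylome) samples
    ref_noise = np.exp(
        rng_i.normal(0.0, config.intensity_noise_sigma, size=(n_probes, config.n_reference))
    )
    ref_total = t0[:, None] * ref_noise
    ref_beta = rng_i.beta(
        np.clip(base, 0.02, 0.98)[:, None] * prec,
        (1 - np.clip(base, 0.02, 0.98))[:, None] * prec,
        size=(n_probes, config.n_reference),
    )
    ref_M = ref_beta * ref_total
    ref_U = ref_total - ref_M

    # --- detection p-values
    rng_d = _rng(config, 6)
    detp = rng_d.uniform(0.0, 0.005, size=(n_probes, n))
    n_fail = int(round(config.failed_probe_fraction * n_probes))
    if n_fail:
        fail_probes = rng_d.choice(n_probes, size=n_fail, replace=False)
        fail_mask = rng_d.random((n_fail, n)) < config.failed_sample_fraction
        fails = rng_d.uniform(0.02, 1.0, size=(n_fail, n))
        detp[fail_probes] = np.where(fail_mask, fails, detp[fail_probes])

    # --- clinical covariates and survival
    rng_c = _rng(config, 4)
    sheet = _clinical_sheet(labels, config, rng_c, sample_ids)
    hazards = np.asarray(config.hazard_per_cluster)[labels]
    surv = generate_survival(
        pd.Series(labels, index=sample_ids),
        config.hazard_per_cluster,
        config.censor_rate,
        seed=np.random.SeedSequence((config.seed, 5)),
    )
    sheet["pfs_years"] = surv["time"].to_numpy()
    sheet["event"] = surv["event"].to_numpy()

    probe_index = manifest.index
    col = pd.Index(sample_ids, name="sample_id")
    truth = GroundTruth(
        true_cluster=pd.Series(labels, index=col, name="true_cluster"),
        planted_dmrs=planted_dmrs,
        cna_events=list(config.cna_events),
        cna_carriers=pd.DataFrame(
            carriers, index=col, columns=_unique_labels(config.cna_events)
        ),
        true_hazard=pd.Series(hazards, index=col, name="true_hazard"),
        ambiguous_flag=pd.Series(ambiguous, index=col, name="ambiguous"),
    )
    ref_cols = pd.Index([f"R{i:03d}" for i in range(config.n_reference)], name="sample_id")
    return Cohort(
        manifest=manifest,
        M=pd.DataFrame(M, index=probe_index, columns=col),
        U=pd.DataFrame(U, index=probe_index, columns=col),
        detp=pd.DataFrame(detp, index=probe_index, columns=col),
        beta=pd.DataFrame(beta, index=probe_index, columns=col),
        samples=sheet,
        truth=truth,
        ref_M=pd.DataFrame(ref_M, index=probe_index, columns=ref_cols),
        ref_U=pd.DataFrame(ref_U, index=probe_index, columns=ref_cols),
    )


def _unique_labels(events: list[CNAEvent]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for ev in events:
        lab = ev.label()
        if lab in seen:
            seen[lab] += 1
            lab = f"{lab}#{seen[lab]}"
        else:
            seen[lab] = 1
        out.append(lab)
    return out


def _event_probe_mask(manifest: pd.DataFrame, ev: CNAEvent) -> np.ndarray:
    on_chrom = (manifest["chrom"] == ev.chrom).to_numpy()
    if ev.kind == "whole":
        return on_chrom
    if ev.kind == "arm":
        return on_chrom & (manifest["arm"] == ev.arm).to_numpy()
    pos = manifest["pos"].to_numpy()
    return on_chrom & (pos >= ev.start) & (pos <= ev.end)


def _clinical_sheet(
    labels: np.ndarray, config: SimConfig, rng: np.random.Generator, sample_ids: list[str]
) -> pd.DataFrame:
    rows = []
    for lab in labels:
        m = config.clinical_model[int(lab)]
        infant = rng.random() < m["infant_p"]
        age = rng.uniform(0.0, 1.4) if infant else 1.5 + rng.gamma(2.0, 2.0)
        mycn = "amp" if rng.random() < m["mycn_p"] else "normal"
        inss = _draw_cat(rng, m["inss"])
        cog = _draw_cat(rng, m["cog"])
        rows.append(
            {"age_years": age, "mycn": mycn, "inss": inss, "cog_risk": cog}
        )
    sheet = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample_id"))
    return sheet


def _draw_cat(rng: np.random.Generator, probs: dict[str, float]) -> str:
    cats = sorted(probs)
    p = np.asarray([probs[c] for c in cats], dtype=float)
    return cats[rng.choice(len(cats), p=p / p.sum())]


# ---------------------------------------------------------------------------
# survival


def generate_survival(
    labels: pd.Series,
    hazards,
    censor_rate: float,
    seed,
) -> pd.DataFrame:
    """Exponential event times with independent exponential censoring.

    ``hazards`` is a per-cluster sequence (events per year); ``labels`` maps
    samples to clusters. Returns time = min(event, censor) and the event
    indicator.
    """
    hazards = np.asarray(hazards, dtype=float)
    if np.any(hazards <= 0) or censor_rate <= 0:
        raise ConfigError("hazards and censor_rate must be > 0")
    rng = np.random.default_rng(seed)
    lam = hazards[np.asarray(labels, dtype=int)]
    t_event = rng.exponential(1.0 / lam)
    t_censor = rng.exponential(1.0 / censor_rate, size=len(lam))
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    return pd.DataFrame(
        {"time": time, "event": event, "group": np.asarray(labels)},
        index=labels.index if hasattr(labels, "index") else None,
    )


# ---------------------------------------------------------------------------
# output


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write the cohort in the pipeline's TSV/JSON dialects."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    nbio.write_matrix(cohort.beta, out / "beta.tsv")
    nbio.write_matrix(cohort.M, out / "intensities.M.tsv")
    nbio.write_matrix(cohort.U, out / "intensities.U.tsv")
    nbio.write_matrix(cohort.ref_M, out / "reference.M.tsv")
    nbio.write_matrix(cohort.ref_U, out / "reference.U.tsv")
    nbio.write_matrix(cohort.detp, out / "detection_p.tsv")
    nbio.write_manifest(cohort.manifest, out / "manifest.tsv")
    nbio.write_sample_sheet(cohort.samples, out / "samples.tsv")
    truth = cohort.truth
    nbio.write_json(
        {
            "true_cluster": truth.true_cluster.to_dict(),
            "planted_dmrs": truth.planted_dmrs.to_dict(orient="records"),
            "cna_events": list(truth.cna_carriers.columns),
            "cna_carriers": {
                c: truth.cna_carriers[c].astype(int).to_dict()
                for c in truth.cna_carriers
            },
            "true_hazard": truth.true_hazard.to_dict(),
            "ambiguous": truth.ambiguous_flag.astype(int).to_dict(),
        },
        out / "truth.json",
    )
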