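"""Seeded fully-synthetic datasets with known ground truth.

The generator emulates the statistical structure of a three-group
portal-venous-blood cfDNA 5hmC cohort: a small multi-chromosome genome with
stranded multi-exon genes; candidate hydroxymethylated regions (hMRs) placed
intron-heavy across genomic features; negative-binomially distributed region
counts with sample-specific library sizes and a planted fraction of
differential regions between the PC-like and MLM-like groups; per-sample
peak lists; a gene-body-enriched coverage track with a dip around each TSS;
and exponential survival times whose hazard depends on a marker's level.
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, CoverageTrack, GeneModel, GenomicRegion

FEATURES = ("promoter", "exon", "intron", "intergenic")

_MIN_EXON = 300
_MIN_SEGMENT = 200


class SizingError(ValueError):
    """Requested content does not fit the available chromosome length."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults describe the study conditions emulated throughout: a 133-sample
    three-group cohort (PC 70, MLM 32, SLM 31), intron-heavy region
    placement, moderate negative-binomial overdispersion, and planted fold
    changes at or above the differential-calling threshold of 0.5 log2
    units.
    """

    seed: int = 0
    n_chromosomes: int = 3
    n_genes: int = 150
    gene_length_range: tuple[int, int] = (4000, 20000)
    n_regions: int = 800
    region_width_range: tuple[int, int] = (100, 999)
    feature_mix: dict[str, float] = field(
        default_factory=lambda: {
            "promoter": 0.12,
            "exon": 0.13,
            "intron": 0.55,
            "intergenic": 0.20,
        }
    )
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"PC": 70, "MLM": 32, "SLM": 31}
    )
    frac_differential: float = 0.05
    lfc_magnitude_range: tuple[float, float] = (0.5, 2.0)
    dispersion_range: tuple[float, float] = (0.05, 0.3)
    baseline_mean_log_mean: float = float(np.log(50.0))
    baseline_mean_log_sd: float = 1.0
    libsize_log_mean: float = 0.0
    libsize_log_sd: float = 0.25
    peak_presence_threshold: int = 5
    survival_baseline_hazard: float = 0.02  # events per month
    survival_hazard_ratio: float = 2.5
    censor_rate: float = 0.01  # censorings per month
    # coverage-track shape
    coverage_background: float = 0.5
    coverage_body_level: float = 5.0
    tss_dip_depth: float = 0.3  # multiplier inside the dip window; 1.0 = no dip
    tss_dip_halfwidth: int = 1000
    chromosome_length: int | None = None  # None: sized to content

    def validate(self) -> None:
        for name in ("gene_length_range", "region_width_range",
                     "lfc_magnitude_range", "dispersion_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: low {lo} > high {hi}")
        if abs(sum(self.feature_mix.values()) - 1.0) > 1e-9:
            raise ValueError("feature_mix proportions must sum to 1")
        if set(self.feature_mix) - set(FEATURES):
            raise ValueError(f"feature_mix keys must be among {FEATURES}")
        if any(p < 0 for p in self.feature_mix.values()):
            raise ValueError("feature_mix proportions must be >= 0")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("all group sizes must be >= 2")
        if not 0.0 <= self.frac_differential <= 1.0:
            raise ValueError("frac_differential must be in [0, 1]")
        if self.dispersion_range[0] <= 0:
            raise ValueError("dispersions must be positive")
        if self.survival_hazard_ratio <= 0:
            raise ValueError("hazard ratio must be positive")
        if self.peak_presence_threshold < 0:
            raise ValueError("peak_presence_threshold must be >= 0")
        if self.gene_length_range[0] < 2 * _MIN_EXON:
            raise ValueError(f"genes must be >= {2 * _MIN_EXON} bp")


@dataclass
class GroundTruth:
    """Planted truth for parameter-recovery tests."""

    differential_region_ids: set[str]
    true_log2fc: dict[str, float]
    true_dispersion: dict[str, float]
    predictive_marker_ids: set[str]
    baseline_mean: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.predictive_marker_ids <= self.differential_region_ids:
            raise ValueError("predictive markers must be differential regions")
        nonzero = {rid for rid, b in self.true_log2fc.items() if abs(b) > 0}
        if not nonzero <= self.differential_region_ids:
            raise ValueError("nonzero planted log2fc outside differential set")

    def to_frame(self) -> pd.DataFrame:
        rids = sorted(self.true_log2fc)
        return pd.DataFrame(
            {
                "log2fc": [self.true_log2fc[r] for r in rids],
                "dispersion": [self.true_dispersion[r] for r in rids],
                "differential": [r in self.differential_region_ids for r in rids],
                "predictive": [r in self.predictive_marker_ids for r in rids],
            },
            index=pd.Index(rids, name="region"),
        )


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    # one stream per stage, derived by fixed offsets so adding regions does
    # not perturb gene simulation
    return np.random.default_rng(np.random.SeedSequence([int(config_seed), stream]))


# ---------------------------------------------------------------------------
# genome


def _make_gene(chrom: str, start: int, length: int, name: str, strand: str,
               rng: np.random.Generator) -> GeneModel:
    max_exons = max(1, min(6, (length + _MIN_SEGMENT) // (_MIN_EXON + _MIN_SEGMENT)))
    lo_exons = 2 if max_exons >= 2 else 1
    n_exons = int(rng.integers(lo_exons, max_exons + 1))
    m = 2 * n_exons - 1
    # introns draw heavier weights than exons: real gene bodies are
    # intron-dominated, and the region mix leans on intron space
    raw = np.where(np.arange(m) % 2 == 0, rng.uniform(0.8, 3.0, m),
                   rng.uniform(2.0, 6.0, m))
    spare = length - m * _MIN_SEGMENT
    seg = np.floor(_MIN_SEGMENT + raw / raw.sum() * spare).astype(int)
    seg[-1] += length - int(seg.sum())
    bounds = start + np.concatenate([[0], np.cumsum(seg)])
    exons = tuple((int(bounds[i]), int(bounds[i + 1])) for i in range(0, m, 2))
    return GeneModel(chrom, start, start + length, name, strand, exons)


def simulate_genome(config: SimulationConfig):
    """Generate gene models and candidate hMRs with planted feature labels.

    Returns ``(genes, regions)`` where each region's name carries its planted
    feature label (``hmr_000001|intron``). Genes are non-overlapping within a
    chromosome; regions are mutually disjoint and placed so that the planted
    label matches the annotation priority rules (promoter windows are
    TSS +/- 2 kb, downstream extends 3 kb past the TTS).
    """
    config.validate()
    rng = _rng(config.seed, 0)
    promoter_hw, downstream = 2000, 3000

    genes: list[GeneModel] = []
    chrom_len: dict[str, int] = {}
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        pos = int(rng.integers(6000, 12000))
        for gi in range(per_chrom[ci]):
            length = int(rng.integers(config.gene_length_range[0],
                                      config.gene_length_range[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            name = f"gene_{len(genes):04d}"
            genes.append(_make_gene(chrom, pos, length, name, strand, rng))
            pos += length + int(rng.integers(12000, 20000))
        chrom_len[chrom] = pos + 6000
        if config.chromosome_length is not None:
            if pos > config.chromosome_length:
                raise SizingError(
                    f"{chrom}: {per_chrom[ci]} genes need {pos} bp but "
                    f"chromosome_length is {config.chromosome_length}"
                )
            chrom_len[chrom] = config.chromosome_length

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    # per-chrom occupancy of placed regions, for disjointness
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_len}

    def free(chrom: str, s: int, e: int) -> bool:
        import bisect

        occ = occupied[chrom]
        i = bisect.bisect_left(occ, (s, e))
        if i > 0 and occ[i - 1][1] >= s:  # >= : keep >=1 bp gap (no abutting)
            return False
        if i < len(occ) and occ[i][0] <= e:
            return False
        return True

    def claim(chrom: str, s: int, e: int) -> None:
        import bisect

        occ = occupied[chrom]
        occ.insert(bisect.bisect_left(occ, (s, e)), (s, e))

    def promoter_window(g: GeneModel) -> tuple[int, int]:
        return (max(0, g.tss - promoter_hw), g.tss + promoter_hw)

    def _clip_out(iv: tuple[int, int], win: tuple[int, int]):
        """Pieces of iv not overlapping win."""
        s, e = iv
        out = []
        if s < win[0]:
            out.append((s, min(e, win[0])))
        if e > win[1]:
            out.append((max(s, win[1]), e))
        return out

    # eligible host intervals per planted label (gene spacing >= 12 kb, so
    # only the gene's own promoter window can intrude on its body)
    exon_hosts: list[tuple[str, int, int]] = []
    intron_hosts: list[tuple[str, int, int]] = []
    for g in genes:
        pw = promoter_window(g)
        for iv in g.exons:
            exon_hosts.extend((g.chrom, s, e) for s, e in _clip_out(iv, pw))
        for iv in g.introns:
            intron_hosts.extend((g.chrom, s, e) for s, e in _clip_out(iv, pw))
    intergenic_hosts: list[tuple[str, int, int]] = []
    for chrom, gl in by_chrom.items():
        gl = sorted(gl, key=lambda g: g.start)
        forbidden = []
        for g in gl:
            pw = promoter_window(g)
            dz = (g.end, g.end + downstream) if g.strand == "+" else \
                (max(0, g.start - downstream), g.start)
            forbidden.append((min(g.start, pw[0], dz[0]), max(g.end, pw[1], dz[1])))
        pos = 0
        for lo, hi in sorted(forbidden):
            if lo > pos:
                intergenic_hosts.append((chrom, pos, lo))
            pos = max(pos, hi)
        if pos < chrom_len[chrom]:
            intergenic_hosts.append((chrom, pos, chrom_len[chrom]))

    hosts = {"exon": exon_hosts, "intron": intron_hosts,
             "intergenic": intergenic_hosts}

    labels = sorted(config.feature_mix)
    probs = np.array([config.feature_mix[l] for l in labels])
    regions: list[GenomicRegion] = []
    for ri in range(config.n_regions):
        feature = labels[int(rng.choice(len(labels), p=probs))]
        width = int(rng.integers(config.region_width_range[0],
                                 config.region_width_range[1] + 1))
        placed = None
        for attempt in range(1000):
            if feature == "promoter":
                g = genes[int(rng.integers(len(genes)))]
                lo = g.tss - promoter_hw + 1 - width // 2
                hi = g.tss + promoter_hw - 1 - width // 2
                s = int(rng.integers(max(0, lo), max(1, hi)))
                e = s + width
            else:
                cand = [h for h in hosts[feature] if h[2] - h[1] > width + 1]
                if not cand:
                    widest = max((h[2] - h[1] for h in hosts[feature]), default=0)
                    if widest <= config.region_width_range[0] + 1:
                        raise SizingError(
                            f"no interval can host a {feature!r} region; "
                            "genome too small for requested feature_mix"
                        )
                    width = widest - 2
                    continue
                chrom0, hs, he = cand[int(rng.integers(len(cand)))]
                s = int(rng.integers(hs, he - width))
                e = s + width
                g = None
            chrom0 = g.chrom if g is not None else chrom0
            if free(chrom0, s, e):
                placed = GenomicRegion(chrom0, s, e, f"hmr_{ri:06d}|{feature}")
                claim(chrom0, s, e)
                break
            if attempt == 600:  # crowded: fall back to the narrowest widths
                width = config.region_width_range[0]
        if placed is None:
            raise SizingError(
                f"could not place region {ri} with label {feature!r}; "
                "genome too small for requested n_regions"
            )
        regions.append(placed)

    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    return genes, regions


def region_id(region: GenomicRegion) -> str:
    """Bare region identifier (strips the planted ``|label`` suffix)."""
    return region.name.split("|")[0]


def planted_label(region: GenomicRegion) -> str:
    return region.name.split("|")[1] if "|" in region.name else ""


# ---------------------------------------------------------------------------
# counts


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean mu, dispersion alpha): var = mu + alpha*mu^2."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    poisson = alpha < 1e-12
    if poisson.any():
        out[poisson] = rng.poisson(mean[poisson])
    if (~poisson).any():
        a = alpha[~poisson]
        m = mean[~poisson]
        n = 1.0 / a
        p = n / (n + m)
        out[~poisson] = rng.negative_binomial(n, p)
    return out


def simulate_counts(config: SimulationConfig, regions: Sequence[GenomicRegion]):
    """Simulate the regions x samples count matrix and its ground truth.

    Count for region i in sample j ~ NB(mean = q_i * s_j * 2^(beta_i x_j),
    dispersion alpha_i), where x_j indicates the MLM-like group, s_j is a
    log-normal latent sequencing depth, and beta_i is zero except for the
    planted differential fraction. Differential effects are planted only
    between the first two configured groups; any further group reuses the
    reference parameters. The stored library size of each sample is the
    realized column total.
    """
    config.validate()
    if not regions:
        raise ValueError("regions must be non-empty")
    rng = _rng(config.seed, 1)
    rids = [region_id(r) for r in regions]
    R = len(rids)

    group_labels = list(config.group_sizes)
    samples, x = [], []
    for gi, glab in enumerate(group_labels):
        for k in range(config.group_sizes[glab]):
            samples.append(f"{glab}_{k + 1:03d}")
            x.append(1.0 if gi == 1 else 0.0)
    x = np.array(x)
    N = len(samples)

    q = rng.lognormal(config.baseline_mean_log_mean, config.baseline_mean_log_sd, R)
    alpha = rng.uniform(*config.dispersion_range, R)
    s = rng.lognormal(config.libsize_log_mean, config.libsize_log_sd, N)

    n_diff = int(round(config.frac_differential * R))
    diff_idx = rng.choice(R, size=n_diff, replace=False) if n_diff else np.array([], int)
    beta = np.zeros(R)
    if n_diff:
        mag = rng.uniform(*config.lfc_magnitude_range, n_diff)
        sign = np.where(rng.random(n_diff) < 0.5, -1.0, 1.0)
        beta[diff_idx] = sign * mag

    mean = q[:, None] * s[None, :] * np.exp2(beta[:, None] * x[None, :])
    counts = _nb_draws(rng, mean, alpha[:, None])

    df = pd.DataFrame(counts, index=pd.Index(rids, name="region"), columns=samples)
    libsizes = df.sum(axis=0).astype(np.int64)
    libsizes[libsizes == 0] = 1  # degenerate all-zero sample
    cm = CountMatrix(df, libsizes)

    diff_ids = {rids[i] for i in diff_idx}
    order = sorted(diff_idx, key=lambda i: -abs(beta[i]))
    predictive = {rids[i] for i in order[:10]}
    truth = GroundTruth(
        differential_region_ids=diff_ids,
        true_log2fc={rids[i]: float(beta[i]) for i in range(R)},
        true_dispersion={rids[i]: float(alpha[i]) for i in range(R)},
        predictive_marker_ids=predictive,
        baseline_mean={rids[i]: float(q[i]) for i in range(R)},
    )
    truth.validate()
    return cm, truth


# ---------------------------------------------------------------------------
# peaks


def simulate_peaks(counts: CountMatrix, regions: Sequence[GenomicRegion],
                   threshold: int) -> dict[str, list[GenomicRegion]]:
    """Per-sample peak lists: a region is a peak in sample j iff its count
    is >= threshold. Lists are sorted in BED convention."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    by_id = {region_id(r): r for r in regions}
    out: dict[str, list[GenomicRegion]] = {}
    arr = counts.counts
    for sample in counts.sample_ids:
        hit = arr.index[arr[sample].to_numpy() >= threshold]
        peaks = [by_id[r] for r in hit if r in by_id]
        peaks.sort(key=lambda r: (r.chrom, r.start, r.end))
        out[sample] = peaks
    return out


# ---------------------------------------------------------------------------
# coverage


def simulate_coverage(genes: Sequence[GeneModel], config: SimulationConfig) -> CoverageTrack:
    """Deterministic piecewise-constant coverage: elevated over gene bodies,
    a multiplicative V-shaped dip in a window around each TSS (deepest at
    the TSS itself, tapering to no effect at the window edges), flat
    background elsewhere. Strand-aware (the dip is centered on the
    strand-specific TSS)."""
    if not genes:
        raise ValueError("genes must be non-empty")
    per_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        per_chrom.setdefault(g.chrom, []).append(g)

    hw = config.tss_dip_halfwidth
    n_sub = 16  # piecewise-constant approximation of the taper
    intervals = {}
    for chrom, gl in sorted(per_chrom.items()):
        gl.sort(key=lambda g: g.start)
        length = gl[-1].end + 6000
        cuts = {0, length}
        for g in gl:
            cuts.update((g.start, g.end))
            lo = max(0, g.tss - hw)
            hi = min(length, g.tss + hw)
            cuts.update(int(round(x)) for x in np.linspace(lo, hi, n_sub + 1))
        bounds = np.array(sorted(cuts))
        starts, ends = bounds[:-1], bounds[1:]
        values = np.full(len(starts), config.coverage_background)
        mids = (starts + ends) / 2.0
        for g in gl:
            body = (mids >= g.start) & (mids < g.end)
            values[body] = config.coverage_body_level
        for g in gl:
            dip = (mids >= g.tss - hw) & (mids < g.tss + hw)
            frac = np.abs(mids[dip] - g.tss) / hw  # 0 at TSS, 1 at edges
            values[dip] *= config.tss_dip_depth + (1.0 - config.tss_dip_depth) * frac
        intervals[chrom] = (starts, ends, values)
    return CoverageTrack(intervals)


# ---------------------------------------------------------------------------
# survival


def simulate_survival(marker_level: np.ndarray, config: SimulationConfig) -> pd.DataFrame:
    """Exponential OS and EFS whose hazard depends on a marker's level.

    Samples with marker level above the median carry hazard
    ``baseline * HR``; below-or-at-median samples carry ``baseline``.
    Censoring times are exponential with rate ``censor_rate`` (0 = no
    censoring). EFS uses a 1.5x baseline hazard with the same ratio.
    Returns a frame with os_months/os_event/efs_months/efs_event.
    """
    config.validate()
    rng = _rng(config.seed, 2)
    level = np.asarray(marker_level, dtype=float)
    high = level > np.median(level)
    out = {}
    for prefix, h0 in (("os", config.survival_baseline_hazard),
                       ("efs", 1.5 * config.survival_baseline_hazard)):
        hazard = h0 * np.where(high, config.survival_hazard_ratio, 1.0)
        t_event = rng.exponential(1.0 / hazard)
        if config.censor_rate > 0:
            t_censor = rng.exponential(1.0 / config.censor_rate, size=level.shape)
        else:
            t_censor = np.full(level.shape, np.inf)
        out[f"{prefix}_months"] = np.minimum(t_event, t_censor)
        out[f"{prefix}_event"] = (t_event <= t_censor).astype(int)
    return pd.DataFrame(out)
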