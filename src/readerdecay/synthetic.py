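"""Synthetic benchmark generator with known ground truth.

Emulates the statistical structure of the experiments this pipeline
analyses, on a toy genome:

* a gene universe with strand-aware 5'UTR/CDS/3'UTR models;
* m6A-IP/input count tables with a methylated/unmethylated spike-in pair,
  negative-binomial noise, and IP enrichment at methylated genes;
* binned CLIP coverage tracks (reader IP, binding-impaired reader IP,
  input) with 3'UTR-biased binding sites;
* transcription-shutoff decay time courses at 0/15/30/60/120 min with
  constant ERCC-like spike-in rows, per-gene exponential decay, and a
  reader-loss genotype whose target decay rates are slowed by a per-site
  multiplicative effect.

All operations are deterministic given the config seed ("expected" sampling
mode returns the exact expectations, so formula tests are noise-free).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval
from .normalization import CountTable

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_genome",
    "simulate_truth",
    "simulate_m6a_experiment",
    "simulate_clip_coverage",
    "simulate_decay_course",
    "simulate_ribo_experiment",
]

GENOTYPES = ("WT", "ect8")
DECAY_TIMES = (0.0, 15.0, 30.0, 60.0, 120.0)

# rng stream tags so each operation has an independent, order-free stream
_TAG_GENOME, _TAG_TRUTH, _TAG_M6A, _TAG_CLIP, _TAG_DECAY, _TAG_RIBO = range(6)


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic benchmark.

    Defaults encode the emulated designs: half the genes methylated, half of
    those reader-bound; binding-site counts distributed ~80/18/2% over
    1/2/3+ sites; decay rates spanning half-lives of ~14-230 min; the
    reader-loss genotype multiplies a target's decay rate by
    ``reader_effect`` per binding site.
    """

    n_genes: int = 1000
    n_chromosomes: int = 5
    frac_m6a: float = 0.5
    frac_reader_target: float = 0.5  # fraction of m6A genes bound by the reader
    binding_site_dist: tuple[float, float, float] = (0.80, 0.18, 0.02)  # 1/2/3+ sites
    decay_rate_range: tuple[float, float] = (0.003, 0.05)  # A, min^-1
    reader_effect: float = 0.6  # per-site multiplier on A in the reader-loss genotype
    ip_enrichment: float = 4.0  # m6A-IP fold enrichment at methylated genes
    depth: float = 2_000_000.0  # expected library size (reads)
    nb_dispersion: float = 0.01
    n_spikeins: int = 10  # constant ERCC-like species in RNA-seq tables
    seed: int = 0
    # genome geometry
    chromosome_length: int | None = None  # None: auto-sized to fit the genes
    gene_length_range: tuple[int, int] = (1500, 3000)
    intergenic_gap: tuple[int, int] = (200, 800)
    # CLIP design
    bin_size: int = 25
    clip_site_fold: float = 6.0  # IP/input enrichment over a binding site
    clip_site_width: int = 60
    site_region_probs: tuple[float, float, float] = (0.05, 0.15, 0.80)  # 5UTR/CDS/3UTR
    salt_binding_factor: float = 2.0  # occupancy multiplier under salt stress
    # spike-in bookkeeping
    spike_fraction: float = 0.02  # expected spike-in share of the library
    spike_ip_enrichment: float = 10.0  # methylated m6A spike-in pulldown fold
    expr_sigma: float = 1.0  # log-normal spread of gene expression
    sampling: str = "nb"  # "nb" | "expected"

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_chromosomes < 1:
            raise ValueError("n_genes and n_chromosomes must be positive")
        for name in ("frac_m6a", "frac_reader_target"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not math.isclose(sum(self.binding_site_dist), 1.0, abs_tol=1e-9):
            raise ValueError("binding_site_dist must sum to 1")
        if min(self.binding_site_dist) < 0:
            raise ValueError("binding_site_dist entries must be non-negative")
        lo, hi = self.decay_rate_range
        if not (0 < lo <= hi):
            raise ValueError("decay_rate_range must be strictly positive")
        if not 0.0 < self.reader_effect <= 1.0:
            raise ValueError("reader_effect must lie in (0, 1]")
        if self.depth < 0 or self.nb_dispersion < 0:
            raise ValueError("depth and nb_dispersion must be non-negative")
        if self.n_spikeins < 1:
            raise ValueError("need at least one spike-in species")
        if self.sampling not in ("nb", "expected"):
            raise ValueError("sampling must be 'nb' or 'expected'")
        if self.gene_length_range[0] < 300:
            raise ValueError("genes need >= 300 bp for a 3-region model")

    def to_dict(self) -> dict:
        return asdict(self)

    def rng(self, *tags: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), *map(int, tags)])


@dataclass
class GroundTruth:
    """Per-gene simulation truth.

    ``genes`` columns: m6a, target (bool), n_sites (int, > 0 iff target),
    expr (relative abundance, sums to 1), A_WT, A_ect8 (min^-1),
    halflife_WT, halflife_ect8 (min). ``sites`` are the reader's true
    binding intervals; ``m6a_regions`` the true methylated intervals.
    ``ip_efficiency`` records per-IP-sample methylated-spike pulldown scale
    factors as experiments are simulated.
    """

    genes: pd.DataFrame
    sites: list[GenomicInterval] = field(default_factory=list)
    m6a_regions: list[GenomicInterval] = field(default_factory=list)
    ip_efficiency: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.genes
        if ((g["n_sites"] > 0) != g["target"]).any():
            raise ValueError("n_sites must be positive exactly for reader targets")
        for geno in GENOTYPES:
            hl = np.log(2) / g[f"A_{geno}"]
            if not np.allclose(hl, g[f"halflife_{geno}"]):
                raise ValueError(f"half-life inconsistent with A for {geno}")

    @property
    def m6a_genes(self) -> set[str]:
        return set(self.genes.index[self.genes["m6a"]])

    @property
    def target_genes(self) -> set[str]:
        return set(self.genes.index[self.genes["target"]])

    def site_counts(self) -> dict[str, int]:
        t = self.genes.loc[self.genes["target"], "n_sites"]
        return {g: int(c) for g, c in t.items()}


def overlap_fixture(
    n_query: int, n_overlapping: int, chrom: str = "chrT", strand: str = "+"
) -> tuple["PeakSet", "PeakSet"]:
    """Two peak sets with an exact overlap count, for overlap arithmetic.

    Builds ``n_query`` disjoint query peaks of which exactly
    ``n_overlapping`` overlap a reference peak (by construction, 1-nt
    overlap rule); the reference set also carries extra peaks in the gaps
    that overlap nothing.
    """
    from .intervals import PeakSet  # local import to avoid cycle at module load

    if not 0 <= n_overlapping <= n_query:
        raise ValueError("need 0 <= n_overlapping <= n_query")
    spacing, width = 300, 100
    query = [
        GenomicInterval(chrom, i * spacing, i * spacing + width, strand, f"q{i}")
        for i in range(n_query)
    ]
    ref = [
        GenomicInterval(chrom, i * spacing + width - 1, i * spacing + width + 49,
                        strand, f"r{i}")
        for i in range(n_overlapping)
    ]
    # decoy reference peaks in the inter-query gaps
    ref += [
        GenomicInterval(chrom, i * spacing + width + 60, i * spacing + width + 120,
                        strand, f"d{i}")
        for i in range(n_overlapping, n_query)
    ]
    ones = np.ones(len(query))
    return (
        PeakSet(query, ones, np.zeros(len(query)), "query"),
        PeakSet(ref, np.ones(len(ref)), np.zeros(len(ref)), "reference"),
    )


# ---------------------------------------------------------------------------
# genome & truth


def simulate_genome(config: SimConfig) -> tuple[list[GeneModel], dict[str, int]]:
    """Place ``n_genes`` non-overlapping 3-region gene models on
    ``n_chromosomes`` chromosomes; returns models and chromosome sizes.

    Raises a sizing error naming the required length when a declared
    chromosome length cannot hold its share of genes.
    """
    config.validate()
    rng = config.rng(_TAG_GENOME)
    lo_len, hi_len = config.gene_length_range
    lo_gap, hi_gap = config.intergenic_gap
    per_chrom: dict[str, list[int]] = {
        f"chr{c + 1}": [] for c in range(config.n_chromosomes)
    }
    for i in range(config.n_genes):
        per_chrom[f"chr{i % config.n_chromosomes + 1}"].append(i)

    models: list[GeneModel] = []
    sizes: dict[str, int] = {}
    width = int(math.ceil(math.log10(config.n_genes + 1)))
    for chrom, idxs in per_chrom.items():
        n = len(idxs)
        lengths = rng.integers(lo_len, hi_len + 1, size=n)
        gaps = rng.integers(lo_gap, hi_gap + 1, size=n + 1)
        required = int(lengths.sum() + gaps.sum())
        if config.chromosome_length is not None and required > config.chromosome_length:
            raise ValueError(
                f"{chrom}: cannot place {n} genes without overlap; requires "
                f"{required} bp but chromosome_length={config.chromosome_length}"
            )
        pos = int(gaps[0])
        for k, i in enumerate(idxs):
            L = int(lengths[k])
            # region split ~15/60/25% with jitter, in transcript order
            f5 = rng.uniform(0.10, 0.20)
            f3 = rng.uniform(0.20, 0.30)
            l5 = max(50, int(L * f5))
            l3 = max(50, int(L * f3))
            lc = L - l5 - l3
            strand = "+" if rng.random() < 0.5 else "-"
            b0, b1, b2, b3 = pos, pos + l5, pos + l5 + lc, pos + L
            if strand == "+":
                utr5, cds, utr3 = (b0, b1), (b1, b2), (b2, b3)
            else:  # 5'UTR genomically rightmost on the minus strand
                utr3 = (b0, b0 + l3)
                cds = (b0 + l3, b0 + l3 + lc)
                utr5 = (b0 + l3 + lc, b3)
            models.append(
                GeneModel(f"G{i + 1:0{width}d}", chrom, strand, utr5, cds, utr3)
            )
            pos = b3 + int(gaps[k + 1])
        sizes[chrom] = config.chromosome_length or pos
    models.sort(key=lambda m: m.gene_id)
    return models, sizes


def _place_sites(
    rng: np.random.Generator, model: GeneModel, k: int, config: SimConfig
) -> list[GenomicInterval]:
    """k disjoint site intervals inside one gene, region-biased."""
    regions = {"5UTR": model.utr5, "CDS": model.cds, "3UTR": model.utr3}
    names = ["5UTR", "CDS", "3UTR"]
    chosen = rng.choice(3, size=k, p=np.asarray(config.site_region_probs))
    sites: list[GenomicInterval] = []
    by_region: dict[str, int] = {}
    for c in chosen:
        by_region[names[c]] = by_region.get(names[c], 0) + 1
    for rname, m in by_region.items():
        lo, hi = regions[rname]
        span = hi - lo
        chunk = span // m
        for j in range(m):
            w = min(config.clip_site_width, max(10, chunk - 2))
            c_lo = lo + j * chunk
            slack = max(1, chunk - w)
            start = c_lo + int(rng.integers(0, slack))
            sites.append(
                GenomicInterval(model.chrom, start, min(start + w, hi),
                                model.strand, model.gene_id)
            )
    return sites


def simulate_truth(config: SimConfig, models: Sequence[GeneModel]) -> GroundTruth:
    """Draw per-gene m6A status, reader binding, site intervals, expression
    and genotype decay rates."""
    config.validate()
    rng = config.rng(_TAG_TRUTH)
    ids = [m.gene_id for m in models]
    n = len(ids)
    m6a = rng.random(n) < config.frac_m6a
    target = m6a & (rng.random(n) < config.frac_reader_target)
    # site counts: categories 1 / 2 / 3-or-more (3 plus a small Poisson tail)
    cat = rng.choice([1, 2, 3], size=n, p=np.asarray(config.binding_site_dist))
    extra = rng.poisson(0.5, size=n)
    n_sites = np.where(target, np.where(cat == 3, 3 + extra, cat), 0)

    expr = rng.lognormal(mean=0.0, sigma=config.expr_sigma, size=n)
    expr /= expr.sum()
    lo, hi = config.decay_rate_range
    A_wt = rng.uniform(lo, hi, size=n)
    A_mut = A_wt * config.reader_effect ** n_sites

    genes = pd.DataFrame(
        {
            "m6a": m6a,
            "target": target,
            "n_sites": n_sites.astype(int),
            "expr": expr,
            "A_WT": A_wt,
            "A_ect8": A_mut,
            "halflife_WT": np.log(2) / A_wt,
            "halflife_ect8": np.log(2) / A_mut,
        },
        index=pd.Index(ids, name="gene_id"),
    )

    sites: list[GenomicInterval] = []
    m6a_regions: list[GenomicInterval] = []
    for m, is_m6a, is_t, k in zip(models, m6a, target, n_sites):
        if is_t:
            gene_sites = _place_sites(rng, m, int(k), config)
            sites.extend(gene_sites)
            # methylated regions of bound genes coincide with the sites
            m6a_regions.extend(gene_sites)
        elif is_m6a:
            m6a_regions.extend(_place_sites(rng, m, 1, config))
    return GroundTruth(genes=genes, sites=sites, m6a_regions=m6a_regions)


# ---------------------------------------------------------------------------
# count sampling


def _draw(rng: np.random.Generator, mu: np.ndarray, config: SimConfig) -> np.ndarray:
    """NB(mu, dispersion) draws, or the exact expectations in expected mode."""
    mu = np.asarray(mu, dtype=float)
    if config.sampling == "expected":
        return mu
    a = config.nb_dispersion
    if a <= 1e-12:
        return rng.poisson(mu).astype(float)
    size_param = 1.0 / a
    p = size_param / (size_param + np.maximum(mu, 1e-300))
    out = np.where(mu > 0, rng.negative_binomial(size_param, np.minimum(p, 1.0)), 0)
    return out.astype(float)


def _spike_ids(config: SimConfig) -> list[str]:
    return [f"SPIKE_ERCC_{i + 1:02d}" for i in range(config.n_spikeins)]


METH_SPIKE = "SPIKE_M6A_METH"
UNMETH_SPIKE = "SPIKE_M6A_UNMETH"


# ---------------------------------------------------------------------------
# experiments


def simulate_m6a_experiment(
    config: SimConfig,
    models: Sequence[GeneModel],
    truth: GroundTruth,
    n_reps: int = 2,
    ip_efficiency: Sequence[float] | None = None,
    label: str = "WT",
    stream: int = 0,
) -> CountTable:
    """m6A-IP and input samples with the methylated/unmethylated spike pair.

    IP rows of methylated genes are inflated ``ip_enrichment``-fold (then
    renormalized to depth, as sequencing fixes the library size); the
    methylated spike-in is additionally scaled by the per-sample IP
    efficiency, which is recorded in ``truth.ip_efficiency``. The
    unmethylated spike-in sees no enrichment.
    """
    config.validate()
    rng = config.rng(_TAG_M6A, stream)
    eff = list(ip_efficiency) if ip_efficiency is not None else [1.0] * n_reps
    if len(eff) != n_reps:
        raise ValueError("need one ip_efficiency per replicate")
    g = truth.genes
    expr = g["expr"].to_numpy()
    enr = np.where(g["m6a"].to_numpy(), config.ip_enrichment, 1.0)
    w_ip = expr * enr
    w_ip = w_ip / w_ip.sum()
    spike_each = config.depth * config.spike_fraction / 2.0

    cols: dict[str, np.ndarray] = {}
    meta: list[dict] = []
    for r in range(n_reps):
        s_in = f"{label}_Input_rep{r + 1}"
        s_ip = f"{label}_IP_rep{r + 1}"
        mu_in = np.concatenate([config.depth * expr, [spike_each, spike_each]])
        mu_ip = np.concatenate(
            [
                config.depth * w_ip,
                [spike_each * config.spike_ip_enrichment * eff[r], spike_each],
            ]
        )
        cols[s_in] = _draw(rng, mu_in, config)
        cols[s_ip] = _draw(rng, mu_ip, config)
        meta.append({"sample": s_in, "genotype": label, "role": "input", "replicate": r + 1})
        meta.append({"sample": s_ip, "genotype": label, "role": "IP", "replicate": r + 1})
        truth.ip_efficiency[s_ip] = float(eff[r])

    index = pd.Index(list(g.index) + [METH_SPIKE, UNMETH_SPIKE], name="feature_id")
    counts = pd.DataFrame(cols, index=index)
    samples = pd.DataFrame(meta).set_index("sample").loc[counts.columns]
    return CountTable(counts=counts, samples=samples)


def _blank_tracks(sizes: Mapping[str, int], bin_size: int) -> dict[str, np.ndarray]:
    return {c: np.zeros(int(np.ceil(s / bin_size)), dtype=float) for c, s in sizes.items()}


def _add_gene_mass(
    track: dict[str, np.ndarray], model: GeneModel, mass: float, bin_size: int
) -> None:
    lo = model.start // bin_size
    hi = (model.end + bin_size - 1) // bin_size
    track[model.chrom][lo:hi] += mass / (hi - lo)


def _boost_intervals(
    track: dict[str, np.ndarray],
    base: dict[str, np.ndarray],
    intervals: Sequence[GenomicInterval],
    fold: float,
    bin_size: int,
) -> None:
    """Raise ``track`` to ``fold`` x the base expectation over interval bins."""
    for iv in intervals:
        lo = iv.start // bin_size
        hi = max(lo + 1, (iv.end + bin_size - 1) // bin_size)
        track[iv.chrom][lo:hi] += (fold - 1.0) * base[iv.chrom][lo:hi]


StrandedTracks = dict[str, dict[str, np.ndarray]]  # strand -> chrom -> binned counts


def simulate_clip_coverage(
    config: SimConfig,
    models: Sequence[GeneModel],
    truth: GroundTruth,
    sizes: Mapping[str, int],
    condition: str = "mock",
    site_intervals: Sequence[GenomicInterval] | None = None,
    site_fold: float | None = None,
    stream: int = 0,
) -> tuple[dict[str, StrandedTracks], list[GenomicInterval]]:
    """Strand-separated binned coverage for reader IP, binding-impaired
    reader IP, and input, plus the true site intervals.

    The reader IP track is enriched ``clip_site_fold``-fold over the sites
    (doubled occupancy under the salt condition); the impaired-reader track
    has enrichment ~1 everywhere. Passing ``site_intervals`` (e.g. the true
    methylated regions) reuses the machinery for m6A-IP coverage.
    """
    config.validate()
    rng = config.rng(_TAG_CLIP, stream, 1 if condition == "salt" else 0)
    sites = list(site_intervals) if site_intervals is not None else list(truth.sites)
    fold = site_fold if site_fold is not None else config.clip_site_fold
    occ = config.salt_binding_factor if condition == "salt" else 1.0

    expr = truth.genes["expr"]
    base: StrandedTracks = {s: _blank_tracks(sizes, config.bin_size) for s in "+-"}
    for m in models:
        _add_gene_mass(base[m.strand], m, config.depth * float(expr[m.gene_id]), config.bin_size)

    reader = {s: {c: a.copy() for c, a in base[s].items()} for s in "+-"}
    by_strand: dict[str, list[GenomicInterval]] = {"+": [], "-": []}
    for iv in sites:
        by_strand[iv.strand].append(iv)
    for s in "+-":
        _boost_intervals(reader[s], base[s], by_strand[s], fold * occ, config.bin_size)

    impaired = {s: {c: a.copy() for c, a in base[s].items()} for s in "+-"}

    tracks: dict[str, StrandedTracks] = {}
    for name, exp in (("reader", reader), ("impaired", impaired), ("input", base)):
        tracks[name] = {
            s: {c: _draw(rng, mu, config) for c, mu in exp[s].items()} for s in "+-"
        }
    return tracks, sites


def simulate_decay_course(
    config: SimConfig,
    truth: GroundTruth,
    genotype: str = "WT",
    n_reps: int = 2,
    times: Sequence[float] = DECAY_TIMES,
    stream: int = 0,
) -> CountTable:
    """Transcription-shutoff time course for one genotype.

    Expected gene counts are depth * expr_g * exp(-A_g t) with the
    genotype's true decay rate; ERCC-like spike-in rows have constant
    expected counts across time (exactly constant in expected mode).
    """
    config.validate()
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    times = [float(t) for t in times]
    if 0.0 not in times:
        raise ValueError("time course must include t = 0")
    rng = config.rng(_TAG_DECAY, {"WT": 0, "ect8": 1}[genotype], stream)
    g = truth.genes
    expr = g["expr"].to_numpy()
    A = g[f"A_{genotype}"].to_numpy()
    spike_ids = _spike_ids(config)
    # fixed, unequal spike abundances summing to the spike share of depth
    spike_mass = np.geomspace(1.0, 8.0, len(spike_ids))
    spike_mass = spike_mass / spike_mass.sum() * config.depth * config.spike_fraction

    cols: dict[str, np.ndarray] = {}
    meta: list[dict] = []
    for t in times:
        decay = np.exp(-A * t)
        mu = np.concatenate([config.depth * expr * decay, spike_mass])
        for r in range(n_reps):
            sid = f"{genotype}_t{int(t)}_rep{r + 1}"
            cols[sid] = _draw(rng, mu, config)
            meta.append(
                {"sample": sid, "genotype": genotype, "time": t, "replicate": r + 1,
                 "role": "decay"}
            )
    index = pd.Index(list(g.index) + spike_ids, name="feature_id")
    counts = pd.DataFrame(cols, index=index)
    samples = pd.DataFrame(meta).set_index("sample").loc[counts.columns]
    return CountTable(counts=counts, samples=samples)


def simulate_ribo_experiment(
    config: SimConfig,
    truth: GroundTruth,
    n_reps: int = 2,
    te_shift: Mapping[str, float] | None = None,
    label: str = "WT",
    stream: int = 0,
) -> CountTable:
    """Ribosome-footprint and matched input samples.

    Footprint expectations are input expectations scaled per gene by a true
    translation efficiency (log-normal around 1, optionally shifted for
    chosen genes via ``te_shift``).
    """
    config.validate()
    rng = config.rng(_TAG_RIBO, stream)
    g = truth.genes
    expr = g["expr"].to_numpy()
    te_true = rng.lognormal(mean=0.0, sigma=0.4, size=len(g))
    if te_shift:
        idx = g.index.get_indexer(list(te_shift))
        te_true[idx] *= np.array(list(te_shift.values()))
    w_ribo = expr * te_true
    w_ribo = w_ribo / w_ribo.sum()
    spike_each = config.depth * config.spike_fraction / 2.0

    cols: dict[str, np.ndarray] = {}
    meta: list[dict] = []
    for r in range(n_reps):
        s_in, s_rb = f"{label}_Input_rep{r + 1}", f"{label}_Ribo_rep{r + 1}"
        cols[s_in] = _draw(
            rng, np.concatenate([config.depth * expr, [spike_each, spike_each]]), config
        )
        cols[s_rb] = _draw(
            rng, np.concatenate([config.depth * w_ribo, [spike_each, spike_each]]), config
        )
        meta.append({"sample": s_in, "genotype": label, "role": "input", "replicate": r + 1})
        meta.append({"sample": s_rb, "genotype": label, "role": "ribo", "replicate": r + 1})
    index = pd.Index(list(g.index) + [METH_SPIKE, UNMETH_SPIKE], name="feature_id")
    counts = pd.DataFrame(cols, index=index)
    samples = pd.DataFrame(meta).set_index("sample").loc[counts.columns]
    table = CountTable(counts=counts, samples=samples)
    table.true_te = pd.Series(te_true, index=g.index)  # ground truth for tests
    return table
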