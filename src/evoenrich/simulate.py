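"""Synthetic reference panels, annotation tracks and GWAS summary
statistics with planted per-annotation enrichment.

The generator emulates the statistical structure the enrichment
framework assumes — block LD, polygenic signal, genic clustering of
annotations, an MHC-like gene-dense region — without any download:

* **Panel**: haplotypes are simulated blockwise.  Within a block every
  site copies a shared latent haplotype and mutates with a per-site flip
  rate tuned so the realized mean within-block r2 approximates the
  target (for flip rate eps, pairwise dosage r2 ~= (1 - 2 eps)^4);
  blocks are independent, so LD is exactly block-diagonal and
  brute-force oracles stay cheap.  Block minor-allele frequencies are
  log-uniform on (0.01, 0.5), mimicking a common-variant panel.

* **Tracks**: non-overlapping gene models with 5'UTR / exon / intron /
  3'UTR parts (introns are the gene interior minus exons and UTRs, so
  the parts are disjoint by construction), a brain-gene and an
  ohnolog-like subset of gene bodies, short HAR-like and wide SD-like
  interval tracks, sparse ncRNA / TFBS / miRNA-binding-site tracks for
  the intergenic definition, and one contiguous MHC-like region with
  boosted gene density.

* **Summary statistics**: causal effects b_j ~ N(0, base_h2_per_snp +
  sum_c tau_c a_jc) with a_jc the raw annotation indicator; marginal
  z = sqrt(n_gwas) R b + e with e ~ N(0, inflation * R) blockwise, R
  the empirical dosage correlation of the block.  tau is on the causal
  effect-variance scale, so a planted annotation adds about
  n_gwas * tau * (LD-weighted burden) to the expected squared z-score
  of tagging SNPs.

Everything is deterministic per seed; the planted truth is emitted
alongside the data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .io import AnnotationTrack, ReferencePanel, SummaryStats, z_to_p


@dataclass
class TrackSpecs:
    """Interval width/density parameters per annotation category."""

    har_per_mb: float = 3.0
    har_length: int = 400
    # segmental duplications cover roughly 5% of the human genome:
    # 1.2 intervals/Mb x ~40 kb mean width
    sd_per_mb: float = 1.2
    sd_length_mean: int = 40_000
    ohno_gene_fraction: float = 0.3
    brain_gene_fraction: float = 0.2
    ncrna_per_mb: float = 1.0
    ncrna_length: int = 2_000
    tfbs_per_mb: float = 2.0
    tfbs_length: int = 500
    mirna_per_mb: float = 1.0
    mirna_length: int = 100
    mhc_gene_boost: float = 3.0


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic pipeline.

    Defaults describe a desk-scale study: 20,000 common SNPs on two
    50 Mb chromosomes, 100 diploid reference samples, 50 kb mean LD
    blocks with moderate within-block r2, a GWAS of 50,000 subjects
    with a small polygenic baseline and no planted enrichment or
    inflation unless requested.
    """

    n_snps: int = 20_000
    n_samples: int = 100
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 50_000_000, "6": 50_000_000}
    )
    block_size_mean: int = 50_000
    within_block_r2: float = 0.5
    maf_range: tuple[float, float] = (0.01, 0.5)
    gene_density_per_mb: float = 1.5
    gene_length_mean: int = 60_000
    track_specs: TrackSpecs = field(default_factory=TrackSpecs)
    tau: dict[str, float] = field(default_factory=dict)
    base_h2_per_snp: float = 1e-5
    n_gwas: int = 50_000
    inflation: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_snps <= 0 or self.n_samples < 2:
            raise ValueError("counts must be positive (and >= 2 samples)")
        if not 0 <= self.within_block_r2 < 1:
            raise ValueError("within_block_r2 must lie in [0, 1)")
        if any(t < 0 for t in self.tau.values()):
            raise ValueError("tau values must be non-negative")
        if self.inflation < 1:
            raise ValueError("inflation must be >= 1")

    def mhc_like_region(self) -> tuple[str, int, int]:
        """One contiguous gene-dense region: the middle 12% of chromosome
        "6" when present, else of the first chromosome (1-based bounds)."""
        chrom = "6" if "6" in self.chrom_lengths else next(iter(self.chrom_lengths))
        L = self.chrom_lengths[chrom]
        return (chrom, int(0.44 * L) + 1, int(0.56 * L))


@dataclass
class SimulatedStudy:
    panel: ReferencePanel
    tracks: dict[str, AnnotationTrack]
    stats: SummaryStats
    truth: dict


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------

def _unique_sorted_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    if n > length:
        raise ValueError("more SNPs than base pairs")
    draw = np.unique(rng.integers(1, length + 1, size=int(n * 1.2) + 16))
    while draw.size < n:
        extra = rng.integers(1, length + 1, size=n)
        draw = np.unique(np.concatenate([draw, extra]))
    return np.sort(rng.choice(draw, size=n, replace=False))


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def _flip_rate(target_r2: float, p: float) -> float:
    """Per-site mutation (flip) rate giving the target pairwise r2.

    Two sites copying a shared Bernoulli(p) haplotype with independent
    flip rate eps have correlation

        r(eps) = (1 - 2 eps)^2 * p (1 - p) / (f (1 - f)),
        f = p + eps (1 - 2 p),

    which is monotone decreasing in eps; solve r(eps) = sqrt(target_r2)
    by bisection.  Flips shift the site frequency away from p, so a
    closed-form (1 - 2 eps)^4 would badly undershoot at low MAF.
    """
    want = np.sqrt(target_r2)

    def r(eps):
        f = p + eps * (1 - 2 * p)
        return (1 - 2 * eps) ** 2 * p * (1 - p) / (f * (1 - f))

    lo, hi = 0.0, 0.5
    for _ in range(50):
        mid = (lo + hi) / 2
        if r(mid) > want:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def generate_panel(config: GeneratorConfig, rng: np.random.Generator | None = None) -> ReferencePanel:
    """Blockwise haplotype panel with tunable within-block r2.

    The variant table carries a ``block`` column (global block id) used
    by the fast summary-statistic simulator.  Deterministic per seed.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    total_bp = sum(config.chrom_lengths.values())
    H = 2 * config.n_samples
    target = config.within_block_r2

    ids, chroms, poss, blocks = [], [], [], []
    hap_cols = []
    block_id = 0
    remaining = config.n_snps
    items = list(config.chrom_lengths.items())
    for ci, (chrom, length) in enumerate(items):
        n_here = remaining if ci == len(items) - 1 else int(
            round(config.n_snps * length / total_bp)
        )
        n_here = min(n_here, remaining)
        remaining -= n_here
        if n_here == 0:
            continue
        pos = _unique_sorted_positions(rng, length, n_here)
        # split into blocks by a renewal process of mean block_size_mean
        block_start = pos[0]
        block_len = rng.exponential(config.block_size_mean)
        members: list[int] = []

        def flush(members):
            nonlocal block_id
            if not members:
                return
            m = len(members)
            p_b = _log_uniform(rng, *config.maf_range)
            if target > 0 and m > 1:
                base = (rng.random(H) < p_b).astype(np.int8)
                flips = rng.random((H, m)) < _flip_rate(target, p_b)
                hap = base[:, None] ^ flips
            else:
                p_site = _log_uniform(rng, *config.maf_range, size=m)
                hap = (rng.random((H, m)) < p_site).astype(np.int8)
            hap_cols.append(hap.astype(np.int8))
            blocks.extend([block_id] * m)
            block_id += 1

        for q in pos:
            if q - block_start > block_len and members:
                flush(members)
                members = []
                block_start = q
                block_len = rng.exponential(config.block_size_mean)
            members.append(q)
        flush(members)
        chroms.extend([chrom] * n_here)
        poss.extend(pos.tolist())
        ids.extend(f"snp_{chrom}_{q}" for q in pos)

    hap = np.concatenate(hap_cols, axis=1)
    dosages = (hap[: config.n_samples] + hap[config.n_samples:]).astype(np.int16)
    # guarantee polymorphism: flip one haplotype at any monomorphic site
    mono = np.flatnonzero(dosages.std(axis=0) == 0)
    if mono.size:
        hap[0, mono] ^= 1
        dosages = (hap[: config.n_samples] + hap[config.n_samples:]).astype(np.int16)

    variants = pd.DataFrame(
        {
            "snp_id": ids,
            "chrom": chroms,
            "pos": np.asarray(poss, dtype=np.int64),
            "a1": "A",
            "a2": "G",
            "block": np.asarray(blocks, dtype=np.int64),
        }
    )
    return ReferencePanel(variants=variants, dosages=dosages)


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def _place_intervals(rng, length, per_mb, width_mean, fixed_width=False):
    n = rng.poisson(per_mb * length / 1e6)
    out = []
    for _ in range(n):
        w = width_mean if fixed_width else max(50, int(rng.exponential(width_mean)))
        s = int(rng.integers(0, max(1, length - w)))
        out.append((s, s + w))
    return out


def _gene_parts(rng, s, e):
    """Split a gene body [s, e) into disjoint utr5/exon/intron/utr3 parts."""
    L = e - s
    u5 = min(1000, max(200, L // 40))
    u3 = min(3000, max(500, L // 15))
    utr5 = (s, s + u5)
    utr3 = (e - u3, e)
    i0, i1 = s + u5, e - u3
    exons, introns = [], []
    n_ex = max(1, (i1 - i0) // 10_000)
    ex_len = min(200, max(60, (i1 - i0) // (2 * n_ex)))
    starts = np.linspace(i0, i1 - ex_len, n_ex).astype(int)
    cursor = i0
    for st in starts:
        st = int(max(st, cursor))
        en = min(st + ex_len, i1)
        if st >= en:
            continue
        if st > cursor:
            introns.append((cursor, st))
        exons.append((st, en))
        cursor = en
    if cursor < i1:
        introns.append((cursor, i1))
    return utr5, exons, introns, utr3


def generate_tracks(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> dict[str, AnnotationTrack]:
    """All annotation tracks the pipeline consumes, internally consistent.

    Gene parts are disjoint within each gene and their union is the gene
    body; brain and ohnolog-like sets are gene subsets; the MHC-like
    region has gene density boosted by ``track_specs.mhc_gene_boost``.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    ts = config.track_specs
    mhc_chrom, mhc_start1, mhc_end1 = config.mhc_like_region()
    mhc_s0, mhc_e0 = mhc_start1 - 1, mhc_end1  # 0-based half-open

    genes: list[tuple[str, int, int]] = []
    parts = {"utr5": [], "exon": [], "intron": [], "utr3": []}
    interval_tracks = {
        "HAR": [], "SD": [], "ncRNA": [], "TFBS": [], "miRNA_bs": [], "MHC": []
    }

    mean_gap = max(20_000.0, 1e6 / config.gene_density_per_mb - config.gene_length_mean)
    for chrom, length in config.chrom_lengths.items():
        in_mhc_chrom = chrom == mhc_chrom
        x = int(rng.exponential(mean_gap))
        while x < length - 10_000:
            inside_mhc = in_mhc_chrom and mhc_s0 <= x < mhc_e0
            L = int(np.clip(rng.exponential(config.gene_length_mean),
                            5_000, 5 * config.gene_length_mean))
            e = min(x + L, length)
            if e - x >= 5_000:
                genes.append((chrom, x, e))
                u5, ex, intr, u3 = _gene_parts(rng, x, e)
                parts["utr5"].append((chrom, *u5))
                parts["utr3"].append((chrom, *u3))
                parts["exon"].extend((chrom, a, b) for a, b in ex)
                parts["intron"].extend((chrom, a, b) for a, b in intr)
            gap = rng.exponential(
                mean_gap / ts.mhc_gene_boost if inside_mhc else mean_gap
            )
            x = e + int(gap)

        for name, per_mb, width, fixed in (
            ("HAR", ts.har_per_mb, ts.har_length, True),
            ("SD", ts.sd_per_mb, ts.sd_length_mean, False),
            ("ncRNA", ts.ncrna_per_mb, ts.ncrna_length, True),
            ("TFBS", ts.tfbs_per_mb, ts.tfbs_length, True),
            ("miRNA_bs", ts.mirna_per_mb, ts.mirna_length, True),
        ):
            interval_tracks[name].extend(
                (chrom, a, b) for a, b in _place_intervals(rng, length, per_mb, width, fixed)
            )

    interval_tracks["MHC"] = [(mhc_chrom, mhc_s0, mhc_e0)]

    n_genes = len(genes)
    ohno_pick = rng.random(n_genes) < ts.ohno_gene_fraction
    brain_pick = rng.random(n_genes) < ts.brain_gene_fraction
    tracks = {
        "protein_coding_gene": AnnotationTrack("protein_coding_gene", genes),
        "Ohno": AnnotationTrack("Ohno", [g for g, k in zip(genes, ohno_pick) if k]),
        "brain": AnnotationTrack("brain", [g for g, k in zip(genes, brain_pick) if k]),
    }
    for name, ivs in parts.items():
        tracks[name] = AnnotationTrack(name, ivs)
    for name, ivs in interval_tracks.items():
        tracks[name] = AnnotationTrack(name, ivs)
    return tracks


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

@dataclass
class BlockModel:
    """Cached per-block correlation structure for fast re-simulation.

    Single-site blocks (R = [[1]]) are kept aside as one index array so
    re-simulation handles them vectorized.
    """

    slices: list[slice]
    R: list[np.ndarray]
    L: list[np.ndarray]  # Cholesky factors
    singletons: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))


def block_model(panel: ReferencePanel, jitters=(0.0, 1e-8, 1e-6, 1e-4)) -> BlockModel:
    """Empirical blockwise dosage correlation and Cholesky factors.

    Near-singular block correlation matrices (perfectly correlated
    sites) are regularized by the smallest jitter that makes the
    Cholesky succeed; an error is raised if none does.
    """
    blocks = panel.variants["block"].to_numpy()
    D = panel.dosages.astype(np.float64)
    edges = np.flatnonzero(np.diff(blocks)) + 1
    bounds = np.concatenate(([0], edges, [len(blocks)]))
    slices, Rs, Ls, singles = [], [], [], []
    for b in range(len(bounds) - 1):
        lo, hi = int(bounds[b]), int(bounds[b + 1])
        if hi - lo == 1:
            singles.append(lo)
            continue
        sl = slice(lo, hi)
        sub = D[:, sl]
        m = sub.shape[1]
        R = np.corrcoef(sub, rowvar=False).reshape(m, m)
        Lc = None
        for jit in jitters:
            try:
                Rj = (R + jit * np.eye(m)) / (1.0 + jit)
                Lc = np.linalg.cholesky(Rj)
                R = Rj
                break
            except np.linalg.LinAlgError:
                continue
        if Lc is None:
            raise RuntimeError(f"block {b}: correlation matrix not positive definite")
        slices.append(sl)
        Rs.append(R)
        Ls.append(Lc)
    return BlockModel(slices=slices, R=Rs, L=Ls,
                      singletons=np.asarray(singles, dtype=np.int64))


def simulate_summary_stats(
    panel: ReferencePanel,
    tracks: dict[str, AnnotationTrack],
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    blocks: BlockModel | None = None,
) -> SummaryStats:
    """GWAS summary statistics under the planted polygenic model.

    b_j ~ N(0, base_h2_per_snp + sum_c tau_c a_jc);
    z = sqrt(n_gwas) R b + e, e ~ N(0, inflation * R), blockwise.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    if blocks is None:
        blocks = block_model(panel)

    chrom = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy()
    var_beta = np.full(panel.n_variants, config.base_h2_per_snp, dtype=float)
    for cat, tau_c in config.tau.items():
        if cat not in tracks:
            raise KeyError(f"tau names unknown category {cat!r}")
        var_beta += tau_c * tracks[cat].contains(chrom, pos)

    beta = rng.standard_normal(panel.n_variants) * np.sqrt(var_beta)
    z = np.empty(panel.n_variants)
    root_n = np.sqrt(config.n_gwas)
    root_inf = np.sqrt(config.inflation)
    for sl, R, L in zip(blocks.slices, blocks.R, blocks.L):
        eta = rng.standard_normal(R.shape[0])
        z[sl] = root_n * (R @ beta[sl]) + root_inf * (L @ eta)
    s = blocks.singletons
    if s.size:
        z[s] = root_n * beta[s] + root_inf * rng.standard_normal(s.size)

    f = panel.allele_freq()
    df = pd.DataFrame(
        {
            "snp_id": panel.variants["snp_id"],
            "chrom": chrom,
            "pos": pos,
            "a1": panel.variants["a1"],
            "a2": panel.variants["a2"],
            "p": z_to_p(z),
            "z": z,
            "n": config.n_gwas,
            "maf": np.minimum(f, 1 - f),
        }
    )
    return SummaryStats(df=df)


def generate_study(config: GeneratorConfig) -> SimulatedStudy:
    """Panel, tracks, summary statistics and the planted truth, per seed."""
    panel = generate_panel(config)
    tracks = generate_tracks(config)
    stats = simulate_summary_stats(panel, tracks, config)
    chrom = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy()
    truth = {
        "seed": config.seed,
        "tau": dict(config.tau),
        "base_h2_per_snp": config.base_h2_per_snp,
        "inflation": config.inflation,
        "n_gwas": config.n_gwas,
        "n_snps": panel.n_variants,
        "n_samples": config.n_samples,
        "mhc_like_region": list(config.mhc_like_region()),
        "n_annotated": {
            name: int(trk.contains(chrom, pos).sum())
            for name, trk in tracks.items()
        },
    }
    return SimulatedStudy(panel=panel, tracks=tracks, stats=stats, truth=truth)


def write_study(study: SimulatedStudy, outdir) -> None:
    """Write the study in the same formats the readers consume."""
    from pathlib import Path

    from .io import write_panel_matrix, write_summary_stats, write_track

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_summary_stats(study.stats, out / "sumstats.tsv")
    write_panel_matrix(
        study.panel, out / "panel_dosages.tsv", out / "panel_variants.tsv"
    )
    for name, track in study.tracks.items():
        write_track(track, out / f"track_{name}.bed")
    with open(out / "truth.json", "w") as fh:
        json.dump(study.truth, fh, indent=2)
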