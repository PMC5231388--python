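"""LD/MAF-matched null SNP sets.

How much of an annotation's apparent enrichment is carried by the
annotation itself, and how much by the LD and allele-frequency profile
of its SNPs?  To separate the two, random SNP sets are drawn from
outside the annotation that replicate, cell by cell, the joint
(MAF x TotLD) distribution of the SNPs physically inside it.  Matching
is on the raw-indicator SNPs with their TotLD as the LD covariate.
Enrichment curves of the matched sets retain LD/frequency-driven
enrichment but carry no annotation content; the pointwise envelope
across sets quantifies it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import EnrichmentCurve, fold_curve, default_grid, GENOME_WIDE_LOG10


@dataclass
class MatchSpec:
    """Binning and sampling plan for matched-set construction.

    MAF is cut into ``n_maf_bins`` equal-width bins on (0, 0.5]; TotLD
    into ``n_totld_bins`` quantile bins of the pooled (source + pool)
    distribution — quantiles adapt to TotLD's heavy right tail.
    """

    n_maf_bins: int = 25
    n_totld_bins: int = 10
    n_sets: int = 100
    seed: int = 0
    allow_reuse: bool = False


class MatchingError(ValueError):
    """A (MAF, TotLD) cell of the pool cannot supply the source's count."""


def _cell_ids(maf, totld, spec: MatchSpec, totld_edges: np.ndarray) -> np.ndarray:
    maf_bin = np.clip(
        np.floor(np.asarray(maf) / (0.5 / spec.n_maf_bins)).astype(int),
        0,
        spec.n_maf_bins - 1,
    )
    totld_bin = np.clip(
        np.searchsorted(totld_edges, totld, side="right") - 1,
        0,
        len(totld_edges) - 2,
    )
    return maf_bin * (len(totld_edges) - 1) + totld_bin


def sample_matched(
    source: np.ndarray,
    table: pd.DataFrame,
    spec: MatchSpec,
    pool: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Draw ``spec.n_sets`` SNP index sets matched to ``source`` on
    (MAF, TotLD).

    ``source`` and ``pool`` are integer row indices into ``table``
    (pool defaults to the complement of source).  For every 2-D cell,
    each matched set samples from the pool exactly the source's count in
    that cell; sets are disjoint from the source by construction.
    Without ``allow_reuse`` an undersupplied cell raises
    ``MatchingError`` listing the deficient cells.
    """
    source = np.asarray(source, dtype=np.int64)
    all_idx = np.arange(len(table))
    if pool is None:
        pool = np.setdiff1d(all_idx, source)
    pool = np.asarray(pool, dtype=np.int64)

    maf = table["maf"].to_numpy(dtype=float)
    totld = table["tot_ld"].to_numpy(dtype=float)
    pooled = np.concatenate([totld[source], totld[pool]])
    qs = np.linspace(0, 1, spec.n_totld_bins + 1)
    edges = np.quantile(pooled, qs) if pooled.size else np.array([0.0, 1.0])
    edges[-1] = np.inf

    src_cells = _cell_ids(maf[source], totld[source], spec, edges)
    pool_cells = _cell_ids(maf[pool], totld[pool], spec, edges)

    cell_ids, src_counts = np.unique(src_cells, return_counts=True)
    pool_by_cell = {c: pool[pool_cells == c] for c in cell_ids}
    if not spec.allow_reuse:
        deficient = [
            (int(c), int(k), len(pool_by_cell[c]))
            for c, k in zip(cell_ids, src_counts)
            if len(pool_by_cell[c]) < k
        ]
        if deficient:
            raise MatchingError(
                "undersupplied (maf, totld) cells (cell, needed, available): "
                f"{deficient[:10]}"
            )
    else:
        # a cell whose pool is empty borrows the nearest nonempty cell in
        # (maf bin, totld bin) space — sampling with replacement cannot
        # conjure SNPs from an empty cell
        n_tot = len(np.unique(pool_cells))
        nonempty = np.unique(pool_cells)
        width = spec.n_totld_bins
        for c in cell_ids:
            if len(pool_by_cell[c]) == 0:
                ci, cj = divmod(int(c), width)
                dist = [
                    (abs(ci - int(o) // width) + abs(cj - int(o) % width), o)
                    for o in nonempty
                ]
                _, nearest = min(dist)
                pool_by_cell[c] = pool[pool_cells == nearest]

    root = np.random.SeedSequence(spec.seed)
    sets: list[np.ndarray] = []
    for child in root.spawn(spec.n_sets):
        rng = np.random.default_rng(child)
        picks = [
            rng.choice(pool_by_cell[c], size=int(k), replace=spec.allow_reuse)
            for c, k in zip(cell_ids, src_counts)
        ]
        sets.append(np.sort(np.concatenate(picks)) if picks else np.empty(0, np.int64))
    return sets


@dataclass
class MatchedEnvelope:
    """Pointwise summary of fold curves across matched sets."""

    thresholds: np.ndarray
    median: np.ndarray
    lo: np.ndarray   # 2.5th percentile
    hi: np.ndarray   # 97.5th percentile
    curves: list[EnrichmentCurve] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "fold_median": self.median,
                "fold_lo": self.lo,
                "fold_hi": self.hi,
            }
        )

    def covers_one_at(self, x: float) -> bool:
        i = int(np.argmin(np.abs(self.thresholds - x)))
        return bool(self.lo[i] <= 1.0 <= self.hi[i])


def matched_enrichment(
    matched_sets: list[np.ndarray],
    p: np.ndarray,
    grid: np.ndarray | None = None,
    pmax_log: float = GENOME_WIDE_LOG10,
) -> MatchedEnvelope:
    """Fold curve per matched set plus the 2.5/50/97.5 percentile envelope."""
    if not matched_sets:
        raise ValueError("no matched sets supplied")
    if grid is None:
        grid = default_grid(pmax_log)
    n = len(p)
    curves = []
    for idx in matched_sets:
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        curves.append(fold_curve(p, mask, grid, pmax_log, ("matched", len(idx))))
    folds = np.vstack([c.fold for c in curves])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN grid tails
        return MatchedEnvelope(
            thresholds=np.asarray(grid, dtype=float),
            median=np.nanmedian(folds, axis=0),
            lo=np.nanpercentile(folds, 2.5, axis=0),
            hi=np.nanpercentile(folds, 97.5, axis=0),
            curves=curves,
        )
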