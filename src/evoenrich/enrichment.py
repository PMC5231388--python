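"""Conditional fold-enrichment curves (stratified QQ logic).

SNPs are split into two strata by an LD-weighted affiliation score
threshold (default 1, the score of an isolated SNP physically inside a
region).  At each -log10(p) threshold x on a grid below genome-wide
significance (7.3, i.e. p = 5e-8), the fold enrichment of a stratum is
the ratio of its -log10(p) exceedance fraction to that of all SNPs:

    fold(x) = S_stratum(x) / S_all(x),   S(x) = frac{-log10 p >= x}.

The cumulative distribution is implemented as the upper-tail exceedance
(survival) fraction: enrichment of small p-values then appears as a
positive deflection above the horizontal line through 1, and the curve
is identically 1 at x = 0.  SNPs at or beyond genome-wide significance
are removed before the curves are formed, focusing the comparison on the
polygenic tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GENOME_WIDE_LOG10 = 7.3  # -log10(5e-8), the standard GWAS threshold


def default_grid(pmax_log: float = GENOME_WIDE_LOG10, n: int = 200) -> np.ndarray:
    """Equally spaced -log10(p) thresholds on [0, pmax_log)."""
    return np.linspace(0.0, pmax_log, n, endpoint=False)


@dataclass
class EnrichmentCurve:
    """Fold enrichment of one stratum over a -log10(p) threshold grid.

    ``fold`` is NaN where no SNP at all exceeds the threshold.
    """

    thresholds: np.ndarray
    fold: np.ndarray
    n_stratum: np.ndarray   # stratum SNPs exceeding each threshold
    n_all: np.ndarray       # all SNPs exceeding each threshold
    stratum_size: int
    total_size: int
    stratum_def: tuple = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "fold": self.fold,
                "n_stratum": self.n_stratum,
                "n_all": self.n_all,
            }
        )

    def fold_at(self, x: float) -> float:
        """Fold at the grid point nearest to x."""
        return float(self.fold[np.argmin(np.abs(self.thresholds - x))])


def stratify(
    table: pd.DataFrame, category: str, score_threshold: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Partition SNPs into (score >= threshold, complement) boolean masks."""
    col = f"ld_{category}" if f"ld_{category}" in table.columns else category
    if col not in table.columns:
        raise KeyError(f"unknown category {category!r}")
    mask_in = table[col].to_numpy(dtype=float) >= score_threshold
    return mask_in, ~mask_in


def fold_curve(
    p: np.ndarray,
    stratum: np.ndarray,
    grid: np.ndarray | None = None,
    pmax_log: float = GENOME_WIDE_LOG10,
    stratum_def: tuple = (),
) -> EnrichmentCurve:
    """Fold-enrichment curve of one SNP stratum against all SNPs.

    ``p`` are per-SNP p-values, ``stratum`` a boolean mask over them.
    SNPs with -log10(p) >= ``pmax_log`` are removed from both sets
    first.  Ties at a grid point count as exceeding (>=).
    """
    p = np.asarray(p, dtype=float)
    stratum = np.asarray(stratum, dtype=bool)
    if stratum.shape != p.shape:
        raise ValueError("stratum mask and p must have the same length")
    if grid is None:
        grid = default_grid(pmax_log)
    grid = np.asarray(grid, dtype=float)
    if grid.size and (grid.min() < 0 or grid.max() >= pmax_log):
        raise ValueError(f"grid must lie within [0, {pmax_log})")

    nlp = -np.log10(p)
    keep = nlp < pmax_log
    nlp, stratum = nlp[keep], stratum[keep]
    n_total = nlp.size
    n_in_total = int(stratum.sum())
    if n_in_total == 0:
        raise ValueError("stratum is empty after the genome-wide-significance filter")

    all_sorted = np.sort(nlp)
    in_sorted = np.sort(nlp[stratum])
    n_all = n_total - np.searchsorted(all_sorted, grid, side="left")
    n_in = n_in_total - np.searchsorted(in_sorted, grid, side="left")
    s_all = n_all / n_total
    s_in = n_in / n_in_total
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(n_all > 0, s_in / s_all, np.nan)
    return EnrichmentCurve(
        thresholds=grid,
        fold=fold,
        n_stratum=n_in,
        n_all=n_all,
        stratum_size=n_in_total,
        total_size=n_total,
        stratum_def=stratum_def,
    )


def stratified_curves(
    table: pd.DataFrame,
    p: np.ndarray,
    category: str,
    score_threshold: float = 1.0,
    grid: np.ndarray | None = None,
    pmax_log: float = GENOME_WIDE_LOG10,
) -> tuple[EnrichmentCurve, EnrichmentCurve]:
    """(in-stratum, out-stratum) curves for one category threshold."""
    mask_in, mask_out = stratify(table, category, score_threshold)
    cin = fold_curve(p, mask_in, grid, pmax_log, (category, score_threshold))
    cout = fold_curve(p, mask_out, grid, pmax_log, (f"non-{category}", score_threshold))
    return cin, cout


def curves_to_frame(cin: EnrichmentCurve, cout: EnrichmentCurve) -> pd.DataFrame:
    """Combined TSV-ready table for the two strata of one category."""
    return pd.DataFrame(
        {
            "threshold": cin.thresholds,
            "fold_in": cin.fold,
            "fold_out": cout.fold,
            "n_in": cin.n_stratum,
            "n_out": cout.n_stratum,
            "n_all": cin.n_all,
        }
    )


def plot_curves(frames: dict[str, pd.DataFrame], path) -> None:
    """Optional thin plotting layer (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(frames), figsize=(4 * len(frames), 3.2),
                             squeeze=False)
    for ax, (name, frame) in zip(axes.ravel(), frames.items()):
        ax.plot(frame["threshold"], frame["fold_in"], label=name)
        ax.plot(frame["threshold"], frame["fold_out"], label=f"non-{name}")
        ax.axhline(1.0, color="grey", lw=0.8)
        ax.set_xlabel(r"nominal $-\log_{10}(p)$")
        ax.set_ylabel("fold enrichment")
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
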