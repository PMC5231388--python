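"""LD-weighted annotation scoring.

A SNP physically outside a region of interest can still tag association
signal inside it through linkage disequilibrium.  The per-SNP affiliation
score for a region category is therefore the sum of squared dosage
correlations to every reference-panel SNP inside the region,

    score_i = sum_j delta_j * r2_ij,

where r2 values below a floor (default 0.2) are zeroed, each SNP carries
r2 = 1.0 with itself, and only panel SNPs within a bp window (default
+-1 Mb) contribute.  The total-LD burden TotLD is the same sum with
delta = 1 everywhere, so TotLD >= 1 and TotLD >= score for every
category.  An isolated SNP inside a region scores exactly 1.

The intergenic flag marks SNPs whose four genic scores are exactly zero
and whose LD neighborhood (self included) contains no panel SNP within
100 kb of a protein-coding gene, nor inside non-coding RNA / TFBS /
miRNA-binding-site tracks; such SNPs serve as an empirical null set for
genomic-control estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import AnnotationTrack, ReferencePanel, AlignedIndex

#: distance (bp) to a protein-coding gene that disqualifies an LD partner
#: from the intergenic definition
GENE_PROXIMITY_BP = 100_000

#: default categories scored when their track is supplied, in output order
DEFAULT_CATEGORIES = ("HAR", "SD", "Ohno", "exon", "intron", "utr5", "utr3", "brain")

#: tracks that define the intergenic context (not scored themselves)
CONTEXT_TRACKS = ("protein_coding_gene", "ncRNA", "TFBS", "miRNA_bs")


class LDError(RuntimeError):
    pass


@dataclass
class LDNeighborhood:
    """Sparse floored-r2 neighborhoods of a set of tag SNPs.

    ``matrix`` is n_tags x n_panel CSR holding r2 >= floor entries for
    same-chromosome panel SNPs within ``window_bp``; the self entry of
    every tag row is exactly 1.0.  ``tag_idx[r]`` gives the panel column
    of tag row r.
    """

    matrix: sp.csr_matrix
    tag_idx: np.ndarray
    window_bp: int
    r2_floor: float

    @property
    def n_tags(self) -> int:
        return self.matrix.shape[0]

    def tag_submatrix(self) -> sp.csr_matrix:
        """Square tag x tag r2 matrix (columns restricted to tag SNPs)."""
        return self.matrix[:, self.tag_idx].tocsr()


def compute_ld(
    panel: ReferencePanel,
    tag_idx: np.ndarray | None = None,
    window_bp: int = 1_000_000,
    r2_floor: float = 0.2,
    chunk: int = 512,
) -> LDNeighborhood:
    """Pairwise floored r2 neighborhoods of tag SNPs against the panel.

    r2 is the squared Pearson correlation of genotype dosage vectors.
    Pairs on different chromosomes or further apart than ``window_bp``
    are excluded; r2 < ``r2_floor`` is treated as 0 and dropped from the
    sparse structure; the self pair is always present with value 1.0.
    """
    if panel.n_variants == 0:
        raise LDError("empty panel")
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    D = panel.dosages.astype(np.float64)
    sd = D.std(axis=0)
    if np.any(sd == 0):
        raise LDError("zero-variance dosage column (monomorphic variant not filtered)")
    Z = (D - D.mean(axis=0)) / sd
    n_samp = Z.shape[0]

    m = panel.n_variants
    if tag_idx is None:
        tag_idx = np.arange(m)
    tag_idx = np.asarray(tag_idx, dtype=np.int64)

    pos = panel.variants["pos"].to_numpy()
    chrom = panel.variants["chrom"].to_numpy()

    rows_acc, cols_acc, vals_acc = [], [], []
    # panel variants are sorted by (chrom, pos): walk contiguous chromosome runs
    change = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1
    bounds = np.concatenate(([0], change, [m]))
    tag_order = np.argsort(tag_idx, kind="stable")
    tag_sorted = tag_idx[tag_order]

    for b in range(len(bounds) - 1):
        c0, c1 = bounds[b], bounds[b + 1]
        t_lo = np.searchsorted(tag_sorted, c0)
        t_hi = np.searchsorted(tag_sorted, c1)
        cpos = pos[c0:c1]
        for s in range(t_lo, t_hi, chunk):
            e = min(s + chunk, t_hi)
            tcols = tag_sorted[s:e]          # panel columns of these tags
            trows = tag_order[s:e]           # their rows in the output
            tpos = pos[tcols]
            lo = int(np.searchsorted(cpos, tpos.min() - window_bp, side="left"))
            hi = int(np.searchsorted(cpos, tpos.max() + window_bp, side="right"))
            span = slice(c0 + lo, c0 + hi)
            corr = Z[:, tcols].T @ Z[:, span] / n_samp
            r2 = corr * corr
            in_window = np.abs(tpos[:, None] - cpos[lo:hi][None, :]) <= window_bp
            keep = in_window & (r2 >= r2_floor)
            # the self pair survives regardless of the floor, with exact 1.0
            self_local = tcols - (c0 + lo)
            keep[np.arange(len(tcols)), self_local] = True
            r2[np.arange(len(tcols)), self_local] = 1.0
            ii, jj = np.nonzero(keep)
            rows_acc.append(trows[ii])
            cols_acc.append(jj + c0 + lo)
            vals_acc.append(r2[ii, jj])

    rows = np.concatenate(rows_acc) if rows_acc else np.empty(0, dtype=np.int64)
    cols = np.concatenate(cols_acc) if cols_acc else np.empty(0, dtype=np.int64)
    vals = np.concatenate(vals_acc) if vals_acc else np.empty(0)
    matrix = sp.coo_matrix((vals, (rows, cols)), shape=(len(tag_idx), m)).tocsr()
    return LDNeighborhood(matrix=matrix, tag_idx=tag_idx,
                          window_bp=window_bp, r2_floor=r2_floor)


def raw_indicator(panel: ReferencePanel, track: AnnotationTrack) -> np.ndarray:
    """0/1 per panel SNP: does its 1-based position fall inside the track union."""
    if track.is_empty:
        return np.zeros(panel.n_variants, dtype=np.uint8)
    return track.contains(
        panel.variants["chrom"].to_numpy(), panel.variants["pos"].to_numpy()
    ).astype(np.uint8)


def ld_weighted_score(nbhd: LDNeighborhood, delta: np.ndarray) -> np.ndarray:
    """score_i = sum over i's neighborhood of delta_j * r2_ij (self included)."""
    delta = np.asarray(delta, dtype=np.float64)
    if delta.shape[0] != nbhd.matrix.shape[1]:
        raise ValueError("delta must be defined for every panel SNP")
    return np.asarray(nbhd.matrix @ delta).ravel()


def total_ld(nbhd: LDNeighborhood) -> np.ndarray:
    """TotLD_i = sum of all floored r2 in i's window (delta = 1 everywhere)."""
    return np.asarray(nbhd.matrix.sum(axis=1)).ravel()


def intergenic_flag(
    nbhd: LDNeighborhood,
    panel: ReferencePanel,
    genic_scores: pd.DataFrame | dict,
    tracks: dict[str, AnnotationTrack],
) -> np.ndarray:
    """Empirical-null flag per tag SNP.

    True iff the exon/intron/utr5/utr3 LD scores are all exactly zero and
    no neighborhood partner (self included) lies within 100 kb of a
    protein-coding gene or inside the ncRNA / TFBS / miRNA-binding-site
    tracks.  ``tracks`` must supply ``protein_coding_gene``; the other
    context tracks default to empty when absent.
    """
    if "protein_coding_gene" not in tracks:
        raise KeyError("intergenic definition requires a protein_coding_gene track")
    chrom = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy()
    near = tracks["protein_coding_gene"].expanded(GENE_PROXIMITY_BP).contains(chrom, pos)
    for name in ("ncRNA", "TFBS", "miRNA_bs"):
        trk = tracks.get(name)
        if trk is not None and not trk.is_empty:
            near |= trk.contains(chrom, pos)
    ld_to_functional = np.asarray(nbhd.matrix @ near.astype(np.float64)).ravel()
    genic_zero = np.ones(nbhd.n_tags, dtype=bool)
    for cat in ("exon", "intron", "utr5", "utr3"):
        genic_zero &= np.asarray(genic_scores[f"ld_{cat}"]) == 0
    return genic_zero & (ld_to_functional == 0)


def build_score_table(
    panel: ReferencePanel,
    index: AlignedIndex,
    tracks: dict[str, AnnotationTrack],
    categories: tuple[str, ...] | None = None,
    window_bp: int = 1_000_000,
    r2_floor: float = 0.2,
    nbhd: LDNeighborhood | None = None,
) -> tuple[pd.DataFrame, LDNeighborhood]:
    """Assemble the per-SNP score table for all aligned SNPs.

    Returns a DataFrame with columns ``snp_id chrom pos maf`` then
    ``raw_<cat>`` and ``ld_<cat>`` per scored category, ``tot_ld`` and
    ``intergenic``, plus the neighborhood used (reusable downstream).
    The intergenic column requires the four genic tracks and a
    ``protein_coding_gene`` context track; if the latter is missing, the
    column is filled with False.
    """
    if categories is None:
        categories = tuple(c for c in DEFAULT_CATEGORIES if c in tracks)
    missing = [c for c in categories if c not in tracks]
    if missing:
        raise KeyError(f"no track supplied for categories {missing}")
    if nbhd is None:
        nbhd = compute_ld(panel, index.panel_idx, window_bp=window_bp, r2_floor=r2_floor)

    table = index.df[["snp_id", "chrom", "pos", "maf"]].copy()
    deltas = {c: raw_indicator(panel, tracks[c]) for c in categories}
    tag_cols = nbhd.tag_idx
    for c in categories:
        table[f"raw_{c}"] = deltas[c][tag_cols]
        table[f"ld_{c}"] = ld_weighted_score(nbhd, deltas[c])
    table["tot_ld"] = total_ld(nbhd)

    genic = {"exon", "intron", "utr5", "utr3"}
    if genic.issubset(set(categories)) and "protein_coding_gene" in tracks:
        table["intergenic"] = intergenic_flag(nbhd, panel, table, tracks)
    else:
        table["intergenic"] = False
    return table, nbhd


def write_score_table(table: pd.DataFrame, path) -> None:
    """Write the score table as TSV with 6 significant digits for reals."""
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
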