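"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's sparse/chunked code paths: LD
scores come from an explicit all-pairs double loop over standardized
dosage columns, and the intergenic rule is applied SNP by SNP.
"""

from __future__ import annotations

import numpy as np


def brute_force_ld_table(panel, deltas, window_bp=1_000_000, r2_floor=0.2):
    """All-pairs LD-weighted scores, TotLD and neighbor lists.

    ``deltas``: dict category -> 0/1 per panel SNP.  Returns
    (scores dict, tot_ld, neighbors list-of-dicts {j: r2}).
    """
    D = panel.dosages.astype(np.float64)
    n = D.shape[0]
    m = panel.n_variants
    Z = (D - D.mean(axis=0)) / D.std(axis=0)
    pos = panel.variants["pos"].to_numpy()
    chrom = panel.variants["chrom"].to_numpy()

    scores = {c: np.zeros(m) for c in deltas}
    tot = np.zeros(m)
    neighbors = [dict() for _ in range(m)]
    for i in range(m):
        for j in range(m):
            if chrom[i] != chrom[j] or abs(int(pos[i]) - int(pos[j])) > window_bp:
                continue
            if i == j:
                r2 = 1.0
            else:
                r = float(Z[:, i] @ Z[:, j]) / n
                r2 = r * r
                if r2 < r2_floor:
                    continue
            neighbors[i][j] = r2
            tot[i] += r2
            for c, d in deltas.items():
                scores[c][i] += d[j] * r2
    return scores, tot, neighbors


def brute_force_intergenic(panel, neighbors, genic_scores, tracks,
                           proximity_bp=100_000):
    """SNP-by-SNP application of the intergenic rule."""
    chrom = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy()
    m = panel.n_variants

    def near_functional(j):
        c, q = chrom[j], int(pos[j])
        for (tc, s, e) in tracks["protein_coding_gene"].intervals:
            if tc == c and (s - proximity_bp) < q <= (e + proximity_bp):
                return True
        for name in ("ncRNA", "TFBS", "miRNA_bs"):
            trk = tracks.get(name)
            if trk is None:
                continue
            for (tc, s, e) in trk.intervals:
                if tc == c and s < q <= e:
                    return True
        return False

    out = np.zeros(m, dtype=bool)
    for i in range(m):
        if any(genic_scores[f"ld_{g}"][i] != 0
               for g in ("exon", "intron", "utr5", "utr3")):
            continue
        out[i] = not any(near_functional(j) for j in neighbors[i])
    return out


def ols_coefficients(X, y):
    """Normal-equations least squares on a standardized design."""
    return np.linalg.solve(X.T @ X, X.T @ y)
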