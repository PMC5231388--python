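"""Partial least squares regression of squared z-scores on LD-weighted
covariates, with LD-aware jackknife inference.

LD-weighted affiliation scores are strongly inter-correlated (a SNP in
an exon of a brain gene scores on exon, brain and TotLD at once), which
destabilizes ordinary least squares.  PLSR regresses through latent
variables that maximize descriptor-response covariance and is stable
under collinearity.  The model is

    y = X b_A + f_A,

with X (SNPs x covariates) and y (squared z-scores) mean-centered and
scaled to unit standard deviation before fitting, and the model order A
chosen as the smallest number of latent variables whose cumulative
descriptor-block variance explained exceeds 99%.

Significance is assessed by approximate t-tests from a cross-model-
validation jackknife: SNPs are partitioned into 50 folds along LD-block
boundaries (connected components of the floored r2 graph, so no fold
boundary splits an LD block), the model is refit with each fold held
out, and the jackknife variance of the coefficients across refits gives
standard deviations, t-statistics (t = b/sd) and two-sided p-values on
k-1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as _sps
from scipy.sparse.csgraph import connected_components

#: default covariate order for the enrichment designs
DEFAULT_COVARIATES = ("intron", "exon", "utr3", "utr5", "brain", "tot_ld")

#: MHC region (chrom, 1-based inclusive start/end), hg19
MHC_REGION = ("6", 25_652_429, 33_421_466)

_EPS = 1e-12


class PLSRError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Standardized descriptor block X and response y.

    X columns and y are centered and scaled to unit (population) standard
    deviation; the means/scales are kept so raw-scale quantities can be
    recovered.
    """

    X: np.ndarray
    y: np.ndarray
    names: tuple[str, ...]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def build_design(
    table: pd.DataFrame,
    z: np.ndarray,
    evo_category: str | None = None,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> DesignMatrix:
    """Assemble the standardized design for one phenotype x category run.

    The response is the squared z-score.  Covariate names refer to
    ``ld_<name>`` columns of the score table where present, else to the
    column itself (``tot_ld``).  ``evo_category`` (e.g. "HAR") is
    inserted before "brain" in the declared order, matching the
    published table layout intron, exon, 3'UTR, 5'UTR, evo, brain,
    TotLD.
    """
    names = list(covariates)
    if evo_category is not None and evo_category not in names:
        if "brain" in names:
            pos = names.index("brain")
        elif "tot_ld" in names:
            pos = names.index("tot_ld")
        else:
            pos = len(names)
        names.insert(pos, evo_category)

    cols = []
    for name in names:
        col = f"ld_{name}" if f"ld_{name}" in table.columns else name
        if col not in table.columns:
            raise KeyError(f"covariate {name!r} not found in score table")
        cols.append(table[col].to_numpy(dtype=float))
    X = np.column_stack(cols)
    y = np.asarray(z, dtype=float) ** 2
    if y.shape[0] != X.shape[0]:
        raise ValueError("z and score table length mismatch")

    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    flat = x_scale <= _EPS
    if flat.any():
        bad = [names[i] for i in np.flatnonzero(flat)]
        raise PLSRError(f"constant covariate column(s): {bad}")
    y_mean = float(y.mean())
    y_scale = float(y.std())
    if y_scale <= _EPS:
        raise PLSRError("response (squared z-scores) is constant")
    return DesignMatrix(
        X=(X - x_mean) / x_scale,
        y=(y - y_mean) / y_scale,
        names=tuple(names),
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
    )


# ---------------------------------------------------------------------------
# PLS1 (NIPALS) core
# ---------------------------------------------------------------------------

def _pls1_path(X: np.ndarray, y: np.ndarray, max_lv: int):
    """Sequential single-response PLS extraction with X deflation.

    Returns (W, P, q, xvar): weight/loading matrices with one column per
    extracted component, the per-component response loadings, and the
    fraction of descriptor-block variance captured by each component.
    Extraction stops early when the residual covariance vanishes.
    """
    Xk = X.copy()
    n, p = X.shape
    tss = float((X * X).sum())
    W, P, q, xvar = [], [], [], []
    for _ in range(max_lv):
        w = Xk.T @ y
        nw = float(np.linalg.norm(w))
        if nw < _EPS * max(1.0, np.abs(y).max()) or nw == 0.0:
            break
        w /= nw
        t = Xk @ w
        tt = float(t @ t)
        if tt < _EPS:
            break
        pload = Xk.T @ t / tt
        q.append(float(y @ t / tt))
        Xk -= np.outer(t, pload)
        W.append(w)
        P.append(pload)
        xvar.append(tt * float(pload @ pload) / tss if tss > 0 else 0.0)
    if not W:
        return (np.zeros((p, 0)), np.zeros((p, 0)), np.zeros(0), np.zeros(0))
    return (np.column_stack(W), np.column_stack(P), np.asarray(q), np.asarray(xvar))


def _coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray, a: int) -> np.ndarray:
    """Regression coefficients of the A-component model, b = W (P'W)^-1 q."""
    if a == 0:
        return np.zeros(W.shape[0])
    Wa, Pa, qa = W[:, :a], P[:, :a], q[:a]
    try:
        return Wa @ np.linalg.solve(Pa.T @ Wa, qa)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate designs
        raise PLSRError("numerical breakdown in coefficient back-mapping") from exc


def _select_order(xvar: np.ndarray, var_threshold: float, max_lv: int) -> int:
    """Smallest component count whose cumulative X-variance exceeds the
    threshold, capped at max_lv (all extracted components if never reached)."""
    if xvar.size == 0:
        return 0
    cum = np.cumsum(xvar)
    above = np.flatnonzero(cum > var_threshold)
    a = int(above[0]) + 1 if above.size else int(xvar.size)
    return min(a, max_lv)


@dataclass
class PLSRFit:
    """Fitted PLSR model with (optionally) jackknife inference attached.

    ``coefficients`` are on the standardized scale (the "non-centered
    standardized" reporting convention of the enrichment tables);
    ``coefficients_raw`` back-transforms to the raw z**2-per-raw-score
    scale for transparency.  After ``jackknife_ttest``, ``jackknife_sd``,
    ``t_stat`` and ``p_value`` are populated; a refit spread of exactly
    zero yields the documented sentinel t = +-inf with p = 0.0.
    """

    names: tuple[str, ...]
    coefficients: np.ndarray
    n_lv: int
    x_variance_explained: np.ndarray
    var_threshold: float
    jackknife_sd: np.ndarray | None = None
    t_stat: np.ndarray | None = None
    p_value: np.ndarray | None = None
    folds: np.ndarray | None = None
    fold_coefficients: np.ndarray | None = None
    seed: int | None = None
    y_scale: float = 1.0
    x_scale: np.ndarray | None = None

    @property
    def coefficients_raw(self) -> np.ndarray:
        if self.x_scale is None:
            return self.coefficients
        return self.coefficients * self.y_scale / self.x_scale

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"covariate": self.names, "coef": self.coefficients})
        if self.jackknife_sd is not None:
            out["sd"] = self.jackknife_sd
            out["t"] = self.t_stat
            out["p"] = self.p_value
        return out


def fit_plsr(
    design: DesignMatrix,
    var_threshold: float = 0.99,
    max_lv: int | None = None,
) -> PLSRFit:
    """Fit the PLS1 model and select the model order.

    A is the smallest number of latent variables explaining more than
    ``var_threshold`` of the descriptor-block variance (capped at
    ``max_lv``, default the number of covariates).
    """
    if not 0 < var_threshold < 1:
        raise ValueError("var_threshold must be in (0, 1)")
    if design.n <= design.p:
        raise PLSRError("need more SNPs than covariates")
    max_lv = design.p if max_lv is None else min(max_lv, design.p)
    W, P, q, xvar = _pls1_path(design.X, design.y, max_lv)
    a = _select_order(xvar, var_threshold, max_lv)
    b = _coefficients(W, P, q, a)
    return PLSRFit(
        names=design.names,
        coefficients=b,
        n_lv=max(a, 1) if xvar.size else 1,
        x_variance_explained=xvar[:a],
        var_threshold=var_threshold,
        y_scale=design.y_scale,
        x_scale=design.x_scale,
    )


def _refit_coefficients(X: np.ndarray, y: np.ndarray, a: int) -> np.ndarray:
    """Coefficients of an A-component PLS1 refit on a (re-centered) subset."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    W, P, q, _ = _pls1_path(Xc, yc, a)
    return _coefficients(W, P, q, min(a, W.shape[1]))


# ---------------------------------------------------------------------------
# LD-aware folds and jackknife
# ---------------------------------------------------------------------------

def ld_folds(
    S: sp.csr_matrix,
    k: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Partition index SNPs into k folds along LD-block boundaries.

    LD blocks are the connected components of the floored r2 graph among
    index SNPs (``S`` square, from ``LDNeighborhood.tag_submatrix``).
    Whole blocks are dealt to folds round-robin in seeded shuffled
    order, so no block is split across folds and fold sizes differ by at
    most one block.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    n_blocks, labels = connected_components(S, directed=False)
    if n_blocks < k:
        raise ValueError(
            f"only {n_blocks} LD blocks for {k} folds; use a smaller k"
        )
    rng = np.random.default_rng(seed)
    block_order = rng.permutation(n_blocks)
    block_fold = np.empty(n_blocks, dtype=np.int64)
    block_fold[block_order] = np.arange(n_blocks) % k
    return block_fold[labels]


def jackknife_ttest(
    design: DesignMatrix,
    fit: PLSRFit,
    folds: np.ndarray,
    k: int | None = None,
) -> PLSRFit:
    """Approximate t-tests of PLSR coefficients via a delete-fold jackknife.

    For every fold f the model is refit (same A) on the remaining SNPs;
    the jackknife variance per covariate is ((k-1)/k) * sum_f
    (b_(-f) - mean b)^2, t = b_full / sd, and two-sided p-values come
    from the t distribution with k-1 degrees of freedom.
    """
    folds = np.asarray(folds)
    if folds.shape[0] != design.n:
        raise ValueError("fold assignment must cover every SNP exactly once")
    fold_ids = np.unique(folds)
    k = len(fold_ids) if k is None else k
    if len(fold_ids) != k:
        raise ValueError(f"expected {k} folds, found {len(fold_ids)}")

    a = fit.n_lv
    B = np.empty((k, design.p))
    for row, f in enumerate(fold_ids):
        mask = folds != f
        try:
            B[row] = _refit_coefficients(design.X[mask], design.y[mask], a)
        except PLSRError as exc:
            raise PLSRError(f"refit failed for held-out fold {f}") from exc

    bbar = B.mean(axis=0)
    var = (k - 1) / k * ((B - bbar) ** 2).sum(axis=0)
    sd = np.sqrt(var)
    b = fit.coefficients
    t = np.empty(design.p)
    p = np.empty(design.p)
    for j in range(design.p):
        if sd[j] > 0:
            t[j] = b[j] / sd[j]
            p[j] = 2.0 * _sps.t.sf(abs(t[j]), df=k - 1)
        elif b[j] == 0:
            t[j], p[j] = 0.0, 1.0
        else:  # documented sentinel: all refits identical
            t[j] = np.inf if b[j] > 0 else -np.inf
            p[j] = 0.0
    fit.jackknife_sd = sd
    fit.t_stat = t
    fit.p_value = p
    fit.folds = folds
    fit.fold_coefficients = B
    return fit


# ---------------------------------------------------------------------------
# residual-vs-TotLD summaries and MHC subsetting
# ---------------------------------------------------------------------------

def residual_vs_totld(
    table: pd.DataFrame,
    z: np.ndarray,
    category: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    drop_category: bool = False,
    n_bins: int = 20,
    var_threshold: float = 0.99,
) -> pd.DataFrame:
    """Binned mean residual squared z-scores against TotLD.

    The squared z-scores are residualized on a PLSR model deprived of
    TotLD (and, with ``drop_category``, of the evolutionary score too);
    TotLD is then cut into ``n_bins`` equal-count bins and the mean
    residual reported per bin for three strata: category score >= 1,
    < 1, and all SNPs.  Residuals are on the raw z**2 scale.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    reduced = tuple(c for c in covariates if c != "tot_ld")
    evo = None if drop_category else category
    design = build_design(table, z, evo_category=evo, covariates=reduced)
    fit = fit_plsr(design, var_threshold=var_threshold)
    yhat_std = design.X @ fit.coefficients
    resid = (design.y - yhat_std) * design.y_scale  # raw z^2 scale, mean removed

    totld = table["tot_ld"].to_numpy(dtype=float)
    bins = pd.qcut(totld, q=n_bins, duplicates="drop")
    mask_in = stratify_scores(table, category)

    rows = []
    for stratum, smask in (
        (category, mask_in),
        (f"non-{category}", ~mask_in),
        ("all", np.ones(len(totld), dtype=bool)),
    ):
        grouped = pd.DataFrame(
            {"bin": bins[smask], "resid": resid[smask]}
        ).groupby("bin", observed=True)
        for interval, grp in grouped:
            rows.append(
                {
                    "stratum": stratum,
                    "bin_center": (interval.left + interval.right) / 2.0,
                    "mean_resid_z2": grp["resid"].mean(),
                    "count": len(grp),
                }
            )
    return pd.DataFrame(rows)


def stratify_scores(table: pd.DataFrame, category: str, threshold: float = 1.0):
    """Boolean mask of SNPs with ld_<category> >= threshold."""
    col = f"ld_{category}" if f"ld_{category}" in table.columns else category
    return table[col].to_numpy(dtype=float) >= threshold


def mhc_subset(
    df: pd.DataFrame,
    mode: str,
    region: tuple[str, int, int] = MHC_REGION,
) -> np.ndarray:
    """Boolean keep-mask for MHC exclude / MHC-only reruns.

    ``df`` needs ``chrom`` and ``pos`` columns; the region bounds are
    1-based inclusive on both ends.  ``mode`` is "exclude" (drop SNPs in
    the region) or "only" (keep exactly those).
    """
    chrom, start, end = region
    if start > end:
        raise ValueError("malformed region")
    in_region = (
        (df["chrom"].astype(str) == str(chrom))
        & (df["pos"] >= start)
        & (df["pos"] <= end)
    ).to_numpy()
    if mode == "exclude":
        keep = ~in_region
    elif mode == "only":
        keep = in_region
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not keep.any():
        raise ValueError(f"MHC {mode} subset is empty")
    return keep
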