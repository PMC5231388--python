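"""Readers, writers and harmonization for GWAS summary statistics,
reference genotype panels and genomic annotation tracks.

Everything downstream works on three containers defined here:

``SummaryStats``
    per-SNP association records (id, position, alleles, p, z, sample size);
``ReferencePanel``
    a samples x variants dosage matrix with a variant table, used to
    estimate pairwise LD;
``AnnotationTrack``
    a named set of genomic intervals in BED convention (0-based,
    half-open), with union semantics for membership.

Coordinate convention: SNP positions are 1-based; BED intervals are
0-based half-open, so a SNP at 1-based position ``q`` lies inside
``[start, end)`` iff ``start < q <= end``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps


class FormatError(ValueError):
    """Malformed input file (missing columns, bad intervals, bad VCF)."""


class EmptyInputError(ValueError):
    """An input was syntactically valid but contained no usable records."""


class AlignmentError(ValueError):
    """Summary statistics and reference panel share no usable variants."""


#: default header names for summary-statistic TSV files
DEFAULT_COLUMNS: dict[str, str] = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "a1": "A1",
    "a2": "A2",
    "p": "P",
    "z": "Z",
    "n": "N",
    "maf": "MAF",
}

_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def p_to_abs_z(p):
    """|z| such that a two-sided normal test of z gives p."""
    return _sps.norm.isf(np.asarray(p, dtype=float) / 2.0)


def z_to_p(z):
    """Two-sided normal p-value of a z-score."""
    return 2.0 * _sps.norm.sf(np.abs(np.asarray(z, dtype=float)))


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

@dataclass
class SummaryStats:
    """Validated per-SNP GWAS association records.

    ``df`` has columns ``snp_id, chrom, pos, a1, a2, p, z, n, maf``
    (``n`` and ``maf`` may be NaN).  ``p`` lies in (0, 1]; where a row
    arrived with only ``p``, ``|z|`` was derived from the two-sided
    normal inverse and the sign set to +1 (``z_sign_imputed``); only z**2
    and p feed downstream statistics, so the sign never matters.
    """

    df: pd.DataFrame
    n_dropped: int = 0
    z_sign_imputed: bool = False
    messages: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    z_precedence: str = "z",
    p_floor: float | None = None,
) -> SummaryStats:
    """Read a whitespace/tab-delimited summary-statistics file.

    Parameters
    ----------
    column_map
        maps internal names (``snp_id, chrom, pos, a1, a2, p, z, n, maf``)
        to header names in the file; defaults to ``DEFAULT_COLUMNS``.
    z_precedence
        which statistic wins when both p and z are present but mutually
        inconsistent under the two-sided normal relation ("z" or "p");
        the loser is recomputed from the winner for those rows.
    p_floor
        if given, p-values of 0 are floored here instead of dropped.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    raw = pd.read_csv(path, sep=r"\s+", dtype={cols["chrom"]: str})
    if raw.empty:
        raise EmptyInputError(f"{path}: no data rows")

    for key in ("snp_id", "chrom", "pos"):
        if cols[key] not in raw.columns:
            raise FormatError(f"{path}: missing mandatory column {cols[key]!r}")
    have_p = cols["p"] in raw.columns
    have_z = cols["z"] in raw.columns
    if not (have_p or have_z):
        raise FormatError(f"{path}: need a {cols['p']!r} or {cols['z']!r} column")

    df = pd.DataFrame(
        {
            "snp_id": raw[cols["snp_id"]].astype(str),
            "chrom": raw[cols["chrom"]].astype(str),
            "pos": pd.to_numeric(raw[cols["pos"]], errors="coerce"),
        }
    )
    for key in ("a1", "a2"):
        df[key] = raw[cols[key]].astype(str).str.upper() if cols[key] in raw.columns else "N"
    df["p"] = pd.to_numeric(raw[cols["p"]], errors="coerce") if have_p else np.nan
    df["z"] = pd.to_numeric(raw[cols["z"]], errors="coerce") if have_z else np.nan
    df["n"] = pd.to_numeric(raw[cols["n"]], errors="coerce") if cols["n"] in raw.columns else np.nan
    df["maf"] = pd.to_numeric(raw[cols["maf"]], errors="coerce") if cols["maf"] in raw.columns else np.nan

    messages: list[str] = []
    n0 = len(df)

    if p_floor is not None and have_p:
        floored = df["p"].notna() & (df["p"] <= 0)
        if floored.any():
            df.loc[floored, "p"] = p_floor
            messages.append(f"floored {int(floored.sum())} p-values at {p_floor}")

    ok = df["pos"].notna() & (df["pos"] > 0)
    if have_p and not have_z:
        ok &= df["p"].notna() & (df["p"] > 0) & (df["p"] <= 1)
    elif have_p:
        # p may be absent row-wise if z is present
        bad_p = df["p"].notna() & ((df["p"] <= 0) | (df["p"] > 1))
        ok &= ~(bad_p & df["z"].isna())
        df.loc[bad_p & df["z"].notna(), "p"] = np.nan
    if have_z and not have_p:
        ok &= df["z"].notna()
    ok &= ~df["snp_id"].duplicated(keep="first")
    df = df.loc[ok].reset_index(drop=True)
    n_dropped = n0 - len(df)
    if n_dropped:
        messages.append(f"dropped {n_dropped} invalid rows")
    if df.empty:
        raise EmptyInputError(f"{path}: all {n0} rows failed validation")

    z_sign_imputed = False
    missing_z = df["z"].isna()
    if missing_z.any():
        df.loc[missing_z, "z"] = p_to_abs_z(df.loc[missing_z, "p"])
        z_sign_imputed = True
        messages.append(
            f"derived |z| from p for {int(missing_z.sum())} rows; sign set to +1"
        )
    missing_p = df["p"].isna()
    if missing_p.any():
        df.loc[missing_p, "p"] = z_to_p(df.loc[missing_p, "z"])

    both = ~missing_z & ~missing_p
    if both.any():
        implied = z_to_p(df.loc[both, "z"])
        rel = np.abs(implied - df.loc[both, "p"]) / np.maximum(df.loc[both, "p"], 1e-300)
        inconsistent = rel > 1e-6
        if inconsistent.any():
            idx = df.index[both][inconsistent]
            messages.append(
                f"{len(idx)} rows have inconsistent p and z; keeping {z_precedence}"
            )
            if z_precedence == "z":
                df.loc[idx, "p"] = z_to_p(df.loc[idx, "z"])
            else:
                df.loc[idx, "z"] = np.sign(df.loc[idx, "z"]) * p_to_abs_z(df.loc[idx, "p"])

    df["pos"] = df["pos"].astype(np.int64)
    return SummaryStats(df=df, n_dropped=n_dropped, z_sign_imputed=z_sign_imputed,
                        messages=messages)


def write_summary_stats(stats: SummaryStats, path) -> None:
    """Write a ``SummaryStats`` back to TSV with the default header names."""
    out = stats.df.rename(columns={k: v for k, v in DEFAULT_COLUMNS.items()})
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------

@dataclass
class ReferencePanel:
    """Genotype dosages for LD estimation.

    ``variants`` columns: ``snp_id, chrom, pos, a1, a2`` (sorted by
    chrom, pos); ``dosages`` is samples x variants with entries in
    {0, 1, 2} counting the a1 allele.  Monomorphic variants are removed
    at read time so every dosage column has nonzero variance.
    """

    variants: pd.DataFrame
    dosages: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Frequency of the a1 allele per variant."""
        return self.dosages.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)


def _finalize_panel(variants: pd.DataFrame, dosages: np.ndarray) -> ReferencePanel:
    if dosages.shape[0] < 2:
        raise FormatError("reference panel needs at least 2 samples")
    # ordering / duplicate checks per chromosome
    for chrom, grp in variants.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise FormatError(f"chromosome {chrom}: variants not sorted by position")
        if np.any(np.diff(pos) == 0):
            raise FormatError(f"chromosome {chrom}: duplicate positions")
    poly = dosages.std(axis=0) > 0
    variants = variants.loc[poly].reset_index(drop=True)
    dosages = np.ascontiguousarray(dosages[:, poly])
    if variants.empty:
        raise EmptyInputError("reference panel has no polymorphic variants")
    return ReferencePanel(variants=variants, dosages=dosages)


def read_panel(path, fmt: str = "vcf", sidecar=None) -> ReferencePanel:
    """Read a reference panel.

    ``fmt="vcf"``: biallelic SNPs from a (possibly bgzipped) VCF with GT
    fields; dosage counts the ALT allele (a1=ALT, a2=REF); sites with
    missing genotypes are skipped.

    ``fmt="matrix"``: TSV dosage table, one row per sample, one column
    per variant (header = snp ids, values 0/1/2), plus a ``sidecar`` TSV
    with columns ``snp_id chrom pos a1 a2`` describing every column.
    """
    if fmt == "vcf":
        return _read_panel_vcf(path)
    if fmt == "matrix":
        if sidecar is None:
            raise FormatError("matrix format requires a variant sidecar file")
        return _read_panel_matrix(path, sidecar)
    raise ValueError(f"unknown panel format {fmt!r}")


def _read_panel_vcf(path) -> ReferencePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    ids, chroms, poss, a1s, a2s, cols = [], [], [], [], [], []
    for v in vcf:
        if len(v.REF) != 1 or len(v.ALT) != 1 or len(v.ALT[0]) != 1:
            continue  # SNPs only
        gt = v.gt_types  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        if np.any(gt == 3):
            continue
        ids.append(v.ID if v.ID else f"{v.CHROM}:{v.POS}")
        chroms.append(str(v.CHROM))
        poss.append(int(v.POS))
        a1s.append(v.ALT[0])
        a2s.append(v.REF)
        cols.append(gt.astype(np.int16))
    if not cols:
        raise EmptyInputError(f"{path}: no usable biallelic SNPs")
    variants = pd.DataFrame(
        {"snp_id": ids, "chrom": chroms, "pos": poss, "a1": a1s, "a2": a2s}
    )
    return _finalize_panel(variants, np.column_stack(cols))


def _read_panel_matrix(path, sidecar) -> ReferencePanel:
    dose = pd.read_csv(path, sep="\t")
    meta = pd.read_csv(sidecar, sep="\t", dtype={"chrom": str})
    need = {"snp_id", "chrom", "pos", "a1", "a2"}
    if not need.issubset(meta.columns):
        raise FormatError(f"{sidecar}: sidecar needs columns {sorted(need)}")
    meta = meta.set_index("snp_id")
    missing = [c for c in dose.columns if c not in meta.index]
    if missing:
        raise FormatError(
            f"{sidecar}: no sidecar row for dosage column(s) {missing[:5]}"
        )
    meta = meta.loc[list(dose.columns)].reset_index()
    variants = meta[["snp_id", "chrom", "pos", "a1", "a2"]].copy()
    variants["pos"] = variants["pos"].astype(np.int64)
    return _finalize_panel(variants, dose.to_numpy(dtype=np.int16))


def write_panel_matrix(panel: ReferencePanel, dosage_path, sidecar_path) -> None:
    pd.DataFrame(panel.dosages, columns=panel.variants["snp_id"]).to_csv(
        dosage_path, sep="\t", index=False
    )
    panel.variants.to_csv(sidecar_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotation tracks
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTrack:
    """A named union of genomic intervals (BED convention).

    Intervals may overlap; membership uses the union.  The merged
    per-chromosome representation is built lazily and cached.
    """

    name: str
    intervals: list[tuple[str, int, int]]
    _merged: dict[str, tuple[np.ndarray, np.ndarray]] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self):
        for chrom, start, end in self.intervals:
            if start >= end:
                raise FormatError(
                    f"track {self.name}: invalid interval {chrom}:{start}-{end}"
                )

    @property
    def is_empty(self) -> bool:
        return not self.intervals

    def merged(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome merged (starts, ends) arrays, non-overlapping, sorted."""
        if self._merged is None:
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            for chrom, s, e in self.intervals:
                by_chrom.setdefault(str(chrom), []).append((s, e))
            merged = {}
            for chrom, ivs in by_chrom.items():
                ivs.sort()
                starts, ends = [], []
                for s, e in ivs:
                    if ends and s <= ends[-1]:
                        ends[-1] = max(ends[-1], e)
                    else:
                        starts.append(s)
                        ends.append(e)
                merged[chrom] = (np.asarray(starts), np.asarray(ends))
            self._merged = merged
        return self._merged

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Membership of 1-based SNP positions in the interval union.

        A SNP at 1-based ``q`` is inside ``[s, e)`` iff ``s < q <= e``.
        """
        chrom = np.asarray(chrom, dtype=object)
        pos0 = np.asarray(pos, dtype=np.int64) - 1  # 0-based
        out = np.zeros(len(pos0), dtype=bool)
        merged = self.merged()
        for c in np.unique(chrom):
            if str(c) not in merged:
                continue
            starts, ends = merged[str(c)]
            sel = chrom == c
            q = pos0[sel]
            i = np.searchsorted(starts, q, side="right") - 1
            hit = (i >= 0) & (q < ends[np.clip(i, 0, None)])
            out[sel] = hit
        return out

    def expanded(self, flank: int) -> "AnnotationTrack":
        """A copy with every interval widened by ``flank`` bp on both sides."""
        ivs = [(c, max(0, s - flank), e + flank) for c, s, e in self.intervals]
        return AnnotationTrack(name=f"{self.name}+-{flank}", intervals=ivs)

    def total_bp(self) -> int:
        return int(
            sum((ends - starts).sum() for starts, ends in self.merged().values())
        )


def read_track(path, name: str) -> AnnotationTrack:
    """Read a BED3+ file into an AnnotationTrack (0-based half-open kept as-is)."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            intervals.append((chrom, start, end))
    return AnnotationTrack(name=name, intervals=intervals)


def write_track(track: AnnotationTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in track.intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignedIndex:
    """Inner join of summary statistics onto the panel variant grid.

    ``df`` columns: ``snp_id, chrom, pos, panel_idx, z, p, n, maf``;
    ``panel_idx`` indexes columns of the panel dosage matrix.  z is
    sign-flipped where the stats allele pair was the swap of the panel's.
    """

    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)

    @property
    def panel_idx(self) -> np.ndarray:
        return self.df["panel_idx"].to_numpy()

    @property
    def z(self) -> np.ndarray:
        return self.df["z"].to_numpy(dtype=float)

    @property
    def p(self) -> np.ndarray:
        return self.df["p"].to_numpy(dtype=float)


def align(
    stats: SummaryStats,
    panel: ReferencePanel,
    drop_ambiguous: bool = False,
) -> AlignedIndex:
    """Match summary statistics to panel variants on (chrom, pos, alleles).

    Allele pairs matching up to a swap are kept with the z sign flipped.
    Strand-ambiguous pairs (A/T, C/G) are kept by default — the synthetic
    pipeline controls its own alleles; enable ``drop_ambiguous`` for real
    data harmonized across platforms.  Missing MAF is filled from panel
    allele frequencies.
    """
    pv = panel.variants.reset_index().rename(
        columns={"index": "panel_idx", "a1": "pa1", "a2": "pa2"}
    )
    merged = stats.df.merge(pv, on=["chrom", "pos"], how="inner", suffixes=("", "_panel"))
    if merged.empty:
        raise AlignmentError("no variants shared between stats and panel")

    same = (merged["a1"] == merged["pa1"]) & (merged["a2"] == merged["pa2"])
    swap = (merged["a1"] == merged["pa2"]) & (merged["a2"] == merged["pa1"])
    unknown = (merged["a1"] == "N") | (merged["a2"] == "N")
    keep = same | swap | unknown
    if drop_ambiguous:
        amb = [
            (a, b) in _AMBIGUOUS_PAIRS
            for a, b in zip(merged["a1"], merged["a2"])
        ]
        keep &= ~np.asarray(amb)
    merged = merged.loc[keep].copy()
    if merged.empty:
        raise AlignmentError("all shared variants removed by allele checks")
    flip = swap.loc[merged.index].to_numpy()
    merged.loc[flip, "z"] = -merged.loc[flip, "z"]

    panel_maf = panel.maf()
    fill = merged["maf"].isna()
    merged.loc[fill, "maf"] = panel_maf[merged.loc[fill, "panel_idx"].to_numpy()]

    out = merged[["snp_id", "chrom", "pos", "panel_idx", "z", "p", "n", "maf"]]
    return AlignedIndex(df=out.reset_index(drop=True))
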