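"""Full-analysis orchestration: annotate -> lambda_GC -> enrichment
curves -> PLSR + jackknife -> MHC reruns -> matched controls.

A single ``RunConfig`` (YAML-loadable) names either on-disk inputs
(summary statistics, reference panel, BED tracks) or a synthetic
``GeneratorConfig``; ``run_full`` executes every stage per phenotype x
category, writes deterministic numeric tables, and records a manifest
with a content hash of every artifact plus every seed and threshold
used.  All randomness flows from the config's named seed; rerunning the
same config reproduces the tables byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import inflation as gc
from . import ld as ldmod
from . import matched as mc
from . import plsr as plsrmod
from . import simulate as sim
from .io import (AlignedIndex, AnnotationTrack, SummaryStats, align,
                 read_panel, read_summary_stats, read_track)

log = logging.getLogger("evoenrich")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one analysis run needs; exactly one of ``generator`` /
    ``inputs`` must be supplied."""

    out: str = "evoenrich_run"
    seed: int = 0
    generator: sim.GeneratorConfig | None = None
    inputs: dict | None = None
    categories: tuple[str, ...] = ("HAR", "SD", "Ohno")
    covariates: tuple[str, ...] = plsrmod.DEFAULT_COVARIATES
    window_bp: int = 1_000_000
    r2_floor: float = 0.2
    score_threshold: float = 1.0
    pmax_log: float = enr.GENOME_WIDE_LOG10
    grid_points: int = 200
    var_threshold: float = 0.99
    k_folds: int = 50
    n_lambda_iter: int = 100
    prune_r2: float = 0.2
    n_bins: int = 20
    n_matched_sets: int = 100
    apply_gc: bool = False
    mhc_region: tuple[str, int, int] | None = None

    def __post_init__(self):
        if (self.generator is None) == (self.inputs is None):
            raise ValueError("supply exactly one of generator / inputs")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        gen = raw.pop("generator", None)
        if gen is not None:
            specs = gen.pop("track_specs", None)
            if specs is not None:
                gen["track_specs"] = sim.TrackSpecs(**specs)
            if "chrom_lengths" in gen:
                gen["chrom_lengths"] = {
                    str(k): int(v) for k, v in gen["chrom_lengths"].items()
                }
            gen = sim.GeneratorConfig(**gen)
        for key in ("categories", "covariates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if raw.get("mhc_region"):
            c, s, e = raw["mhc_region"]
            raw["mhc_region"] = (str(c), int(s), int(e))
        return cls(generator=gen, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class LoadedInputs:
    stats: dict[str, SummaryStats]
    panel: object
    tracks: dict[str, AnnotationTrack]
    truth: dict | None = None
    mhc_region: tuple[str, int, int] | None = None


def load_inputs(config: RunConfig) -> LoadedInputs:
    """Materialize inputs: read files or run the synthetic generator."""
    if config.generator is not None:
        study = sim.generate_study(config.generator)
        region = tuple(study.truth["mhc_like_region"])
        return LoadedInputs(
            stats={"sim": study.stats},
            panel=study.panel,
            tracks=study.tracks,
            truth=study.truth,
            mhc_region=region,
        )
    inp = config.inputs
    stats = {
        name: read_summary_stats(path, column_map=inp.get("column_map"))
        for name, path in inp["stats"].items()
    }
    panel_spec = inp["panel"]
    panel = read_panel(
        panel_spec["path"],
        fmt=panel_spec.get("format", "vcf"),
        sidecar=panel_spec.get("sidecar"),
    )
    tracks = {name: read_track(path, name) for name, path in inp["tracks"].items()}
    return LoadedInputs(
        stats=stats, panel=panel, tracks=tracks, mhc_region=plsrmod.MHC_REGION
    )


def brain_stratified_curves(
    table: pd.DataFrame,
    p: np.ndarray,
    category: str,
    score_threshold: float = 1.0,
    grid: np.ndarray | None = None,
    pmax_log: float = enr.GENOME_WIDE_LOG10,
) -> dict[str, enr.EnrichmentCurve]:
    """Curves for brain, category, and category-and-brain strata.

    The intersection stratum (both scores >= threshold) is omitted with
    a log entry when empty.
    """
    masks = {
        "brain": table["ld_brain"].to_numpy(dtype=float) >= score_threshold,
        category: table[f"ld_{category}"].to_numpy(dtype=float) >= score_threshold,
    }
    masks[f"{category}_brain"] = masks["brain"] & masks[category]
    out = {}
    for name, mask in masks.items():
        if not mask.any():
            log.info("brain-stratified stratum %s is empty; omitted", name)
            continue
        try:
            out[name] = enr.fold_curve(p, mask, grid, pmax_log, (name, score_threshold))
        except ValueError:
            log.info("brain-stratified stratum %s empty after p filter; omitted", name)
    return out


def _plsr_table(
    fits: dict[str, plsrmod.PLSRFit | None], names: tuple[str, ...]
) -> pd.DataFrame:
    """Tables-style layout: rows phenotypes, columns covariates, with
    sd/t/p companion columns."""
    rows = []
    for pheno, fit in fits.items():
        row: dict = {"phenotype": pheno}
        if fit is None:
            for nm in names:
                row[nm] = np.nan
        else:
            for nm, b in zip(fit.names, fit.coefficients):
                row[nm] = b
            if fit.jackknife_sd is not None:
                for nm, s, t, p in zip(fit.names, fit.jackknife_sd,
                                       fit.t_stat, fit.p_value):
                    row[f"{nm}_sd"] = s
                    row[f"{nm}_t"] = t
                    row[f"{nm}_p"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def _fit_with_jackknife(table, z, category, config, S, seed):
    design = plsrmod.build_design(
        table, z, evo_category=category, covariates=config.covariates
    )
    fit = plsrmod.fit_plsr(design, var_threshold=config.var_threshold)
    from scipy.sparse.csgraph import connected_components

    n_blocks, _ = connected_components(S, directed=False)
    k = min(config.k_folds, n_blocks)
    if k < config.k_folds:
        log.info("reduced folds to %d (only %d LD blocks)", k, n_blocks)
    folds = plsrmod.ld_folds(S, k=k, seed=seed)
    fit = plsrmod.jackknife_ttest(design, fit, folds, k=k)
    fit.seed = seed
    return fit


def run_full(config: RunConfig) -> Path:
    """Execute the whole analysis; returns the run directory.

    Any stage error aborts with the stage name; artifacts already
    written are retained.
    """
    t0 = time.time()
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("generator", "inputs")
        },
        "stages": [],
        "files": {},
    }
    if config.generator is not None:
        manifest["generator"] = dataclasses.asdict(config.generator)

    def record(stage, t_start, **info):
        manifest["stages"].append(
            {"stage": stage, "seconds": round(time.time() - t_start, 3), **info}
        )
        log.info("stage %s done in %.1fs %s", stage, time.time() - t_start, info)

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest["files"][name] = _sha256(path)

    stage = "load"
    try:
        t = time.time()
        data = load_inputs(config)
        mhc_region = config.mhc_region or data.mhc_region or plsrmod.MHC_REGION
        if data.truth is not None:
            emit("truth.json", lambda p: Path(p).write_text(
                json.dumps(data.truth, indent=2, sort_keys=True)))
        record(stage, t, phenotypes=list(data.stats),
               n_panel=data.panel.n_variants)

        stage = "annotate"
        t = time.time()
        first = next(iter(data.stats.values()))
        index = align(first, data.panel)
        categories = tuple(c for c in config.categories if c in data.tracks)
        score_cats = tuple(
            dict.fromkeys(
                list(categories) + ["exon", "intron", "utr5", "utr3", "brain"]
            )
        )
        table, nbhd = ldmod.build_score_table(
            data.panel, index, data.tracks, categories=score_cats,
            window_bp=config.window_bp, r2_floor=config.r2_floor,
        )
        S = nbhd.tag_submatrix()
        emit("score_table.tsv", lambda p: ldmod.write_score_table(table, p))
        record(stage, t, n_snps=len(table),
               n_intergenic=int(table["intergenic"].sum()))

        grid = enr.default_grid(config.pmax_log, config.grid_points)
        phen_z: dict[str, np.ndarray] = {}
        phen_p: dict[str, np.ndarray] = {}
        for pheno, stats in data.stats.items():
            idx = align(stats, data.panel)
            if not np.array_equal(idx.panel_idx, index.panel_idx):
                raise PipelineError(
                    f"phenotype {pheno} aligns to a different variant set; "
                    "summary statistics must share the variant grid"
                )
            phen_z[pheno] = idx.z
            phen_p[pheno] = idx.p

        stage = "lambda"
        t = time.time()
        lambdas = {}
        for pheno in data.stats:
            lam = gc.estimate_lambda(
                phen_z[pheno], table["intergenic"].to_numpy(), S,
                n_iter=config.n_lambda_iter, prune_r2=config.prune_r2,
                seed=config.seed,
            )
            lambdas[pheno] = lam
            emit(f"lambda_{pheno}.json", lambda p, lam=lam: Path(p).write_text(
                json.dumps(lam.to_dict(), indent=2, sort_keys=True)))
            if config.apply_gc:
                z2c, pc = gc.apply_gc(phen_z[pheno], lam)
                phen_z[pheno] = np.sqrt(z2c) * np.sign(phen_z[pheno])
                phen_p[pheno] = pc
        record(stage, t, lambdas={k: round(v.lambda_gc, 4) for k, v in lambdas.items()})

        stage = "enrichment"
        t = time.time()
        mhc_keep = None
        try:
            mhc_keep = plsrmod.mhc_subset(table, "exclude", mhc_region)
        except ValueError:
            log.info("MHC region empty or covers everything; skipping MHC reruns")
        for pheno in data.stats:
            for cat in categories:
                cin, cout = enr.stratified_curves(
                    table, phen_p[pheno], cat, config.score_threshold, grid,
                    config.pmax_log,
                )
                frame = enr.curves_to_frame(cin, cout)
                emit(f"enrichment_{pheno}_{cat}.tsv",
                     lambda p, fr=frame: fr.to_csv(p, sep="\t", index=False))
                if mhc_keep is not None:
                    cin_x, cout_x = enr.stratified_curves(
                        table.loc[mhc_keep], phen_p[pheno][mhc_keep], cat,
                        config.score_threshold, grid, config.pmax_log,
                    )
                    frame_x = enr.curves_to_frame(cin_x, cout_x)
                    emit(f"enrichment_{pheno}_{cat}_noMHC.tsv",
                         lambda p, fr=frame_x: fr.to_csv(p, sep="\t", index=False))
                bcurves = brain_stratified_curves(
                    table, phen_p[pheno], cat, config.score_threshold, grid,
                    config.pmax_log,
                )
                bframe = pd.DataFrame({"threshold": grid} | {
                    f"fold_{name}": c.fold for name, c in bcurves.items()
                })
                emit(f"enrichment_{pheno}_{cat}_brain.tsv",
                     lambda p, fr=bframe: fr.to_csv(p, sep="\t", index=False))
        record(stage, t)

        stage = "plsr"
        t = time.time()
        modes = {"all": None, "noMHC": "exclude", "onlyMHC": "only"}
        meta: dict = {}
        for cat in categories:
            for mode_name, mode in modes.items():
                fits: dict[str, plsrmod.PLSRFit | None] = {}
                for pheno in data.stats:
                    try:
                        if mode is None:
                            sub_table, sub_z, sub_S = table, phen_z[pheno], S
                        else:
                            keep = plsrmod.mhc_subset(table, mode, mhc_region)
                            kidx = np.flatnonzero(keep)
                            sub_table = table.loc[keep]
                            sub_z = phen_z[pheno][keep]
                            sub_S = S[kidx][:, kidx]
                        fit = _fit_with_jackknife(
                            sub_table, sub_z, cat, config, sub_S, config.seed
                        )
                        fits[pheno] = fit
                        meta[f"{cat}_{mode_name}_{pheno}"] = {
                            "n_lv": fit.n_lv,
                            "x_variance_explained":
                                [round(float(v), 6) for v in fit.x_variance_explained],
                            "k_folds": int(len(np.unique(fit.folds))),
                        }
                    except (plsrmod.PLSRError, ValueError) as exc:
                        log.warning("PLSR %s/%s/%s skipped: %s",
                                    cat, mode_name, pheno, exc)
                        fits[pheno] = None
                frame = _plsr_table(fits, tuple(config.covariates) + (cat,))
                emit(f"plsr_{cat}_{mode_name}.tsv",
                     lambda p, fr=frame: fr.to_csv(p, sep="\t", index=False))
            # residual-vs-TotLD summaries (all-SNP run only)
            for pheno in data.stats:
                try:
                    resid = plsrmod.residual_vs_totld(
                        table, phen_z[pheno], cat,
                        covariates=config.covariates, n_bins=config.n_bins,
                        var_threshold=config.var_threshold,
                    )
                    emit(f"residual_totld_{pheno}_{cat}.tsv",
                         lambda p, fr=resid: fr.to_csv(p, sep="\t", index=False))
                except (plsrmod.PLSRError, ValueError) as exc:
                    log.warning("residual summary %s/%s skipped: %s", cat, pheno, exc)
        emit("plsr_meta.json", lambda p: Path(p).write_text(
            json.dumps(meta, indent=2, sort_keys=True)))
        record(stage, t)

        stage = "matched"
        t = time.time()
        spec = mc.MatchSpec(n_sets=config.n_matched_sets, seed=config.seed,
                            allow_reuse=True)
        for cat in categories:
            source = np.flatnonzero(table[f"raw_{cat}"].to_numpy() == 1)
            if source.size == 0:
                log.info("no raw %s SNPs; matched controls skipped", cat)
                continue
            sets = mc.sample_matched(source, table, spec)
            for pheno in data.stats:
                env = mc.matched_enrichment(sets, phen_p[pheno], grid,
                                            config.pmax_log)
                emit(f"matched_{pheno}_{cat}.tsv",
                     lambda p, fr=env.to_frame(): fr.to_csv(p, sep="\t", index=False))
        record(stage, t)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest["total_seconds"] = round(time.time() - t0, 3)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return outdir


def verify_manifest(outdir) -> bool:
    """Re-hash every artifact listed in the manifest; True iff all match."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    return all(
        _sha256(outdir / name) == digest
        for name, digest in manifest["files"].items()
    )
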