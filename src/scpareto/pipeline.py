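"""End-to-end orchestration: simulate → qc → pca → select-k → fit → score →
enrich → annotate → cnv → dynamics, driven by one YAML-able config with
explicit per-stage seeds and a JSON manifest (parameters, seeds, checksums)
for reproducibility.  Stages write their outputs under the run directory and
later stages re-read them from disk, so a run is resumable per stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cnv import GenomicTrack, archetype_subclone_association, cluster_subclones, infer_cnv_profile
from .dynamics import cohort_shift_test, fishplot_long, specialist_proportions
from .enrichment import read_gmt, ssgsea_scores
from .io_qc import PCSpace, QCParams, normalize_log, pca_project, qc_filter, read_counts, select_hvg
from .model_selection import scan_k, select_k_elbow, t_ratio, t_ratio_test
from .pcha import fit_pcha
from .scores import classify_specialists, score_cells
from .synthetic import (
    make_gene_track, make_truth, plant_cnv_subclones, simulate_longitudinal,
    truth_gene_sets, write_gene_track, write_gmt, write_mtx,
)
from .tasks import cluster_coefficients, cv_grouplasso, standardize

STAGES = ["simulate", "qc", "pca", "select_k", "fit", "score",
          "enrich", "annotate", "cnv", "dynamics"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Parameters for a full run; any subset may be overridden from YAML."""

    seed: int = 0
    simulate: dict = field(default_factory=lambda: {
        "k": 3, "n_genes": 400, "d": 5, "alpha": 0.3,
        "cells_per_time": 150, "n_times": 2,
        "proportions_by_time": None,  # default: drift toward archetype 1
        "depth": 5000.0, "dispersion": 2.0, "dropout": 0.05,
        "cnv_segment_genes": 80, "cnv_fold_change": 2.0,
    })
    qc: dict = field(default_factory=lambda: {
        "min_genes": 100, "min_umis": 200, "max_mito_pct": 25.0})
    pca: dict = field(default_factory=lambda: {"d": 5, "n_hvg": 300})
    select_k: dict = field(default_factory=lambda: {
        "k_min": 3, "k_max": 6, "restarts": 5, "gain_threshold": 0.02,
        "shuffles": 0})
    fit: dict = field(default_factory=lambda: {"restarts": 10})
    score: dict = field(default_factory=lambda: {"percentile": 80.0})
    enrich: dict = field(default_factory=lambda: {"gmt": None, "alpha": 0.25})
    annotate: dict = field(default_factory=lambda: {"folds": 10, "n_clusters": 3})
    cnv: dict = field(default_factory=lambda: {
        "window": 21, "m": 2, "n_reference": 40})
    dynamics: dict = field(default_factory=lambda: {"group_column": None})
    counts_path: str | None = None  # skip simulate and read real data instead
    counts_format: str = "mtx"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ConfigError(f"unknown config key {key!r}")
            cur = getattr(cfg, key)
            if isinstance(cur, dict) and isinstance(val, dict):
                cur.update(val)
            else:
                setattr(cfg, key, val)
        return cfg

    def validate(self):
        gmt = self.enrich.get("gmt")
        if gmt is not None and not Path(gmt).exists():
            raise ConfigError(f"GMT file not found: {gmt}")
        if self.counts_path is not None and not Path(self.counts_path).exists():
            raise ConfigError(f"counts path not found: {self.counts_path}")
        for s in (self.dynamics, self.cnv, self.select_k):
            if not isinstance(s, dict):
                raise ConfigError("stage configs must be mappings")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir, stages=None) -> Path:
    """Execute the requested stages in order; returns the run directory.

    A failed stage halts the run with the stage name, preserving earlier
    outputs.  The manifest records package version, parameters, seeds and
    per-file checksums (no timestamps, so repeated runs agree byte-for-byte).
    """
    config.validate()
    if stages is None:
        stages = list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed,
                "stages": stages, "params": asdict(config), "outputs": {}}

    for stage in stages:
        try:
            files = _STAGE_FUNCS[stage](config, out)
        except Exception as e:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
        manifest["outputs"][stage] = {
            str(f.relative_to(out)): _sha256(f) for f in files
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


# --------------------------------------------------------------------------
# stages

def _stage_simulate(cfg: PipelineConfig, out: Path):
    p = cfg.simulate
    truth = make_truth(p["k"], p["n_genes"], p["d"], p["alpha"], seed=cfg.seed,
                       n_signature=min(50, p["n_genes"] // (2 * p["k"])))
    props = p.get("proportions_by_time")
    if props is None:
        k, T = p["k"], p["n_times"]
        props = []
        for t in range(T):
            w = np.full(k, 1.0)
            w[0] += 2.0 * t / max(T - 1, 1)  # drift toward archetype 1
            props.append((w / w.sum()).tolist())
    ds = simulate_longitudinal(
        truth, props, p["cells_per_time"], seed=cfg.seed + 1,
        depth=p["depth"], dispersion=p["dispersion"], dropout=p["dropout"],
    )
    seg_genes = p.get("cnv_segment_genes", 0)
    if seg_genes:
        n_cells = len(ds.counts.cell_ids)
        clone = pd.Series(
            ["c1" if i < n_cells // 2 else "c2" for i in range(n_cells)],
            index=ds.counts.cell_ids,
        )
        ds = plant_cnv_subclones(
            ds, [("chr1", 0, seg_genes - 1, "c2")], clone,
            [p.get("cnv_fold_change", 2.0)], seed=cfg.seed + 2,
        )
    data = out / "data"
    write_mtx(ds, data)
    write_gmt(truth_gene_sets(truth), data / "sets.gmt")
    write_gene_track(make_gene_track(ds.counts.gene_ids), data / "genes_track.tsv")
    np.savetxt(data / "true_weights.csv", ds.weights, delimiter=",")
    return sorted(data.iterdir())


def _load_counts(cfg, out):
    if cfg.counts_path:
        return read_counts(cfg.counts_path, format=cfg.counts_format)
    return read_counts(out / "data", format="mtx")


def _stage_qc(cfg: PipelineConfig, out: Path):
    counts = _load_counts(cfg, out)
    params = QCParams(**{k: v for k, v in cfg.qc.items()})
    filtered, report = qc_filter(counts, params)
    norm = normalize_log(filtered)
    report.to_json(out / "qc_report.json")
    df = pd.DataFrame(norm, index=filtered.gene_ids, columns=filtered.cell_ids)
    df.to_csv(out / "normalized.csv", float_format="%.6g")
    if filtered.cell_meta is not None:
        filtered.cell_meta.to_csv(out / "cells_meta.csv")
    return [out / "qc_report.json", out / "normalized.csv"] + (
        [out / "cells_meta.csv"] if filtered.cell_meta is not None else []
    )


def _read_normalized(out):
    df = pd.read_csv(out / "normalized.csv", index_col=0)
    return df.to_numpy(), list(df.index.astype(str)), list(df.columns.astype(str))


def _stage_pca(cfg: PipelineConfig, out: Path):
    norm, genes, cells = _read_normalized(out)
    hvg = select_hvg(norm, genes, n_top=min(cfg.pca["n_hvg"], len(genes)))
    gi = [genes.index(g) for g in hvg]
    ps = pca_project(norm[gi], d=cfg.pca["d"], gene_ids=hvg, cell_ids=cells)
    df = pd.DataFrame(ps.coords, index=cells,
                      columns=[f"PC{i + 1}" for i in range(ps.d)])
    df.to_csv(out / "pcs.csv", float_format="%.8g")
    np.savetxt(out / "pc_variance_ratio.csv", ps.explained_variance_ratio, delimiter=",")
    return [out / "pcs.csv", out / "pc_variance_ratio.csv"]


def _read_pcs(out) -> PCSpace:
    df = pd.read_csv(out / "pcs.csv", index_col=0)
    evr = np.loadtxt(out / "pc_variance_ratio.csv", delimiter=",")
    return PCSpace(coords=df.to_numpy(), explained_variance_ratio=evr,
                   cell_ids=list(df.index.astype(str)))


def _stage_select_k(cfg: PipelineConfig, out: Path):
    ps = _read_pcs(out)
    p = cfg.select_k
    scan = scan_k(ps, p["k_min"], p["k_max"], restarts=p["restarts"],
                  seed=cfg.seed + 10, with_t_ratio=True)
    chosen = select_k_elbow(scan, p["gain_threshold"])
    result = {"records": scan.records, "chosen_k": chosen,
              "chose_k_max": scan.chose_k_max}
    if p.get("shuffles"):
        tr, pval = t_ratio_test(ps, chosen, n_shuffles=p["shuffles"],
                                seed=cfg.seed + 11)
        result["t_ratio_observed"], result["t_ratio_pvalue"] = tr, pval
    (out / "kscan.json").write_text(json.dumps(result, indent=2))
    return [out / "kscan.json"]


def _stage_fit(cfg: PipelineConfig, out: Path):
    ps = _read_pcs(out)
    chosen = json.loads((out / "kscan.json").read_text())["chosen_k"]
    fit = fit_pcha(ps, chosen, restarts=cfg.fit["restarts"], seed=cfg.seed + 20)
    np.savetxt(out / "archetypes_Z.csv", fit.Z, delimiter=",")
    np.savetxt(out / "weights_S.csv", fit.S, delimiter=",")
    meta = {"k": fit.k, "sse": fit.sse, "ev": fit.ev, "n_iter": fit.n_iter,
            "converged": fit.converged, "t_ratio": t_ratio(fit, ps) if fit.k >= 3 else None}
    (out / "fit.json").write_text(json.dumps(meta, indent=2))
    return [out / "fit.json", out / "archetypes_Z.csv", out / "weights_S.csv"]


def _load_fit(out, ps):
    from .pcha import ArchetypeFit
    Z = np.loadtxt(out / "archetypes_Z.csv", delimiter=",")
    S = np.loadtxt(out / "weights_S.csv", delimiter=",")
    meta = json.loads((out / "fit.json").read_text())
    n = ps.coords.shape[0]
    return ArchetypeFit(k=meta["k"], Z=Z, C=np.zeros((n, meta["k"])), S=S,
                        sse=meta["sse"], ev=meta["ev"], n_iter=meta["n_iter"],
                        restarts_used=0)


def _stage_score(cfg: PipelineConfig, out: Path):
    ps = _read_pcs(out)
    fit = _load_fit(out, ps)
    table = classify_specialists(score_cells(ps, fit, cell_ids=ps.cell_ids),
                                 percentile=cfg.score["percentile"])
    table.to_frame().to_csv(out / "scores.tsv", sep="\t", float_format="%.8g")
    return [out / "scores.tsv"]


def _stage_enrich(cfg: PipelineConfig, out: Path):
    norm, genes, cells = _read_normalized(out)
    gmt = cfg.enrich.get("gmt") or (out / "data" / "sets.gmt")
    coll = read_gmt(gmt)
    em = ssgsea_scores(norm, genes, coll, cell_ids=cells,
                       alpha=cfg.enrich["alpha"], normalization="none")
    em.values.to_csv(out / "enrichment.tsv", sep="\t", float_format="%.8g")
    return [out / "enrichment.tsv"]


def _stage_annotate(cfg: PipelineConfig, out: Path):
    scores_df = pd.read_csv(out / "scores.tsv", sep="\t", index_col=0)
    score_cols = [c for c in scores_df.columns if c.startswith("archetype_")]
    enrich = pd.read_csv(out / "enrichment.tsv", sep="\t", index_col=0)
    Xp = standardize(enrich.T.to_numpy())
    Y = scores_df[score_cols].to_numpy()
    model = cv_grouplasso(Xp, Y, folds=min(cfg.annotate["folds"], Xp.shape[0]),
                          seed=cfg.seed + 30, pathway_names=list(enrich.index))
    pd.DataFrame(model.B, index=model.pathway_names, columns=score_cols).to_csv(
        out / "coefficients.tsv", sep="\t", float_format="%.8g")
    pd.DataFrame({"lambda": model.lambda_path, "cv_mean": model.cv_mean,
                  "cv_se": model.cv_se}).to_csv(out / "cv_curve.tsv", sep="\t",
                                                index=False, float_format="%.8g")
    try:
        labels = cluster_coefficients(model, n_clusters=min(
            cfg.annotate["n_clusters"], max(len(model.active_pathways()), 1)))
        clusters = {"pathway_clusters": labels.pathway_clusters,
                    "cluster_to_archetype": labels.cluster_to_archetype,
                    "lambda_1se": model.lambda_1se}
    except ValueError:
        clusters = {"pathway_clusters": {}, "cluster_to_archetype": {},
                    "lambda_1se": model.lambda_1se}
    (out / "clusters.json").write_text(json.dumps(clusters, indent=2))
    return [out / "coefficients.tsv", out / "cv_curve.tsv", out / "clusters.json"]


def _stage_cnv(cfg: PipelineConfig, out: Path):
    norm, genes, cells = _read_normalized(out)
    track_path = cfg.cnv.get("track") or (out / "data" / "genes_track.tsv")
    track = GenomicTrack.from_tsv(track_path)
    refs = cfg.cnv.get("reference_cells") or cells[: cfg.cnv.get("n_reference", 40)]
    profiles = infer_cnv_profile(norm, genes, cells, track, refs,
                                 window=cfg.cnv["window"])
    assign = cluster_subclones(profiles, m=cfg.cnv["m"])
    assign.labels.to_csv(out / "subclones.tsv", sep="\t")
    scores_df = pd.read_csv(out / "scores.tsv", sep="\t", index_col=0)
    score_cols = [c for c in scores_df.columns if c.startswith("archetype_")]
    from .scores import ArchetypeScoreTable
    table = ArchetypeScoreTable(
        cell_ids=list(scores_df.index.astype(str)),
        distances=np.zeros_like(scores_df[score_cols].to_numpy()),
        scores=scores_df[score_cols].to_numpy(),
    )
    anova, pairs = archetype_subclone_association(table, assign)
    anova.to_csv(out / "cnv_anova.tsv", sep="\t", index=False, float_format="%.8g")
    pairs.to_csv(out / "cnv_tukey.tsv", sep="\t", index=False, float_format="%.8g")
    return [out / "subclones.tsv", out / "cnv_anova.tsv", out / "cnv_tukey.tsv"]


def _stage_dynamics(cfg: PipelineConfig, out: Path):
    scores_df = pd.read_csv(out / "scores.tsv", sep="\t", index_col=0)
    score_cols = [c for c in scores_df.columns if c.startswith("archetype_")]
    from .scores import ArchetypeScoreTable
    table = ArchetypeScoreTable(
        cell_ids=list(scores_df.index.astype(str)),
        distances=np.zeros_like(scores_df[score_cols].to_numpy()),
        scores=scores_df[score_cols].to_numpy(),
        specialist_label=pd.Series(
            [int(v) if str(v).isdigit() else v for v in scores_df["label"]],
            index=scores_df.index.astype(str)),
        percentile_used=cfg.score["percentile"],
    )
    meta = pd.read_csv(out / "cells_meta.csv", index_col=0)
    meta.index = meta.index.astype(str)
    props = specialist_proportions(table, meta)
    props.to_csv(out / "proportions.tsv", sep="\t", index=False, float_format="%.8g")
    fishplot_long(props).to_csv(out / "fishplot.csv", index=False, float_format="%.8g")
    stats = {}
    gcol = cfg.dynamics.get("group_column")
    if gcol and props[gcol].nunique() == 2 and props.groupby(gcol).size().min() >= 2:
        stats["cohort_shift"] = cohort_shift_test(props, gcol).to_dict("records")
    (out / "dynamics_stats.json").write_text(json.dumps(stats, indent=2))
    return [out / "proportions.tsv", out / "fishplot.csv", out / "dynamics_stats.json"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate, "qc": _stage_qc, "pca": _stage_pca,
    "select_k": _stage_select_k, "fit": _stage_fit, "score": _stage_score,
    "enrich": _stage_enrich, "annotate": _stage_annotate,
    "cnv": _stage_cnv, "dynamics": _stage_dynamics,
}
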