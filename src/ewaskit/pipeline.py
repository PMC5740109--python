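"""Configured, resumable orchestration of the full synthetic study.

Runs simulate -> qc -> ewas -> dmr -> meta -> panel -> predict in
dependency order from a single YAML/JSON config.  Every stage writes its
outputs before the next starts; a run manifest records a parameter/input
hash and the SHA-256 of every output file, so re-running with an
unchanged config skips completed stages and two fresh runs of the same
config produce byte-identical outputs.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dmr as dmr_mod
from . import ewas as ewas_mod
from . import frailty as frailty_mod
from . import meta as meta_mod
from . import qc as qc_mod
from . import simulate as sim_mod

log = logging.getLogger("ewaskit.pipeline")

STAGES = ("simulate", "qc", "ewas", "dmr", "meta", "panel", "predict")

#: Which stage each stage consumes outputs from.
STAGE_DEPS = {
    "simulate": (),
    "qc": ("simulate",),
    "ewas": ("simulate", "qc"),
    "dmr": ("simulate", "qc", "ewas"),
    "meta": ("ewas",),
    "panel": ("simulate", "qc", "ewas"),
    "predict": ("simulate", "qc", "ewas", "panel"),
}

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "stages": list(STAGES),
    "simulate": {
        "n_autosomal": 3000,
        "n_sex": 60,
        "n_snp_flagged": 40,
        "n_control": 60,
        "n_genes": 300,
        "n_marker_per_type": 10,
        "cohorts": {
            "discovery": {"n_case": 60, "n_control": 60},
            "replication": {"n_case": 40, "n_control": 80},
            "test": {"n_case": 40, "n_control": 80},
        },
        "spike": {"n_probes": 6, "delta_beta": 0.05, "region_genes": 1,
                  "region_delta": 0.06},
        "batch_sd": 1.0,
        "score_index_r": 0.6,
    },
    "qc": {"detection_threshold": 1e-12, "call_rate": 0.98, "max_fail_fraction": 0.05},
    "ewas": {"n_control_pcs": 30, "n_residual_pcs": 5, "threshold": 5e-7,
             "permutation_check_B": 100},
    "dmr": {"max_gap": 500, "window": 3, "cutoff_quantile": 0.99, "min_probes": 3,
            "permutations": 30},
    "panel": {"p_cut": 1e-3},
    "predict": {"high_cut": 50, "low_cut": 16, "folds": 10, "permutations": 50,
                "ci_reps": 200},
}


class StageDependencyError(RuntimeError):
    """An enabled stage needs outputs of a stage that has not run."""


# ---------------------------------------------------------------------------
# Config handling
# ---------------------------------------------------------------------------


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def load_config(path: str | Path | None) -> dict:
    """Load a YAML/JSON config, filling unset keys from the defaults."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    validate_config(cfg)
    return cfg


def _deep_update(base: dict, other: dict) -> None:
    for k, v in other.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def validate_config(cfg: dict) -> None:
    unknown = [s for s in cfg.get("stages", []) if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages in config: {unknown}")
    if not isinstance(cfg.get("seed"), int):
        raise ValueError("config seed must be an integer")
    enabled = set(cfg["stages"])
    for s in enabled:
        missing = [d for d in STAGE_DEPS[s] if d not in enabled]
        # a disabled dependency is fine if its outputs already exist on disk;
        # checked at run time, but flag the common misconfiguration early
        if missing:
            log.info("stage %s depends on disabled stage(s) %s; their outputs "
                     "must already exist", s, missing)


def config_to_yaml(cfg: dict) -> str:
    return yaml.safe_dump(cfg, sort_keys=True)


# ---------------------------------------------------------------------------
# Run manifest / hashing
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _params_key(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Per-stage parameter keys, output paths and content hashes."""

    version: str = "0.1.0"
    stages: dict = dataclasses.field(default_factory=dict)

    def record(self, stage: str, key: str, outputs: list[Path], status: str) -> None:
        self.stages[stage] = {
            "key": key,
            "outputs": {str(p): _sha256(p) for p in sorted(outputs)},
            "status": status,
        }

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"version": self.version, "stages": self.stages}, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        d = json.loads(path.read_text())
        return cls(version=d.get("version", "?"), stages=d.get("stages", {}))


def _stage_complete(manifest: RunManifest, stage: str, key: str) -> bool:
    rec = manifest.stages.get(stage)
    if not rec or rec.get("key") != key:
        return False
    return all(Path(p).exists() and _sha256(Path(p)) == h
               for p, h in rec["outputs"].items())


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------

_FMT = "%.10g"


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = None) -> Path:
    df.to_csv(path, sep="\t", float_format=_FMT, index_label=index_label)
    return path


def _covariate_table(samples: pd.DataFrame, cellprops: pd.DataFrame) -> pd.DataFrame:
    return pd.concat(
        [samples[ewas_mod.NUISANCE_COVARIATES].astype(float), cellprops], axis=1,
        join="inner",
    )


def _load_cohort_inputs(outdir: Path, cohort: str) -> dict:
    """Load the qc-stage outputs a downstream stage needs for one cohort."""
    qcdir = outdir / "qc" / cohort
    simdir = outdir / "sim" / cohort
    needed = [qcdir / "beta_filtered.tsv", qcdir / "cell_proportions.csv",
              simdir / "samples.csv", simdir / "control_intensities.tsv"]
    for p in needed:
        if not p.exists():
            stage = "qc" if "qc" in str(p) else "simulate"
            raise StageDependencyError(
                f"missing {p}; run the '{stage}' stage first")
    beta = pd.read_csv(qcdir / "beta_filtered.tsv", sep="\t", index_col=0)
    cellprops = pd.read_csv(qcdir / "cell_proportions.csv", index_col=0)
    samples = pd.read_csv(simdir / "samples.csv", index_col=0)
    ctl = pd.read_csv(simdir / "control_intensities.tsv", sep="\t", index_col=0)
    samples = samples.loc[beta.columns]
    return {
        "beta": beta,
        "covariates": _covariate_table(samples, cellprops.loc[beta.columns]),
        "group": samples["group"],
        "samples": samples,
        "control_intensities": ctl[beta.columns],
    }


def _ewas_basis(inputs: dict, cfg: dict) -> tuple[pd.DataFrame | None, pd.DataFrame | None]:
    k_ctl, k_res = cfg["ewas"]["n_control_pcs"], cfg["ewas"]["n_residual_pcs"]
    cpcs = (ewas_mod.control_probe_pcs(inputs["control_intensities"], k=k_ctl).scores
            if k_ctl > 0 else None)
    rpcs = None
    if k_res > 0:
        resid = ewas_mod.stage1_residuals(
            inputs["beta"], inputs["covariates"],
            cpcs if cpcs is not None else inputs["covariates"].iloc[:, :0])
        rpcs = ewas_mod.residual_pcs(resid, k=k_res).scores
    return cpcs, rpcs


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: dict, outdir: Path) -> list[Path]:
    sc = cfg["simulate"]
    seed = cfg["seed"]
    manifest = sim_mod.generate_manifest(
        sc["n_autosomal"], sc["n_sex"], sc["n_snp_flagged"], sc["n_control"],
        sc["n_genes"], seed=seed)
    reference = sim_mod.generate_cell_reference(sc["n_marker_per_type"], seed=seed + 1)

    rng = np.random.default_rng(seed + 2)
    genic = manifest.loc[(manifest["gene"] != "") & (~manifest["is_control"])]
    spike_ids = list(rng.choice(genic["probe_id"].to_numpy(),
                                size=sc["spike"]["n_probes"], replace=False))
    sizes = genic.groupby("gene").size()
    big_genes = sizes.index[sizes >= 5]
    region_genes = list(rng.choice(np.asarray(big_genes),
                                   size=sc["spike"]["region_genes"], replace=False))
    spiked_region_probes = set(genic.loc[genic["gene"].isin(region_genes), "probe_id"])
    spike_probes = [(p, sc["spike"]["delta_beta"]) for p in spike_ids
                    if p not in spiked_region_probes]
    spike_regions = [(g, sc["spike"]["region_delta"]) for g in region_genes]

    paths: list[Path] = []
    for i, (name, sizes_cfg) in enumerate(sorted(sc["cohorts"].items())):
        study = sim_mod.generate_cohort(
            manifest, reference,
            n_case=sizes_cfg["n_case"], n_control=sizes_cfg["n_control"],
            spike_probes=spike_probes, spike_regions=spike_regions,
            batch_sd=sc["batch_sd"], score_index_r=sc["score_index_r"],
            seed=seed + 10 + i, cohort_id=name)
        paths.extend(study.write(outdir / "sim" / name).values())
    refdir = outdir / "sim"
    refpath = refdir / "cell_reference.tsv"
    reference.profiles.to_csv(refpath, sep="\t", float_format=_FMT)
    paths.append(refpath)
    log.info("simulate: %d cohorts, %d probes", len(sc["cohorts"]),
             len(manifest))
    return paths


def _stage_qc(cfg: dict, outdir: Path) -> list[Path]:
    qcfg = cfg["qc"]
    refpath = outdir / "sim" / "cell_reference.tsv"
    if not refpath.exists():
        raise StageDependencyError("missing simulate outputs; run 'simulate' first")
    reference = sim_mod.CellReference(pd.read_csv(refpath, sep="\t", index_col=0))
    paths: list[Path] = []
    for codir in sorted((outdir / "sim").iterdir()):
        if not codir.is_dir():
            continue
        name = codir.name
        manifest = pd.read_csv(codir / "manifest.tsv", sep="\t",
                               keep_default_na=False,
                               dtype={"chromosome": str, "gene": str,
                                      "control_class": str})
        beta = pd.read_csv(codir / "beta.tsv", sep="\t", index_col=0)
        intensity = pd.read_csv(codir / "intensity.tsv", sep="\t", index_col=0)
        ctl = pd.read_csv(codir / "control_intensities.tsv", sep="\t", index_col=0)
        samples = pd.read_csv(codir / "samples.csv", index_col=0)

        neg_ids = manifest.loc[manifest["control_class"] == "NEGATIVE", "probe_id"]
        stacked = pd.concat([intensity, ctl.loc[[p for p in neg_ids if p in ctl.index]]])
        detection = qc_mod.compute_detection_p(stacked, list(neg_ids))
        detection = detection.loc[intensity.index]

        retained_probes, report = qc_mod.filter_probes(
            manifest, detection, threshold=qcfg["detection_threshold"],
            max_fail_fraction=qcfg["max_fail_fraction"])
        retained_samples, removed = qc_mod.filter_samples(
            detection.loc[retained_probes], call_rate_threshold=qcfg["call_rate"],
            detection_threshold=qcfg["detection_threshold"])
        sex_calls, mismatches = qc_mod.predict_sex(beta, manifest, samples)
        report.removed_samples.update(removed)
        for s in mismatches:
            report.removed_samples.setdefault(s, "predicted/reported sex mismatch")
        kept = [s for s in retained_samples if s not in report.removed_samples]

        cellprops = qc_mod.estimate_cell_proportions(beta[kept], reference)

        qdir = outdir / "qc" / name
        qdir.mkdir(parents=True, exist_ok=True)
        paths.append(_write_tsv(beta.loc[retained_probes, kept],
                                qdir / "beta_filtered.tsv"))
        p = qdir / "filter_report.json"
        p.write_text(json.dumps(dataclasses.asdict(report), indent=1, sort_keys=True))
        paths.append(p)
        cellprops.fractions.to_csv(qdir / "cell_proportions.csv", float_format=_FMT)
        paths.append(qdir / "cell_proportions.csv")
        sex_calls.to_frame().to_csv(qdir / "predicted_sex.csv")
        paths.append(qdir / "predicted_sex.csv")
        log.info("qc[%s]: retained %d/%d probes, %d/%d samples", name,
                 report.n_retained, report.n_input_probes, len(kept), len(samples))
    return paths


def _stage_ewas(cfg: dict, outdir: Path) -> list[Path]:
    paths: list[Path] = []
    for cohort in ("discovery", "replication"):
        inputs = _load_cohort_inputs(outdir, cohort)
        cpcs, rpcs = _ewas_basis(inputs, cfg)
        result = ewas_mod.fit_final_glm(
            inputs["beta"], inputs["group"], inputs["covariates"], cpcs, rpcs)
        edir = outdir / "ewas" / cohort
        edir.mkdir(parents=True, exist_ok=True)
        paths.append(_write_tsv(result.table, edir / "results.tsv",
                                index_label="probe_id"))
        thr = cfg["ewas"]["threshold"]
        hits = list(result.significant(thr).index)
        perm = {}
        if hits:
            emp = ewas_mod.permutation_check(
                inputs["beta"], inputs["group"], inputs["covariates"], hits,
                cpcs, rpcs, B=cfg["ewas"]["permutation_check_B"], seed=cfg["seed"])
            perm = {k: float(v) for k, v in emp.items()}
        summary = {"lambda": result.lambda_, "n_probes": len(result.table),
                   "n_significant": len(hits), "threshold": thr,
                   "permutation_empirical_p": perm}
        p = edir / "summary.json"
        p.write_text(json.dumps(summary, indent=1, sort_keys=True))
        paths.append(p)
        log.info("ewas[%s]: lambda=%.3f, %d hits at p<%g", cohort,
                 result.lambda_, len(hits), thr)
    return paths


def _stage_dmr(cfg: dict, outdir: Path) -> list[Path]:
    if not (outdir / "ewas" / "discovery" / "results.tsv").exists():
        raise StageDependencyError("missing ewas outputs; run 'ewas' first")
    dcfg = cfg["dmr"]
    inputs = _load_cohort_inputs(outdir, "discovery")
    manifest = pd.read_csv(outdir / "sim" / "discovery" / "manifest.tsv", sep="\t",
                           keep_default_na=False,
                           dtype={"chromosome": str, "gene": str, "control_class": str})
    cpcs, rpcs = _ewas_basis(inputs, cfg)
    records = dmr_mod.call_dmrs(
        inputs["beta"], inputs["group"], inputs["covariates"], manifest,
        control_pcs=cpcs, residual_pcs=rpcs,
        max_gap=dcfg["max_gap"], window=dcfg["window"],
        cutoff_quantile=dcfg["cutoff_quantile"], min_probes=dcfg["min_probes"],
        B=dcfg["permutations"], seed=cfg["seed"])
    ddir = outdir / "dmr"
    ddir.mkdir(parents=True, exist_ok=True)
    frame = dmr_mod.records_to_frame(records)
    paths = [_write_tsv(frame, ddir / "dmrs.tsv")]
    (ddir / "dmrs.bed").write_text(dmr_mod.records_to_bed(records))
    paths.append(ddir / "dmrs.bed")
    log.info("dmr: %d candidates, %d at q<0.05", len(records),
             int((frame["q"] < 0.05).sum()) if len(frame) else 0)
    return paths


def _stage_meta(cfg: dict, outdir: Path) -> list[Path]:
    studies = []
    for cohort in ("discovery", "replication"):
        p = outdir / "ewas" / cohort / "results.tsv"
        if not p.exists():
            raise StageDependencyError(f"missing {p}; run 'ewas' first")
        studies.append(pd.read_csv(p, sep="\t", index_col=0))
    iv = meta_mod.inverse_variance_meta(studies)
    sz = meta_mod.sample_size_meta(studies)
    mdir = outdir / "meta"
    mdir.mkdir(parents=True, exist_ok=True)
    paths = [_write_tsv(iv, mdir / "meta_inverse_variance.tsv", index_label="probe_id"),
             _write_tsv(sz, mdir / "meta_sample_size.tsv", index_label="probe_id")]
    log.info("meta: %d probes pooled", int((~iv["unpooled"]).sum()))
    return paths


def _stage_panel(cfg: dict, outdir: Path) -> list[Path]:
    p = outdir / "ewas" / "discovery" / "results.tsv"
    if not p.exists():
        raise StageDependencyError("missing ewas outputs; run 'ewas' first")
    table = pd.read_csv(p, sep="\t", index_col=0)
    result = ewas_mod.EwasResult(table=table, lambda_=float("nan"), terms=[])
    inputs = _load_cohort_inputs(outdir, "discovery")
    manifest = pd.read_csv(outdir / "sim" / "discovery" / "manifest.tsv", sep="\t",
                           keep_default_na=False,
                           dtype={"chromosome": str, "gene": str, "control_class": str})
    panel = frailty_mod.select_panel(result, p_cut=cfg["panel"]["p_cut"],
                                     manifest=manifest)
    residuals = frailty_mod.residualize_panel(inputs["beta"], panel,
                                              inputs["covariates"])
    labels, _ = frailty_mod.hierarchical_cluster(residuals, k=2)
    assoc = frailty_mod.cluster_phenotype_association(labels, inputs["samples"])
    scores = frailty_mod.cumulative_score(residuals, panel)
    r, pval, n = frailty_mod.correlate_score_index(
        scores, inputs["samples"]["vacs_index"])

    pdir = outdir / "panel"
    pdir.mkdir(parents=True, exist_ok=True)
    paths = []
    pj = pdir / "panel.json"
    pj.write_text(json.dumps(
        {"probe_ids": panel.probe_ids,
         "weights": {k: float(v) for k, v in panel.weights.items()},
         "gene_map": panel.gene_map}, indent=1, sort_keys=True))
    paths.append(pj)
    scores.rename("score").to_frame().to_csv(pdir / "scores.csv", float_format=_FMT)
    paths.append(pdir / "scores.csv")
    cj = pdir / "clustering.json"
    cj.write_text(json.dumps(
        {"labels": {k: int(v) for k, v in labels.items()},
         "phenotype_association_p": {k: float(v) for k, v in assoc["p"].items()},
         "score_index": {"r": r, "p": pval, "n": n}}, indent=1, sort_keys=True))
    paths.append(cj)
    log.info("panel: %d probes, score-index r=%.3f (p=%.2g)", len(panel.probe_ids),
             r, pval)
    return paths


def _stage_predict(cfg: dict, outdir: Path) -> list[Path]:
    pj = outdir / "panel" / "panel.json"
    if not pj.exists():
        raise StageDependencyError("missing panel outputs; run 'panel' first")
    panel_info = json.loads(pj.read_text())
    pcfg = cfg["predict"]
    train = _load_cohort_inputs(outdir, "discovery")
    test = _load_cohort_inputs(outdir, "test")

    panel = frailty_mod.PanelModel(
        probe_ids=panel_info["probe_ids"],
        weights=pd.Series(panel_info["weights"]),
        gene_map=panel_info["gene_map"])
    rz = frailty_mod.Residualizer().fit(
        train["beta"].loc[panel.probe_ids], train["covariates"])
    Xtr = rz.transform(train["beta"].loc[panel.probe_ids], train["covariates"])
    Xte = rz.transform(test["beta"].loc[panel.probe_ids], test["covariates"])
    lab_tr = frailty_mod.define_frailty_labels(
        train["samples"]["vacs_index"], pcfg["high_cut"], pcfg["low_cut"])
    lab_te = frailty_mod.define_frailty_labels(
        test["samples"]["vacs_index"], pcfg["high_cut"], pcfg["low_cut"])

    out = {}
    for task in ("high", "low"):
        ytr, yte = getattr(lab_tr, task), getattr(lab_te, task)
        clf = frailty_mod.train_frailty_classifier(
            Xtr, ytr, folds=pcfg["folds"], seed=cfg["seed"])
        roc = frailty_mod.evaluate_roc(clf, Xte, yte, ci_reps=pcfg["ci_reps"],
                                       seed=cfg["seed"])
        null = frailty_mod.permutation_panel_null(
            train["beta"], test["beta"], train["covariates"], test["covariates"],
            ytr, yte, panel_size=len(panel.probe_ids),
            observed_panel=panel.probe_ids, B=pcfg["permutations"],
            seed=cfg["seed"])
        out[task] = {
            "auc": roc.auc, "ci": [roc.ci_lower, roc.ci_upper],
            "fixed_c_auc": null.auc, "permutation_p": null.permutation_p,
            "null_auc_mean": float(np.mean(null.null_aucs)),
        }
        log.info("predict[%s]: AUC=%.3f (%.3f-%.3f), perm p=%.4g", task,
                 roc.auc, roc.ci_lower, roc.ci_upper, null.permutation_p)
    fdir = outdir / "predict"
    fdir.mkdir(parents=True, exist_ok=True)
    p = fdir / "roc.json"
    p.write_text(json.dumps(out, indent=1, sort_keys=True))
    return [p]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "ewas": _stage_ewas,
    "dmr": _stage_dmr,
    "meta": _stage_meta,
    "panel": _stage_panel,
    "predict": _stage_predict,
}


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


def _summary(outdir: Path) -> dict:
    """Collect the pipeline-level summary from stage outputs on disk."""
    out: dict = {}
    for cohort in ("discovery", "replication"):
        p = outdir / "ewas" / cohort / "summary.json"
        if p.exists():
            s = json.loads(p.read_text())
            out[f"lambda_{cohort}"] = s["lambda"]
            out[f"n_significant_{cohort}"] = s["n_significant"]
    p = outdir / "dmr" / "dmrs.tsv"
    if p.exists():
        frame = pd.read_csv(p, sep="\t")
        out["n_dmr_candidates"] = int(len(frame))
        out["n_dmr_q05"] = int((frame["q"] < 0.05).sum()) if len(frame) else 0
    p = outdir / "panel" / "clustering.json"
    if p.exists():
        out["score_index"] = json.loads(p.read_text())["score_index"]
    p = outdir / "predict" / "roc.json"
    if p.exists():
        out["prediction"] = json.loads(p.read_text())
    return out


def run_pipeline(cfg: dict, outdir: str | Path, resume: bool = True) -> RunManifest:
    """Execute the enabled stages in dependency order.

    Completed stages (matching parameter key and intact output hashes) are
    skipped when ``resume``.  Outputs of each stage land under
    ``outdir/<stage-specific subdirectory>``; a ``run_manifest.json`` and a
    ``summary.json``/``summary.txt`` pair are written at the end.
    """
    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mpath = outdir / "run_manifest.json"
    manifest = RunManifest.load(mpath) if (resume and mpath.exists()) else RunManifest()

    enabled = [s for s in STAGES if s in cfg["stages"]]
    for stage in enabled:
        key = _params_key({"seed": cfg["seed"], "stage": stage,
                           "params": cfg.get(stage, {}),
                           "upstream": [manifest.stages.get(d, {}).get("key")
                                        for d in STAGE_DEPS[stage]]})
        if resume and _stage_complete(manifest, stage, key):
            log.info("%s: up to date, skipping", stage)
            continue
        log.info("running stage %s", stage)
        try:
            outputs = _STAGE_FUNCS[stage](cfg, outdir)
        except StageDependencyError:
            raise
        except Exception as exc:  # halt with the stage named
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest.record(stage, key, outputs, status="ok")
        manifest.save(mpath)

    summary = _summary(outdir)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    lines = [f"{k}: {json.dumps(v, sort_keys=True)}" for k, v in sorted(summary.items())]
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    manifest.save(mpath)
    return manifest
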