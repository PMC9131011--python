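"""End-to-end pipeline: ingest or simulate, filter, aggregate, diversity,
PERMANOVA, differential abundance, correlation screen, prediction.

Configuration is a plain-text ``key = value`` file (one pair per line,
``#`` comments) with explicit seeds for every stochastic stage, so each
random draw is auditable.  Each stage writes its output as TSV/JSON
through declared files only, and a JSON run manifest recording the
config, seeds, input digests, per-stage outputs and software version is
written last.  Stage failure aborts with the stage name; the partial
output is kept under a ``.partial`` suffix.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .tables import (
    FeatureTable,
    read_counts,
    read_taxonomy,
    read_metadata,
    write_counts,
    filter_by_prevalence,
    aggregate_to_rank,
    relative_abundance,
)
from .simulate import SimulationConfig, generate_cohort
from . import ecology, diffabund, association, prediction

log = logging.getLogger("pdbiome.pipeline")

STAGES = ["filter", "aggregate", "alpha", "beta", "permanova", "diffabund",
          "correlate", "predict"]

_DEFAULTS = {
    "rank": "genus",
    "prevalence_fraction": "0.10",
    "permutations": "999",
    "mc_samples": "128",
    "predict_variable": "carbohydrate_g",
    "n_estimators": "200",
    "correlate_covariates": "ccs,bdi,moca",
    "adjust_for": "age,sex,bmi",
    "skip": "",
    "seed": "0",
}


def read_config(path) -> dict[str, str]:
    """Parse a ``key = value`` configuration file."""
    cfg = dict(_DEFAULTS)
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        cfg[key.strip()] = value.strip()
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _bool(v: str) -> bool:
    return v.lower() in ("1", "true", "yes", "on")


def run_pipeline(config_path) -> dict:
    """Execute the configured stages in dependency order and return the
    run manifest (also written to ``<out_dir>/manifest.json``)."""
    cfg = read_config(config_path)
    out_dir = Path(cfg.get("out_dir", "pdbiome_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    skip = {s.strip() for s in cfg["skip"].split(",") if s.strip()}

    manifest: dict = {
        "config": cfg,
        "software_version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": {},
        "stages": {},
        "warnings": [],
    }

    tree = None
    if _bool(cfg.get("synthetic", "false")):
        sim = SimulationConfig(
            n_group_a=int(cfg.get("n_pd", 103)),
            n_group_b=int(cfg.get("n_hc", 81)),
            n_asv=int(cfg.get("n_asv", 300)),
            n_differential=int(cfg.get("n_differential", 10)),
            effect_log2=float(cfg.get("effect_log2", 1.0)),
            stratum_effect=_bool(cfg.get("stratum_effect", "false")),
            seed=seed,
        )
        cohort = generate_cohort(sim)
        paths = cohort.write(out_dir / "synthetic")
        counts, taxonomy, metadata, tree = (
            cohort.counts, cohort.taxonomy, cohort.metadata, cohort.tree
        )
        manifest["inputs"] = {k: str(v) for k, v in paths.items()}
    else:
        for key in ("counts", "taxonomy", "metadata"):
            if key not in cfg:
                raise ValueError(f"config must name {key!r} (or set synthetic = true)")
            p = Path(cfg[key])
            if not p.exists():
                raise FileNotFoundError(f"missing input {key!r}: {p}")
            manifest["inputs"][key] = f"{p} sha256:{_digest(p)}"
        counts = read_counts(cfg["counts"])
        taxonomy = read_taxonomy(cfg["taxonomy"])
        metadata = read_metadata(cfg["metadata"])
        if cfg.get("tree"):
            from skbio import TreeNode

            tree = TreeNode.read(cfg["tree"])
            manifest["inputs"]["tree"] = f"{cfg['tree']} sha256:{_digest(Path(cfg['tree']))}"

    rank = cfg["rank"]
    state: dict = {}

    def _run(stage: str, fn) -> None:
        if stage in skip:
            log.info("stage %s skipped by config", stage)
            manifest["stages"][stage] = {"status": "skipped", "reason": "config"}
            return
        t0 = time.time()
        try:
            outputs = fn()
        except Exception as exc:  # pragma: no cover - error path
            for p in out_dir.glob(f"{stage}*.tsv"):
                p.rename(p.with_suffix(p.suffix + ".partial"))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "status": "ok",
            "outputs": [str(p) for p in outputs],
            "seconds": round(time.time() - t0, 2),
        }
        log.info("stage %s done (%.1fs)", stage, time.time() - t0)

    def stage_filter():
        state["filtered"] = filter_by_prevalence(counts, float(cfg["prevalence_fraction"]))
        p = out_dir / "filter_counts.tsv"
        write_counts(state["filtered"], p)
        return [p]

    def stage_aggregate():
        state["ranked"] = aggregate_to_rank(state["filtered"], taxonomy, rank)
        p = out_dir / f"aggregate_{rank}.tsv"
        write_counts(state["ranked"], p)
        return [p]

    def stage_alpha():
        adf = ecology.alpha_diversity(state["filtered"])
        p = out_dir / "alpha_diversity.tsv"
        adf.rename_axis("sample_id").to_csv(p, sep="\t")
        return [p]

    def stage_beta():
        outs = []
        state["bc"] = ecology.bray_curtis(state["filtered"])
        p = out_dir / "beta_bray_curtis.tsv"
        pd.DataFrame(
            state["bc"].data, index=state["bc"].ids, columns=state["bc"].ids
        ).rename_axis("sample_id").to_csv(p, sep="\t")
        outs.append(p)
        if tree is not None:
            for weighted, name in ((False, "unweighted_unifrac"), (True, "weighted_unifrac")):
                dm = ecology.unifrac(state["filtered"], tree, weighted=weighted)
                q = out_dir / f"beta_{name}.tsv"
                pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).rename_axis(
                    "sample_id"
                ).to_csv(q, sep="\t")
                outs.append(q)
        else:
            manifest["warnings"].append("no tree provided: UniFrac skipped")
            log.warning("no tree provided: UniFrac skipped")
        ord_res = ecology.pcoa(state["bc"], n_axes=2)
        q = out_dir / "beta_pcoa.tsv"
        ord_res.coordinates.rename_axis("sample_id").to_csv(q, sep="\t")
        outs.append(q)
        return outs

    def stage_permanova():
        res = ecology.permanova(
            state["bc"],
            metadata.loc[state["bc"].ids, ["group"]],
            n_permutations=int(cfg["permutations"]),
            seed=seed,
        )
        p = out_dir / "permanova.json"
        p.write_text(json.dumps({
            "terms": res.terms,
            "pseudo_f": res.pseudo_f,
            "r_squared": res.r_squared,
            "p_value": res.p_value,
            "n_permutations": res.n_permutations,
        }, indent=2))
        return [p]

    def stage_diffabund():
        res = diffabund.test_features(
            state["ranked"], metadata, n_mc=int(cfg["mc_samples"]), seed=seed
        )
        p = out_dir / "diffabund.tsv"
        res.table.rename_axis("feature").to_csv(p, sep="\t")
        return [p]

    def stage_correlate():
        covs = [c.strip() for c in cfg["correlate_covariates"].split(",") if c.strip()]
        adjust = [c.strip() for c in cfg["adjust_for"].split(",") if c.strip()]
        res = association.spearman_screen(state["ranked"], metadata, covs, adjust_for=adjust)
        p = out_dir / "correlations.tsv"
        res.to_csv(p, sep="\t", index=False)
        return [p]

    def stage_predict():
        feats = relative_abundance(state["ranked"]).T
        labels = metadata.loc[feats.index, "group"]
        res = prediction.loocv_two_stage(
            feats, metadata, labels, cfg["predict_variable"],
            seed=seed, n_estimators=int(cfg["n_estimators"]),
        )
        _, single_auc = prediction.loocv_single(
            feats, labels, seed=seed, n_estimators=int(cfg["n_estimators"])
        )
        p = out_dir / "prediction.json"
        p.write_text(json.dumps({
            "variable": cfg["predict_variable"],
            "threshold": res.stump.threshold,
            "auc_two_stage": res.auc,
            "auc_single_stage": single_auc,
            "sensitivity": res.sensitivity,
            "specificity": res.specificity,
            "n_fallback_folds": res.n_fallback,
        }, indent=2))
        q = out_dir / "prediction_scores.tsv"
        res.scores.rename_axis("sample_id").to_csv(q, sep="\t")
        return [p, q]

    _run("filter", stage_filter)
    _run("aggregate", stage_aggregate)
    _run("alpha", stage_alpha)
    _run("beta", stage_beta)
    _run("permanova", stage_permanova)
    _run("diffabund", stage_diffabund)
    _run("correlate", stage_correlate)
    _run("predict", stage_predict)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
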