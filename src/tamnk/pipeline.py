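"""End-to-end pipeline: simulate (or ingest) → QC → enrich → score → LR → survive.

A single YAML config drives all stages; every output is a TSV/CSV/JSON
file under the output directory, and a manifest records the package
version, seed and per-stage parameters.  Outputs carry no timestamps,
so a fixed config and seed reproduce byte-identical files.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import GeneSetScorer
from .io import (
    builtin_gene_sets,
    builtin_lr_pairs,
    read_dense_csv,
    read_survival_table,
    write_dense_csv,
    write_survival_table,
)
from .matrix import ValidationError
from .qc import DoubletFlagger, LogNormalizer, QCFilter
from .scoring import PolarizationAnnotator, TamNkScorer, lr_interaction
from .simulate import CohortConfig, SimulationConfig, simulate_cohort, simulate_single_cell
from .survival import stratified_analysis

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "enrich", "score", "lr", "survive")


def default_config() -> dict:
    """The bundled demo configuration (fully synthetic inputs)."""
    text = resources.files("tamnk").joinpath("data/demo_config.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: str | Path | None = None) -> dict:
    if path is None:
        return default_config()
    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_config(cfg: dict) -> None:
    """Check cross-stage requirements before any stage runs."""
    known = set(STAGES) | {"seed"}
    unknown = set(cfg) - known
    if unknown:
        raise ValidationError(f"unknown config sections: {sorted(unknown)}")
    has_sim = "simulate" in cfg
    if not has_sim:
        inputs = cfg.get("qc", {}).get("counts_csv")
        if "qc" in cfg and not inputs:
            raise ValidationError("qc stage needs counts_csv when simulate is absent")
        if "survive" in cfg and not cfg.get("survive", {}).get("survival_tsv"):
            raise ValidationError("survive stage needs survival_tsv when simulate is absent")
        if "survive" in cfg and not cfg.get("survive", {}).get("expression_csv"):
            raise ValidationError("survive stage needs expression_csv when simulate is absent")
    # construct simulation configs eagerly so invalid parameters fail early
    if has_sim:
        sim = cfg["simulate"]
        SimulationConfig(**sim.get("single_cell", {})).validate()
        CohortConfig(**sim.get("cohort", {})).validate()


def run_all(cfg: dict, outdir: str | Path, seed: int | None = None) -> dict:
    """Execute every configured stage; returns the manifest dict.

    ``seed`` overrides the config seed for every stochastic stage.
    """
    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0)) if seed is None else int(seed)
    manifest: dict[str, Any] = {
        "package": "tamnk",
        "version": __version__,
        "seed": seed,
        "stages": [],
    }

    def record(stage: str, params: dict, outputs: list[str]) -> None:
        manifest["stages"].append({"name": stage, "params": params, "outputs": outputs})

    # -- simulate / ingest ---------------------------------------------------
    sim_cfg = cfg.get("simulate", {})
    if "simulate" in cfg:
        sc_cfg = SimulationConfig(**{**sim_cfg.get("single_cell", {}), "seed": seed})
        cohort_cfg = CohortConfig(**{**sim_cfg.get("cohort", {}), "seed": seed + 1})
        counts, labels = simulate_single_cell(sc_cfg)
        cohort, records, true_group = simulate_cohort(cohort_cfg)
        write_dense_csv(counts, outdir / "sc_counts.csv")
        pd.DataFrame({"cell_id": counts.obs_ids, "true_label": labels}).to_csv(
            outdir / "sc_true_labels.tsv", sep="\t", index=False
        )
        write_dense_csv(cohort, outdir / "cohort_expression.csv")
        write_survival_table(records, outdir / "cohort_survival.tsv")
        pd.DataFrame({"sample_id": cohort.obs_ids, "true_group": true_group}).to_csv(
            outdir / "cohort_true_groups.tsv", sep="\t", index=False
        )
        record(
            "simulate",
            {"single_cell": vars(sc_cfg), "cohort": vars(cohort_cfg)},
            ["sc_counts.csv", "sc_true_labels.tsv", "cohort_expression.csv",
             "cohort_survival.tsv", "cohort_true_groups.tsv"],
        )
    else:
        counts = read_dense_csv(cfg["qc"]["counts_csv"], layer_tag="counts")
        labels = None
        cohort = read_dense_csv(cfg["survive"]["expression_csv"], layer_tag="lognorm")
        records = read_survival_table(cfg["survive"]["survival_tsv"])
        record("simulate", {"mode": "ingest"}, [])

    # -- qc ------------------------------------------------------------------
    qc_cfg = cfg.get("qc", {})
    qc = QCFilter(
        min_genes=qc_cfg.get("min_genes", 500),
        max_genes=qc_cfg.get("max_genes", 50000),
        max_umi=qc_cfg.get("max_umi", 30000),
        max_pct_mito=qc_cfg.get("max_pct_mito", 20.0),
    )
    qc.fit(counts)
    flagger = DoubletFlagger(z_threshold=qc_cfg.get("doublet_z_threshold", 2.0))
    doublet_flags = flagger.fit_predict(counts)
    report = qc.metrics_.copy()
    report["kept"] = qc.kept_mask_
    report["doublet"] = doublet_flags
    report.to_csv(outdir / "qc_report.tsv", sep="\t")
    keep_idx = np.flatnonzero(qc.kept_mask_ & ~doublet_flags)
    filtered = counts.subset_obs(keep_idx)
    lognorm = LogNormalizer(scale=qc_cfg.get("scale", 10000.0)).transform(filtered)
    write_dense_csv(lognorm, outdir / "sc_lognorm.csv")
    if labels is not None:
        labels = np.asarray(labels)[keep_idx]
    record(
        "qc",
        {**{k: v for k, v in qc.get_params().items() if k != "mito_prefixes"},
         "scale": qc_cfg.get("scale", 10000.0),
         "n_kept": int(len(keep_idx)), "n_input": counts.n_obs},
        ["qc_report.tsv", "sc_lognorm.csv"],
    )

    # -- enrich --------------------------------------------------------------
    en_cfg = cfg.get("enrich", {})
    cell_scorer = GeneSetScorer(
        method=en_cfg.get("cell_method", "ssgsea"),
        kernel=en_cfg.get("cell_kernel", "none"),
        tau=en_cfg.get("tau"),
        es_mode=en_cfg.get("es_mode", "diff"),
    )
    cell_scores = cell_scorer.transform(lognorm)
    cell_scores.to_frame().to_csv(outdir / "sc_enrichment.tsv", sep="\t")
    patient_scorer = GeneSetScorer(method=en_cfg.get("patient_method", "zscore"))
    patient_scores = patient_scorer.transform(cohort)
    patient_scores.to_frame().to_csv(outdir / "cohort_enrichment.tsv", sep="\t")
    record(
        "enrich",
        {"cell_method": cell_scorer.method, "cell_kernel": cell_scorer.kernel,
         "patient_method": patient_scorer.method},
        ["sc_enrichment.tsv", "cohort_enrichment.tsv"],
    )

    # -- score ---------------------------------------------------------------
    sc_score_cfg = cfg.get("score", {})
    scorer = TamNkScorer(mode=sc_score_cfg.get("mode", "difference"))
    cell_tamnk = scorer.transform(cell_scores)
    cell_tamnk.to_csv(outdir / "sc_tamnk_scores.tsv", sep="\t")
    patient_tamnk = scorer.transform(patient_scores)
    patient_tamnk.to_csv(outdir / "cohort_tamnk_scores.tsv", sep="\t")
    annot = PolarizationAnnotator(margin=sc_score_cfg.get("margin", 0.0))
    polar = annot.predict(lognorm)
    pd.DataFrame(
        {"cell_id": lognorm.obs_ids, "polarization": polar}
    ).to_csv(outdir / "sc_polarization.tsv", sep="\t", index=False)
    record(
        "score",
        {"mode": scorer.mode, "margin": annot.margin},
        ["sc_tamnk_scores.tsv", "cohort_tamnk_scores.tsv", "sc_polarization.tsv"],
    )

    # -- lr ------------------------------------------------------------------
    lr_cfg = cfg.get("lr", {})
    lr_outputs: list[str] = []
    if labels is not None:
        sender = lr_cfg.get("sender", "M2")
        receiver = lr_cfg.get("receiver", "NK_LIKE")
        results = lr_interaction(
            lognorm, labels, builtin_lr_pairs(), sender, receiver,
            combine=lr_cfg.get("combine", "mean"),
        )
        pd.DataFrame(
            [(r.pair.name, r.sender_type, r.receiver_type, r.score) for r in results],
            columns=["pair", "sender", "receiver", "score"],
        ).to_csv(outdir / "lr_scores.tsv", sep="\t", index=False)
        lr_outputs = ["lr_scores.tsv"]
        record("lr", {"sender": sender, "receiver": receiver,
                      "combine": lr_cfg.get("combine", "mean")}, lr_outputs)
    else:
        record("lr", {"skipped": "no cell-type labels available"}, [])

    # -- survive -------------------------------------------------------------
    sv_cfg = cfg.get("survive", {})
    score_map = {str(i): float(v) for i, v in patient_tamnk["score"].items()}
    report_obj = stratified_analysis(
        score_map,
        records,
        q_low=sv_cfg.get("q_low", 0.1),
        q_high=sv_cfg.get("q_high", 0.9),
        n_perm=sv_cfg.get("n_perm", 1000),
        seed=seed + 2,
    )
    (outdir / "survival_report.json").write_text(
        json.dumps(report_obj.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    for name, curve in (("low", report_obj.km_low), ("high", report_obj.km_high)):
        pd.DataFrame(
            {"time": curve.times, "survival": curve.survival,
             "at_risk": curve.at_risk, "n_events": curve.n_events}
        ).to_csv(outdir / f"km_{name}.tsv", sep="\t", index=False)
    record(
        "survive",
        {"q_low": sv_cfg.get("q_low", 0.1), "q_high": sv_cfg.get("q_high", 0.9),
         "n_perm": sv_cfg.get("n_perm", 1000)},
        ["survival_report.json", "km_low.tsv", "km_high.tsv"],
    )

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
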