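"""End-to-end orchestration: QC -> ISC -> controls -> IS-RSA -> summaries.

One run consumes one time-course set, one behavioral table and (optionally)
a node-to-network map, and writes a per-(node, model) results TSV, a QC
report TSV, a JSON run summary and a plain-text log.  All result files are
reproducible bit-for-bit from (config, seed, inputs); only the log carries
wall-clock timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .inference import (
    familywise_count_test,
    isc_fit_correlation,
    model_comparison,
    network_enrichment,
    run_all_nodes,
    split_half,
)
from .io import read_behavior, read_network_map, read_timecourses
from .isc import mean_isc, pairwise_isc
from .qc import qc_filter
from .similarity import control_design

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis described by ``config``; return the summary.

    Stages: QC filter -> per-node pairwise ISC -> nuisance control design
    -> per-node permutation IS-RSA for each requested model (one shared
    permutation stream) with Holm-Bonferroni correction -> familywise
    count test per model -> AnnaK-vs-NN comparison (when both ran) ->
    optional split-half consistency -> ISC-vs-fit correlation ->
    optional network enrichment.  Any stage failure aborts with the stage
    named in the exception.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("isrsa")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    t0 = time.perf_counter()
    stage = "setup"
    try:
        logger.info("isrsa %s  seed=%d  config_hash=%s", __version__, config.seed, _config_hash(config))
        rng = np.random.default_rng(config.seed)

        stage = "load-behavior"
        behavior = read_behavior(config.behavior, config.columns, config.score_column)
        if config.include:
            behavior = behavior[behavior["subject_id"].isin(config.include)].reset_index(drop=True)
        if config.exclude:
            behavior = behavior[~behavior["subject_id"].isin(config.exclude)].reset_index(drop=True)

        stage = "qc"
        behavior, qc_report = qc_filter(
            behavior, mean_fd=config.qc_mean_fd, max_displacement=config.qc_max_displacement
        )
        qc_report.table.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        logger.info("QC: retained %d, excluded %d", qc_report.n_retained, qc_report.n_excluded)
        if qc_report.n_retained < 3:
            raise ValueError(f"only {qc_report.n_retained} subjects survive QC")

        stage = "load-timecourses"
        tc = read_timecourses(
            config.timecourses, behavior["subject_id"].tolist(), transpose=config.transpose
        )

        stage = "isc"
        isc_matrices = pairwise_isc(tc)
        mean_isc_values = np.array([mean_isc(m) for m in isc_matrices])
        pd.DataFrame({"node_id": tc.node_ids, "mean_isc": mean_isc_values}).to_csv(
            outdir / "mean_isc.tsv", sep="\t", index=False
        )

        stage = "control-design"
        design = control_design(behavior)
        logger.info("control design columns: %s", design.names)

        stage = "isrsa"
        scores = behavior["score"].to_numpy(dtype=float)
        result = run_all_nodes(
            isc_matrices, tc.node_ids, scores, list(config.models), design,
            config.n_perm, rng, alpha=config.alpha,
        )
        result.table.to_csv(outdir / "results.tsv", sep="\t", index=False, float_format="%.10g")

        stage = "familywise"
        familywise = {}
        for m in config.models:
            sub = result.table[result.table["model"] == m]
            fw = familywise_count_test(
                int(sub["sig_uncorrected"].sum()), len(tc.node_ids), config.alpha,
                config.familywise_reps, rng,
            )
            familywise[m] = {
                "observed_count": fw.observed_count,
                "n_nodes": len(tc.node_ids),
                "p_familywise": fw.p_familywise,
            }

        stage = "model-comparison"
        comparison = None
        if {"annak", "nn"} <= set(config.models):
            mc = model_comparison(result, "annak", "nn")
            comparison = {
                "mean_z_diff": mc.mean_z_diff,
                "rho_scale_diff": mc.rho_scale_diff,
                "p_two_sided": mc.p_two_sided,
            }

        stage = "split-half"
        split = None
        if config.split_half:
            split = {}
            for m in config.models:
                sh = split_half(tc, behavior, m, rng)
                split[m] = {"consistency_r": sh.consistency_r}

        stage = "isc-fit-correlation"
        fit_corr = {m: isc_fit_correlation(mean_isc_values, result.rho(m)) for m in config.models}

        stage = "network-enrichment"
        enrichment = None
        if config.network_map is not None:
            net = read_network_map(config.network_map)
            enrichment = {}
            for m in config.models:
                sub = result.table[result.table["model"] == m]
                flags = pd.Series(sub["sig_corrected"].to_numpy(), index=sub["node_id"])
                tab = network_enrichment(flags, net)
                tab.to_csv(outdir / f"enrichment_{m}.tsv", sep="\t", index=False)
                enrichment[m] = tab.to_dict(orient="records")

        stage = "summary"
        summary = {
            "software": {"name": "isrsa", "version": __version__},
            "seed": config.seed,
            "config": asdict(config),
            "config_hash": _config_hash(config),
            "n_subjects": int(tc.n_subjects),
            "n_nodes": len(tc.node_ids),
            "qc": {"retained": qc_report.n_retained, "excluded": qc_report.n_excluded},
            "mean_isc_overall": float(mean_isc_values.mean()),
            "familywise": familywise,
            "model_comparison": comparison,
            "split_half": split,
            "isc_fit_correlation": fit_corr,
            "significant_corrected": {
                m: int(result.table.loc[result.table["model"] == m, "sig_corrected"].sum())
                for m in config.models
            },
        }
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=_jsonable) + "\n"
        )
        logger.info("done in %.2f s", time.perf_counter() - t0)
        return summary
    except Exception as err:
        logger.error("stage %r failed: %s", stage, err)
        # flag any partial outputs so a half-written directory is never
        # mistaken for a completed run
        (outdir / "FAILED").write_text(f"pipeline stage {stage!r} failed: {err}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    finally:
        root.removeHandler(handler)
        handler.close()
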