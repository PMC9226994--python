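"""End-to-end run: simulate (or ingest) -> fit -> score -> evaluate -> diff
-> longitudinal, with a run manifest recording seeds, digests, timings and
every warning surfaced along the way."""

from __future__ import annotations

import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import io
from .classify import evaluate_scores
from .config import CohortConfig
from .diffstats import subset_ttests
from .errors import ImmunosigError
from .longitudinal import compute_associations, cohort_trajectory_summary
from .profiles import split_by_group
from .signature import fit_signature_model, score_cohort
from .simulate import simulate_longitudinal, simulate_percentages


def run_pipeline(
    config: CohortConfig,
    outdir,
    table_path=None,
    n_boot: int = 2000,
    correction: str = "none",
) -> dict:
    """Run every stage into ``outdir``; returns a summary dict.

    When ``table_path`` is given the cohort is read from it instead of
    simulated (the simulate stage is skipped).  Any stage failure aborts
    with the stage name attached and a partial manifest on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    timings: dict[str, float] = {}
    inputs: dict[str, str] = {}
    summary: dict = {}
    manifest_path = outdir / "manifest.json"

    def _stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except ImmunosigError as exc:
            warnings.append(f"stage {name} failed: {exc}")
            manifest = io.build_manifest(
                "run", config.to_dict(), inputs, {"master": config.seed}, warnings
            )
            manifest["timings_s"] = timings
            manifest["failed_stage"] = name
            io.write_manifest(manifest, manifest_path)
            raise type(exc)(f"stage {name!r}: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 4)
        return result

    if table_path is not None:
        profiles = _stage("ingest", lambda: io.read_subject_table(table_path))
        inputs[str(table_path)] = io.file_digest(table_path)
    else:
        profiles = _stage("simulate", lambda: simulate_percentages(config))
    io.write_subject_table(profiles, outdir / "cohort.csv")

    def _fit():
        model, w = fit_signature_model(profiles)
        warnings.extend(w)
        return model

    model = _stage("fit", _fit)
    io.write_model(model, outdir / "model.json")

    results = _stage("score", lambda: score_cohort(profiles, model))
    io.write_scores(results, outdir / "scores.csv")
    io.write_rank_matrix(results, outdir / "ranks.csv")

    sle, hc = split_by_group(profiles)
    s_scores = [r.score for r in results if r.group == "SLE"]
    h_scores = [r.score for r in results if r.group == "HC"]
    roc = _stage(
        "evaluate",
        lambda: evaluate_scores(s_scores, h_scores, n_boot=n_boot, seed=config.seed),
    )
    pd.DataFrame(roc.points, columns=["threshold", "sensitivity", "specificity"]).to_csv(
        outdir / "roc_points.csv", index=False
    )

    def _diff():
        res, w = subset_ttests(profiles, correction=correction)
        warnings.extend(w)
        return res

    tests = _stage("diff", _diff)
    pd.DataFrame([asdict(t) for t in tests]).to_csv(outdir / "diff.csv", index=False)

    def _longitudinal():
        records = simulate_longitudinal(config)
        io.write_longitudinal_table(records, outdir / "longitudinal.csv")
        assoc, w = compute_associations(records)
        warnings.extend(w)
        return assoc

    associations = _stage("longitudinal", _longitudinal)
    pd.DataFrame([asdict(a) for a in associations]).to_csv(
        outdir / "trajectories.csv", index=False
    )

    summary = {
        "n_subjects": len(profiles),
        "n_sle": len(sle),
        "n_hc": len(hc),
        "n_subsets_modelled": len(model.subsets),
        "n_subsets_skipped": len(model.skipped),
        "auc": roc.auc,
        "threshold": roc.chosen_threshold,
        "sensitivity": roc.sensitivity,
        "specificity": roc.specificity,
        "auc_ci": [roc.ci_low, roc.ci_high],
        "n_significant_subsets": sum(t.significant for t in tests),
        "trajectory_tally": cohort_trajectory_summary(associations),
    }
    manifest = io.build_manifest(
        "run", config.to_dict(), inputs, {"master": config.seed}, warnings
    )
    manifest["timings_s"] = timings
    manifest["summary"] = summary
    io.write_manifest(manifest, manifest_path)
    return summary
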