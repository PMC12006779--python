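"""End-to-end orchestration: synth -> qc -> features -> analyze -> report.

One global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence(seed).generate_state``, so each stage is
individually reproducible when rerun in isolation. The run manifest
records the config snapshot, seeds, SHA-256 digests of every output
file and the participant accounting (in / excluded at the rate step /
excluded with no valid test / analyzed), which must always reconcile.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import features as feats
from . import qc as qcmod
from . import stats as statsmod
from . import synth
from .types import SchemaError, TESTS

log = logging.getLogger(__name__)

MANIFEST_NAME = "manifest.json"
FAILURE_MARKER = "FAILED"


def stage_seeds(seed: int, n: int = 2) -> list[int]:
    """Child seeds for the pipeline stages (kept below 2**31)."""
    state = np.random.SeedSequence(int(seed)).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_config(config: dict) -> tuple[synth.SimulationConfig,
                                           statsmod.AnalysisConfig, int]:
    """Validate the run config document before any compute starts."""
    known = {"simulation", "analysis", "seed"}
    unknown = set(config) - known
    if unknown:
        raise SchemaError(f"unknown config sections: {sorted(unknown)}")
    seed = int(config.get("seed", 0))
    synth_seed, analysis_seed = stage_seeds(seed)
    sim_dict = dict(config.get("simulation", {}))
    sim_dict.setdefault("seed", synth_seed)
    ana_dict = dict(config.get("analysis", {}))
    ana_dict.setdefault("seed", analysis_seed)
    return (synth.SimulationConfig.from_dict(sim_dict),
            statsmod.AnalysisConfig.from_dict(ana_dict), seed)


# ---------------------------------------------------------------------------
# stage helpers (shared by the pipeline and the CLI subcommands)
# ---------------------------------------------------------------------------

def qc_sessions(sessions, thresholds: Optional[qcmod.QCThresholds] = None
                ) -> pd.DataFrame:
    """QC verdict per session, with schema violations reported not fatal."""
    thresholds = thresholds or qcmod.QCThresholds()
    rows = []
    for s in sessions:
        try:
            res = qcmod.evaluate_session(s, thresholds)
        except SchemaError as exc:
            log.warning("session %s excluded: %s", s.session_id, exc)
            rows.append({"session_id": s.session_id,
                         "participant_id": s.participant_id,
                         "test_type": s.test_type,
                         "run_index": s.run_index, "rate_ok": False,
                         "flags": "schema_error", "valid": False})
            continue
        rows.append({"session_id": s.session_id,
                     "participant_id": s.participant_id,
                     "test_type": s.test_type, "run_index": s.run_index,
                     "rate_ok": res.rate_ok,
                     "flags": ";".join(sorted(res.flags)),
                     "valid": res.valid})
    return pd.DataFrame(rows)


def extract_features(sessions, qc_table: pd.DataFrame) -> pd.DataFrame:
    """Session-level feature table; invalid sessions keep a NaN value."""
    validity = qc_table.set_index("session_id")["valid"]
    rows = []
    for s in sessions:
        valid = bool(validity.get(s.session_id, False))
        row = {"participant_id": s.participant_id,
               "session_id": s.session_id, "test_type": s.test_type,
               "run_index": s.run_index,
               "feature_name": feats.FEATURE_NAME[s.test_type],
               "valid": valid, "value": np.nan}
        if valid:
            row["value"] = feats.extract(s, None).value
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: dict, outdir) -> dict:
    """Execute every stage under one seed; returns the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / FAILURE_MARKER
    sim_config, ana_config, seed = validate_config(config)
    started = time.time()
    stage = "synth"
    try:
        cohort = synth.generate_cohort(sim_config)
        sessions = synth.generate_sessions(cohort, sim_config)
        synth.write_cohort_csv(cohort, outdir / "cohort.csv")
        synth.write_sessions_jsonl(sessions, outdir / "sessions.jsonl")

        stage = "qc"
        qc_table = qc_sessions(sessions)
        qc_table.to_csv(outdir / "qc_results.csv", index=False)
        summary = qcmod.summarize_validity(
            [qcmod.QCResult(r.session_id, r.test_type, bool(r.rate_ok), None,
                            frozenset(r.flags.split(";")) if r.flags
                            else frozenset())
             for r in qc_table.itertuples()])
        summary_df = summary["per_test"].copy()
        summary_df.loc[len(summary_df)] = {
            "test_type": "ALL_RATE_CHECK", "valid": summary["rate_ok"],
            "total": summary["total"],
            "percent_valid": summary["rate_ok_percent"]}
        summary_df.to_csv(outdir / "qc_summary.csv", index=False)

        stage = "features"
        feature_table = extract_features(sessions, qc_table)
        feature_table.to_csv(outdir / "features.csv", index=False)

        stage = "analyze"
        selected = statsmod.select_first_valid(feature_table)
        cohort_df = synth.cohort_to_frame(cohort)
        adjusted = statsmod.adjust_covariates(selected, cohort_df,
                                              ana_config)
        comparisons = statsmod.run_equivalence(adjusted, cohort_df,
                                               ana_config)
        comparisons.to_csv(outdir / "comparisons.csv", index=False)
        screen = statsmod.screen_size_comparison(adjusted, cohort_df,
                                                 ana_config)
        screen.to_csv(outdir / "screen_size.csv", index=False)
    except Exception as exc:
        marker.write_text(f"stage={stage}\nerror={exc}\n")
        raise

    # participant accounting: all-sessions-rate-fail -> rate exclusion;
    # otherwise no analyzable feature -> no-valid-test exclusion
    per_pid = qc_table.groupby("participant_id")["rate_ok"].any()
    excluded_rate = sorted(per_pid[~per_pid].index)
    analyzed_ids = set(selected.participant_id.unique())
    excluded_no_valid = sorted(set(per_pid[per_pid].index) - analyzed_ids)
    n_in = int(cohort_df.participant_id.nunique())
    counts = {
        "participants_in": n_in,
        "excluded_rate": len(excluded_rate),
        "excluded_no_valid_test": len(excluded_no_valid),
        "analyzed": n_in - len(excluded_rate) - len(excluded_no_valid),
    }
    assert counts["analyzed"] == len(analyzed_ids)

    manifest = {
        "config": config,
        "seed": seed,
        "stage_seeds": {"synth": sim_config.seed,
                        "analysis": ana_config.seed},
        "counts": counts,
        "digests": {p.name: _sha256(p) for p in sorted(outdir.iterdir())
                    if p.is_file() and p.name != MANIFEST_NAME},
        "started": started,
        "finished": time.time(),
    }
    with open(outdir / MANIFEST_NAME, "w") as fh:
        json.dump(manifest, fh, indent=2)
    if marker.exists():
        marker.unlink()
    return manifest


# ---------------------------------------------------------------------------
# table rendering
# ---------------------------------------------------------------------------

def _fmt(value: float, decimals: int) -> str:
    """Fixed-decimal formatting with round-half-even."""
    return f"{round(float(value), decimals):.{decimals}f}"


def render_tables(comparisons: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-category report tables with the publication rounding rules.

    Means and SDs to one decimal, effect sizes to two, percent
    differences to one; p-values to three. Empty categories are omitted
    with a log notice.
    """
    if comparisons.empty:
        raise SchemaError("no comparisons to render")
    out = {}
    for category in comparisons.category.unique():
        sub = comparisons[comparisons.category == category]
        if sub.empty:
            log.info("category %s empty; omitted", category)
            continue
        rows = []
        for r in sub.itertuples():
            rows.append({
                "test": r.test_type,
                "subgroup": r.subgroup,
                "n": int(r.n_subgroup),
                "mean (SD)": f"{_fmt(r.mean_subgroup, 1)} "
                             f"({_fmt(r.sd_subgroup, 1)})",
                "reference mean (SD)": f"{_fmt(r.mean_reference, 1)} "
                                       f"({_fmt(r.sd_reference, 1)})",
                "absolute difference": _fmt(r.absolute_difference, 1),
                "percent difference": _fmt(r.percent_difference, 1),
                "effect size": _fmt(r.effect_size, 2),
                "95% CI": f"{_fmt(r.ci_low, 1)}-{_fmt(r.ci_high, 1)}",
                "p unadjusted": _fmt(r.p_unadjusted, 3),
                "p adjusted": _fmt(r.p_adjusted, 3),
            })
        out[category] = pd.DataFrame(rows)
    return out
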