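"""End-to-end orchestration: ingest/simulate -> features -> EDA outcomes ->
inference -> report.

All analysis constants (specific-response threshold 0.05 uS, 1.5 s
post-gesture pad, 1.5 s quote tolerance, >= 2 participants for resonance,
forest size/mtry) are surfaced in :class:`PipelineConfig` with the study
values as defaults, and the resolved configuration is embedded in every run
report for provenance.  Runs are reproducible: the same configuration and
seed give byte-identical JSON results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import eda as eda_mod
from . import io as io_mod
from .corpus import validate_referential_integrity
from .eda import CoverageError
from .features import build_feature_table
from .inference import (
    fit_arousal,
    fit_crescendo,
    fit_resonance_forest,
)
from .simulate import SimConfig, SimRecording, simulate_corpus

log = logging.getLogger("resogest")

__all__ = ["PipelineConfig", "run_pipeline", "load_config",
           "write_simulated_corpus", "load_corpus"]


@dataclass
class PipelineConfig:
    """Resolved settings for one pipeline run."""

    sim: SimConfig | None = None
    input_dirs: list[str] = field(default_factory=list)
    threshold: float = eda_mod.SPECIFIC_THRESHOLD
    latency_pad: float = eda_mod.LATENCY_PAD
    quote_tolerance: float = 1.5
    resonance_min: int = eda_mod.RESONANCE_MIN
    require_narrator: bool = False
    forest_trees: int = 1500
    forest_mtry: int = 3
    importance_repeats: int = 10
    seed: int = 0
    outdir: str = "resogest_out"
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.latency_pad < 0:
            raise ValueError("latency_pad must be >= 0")
        if self.resonance_min < 1:
            raise ValueError("resonance_min must be >= 1")
        if self.sim is None and not self.input_dirs:
            raise ValueError("config needs either `simulate` or `inputs`")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def load_config(path) -> PipelineConfig:
    """Read a YAML pipeline configuration.

    Top-level keys mirror :class:`PipelineConfig` fields; the ``simulate``
    mapping (if present) populates :class:`~resogest.simulate.SimConfig`,
    and ``inputs`` lists tier directories of recorded data.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("simulate", None)
    inputs = raw.pop("inputs", [])
    sim = None
    if sim_raw is not None:
        if "gestures_per_story" in sim_raw:
            sim_raw["gestures_per_story"] = tuple(
                sim_raw["gestures_per_story"]
            )
        for key in ("scr_amplitude_range", "latency_range",
                    "gesture_gap_range"):
            if key in sim_raw:
                sim_raw[key] = tuple(sim_raw[key])
        sim = SimConfig(**sim_raw)
    return PipelineConfig(sim=sim, input_dirs=list(inputs), **raw)


def write_simulated_corpus(recs: list[SimRecording], outdir) -> list[Path]:
    """Write each simulated recording as a tier directory + EDA CSVs +
    ground-truth JSON; returns the directories written."""
    outdir = Path(outdir)
    dirs = []
    for rec in recs:
        d = outdir / rec.recording.id
        io_mod.write_annotations(
            d, rec.recording, rec.stories, rec.gestures, rec.ipus,
            rec.quotes,
        )
        for pid, trace in rec.traces.items():
            io_mod.write_eda(trace, d / f"eda_{pid}.csv")
        with open(d / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(rec.truth.to_dict(), fh, indent=1, sort_keys=True)
        dirs.append(d)
    return dirs


def load_corpus(input_dirs) -> list[SimRecording]:
    """Load tier directories (with ``eda_<participant>.csv`` files) into the
    same bundles the simulator produces (without ground truth)."""
    out = []
    for d in map(Path, input_dirs):
        recording = io_mod.read_recording(d)
        stories, gestures, ipus, quotes = io_mod.read_annotations(
            d, "tabular"
        )
        validate_referential_integrity(
            recording, stories, gestures, ipus, quotes
        )
        traces = {}
        for p in recording.participants:
            traces[p.id] = io_mod.read_eda(d / f"eda_{p.id}.csv")
        out.append(
            SimRecording(
                recording=recording, stories=stories, gestures=gestures,
                ipus=ipus, quotes=quotes, traces=traces, truth=None,
            )
        )
    return out


def _results_payload(cres, arous, forest, importance) -> dict:
    return {
        "crescendo": {
            "fe_params": cres.fe_params.to_dict(),
            "bse": cres.bse.to_dict(),
            "lrt": None if cres.lrt is None else {
                "statistic": cres.lrt.statistic,
                "df": cres.lrt.df,
                "pvalue": cres.lrt.pvalue,
                "full": cres.lrt.full_desc,
                "null": cres.lrt.null_desc,
            },
            "pseudo_r2_conditional": cres.pseudo_r2_conditional,
            "frac_positive_slope": cres.frac_positive_slope,
            "random_structure": cres.random_structure,
            "nobs": cres.nobs,
            "n_groups": cres.n_groups,
        },
        "arousal": {
            "fe_params": arous.fe_params.to_dict(),
            "bse": arous.bse.to_dict(),
            "sigmas": arous.sigmas.to_dict(),
            "lrt": {
                "statistic": arous.lrt.statistic,
                "df": arous.lrt.df,
                "pvalue": arous.lrt.pvalue,
            },
            "pseudo_r2_conditional": arous.pseudo_r2_conditional,
            "nobs": arous.nobs,
        },
        "forest": {
            "n_trees": forest.n_trees,
            "mtry": forest.mtry,
            "oob_accuracy": forest.oob_accuracy,
            "baseline_rate": forest.baseline_rate,
            "binom_pvalue": forest.binom_pvalue,
            "r2_traditional": forest.r2_traditional,
            "r2_mcfadden": forest.r2_mcfadden,
            "importance": importance.to_dict(orient="records"),
            "importance_note": (
                "OOB permutation importance (mean decrease in accuracy); "
                "not party-style conditional importance"
            ),
        },
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages and write artifacts under ``cfg.outdir``.

    Returns the run report (also written as ``results.json``).  Every stage
    logs record counts; gestures whose EDA windows have no trace coverage
    are excluded and listed with a reason in the report.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.sim is not None:
        recs = simulate_corpus(cfg.sim)
        write_simulated_corpus(recs, outdir / "corpus")
        log.info("simulated %d recordings", len(recs))
    else:
        recs = load_corpus(cfg.input_dirs)
        log.info("loaded %d recordings", len(recs))

    tables = []
    resp_tables = []
    exclusions: list[dict] = []
    n_gestures_in = 0
    for rec in recs:
        n_gestures_in += len(rec.gestures)
        feats = build_feature_table(
            rec.recording, rec.stories, rec.gestures, rec.ipus, rec.quotes,
            quote_tolerance=cfg.quote_tolerance,
        )
        # exclude gestures without any EDA coverage, with a reason
        keep_ids = []
        for g in rec.gestures:
            try:
                for pid in rec.traces:
                    eda_mod.extract_window(
                        g, rec.traces[pid], cfg.latency_pad
                    )
                keep_ids.append(g.id)
            except CoverageError as exc:
                exclusions.append(
                    {"gesture_id": g.id, "reason": str(exc)}
                )
        feats = feats[feats["gesture_id"].isin(keep_ids)]
        kept = [g for g in rec.gestures if g.id in set(keep_ids)]
        feats = eda_mod.append_eda_outcomes(
            feats, kept, rec.traces,
            threshold=cfg.threshold, latency_pad=cfg.latency_pad,
            resonance_min=cfg.resonance_min,
            require_narrator=cfg.require_narrator,
        )
        resp = eda_mod.build_response_table(
            feats, kept, rec.traces,
            threshold=cfg.threshold, latency_pad=cfg.latency_pad,
        )
        log.info(
            "recording %s: %d gestures in, %d in table, %d excluded",
            rec.recording.id, len(rec.gestures), len(feats),
            len(rec.gestures) - len(feats),
        )
        tables.append(feats)
        resp_tables.append(resp)

    table = pd.concat(tables, ignore_index=True)
    responses = pd.concat(resp_tables, ignore_index=True)
    assert len(table) + len(exclusions) == n_gestures_in
    io_mod.write_feature_table(table, outdir / "feature_table.csv")
    responses.to_csv(outdir / "response_table.csv", index=False)
    log.info("feature table: %d gestures; response table: %d rows",
             len(table), len(responses))

    cres = fit_crescendo(table)
    log.info("crescendo model fitted (%s)", cres.random_structure)
    arous = fit_arousal(responses)
    log.info("arousal model fitted (logLik %.2f)", arous.llf)
    forest = fit_resonance_forest(
        table, seed=cfg.seed, n_trees=cfg.forest_trees, mtry=cfg.forest_mtry
    )
    importance = forest.permutation_importance(
        n_repeats=cfg.importance_repeats, seed=cfg.seed
    )
    log.info("forest fitted (OOB accuracy %.3f)", forest.oob_accuracy)

    report = {
        "config": cfg.to_dict(),
        "counts": {
            "recordings": len(recs),
            "stories": int(sum(len(r.stories) for r in recs)),
            "gestures_in": n_gestures_in,
            "gestures_analyzed": int(len(table)),
            "excluded": exclusions,
            "response_rows": int(len(responses)),
        },
        "results": _results_payload(cres, arous, forest, importance),
    }
    with open(outdir / "results.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)

    with open(outdir / "report.txt", "w", encoding="utf-8") as fh:
        fh.write("\n\n".join([
            cres.summary(), arous.summary(), forest.summary(),
            "Permutation importance (mean decrease in OOB accuracy):\n"
            + importance.to_string(index=False),
        ]) + "\n")

    if cfg.make_plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ax = forest.plot_importance(importance)
        ax.figure.tight_layout()
        ax.figure.savefig(outdir / "importance.png", dpi=150)
        plt.close(ax.figure)
        for pred in ("SZ", "ND"):
            ice = forest.ice_curves(pred)
            ax = ice.plot()
            ax.figure.tight_layout()
            ax.figure.savefig(outdir / f"ice_{pred}.png", dpi=150)
            plt.close(ax.figure)

    return report
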