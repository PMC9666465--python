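"""End-to-end orchestration: generate -> growth -> genomics -> crm -> richness.

Stages communicate exclusively through TSV/JSON files in the output
directory, so any stage can be re-run on unchanged inputs and must produce
byte-identical primary outputs for an identical (config, seed) pair. The
manifest lists every file a stage wrote plus run metadata (config hash,
seed, package version).
"""

from __future__ import annotations

import hashlib
import json
import math
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.tree import export_text

from . import __version__, crm, genomics, io, synthetic
from .config import RunConfig
from .growth import DeviationCall, detect_deviation

__all__ = ["ResultBundle", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed or a required upstream output is missing."""


@dataclass
class ResultBundle:
    outdir: Path
    manifest: dict[str, list[str]]
    metadata: dict[str, object] = field(default_factory=dict)

    def files(self) -> list[Path]:
        return [self.outdir / f for files in self.manifest.values() for f in files]


def _log(level: str, stage: str, message: str, t0: float, **extra) -> None:
    record = {"stage": stage, "level": level, "message": message,
              "elapsed_s": round(time.monotonic() - t0, 3), **extra}
    print(json.dumps(record), file=sys.stderr)


def _stage_seed(seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([seed, int.from_bytes(stage.encode(), "big") % 2**31])
    return int(ss.generate_state(1)[0] % 2**31)


def _require(outdir: Path, names: list[str], stage: str) -> None:
    missing = [n for n in names if not (outdir / n).exists()]
    if missing:
        raise PipelineError(f"stage {stage!r} needs upstream outputs: {missing}")


def _stage_generate(cfg: RunConfig, outdir: Path) -> list[str]:
    gen = cfg.generator
    vitamins = list(gen["vitamins"])
    seed = _stage_seed(cfg.seed, "generate")

    # depletion curves: one spec per strain; each strain is auxotrophic for a
    # random subset of vitamins with storage 1-6 doublings
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    series = []
    truth_rows = []
    for i in range(int(gen["n_curve_strains"])):
        strain = f"curve_{i+1:02d}"
        storage = {}
        for v in vitamins:
            aux = bool(rng.random() < 0.5)
            storage[v] = float(rng.uniform(1.0, 6.0)) if aux else math.inf
            truth_rows.append({"strain": strain, "vitamin": v,
                               "auxotroph": aux, "true_storage": storage[v]})
        spec = synthetic.CurveSpec(
            strain_id=strain,
            mu_max=float(rng.uniform(0.4, 0.8)),
            storage_doublings=storage,
            seed=seed + i,
            **cfg.generator["curve"],
        )
        first = True
        for v in vitamins:
            controls, depleted = synthetic.simulate_plate_growth(spec, v)
            if first:  # controls are identical across vitamins (shared stream)
                series.extend(controls)
                first = False
            series.extend(depleted)
    io.write_plate_tsv(series, outdir / "plate.tsv", outdir / "plate_events.tsv")
    pd.DataFrame(truth_rows).to_csv(outdir / "truth_auxotrophy.tsv", sep="\t", index=False)

    marker_cogs = {v: [f"{v.upper()}_M1", f"{v.upper()}_M2"] for v in vitamins}
    pathway_map = {c: f"{v}_biosynthesis" for v, cogs in marker_cogs.items() for c in cogs}
    gspec = synthetic.GenomeSpec(
        marker_cogs=marker_cogs, pathway_map=pathway_map,
        seed=_stage_seed(cfg.seed, "genome"), **cfg.generator["genome"],
    )
    matrix = synthetic.simulate_cog_matrix(gspec)
    io.write_cog_tsvs(matrix, outdir / "cog_presence.tsv", outdir / "cog_labels.tsv",
                      outdir / "pathway_map.tsv")

    cspec = synthetic.CommunitySpec(seed=_stage_seed(cfg.seed, "community"),
                                    **cfg.generator["community"])
    io.write_strain_params_tsv(synthetic.simulate_strain_params(cspec),
                               outdir / "strain_params.tsv")
    return ["plate.tsv", "plate_events.tsv", "truth_auxotrophy.tsv", "cog_presence.tsv",
            "cog_labels.tsv", "pathway_map.tsv", "strain_params.tsv"]


def _stage_growth(cfg: RunConfig, outdir: Path) -> list[str]:
    _require(outdir, ["plate.tsv"], "growth")
    series = io.read_plate_tsv(outdir / "plate.tsv", outdir / "plate_events.tsv")
    by_strain: dict[str, dict[str, list]] = {}
    for s in series:
        by_strain.setdefault(s.strain, {}).setdefault(s.condition, []).append(s)
    calls: list[DeviationCall] = []
    report = {}
    for strain in sorted(by_strain):
        arms = by_strain[strain]
        controls = arms.get("supplemented", [])
        for cond in sorted(arms):
            if not cond.startswith("depleted:"):
                continue
            call = detect_deviation(
                arms[cond], controls, cfg.thresholds(),
                post_window_h=cfg.growth["post_window_h"],
                post_window_points=cfg.growth["post_window_points"],
            )
            calls.append(call)
            report[f"{strain}:{call.vitamin}"] = {
                "deviated": call.deviated,
                "per_replicate_rate_reduction": list(call.per_replicate_rate_reduction),
            }
    io.write_calls_tsv(calls, outdir / "calls.tsv")
    (outdir / "growth_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return ["calls.tsv", "growth_report.json"]


def _stage_genomics(cfg: RunConfig, outdir: Path) -> list[str]:
    _require(outdir, ["cog_presence.tsv", "cog_labels.tsv", "pathway_map.tsv"], "genomics")
    matrix = io.read_cog_tsvs(outdir / "cog_presence.tsv", outdir / "cog_labels.tsv",
                              outdir / "pathway_map.tsv")
    g = cfg.genomics
    assoc_frames = []
    diff_rows = []
    clf_report = {}
    predictions = {}
    seed = _stage_seed(cfg.seed, "genomics")
    for vitamin in matrix.labels.columns:
        records = genomics.cog_association(matrix, vitamin,
                                           correction=g["continuity_correction"])
        frame = genomics.association_frame(records)
        frame.insert(0, "vitamin", vitamin)
        assoc_frames.append(frame)
        for d in genomics.pathway_differential(records, matrix, cutoff=g["cutoff"],
                                               alpha=g["alpha"]):
            diff_rows.append({"vitamin": vitamin, "pathway": d.pathway, "n_genes": d.n_genes,
                              "n_differential": d.n_differential, "fraction": d.fraction,
                              "enriched_group": d.enriched_group})
        sig = frame[frame["q"] < g["alpha"]].sort_values("q")
        features = list((sig if len(sig) else frame.sort_values("q"))["cog"].head(3))
        clf = genomics.train_auxotrophy_classifier(
            matrix, vitamin, features, test_fraction=g["classifier"]["test_fraction"],
            max_depth=g["classifier"]["max_depth"], seed=seed,
        )
        clf_report[vitamin] = {
            "features": list(clf.features), "metrics": clf.metrics, "seed": clf.seed,
            "tree": export_text(clf.model, feature_names=list(clf.features)),
        }
        predictions[vitamin] = genomics.predict_auxotrophy(clf, matrix)

    pd.concat(assoc_frames).to_csv(outdir / "association.tsv", sep="\t", index=False)
    completeness = genomics.pathway_completeness(matrix)
    completeness.index.name = "strain"
    completeness.to_csv(outdir / "pathway_completeness.tsv", sep="\t")
    pd.DataFrame(diff_rows, columns=["vitamin", "pathway", "n_genes", "n_differential",
                                     "fraction", "enriched_group"]
                 ).to_csv(outdir / "pathway_diff.tsv", sep="\t", index=False)
    (outdir / "classifier_report.json").write_text(json.dumps(clf_report, indent=2,
                                                              sort_keys=True))
    pred = pd.DataFrame(predictions)
    pred.index.name = "strain"
    pred.to_csv(outdir / "predictions.tsv", sep="\t")
    return ["association.tsv", "pathway_completeness.tsv", "pathway_diff.tsv",
            "classifier_report.json", "predictions.tsv"]


def _stage_crm(cfg: RunConfig, outdir: Path) -> list[str]:
    _require(outdir, ["strain_params.tsv"], "crm")
    raw = io.read_strain_params_tsv(outdir / "strain_params.tsv")
    params = crm.derive_params(raw)
    config = cfg.crm_config()
    io.write_trajectory_tsv(crm.simulate_default(params, config),
                            outdir / "trajectory_default.tsv")
    io.write_trajectory_tsv(crm.simulate_carbon_xfeed(params, config),
                            outdir / "trajectory_carbon.tsv")
    pref = params.copy()
    pref.loc[pref["is_auxotroph"], "scaling_factor"] = 1.0
    io.write_trajectory_tsv(crm.simulate_carbon_xfeed(pref, config),
                            outdir / "trajectory_carbon_preferential.tsv")
    return ["trajectory_default.tsv", "trajectory_carbon.tsv",
            "trajectory_carbon_preferential.tsv"]


def _read_trajectory(path: Path) -> crm.Trajectory:
    df = pd.read_csv(path, sep="\t")
    wide = df.pivot(index="strain", columns="time_h", values="abundance")
    per_time = df.drop_duplicates("time_h").sort_values("time_h")
    return crm.Trajectory(
        times=per_time["time_h"].to_numpy(float),
        abundances=wide[sorted(wide.columns)],
        glucose=per_time["glucose_mM"].to_numpy(float),
        second_carbon=per_time["s2_mM"].to_numpy(float),
        realized_rates=pd.DataFrame(index=wide.index),
    )


def _stage_richness(cfg: RunConfig, outdir: Path) -> list[str]:
    _require(outdir, ["strain_params.tsv", "trajectory_default.tsv"], "richness")
    raw = io.read_strain_params_tsv(outdir / "strain_params.tsv")
    groups = pd.Series(
        np.where(raw["is_auxotroph"], "auxotrophs", "prototrophs"),
        index=raw["strain_id"],
    )
    thr = cfg.crm_config().presence_threshold
    written = []
    for name in ("default", "carbon", "carbon_preferential"):
        path = outdir / f"trajectory_{name}.tsv"
        if not path.exists():
            continue
        rich = crm.species_richness(_read_trajectory(path), groups, presence_threshold=thr)
        io.write_richness_tsv(rich, outdir / f"richness_{name}.tsv")
        written.append(f"richness_{name}.tsv")
    return written


_STAGE_FNS = {
    "generate": _stage_generate,
    "growth": _stage_growth,
    "genomics": _stage_genomics,
    "crm": _stage_crm,
    "richness": _stage_richness,
}
_STAGE_ORDER = ("generate", "growth", "genomics", "crm", "richness")


def run_pipeline(cfg: RunConfig) -> ResultBundle:
    """Execute the selected stages in dependency order.

    Raises :class:`PipelineError` when an upstream output is missing or a
    stage fails; outputs are deterministic for identical (config, seed).
    """
    t0 = time.monotonic()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[str]] = {}
    for stage in _STAGE_ORDER:
        if stage not in cfg.stages:
            continue
        _log("INFO", stage, "starting", t0)
        try:
            manifest[stage] = _STAGE_FNS[stage](cfg, outdir)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        _log("INFO", stage, "finished", t0, files=manifest[stage])
    config_hash = hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()
    ).hexdigest()
    metadata = {"config_hash": config_hash, "seed": cfg.seed, "version": __version__}
    bundle = ResultBundle(outdir=outdir, manifest=manifest, metadata=metadata)
    (outdir / "manifest.json").write_text(
        json.dumps({"metadata": metadata, "files": manifest}, indent=2, sort_keys=True)
    )
    missing = [str(p) for p in bundle.files() if not p.exists()]
    if missing:
        raise PipelineError(f"manifest lists missing files: {missing}")
    return bundle
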