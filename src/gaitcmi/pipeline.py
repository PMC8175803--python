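"""End-to-end pipeline: synth -> prep -> segment -> features -> classify
-> tfcmi -> stats, with cached stage outputs and a run manifest."""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import classify, features, gait_events, phase_stats, sigprep, synth, tfcmi
from .models import CorticomuscularCoupling
from .types import EMG_CHANNELS

STAGES = ("synth", "prep", "segment", "features", "classify", "tfcmi",
          "stats")


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    out_dir: str = "gaitcmi_run"
    seed: int = 0
    duration_s: float = 30.0
    speed_label: float = 2.0
    cases: tuple[int, ...] = (1, 2)
    coupling: list[synth.Coupling] = field(default_factory=lambda: [
        synth.Coupling("Cz", "Rt. TA", "LR", 0.8)])
    eog_threshold: float = 0.7
    skip_ica: bool = False
    pso: classify.PsoParams | None = None
    epoch_len: int = tfcmi.DEFAULT_EPOCH_LEN
    mst_rule: str = "left"

    _KNOWN = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        import dataclasses

        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "coupling" in d:
            d["coupling"] = [
                c if isinstance(c, synth.Coupling) else synth.Coupling(**c)
                for c in d["coupling"]
            ]
        if "cases" in d:
            d["cases"] = tuple(d["cases"])
        if "pso" in d and isinstance(d["pso"], dict):
            d["pso"] = classify.PsoParams(**d["pso"])
        return cls(**d)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Execute every stage in order, caching outputs under ``out_dir``.

    Rerunning with an unchanged config reuses completed stage outputs
    (idempotence is keyed on the serialized config); any stage failure
    raises :class:`StageError` naming the stage. Returns the report
    bundle plus the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import dataclasses

    cfg_desc = json.dumps({
        "seed": config.seed, "duration_s": config.duration_s,
        "speed_label": config.speed_label, "cases": list(config.cases),
        "coupling": [dataclasses.asdict(c) for c in config.coupling],
        "epoch_len": config.epoch_len, "mst_rule": config.mst_rule,
    }, sort_keys=True)
    manifest_path = out / "manifest.json"
    manifest = {"config": cfg_desc, "stages": []}
    if manifest_path.exists() and not force:
        prev = json.loads(manifest_path.read_text())
        if prev.get("config") == cfg_desc and len(
                prev.get("stages", [])) == len(STAGES):
            prev["cached"] = True
            return prev

    def done(stage: str, **info) -> None:
        manifest["stages"].append({"stage": stage, **info})
        manifest_path.write_text(json.dumps(manifest, indent=1))

    # synth
    try:
        scfg = synth.SynthConfig(
            duration_s=config.duration_s, speed_label=config.speed_label,
            coupling=list(config.coupling), seed=config.seed)
        markers, rec, gt = synth.generate_session(scfg)
        synth.save_session(out / "session", markers, rec, gt)
        done("synth", n_cycles=gt.n_cycles, channels=rec.n_channels)
    except Exception as e:
        raise StageError("synth", e) from e
    # prep
    try:
        prec, pmarkers, report = sigprep.preprocess(
            rec, markers, eog_threshold=config.eog_threshold,
            seed=config.seed, skip_ica=config.skip_ica)
        (out / "prep_report.json").write_text(json.dumps({
            "filters_applied": report.filters_applied,
            "removed_ics": report.removed_ics,
            "removed_channels": report.removed_channels,
        }, indent=1))
        done("prep", rate=prec.rate, removed_ics=len(report.removed_ics))
    except Exception as e:
        raise StageError("prep", e) from e
    # segment
    try:
        segs = gait_events.segment_session(pmarkers, mst_rule=config.mst_rule)
        rows = gait_events.segmentation_to_records(segs, pmarkers.rate)
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "segmentation.tsv", sep="\t",
                                  index=False)
        labels = gait_events.label_biosignal(segs, prec, pmarkers.rate)
        done("segment", n_cycles=len(segs))
    except Exception as e:
        raise StageError("segment", e) from e
    # features
    try:
        fms = {
            case: features.features_from_session(
                prec, labels, case, speed_label=config.speed_label)
            for case in config.cases
        }
        for case, fm in fms.items():
            fm.to_frame().to_csv(out / f"features_case{case}.tsv",
                                 sep="\t", index=False)
        done("features", cases=list(config.cases),
             instances={c: fm.n_instances for c, fm in fms.items()})
    except Exception as e:
        raise StageError("features", e) from e
    # classify
    try:
        acc_rows = []
        for case, fm in fms.items():
            res = classify.train_eval(fm, pso=config.pso, seed=config.seed)
            acc_rows.append({
                "case": case, "speed": config.speed_label,
                "mean_accuracy": res.mean_accuracy,
                "sd_accuracy": res.sd_accuracy,
                "per_phase": res.per_phase_accuracy,
                "C": res.best_C, "gamma": res.best_gamma,
            })
        (out / "classification.json").write_text(
            json.dumps(acc_rows, indent=1))
        done("classify", results=len(acc_rows))
    except Exception as e:
        raise StageError("classify", e) from e
    # tfcmi
    try:
        model = CorticomuscularCoupling(
            prec, segs, marker_rate=pmarkers.rate,
            epoch_len=config.epoch_len)
        coupling_res = model.fit()
        for phase, mat in coupling_res.phase_maps.items():
            np.savetxt(out / f"tfcmi_{phase}.tsv", mat.values,
                       delimiter="\t", header="\t".join(mat.labels),
                       comments="")
        done("tfcmi", phases=len(coupling_res.phase_maps))
    except Exception as e:
        raise StageError("tfcmi", e) from e
    # stats
    try:
        nonsig = []
        for muscle, an in coupling_res.anova.items():
            nonsig.append({
                "muscle": muscle, "phase_a": "__anova__", "phase_b": "",
                "p": an.p_value, "F": an.f_statistic,
            })
        bundle = phase_stats.report(
            accuracy_tables=acc_rows,
            topographies=coupling_res.topographies,
            lobe_summary=coupling_res.lobe_summary,
            nonsignificant_pairs=nonsig,
            out_dir=out,
        )
        done("stats", tables=len(bundle))
    except Exception as e:
        raise StageError("stats", e) from e
    manifest["report"] = {
        k: v for k, v in bundle.items() if k == "accuracy_tables"}
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
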