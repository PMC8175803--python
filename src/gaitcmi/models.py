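"""Model-style facades over the pipeline.

Two fit/results pairs wrap the package's two analyses the way statistical
modelling libraries present an estimator: a model object is built from
data, ``fit()`` returns a results object carrying estimates, dispersions
and a ``summary()`` table.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import classify, features, gait_events, phase_stats, tfcmi
from .features import FeatureMatrix
from .types import EMG_CHANNELS, PHASES, MultiChannelRecording


class GaitPhaseClassifier:
    """Seven-phase PSO-SVM classifier over a feature matrix.

    Parameters
    ----------
    fm : FeatureMatrix
        Phase-labeled instances, e.g. from
        :func:`gaitcmi.features.features_from_session`.
    pso : PsoParams, optional
        Swarm settings for hyperparameter tuning.
    """

    def __init__(self, fm: FeatureMatrix,
                 pso: classify.PsoParams | None = None):
        self.fm = fm
        self.pso = pso

    @classmethod
    def from_session(cls, rec: MultiChannelRecording, labels, case_id: int,
                     speed_label: float | None = None, **kwargs):
        fm = features.features_from_session(
            rec, labels, case_id, speed_label=speed_label)
        return cls(fm, **kwargs)

    def fit(self, seed: int = 0) -> classify.ClassResult:
        return classify.train_eval(self.fm, pso=self.pso, seed=seed)


@dataclass
class CouplingResults:
    """Per-phase corticomuscular coupling maps and their statistics."""

    phase_maps: dict[str, tfcmi.TFCMIMatrix]
    topographies: dict[tuple[str, str], dict[str, float]]
    lobe_summary: phase_stats.LobeSummary
    anova: dict[str, phase_stats.AnovaResult] = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Corticomuscular coupling (mean normalized TFCMI)",
                 "  muscle   " + "  ".join(f"{p:>6s}" for p in PHASES)]
        for muscle in EMG_CHANNELS:
            vals = []
            for phase in PHASES:
                topo = self.topographies.get((muscle, phase))
                vals.append(np.mean(list(topo.values())) if topo else np.nan)
            lines.append(
                f"  {muscle:<8s}" + "  ".join(f"{v:6.3f}" for v in vals))
        for muscle, an in self.anova.items():
            lines.append(
                f"  ANOVA {muscle}: F({an.df_between},{an.df_within}) = "
                f"{an.f_statistic:.2f}, p = {an.p_value:.3g}")
        return "\n".join(lines)


class CorticomuscularCoupling:
    """Phase-resolved EEG-muscle coupling model for one session.

    Built from a preprocessed recording and its marker segmentation;
    ``fit()`` computes the seven per-phase 31x31 coupling maps, the
    13-electrode topography of every muscle, lobe means, and a per-muscle
    ANOVA across phases using per-cycle lobe means as replicates.
    """

    def __init__(
        self,
        rec: MultiChannelRecording,
        segmentations: list[gait_events.PhaseSegmentation],
        marker_rate: float | None = None,
        epoch_len: int = tfcmi.DEFAULT_EPOCH_LEN,
    ):
        self.rec = rec
        self.segmentations = segmentations
        self.marker_rate = marker_rate
        self.epoch_len = epoch_len

    def fit(self, run_anova: bool = True) -> CouplingResults:
        chans = tfcmi.session_channels(self.rec)
        muscles = [m for m in EMG_CHANNELS if m in self.rec.labels]
        maps: dict[str, tfcmi.TFCMIMatrix] = {}
        per_cycle = {m: {p: [] for p in PHASES} for m in muscles}
        for phase in PHASES:
            cycle_mats = []
            for seg in self.segmentations:
                try:
                    mat = tfcmi.phase_tfcmi(
                        self.rec, [seg], phase, epoch_len=self.epoch_len,
                        marker_rate=self.marker_rate, channels=chans)
                except ValueError:
                    continue
                cycle_mats.append(mat)
                for m in muscles:
                    topo = tfcmi.extract_topography(mat, m)
                    per_cycle[m][phase].append(
                        float(np.mean(list(topo.values()))))
            if not cycle_mats:
                raise ValueError(f"no usable cycles for phase {phase}")
            mean = np.mean([m.values for m in cycle_mats], axis=0)
            np.fill_diagonal(mean, 1.0)
            maps[phase] = tfcmi.TFCMIMatrix(
                mean, cycle_mats[0].labels, n_cycles=len(cycle_mats))
        topo = {
            (muscle, phase): tfcmi.extract_topography(maps[phase], muscle)
            for phase in PHASES for muscle in muscles
        }
        lobes = phase_stats.lobe_means(topo)
        anova = {}
        if run_anova:
            for muscle in muscles:
                groups = [np.asarray(per_cycle[muscle][p]) for p in PHASES
                          if len(per_cycle[muscle][p]) >= 2]
                if len(groups) >= 2:
                    anova[muscle] = phase_stats.anova_oneway(groups)
        return CouplingResults(maps, topo, lobes, anova)
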