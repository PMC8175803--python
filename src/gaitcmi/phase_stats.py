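"""Inferential statistics on coupling values and classification results.

Lobe summaries average the 13 movement-related electrodes into frontal,
central and parietal groups; differences across the seven gait phases are
tested per muscle with one-way ANOVA and Tukey-HSD (or Bonferroni-Welch)
pairwise multiple comparisons.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy import stats

from .types import PHASES, TOPO_ELECTRODES

#: Standard 10-20 regional grouping of the 13 movement-related electrodes.
LOBES: dict[str, tuple[str, ...]] = {
    "frontal": ("F3", "F4", "F7", "F8", "Fz"),
    "central": ("C3", "C4", "Cz"),
    "parietal": ("P3", "P4", "P7", "P8", "Pz"),
}


@dataclass
class LobeSummary:
    """Mean coupling per (lobe, muscle, phase)."""

    means: dict[tuple[str, str, str], float]
    membership: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(LOBES))

    def value(self, lobe: str, muscle: str, phase: str) -> float:
        return self.means[(lobe, muscle, phase)]


@dataclass
class AnovaResult:
    """Classical one-way ANOVA with optional post-hoc table."""

    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: list[float]
    zero_within_variance: bool = False
    posthoc: dict[tuple[int, int], float] | None = None


def lobe_means(
    topographies: dict[tuple[str, str], dict[str, float]],
    membership: dict[str, tuple[str, ...]] | None = None,
) -> LobeSummary:
    """Average electrode topographies into lobes.

    ``topographies`` maps (muscle, phase) to the 13-electrode value dict.
    """
    memb = membership or LOBES
    covered = [e for els in memb.values() for e in els]
    if sorted(covered) != sorted(TOPO_ELECTRODES):
        raise ValueError("lobes must partition the 13 electrodes exactly")
    means = {}
    for (muscle, phase), topo in topographies.items():
        for lobe, electrodes in memb.items():
            means[(lobe, muscle, phase)] = float(
                np.mean([topo[e] for e in electrodes]))
    return LobeSummary(means, dict(memb))


def anova_oneway(groups: list[np.ndarray]) -> AnovaResult:
    """Classical one-way F test across ``groups``.

    Zero within-group variance with unequal means returns p = 0 with a
    flag; all values identical raises.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    means = [g.mean() for g in groups]
    ss_between = sum(len(g) * (m - grand) ** 2
                     for g, m in zip(groups, means))
    ss_within = sum(((g - m) ** 2).sum() for g, m in zip(groups, means))
    df_b, df_w = k - 1, n - k
    if ss_within == 0:
        if ss_between == 0:
            raise ValueError("all values identical: ANOVA undefined")
        return AnovaResult(np.inf, df_b, df_w, 0.0, means,
                           zero_within_variance=True)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), df_b, df_w, p, means)


def posthoc_pairwise(
    groups: list[np.ndarray], method: str = "tukey"
) -> dict[tuple[int, int], float]:
    """All-pairs p-values: Tukey HSD (default) or Bonferroni-Welch."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    pairs = list(combinations(range(len(groups)), 2))
    if method == "tukey":
        res = stats.tukey_hsd(*groups)
        return {(i, j): float(res.pvalue[i, j]) for i, j in pairs}
    if method == "bonferroni":
        m = len(pairs)
        out = {}
        for i, j in pairs:
            p = stats.ttest_ind(groups[i], groups[j], equal_var=False).pvalue
            out[(i, j)] = float(min(1.0, p * m))
        return out
    raise ValueError(f"unknown post-hoc method {method!r}")


def phase_comparison_table(
    per_phase_samples: dict[str, dict[str, np.ndarray]],
    alpha: float = 0.05,
    method: str = "tukey",
) -> list[dict]:
    """Per-muscle ANOVA across phases plus the non-significant-pair table.

    ``per_phase_samples`` maps muscle -> phase -> replicate coupling
    values. Returns rows ``{muscle, phase_a, phase_b, p}`` for every pair
    whose post-hoc p exceeds ``alpha`` (mirroring a table of
    non-significant phase pairs), plus an ``__anova__`` row per muscle.
    """
    rows = []
    for muscle, by_phase in per_phase_samples.items():
        phases = [p for p in PHASES if p in by_phase]
        groups = [np.asarray(by_phase[p], dtype=float) for p in phases]
        an = anova_oneway(groups)
        rows.append({
            "muscle": muscle, "phase_a": "__anova__", "phase_b": "",
            "p": an.p_value, "F": an.f_statistic,
        })
        ph = posthoc_pairwise(groups, method=method)
        for (i, j), p in sorted(ph.items()):
            if p > alpha:
                rows.append({
                    "muscle": muscle, "phase_a": phases[i],
                    "phase_b": phases[j], "p": p,
                })
    return rows


REPORT_SCHEMA = {
    "type": "object",
    "required": ["accuracy_tables", "topographies", "lobe_summary",
                 "nonsignificant_pairs"],
}


def report(
    accuracy_tables: list[dict] | None = None,
    topographies: dict[tuple[str, str], dict[str, float]] | None = None,
    lobe_summary: LobeSummary | None = None,
    nonsignificant_pairs: list[dict] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Bundle the result structure as JSON-serializable tables.

    When ``out_dir`` is given, writes ``report.json`` plus long-format
    TSVs for topographies and lobe means.
    """
    topo_rows = []
    for (muscle, phase), topo in (topographies or {}).items():
        for el, v in topo.items():
            topo_rows.append({"muscle": muscle, "phase": phase,
                              "electrode": el, "value": v})
    lobe_rows = []
    if lobe_summary is not None:
        for (lobe, muscle, phase), v in sorted(lobe_summary.means.items()):
            lobe_rows.append({"lobe": lobe, "muscle": muscle,
                              "phase": phase, "value": v})
    bundle = {
        "accuracy_tables": accuracy_tables or [],
        "topographies": topo_rows,
        "lobe_summary": lobe_rows,
        "nonsignificant_pairs": nonsignificant_pairs or [],
    }
    for key in REPORT_SCHEMA["required"]:
        if key not in bundle:
            raise ValueError(f"report bundle missing {key}")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(bundle, indent=1))
        import pandas as pd

        if topo_rows:
            pd.DataFrame(topo_rows).to_csv(
                out / "topographies.tsv", sep="\t", index=False)
        if lobe_rows:
            pd.DataFrame(lobe_rows).to_csv(
                out / "lobe_means.tsv", sep="\t", index=False)
    return bundle
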