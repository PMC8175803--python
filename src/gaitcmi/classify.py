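"""PSO-tuned RBF-SVM classification of the seven gait phases.

The evaluation protocol: a stratified 2/3 train - 1/3 test split per
phase, features z-scored on training statistics, hyperparameters
``(log10 C, log10 gamma)`` tuned by canonical global-best particle swarm
optimization against 5-fold cross-validated training accuracy, final
refit on the full training split, metrics from the held-out third.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .features import FeatureMatrix
from .types import PHASES


@dataclass
class PsoParams:
    """Canonical global-best PSO settings."""

    swarm_size: int = 20
    iterations: int = 50
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    bounds: tuple[tuple[float, float], ...] = ((-2.0, 3.0), (-4.0, 1.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        for lo, hi in self.bounds:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("bounds must be finite with low < high")


@dataclass
class ClassResult:
    """Per-phase and aggregate accuracy of one train/eval run."""

    per_phase_accuracy: dict[str, float]
    mean_accuracy: float
    sd_accuracy: float
    confusion: np.ndarray               # 7x7 counts, rows = true phase
    phase_order: list[str]
    best_C: float
    best_gamma: float
    cv_accuracy: float
    case_id: int | None = None
    speed_label: float | None = None
    pso_trace: list[float] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Gait-phase classification"
            + (f" (case {self.case_id}" if self.case_id else "(")
            + (f", {self.speed_label} km/h)" if self.speed_label else ")"),
            f"  mean accuracy {100 * self.mean_accuracy:.2f}%  "
            f"(SD across phases {self.sd_accuracy:.3f})",
            f"  C = {self.best_C:.4g}, gamma = {self.best_gamma:.4g}, "
            f"CV accuracy {100 * self.cv_accuracy:.2f}%",
        ]
        for ph in self.phase_order:
            lines.append(
                f"    {ph:<4s} {100 * self.per_phase_accuracy[ph]:6.2f}%")
        return "\n".join(lines)


def split_train_test(
    fm: FeatureMatrix, seed: int = 0, train_frac: float = 2 / 3
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified seeded 2/3-1/3 split; returns (train_idx, test_idx)."""
    rng = np.random.default_rng(seed)
    train, test = [], []
    for phase in np.unique(fm.labels):
        idx = np.flatnonzero(fm.labels == phase)
        rng.shuffle(idx)
        k = int(round(train_frac * len(idx)))
        train.extend(idx[:k])
        test.extend(idx[k:])
    return np.sort(np.array(train)), np.sort(np.array(test))


def pso_optimize(
    objective, params: PsoParams
) -> tuple[np.ndarray, float, list[float]]:
    """Global-best PSO minimizing ``objective`` within box bounds.

    Velocity update ``v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x)``,
    positions clipped to the bounds. Non-finite objective values penalize
    the particle (+inf) without stopping the run. Returns the best
    position, its value, and the per-iteration global-best trace
    (nonincreasing by construction).
    """
    rng = np.random.default_rng(params.seed)
    bounds = np.asarray(params.bounds, dtype=float)
    dim = len(bounds)
    lo, hi = bounds[:, 0], bounds[:, 1]
    x = rng.uniform(lo, hi, size=(params.swarm_size, dim))
    v = rng.uniform(-(hi - lo), hi - lo, size=(params.swarm_size, dim)) * 0.1

    def safe_eval(pos: np.ndarray) -> float:
        val = objective(pos)
        return float(val) if np.isfinite(val) else np.inf

    pbest = x.copy()
    pval = np.array([safe_eval(p) for p in x])
    if not np.any(np.isfinite(pval)):
        raise RuntimeError("objective non-finite for the entire swarm")
    gi = int(np.argmin(pval))
    gbest, gval = pbest[gi].copy(), float(pval[gi])
    trace = [gval]
    for _ in range(params.iterations):
        r1 = rng.random((params.swarm_size, dim))
        r2 = rng.random((params.swarm_size, dim))
        v = (params.inertia * v
             + params.cognitive * r1 * (pbest - x)
             + params.social * r2 * (gbest[None, :] - x))
        x = np.clip(x + v, lo, hi)
        val = np.array([safe_eval(p) for p in x])
        improved = val < pval
        pbest[improved] = x[improved]
        pval[improved] = val[improved]
        gi = int(np.argmin(pval))
        if pval[gi] < gval:
            gbest, gval = pbest[gi].copy(), float(pval[gi])
        trace.append(gval)
    return gbest, gval, trace


def _zscore_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


def train_eval(
    fm: FeatureMatrix,
    pso: PsoParams | None = None,
    seed: int = 0,
    cv_folds: int = 5,
) -> ClassResult:
    """Tune, train and evaluate the seven-phase SVM on one feature matrix."""
    pso = pso or PsoParams(seed=seed)
    phases = [p for p in PHASES if p in set(fm.labels)]
    counts = {p: int((fm.labels == p).sum()) for p in phases}
    bad = [p for p, c in counts.items() if c < 3]
    if bad:
        raise ValueError(f"degenerate classes (fewer than 3 instances): {bad}")
    tr, te = split_train_test(fm, seed=seed)
    x_tr, y_tr = fm.values[tr], fm.labels[tr].astype(str)
    x_te, y_te = fm.values[te], fm.labels[te].astype(str)
    mu, sd = _zscore_fit(x_tr)
    x_tr = (x_tr - mu) / sd
    x_te = (x_te - mu) / sd

    folds = min(cv_folds, min(int((y_tr == p).sum()) for p in phases))
    cv = StratifiedKFold(n_splits=max(folds, 2), shuffle=True,
                         random_state=seed)

    def objective(pos: np.ndarray) -> float:
        c, g = 10.0 ** pos[0], 10.0 ** pos[1]
        clf = SVC(kernel="rbf", C=c, gamma=g)
        acc = cross_val_score(clf, x_tr, y_tr, cv=cv).mean()
        return 1.0 - acc

    best, best_val, trace = pso_optimize(objective, pso)
    best_c, best_g = 10.0 ** best[0], 10.0 ** best[1]
    clf = SVC(kernel="rbf", C=best_c, gamma=best_g)
    clf.fit(x_tr, y_tr)
    pred = clf.predict(x_te)

    k = len(phases)
    confusion = np.zeros((k, k), dtype=int)
    pos = {p: i for i, p in enumerate(phases)}
    for yt, yp in zip(y_te, pred):
        confusion[pos[yt], pos[yp]] += 1
    per_phase = {
        p: confusion[i, i] / confusion[i].sum()
        for i, p in enumerate(phases)
    }
    accs = np.array([per_phase[p] for p in phases])
    return ClassResult(
        per_phase_accuracy=per_phase,
        mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std(ddof=0)),
        confusion=confusion,
        phase_order=phases,
        best_C=float(best_c),
        best_gamma=float(best_g),
        cv_accuracy=float(1.0 - best_val),
        case_id=fm.case_id,
        speed_label=fm.speed_label,
        pso_trace=trace,
    )


# --------------------------------------------------------------------------
# Mann-Whitney U


def _mwu_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic of sample a via midranks (handles ties)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: len(a)].sum()
    return r1 - len(a) * (len(a) + 1) / 2.0


def compare_cases(
    results_a: np.ndarray, results_b: np.ndarray
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two accuracy samples.

    For groups of at most 8 values each, the exact null is computed by
    full enumeration of the C(n1+n2, n1) group assignments of the pooled
    values (valid under ties); otherwise the normal approximation with
    tie correction is used. Returns ``(U, p)`` with U the first sample's
    statistic.
    """
    a = np.asarray(results_a, dtype=float)
    b = np.asarray(results_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    u_obs = _mwu_statistic(a, b)
    if n1 <= 8 and n2 <= 8:
        pooled = np.concatenate([a, b])
        center = n1 * n2 / 2.0
        dev = abs(u_obs - center)
        total = comb(n1 + n2, n1)
        hits = 0
        idx_all = np.arange(n1 + n2)
        for pick in combinations(idx_all, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(pick)] = True
            u = _mwu_statistic(pooled[mask], pooled[~mask])
            if abs(u - center) >= dev - 1e-12:
                hits += 1
        return float(u_obs), hits / total
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic")
    return float(u_obs), float(res.pvalue)
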