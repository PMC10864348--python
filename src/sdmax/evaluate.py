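"""Model evaluation: cross-validated AUC, threshold choice, and the three
variable-importance procedures (percent contribution, permutation
importance, jackknife).

AUC here is the rank-based Mann–Whitney construction — the probability that
a randomly chosen presence outscores a randomly chosen background point,
ties counted one half — so it is invariant under any strictly monotone
transform of the scores, and 0.5 means the model ranks no better than
chance. Cross-validation folds partition the presences only; the background
sample is shared across folds, which keeps per-fold AUCs comparable.

The binarization threshold τ* maximizes sensitivity + specificity (Youden's
J) over observed scores, predicting "suitable" where score ≥ τ*; ties go to
the smallest such τ*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .maxent import (
    FeatureSpec,
    FitTrace,
    MaxEntModel,
    fit_maxent,
    predict_logistic,
    training_gain,
)
from .sampling import SampleTable

__all__ = [
    "EvalConfig",
    "EvaluationReport",
    "auc",
    "kfold_cv",
    "select_threshold",
    "percent_contribution",
    "permutation_importance",
    "jackknife",
    "importance_table",
]


@dataclass
class EvalConfig:
    k_folds: int = 10
    seed: int = 0
    permutation_repeats: int = 10
    threshold_rule: str = "max_sens_plus_spec"

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.threshold_rule not in ("max_sens_plus_spec", "equal_sens_spec"):
            raise ValueError(f"unknown threshold rule {self.threshold_rule!r}")


@dataclass
class EvaluationReport:
    fold_auc: list[float]
    mean_auc: float
    threshold: float
    sensitivity: float
    specificity: float
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": f"auc_fold_{i + 1}", "value": v}
            for i, v in enumerate(self.fold_auc)
        ]
        rows += [
            {"metric": "auc_mean", "value": self.mean_auc},
            {"metric": "threshold", "value": self.threshold},
            {"metric": "sensitivity", "value": self.sensitivity},
            {"metric": "specificity", "value": self.specificity},
        ]
        return pd.DataFrame(rows)


def auc(presence_scores, background_scores) -> float:
    """Mann–Whitney AUC: P(presence score > background score) + ½P(tie)."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be non-empty")
    u = mannwhitneyu(p, b, alternative="two-sided").statistic
    return float(u / (p.size * b.size))


def select_threshold(
    presence_scores, background_scores, rule: str = "max_sens_plus_spec"
) -> tuple[float, float, float]:
    """Pick τ* from the observed scores; returns (τ*, sensitivity, specificity).

    Prediction is "suitable iff score ≥ τ". The default rule maximizes
    sensitivity + specificity; ``equal_sens_spec`` minimizes |sens − spec|.
    Ties resolve to the smallest qualifying τ.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be non-empty")
    cand = np.unique(np.concatenate([p, b]))
    # sens(τ) = share of presences ≥ τ; spec(τ) = share of background < τ
    sens = 1.0 - np.searchsorted(np.sort(p), cand, side="left") / p.size
    spec = np.searchsorted(np.sort(b), cand, side="left") / b.size
    if rule == "max_sens_plus_spec":
        score = sens + spec
        best = int(np.argmax(score))  # argmax takes the first (smallest τ) on ties
    elif rule == "equal_sens_spec":
        best = int(np.argmin(np.abs(sens - spec)))
    else:
        raise ValueError(f"unknown threshold rule {rule!r}")
    return float(cand[best]), float(sens[best]), float(spec[best])


def _make_folds(m: int, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    return [np.sort(f) for f in np.array_split(perm, k)]


def kfold_cv(
    presences: SampleTable,
    background: SampleTable,
    model_settings: dict | None = None,
    config: EvalConfig | None = None,
) -> EvaluationReport:
    """k-fold cross-validated AUC plus full-data threshold.

    The presences are split into ``k`` seed-deterministic folds of sizes
    differing by at most one; for each fold a model is fitted on the other
    k−1 folds against the shared background and scored on the held-out
    presences vs the background. The reported threshold comes from a final
    refit on all presences (the model later used for mapping).
    """
    config = config or EvalConfig()
    settings = dict(model_settings or {})
    classes = tuple(settings.pop("classes", ("linear", "quadratic")))
    layers = settings.pop("layers", None)
    m = len(presences)
    if config.k_folds > m:
        raise ValueError(f"k_folds={config.k_folds} exceeds {m} presences")

    spec = FeatureSpec.from_background(background, layers=layers, classes=classes)
    P = spec.build(presences)
    B = spec.build(background)

    folds = _make_folds(m, config.k_folds, config.seed)
    fold_auc = []
    flags: list[str] = []
    for i, hold in enumerate(folds):
        train = np.setdiff1d(np.arange(m), hold)
        model, _ = fit_maxent(P[train], B, spec, **settings)
        if not model.converged:
            flags.append(f"fold {i + 1}: fit did not converge")
        scores_p = P[hold] @ model.lam  # monotone in suitability; AUC-invariant
        scores_b = B @ model.lam
        fold_auc.append(auc(scores_p, scores_b))

    full_model, _ = fit_maxent(P, B, spec, **settings)
    if not full_model.converged:
        flags.append("full refit did not converge")
    q_p = predict_logistic(full_model, P)
    q_b = predict_logistic(full_model, B)
    tau, sens, spc = select_threshold(q_p, q_b, config.threshold_rule)
    return EvaluationReport(
        fold_auc=fold_auc,
        mean_auc=float(np.mean(fold_auc)),
        threshold=tau,
        sensitivity=sens,
        specificity=spc,
        flags=flags,
    )


def percent_contribution(trace: FitTrace, layers: list[str] | None = None) -> pd.Series:
    """Percent contribution per variable from the fit trace.

    Each coordinate update's objective improvement is credited to the
    owning layer (the quadratic of v credits v); negative accumulations are
    floored at zero, then the vector is normalized to sum 100. An all-zero
    trace yields all zeros (callers should treat that as "no signal").
    """
    acc: dict[str, float] = {l: 0.0 for l in (layers or [])}
    for owner, gain in zip(trace.owner, trace.improvement):
        acc[owner] = acc.get(owner, 0.0) + gain
    s = pd.Series(acc, dtype=float).clip(lower=0.0)
    total = s.sum()
    if total <= 0:
        return s * 0.0
    return s / total * 100.0


def permutation_importance(
    model: MaxEntModel,
    presences: SampleTable,
    background: SampleTable,
    repeats: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Permutation importance per variable (normalized AUC drops).

    For each layer, its raw values are permuted jointly across the
    concatenated presence + background rows (a fresh permutation per
    repeat), features rebuilt, and the training AUC recomputed; the drop
    from the unpermuted AUC, floored at zero and averaged over repeats, is
    normalized across layers to sum 100.
    """
    rng = np.random.default_rng(seed)
    layers = model.spec.layers
    df_all = pd.concat(
        [presences.data[layers], background.data[layers]], ignore_index=True
    )
    m = len(presences)
    base_scores = model.spec.build(df_all) @ model.lam
    auc0 = auc(base_scores[:m], base_scores[m:])

    drops = {}
    for layer in layers:
        vals = []
        for _ in range(repeats):
            shuffled = df_all.copy()
            shuffled[layer] = rng.permutation(shuffled[layer].to_numpy())
            s = model.spec.build(shuffled) @ model.lam
            vals.append(auc(s[:m], s[m:]))
        drops[layer] = max(0.0, auc0 - float(np.mean(vals)))
    s = pd.Series(drops, dtype=float)
    total = s.sum()
    if total <= 0:
        return s * 0.0
    return s / total * 100.0


def jackknife(
    presences: SampleTable,
    background: SampleTable,
    layers: list[str] | None = None,
    model_settings: dict | None = None,
) -> pd.DataFrame:
    """Leave-one-in / leave-one-out training gains per variable.

    For each variable v the model family is refitted on v alone
    (``gain_only``) and on all variables but v (``gain_without``); the
    full-model gain is attached to every row for reference. A variable
    whose exclusion barely moves the gain carries little unique
    information; one with high gain alone is individually informative.
    """
    settings = dict(model_settings or {})
    classes = tuple(settings.pop("classes", ("linear", "quadratic")))
    layers = list(layers) if layers is not None else list(background.data.columns)
    if not layers:
        raise ValueError("jackknife needs at least 1 variable")
    # with a single variable, "all but v" is the null model: gain 0

    def gain_for(subset: list[str]) -> float:
        if not subset:
            return 0.0
        spec = FeatureSpec.from_background(background, layers=subset, classes=classes)
        P = spec.build(presences)
        B = spec.build(background)
        model, _ = fit_maxent(P, B, spec, **settings)
        return training_gain(model, P)

    full = gain_for(layers)
    rows = []
    for v in layers:
        rows.append(
            {
                "variable": v,
                "gain_only": gain_for([v]),
                "gain_without": gain_for([l for l in layers if l != v]),
                "gain_full": full,
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def importance_table(
    pc: pd.Series, pi: pd.Series, jack: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Assemble the per-variable importance table (PC %, PI %, jackknife)."""
    out = pd.DataFrame({"PC": pc, "PI": pi})
    if jack is not None:
        out = out.join(jack[["gain_only", "gain_without"]])
    out.index.name = "variable"
    return out
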