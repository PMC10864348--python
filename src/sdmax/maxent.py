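"""Presence-background maximum-entropy (Gibbs) model.

The model picks, among all distributions over the background cells whose
feature expectations stay within a slack β of the presence-sample feature
means, the one with maximum entropy — equivalently the L1-regularized
maximum-likelihood exponential-family fit

    min_λ  J(λ) = −(1/m) Σ_presences λ·f(x_i)
                  + log Σ_background exp(λ·f(x))
                  + Σ_j β_j |λ_j|,

with per-feature β_j = beta0 · s_j / √m (s_j the presence std-dev of feature
j, floored at 1e-4). J is convex; we minimize it by cyclic coordinate
descent with an exact 1-D solve per coefficient, which makes the per-update
objective improvements well-defined — they are the raw material of the
percent-contribution importance measure. At the optimum the KKT conditions
hold: |E_λ[f_j] − presence mean f_j| ≤ β_j, with equality wherever λ_j ≠ 0.

Features are linear and quadratic transforms of predictors min-max scaled to
[0, 1] on the training background; at projection time values outside the
training range are clamped into [0, 1] so suitability stays finite under
novel climates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

__all__ = [
    "FeatureSpec",
    "MaxEntModel",
    "FitTrace",
    "build_features",
    "fit_maxent",
    "kkt_slack",
    "predict_raw",
    "predict_logistic",
    "training_gain",
]

BETA_FLOOR = 1e-4


@dataclass
class FeatureSpec:
    """Feature construction recipe: which transforms of which layers.

    ``bounds`` holds per-layer (min, max) over the reference background
    sample; scaling is (v − min)/(max − min) clamped into [0, 1].
    """

    layers: list[str]
    classes: tuple[str, ...] = ("linear", "quadratic")
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.classes) - {"linear", "quadratic"}
        if bad:
            raise ValueError(f"unsupported feature classes: {sorted(bad)}")
        if not self.classes:
            raise ValueError("at least one feature class required")

    @classmethod
    def from_background(
        cls, background, layers: list[str] | None = None,
        classes: tuple[str, ...] = ("linear", "quadratic"),
    ) -> "FeatureSpec":
        """Derive scaling bounds from the training background sample."""
        df = background.data if hasattr(background, "data") else background
        layers = list(layers) if layers is not None else list(df.columns)
        bounds = {}
        for name in layers:
            lo, hi = float(df[name].min()), float(df[name].max())
            if not np.isfinite([lo, hi]).all() or hi <= lo:
                raise ValueError(f"degenerate scaling bounds for layer {name!r}")
            bounds[name] = (lo, hi)
        return cls(layers=layers, classes=classes, bounds=bounds)

    @property
    def feature_names(self) -> list[str]:
        out = []
        if "linear" in self.classes:
            out += list(self.layers)
        if "quadratic" in self.classes:
            out += [f"{l}^2" for l in self.layers]
        return out

    @property
    def owners(self) -> list[str]:
        """Source layer of each feature (quadratic of v is owned by v)."""
        out = []
        if "linear" in self.classes:
            out += list(self.layers)
        if "quadratic" in self.classes:
            out += list(self.layers)
        return out

    def scale_layer(self, name: str, values: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds[name]
        return np.clip((np.asarray(values, dtype=float) - lo) / (hi - lo), 0.0, 1.0)

    def build(self, samples) -> np.ndarray:
        """Feature matrix (n_rows, n_features) from a sample table/DataFrame."""
        df = samples.data if hasattr(samples, "data") else samples
        missing = [l for l in self.layers if l not in df.columns]
        if missing:
            raise KeyError(f"samples lack required layer(s): {missing}")
        scaled = np.column_stack([self.scale_layer(l, df[l].to_numpy()) for l in self.layers])
        blocks = []
        if "linear" in self.classes:
            blocks.append(scaled)
        if "quadratic" in self.classes:
            blocks.append(scaled ** 2)
        return np.hstack(blocks)


def build_features(samples, spec: FeatureSpec) -> np.ndarray:
    """Functional alias for :meth:`FeatureSpec.build`."""
    return spec.build(samples)


@dataclass
class FitTrace:
    """Per coefficient-update record of the coordinate descent."""

    feature: list[str] = field(default_factory=list)
    owner: list[str] = field(default_factory=list)
    improvement: list[float] = field(default_factory=list)

    def add(self, feature: str, owner: str, improvement: float) -> None:
        self.feature.append(feature)
        self.owner.append(owner)
        self.improvement.append(float(improvement))

    def total(self) -> float:
        return float(sum(self.improvement))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.feature, "owner": self.owner, "improvement": self.improvement}
        )


@dataclass
class MaxEntModel:
    """Fitted maximum-entropy model.

    ``log_partition`` is log Σ_background exp(λ·f) over the *training*
    background, so raw probabilities on that background sum to one;
    ``entropy`` is the entropy of that fitted distribution (≤ log N).
    """

    spec: FeatureSpec
    lam: np.ndarray              # coefficient per feature
    beta: np.ndarray             # per-feature regularization
    log_partition: float
    entropy: float
    n_presence: int
    n_background: int
    iterations: int
    objective: float
    converged: bool = True
    presence_means: np.ndarray | None = None

    @property
    def feature_names(self) -> list[str]:
        return self.spec.feature_names

    def coefficients(self) -> pd.Series:
        return pd.Series(self.lam, index=self.feature_names, name="lambda")

    def coefficients_raw_scale(self) -> pd.Series:
        """Linear-feature coefficients converted back to raw layer units.

        The fit operates on min-max scaled layers; dividing each linear
        coefficient by its layer's (max − min) expresses it per unit of the
        original variable — the scale on which a generating model is stated.
        """
        if "linear" not in self.spec.classes:
            raise ValueError("model has no linear features")
        out = {}
        for i, name in enumerate(self.spec.layers):
            lo, hi = self.spec.bounds[name]
            out[name] = self.lam[i] / (hi - lo)
        return pd.Series(out, name="lambda_raw")

    # -- persistence ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "format": "sdmax-model/1",
            "classes": list(self.spec.classes),
            "layers": list(self.spec.layers),
            "bounds": {k: [float(a), float(b)] for k, (a, b) in self.spec.bounds.items()},
            "lambda": [float(v) for v in self.lam],
            "beta": [float(v) for v in self.beta],
            "log_partition": float(self.log_partition),
            "entropy": float(self.entropy),
            "n_presence": int(self.n_presence),
            "n_background": int(self.n_background),
            "iterations": int(self.iterations),
            "objective": float(self.objective),
            "converged": bool(self.converged),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MaxEntModel":
        doc = yaml.safe_load(Path(path).read_text())
        if doc.get("format") != "sdmax-model/1":
            raise ValueError(f"{path}: not an sdmax model file")
        spec = FeatureSpec(
            layers=list(doc["layers"]),
            classes=tuple(doc["classes"]),
            bounds={k: (float(a), float(b)) for k, (a, b) in doc["bounds"].items()},
        )
        return cls(
            spec=spec,
            lam=np.asarray(doc["lambda"], dtype=float),
            beta=np.asarray(doc["beta"], dtype=float),
            log_partition=float(doc["log_partition"]),
            entropy=float(doc["entropy"]),
            n_presence=int(doc["n_presence"]),
            n_background=int(doc["n_background"]),
            iterations=int(doc["iterations"]),
            objective=float(doc["objective"]),
            converged=bool(doc["converged"]),
        )


def _objective(lam, pres_means, bg_F, beta):
    return float(
        -pres_means @ lam + logsumexp(bg_F @ lam) + beta @ np.abs(lam)
    )


def _expected_feature(base_eta: np.ndarray, f: np.ndarray, t: float) -> float:
    """E_w[f] with w ∝ exp(base_eta + t f)."""
    eta = base_eta + t * f
    eta = eta - eta.max()
    w = np.exp(eta)
    return float(w @ f / w.sum())


def _solve_coordinate(base_eta, f, a_j, beta_j, lo=-1e6, hi=1e6):
    """Exact 1-D minimizer of the convex coordinate objective.

    g(t) = −a_j t + log Σ exp(base_eta + t f) + β_j |t| has derivative
    E_t[f] − a_j + β_j sign(t) away from zero; E_t[f] is increasing in t, so
    the minimizer is 0 when |E_0[f] − a_j| ≤ β_j and otherwise the root of
    the appropriate smooth branch, found by bracketed root-finding.
    """
    d0 = _expected_feature(base_eta, f, 0.0) - a_j
    if abs(d0) <= beta_j:
        return 0.0
    if d0 < -beta_j:
        # derivative negative at 0+; root of E_t[f] − a_j + β_j on t > 0
        def dg(t):
            return _expected_feature(base_eta, f, t) - a_j + beta_j
        a, b = 0.0, 1.0
        while dg(b) < 0:
            a, b = b, b * 2.0
            if b > hi:
                return hi
    else:
        def dg(t):
            return _expected_feature(base_eta, f, t) - a_j - beta_j
        a, b = -1.0, 0.0
        while dg(a) > 0:
            a, b = a * 2.0, a
            if a < lo:
                return lo
    return float(brentq(dg, a, b, xtol=1e-12, rtol=8.9e-16))


def fit_maxent(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    spec: FeatureSpec,
    beta0: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int | None = None,
) -> tuple[MaxEntModel, FitTrace]:
    """Fit the L1-regularized Gibbs model by cyclic coordinate descent.

    Parameters
    ----------
    presence_features, background_features
        Feature matrices built by the same :class:`FeatureSpec` (``spec``).
    beta0
        Regularization multiplier; β_j = beta0·s_j/√m with s_j the presence
        std-dev of feature j, floored at 1e-4.
    tol
        Convergence: objective improvement below ``tol`` over a full cycle.
    seed
        Accepted for interface symmetry and recorded nowhere: the cyclic
        sweep order is fixed, so the fit is deterministic.

    Returns the fitted model and the per-update improvement trace.
    """
    P = np.asarray(presence_features, dtype=float)
    B = np.asarray(background_features, dtype=float)
    if P.ndim != 2 or B.ndim != 2 or P.shape[1] != B.shape[1]:
        raise ValueError("presence/background feature matrices must align")
    m, J = P.shape
    N = B.shape[0]
    if m < 5:
        raise ValueError("need at least 5 presence records")
    if N < 50:
        raise ValueError("need at least 50 background cells")
    if not (np.isfinite(P).all() and np.isfinite(B).all()):
        raise ValueError("features must be finite")

    a = P.mean(axis=0)                      # presence feature means
    s = P.std(axis=0, ddof=0)
    beta = np.maximum(beta0 * s / np.sqrt(m), BETA_FLOOR)

    lam = np.zeros(J)
    eta = B @ lam                           # cached background linear predictor
    obj = _objective(lam, a, B, beta)
    if not np.isfinite(obj):
        raise FloatingPointError("non-finite objective at initialization")

    names = spec.feature_names
    owners = spec.owners
    trace = FitTrace()

    def kkt_residual() -> float:
        # stationarity: |E[f_j] - a_j| <= beta_j, equality where lam_j != 0
        w = np.exp(eta - eta.max())
        e = (w @ B) / w.sum()
        gap = np.abs(e - a)
        resid = np.maximum(0.0, gap - beta)            # feasibility
        resid = np.where(lam != 0, np.abs(gap - beta), resid)  # active equality
        return float(resid.max())

    converged = False
    cycles = 0
    for cycles in range(1, max_iter + 1):
        cycle_start = obj
        for j in range(J):
            old = lam[j]
            base = eta - old * B[:, j]
            t = _solve_coordinate(base, B[:, j], a[j], beta[j])
            if t != old:
                lam[j] = t
                eta = base + t * B[:, j]
                new_obj = _objective(lam, a, B, beta)
                if not np.isfinite(new_obj):
                    raise FloatingPointError("non-finite objective during descent")
                gain = obj - new_obj
                if gain != 0.0:
                    trace.add(names[j], owners[j], gain)
                obj = new_obj
        # stop only when progress has stalled AND the optimality certificate
        # holds, so every returned model carries a valid KKT certificate
        if cycle_start - obj < tol and kkt_residual() <= 10 * tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"coordinate descent did not converge in {max_iter} cycles "
            f"(last-cycle improvement above {tol})",
            RuntimeWarning,
        )

    logZ = float(logsumexp(eta))
    log_p = eta - logZ
    entropy = float(-(np.exp(log_p) @ log_p))
    model = MaxEntModel(
        spec=spec,
        lam=lam,
        beta=beta,
        log_partition=logZ,
        entropy=entropy,
        n_presence=m,
        n_background=N,
        iterations=cycles,
        objective=obj,
        converged=converged,
        presence_means=a,
    )
    return model, trace


def kkt_slack(model: MaxEntModel, background_features: np.ndarray) -> pd.DataFrame:
    """KKT certificate per feature: constraint violation beyond β.

    Columns: ``gap`` = |E_λ[f_j] − presence mean|, ``beta``, ``violation`` =
    max(0, gap − β), and ``active_slack`` = |gap − β| for features with
    λ_j ≠ 0 (should be ~0 at an exact optimum).
    """
    if model.presence_means is None:
        raise ValueError("model carries no presence means (loaded from file?)")
    B = np.asarray(background_features, dtype=float)
    eta = B @ model.lam
    eta = eta - eta.max()
    w = np.exp(eta)
    w /= w.sum()
    e = w @ B
    gap = np.abs(e - model.presence_means)
    violation = np.maximum(0.0, gap - model.beta)
    active = model.lam != 0
    active_slack = np.where(active, np.abs(gap - model.beta), 0.0)
    return pd.DataFrame(
        {
            "feature": model.feature_names,
            "gap": gap,
            "beta": model.beta,
            "violation": violation,
            "active": active,
            "active_slack": active_slack,
        }
    )


def predict_raw(model: MaxEntModel, samples) -> np.ndarray:
    """Training-normalized raw suitability exp(λ·f − log Z).

    Over the training background these sum to one; on new cells they are
    relative Gibbs weights on the training normalizer's scale.
    """
    F = model.spec.build(samples) if not isinstance(samples, np.ndarray) else samples
    return np.exp(F @ model.lam - model.log_partition)


def predict_logistic(model: MaxEntModel, samples) -> np.ndarray:
    """Logistic suitability in [0, 1] at default prevalence 0.5.

    q = e^H p_raw / (1 + e^H p_raw), with H the entropy of the fitted
    training distribution, so a "typical" cell (p_raw = e^{−H}) maps to 0.5
    and the uniform null model maps every cell to 0.5.
    """
    F = model.spec.build(samples) if not isinstance(samples, np.ndarray) else samples
    # log odds = H + log p_raw, computed in log space so extreme cells stay finite
    log_odds = model.entropy + (F @ model.lam - model.log_partition)
    return expit(log_odds)


def training_gain(model: MaxEntModel, presence_features: np.ndarray) -> float:
    """Mean presence log-probability improvement over uniform (nats).

    gain = (1/m) Σ λ·f(x_i) − log Z + log N; zero for the null model and at
    most log N for a point mass on the single best cell.
    """
    P = np.asarray(presence_features, dtype=float)
    return float(P.mean(axis=0) @ model.lam - model.log_partition + np.log(model.n_background))
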