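"""Virtual landscapes and virtual species with a known truth.

Every downstream stage (screening, fitting, evaluation, projection) is
exercised on data from this module, so each generator is a pure function of
its parameters and a seed, and the generating model is exposed so parameter
recovery is a testable claim rather than a hope.

Layers are spatially autocorrelated Gaussian random fields: white noise
smoothed by a truncated Gaussian kernel (reflected boundaries) and then
re-standardized to zero mean / unit variance over valid cells, so a stated
true coefficient has the same meaning regardless of the smoothing radius.
The true suitability surface is an exponential-family (Gibbs) response
``p(x) ∝ exp(λ*·f(x))`` over valid cells — the same family the fitter
assumes, which makes coefficient recovery well-posed. Presences are drawn
with probability proportional to suitability, with replacement (herbarium
records cluster), and placed at cell centers. "Future" stacks are additive
and/or multiplicative shifts of selected layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .grids import GridStack, GridTransform
from .occurrences import OccurrenceSet

__all__ = [
    "TrueModel",
    "ScenarioShift",
    "generate_landscape",
    "true_suitability",
    "sample_presences",
    "apply_shift",
]


@dataclass
class TrueModel:
    """Generating coefficients of the virtual species.

    ``linear`` and ``quadratic`` map layer names to coefficients on the raw
    (standardized) layer values; the surface is intercept-free because the
    Gibbs normalizer absorbs any constant.
    """

    linear: dict[str, float] = field(default_factory=dict)
    quadratic: dict[str, float] = field(default_factory=dict)

    @property
    def layers(self) -> list[str]:
        seen: list[str] = []
        for name in list(self.linear) + list(self.quadratic):
            if name not in seen:
                seen.append(name)
        return seen

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {"linear": dict(self.linear), "quadratic": dict(self.quadratic)},
                sort_keys=True,
            )
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrueModel":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(linear=raw.get("linear", {}), quadratic=raw.get("quadratic", {}))


@dataclass
class ScenarioShift:
    """Per-layer change defining one future climate: value*factor + delta."""

    label: str
    delta: dict[str, float] = field(default_factory=dict)
    factor: dict[str, float] = field(default_factory=dict)

    @property
    def layers(self) -> list[str]:
        return sorted(set(self.delta) | set(self.factor))


def _smooth_field(rows: int, cols: int, radius: float,
                  rng: np.random.Generator) -> np.ndarray:
    z = rng.standard_normal((rows, cols))
    if radius > 0:
        z = ndimage.gaussian_filter(z, sigma=radius, mode="reflect", truncate=3.0)
    return z


def generate_landscape(
    n_layers: int,
    shape: tuple[int, int] = (150, 150),
    smooth_radius: float = 3.0,
    corr_spec: dict[tuple[int, int], float] | np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    layer_names: list[str] | None = None,
    transform: GridTransform | None = None,
) -> GridStack:
    """Generate a stack of autocorrelated, standardized random layers.

    Parameters
    ----------
    corr_spec
        Optional target pairwise Pearson correlations between layers, either
        a full symmetric positive-definite matrix or a ``{(i, j): r}`` dict
        (unspecified pairs default to 0). The generated fields are first
        decorrelated exactly (empirical whitening) and then mixed by the
        Cholesky factor of the target matrix, so realized correlations match
        the targets to floating-point precision while remaining spatially
        smooth.
    """
    rows, cols = shape
    if rows < 20 or cols < 20:
        raise ValueError("shape must be at least 20x20 for smoothing validity")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if layer_names is None:
        layer_names = [f"env{i + 1}" for i in range(n_layers)]
    if len(layer_names) != n_layers:
        raise ValueError("need one name per layer")
    if transform is None:
        transform = GridTransform(x_origin=0.0, y_origin=float(rows), cell=1.0)

    fields = np.stack([_smooth_field(rows, cols, smooth_radius, rng)
                       for _ in range(n_layers)])
    flat = fields.reshape(n_layers, -1)
    flat = flat - flat.mean(axis=1, keepdims=True)

    if corr_spec is not None:
        target = np.eye(n_layers)
        if isinstance(corr_spec, dict):
            for (i, j), r in corr_spec.items():
                target[i, j] = target[j, i] = float(r)
        else:
            target = np.asarray(corr_spec, dtype=float)
            if target.shape != (n_layers, n_layers) or not np.allclose(target, target.T):
                raise ValueError("corr_spec matrix must be symmetric n_layers x n_layers")
        try:
            chol = np.linalg.cholesky(target)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "corr_spec is not positive definite; the requested pairwise "
                "correlations are jointly infeasible"
            ) from exc
        cov = flat @ flat.T / flat.shape[1]
        white = np.linalg.solve(np.linalg.cholesky(cov), flat)
        flat = chol @ white

    flat = flat / flat.std(axis=1, keepdims=True)
    return GridStack(
        layer_names=list(layer_names),
        values=flat.reshape(n_layers, rows, cols),
        transform=transform,
    )


def true_suitability(stack: GridStack, model: TrueModel) -> np.ndarray:
    """Gibbs suitability surface, normalized to sum 1 over valid cells.

    Returns a grid with NaN on invalid cells and
    ``exp(λ*·f(x)) / Σ exp`` elsewhere; ``f`` takes raw layer values
    (linear) and their squares (quadratic).
    """
    missing = [l for l in model.layers if l not in stack.layer_names]
    if missing:
        raise KeyError(f"true model references absent layers: {missing}")
    eta = np.zeros(stack.shape)
    for name, coef in model.linear.items():
        eta = eta + coef * stack.layer(name)
    for name, coef in model.quadratic.items():
        eta = eta + coef * stack.layer(name) ** 2
    mask = stack.valid_mask
    out = np.full(stack.shape, np.nan)
    e = eta[mask]
    e = np.exp(e - e.max())
    out[mask] = e / e.sum()
    return out


def sample_presences(
    suitability: np.ndarray,
    stack: GridStack,
    m: int,
    seed: int | np.random.Generator = 0,
    species: str = "virtual",
) -> OccurrenceSet:
    """Draw ``m`` presence cells ∝ suitability (with replacement).

    Points are placed at cell centers. Duplicated cells are intentional —
    real herbarium records cluster — and are thinned later by
    ``dedupe_to_cells`` when the pipeline asks for it.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flat = np.asarray(suitability, dtype=float).ravel()
    finite = np.isfinite(flat)
    total = flat[finite].sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("suitability surface is degenerate (no positive mass)")
    p = np.zeros_like(flat)
    p[finite] = flat[finite] / total
    idx = rng.choice(len(flat), size=m, replace=True, p=p)
    x, y = stack.cell_centers(idx)
    return OccurrenceSet(species=species, points=np.column_stack([x, y]))


def apply_shift(stack: GridStack, shift: ScenarioShift) -> GridStack:
    """Build a future stack: per named layer, ``value*factor + delta``.

    Untouched layers are copied verbatim; the validity mask is preserved.
    """
    unknown = [l for l in shift.layers if l not in stack.layer_names]
    if unknown:
        raise KeyError(f"shift {shift.label!r} references absent layers: {unknown}")
    out = stack.copy()
    for i, name in enumerate(out.layer_names):
        fac = shift.factor.get(name, 1.0)
        delta = shift.delta.get(name, 0.0)
        if fac != 1.0 or delta != 0.0:
            out.values[i] = out.values[i] * fac + delta
    return out
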