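"""Pearson-correlation collinearity screening of candidate predictors.

When two predictors are strongly correlated (|r| above a cut, 0.70 by
default), one of each offending pair is excluded before model fitting. The
comparison is strict: a pair at exactly |r| = 0.70 is retained. Which member
to drop is an expert call in practice; here the rule is deterministic and
documented — an optional priority list wins first, otherwise the member with
the larger mean |r| against the remaining candidates is dropped (it is the
more redundant one), with ties broken by reverse input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["FilterConfig", "FilterReport", "pearson_matrix", "greedy_collinearity_filter"]


@dataclass
class FilterConfig:
    threshold: float = 0.70
    priority: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")


@dataclass
class FilterReport:
    matrix: pd.DataFrame  # full symmetric r matrix over candidates
    kept: list[str]
    dropped: list[dict]  # each: {variable, partner, r}

    def write(self, matrix_csv: str | Path, summary_yaml: str | Path) -> None:
        self.matrix.to_csv(matrix_csv)
        Path(summary_yaml).write_text(
            yaml.safe_dump(
                {"kept": list(self.kept), "dropped": [dict(d) for d in self.dropped]},
                sort_keys=False,
            )
        )


def pearson_matrix(samples) -> pd.DataFrame:
    """Pairwise Pearson r between predictor columns of a sample table.

    Accepts a :class:`~sdmax.sampling.SampleTable` or a DataFrame. Requires
    at least 3 rows; a constant column makes r undefined and is an error
    naming the column.
    """
    df = samples.data if hasattr(samples, "data") else samples
    if len(df) < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    sd = df.std(ddof=0)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant column(s) make r undefined: {constant}")
    mat = df.corr(method="pearson")
    return mat


def greedy_collinearity_filter(
    matrix: pd.DataFrame, config: FilterConfig | None = None
) -> FilterReport:
    """Drop predictors until no retained pair exceeds the |r| threshold.

    Repeatedly resolves the not-yet-resolved pair with the largest |r| above
    the (strict) threshold, dropping the lower-priority member — or, with no
    priority given, the member more correlated on average with everything
    still in play. Idempotent: running it on its own kept set is a no-op.
    """
    config = config or FilterConfig()
    names = list(matrix.columns)
    r = matrix.to_numpy(dtype=float)
    if r.shape != (len(names), len(names)) or not np.allclose(r, r.T, atol=1e-12):
        raise ValueError("matrix must be symmetric with matching index/columns")

    alive = list(range(len(names)))
    dropped: list[dict] = []
    prio = {name: i for i, name in enumerate(config.priority)}

    def mean_abs_r(i: int) -> float:
        others = [j for j in alive if j != i]
        if not others:
            return 0.0
        return float(np.mean([abs(r[i, j]) for j in others]))

    while True:
        best: tuple[float, int, int] | None = None
        for ai, i in enumerate(alive):
            for j in alive[ai + 1:]:
                v = abs(r[i, j])
                if v > config.threshold and (best is None or v > best[0]):
                    best = (v, i, j)
        if best is None:
            break
        v, i, j = best
        pi, pj = prio.get(names[i]), prio.get(names[j])
        if pi is not None or pj is not None:
            # listed (or earlier-listed) variable is preferred for retention
            if pi is None:
                drop = i
            elif pj is None:
                drop = j
            else:
                drop = i if pi > pj else j
        else:
            mi, mj = mean_abs_r(i), mean_abs_r(j)
            if mi > mj:
                drop = i
            elif mj > mi:
                drop = j
            else:
                drop = max(i, j)  # tie: later input dropped first
        keep = j if drop == i else i
        alive.remove(drop)
        dropped.append(
            {"variable": names[drop], "partner": names[keep], "r": float(r[drop, keep])}
        )

    kept = [names[i] for i in alive]
    return FilterReport(matrix=matrix, kept=kept, dropped=dropped)
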