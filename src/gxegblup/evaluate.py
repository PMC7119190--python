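"""Prediction-accuracy metrics and report aggregation.

Genomic prediction accuracy is the Pearson correlation between predicted
genetic values (BLUPs/GEBVs) and the "observed" values, taken to be the
per-environment BLUEs from the full data. Accuracies are computed over the
masked cells only, per environment and pooled across environments
("combined"), then averaged over design replicates.

Pooled correlations mix environment mean differences with genetic signal;
``center_envs=True`` z-scores each environment's predictions and BLUEs
before pooling (off by default, matching the raw-pooling convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["accuracy", "summarize", "response_to_selection",
           "AccuracyReport"]

#: scope key for the pooled cross-environment correlation
COMBINED = "combined"


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r, or nan when undefined (fewer than 3 pairs/zero variance)."""
    if len(a) < 3 or np.std(a) == 0.0 or np.std(b) == 0.0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


def accuracy(predictions: pd.DataFrame, blues: pd.DataFrame,
             envs=None, center_envs: bool = False) -> dict:
    """Correlate predictions with BLUEs over masked cells.

    Parameters
    ----------
    predictions : DataFrame
        Columns ``line``, ``env`` and one of ``prediction`` (preferred) or
        ``gebv``/``value``; one row per masked cell.
    blues : DataFrame
        Columns ``line``, ``env``, ``blue`` (from
        :func:`gxegblup.model.compute_blues` on the full data).
    envs : sequence, optional
        Environments to report individually (default: those present).
    center_envs : bool
        Z-score both vectors within environment before pooling.

    Returns
    -------
    dict
        ``{env: r, ..., "combined": r}``; ``nan`` marks an undefined
        accuracy (never coerced to 0). Cells lacking a BLUE are dropped;
        their count is under the ``"n_dropped"`` key.
    """
    pred_col = next(c for c in ("prediction", "gebv", "value")
                    if c in predictions.columns)
    merged = predictions.merge(blues[["line", "env", "blue"]],
                               on=["line", "env"], how="left")
    n_dropped = int(merged["blue"].isna().sum())
    merged = merged.dropna(subset=["blue"])
    if envs is None:
        envs = sorted(merged["env"].unique())
    out = {}
    parts = []
    for e in envs:
        sub = merged[merged["env"] == e]
        x = sub[pred_col].to_numpy(dtype=float)
        y = sub["blue"].to_numpy(dtype=float)
        out[e] = _pearson(x, y)
        if center_envs and len(sub) >= 2 and x.std() > 0 and y.std() > 0:
            x = (x - x.mean()) / x.std()
            y = (y - y.mean()) / y.std()
        parts.append((x, y))
    if parts:
        xs = np.concatenate([p[0] for p in parts])
        ys = np.concatenate([p[1] for p in parts])
        out[COMBINED] = _pearson(xs, ys)
    else:
        out[COMBINED] = float("nan")
    out["n_dropped"] = n_dropped
    return out


@dataclass
class AccuracyReport:
    """Replicate-averaged accuracies for one scheme.

    ``mean``/``sd`` map scope (environment id or ``"combined"``) to the
    arithmetic mean and sample SD (n-1 denominator) over replicates with a
    defined accuracy; ``n_undefined`` counts the excluded replicates.
    """

    scheme: str
    mean: dict
    sd: dict
    n_replicates: int
    n_undefined: dict
    per_replicate: list = field(default_factory=list)
    seeds: list = field(default_factory=list)
    convergence: list = field(default_factory=list)
    trait: str = "trait"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for scope in self.mean:
            rows.append({
                "scheme": self.scheme, "trait": self.trait, "scope": scope,
                "mean_accuracy": self.mean[scope], "sd_accuracy": self.sd[scope],
                "n_replicates": self.n_replicates,
                "n_undefined": self.n_undefined[scope],
            })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme, "trait": self.trait,
            "mean": self.mean, "sd": self.sd,
            "n_replicates": self.n_replicates,
            "n_undefined": self.n_undefined,
            "per_replicate": self.per_replicate,
            "seeds": list(self.seeds),
            "convergence": [bool(c) for c in self.convergence],
        }


def summarize(per_replicate: list, scheme: str = "", seeds=None,
              convergence=None, trait: str = "trait") -> AccuracyReport:
    """Average per-replicate accuracy dicts into an :class:`AccuracyReport`.

    Replicates whose accuracy is undefined (nan) in a scope are excluded
    from that scope's mean/SD and counted in ``n_undefined``. A single
    defined replicate reports ``sd = nan`` (not available), and a scope with
    no defined replicates reports ``mean = nan``.
    """
    if not per_replicate:
        raise ValueError("need >= 1 replicate")
    scopes = [k for k in per_replicate[0] if k != "n_dropped"]
    mean, sd, n_undef = {}, {}, {}
    for scope in scopes:
        vals = np.array([rep.get(scope, float("nan"))
                         for rep in per_replicate], dtype=float)
        ok = vals[~np.isnan(vals)]
        n_undef[scope] = int(np.isnan(vals).sum())
        mean[scope] = float(ok.mean()) if ok.size else float("nan")
        sd[scope] = float(ok.std(ddof=1)) if ok.size > 1 else float("nan")
    return AccuracyReport(
        scheme=scheme, mean=mean, sd=sd,
        n_replicates=len(per_replicate), n_undefined=n_undef,
        per_replicate=[{k: (None if isinstance(v, float) and math.isnan(v)
                            else v) for k, v in rep.items()}
                       for rep in per_replicate],
        seeds=list(seeds or []), convergence=list(convergence or []),
        trait=trait)


def response_to_selection(i: float, r: float, sigma_a: float,
                          L: float) -> float:
    """Breeder's equation: response per year ``R = i * r * sigma_a / L``.

    Parameters
    ----------
    i : selection intensity (standardized selection differential)
    r : selection accuracy
    sigma_a : additive genetic standard deviation, trait units
    L : generation interval, years (must be positive)
    """
    if L <= 0:
        raise ValueError(f"generation interval must be positive, got {L}")
    if sigma_a < 0:
        raise ValueError(f"sigma_a must be nonnegative, got {sigma_a}")
    return i * r * sigma_a / L
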