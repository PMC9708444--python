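"""CASP-style assessment of a quality-assessment method over decoy sets.

Per target: Pearson r and Spearman rho between predicted and observed
GDT-TS, the absolute loss d = |predicted - observed| of the top-ranked
decoy, and the GDT-TS loss g, i.e. how much observed quality the method
forfeits by not picking the truly best decoy.  Aggregates are unweighted
means +/- sample standard deviation across targets; method comparison is
a two-sample Kolmogorov-Smirnov test on per-target metric distributions.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


@dataclasses.dataclass
class DecoySet:
    """Predicted and observed GDT-TS for the decoys of one target."""

    target_id: str
    model_ids: list[str]
    predicted: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.observed = np.asarray(self.observed, dtype=float)
        n = len(self.model_ids)
        if self.predicted.shape != (n,) or self.observed.shape != (n,):
            raise ValidationError(f"{self.target_id}: ragged decoy set")
        if n == 0:
            raise ValidationError(f"{self.target_id}: empty decoy set")
        for name, arr in (("predicted", self.predicted), ("observed", self.observed)):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{self.target_id}: non-finite {name} scores")
            if arr.min() < 0.0 or arr.max() > 1.0:
                raise ValidationError(f"{self.target_id}: {name} scores outside [0, 1]")

    def __len__(self) -> int:
        return len(self.model_ids)

    def _top_by_predicted(self) -> int:
        """Index of the top-ranked decoy; ties go to the smallest model id."""
        return min(range(len(self)),
                   key=lambda i: (-self.predicted[i], self.model_ids[i]))

    def _best_by_observed(self) -> int:
        return min(range(len(self)),
                   key=lambda i: (-self.observed[i], self.model_ids[i]))


def absolute_loss(decoys: DecoySet) -> float:
    """d = |predicted - observed| GDT-TS of the method's top-ranked decoy."""
    top = decoys._top_by_predicted()
    return float(abs(decoys.predicted[top] - decoys.observed[top]))


def gdt_loss(decoys: DecoySet, convention: str = "conventional") -> float:
    """g: the error by which the method misses the best available decoy.

    'conventional' (CASP usage, default): observed score of the truly best
    decoy minus observed score of the method's pick (always >= 0).
    'predicted_vs_best': |predicted score of the pick - observed score of
    the best decoy|, a literal reading of the loss formula kept for
    comparison.
    """
    if len(decoys) < 2:
        raise ValidationError("gdt_loss needs at least 2 decoys")
    top = decoys._top_by_predicted()
    best = decoys._best_by_observed()
    if convention == "conventional":
        return float(decoys.observed[best] - decoys.observed[top])
    if convention == "predicted_vs_best":
        return float(abs(decoys.predicted[top] - decoys.observed[best]))
    raise ValueError(f"unknown convention {convention!r}")


def correlations(decoys: DecoySet) -> tuple[Optional[float], Optional[float]]:
    """(Pearson r, Spearman rho); (None, None) when either score vector is
    constant and the correlation undefined."""
    if len(decoys) < 3:
        raise ValidationError("correlations need at least 3 decoys")
    if np.ptp(decoys.predicted) == 0.0 or np.ptp(decoys.observed) == 0.0:
        return None, None
    r = float(stats.pearsonr(decoys.predicted, decoys.observed)[0])
    rho = float(stats.spearmanr(decoys.predicted, decoys.observed)[0])
    return r, rho


@dataclasses.dataclass
class EvaluationReport:
    """Per-target metrics and their unweighted aggregates."""

    per_target: pd.DataFrame
    aggregates: dict[str, tuple[float, float]]
    n_targets: int
    n_correlation_excluded: int
    single_target: bool = False

    def to_json_dict(self) -> dict:
        return {
            "n_targets": self.n_targets,
            "n_correlation_excluded": self.n_correlation_excluded,
            "aggregates": {k: {"mean": m, "sd": s}
                           for k, (m, s) in self.aggregates.items()},
            "per_target": self.per_target.to_dict(orient="records"),
        }


def evaluate_method(
    sets: Iterable[DecoySet],
    convention: str = "conventional",
) -> EvaluationReport:
    """Target-wise r, rho, d, g and their mean +/- sample sd.

    Targets with undefined correlations (constant score vectors) are
    excluded from the r/rho aggregates and counted in the report.
    """
    sets = list(sets)
    if not sets:
        raise ValidationError("no decoy sets to evaluate")
    rows = []
    excluded = 0
    for ds in sets:
        r = rho = None
        if len(ds) >= 3:
            r, rho = correlations(ds)
            if r is None:
                excluded += 1
        g = gdt_loss(ds, convention) if len(ds) >= 2 else np.nan
        rows.append({
            "target_id": ds.target_id, "n_decoys": len(ds),
            "pearson_r": np.nan if r is None else r,
            "spearman_rho": np.nan if rho is None else rho,
            "absolute_loss": absolute_loss(ds),
            "gdt_loss": g,
        })
    per_target = pd.DataFrame(rows).sort_values("target_id").reset_index(drop=True)

    aggregates: dict[str, tuple[float, float]] = {}
    for col in ("pearson_r", "spearman_rho", "absolute_loss", "gdt_loss"):
        vals = per_target[col].dropna().to_numpy()
        if vals.size == 0:
            aggregates[col] = (float("nan"), float("nan"))
        elif vals.size == 1:
            aggregates[col] = (float(vals[0]), 0.0)
        else:
            aggregates[col] = (float(vals.mean()), float(vals.std(ddof=1)))
    return EvaluationReport(
        per_target=per_target, aggregates=aggregates, n_targets=len(sets),
        n_correlation_excluded=excluded, single_target=len(sets) == 1)


def compare_methods(
    per_target_metric_a: Sequence[float],
    per_target_metric_b: Sequence[float],
) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test on per-target metrics.

    Returns (statistic, p-value); exact p for small samples, asymptotic
    otherwise (scipy's automatic switch).
    """
    a = np.asarray(per_target_metric_a, dtype=float)
    b = np.asarray(per_target_metric_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValidationError("method comparison needs at least 5 targets per sample")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
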