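"""Linear models of normalized B values.

Two model kinds are supported:

* ``contact`` — simple linear regression on the number of contacts (orbit
  O0 only), the classical baseline; the published fit has intercept 0 and
  slope -0.64 at a 7.0 Å cutoff and ships as the built-in preset.
* ``gdv`` — multiple linear regression on all 15 orbit degrees
  (graphlet degree vector), B_n = b0 + sum_k beta_k O_{n,k}.

Fitting is ordinary least squares (statsmodels) on z-scored features and a
z-scored response; variable importance is the absolute t-statistic rescaled
so the top variable scores 100.  Model accuracy is summarized as the
Pearson correlation between predicted and deposited normalized B values,
computed per structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import BValueVector, FeatureMatrix
from .graphlet_orbits import N_ORBITS

__all__ = [
    "CoefficientSet",
    "FitReport",
    "EvaluationReport",
    "fit_linear",
    "predict",
    "evaluate_correlation",
    "crossvalidate",
    "variable_importance",
    "contact_preset",
    "read_coefficients",
    "write_coefficients",
    "rescale_to_raw",
]


@dataclass
class CoefficientSet:
    """Intercept and per-orbit regression coefficients."""

    intercept: float
    betas: dict[int, float]
    model_kind: str  # "contact" or "gdv"
    cutoff: float | None = None
    provenance: str = "user"  # "fitted", "preset" or "user"

    def __post_init__(self) -> None:
        if self.model_kind == "contact":
            if set(self.betas) != {0}:
                raise ValueError("contact model takes exactly one beta, for O0")
        elif self.model_kind == "gdv":
            if set(self.betas) != set(range(N_ORBITS)):
                raise ValueError(f"gdv model needs betas for O0..O{N_ORBITS - 1}")
        else:
            raise ValueError(f"unknown model_kind: {self.model_kind!r}")

    @property
    def orbit_indices(self) -> list[int]:
        return sorted(self.betas)

    def beta_vector(self) -> np.ndarray:
        return np.array([self.betas[k] for k in self.orbit_indices], dtype=float)


@dataclass
class FitReport:
    coefficients: CoefficientSet
    t_statistics: np.ndarray  # per beta, intercept excluded
    importance: np.ndarray  # |t| rescaled so max == 100
    r_squared: float
    n_obs: int


@dataclass
class EvaluationReport:
    """Per-entry Pearson correlations, optionally for both model kinds."""

    per_entry: pd.DataFrame  # columns: entry_id, model_kind, pearson_r

    @property
    def summary(self) -> pd.DataFrame:
        return (
            self.per_entry.groupby("model_kind")["pearson_r"]
            .agg(["mean", "median", "min", "max", "count"])
            .reset_index()
        )

    @property
    def deltas(self) -> pd.DataFrame | None:
        """Per-entry r(gdv) - r(contact) where both model kinds are present."""
        kinds = set(self.per_entry["model_kind"])
        if not {"gdv", "contact"} <= kinds:
            return None
        wide = self.per_entry.pivot(
            index="entry_id", columns="model_kind", values="pearson_r"
        ).dropna()
        return (wide["gdv"] - wide["contact"]).rename("delta_r").reset_index()


def contact_preset() -> CoefficientSet:
    """The published contact model: B_p = -0.64 * O0 (intercept 0, 7.0 Å)."""
    return CoefficientSet(
        intercept=0.0,
        betas={0: -0.64},
        model_kind="contact",
        cutoff=7.0,
        provenance="preset",
    )


def _design(features: FeatureMatrix, orbit_indices: Sequence[int]) -> np.ndarray:
    v = features.values
    if v.shape[1] == len(orbit_indices):
        return v
    if v.shape[1] == N_ORBITS:
        return v[:, list(orbit_indices)]
    raise ValueError(
        f"feature matrix has {v.shape[1]} columns; expected {len(orbit_indices)} "
        f"or {N_ORBITS}"
    )


def fit_linear(
    features: FeatureMatrix,
    response: BValueVector,
    model_kind: str = "gdv",
) -> FitReport:
    """Ordinary least squares fit of normalized B on orbit features.

    The design is the full 15-column GDV (or the single O0 column for the
    contact model) plus an intercept.  Raises on rank-deficient designs,
    naming the collinear columns.
    """
    import statsmodels.api as sm

    orbit_indices = [0] if model_kind == "contact" else list(range(N_ORBITS))
    X = _design(features, orbit_indices)
    y = np.asarray(response.values, dtype=float)
    if X.shape[0] != len(y):
        raise ValueError("features and response have different lengths")
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError(
            f"need more than {X.shape[1] + 1} observations, got {X.shape[0]}"
        )
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X]))
    if rank < X.shape[1] + 1:
        corr = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        pairs = np.argwhere(np.isclose(np.abs(corr), 1.0))
        cols = sorted({f"O{orbit_indices[i]}" for i, _ in pairs})
        raise ValueError(f"rank-deficient design; collinear columns: {cols or 'constant'}")
    res = sm.OLS(y, sm.add_constant(X)).fit()
    betas = {k: float(b) for k, b in zip(orbit_indices, res.params[1:])}
    coeffs = CoefficientSet(
        intercept=float(res.params[0]),
        betas=betas,
        model_kind=model_kind,
        cutoff=features.cutoff,
        provenance="fitted",
    )
    t = np.asarray(res.tvalues[1:], dtype=float)
    imp = np.minimum(100.0 * np.abs(t) / np.abs(t).max(), 100.0)
    return FitReport(
        coefficients=coeffs,
        t_statistics=t,
        importance=imp,
        r_squared=float(res.rsquared),
        n_obs=int(res.nobs),
    )


def predict(features: FeatureMatrix, coefficients: CoefficientSet) -> np.ndarray:
    """b0 + sum_k beta_k * O_{n,k}; no clipping of the output."""
    X = _design(features, coefficients.orbit_indices)
    return coefficients.intercept + X @ coefficients.beta_vector()


def evaluate_correlation(predicted: Sequence[float], reference: Sequence[float]) -> float:
    """Pearson correlation between predicted and deposited values."""
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if len(p) != len(r):
        raise ValueError("length mismatch")
    if len(p) < 3:
        raise ValueError("need at least 3 points")
    if p.std() == 0 or r.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(p, r).statistic)


def crossvalidate(
    entries: Sequence[tuple[FeatureMatrix, BValueVector]],
    k: int = 10,
    seed: int = 0,
    model_kind: str = "gdv",
    entry_ids: Sequence[str] | None = None,
) -> EvaluationReport:
    """k-fold cross-validation with folds split by *structure*, not by atom.

    Each fold fits one model on the pooled atoms of the training structures
    and records, for every held-out structure, the Pearson correlation
    between its predicted and its deposited normalized B values.
    """
    n = len(entries)
    if n < k:
        raise ValueError(f"need at least k={k} entries, got {n}")
    if entry_ids is None:
        entry_ids = [f"entry{i:03d}" for i in range(n)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = [order[f::k] for f in range(k)]
    rows = []
    for fold in folds:
        test = set(int(i) for i in fold)
        X_train = np.vstack(
            [entries[i][0].values for i in range(n) if i not in test]
        )
        y_train = np.concatenate(
            [entries[i][1].values for i in range(n) if i not in test]
        )
        report = fit_linear(
            FeatureMatrix(X_train, cutoff=entries[0][0].cutoff),
            BValueVector(y_train, scale="normalized"),
            model_kind=model_kind,
        )
        for i in sorted(test):
            pred = predict(entries[i][0], report.coefficients)
            rows.append(
                {
                    "entry_id": entry_ids[i],
                    "model_kind": model_kind,
                    "pearson_r": evaluate_correlation(pred, entries[i][1].values),
                }
            )
    return EvaluationReport(per_entry=pd.DataFrame(rows))


def variable_importance(report: FitReport) -> pd.DataFrame:
    """|t|-based importance table, max scaled to 100, sorted descending."""
    labels = [f"O{k}" for k in report.coefficients.orbit_indices]
    df = pd.DataFrame(
        {
            "orbit": labels,
            "t_statistic": report.t_statistics,
            "importance": report.importance,
        }
    )
    return df.sort_values("importance", ascending=False).reset_index(drop=True)


def rescale_to_raw(
    normalized: Sequence[float], mean_b: float, sd_b: float
) -> np.ndarray:
    """Map normalized predictions back to Å² given a target mean and sd.

    Only as reliable as the supplied moments: at a given resolution the
    plausible mean/sd ranges are wide, so absolute-scale predictions should
    be treated with caution.
    """
    if sd_b <= 0:
        raise ValueError("sd_b must be positive")
    return mean_b + sd_b * np.asarray(normalized, dtype=float)


def write_coefficients(coefficients: CoefficientSet, path: str | Path) -> None:
    """Serialize as round-trippable key=value text."""
    lines = [
        f"model_kind={coefficients.model_kind}",
        f"cutoff={'' if coefficients.cutoff is None else coefficients.cutoff!r}",
        f"provenance={coefficients.provenance}",
        f"intercept={coefficients.intercept!r}",
    ]
    for k in coefficients.orbit_indices:
        lines.append(f"O{k}={coefficients.betas[k]!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_coefficients(path: str | Path) -> CoefficientSet:
    kv: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        kv[key.strip()] = val.strip()
    try:
        betas = {
            int(key[1:]): float(val)
            for key, val in kv.items()
            if key.startswith("O") and key[1:].isdigit()
        }
        return CoefficientSet(
            intercept=float(kv["intercept"]),
            betas=betas,
            model_kind=kv["model_kind"],
            cutoff=float(kv["cutoff"]) if kv.get("cutoff") else None,
            provenance=kv.get("provenance", "user"),
        )
    except KeyError as exc:
        raise ValueError(f"coefficient file {path} missing key {exc}") from exc
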