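"""Fish total-length reconstruction from bone measurements.

Estimated total length (ETL) is obtained from quadratic regressions of
total length on cranial-bone measurements (dentary, premaxilla,
basioccipital), fitted to a modern reference collection of skeletons of
known length. Specimens too fragmentary to measure carry only a relative
size class (e.g. "800-1000 mm"), which is mapped to a normal prior.

Both routes produce a (mean, sd) pair that downstream errors-in-variables
models consume as the prior for the latent true length.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SizeModel",
    "SizeClassPrior",
    "fit_size_model",
    "predict_etl",
    "size_class_prior",
    "size_priors_from_table",
]


@dataclass
class SizeModel:
    """Quadratic osteometric regression with predictive uncertainty.

    ``coef`` is ordered (intercept, then linear and quadratic terms per
    predictor); ``coef_cov`` is the OLS covariance of those coefficients.
    """

    element: str
    form: str  # "bivariate" (1 predictor) or "multivariate"
    predictors: list[str]
    coef: np.ndarray
    coef_cov: np.ndarray
    residual_sd: float
    n_reference: int

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        self.coef_cov = np.asarray(self.coef_cov, dtype=float)
        if self.residual_sd < 0:
            raise ValueError("residual sd must be non-negative")
        if self.n_reference < len(self.coef):
            raise ValueError("fewer reference specimens than coefficients")

    @property
    def term_names(self) -> list[str]:
        names = ["intercept"]
        for p in self.predictors:
            names += [p, f"{p}^2"]
        return names

    def design_row(self, measurements) -> np.ndarray:
        """Build the (1, m, m^2, ...) design row(s) for measurement input."""
        if isinstance(measurements, pd.DataFrame):
            missing = [p for p in self.predictors if p not in measurements.columns]
            if missing:
                raise KeyError(f"missing predictors: {missing}")
            m = measurements[self.predictors].to_numpy(dtype=float)
        elif isinstance(measurements, dict):
            missing = [p for p in self.predictors if p not in measurements]
            if missing:
                raise KeyError(f"missing predictors: {missing}")
            m = np.array([[measurements[p] for p in self.predictors]], dtype=float)
        else:
            m = np.atleast_2d(np.asarray(measurements, dtype=float))
            if m.shape[1] != len(self.predictors):
                raise ValueError(
                    f"expected {len(self.predictors)} measurements, got {m.shape[1]}"
                )
        cols = [np.ones(len(m))]
        for j in range(m.shape[1]):
            cols += [m[:, j], m[:, j] ** 2]
        return np.column_stack(cols)

    def to_json(self) -> str:
        return json.dumps(
            {
                "element": self.element,
                "form": self.form,
                "predictors": self.predictors,
                "terms": self.term_names,
                "coef": self.coef.tolist(),
                "coef_cov": self.coef_cov.tolist(),
                "residual_sd": self.residual_sd,
                "n_reference": self.n_reference,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SizeModel":
        d = json.loads(text)
        return cls(
            element=d["element"],
            form=d["form"],
            predictors=list(d["predictors"]),
            coef=np.array(d["coef"]),
            coef_cov=np.array(d["coef_cov"]),
            residual_sd=float(d["residual_sd"]),
            n_reference=int(d["n_reference"]),
        )


@dataclass(frozen=True)
class SizeClassPrior:
    """Normal prior for true length implied by a relative size class."""

    label: str
    lower: float
    upper: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"size class {self.label!r}: lower must be < upper")
        if not (self.lower <= self.mean <= self.upper):
            raise ValueError(f"size class {self.label!r}: mean outside bounds")
        if self.sd <= 0:
            raise ValueError(f"size class {self.label!r}: sd must be positive")


def fit_size_model(
    reference: pd.DataFrame,
    predictors: list[str] | None = None,
    element: str = "dentary",
    length_column: str = "total_length",
) -> SizeModel:
    """OLS fit of total length on quadratic terms of bone measurements.

    ``reference`` holds one row per modern skeleton with measurement
    columns (mm) and known ``total_length`` (mm). One predictor gives the
    bivariate form; several give the multivariate form (linear and
    quadratic terms per predictor, no cross terms). Residual sd uses the
    n - p denominator.
    """
    if predictors is None:
        predictors = [c for c in reference.columns if c != length_column]
    if not predictors:
        raise ValueError("no predictor columns")
    y = reference[length_column].to_numpy(dtype=float)
    if (y <= 0).any():
        raise ValueError("all reference total lengths must be positive")
    p = 1 + 2 * len(predictors)
    if len(reference) < 3 * len(predictors) + 1:
        raise ValueError(
            f"need at least {3 * len(predictors) + 1} reference rows, got {len(reference)}"
        )
    m = reference[predictors].to_numpy(dtype=float)
    cols = [np.ones(len(m))]
    names = ["intercept"]
    for j, name in enumerate(predictors):
        cols += [m[:, j], m[:, j] ** 2]
        names += [name, f"{name}^2"]
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise np.linalg.LinAlgError(
            f"rank-deficient osteometric design; collinear columns: {bad}"
        )
    res = sm.OLS(y, X).fit()
    resid_sd = float(np.sqrt(res.ssr / (len(y) - p)))
    return SizeModel(
        element=element,
        form="bivariate" if len(predictors) == 1 else "multivariate",
        predictors=list(predictors),
        coef=res.params,
        coef_cov=res.cov_params(),
        residual_sd=resid_sd,
        n_reference=len(reference),
    )


def predict_etl(model: SizeModel, measurements):
    """Predict estimated total length and its sd for new measurements.

    The sd combines the regression residual sd and the coefficient-
    covariance prediction variance in quadrature, i.e. it is the sd of a
    new individual's length, not of the mean response.
    """
    X = model.design_row(measurements)
    mean = X @ model.coef
    var_fit = np.einsum("ij,jk,ik->i", X, model.coef_cov, X)
    sd = np.sqrt(model.residual_sd**2 + var_fit)
    if np.ndim(measurements) == 0 or isinstance(measurements, dict):
        return float(mean[0]), float(sd[0])
    if mean.shape[0] == 1 and not isinstance(measurements, pd.DataFrame):
        arr = np.asarray(measurements)
        if arr.ndim == 1:
            return float(mean[0]), float(sd[0])
    return mean, sd


_CLASS_RE = re.compile(
    r"^\s*(\d+(?:\.\d+)?)\s*[-−–]\s*(\d+(?:\.\d+)?)\s*mm\s*$"
)


def size_class_prior(label: str) -> SizeClassPrior:
    """Map a relative size-class label like ``"800-1000 mm"`` to a prior.

    The normal prior takes the class midpoint as mean and a quarter of the
    class range as sd, so the class spans mean +/- 2 sd (~95.4% of mass
    inside the class).
    """
    m = _CLASS_RE.match(label)
    if m is None:
        raise ValueError(
            f"cannot parse size class {label!r}; expected '<lo>-<hi> mm'"
        )
    lo, hi = float(m.group(1)), float(m.group(2))
    if not lo < hi:
        raise ValueError(f"size class {label!r}: lower bound must be below upper")
    return SizeClassPrior(
        label=label, lower=lo, upper=hi, mean=(lo + hi) / 2, sd=(hi - lo) / 4
    )


def size_priors_from_table(
    records: pd.DataFrame,
    model: SizeModel | None = None,
    class_column: str = "size_class",
) -> pd.DataFrame:
    """Resolve a per-specimen length prior (etl_mean, etl_sd) for each record.

    Measured ETL (either precomputed ``etl_mean``/``etl_sd`` columns or
    bone measurements run through ``model``) takes precedence; the size-
    class prior is the fallback for unmeasurable specimens.
    """
    out = records.copy()
    if "etl_mean" not in out.columns:
        out["etl_mean"] = np.nan
        out["etl_sd"] = np.nan
    if model is not None:
        have = out[model.predictors].notna().all(axis=1) if all(
            p in out.columns for p in model.predictors
        ) else pd.Series(False, index=out.index)
        if have.any():
            mean, sd = predict_etl(model, out.loc[have, model.predictors])
            out.loc[have, "etl_mean"] = mean
            out.loc[have, "etl_sd"] = sd
    if class_column in out.columns:
        need = out["etl_mean"].isna() & out[class_column].notna()
        for idx in out.index[need]:
            prior = size_class_prior(str(out.at[idx, class_column]))
            out.at[idx, "etl_mean"] = prior.mean
            out.at[idx, "etl_sd"] = prior.sd
    return out
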