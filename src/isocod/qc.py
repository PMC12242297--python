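"""Collagen and amino-acid quality control.

Implements the screening steps applied before any modelling:

* atomic C:N screening of bulk collagen (acceptable preservation window),
* per-batch linear calibration of raw delta-15N against reference standards,
* mass-balance reconstruction of bulk collagen delta-15N from the
  amino-acid values and their nitrogen fractions, and
* the estimated-vs-observed bulk offset filter (2 sd exclusion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import (
    ALL_AAS,
    CN_RATIO_MAX,
    CN_RATIO_MIN,
    NITROGEN_FRACTIONS,
    aa_column,
)

__all__ = [
    "AAProfile",
    "CalibrationStandard",
    "CalibrationCurve",
    "EstObsFilterResult",
    "check_cn_ratio",
    "fit_calibration",
    "apply_calibration",
    "estimate_bulk_from_aas",
    "qc_est_obs_filter",
    "propagate_uncertainty",
]


@dataclass
class AAProfile:
    """Per-amino-acid delta-15N values with uncertainties and N fractions.

    Parameters
    ----------
    values : mapping of AA name -> delta-15N (per mil vs AIR)
    sds : mapping of AA name -> replicate sd (per mil); defaults to 0
    counts : mapping of AA name -> replicate count; defaults to 1
    fractions : mapping of AA name -> nitrogen fraction of bulk collagen;
        defaults to the standard composition in :mod:`isocod.constants`.
        Fractions must be non-negative and sum to at most 1 (partial
        coverage of collagen nitrogen is the normal case).
    """

    values: dict[str, float]
    sds: dict[str, float] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    fractions: dict[str, float] = field(default_factory=lambda: dict(NITROGEN_FRACTIONS))

    def __post_init__(self) -> None:
        for aa, sd in self.sds.items():
            if sd < 0:
                raise ValueError(f"negative sd for {aa}: {sd}")
        fr = np.asarray(list(self.fractions.values()), dtype=float)
        if (fr < 0).any():
            raise ValueError("nitrogen fractions must be non-negative")
        if fr.sum() > 1 + 1e-9:
            raise ValueError(f"nitrogen fractions sum to {fr.sum():.4f} > 1")


@dataclass(frozen=True)
class CalibrationStandard:
    """A reference standard: its raw (measured) and true delta-15N."""

    name: str
    raw: float
    true: float
    raw_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.raw_sd < 0:
            raise ValueError(f"negative raw_sd for standard {self.name!r}")


@dataclass(frozen=True)
class CalibrationCurve:
    """Per-batch linear calibration: true = slope * raw + intercept."""

    batch: str
    slope: float
    intercept: float
    residual_sd: float
    n_standards: int

    def __post_init__(self) -> None:
        if self.n_standards < 2:
            raise ValueError("a calibration curve needs at least 2 standards")
        if self.residual_sd < 0:
            raise ValueError("negative residual sd")


def check_cn_ratio(ratio: float) -> bool:
    """Screen a bulk-collagen atomic C:N ratio for acceptable preservation.

    Returns True iff the ratio lies in the closed interval
    [3.0, 3.6]; non-positive ratios are physically impossible and raise.
    """
    if ratio <= 0:
        raise ValueError(f"atomic C:N ratio must be positive, got {ratio}")
    return CN_RATIO_MIN <= ratio <= CN_RATIO_MAX


def fit_calibration(
    standards: Sequence[CalibrationStandard], batch: str = "batch"
) -> CalibrationCurve:
    """Ordinary least-squares calibration line, true vs raw delta-15N.

    Each analytical batch is calibrated with its own curve. The fit is
    unweighted; the raw sds of the standards enter the uncertainty of
    corrected values (see :func:`apply_calibration`), not the fit.
    """
    if len(standards) < 2:
        raise ValueError("need at least 2 calibration standards")
    raw = np.array([s.raw for s in standards], dtype=float)
    true = np.array([s.true for s in standards], dtype=float)
    if np.ptp(raw) == 0:
        raise np.linalg.LinAlgError(
            "singular calibration design: all raw values are equal"
        )
    res = stats.linregress(raw, true)
    fitted = res.intercept + res.slope * raw
    dof = max(len(standards) - 2, 1)
    resid_sd = math.sqrt(float(np.sum((true - fitted) ** 2)) / dof)
    return CalibrationCurve(
        batch=batch,
        slope=float(res.slope),
        intercept=float(res.intercept),
        residual_sd=resid_sd,
        n_standards=len(standards),
    )


def apply_calibration(curve: CalibrationCurve, raw, raw_sd=None):
    """Correct raw delta-15N values with a batch calibration curve.

    Returns ``slope * raw + intercept``. When ``raw_sd`` is given, also
    returns the corrected sd: the raw sd scaled by ``|slope|`` combined in
    quadrature with the curve's residual sd.
    """
    corrected = curve.slope * np.asarray(raw, dtype=float) + curve.intercept
    if np.ndim(raw) == 0:
        corrected = float(corrected)
    if raw_sd is None:
        return corrected
    sd = np.hypot(abs(curve.slope) * np.asarray(raw_sd, dtype=float), curve.residual_sd)
    if np.ndim(raw_sd) == 0:
        sd = float(sd)
    return corrected, sd


def estimate_bulk_from_aas(profile: AAProfile | Mapping[str, float],
                           fractions: Mapping[str, float] | None = None) -> float:
    """Mass-balance estimate of bulk collagen delta-15N from AA values.

    The estimate is the nitrogen-fraction-weighted mean of the measured
    amino-acid values, with the fractions renormalized over the AAs
    actually present. Renormalization makes partial coverage (the AA
    measurements capture ~80.7% of collagen nitrogen) an unbiased
    weighted mean rather than a systematically low total.
    """
    if isinstance(profile, AAProfile):
        values = profile.values
        fractions = profile.fractions if fractions is None else fractions
    else:
        values = dict(profile)
        fractions = NITROGEN_FRACTIONS if fractions is None else fractions
    keys = [aa for aa in values if aa in fractions and np.isfinite(values[aa])]
    if not keys:
        raise ValueError("empty amino-acid profile: no values with known fractions")
    f = np.array([fractions[aa] for aa in keys], dtype=float)
    v = np.array([values[aa] for aa in keys], dtype=float)
    if f.sum() <= 0:
        raise ValueError("nitrogen fractions sum to zero over measured AAs")
    return float(np.dot(f, v) / f.sum())


@dataclass
class EstObsFilterResult:
    """Outcome of the estimated-vs-observed bulk delta-15N filter."""

    kept: pd.DataFrame
    excluded: pd.DataFrame
    offsets: pd.DataFrame  # per-record est, obs, offset, excluded flag
    mean_offset: float
    sd_offset: float

    def __iter__(self):  # (kept, excluded, offsets) unpacking
        return iter((self.kept, self.excluded, self.offsets))


def qc_est_obs_filter(
    records: pd.DataFrame,
    fractions: Mapping[str, float] | None = None,
    obs_column: str = "d15N_bulk",
    n_sd: float = 2.0,
) -> EstObsFilterResult:
    """Exclude specimens whose mass-balance bulk estimate disagrees with EA-IRMS.

    For each record the offset ``d15N_Est - d15N_Obs`` is computed; records
    whose offset lies more than ``n_sd`` sample standard deviations from the
    mean offset are excluded. The threshold is computed once from all
    offsets (no iterative re-trimming).
    """
    if len(records) < 3:
        raise ValueError(
            f"est-vs-obs filter needs at least 3 records, got {len(records)}"
        )
    if obs_column not in records.columns:
        raise KeyError(f"records lack observed bulk column {obs_column!r}")
    fractions = NITROGEN_FRACTIONS if fractions is None else fractions
    aa_cols = {aa: aa_column(aa) for aa in ALL_AAS if aa_column(aa) in records.columns}
    if not aa_cols:
        raise ValueError("records carry no amino-acid d15N columns")

    est = np.empty(len(records), dtype=float)
    for i, (_, row) in enumerate(records.iterrows()):
        values = {aa: row[col] for aa, col in aa_cols.items() if pd.notna(row[col])}
        est[i] = estimate_bulk_from_aas(values, fractions)
    obs = records[obs_column].to_numpy(dtype=float)
    offset = est - obs
    mean = float(np.mean(offset))
    sd = float(np.std(offset, ddof=1))
    # numerically identical offsets (sd at round-off scale) exclude nothing
    tiny = 1e-10 * max(1.0, float(np.max(np.abs(offset), initial=0.0)))
    bad = np.abs(offset - mean) > n_sd * sd if sd > tiny else np.zeros(len(offset), bool)

    offsets = pd.DataFrame(
        {
            "d15N_est": est,
            "d15N_obs": obs,
            "offset": offset,
            "excluded": bad,
        },
        index=records.index,
    )
    if "specimen_id" in records.columns:
        offsets.insert(0, "specimen_id", records["specimen_id"].to_numpy())
    return EstObsFilterResult(
        kept=records.loc[~bad].copy(),
        excluded=records.loc[bad].copy(),
        offsets=offsets,
        mean_offset=mean,
        sd_offset=sd,
    )


def propagate_uncertainty(standard_sd: float, replicate_sd: float) -> float:
    """Combine standard-derived and replicate sds in quadrature."""
    if standard_sd < 0 or replicate_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    return math.hypot(standard_sd, replicate_sd)
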