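"""Collagen / amino-acid QC: C:N screen, calibration, mass balance, filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isocod.constants import ALL_AAS, NITROGEN_FRACTIONS, aa_column
from isocod.qc import (
    AAProfile,
    CalibrationStandard,
    apply_calibration,
    check_cn_ratio,
    estimate_bulk_from_aas,
    fit_calibration,
    propagate_uncertainty,
    qc_est_obs_filter,
)

# the nine AA reference standards: (name, raw, true) delta-15N in per mil
NINE_STANDARDS = [
    ("Ala", 41.50, 43.25),
    ("Gly", -1.08, 1.76),
    ("Val", -6.68, -5.21),
    ("Leu", 4.4, 6.22),
    ("Nle", 12.60, 13.96),
    ("Asx", 32.99, 35.2),
    ("Glx", -5.53, -4.52),
    ("Hyp", -9.95, -9.17),
    ("Phe", 0.70, 1.70),
]


class TestCNRatio:
    @pytest.mark.parametrize(
        "ratio,expected",
        [(3.0, True), (3.6, True), (3.3, True), (2.99, False), (3.61, False)],
    )
    def test_closed_interval(self, ratio, expected):
        assert check_cn_ratio(ratio) is expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            check_cn_ratio(0.0)


class TestCalibration:
    def test_identity_curve(self):
        stds = [CalibrationStandard(n, r, r) for n, r, _ in NINE_STANDARDS]
        curve = fit_calibration(stds)
        assert curve.slope == pytest.approx(1.0, abs=1e-12)
        assert curve.intercept == pytest.approx(0.0, abs=1e-10)
        assert apply_calibration(curve, 5.0) == pytest.approx(5.0, abs=1e-10)

    def test_pure_offset(self):
        stds = [CalibrationStandard(n, r, r + 1.5) for n, r, _ in NINE_STANDARDS]
        curve = fit_calibration(stds)
        assert curve.slope == pytest.approx(1.0, abs=1e-12)
        assert curve.intercept == pytest.approx(1.5, abs=1e-10)
        # a raw methionine-like value under a unit-slope +1.5 curve
        assert apply_calibration(curve, -1.13) == pytest.approx(0.37, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        """Slope/intercept agree with a direct normal-equations solve."""
        stds = [CalibrationStandard(n, r, t) for n, r, t in NINE_STANDARDS]
        curve = fit_calibration(stds)
        X = np.column_stack([np.ones(len(stds)), [s.raw for s in stds]])
        y = np.array([s.true for s in stds])
        intercept, slope = np.linalg.solve(X.T @ X, X.T @ y)
        assert curve.slope == pytest.approx(slope, abs=1e-10)
        assert curve.intercept == pytest.approx(intercept, abs=1e-10)

    def test_monotone_when_slope_positive(self):
        stds = [CalibrationStandard(n, r, t) for n, r, t in NINE_STANDARDS]
        curve = fit_calibration(stds)
        assert curve.slope > 0
        assert apply_calibration(curve, -1.0) < apply_calibration(curve, 1.0)

    def test_degenerate_raw_values(self):
        stds = [CalibrationStandard("a", 1.0, 2.0), CalibrationStandard("b", 1.0, 3.0)]
        with pytest.raises(np.linalg.LinAlgError):
            fit_calibration(stds)

    def test_corrected_sd_combines_slope_and_residual(self):
        stds = [CalibrationStandard(n, r, t) for n, r, t in NINE_STANDARDS]
        curve = fit_calibration(stds)
        _, sd = apply_calibration(curve, 5.0, raw_sd=0.3)
        assert sd == pytest.approx(
            np.hypot(abs(curve.slope) * 0.3, curve.residual_sd)
        )

    def test_roundtrip_through_inverse_curve(self):
        """Calibrating then applying the inverse line returns the input."""
        stds = [CalibrationStandard(n, r, t) for n, r, t in NINE_STANDARDS]
        curve = fit_calibration(stds)
        raw = np.linspace(-10, 40, 7)
        corrected = apply_calibration(curve, raw)
        back = (corrected - curve.intercept) / curve.slope
        np.testing.assert_allclose(back, raw, atol=1e-10)


class TestMassBalance:
    def test_constant_field(self):
        values = {aa: 12.0 for aa in ALL_AAS}
        assert estimate_bulk_from_aas(values) == pytest.approx(12.0, abs=1e-12)

    def test_hand_computed_two_aa_case(self):
        est = estimate_bulk_from_aas({"Gly": 10.0, "Phe": 20.0},
                                     fractions={"Gly": 0.3, "Phe": 0.1})
        assert est == pytest.approx(12.5, abs=1e-12)

    def test_renormalization_invariance(self):
        values = {aa: i * 1.7 for i, aa in enumerate(ALL_AAS)}
        half = {aa: f / 2 for aa, f in NITROGEN_FRACTIONS.items()}
        assert estimate_bulk_from_aas(values) == pytest.approx(
            estimate_bulk_from_aas(values, fractions=half), abs=1e-12
        )

    def test_matches_bruteforce_oracle_on_random_profiles(self, rng):
        for _ in range(200):
            values = {aa: rng.normal(10, 5) for aa in ALL_AAS}
            fr = {aa: rng.uniform(0.001, 0.08) for aa in ALL_AAS}
            expected = sum(fr[a] * values[a] for a in ALL_AAS) / sum(fr.values())
            assert estimate_bulk_from_aas(values, fractions=fr) == pytest.approx(
                expected, abs=1e-12
            )

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            estimate_bulk_from_aas({})

    def test_profile_dataclass_validation(self):
        with pytest.raises(ValueError):
            AAProfile(values={"Glx": 10.0}, sds={"Glx": -0.1})
        with pytest.raises(ValueError):
            AAProfile(values={"Glx": 10.0}, fractions={"Glx": 1.2})


def _records_with_offsets(offsets, rng):
    """Build records whose est-obs offset equals the requested vector."""
    n = len(offsets)
    base = rng.normal(14, 2, n)
    df = pd.DataFrame({"specimen_id": [f"S{i}" for i in range(n)]})
    for aa in ALL_AAS:
        df[aa_column(aa)] = base  # constant profile per record -> est = base
    df["d15N_bulk"] = base - np.asarray(offsets)
    return df


class TestEstObsFilter:
    def test_identical_offsets_exclude_nothing(self, rng):
        df = _records_with_offsets(np.full(20, 0.22), rng)
        result = qc_est_obs_filter(df)
        assert len(result.excluded) == 0
        assert result.mean_offset == pytest.approx(0.22, abs=1e-10)

    def test_planted_outlier_is_unique_exclusion(self, rng):
        """A 5-sd outlier among well-behaved normal offsets is the unique
        exclusion (background draws kept inside 1.5 sd so no incidental
        outlier competes with the planted one)."""
        from scipy.stats import truncnorm

        offsets = 0.2 + 0.5 * truncnorm.rvs(
            -1.5, 1.5, size=100, random_state=np.random.RandomState(0)
        )
        offsets[37] = offsets.mean() + 5 * offsets.std()
        df = _records_with_offsets(offsets, rng)
        result = qc_est_obs_filter(df)
        assert list(result.excluded["specimen_id"]) == ["S37"]

    def test_noise_free_mean_offset_zero(self, rng):
        df = _records_with_offsets(np.zeros(30), rng)
        result = qc_est_obs_filter(df)
        assert abs(result.mean_offset) < 1e-10

    def test_expected_exclusion_rate_under_normal_offsets(self, rng):
        """~4.6% of pure-normal offsets fall beyond 2 sample sds."""
        df = _records_with_offsets(rng.normal(0, 1, 10_000), rng)
        result = qc_est_obs_filter(df)
        rate = len(result.excluded) / 10_000
        assert abs(rate - 0.0455) < 0.02

    def test_too_few_records_refused(self, rng):
        df = _records_with_offsets([0.1, 0.2], rng)
        with pytest.raises(ValueError):
            qc_est_obs_filter(df)


class TestPropagation:
    def test_three_four_five(self):
        assert propagate_uncertainty(0.3, 0.4) == pytest.approx(0.5)

    def test_zero_passthrough(self):
        assert propagate_uncertainty(0.0, 0.2) == pytest.approx(0.2)

    @given(
        a=st.floats(0, 10, allow_nan=False),
        b=st.floats(0, 10, allow_nan=False),
    )
    @settings(max_examples=50, derandomize=True)
    def test_symmetric_and_dominates_components(self, a, b):
        combined = propagate_uncertainty(a, b)
        assert combined == propagate_uncertainty(b, a)
        assert combined >= max(a, b) - 1e-12

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            propagate_uncertainty(-0.1, 0.2)
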