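"""Linear Δ-vs-Δs modelling: fits, predictions, flags, ranking."""

from dataclasses import replace

import numpy as np
import pytest

from catfield.catalytic_field import CatalyticFieldValue, ProbePoint
from catfield.errors import UsageError
from catfield.structures_io import Atom, Molecule
from catfield.substituent_analysis import (
    SubstitutionRecord,
    fit_field_model,
    flag_near_reaction_sites,
    predict_substituent_effects,
    rank_sites,
)
from catfield.synthetic_fixtures import make_linear_dataset


def _records(delta_s, observed=None, near=None):
    out = []
    for i, ds in enumerate(delta_s):
        out.append(
            SubstitutionRecord(
                site_label=str(i + 1),
                site_index=i + 1,
                delta_s=float(ds),
                observed_delta=None if observed is None else float(observed[i]),
                near_reaction=bool(near[i]) if near is not None else False,
            )
        )
    return out


def _ols_normal_equations(x, y, intercept=True):
    """Independent closed-form OLS by direct loops."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if intercept:
        sx = sum(x)
        sy = sum(y)
        sxx = sum(v * v for v in x)
        sxy = sum(a * b for a, b in zip(x, y))
        slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        b0 = (sy - slope * sx) / n
        p = 2
    else:
        slope = sum(a * b for a, b in zip(x, y)) / sum(v * v for v in x)
        b0 = 0.0
        p = 1
    ssr = sum((yi - slope * xi - b0) ** 2 for xi, yi in zip(x, y))
    sd = np.sqrt(ssr / (n - p)) if n > p else 0.0
    return slope, b0, sd


class TestFit:
    def test_exact_line_no_intercept(self):
        ds = np.array([-4.0, -1.0, 2.0, 5.0])
        records = _records(ds, observed=0.2 * ds)
        model = fit_field_model(records, use_intercept=False)
        assert model.slope == pytest.approx(0.2, rel=1e-12)
        assert model.intercept == 0.0
        assert model.residual_sd == pytest.approx(0.0, abs=1e-12)
        assert model.n_used == 4

    def test_saturated_two_point_fit_warns(self):
        records = _records([1.0, 3.0], observed=[0.5, 2.5])
        with pytest.warns(UserWarning, match="saturated"):
            model = fit_field_model(records, use_intercept=True)
        assert model.residual_sd == 0.0
        assert model.slope == pytest.approx(1.0)

    def test_parameter_recovery(self):
        records = make_linear_dataset(
            n_sites=50, slope=0.15, intercept=0.5, noise_sd=1.0, seed=42
        )
        model = fit_field_model(records, use_intercept=True)
        assert abs(model.slope - 0.15) < 3.0 * model.slope_se
        assert 0.7 <= model.residual_sd <= 1.3

    @pytest.mark.parametrize("intercept", [True, False])
    def test_matches_normal_equations(self, intercept, rng):
        ds = rng.uniform(-10, 10, size=12)
        obs = 0.3 * ds - 1.0 + rng.normal(0, 0.5, size=12)
        model = fit_field_model(_records(ds, observed=obs), use_intercept=intercept)
        slope, b0, sd = _ols_normal_equations(ds, obs, intercept=intercept)
        assert model.slope == pytest.approx(slope, abs=1e-10)
        assert model.intercept == pytest.approx(b0, abs=1e-10)
        assert model.residual_sd == pytest.approx(sd, abs=1e-10)

    def test_exclusions_match_manual_subset(self, rng):
        ds = rng.uniform(-10, 10, size=10)
        obs = 0.3 * ds + rng.normal(0, 0.5, size=10)
        records = _records(ds, observed=obs)
        excl = {"2", "7"}
        m1 = fit_field_model(records, exclude=excl)
        m2 = fit_field_model([r for r in records if r.site_label not in excl])
        assert m1.slope == pytest.approx(m2.slope, abs=1e-12)
        assert m1.residual_sd == pytest.approx(m2.residual_sd, abs=1e-12)
        assert set(m1.excluded_labels) == excl

    def test_near_reaction_records_skipped_by_default(self, rng):
        ds = rng.uniform(-10, 10, size=8)
        obs = 0.3 * ds
        near = [False] * 8
        near[0] = near[4] = True
        obs = np.array(obs)
        obs[0] += 25.0  # the near-reaction outlier the flag exists for
        records = _records(ds, observed=obs, near=near)
        model = fit_field_model(records)
        assert model.n_used == 6
        assert set(model.excluded_labels) == {"1", "5"}
        assert model.slope == pytest.approx(0.3, abs=1e-10)

    def test_insufficient_records_rejected(self):
        with pytest.raises(UsageError, match="at least"):
            fit_field_model(_records([1.0], observed=[0.1]))

    def test_degenerate_design_rejected(self):
        with pytest.raises(UsageError, match="variance"):
            fit_field_model(_records([2.0, 2.0, 2.0], observed=[1.0, 2.0, 3.0]))

    def test_ci_coverage_over_replicates(self):
        hits = 0
        for rep in range(200):
            records = make_linear_dataset(
                n_sites=50, slope=0.15, intercept=0.5, noise_sd=1.0, seed=1000 + rep
            )
            m = fit_field_model(records)
            if abs(m.slope - 0.15) <= 1.96 * m.slope_se:
                hits += 1
        assert hits >= 0.90 * 200


class TestPredict:
    def test_identity_model(self):
        records = _records([-3.0])
        model = fit_field_model(_records([0.0, 1.0], observed=[0.0, 1.0]), use_intercept=False)
        out = predict_substituent_effects(model, records)
        assert out[0].predicted_delta == pytest.approx(-3.0)
        assert records[0].predicted_delta is None  # inputs untouched

    def test_zero_slope_gives_intercept(self):
        records = _records([1.0, -5.0, 9.0], observed=[2.0, 2.0, 2.0])
        # fit on constant y: slope 0, intercept 2
        model = fit_field_model(_records([0.0, 1.0, 2.0], observed=[2.0, 2.0, 2.0]))
        out = predict_substituent_effects(model, records)
        assert all(r.predicted_delta == pytest.approx(2.0, abs=1e-10) for r in out)

    def test_training_residual_identity(self, rng):
        ds = rng.uniform(-10, 10, size=20)
        obs = 0.2 * ds + 1.0 + rng.normal(0, 0.8, size=20)
        records = _records(ds, observed=obs)
        model = fit_field_model(records, use_intercept=True)
        out = predict_substituent_effects(model, records)
        resid = np.array([r.observed_delta - r.predicted_delta for r in out])
        n, p = 20, 2
        rms = np.sqrt(np.mean(resid**2))
        assert rms == pytest.approx(model.residual_sd * np.sqrt((n - p) / n), rel=1e-10)


class TestNearReactionFlag:
    @pytest.fixture
    def carbonyl_like(self):
        # C1=O2 with H3 on the carbonyl carbon and a remote H5 on C4
        atoms = (
            Atom(1, "C", [0.0, 0.0, 0.0]),
            Atom(2, "O", [1.22, 0.0, 0.0]),
            Atom(3, "H", [-0.55, 0.95, 0.0]),
            Atom(4, "C", [-0.77, -1.26, 0.0]),
            Atom(5, "H", [-6.0, -7.0, 0.0]),
        )
        return Molecule("carbonyl-like", atoms)

    def test_h_on_reacting_carbon_flagged(self, carbonyl_like):
        base = _records([1.0, 2.0])
        records = [
            replace(base[0], site_index=3),
            replace(base[1], site_index=5),
        ]
        out = flag_near_reaction_sites(records, carbonyl_like, reacting_atoms=[1, 2], cutoff=3.0)
        assert out[0].near_reaction is True  # part of the reacting carbonyl
        assert out[1].near_reaction is False

    def test_zero_cutoff_flags_nothing(self, carbonyl_like):
        records = _records([1.0])
        out = flag_near_reaction_sites(records, carbonyl_like, [1, 2], cutoff=0.0)
        assert not any(r.near_reaction for r in out)

    def test_huge_cutoff_flags_everything(self, carbonyl_like):
        records = _records([1.0, 2.0, 3.0])
        out = flag_near_reaction_sites(records, carbonyl_like, [1], cutoff=1e6)
        assert all(r.near_reaction for r in out)


def _field_values(delta_s_by_site):
    values = []
    for site, ds in delta_s_by_site.items():
        probe = ProbePoint([0.0, 0.0, float(site)], "bond_directed", site_index=site)
        values.append(CatalyticFieldValue(probe=probe, V_S=0.0, V_TS=-ds, delta_s=ds))
    return values


class TestRanking:
    def test_negative_substituent_sign_logic(self):
        # Δ for charge q at the probe is −q·Δs; with q = −1 e, Δ = Δs,
        # so the most negative Δs lowers the barrier most.
        values = _field_values({1: -5.0, 2: 2.0, 3: 0.0})
        assert rank_sites(values, objective="lower") == ["1", "3", "2"]

    def test_positive_substituent_reverses_sign(self):
        values = _field_values({1: -5.0, 2: 2.0, 3: 0.0})
        assert rank_sites(values, objective="lower", substituent_charge=1.0) == ["2", "3", "1"]

    def test_ties_break_by_site_index(self):
        values = _field_values({3: 1.0, 1: 1.0, 2: 1.0})
        assert rank_sites(values, objective="lower") == ["1", "2", "3"]
        assert rank_sites(values, objective="raise") == ["1", "2", "3"]

    def test_objective_switch_reverses(self):
        values = _field_values({1: -5.0, 2: 2.0, 3: 0.5, 4: -1.0})
        fwd = rank_sites(values, objective="lower")
        assert rank_sites(values, objective="raise") == fwd[::-1]

    def test_surface_probes_rejected(self):
        bad = CatalyticFieldValue(
            probe=ProbePoint([0, 0, 0], "surface"), V_S=0.0, V_TS=1.0, delta_s=-1.0
        )
        with pytest.raises(UsageError, match="bond-directed"):
            rank_sites([bad])
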