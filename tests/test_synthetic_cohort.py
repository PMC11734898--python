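import numpy as np
import pandas as pd
import pytest

from underdx.strata import KEY_COLUMNS
from underdx.synthetic_cohort import (ParameterError, SimulationParams,
                                      default_params, equilibrium_occupancy,
                                      generate_area_tables, generate_cohort,
                                      uniform_rate_table, validate_params,
                                      _iterate_equilibrium)


def _uniform_params(years=(2010, 2014), cohort_size=8000, seed=5, **rates):
    r = dict(A=0.03, B=0.25, C1=0.10, C_later=0.06, D=0.10, E=0.01)
    r.update(rates)
    yr = list(range(years[0], years[1] + 1))
    tab = uniform_rate_table(yr, **r)
    return SimulationParams(conditions=["cond"], years=years,
                            strata_rates={"cond": tab},
                            cohort_size=cohort_size, seed=seed)


def test_same_seed_gives_identical_event_logs():
    p = default_params(conditions=["chd"], years=(2008, 2010),
                       cohort_size=4000, seed=42)
    out1 = generate_cohort(p)
    out2 = generate_cohort(p)
    for a, b in zip(out1, out2):
        pd.testing.assert_frame_equal(a, b)


def test_occupancies_and_deaths_conserve_cohort_size():
    params, _, _, _, truth = None, None, None, None, None
    p = _uniform_params()
    persons, dx, deaths, truth = generate_cohort(p)
    per_year = truth.groupby("year")[["H", "X", "Y", "Z_U", "Z_D", "Z_0"]].sum()
    alive = per_year[["H", "X", "Y"]].sum(axis=1)
    cum_dead = per_year[["Z_U", "Z_D", "Z_0"]].sum(axis=1).cumsum().shift(
        fill_value=0)
    assert ((alive + cum_dead) == p.cohort_size).all()


def test_zero_incidence_means_no_disease_events():
    p = _uniform_params(A=0.0)
    persons, dx, deaths, truth = generate_cohort(p)
    assert dx.empty
    assert (deaths["cause"] == "other").all()
    assert truth[["X", "Y", "Z_U", "Z_D"]].to_numpy().sum() == 0


def test_near_instant_diagnosis_leaves_almost_no_undiagnosed():
    # the undiagnosed pool turns over yearly while the diagnosed pool
    # accumulates, so the limit shows once the cohort has lived with the
    # disease process for a while: evaluate the final simulated year
    p = _uniform_params(years=(2010, 2039), B=0.95, A=0.05, C1=0.01,
                        C_later=0.001, D=0.01, E=0.002, cohort_size=10_000)
    _, _, _, truth = generate_cohort(p)
    last = truth[truth["year"] == 2039][["X", "Y"]].sum()
    assert last["X"] / (last["X"] + last["Y"]) < 0.02


def test_diagnosis_dates_precede_disease_death_dates():
    p = _uniform_params()
    persons, dx, deaths, truth = generate_cohort(p)
    first_dx = dx.groupby("person_id")["diagnosis_date"].min()
    dz = deaths[deaths["cause"] == "cond"].set_index("person_id")["death_date"]
    both = first_dx.index.intersection(dz.index)
    assert (first_dx[both] < dz[both]).all()
    # undiagnosed disease deaths never have a diagnosis event
    undx_deaths = dz.index.difference(first_dx.index)
    assert len(undx_deaths) > 0
    # and person dates are internally consistent
    m = persons.set_index("person_id")
    assert (m["registration_start"] <= m["registration_end"]).all()
    assert (dx.join(m, on="person_id")["registration_start"]
            <= dx["diagnosis_date"]).all()


class TestEquilibrium:
    def test_no_incidence_fixed_point_is_all_healthy(self):
        r = dict(A=0.0, B=0.3, C1=0.1, C_later=0.1, D=0.1, E=0.02)
        eq = equilibrium_occupancy(r)
        assert eq.converged
        assert eq.x == pytest.approx(0.0, abs=1e-12)
        assert eq.y == pytest.approx(0.0, abs=1e-12)
        assert eq.h == pytest.approx(1.0, abs=1e-12)

    def test_instant_diagnosis_drives_undiagnosed_share_to_zero(self):
        r = dict(A=0.05, B=0.9, C1=0.02, C_later=0.02, D=0.02, E=0.01)
        eq = equilibrium_occupancy(r)
        assert eq.converged
        assert eq.x / (eq.x + eq.y) < 0.04

    def test_fixed_point_matches_500_step_iteration_oracle(self):
        # oracle: run the published update equations 500 steps directly
        r = dict(A=0.04, B=0.2, C1=0.15, C_later=0.08, D=0.15, E=0.02)
        h = x = y1 = y2 = None
        state = np.array([1.0, 0.0, 0.0, 0.0])
        for _ in range(500):
            h, x, y1, y2 = state
            hn = h * (1 - r["A"] - r["E"])
            xn = x * (1 - r["B"] - r["D"] - r["E"]) + h * r["A"]
            y1n = x * r["B"]
            y2n = y1 * (1 - r["C1"] - r["E"]) + y2 * (1 - r["C_later"] - r["E"])
            state = np.array([hn, xn, y1n, y2n]) / (hn + xn + y1n + y2n)
        eq = equilibrium_occupancy(r)
        assert eq.h == pytest.approx(state[0], abs=1e-9)
        assert eq.x == pytest.approx(state[1], abs=1e-9)
        assert eq.y == pytest.approx(state[2] + state[3], abs=1e-9)

    def test_raising_diagnosis_rate_never_raises_undiagnosed_share(self):
        base = dict(A=0.03, C1=0.1, C_later=0.05, D=0.1, E=0.01)
        shares = []
        for b in (0.05, 0.1, 0.2, 0.4, 0.8):
            eq = equilibrium_occupancy({**base, "B": b})
            shares.append(eq.x / (eq.x + eq.y))
        assert all(a >= b - 1e-12 for a, b in zip(shares, shares[1:]))

    def test_simulator_tracks_iterated_update_equations(self):
        # constant rates, everyone initially healthy: after T years the
        # living-state split must match T iterations of the update equations
        r = dict(A=0.05, B=0.5, C1=0.3, C_later=0.3, D=0.3, E=0.02)
        T = 12
        p = _uniform_params(years=(2010, 2010 + T - 1), cohort_size=30_000,
                            seed=9, **r)
        p.initial_state = "healthy"
        _, _, _, truth = generate_cohort(p)
        last = truth[truth["year"] == 2010 + T - 1][["H", "X", "Y"]].sum()
        alive = last.sum()
        h, x, y1, y2, _, _ = _iterate_equilibrium(
            r["A"], r["B"], r["C1"], r["C_later"], r["D"], r["E"],
            n_iter=T - 1, tol=0)
        expect = np.array([h, x, y1 + y2], dtype=float)
        got = last.to_numpy() / alive
        # binomial Monte-Carlo tolerance, 5 sigma
        tol = 5 * np.sqrt(expect * (1 - expect) / alive)
        assert (np.abs(got - expect) <= tol + 1e-12).all()


class TestParamValidation:
    def test_rates_above_one_rejected(self):
        p = _uniform_params()
        p.strata_rates["cond"].loc[0, "A"] = 1.3
        with pytest.raises(ParameterError, match="outside"):
            validate_params(p)

    def test_outcome_probabilities_must_sum_below_one(self):
        p = _uniform_params(B=0.6, D=0.3, E=0.2)
        with pytest.raises(ParameterError, match="B \\+ D \\+ E"):
            validate_params(p)

    def test_incomplete_stratum_coverage_rejected(self):
        p = _uniform_params()
        p.strata_rates["cond"] = p.strata_rates["cond"].iloc[:-1]
        with pytest.raises(ParameterError, match="450"):
            validate_params(p)

    def test_other_cause_mortality_must_be_shared(self):
        p = _uniform_params()
        tab2 = p.strata_rates["cond"].copy()
        tab2["E"] = tab2["E"] * 2
        p.conditions = ["cond", "cond2"]
        p.strata_rates["cond2"] = tab2
        with pytest.raises(ParameterError, match="identical"):
            validate_params(p)


class TestAreaTables:
    def test_one_area_per_region_gives_nine_health_areas(self):
        p = _uniform_params()
        areas = generate_area_tables(p, 1, seed=0, areas_per_health_area=1)
        assert areas["health_area_id"].nunique() == 9
        assert areas["area_id"].nunique() == 9

    def test_population_conserved_and_positive(self):
        p = _uniform_params()
        areas = generate_area_tables(p, 5, seed=1,
                                     national_population=120_000)
        assert (areas["population"] > 0).all()
        assert areas.groupby("year")["population"].sum().eq(120_000).all()

    def test_each_area_has_single_attributes(self):
        p = _uniform_params()
        areas = generate_area_tables(p, 4, seed=2)
        per_area = areas.groupby("area_id")[["qimd", "region",
                                             "health_area_id"]].nunique()
        assert (per_area == 1).all().all()
        # health areas never span regions
        spans = areas.groupby("health_area_id")["region"].nunique()
        assert (spans == 1).all()

    def test_repeated_seed_reproduces_tables(self):
        p = _uniform_params()
        a1 = generate_area_tables(p, 3, seed=7)
        a2 = generate_area_tables(p, 3, seed=7)
        pd.testing.assert_frame_equal(a1, a2)

    def test_zero_population_rejected(self):
        p = _uniform_params()
        with pytest.raises(ValueError):
            generate_area_tables(p, 2, seed=0, national_population=0)
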