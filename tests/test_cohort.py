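"""D-optimal design selection and Monte Carlo cohort completion."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from copdtriage.cohort import (
    CategoricalMarginal,
    CohortConfig,
    ConfigError,
    ContinuousMarginal,
    DesignError,
    PointMass,
    _complete_batch,
    code_profiles,
    complete_case,
    d_criterion,
    default_marginals,
    federov_exchange,
    generate_cohort,
    profile_variables,
    sample_candidate_profiles,
)
from copdtriage.schema import UNKNOWN, default_schema, validate_case
from .conftest import make_case


def brute_force_best(C: np.ndarray, n: int) -> float:
    """Exhaustive search oracle for the best log det(X'X) over n-subsets."""
    best = -math.inf
    for subset in itertools.combinations(range(C.shape[0]), n):
        X = C[list(subset)]
        sign, logdet = np.linalg.slogdet(X.T @ X)
        if sign > 0:
            best = max(best, logdet)
    return best


class TestDCriterion:
    def test_identity_design(self):
        assert d_criterion(np.eye(4)) == pytest.approx(0.0)

    def test_duplicated_row_is_singular(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        assert d_criterion(X) == -math.inf

    def test_two_level_factorial_with_intercept(self):
        # 2^2 full factorial coded +-1 plus intercept: X'X = 4 I_3, det = 64
        X = np.array([[1, a, b] for a in (-1, 1) for b in (-1, 1)], dtype=float)
        assert d_criterion(X) == pytest.approx(math.log(64.0))

    def test_empty_design_rejected(self):
        with pytest.raises(DesignError, match="empty design"):
            d_criterion(np.empty((0, 3)))


class TestFederovExchange:
    def test_one_factor_three_levels_picks_extremes(self):
        # intercept + linear factor at levels {-1, 0, +1}: best 2-point design
        # is {-1, +1} with det(X'X) = 4 (brute force over the 3 subsets)
        C = np.array([[1, -1], [1, 0], [1, 1]], dtype=float)
        sel = federov_exchange(C, n=2, seed=0, restarts=3)
        assert sorted(sel.row_ids.tolist()) == [0, 2]
        assert d_criterion(sel) == pytest.approx(math.log(4.0))

    def test_full_candidate_set_returned_when_n_equals_m(self):
        C = np.array([[1, -1], [1, 0], [1, 1]], dtype=float)
        sel = federov_exchange(C, n=3, seed=0)
        assert sorted(sel.row_ids.tolist()) == [0, 1, 2]

    def test_factorial_candidates_reach_global_optimum(self):
        C = np.array([[1, a, b] for a in (-1, 1) for b in (-1, 1)], dtype=float)
        sel = federov_exchange(C, n=4, seed=1)
        assert d_criterion(sel) == pytest.approx(brute_force_best(C, 4))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_search_on_random_geometries(self, seed):
        # candidate sets of <= 12 points in several seeded geometries
        rng = np.random.default_rng(seed)
        m = int(rng.integers(8, 13))
        p = int(rng.integers(2, 4))
        C = np.column_stack([np.ones(m), rng.normal(size=(m, p))])
        n = int(rng.integers(p + 1, min(m, p + 4) + 1))
        sel = federov_exchange(C, n=n, seed=seed, restarts=8)
        assert d_criterion(sel) == pytest.approx(brute_force_best(C, n), abs=1e-8)

    def test_beats_mean_random_subset(self):
        rng = np.random.default_rng(5)
        C = np.column_stack([np.ones(30), rng.normal(size=(30, 4))])
        sel = federov_exchange(C, n=8, seed=5, restarts=3)
        crits = []
        for _ in range(50):
            idx = rng.choice(30, size=8, replace=False)
            c = d_criterion(C[idx])
            if math.isfinite(c):
                crits.append(c)
        assert d_criterion(sel) >= np.mean(crits)

    def test_infeasible_when_n_exceeds_candidates(self):
        with pytest.raises(DesignError, match="infeasible"):
            federov_exchange(np.eye(3), n=5, seed=0)


class TestCompletion:
    def test_point_mass_marginals_are_deterministic(self, schema):
        marginals = {}
        for name, m in default_marginals().items():
            if isinstance(m, CategoricalMarginal):
                marginals[name] = PointMass(m.levels[0])
            else:
                marginals[name] = PointMass(98.0 if name != "temperature" else 98.6)
        config = CohortConfig(marginals=marginals, unknown_rate=0.0, seed=0)
        partial = make_case(schema)
        done = complete_case(partial, config, seed=1)
        assert done.values["chf"] == "yes"
        assert done.values["o2sat"] == 98.0

    def test_identity_correlation_latents_uncorrelated(self, schema):
        cfg = CohortConfig(
            correlation=pd.DataFrame(
                np.eye(len(default_marginals())),
                index=list(default_marginals()), columns=list(default_marginals()),
            ),
            unknown_rate=0.0, seed=0,
        )
        rng = np.random.default_rng(0)
        profiles = sample_candidate_profiles(10_000, rng)
        out = _complete_batch(profiles, cfg, rng, default_schema())
        # binary comorbidity indicators inherit the latent independence
        pairs = [("chf", "pulm_htn"), ("hbp", "cad"), ("diabetes", "anemia")]
        for a, b in pairs:
            xa = (out[a] == "yes").astype(float)
            xb = (out[b] == "yes").astype(float)
            assert abs(np.corrcoef(xa, xb)[0, 1]) < 0.05

    def test_default_correlation_induces_dependence(self):
        cfg = CohortConfig(unknown_rate=0.0, seed=0)
        rng = np.random.default_rng(0)
        profiles = sample_candidate_profiles(10_000, rng)
        out = _complete_batch(profiles, cfg, rng, default_schema())
        xa = (out["sputum_col"] == "yes").astype(float)
        xb = (out["sputum_vol"] == "yes").astype(float)
        assert np.corrcoef(xa, xb)[0, 1] > 0.15

    def test_unknown_rate_respected(self):
        cfg = CohortConfig(unknown_rate=0.1, seed=0)
        rng = np.random.default_rng(0)
        profiles = sample_candidate_profiles(10_000, rng)
        out = _complete_batch(profiles, cfg, rng, default_schema())
        by_name = {s.name: s for s in default_schema()}
        for var in cfg.marginals:
            share = (out[var].astype(str) == UNKNOWN).mean()
            if by_name[var].allows_unknown:
                assert abs(share - 0.1) < 0.02
            else:
                assert share == 0.0

    def test_missing_marginal_rejected(self, schema):
        marginals = default_marginals()
        del marginals["chf"]
        with pytest.raises(ConfigError, match="config incomplete"):
            cfg = CohortConfig(marginals=marginals, seed=0)
            complete_case(make_case(schema), cfg, seed=0)

    def test_asymmetric_correlation_rejected(self):
        names = list(default_marginals())
        R = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        R.iloc[0, 1] = 0.5  # not mirrored
        with pytest.raises(ConfigError, match="symmetric"):
            CohortConfig(correlation=R)


class TestGenerateCohort:
    def test_split_sizes_match_config(self, small_cohort):
        assert len(small_cohort) == 200
        assert sum(c.split == "validation" for c in small_cohort) == 30
        assert sum(c.split == "train" for c in small_cohort) == 170

    def test_all_cases_validate(self, small_cohort):
        assert all(validate_case(c).ok for c in small_cohort)

    def test_every_design_profile_distinct_when_total_equals_design(self):
        # the coded profile model has 19 columns, so the design needs >= 19 rows
        cfg = CohortConfig(
            n_design=20, n_candidates=100, n_total=20, n_validation=3,
            unknown_rate=0.0, seed=3,
        )
        cases = generate_cohort(cfg)
        profiles = [
            tuple(c.values[v] for v in profile_variables()) for c in cases
        ]
        assert len(set(profiles)) == len(profiles)

    def test_reproducible_under_seed(self):
        cfg = dict(n_design=20, n_candidates=80, n_total=40, n_validation=8, seed=9)
        a = generate_cohort(CohortConfig(**cfg))
        b = generate_cohort(CohortConfig(**cfg))
        assert [(c.case_id, c.split, c.values) for c in a] == [
            (c.case_id, c.split, c.values) for c in b
        ]

    def test_exchange_on_coded_profiles_beats_random(self):
        rng = np.random.default_rng(2)
        candidates = sample_candidate_profiles(120, rng)
        coded = code_profiles(candidates[profile_variables()])
        sel = federov_exchange(coded, n=30, seed=2, restarts=2)
        rand_crits = []
        for _ in range(20):
            idx = rng.choice(120, size=30, replace=False)
            c = d_criterion(coded.X[idx])
            if math.isfinite(c):
                rand_crits.append(c)
        assert d_criterion(sel) >= np.mean(rand_crits)
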