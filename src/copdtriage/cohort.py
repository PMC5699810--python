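"""Synthetic cohort generation.

Two stages mirror how the study cases are constructed:

1. A D-optimal *profile design*: candidate patient profiles (background
   characteristics plus baseline vitals) are coded into a linear main-effects
   model matrix and a subset maximising ``det(X'X)`` is selected with a
   Fedorov exchange algorithm (greedy best swap, multiple restarts).
2. *Monte Carlo completion*: each selected profile is fleshed out with
   comorbidities, current symptoms and current vitals drawn from per-variable
   marginals coupled through a Gaussian copula, with an optional rate of
   "unknown" responses injected into the variables that admit them.

The default cohort reproduces the study shape: a 100-point profile design
expanded to 2,501 cases, of which 101 are held out for validation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .schema import (
    PatientCase,
    VariableSpec,
    UNKNOWN,
    default_schema,
    validate_case,
)


class DesignError(ValueError):
    pass


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Design matrices and the D-criterion
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Coded model matrix of a candidate or selected design.

    Columns: intercept, then dummy columns for categorical levels (first
    level dropped) and centred/scaled numeric columns, i.e. a linear
    main-effects model.
    """

    X: np.ndarray
    row_ids: np.ndarray  # indices into the candidate set
    columns: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.X.shape[0]


def code_profiles(profiles: pd.DataFrame, schema: list[VariableSpec] | None = None) -> DesignMatrix:
    """Code raw profile rows into the design model matrix.

    Categorical variables become dummy columns (first level dropped);
    continuous variables are scaled to [-1, 1] over their schema range;
    an intercept column is prepended.
    """
    by_name = {s.name: s for s in (schema or default_schema())}
    cols: list[np.ndarray] = [np.ones(len(profiles))]
    names = ["intercept"]
    for var in profiles.columns:
        spec = by_name[var]
        if spec.kind == "categorical":
            vals = profiles[var].astype(str)
            for level in spec.levels[1:]:  # type: ignore[index]
                cols.append((vals == level).to_numpy(float))
                names.append(f"{var}[{level}]")
        else:
            lo, hi = spec.range  # type: ignore[misc]
            x = profiles[var].to_numpy(float)
            cols.append(2.0 * (x - lo) / (hi - lo) - 1.0)
            names.append(var)
    X = np.column_stack(cols)
    return DesignMatrix(X=X, row_ids=np.arange(len(profiles)), columns=names)


def d_criterion(design: DesignMatrix | np.ndarray) -> float:
    """log det(X'X) of a design; ``-inf`` when the information matrix is singular."""
    X = design.X if isinstance(design, DesignMatrix) else np.asarray(design, float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise DesignError("empty design")
    M = X.T @ X
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0 or not np.isfinite(logdet) or np.linalg.matrix_rank(M) < M.shape[0]:
        return -math.inf
    return float(logdet)


def federov_exchange(
    candidates: DesignMatrix | np.ndarray,
    n: int,
    seed: int = 0,
    restarts: int = 5,
    max_sweeps: int = 200,
    tol: float = 1e-10,
) -> DesignMatrix:
    """Select an n-row subset of the candidates maximising ``det(X'X)``.

    Greedy best-swap exchange: starting from a random nonsingular subset,
    repeatedly perform the single candidate-for-selected swap with the
    largest determinant gain until no swap improves; keep the best of
    ``restarts`` random initialisations.  Deterministic given ``seed``.
    """
    if isinstance(candidates, DesignMatrix):
        C, columns = candidates.X, candidates.columns
    else:
        C, columns = np.asarray(candidates, float), []
    m, p = C.shape
    if n > m:
        raise DesignError(f"design infeasible: n={n} exceeds {m} candidates")
    if n < 1:
        raise DesignError("empty design")
    rng = np.random.default_rng(seed)

    best_idx: np.ndarray | None = None
    best_crit = -math.inf
    for _ in range(max(1, restarts)):
        idx = _nonsingular_start(C, n, rng)
        if idx is None:
            continue
        idx, crit = _exchange_from(C, idx, max_sweeps, tol)
        if crit > best_crit:
            best_crit, best_idx = crit, idx
    if best_idx is None or not np.isfinite(best_crit):
        raise DesignError("design infeasible: no nonsingular size-n subset found")
    order = np.sort(best_idx)
    return DesignMatrix(X=C[order], row_ids=order, columns=columns)


def _nonsingular_start(C: np.ndarray, n: int, rng: np.random.Generator, tries: int = 200):
    m, p = C.shape
    for _ in range(tries):
        idx = rng.choice(m, size=n, replace=False)
        M = C[idx].T @ C[idx]
        sign, _ = np.linalg.slogdet(M)
        if sign > 0:
            return idx
    return None


def _exchange_from(C: np.ndarray, idx: np.ndarray, max_sweeps: int, tol: float):
    """Best-swap sweeps using Fedorov's determinant-ratio delta."""
    idx = np.array(idx, dtype=int)
    m = C.shape[0]
    for _ in range(max_sweeps):
        X = C[idx]
        M = X.T @ X
        try:
            Minv = np.linalg.inv(M)
        except np.linalg.LinAlgError:
            break
        # d(v) = v' Minv v for all candidates; cross terms c(u, v)
        CM = C @ Minv  # m x p
        d_all = np.einsum("ij,ij->i", CM, C)
        d_sel = d_all[idx]  # n
        cross = X @ CM.T  # n x m ; cross[i, j] = x_i' Minv c_j
        # det ratio after swapping selected i for candidate j:
        delta = (
            d_all[None, :]
            - d_sel[:, None]
            - (d_sel[:, None] * d_all[None, :] - cross**2)
        )
        delta[:, idx] = -math.inf  # never swap in an already-selected row
        i, j = np.unravel_index(np.argmax(delta), delta.shape)
        if delta[i, j] <= tol:
            break
        idx[i] = j
    X = C[idx]
    return idx, d_criterion(X)


# ---------------------------------------------------------------------------
# Marginal distributions for Monte Carlo completion
# ---------------------------------------------------------------------------

class Marginal:
    """Maps a copula uniform (and the partial case) to a variable value."""

    def ppf(self, u: np.ndarray, case_frame: pd.DataFrame) -> np.ndarray:
        raise NotImplementedError


@dataclass
class CategoricalMarginal(Marginal):
    levels: tuple[str, ...]
    probs: tuple[float, ...]

    def __post_init__(self):
        if len(self.levels) != len(self.probs):
            raise ConfigError("levels/probs length mismatch")
        if abs(sum(self.probs) - 1.0) > 1e-9 or any(p < 0 for p in self.probs):
            raise ConfigError("probs must be a distribution")

    def ppf(self, u, case_frame):
        cum = np.cumsum(self.probs)
        idx = np.searchsorted(cum, u, side="left")
        idx = np.clip(idx, 0, len(self.levels) - 1)
        return np.asarray(self.levels, object)[idx]


@dataclass
class ContinuousMarginal(Marginal):
    """Truncated-normal marginal clipped to [lo, hi], rounded to ``decimals``."""

    mean: float
    sd: float
    lo: float
    hi: float
    decimals: int = 0

    def ppf(self, u, case_frame):
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        x = stats.truncnorm.ppf(u, a, b, loc=self.mean, scale=self.sd)
        return np.round(np.clip(x, self.lo, self.hi), self.decimals)


@dataclass
class DeltaFromBaseline(Marginal):
    """Current vital = baseline + truncated-normal shift (absolute or percent)."""

    base_var: str
    mean: float
    sd: float
    lo: float
    hi: float
    percent: bool = False
    decimals: int = 0
    delta_span: float = 30.0

    def ppf(self, u, case_frame):
        a = -self.delta_span
        b = self.delta_span
        an = (a - self.mean) / self.sd
        bn = (b - self.mean) / self.sd
        delta = stats.truncnorm.ppf(u, an, bn, loc=self.mean, scale=self.sd)
        base = case_frame[self.base_var].to_numpy(float)
        x = base * (1.0 + delta / 100.0) if self.percent else base + delta
        return np.round(np.clip(x, self.lo, self.hi), self.decimals)


@dataclass
class PointMass(Marginal):
    value: object

    def ppf(self, u, case_frame):
        return np.full(len(u), self.value, dtype=object)


def default_marginals() -> dict[str, Marginal]:
    """Completion marginals for comorbidities, symptoms and current vitals.

    Prevalences and vital-sign shifts are package defaults chosen to be
    clinically plausible for an older COPD population; they are configuration,
    not estimates fitted to any dataset.
    """
    yn = lambda p_yes: CategoricalMarginal(("yes", "no"), (p_yes, 1.0 - p_yes))
    return {
        # comorbidities
        "chf": yn(0.20),
        "hbp": yn(0.55),
        "cad": yn(0.25),
        "diabetes": yn(0.25),
        "anemia": yn(0.15),
        "pulm_htn": yn(0.12),
        "acid_reflux": yn(0.35),
        # symptoms (levels 1 = less than usual, 2 = same, 3 = more)
        "shortbreath": CategoricalMarginal(("1", "2", "3"), (0.20, 0.45, 0.35)),
        "cough": CategoricalMarginal(("1", "2", "3"), (0.20, 0.45, 0.35)),
        "wheeze": CategoricalMarginal(("1", "2", "3"), (0.25, 0.45, 0.30)),
        "sputum_col": yn(0.25),
        "sputum_vol": yn(0.30),
        "infection": yn(0.20),
        "med_comp": CategoricalMarginal(("1", "2", "3"), (0.20, 0.30, 0.50)),
        "sleeplessness": yn(0.35),
        "mmrc_cur": CategoricalMarginal(("1", "2", "3", "4", "5"), (0.15, 0.25, 0.25, 0.20, 0.15)),
        # current vitals relative to baseline where a baseline exists
        "o2sat": DeltaFromBaseline("o2sat_base", mean=-1.5, sd=2.5, lo=50, hi=100, decimals=0, delta_span=15),
        "fev1": DeltaFromBaseline("fev1_base", mean=-5.0, sd=10.0, lo=1, hi=100, percent=True, decimals=0, delta_span=50),
        "heartrate": ContinuousMarginal(mean=90, sd=18, lo=40, hi=180, decimals=0),
        "temperature": ContinuousMarginal(mean=98.6, sd=1.0, lo=95, hi=104, decimals=1),
    }


_DEFAULT_CORR_PAIRS = [
    ("shortbreath", "wheeze", 0.40),
    ("shortbreath", "cough", 0.30),
    ("shortbreath", "mmrc_cur", 0.45),
    ("shortbreath", "o2sat", -0.35),
    ("cough", "sputum_vol", 0.35),
    ("sputum_col", "sputum_vol", 0.50),
    ("sputum_col", "infection", 0.30),
    ("infection", "temperature", 0.40),
    ("heartrate", "temperature", 0.30),
    ("heartrate", "shortbreath", 0.30),
    ("chf", "pulm_htn", 0.40),
    ("chf", "cad", 0.30),
    ("hbp", "cad", 0.35),
    ("hbp", "diabetes", 0.25),
]


def default_correlation(variables: list[str] | None = None) -> pd.DataFrame:
    """Latent (copula) correlation matrix over the completion variables."""
    variables = variables or list(default_marginals())
    R = pd.DataFrame(np.eye(len(variables)), index=variables, columns=variables)
    for a, b, r in _DEFAULT_CORR_PAIRS:
        if a in R.index and b in R.index:
            R.loc[a, b] = R.loc[b, a] = r
    return R


def _nearest_psd(R: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= -1e-10:
        return R
    warnings.warn("correlation matrix not PSD; clipping negative eigenvalues")
    vals = np.clip(vals, 1e-8, None)
    M = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(M))
    return M / np.outer(d, d)


# ---------------------------------------------------------------------------
# Cohort configuration and generation
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Shape and statistical structure of the simulated cohort."""

    n_design: int = 100
    n_candidates: int = 800
    n_total: int = 2501
    n_validation: int = 101
    marginals: dict[str, Marginal] = field(default_factory=default_marginals)
    correlation: pd.DataFrame | None = None
    unknown_rate: float = 0.05
    seed: int = 0
    design_restarts: int = 3

    def __post_init__(self):
        if self.n_design > self.n_total:
            raise ConfigError("n_design must not exceed n_total")
        if not (0.0 <= self.unknown_rate <= 1.0):
            raise ConfigError("unknown_rate must be in [0, 1]")
        if self.n_validation >= self.n_total:
            raise ConfigError("n_validation must be smaller than n_total")
        if self.correlation is None:
            self.correlation = default_correlation(list(self.marginals))
        R = self.correlation
        if not np.allclose(R.values, R.values.T) or not np.allclose(np.diag(R.values), 1.0):
            raise ConfigError("correlation must be symmetric with unit diagonal")


def profile_variables(schema: list[VariableSpec] | None = None) -> list[str]:
    schema = schema or default_schema()
    return [s.name for s in schema if s.group in ("profile", "baseline_vital")]


def sample_candidate_profiles(
    n: int, rng: np.random.Generator, schema: list[VariableSpec] | None = None
) -> pd.DataFrame:
    """Uniform candidate profiles over the schema's levels and ranges.

    Uniform (rather than population-weighted) sampling gives the exchange
    algorithm full coverage of the profile space, which is the point of the
    design stage.
    """
    schema = schema or default_schema()
    cols: dict[str, np.ndarray] = {}
    for s in schema:
        if s.group not in ("profile", "baseline_vital"):
            continue
        if s.kind == "categorical":
            cols[s.name] = rng.choice(np.asarray(s.levels, object), size=n)
        else:
            lo, hi = s.range  # type: ignore[misc]
            dec = 1 if s.name == "temperature" else 0
            cols[s.name] = np.round(rng.uniform(lo, hi, size=n), dec)
    return pd.DataFrame(cols)


def _complete_batch(
    profiles: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
    schema: list[VariableSpec],
) -> pd.DataFrame:
    """Vectorised Gaussian-copula completion of many partial cases."""
    variables = list(config.marginals)
    by_name = {s.name: s for s in schema}
    missing = [v for v in variables if v not in by_name]
    if missing:
        raise ConfigError(f"config incomplete: marginals for unknown variables {missing}")
    needed = [
        s.name
        for s in schema
        if s.group in ("comorbidity", "symptom", "vital") and s.name not in variables
    ]
    if needed:
        raise ConfigError(f"config incomplete: no marginal for {needed}")

    R = config.correlation.loc[variables, variables].to_numpy(float)
    R = _nearest_psd(R)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(len(variables)))
    n = len(profiles)
    Z = rng.standard_normal((n, len(variables))) @ L.T
    U = stats.norm.cdf(Z)

    out = profiles.reset_index(drop=True).copy()
    for k, var in enumerate(variables):
        out[var] = config.marginals[var].ppf(U[:, k], out)

    # unknown injection into variables that admit it (completion block only)
    if config.unknown_rate > 0:
        for var in variables:
            if by_name[var].allows_unknown:
                mask = rng.random(n) < config.unknown_rate
                if mask.any():
                    col = out[var].astype(object)
                    col[mask] = UNKNOWN
                    out[var] = col
    return out


def complete_case(
    profile_point: PatientCase,
    config: CohortConfig,
    seed: int | np.random.Generator = 0,
    schema: list[VariableSpec] | None = None,
) -> PatientCase:
    """Fill comorbidities, symptoms and current vitals of one partial case."""
    schema = schema or default_schema()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prof = pd.DataFrame([profile_point.values])
    completed = _complete_batch(prof, config, rng, schema)
    values = completed.iloc[0].to_dict()
    case = PatientCase(case_id=profile_point.case_id, values=values, split=profile_point.split)
    report = validate_case(case, schema)
    if not report.ok:
        raise ConfigError(f"completion produced invalid case: {report.violations}")
    return case


def generate_cohort(
    config: CohortConfig, schema: list[VariableSpec] | None = None
) -> list[PatientCase]:
    """Build the full cohort: design, replicate, complete, split.

    Each of the ``n_design`` selected profiles appears at least once; the
    remaining ``n_total - n_design`` cases resample design profiles uniformly.
    ``n_validation`` cases are assigned to the validation split at random.
    Reproducible bit-for-bit under ``config.seed``.
    """
    schema = schema or default_schema()
    ss = np.random.SeedSequence(config.seed)
    rng_cand, rng_rep, rng_complete, rng_split = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    design_seed = int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))

    candidates = sample_candidate_profiles(config.n_candidates, rng_cand, schema)
    coded = code_profiles(candidates[profile_variables(schema)], schema)
    selected = federov_exchange(
        coded, config.n_design, seed=design_seed, restarts=config.design_restarts
    )
    design_profiles = candidates.iloc[selected.row_ids].reset_index(drop=True)

    extra = rng_rep.integers(0, config.n_design, size=config.n_total - config.n_design)
    rows = np.concatenate([np.arange(config.n_design), extra])
    profiles = design_profiles.iloc[rows].reset_index(drop=True)

    completed = _complete_batch(profiles, config, rng_complete, schema)

    val_idx = set(rng_split.choice(config.n_total, size=config.n_validation, replace=False).tolist())
    width = len(str(config.n_total))
    cases = []
    for i in range(config.n_total):
        case = PatientCase(
            case_id=f"case-{i + 1:0{width}d}",
            values=completed.iloc[i].to_dict(),
            split="validation" if i in val_idx else "train",
        )
        cases.append(case)
    return cases
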