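"""Synthetic postoperative-delirium cohort generator.

Emulates the structure of a prospective diagnostic-accuracy study on a
cardiac-surgery intermediate-care unit: ~155 patients assessed over
three postoperative days by two independent index raters and one
reference rater, with roughly 9% of observations delirium-positive and
an index-rater agreement of kappa ~ 0.80.

The generative model
--------------------
* Each patient carries a latent daily delirium state following a
  two-state Markov chain.  The day-1 probability equals the target
  observation-level prevalence and the day-to-day onset probability is
  solved so that the marginal prevalence is constant across days.
* Given the latent state, each CAM-IMC feature response is drawn from a
  state-conditional distribution calibrated so that its dichotomised
  operating characteristics (sensitivity against the latent state,
  specificity) match configured targets:

  - fluctuation and RASS != 0 are Bernoulli;
  - inattention error counts (0-10) follow a geometric-family pmf
    ``w_k \\propto r^k`` whose ratio ``r`` is solved so that
    ``P(errors >= 3 | state)`` hits the target;
  - disorientation dimension errors follow Binomial(5, q) with ``q``
    solved so that ``P(errors >= 2 | state)`` hits the target.

* The two index raters see the same patient-day through a Gaussian
  copula: for each feature a shared per-patient-day severity latent is
  mixed with independent rater noise, ``z_r = sqrt(lam) z_shared +
  sqrt(1-lam) eps_r``.  The mixing weight is calibrated by root-finding
  so that the simulated between-rater kappa of CAM-IMC positivity
  matches the configured target.  Because the shared latent is drawn
  independently per feature, features remain conditionally independent
  within a rater and the marginal operating characteristics of the
  total score have the closed (convolution) form exposed by
  :func:`expected_score_distribution`.

* The reference rater reports the latent state, optionally flipped with
  a configurable misclassification probability (default 0: reference =
  truth).

* Index assessments are independently missing at a configurable rate;
  with the defaults this reproduces both the completed-observation
  count (~624 of 930 possible) and the number of dual-rater
  patient-days (~218) seen in practice.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import optimize, stats
from scipy.special import ndtr

from .accuracy import cohen_kappa
from .instrument import DISORIENTATION_DIMENSIONS, DEFAULT_CUTOFF

__all__ = [
    "ItemModel",
    "AgeModel",
    "CohortConfig",
    "SimulatedCohort",
    "study_default_config",
    "simulate_cohort",
    "expected_score_distribution",
    "expected_test_characteristics",
    "expected_item_rates",
    "day1_prevalence_for_patient_incidence",
]

#: Observations completed out of the possible index assessments
#: (155 patients x 3 days x 2 raters) in the cohort being emulated.
_OBS_COMPLETED, _OBS_POSSIBLE = 624, 930
_OBS_POSITIVE = 54

_FEATURES = ("fluctuation", "consciousness", "inattention", "disorientation")

#: Conditional distribution of nonzero RASS values when consciousness is
#: altered.  Postoperative IMC patients are mostly lightly sedated or
#: mildly agitated; deeply sedated levels -4/-5 (unassessable) are not
#: generated by default.
_RASS_NONZERO_VALUES = np.array([-3, -2, -1, 1, 2, 3, 4])
_RASS_NONZERO_PROBS = np.array([0.05, 0.20, 0.35, 0.25, 0.10, 0.03, 0.02])


class ItemModel(BaseModel):
    """Per-feature operating characteristics against the latent state.

    ``*_sens`` is P(item positive | delirium) and ``*_spec`` is
    P(item negative | no delirium), using the item dichotomisations
    (inattention >= 3 errors, disorientation >= 2 dimension errors,
    RASS != 0, fluctuation present).
    """

    model_config = ConfigDict(frozen=True)

    fluctuation_sens: float = 0.83
    fluctuation_spec: float = 0.81
    consciousness_sens: float = 0.35
    consciousness_spec: float = 0.89
    inattention_sens: float = 0.83
    inattention_spec: float = 0.99
    disorientation_sens: float = 0.80
    disorientation_spec: float = 0.99

    @model_validator(mode="after")
    def _probabilities(self):
        for name, v in self.model_dump().items():
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be strictly inside (0, 1), got {v}")
        return self

    def positive_rate(self, feature: str, delirious: bool) -> float:
        if delirious:
            return getattr(self, f"{feature}_sens")
        return 1.0 - getattr(self, f"{feature}_spec")


class AgeModel(BaseModel):
    """Skew-normal age distribution matched to median and IQR, truncated
    to the inclusion criteria."""

    model_config = ConfigDict(frozen=True)

    median: float = 68.0
    q1: float = 61.0
    q3: float = 73.0
    minimum: float = 50.0
    maximum: float = 95.0

    @model_validator(mode="after")
    def _ordered(self):
        if not (self.minimum <= self.q1 < self.median < self.q3 <= self.maximum):
            raise ValueError("age quantiles must satisfy min <= q1 < median < q3 <= max")
        return self


class CohortConfig(BaseModel):
    """Full parameterisation of the synthetic cohort.

    Defaults reproduce the cohort being emulated: 155 patients, 3
    postoperative days, two index raters, observation-level delirium
    prevalence 54/624, item operating characteristics as in
    :class:`ItemModel`, index-rater agreement kappa 0.80, an error-free
    reference rater, and a uniform index-assessment missing rate of
    1 - 624/930.
    """

    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(default=155, ge=1)
    n_days: int = Field(default=3, ge=1)
    #: Target P(delirium) for each patient-day (observation-level prevalence).
    delirium_incidence: float = Field(default=_OBS_POSITIVE / _OBS_COMPLETED,
                                      ge=0.0, lt=1.0)
    #: P(delirious tomorrow | delirious today).
    state_persistence: float = Field(default=0.5, ge=0.0, le=1.0)
    item_model: ItemModel = Field(default_factory=ItemModel)
    #: Target Cohen's kappa between the two index raters' positivity.
    rater_agreement: float = Field(default=0.80, gt=0.0, lt=1.0)
    #: P(reference rater misclassifies the latent state).
    reference_error: float = Field(default=0.0, ge=0.0, le=0.5)
    #: P(an index assessment is not completed).
    missing_rate: float = Field(default=1.0 - _OBS_COMPLETED / _OBS_POSSIBLE,
                                ge=0.0, lt=1.0)
    female_fraction: float = Field(default=0.213, ge=0.0, le=1.0)
    age: AgeModel = Field(default_factory=AgeModel)
    #: P(Mini-Cog = k) for k = 0..5; defaults give median 4, IQR 2-5.
    minicog_probs: tuple = (0.06, 0.10, 0.12, 0.16, 0.26, 0.30)
    #: P(baseline orientation = k) for k = 0..5; defaults give median 5, IQR 5-5.
    orientation_probs: tuple = (0.005, 0.005, 0.01, 0.03, 0.10, 0.85)
    cutoff: int = Field(default=DEFAULT_CUTOFF, ge=0, le=10)
    seed: int = 0

    @model_validator(mode="after")
    def _distributions(self):
        for name in ("minicog_probs", "orientation_probs"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.size != 6 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be 6 non-negative values summing to 1")
        if self.onset_probability > 1.0:
            raise ValueError(
                "delirium_incidence and state_persistence imply an onset "
                "probability above 1; lower the incidence or raise persistence"
            )
        return self

    @property
    def onset_probability(self) -> float:
        """P(delirious tomorrow | not delirious today) keeping the
        marginal prevalence constant across days."""
        m, rho = self.delirium_incidence, self.state_persistence
        return m * (1.0 - rho) / (1.0 - m)


def study_default_config(seed: int = 0) -> CohortConfig:
    """The calibrated default configuration (cohort-shaped defaults)."""
    return CohortConfig(seed=seed)


def day1_prevalence_for_patient_incidence(
    target: float, n_days: int = 3, state_persistence: float = 0.5
) -> float:
    """Day-1 prevalence whose Markov chain yields a given probability
    that a patient is delirious on at least one of ``n_days`` days.

    Utility for calibrating against a patient-level incidence figure
    instead of the (default) observation-level prevalence.
    """
    if not (0.0 < target < 1.0):
        raise ValueError("target incidence must be in (0, 1)")

    def p_ever(pi: float) -> float:
        onset = pi * (1.0 - state_persistence) / (1.0 - pi)
        if onset > 1.0:
            return 1.0
        return 1.0 - (1.0 - pi) * (1.0 - onset) ** (n_days - 1)

    return float(optimize.brentq(lambda pi: p_ever(pi) - target, 1e-9, target))


# ---------------------------------------------------------------------------
# state-conditional response distributions
# ---------------------------------------------------------------------------

def _geometric_family_pmf(log_r: float, support: int = 11) -> np.ndarray:
    w = np.exp(np.arange(support) * log_r)
    return w / w.sum()


@functools.lru_cache(maxsize=None)
def _solve_inattention_pmf(p_ge3: float) -> tuple:
    """pmf over 0..10 errors with ``w_k \\propto r^k`` and P(X>=3) = p_ge3."""
    def f(log_r: float) -> float:
        return _geometric_family_pmf(log_r)[3:].sum() - p_ge3

    log_r = optimize.brentq(f, -25.0, 25.0, xtol=1e-14)
    return tuple(_geometric_family_pmf(log_r))


@functools.lru_cache(maxsize=None)
def _solve_disorientation_pmf(p_ge2: float) -> tuple:
    """Binomial(5, q) pmf over 0..5 dimension errors with P(X>=2) = p_ge2."""
    def f(q: float) -> float:
        return 1.0 - stats.binom.cdf(1, 5, q) - p_ge2

    q = optimize.brentq(f, 1e-12, 1.0 - 1e-12, xtol=1e-14)
    return tuple(stats.binom.pmf(np.arange(6), 5, q))


def _count_cdfs(config: CohortConfig):
    """CDFs of the count features conditional on state: dict
    feature -> (cdf | no delirium, cdf | delirium)."""
    im = config.item_model
    out = {}
    for feature, solver in (
        ("inattention", _solve_inattention_pmf),
        ("disorientation", _solve_disorientation_pmf),
    ):
        cdfs = []
        for delirious in (False, True):
            pmf = np.asarray(solver(im.positive_rate(feature, delirious)))
            cdfs.append(np.cumsum(pmf))
        out[feature] = cdfs
    return out


def expected_item_rates(config: CohortConfig) -> pd.DataFrame:
    """Configured item positivity rates by state (the generator's truth)."""
    rows = [
        {
            "feature": f,
            "sensitivity": config.item_model.positive_rate(f, True),
            "specificity": 1.0 - config.item_model.positive_rate(f, False),
        }
        for f in _FEATURES
    ]
    return pd.DataFrame(rows).set_index("feature")


def expected_score_distribution(config: CohortConfig, delirious: bool) -> np.ndarray:
    """Analytic pmf of the CAM-IMC total (0-10) given the latent state.

    Features are conditionally independent given the state, so the pmf
    is the convolution of the four component point distributions: the
    two Bernoulli items, ``min(inattention errors, 3)`` and the
    disorientation error count.
    """
    im = config.item_model
    p_f = im.positive_rate("fluctuation", delirious)
    p_c = im.positive_rate("consciousness", delirious)
    inatt = np.asarray(_solve_inattention_pmf(im.positive_rate("inattention", delirious)))
    inatt_pts = np.r_[inatt[:3], inatt[3:].sum()]  # capped at 3 points
    disor = np.asarray(_solve_disorientation_pmf(
        im.positive_rate("disorientation", delirious)))
    pmf = np.array([1.0])
    for comp in ([1 - p_f, p_f], [1 - p_c, p_c], inatt_pts, disor):
        pmf = np.convolve(pmf, comp)
    assert pmf.size == 11 and abs(pmf.sum() - 1.0) < 1e-12
    return pmf


def expected_test_characteristics(
    config: CohortConfig, cutoff: Optional[int] = None
) -> tuple:
    """Analytic (sensitivity, specificity) of the CAM-IMC total at a
    cut-off under the generative model — the ground truth that
    parameter-recovery checks compare against."""
    c = config.cutoff if cutoff is None else cutoff
    sens = float(expected_score_distribution(config, True)[c:].sum())
    spec = float(expected_score_distribution(config, False)[:c].sum())
    return sens, spec


# ---------------------------------------------------------------------------
# rater-agreement calibration
# ---------------------------------------------------------------------------

_CALIBRATION_SEED = 20211001  # fixed: common random numbers across lambda
_CALIBRATION_DAYS = 20_000


def _simulate_totals(
    u: np.ndarray, states: np.ndarray, config: CohortConfig
) -> np.ndarray:
    """CAM-IMC totals for uniform feature draws ``u`` of shape
    (n_obs, n_raters, 4 features), given per-observation states."""
    im = config.item_model
    cdfs = _count_cdfs(config)
    n_obs, n_raters, _ = u.shape
    totals = np.zeros((n_obs, n_raters), dtype=int)
    for j, feature in enumerate(_FEATURES):
        uj = u[:, :, j]
        if feature in ("fluctuation", "consciousness"):
            p = np.where(states, im.positive_rate(feature, True),
                         im.positive_rate(feature, False))[:, None]
            totals += (uj > 1.0 - p).astype(int)
        else:
            counts = np.empty_like(totals)
            for s_val in (False, True):
                mask = states == s_val
                cdf = cdfs[feature][int(s_val)]
                counts[mask] = np.searchsorted(cdf, uj[mask], side="right")
            if feature == "inattention":
                counts = np.minimum(counts, 3)
            totals += counts
    return totals


def _copula_uniforms(
    rng: np.random.Generator, n_obs: int, n_raters: int, lam: float
) -> np.ndarray:
    z_shared = rng.standard_normal((n_obs, 1, len(_FEATURES)))
    eps = rng.standard_normal((n_obs, n_raters, len(_FEATURES)))
    z = math.sqrt(lam) * z_shared + math.sqrt(1.0 - lam) * eps
    # keep strictly inside (0, 1) so quantile lookups stay on the support
    return np.clip(ndtr(z), 1e-12, 1.0 - 1e-12)


def _kappa_given_lambda(
    lam: float, base: tuple, config: CohortConfig
) -> float:
    z_shared, eps, states = base
    z = math.sqrt(lam) * z_shared + math.sqrt(1.0 - lam) * eps
    totals = _simulate_totals(ndtr(z), states, config)
    pos = totals >= config.cutoff
    return cohen_kappa(pos[:, 0], pos[:, 1]).kappa


def _calibration_key(config: CohortConfig) -> tuple:
    return (
        config.delirium_incidence,
        config.rater_agreement,
        config.cutoff,
        tuple(sorted(config.item_model.model_dump().items())),
    )


@functools.lru_cache(maxsize=32)
def _solve_rater_lambda_cached(key: tuple, config_json: str) -> float:
    config = CohortConfig.model_validate_json(config_json)
    rng = np.random.default_rng(_CALIBRATION_SEED)
    n = _CALIBRATION_DAYS
    states = rng.random(n) < config.delirium_incidence
    z_shared = rng.standard_normal((n, 1, len(_FEATURES)))
    eps = rng.standard_normal((n, 2, len(_FEATURES)))
    base = (z_shared, eps, states)

    k0 = _kappa_given_lambda(0.0, base, config)
    k1 = _kappa_given_lambda(1.0, base, config)  # identical raters -> 1
    target = config.rater_agreement
    if not (k0 <= target <= k1):
        raise ValueError(
            f"rater_agreement target {target:.3f} is outside the feasible "
            f"range [{k0:.3f}, {k1:.3f}] for this item model and prevalence"
        )
    return float(optimize.brentq(
        lambda lam: _kappa_given_lambda(lam, base, config) - target,
        0.0, 1.0, xtol=1e-4,
    ))


def _solve_rater_lambda(config: CohortConfig) -> float:
    """Copula mixing weight achieving the target index-rater kappa.

    Calibrated by root-finding on a large fixed-seed simulation with
    common random numbers, so the mapping is deterministic and smooth
    in the mixing weight.
    """
    return _solve_rater_lambda_cached(
        _calibration_key(config), config.model_dump_json()
    )


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=8)
def _fit_skewnorm(median: float, q1: float, q3: float) -> tuple:
    """Skew-normal (shape, loc, scale) matching three quartiles."""
    def resid(params):
        a, loc, scale = params
        return stats.skewnorm.ppf([0.25, 0.5, 0.75], a, loc, scale) - [q1, median, q3]

    iqr = q3 - q1
    sol = optimize.least_squares(
        resid, x0=[-1.0, median + iqr / 4, iqr],
        bounds=([-20, median - 5 * iqr, iqr / 10], [20, median + 5 * iqr, 5 * iqr]),
    )
    # the skew-normal cannot always hit three quartiles exactly; a
    # quarter-year residual is immaterial for integer ages
    if not sol.success or np.abs(sol.fun).max() > 0.25:
        raise RuntimeError(f"could not match age quartiles {q1}/{median}/{q3}")
    return tuple(sol.x)


def _draw_ages(rng: np.random.Generator, n: int, age: AgeModel) -> np.ndarray:
    a, loc, scale = _fit_skewnorm(age.median, age.q1, age.q3)
    lo, hi = stats.skewnorm.cdf([age.minimum, age.maximum], a, loc, scale)
    u = rng.uniform(lo, hi, size=n)
    return np.floor(stats.skewnorm.ppf(u, a, loc, scale)).astype(int)


# ---------------------------------------------------------------------------
# main simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedCohort:
    """Simulator output: tidy tables plus the configuration that made them.

    ``assessments`` has one row per completed patient-day-rater
    assessment (index raters with their raw feature responses, the
    reference rater with the diagnosis only) in the same CSV dialect the
    scoring front-end consumes.  ``truth`` carries the latent state per
    patient-day.
    """

    config: CohortConfig
    assessments: pd.DataFrame
    baseline: pd.DataFrame
    truth: pd.DataFrame

    @property
    def n_index_observations(self) -> int:
        return int((self.assessments["rater_role"] == "index").sum())


def simulate_cohort(
    config: Optional[CohortConfig] = None, seed: Optional[int] = None
) -> SimulatedCohort:
    """Generate a synthetic cohort under the configured model.

    Parameters
    ----------
    config : CohortConfig, optional
        Defaults to :func:`study_default_config`.
    seed : int, optional
        Overrides ``config.seed``.  Identical config + seed give
        byte-identical output.
    """
    config = config or study_default_config()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_pat, n_days = config.n_patients, config.n_days
    lam = _solve_rater_lambda(config)

    # --- baseline covariates -------------------------------------------------
    patient_ids = np.array([f"P{i + 1:04d}" for i in range(n_pat)])
    ages = _draw_ages(rng, n_pat, config.age)
    sexes = np.where(rng.random(n_pat) < config.female_fraction, "female", "male")
    minicog = rng.choice(6, size=n_pat, p=np.asarray(config.minicog_probs))
    orientation = rng.choice(6, size=n_pat, p=np.asarray(config.orientation_probs))
    baseline = pd.DataFrame({
        "patient_id": patient_ids,
        "age": ages,
        "sex": sexes,
        "minicog": minicog,
        "baseline_orientation": orientation,
        "baseline_rass": np.zeros(n_pat, dtype=int),
    })

    # --- latent states (two-state Markov chain per patient) ------------------
    states = np.zeros((n_pat, n_days), dtype=bool)
    states[:, 0] = rng.random(n_pat) < config.delirium_incidence
    onset = config.onset_probability
    for d in range(1, n_days):
        u = rng.random(n_pat)
        states[:, d] = np.where(states[:, d - 1],
                                u < config.state_persistence, u < onset)

    flat_states = states.reshape(-1)  # patient-major, day-minor
    n_obs = n_pat * n_days
    pat_idx = np.repeat(np.arange(n_pat), n_days)
    day_idx = np.tile(np.arange(1, n_days + 1), n_pat)

    # --- reference diagnosis --------------------------------------------------
    ref = flat_states.copy()
    if config.reference_error > 0:
        flip = rng.random(n_obs) < config.reference_error
        ref = ref ^ flip

    # --- index-rater responses through the shared-severity copula -----------
    u = _copula_uniforms(rng, n_obs, 2, lam)
    im = config.item_model
    cdfs = _count_cdfs(config)

    def _rate(feature):
        return np.where(flat_states, im.positive_rate(feature, True),
                        im.positive_rate(feature, False))[:, None]

    fluct = u[:, :, 0] > 1.0 - _rate("fluctuation")
    cons_pos = u[:, :, 1] > 1.0 - _rate("consciousness")
    rass = np.zeros((n_obs, 2), dtype=int)
    n_altered = int(cons_pos.sum())
    rass[cons_pos] = rng.choice(
        _RASS_NONZERO_VALUES, size=n_altered, p=_RASS_NONZERO_PROBS
    )
    inatt = np.empty((n_obs, 2), dtype=int)
    disor_n = np.empty((n_obs, 2), dtype=int)
    for s_val in (False, True):
        mask = flat_states == s_val
        inatt[mask] = np.searchsorted(cdfs["inattention"][int(s_val)],
                                      u[mask][:, :, 2], side="right")
        disor_n[mask] = np.searchsorted(cdfs["disorientation"][int(s_val)],
                                        u[mask][:, :, 3], side="right")

    # distribute disorientation errors over the five named dimensions
    dim_rank = np.argsort(rng.random((n_obs, 2, 5)), axis=-1)
    dim_error = dim_rank < disor_n[:, :, None]

    present = rng.random((n_obs, 2)) >= config.missing_rate

    # --- assemble tidy assessment rows ---------------------------------------
    frames = []
    for r in range(2):
        keep = present[:, r]
        df = pd.DataFrame({
            "patient_id": patient_ids[pat_idx[keep]],
            "day": day_idx[keep],
            "rater_id": f"I{r + 1}",
            "rater_role": "index",
            "fluctuation": np.where(fluct[keep, r], "yes", "no"),
            "rass": rass[keep, r],
            "inattention_errors": inatt[keep, r],
        })
        for j, dim in enumerate(DISORIENTATION_DIMENSIONS):
            df[f"disorient_{dim}"] = np.where(
                dim_error[keep, r, j], "error", "correct"
            )
        df["reference_delirium"] = ref[keep].astype(int)
        frames.append(df)

    ref_rows = pd.DataFrame({
        "patient_id": patient_ids[pat_idx],
        "day": day_idx,
        "rater_id": "R1",
        "rater_role": "reference",
        "fluctuation": "",
        "rass": pd.array([pd.NA] * n_obs, dtype="Int64"),
        "inattention_errors": pd.array([pd.NA] * n_obs, dtype="Int64"),
    })
    for dim in DISORIENTATION_DIMENSIONS:
        ref_rows[f"disorient_{dim}"] = ""
    ref_rows["reference_delirium"] = ref.astype(int)
    frames.append(ref_rows)

    assessments = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["patient_id", "day", "rater_id"], kind="stable")
        .reset_index(drop=True)
    )
    assessments["rass"] = assessments["rass"].astype("Int64")
    assessments["inattention_errors"] = assessments["inattention_errors"].astype("Int64")

    truth = pd.DataFrame({
        "patient_id": patient_ids[pat_idx],
        "day": day_idx,
        "true_delirium": flat_states.astype(int),
        "reference_delirium": ref.astype(int),
    })
    return SimulatedCohort(
        config=config, assessments=assessments, baseline=baseline, truth=truth
    )
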