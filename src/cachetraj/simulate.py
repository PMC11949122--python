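"""Synthetic longitudinal cohort generator.

Emulates the statistical structure of an EHR-derived cancer cohort so the
full scoring -> DTW -> clustering -> survival pipeline is testable without
patient data:

* irregular encounter times from a homogeneous Poisson process per patient
  (plus a guaranteed diagnosis-day measurement), integer-day resolution;
* three latent weight-trajectory archetypes — ``persistent`` (early,
  sustained loss), ``smouldering`` (late, shallow loss) and
  ``rapid_recovery`` (fast loss, then regain) — each piecewise linear in
  fractional weight: flat until onset, loss at a constant rate until a
  nadir, optional linear regain capped at the reference weight;
* multiplicative lognormal measurement noise;
* archetype-dependent constant event hazards, with events, loss to
  follow-up and administrative censoring drawn as competing exponential
  clocks; three endpoint channels generated independently with
  channel-specific hazard multipliers, the disability-free and
  hospitalization-free channels censored at death;
* BMI as weight / height^2 with per-patient height fixed at baseline; a
  configurable fraction of patients receives heights making the baseline
  BMI < 20, exercising the tightened cachexia threshold.

Default archetype rates and hazards are calibration choices (the source
cohorts are proprietary): shapes target the three canonical prevalence
morphologies and hazards target median survivals of roughly 0.9, 6 and
3.5 years for persistent, smouldering and rapid-recovery patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import DAYS_PER_YEAR, PatientSeries

__all__ = ["ArchetypeSpec", "CohortSpec", "default_archetypes",
           "generate_trajectory", "generate_cohort"]

ENDPOINT_HAZARD_MULTIPLIERS = {
    "overall": 1.0,
    "disability_free": 1.3,
    "hospitalization_free": 3.0,
}


@dataclass(frozen=True)
class ArchetypeSpec:
    """Latent trajectory archetype parameters.

    loss_rate and recovery_rate are fractions of the reference weight per
    30 days; hazard_rate is the constant overall-survival event hazard per
    year.
    """

    name: str
    onset_time: float       # days from diagnosis when loss begins (may be < 0)
    loss_rate: float        # fraction of reference weight lost per 30 days
    nadir_frac: float       # maximum cumulative fractional loss
    recovery_rate: float    # fraction regained per 30 days after nadir
    noise_sd: float         # sd of multiplicative lognormal measurement noise
    hazard_rate: float      # events per year

    def __post_init__(self):
        if self.loss_rate < 0:
            raise ValueError("loss_rate must be >= 0")
        if not 0 <= self.nadir_frac < 1:
            raise ValueError("nadir_frac must be in [0, 1)")
        if self.recovery_rate < 0:
            raise ValueError("recovery_rate must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.hazard_rate <= 0:
            raise ValueError("hazard_rate must be > 0")


def default_archetypes() -> dict[str, ArchetypeSpec]:
    """Calibrated archetype trio (see module docstring for rationale)."""
    return {
        "persistent": ArchetypeSpec(
            name="persistent", onset_time=-20.0, loss_rate=0.05,
            nadir_frac=0.25, recovery_rate=0.0, noise_sd=0.003,
            hazard_rate=0.80),
        "smouldering": ArchetypeSpec(
            name="smouldering", onset_time=60.0, loss_rate=0.01,
            nadir_frac=0.02, recovery_rate=0.0, noise_sd=0.003,
            hazard_rate=0.115),
        "rapid_recovery": ArchetypeSpec(
            name="rapid_recovery", onset_time=-20.0, loss_rate=0.08,
            nadir_frac=0.15, recovery_rate=0.15, noise_sd=0.003,
            hazard_rate=0.20),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level simulation settings.

    ``mixture`` gives the archetype proportions in the order
    (persistent, smouldering, rapid_recovery) and must sum to 1.
    ``visit_rate`` is the expected number of post-diagnosis measurements per
    year of follow-up (also applied to the pre-diagnosis window).
    """

    n_patients: int = 600
    mixture: tuple = (0.40, 0.25, 0.35)
    visit_rate: float = 30.0
    baseline_window_days: int = 183
    followup_max_years: float = 5.0
    censor_rate: float = 0.10
    bmi_low_frac: float = 0.05
    seed: int = 1
    archetypes: dict = field(default_factory=default_archetypes)

    def __post_init__(self):
        mix = np.asarray(self.mixture, dtype=float)
        if np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("mixture entries must be nonnegative and sum to 1 "
                             f"(got {tuple(self.mixture)})")
        if len(mix) != len(self.archetypes):
            raise ValueError("mixture length must match the number of archetypes")
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.visit_rate <= 0:
            raise ValueError("visit_rate must be > 0")


def generate_trajectory(archetype: ArchetypeSpec, reference_weight: float,
                        times, rng) -> np.ndarray:
    """Evaluate the noisy piecewise weight trajectory at the given times.

    Deterministic part: flat at ``reference_weight`` until ``onset_time``,
    linear fractional loss at ``loss_rate`` until ``nadir_frac`` is reached,
    then linear regain at ``recovery_rate`` capped at the reference weight.
    Each observation is multiplied by lognormal noise with sd ``noise_sd``.
    """
    if reference_weight <= 0:
        raise ValueError("reference_weight must be positive")
    t = np.asarray(times, dtype=float)
    frac_loss = np.zeros_like(t)
    if archetype.loss_rate > 0:
        active = t > archetype.onset_time
        frac_loss[active] = np.minimum(
            archetype.loss_rate * (t[active] - archetype.onset_time) / 30.0,
            archetype.nadir_frac)
        if archetype.recovery_rate > 0 and archetype.nadir_frac > 0:
            t_nadir = archetype.onset_time + 30.0 * archetype.nadir_frac / archetype.loss_rate
            rec = t > t_nadir
            frac_loss[rec] = np.maximum(
                archetype.nadir_frac
                - archetype.recovery_rate * (t[rec] - t_nadir) / 30.0,
                0.0)
    weights = reference_weight * (1.0 - frac_loss)
    if archetype.noise_sd > 0:
        weights = weights * np.exp(rng.normal(0.0, archetype.noise_sd, size=t.shape))
    return weights


def _poisson_times(rng, rate_per_year: float, t0: float, t1: float) -> np.ndarray:
    span_years = (t1 - t0) / DAYS_PER_YEAR
    n = rng.poisson(rate_per_year * span_years)
    return np.sort(rng.uniform(t0, t1, size=n))


def _to_days(t_years: float) -> int:
    return max(1, round(t_years * DAYS_PER_YEAR))


def generate_cohort(spec: CohortSpec) -> list[PatientSeries]:
    """Draw a synthetic cohort; deterministic given ``spec.seed``.

    Each patient gets a latent archetype from the mixture, a pre-diagnosis
    window with at least one measurement, a diagnosis-day measurement plus
    Poisson-process encounters up to the overall-survival channel time, and
    three endpoint channels.
    """
    rng = np.random.default_rng(spec.seed)
    names = list(spec.archetypes)
    patients = []
    width = len(str(spec.n_patients - 1))
    for i in range(spec.n_patients):
        arch_name = names[rng.choice(len(names), p=np.asarray(spec.mixture))]
        arch = spec.archetypes[arch_name]

        reference_weight = max(40.0, rng.normal(78.0, 12.0))
        if rng.uniform() < spec.bmi_low_frac:
            baseline_bmi = rng.uniform(17.5, 19.5)
        else:
            baseline_bmi = max(20.5, rng.normal(26.5, 3.5))
        height = np.sqrt(reference_weight / baseline_bmi)

        # competing exponential clocks; one loss-to-follow-up time per patient
        t_death = rng.exponential(1.0 / arch.hazard_rate)
        t_censor = (rng.exponential(1.0 / spec.censor_rate)
                    if spec.censor_rate > 0 else np.inf)
        t_end = min(t_censor, spec.followup_max_years)
        os_years = min(t_death, t_end)
        os_event = int(t_death <= t_end)
        os_days = _to_days(os_years)
        channels = {"overall": (os_days, os_event)}
        # DFS/HFS: independent event clocks, censored at death or follow-up end
        for ep in ("disability_free", "hospitalization_free"):
            mult = ENDPOINT_HAZARD_MULTIPLIERS[ep]
            t_ep = rng.exponential(1.0 / (arch.hazard_rate * mult))
            ep_event = int(t_ep <= os_years)
            channels[ep] = (_to_days(min(t_ep, os_years)), ep_event)

        # pre-diagnosis encounters are far sparser than oncologic follow-up
        pre_t = _poisson_times(rng, 0.2 * spec.visit_rate,
                               -float(spec.baseline_window_days), 0.0)
        if len(pre_t) == 0:
            pre_t = rng.uniform(-float(spec.baseline_window_days), 0.0, size=1)
        post_t = np.concatenate([[0.0], _poisson_times(rng, spec.visit_rate,
                                                       0.0, float(os_days))])
        pre_t = np.unique(np.minimum(np.round(pre_t), -1).astype(int))
        post_t = np.unique(np.round(post_t).astype(int))

        pre_w = generate_trajectory(arch, reference_weight, pre_t, rng)
        post_w = generate_trajectory(arch, reference_weight, post_t, rng)
        pre_bmi = pre_w / height ** 2
        post_bmi = post_w / height ** 2

        patients.append(PatientSeries(
            patient_id=f"P{i:0{width}d}",
            pre_times=pre_t, pre_weights=pre_w, pre_bmis=pre_bmi,
            post_times=post_t, post_weights=post_w, post_bmis=post_bmi,
            event_channels=channels,
            true_archetype=arch_name,
            covariates={"age_high": int(rng.uniform() < 0.5)},
        ))
    return patients
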