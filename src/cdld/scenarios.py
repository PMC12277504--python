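"""Named simulation scenarios used throughout the tests and reproduction script.

Each returns a :class:`~cdld.synthetic_data.SimConfig` describing one study
condition:

* ``study_scale`` — the study cohort shape: 5,001 interactions from 2,551
  patients, 300 providers, moderate provider effects and observation noise;
* ``zero_noise`` — no observation noise, fully informative features, strong
  provider effects: the outcome is an exact function of the observables, so
  a correct implementation can drive test RMSE toward zero;
* ``noise_floor`` — observation noise sd 0.05 with otherwise-exact structure,
  so test RMSE should settle near 0.05 and train RMSE should not collapse
  far below it;
* ``interaction_rich`` — provider effects dominate the outcome variance
  (share well above 30%), the regime where modelling the provider side must
  beat a patient-only model;
* ``no_provider_effect`` — provider effects switched off: the provider side
  carries no signal and CDLD should match the patient-only baseline.
"""

from __future__ import annotations

from .synthetic_data import SimConfig


def study_scale(seed: int = 0) -> SimConfig:
    return SimConfig(seed=seed)


def zero_noise(seed: int = 0) -> SimConfig:
    return SimConfig(
        n_patients=5000,
        n_admissions=5000,
        n_providers=300,
        provider_effect_sd=0.3,
        noise_sd=0.0,
        feature_informativeness=1.0,
        latent_dim_true=4,
        seed=seed,
    )


def noise_floor(seed: int = 0, noise_sd: float = 0.05) -> SimConfig:
    return SimConfig(
        n_patients=5000,
        n_admissions=5000,
        n_providers=300,
        provider_effect_sd=0.3,
        noise_sd=noise_sd,
        feature_informativeness=1.0,
        latent_dim_true=4,
        seed=seed,
    )


def interaction_rich(seed: int = 0) -> SimConfig:
    # provider variance share: 0.3^2 / (0.15^2 + 0.3^2 + 0.05^2) ~ 0.78
    return SimConfig(
        n_patients=5000,
        n_admissions=5000,
        n_providers=300,
        provider_effect_sd=0.3,
        noise_sd=0.05,
        feature_informativeness=1.0,
        latent_dim_true=4,
        seed=seed,
    )


def no_provider_effect(seed: int = 0) -> SimConfig:
    return SimConfig(
        n_patients=5000,
        n_admissions=5000,
        n_providers=300,
        provider_effect_sd=0.0,
        noise_sd=0.05,
        feature_informativeness=1.0,
        latent_dim_true=4,
        seed=seed,
    )
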