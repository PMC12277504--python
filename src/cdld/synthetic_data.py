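"""Synthetic hospital tables with a known latent patient-provider outcome model.

Emulates the four hosp-module tables the pipeline consumes — patients
(subject_id, gender, age), admissions (subject_id, hadm_id), labevents
(hadm_id, charttime, glucose_value) and poe provider orders (hadm_id,
provider_id) — on top of a generative process whose ground truth is
retained, so every downstream stage (cohort filter, feature engineering,
cyclic training, latent recovery) can be tested without credentialed data.

Generative model, all on the unit outcome scale (125-500 mg/dL maps to
[0, 1]):

* each patient i carries a latent vector ``u_i ~ N(0, I_d)``; the first
  coordinate is the patient's severity trait;
* the stay's peak glucose is a deterministic monotone map of that severity
  (``0.25 + 0.75 * Phi(severity)`` on the unit scale), so the observed
  numeric feature is genuinely informative;
* each provider j carries a latent vector ``v_j ~ N(0, I_d)`` and
  contributes ``provider_effect_sd * v_j[0]`` to the outcome;
* the patient contribution splits into an observable part (driven by the
  severity behind the peak) and a hidden part, mixed by
  ``feature_informativeness``; demographics add a small exactly-encodable
  bucket effect;
* the noise-free outcome is an affine blend
  ``0.3 + patient + provider`` capped at the stay's own peak (a last reading
  cannot exceed the stay maximum) and clipped to [0, 1]; the observed last
  reading adds Gaussian noise with sd ``noise_sd`` before the same caps.

Dominant-provider structure: every admission's true provider gets strictly
more poe rows than any decoy, so the most-frequent-provider rule recovers
the assignment exactly.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .preprocessing import GLUCOSE_FLOOR, GLUCOSE_SPAN, age_bucket_index

__all__ = ["SimConfig", "RawTables", "GroundTruth", "generate", "write_raw_tables", "read_raw_tables"]

TABLE_NAMES = ("patients", "admissions", "labevents", "poe")

# fixed generator constants (unit outcome scale)
_BASELINE_OUTCOME = 0.3
_PEAK_NORM_LO = 0.25  # peak glucose spans [0.25, 1.0] on the unit scale
_AGE_EFFECT = 0.05
_GENDER_EFFECT = 0.02
_SUBNORMAL_LO, _SUBNORMAL_SPAN = 60.0, 64.0  # mg/dL band for never-abnormal stays


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic cohort.

    Defaults emulate the study cohort: 5,001 interactions drawn from 2,551
    patients, ~53.8% male, mean age about 63 years, every stay containing at
    least one abnormal (>= 125 mg/dL) glucose reading.
    """

    n_patients: int = 2551
    n_providers: int = 300
    n_admissions: int | None = 5001  # None -> one admission per patient
    measurements_per_stay_range: tuple[int, int] = (3, 10)
    provider_effect_sd: float = 0.1
    noise_sd: float = 0.05
    feature_informativeness: float = 1.0
    patient_effect_sd: float = 0.15
    frac_abnormal: float = 1.0
    latent_dim_true: int = 4
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_patients, self.n_providers, self.latent_dim_true) <= 0:
            raise ValueError("counts must be positive")
        if self.n_admissions is not None and self.n_admissions < self.n_patients:
            raise ValueError("n_admissions must be >= n_patients (every patient gets a stay)")
        if self.n_providers > 10 * self.n_patients:
            raise ValueError(
                f"degenerate sparsity: {self.n_providers} providers for "
                f"{self.n_patients} patients (limit is 10 per patient)"
            )
        lo, hi = self.measurements_per_stay_range
        if lo < 2 or hi < lo:
            raise ValueError("measurements_per_stay_range needs min >= 2 and max >= min")
        if self.provider_effect_sd < 0 or self.noise_sd < 0 or self.patient_effect_sd < 0:
            raise ValueError("effect and noise standard deviations must be nonnegative")
        if not 0.0 <= self.feature_informativeness <= 1.0:
            raise ValueError("feature_informativeness must lie in [0, 1]")
        if not 0.0 <= self.frac_abnormal <= 1.0:
            raise ValueError("frac_abnormal must lie in [0, 1]")
        if self.latent_dim_true < 2:
            raise ValueError("latent_dim_true must be >= 2 (observable + hidden coordinates)")


@dataclass
class RawTables:
    """The four relational tables a pipeline run consumes."""

    patients: pd.DataFrame
    admissions: pd.DataFrame
    labevents: pd.DataFrame
    poe: pd.DataFrame


@dataclass
class GroundTruth:
    """Simulator-side truth for recovery tests; arrays are in admission order."""

    patient_latents: pd.DataFrame  # index subject_id, columns u0..u{d-1}
    provider_latents: pd.DataFrame  # index provider_id, columns v0..v{d-1}
    hadm_ids: np.ndarray
    noise_free_outcome: np.ndarray  # unit scale, in [0, 1]
    provider_assignment: np.ndarray  # provider_id string per admission
    provider_effects: np.ndarray = field(repr=False)  # per-provider scalar effect
    abnormal: np.ndarray = field(repr=False)  # per-admission cohort-eligibility flag


def _provider_id_strings(rng: np.random.Generator, n: int) -> list[str]:
    """Unique opaque alphanumeric provider ids (MIMIC-style, e.g. 'P03XQ7')."""
    alphabet = np.array(list(string.ascii_uppercase + string.digits))
    ids: list[str] = []
    seen: set[str] = set()
    while len(ids) < n:
        tag = "P" + "".join(rng.choice(alphabet, size=5))
        if tag not in seen:
            seen.add(tag)
            ids.append(tag)
    return ids


def _demographic_effect(ages: np.ndarray, genders: np.ndarray) -> np.ndarray:
    """Small, exactly one-hot-encodable demographic contribution to the outcome."""
    buckets = np.array([age_bucket_index(int(a)) for a in ages], dtype=float)
    age_term = _AGE_EFFECT * (buckets - 2.5) / 2.5
    gender_term = np.where(genders == "M", _GENDER_EFFECT, -_GENDER_EFFECT)
    return age_term + gender_term


def generate(config: SimConfig) -> tuple[RawTables, GroundTruth]:
    """Draw a full synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    d = config.latent_dim_true
    n_pat, n_prov = config.n_patients, config.n_providers
    n_adm = config.n_admissions if config.n_admissions is not None else n_pat

    # patients: demographics match the study cohort profile
    subject_ids = 10_000 + np.arange(n_pat)
    ages = np.clip(np.rint(rng.normal(63.2, 15.5, size=n_pat)), 18, 95).astype(int)
    genders = np.where(rng.random(n_pat) < 0.538, "M", "F")
    u = rng.normal(size=(n_pat, d))

    # providers
    provider_ids = _provider_id_strings(rng, n_prov)
    v = rng.normal(size=(n_prov, d))
    provider_effects = config.provider_effect_sd * v[:, 0]

    # admissions: every patient gets one stay, extras assigned at random
    subj_idx = np.concatenate(
        [np.arange(n_pat), rng.integers(0, n_pat, size=n_adm - n_pat)]
    )
    hadm_ids = 20_000_000 + np.arange(n_adm)
    prov_idx = rng.integers(0, n_prov, size=n_adm)

    # outcome model (unit scale); severity is a pure patient trait, so with
    # zero noise and no provider effect a patient's stays have equal outcomes
    f = config.feature_informativeness
    severity = u[subj_idx, 0]
    hidden = u[subj_idx, 1]
    demo = _demographic_effect(ages, genders)[subj_idx]
    patient_contrib = (
        config.patient_effect_sd * (np.sqrt(f) * severity + np.sqrt(1.0 - f) * hidden) + demo
    )
    peak_norm = _PEAK_NORM_LO + (1.0 - _PEAK_NORM_LO) * ndtr(severity)
    raw_outcome = _BASELINE_OUTCOME + patient_contrib + provider_effects[prov_idx]
    noise_free = np.clip(np.minimum(raw_outcome, peak_norm), 0.0, 1.0)
    eps = rng.normal(0.0, config.noise_sd, size=n_adm) if config.noise_sd > 0 else 0.0
    observed = np.clip(np.minimum(raw_outcome + eps, peak_norm), 0.0, 1.0)

    abnormal = rng.random(n_adm) < config.frac_abnormal
    # mg/dL values: abnormal stays live on the study band, the rest below 125
    peak_mgdl = np.where(
        abnormal,
        GLUCOSE_FLOOR + GLUCOSE_SPAN * peak_norm,
        _SUBNORMAL_LO + _SUBNORMAL_SPAN * peak_norm,
    )
    last_mgdl = np.where(
        abnormal,
        GLUCOSE_FLOOR + GLUCOSE_SPAN * observed,
        _SUBNORMAL_LO + _SUBNORMAL_SPAN * observed,
    )

    # lab series: one slot holds the peak (never the last slot), the last slot
    # holds the final reading, fillers sit strictly below the peak
    lo, hi = config.measurements_per_stay_range
    lengths = rng.integers(lo, hi + 1, size=n_adm)
    lab_hadm: list[np.ndarray] = []
    lab_time: list[np.ndarray] = []
    lab_val: list[np.ndarray] = []
    for i in range(n_adm):
        m = int(lengths[i])
        floor_i = _SUBNORMAL_LO if not abnormal[i] else max(90.0, 0.5 * peak_mgdl[i])
        vals = rng.uniform(floor_i, peak_mgdl[i], size=m)
        vals[rng.integers(0, m - 1)] = peak_mgdl[i]
        vals[-1] = last_mgdl[i]
        times = np.cumsum(rng.integers(20, 240, size=m))
        lab_hadm.append(np.full(m, hadm_ids[i]))
        lab_time.append(times)
        lab_val.append(np.round(vals, 1))

    labevents = pd.DataFrame(
        {
            "hadm_id": np.concatenate(lab_hadm),
            "charttime": np.concatenate(lab_time),
            "glucose_value": np.concatenate(lab_val),
        }
    )

    # poe orders: dominant provider strictly out-counts <= 2 decoys
    poe_hadm: list[int] = []
    poe_prov: list[str] = []
    for i in range(n_adm):
        k_dom = int(rng.integers(3, 7))
        poe_hadm.extend([hadm_ids[i]] * k_dom)
        poe_prov.extend([provider_ids[prov_idx[i]]] * k_dom)
        if n_prov > 1:
            n_decoys = int(rng.integers(0, min(3, n_prov)))
            if n_decoys:
                others = [j for j in rng.choice(n_prov, size=n_decoys + 1, replace=False) if j != prov_idx[i]][:n_decoys]
                for j in others:
                    k = int(rng.integers(1, k_dom))  # strictly fewer than dominant
                    poe_hadm.extend([hadm_ids[i]] * k)
                    poe_prov.extend([provider_ids[j]] * k)
    poe = pd.DataFrame({"hadm_id": poe_hadm, "provider_id": poe_prov})

    tables = RawTables(
        patients=pd.DataFrame({"subject_id": subject_ids, "gender": genders, "age": ages}),
        admissions=pd.DataFrame({"subject_id": subject_ids[subj_idx], "hadm_id": hadm_ids}),
        labevents=labevents,
        poe=poe,
    )
    truth = GroundTruth(
        patient_latents=pd.DataFrame(
            u, index=pd.Index(subject_ids, name="subject_id"), columns=[f"u{k}" for k in range(d)]
        ),
        provider_latents=pd.DataFrame(
            v, index=pd.Index(provider_ids, name="provider_id"), columns=[f"v{k}" for k in range(d)]
        ),
        hadm_ids=hadm_ids,
        noise_free_outcome=noise_free,
        provider_assignment=np.array(provider_ids)[prov_idx],
        provider_effects=provider_effects,
        abnormal=abnormal,
    )
    return tables, truth


def write_raw_tables(tables: RawTables, directory: str | Path) -> dict[str, Path]:
    """Write the four tables as headered CSVs; returns name -> path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name in TABLE_NAMES:
        path = directory / f"{name}.csv"
        try:
            getattr(tables, name).to_csv(path, index=False)
        except OSError as exc:  # pragma: no cover - environment dependent
            raise OSError(f"failed writing table {name!r} to {path}: {exc}") from exc
        paths[name] = path
    return paths


def read_raw_tables(directory: str | Path) -> RawTables:
    """Read the four CSVs written by :func:`write_raw_tables`."""
    directory = Path(directory)
    frames = {}
    for name in TABLE_NAMES:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing table {name!r} at {path}")
        frames[name] = pd.read_csv(path, dtype={"provider_id": str, "gender": str})
    return RawTables(**frames)


def subsampled(config: SimConfig, **overrides) -> SimConfig:
    """Convenience: a copy of ``config`` with fields replaced."""
    return replace(config, **overrides)
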