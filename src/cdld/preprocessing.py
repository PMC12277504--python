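"""Cohort extraction and feature engineering for patient-provider encounters.

Turns the four raw hospital tables (patients, admissions, labevents, poe)
into one model-ready interaction table: one row per retained admission with
the patient's demographic one-hots, the normalized peak glucose of the stay,
an integer provider code, and the normalized last-measured glucose as the
prediction target.

Pipeline stages, in order:

1. group lab events into per-admission, time-ordered glucose series;
2. keep admissions whose peak glucose is abnormal (>= 125 mg/dL);
3. extract (peak, last) per stay, winsorize at 500 mg/dL and map linearly
   onto [0, 1] via (min(v, 500) - 125) / 375;
4. one-hot encode age (six decade-style buckets covering all adults) and
   gender (M/F);
5. assign each admission its most frequently ordering provider and map the
   provider-id strings onto dense integer codes;
6. split rows 80/10/10 and, for the training split only, augment fivefold
   by perturbing the numeric peak feature with uniform noise of magnitude 0.1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_data import RawTables

logger = logging.getLogger("cdld.preprocessing")

# Glucose scale: the study band is 125-500 mg/dL, normalized to [0, 1].
GLUCOSE_FLOOR = 125.0
GLUCOSE_CAP = 500.0
GLUCOSE_SPAN = GLUCOSE_CAP - GLUCOSE_FLOOR  # 375 mg/dL per unit

# Age buckets: [18,30), [30,40), [40,50), [50,60), [60,70), [70,inf).
AGE_BUCKET_LOWER = (18, 30, 40, 50, 60, 70)
AGE_COLS = ("age_18_29", "age_30_39", "age_40_49", "age_50_59", "age_60_69", "age_70_plus")
GENDER_COLS = ("gender_m", "gender_f")
FEATURE_COLS = AGE_COLS + GENDER_COLS + ("peak_glucose_norm",)


# ---------------------------------------------------------------------------
# scalar encodings


def cap_and_normalize(value: float | np.ndarray) -> float | np.ndarray:
    """Winsorize a glucose value at 500 mg/dL and map onto the unit scale.

    125 -> 0.0, 500 -> 1.0, anything above 500 -> 1.0; values below the
    125 mg/dL floor (possible for last measurements, since the cohort filter
    applies to the stay peak) clip to 0.0.
    """
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        bad = arr[~np.isfinite(arr) | (arr <= 0)]
        raise ValueError(f"glucose values must be positive and finite, got {bad!r}")
    out = np.clip((np.minimum(arr, GLUCOSE_CAP) - GLUCOSE_FLOOR) / GLUCOSE_SPAN, 0.0, 1.0)
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


def denormalize(value: float | np.ndarray) -> float | np.ndarray:
    """Inverse of the unit-scale map: 0 -> 125 mg/dL, 1 -> 500 mg/dL."""
    return GLUCOSE_FLOOR + GLUCOSE_SPAN * np.asarray(value, dtype=float)


def age_bucket_index(age: int) -> int:
    """Index of the decade-style age bucket for an adult age (>= 18)."""
    if age < AGE_BUCKET_LOWER[0]:
        raise ValueError(f"cohort excludes ages below 18, got {age}")
    for i in range(len(AGE_BUCKET_LOWER) - 1, -1, -1):
        if age >= AGE_BUCKET_LOWER[i]:
            return i
    raise AssertionError("unreachable")


def encode_age(age: int) -> np.ndarray:
    """One-hot encode age over the six adult buckets."""
    out = np.zeros(len(AGE_COLS), dtype=bool)
    out[age_bucket_index(age)] = True
    return out


def encode_gender(g: str) -> np.ndarray:
    """One-hot encode gender: M -> [1, 0], F -> [0, 1]."""
    if g == "M":
        return np.array([True, False])
    if g == "F":
        return np.array([False, True])
    raise ValueError(f"gender must be 'M' or 'F', got {g!r}")


# ---------------------------------------------------------------------------
# per-admission series


def extract_admission_series(
    labevents: pd.DataFrame, admissions: pd.DataFrame
) -> dict[int, np.ndarray]:
    """Group glucose rows into one time-ordered series per admission.

    Returns a dict keyed by hadm_id (ascending) of float arrays sorted by
    charttime. Admissions with no lab rows are dropped and counted in the
    log. Duplicate (hadm_id, charttime) rows keep their original file order
    (stable sort) and trigger a warning.
    """
    lab = labevents.sort_values("charttime", kind="stable")
    if labevents.duplicated(subset=["hadm_id", "charttime"]).any():
        logger.warning("duplicate (hadm_id, charttime) lab rows: keeping file order")
    series = {
        int(h): grp["glucose_value"].to_numpy(dtype=float)
        for h, grp in lab.groupby("hadm_id", sort=True)
    }
    dropped = int(admissions["hadm_id"].nunique() - len(series))
    if dropped:
        logger.info("dropped %d admissions with no glucose measurements", dropped)
    return series


def select_cohort(series_by_admission: Mapping[int, np.ndarray]) -> list[int]:
    """Keep admissions with at least one abnormal glucose reading (>= 125 mg/dL)."""
    return [h for h, s in series_by_admission.items() if float(np.max(s)) >= GLUCOSE_FLOOR]


def peak_and_last(series: Sequence[float] | np.ndarray) -> tuple[float, float]:
    """Peak (max) and last (final by time) glucose of a non-empty stay series."""
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise ValueError("empty glucose series")
    return float(arr.max()), float(arr[-1])


# ---------------------------------------------------------------------------
# provider assignment


def assign_provider(poe: pd.DataFrame, hadm_id: int) -> str:
    """Most frequently recorded provider for one admission.

    Ties break to the lexicographically smallest provider_id so the result
    is deterministic and data-order independent.
    """
    rows = poe.loc[poe["hadm_id"] == hadm_id, "provider_id"]
    if rows.empty:
        raise ValueError(f"admission {hadm_id} has no provider order rows")
    counts = rows.value_counts()
    top = counts.max()
    return min(counts.index[counts == top])


def assign_providers(poe: pd.DataFrame) -> pd.Series:
    """Vectorized most-frequent-provider assignment for every admission in poe."""
    counts = (
        poe.groupby(["hadm_id", "provider_id"], sort=True).size().reset_index(name="n")
    )
    # sort: count descending, provider_id ascending -> first row per hadm wins
    counts = counts.sort_values(["hadm_id", "n", "provider_id"], ascending=[True, False, True])
    first = counts.drop_duplicates("hadm_id", keep="first")
    return first.set_index("hadm_id")["provider_id"]


def encode_provider_ids(provider_ids: Iterable[str]) -> dict[str, int]:
    """Dense integer codes 0..K-1 assigned in sorted provider-id order."""
    uniq = sorted(set(provider_ids))
    if not uniq:
        raise ValueError("no provider ids to encode")
    return {p: i for i, p in enumerate(uniq)}


# ---------------------------------------------------------------------------
# interaction table


def build_interaction_table(tables: "RawTables") -> tuple[pd.DataFrame, dict[str, int]]:
    """Compose the full preprocessing pipeline into the interaction table.

    One row per retained admission, ordered by hadm_id. Returns the table and
    the provider-id -> integer-code mapping. Dropped-admission counts for each
    stage (no labs, sub-threshold peak, no provider orders) are logged.
    """
    series = extract_admission_series(tables.labevents, tables.admissions)
    kept = select_cohort(series)
    n_filtered = len(series) - len(kept)
    if n_filtered:
        logger.info("dropped %d admissions below the 125 mg/dL peak threshold", n_filtered)

    provider_of = assign_providers(tables.poe)
    kept_with_poe = [h for h in kept if h in provider_of.index]
    if len(kept_with_poe) < len(kept):
        logger.info("dropped %d admissions with no provider orders", len(kept) - len(kept_with_poe))

    code_of = encode_provider_ids(provider_of.loc[kept_with_poe])

    adm = tables.admissions.set_index("hadm_id")["subject_id"]
    pat = tables.patients.set_index("subject_id")

    records = []
    for h in sorted(kept_with_poe):
        peak, last = peak_and_last(series[h])
        subj = int(adm.loc[h])
        row = {"subject_id": subj, "hadm_id": h}
        age_flags = encode_age(int(pat.loc[subj, "age"]))
        gender_flags = encode_gender(str(pat.loc[subj, "gender"]))
        row.update(dict(zip(AGE_COLS, age_flags)))
        row.update(dict(zip(GENDER_COLS, gender_flags)))
        row["peak_glucose_norm"] = cap_and_normalize(peak)
        row["provider_code"] = code_of[provider_of.loc[h]]
        row["target_last_glucose_norm"] = cap_and_normalize(last)
        records.append(row)
    table = pd.DataFrame.from_records(records)
    for c in AGE_COLS + GENDER_COLS:
        table[c] = table[c].astype(bool)
    logger.info("interaction table: %d rows from %d admissions", len(table), len(series))
    return table, code_of


def feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(X, provider codes, targets) arrays from an interaction table.

    X stacks the 8 boolean flags and the normalized peak, in FEATURE_COLS
    order, as float64.
    """
    X = table.loc[:, list(FEATURE_COLS)].to_numpy(dtype=float)
    codes = table["provider_code"].to_numpy(dtype=np.int64)
    y = table["target_last_glucose_norm"].to_numpy(dtype=float)
    return X, codes, y


# ---------------------------------------------------------------------------
# splitting and augmentation


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint row-index sets covering an interaction table."""

    train_rows: np.ndarray
    valid_rows: np.ndarray
    test_rows: np.ndarray
    seed: int

    def as_frame(self) -> pd.DataFrame:
        rows = np.concatenate([self.train_rows, self.valid_rows, self.test_rows])
        split = (
            ["train"] * len(self.train_rows)
            + ["valid"] * len(self.valid_rows)
            + ["test"] * len(self.test_rows)
        )
        return pd.DataFrame({"row": rows, "split": split}).sort_values("row").reset_index(drop=True)


def split_data(
    n: int, fractions: tuple[float, float, float] = (0.8, 0.1, 0.1), seed: int = 0
) -> SplitIndices:
    """Uniform random 80/10/10 partition of row indices.

    Sizes are floor(f_train * n) and floor(f_valid * n), remainder to test,
    so a 5,001-row table splits 4000/500/501. Deterministic given the seed.
    """
    if n < 10:
        raise ValueError(f"need at least 10 rows to split, got {n}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(fractions[0] * n))
    n_valid = int(np.floor(fractions[1] * n))
    return SplitIndices(
        train_rows=np.sort(perm[:n_train]),
        valid_rows=np.sort(perm[n_train : n_train + n_valid]),
        test_rows=np.sort(perm[n_train + n_valid :]),
        seed=seed,
    )


@dataclass
class AugmentedTrainingSet:
    """Training rows plus noisy copies; provenance maps each row to its source."""

    frame: pd.DataFrame
    provenance: np.ndarray = field(repr=False)


def augment_training(
    train_table: pd.DataFrame,
    magnitude: float = 0.1,
    factor: int = 5,
    seed: int = 0,
) -> AugmentedTrainingSet:
    """Fivefold training-set augmentation by perturbing the numeric feature.

    The original rows are kept and (factor - 1) copies are appended in which
    peak_glucose_norm is shifted by uniform noise on [-magnitude, +magnitude]
    and clipped back to [0, 1]. Boolean flags, provider codes and targets are
    never touched; validation and test rows are never augmented.
    """
    if magnitude < 0:
        raise ValueError("noise magnitude must be nonnegative")
    if factor < 1:
        raise ValueError("augmentation factor must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(train_table)
    blocks = [train_table.copy()]
    for _ in range(factor - 1):
        copy = train_table.copy()
        noise = rng.uniform(-magnitude, magnitude, size=n)
        copy["peak_glucose_norm"] = np.clip(copy["peak_glucose_norm"].to_numpy() + noise, 0.0, 1.0)
        blocks.append(copy)
    frame = pd.concat(blocks, ignore_index=True)
    provenance = np.tile(np.arange(n), factor)
    return AugmentedTrainingSet(frame=frame, provenance=provenance)
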