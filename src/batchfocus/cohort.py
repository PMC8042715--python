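"""Cohort I/O, validation, preprocessing and splitting.

Tabular patient cohorts follow a fixed 29-feature clinical schema
(demographics, obstetric history, pre-gestational disease status as a
three-way one-hot group, clinical manifestations, serology, and treatment
flags) with a binary outcome: ``fetal_loss`` is the positive minority
class, ``live_birth`` the negative majority.

The module provides

* the 24-h urinary-protein clipping transform (values at or below the
  0.5 g/24h renal-damage threshold, or untested, map to 0; larger values
  are shifted down by 0.5),
* per-feature min-max normalization whose statistics are computed on the
  training cohort only and re-applied to held-out cohorts,
* one-hot encoding of pre-gestational disease status, and
* a seeded random train/validation split whose training size is rounded
  down to a multiple of the mini-batch size.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("batchfocus")

POSITIVE_LABEL = "fetal_loss"
NEGATIVE_LABEL = "live_birth"
LABEL_COLUMN = "outcome"
ID_COLUMN = "id"

#: Threshold (g/24h) below which 24-h urinary protein is clinically benign.
PROTEINURIA_THRESHOLD = 0.5

PREGESTATIONAL_CATEGORIES = ("remission", "active", "initial_onset")


class CohortValidationError(ValueError):
    """Raised when a record or cohort violates the schema contract."""


# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSpec:
    name: str
    kind: str  # binary | count | continuous | onehot
    unit: str = ""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered 29-feature schema with one mutually exclusive one-hot group."""

    entries: tuple[FeatureSpec, ...]

    def __post_init__(self) -> None:
        if len(self.entries) != 29:
            raise CohortValidationError(
                f"schema must have exactly 29 entries, got {len(self.entries)}"
            )
        kinds = {e.kind for e in self.entries}
        unknown = kinds - {"binary", "count", "continuous", "onehot"}
        if unknown:
            raise CohortValidationError(f"unknown feature kinds: {sorted(unknown)}")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def onehot_indices(self) -> list[int]:
        return [i for i, e in enumerate(self.entries) if e.kind == "onehot"]

    @property
    def scaled_indices(self) -> list[int]:
        """Indices normalized by min-max scaling (count + continuous)."""
        return [i for i, e in enumerate(self.entries) if e.kind in ("count", "continuous")]

    @property
    def binary_like_indices(self) -> list[int]:
        return [i for i, e in enumerate(self.entries) if e.kind in ("binary", "onehot")]

    def to_dict(self) -> dict:
        return {"features": [vars(e) for e in self.entries]}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        return cls(tuple(FeatureSpec(**e) for e in d["features"]))


def default_schema() -> FeatureSchema:
    """The 29-feature clinical schema used throughout the package."""
    b, c, k, o = "binary", "continuous", "count", "onehot"
    specs = [
        ("age", c, "years"),
        ("region", b, "city/rural"),
        ("history_live_birth", k, "frequency"),
        ("history_spontaneous_abortion", k, "frequency"),
        ("history_therapeutic_abortion", k, "frequency"),
        ("history_artificial_abortion", k, "frequency"),
        ("other_adverse_reproductive_history", k, "frequency"),
        ("history_caesarean", k, "frequency"),
        ("other_chronic_disease", b, "Y/N"),
        ("sle_history_years", c, "years"),
        ("pregest_remission", o, "Y/N"),
        ("pregest_active", o, "Y/N"),
        ("pregest_initial_onset", o, "Y/N"),
        ("nephritis", b, "Y/N"),
        ("cutaneous_lesion", b, "Y/N"),
        ("hematological_disorder", b, "Y/N"),
        ("arthritis", b, "Y/N"),
        ("serositis", b, "Y/N"),
        ("anti_ssa", b, "pos/neg"),
        ("anti_ssb", b, "pos/neg"),
        ("anti_dsdna", b, "pos/neg"),
        ("anti_sm", b, "pos/neg"),
        ("apl", b, "pos/neg"),
        ("c3_level", c, "g/L"),
        ("c4_level", c, "g/L"),
        ("urinary_protein_24h", c, "g/24h"),
        ("adp_percent", c, "%"),
        ("glucocorticoid", b, "Y/N"),
        ("aspirin", b, "Y/N"),
    ]
    return FeatureSchema(tuple(FeatureSpec(n, kk, u) for n, kk, u in specs))


# ---------------------------------------------------------------------------
# Elementary transforms
# ---------------------------------------------------------------------------

def clip_proteinuria(raw: float | None) -> float:
    """Clip a raw 24-h urinary protein value (g/24h).

    Values at or below 0.5 g/24h — or missing, because the test is not
    prescribed when routine urinalysis is benign — carry no evidence of
    renal damage and map to 0; larger values are shifted down by the
    0.5 g/24h threshold so the transformed feature is continuous at the
    boundary and non-negative everywhere.
    """
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return 0.0
    raw = float(raw)
    if raw < 0:
        raise CohortValidationError(f"negative proteinuria value {raw!r}")
    if raw <= PROTEINURIA_THRESHOLD:
        return 0.0
    return raw - PROTEINURIA_THRESHOLD


def encode_pregestational_status(status: str) -> tuple[int, int, int]:
    """One-hot encode pre-gestational disease status.

    ``remission`` -> (1,0,0), ``active`` -> (0,1,0),
    ``initial_onset`` -> (0,0,1).
    """
    try:
        i = PREGESTATIONAL_CATEGORIES.index(status)
    except ValueError:
        raise CohortValidationError(
            f"unknown pre-gestational status {status!r}; "
            f"expected one of {PREGESTATIONAL_CATEGORIES}"
        ) from None
    out = [0, 0, 0]
    out[i] = 1
    return tuple(out)


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """An id-indexed feature matrix with binary outcome labels.

    ``X`` has one row per patient and one column per schema feature;
    ``y`` holds 1 for the positive (fetal-loss) minority and 0 for the
    negative (live-birth) majority. ``normalization_state`` is a list of
    per-feature ``(min, max)`` tuples (``None`` for binary/one-hot
    features) recorded when the cohort is normalized, so held-out data
    can be scaled with the training statistics.
    """

    ids: list[str]
    X: np.ndarray
    y: np.ndarray
    schema: FeatureSchema = field(default_factory=default_schema)
    normalization_state: list[tuple[float, float] | None] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.schema.entries):
            raise CohortValidationError(
                f"feature matrix shape {self.X.shape} does not match the "
                f"{len(self.schema.entries)}-feature schema"
            )
        if len(self.ids) != self.X.shape[0] or self.y.shape[0] != self.X.shape[0]:
            raise CohortValidationError("ids, X and y lengths disagree")

    # -- basic queries ----------------------------------------------------
    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_positive(self) -> int:
        return int(self.y.sum())

    @property
    def n_negative(self) -> int:
        return int(self.n - self.y.sum())

    def validate(self) -> None:
        """Check schema invariants for every record."""
        if not np.all(np.isfinite(self.X)):
            raise CohortValidationError("non-finite feature values present")
        Xb = self.X[:, self.schema.binary_like_indices]
        if not np.all((Xb == 0) | (Xb == 1)):
            raise CohortValidationError("binary features must be exactly 0 or 1")
        oh = self.X[:, self.schema.onehot_indices]
        if not np.all(oh.sum(axis=1) == 1):
            raise CohortValidationError(
                "exactly one pre-gestational status flag must be set per record"
            )
        prot = self.X[:, self.schema.index("urinary_protein_24h")]
        if self.normalization_state is None and np.any(prot < 0):
            raise CohortValidationError("urinary protein must be non-negative")
        if not np.all(np.isin(self.y, (0, 1))):
            raise CohortValidationError("labels must be 0/1")

    def subset(self, ids: Sequence[str]) -> "Cohort":
        pos = {pid: i for i, pid in enumerate(self.ids)}
        idx = [pos[i] for i in ids]
        return Cohort(
            ids=list(ids),
            X=self.X[idx].copy(),
            y=self.y[idx].copy(),
            schema=self.schema,
            normalization_state=self.normalization_state,
        )

    # -- serialization ----------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X.copy(), columns=self.schema.names)
        df.insert(0, ID_COLUMN, self.ids)
        df[LABEL_COLUMN] = np.where(self.y == 1, POSITIVE_LABEL, NEGATIVE_LABEL)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        schema: FeatureSchema | None = None,
        raw_proteinuria: bool = False,
    ) -> "Cohort":
        """Build a cohort from a dataframe in the package's CSV dialect.

        The urinary-protein column is assumed to be on the clipped
        (non-negative) scale already; blanks map to 0 either way. Pass
        ``raw_proteinuria`` when reading raw laboratory values to apply
        the clipping transform during ingestion.
        """
        schema = schema or default_schema()
        missing = [c for c in [ID_COLUMN, LABEL_COLUMN, *schema.names] if c not in df.columns]
        if missing:
            raise CohortValidationError(f"missing columns: {missing}")
        labels = df[LABEL_COLUMN].astype(str)
        bad = sorted(set(labels) - {POSITIVE_LABEL, NEGATIVE_LABEL})
        if bad:
            raise CohortValidationError(f"unknown outcome labels: {bad}")
        X = df[schema.names].to_numpy(dtype=float)
        # Only the proteinuria feature may be missing; the clip transform
        # maps blanks to 0. Any other NaN is a data error.
        prot_j = schema.index("urinary_protein_24h")
        nan_mask = np.isnan(X)
        other_nan = nan_mask.copy()
        other_nan[:, prot_j] = False
        if other_nan.any():
            cols = [schema.names[j] for j in sorted(set(np.where(other_nan)[1]))]
            raise CohortValidationError(f"missing values in non-proteinuria columns: {cols}")
        if raw_proteinuria:
            X[:, prot_j] = [
                clip_proteinuria(None if math.isnan(v) else v) for v in X[:, prot_j]
            ]
        else:
            col = X[:, prot_j]
            if np.any(col[~np.isnan(col)] < 0):
                raise CohortValidationError("urinary protein must be non-negative")
            X[np.isnan(col), prot_j] = 0.0
        cohort = cls(
            ids=[str(i) for i in df[ID_COLUMN]],
            X=X,
            y=(labels == POSITIVE_LABEL).to_numpy(),
            schema=schema,
        )
        cohort.validate()
        return cohort

    @classmethod
    def read_csv(
        cls, path, schema: FeatureSchema | None = None, raw_proteinuria: bool = False
    ) -> "Cohort":
        return cls.from_dataframe(pd.read_csv(path), schema, raw_proteinuria)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_cohort(
    cohort: Cohort,
    state: list[tuple[float, float] | None] | None = None,
) -> Cohort:
    """Min-max scale count/continuous features to [0, 1].

    Binary and one-hot features are left untouched. When ``state`` is
    omitted the per-feature (min, max) is computed from ``cohort`` itself
    and stored on the result; pass a training cohort's
    ``normalization_state`` to scale held-out data consistently (scaled
    values may then fall outside [0, 1]; this is allowed and logged).
    A constant feature (max == min) maps to all-zeros with a warning.
    """
    if cohort.normalization_state is not None and state is None:
        raise CohortValidationError("cohort is already normalized")
    X = cohort.X.copy()
    if state is None:
        state = [None] * len(cohort.schema.entries)
        for j in cohort.schema.scaled_indices:
            state[j] = (float(X[:, j].min()), float(X[:, j].max()))
    out_of_range = 0
    for j, mm in enumerate(state):
        if mm is None:
            continue
        lo, hi = mm
        if hi == lo:
            logger.warning(
                "feature %r is constant (min == max == %g); mapped to zeros",
                cohort.schema.names[j], lo,
            )
            X[:, j] = 0.0
        else:
            X[:, j] = (X[:, j] - lo) / (hi - lo)
            out_of_range += int(np.sum((X[:, j] < 0) | (X[:, j] > 1)))
    if out_of_range:
        # routine for held-out cohorts scaled with training statistics
        logger.info(
            "%d scaled values fall outside [0, 1] (held-out data beyond the "
            "training range); values kept as-is", out_of_range,
        )
    return Cohort(
        ids=list(cohort.ids), X=X, y=cohort.y.copy(),
        schema=cohort.schema, normalization_state=list(state),
    )


def denormalize_cohort(cohort: Cohort) -> Cohort:
    """Invert min-max scaling using the cohort's stored state."""
    if cohort.normalization_state is None:
        raise CohortValidationError("cohort has no normalization state")
    X = cohort.X.copy()
    for j, mm in enumerate(cohort.normalization_state):
        if mm is None:
            continue
        lo, hi = mm
        X[:, j] = X[:, j] * (hi - lo) + lo
    return Cohort(ids=list(cohort.ids), X=X, y=cohort.y.copy(), schema=cohort.schema)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """A reproducible train/validation partition of a cohort.

    The training size is the largest multiple of ``batch_size`` not
    exceeding ``train_fraction * n``, so every epoch divides evenly into
    mini-batches.
    """

    train_ids: list[str]
    validation_ids: list[str]
    batch_size: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.train_ids) % self.batch_size != 0:
            raise CohortValidationError("training size must be a multiple of batch size")
        if set(self.train_ids) & set(self.validation_ids):
            raise CohortValidationError("train/validation ids overlap")

    def to_json(self) -> str:
        return json.dumps(
            {
                "train_ids": self.train_ids,
                "validation_ids": self.validation_ids,
                "batch_size": self.batch_size,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "SplitPlan":
        return cls(**json.loads(s))


def split_cohort(
    cohort: Cohort,
    train_fraction: float = 0.7,
    batch_size: int = 13,
    seed: int = 0,
    stratify: bool = False,
) -> SplitPlan:
    """Randomly split a cohort, rounding the training size down to a
    multiple of ``batch_size``.

    With ``stratify`` the class proportions are preserved approximately
    (positives are permuted and allocated proportionally); the default is
    a plain random split.
    """
    if not 0 < train_fraction < 1:
        raise CohortValidationError("train_fraction must be in (0, 1)")
    if batch_size < 1:
        raise CohortValidationError("batch_size must be >= 1")
    n_train = int(batch_size * math.floor(train_fraction * cohort.n / batch_size))
    if n_train == 0:
        raise CohortValidationError(
            f"training size 0 for n={cohort.n}, fraction={train_fraction}, "
            f"batch_size={batch_size}"
        )
    rng = np.random.default_rng(seed)
    ids = np.asarray(cohort.ids, dtype=object)
    if stratify:
        pos = rng.permutation(np.where(cohort.y == 1)[0])
        neg = rng.permutation(np.where(cohort.y == 0)[0])
        n_pos_train = round(n_train * len(pos) / cohort.n)
        train_idx = np.concatenate([pos[:n_pos_train], neg[: n_train - n_pos_train]])
        train_idx = rng.permutation(train_idx)
        val_idx = np.setdiff1d(np.arange(cohort.n), train_idx)
    else:
        perm = rng.permutation(cohort.n)
        train_idx, val_idx = perm[:n_train], perm[n_train:]
    return SplitPlan(
        train_ids=list(ids[train_idx]),
        validation_ids=list(ids[val_idx]),
        batch_size=batch_size,
        seed=seed,
    )
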