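"""Synthetic imbalanced clinical cohorts.

The study population this generator emulates — pregnant patients with
systemic lupus erythematosus (SLE), whose rare adverse outcome (fetal
loss, ~10.4% prevalence) must be predicted from 29 mixed-type clinical
indices — is private, so every other module is exercised on cohorts
drawn from an explicit synthetic stand-in.

The generative model is deliberately simple and documented as such: a
label is drawn at the configured minority rate, then each feature is
drawn from a class-conditional distribution. A configurable subset of
"signal" features (default 8, named after clinically plausible risk
markers purely as naming sugar) separates the classes by a standardized
effect size d, scaled per positive record by a severity multiplier
u ~ Uniform(0.3, 1) — adverse outcomes range from florid to subtle.
Continuous signal features shift their class mean by u·d standard
deviations, binary ones shift their success probability by u·d baseline
standard deviations (clipped away from 0/1), count features shift their
Poisson mean likewise, the one-hot disease-status group shifts mass
toward the active stage, and the zero-inflated proteinuria feature
becomes non-zero more often and larger. With ``effect_size = 0`` the
labels are independent of every feature. Observed labels are flipped
with a small noise rate, mimicking clinically unpredictable outcomes.
No attempt is made to reproduce real inter-feature correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .cohort import Cohort, default_schema

#: Default class-separating features, in priority order. Extending
#: ``n_signal_features`` past this list recruits extra binary markers.
SIGNAL_FEATURES = (
    "nephritis",
    "urinary_protein_24h",
    "c3_level",
    "c4_level",
    "pregest_active",
    "anti_dsdna",
    "apl",
    "history_spontaneous_abortion",
    "anti_ssa",
    "hematological_disorder",
    "serositis",
    "other_chronic_disease",
)

#: Features whose risk direction is a *decrease* (complement consumption).
NEGATIVE_DIRECTION = {"c3_level", "c4_level"}

#: Range of the per-positive severity multiplier applied to effect_size.
SEVERITY_RANGE = (0.3, 1.0)

REFERENCE_SEED = 20110901
REFERENCE_POOL_SIZE = 338
REFERENCE_EXTERNAL_SIZE = 131
REFERENCE_EXTERNAL_POSITIVES = 11


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort generator.

    ``effect_size`` is the standardized per-feature class separation on
    the ``n_signal_features`` signal features; ``noise_flip_rate`` is
    the probability that an observed outcome label contradicts the
    feature-generating class. ``exact_counts`` fixes the positive count
    to ``round(n * minority_rate)`` instead of drawing it binomially.
    """

    n: int = 469
    minority_rate: float = 0.104
    effect_size: float = 1.5
    n_signal_features: int = 8
    noise_flip_rate: float = 0.01
    seed: int = 0
    exact_counts: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.minority_rate < 1:
            raise ValueError("minority_rate must be in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.noise_flip_rate < 0.5:
            raise ValueError("noise_flip_rate must be in [0, 0.5)")
        if not 1 <= self.n_signal_features <= len(SIGNAL_FEATURES):
            raise ValueError(
                f"n_signal_features must be in [1, {len(SIGNAL_FEATURES)}]"
            )
        if self.n < 4:
            raise ValueError("n too small to contain both classes")


# Baseline (majority-class) distribution parameters for each feature.
_BINARY_P = {
    "region": 0.5,
    "other_chronic_disease": 0.12,
    "nephritis": 0.25,
    "cutaneous_lesion": 0.30,
    "hematological_disorder": 0.20,
    "arthritis": 0.30,
    "serositis": 0.10,
    "anti_ssa": 0.45,
    "anti_ssb": 0.25,
    "anti_dsdna": 0.40,
    "anti_sm": 0.20,
    "apl": 0.12,
    "glucocorticoid": 0.80,
    "aspirin": 0.50,
}
_COUNT_LAMBDA = {
    "history_live_birth": 0.6,
    "history_spontaneous_abortion": 0.30,
    "history_therapeutic_abortion": 0.15,
    "history_artificial_abortion": 0.30,
    "other_adverse_reproductive_history": 0.10,
    "history_caesarean": 0.20,
}
_CONTINUOUS_MU_SD = {
    "age": (30.0, 4.5),
    "sle_history_years": (4.0, 3.0),
    "c3_level": (0.85, 0.25),
    "c4_level": (0.16, 0.07),
    "adp_percent": (50.0, 15.0),
}
# zero-inflated proteinuria (post-clip scale): P(non-zero), exp scale
_PROTEINURIA_P_NONZERO = 0.25
_PROTEINURIA_SCALE = 0.8
# one-hot pre-gestational status baseline: remission / active / initial onset
_PREGEST_P = (0.62, 0.26, 0.12)


def generate(config: GeneratorConfig) -> Cohort:
    """Draw a synthetic cohort; fully deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    schema = default_schema()
    n = config.n
    # effect_size is the per-feature standardized mean shift between the
    # two classes on each signal feature
    d = config.effect_size
    signal = set(SIGNAL_FEATURES[: config.n_signal_features])

    if config.exact_counts:
        n_pos = int(round(n * config.minority_rate))
        true_y = np.zeros(n, dtype=int)
        true_y[rng.choice(n, size=n_pos, replace=False)] = 1
    else:
        true_y = (rng.random(n) < config.minority_rate).astype(int)
        if true_y.sum() == 0 or true_y.sum() == n:
            raise ValueError(
                f"n={n} too small: a single class was drawn; increase n"
            )
    pos = true_y == 1

    # Per-case severity: adverse outcomes range from florid presentations
    # (full effect) to subtle ones that barely separate from the majority.
    # Each positive draws a severity u ~ Uniform(SEVERITY_RANGE) and its
    # signal features shift by u * d; negatives sit at the baseline.
    sev = np.zeros(n)
    sev[pos] = rng.uniform(*SEVERITY_RANGE, size=int(pos.sum()))

    X = np.zeros((n, 29))
    for j, spec in enumerate(schema.entries):
        name = spec.name
        shift = sev * d if name in signal else np.zeros(n)
        if name in NEGATIVE_DIRECTION:
            shift = -shift
        if spec.kind == "binary":
            p0 = _BINARY_P[name]
            # shift on the standardized scale: d standard deviations of the
            # baseline Bernoulli, clipped away from degenerate probabilities
            p = np.clip(p0 + shift * math.sqrt(p0 * (1 - p0)), 0.01, 0.99)
            X[:, j] = (rng.random(n) < p).astype(float)
        elif spec.kind == "count":
            lam0 = _COUNT_LAMBDA[name]
            lam = np.maximum(lam0 + shift * math.sqrt(lam0), 0.01)
            X[:, j] = rng.poisson(lam).astype(float)
        elif spec.kind == "continuous" and name != "urinary_protein_24h":
            mu, sd = _CONTINUOUS_MU_SD[name]
            x = rng.normal(mu + shift * sd, sd, size=n)
            X[:, j] = np.clip(x, 0.0, None)
            if name == "adp_percent":
                X[:, j] = np.clip(X[:, j], 0.0, 100.0)

    # one-hot pre-gestational status; signal shifts mass toward "active"
    p_rem, p_act, p_ini = _PREGEST_P
    shift = sev * d if "pregest_active" in signal else np.zeros(n)
    p_act_i = np.clip(p_act + shift * math.sqrt(p_act * (1 - p_act)), 0.01, 0.99)
    rest = (1 - p_act_i) / (p_rem + p_ini)
    u = rng.random(n)
    j_rem = schema.index("pregest_remission")
    for i in range(n):
        pr = (p_rem * rest[i], p_act_i[i], p_ini * rest[i])
        cat = int(np.searchsorted(np.cumsum(pr), u[i]))
        X[i, j_rem + min(cat, 2)] = 1.0

    # zero-inflated proteinuria, already on the clipped (>= 0) scale
    j = schema.index("urinary_protein_24h")
    shift = sev * d if "urinary_protein_24h" in signal else np.zeros(n)
    p0 = _PROTEINURIA_P_NONZERO
    p_nz = np.clip(p0 + shift * math.sqrt(p0 * (1 - p0)), 0.01, 0.99)
    nonzero = rng.random(n) < p_nz
    scale = _PROTEINURIA_SCALE * (1 + 0.5 * np.maximum(shift, 0.0))
    X[:, j] = np.where(nonzero, rng.exponential(scale, size=n), 0.0)

    # Observed labels: flip with the noise rate. In exact_counts mode the
    # class totals are contractual, so noise is applied as count-preserving
    # swaps (k mislabeled pairs) instead of independent flips.
    y = true_y.copy()
    if config.noise_flip_rate > 0:
        if config.exact_counts:
            pos_idx = np.where(true_y == 1)[0]
            neg_idx = np.where(true_y == 0)[0]
            k = int(rng.binomial(min(pos_idx.size, neg_idx.size), config.noise_flip_rate))
            if k:
                y[rng.choice(pos_idx, size=k, replace=False)] = 0
                y[rng.choice(neg_idx, size=k, replace=False)] = 1
        else:
            flips = rng.random(n) < config.noise_flip_rate
            y[flips] = 1 - y[flips]

    cohort = Cohort(
        ids=[f"S{i:04d}" for i in range(n)],
        X=X,
        y=y,
        schema=schema,
    )
    cohort.validate()
    return cohort


class ReferenceCohorts(NamedTuple):
    """The fixed benchmark pair: a development pool and an external pool."""

    pool: Cohort
    external: Cohort


def reference_cohort() -> ReferenceCohorts:
    """The fixed benchmark cohorts used by the acceptance experiments.

    A 338-patient development pool (prevalence 0.104, effect size 1.5)
    and a 131-patient external pool containing exactly 11 positives,
    regenerated identically on every call.
    """
    pool = generate(
        GeneratorConfig(
            n=REFERENCE_POOL_SIZE,
            minority_rate=0.104,
            effect_size=1.5,
            seed=REFERENCE_SEED,
            exact_counts=True,
        )
    )
    external = generate(
        GeneratorConfig(
            n=REFERENCE_EXTERNAL_SIZE,
            minority_rate=REFERENCE_EXTERNAL_POSITIVES / REFERENCE_EXTERNAL_SIZE,
            effect_size=1.5,
            seed=REFERENCE_SEED + 1,
            exact_counts=True,
        )
    )
    external = Cohort(
        ids=[f"E{i:04d}" for i in range(external.n)],
        X=external.X,
        y=external.y,
        schema=external.schema,
    )
    return ReferenceCohorts(pool=pool, external=external)
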