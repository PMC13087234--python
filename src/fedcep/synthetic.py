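"""Synthetic EHR cohorts and lagged-causal time-series panels.

Every downstream stage of the simulator is exercised on data produced here:
tabular patient cohorts with mixed numeric/categorical features, missingness
and a binary outcome (mirroring the public heart-failure / stroke / cirrhosis
style of EHR table), and multivariate time-series panels with planted lagged
causal edges so that temporal-causal-graph recovery can be verified against
ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

LABEL_COLUMN = "event"

#: Default cohort template, shaped like a heart-failure EHR table.
HEART_FAILURE_TEMPLATE = dict(
    numeric_features=[
        ("age", 54.0, 9.0),
        ("resting_bp", 132.0, 18.0),
        ("cholesterol", 198.0, 110.0),
        ("max_heart_rate", 137.0, 25.0),
        ("oldpeak", 0.9, 1.1),
    ],
    categorical_features=[
        ("sex", ("F", "M"), (0.21, 0.79)),
        ("chest_pain_type", ("ASY", "ATA", "NAP", "TA"), (0.54, 0.19, 0.22, 0.05)),
        ("fasting_blood_sugar", ("no", "yes"), (0.77, 0.23)),
        ("exercise_angina", ("no", "yes"), (0.6, 0.4)),
    ],
)


@dataclass(frozen=True)
class CohortSpec:
    """Generative recipe for one hospital's patient cohort.

    ``label_model`` maps the z-scored numeric features (in listed order) to a
    logistic linear predictor; categorical features enter through per-category
    offsets when listed in ``categorical_effects``.
    """

    n_records: int
    numeric_features: Sequence[tuple[str, float, float]]
    categorical_features: Sequence[tuple[str, Sequence[str], Sequence[float]]] = ()
    missing_rate: float = 0.0
    coefficients: Sequence[float] = ()
    intercept: float = 0.0
    categorical_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_records < 2:
            raise ConfigurationError(f"n_records must be >= 2, got {self.n_records}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        for name, _, sd in self.numeric_features:
            if sd <= 0:
                raise ConfigurationError(f"numeric feature {name!r}: sd must be > 0")
        for name, cats, probs in self.categorical_features:
            if len(cats) != len(probs):
                raise ConfigurationError(f"categorical feature {name!r}: categories/probabilities length mismatch")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigurationError(f"categorical feature {name!r}: probabilities sum to {sum(probs)}, not 1")
        if self.coefficients and len(self.coefficients) != len(self.numeric_features):
            raise ConfigurationError("coefficients length must match numeric_features")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_records": self.n_records,
                "numeric_features": [list(f) for f in self.numeric_features],
                "categorical_features": [[n, list(c), list(p)] for n, c, p in self.categorical_features],
                "missing_rate": self.missing_rate,
                "coefficients": list(self.coefficients),
                "intercept": self.intercept,
                "categorical_effects": self.categorical_effects,
                "seed": self.seed,
            },
            sort_keys=True,
        )


@dataclass(frozen=True)
class PanelSpec:
    """Recipe for a multivariate series with planted lagged linear edges.

    Each planted edge ``(source, target, coefficient)`` contributes
    ``coefficient * x_source(t - lag)`` to ``x_target(t)``; nodes with no
    parents are pure Gaussian noise of ``noise_sd``.
    """

    n_nodes: int
    n_steps: int
    lag: int = 1
    planted_edges: Sequence[tuple[int, int, float]] = ()
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_nodes < 1:
            raise ConfigurationError("n_nodes must be positive")
        if self.lag < 1:
            raise ConfigurationError("lag must be a positive integer")
        if self.lag >= self.n_steps:
            raise ConfigurationError(f"lag ({self.lag}) must be < n_steps ({self.n_steps})")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        for s, t, _ in self.planted_edges:
            if not (0 <= s < self.n_nodes and 0 <= t < self.n_nodes):
                raise ConfigurationError(f"planted edge ({s}, {t}) has out-of-range endpoints")


def default_cohort_spec(n_records: int = 500, missing_rate: float = 0.0, seed: int = 0,
                        flip_sign: bool = False, label_scale: float = 1.0) -> CohortSpec:
    """Heart-failure-shaped cohort with a logistic outcome.

    ``label_scale`` multiplies the label model's coefficients: 1.0 gives a
    noisy clinical-looking outcome (Bayes accuracy around 0.83), larger
    values approach a separable task. ``flip_sign`` negates the
    coefficients, producing a conflicting task for continual-learning
    experiments.
    """
    sign = (-1.0 if flip_sign else 1.0) * label_scale
    return CohortSpec(
        n_records=n_records,
        missing_rate=missing_rate,
        seed=seed,
        coefficients=[sign * c for c in (1.8, 1.2, 0.6, -1.5, 1.0)],
        intercept=0.0,
        categorical_effects={"exercise_angina": {"yes": sign * 1.2, "no": sign * -0.4}},
        **HEART_FAILURE_TEMPLATE,
    )


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort table; the label column is named ``event``.

    Numeric cells are Gaussian, categorical cells multinomial, and the binary
    outcome is Bernoulli(sigmoid(linear predictor)) on the z-scored numerics
    plus categorical offsets. Missing cells are masked independently at
    ``missing_rate`` in feature columns only — never in the label.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cols: dict[str, np.ndarray] = {}
    eta = np.full(spec.n_records, float(spec.intercept))
    for i, (name, mean, sd) in enumerate(spec.numeric_features):
        x = rng.normal(mean, sd, size=spec.n_records)
        cols[name] = x
        if spec.coefficients:
            eta += spec.coefficients[i] * (x - mean) / sd
    for name, cats, probs in spec.categorical_features:
        idx = rng.choice(len(cats), size=spec.n_records, p=np.asarray(probs, dtype=float))
        values = np.asarray(cats, dtype=object)[idx]
        cols[name] = values
        effects = spec.categorical_effects.get(name)
        if effects:
            eta += np.array([effects.get(v, 0.0) for v in values])
    prob = 1.0 / (1.0 + np.exp(-eta))
    cols[LABEL_COLUMN] = (rng.uniform(size=spec.n_records) < prob).astype(int)
    df = pd.DataFrame(cols)
    if spec.missing_rate > 0:
        feature_cols = [c for c in df.columns if c != LABEL_COLUMN]
        mask = rng.uniform(size=(spec.n_records, len(feature_cols))) < spec.missing_rate
        for j, c in enumerate(feature_cols):
            values = df[c].to_numpy(copy=True)
            if values.dtype == object:
                values[mask[:, j]] = None
            else:
                values = values.astype(float)
                values[mask[:, j]] = np.nan
            df[c] = values
    return df


def expected_prevalence(spec: CohortSpec, n_mc: int = 200_000, seed: int = 12345) -> float:
    """Monte-Carlo expected label prevalence of a cohort spec (test oracle)."""
    probe = CohortSpec(**{**spec.__dict__, "n_records": n_mc, "missing_rate": 0.0, "seed": seed})
    return float(generate_cohort(probe)[LABEL_COLUMN].mean())


def generate_panel(spec: PanelSpec) -> tuple[np.ndarray, list[tuple[int, int, float]]]:
    """Simulate the lag-``spec.lag`` linear autoregressive panel.

    Returns ``(panel, planted_edges)`` with panel shaped (n_steps, n_nodes).
    The first ``lag`` steps are pure noise (burn-in of the recursion).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    x = rng.normal(0.0, spec.noise_sd, size=(spec.n_steps, spec.n_nodes))
    for t in range(spec.lag, spec.n_steps):
        for s, tgt, coeff in spec.planted_edges:
            x[t, tgt] += coeff * x[t - spec.lag, s]
    return x, list(spec.planted_edges)


def cohort_to_csv(df: pd.DataFrame, path: str, spec: CohortSpec | None = None) -> None:
    """Write a cohort as CSV (missing cells as empty fields) + JSON spec sidecar."""
    df.to_csv(path, index=False, na_rep="")
    if spec is not None:
        with open(str(path) + ".spec.json", "w") as fh:
            fh.write(spec.to_json())


def panel_to_csv(panel: np.ndarray, path: str) -> None:
    """Write a panel as wide CSV: one column per node, one row per time step."""
    pd.DataFrame(panel, columns=[f"node_{i}" for i in range(panel.shape[1])]).to_csv(path, index=False)
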