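"""Synthetic morphometry cohorts and tiny enumerable model fixtures.

The cohort generator emulates the statistical structure the analysis
assumes for a case-control morphometry table: group-dependent region
means, additive age and sex confound effects, Gaussian residual noise
with optional equicorrelation across features, and an intermediate
third group (first-episode psychosis) whose planted effect is a
fraction ``lambda`` of the chronic-patient effect.

The subject model for feature j of subject i is

    x_ij = mu_j + beta_age_j * (age_i - mean age) + beta_sex_j * sex_i
           + delta_j * g_i + eps_ij

with ``g = 0`` for HC, ``1`` for SCZ and ``lambda`` for FEP, and
``delta_j = d * sigma_j`` on the planted effect regions (zero
elsewhere), so that ``d`` is a standardized mean difference.  Residuals
are Gaussian with per-feature sd ``sigma_j`` and equicorrelation
``rho`` (one shared subject-level factor).

Default group sizes and demographics follow the cohort this pipeline
targets: 83 HC (age 35.49 +/- 11.08, 67% male), 143 SCZ (37.12 +/-
10.99, 66% male), 32 FEP (27.09 +/- 7.97, 46% male).  The default
planted regions are the ten regions the analysis is designed to
surface: cerebellar white matter, lateral ventricle, entorhinal,
rostral anterior cingulate, inferior parietal, insula, transverse
temporal, inferior temporal, lateral orbitofrontal and putamen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io import MorphometryTable
from .rbm import BERNOULLI, RBMParameters, _all_binary_states, free_energy
from .schema import DEFAULT_SCHEMA, FeatureSchema

#: Planted-effect regions used by default (schema names).
DEFAULT_EFFECT_REGIONS: tuple[str, ...] = (
    "Right-Cerebellum-White-Matter",
    "Right-Lateral-Ventricle",
    "rh_entorhinal",
    "rh_rostralanteriorcingulate",
    "lh_inferiorparietal",
    "rh_insula",
    "lh_transversetemporal",
    "rh_inferiortemporal",
    "lh_lateralorbitofrontal",
    "Left-Putamen",
)

# Rough typical volumes (mm^3) used as baselines so that back-transformed
# reports look anatomically plausible; the analysis operates on z-scores,
# so only the relative noise scale matters downstream.
_TYPICAL_VOLUMES: Mapping[str, float] = {
    "Lateral-Ventricle": 7500.0, "Inf-Lat-Vent": 350.0,
    "Cerebellum-White-Matter": 14000.0, "Cerebellum-Cortex": 52000.0,
    "Thalamus-Proper": 7500.0, "Caudate": 3700.0, "Putamen": 5500.0,
    "Pallidum": 1700.0, "3rd-Ventricle": 1000.0, "4th-Ventricle": 1800.0,
    "Brain-Stem": 20000.0, "Hippocampus": 4100.0, "Amygdala": 1600.0,
    "CSF": 900.0, "Accumbens-area": 600.0, "VentralDC": 4000.0,
    "vessel": 60.0, "choroid-plexus": 700.0, "5th-Ventricle": 20.0,
    "WM-hypointensities": 1500.0, "non-WM-hypointensities": 100.0,
    "Optic-Chiasm": 200.0, "CC_Posterior": 1000.0,
    "CC_Mid_Posterior": 450.0, "CC_Central": 450.0,
    "CC_Mid_Anterior": 450.0, "CC_Anterior": 900.0,
}


def _typical_volume(name: str) -> float:
    stripped = name
    for prefix in ("Left-", "Right-"):
        if stripped.startswith(prefix):
            stripped = stripped[len(prefix):]
    if stripped in _TYPICAL_VOLUMES:
        return _TYPICAL_VOLUMES[stripped]
    return 500.0


@dataclass
class GroupSpec:
    n: int
    age_mean: float
    age_sd: float
    male_fraction: float


@dataclass
class SimulationConfig:
    """Cohort generator settings; defaults define the study conditions."""

    hc: GroupSpec = field(default_factory=lambda: GroupSpec(83, 35.49, 11.08, 56 / 83))
    scz: GroupSpec = field(default_factory=lambda: GroupSpec(143, 37.12, 10.99, 95 / 143))
    fep: GroupSpec = field(default_factory=lambda: GroupSpec(32, 27.09, 7.97, 15 / 32))
    effect_regions: tuple[str, ...] = DEFAULT_EFFECT_REGIONS
    effect_size_d: float = 1.0
    fep_scale: float = 0.5
    equicorrelation: float = 0.2
    seed: int = 0
    schema: FeatureSchema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def __post_init__(self) -> None:
        if not (0.0 <= self.fep_scale <= 1.0):
            raise ValueError("fep_scale must lie in [0, 1]")
        if self.effect_size_d < 0:
            raise ValueError("effect_size_d must be non-negative")
        if not (0.0 <= self.equicorrelation < 1.0):
            raise ValueError("equicorrelation must lie in [0, 1)")
        for spec in (self.hc, self.scz, self.fep):
            if spec.n < 0:
                raise ValueError("group sizes must be non-negative")
        unknown = [r for r in self.effect_regions
                   if r not in self.schema.canonical_order]
        if unknown:
            raise ValueError(f"unknown effect regions: {unknown}")


@dataclass
class GroundTruth:
    """What was actually planted, for recovery tests."""

    effect_regions: tuple[str, ...]
    effect_vector: np.ndarray        # per-feature raw-unit mean shift (SCZ-HC)
    standardized_effect: np.ndarray  # per-feature d
    beta_age: np.ndarray
    beta_sex: np.ndarray
    residual_sd: np.ndarray


def _feature_baselines(schema: FeatureSchema
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature baseline mean, residual sd, beta_age, beta_sex.

    Thickness features sit near 2.5 mm (deterministic per-region
    jitter), thin slightly with age and carry no sex effect; volumes
    take structure-typical magnitudes, shrink ~0.3%/year and are ~4%
    larger in males.
    """
    n = schema.n_features
    mu = np.empty(n)
    sd = np.empty(n)
    beta_age = np.empty(n)
    beta_sex = np.empty(n)
    jitter = np.random.default_rng(20160)  # fixed: part of the schema's world
    for i, name in enumerate(schema.canonical_order):
        if i < len(schema.thickness_names):
            mu[i] = 2.5 + jitter.uniform(-0.4, 0.4)
            sd[i] = 0.15
            beta_age[i] = -0.005
            beta_sex[i] = 0.0
        else:
            base = _typical_volume(name)
            mu[i] = base
            sd[i] = max(0.10 * base, 5.0)
            beta_age[i] = -0.003 * base
            beta_sex[i] = 0.04 * base
    return mu, sd, beta_age, beta_sex


def generate_cohort(config: SimulationConfig | None = None
                    ) -> tuple[MorphometryTable, GroundTruth]:
    """Draw a synthetic cohort; returns the table and its ground truth."""
    if config is None:
        config = SimulationConfig()
    schema = config.schema
    rng = np.random.default_rng(config.seed)
    mu, sigma, beta_age, beta_sex = _feature_baselines(schema)

    delta = np.zeros(schema.n_features)
    d_vec = np.zeros(schema.n_features)
    for region in config.effect_regions:
        j = schema.index_of(region)
        d_vec[j] = config.effect_size_d
        delta[j] = config.effect_size_d * sigma[j]

    groups = (("HC", config.hc, 0.0), ("SCZ", config.scz, 1.0),
              ("FEP", config.fep, config.fep_scale))
    ids: list[str] = []
    labels: list[str] = []
    ages: list[np.ndarray] = []
    sexes: list[np.ndarray] = []
    gvals: list[np.ndarray] = []
    for label, spec, g in groups:
        ids.extend(f"{label}{i + 1:03d}" for i in range(spec.n))
        labels.extend([label] * spec.n)
        ages.append(rng.normal(spec.age_mean, spec.age_sd, spec.n))
        sexes.append((rng.random(spec.n) < spec.male_fraction).astype(int))
        gvals.append(np.full(spec.n, g))
    age = np.concatenate(ages) if ages else np.empty(0)
    sex = np.concatenate(sexes) if sexes else np.empty(0, dtype=int)
    g = np.concatenate(gvals) if gvals else np.empty(0)
    n = age.shape[0]

    rho = config.equicorrelation
    shared = rng.standard_normal((n, 1))
    unique = rng.standard_normal((n, schema.n_features))
    eps = (np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * unique) * sigma

    centered_age = age - age.mean() if n else age
    features = (mu
                + centered_age[:, None] * beta_age
                + sex[:, None].astype(float) * beta_sex
                + g[:, None] * delta
                + eps)
    table = MorphometryTable(ids, labels, age, sex, features,
                             provenance="synthetic", schema=schema)
    truth = GroundTruth(
        effect_regions=config.effect_regions, effect_vector=delta,
        standardized_effect=d_vec, beta_age=beta_age, beta_sex=beta_sex,
        residual_sd=sigma)
    return table, truth


@dataclass
class TinyFixture:
    """Small enumerable model plus a dataset drawn exactly from it."""

    params: RBMParameters | None
    data: np.ndarray
    labels: np.ndarray | None = None
    n_label_units: int = 0
    net: "object | None" = None  # FineTunedNetwork for kind="network"


def _sample_from_rbm(params: RBMParameters, n_samples: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Exact ancestral sampling of visible states via enumeration."""
    states = _all_binary_states(params.n_visible)
    log_p = -free_energy(params, states)
    log_p -= log_p.max()
    p = np.exp(log_p)
    p /= p.sum()
    idx = rng.choice(states.shape[0], size=n_samples, p=p)
    return states[idx]


def tiny_fixture(kind: str, seed: int = 0, n_samples: int = 80) -> TinyFixture:
    """Enumerable fixtures for oracle tests.

    ``rbm``: a 4-visible / 3-hidden Bernoulli RBM and an exact sample
    from it.  ``associative``: a 8-visible (6 penultimate + 2 label) /
    6-hidden RBM, 14 units total so that clamped conditionals can be
    enumerated; the last two visible columns are the label block.
    """
    rng = np.random.default_rng(seed)
    if kind == "rbm":
        params = RBMParameters(
            W=rng.normal(0, 1.0, (3, 4)),
            b_vis=rng.normal(0, 0.5, 4),
            b_hid=rng.normal(0, 0.5, 3),
            visible_family=BERNOULLI)
        data = _sample_from_rbm(params, n_samples, rng)
        return TinyFixture(params=params, data=data)
    if kind == "associative":
        params = RBMParameters(
            W=rng.normal(0, 1.0, (6, 8)),
            b_vis=rng.normal(0, 0.5, 8),
            b_hid=rng.normal(0, 0.5, 6),
            visible_family=BERNOULLI)
        data = _sample_from_rbm(params, n_samples, rng)
        labels = data[:, -2:].argmax(axis=1)
        return TinyFixture(params=params, data=data, labels=labels,
                           n_label_units=2)
    if kind == "network":
        from .dbn import random_network

        centers = np.array([[-1.5, 0.0], [1.5, 0.0]])
        labels = rng.integers(0, 2, n_samples)
        data = centers[labels] + rng.standard_normal((n_samples, 2)) * 0.5
        net = random_network(n_inputs=2, n_hidden_layers=1, width=6,
                             seed=seed, init_sd=0.1)
        return TinyFixture(params=None, data=data, labels=labels, net=net)
    raise ValueError(f"unknown fixture kind {kind!r}")
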