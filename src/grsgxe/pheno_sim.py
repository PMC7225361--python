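"""Trait simulation with SNP main effects, an exposure effect, and SNP x E
interactions.

Continuous traits follow

    Y_i = sum_d beta_Gd G_id + beta_E E_i + sum_d beta_Intd G_id E_i + eps_i,

with eps_i standard normal; binary traits follow the logistic analogue with
an intercept fixing the population prevalence (log(0.1/0.9) or log(0.4/0.6)
for 10% / 40%).  Four causal SNPs are assumed throughout; either all four or
only two of them carry interactions, with sign patterns given by fourteen
canonical scenarios covering exacerbation, attenuation, and cross-over
interaction structure for exposures that raise or lower the trait.

Effect magnitudes are sampled uniformly: |beta_Gd| from [0.04, 0.08]
(continuous) or [log 1.05, log 1.15] (binary, log-odds scale); |beta_E| is
fixed at 0.3 or log(1.3); |beta_Intd| is drawn from the same range as the
main effects but independently of them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .data_io import CohortTable, GenotypePanel

__all__ = [
    "ScenarioSpec",
    "EffectConfig",
    "SimulatedCohort",
    "scenario_table",
    "get_scenario",
    "sample_exposure",
    "sample_effects",
    "prevalence_intercept",
    "simulate_trait",
    "EFFECT_RANGES",
    "EXPOSURE_EFFECT",
]

#: |beta_G| and |beta_Int| sampling ranges per trait family
EFFECT_RANGES = {
    "gaussian": (0.04, 0.08),
    "binomial": (np.log(1.05), np.log(1.15)),
}

#: |beta_E| per trait family
EXPOSURE_EFFECT = {
    "gaussian": 0.3,
    "binomial": np.log(1.3),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One row of the 14-scenario sign table.

    ``e_sign`` is the sign of the exposure main effect; ``g_signs`` the four
    SNP main-effect signs; ``int_signs`` the four interaction signs (0 marks
    a causal SNP with no interaction).  ``label`` classifies the pattern as
    exacerbation, attenuation, or cross-over.
    """

    scenario_id: int
    e_sign: int
    g_signs: tuple[int, int, int, int]
    int_signs: tuple[int, int, int, int]
    label: str

    @property
    def n_interacting(self) -> int:
        """D: number of causal SNPs that also interact with E (2 or 4)."""
        return sum(1 for s in self.int_signs if s != 0)

    @property
    def true_int_sign(self) -> int | None:
        """Sign of the aggregate GRS x E coefficient; None for cross-over."""
        if self.label == "exacerbation":
            return +1
        if self.label == "attenuation":
            return -1
        return None


_TABLE = [
    (1, +1, (+1, +1, +1, +1), (+1, +1, +1, +1), "exacerbation"),
    (2, +1, (+1, +1, +1, +1), (-1, -1, -1, -1), "attenuation"),
    (3, +1, (+1, +1, +1, +1), (+1, +1, 0, 0), "exacerbation"),
    (4, +1, (+1, +1, +1, +1), (-1, -1, 0, 0), "attenuation"),
    (5, +1, (+1, +1, +1, +1), (+1, +1, -1, -1), "cross-over"),
    (6, +1, (+1, +1, -1, -1), (+1, +1, -1, -1), "exacerbation"),
    (7, +1, (+1, +1, -1, -1), (-1, -1, +1, +1), "attenuation"),
    (8, -1, (+1, +1, +1, +1), (+1, +1, +1, +1), "exacerbation"),
    (9, -1, (+1, +1, +1, +1), (-1, -1, -1, -1), "attenuation"),
    (10, -1, (+1, +1, +1, +1), (+1, +1, 0, 0), "exacerbation"),
    (11, -1, (+1, +1, +1, +1), (-1, -1, 0, 0), "attenuation"),
    (12, -1, (+1, +1, +1, +1), (+1, +1, -1, -1), "cross-over"),
    (13, -1, (+1, +1, -1, -1), (+1, +1, -1, -1), "exacerbation"),
    (14, -1, (+1, +1, -1, -1), (-1, -1, +1, +1), "attenuation"),
]


def scenario_table() -> list[ScenarioSpec]:
    """The 14 canonical sign scenarios used by the power study."""
    return [ScenarioSpec(*row) for row in _TABLE]


def get_scenario(scenario_id: int) -> ScenarioSpec:
    if not 1 <= scenario_id <= 14:
        raise ValueError(f"scenario_id must be 1..14, got {scenario_id}")
    return ScenarioSpec(*_TABLE[scenario_id - 1])


@dataclass
class EffectConfig:
    """Realized effect sizes for one simulation replicate."""

    beta_G: np.ndarray            # 4 signed SNP main effects
    beta_E: float
    beta_int: np.ndarray          # 4 signed interaction effects (0 allowed)
    trait_family: str = "gaussian"
    intercept: float | None = None  # binomial only (logit of prevalence)

    def __post_init__(self) -> None:
        self.beta_G = np.asarray(self.beta_G, dtype=float)
        self.beta_int = np.asarray(self.beta_int, dtype=float)
        if self.beta_G.shape != (4,) or self.beta_int.shape != (4,):
            raise ValueError("beta_G and beta_int must each have 4 entries")
        if self.trait_family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown trait family {self.trait_family!r}")
        if self.trait_family == "binomial" and self.intercept is None:
            raise ValueError("binomial effects require an intercept")


@dataclass
class SimulatedCohort:
    """A simulated cohort bundled with its generating configuration."""

    cohort: CohortTable
    causal_indices: np.ndarray
    effects: EffectConfig
    scenario: ScenarioSpec | None = None


def prevalence_intercept(prevalence: float) -> float:
    """Logit intercept yielding the requested disease prevalence when all
    other effects are zero (e.g. log(0.1/0.9) for 10%)."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    return float(np.log(prevalence / (1.0 - prevalence)))


def sample_exposure(kind: str, n: int, p_exposed: float = 0.2,
                    seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw the exposure: Bernoulli(p_exposed) or Normal(0, sd = 0.5)."""
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    if kind == "binary":
        if not 0.0 < p_exposed < 1.0:
            raise ValueError("p_exposed must lie in (0, 1)")
        return rng.binomial(1, p_exposed, size=n).astype(float)
    if kind == "continuous":
        return rng.normal(0.0, 0.5, size=n)
    raise ValueError(f"unknown exposure kind {kind!r}")


def sample_effects(scenario: ScenarioSpec, family: str = "gaussian",
                   seed: int | np.random.Generator = 0,
                   prevalence: float = 0.1,
                   effect_scale: float = 1.0,
                   null_interactions: bool = False) -> EffectConfig:
    """Sample signed effect sizes for one replicate under a scenario.

    Main-effect and interaction magnitudes are drawn independently of each
    other from the family-specific uniform range; signs come from the
    scenario, and structural-zero interactions stay exactly zero.
    ``effect_scale`` multiplies all genetic magnitudes (used for inflated-
    effect studies); ``null_interactions`` forces every beta_Int to 0 for
    type-I-error generation.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    if family not in EFFECT_RANGES:
        raise ValueError(f"unknown trait family {family!r}")
    lo, hi = EFFECT_RANGES[family]
    g_signs = np.array(scenario.g_signs, dtype=float)
    i_signs = np.array(scenario.int_signs, dtype=float)
    beta_G = g_signs * rng.uniform(lo, hi, size=4) * effect_scale
    beta_int = i_signs * rng.uniform(lo, hi, size=4) * effect_scale
    if null_interactions:
        beta_int = np.zeros(4)
    beta_E = scenario.e_sign * EXPOSURE_EFFECT[family]
    intercept = prevalence_intercept(prevalence) if family == "binomial" else None
    return EffectConfig(beta_G=beta_G, beta_E=beta_E, beta_int=beta_int,
                        trait_family=family, intercept=intercept)


def simulate_trait(panel: GenotypePanel, causal: np.ndarray,
                   effects: EffectConfig, exposure: np.ndarray,
                   seed: int | np.random.Generator = 0,
                   scenario: ScenarioSpec | None = None) -> SimulatedCohort:
    """Simulate a trait from the panel, causal set, and effect sizes.

    Gaussian traits add a standard-normal error to the linear predictor;
    binary traits are Bernoulli draws from the logistic model (cohort-style
    sampling; no case-control ascertainment).
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    causal = np.asarray(causal, dtype=int)
    if causal.shape != (4,):
        raise ValueError("exactly 4 causal SNP indices are required")
    exposure = np.asarray(exposure, dtype=float).ravel()
    if exposure.shape[0] != panel.n_samples:
        raise ValueError("exposure length must match panel sample count")

    G = panel.imputed_dosages()[:, causal]
    lp = (G @ effects.beta_G + effects.beta_E * exposure
          + (G * exposure[:, None]) @ effects.beta_int)
    if effects.trait_family == "gaussian":
        y = lp + rng.standard_normal(panel.n_samples)
    else:
        prob = expit(effects.intercept + lp)
        y = rng.binomial(1, prob).astype(float)

    cohort = CohortTable(y=y, exposure=exposure,
                         covariates=np.zeros((panel.n_samples, 0)),
                         family=effects.trait_family)
    return SimulatedCohort(cohort=cohort, causal_indices=causal,
                           effects=effects, scenario=scenario)
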