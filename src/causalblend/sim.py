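"""Synthetic HIV-like causal system with known ground truth.

The generator draws a semi-realistic observational study with measured
confounders (age ``X0``, immune status ``X2``, comorbidity ``X4``), a
geography-driven binary instrument ``Z``, a viral-load-like post-treatment
mediator ``M``, a latent health factor ``X7`` withheld from the released
data, and an age-modulated heterogeneous treatment effect. Two tables are
produced per study: the *observed* data an analyst would see, and a
*ground-truth* table carrying the per-unit effect (on both the logit and the
probability scale), the realized propensity, and both potential-outcome
probabilities — the oracle every benchmark in this package is scored against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "SimConfig",
    "SimulatedStudy",
    "draw_covariates",
    "assign_instrument",
    "assign_treatment",
    "generate_mediator",
    "true_ite",
    "generate_outcome",
    "simulate_study",
]

OBSERVED_COLUMNS = [
    "X0", "X1", "X2", "X3", "X4", "X5", "X6", "X8", "X9", "Z", "M", "T", "Y",
]


@dataclass
class SimConfig:
    """Configuration of the data-generating process.

    Defaults reproduce the study conditions exactly: ``n=5000`` units at seed
    42, treatment/outcome logit noise with SD 0.5, mediator noise SD 1, and
    the printed structural coefficients. ``confound_scale`` multiplies the
    confounder coefficients of the treatment equation for robustness sweeps.
    """

    n: int = 5000
    seed: int = 42
    noise_sd_t: float = 0.5
    noise_sd_y: float = 0.5
    noise_sd_m: float = 1.0
    confound_scale: float = 1.0
    # coefficient blocks; defaults are the structural equations of the system
    instrument_coefs: dict = field(
        default_factory=lambda: {"X8": 0.8, "intercept": -0.5}
    )
    treatment_coefs: dict = field(
        default_factory=lambda: {"X0c": 0.02, "X2": 0.6, "X4": 0.5, "Z": 1.5}
    )
    mediator_coefs: dict = field(
        default_factory=lambda: {"intercept": 2.0, "T": -1.5, "X3": 0.5}
    )
    effect_coefs: dict = field(default_factory=lambda: {"intercept": -1.5, "X0c": 0.08})
    outcome_coefs: dict = field(
        default_factory=lambda: {"X0c": 0.03, "X2": -0.8, "X4": 0.7, "M": 0.5, "X7": 0.4}
    )

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        for name in ("noise_sd_t", "noise_sd_y", "noise_sd_m", "confound_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class SimulatedStudy:
    """Paired observed/ground-truth tables released by one simulation."""

    observed: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.observed.to_csv(outdir / "observed.csv", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)


def draw_covariates(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the exogenous covariates X0-X9 (including the latent X7)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n
    return pd.DataFrame(
        {
            "X0": rng.normal(50.0, 10.0, n),          # age
            "X1": rng.binomial(1, 0.5, n).astype(float),   # gender
            "X2": rng.normal(0.0, 1.0, n),            # immune status
            "X3": rng.normal(0.0, 1.0, n),
            "X4": rng.binomial(1, 0.2, n).astype(float),   # comorbidity
            "X5": rng.uniform(0.0, 1.0, n),           # behavior
            "X6": rng.poisson(2.0, n).astype(float),  # visits
            "X7": rng.normal(0.0, 1.0, n),            # latent health factor
            "X8": rng.binomial(1, 0.6, n).astype(float),   # geography
            "X9": rng.normal(0.0, 1.0, n),
        }
    )


def assign_instrument(X8: np.ndarray, rng: np.random.Generator,
                      coefs: dict | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Draw the policy-like instrument Z from geography X8."""
    X8 = np.asarray(X8, dtype=float)
    if not np.isin(X8, (0.0, 1.0)).all():
        raise ValueError("X8 must be binary")
    coefs = coefs or {"X8": 0.8, "intercept": -0.5}
    prob = expit(coefs["X8"] * X8 + coefs["intercept"])
    z = rng.binomial(1, prob).astype(float)
    return z, prob


def assign_treatment(X: pd.DataFrame, Z: np.ndarray, config: SimConfig,
                     rng: np.random.Generator,
                     eps_t: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Assign treatment from a logistic model with confounding and the instrument.

    The recorded propensity is the sigmoid of the *realized* logit (noise
    included) actually used to draw T.
    """
    c = config.treatment_coefs
    if eps_t is None:
        eps_t = rng.normal(0.0, config.noise_sd_t, len(X))
    logit = (
        c["X0c"] * (X["X0"].to_numpy() - 50.0)
        + config.confound_scale * (c["X2"] * X["X2"].to_numpy() + c["X4"] * X["X4"].to_numpy())
        + c["Z"] * np.asarray(Z, dtype=float)
        + eps_t
    )
    propensity = expit(logit)
    t = rng.binomial(1, propensity).astype(float)
    return t, propensity


def generate_mediator(T: np.ndarray, X3: np.ndarray, config: SimConfig,
                      eps_m: np.ndarray) -> np.ndarray:
    """Post-treatment mediator: M = 2 - 1.5 T + 0.5 X3 + noise."""
    c = config.mediator_coefs
    return c["intercept"] + c["T"] * np.asarray(T, float) + c["X3"] * np.asarray(X3, float) + eps_m


def true_ite(X0: np.ndarray, config: SimConfig | None = None) -> np.ndarray:
    """Age-modulated effect on the outcome-logit scale: -1.5 + 0.08 (X0 - 50)."""
    c = (config or SimConfig(n=1)).effect_coefs
    return c["intercept"] + c["X0c"] * (np.asarray(X0, float) - 50.0)


def _outcome_logit(X: pd.DataFrame, M: np.ndarray, T: np.ndarray,
                   tau: np.ndarray, config: SimConfig, eps_y: np.ndarray) -> np.ndarray:
    c = config.outcome_coefs
    return (
        c["X0c"] * (X["X0"].to_numpy() - 50.0)
        + c["X2"] * X["X2"].to_numpy()
        + c["X4"] * X["X4"].to_numpy()
        + c["M"] * np.asarray(M, float)
        + c["X7"] * X["X7"].to_numpy()
        + np.asarray(T, float) * tau
        + eps_y
    )


def generate_outcome(X: pd.DataFrame, M: np.ndarray, T: np.ndarray, tau: np.ndarray,
                     config: SimConfig, rng: np.random.Generator,
                     eps_m: np.ndarray, eps_y: np.ndarray | None = None):
    """Draw the binary outcome and the per-unit potential-outcome probabilities.

    The potential-outcome probability p(t) sets T=t and propagates t through
    the mediator equation (total effect), holding each unit's noise draws
    fixed; the factual probability therefore equals p(T_i) exactly.
    """
    if eps_y is None:
        eps_y = rng.normal(0.0, config.noise_sd_y, len(X))
    p_factual = expit(_outcome_logit(X, M, T, tau, config, eps_y))
    y = rng.binomial(1, p_factual).astype(float)
    n = len(X)
    m1 = generate_mediator(np.ones(n), X["X3"].to_numpy(), config, eps_m)
    m0 = generate_mediator(np.zeros(n), X["X3"].to_numpy(), config, eps_m)
    p1 = expit(_outcome_logit(X, m1, np.ones(n), tau, config, eps_y))
    p0 = expit(_outcome_logit(X, m0, np.zeros(n), tau, config, eps_y))
    return y, p1, p0


def simulate_study(config: SimConfig | None = None) -> SimulatedStudy:
    """Run the full data-generating process and release both tables.

    All per-unit noise is drawn before any derived quantity so unit order
    never affects values; the same config yields byte-identical tables.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    X = draw_covariates(config, rng)
    eps_t = rng.normal(0.0, config.noise_sd_t, config.n)
    eps_m = rng.normal(0.0, config.noise_sd_m, config.n)
    eps_y = rng.normal(0.0, config.noise_sd_y, config.n)

    z, _ = assign_instrument(X["X8"].to_numpy(), rng, config.instrument_coefs)
    t, propensity = assign_treatment(X, z, config, rng, eps_t=eps_t)
    m = generate_mediator(t, X["X3"].to_numpy(), config, eps_m)
    tau = true_ite(X["X0"].to_numpy(), config)
    y, p1, p0 = generate_outcome(X, m, t, tau, config, rng, eps_m, eps_y=eps_y)

    observed = X.drop(columns=["X7"]).copy()
    observed["Z"] = z
    observed["M"] = m
    observed["T"] = t
    observed["Y"] = y
    observed = observed[OBSERVED_COLUMNS]

    truth = pd.DataFrame(
        {
            "tau_logit": tau,            # printed effect modulator (logit scale)
            "tau_prob": p1 - p0,         # probability-scale contrast (Eq-2 estimand)
            "propensity": propensity,
            "p1": p1,
            "p0": p0,
        }
    )
    return SimulatedStudy(observed=observed, truth=truth, config=config)
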