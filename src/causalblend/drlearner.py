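"""Cross-fitted doubly robust treatment-effect estimation.

Nuisances are a per-arm random-forest outcome regression and an
L2-regularized logistic propensity model, fit under K-fold cross-fitting so
no unit's nuisance prediction comes from a model that saw its fold. Effects
combine both nuisances in the doubly robust pseudo-outcome, whose mean is
the ATE and whose second-stage regression on the covariates yields a
smoothed per-unit effect function. The estimator stays consistent when
either nuisance (but not both) is misspecified. Binary and multi-arm
treatments are supported; multi-arm propensities come from one multinomial
model so they sum to one across arms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "DRConfig",
    "NuisanceFit",
    "EffectEstimate",
    "fit_nuisances",
    "pseudo_outcome",
    "multiarm_pseudo_outcome",
    "estimate_effects",
]


@dataclass
class DRConfig:
    n_folds: int = 5
    clip: float = 0.01              # propensity clipping bound eta
    n_estimators: int = 100
    max_depth: int = 5
    min_samples_leaf: int = 50
    propensity_c: float = 1.0
    propensity_max_iter: int = 1000
    propensity_tol: float = 1e-4
    # second stage: pseudo-outcomes carry inverse-propensity noise far above
    # the outcome scale, so the effect regression smooths more aggressively
    # and averages more trees
    second_stage_max_depth: int = 4
    second_stage_min_leaf: int = 200
    second_stage_n_estimators: int = 300
    linear_outcome: bool = False    # deliberate misspecification toggle
    seed: int = 0


@dataclass
class NuisanceFit:
    """Cross-fitted nuisance predictions for every unit."""

    mu: dict            # arm -> (n,) cross-fitted outcome predictions mu_t(x_i)
    propensity: np.ndarray  # (n, n_arms) clipped generalized propensities
    arms: tuple
    folds: np.ndarray   # fold id per unit
    config: DRConfig
    outcome_models: dict = field(default_factory=dict)   # (fold, arm) -> model
    propensity_models: dict = field(default_factory=dict)  # fold -> model

    def propensity_for(self, arm) -> np.ndarray:
        return self.propensity[:, self.arms.index(arm)]

    def tree_std(self, arm, X: np.ndarray) -> np.ndarray:
        """Across-tree SD of the arm's outcome forests (prediction uncertainty).

        Averaged over folds; zero when the outcome model is not a forest.
        """
        stds = []
        for (fold, a), model in self.outcome_models.items():
            if a != arm or not hasattr(model, "estimators_"):
                continue
            per_tree = np.stack([t.predict(X) for t in model.estimators_])
            stds.append(per_tree.std(axis=0))
        if not stds:
            return np.zeros(len(X))
        return np.mean(stds, axis=0)


@dataclass
class EffectEstimate:
    pseudo: np.ndarray        # per-unit DR pseudo-outcomes tau_hat_i
    ite: np.ndarray           # smoothed effect function tau_hat(x_i)
    ate: float
    contrast: tuple           # (a, b)
    second_stage: object = None

    def predict_ite(self, X: np.ndarray) -> np.ndarray:
        return self.second_stage.predict(np.asarray(X, float))

    def write(self, outdir, unit_ids=None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        n = len(self.pseudo)
        pd.DataFrame({
            "unit": unit_ids if unit_ids is not None else np.arange(n),
            "pseudo_outcome": self.pseudo,
            "smoothed_ite": self.ite,
            "contrast": [f"{self.contrast[0]}-vs-{self.contrast[1]}"] * n,
        }).to_csv(outdir / "effects.csv", index=False)
        (outdir / "ate.json").write_text(json.dumps(
            {"ate": self.ate, "contrast": list(self.contrast)}, indent=2))


def _outcome_model(config: DRConfig, seed: int):
    if config.linear_outcome:
        return LinearRegression()
    return RandomForestRegressor(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        min_samples_leaf=config.min_samples_leaf,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )


def fit_nuisances(X: np.ndarray, T: np.ndarray, Y: np.ndarray,
                  config: DRConfig | None = None) -> NuisanceFit:
    """Cross-fit outcome and propensity models over stratified folds."""
    config = config or DRConfig()
    X = np.asarray(X, float)
    T = np.asarray(T).ravel()
    Y = np.asarray(Y, float).ravel()
    arms = tuple(sorted(np.unique(T).tolist()))
    if len(arms) < 2:
        raise ValueError("treatment must have at least two levels")
    n = len(X)
    splitter = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                               random_state=config.seed)
    folds = np.empty(n, dtype=int)
    mu = {arm: np.full(n, np.nan) for arm in arms}
    prop = np.full((n, len(arms)), np.nan)
    outcome_models: dict = {}
    propensity_models: dict = {}
    for fold, (train_idx, test_idx) in enumerate(splitter.split(X, T)):
        folds[test_idx] = fold
        for arm in arms:
            mask = train_idx[T[train_idx] == arm]
            if len(mask) == 0:
                raise ValueError(f"arm {arm!r} absent from training fold {fold}")
            model = _outcome_model(config, config.seed + fold)
            model.fit(X[mask], Y[mask])
            mu[arm][test_idx] = model.predict(X[test_idx])
            outcome_models[(fold, arm)] = model
        lr = LogisticRegression(  # default penalty is the L2 ridge
            C=config.propensity_c,
            max_iter=config.propensity_max_iter, tol=config.propensity_tol,
        )
        lr.fit(X[train_idx], T[train_idx])
        probs = lr.predict_proba(X[test_idx])
        cols = [lr.classes_.tolist().index(arm) for arm in arms]
        prop[test_idx] = probs[:, cols]
        propensity_models[fold] = lr
    prop = np.clip(prop, config.clip, 1.0 - config.clip)
    return NuisanceFit(mu=mu, propensity=prop, arms=arms, folds=folds,
                       config=config, outcome_models=outcome_models,
                       propensity_models=propensity_models)


def pseudo_outcome(y, t, e, mu1, mu0):
    """Binary-treatment doubly robust pseudo-outcome.

    tau = (t - e) / (e (1 - e)) * (y - mu_t) + mu_1 - mu_0, with mu_t the
    factual arm's outcome prediction and e the (clipped) propensity.
    """
    y = np.asarray(y, float)
    t = np.asarray(t, float)
    e = np.asarray(e, float)
    mu1 = np.asarray(mu1, float)
    mu0 = np.asarray(mu0, float)
    if np.any((e <= 0) | (e >= 1)):
        raise ValueError("propensities must lie strictly in (0, 1); clip upstream")
    mu_t = np.where(t == 1, mu1, mu0)
    return (t - e) / (e * (1.0 - e)) * (y - mu_t) + mu1 - mu0


def multiarm_pseudo_outcome(y, t, a, b, e_a, e_b, mu_a, mu_b):
    """Doubly robust pseudo-outcome for the contrast of arms a vs b."""
    if a == b:
        raise ValueError("contrast arms must differ")
    y = np.asarray(y, float)
    t = np.asarray(t)
    e_a = np.asarray(e_a, float)
    e_b = np.asarray(e_b, float)
    if np.any((e_a <= 0) | (e_a >= 1)) or np.any((e_b <= 0) | (e_b >= 1)):
        raise ValueError("propensities must lie strictly in (0, 1); clip upstream")
    mu_a = np.asarray(mu_a, float)
    mu_b = np.asarray(mu_b, float)
    ind_a = (t == a).astype(float)
    ind_b = (t == b).astype(float)
    return ind_a / e_a * (y - mu_a) - ind_b / e_b * (y - mu_b) + mu_a - mu_b


def estimate_effects(nuisances: NuisanceFit, X: np.ndarray, T: np.ndarray,
                     Y: np.ndarray, contrast: tuple | None = None) -> EffectEstimate:
    """ATE and smoothed per-unit effects from the DR pseudo-outcomes.

    The ATE is exactly the mean pseudo-outcome; the per-unit effect function
    is a second-stage random-forest regression of the pseudo-outcomes on the
    covariates, which trades the raw pseudo-outcomes' variance for smooth
    heterogeneity in x.
    """
    X = np.asarray(X, float)
    T = np.asarray(T).ravel()
    Y = np.asarray(Y, float).ravel()
    arms = nuisances.arms
    if contrast is None:
        contrast = (arms[-1], arms[0])
    a, b = contrast
    if len(arms) == 2 and set(contrast) == set(arms):
        hi, lo = contrast
        e_hi = nuisances.propensity_for(hi)
        t_bin = (T == hi).astype(float)
        pseudo = pseudo_outcome(Y, t_bin, e_hi,
                                nuisances.mu[hi], nuisances.mu[lo])
    else:
        pseudo = multiarm_pseudo_outcome(
            Y, T, a, b,
            nuisances.propensity_for(a), nuisances.propensity_for(b),
            nuisances.mu[a], nuisances.mu[b],
        )
    cfg = nuisances.config
    second = RandomForestRegressor(
        n_estimators=cfg.second_stage_n_estimators,
        max_depth=cfg.second_stage_max_depth,
        min_samples_leaf=cfg.second_stage_min_leaf, bootstrap=True,
        random_state=cfg.seed, n_jobs=1,
    )
    second.fit(X, pseudo)
    ite = second.predict(X)
    return EffectEstimate(pseudo=pseudo, ite=ite, ate=float(pseudo.mean()),
                          contrast=(a, b), second_stage=second)
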