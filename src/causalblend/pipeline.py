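"""End-to-end orchestration: preprocessing, graph selection, dual-branch
fitting, RL blending, uncertainty, drift and metrics.

``run_study`` executes the full stack on one dataset (real CSVs or the
built-in simulator): preprocess -> DAG selection -> role-based feature
selection -> attention-predictor fit -> doubly robust fit -> state
construction -> agent fit on the validation split -> blended inference with
Monte Carlo-dropout uncertainty and a drift check on the test split ->
metric reports. ``run_benchmark`` repeats this across component-ablation
variants and seeds and tabulates the results.
"""

from __future__ import annotations

import logging
import time
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import drlearner, ensemble, evaluation, graph, reliability, sim, titan

__all__ = [
    "Preprocessor",
    "preprocess",
    "infer_schema",
    "RunConfig",
    "StudyResult",
    "run_study",
    "run_benchmark",
    "VARIANTS",
]

VARIANTS = (
    "full", "no_rl", "no_titan", "no_drlearner", "no_graph",
    "no_uncertainty", "no_drift", "titan_only", "drlearner_only", "mlp_baseline",
)

logger = logging.getLogger(__name__)


@contextmanager
def _stage(name: str):
    start = time.perf_counter()
    yield
    logger.info("stage %-22s %6.2fs", name, time.perf_counter() - start)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def infer_schema(table: pd.DataFrame, max_categories: int = 10) -> dict:
    """Columns with few distinct values are categorical, the rest continuous."""
    schema = {}
    for col in table.columns:
        values = table[col].dropna()
        if values.nunique() <= max_categories or not np.issubdtype(
                values.dtype, np.number):
            schema[col] = "categorical"
        else:
            schema[col] = "continuous"
    return schema


class Preprocessor:
    """Median-impute + robust-scale continuous columns; mode-impute +
    integer-encode categorical columns. Fit on training data, apply anywhere."""

    def __init__(self, schema: dict):
        self.schema = dict(schema)
        self.medians: dict = {}
        self.iqrs: dict = {}
        self.modes: dict = {}
        self.mappings: dict = {}

    def fit(self, table: pd.DataFrame) -> "Preprocessor":
        for col, kind in self.schema.items():
            series = table[col]
            if series.isna().all():
                raise ValueError(f"column {col!r} is entirely missing")
            if kind == "continuous":
                self.medians[col] = float(series.median())
                q1, q3 = series.quantile([0.25, 0.75])
                iqr = float(q3 - q1)
                if iqr == 0:
                    warnings.warn(f"zero IQR in column {col!r}; scaling by 1")
                    iqr = 1.0
                self.iqrs[col] = iqr
            else:
                non_null = series.dropna()
                counts = non_null.value_counts(sort=False)
                mode = counts.index[counts.to_numpy().argmax()]
                self.modes[col] = mode
                codes = {}
                for v in non_null:
                    if v not in codes:
                        codes[v] = len(codes)  # first-seen encoding
                self.mappings[col] = codes
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for col, kind in self.schema.items():
            series = table[col]
            if kind == "continuous":
                filled = series.fillna(self.medians[col]).astype(float)
                out[col] = (filled - self.medians[col]) / self.iqrs[col]
            else:
                filled = series.where(series.notna(), other=self.modes[col])
                codes = self.mappings[col]
                out[col] = filled.map(
                    lambda v: codes.setdefault(v, len(codes))).astype(float)
        return pd.DataFrame(out, index=table.index)


def preprocess(table: pd.DataFrame, schema: dict) -> pd.DataFrame:
    """One-shot fit-and-transform convenience wrapper."""
    return Preprocessor(schema).fit(table).transform(table)


# ---------------------------------------------------------------------------
# Run configuration / result containers
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    treatment: str = "T"
    outcome: str = "Y"
    data_path: str | None = None      # observed CSV; None -> simulate
    truth_path: str | None = None
    expert_dag_path: str | None = None
    dag_source: str = "auto"          # expert | discover | auto
    variant: str = "full"
    split: tuple = (0.64, 0.16, 0.20)
    seed: int = 0
    mc_passes: int = 50
    nominal: float = 0.95
    balanced_resampling: bool = False  # class-balanced resample of train split
    sim_config: sim.SimConfig = field(default_factory=sim.SimConfig)
    titan_config: titan.TitanConfig = field(default_factory=titan.TitanConfig)
    dr_config: drlearner.DRConfig = field(default_factory=drlearner.DRConfig)
    agent_config: ensemble.AgentConfig = field(default_factory=ensemble.AgentConfig)
    discovery_config: graph.DiscoveryConfig = field(
        default_factory=graph.DiscoveryConfig)
    discovery_subsample: int = 1000   # rows used for HSIC orientation

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9 or any(f <= 0 for f in self.split):
            raise ValueError("split fractions must be positive and sum to 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class StudyResult:
    predictions: pd.DataFrame
    dag: graph.CausalDAG
    roles: graph.RoleAssignment
    metrics: dict
    drift: reliability.DriftReport | None
    uncertainty: reliability.UncertaintyReport | None
    config_echo: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.predictions.to_csv(outdir / "predictions.csv", index=False)
        self.dag.write_edge_list(outdir / "selected_dag.tsv")
        self.dag.write_graphml(outdir / "selected_dag.graphml")
        evaluation.write_reports(outdir, self.metrics)


# ---------------------------------------------------------------------------
# Internal helpers
# ---------------------------------------------------------------------------

def _dr_mu(nuis: drlearner.NuisanceFit, X: np.ndarray, arm) -> np.ndarray:
    preds = [m.predict(X) for (fold, a), m in nuis.outcome_models.items() if a == arm]
    return np.mean(preds, axis=0)


def _dr_propensity(nuis: drlearner.NuisanceFit, X: np.ndarray, arm) -> np.ndarray:
    cols = []
    for model in nuis.propensity_models.values():
        probs = model.predict_proba(X)
        cols.append(probs[:, model.classes_.tolist().index(arm)])
    return np.clip(np.mean(cols, axis=0), nuis.config.clip, 1 - nuis.config.clip)


def _split_indices(n: int, split: tuple, rng: np.random.Generator):
    order = rng.permutation(n)
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    return order[:n_train], order[n_train:n_train + n_val], order[n_train + n_val:]


def _select_features(config: RunConfig, observed: pd.DataFrame):
    """DAG selection and role-based feature sets."""
    t, y = config.treatment, config.outcome
    covariates = [c for c in observed.columns if c not in (t, y)]
    if config.variant == "no_graph":
        dag = graph.CausalDAG(nodes=tuple(observed.columns), edges=(),
                              provenance="expert")
        roles = graph.RoleAssignment(frozenset(covariates), frozenset(), frozenset())
        return dag, roles

    expert = None
    if config.expert_dag_path is not None:
        expert = graph.CausalDAG.from_edge_list(config.expert_dag_path)
    elif config.data_path is None:
        expert = graph.ground_truth_dag()  # the simulator's known structure

    if config.dag_source == "expert":
        if expert is None:
            raise ValueError("dag_source='expert' requires an expert DAG")
        selected = expert
    else:
        sub = observed
        if len(sub) > config.discovery_subsample:
            sub = sub.sample(config.discovery_subsample,
                             random_state=config.discovery_config.seed)
        discovered = graph.discover_dag(sub, config.discovery_config)
        if config.dag_source == "discover" or expert is None:
            selected = discovered
        else:
            selected = graph.select_dag(expert, discovered, t, y)
    roles = graph.extract_roles(selected, t, y)
    return selected, roles


class _PooledOutcomeBranch:
    """Plain per-arm outcome regressions (no cross-fitting, no DR correction);
    stands in for the doubly robust branch in its ablation."""

    def __init__(self, config: drlearner.DRConfig):
        self.config = config
        self.models: dict = {}

    def fit(self, X, T, Y):
        from sklearn.ensemble import RandomForestRegressor

        self.arms = tuple(sorted(np.unique(T).tolist()))
        for arm in self.arms:
            m = RandomForestRegressor(
                n_estimators=self.config.n_estimators,
                max_depth=self.config.max_depth,
                min_samples_leaf=self.config.min_samples_leaf,
                random_state=self.config.seed, n_jobs=1)
            m.fit(X[T == arm], Y[T == arm])
            self.models[arm] = m
        return self

    def mu(self, X, arm):
        return self.models[arm].predict(X)


# ---------------------------------------------------------------------------
# Main orchestration
# ---------------------------------------------------------------------------

def run_study(config: RunConfig,
              study: sim.SimulatedStudy | None = None) -> StudyResult:
    """Execute the configured pipeline and return all per-unit outputs,
    reports and provenance. ``study`` may inject a pre-generated simulation."""
    t_col, y_col = config.treatment, config.outcome
    truth = None
    if study is not None:
        observed, truth = study.observed, study.truth
    elif config.data_path is None:
        study = sim.simulate_study(config.sim_config)
        observed, truth = study.observed, study.truth
    else:
        observed = pd.read_csv(config.data_path)
        if config.truth_path is not None:
            truth = pd.read_csv(config.truth_path)
    for col in (t_col, y_col):
        if col not in observed.columns:
            raise ValueError(f"declared column {col!r} missing from data")
    T_raw = observed[t_col].to_numpy()
    arms = tuple(sorted(np.unique(T_raw).tolist()))
    if len(arms) < 2:
        raise ValueError("treatment column must have at least two levels")

    # -- preprocessing (fit on train only) ----------------------------------
    rng = np.random.default_rng(config.seed)
    idx_train, idx_val, idx_test = _split_indices(len(observed), config.split, rng)
    if config.balanced_resampling:
        counts = pd.Series(T_raw[idx_train]).value_counts()
        target_n = counts.max()
        resampled = []
        for arm in arms:
            members = idx_train[T_raw[idx_train] == arm]
            resampled.append(rng.choice(members, target_n, replace=True))
        idx_train = rng.permutation(np.concatenate(resampled))
    covar_cols = [c for c in observed.columns if c not in (t_col, y_col)]
    schema = infer_schema(observed[covar_cols])
    prep = Preprocessor(schema).fit(observed.iloc[idx_train][covar_cols])
    Xall = prep.transform(observed[covar_cols])
    Y = observed[y_col].to_numpy(float)

    # -- DAG + roles ----------------------------------------------------------
    dag_input = observed.iloc[idx_train]
    with _stage("graph selection"):
        dag, roles = _select_features(config, dag_input)
    conf = sorted(roles.confounders & set(covar_cols))
    medi = sorted(roles.mediators & set(covar_cols))
    inst = sorted(roles.instruments & set(covar_cols))
    # post-treatment variables (mediators) are excluded from every outcome
    # model's inputs; the propensity model additionally never sees them
    pre_treatment = conf + inst if (conf or inst) else covar_cols
    titan_features = sorted(set(conf + inst)) or covar_cols

    Xdr = Xall[pre_treatment].to_numpy(float)
    Xtitan_cov = Xall[titan_features].to_numpy(float)
    # treatment appended to the covariate vector (one-hot for >2 arms)
    if len(arms) == 2:
        t_enc = (T_raw == arms[-1]).astype(float)[:, None]
        treatment_cols = [Xtitan_cov.shape[1]]
    else:
        t_enc = np.column_stack([(T_raw == a).astype(float) for a in arms])
        treatment_cols = list(range(Xtitan_cov.shape[1],
                                    Xtitan_cov.shape[1] + len(arms)))
    Xtitan = np.column_stack([Xtitan_cov, t_enc])
    contrast = (arms[-1], arms[0])

    use_titan = config.variant not in ("drlearner_only", "no_titan")
    use_dr = config.variant not in ("titan_only", "no_drlearner", "mlp_baseline")
    use_rl = config.variant not in (
        "no_rl", "titan_only", "drlearner_only", "no_titan", "mlp_baseline")

    # -- neural branch ---------------------------------------------------------
    if config.variant == "mlp_baseline":
        predictor = titan.MLPModel(titan.MLPConfig(seed=config.seed),
                                   Xtitan.shape[1], treatment_cols)
    else:
        tc = config.titan_config
        predictor = titan.TitanModel(
            titan.TitanConfig(**{**asdict(tc), "seed": config.seed}),
            Xtitan.shape[1], treatment_cols)
    if use_titan or config.variant in ("mlp_baseline", "no_drlearner"):
        with _stage("predictor fit"):
            predictor.fit(Xtitan[idx_train], Y[idx_train],
                          Xtitan[idx_val], Y[idx_val])

    def titan_arm(idx, arm, rng_=None):
        return predictor.counterfactual_predict(
            Xtitan[idx], arms.index(arm) if len(arms) > 2 else arm, rng=rng_)

    # -- doubly robust branch ----------------------------------------------------
    pooled = None
    if use_dr:
        dr_cfg = drlearner.DRConfig(**{**asdict(config.dr_config),
                                       "seed": config.seed})
        with _stage("doubly robust fit"):
            nuis = drlearner.fit_nuisances(Xdr[idx_train], T_raw[idx_train],
                                           Y[idx_train], dr_cfg)
            effects = drlearner.estimate_effects(nuis, Xdr[idx_train],
                                                 T_raw[idx_train],
                                                 Y[idx_train], contrast)
    else:
        pooled = _PooledOutcomeBranch(
            drlearner.DRConfig(**{**asdict(config.dr_config),
                                  "seed": config.seed}))
        pooled.fit(Xdr[idx_train], T_raw[idx_train], Y[idx_train])

    def dr_arm(idx, arm):
        X_ = Xdr[idx]
        if pooled is not None:
            return np.clip(pooled.mu(X_, arm), 1e-6, 1 - 1e-6)
        if len(arms) == 2 and arm == contrast[0]:
            # treated arm: control prediction plus the smoothed effect function
            mu_lo = _dr_mu(nuis, X_, contrast[1])
            return np.clip(mu_lo + effects.predict_ite(X_), 1e-6, 1 - 1e-6)
        return np.clip(_dr_mu(nuis, X_, arm), 1e-6, 1 - 1e-6)

    def dr_propensity(idx):
        X_ = Xdr[idx]
        if pooled is not None:
            frac = float((T_raw[idx_train] == contrast[0]).mean())
            return np.full(len(X_), np.clip(frac, 0.01, 0.99))
        return _dr_propensity(nuis, X_, contrast[0])

    def dr_uncertainty(idx):
        if pooled is not None:
            return np.zeros(len(idx))
        return nuis.tree_std(contrast[0], Xdr[idx])

    # -- state construction ------------------------------------------------------
    def build_states(idx):
        factual_titan = np.empty(len(idx))
        factual_dr = np.empty(len(idx))
        for arm in arms:
            mask = T_raw[idx] == arm
            if not mask.any():
                continue
            sub = idx[mask]
            factual_titan[mask] = (titan_arm(sub, arm) if use_titan
                                   else dr_arm(sub, arm))
            factual_dr[mask] = (dr_arm(sub, arm) if (use_dr or pooled is not None)
                                else factual_titan[mask])
        if use_titan:
            mc_rng = np.random.default_rng(config.seed + 7)
            passes = np.stack([predictor.predict_stochastic(Xtitan[idx], mc_rng)
                               for _ in range(10)])
            u_titan = passes.std(axis=0)
        else:
            u_titan = np.zeros(len(idx))
        u_dr = dr_uncertainty(idx)
        e = dr_propensity(idx)
        bal = ensemble.covariate_balance(
            Xdr[idx], T_raw[idx],
            np.where(T_raw[idx] == contrast[0], 1.0 / e, 1.0 / (1.0 - e))
            if len(arms) == 2 else None)
        state = ensemble.build_state(factual_titan, factual_dr, u_titan, u_dr,
                                     e, bal, config.agent_config.overlap_eta)
        return state, factual_titan, factual_dr

    # -- RL agent -----------------------------------------------------------------
    alpha_fixed = None
    agent = None
    if use_rl and use_titan and (use_dr or pooled is not None):
        val_state, val_titan, val_dr = build_states(idx_val)
        ctx = {"y_titan": val_titan, "y_dr": val_dr,
               "X_cov": Xdr[idx_val], "T": T_raw[idx_val]}
        if use_dr and truth is not None and "tau_prob" in truth:
            hi, lo = contrast
            ctx["ite_titan"] = (titan_arm(idx_val, hi)
                                - titan_arm(idx_val, lo))
            ctx["ite_dr"] = dr_arm(idx_val, hi) - dr_arm(idx_val, lo)
            ctx["tau_true"] = truth["tau_prob"].to_numpy()[idx_val]
        agent_cfg = ensemble.AgentConfig(**{**asdict(config.agent_config),
                                            "seed": config.seed})
        with _stage("agent fit"):
            agent = ensemble.train_agent(val_state, Y[idx_val], ctx, agent_cfg)
    elif config.variant in ("titan_only", "no_drlearner", "mlp_baseline"):
        alpha_fixed = 1.0
    elif config.variant in ("drlearner_only", "no_titan"):
        alpha_fixed = 0.0
    else:  # no_rl: fixed equal-weight blend
        alpha_fixed = 0.5

    # -- test-split inference ------------------------------------------------------
    with _stage("test inference"):
        test_state, test_titan_fact, test_dr_fact = build_states(idx_test)
    titan_preds = {}
    dr_preds = {}
    for arm in contrast:
        titan_preds[arm] = (titan_arm(idx_test, arm) if use_titan
                            else dr_arm(idx_test, arm))
        dr_preds[arm] = (dr_arm(idx_test, arm) if (use_dr or pooled is not None)
                         else titan_preds[arm])
    if agent is not None:
        blended = ensemble.predict_ensemble(agent, test_state, titan_preds, dr_preds)
    else:
        alpha = np.full(len(idx_test), alpha_fixed)
        probs = {arm: ensemble.blend(alpha, titan_preds[arm], dr_preds[arm])
                 for arm in contrast}
        blended = ensemble.BlendedPrediction(
            alpha=alpha, probs=probs,
            ite=probs[contrast[0]] - probs[contrast[1]])
    factual_prob = ensemble.blend(blended.alpha, test_titan_fact, test_dr_fact)

    # -- uncertainty (Monte Carlo dropout over the blended ITE) --------------------
    uncertainty = None
    ite_samples = None
    if config.variant != "no_uncertainty" and use_titan:
        mc_rng = np.random.default_rng(config.seed + 13)
        hi, lo = contrast
        arm_hi = arms.index(hi) if len(arms) > 2 else hi
        arm_lo = arms.index(lo) if len(arms) > 2 else lo
        fact_samples = []
        ite_samples = []
        t_test_bin = (T_raw[idx_test] == hi)
        dr_ite_point = dr_preds[hi] - dr_preds[lo]
        dr_trees = (effects.second_stage.estimators_
                    if use_dr and hasattr(effects.second_stage, "estimators_")
                    else None)
        for _ in range(config.mc_passes):
            p_hi = predictor.counterfactual_predict(Xtitan[idx_test], arm_hi,
                                                    rng=mc_rng)
            p_lo = predictor.counterfactual_predict(Xtitan[idx_test], arm_lo,
                                                    rng=mc_rng)
            b_hi = ensemble.blend(blended.alpha, p_hi, dr_preds[hi])
            b_lo = ensemble.blend(blended.alpha, p_lo, dr_preds[lo])
            # one bootstrap tree per pass: the DR branch's epistemic draw
            if dr_trees is not None:
                tree = dr_trees[mc_rng.integers(0, len(dr_trees))]
                dr_ite_draw = tree.predict(Xdr[idx_test])
            else:
                dr_ite_draw = dr_ite_point
            # the ensemble's ITE predictive distribution is the alpha-gated
            # mixture of the branch distributions, so each pass samples the
            # gate as well; the mixture mean stays the convex blend
            gate = mc_rng.random(len(idx_test)) < blended.alpha
            ite_samples.append(np.where(gate, p_hi - p_lo, dr_ite_draw))
            fact_samples.append(np.where(t_test_bin, b_hi, b_lo))
        ite_samples = np.stack(ite_samples)
        fact_samples = np.stack(fact_samples)
        aleo, epi, total = reliability.decompose(
            fact_samples, fact_samples * (1 - fact_samples))
        lower, upper = reliability.percentile_intervals(ite_samples,
                                                        config.nominal)
        uncertainty = reliability.UncertaintyReport(
            mean=fact_samples.mean(axis=0), total=total, aleatoric=aleo,
            epistemic=epi, n_passes=config.mc_passes, lower=lower,
            upper=upper, samples=ite_samples)

    # -- drift ----------------------------------------------------------------------
    drift = None
    if config.variant != "no_drift":
        baseline = reliability.fit_drift_baseline(
            Xall.iloc[idx_train].to_numpy(), feature_names=tuple(covar_cols),
            seed=config.seed, n_boot=200, batch_size=len(idx_test))
        drift = reliability.detect_drift(baseline, Xall.iloc[idx_test].to_numpy())

    # -- metrics ----------------------------------------------------------------------
    metrics: dict = {
        "classification": evaluation.classification_metrics(
            Y[idx_test], factual_prob),
    }
    if truth is not None and "tau_prob" in truth:
        tau_true_test = truth["tau_prob"].to_numpy()[idx_test]
        metrics["causal"] = evaluation.causal_metrics(blended.ite, tau_true_test)
        if uncertainty is not None:
            metrics["intervals"] = evaluation.interval_metrics(
                uncertainty.lower, uncertainty.upper, tau_true_test,
                config.nominal)

    predictions = pd.DataFrame({
        "unit": idx_test,
        "titan_p_hi": titan_preds[contrast[0]],
        "titan_p_lo": titan_preds[contrast[1]],
        "dr_p_hi": dr_preds[contrast[0]],
        "dr_p_lo": dr_preds[contrast[1]],
        "alpha": blended.alpha,
        "blended_p_hi": blended.probs[contrast[0]],
        "blended_p_lo": blended.probs[contrast[1]],
        "blended_ite": blended.ite,
        "factual_prob": factual_prob,
        "y_observed": Y[idx_test],
    })
    if uncertainty is not None:
        predictions["ite_lower"] = uncertainty.lower
        predictions["ite_upper"] = uncertainty.upper
        predictions["total_uncertainty"] = uncertainty.total
        predictions["epistemic"] = uncertainty.epistemic
        predictions["aleatoric"] = uncertainty.aleatoric

    return StudyResult(
        predictions=predictions, dag=dag, roles=roles, metrics=metrics,
        drift=drift, uncertainty=uncertainty,
        config_echo={
            "variant": config.variant, "seed": config.seed,
            "treatment": t_col, "outcome": y_col,
            "split": list(config.split), "arms": [str(a) for a in arms],
            "roles": roles.as_dict(), "dag_provenance": dag.provenance,
            "features": {"pre_treatment": pre_treatment,
                         "predictor": titan_features},
        },
    )


def run_benchmark(config: RunConfig, variants=("full", "drlearner_only"),
                  seeds=(0, 1, 2, 3, 4)) -> pd.DataFrame:
    """Per (variant, seed) metrics table plus across-seed medians."""
    rows = []
    for variant in variants:
        for seed in seeds:
            cfg = RunConfig(**{**asdict_shallow(config),
                               "variant": variant, "seed": seed})
            result = run_study(cfg)
            row = {"variant": variant, "seed": seed}
            for group, report in result.metrics.items():
                for k, v in asdict(report).items():
                    row[f"{group}.{k}"] = v
            rows.append(row)
    table = pd.DataFrame(rows)
    medians = table.drop(columns="seed").groupby("variant").median(numeric_only=True)
    medians["seed"] = "median"
    return pd.concat([table, medians.reset_index()], ignore_index=True)


def asdict_shallow(config: RunConfig) -> dict:
    """RunConfig fields with nested configs kept as objects (not dicts)."""
    return {f: getattr(config, f) for f in config.__dataclass_fields__}
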