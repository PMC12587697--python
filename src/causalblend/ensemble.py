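"""Actor-critic agent learning per-instance blend weights.

The agent treats every unit as a one-step decision: given a 7-component
state summarizing both branch predictions, their uncertainties, the
propensity, an overlap indicator and a covariate-balance score, the
deterministic actor emits a blend weight alpha in [0, 1]; the final
prediction is the convex combination alpha * titan + (1 - alpha) * dr. The
critic learns an action-value function from a causal-aware reward (negative
cross-entropy, an optional doubly robust effect-error term available when a
ground-truth effect exists, and a balance penalty). Training uses a replay
buffer, Ornstein-Uhlenbeck exploration noise and Polyak-averaged target
networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._autograd import Adam, Tensor, concat

__all__ = [
    "AgentConfig",
    "EnsembleState",
    "BlendedPrediction",
    "ReplayBuffer",
    "ActorCritic",
    "build_state",
    "blend",
    "reward",
    "covariate_balance",
    "ou_step",
    "polyak_update",
    "train_agent",
    "predict_ensemble",
]

STATE_DIM = 7


@dataclass
class AgentConfig:
    gamma: float = 0.9193
    polyak: float = 0.0139
    actor_lr: float = 2.26e-5
    critic_lr: float = 5.01e-4
    hidden: int = 128
    update_freq: int = 2
    epochs: int = 30
    ou_theta: float = 0.15
    ou_mu: float = 0.0
    ou_sigma: float = 0.2
    ou_dt: float = 1.0
    w_bce: float = 1.0
    w_dr: float = 1.0
    w_balance: float = 0.1
    buffer_capacity: int = 50_000
    batch_size: int = 64
    seed: int = 0
    overlap_eta: float = 0.05

    def __post_init__(self):
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must lie in (0, 1)")
        if not 0 < self.polyak < 1:
            raise ValueError("polyak coefficient must lie in (0, 1)")


@dataclass
class EnsembleState:
    """Row-wise 7-component state matrix (n, 7)."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, float))
        if self.matrix.shape[1] != STATE_DIM:
            raise ValueError(f"state must have {STATE_DIM} components")
        if not np.isfinite(self.matrix).all():
            raise ValueError("state components must be finite")


@dataclass
class BlendedPrediction:
    alpha: np.ndarray
    probs: dict          # arm -> blended potential-outcome probabilities
    ite: np.ndarray      # blended probability contrast between the two arms


def build_state(titan_out, dr_out, u_titan, u_dr, propensity,
                balance_score, eta: float = 0.05) -> EnsembleState:
    """Assemble the state: both factual-arm predictions, both uncertainties,
    the propensity, the overlap indicator 1{eta <= e <= 1-eta}, and the
    covariate balance score."""
    parts = [np.asarray(v, float).ravel()
             for v in (titan_out, dr_out, u_titan, u_dr, propensity)]
    n = len(parts[0])
    if any(len(p) != n for p in parts):
        raise ValueError("state components must be aligned")
    if np.any(parts[2] < 0) or np.any(parts[3] < 0):
        raise ValueError("uncertainties must be nonnegative")
    e = parts[4]
    overlap = ((e >= eta) & (e <= 1.0 - eta)).astype(float)
    balance = np.broadcast_to(np.asarray(balance_score, float), (n,))
    return EnsembleState(np.column_stack(parts + [overlap, balance]))


def blend(alpha, y_titan, y_dr):
    """Convex combination alpha * y_titan + (1 - alpha) * y_dr."""
    alpha = np.asarray(alpha, float)
    if np.any(alpha < 0) or np.any(alpha > 1):
        warnings.warn("blend weight outside [0, 1]; clipping")
        alpha = np.clip(alpha, 0.0, 1.0)
    return alpha * np.asarray(y_titan, float) + (1.0 - alpha) * np.asarray(y_dr, float)


def covariate_balance(X_cov: np.ndarray, T: np.ndarray,
                      weights: np.ndarray | None = None) -> float:
    """Sum of squared standardized weighted mean differences across arms.

    With two arms this is the classic imbalance score; zero when the
    (weighted) covariate means agree.
    """
    X_cov = np.atleast_2d(np.asarray(X_cov, float))
    T = np.asarray(T).ravel()
    if weights is None:
        weights = np.ones(len(T))
    weights = np.asarray(weights, float)
    arms = np.unique(T)
    sd = X_cov.std(axis=0)
    sd[sd == 0] = 1.0
    means = []
    for arm in arms:
        mask = T == arm
        w = weights[mask]
        means.append((X_cov[mask] * w[:, None]).sum(axis=0) / w.sum())
    total = 0.0
    for i in range(len(arms)):
        for j in range(i + 1, len(arms)):
            total += float((((means[i] - means[j]) / sd) ** 2).sum())
    return total


def reward(y_hat, y, weights=(1.0, 1.0, 0.1), dr_pseudo=None,
           tau_true=None, balance_penalty: float = 0.0,
           eps: float = 1e-12) -> np.ndarray:
    """Causal-aware reward.

    r = w_bce * (-BCE(y_hat, y)) + w_dr * (-(dr_pseudo - tau_true)^2)
        + w_balance * (-balance_penalty).
    The doubly robust term only applies when a ground-truth effect is
    available (simulation mode); otherwise its weight is zeroed.
    """
    w_bce, w_dr, w_balance = weights
    y_hat = np.clip(np.asarray(y_hat, float), eps, 1 - eps)
    y = np.asarray(y, float)
    r = w_bce * (y * np.log(y_hat) + (1 - y) * np.log(1 - y_hat))
    if tau_true is not None and dr_pseudo is not None and w_dr != 0.0:
        r = r - w_dr * (np.asarray(dr_pseudo, float) - np.asarray(tau_true, float)) ** 2
    r = r - w_balance * float(balance_penalty)
    return r


def ou_step(noise, theta, mu, sigma, dt, rng: np.random.Generator):
    """One Ornstein-Uhlenbeck increment: N' = N + theta (mu - N) dt + sigma sqrt(dt) eps."""
    if theta < 0 or sigma < 0 or dt <= 0:
        raise ValueError("require theta >= 0, sigma >= 0, dt > 0")
    return noise + theta * (mu - noise) * dt + sigma * np.sqrt(dt) * rng.standard_normal()


def polyak_update(current: list[Tensor], target: list[Tensor], tau: float) -> None:
    """Soft target update: theta_target <- tau theta + (1 - tau) theta_target."""
    if not 0 <= tau <= 1:
        raise ValueError("tau must lie in [0, 1]")
    for c, t in zip(current, target):
        if c.data.shape != t.data.shape:
            raise ValueError("parameter shape mismatch")
        t.data = tau * c.data + (1.0 - tau) * t.data


class ReplayBuffer:
    def __init__(self, capacity: int):
        self.capacity = int(capacity)
        self._s = []
        self._a = []
        self._r = []
        self._s2 = []
        self._pos = 0

    def __len__(self):
        return len(self._s)

    def push(self, s, a, r, s2):
        if len(self._s) < self.capacity:
            self._s.append(s)
            self._a.append(a)
            self._r.append(r)
            self._s2.append(s2)
        else:
            self._s[self._pos] = s
            self._a[self._pos] = a
            self._r[self._pos] = r
            self._s2[self._pos] = s2
            self._pos = (self._pos + 1) % self.capacity

    def sample(self, batch_size: int, rng: np.random.Generator):
        if len(self) == 0:
            raise ValueError("cannot sample from an empty replay buffer")
        idx = rng.integers(0, len(self), min(batch_size, len(self)))
        return (
            np.stack([self._s[i] for i in idx]),
            np.array([self._a[i] for i in idx]),
            np.array([self._r[i] for i in idx]),
            np.stack([self._s2[i] for i in idx]),
        )


def _mlp_params(sizes: list[int], rng: np.random.Generator) -> list[Tensor]:
    params = []
    last = len(sizes) - 2
    for i, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        if i == last:
            # small-uniform output-layer init: the policy starts near the
            # midpoint blend and the critic near zero value
            w = rng.uniform(-3e-3, 3e-3, (fan_in, fan_out))
        else:
            w = rng.normal(0, 1.0 / np.sqrt(fan_in), (fan_in, fan_out))
        params.append(Tensor(w, requires_grad=True))
        params.append(Tensor(np.zeros(fan_out), requires_grad=True))
    return params


def _mlp_forward(params: list[Tensor], x: Tensor, final) -> Tensor:
    h = x
    n_layers = len(params) // 2
    for i in range(n_layers):
        h = h @ params[2 * i] + params[2 * i + 1]
        if i < n_layers - 1:
            h = h.relu()
    if final == "sigmoid":
        h = h.sigmoid()
    return h


class ActorCritic:
    """Deterministic actor (state -> alpha) and critic (state, action -> Q)
    with Polyak-tracked target copies."""

    def __init__(self, config: AgentConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        h = config.hidden
        self.actor = _mlp_params([STATE_DIM, h, h, 1], rng)
        self.critic = _mlp_params([STATE_DIM + 1, h, h, 1], rng)
        self.actor_target = [Tensor(p.data.copy()) for p in self.actor]
        self.critic_target = [Tensor(p.data.copy()) for p in self.critic]
        self.alpha_trace: list[float] = []

    def act(self, states: np.ndarray) -> np.ndarray:
        """Noise-free blend weights for a batch of states."""
        out = _mlp_forward(self.actor, Tensor(np.atleast_2d(states)), "sigmoid")
        return np.clip(out.data.ravel(), 0.0, 1.0)

    def q_value(self, states: np.ndarray, actions: np.ndarray,
                target: bool = False) -> np.ndarray:
        params = self.critic_target if target else self.critic
        sa = np.column_stack([np.atleast_2d(states), np.asarray(actions).reshape(-1, 1)])
        return _mlp_forward(params, Tensor(sa), None).data.ravel()

    def save(self, path) -> None:
        """Single-file agent checkpoint (npz) with a config echo."""
        import json
        from dataclasses import asdict

        arrays = {}
        for name, params in (("actor", self.actor), ("critic", self.critic),
                             ("actor_target", self.actor_target),
                             ("critic_target", self.critic_target)):
            for i, p in enumerate(params):
                arrays[f"{name}_{i}"] = p.data
        np.savez(path, config=json.dumps(asdict(self.config)),
                 alpha_trace=np.array(self.alpha_trace), **arrays)

    @classmethod
    def load(cls, path) -> "ActorCritic":
        import json

        with np.load(path, allow_pickle=False) as data:
            agent = cls(AgentConfig(**json.loads(str(data["config"]))))
            for name, params in (("actor", agent.actor),
                                 ("critic", agent.critic),
                                 ("actor_target", agent.actor_target),
                                 ("critic_target", agent.critic_target)):
                for i, p in enumerate(params):
                    p.data = data[f"{name}_{i}"]
            agent.alpha_trace = data["alpha_trace"].tolist()
        return agent


def train_agent(states: EnsembleState | np.ndarray, labels: np.ndarray,
                reward_context: dict, config: AgentConfig | None = None) -> ActorCritic:
    """Fit the blending policy on aligned states, labels and branch outputs.

    ``reward_context`` carries ``y_titan`` and ``y_dr`` (factual-arm
    probabilities per unit); optionally ``ite_titan``/``ite_dr`` and
    ``tau_true`` for the simulation-mode effect-error reward term — the
    blended effect alpha*ite_titan + (1-alpha)*ite_dr enters the squared
    error, so the term rewards actions that improve causal accuracy (a term
    built from nuisances alone would be constant in the action and steer
    nothing) — and ``X_cov`` (+``T``) for the balance penalty. Each unit is
    a one-step episode whose successor state is the next unit in the
    epoch's seeded order.
    """
    config = config or AgentConfig()
    S = states.matrix if isinstance(states, EnsembleState) else np.atleast_2d(states)
    y = np.asarray(labels, float).ravel()
    y_titan = np.asarray(reward_context["y_titan"], float).ravel()
    y_dr = np.asarray(reward_context["y_dr"], float).ravel()
    ite_titan = reward_context.get("ite_titan")
    ite_dr = reward_context.get("ite_dr")
    tau_true = reward_context.get("tau_true")
    has_effect_term = (tau_true is not None and ite_titan is not None
                       and ite_dr is not None)
    X_cov = reward_context.get("X_cov")
    T_arm = reward_context.get("T")
    n = len(S)
    rng = np.random.default_rng(config.seed)
    agent = ActorCritic(config)
    buffer = ReplayBuffer(config.buffer_capacity)
    opt_actor = Adam(agent.actor, lr=config.actor_lr)
    opt_critic = Adam(agent.critic, lr=config.critic_lr)
    weights = (config.w_bce,
               config.w_dr if has_effect_term else 0.0,
               config.w_balance)
    noise = config.ou_mu
    step = 0
    for _ in range(config.epochs):
        order = rng.permutation(n)
        base_alpha = agent.act(S[order])
        # correlated exploration noise along the epoch's unit sequence
        ou = np.empty(n)
        for i in range(n):
            noise = ou_step(noise, config.ou_theta, config.ou_mu,
                            config.ou_sigma, config.ou_dt, rng)
            ou[i] = noise
        alpha = np.clip(base_alpha + ou, 0.0, 1.0)
        y_hat = blend(alpha, y_titan[order], y_dr[order])
        balance_pen = 0.0
        if X_cov is not None and T_arm is not None:
            w_ipw = np.ones(n)
            e = S[order, 4]
            t_bin = np.asarray(T_arm).ravel()[order]
            lvl = np.unique(t_bin)
            if len(lvl) == 2:
                treated = t_bin == lvl[-1]
                w_ipw = np.where(treated, 1.0 / e, 1.0 / (1.0 - e))
            balance_pen = covariate_balance(np.asarray(X_cov)[order], t_bin, w_ipw)
        blended_effect = None
        if has_effect_term:
            blended_effect = (alpha * np.asarray(ite_titan, float)[order]
                              + (1 - alpha) * np.asarray(ite_dr, float)[order])
        r = reward(
            y_hat, y[order], weights,
            dr_pseudo=blended_effect,
            tau_true=None if tau_true is None else np.asarray(tau_true)[order],
            balance_penalty=balance_pen,
        )
        nxt = np.roll(order, -1)
        for i in range(n):
            buffer.push(S[order[i]], alpha[i], r[i], S[nxt[i]])
            step += 1
            s_b, a_b, r_b, s2_b = buffer.sample(config.batch_size, rng)
            # critic: TD target with target networks
            a2 = _mlp_forward(agent.actor_target, Tensor(s2_b), "sigmoid").data
            q2 = _mlp_forward(agent.critic_target,
                              Tensor(np.column_stack([s2_b, a2])), None).data.ravel()
            target = r_b + config.gamma * q2
            q = _mlp_forward(agent.critic,
                             Tensor(np.column_stack([s_b, a_b.reshape(-1, 1)])), None)
            td = q.reshape(len(s_b)) - Tensor(target)
            critic_loss = (td ** 2).mean()
            opt_critic.zero_grad()
            critic_loss.backward()
            opt_critic.step()
            if step % config.update_freq == 0:
                # actor: ascend Q(s, actor(s))
                s_t = Tensor(s_b)
                a_pred = _mlp_forward(agent.actor, s_t, "sigmoid")
                q_pred = _mlp_forward(agent.critic, concat([s_t, a_pred], axis=1), None)
                actor_loss = -q_pred.mean()
                opt_actor.zero_grad()
                for p in agent.critic:
                    p.grad = None
                actor_loss.backward()
                opt_actor.step()
                for p in agent.critic:
                    p.grad = None
                polyak_update(agent.actor, agent.actor_target, config.polyak)
                polyak_update(agent.critic, agent.critic_target, config.polyak)
        agent.alpha_trace.append(float(agent.act(S).mean()))
    return agent


def predict_ensemble(agent: ActorCritic, states: EnsembleState | np.ndarray,
                     titan_preds: dict, dr_preds: dict) -> BlendedPrediction:
    """Noise-free blended per-arm probabilities and probability-scale ITE.

    ``titan_preds`` / ``dr_preds`` map each treatment arm to per-unit
    potential-outcome probabilities; the ITE is the blended contrast between
    the highest and lowest arm.
    """
    S = states.matrix if isinstance(states, EnsembleState) else np.atleast_2d(states)
    alpha = agent.act(S)
    arms = sorted(titan_preds)
    probs = {arm: blend(alpha, titan_preds[arm], dr_preds[arm]) for arm in arms}
    ite = probs[arms[-1]] - probs[arms[0]]
    return BlendedPrediction(alpha=alpha, probs=probs, ite=ite)
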