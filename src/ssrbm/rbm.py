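"""Spin restricted Boltzmann machine with one-hot categorical visible blocks.

Both layers carry spin variables in {-1, +1}.  A configuration ``(v, h)`` has
energy

    E(v, h) = - sum_i a_i v_i - sum_j b_j h_j - sum_ij w_ij v_i h_j

and statistical weight ``exp(-E)``.  The visible layer is constrained to the
one-hot manifold: ``gamma`` blocks of 20 sites, exactly one ``+1`` per block,
so a visible configuration encodes a sequence of ``gamma`` residues.  Given
``h``, block ``g`` picks residue ``k`` with probability proportional to
``exp(2 phi_k)`` where ``phi = a + W h`` is the local field: flipping the
block's ``+1`` from site ``l`` to site ``k`` changes the energy by
``2 phi_l - 2 phi_k``, and the common ``-sum_block phi`` background cancels
in the softmax.

Training maximises the data log-likelihood by contrastive divergence (CD-n)
or its persistent variant (PCD-n) with Adam updates.  For small hidden
layers everything downstream is exact: the hidden layer is enumerable
(``2^n_hidden`` states), giving exact partition functions and exact,
burn-in-free sequence generation.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit, logsumexp

from .ingest import AMINO_ACIDS, N_ALPHABET, DatasetSplit, decode_samples

#: Hidden-layer size above which 2^n_hidden enumeration is refused.
MAX_EXACT_HIDDEN = 12


class TrainingDivergedError(RuntimeError):
    """Raised when parameters become non-finite during training."""


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class RBMParams:
    """Weights and biases of a spin RBM.

    Attributes
    ----------
    weights:
        ``(n_visible, n_hidden)`` coupling matrix ``w_ij``.
    visible_bias:
        ``(n_visible,)`` local fields ``a_i`` on the visible sites.
    hidden_bias:
        ``(n_hidden,)`` local fields ``b_j`` on the hidden units.
    """

    weights: np.ndarray
    visible_bias: np.ndarray
    hidden_bias: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.visible_bias = np.asarray(self.visible_bias, dtype=float)
        self.hidden_bias = np.asarray(self.hidden_bias, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be a 2-D (n_visible, n_hidden) matrix")
        nv, nh = self.weights.shape
        if self.visible_bias.shape != (nv,) or self.hidden_bias.shape != (nh,):
            raise ValueError("bias shapes inconsistent with the weight matrix")
        if not (np.all(np.isfinite(self.weights))
                and np.all(np.isfinite(self.visible_bias))
                and np.all(np.isfinite(self.hidden_bias))):
            raise ValueError("parameters contain non-finite entries")

    @property
    def n_visible(self) -> int:
        return self.weights.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.weights.shape[1]

    @property
    def gamma(self) -> int:
        """Number of residue positions; requires the one-hot block structure."""
        if self.n_visible % N_ALPHABET:
            raise ValueError("n_visible is not a multiple of 20; this model has "
                             "no one-hot block structure")
        return self.n_visible // N_ALPHABET

    def copy(self) -> "RBMParams":
        return RBMParams(self.weights.copy(), self.visible_bias.copy(),
                         self.hidden_bias.copy())

    def gauge_flip(self, units) -> "RBMParams":
        """Return a copy with (w_.j, b_j) -> (-w_.j, -b_j) for the given units.

        Jointly flipping a hidden unit's value, weights and bias leaves the
        model distribution over ``v`` unchanged.
        """
        out = self.copy()
        units = np.atleast_1d(units)
        out.weights[:, units] *= -1
        out.hidden_bias[units] *= -1
        return out


# ---------------------------------------------------------------------------
# Energies, conditionals and fields
# ---------------------------------------------------------------------------

def energy(v: np.ndarray, h: np.ndarray, params: RBMParams) -> np.ndarray:
    """Energy E(v, h); supports single configurations or matching batches."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if v.shape[-1] != params.n_visible or h.shape[-1] != params.n_hidden:
        raise ValueError("configuration shapes do not match the parameters")
    return -(v @ params.visible_bias) - (h @ params.hidden_bias) \
        - np.einsum("...i,ij,...j->...", v, params.weights, h)


def hidden_input(v: np.ndarray, params: RBMParams) -> np.ndarray:
    """Total input u_j = b_j + sum_i w_ij v_i on each hidden unit."""
    return params.hidden_bias + np.asarray(v, dtype=float) @ params.weights


def hidden_conditional(v: np.ndarray, params: RBMParams) -> np.ndarray:
    """p(h_j = +1 | v) = e^{u_j} / (2 cosh u_j), computed in a stable form."""
    return expit(2.0 * hidden_input(v, params))


def local_fields(h: np.ndarray, params: RBMParams) -> np.ndarray:
    """Local fields phi_i = a_i + sum_j w_ij h_j on the visible sites."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != params.n_hidden:
        raise ValueError("hidden state length does not match the parameters")
    return params.visible_bias + h @ params.weights.T


def block_probs(h: np.ndarray, params: RBMParams, position: int) -> np.ndarray:
    """Residue probabilities for block ``position`` (0-based) at fixed ``h``.

    p(k) = exp(2 phi_k) / sum_l exp(2 phi_l) over the block's 20 sites.
    """
    if not 0 <= position < params.gamma:
        raise ValueError(f"position {position} outside 0..{params.gamma - 1}")
    phi = local_fields(h, params)
    sl = slice(N_ALPHABET * position, N_ALPHABET * (position + 1))
    z = 2.0 * phi[..., sl]
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def all_block_probs(h: np.ndarray, params: RBMParams) -> np.ndarray:
    """Residue probabilities for every block: shape (..., gamma, 20)."""
    phi = local_fields(h, params)
    z = 2.0 * phi.reshape(phi.shape[:-1] + (params.gamma, N_ALPHABET))
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample_hidden(v: np.ndarray, params: RBMParams, rng: np.random.Generator) -> np.ndarray:
    """Draw h ~ p(h | v); each unit independently, values in {-1, +1}."""
    p = hidden_conditional(v, params)
    return np.where(rng.random(p.shape) < p, 1.0, -1.0)


def sample_visible(h: np.ndarray, params: RBMParams, rng: np.random.Generator) -> np.ndarray:
    """Draw v ~ p(v | h); each 20-site block independently categorical.

    Uses the Gumbel-max trick on the block logits ``2 phi`` so the whole
    batch is sampled in one vectorised pass; the result stays exactly on the
    one-hot manifold.
    """
    phi = local_fields(h, params)
    logits = 2.0 * phi.reshape(phi.shape[:-1] + (params.gamma, N_ALPHABET))
    gumbel = -np.log(-np.log(rng.random(logits.shape)))
    winners = (logits + gumbel).argmax(axis=-1)
    v = np.full(logits.shape, -1.0)
    np.put_along_axis(v, winners[..., None], 1.0, axis=-1)
    return v.reshape(phi.shape)


# ---------------------------------------------------------------------------
# Free energies, PLL, exact enumeration
# ---------------------------------------------------------------------------

def _log2cosh(x: np.ndarray) -> np.ndarray:
    x = np.abs(x)
    return x + np.log1p(np.exp(-2.0 * x))


def free_energy(v: np.ndarray, params: RBMParams) -> np.ndarray:
    """Visible free energy F(v) = -a.v - sum_j log 2 cosh(u_j); p(v) ~ e^{-F}."""
    v = np.asarray(v, dtype=float)
    return -(v @ params.visible_bias) - _log2cosh(hidden_input(v, params)).sum(axis=-1)


def pseudo_log_likelihood(params: RBMParams, samples: np.ndarray,
                          per_position: bool = False) -> float:
    """Mean pseudo-log-likelihood of one-hot samples, in nats.

    For each residue position the exact conditional probability of the
    observed residue given all other positions is computed by renormalising
    ``exp(-F)`` over the 20 candidate residues of that block (the hidden
    layer is marginalised analytically inside ``F``, so this is exact for
    any hidden-layer size).  Returns the mean over samples of the sum over
    positions, or the per-position mean if ``per_position``.
    """
    v = np.asarray(samples, dtype=float)
    if v.ndim == 1:
        v = v[None, :]
    n, nv = v.shape
    if nv != params.n_visible:
        raise ValueError("sample width does not match the model")
    if n == 0:
        raise ValueError("empty sample set")
    gamma = params.gamma
    w, a = params.weights, params.visible_bias
    u = hidden_input(v, params)  # (n, nh)
    av = v @ a  # (n,)

    total = 0.0
    for g in range(gamma):
        sl = slice(N_ALPHABET * g, N_ALPHABET * (g + 1))
        cur = v[:, sl].argmax(axis=1)  # observed residue index per sample
        # candidate k: flip the block's +1 from `cur` to k
        u_cand = (u[:, None, :]
                  - 2.0 * w[sl][cur][:, None, :]
                  + 2.0 * w[sl][None, :, :])  # (n, 20, nh)
        av_cand = av[:, None] - 2.0 * a[sl][cur][:, None] + 2.0 * a[sl][None, :]
        neg_F = av_cand + _log2cosh(u_cand).sum(axis=-1)  # (n, 20)
        log_cond = neg_F[np.arange(n), cur] - logsumexp(neg_F, axis=1)
        total += log_cond.mean()
    return total / gamma if per_position else total


def enumerate_hidden_states(n_hidden: int) -> np.ndarray:
    """All 2^n_hidden hidden states in lexicographic order, +1 before -1."""
    if n_hidden > MAX_EXACT_HIDDEN:
        raise ValueError(f"n_hidden={n_hidden} exceeds the exact-enumeration "
                         f"bound of {MAX_EXACT_HIDDEN}")
    states = np.array(list(itertools.product((1.0, -1.0), repeat=n_hidden)))
    return states.reshape(2 ** n_hidden, n_hidden)


def hidden_state_log_weights(params: RBMParams,
                             states: np.ndarray | None = None) -> np.ndarray:
    """Unnormalised log p(h) for each enumerated hidden state.

    log w(h) = b.h + sum_g [logsumexp_k(2 phi_k) - sum_{i in block g} phi_i],
    where the second term accounts for the one-hot visible marginalisation
    including the -1 background sites.
    """
    if states is None:
        states = enumerate_hidden_states(params.n_hidden)
    phi = local_fields(states, params)  # (S, nv)
    blocks = phi.reshape(len(states), params.gamma, N_ALPHABET)
    block_terms = logsumexp(2.0 * blocks, axis=-1) - blocks.sum(axis=-1)
    return states @ params.hidden_bias + block_terms.sum(axis=-1)


def exact_log_partition(params: RBMParams) -> float:
    """Exact log Z over the one-hot visible manifold and all hidden states."""
    return float(logsumexp(hidden_state_log_weights(params)))


def exact_log_likelihood(params: RBMParams, samples: np.ndarray) -> float:
    """Exact mean log p(v) (nats per sample); needs n_hidden <= 12."""
    v = np.asarray(samples, dtype=float)
    return float(-free_energy(v, params).mean() - exact_log_partition(params))


def exact_likelihood_gradient(params: RBMParams, samples: np.ndarray):
    """Analytic gradient of the exact mean log-likelihood.

    Data term: <v_i tanh u_j>, <v_i>, <tanh u_j> over the samples.  Model
    term: exact expectations from the enumerated hidden marginal and the
    per-block residue probabilities.  Returns ``(gw, ga, gb)``.
    """
    v = np.asarray(samples, dtype=float)
    n = v.shape[0]
    th = np.tanh(hidden_input(v, params))
    gw_data = v.T @ th / n
    ga_data = v.mean(axis=0)
    gb_data = th.mean(axis=0)

    states = enumerate_hidden_states(params.n_hidden)
    logw = hidden_state_log_weights(params, states)
    p_h = np.exp(logw - logsumexp(logw))  # (S,)
    probs = all_block_probs(states, params)  # (S, gamma, 20)
    ev_given_h = (2.0 * probs - 1.0).reshape(len(states), params.n_visible)
    gw_model = (ev_given_h * p_h[:, None]).T @ states  # (nv, nh)
    ga_model = p_h @ ev_given_h
    gb_model = p_h @ states
    return gw_data - gw_model, ga_data - ga_model, gb_data - gb_model


def generate_sequences(params: RBMParams, n_samples: int,
                       rng: np.random.Generator, as_spins: bool = False,
                       return_hidden: bool = False):
    """Exact ancestral sampling: h from its enumerated marginal, then blocks.

    Returns residue strings, or the (n, n_visible) spin array if
    ``as_spins``; with ``return_hidden`` additionally the drawn hidden
    states.  No burn-in is involved; draws are i.i.d. from the model.
    """
    states = enumerate_hidden_states(params.n_hidden)
    logw = hidden_state_log_weights(params, states)
    p_h = np.exp(logw - logsumexp(logw))
    p_h = p_h / p_h.sum()
    which = rng.choice(len(states), size=n_samples, p=p_h)
    h = states[which]
    v = sample_visible(h, params, rng).astype(np.int8)
    out = v if as_spins else decode_samples(v)
    return (out, h) if return_hidden else out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Hyper-parameters for CD/PCD training.

    ``cd_steps`` is the number of alternating block-Gibbs sweeps per
    gradient estimate; with ``persistent`` the model-side chains survive
    across updates and epochs (PCD).  ``pll_samples`` bounds the number of
    samples used for the per-epoch PLL monitor (None = all).
    """

    cd_steps: int = 1
    persistent: bool = False
    epochs: int = 50
    learning_rate: float = 0.2
    batch_size: int = 128
    seed: int = 0
    optimizer: str = "sgd"  # "sgd" (momentum) or "adam"
    momentum: float = 0.9
    init_scale: float = 0.01
    init_visible_bias_from_data: bool = True
    centered: bool = True
    weight_decay: float = 1e-4
    final_learning_rate: float | None = 0.02
    restarts: int = 3
    selection_epochs: int = 15
    pll_samples: int | None = 2048

    def __post_init__(self) -> None:
        if self.cd_steps < 1:
            raise ValueError("cd_steps must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")


@dataclass
class TrainedRBM:
    """A trained model plus its per-epoch PLL monitoring series."""

    params: RBMParams
    pll_train: np.ndarray
    pll_valid: np.ndarray
    config: TrainConfig
    split_seed: int = 0


def initial_params(n_visible: int, n_hidden: int, config: TrainConfig,
                   rng: np.random.Generator,
                   data: np.ndarray | None = None) -> RBMParams:
    """Random initialisation: Gaussian weights (sd ``init_scale``), zero biases.

    If ``init_visible_bias_from_data``, the visible bias is set to half the
    empirical log-odds of each site being +1 (so the independent-site model
    matches the data marginals at zero weights).
    """
    w = rng.normal(0.0, config.init_scale, size=(n_visible, n_hidden))
    a = np.zeros(n_visible)
    if config.init_visible_bias_from_data and data is not None:
        p = np.clip((np.asarray(data, dtype=float).mean(axis=0) + 1.0) / 2.0,
                    1e-4, 1.0 - 1e-4)
        a = 0.5 * np.log(p / (1.0 - p))
    return RBMParams(w, a, np.zeros(n_hidden))


def cd_gradient(batch: np.ndarray, params: RBMParams, n_steps: int,
                chains: np.ndarray | None, rng: np.random.Generator,
                offsets: tuple[np.ndarray, np.ndarray] | None = None):
    """One CD-n / PCD-n stochastic estimate of the log-likelihood gradient.

    The data-side hidden statistics use the exact conditional expectation
    ``tanh(u)`` (Rao-Blackwellised); the model side runs ``n_steps``
    alternating block-Gibbs sweeps from the data batch (CD) or from the
    supplied persistent chains (PCD) and likewise uses ``tanh(u)`` at the
    final chain state.

    With ``offsets`` = (lambda, mu) the *centered* gradient is returned:
    ``v`` and ``tanh(u)`` enter the weight statistics as deviations from
    these offsets, and the bias gradients are compensated so the update
    direction is a reparametrisation (not a change) of the likelihood
    gradient.  Centering removes the mean-field component from the weight
    gradient, which stops all hidden units from collectively chasing the
    data mean and greatly improves the differentiation of units into
    distinct modes.  Returns ``((gw, ga, gb), new_chains)``.
    """
    batch = np.asarray(batch, dtype=float)
    if batch.size == 0:
        raise ValueError("empty batch")
    m = batch.shape[0]
    th_data = np.tanh(hidden_input(batch, params))

    v = batch if chains is None else chains
    for _ in range(n_steps):
        h = sample_hidden(v, params, rng)
        v = sample_visible(h, params, rng)
    k = v.shape[0]
    th_model = np.tanh(hidden_input(v, params))

    ga = batch.mean(axis=0) - v.mean(axis=0)
    gb = th_data.mean(axis=0) - th_model.mean(axis=0)
    if offsets is None:
        gw = batch.T @ th_data / m - v.T @ th_model / k
        return (gw, ga, gb), v
    lam, mu = offsets
    gw = ((batch - lam).T @ (th_data - mu) / m
          - (v - lam).T @ (th_model - mu) / k)
    return (gw, ga - gw @ mu, gb - gw.T @ lam), v


class _Adam:
    """Minimal Adam optimiser (ascent) over a list of arrays."""

    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, grads):
        self.t += 1
        out = []
        for i, g in enumerate(grads):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            out.append(self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


class _MomentumSGD:
    """Stochastic gradient ascent with classical momentum.

    Preferred default here: unlike Adam, it does not rescale the gradient
    per coordinate, a rescaling that flattens the weak curvature separating
    near-degenerate mixed solutions from the true hidden-unit basis and
    traps training there.
    """

    def __init__(self, shapes, lr, momentum=0.9):
        self.lr, self.momentum = lr, momentum
        self.vel = [np.zeros(s) for s in shapes]

    def step(self, grads):
        out = []
        for i, g in enumerate(grads):
            self.vel[i] = self.momentum * self.vel[i] + self.lr * g
            out.append(self.vel[i].copy())
        return out


def _pll_monitor(params: RBMParams, samples: np.ndarray, limit: int | None) -> float:
    if limit is not None and samples.shape[0] > limit:
        samples = samples[:limit]
    return pseudo_log_likelihood(params, samples)


class _Trainer:
    """Stateful single-run trainer: one init, resumable epoch by epoch."""

    def __init__(self, split: DatasetSplit, n_hidden: int, config: TrainConfig,
                 seed: int):
        self.split = split
        self.config = config
        self.data = np.asarray(split.train, dtype=float)
        if self.data.shape[0] == 0:
            raise ValueError("empty training set")
        n, nv = self.data.shape
        self.rng = np.random.default_rng(seed)
        self.params = initial_params(nv, n_hidden, config, self.rng, self.data)
        shapes = [self.params.weights.shape, self.params.visible_bias.shape,
                  self.params.hidden_bias.shape]
        if config.optimizer == "adam":
            self.opt = _Adam(shapes, config.learning_rate)
        else:
            self.opt = _MomentumSGD(shapes, config.learning_rate,
                                    config.momentum)
        self.chains = None
        if config.persistent:
            self.chains = self.data[self.rng.choice(
                n, size=min(config.batch_size, n), replace=False)].copy()
        # centering offsets: visible offset fixed at the data mean, hidden
        # offset an exponential moving average of data-side tanh(u) means
        self.lam = self.data.mean(axis=0)
        self.mu = np.zeros(n_hidden)
        self.epoch = 0
        self.pll_train: list[float] = []
        self.pll_valid: list[float] = []

    def _lr_at(self, epoch: int) -> float:
        cfg = self.config
        if (cfg.final_learning_rate is None or cfg.epochs <= 1
                or cfg.learning_rate <= 0):
            return cfg.learning_rate
        # exponential decay from learning_rate to final_learning_rate: a
        # large early step escapes collapsed/duplicated-unit saddles, a
        # small late step refines the recovered units
        frac = epoch / (cfg.epochs - 1)
        return cfg.learning_rate * (
            cfg.final_learning_rate / cfg.learning_rate) ** frac

    def run_epochs(self, n_epochs: int) -> None:
        cfg = self.config
        params, data = self.params, self.data
        n = data.shape[0]
        for _ in range(n_epochs):
            self.opt.lr = self._lr_at(self.epoch)
            order = self.rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                batch = data[order[start:start + cfg.batch_size]]
                offsets = None
                if cfg.centered:
                    self.mu = (0.99 * self.mu + 0.01 * np.tanh(
                        hidden_input(batch, params)).mean(axis=0))
                    offsets = (self.lam, self.mu)
                grads, new_chains = cd_gradient(
                    batch, params, cfg.cd_steps,
                    self.chains if cfg.persistent else None, self.rng,
                    offsets=offsets)
                if cfg.weight_decay:
                    # L2 decay on the couplings only; lets redundant
                    # (duplicated) units shrink and re-differentiate
                    grads = (grads[0] - cfg.weight_decay * params.weights,
                             grads[1], grads[2])
                if cfg.persistent:
                    self.chains = new_chains
                dw, da, db = self.opt.step(grads)
                params.weights += dw
                params.visible_bias += da
                params.hidden_bias += db
            self.epoch += 1
            if not (np.all(np.isfinite(params.weights))
                    and np.all(np.isfinite(params.visible_bias))
                    and np.all(np.isfinite(params.hidden_bias))):
                raise TrainingDivergedError(
                    f"non-finite parameters at epoch {self.epoch} "
                    f"(lr={cfg.learning_rate}, cd_steps={cfg.cd_steps})")
            self.pll_train.append(_pll_monitor(params, data, cfg.pll_samples))
            self.pll_valid.append(_pll_monitor(params, self.split.valid,
                                               cfg.pll_samples))


def train(split: DatasetSplit, n_hidden: int, config: TrainConfig) -> TrainedRBM:
    """Train an RBM on a train/validation split.

    Runs ``config.epochs`` passes of minibatch CD-n (or PCD-n), recording
    the PLL of both sets after every epoch.  With ``config.restarts > 1``,
    several weight initialisations are advanced for
    ``config.selection_epochs`` and only the one with the best validation
    PLL is trained to completion — the likelihood surface has attractive
    sub-optimal solutions in which hidden units mix several latent modes,
    and those sit roughly a nat below the well-separated optimum, so a
    short validation race reliably discards them.  Fully deterministic
    given ``(config.seed, split)``.  Raises
    :class:`TrainingDivergedError` on non-finite parameters.
    """
    n_candidates = max(1, config.restarts)
    selection = min(config.selection_epochs, config.epochs)
    if n_candidates == 1 or selection == 0:
        trainer = _Trainer(split, n_hidden, config, config.seed)
        trainer.run_epochs(config.epochs)
    else:
        candidates = [_Trainer(split, n_hidden, config,
                               config.seed + 100_003 * k)
                      for k in range(n_candidates)]
        for cand in candidates:
            cand.run_epochs(selection)
        trainer = max(candidates, key=lambda c: c.pll_valid[-1])
        trainer.run_epochs(config.epochs - selection)
    return TrainedRBM(trainer.params, np.array(trainer.pll_train),
                      np.array(trainer.pll_valid), config, split.split_seed)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def model_to_dict(trained: TrainedRBM) -> dict:
    p = trained.params
    return {
        "n_visible": p.n_visible,
        "n_hidden": p.n_hidden,
        "gamma": p.gamma,
        "alphabet": AMINO_ACIDS,
        "weights": p.weights.tolist(),  # row-major: weights[i][j] = w_ij
        "visible_bias": p.visible_bias.tolist(),
        "hidden_bias": p.hidden_bias.tolist(),
        "config": asdict(trained.config),
        "pll_history": {"train": list(map(float, trained.pll_train)),
                        "valid": list(map(float, trained.pll_valid))},
        "split_seed": trained.split_seed,
    }


def model_from_dict(doc: dict) -> TrainedRBM:
    params = RBMParams(np.array(doc["weights"]), np.array(doc["visible_bias"]),
                       np.array(doc["hidden_bias"]))
    config = TrainConfig(**doc.get("config", {}))
    hist = doc.get("pll_history", {"train": [], "valid": []})
    return TrainedRBM(params, np.array(hist["train"]), np.array(hist["valid"]),
                      config, doc.get("split_seed", 0))


def save_model(trained: TrainedRBM, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(trained), fh)


def load_model(path) -> TrainedRBM:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
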