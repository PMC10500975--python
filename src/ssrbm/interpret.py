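"""Hidden-state decomposition of an average RBM.

With ``n_hidden`` spin hidden units the model has ``2^n_hidden`` hidden
states, each acting as a "mode" that induces a position-specific 20 x gamma
residue probability table.  This module computes the empirical frequency of
each state over a dataset (the dataset-averaged posterior), the per-state
tables, their frequency-weighted mixture, and the comparison of that
mixture against the raw empirical residue frequencies — plus the plain
two-site-correlation matrix that a standard statistical analysis of the
same data would start from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .ingest import N_ALPHABET, encode_sequences
from .rbm import (RBMParams, all_block_probs, enumerate_hidden_states,
                  hidden_conditional, hidden_state_log_weights)


@dataclass
class StateDecomposition:
    """All hidden states of a model, ranked by decreasing frequency.

    ``states[s]`` is the spin vector of the s-th most frequent state,
    ``frequencies[s]`` its dataset-averaged posterior probability,
    ``tables[s]`` the 20 x gamma column-stochastic residue table it
    induces, and ``labels[s]`` its rank name ("S1", "S2", ...).
    ``prior_frequencies`` holds the model's own state marginal p(h) for
    reference.
    """

    states: np.ndarray  # (S, n_hidden), ranked
    frequencies: np.ndarray  # (S,)
    tables: np.ndarray  # (S, 20, gamma)
    labels: list[str]
    prior_frequencies: np.ndarray | None = None

    @property
    def n_states(self) -> int:
        return len(self.frequencies)


def state_frequencies(params: RBMParams, samples: np.ndarray) -> np.ndarray:
    """Dataset-averaged posterior probability of every hidden state.

    f_s = mean over samples v of prod_j p(h_j = s_j | v), in the canonical
    enumeration order of :func:`~ssrbm.rbm.enumerate_hidden_states`.
    """
    v = np.asarray(samples, dtype=float)
    if v.ndim != 2 or v.shape[0] == 0:
        raise ValueError("need a nonempty (n, n_visible) sample array")
    p = hidden_conditional(v, params)  # (n, nh), P(h_j = +1 | v)
    states = enumerate_hidden_states(params.n_hidden)
    f = np.empty(len(states))
    for s, state in enumerate(states):
        per_unit = np.where(state > 0, p, 1.0 - p)  # (n, nh)
        f[s] = per_unit.prod(axis=1).mean()
    return f


def prior_state_frequencies(params: RBMParams) -> np.ndarray:
    """The model's own hidden-state marginal p(h), for comparison."""
    logw = hidden_state_log_weights(params)
    return np.exp(logw - logsumexp(logw))


def state_tables(params: RBMParams) -> np.ndarray:
    """Per-state residue probability tables, shape (2^n_hidden, 20, gamma).

    Table columns (positions) are the block conditionals at fixed hidden
    state, hence each column sums to 1.
    """
    states = enumerate_hidden_states(params.n_hidden)
    probs = all_block_probs(states, params)  # (S, gamma, 20)
    return probs.transpose(0, 2, 1)


def decompose(params: RBMParams, samples: np.ndarray) -> StateDecomposition:
    """Rank the hidden states of ``params`` by their frequency over ``samples``.

    Ties in frequency are broken by the lexicographic order of the state
    vector (+1 before -1), so labels are a pure function of the inputs.
    """
    f = state_frequencies(params, samples)
    tables = state_tables(params)
    states = enumerate_hidden_states(params.n_hidden)
    prior = prior_state_frequencies(params)
    # stable sort on -f keeps the lexicographic enumeration order for ties
    order = np.argsort(-f, kind="stable")
    labels = [f"S{r + 1}" for r in range(len(order))]
    return StateDecomposition(states[order], f[order], tables[order], labels,
                              prior_frequencies=prior[order])


# ---------------------------------------------------------------------------
# Mixture vs empirical frequencies
# ---------------------------------------------------------------------------

def mixture_reconstruction(decomposition: StateDecomposition) -> np.ndarray:
    """Frequency-weighted mixture of the state tables: sum_s f_s P_s (20 x gamma)."""
    return np.einsum("s,skg->kg", decomposition.frequencies,
                     decomposition.tables)


def empirical_frequencies(samples) -> np.ndarray:
    """Column-normalised residue counts (20 x gamma) of a dataset.

    Accepts an (n, 20*gamma) spin array or an iterable of residue strings.
    """
    if not isinstance(samples, np.ndarray):
        samples = encode_sequences(samples)
    v = np.asarray(samples, dtype=float)
    if v.ndim != 2 or v.shape[0] == 0:
        raise ValueError("need a nonempty sample array")
    counts = (v.reshape(v.shape[0], -1, N_ALPHABET) + 1.0) / 2.0
    table = counts.sum(axis=0).T  # (20, gamma)
    return table / table.sum(axis=0, keepdims=True)


def compare_tables(table_a: np.ndarray, table_b: np.ndarray) -> np.ndarray:
    """Per-position total-variation distance between two 20 x gamma tables."""
    a, b = np.asarray(table_a), np.asarray(table_b)
    if a.shape != b.shape:
        raise ValueError("tables have different shapes")
    return 0.5 * np.abs(a - b).sum(axis=0)


# ---------------------------------------------------------------------------
# Two-site correlation baseline
# ---------------------------------------------------------------------------

def two_site_correlations(samples: np.ndarray) -> np.ndarray:
    """Pearson correlations of the one-hot indicators across samples.

    Returns the (20*gamma)^2 symmetric matrix with unit diagonal.  Entries
    within a block are negative by one-hot exclusivity; between-block
    entries measure residue co-occurrence between positions.  Constant
    indicators (residues never/always seen at a position) yield zero
    off-diagonal correlation.
    """
    v = np.asarray(samples, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    x = v - v.mean(axis=0)
    cov = x.T @ x / (v.shape[0] - 1)
    sd = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(sd, sd)
    corr[~np.isfinite(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr
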