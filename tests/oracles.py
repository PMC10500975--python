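"""Brute-force enumeration oracle for tiny spin RBMs.

Everything here is computed by literal summation over all
``20**gamma * 2**n_hidden`` joint configurations, independently of the
package's analytic shortcuts, so it can serve as ground truth for
conditionals, free energies, pseudo-log-likelihoods and partition
functions on toy models.
"""

import itertools

import numpy as np

N_AA = 20


def one_hot_states(gamma):
    """All 20**gamma one-hot visible spin vectors, with their index tuples."""
    configs = []
    for combo in itertools.product(range(N_AA), repeat=gamma):
        v = -np.ones(N_AA * gamma)
        for g, k in enumerate(combo):
            v[N_AA * g + k] = 1.0
        configs.append((combo, v))
    return configs


def hidden_states(n_hidden):
    return [np.array(h, dtype=float)
            for h in itertools.product((1.0, -1.0), repeat=n_hidden)]


def energy(v, h, w, a, b):
    return -(a @ v) - (b @ h) - v @ w @ h


class EnumeratedRBM:
    """Exhaustive joint distribution of a small RBM on the one-hot manifold."""

    def __init__(self, w, a, b):
        self.w, self.a, self.b = (np.asarray(x, dtype=float) for x in (w, a, b))
        self.gamma = self.w.shape[0] // N_AA
        self.visibles = one_hot_states(self.gamma)
        self.hiddens = hidden_states(self.w.shape[1])
        self.joint = np.array([[np.exp(-energy(v, h, self.w, self.a, self.b))
                                for h in self.hiddens]
                               for _, v in self.visibles])
        self.z = self.joint.sum()

    def log_partition(self):
        return np.log(self.z)

    def p_v(self):
        return self.joint.sum(axis=1) / self.z

    def free_energy(self, v):
        """-log sum_h exp(-E(v, h)) for an arbitrary spin vector v."""
        return -np.log(sum(np.exp(-energy(v, h, self.w, self.a, self.b))
                           for h in self.hiddens))

    def p_h_given_v(self, v):
        """Vector of p(h_j = +1 | v) by two-state enumeration per unit."""
        weights = np.array([np.exp(-energy(v, h, self.w, self.a, self.b))
                            for h in self.hiddens])
        weights /= weights.sum()
        plus = np.array([[hj > 0 for hj in h] for h in self.hiddens])
        return weights @ plus

    def p_block_given_h(self, h, g):
        """20-vector p(residue k at position g | h) by enumeration."""
        weights = np.empty(N_AA)
        base = -np.ones(N_AA * self.gamma)
        for k in range(N_AA):
            v = base.copy()
            v[N_AA * g + k] = 1.0
            # other blocks fixed at all -1: their contribution cancels in
            # the normalisation over k
            weights[k] = np.exp(-energy(v, h, self.w, self.a, self.b))
        return weights / weights.sum()

    def block_conditional(self, combo, g):
        """p(k at position g | other positions of `combo`) over k = 0..19."""
        weights = np.empty(N_AA)
        for k in range(N_AA):
            modified = list(combo)
            modified[g] = k
            v = -np.ones(N_AA * self.gamma)
            for gg, kk in enumerate(modified):
                v[N_AA * gg + kk] = 1.0
            weights[k] = np.exp(self._neg_free(v))
        return weights / weights.sum()

    def _neg_free(self, v):
        return np.log(sum(np.exp(-energy(v, h, self.w, self.a, self.b))
                          for h in self.hiddens))

    def pll(self, sample_combos):
        """Mean over samples of sum_g log p(k_g | rest) by enumeration."""
        total = 0.0
        for combo in sample_combos:
            for g in range(self.gamma):
                total += np.log(self.block_conditional(combo, g)[combo[g]])
        return total / len(sample_combos)

    def marginal_table(self):
        """Exact 20 x gamma single-position marginals of the model."""
        pv = self.p_v()
        table = np.zeros((N_AA, self.gamma))
        for (combo, _), p in zip(self.visibles, pv):
            for g, k in enumerate(combo):
                table[k, g] += p
        return table
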