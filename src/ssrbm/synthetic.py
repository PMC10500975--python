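"""Synthetic sequence generators with planted latent structure.

Two generators cover the statistical structure the pipeline assumes:

* a *planted RBM*: hidden units whose weights implement amphiphilic
  alternation — a binary polar (P) / hydrophobic (H) partition of the
  residues, pushed with amplitude ``c`` at a mask of positions (odd
  positions for the period-2 helix-like pattern, every position for the
  period-1 strand-like pattern).  Sampling is exact (enumerated hidden
  marginal, then categorical blocks), so recovery of the planted units by
  ensemble training is a well-posed test;
* a *mode mixture*: a small number of explicit 20 x gamma column-stochastic
  residue tables mixed at configurable frequencies, for tests that need
  direct control of the visible distribution.

The default P/H partition is balanced (10 residues per class) and fully
overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ingest import AMINO_ACIDS, AA_INDEX, N_ALPHABET
from .rbm import RBMParams, generate_sequences

#: Default residue partition: hydrophobic (+1) vs polar/charged (-1).  The
#: partition follows the dichotomy learned weights expose on real boundary
#: data (Tyr with the hydrophobics, Pro with the polars); Ala and Gly, the
#: two class-ambiguous residues, are assigned to the hydrophobic side so
#: that both classes have exactly 10 members and each planted mode is
#: gauge-symmetric rather than pinned at one value.
HYDROPHOBIC_CLASS = "ACFGILMVWY"
POLAR_CLASS = "DEHKNPQRST"

#: A secondary, balanced dichotomy (aliphatic/acidic/small-polar vs
#: aromatic/sulfur/long-polar), orthogonal to the primary one over the 20
#: residues, used to make a third planted unit linearly independent of the
#: two amphiphilic ones.
SECONDARY_PLUS = "ADEFIKLNSV"
SECONDARY_MINUS = "CGHMPQRTWY"


def class_signs(assignment: dict[str, int] | None = None) -> np.ndarray:
    """Per-residue class sign vector (alphabetical order) from an assignment.

    ``assignment`` maps residues to +1 (H), -1 (P) or 0 (class-neutral);
    missing residues default to 0.  With no argument the default balanced
    partition above is used.
    """
    if assignment is None:
        assignment = {**{aa: 1 for aa in HYDROPHOBIC_CLASS},
                      **{aa: -1 for aa in POLAR_CLASS}}
    bad = set(assignment) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"unknown residues in class assignment: {sorted(bad)}")
    chi = np.zeros(N_ALPHABET)
    for aa, s in assignment.items():
        if s not in (-1, 0, 1):
            raise ValueError(f"class sign for {aa!r} must be -1, 0 or +1")
        chi[AA_INDEX[aa]] = s
    return chi


@dataclass(frozen=True)
class PlantedUnit:
    """One planted hidden unit: a position mask, an amplitude, a dichotomy."""

    positions: tuple[int, ...]  # 1-based residue positions it acts on
    amplitude: float
    assignment: dict[str, int] | None = None  # None = default partition

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("position mask must be non-empty")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass
class PlantedSpec:
    """Full description of a planted RBM."""

    gamma: int = 5
    units: list[PlantedUnit] = field(default_factory=list)
    visible_bias: np.ndarray | None = None  # (20, gamma) profile
    hidden_bias: np.ndarray | None = None  # (n_hidden,)
    seed: int = 0

    @property
    def n_hidden(self) -> int:
        return len(self.units)

    def __post_init__(self) -> None:
        if self.n_hidden > 12:
            raise ValueError("planted models are limited to 12 hidden units")
        for u in self.units:
            if max(u.positions) > self.gamma or min(u.positions) < 1:
                raise ValueError("unit mask outside 1..gamma")


#: Default prior activation p(h_j = +1) of the planted units: close to but
#: not exactly 1/2, so every mode is genuinely bistable while the
#: hidden-state frequencies still have a unique rank order.
DEFAULT_UNIT_ACTIVATIONS = (0.62, 0.45, 0.55, 0.48)


def balance_hidden_bias(params: RBMParams, targets) -> RBMParams:
    """Set hidden biases so each unit's prior marginal p(h_j = +1) hits a target.

    The one-hot visible blocks make the hidden free energy strongly
    asymmetric whenever a unit's residue classes are unbalanced, which can
    freeze the unit at one value; this coordinate-wise fixed point (using
    the exactly enumerated hidden marginal) restores genuine bistability.
    """
    from .rbm import enumerate_hidden_states, hidden_state_log_weights
    from scipy.special import logit, logsumexp

    targets = np.asarray(targets, dtype=float)
    if targets.shape != (params.n_hidden,):
        raise ValueError("one activation target per hidden unit required")
    p = params.copy()
    states = enumerate_hidden_states(p.n_hidden)
    plus = states > 0
    for _ in range(200):
        logw = hidden_state_log_weights(p, states)
        prob = np.exp(logw - logsumexp(logw))
        marg = np.clip(prob @ plus, 1e-12, 1 - 1e-12)
        delta = 0.5 * (logit(targets) - logit(marg))
        p.hidden_bias += delta
        if np.abs(delta).max() < 1e-10:
            break
    return p


def default_planted_spec(n_hidden: int = 3, gamma: int = 5,
                         amplitude: float = 1.0, seed: int = 0) -> PlantedSpec:
    """Standard planted model: K well-separated amphiphilic-style units.

    Unit 1 pushes the P/H alternation at odd positions (helix-like period
    2), unit 2 at even positions, unit 3 applies the secondary dichotomy at
    every position (strand-like period 1), unit 4 the secondary dichotomy
    at odd positions.  Hidden biases are balanced (see
    :func:`balance_hidden_bias`) to the slightly non-uniform default
    activations, so the hidden-state frequencies have a unique rank order
    and every unit is a live mode rather than a frozen bias.
    """
    if not 1 <= n_hidden <= 4:
        raise ValueError("default planted spec supports 1..4 hidden units")
    odd = tuple(range(1, gamma + 1, 2))
    even = tuple(range(2, gamma + 1, 2))
    full = tuple(range(1, gamma + 1))
    secondary = {**{aa: 1 for aa in SECONDARY_PLUS},
                 **{aa: -1 for aa in SECONDARY_MINUS}}
    units = [PlantedUnit(odd, amplitude),
             PlantedUnit(even, amplitude),
             PlantedUnit(full, amplitude, secondary),
             PlantedUnit(odd, amplitude, secondary)][:n_hidden]
    spec = PlantedSpec(gamma=gamma, units=units, seed=seed)
    balanced = balance_hidden_bias(
        make_planted_rbm(spec), DEFAULT_UNIT_ACTIVATIONS[:n_hidden])
    spec.hidden_bias = balanced.hidden_bias
    return spec


def make_planted_rbm(spec: PlantedSpec) -> RBMParams:
    """Materialise the planted weights: +c for class-H residues and -c for
    class-P residues at masked positions, 0 elsewhere."""
    nv = N_ALPHABET * spec.gamma
    w = np.zeros((nv, spec.n_hidden))
    for j, unit in enumerate(spec.units):
        chi = class_signs(unit.assignment)
        for pos in unit.positions:
            sl = slice(N_ALPHABET * (pos - 1), N_ALPHABET * pos)
            w[sl, j] = unit.amplitude * chi
    if spec.visible_bias is None:
        a = np.zeros(nv)
    else:
        profile = np.asarray(spec.visible_bias, dtype=float)
        if profile.shape != (N_ALPHABET, spec.gamma):
            raise ValueError("visible_bias profile must be (20, gamma)")
        a = profile.T.reshape(-1)
    b = (np.zeros(spec.n_hidden) if spec.hidden_bias is None
         else np.asarray(spec.hidden_bias, dtype=float))
    return RBMParams(w, a, b)


def _sequence_frame(sequences: list[str], gamma: int,
                    prefix: str = "synthetic") -> pd.DataFrame:
    return pd.DataFrame({
        "protein_id": [f"{prefix}_{i}" for i in range(len(sequences))],
        "element_kind": "synthetic",
        "terminus": "synthetic",
        "sequence": sequences,
        "element_length": gamma,
    })


def sample_planted(params: RBMParams, n_samples: int, seed: int = 0,
                   as_spins: bool = False):
    """Draw i.i.d. sequences from a planted RBM (exact ancestral sampling).

    Returns a stretch-table DataFrame, or the raw (n, 20*gamma) spin array
    when ``as_spins``.
    """
    rng = np.random.default_rng(seed)
    if n_samples == 0:
        return (np.empty((0, params.n_visible), dtype=np.int8) if as_spins
                else _sequence_frame([], params.gamma))
    if as_spins:
        return generate_sequences(params, n_samples, rng, as_spins=True)
    return _sequence_frame(generate_sequences(params, n_samples, rng),
                           params.gamma)


# ---------------------------------------------------------------------------
# Mode-mixture generator
# ---------------------------------------------------------------------------

@dataclass
class ModeMixtureSpec:
    """A mixture of explicit position-specific residue tables."""

    tables: list[np.ndarray]  # each (20, gamma), column-stochastic
    probabilities: np.ndarray  # simplex over modes
    n_samples: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        self.tables = [np.asarray(t, dtype=float) for t in self.tables]
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.tables) != len(self.probabilities):
            raise ValueError("one probability per mode required")
        if not np.isclose(self.probabilities.sum(), 1.0) or (self.probabilities < 0).any():
            raise ValueError("mode probabilities must form a simplex")
        gamma = self.tables[0].shape[1]
        for t in self.tables:
            if t.shape != (N_ALPHABET, gamma):
                raise ValueError("all mode tables must be (20, gamma)")
            if not np.allclose(t.sum(axis=0), 1.0, atol=1e-8) or (t < 0).any():
                raise ValueError("mode tables must be column-stochastic")

    @property
    def gamma(self) -> int:
        return self.tables[0].shape[1]


def sample_mode_mixture(spec: ModeMixtureSpec) -> pd.DataFrame:
    """Draw a mode per sample, then residues independently per position.

    Returns a stretch-table DataFrame with an extra ``mode`` column.
    """
    rng = np.random.default_rng(spec.seed)
    modes = rng.choice(len(spec.tables), size=spec.n_samples, p=spec.probabilities)
    sequences = []
    for m in modes:
        table = spec.tables[m]
        seq = "".join(AMINO_ACIDS[rng.choice(N_ALPHABET, p=table[:, g])]
                      for g in range(spec.gamma))
        sequences.append(seq)
    df = _sequence_frame(sequences, spec.gamma)
    df["mode"] = modes
    return df


def amphiphilic_table(gamma: int, phase: int, strength: float = 3.0,
                      period: int = 2) -> np.ndarray:
    """Column-stochastic table favouring class H at positions matching ``phase``.

    Position g (1-based) favours the hydrophobic class when
    ``(g - 1) % period == phase``, else the polar class; favoured residues
    get ``strength`` times the weight of the others.
    """
    chi = class_signs()
    table = np.empty((N_ALPHABET, gamma))
    for g in range(gamma):
        sign = 1.0 if (g % period) == phase else -1.0
        col = np.where(chi * sign > 0, strength, 1.0)
        table[:, g] = col / col.sum()
    return table


def amphiphilic_mixture_spec(gamma: int = 5, n_samples: int = 10000,
                             seed: int = 0, strength: float = 3.0,
                             probabilities=(0.6, 0.4)) -> ModeMixtureSpec:
    """Two antiphase amphiphilic modes — the minimal correlated generator.

    Mixing the two phases makes positions of equal parity positively
    correlated in class, the signature the two-site-correlation baseline
    should pick up.
    """
    tables = [amphiphilic_table(gamma, 0, strength),
              amphiphilic_table(gamma, 1, strength)]
    return ModeMixtureSpec(tables, np.asarray(probabilities, dtype=float),
                           n_samples=n_samples, seed=seed)
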