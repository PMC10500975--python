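"""Statistical-ensemble consolidation of independently trained RBMs.

Independent training realizations (different weight initialisations and
train/validation splits) need not learn the same hidden units, and each
unit is only defined up to the gauge flip ``(h, w, b) -> (-h, -w, -b)``.
This module pools all hidden units of an ensemble, measures pairwise
(sign-aligned) Euclidean distances between their weight vectors, groups
them by density-based clustering (DBSCAN) with unmatched units labelled as
noise, and averages each group into a consensus "average RBM" (aRBM).
Scanning the number of hidden units and asking for how long every
realization keeps learning the same palette of units gives a
model-selection rule for the hidden-layer size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .ingest import split_train_valid
from .rbm import (RBMParams, TrainConfig, TrainedRBM, TrainingDivergedError,
                  pseudo_log_likelihood, train)

logger = logging.getLogger(__name__)

#: Cluster label assigned to units not belonging to any group.
NOISE = -1


@dataclass(frozen=True)
class HiddenUnit:
    """One hidden unit of one realization, with provenance."""

    weight_vector: np.ndarray
    bias: float
    rbm_index: int
    unit_index: int


@dataclass
class UnitClustering:
    """Pairwise unit distances, group labels and sign-alignment factors.

    ``labels[j]`` is a positive group id (1, 2, ... in decreasing group
    size) or :data:`NOISE`.  ``signs[j]`` is the factor applied to unit j's
    weights and bias before averaging, chosen per group so that members
    have positive inner product with the group's largest-norm member.
    """

    distance: np.ndarray
    labels: np.ndarray
    signs: np.ndarray
    eps: float
    min_samples: int

    @property
    def n_groups(self) -> int:
        return int((np.unique(self.labels) != NOISE).sum())

    @property
    def noise_fraction(self) -> float:
        return float((self.labels == NOISE).mean())

    def members(self, group_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == group_id)


@dataclass
class AverageRBM:
    """Group-averaged consensus model (aRBM) with provenance.

    ``group_weights[g]`` and ``group_bias[g]`` are the sign-aligned means
    over the members of group ``g+1``; ``visible_bias`` is the mean visible
    bias over all contributing realizations.
    """

    group_weights: np.ndarray  # (n_groups, n_visible)
    group_bias: np.ndarray  # (n_groups,)
    visible_bias: np.ndarray  # (n_visible,)
    group_sizes: np.ndarray  # (n_groups,)
    source: str = ""

    @property
    def n_groups(self) -> int:
        return len(self.group_bias)

    def to_params(self) -> RBMParams:
        """View the aRBM as an RBM with one hidden unit per group."""
        return RBMParams(self.group_weights.T.copy(), self.visible_bias.copy(),
                         self.group_bias.copy())


# ---------------------------------------------------------------------------
# Ensemble training
# ---------------------------------------------------------------------------

def train_ensemble(samples: np.ndarray, n_hidden: int, config: TrainConfig,
                   n_realizations: int, fraction: float = 0.8) -> list[TrainedRBM]:
    """Train ``n_realizations`` independent RBMs on fresh 80/20 splits.

    Realization ``r`` derives its seed as ``config.seed + r`` and uses it
    for both the weight initialisation and its own train/validation split.
    Realizations whose training diverges are dropped (and counted in the
    log), not retrained, so seeds stay interpretable.
    """
    if n_realizations < 2:
        raise ValueError("need at least 2 realizations for an ensemble")
    samples = np.asarray(samples)
    models: list[TrainedRBM] = []
    diverged = 0
    for r in range(n_realizations):
        seed = config.seed + r
        split = split_train_valid(samples, fraction=fraction, seed=seed)
        cfg = replace(config, seed=seed)
        try:
            models.append(train(split, n_hidden, cfg))
        except TrainingDivergedError as err:
            diverged += 1
            logger.warning("realization %d diverged and was dropped: %s", r, err)
    if diverged:
        logger.warning("%d/%d realizations diverged", diverged, n_realizations)
    return models


def collect_units(models: list[TrainedRBM]) -> list[HiddenUnit]:
    """Pool all hidden units of the ensemble, keeping provenance indices."""
    units = []
    for r, model in enumerate(models):
        p = model.params
        for j in range(p.n_hidden):
            units.append(HiddenUnit(p.weights[:, j].copy(),
                                    float(p.hidden_bias[j]), r, j))
    return units


# ---------------------------------------------------------------------------
# Distances and clustering
# ---------------------------------------------------------------------------

def unit_distance_matrix(units: list[HiddenUnit], sign_align: bool = True):
    """Pairwise Euclidean distances between unit weight vectors.

    With ``sign_align`` (default) the gauge flip is quotiented out:
    ``d_jm = min(|w_j - w_m|, |w_j + w_m|)``, and a provisional sign per
    unit is produced by orienting every unit to a positive inner product
    with the largest-norm unit (final per-group signs are recomputed in
    :func:`build_arbm`).  Returns ``(d, signs)``.
    """
    if len(units) < 2:
        raise ValueError("need at least 2 units")
    w = np.stack([u.weight_vector for u in units])
    if w.ndim != 2:
        raise ValueError("unit weight vectors have unequal lengths")
    sq = (w * w).sum(axis=1)
    gram = w @ w.T
    if sign_align:
        d2 = sq[:, None] + sq[None, :] - 2.0 * np.abs(gram)
        ref = int(np.argmax(sq))
        signs = np.where(gram[ref] < 0, -1.0, 1.0)
    else:
        d2 = sq[:, None] + sq[None, :] - 2.0 * gram
        signs = np.ones(len(units))
    d = np.sqrt(np.clip(d2, 0.0, None))
    np.fill_diagonal(d, 0.0)
    return d, signs


def knee_eps(distance: np.ndarray, min_samples: int) -> float:
    """Default DBSCAN radius: knee of the sorted k-NN distance curve.

    The k-th-nearest-neighbour distance (k = ``min_samples``) is sorted
    increasingly and the knee is located as the point furthest from the
    chord joining the curve's endpoints.
    """
    k = min(min_samples, distance.shape[0] - 1)
    kdist = np.sort(np.sort(distance, axis=1)[:, k])
    n = len(kdist)
    if n < 3 or kdist[-1] <= kdist[0]:
        return float(kdist[-1]) if kdist[-1] > 0 else 1.0
    x = np.arange(n, dtype=float)
    chord = np.array([x[-1] - x[0], kdist[-1] - kdist[0]])
    chord /= np.hypot(*chord)
    rel = np.stack([x - x[0], kdist - kdist[0]], axis=1)
    dist_to_chord = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    eps = float(kdist[int(np.argmax(dist_to_chord))])
    return eps if eps > 0 else float(kdist[-1])


def cluster_units(distance: np.ndarray, signs: np.ndarray,
                  eps: float | str = "auto",
                  min_samples: int | str = "auto",
                  n_realizations: int | None = None) -> UnitClustering:
    """Group the pooled units with DBSCAN on the precomputed distances.

    ``min_samples='auto'`` uses ``max(3, R // 3)`` when the number of
    realizations ``R`` is given (else 3); ``eps='auto'`` uses
    :func:`knee_eps`.  Groups are renumbered 1, 2, ... by decreasing size
    (ties broken by lowest member index); unclustered units get
    :data:`NOISE`.
    """
    distance = np.asarray(distance, dtype=float)
    if min_samples == "auto":
        min_samples = max(3, (n_realizations or 0) // 3)
    min_samples = int(min_samples)
    if eps == "auto":
        eps = knee_eps(distance, min_samples)
    eps = float(eps)
    if eps <= 0:
        raise ValueError("eps must be positive")
    raw = DBSCAN(eps=eps, min_samples=min_samples,
                 metric="precomputed").fit_predict(distance)
    labels = np.full(len(raw), NOISE)
    groups = [g for g in np.unique(raw) if g != -1]
    order = sorted(groups, key=lambda g: (-(raw == g).sum(),
                                          int(np.flatnonzero(raw == g)[0])))
    for new_id, g in enumerate(order, start=1):
        labels[raw == g] = new_id
    return UnitClustering(distance, labels, np.asarray(signs, dtype=float),
                          eps, min_samples)


# ---------------------------------------------------------------------------
# Average RBM
# ---------------------------------------------------------------------------

def build_arbm(models: list[TrainedRBM], clustering: UnitClustering,
               units: list[HiddenUnit] | None = None,
               source: str = "") -> AverageRBM:
    """Average sign-aligned units within each group into the consensus model.

    Within each group, members are oriented to a positive inner product
    with the group's largest-norm member before averaging weights and
    hidden biases; the visible bias is averaged over all realizations.
    Noise units contribute nothing.
    """
    if units is None:
        units = collect_units(models)
    if clustering.n_groups < 1:
        raise ValueError("all units are noise; no groups to average")
    w = np.stack([u.weight_vector for u in units])
    b = np.array([u.bias for u in units])

    n_groups = clustering.n_groups
    gw = np.empty((n_groups, w.shape[1]))
    gb = np.empty(n_groups)
    sizes = np.empty(n_groups, dtype=int)
    final_signs = clustering.signs.copy()
    for g in range(1, n_groups + 1):
        idx = clustering.members(g)
        ref = idx[np.argmax((w[idx] ** 2).sum(axis=1))]
        s = np.where(w[idx] @ w[ref] < 0, -1.0, 1.0)
        final_signs[idx] = s
        gw[g - 1] = (s[:, None] * w[idx]).mean(axis=0)
        gb[g - 1] = (s * b[idx]).mean()
        sizes[g - 1] = len(idx)
    clustering.signs = final_signs
    visible_bias = np.mean([m.params.visible_bias for m in models], axis=0)
    return AverageRBM(gw, gb, visible_bias, sizes, source=source)


# ---------------------------------------------------------------------------
# Model-complexity scan
# ---------------------------------------------------------------------------

@dataclass
class ComplexityScan:
    """Group counts, noise fractions and PLLs across hidden-layer sizes."""

    table: pd.DataFrame  # one row per n_hidden
    noise_threshold: float

    @property
    def recommended_n_hidden(self) -> int | None:
        """Largest n_hidden with one group per unit and noise below threshold."""
        ok = self.table[(self.table.n_groups == self.table.n_hidden)
                        & (self.table.noise_fraction <= self.noise_threshold)]
        return int(ok.n_hidden.max()) if len(ok) else None


def scan_model_complexity(samples: np.ndarray, n_hidden_values, config: TrainConfig,
                          n_realizations: int, eps="auto", min_samples="auto",
                          sign_align: bool = True,
                          noise_threshold: float = 0.1,
                          keep_models: bool = False) -> ComplexityScan:
    """Train an ensemble at each hidden-layer size and summarise its coherence.

    For each ``n_hidden`` the scan reports the number of unit groups, the
    noise fraction and the ensemble-mean train/validation PLL (evaluated
    exactly on each realization's own split).  The recommended size is the
    largest one whose group count equals ``n_hidden`` with noise below
    ``noise_threshold`` — the most complex model the ensemble still agrees
    on.
    """
    n_hidden_values = list(n_hidden_values)
    if not n_hidden_values:
        raise ValueError("n_hidden_values must be nonempty")
    rows = []
    kept = {}
    for nh in n_hidden_values:
        models = train_ensemble(samples, nh, config, n_realizations)
        units = collect_units(models)
        d, s = unit_distance_matrix(units, sign_align=sign_align)
        clustering = cluster_units(d, s, eps=eps, min_samples=min_samples,
                                   n_realizations=len(models))
        pll_t, pll_v = _ensemble_plls(models, samples, config)
        rows.append({
            "n_hidden": nh,
            "n_groups": clustering.n_groups,
            "noise_fraction": clustering.noise_fraction,
            "pll_train": pll_t,
            "pll_valid": pll_v,
            "n_realizations": len(models),
        })
        if keep_models:
            kept[nh] = (models, units, clustering)
    scan = ComplexityScan(pd.DataFrame(rows), noise_threshold)
    if keep_models:
        scan.models = kept
    return scan


def _ensemble_plls(models: list[TrainedRBM], samples: np.ndarray,
                   config: TrainConfig) -> tuple[float, float]:
    """Mean exact train/valid PLL over realizations, on their own splits."""
    pt, pv = [], []
    for m in models:
        split = split_train_valid(samples, seed=m.split_seed)
        pt.append(pseudo_log_likelihood(m.params, split.train))
        pv.append(pseudo_log_likelihood(m.params, split.valid))
    return float(np.mean(pt)), float(np.mean(pv))
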