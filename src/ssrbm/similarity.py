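"""Amino-acid similarity from learned weights: PCA and hydrophobicity.

Each hidden-unit group of an average RBM assigns every amino acid a row of
``gamma`` weights (its coupling to that unit at each position).  Treating
the 20 amino acids as observations and the ``gamma`` positions as
variables, a PCA of this 20 x gamma matrix places the amino acids on a
plane where the first component captures how strongly each residue commits
to one side of the polar/nonpolar alternation — an *effective
hydrophobicity*.  The component sign is arbitrary, so PC1 is oriented to
correlate positively with a reference hydrophobicity scale; the default
shipped scale is the Fauchere-Pliska (1983) octanol/water side-chain
partition scale (pi values, unitless; Trp most hydrophobic, Arg/Lys
least), replaceable by any two-column residue/value TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.decomposition import PCA

from .ensemble import AverageRBM
from .ingest import AMINO_ACIDS, N_ALPHABET

DEFAULT_SCALE_RESOURCE = "fauchere_pliska_1983.tsv"


@dataclass
class GroupPCA:
    """PCA of one group's 20 x gamma amino-acid weight matrix.

    ``coords`` holds the PC1/PC2 scores for the 20 amino acids in fixed
    alphabetical order; ``explained`` the variance fraction of every
    component (summing to 1); ``orientation`` the sign applied to PC1 by
    :func:`orient_and_correlate` (+1 until then); ``degenerate`` flags an
    all-rows-equal input, for which all scores are zero.
    """

    coords: np.ndarray  # (20, 2)
    explained: np.ndarray  # (n_components_total,)
    group_id: int = 0
    orientation: int = 1
    degenerate: bool = False


@dataclass
class HydroScale:
    """A per-amino-acid hydrophobicity scale (values in scale units)."""

    name: str
    values: np.ndarray  # (20,), alphabetical residue order

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_ALPHABET,):
            raise ValueError("scale must cover exactly the 20 canonical residues")


def load_hydro_scale(path=None) -> HydroScale:
    """Load a residue/value TSV scale; default is the shipped octanol scale."""
    if path is None:
        ref = resources.files("ssrbm.data") / DEFAULT_SCALE_RESOURCE
        with resources.as_file(ref) as p:
            return load_hydro_scale(p)
    df = pd.read_csv(path, sep="\t")
    series = df.set_index("residue")["value"]
    missing = set(AMINO_ACIDS) - set(series.index)
    if missing:
        raise ValueError(f"scale is missing residues: {sorted(missing)}")
    return HydroScale(str(getattr(path, "stem", path)),
                      series.reindex(list(AMINO_ACIDS)).to_numpy())


# ---------------------------------------------------------------------------
# Weight matrices and PCA
# ---------------------------------------------------------------------------

def amino_acid_weight_matrix(arbm: AverageRBM, group_id: int) -> np.ndarray:
    """Reshape a group's weight vector to a (20, gamma) residue-by-position matrix.

    Visible index ``20*g + k`` maps to entry ``(k, g)``: row = amino acid in
    alphabetical order, column = position.
    """
    if not 1 <= group_id <= arbm.n_groups:
        raise ValueError(f"unknown group {group_id} (have 1..{arbm.n_groups})")
    return arbm.group_weights[group_id - 1].reshape(-1, N_ALPHABET).T


def group_pca(matrix: np.ndarray, member_matrices=None, group_id: int = 0) -> GroupPCA:
    """PCA of a residue-by-position weight matrix.

    Amino acids are the 20 observations and the ``gamma`` positions the
    variables; columns are mean-centered.  When the per-member matrices of
    the group's units are supplied, the reported explained-variance
    fractions are the mean of the members' own fractions; otherwise they
    come from the averaged matrix itself.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != N_ALPHABET:
        raise ValueError("expected a (20, gamma) matrix")
    if m.shape[1] < 2:
        raise ValueError("need gamma >= 2 for a two-component PCA")
    if np.allclose(m, m[0]):
        return GroupPCA(np.zeros((N_ALPHABET, 2)), np.zeros(m.shape[1]),
                        group_id=group_id, degenerate=True)
    pca = PCA(n_components=None).fit(m)
    scores = pca.transform(m)
    coords = np.zeros((N_ALPHABET, 2))
    coords[:, :min(2, scores.shape[1])] = scores[:, :2]
    if member_matrices is not None:
        fractions = [PCA(n_components=None).fit(np.asarray(mm, dtype=float))
                     .explained_variance_ratio_ for mm in member_matrices]
        width = max(len(f) for f in fractions)
        padded = np.zeros((len(fractions), width))
        for i, f in enumerate(fractions):
            padded[i, :len(f)] = f
        explained = padded.mean(axis=0)
    else:
        explained = pca.explained_variance_ratio_
    return GroupPCA(coords, np.asarray(explained), group_id=group_id)


def orient_and_correlate(pca: GroupPCA, scale: HydroScale) -> tuple[GroupPCA, float]:
    """Fix the PC1 sign against a hydrophobicity scale and report Pearson r.

    PC1 is flipped if its correlation with the scale is negative, so the
    returned r is non-negative; the applied sign is recorded in
    ``orientation`` (the raw r is ``orientation * r``).
    """
    pc1 = pca.coords[:, 0]
    if np.allclose(pc1, pc1[0]):
        raise ValueError("PC1 is constant; correlation undefined")
    r = float(pearsonr(pc1, scale.values)[0])
    orientation = -1 if r < 0 else 1
    coords = pca.coords.copy()
    coords[:, 0] *= orientation
    oriented = replace(pca, coords=coords, orientation=orientation)
    return oriented, abs(r)


def pca_frame(pca: GroupPCA) -> pd.DataFrame:
    """The PC scores as a tidy table (residue, pc1, pc2)."""
    return pd.DataFrame({"residue": list(AMINO_ACIDS),
                         "pc1": pca.coords[:, 0], "pc2": pca.coords[:, 1]})
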