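"""Sequence ingestion: DSSP parsing, boundary-stretch extraction, spin encoding.

The analysis operates on fixed-length stretches of ``gamma`` residues taken
from the start or end of secondary-structure elements (alpha-helices, DSSP
code ``H``; beta-strands, code ``E``).  Each stretch is encoded as a
``20 * gamma``-digit spin vector: one block of 20 sites per position, with a
single ``+1`` at the alphabetical index of the residue and ``-1`` elsewhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical amino-acid alphabet, alphabetical one-letter order.  This fixed
#: order defines the row indexing of every 20 x gamma table in the package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
N_ALPHABET = 20

#: Mapping from element kind to the DSSP code defining it.  Strict codes
#: only: 3-10 (G) and pi (I) helices and beta-bridges (B) are excluded.
ELEMENT_CODES = {"helix": "H", "strand": "E"}

STRETCH_COLUMNS = ["protein_id", "element_kind", "terminus", "sequence", "element_length"]


class DSSPParseError(ValueError):
    """Raised when a DSSP file cannot be parsed."""


class EncodingError(ValueError):
    """Raised when a stretch contains a residue outside the canonical alphabet."""


@dataclass(frozen=True)
class ResidueStretch:
    """A ``gamma``-residue window at one terminus of a secondary-structure element."""

    protein_id: str
    element_kind: str  # "helix" | "strand"
    terminus: str  # "start" | "end"
    residues: str  # gamma one-letter codes, N->C order
    element_length: int  # length of the source element, in residues

    def __post_init__(self) -> None:
        if self.element_kind not in ELEMENT_CODES:
            raise ValueError(f"unknown element kind {self.element_kind!r}")
        if self.terminus not in ("start", "end"):
            raise ValueError(f"unknown terminus {self.terminus!r}")
        if self.element_length < len(self.residues):
            raise ValueError("element_length shorter than the stretch itself")


@dataclass(frozen=True)
class ChainSegment:
    """A break-free stretch of one chain: sequence and per-residue SS codes."""

    protein_id: str
    chain_id: str
    sequence: str
    ss_codes: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.ss_codes):
            raise ValueError("sequence and SS annotation differ in length")


# ---------------------------------------------------------------------------
# DSSP parsing (classic column-formatted dialect)
# ---------------------------------------------------------------------------

def parse_secondary_structure(text: str, protein_id: str = "") -> list[ChainSegment]:
    """Parse classic column-formatted DSSP output into per-chain segments.

    Chain changes and chain-break records (``!`` in the amino-acid column)
    both terminate the current segment, so no extracted element can ever
    span a break.  Lowercase amino-acid letters (DSSP's convention for
    disulfide-bonded cysteines) are mapped to ``C``.  Unknown SS codes are
    kept verbatim and simply never match an element code.

    Parameters
    ----------
    text:
        Full contents of a ``.dssp`` file.
    protein_id:
        Identifier stored on the returned segments.

    Returns
    -------
    list of :class:`ChainSegment`, in file order.
    """
    lines = text.splitlines()
    if not any(line.strip() for line in lines):
        raise DSSPParseError("empty DSSP file")

    header_idx = None
    for i, line in enumerate(lines):
        if line.lstrip().startswith("#") and "RESIDUE" in line and "AA" in line:
            header_idx = i
            break
    if header_idx is None:
        raise DSSPParseError("no '#  RESIDUE AA ...' header line found")

    segments: list[ChainSegment] = []
    seq: list[str] = []
    ss: list[str] = []
    chain = ""

    def flush() -> None:
        nonlocal seq, ss
        if seq:
            segments.append(ChainSegment(protein_id, chain, "".join(seq), "".join(ss)))
        seq, ss = [], []

    for lineno, line in enumerate(lines[header_idx + 1:], start=header_idx + 2):
        if not line.strip():
            continue
        if len(line) < 17:
            raise DSSPParseError(f"truncated DSSP record at line {lineno}")
        aa = line[13]
        if aa == "!":
            flush()
            continue
        if aa.islower():  # disulfide-bonded cysteine
            aa = "C"
        new_chain = line[11].strip()
        if seq and new_chain != chain:
            flush()
        chain = new_chain
        seq.append(aa)
        code = line[16]
        ss.append(code if code != " " else "-")
    flush()
    return segments


# ---------------------------------------------------------------------------
# Stretch extraction
# ---------------------------------------------------------------------------

def _runs(ss_codes: str, code: str):
    """Yield 0-based half-open (start, stop) spans of maximal runs of `code`."""
    i, n = 0, len(ss_codes)
    while i < n:
        if ss_codes[i] == code:
            j = i
            while j < n and ss_codes[j] == code:
                j += 1
            yield i, j
            i = j
        else:
            i += 1


def extract_stretches(
    segments: list[ChainSegment],
    element_kind: str,
    terminus: str,
    gamma: int = 5,
    report: dict | None = None,
) -> list[ResidueStretch]:
    """Extract the first or last ``gamma`` residues of every qualifying element.

    A qualifying element is a maximal run of the element's DSSP code with
    length >= ``gamma`` inside a single break-free chain segment.  Stretches
    containing residues outside the 20-letter alphabet are dropped; their
    count is logged and recorded under ``report["rejected"]`` if a dict is
    supplied.
    """
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    code = ELEMENT_CODES[element_kind]
    if terminus not in ("start", "end"):
        raise ValueError(f"unknown terminus {terminus!r}")

    stretches: list[ResidueStretch] = []
    rejected = 0
    for seg in segments:
        for start, stop in _runs(seg.ss_codes, code):
            length = stop - start
            if length < gamma:
                continue
            if terminus == "start":
                window = seg.sequence[start:start + gamma]
            else:
                window = seg.sequence[stop - gamma:stop]
            if any(aa not in AA_INDEX for aa in window):
                rejected += 1
                continue
            stretches.append(
                ResidueStretch(seg.protein_id, element_kind, terminus, window, length)
            )
    if rejected:
        logger.info(
            "dropped %d %s-%s stretches containing non-canonical residues",
            rejected, element_kind, terminus,
        )
    if report is not None:
        report["rejected"] = report.get("rejected", 0) + rejected
    return stretches


# ---------------------------------------------------------------------------
# Spin encoding
# ---------------------------------------------------------------------------

def block_slice(position: int) -> slice:
    """Visible-site slice for residue position ``position`` (0-based)."""
    return slice(N_ALPHABET * position, N_ALPHABET * (position + 1))


def encode_one_hot(sequence: str) -> np.ndarray:
    """Encode a residue string as a ``20*gamma`` spin vector in {-1, +1}.

    Block ``g`` carries ``+1`` at the alphabetical index of residue ``g``
    and ``-1`` at the other 19 sites.
    """
    values = np.full(N_ALPHABET * len(sequence), -1, dtype=np.int8)
    for g, aa in enumerate(sequence):
        k = AA_INDEX.get(aa)
        if k is None:
            raise EncodingError(f"non-canonical residue {aa!r} at position {g + 1}")
        values[N_ALPHABET * g + k] = 1
    return values


def decode_one_hot(values: np.ndarray) -> str:
    """Invert :func:`encode_one_hot`."""
    values = np.asarray(values)
    if values.ndim != 1 or values.size % N_ALPHABET:
        raise ValueError("spin vector length must be a multiple of 20")
    blocks = values.reshape(-1, N_ALPHABET)
    if not np.all(blocks.sum(axis=1) == 2 - N_ALPHABET):
        raise ValueError("not a valid one-hot spin vector (block sums != 2 - 20)")
    return "".join(AMINO_ACIDS[k] for k in blocks.argmax(axis=1))


def encode_sequences(sequences) -> np.ndarray:
    """Encode an iterable of equal-length residue strings as an (n, 20*gamma) array."""
    seqs = list(sequences)
    if not seqs:
        return np.empty((0, 0), dtype=np.int8)
    gamma = len(seqs[0])
    out = np.empty((len(seqs), N_ALPHABET * gamma), dtype=np.int8)
    for i, s in enumerate(seqs):
        if len(s) != gamma:
            raise EncodingError("sequences have unequal lengths")
        out[i] = encode_one_hot(s)
    return out


def decode_samples(samples: np.ndarray) -> list[str]:
    """Decode an (n, 20*gamma) spin array back to residue strings."""
    return [decode_one_hot(row) for row in np.asarray(samples)]


# ---------------------------------------------------------------------------
# Train / validation split
# ---------------------------------------------------------------------------

@dataclass
class DatasetSplit:
    """A reproducible random partition of encoded samples."""

    train: np.ndarray
    valid: np.ndarray
    train_idx: np.ndarray = field(repr=False, default=None)
    valid_idx: np.ndarray = field(repr=False, default=None)
    split_seed: int = 0
    fraction: float = 0.8


def split_train_valid(samples: np.ndarray, fraction: float = 0.8, seed: int = 0) -> DatasetSplit:
    """Uniform random train/validation partition, reproducible from ``seed``."""
    samples = np.asarray(samples)
    n = samples.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = min(max(int(round(n * fraction)), 1), n - 1)
    train_idx = np.sort(perm[:n_train])
    valid_idx = np.sort(perm[n_train:])
    return DatasetSplit(
        train=samples[train_idx],
        valid=samples[valid_idx],
        train_idx=train_idx,
        valid_idx=valid_idx,
        split_seed=seed,
        fraction=fraction,
    )


# ---------------------------------------------------------------------------
# Stretch tables on disk
# ---------------------------------------------------------------------------

def stretches_to_frame(stretches: list[ResidueStretch]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.protein_id, s.element_kind, s.terminus, s.residues, s.element_length)
         for s in stretches],
        columns=STRETCH_COLUMNS,
    )


def read_stretch_table(path) -> pd.DataFrame:
    """Read a stretch table TSV (columns: protein_id, element_kind, terminus,
    sequence[, element_length])."""
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str})
    missing = {"sequence"} - set(df.columns)
    if missing:
        raise ValueError(f"stretch table missing columns: {sorted(missing)}")
    return df


def write_stretch_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
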