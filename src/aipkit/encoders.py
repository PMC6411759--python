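"""Fixed-dimension feature encodings for padded peptides.

Five encoders are provided, each producing one vector per peptide with a
dimension independent of peptide length:

========  ======================================================  =========
encoder   input                                                   dimension
========  ======================================================  =========
KSAAP     padded sequence (25 symbols)                            2000
pKSAAP    PSSM profile (L x 20 log-odds matrix)                   2000
AAindex   padded sequence + physicochemical index table (8 x 20)  200
SPIDER2   per-residue structural table (8 channels)               200
PEP2D     per-residue secondary-structure probabilities           75
========  ======================================================  =========

KSAAP is the composition of k-spaced amino-acid pairs: for each spacing
k = 0..k_max and each ordered residue pair (a, b), the fraction of valid
(i, i+k+1) index pairs whose symbols are a and b.  Pairs touching a gap are
excluded from both numerator and denominator, so the composition is
invariant to the amount of gap padding and each k-block sums to 1 whenever
any valid pair exists.  pKSAAP applies the same construction to a
position-specific scoring matrix: raw scores are squashed to [0, 1] by the
logistic map and the pair count is replaced by the mean of position-wise
products, capturing evolutionary conservation rather than the literal
sequence.

Residue pairs are ordered lexicographically (AA, AC, ..., YY) over the
alphabetical amino-acid order, and k-blocks are concatenated in increasing
k; these orders are frozen so fitted models are portable.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, TransformerMixin

from .peptide_io import AMINO_ACIDS, GAP, WINDOW, PeptideRecord, pad_peptide

log = logging.getLogger(__name__)

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_AA = len(AMINO_ACIDS)

#: PSI-BLAST writes PSSM columns in this residue order; profiles are
#: re-ordered to alphabetical (`AMINO_ACIDS`) on parse.
PSIBLAST_COLUMN_ORDER = "ARNDCQEGHILKMFPSTWYV"

SPIDER2_CHANNELS = ("ASA", "phi", "psi", "theta", "tau", "coil", "strand", "helix")
PEP2D_CHANNELS = ("helix_prob", "sheet_prob", "coil_prob")
_ANGLE_CHANNELS = frozenset({"phi", "psi", "theta", "tau"})


class EncodingError(ValueError):
    """Invalid input to a feature encoder or table reader."""


def ksaap_feature_names(k_max: int = 4) -> list[str]:
    """Motif-style names for the KSAAP/pKSAAP columns, e.g. ``LxL`` for k=1 'LL'."""
    return [
        f"{a}{'x' * k}{b}"
        for k in range(k_max + 1)
        for a in AMINO_ACIDS
        for b in AMINO_ACIDS
    ]


# ---------------------------------------------------------------------------
# KSAAP
# ---------------------------------------------------------------------------

def encode_ksaap(padded: str, k_max: int = 4) -> np.ndarray:
    """Composition of k-spaced amino-acid pairs of a padded peptide.

    For each k in ``0..k_max`` the block entry for ordered pair (a, b) is
    ``count{i: padded[i]=a, padded[i+k+1]=b, both non-gap} / n_valid_pairs(k)``;
    a block with no valid pair is all zeros.
    """
    if k_max < 0:
        raise EncodingError("k_max must be >= 0")
    if k_max + 2 > len(padded):
        raise EncodingError(
            f"k_max={k_max} needs windows of k_max+2={k_max + 2} symbols, "
            f"but the padded length is {len(padded)}"
        )
    out = np.zeros((k_max + 1, N_AA, N_AA))
    for k in range(k_max + 1):
        valid = 0
        for i in range(len(padded) - k - 1):
            a, b = padded[i], padded[i + k + 1]
            if a == GAP or b == GAP:
                continue
            try:
                out[k, AA_INDEX[a], AA_INDEX[b]] += 1.0
            except KeyError as exc:
                raise EncodingError(f"non-standard symbol {exc.args[0]!r}") from None
            valid += 1
        if valid:
            out[k] /= valid
    return out.reshape(-1)


# ---------------------------------------------------------------------------
# AAindex
# ---------------------------------------------------------------------------

# Default physicochemical index table (8 scales x 20 residues).  These are
# standard published scales shipped as a usable default; any 8-row table can
# be substituted via AAIndexTable.from_tsv.
_DEFAULT_AAINDEX_ROWS = {
    # Kyte-Doolittle hydropathy
    "hydropathy": {
        "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
        "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
        "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
        "W": -0.9, "Y": -1.3,
    },
    # Hopp-Woods hydrophilicity
    "hydrophilicity": {
        "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
        "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
        "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
        "W": -3.4, "Y": -2.3,
    },
    # Grantham polarity
    "polarity": {
        "A": 8.1, "C": 5.5, "D": 13.0, "E": 12.3, "F": 5.2, "G": 9.0,
        "H": 10.4, "I": 5.2, "K": 11.3, "L": 4.9, "M": 5.7, "N": 11.6,
        "P": 8.0, "Q": 10.5, "R": 10.5, "S": 9.2, "T": 8.6, "V": 5.9,
        "W": 5.4, "Y": 6.2,
    },
    # residue side-chain volume (A^3)
    "volume": {
        "A": 88.6, "C": 108.5, "D": 111.1, "E": 138.4, "F": 189.9, "G": 60.1,
        "H": 153.2, "I": 166.7, "K": 168.6, "L": 166.7, "M": 162.9, "N": 114.1,
        "P": 112.7, "Q": 143.8, "R": 173.4, "S": 89.0, "T": 116.1, "V": 140.0,
        "W": 227.8, "Y": 193.6,
    },
    # isoelectric point of the free amino acid
    "isoelectric_point": {
        "A": 6.00, "C": 5.07, "D": 2.77, "E": 3.22, "F": 5.48, "G": 5.97,
        "H": 7.59, "I": 6.02, "K": 9.74, "L": 5.98, "M": 5.74, "N": 5.41,
        "P": 6.30, "Q": 5.65, "R": 10.76, "S": 5.68, "T": 5.60, "V": 5.96,
        "W": 5.89, "Y": 5.66,
    },
    # Chou-Fasman alpha-helix propensity
    "helix_propensity": {
        "A": 1.42, "C": 0.70, "D": 1.01, "E": 1.51, "F": 1.13, "G": 0.57,
        "H": 1.00, "I": 1.08, "K": 1.16, "L": 1.21, "M": 1.45, "N": 0.67,
        "P": 0.57, "Q": 1.11, "R": 0.98, "S": 0.77, "T": 0.83, "V": 1.06,
        "W": 1.08, "Y": 0.69,
    },
    # Chou-Fasman beta-sheet propensity
    "sheet_propensity": {
        "A": 0.83, "C": 1.19, "D": 0.54, "E": 0.37, "F": 1.38, "G": 0.75,
        "H": 0.87, "I": 1.60, "K": 0.74, "L": 1.30, "M": 1.05, "N": 0.89,
        "P": 0.55, "Q": 1.10, "R": 0.93, "S": 0.75, "T": 1.19, "V": 1.70,
        "W": 1.37, "Y": 1.47,
    },
    # net side-chain charge at pH 7
    "charge": {
        "A": 0.0, "C": 0.0, "D": -1.0, "E": -1.0, "F": 0.0, "G": 0.0,
        "H": 0.1, "I": 0.0, "K": 1.0, "L": 0.0, "M": 0.0, "N": 0.0,
        "P": 0.0, "Q": 0.0, "R": 1.0, "S": 0.0, "T": 0.0, "V": 0.0,
        "W": 0.0, "Y": 0.0,
    },
}


@dataclass
class AAIndexTable:
    """Physicochemical index table: one row per index, one column per residue.

    ``values`` is an (n_indices x 20) DataFrame with residue columns in
    alphabetical order.  ``scaled`` records whether rows were min-max scaled
    to [0, 1].
    """

    values: pd.DataFrame
    scaled: bool = False

    def __post_init__(self) -> None:
        missing = [aa for aa in AMINO_ACIDS if aa not in self.values.columns]
        if missing:
            raise EncodingError(f"index table lacks residue column(s) {missing}")
        self.values = self.values.loc[:, list(AMINO_ACIDS)].astype(float)
        if self.values.isna().any().any():
            raise EncodingError("index table contains missing values")

    @property
    def index_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_indices(self) -> int:
        return len(self.values)

    def minmax_scaled(self) -> "AAIndexTable":
        v = self.values
        rng = v.max(axis=1) - v.min(axis=1)
        rng = rng.replace(0.0, 1.0)
        return AAIndexTable(values=v.sub(v.min(axis=1), axis=0).div(rng, axis=0),
                            scaled=True)

    @classmethod
    def default(cls, scaled: bool = True) -> "AAIndexTable":
        table = cls(values=pd.DataFrame(_DEFAULT_AAINDEX_ROWS).T)
        return table.minmax_scaled() if scaled else table

    @classmethod
    def from_tsv(cls, path: str | Path, scaled: bool = False) -> "AAIndexTable":
        """Read ``index_id`` + 20 residue columns from TSV."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        table = cls(values=df)
        return table.minmax_scaled() if scaled else table

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="index_id")

    def lookup(self, residue: str) -> np.ndarray:
        if residue not in self.values.columns:
            raise EncodingError(f"residue {residue!r} missing from index table")
        return self.values[residue].to_numpy()


def encode_aaindex(padded: str, table: AAIndexTable) -> np.ndarray:
    """Position-major AAindex encoding: per position, the table's index values
    of the residue there; gap positions contribute zeros.  Dimension
    ``window x n_indices`` (200 with the default 8-index table).
    """
    out = np.zeros((len(padded), table.n_indices))
    for i, ch in enumerate(padded):
        if ch != GAP:
            out[i] = table.lookup(ch)
    return out.reshape(-1)


# ---------------------------------------------------------------------------
# PSSM / pKSAAP
# ---------------------------------------------------------------------------

@dataclass
class PSSMProfile:
    """Parsed position-specific scoring matrix for one peptide.

    ``matrix`` is L x 20 with columns in alphabetical residue order
    (`AMINO_ACIDS`); ``sequence`` is the residue string the profile belongs
    to (parsed from the row labels where available).
    """

    peptide_id: str
    matrix: np.ndarray
    sequence: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != N_AA:
            raise EncodingError(
                f"PSSM for {self.peptide_id!r} must be L x {N_AA}, "
                f"got {self.matrix.shape}"
            )
        if self.matrix.shape[0] == 0:
            raise EncodingError(f"PSSM for {self.peptide_id!r} has no rows")
        if not np.isfinite(self.matrix).all():
            raise EncodingError(f"PSSM for {self.peptide_id!r} has non-finite cells")

    @property
    def length(self) -> int:
        return int(self.matrix.shape[0])

    def squashed(self) -> np.ndarray:
        """Logistic squashing 1 / (1 + exp(-x)) applied elementwise."""
        return expit(self.matrix)

    @classmethod
    def one_hot(cls, record: PeptideRecord) -> "PSSMProfile":
        """Degenerate self-profile: 1 at the observed residue, 0 elsewhere.

        Stored as squashed values directly (see `encode_pksaap`); used as the
        documented fallback when no PSI-BLAST profile is available, under
        which pKSAAP reduces exactly to KSAAP.
        """
        m = np.zeros((record.raw_length, N_AA))
        for i, ch in enumerate(record.sequence):
            m[i, AA_INDEX[ch]] = 1.0
        prof = cls.__new__(cls)
        prof.peptide_id = record.id
        prof.matrix = m
        prof.sequence = record.sequence
        prof._presquashed = True
        return prof


def _looks_like_aa_header(tokens: list[str]) -> bool:
    heads = tokens[:N_AA]
    return len(heads) >= N_AA and all(t in AA_INDEX for t in heads) and (
        len(set(heads)) == N_AA
    )


def read_pssm(path: str | Path, peptide_id: str | None = None) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM file into an L x 20 profile.

    The first 20 score columns (log-odds) of each position row are read; the
    residue column order is taken from the header line and re-ordered to
    alphabetical.  Malformed rows (wrong width, non-numeric cells) raise
    :class:`EncodingError`.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header_order: str | None = None
    rows: list[list[float]] = []
    seq_chars: list[str] = []
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if not tokens:
            if rows:
                break  # blank line ends the matrix section
            continue
        if header_order is None:
            if _looks_like_aa_header(tokens):
                header_order = "".join(tokens[:N_AA])
            continue
        if not tokens[0].lstrip("-").isdigit():
            break  # footer (Lambda/K statistics)
        if len(tokens) < 2 + N_AA:
            raise EncodingError(
                f"{path}:{lineno}: expected at least {2 + N_AA} columns "
                f"(position, residue, 20 scores), got {len(tokens)}"
            )
        residue = tokens[1]
        try:
            scores = [float(t) for t in tokens[2:2 + N_AA]]
        except ValueError as exc:
            raise EncodingError(f"{path}:{lineno}: non-numeric score cell ({exc})")
        rows.append(scores)
        seq_chars.append(residue if residue in AA_INDEX else "")
    if header_order is None:
        raise EncodingError(f"{path}: no residue-order header line found")
    if not rows:
        raise EncodingError(f"{path}: empty matrix section")
    raw = np.asarray(rows)
    order = [header_order.index(aa) for aa in AMINO_ACIDS]
    matrix = raw[:, order]
    return PSSMProfile(
        peptide_id=peptide_id or path.stem,
        matrix=matrix,
        sequence="".join(seq_chars) if all(seq_chars) else "",
    )


def write_pssm(profile: PSSMProfile, path: str | Path) -> None:
    """Write a profile in the PSI-BLAST ASCII layout (scores to 3 decimals)."""
    buf = io.StringIO()
    buf.write("\n")
    buf.write(
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts\n"
    )
    buf.write("      " + "".join(f"{aa:>9}" for aa in PSIBLAST_COLUMN_ORDER) + "\n")
    order = [AA_INDEX[aa] for aa in PSIBLAST_COLUMN_ORDER]
    seq = profile.sequence or "X" * profile.length
    for i in range(profile.length):
        row = profile.matrix[i, order]
        cells = "".join(f"{v:9.3f}" for v in row)
        buf.write(f"{i + 1:>4} {seq[i] if seq[i] in AA_INDEX else 'A'}{cells}\n")
    buf.write("\n")
    Path(path).write_text(buf.getvalue())


def encode_pksaap(profile: PSSMProfile, k_max: int = 4) -> np.ndarray:
    """Profile-based k-spaced pair composition (pKSAAP).

    Raw scores are squashed by the logistic map to M in [0, 1]; the block
    entry for spacing k and ordered pair (a, b) is
    ``sum_i M[i, a] * M[i+k+1, b] / (L - k - 1)``; k-blocks with no valid
    position pair are zeros.  Dimension matches `encode_ksaap`.
    """
    if k_max < 0:
        raise EncodingError("k_max must be >= 0")
    M = profile.matrix if getattr(profile, "_presquashed", False) else profile.squashed()
    L = profile.length
    out = np.zeros((k_max + 1, N_AA, N_AA))
    for k in range(k_max + 1):
        n_pairs = L - k - 1
        if n_pairs <= 0:
            continue
        out[k] = (M[:n_pairs].T @ M[k + 1:]) / n_pairs
    return out.reshape(-1)


# ---------------------------------------------------------------------------
# Structural tables
# ---------------------------------------------------------------------------

@dataclass
class StructuralTable:
    """Per-residue structural channels from an external structure predictor.

    Two flavors: ``SPIDER2`` (ASA, four backbone torsion angles, three
    secondary-structure probabilities) and ``PEP2D`` (helix/sheet/coil
    probabilities, each row summing to 1).
    """

    peptide_id: str
    flavor: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        channels = self.channels_for(self.flavor)
        missing = [c for c in channels if c not in self.values.columns]
        if missing:
            raise EncodingError(
                f"{self.flavor} table for {self.peptide_id!r} lacks channel(s) {missing}"
            )
        self.values = self.values.loc[:, list(channels)].astype(float)
        if self.values.isna().any().any():
            raise EncodingError(f"structural table {self.peptide_id!r} has missing cells")
        if self.flavor == "PEP2D":
            sums = self.values.to_numpy().sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise EncodingError(
                    f"PEP2D rows for {self.peptide_id!r} must each sum to 1 "
                    f"(found sums in [{sums.min():.6f}, {sums.max():.6f}])"
                )

    @staticmethod
    def channels_for(flavor: str) -> tuple[str, ...]:
        if flavor == "SPIDER2":
            return SPIDER2_CHANNELS
        if flavor == "PEP2D":
            return PEP2D_CHANNELS
        raise EncodingError(f"unknown structural flavor {flavor!r}")

    @property
    def n_residues(self) -> int:
        return len(self.values)

    @classmethod
    def from_tsv(cls, path: str | Path, flavor: str,
                 peptide_id: str | None = None) -> "StructuralTable":
        df = pd.read_csv(path, sep="\t")
        drop = [c for c in df.columns if c.lower() in ("pos", "position", "residue", "aa")]
        return cls(peptide_id=peptide_id or Path(path).stem, flavor=flavor,
                   values=df.drop(columns=drop))

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "position", np.arange(1, len(out) + 1))
        out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def encode_structural(table: StructuralTable, window: int = WINDOW) -> np.ndarray:
    """Position-major flattening of a structural table over a fixed window.

    Missing positions are zero-filled; tables longer than the window are
    truncated with a warning.  Angle channels (phi/psi/theta/tau) are
    rescaled to [-1, 1] by dividing by 180.
    """
    values = table.values
    if len(values) > window:
        warnings.warn(
            f"structural table {table.peptide_id!r} has {len(values)} rows; "
            f"truncating to {window}",
            stacklevel=2,
        )
        values = values.iloc[:window]
    arr = values.to_numpy(dtype=float).copy()
    for j, ch in enumerate(values.columns):
        if ch in _ANGLE_CHANNELS:
            arr[:, j] /= 180.0
    out = np.zeros((window, arr.shape[1]))
    out[: arr.shape[0]] = arr
    return out.reshape(-1)


# ---------------------------------------------------------------------------
# scikit-learn transformer wrappers
# ---------------------------------------------------------------------------

def _as_padded(X: Iterable) -> list[str]:
    padded = []
    for x in X:
        if isinstance(x, PeptideRecord):
            padded.append(x.padded())
        else:
            padded.append(pad_peptide(str(x)) if len(str(x)) < WINDOW else str(x)[:WINDOW])
    return padded


class KSAAPEncoder(TransformerMixin, BaseEstimator):
    """Transform peptides into k-spaced amino-acid pair compositions."""

    def __init__(self, k_max: int = 4):
        self.k_max = k_max

    def fit(self, X, y=None):
        self.n_features_out_ = (self.k_max + 1) * N_AA * N_AA
        return self

    def transform(self, X) -> np.ndarray:
        return np.array([encode_ksaap(p, k_max=self.k_max) for p in _as_padded(X)])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(ksaap_feature_names(self.k_max), dtype=object)


class AAIndexEncoder(TransformerMixin, BaseEstimator):
    """Transform peptides into positionwise physicochemical index vectors."""

    def __init__(self, table: AAIndexTable | None = None):
        self.table = table

    def fit(self, X, y=None):
        self.table_ = self.table if self.table is not None else AAIndexTable.default()
        self.n_features_out_ = WINDOW * self.table_.n_indices
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "table_"):
            self.fit(X)
        return np.array([encode_aaindex(p, self.table_) for p in _as_padded(X)])

    def get_feature_names_out(self, input_features=None):
        table = self.table if self.table is not None else AAIndexTable.default()
        return np.asarray(
            [f"p{i + 1}|{idx}" for i in range(WINDOW) for idx in table.index_ids],
            dtype=object,
        )


class PSSMKSAAPEncoder(TransformerMixin, BaseEstimator):
    """Transform PSSM profiles (or bare peptides, via the documented one-hot
    fallback) into pKSAAP vectors."""

    def __init__(self, k_max: int = 4):
        self.k_max = k_max

    def fit(self, X, y=None):
        self.n_features_out_ = (self.k_max + 1) * N_AA * N_AA
        return self

    def transform(self, X) -> np.ndarray:
        vectors = []
        fell_back = 0
        for x in X:
            if isinstance(x, PSSMProfile):
                prof = x
            elif isinstance(x, PeptideRecord):
                prof = PSSMProfile.one_hot(x)
                fell_back += 1
            else:
                raise EncodingError(
                    "PSSMKSAAPEncoder expects PSSMProfile or PeptideRecord inputs"
                )
            vectors.append(encode_pksaap(prof, k_max=self.k_max))
        if fell_back:
            log.warning(
                "pKSAAP: %d peptide(s) had no PSSM profile; used one-hot "
                "self-profiles (pKSAAP == KSAAP for those)", fell_back
            )
        return np.array(vectors)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(
            [f"pssm:{n}" for n in ksaap_feature_names(self.k_max)], dtype=object
        )


class StructuralEncoder(TransformerMixin, BaseEstimator):
    """Transform per-residue structural tables into fixed-window vectors."""

    def __init__(self, flavor: str = "SPIDER2"):
        self.flavor = flavor

    def fit(self, X, y=None):
        self.channels_ = StructuralTable.channels_for(self.flavor)
        self.n_features_out_ = WINDOW * len(self.channels_)
        return self

    def transform(self, X) -> np.ndarray:
        out = []
        for t in X:
            if not isinstance(t, StructuralTable):
                raise EncodingError("StructuralEncoder expects StructuralTable inputs")
            if t.flavor != self.flavor:
                raise EncodingError(
                    f"table flavor {t.flavor!r} does not match encoder {self.flavor!r}"
                )
            out.append(encode_structural(t))
        return np.array(out)

    def get_feature_names_out(self, input_features=None):
        chans = StructuralTable.channels_for(self.flavor)
        return np.asarray(
            [f"p{i + 1}|{c}" for i in range(WINDOW) for c in chans], dtype=object
        )


def build_feature_matrices(
    records: Sequence[PeptideRecord],
    profiles: Mapping[str, PSSMProfile] | None = None,
    spider2: Mapping[str, StructuralTable] | None = None,
    pep2d: Mapping[str, StructuralTable] | None = None,
    k_max: int = 4,
    aaindex_table: AAIndexTable | None = None,
    encoders: Sequence[str] = ("KSAAP", "AAindex", "pKSAAP"),
) -> dict[str, np.ndarray]:
    """Encode a peptide collection under each requested encoder.

    Returns ``{encoder_name: (n_peptides, dim) array}``.  pKSAAP uses the
    profile keyed by each record id, falling back to the one-hot self-profile
    where absent; SPIDER2/PEP2D require a table per record.
    """
    out: dict[str, np.ndarray] = {}
    for name in encoders:
        if name == "KSAAP":
            out[name] = KSAAPEncoder(k_max=k_max).fit(records).transform(records)
        elif name == "AAindex":
            out[name] = AAIndexEncoder(table=aaindex_table).fit(records).transform(records)
        elif name == "pKSAAP":
            inputs = [
                (profiles or {}).get(r.id, r) for r in records
            ]
            out[name] = PSSMKSAAPEncoder(k_max=k_max).fit(inputs).transform(inputs)
        elif name in ("SPIDER2", "PEP2D"):
            source = spider2 if name == "SPIDER2" else pep2d
            if source is None:
                raise EncodingError(f"{name} requested but no structural tables given")
            missing = [r.id for r in records if r.id not in source]
            if missing:
                raise EncodingError(
                    f"{name}: no structural table for {', '.join(missing[:5])}"
                )
            tables = [source[r.id] for r in records]
            out[name] = StructuralEncoder(flavor=name).fit(tables).transform(tables)
        else:
            raise EncodingError(f"unknown encoder {name!r}")
    return out
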