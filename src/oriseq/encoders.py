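"""Classical sequence encodings: CKSNAP, PseDNC/PCPseDNC and DCC.

All three descriptors operate on validated ACGT windows and are pure
functions of (sequence, configuration, index table): no statistics are
pooled across sequences, so ``fit`` only validates parameters and the
transformers compose freely with scikit-learn pipelines.

CKSNAP counts nucleotide pairs X··Y separated by k intervening bases and
normalizes each k's 16 counts by C_total = L - k - 1, the number of
k-spaced pairs in a length-L window.

PseDNC augments the 16 normalized dinucleotide frequencies f_m with λ
sequence-order terms θ_j, the mean squared physicochemical-index
difference between dinucleotides j positions apart, down-weighted by w;
the full (16+λ)-vector is normalized to sum 1.  PCPseDNC is the same
construction over a wider index set (38 vs 6 properties).

DCC is the cross-covariance of two different standardized indices
evaluated at dinucleotides separated by a lag, for every ordered distinct
index pair and every lag 1..LAG.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .index_tables import DINUCLEOTIDES, IndexTable, default_table
from .seq_data import validate_sequence

_DINUC_INDEX = {d: i for i, d in enumerate(DINUCLEOTIDES)}


@dataclass
class FeatureBlock:
    """A named matrix of per-sequence features with ordered feature names."""

    name: str
    feature_names: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("matrix width must equal number of feature names")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError(f"duplicate feature names in block {self.name!r}")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def _dinuc_codes(seq: str) -> np.ndarray:
    """Integer codes 0..15 of the L-1 overlapping dinucleotides."""
    b = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int64)
    for i, ch in enumerate("ACGT"):
        lut[ord(ch)] = i
    codes = lut[b]
    return codes[:-1] * 4 + codes[1:]


class _SequenceTransformer(TransformerMixin, BaseEstimator):
    """Shared plumbing: accepts a list of sequences, emits a FeatureBlock."""

    block_name: str = ""

    def fit(self, X, y=None):
        seqs = self._check_sequences(X)
        self._validate_config(len(seqs[0]) if seqs else None)
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        seqs = self._check_sequences(X)
        self._validate_config(len(seqs[0]) if seqs else None)
        return np.vstack([self._encode_one(s) for s in seqs])

    def encode_block(self, X) -> FeatureBlock:
        return FeatureBlock(self.block_name, list(self.get_feature_names_out()), self.transform(X))

    @staticmethod
    def _check_sequences(X) -> list[str]:
        seqs = [validate_sequence(s) for s in X]
        if not seqs:
            raise ValueError("no sequences given")
        return seqs

    # subclasses implement:
    def _validate_config(self, L: int | None) -> None:  # pragma: no cover
        raise NotImplementedError

    def _encode_one(self, seq: str) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class CKSNAPEncoder(_SequenceTransformer):
    """Composition of k-spaced nucleic acid pairs.

    Parameters
    ----------
    k_values : iterable of int
        Gap sizes; default 0..5.  For each k (ascending) a 16-entry
        sub-block in AA..TT order, each entry a pair count divided by
        C_total = L - k - 1.
    """

    block_name = "CKSNAP"

    def __init__(self, k_values=(0, 1, 2, 3, 4, 5)):
        self.k_values = k_values

    def _ks(self) -> list[int]:
        ks = sorted(int(k) for k in self.k_values)
        if not ks or ks[0] < 0:
            raise ValueError("k_values must be non-negative and non-empty")
        return ks

    def _validate_config(self, L):
        ks = self._ks()
        if L is not None and L <= max(ks) + 1:
            raise ValueError(
                f"window length {L} too short for gap k={max(ks)} (need L > k+1)"
            )

    def _encode_one(self, seq):
        b = np.frombuffer(seq.encode(), dtype=np.uint8)
        lut = np.zeros(256, dtype=np.int64)
        for i, ch in enumerate("ACGT"):
            lut[ord(ch)] = i
        codes = lut[b]
        out = []
        for k in self._ks():
            pairs = codes[: len(codes) - k - 1] * 4 + codes[k + 1 :]
            counts = np.bincount(pairs, minlength=16).astype(float)
            out.append(counts / (len(seq) - k - 1))
        return np.concatenate(out)

    def get_feature_names_out(self, input_features=None):
        return np.array(
            [f"CKSNAP:k{k}:{d}" for k in self._ks() for d in DINUCLEOTIDES], dtype=object
        )


class PCPseDNCEncoder(_SequenceTransformer):
    """Parallel-correlation pseudo dinucleotide composition.

    Parameters
    ----------
    lam : int
        Number of correlation tiers λ (must satisfy λ < L - 1).
    w : float
        Weight of the pseudo components, in (0, 1].
    n_indices : int
        Width of the default packaged index table (38 here, 6 for the
        PseDNC subclass); ignored when ``table`` is given.
    table : IndexTable, optional
        Custom property table; standardized internally if needed.
    """

    block_name = "PCPseDNC"
    _default_n_indices = 38

    def __init__(self, lam=2, w=0.1, n_indices=None, table=None):
        self.lam = lam
        self.w = w
        self.n_indices = n_indices
        self.table = table

    def _resolved_table(self) -> IndexTable:
        if self.table is not None:
            t = self.table
            if t.n_indices == 0:
                raise ValueError("empty index subset")
            if not t.standardized:
                from .index_tables import standardize_index_table

                t = standardize_index_table(t)
            return t
        return default_table(self.n_indices or self._default_n_indices)

    def _validate_config(self, L):
        if self.lam < 1:
            raise ValueError("lambda must be >= 1")
        if not 0.0 < self.w <= 1.0:
            raise ValueError("w must lie in (0, 1]")
        if L is not None and self.lam >= L - 1:
            raise ValueError(f"lambda={self.lam} must be < L-1 = {L - 1}")
        self._table_ = self._resolved_table()

    def _encode_one(self, seq):
        table = self._table_
        codes = _dinuc_codes(seq)
        L = len(seq)
        # P: (mu, L-1) property profile along the sequence
        P = table.values.to_numpy()[:, codes]
        f = np.bincount(codes, minlength=16).astype(float)
        f /= f.sum()
        thetas = np.empty(self.lam)
        for j in range(1, self.lam + 1):
            diff = P[:, : L - 1 - j] - P[:, j:]
            thetas[j - 1] = np.mean(diff**2, axis=0).mean()
        denom = 1.0 + self.w * thetas.sum()  # Σf_m = 1
        return np.concatenate([f, self.w * thetas]) / denom

    def get_feature_names_out(self, input_features=None):
        names = [f"{self.block_name}:f:{d}" for d in DINUCLEOTIDES]
        names += [f"{self.block_name}:theta:{j}" for j in range(1, self.lam + 1)]
        return np.array(names, dtype=object)


class PseDNCEncoder(PCPseDNCEncoder):
    """Pseudo dinucleotide composition over the 6-index default table."""

    block_name = "PseDNC"
    _default_n_indices = 6


class DCCEncoder(_SequenceTransformer):
    """Dinucleotide-based cross covariance.

    For each ordered pair (u1, u2) of distinct indices and each lag in
    1..LAG:

        DCC = Σ_{i=1}^{L-lag-1} (P_u1(i) - P̄_u1)(P_u2(i+lag) - P̄_u2) / (L-lag-1)

    with P̄_u the mean of P_u over all L-1 dinucleotides.

    Parameters
    ----------
    max_lag : int
        LAG, the largest dinucleotide separation (requires LAG <= L - 2).
    index_names : sequence of str, optional
        Indices drawn from the table; default the two Breslauer
        enthalpy/entropy profiles of the packaged thermodynamic table.
    table : IndexTable, optional
        Custom property table (standardized internally if needed).
    """

    block_name = "DCC"

    def __init__(self, max_lag=2, index_names=("dH_BR86", "dS_BR86"), table=None):
        self.max_lag = max_lag
        self.index_names = index_names
        self.table = table

    def _resolved_table(self) -> IndexTable:
        t = self.table if self.table is not None else default_table(6)
        if not t.standardized:
            from .index_tables import standardize_index_table

            t = standardize_index_table(t)
        t = t.subset(self.index_names)
        if t.n_indices < 2:
            raise ValueError("DCC needs at least two distinct indices")
        return t

    def _pairs(self) -> list[tuple[str, str]]:
        names = list(self.index_names)
        if len(set(names)) != len(names):
            raise ValueError("index_names must be distinct (u1 != u2)")
        return list(permutations(names, 2))

    def _validate_config(self, L):
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        if L is not None and self.max_lag > L - 2:
            raise ValueError(f"max_lag={self.max_lag} must be <= L-2 = {L - 2}")
        self._table_ = self._resolved_table()

    def _encode_one(self, seq):
        table = self._table_
        codes = _dinuc_codes(seq)
        L = len(seq)
        P = table.values.to_numpy()[:, codes]  # (mu, L-1)
        pbar = P.mean(axis=1, keepdims=True)
        D = P - pbar
        row = {n: i for i, n in enumerate(table.index_names)}
        out = []
        for u1, u2 in self._pairs():
            a, b = D[row[u1]], D[row[u2]]
            for lag in range(1, self.max_lag + 1):
                n = L - lag - 1
                out.append(float(a[:n] @ b[lag : lag + n]) / n)
        return np.array(out)

    def get_feature_names_out(self, input_features=None):
        return np.array(
            [
                f"DCC:{u1}|{u2}:lag{lag}"
                for u1, u2 in self._pairs()
                for lag in range(1, self.max_lag + 1)
            ],
            dtype=object,
        )


# thin functional wrappers -------------------------------------------------


def cksnap(seq: str, k_values=(0, 1, 2, 3, 4, 5)) -> FeatureBlock:
    return CKSNAPEncoder(k_values=k_values).encode_block([seq])


def pcpsednc(seq: str, lam: int = 2, w: float = 0.1, table: IndexTable | None = None) -> FeatureBlock:
    return PCPseDNCEncoder(lam=lam, w=w, table=table).encode_block([seq])


def psednc(seq: str, lam: int = 2, w: float = 0.1, table: IndexTable | None = None) -> FeatureBlock:
    return PseDNCEncoder(lam=lam, w=w, table=table).encode_block([seq])


def dcc(
    seq: str,
    max_lag: int = 2,
    index_names=("dH_BR86", "dS_BR86"),
    table: IndexTable | None = None,
) -> FeatureBlock:
    return DCCEncoder(max_lag=max_lag, index_names=index_names, table=table).encode_block([seq])
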