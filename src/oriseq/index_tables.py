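"""Dinucleotide physicochemical index tables.

Pseudo-dinucleotide and covariance encoders consume a table of numeric
properties P_u(XY), one value per property u and per dinucleotide XY.
Values are z-standardized across the 16 dinucleotides (population SD)
before use so that correlation functions built from squared differences
or cross-products are scale-free.

Two tables ship with the package:

* ``thermo6`` — six real nearest-neighbour thermodynamic indices (ΔH, ΔS
  and ΔG at 37°C from the Breslauer 1986 and the unified SantaLucia 1998
  parameter sets, as distributed with Biopython's melting-temperature
  tables).  Strand-symmetric by construction.
* ``synthetic38`` — a SYNTHETIC 38-index stand-in, generated
  deterministically, for exercising the 38-index parallel-correlation
  encoder at full width.  It is not any published property compilation;
  supply your own TSV (``IndexTable.from_tsv``) to use real indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import product

import numpy as np
import pandas as pd

DINUCLEOTIDES: tuple[str, ...] = tuple(a + b for a, b in product("ACGT", repeat=2))


@dataclass
class IndexTable:
    """Named per-dinucleotide property values P_u(XY).

    ``values`` is indexed by property name (rows) with the 16 dinucleotide
    columns in lexicographic AA..TT order.
    """

    values: pd.DataFrame
    standardized: bool = False
    provenance: str = ""

    def __post_init__(self):
        missing = set(DINUCLEOTIDES) - set(self.values.columns)
        if missing:
            raise ValueError(f"table lacks dinucleotide columns: {sorted(missing)}")
        self.values = self.values.loc[:, list(DINUCLEOTIDES)].astype(float)
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("non-finite index values")

    @property
    def index_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_indices(self) -> int:
        return len(self.values)

    def subset(self, names) -> "IndexTable":
        names = list(names)
        unknown = set(names) - set(self.values.index)
        if unknown:
            raise KeyError(f"unknown indices: {sorted(unknown)}")
        return IndexTable(self.values.loc[names].copy(), self.standardized, self.provenance)

    def lookup_matrix(self, seq: str) -> np.ndarray:
        """(n_indices, L-1) matrix of P_u over the sequence's dinucleotides."""
        cols = [seq[i : i + 2] for i in range(len(seq) - 1)]
        return self.values.loc[:, cols].to_numpy()

    @classmethod
    def from_tsv(cls, path, provenance: str = "") -> "IndexTable":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        return cls(df, standardized=False, provenance=provenance or str(path))

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="index")


def standardize_index_table(raw: IndexTable) -> IndexTable:
    """Z-score each index across the 16 dinucleotides (population SD).

    Idempotent; raises on a constant index, which carries no signal and
    would divide by zero.
    """
    vals = raw.values.to_numpy()
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)  # population SD, ddof=0
    flat = np.flatnonzero(sd.ravel() == 0.0)
    if flat.size:
        names = [raw.index_names[i] for i in flat]
        raise ValueError(f"constant index (SD 0) cannot be standardized: {names}")
    out = pd.DataFrame(
        (vals - mean) / sd, index=raw.values.index, columns=raw.values.columns
    )
    return IndexTable(out, standardized=True, provenance=raw.provenance)


def _load_packaged(name: str) -> IndexTable:
    ref = resources.files("oriseq").joinpath(f"data/{name}")
    with resources.as_file(ref) as path:
        provenance = ""
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    provenance += line[1:].strip() + " "
                else:
                    break
        return IndexTable.from_tsv(path, provenance=provenance.strip())


def load_thermo6() -> IndexTable:
    """Six nearest-neighbour thermodynamic indices (raw, unstandardized)."""
    return _load_packaged("dinucleotide_indices_thermo6.tsv")


def load_synthetic38() -> IndexTable:
    """The synthetic 38-index stand-in table (raw, unstandardized)."""
    return _load_packaged("dinucleotide_indices_38_synthetic.tsv")


def default_table(n_indices: int) -> IndexTable:
    """Standardized default table with ``n_indices`` ∈ {6, 38} properties."""
    if n_indices == 6:
        return standardize_index_table(load_thermo6())
    if n_indices == 38:
        return standardize_index_table(load_synthetic38())
    raise ValueError("packaged defaults exist for 6 or 38 indices")
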