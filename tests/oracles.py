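"""Literal, unoptimized transcriptions of the encoder definitions.

These are the independent oracles the fast implementations are checked
against: plain Python loops over the defining formulas, kept free of any
code shared with the package implementation.
"""

from itertools import product

import numpy as np

DINUC = [a + b for a, b in product("ACGT", repeat=2)]


def naive_cksnap(seq: str, k_values) -> list[float]:
    out = []
    L = len(seq)
    for k in sorted(k_values):
        total = L - k - 1
        for pair in DINUC:
            count = 0
            for i in range(L - k - 1):
                if seq[i] == pair[0] and seq[i + k + 1] == pair[1]:
                    count += 1
            out.append(count / total)
    return out


def _theta_corr(d1: str, d2: str, table: dict) -> float:
    """Mean squared index difference between two dinucleotides."""
    mu = len(table)
    return sum((vals[d1] - vals[d2]) ** 2 for vals in table.values()) / mu


def naive_pcpsednc(seq: str, lam: int, w: float, table: dict) -> list[float]:
    """table: {index_name: {dinucleotide: standardized value}}."""
    L = len(seq)
    dinucs = [seq[i : i + 2] for i in range(L - 1)]
    freqs = [dinucs.count(d) / len(dinucs) for d in DINUC]
    thetas = []
    for j in range(1, lam + 1):
        acc = 0.0
        for i in range(L - 1 - j):
            acc += _theta_corr(dinucs[i], dinucs[i + j], table)
        thetas.append(acc / (L - 1 - j))
    denom = sum(freqs) + w * sum(thetas)
    return [f / denom for f in freqs] + [w * t / denom for t in thetas]


def naive_dcc(seq: str, max_lag: int, table: dict, pair_order) -> list[float]:
    """pair_order: ordered distinct (u1, u2) index-name pairs."""
    L = len(seq)
    dinucs = [seq[i : i + 2] for i in range(L - 1)]
    pbar = {u: sum(vals[d] for d in dinucs) / (L - 1) for u, vals in table.items()}
    out = []
    for u1, u2 in pair_order:
        for lag in range(1, max_lag + 1):
            acc = 0.0
            for i in range(L - lag - 1):
                acc += (table[u1][dinucs[i]] - pbar[u1]) * (
                    table[u2][dinucs[i + lag]] - pbar[u2]
                )
            out.append(acc / (L - lag - 1))
    return out


def naive_attention(query, keys, values):
    """Softmax of dot-product scores, then the weighted sum of values."""
    scores = [float(np.dot(k, query)) for k in keys]
    m = max(scores)
    exp = [np.exp(s - m) for s in scores]
    z = sum(exp)
    weights = [e / z for e in exp]
    pooled = sum(w * np.asarray(v, dtype=float) for w, v in zip(weights, values))
    return pooled, np.array(weights)


def table_as_dict(index_table) -> dict:
    """IndexTable -> {index: {dinucleotide: value}} for the oracles."""
    return {
        name: {d: float(index_table.values.loc[name, d]) for d in DINUC}
        for name in index_table.index_names
    }
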