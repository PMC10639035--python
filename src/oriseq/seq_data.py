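"""Sequence containers, FASTA I/O, validation, synthetic benchmarks, folds.

Replication-origin (ORI) predictors in this family are trained on
fixed-length windows: positive windows centred on experimentally mapped
origins, negative windows cut from the flanks of the same loci (300-600 bp
up- or downstream of the positive window edge).  The synthetic generator
here reproduces that geometry on simulated loci so the whole pipeline can
be exercised, end to end, without any external download: positives carry
two controllable, biologically motivated signals — a planted consensus
motif and a G-vs-C strand asymmetry (GC skew) — while the paired negative
is an unmodified flank of the same simulated segment.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord
from sklearn.model_selection import StratifiedKFold

DNA_ALPHABET = "ACGT"
_DNA_SET = frozenset(DNA_ALPHABET)


class SequenceValidationError(ValueError):
    """A sequence contains characters outside the ACGT alphabet."""


class FastaParseError(ValueError):
    """Malformed FASTA input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One fixed-length DNA window with an optional binary label."""

    id: str
    seq: str
    label: int | None = None

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class LabeledSequenceSet:
    """An ordered collection of same-length windows for one cell/dataset."""

    records: list[SequenceRecord]
    window_length: int
    tag: str = ""

    def __post_init__(self):
        for r in self.records:
            if len(r.seq) != self.window_length:
                raise ValueError(
                    f"record {r.id!r} has length {len(r.seq)}, "
                    f"expected window_length={self.window_length}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def class_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for r in self.records:
            if r.label is not None:
                counts[r.label] = counts.get(r.label, 0) + 1
        return counts

    def sequences(self) -> list[str]:
        return [r.seq for r in self.records]

    def labels(self) -> np.ndarray:
        if any(r.label is None for r in self.records):
            raise ValueError("set contains unlabelled records")
        return np.array([r.label for r in self.records], dtype=int)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, indices) -> "LabeledSequenceSet":
        return LabeledSequenceSet(
            [self.records[i] for i in indices], self.window_length, self.tag
        )


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the simulated ORI benchmark.

    ``n_per_class`` positive and negative windows of ``window_length`` bp
    are produced.  Each positive carries the consensus ``motif`` at a
    uniform position with probability ``motif_rate`` and a G/C probability
    asymmetry of ``gc_skew_shift`` (p_G raised, p_C lowered by shift/2, so
    GC content is unchanged but strand skew is not).  The paired negative
    is cut from the same simulated segment at a uniform offset within
    ``flank_offset_range`` of the positive window edge, side chosen
    uniformly — emulating flank-negative dataset construction.
    """

    n_per_class: int
    window_length: int = 300
    motif: str = "ACGTACGT"
    motif_rate: float = 0.8
    gc_skew_shift: float = 0.05
    flank_offset_range: tuple[int, int] = (300, 600)
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_class <= 0:
            raise ValueError("n_per_class must be positive")
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        if not 0.0 <= self.motif_rate <= 1.0:
            raise ValueError("motif_rate must lie in [0, 1]")
        if self.motif and len(self.motif) > self.window_length:
            raise ValueError("motif longer than window")
        if self.motif and (set(self.motif) - _DNA_SET):
            raise SequenceValidationError("motif must be over ACGT")
        lo, hi = self.flank_offset_range
        if not (0 <= lo <= hi):
            raise ValueError("flank_offset_range must satisfy 0 <= min <= max")
        p = np.asarray(self.base_composition, dtype=float)
        if p.shape != (4,) or not np.isclose(p.sum(), 1.0) or (p < 0).any():
            raise ValueError("base_composition must be 4 non-negative probs summing to 1")
        if self.gc_skew_shift / 2 > p[1] or self.gc_skew_shift / 2 > p[2]:
            raise ValueError("gc_skew_shift too large for base_composition")


@dataclass
class FoldAssignment:
    """A stratified partition of record ids into cross-validation folds."""

    n_folds: int
    fold_of: dict[str, int]
    seed: int

    def fold_indices(self, dataset: LabeledSequenceSet) -> list[np.ndarray]:
        unknown = set(self.fold_of) - set(dataset.ids())
        if unknown:
            raise KeyError(f"fold assignment references unknown ids: {sorted(unknown)[:5]}")
        out = [[] for _ in range(self.n_folds)]
        for i, rid in enumerate(dataset.ids()):
            out[self.fold_of[rid]].append(i)
        return [np.array(ix, dtype=int) for ix in out]


# ---------------------------------------------------------------------------
# validation


def validate_sequence(seq: str, policy: str = "strict", seed: int | None = None) -> str | None:
    """Normalize a DNA string to upper-case ACGT under an ambiguity policy.

    strict    -> raise listing the 1-based offending positions
    drop      -> return None (caller excludes the record)
    randomize -> replace each non-ACGT char by a seeded uniform base
    """
    if not seq:
        raise SequenceValidationError("empty sequence")
    s = seq.upper()
    bad = [i + 1 for i, ch in enumerate(s) if ch not in _DNA_SET]
    if not bad:
        return s
    if policy == "strict":
        raise SequenceValidationError(
            f"non-ACGT characters at position(s) {bad[:20]}"
        )
    if policy == "drop":
        return None
    if policy == "randomize":
        rng = np.random.default_rng(seed)
        chars = list(s)
        for i in bad:
            chars[i - 1] = DNA_ALPHABET[rng.integers(4)]
        return "".join(chars)
    raise ValueError(f"unknown policy {policy!r}")


# ---------------------------------------------------------------------------
# FASTA I/O


def _label_from_header(header_id: str) -> tuple[str, int | None]:
    if "|" in header_id:
        stem, _, suffix = header_id.rpartition("|")
        if suffix in ("0", "1"):
            return stem, int(suffix)
    return header_id, None


def read_fasta(
    path,
    labels_tsv=None,
    policy: str = "strict",
    seed: int | None = None,
    tag: str = "",
) -> LabeledSequenceSet:
    """Read labelled windows from FASTA (labels via ``|0``/``|1`` header
    suffix, or overridden by a two-column id<TAB>label TSV)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    side_labels: dict[str, int] = {}
    if labels_tsv is not None:
        with open(labels_tsv, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if row:
                    side_labels[row[0]] = int(row[1])
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected a '>' header before sequence data"
                )
            break
        else:
            raise FastaParseError(f"{path}: no FASTA records found")
    records: list[SequenceRecord] = []
    parsed = list(SeqIO.parse(str(path), "fasta"))
    if not parsed:
        raise FastaParseError(f"{path}: no FASTA records found")
    for rec in parsed:
        rid, label = _label_from_header(rec.id)
        if rid in side_labels:
            label = side_labels[rid]
        try:
            seq = validate_sequence(str(rec.seq), policy=policy, seed=seed)
        except SequenceValidationError as exc:
            raise SequenceValidationError(f"record {rid!r}: {exc}") from exc
        if seq is None:
            continue
        records.append(SequenceRecord(rid, seq, label))
    if not records:
        raise FastaParseError(f"{path}: all records excluded by validation policy")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"{path}: mixed sequence lengths {sorted(lengths)}")
    return LabeledSequenceSet(records, lengths.pop(), tag=tag or path.stem)


def write_fasta(dataset: LabeledSequenceSet, path) -> None:
    """Write records with labels encoded as ``|0``/``|1`` header suffixes."""
    recs = []
    for r in dataset:
        rid = r.id if r.label is None else f"{r.id}|{r.label}"
        recs.append(BioSeqRecord(Seq(r.seq), id=rid, description=""))
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# synthetic benchmark generator


def _draw(rng: np.random.Generator, probs: np.ndarray, n: int) -> np.ndarray:
    return rng.choice(4, size=n, p=probs)


def generate_synthetic_dataset(cfg: SyntheticConfig) -> LabeledSequenceSet:
    """Simulate paired ORI/flank windows (see module docstring).

    Per locus, a background segment long enough to hold the positive
    window plus the farthest flank on either side is drawn i.i.d. from
    ``base_composition``; the positive window is re-drawn with the skewed
    composition and (with probability ``motif_rate``) receives the motif
    at a uniform position; the negative is an untouched flank slice.
    Coordinates are 0-based half-open.  Fully reproducible from ``seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    base = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)
    probs = np.asarray(cfg.base_composition, dtype=float)
    s = cfg.gc_skew_shift
    pos_probs = probs + np.array([0.0, -s / 2, s / 2, 0.0])
    lo, hi = cfg.flank_offset_range
    w = cfg.window_length
    margin = hi + w  # farthest a negative window can reach past either edge
    seg_len = w + 2 * margin
    pos_start = margin

    positives: list[SequenceRecord] = []
    negatives: list[SequenceRecord] = []
    for i in range(cfg.n_per_class):
        segment = _draw(rng, probs, seg_len)
        # positive window: skewed composition, then optional planted motif
        window = _draw(rng, pos_probs, w)
        if cfg.motif and rng.random() < cfg.motif_rate:
            mlen = len(cfg.motif)
            at = rng.integers(0, w - mlen + 1)
            window[at : at + mlen] = [DNA_ALPHABET.index(c) for c in cfg.motif]
        segment[pos_start : pos_start + w] = window
        # negative window: flank slice at a uniform offset, side uniform
        offset = int(rng.integers(lo, hi + 1))
        if rng.random() < 0.5:  # downstream of the positive window edge
            neg_start = pos_start + w + offset
        else:  # upstream
            neg_start = pos_start - offset - w
        neg = segment[neg_start : neg_start + w]
        positives.append(
            SequenceRecord(f"locus{i}_ori", base[segment[pos_start : pos_start + w]].tobytes().decode(), 1)
        )
        negatives.append(SequenceRecord(f"locus{i}_flank", base[neg].tobytes().decode(), 0))
    return LabeledSequenceSet(positives + negatives, w, tag="synthetic")


# ---------------------------------------------------------------------------
# fold splitting


def split_folds(dataset: LabeledSequenceSet, n_folds: int = 10, seed: int = 0) -> FoldAssignment:
    """Stratified k-fold assignment of record ids, reproducible from seed."""
    y = dataset.labels()
    counts = np.bincount(y, minlength=2)
    if (counts == 0).any():
        raise ValueError("both classes must be present for fold splitting")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > counts.min():
        raise ValueError(
            f"n_folds={n_folds} exceeds minority class size {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    ids = dataset.ids()
    fold_of: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        for i in test_idx:
            fold_of[ids[i]] = fold
    return FoldAssignment(n_folds=n_folds, fold_of=fold_of, seed=seed)


def train_test_split_set(
    dataset: LabeledSequenceSet, test_fraction: float = 0.2, seed: int = 0
) -> tuple[LabeledSequenceSet, LabeledSequenceSet]:
    """Stratified held-out split mirroring an independent-test partition."""
    y = dataset.labels()
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_test = max(1, int(round(test_fraction * len(idx))))
        test_idx.extend(idx[:n_test])
    test_mask = np.zeros(len(y), dtype=bool)
    test_mask[test_idx] = True
    return dataset.subset(np.flatnonzero(~test_mask)), dataset.subset(np.flatnonzero(test_mask))
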