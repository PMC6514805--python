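"""Seven fixed-length peptide descriptors over variable-length sequences.

Each encoder maps a peptide to a vector of fixed dimension:

========  ====  ==========================================================
scheme    dim   description
========  ====  ==========================================================
AAC        20   amino-acid composition (residue frequencies)
DPC       400   dipeptide composition (adjacent-pair frequencies)
QSO       100   quasi-sequence-order: composition plus lagged
                physicochemical-distance coupling terms, two matrices
CTF       343   conjoint triad: class-triple counts over 7 residue classes,
                min-max normalized
NC5       200   binary profile of the 5 N-terminal and 5 C-terminal residues
AAIF      160   8 standardized AAindex scales weighted by composition
CTD       147   composition (21) / transition (21) / distribution (105) over
                7 three-class physicochemical partitions
========  ====  ==========================================================

All encoders are pure functions of the sequence and the property tables;
feature order is canonical and deterministic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .seqio import Peptide, PeptideSet
from .tables import AA_ORDER, AA_INDEX, AAINDEX_IDS, CTD_PROPERTIES, PropertyTables, default_tables

CANONICAL_SCHEMES = ("AAC", "DPC", "QSO", "CTF", "NC5", "AAIF", "CTD")

SCHEME_DIMENSIONS = {
    "AAC": 20,
    "DPC": 400,
    "QSO": 100,
    "CTF": 343,
    "NC5": 200,
    "AAIF": 160,
    "CTD": 147,
}

#: Minimum sequence length each descriptor is defined for.
SCHEME_MIN_LENGTH = {
    "AAC": 1,
    "DPC": 2,
    "QSO": 1,
    "CTF": 3,
    "NC5": 5,
    "AAIF": 1,
    "CTD": 2,
}


@dataclass(frozen=True)
class EncodingScheme:
    name: str
    dimension: int

    def __post_init__(self) -> None:
        if self.name not in SCHEME_DIMENSIONS:
            raise ValueError(f"unknown encoding scheme {self.name!r}")
        if self.dimension != SCHEME_DIMENSIONS[self.name]:
            raise ValueError(
                f"{self.name} dimension must be {SCHEME_DIMENSIONS[self.name]}, got {self.dimension}"
            )


def scheme(name: str) -> EncodingScheme:
    return EncodingScheme(name, SCHEME_DIMENSIONS[name])


@dataclass(frozen=True)
class FeatureVector:
    scheme: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")
        if len(self.values) != SCHEME_DIMENSIONS[self.scheme]:
            raise ValueError(
                f"{self.scheme} vector has {len(self.values)} entries, "
                f"expected {SCHEME_DIMENSIONS[self.scheme]}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")


@dataclass
class FeatureMatrix:
    """Peptides x features numeric matrix with named rows and columns."""

    peptide_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.peptide_ids), len(self.feature_names)):
            raise ValueError("matrix shape does not match ids/feature names")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != len(self.peptide_ids):
                raise ValueError("labels length mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(
            list(self.peptide_ids), list(names), self.values[:, idx], self.labels
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.peptide_ids, columns=self.feature_names)

    def to_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "id"
        df.to_csv(path, sep="\t", float_format="%.10g")


def _seq(p: Peptide | str) -> str:
    return p.sequence if isinstance(p, Peptide) else p


def _require_length(seq: str, minimum: int, scheme_name: str) -> None:
    if len(seq) < minimum:
        raise ValueError(f"{scheme_name} requires length >= {minimum}, got {len(seq)}")


# --- feature-name builders (cached: canonical order is fixed) ---------------

@lru_cache(maxsize=None)
def feature_names(scheme_name: str, tables_key: str = "") -> tuple[str, ...]:
    tables = default_tables()
    if scheme_name == "AAC":
        return tuple(f"AAC.{a}" for a in AA_ORDER)
    if scheme_name == "DPC":
        return tuple(f"DPC.{a}{b}" for a in AA_ORDER for b in AA_ORDER)
    if scheme_name == "QSO":
        names: list[str] = []
        for mat in sorted(tables.qso_distance):
            names += [f"QSO.{mat}.comp.{a}" for a in AA_ORDER]
            names += [f"QSO.{mat}.lag{d}" for d in range(1, tables.qso_nlag + 1)]
        return tuple(names)
    if scheme_name == "CTF":
        return tuple(
            f"CTF.{i}{j}{k}"
            for i, j, k in itertools.product(range(1, 8), repeat=3)
        )
    if scheme_name == "NC5":
        w = tables.nc5_window
        names = [f"NC5.N{p}.{a}" for p in range(1, w + 1) for a in AA_ORDER]
        names += [f"NC5.C{p}.{a}" for p in range(1, w + 1) for a in AA_ORDER]
        return tuple(names)
    if scheme_name == "AAIF":
        return tuple(f"AAIF.{idx}.{a}" for idx in AAINDEX_IDS for a in AA_ORDER)
    if scheme_name == "CTD":
        comp = [f"CTD.C.{p}.{c}" for p in CTD_PROPERTIES for c in (1, 2, 3)]
        tran = [f"CTD.T.{p}.{pair}" for p in CTD_PROPERTIES for pair in ("12", "13", "23")]
        dist = [
            f"CTD.D.{p}.{c}.p{q}"
            for p in CTD_PROPERTIES
            for c in (1, 2, 3)
            for q in (0, 25, 50, 75, 100)
        ]
        return tuple(comp + tran + dist)
    raise ValueError(f"unknown scheme {scheme_name!r}")


# --- encoders ----------------------------------------------------------------

def _counts(seq: str) -> np.ndarray:
    c = np.zeros(20)
    for ch in seq:
        c[AA_INDEX[ch]] += 1
    return c


def encode_aac(p: Peptide | str) -> FeatureVector:
    """Amino-acid composition: residue frequency over the 20-letter alphabet."""
    seq = _seq(p)
    _require_length(seq, 1, "AAC")
    return FeatureVector("AAC", feature_names("AAC"), _counts(seq) / len(seq))


def encode_dpc(p: Peptide | str) -> FeatureVector:
    """Dipeptide composition: adjacent residue-pair frequencies (L-1 pairs)."""
    seq = _seq(p)
    _require_length(seq, 2, "DPC")
    v = np.zeros(400)
    for a, b in zip(seq, seq[1:]):
        v[AA_INDEX[a] * 20 + AA_INDEX[b]] += 1
    return FeatureVector("DPC", feature_names("DPC"), v / (len(seq) - 1))


def encode_qso(p: Peptide | str, tables: PropertyTables | None = None) -> FeatureVector:
    """Quasi-sequence-order descriptor over two distance matrices.

    For each matrix: 20 composition terms ``f_a / (1 + w * sum_d tau_d)``
    followed by ``nlag`` coupling terms ``w * tau_d / (1 + w * sum_d tau_d)``
    where ``tau_d = sum_i dist(r_i, r_{i+d})^2`` and ``tau_d = 0`` for lags
    reaching beyond the sequence (short-peptide convention).
    """
    tables = tables or default_tables()
    seq = _seq(p)
    _require_length(seq, 1, "QSO")
    L = len(seq)
    idx = np.array([AA_INDEX[a] for a in seq])
    freq = _counts(seq) / L
    w, nlag = tables.qso_weight, tables.qso_nlag

    blocks: list[np.ndarray] = []
    for name in sorted(tables.qso_distance):
        dm = tables.qso_distance[name]
        tau = np.zeros(nlag)
        for d in range(1, min(nlag + 1, L)):
            tau[d - 1] = np.sum(dm[idx[:-d], idx[d:]] ** 2)
        denom = 1.0 + w * tau.sum()
        blocks.append(np.concatenate([freq / denom, w * tau / denom]))
    return FeatureVector("QSO", feature_names("QSO"), np.concatenate(blocks))


def encode_ctf(p: Peptide | str, tables: PropertyTables | None = None) -> FeatureVector:
    """Conjoint triad: counts of residue-class triples, min-max normalized.

    Residues are mapped into 7 dipole/side-chain-volume classes; every
    consecutive triple increments its ordered class-triad count; the 343 raw
    counts are then rescaled by (v - min) / (max - min), or set to all zeros
    when every count is equal.
    """
    tables = tables or default_tables()
    seq = _seq(p)
    _require_length(seq, 3, "CTF")
    cls = {a: c for c, group in enumerate(tables.ctf_classes) for a in group}
    v = np.zeros(343)
    for i in range(len(seq) - 2):
        c1, c2, c3 = cls[seq[i]], cls[seq[i + 1]], cls[seq[i + 2]]
        v[c1 * 49 + c2 * 7 + c3] += 1
    lo, hi = v.min(), v.max()
    v = np.zeros(343) if hi == lo else (v - lo) / (hi - lo)
    return FeatureVector("CTF", feature_names("CTF"), v)


def encode_nc5(p: Peptide | str, tables: PropertyTables | None = None) -> FeatureVector:
    """Binary profile of the terminal residues (one-hot, N-then-C blocks).

    The first ``w``=5 and last 5 residues are each one-hot encoded over the
    20-letter alphabet; for 5 <= L < 10 the two windows overlap.
    """
    tables = tables or default_tables()
    seq = _seq(p)
    w = tables.nc5_window
    _require_length(seq, w, "NC5")
    v = np.zeros(2 * w * 20)
    for pos, a in enumerate(seq[:w]):
        v[pos * 20 + AA_INDEX[a]] = 1.0
    for pos, a in enumerate(seq[-w:]):
        v[(w + pos) * 20 + AA_INDEX[a]] = 1.0
    return FeatureVector("NC5", feature_names("NC5"), v)


def encode_aaif(p: Peptide | str, tables: PropertyTables | None = None) -> FeatureVector:
    """Composition-weighted AAindex profile (8 scales x 20 residues).

    Each scale is standardized to zero mean / unit variance across the 20
    residues; feature (scale j, residue a) is the standardized value times the
    residue's frequency in the peptide, so absent residues contribute zeros.
    """
    tables = tables or default_tables()
    seq = _seq(p)
    _require_length(seq, 1, "AAIF")
    freq = _counts(seq) / len(seq)
    blocks = []
    for idx_id in AAINDEX_IDS:
        x = tables.aaindex8[idx_id]
        z = (x - x.mean()) / x.std()
        blocks.append(z * freq)
    return FeatureVector("AAIF", feature_names("AAIF"), np.concatenate(blocks))


def _occurrence_positions(member: np.ndarray) -> np.ndarray:
    return np.flatnonzero(member) + 1  # 1-based


def encode_ctd(p: Peptide | str, tables: PropertyTables | None = None) -> FeatureVector:
    """Composition/transition/distribution descriptor (21 + 21 + 105 values).

    Composition: per property, the residue fraction in each of 3 classes.
    Transition: per property, counts of adjacent positions whose classes form
    each unordered pair, divided by L-1.  Distribution: per property and
    class, the sequence position (percent of L) of the 1st, 25th-, 50th-,
    75th-percentile and last occurrence (ceiling occurrence index); a class
    with no occurrences yields five zeros.
    """
    tables = tables or default_tables()
    seq = _seq(p)
    _require_length(seq, 2, "CTD")
    L = len(seq)
    comp: list[float] = []
    tran: list[float] = []
    dist: list[float] = []
    pair_index = {(0, 1): 0, (0, 2): 1, (1, 2): 2}
    for prop in CTD_PROPERTIES:
        classes = tables.ctd_classes[prop]
        cls_of = {a: c for c, group in enumerate(classes) for a in group}
        labels = np.array([cls_of[a] for a in seq])
        for c in range(3):
            comp.append(float(np.mean(labels == c)))
        t = [0, 0, 0]
        for a, b in zip(labels, labels[1:]):
            if a != b:
                t[pair_index[(min(a, b), max(a, b))]] += 1
        tran.extend(x / (L - 1) for x in t)
        for c in range(3):
            pos = _occurrence_positions(labels == c)
            if pos.size == 0:
                dist.extend([0.0] * 5)
            else:
                n = pos.size
                picks = [1, math.ceil(0.25 * n), math.ceil(0.50 * n), math.ceil(0.75 * n), n]
                dist.extend(100.0 * pos[max(k, 1) - 1] / L for k in picks)
    values = np.array(comp + tran + dist)
    return FeatureVector("CTD", feature_names("CTD"), values)


_ENCODERS = {
    "AAC": lambda p, t: encode_aac(p),
    "DPC": lambda p, t: encode_dpc(p),
    "QSO": encode_qso,
    "CTF": encode_ctf,
    "NC5": encode_nc5,
    "AAIF": encode_aaif,
    "CTD": encode_ctd,
}


def encode_peptide(p: Peptide | str, scheme_name: str, tables: PropertyTables | None = None) -> FeatureVector:
    """Encode one peptide under a named scheme."""
    if scheme_name not in _ENCODERS:
        raise ValueError(f"unknown encoding scheme {scheme_name!r}")
    return _ENCODERS[scheme_name](p, tables or default_tables())


def encode_matrix(
    pset: PeptideSet,
    scheme_name: str,
    tables: PropertyTables | None = None,
) -> FeatureMatrix:
    """Encode a whole peptide set; rows in input order, canonical columns."""
    tables = tables or default_tables()
    rows = []
    for p in pset:
        if len(p) < SCHEME_MIN_LENGTH[scheme_name]:
            raise ValueError(
                f"peptide {p.id!r} (length {len(p)}) is too short for {scheme_name} "
                f"(minimum {SCHEME_MIN_LENGTH[scheme_name]})"
            )
        rows.append(encode_peptide(p, scheme_name, tables).values)
    labels = None
    if all(p.label is not None for p in pset):
        labels = np.array([p.label for p in pset])
    return FeatureMatrix(
        pset.ids(), list(feature_names(scheme_name)), np.vstack(rows), labels
    )


def hybrid_concat(
    pset: PeptideSet,
    schemes: Sequence[str],
    tables: PropertyTables | None = None,
) -> FeatureMatrix:
    """Column-wise concatenation of several encodings (hybrid feature space)."""
    if len(schemes) < 2:
        raise ValueError("hybrid encoding needs at least 2 schemes")
    if len(set(schemes)) != len(schemes):
        raise ValueError("duplicate scheme in hybrid list")
    mats = [encode_matrix(pset, s, tables) for s in schemes]
    names = [n for m in mats for n in m.feature_names]
    return FeatureMatrix(pset.ids(), names, np.hstack([m.values for m in mats]), mats[0].labels)
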