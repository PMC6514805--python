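"""Embedded amino-acid property tables backing the physicochemical encoders.

Everything a descriptor needs at run time is a packaged constant (like a
substitution matrix): eight curated AAindex scales, two 20x20 physicochemical
distance matrices for the quasi-sequence-order descriptor, the seven conjoint
triad classes, and the seven three-class partitions used by the
composition/transition/distribution descriptor.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

#: Canonical residue order used by every encoder (alphabetical one-letter codes).
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

# ---------------------------------------------------------------------------
# Eight curated AAindex scales (values keyed by one-letter residue code).
# LIFS790101  beta-strand conformational preference (Lifson & Sander)
# CEDJ970104  composition of intracellular proteins, percent (Cedano et al.)
# MIYS990104  optimized relative partition energies (Miyazawa & Jernigan)
# NAKH920108  composition of single-spanning membrane proteins (Nakashima & Nishikawa)
# TSAJ990101  residue volume, ProtOr (Tsai et al.)
# MAXF760101  normalized alpha-helix frequency (Maxfield & Scheraga)
# BIOV880101  information value for accessibility (Biou et al.)
# BLAM930101  helix propensity, T4 lysozyme position 44 (Blaber et al.)
# ---------------------------------------------------------------------------

AAINDEX_IDS = (
    "LIFS790101",
    "CEDJ970104",
    "MIYS990104",
    "NAKH920108",
    "TSAJ990101",
    "MAXF760101",
    "BIOV880101",
    "BLAM930101",
)

_AAINDEX_RAW: dict[str, dict[str, float]] = {
    "LIFS790101": {
        "A": 0.92, "R": 0.93, "N": 0.60, "D": 0.48, "C": 1.16,
        "Q": 0.95, "E": 0.61, "G": 0.61, "H": 0.93, "I": 1.81,
        "L": 1.30, "K": 0.70, "M": 1.19, "F": 1.25, "P": 0.40,
        "S": 0.82, "T": 1.12, "W": 1.54, "Y": 1.53, "V": 1.81,
    },
    "CEDJ970104": {
        "A": 7.9, "R": 4.9, "N": 4.0, "D": 5.5, "C": 1.9,
        "Q": 4.4, "E": 7.1, "G": 7.1, "H": 2.1, "I": 5.2,
        "L": 8.6, "K": 6.7, "M": 2.4, "F": 3.9, "P": 5.3,
        "S": 6.6, "T": 5.3, "W": 1.2, "Y": 3.1, "V": 6.8,
    },
    "MIYS990104": {
        "A": -0.04, "R": 0.07, "N": 0.13, "D": 0.19, "C": -0.38,
        "Q": 0.14, "E": 0.23, "G": 0.09, "H": -0.04, "I": -0.34,
        "L": -0.37, "K": 0.33, "M": -0.30, "F": -0.38, "P": 0.19,
        "S": 0.12, "T": 0.03, "W": -0.33, "Y": -0.29, "V": -0.29,
    },
    "NAKH920108": {
        "A": 9.36, "R": 0.27, "N": 2.31, "D": 0.94, "C": 2.56,
        "Q": 1.14, "E": 0.94, "G": 6.17, "H": 0.47, "I": 13.73,
        "L": 16.64, "K": 0.58, "M": 3.93, "F": 10.99, "P": 1.96,
        "S": 5.58, "T": 4.68, "W": 2.20, "Y": 3.13, "V": 12.43,
    },
    "TSAJ990101": {
        "A": 89.3, "R": 190.3, "N": 122.4, "D": 114.4, "C": 102.5,
        "Q": 146.9, "E": 138.8, "G": 63.8, "H": 157.5, "I": 163.0,
        "L": 163.1, "K": 165.1, "M": 165.8, "F": 190.8, "P": 121.6,
        "S": 94.2, "T": 119.6, "W": 226.4, "Y": 194.6, "V": 138.2,
    },
    "MAXF760101": {
        "A": 1.43, "R": 1.18, "N": 0.64, "D": 0.92, "C": 0.94,
        "Q": 1.22, "E": 1.67, "G": 0.46, "H": 0.98, "I": 1.04,
        "L": 1.36, "K": 1.27, "M": 1.53, "F": 1.19, "P": 0.49,
        "S": 0.70, "T": 0.78, "W": 1.01, "Y": 0.69, "V": 0.98,
    },
    "BIOV880101": {
        "A": 16.0, "R": -70.0, "N": -74.0, "D": -78.0, "C": 168.0,
        "Q": -73.0, "E": -106.0, "G": -13.0, "H": 50.0, "I": 151.0,
        "L": 145.0, "K": -141.0, "M": 124.0, "F": 189.0, "P": -20.0,
        "S": -70.0, "T": -38.0, "W": 145.0, "Y": 53.0, "V": 123.0,
    },
    "BLAM930101": {
        "A": 0.96, "R": 0.77, "N": 0.39, "D": 0.42, "C": 0.42,
        "Q": 0.80, "E": 0.53, "G": 0.00, "H": 0.57, "I": 0.84,
        "L": 0.92, "K": 0.73, "M": 0.86, "F": 0.59, "P": -2.50,
        "S": 0.53, "T": 0.54, "W": 0.58, "Y": 0.72, "V": 0.63,
    },
}


def aaindex_vector(index_id: str) -> np.ndarray:
    """Return the 20 values of one AAindex scale in canonical residue order."""
    raw = _AAINDEX_RAW[index_id]
    return np.array([raw[aa] for aa in AA_ORDER], dtype=float)


# ---------------------------------------------------------------------------
# Grantham (1974) chemical distance, rebuilt from its defining side-chain
# properties: composition c, polarity p, volume v, with
# D_ab = rho * sqrt(alpha (c_a-c_b)^2 + beta (p_a-p_b)^2 + gamma (v_a-v_b)^2)
# and rho fixed so that the mean over the 190 unordered pairs equals 100.
# ---------------------------------------------------------------------------

_GRANTHAM_C = {
    "A": 0.0, "R": 0.65, "N": 1.33, "D": 1.38, "C": 2.75,
    "Q": 0.89, "E": 0.92, "G": 0.74, "H": 0.58, "I": 0.0,
    "L": 0.0, "K": 0.33, "M": 0.0, "F": 0.0, "P": 0.39,
    "S": 1.42, "T": 0.71, "W": 0.13, "Y": 0.20, "V": 0.0,
}
_GRANTHAM_P = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5,
    "Q": 10.5, "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2,
    "L": 4.9, "K": 11.3, "M": 5.7, "F": 5.2, "P": 8.0,
    "S": 9.2, "T": 8.6, "W": 5.4, "Y": 6.2, "V": 5.9,
}
_GRANTHAM_V = {
    "A": 31.0, "R": 124.0, "N": 56.0, "D": 54.0, "C": 55.0,
    "Q": 85.0, "E": 83.0, "G": 3.0, "H": 96.0, "I": 111.0,
    "L": 111.0, "K": 119.0, "M": 105.0, "F": 132.0, "P": 32.5,
    "S": 32.0, "T": 61.0, "W": 170.0, "Y": 136.0, "V": 84.0,
}
_GRANTHAM_ALPHA, _GRANTHAM_BETA, _GRANTHAM_GAMMA = 1.833, 0.1018, 0.000399


def grantham_matrix(normalized: bool = False) -> np.ndarray:
    """20x20 Grantham chemical distance matrix in canonical residue order.

    With ``normalized=True`` the matrix is rescaled to [0, 1] by its maximum
    entry (the form consumed by the quasi-sequence-order descriptor);
    otherwise the mean over distinct pairs is 100, as originally published.
    """
    c = np.array([_GRANTHAM_C[a] for a in AA_ORDER])
    p = np.array([_GRANTHAM_P[a] for a in AA_ORDER])
    v = np.array([_GRANTHAM_V[a] for a in AA_ORDER])
    d = np.sqrt(
        _GRANTHAM_ALPHA * (c[:, None] - c[None, :]) ** 2
        + _GRANTHAM_BETA * (p[:, None] - p[None, :]) ** 2
        + _GRANTHAM_GAMMA * (v[:, None] - v[None, :]) ** 2
    )
    off = d[np.triu_indices(20, k=1)]
    d *= 100.0 / off.mean()
    if normalized:
        d /= d.max()
    return d


# ---------------------------------------------------------------------------
# Synthetic stand-in for the Schneider-Wrede physicochemical distance matrix.
# The published matrix is not redistributable here, so a SYNTHETIC surrogate
# with the same role is derived from three classical residue scales
# (Kyte-Doolittle hydropathy, Hopp-Woods hydrophilicity, residue mass), each
# standardized across the 20 residues; the Euclidean distance in that space is
# rescaled to [0, 1].  It preserves the properties the descriptor relies on:
# symmetry, zero diagonal and a chemically sensible neighbourhood structure.
# ---------------------------------------------------------------------------

_KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
_HOPP_WOODS = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0,
    "Q": 0.2, "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8,
    "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5, "P": 0.0,
    "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5,
}
_RESIDUE_MASS = {
    "A": 71.08, "R": 156.19, "N": 114.10, "D": 115.09, "C": 103.14,
    "Q": 128.13, "E": 129.12, "G": 57.05, "H": 137.14, "I": 113.16,
    "L": 113.16, "K": 128.17, "M": 131.19, "F": 147.18, "P": 97.12,
    "S": 87.08, "T": 101.10, "W": 186.21, "Y": 163.18, "V": 99.13,
}


def synthetic_physchem_matrix() -> np.ndarray:
    """Synthetic Schneider-Wrede-like distance matrix, scaled to [0, 1]."""
    cols = []
    for scale in (_KYTE_DOOLITTLE, _HOPP_WOODS, _RESIDUE_MASS):
        x = np.array([scale[a] for a in AA_ORDER])
        cols.append((x - x.mean()) / x.std())
    props = np.stack(cols, axis=1)
    d = np.sqrt(((props[:, None, :] - props[None, :, :]) ** 2).sum(axis=2))
    return d / d.max()


# ---------------------------------------------------------------------------
# Conjoint-triad classes: the 20 residues grouped into 7 classes by dipole
# moment and side-chain volume (Shen et al. convention).
# ---------------------------------------------------------------------------

CTF_CLASSES: tuple[frozenset[str], ...] = (
    frozenset("AGV"),
    frozenset("ILFP"),
    frozenset("YMTS"),
    frozenset("HNQW"),
    frozenset("RK"),
    frozenset("DE"),
    frozenset("C"),
)

# ---------------------------------------------------------------------------
# Composition/transition/distribution partitions: seven physicochemical
# properties, each splitting the 20 residues into 3 classes (Dubchak
# convention).
# ---------------------------------------------------------------------------

CTD_PROPERTIES = (
    "hydrophobicity",
    "vdw_volume",
    "polarity",
    "polarizability",
    "charge",
    "secondary_structure",
    "solvent_accessibility",
)

CTD_CLASSES: dict[str, tuple[frozenset[str], ...]] = {
    "hydrophobicity": (
        frozenset("EDKNQR"),       # polar
        frozenset("AGHPSTY"),      # neutral
        frozenset("CLVIMFW"),      # hydrophobic
    ),
    "vdw_volume": (
        frozenset("ACDGPST"),      # 0-2.78
        frozenset("EILNVQ"),       # 2.95-4.0
        frozenset("MHKFRYW"),      # 4.03-8.08
    ),
    "polarity": (
        frozenset("LIFWCMVY"),     # 4.9-6.2
        frozenset("AGPST"),        # 8.0-9.2
        frozenset("HQRKNED"),      # 10.4-13.0
    ),
    "polarizability": (
        frozenset("ADGST"),        # 0-0.108
        frozenset("CEILPQVN"),     # 0.128-0.186
        frozenset("KMHFRYW"),      # 0.219-0.409
    ),
    "charge": (
        frozenset("KR"),                   # positive
        frozenset("ANCQGHILMFPSTWYV"),     # neutral
        frozenset("DE"),                   # negative
    ),
    "secondary_structure": (
        frozenset("AEHKLMQR"),     # helix
        frozenset("VIYCWFT"),      # strand
        frozenset("DGNPS"),        # coil
    ),
    "solvent_accessibility": (
        frozenset("ACFGILVW"),     # buried
        frozenset("DEKNQR"),       # exposed
        frozenset("MSPTHY"),       # intermediate
    ),
}


def _check_partition(classes: tuple[frozenset[str], ...], what: str) -> None:
    seen: list[str] = []
    for cls in classes:
        seen.extend(cls)
    if sorted(seen) != sorted(AA_ORDER):
        raise ValueError(f"partition {what!r} does not cover the 20 residues exactly once")


@dataclass(frozen=True)
class PropertyTables:
    """Bundle of all residue-property constants consumed by the encoders.

    ``qso_distance`` maps a matrix name to a 20x20 symmetric distance matrix
    with zero diagonal, in canonical residue order.  ``qso_weight`` and
    ``qso_nlag`` are the sequence-order coupling weight and maximum lag of the
    quasi-sequence-order descriptor; ``nc5_window`` is the terminal window
    length of the binary profile descriptor.
    """

    aaindex8: dict[str, np.ndarray]
    qso_distance: dict[str, np.ndarray]
    ctf_classes: tuple[frozenset[str], ...] = CTF_CLASSES
    ctd_classes: dict[str, tuple[frozenset[str], ...]] = field(
        default_factory=lambda: dict(CTD_CLASSES)
    )
    qso_weight: float = 0.1
    qso_nlag: int = 30
    nc5_window: int = 5

    def __post_init__(self) -> None:
        _check_partition(self.ctf_classes, "conjoint-triad")
        for prop, classes in self.ctd_classes.items():
            _check_partition(classes, prop)
        for name, mat in self.qso_distance.items():
            if mat.shape != (20, 20):
                raise ValueError(f"distance matrix {name!r} is not 20x20")
            if not np.allclose(np.diag(mat), 0.0):
                raise ValueError(f"distance matrix {name!r} has a nonzero diagonal")

    def checksum(self) -> str:
        """Stable digest of every table, recorded with trained models."""
        h = hashlib.sha256()
        for key in sorted(self.aaindex8):
            h.update(key.encode())
            h.update(self.aaindex8[key].tobytes())
        for key in sorted(self.qso_distance):
            h.update(key.encode())
            h.update(self.qso_distance[key].tobytes())
        meta = {
            "ctf": sorted("".join(sorted(c)) for c in self.ctf_classes),
            "ctd": {p: ["".join(sorted(c)) for c in cls] for p, cls in self.ctd_classes.items()},
            "w": self.qso_weight,
            "nlag": self.qso_nlag,
            "window": self.nc5_window,
        }
        h.update(json.dumps(meta, sort_keys=True).encode())
        return h.hexdigest()


@lru_cache(maxsize=1)
def default_tables() -> PropertyTables:
    """The packaged default tables (cached; treat as immutable)."""
    return PropertyTables(
        aaindex8={i: aaindex_vector(i) for i in AAINDEX_IDS},
        qso_distance={
            "sw_synthetic": synthetic_physchem_matrix(),
            "grantham": grantham_matrix(normalized=True),
        },
    )
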