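"""Synthetic labelled peptide sets with a controllable class signal.

Two peptide classes are drawn residue-wise from mixture distributions over the
20-letter alphabet: positives from ``(1-effect)*uniform + effect*bias`` and
negatives from ``(1-effect)*uniform + effect*reversed(bias)``, where the
default bias enriches cationic/hydrophobic residues (K, R, L, F, W), the
hallmark composition of membranolytic anticancer peptides, and ``reversed``
flips the bias vector along the canonical residue order so the negative class
is enriched in a disjoint residue group.  ``effect=0`` gives two statistically
identical classes; ``effect=1`` gives maximally divergent compositions.
Lengths are uniform on the configured range (default 5-50, the dataset rule).

An optional terminal-motif mode plants a fixed 3-mer at the N-terminus of
positives, adding a position-specific signal that composition descriptors
cannot see but the terminal binary profile can.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import MAX_LENGTH, MIN_LENGTH, NEGATIVE_LABEL, POSITIVE_LABEL, Peptide, PeptideSet
from .tables import AA_ORDER


def default_pos_bias() -> dict[str, float]:
    """ACP-like residue tilt: enriched K, R (cationic) and L, F, W (hydrophobic)."""
    bias = {aa: 0.028 for aa in AA_ORDER}
    bias.update({"K": 0.14, "R": 0.14, "L": 0.11, "F": 0.10, "W": 0.09})
    return bias


@dataclass
class SynthConfig:
    """Generator settings: class sizes, length range, signal strength, seed."""

    n_pos: int = 266
    n_neg: int = 266
    length_range: tuple[int, int] = (MIN_LENGTH, MAX_LENGTH)
    effect: float = 0.8
    seed: int = 0
    pos_bias: dict[str, float] = field(default_factory=default_pos_bias)
    terminal_motif: str | None = None

    def __post_init__(self) -> None:
        if self.n_pos <= 0 or self.n_neg <= 0:
            raise ValueError("class sizes must be positive")
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError("effect must lie in [0, 1]")
        lo, hi = self.length_range
        if not (MIN_LENGTH <= lo <= hi <= MAX_LENGTH):
            raise ValueError(f"length range must lie within [{MIN_LENGTH}, {MAX_LENGTH}]")
        total = sum(self.pos_bias.get(aa, 0.0) for aa in AA_ORDER)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("pos_bias must sum to 1 over the 20 residues")


def _class_distributions(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    uniform = np.full(20, 1.0 / 20.0)
    bias = np.array([cfg.pos_bias.get(aa, 0.0) for aa in AA_ORDER])
    p_pos = (1.0 - cfg.effect) * uniform + cfg.effect * bias
    p_neg = (1.0 - cfg.effect) * uniform + cfg.effect * bias[::-1]
    return p_pos, p_neg


def _draw(rng: np.random.Generator, p: np.ndarray, n: int, lo: int, hi: int,
          prefix: str, label: str, motif: str | None) -> list[Peptide]:
    alphabet = np.array(list(AA_ORDER))
    out = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(alphabet, size=length, p=p))
        if motif:
            seq = motif + seq[len(motif):]
        out.append(Peptide(f"{prefix}_{i:04d}", seq, label))
    return out


def generate(cfg: SynthConfig) -> PeptideSet:
    """Generate a labelled peptide set, fully reproducible from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    p_pos, p_neg = _class_distributions(cfg)
    lo, hi = cfg.length_range
    pos = _draw(rng, p_pos, cfg.n_pos, lo, hi, "pos", POSITIVE_LABEL, cfg.terminal_motif)
    neg = _draw(rng, p_neg, cfg.n_neg, lo, hi, "neg", NEGATIVE_LABEL, None)
    return PeptideSet(pos + neg, provenance=[f"synthetic(seed={cfg.seed}, effect={cfg.effect})"])


def generate_split(cfg: SynthConfig, n_test_pos: int, n_test_neg: int) -> tuple[PeptideSet, PeptideSet]:
    """Generate independent train and held-out test sets from one seed."""
    train = generate(cfg)
    test_cfg = SynthConfig(
        n_pos=n_test_pos,
        n_neg=n_test_neg,
        length_range=cfg.length_range,
        effect=cfg.effect,
        seed=cfg.seed + 10_000,
        pos_bias=dict(cfg.pos_bias),
        terminal_motif=cfg.terminal_motif,
    )
    test = generate(test_cfg)
    test = PeptideSet(
        [Peptide(f"t{p.id}", p.sequence, p.label) for p in test],
        provenance=test.provenance,
    )
    return train, test
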