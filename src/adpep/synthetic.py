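"""Seeded synthetic peptide dataset generator.

Emulates the statistical shape of a curated antidiabetic-peptide collection
with two target classes (label 0 = effective against type 1 diabetes,
label 1 = type 2): roughly 2281 peptides with a ~73/27 class split, class 0
peptides shorter (mostly 5–15 residues, length mode near 9–10) and enriched
in polar/charged residues, class 1 peptides longer and enriched in the
hydrophobic residues I/L/V/F.  All class differences scale with a single
``effect_scale`` multiplier; at 0 the two classes are drawn from identical
distributions, giving null data for calibration checks.

The generator is a statistical stand-in for the real database, not a
surrogate of its actual marginals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .featurize import CANONICAL_RESIDUES, PeptideRecord

MIN_LENGTH, MAX_LENGTH = 2, 60
NONCANONICAL = "BJOUXZ"

# hydrophobicity tilt direction: +1 for strongly hydrophobic residues,
# -1 for polar/charged, 0 otherwise
_TILT = {aa: (1.0 if aa in "ILVF" else -1.0 if aa in "DEKRSTNQ" else 0.0)
         for aa in CANONICAL_RESIDUES}


def _lognormal_length_pmf(median: float, sigma: float) -> np.ndarray:
    """Discretized lognormal pmf over lengths 2..60."""
    k = np.arange(MIN_LENGTH, MAX_LENGTH + 1, dtype=float)
    logpdf = -((np.log(k) - np.log(median)) ** 2) / (2 * sigma ** 2) - np.log(k)
    pmf = np.exp(logpdf - logpdf.max())
    return pmf / pmf.sum()


def _composition(effect_scale: float, direction: float) -> np.ndarray:
    """Residue frequencies tilted along the hydrophobicity axis.

    ``direction`` is +1 (hydrophobic enrichment, class 1) or -1
    (polar/charged enrichment, class 0).
    """
    tilt = np.array([_TILT[aa] for aa in CANONICAL_RESIDUES])
    freq = np.exp(0.4 * effect_scale * direction * tilt)
    return freq / freq.sum()


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic dataset.

    ``length_dist`` and ``composition_bias`` may be given explicitly as
    per-class distributions; otherwise they are derived from
    ``effect_scale``: class 0 lengths follow a discretized lognormal with
    median 9.5, class 1 with median 9.5 * 1.9**effect_scale and a slightly
    heavier tail, and residue frequencies are exponentially tilted along a
    hydrophobicity axis.  ``class1_fraction`` defaults to 0.27, an
    approximation read off the pooled logistic confusion-matrix row totals
    (618/2281); the source tables are not fully consistent across methods,
    so this is an inference, not a database fact.
    """

    n_total: int = 2281
    class1_fraction: float = 0.27
    effect_scale: float = 1.0
    seed: int = 0
    length_dist: dict[int, np.ndarray] | None = None
    composition_bias: dict[int, np.ndarray] | None = None
    noncanonical_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not 0.0 < self.class1_fraction < 1.0:
            raise ValueError("class1_fraction must lie in (0, 1)")
        if self.effect_scale < 0:
            raise ValueError("effect_scale must be >= 0")
        if not 0.0 <= self.noncanonical_rate < 1.0:
            raise ValueError("noncanonical_rate must lie in [0, 1)")
        if self.length_dist is None:
            self.length_dist = {
                0: _lognormal_length_pmf(9.5, 0.35),
                1: _lognormal_length_pmf(
                    9.5 * 1.9 ** self.effect_scale,
                    0.35 + 0.10 * self.effect_scale),
            }
        if self.composition_bias is None:
            self.composition_bias = {
                0: _composition(self.effect_scale, -1.0),
                1: _composition(self.effect_scale, +1.0),
            }
        for cls in (0, 1):
            pmf = np.asarray(self.length_dist[cls], dtype=float)
            if pmf.shape != (MAX_LENGTH - MIN_LENGTH + 1,) or \
                    not np.isclose(pmf.sum(), 1.0) or (pmf < 0).any():
                raise ValueError(
                    f"length_dist[{cls}] must be a pmf over lengths "
                    f"{MIN_LENGTH}..{MAX_LENGTH}")
            freq = np.asarray(self.composition_bias[cls], dtype=float)
            if freq.shape != (len(CANONICAL_RESIDUES),) or \
                    not np.isclose(freq.sum(), 1.0) or (freq < 0).any():
                raise ValueError(
                    f"composition_bias[{cls}] must be residue frequencies "
                    f"over {CANONICAL_RESIDUES}")

    def to_dict(self) -> dict:
        """JSON-serializable echo of the resolved configuration."""
        return {
            "n_total": self.n_total,
            "class1_fraction": self.class1_fraction,
            "effect_scale": self.effect_scale,
            "seed": self.seed,
            "noncanonical_rate": self.noncanonical_rate,
            "length_support": [MIN_LENGTH, MAX_LENGTH],
            "length_dist": {c: list(map(float, self.length_dist[c]))
                            for c in (0, 1)},
            "composition_bias": {c: list(map(float, self.composition_bias[c]))
                                 for c in (0, 1)},
        }


def generate(config: SyntheticConfig) -> list[PeptideRecord]:
    """Draw a synthetic peptide dataset; deterministic per config seed."""
    rng = np.random.default_rng(config.seed)
    n1 = int(round(config.n_total * config.class1_fraction))
    labels = np.array([1] * n1 + [0] * (config.n_total - n1))
    rng.shuffle(labels)

    lengths_support = np.arange(MIN_LENGTH, MAX_LENGTH + 1)
    residues = np.array(list(CANONICAL_RESIDUES))
    noncanon = np.array(list(NONCANONICAL))
    width = len(str(config.n_total))

    records = []
    for i, label in enumerate(labels):
        length = int(rng.choice(lengths_support,
                                p=config.length_dist[int(label)]))
        seq_arr = rng.choice(residues, size=length,
                             p=config.composition_bias[int(label)])
        if config.noncanonical_rate > 0:
            mask = rng.random(length) < config.noncanonical_rate
            if mask.any():
                seq_arr[mask] = rng.choice(noncanon, size=int(mask.sum()))
        records.append(PeptideRecord(
            id=f"pep{i + 1:0{width}d}",
            sequence="".join(seq_arr),
            label=int(label)))
    return records
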