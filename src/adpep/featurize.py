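"""Sequence-derived and physicochemical peptide descriptors.

Each peptide sequence is mapped to a fixed-order numeric feature vector:

* ``AminoCount_*`` — occurrence counts of every letter A–Z (26 columns);
* ``AvgPosition_*`` — mean 1-based position of every letter, 0 when the
  letter is absent (26 columns);
* ``PairCount_*`` — overlapping dipeptide counts over the full 'AA'…'ZZ'
  alphabet (676 columns);
* ``Entropy`` — Shannon entropy of the residue distribution, in bits;
* ``MaxRepeat`` — longest run of a single residue;
* ``LZComplexity`` — phrase count of the LZ76 exhaustive-history parsing;
* ``PeptideLength`` and five physicochemical summaries (mean hydrophobicity,
  mean hydropathicity, mean hydrophilicity, net integer charge at pH 7,
  molecular weight in Da).

The full A–Z alphabet is used for the composition features so that rare
non-canonical letters (B, J, O, U, X, Z) are counted rather than silently
dropped; the physicochemical computation, by contrast, is strict by default
and rejects residues missing from its scales.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

ALPHABET: str = string.ascii_uppercase
CANONICAL_RESIDUES: str = "ARNDCQEGHILKMFPSTWYV"
PAIR_ALPHABET: tuple[str, ...] = tuple(a + b for a in ALPHABET for b in ALPHABET)

#: Eisenberg consensus hydrophobicity scale (normalized, unitless).
EISENBERG_HYDROPHOBICITY: dict[str, float] = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

#: Kyte–Doolittle hydropathy index (unitless).
KYTE_DOOLITTLE_HYDROPATHICITY: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Hopp–Woods hydrophilicity scale (unitless).
HOPP_WOODS_HYDROPHILICITY: dict[str, float] = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0,
    "Q": 0.2, "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8,
    "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5, "P": 0.0,
    "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5,
}

#: Integer side-chain charge at pH 7: K, R = +1; D, E = -1; everything else
#: (including H) = 0.
RESIDUE_CHARGE: dict[str, int] = {
    aa: (1 if aa in "KR" else -1 if aa in "DE" else 0)
    for aa in CANONICAL_RESIDUES
}

#: Average residue (monomer minus water) masses in Da.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "Q": 128.1307, "E": 129.1155, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

WATER_MASS: float = 18.02


class InvalidSequenceError(ValueError):
    """Raised for empty or otherwise unusable peptide sequences."""


class UnknownResidueError(ValueError):
    """Raised in strict mode when a residue is missing from the scales."""


def normalize_sequence(raw: str) -> str:
    """Uppercase and strip whitespace; error if nothing is left.

    Raises :class:`InvalidSequenceError` on an empty result and on characters
    outside A–Z.
    """
    seq = "".join(raw.split()).upper()
    if not seq:
        raise InvalidSequenceError("sequence is empty after normalization")
    bad = sorted(set(seq) - set(ALPHABET))
    if bad:
        raise InvalidSequenceError(
            f"sequence contains non-letter characters: {bad!r}"
        )
    return seq


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide: id, normalized sequence, binary label, extra columns.

    ``label`` is 0 for peptides effective against type 1 diabetes and 1 for
    those targeting type 2 diabetes.
    """

    id: str
    sequence: str
    label: int
    extras: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass(frozen=True)
class ResidueScales:
    """Per-residue scales used by :func:`physchem`.

    The defaults ship the Eisenberg consensus hydrophobicity, Kyte–Doolittle
    hydropathicity, Hopp–Woods hydrophilicity, integer charges at pH 7 and
    average residue masses; any of them can be swapped for an alternative
    convention.
    """

    hydrophobicity: Mapping[str, float] = field(
        default_factory=lambda: dict(EISENBERG_HYDROPHOBICITY))
    hydropathicity: Mapping[str, float] = field(
        default_factory=lambda: dict(KYTE_DOOLITTLE_HYDROPATHICITY))
    hydrophilicity: Mapping[str, float] = field(
        default_factory=lambda: dict(HOPP_WOODS_HYDROPHILICITY))
    charge: Mapping[str, int] = field(
        default_factory=lambda: dict(RESIDUE_CHARGE))
    mass: Mapping[str, float] = field(
        default_factory=lambda: dict(AVERAGE_RESIDUE_MASS))
    water_mass: float = WATER_MASS

    def __post_init__(self) -> None:
        for name in ("hydrophobicity", "hydropathicity", "hydrophilicity",
                     "charge", "mass"):
            scale = getattr(self, name)
            missing = sorted(set(CANONICAL_RESIDUES) - set(scale))
            if missing:
                raise ValueError(f"{name} scale is missing residues {missing}")
        if any(c not in (-1, 0, 1) for c in self.charge.values()):
            raise ValueError("charge values must be in {-1, 0, +1}")


DEFAULT_SCALES = ResidueScales()


# ---------------------------------------------------------------------------
# per-sequence descriptors
# ---------------------------------------------------------------------------

def amino_counts(seq: str) -> dict[str, int]:
    """Count occurrences of every letter A–Z in ``seq``."""
    seq = normalize_sequence(seq)
    counts = dict.fromkeys(ALPHABET, 0)
    for ch in seq:
        counts[ch] += 1
    return counts


def pair_counts(seq: str) -> dict[str, int]:
    """Count every overlapping adjacent pair over the 676-pair alphabet."""
    seq = normalize_sequence(seq)
    counts = dict.fromkeys(PAIR_ALPHABET, 0)
    for i in range(len(seq) - 1):
        counts[seq[i:i + 2]] += 1
    return counts


def avg_positions(seq: str) -> dict[str, float]:
    """Mean 1-based position of each letter; absent letters map to 0."""
    seq = normalize_sequence(seq)
    sums = dict.fromkeys(ALPHABET, 0)
    counts = dict.fromkeys(ALPHABET, 0)
    for i, ch in enumerate(seq, start=1):
        sums[ch] += i
        counts[ch] += 1
    return {aa: (sums[aa] / counts[aa] if counts[aa] else 0.0)
            for aa in ALPHABET}


def entropy(seq: str) -> float:
    """Shannon entropy of the residue composition, in bits."""
    seq = normalize_sequence(seq)
    n = len(seq)
    h = 0.0
    for count in amino_counts(seq).values():
        if count:
            p = count / n
            h -= p * math.log2(p)
    return h


def max_repeat(seq: str) -> int:
    """Length of the longest run of a single residue."""
    seq = normalize_sequence(seq)
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


def lz_complexity(seq: str) -> int:
    """LZ76 complexity: phrase count of the exhaustive-history parsing.

    Follows the Lempel–Ziv production process: the sequence is scanned left
    to right and split into the minimal number of phrases such that each
    phrase, minus its final symbol, is reproducible from the preceding
    history.  A run ``A^n`` (n >= 2) parses as ``A | A...A`` giving 2; a
    single symbol gives 1.
    """
    s = normalize_sequence(seq)
    n = len(s)
    if n == 1:
        return 1
    # Kaspar–Schuster scan; self-overlapping reproduction allowed, and an
    # incomplete final phrase counts as one phrase.
    c, i, k, l, k_max = 1, 0, 1, 1, 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            k_max = max(k, k_max)
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i, k, k_max = 0, 1, 1
            else:
                k = 1
    return c


def physchem(seq: str, scales: ResidueScales = DEFAULT_SCALES,
             strict: bool = True) -> dict[str, float]:
    """Physicochemical summary of a sequence.

    Hydrophobicity, hydropathicity and hydrophilicity are length-normalized
    means of per-residue scale values; charge is the integer sum of residue
    charges; molecular weight is the sum of average residue masses plus one
    water for the chain termini.

    With ``strict=False`` residues missing from a scale contribute 0 to sums
    and are excluded from the mean denominators.
    """
    seq = normalize_sequence(seq)
    unknown = sorted(set(seq) - set(scales.mass))
    if unknown and strict:
        raise UnknownResidueError(
            f"residue(s) {unknown} have no physicochemical scale entry"
        )
    known = [ch for ch in seq if ch in scales.mass]
    if not known:
        raise UnknownResidueError(
            "no residue in the sequence is covered by the scales"
        )
    n = len(known)
    return {
        "Hydrophobicity": sum(scales.hydrophobicity[c] for c in known) / n,
        "Hydropathicity": sum(scales.hydropathicity[c] for c in known) / n,
        "Hydrophilicity": sum(scales.hydrophilicity[c] for c in known) / n,
        "Charge": float(sum(scales.charge[c] for c in known)),
        "MolecularWeight": sum(scales.mass[c] for c in known)
        + scales.water_mass,
        "PeptideLength": float(len(seq)),
    }


# ---------------------------------------------------------------------------
# feature-table assembly
# ---------------------------------------------------------------------------

SEQUENCE_FEATURES = ("Entropy", "MaxRepeat", "LZComplexity")
PHYSCHEM_FEATURES = ("PeptideLength", "Hydrophobicity", "Hydropathicity",
                     "Hydrophilicity", "Charge", "MolecularWeight")


def feature_columns(extras: Sequence[str] = ()) -> list[str]:
    """The fixed, documented column order of the feature table."""
    cols = [f"AminoCount_{aa}" for aa in ALPHABET]
    cols += [f"AvgPosition_{aa}" for aa in ALPHABET]
    cols += [f"PairCount_{p}" for p in PAIR_ALPHABET]
    cols += list(SEQUENCE_FEATURES)
    cols += list(PHYSCHEM_FEATURES)
    cols += list(extras)
    return cols


def featurize_sequence(seq: str, scales: ResidueScales = DEFAULT_SCALES,
                       strict: bool = True) -> dict[str, float]:
    """All descriptors of one sequence, keyed by feature-column name."""
    row: dict[str, float] = {}
    for aa, c in amino_counts(seq).items():
        row[f"AminoCount_{aa}"] = float(c)
    for aa, p in avg_positions(seq).items():
        row[f"AvgPosition_{aa}"] = p
    for pair, c in pair_counts(seq).items():
        row[f"PairCount_{pair}"] = float(c)
    row["Entropy"] = entropy(seq)
    row["MaxRepeat"] = float(max_repeat(seq))
    row["LZComplexity"] = float(lz_complexity(seq))
    row.update(physchem(seq, scales, strict=strict))
    return row


def featurize_all(records: Iterable[PeptideRecord],
                  scales: ResidueScales = DEFAULT_SCALES,
                  strict: bool = True) -> pd.DataFrame:
    """Feature table for a set of peptides (rows indexed by peptide id).

    The column order is fixed and documented by :func:`feature_columns`;
    extra pass-through columns follow the computed descriptors.  A failure
    on any sequence is re-raised annotated with the offending record id.
    """
    records = list(records)
    if not records:
        raise InvalidSequenceError("no records to featurize")
    extra_names: list[str] = []
    for rec in records:
        for name in rec.extras:
            if name not in extra_names:
                extra_names.append(name)
    rows = []
    for rec in records:
        try:
            row = featurize_sequence(rec.sequence, scales, strict=strict)
        except ValueError as exc:
            raise type(exc)(f"record {rec.id!r}: {exc}") from exc
        for name in extra_names:
            row[name] = float(rec.extras.get(name, 0.0))
        rows.append(row)
    table = pd.DataFrame(rows, index=pd.Index([r.id for r in records],
                                              name="id"))
    return table[feature_columns(extra_names)]


def labels_vector(records: Iterable[PeptideRecord]) -> pd.Series:
    """Binary label series aligned with :func:`featurize_all` rows."""
    records = list(records)
    return pd.Series([r.label for r in records],
                     index=pd.Index([r.id for r in records], name="id"),
                     name="label", dtype=int)


def column_manifest(extras: Sequence[str] = ()) -> list[dict[str, str]]:
    """Machine-readable provenance of every feature column, in order."""
    manifest = []
    for name in feature_columns(extras):
        if name.startswith("AminoCount_"):
            group = "amino-acid composition (count of one letter)"
        elif name.startswith("AvgPosition_"):
            group = "amino-acid composition (mean 1-based position; 0 = absent)"
        elif name.startswith("PairCount_"):
            group = "dipeptide composition (overlapping pair count)"
        elif name in SEQUENCE_FEATURES:
            group = "sequence characteristic"
        elif name in PHYSCHEM_FEATURES:
            group = "physicochemical property"
        else:
            group = "pass-through extra"
        manifest.append({"name": name, "group": group})
    return manifest
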