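"""Physicochemical featurization of protein sequences.

Each protein is described by a fixed, ordered 431-component vector:
20 amino-acid composition fractions, 400 overlapping dipeptide
composition fractions, and 11 scalar descriptors (length, average
molecular weight, aromaticity, Guruprasad instability index,
isoelectric point, Kyte-Doolittle GRAVY, net charge at pH 7, helix /
turn / sheet residue fractions, and the reduced-cysteine molar
extinction coefficient at 280 nm).  The ordering is frozen: feature
matrices written by different runs are column-compatible by
construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    AA_AVERAGE_MASS,
    AMINO_ACIDS,
    AROMATIC_SET,
    DIWV,
    EXTINCTION_W,
    EXTINCTION_Y,
    HELIX_SET,
    KYTE_DOOLITTLE,
    MIN_PROTEIN_LENGTH,
    PKA_NEGATIVE,
    PKA_POSITIVE,
    SHEET_SET,
    TURN_SET,
    WATER_MASS,
)
from .errors import TooShortError

logger = logging.getLogger(__name__)

_STANDARD = set(AMINO_ACIDS)

#: Frozen 431-entry feature-name list.
FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"aac_{a}" for a in AMINO_ACIDS)
    + tuple(f"dpc_{a}{b}" for a in AMINO_ACIDS for b in AMINO_ACIDS)
    + (
        "length",
        "mol_weight_Da",
        "aromaticity",
        "instability_index",
        "isoelectric_point",
        "gravy",
        "charge_pH7",
        "frac_helix",
        "frac_turn",
        "frac_sheet",
        "extinction_reduced_M-1cm-1",
    )
)

N_FEATURES: int = len(FEATURE_NAMES)  # 431


@dataclass
class ProteinRecord:
    """An amino-acid sequence with its annotation and genome linkage."""

    id: str
    sequence: str
    product: str = ""
    genome_id: str = ""
    family_label: str = ""


@dataclass
class FeatureVector:
    """Ordered, named physicochemical description of one protein."""

    values: np.ndarray
    names: tuple[str, ...] = field(default=FEATURE_NAMES, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError(
                f"expected {len(self.names)} features, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite entries")

    def __len__(self) -> int:
        return len(self.values)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def sanitize(raw_sequence: str, min_length: int = MIN_PROTEIN_LENGTH) -> str:
    """Uppercase, strip gaps/stops, drop non-standard letters.

    Ambiguity codes (B, Z, X), selenocysteine/pyrrolysine (U, O) and any
    other non-standard character are removed with a logged warning; '*'
    and '-' are stripped silently.  Raises :class:`TooShortError` when
    fewer than ``min_length`` standard residues remain.
    """
    seq = raw_sequence.upper().replace("*", "").replace("-", "")
    kept = [c for c in seq if c in _STANDARD]
    n_dropped = len(seq) - len(kept)
    if n_dropped:
        logger.warning(
            "dropped %d non-standard residue(s) from sequence", n_dropped
        )
    if len(kept) < min_length:
        raise TooShortError(
            f"only {len(kept)} standard residues remain (minimum {min_length})"
        )
    return "".join(kept)


def aa_composition(sequence: str) -> np.ndarray:
    """Fraction of each of the 20 standard residues, in alphabetical order."""
    counts = np.array([sequence.count(a) for a in AMINO_ACIDS], dtype=float)
    return counts / len(sequence)


def dipeptide_composition(sequence: str) -> np.ndarray:
    """Overlapping dipeptide fractions (400 entries, row-major AA..YY)."""
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    counts = np.zeros((20, 20))
    for a, b in zip(sequence, sequence[1:]):
        counts[idx[a], idx[b]] += 1
    return counts.ravel() / max(len(sequence) - 1, 1)


def molecular_weight(sequence: str) -> float:
    """Average molecular weight in Daltons (residue masses + one water)."""
    free = sum(AA_AVERAGE_MASS[a] for a in sequence)
    return free - (len(sequence) - 1) * WATER_MASS


def aromaticity(sequence: str) -> float:
    """Fraction of aromatic residues (F, W, Y)."""
    return sum(1 for a in sequence if a in AROMATIC_SET) / len(sequence)


def instability_index(sequence: str) -> float:
    """Guruprasad instability index: (10/L) * sum of dipeptide weights."""
    total = sum(DIWV[a][b] for a, b in zip(sequence, sequence[1:]))
    return total * 10.0 / len(sequence)


def charge_at_pH(sequence: str, pH: float) -> float:
    """Net charge from Henderson-Hasselbalch over termini and side chains.

    Uses the flat Bjellqvist pKa set in :mod:`phagekit.constants`;
    strictly decreasing in pH.
    """
    pos = 0.0
    pos += 1.0 / (1.0 + 10.0 ** (pH - PKA_POSITIVE["Nterm"]))
    for aa in "KRH":
        n = sequence.count(aa)
        if n:
            pos += n / (1.0 + 10.0 ** (pH - PKA_POSITIVE[aa]))
    neg = 0.0
    neg += 1.0 / (1.0 + 10.0 ** (PKA_NEGATIVE["Cterm"] - pH))
    for aa in "DECY":
        n = sequence.count(aa)
        if n:
            neg += n / (1.0 + 10.0 ** (PKA_NEGATIVE[aa] - pH))
    return pos - neg


def isoelectric_point(sequence: str, tol: float = 1e-4, max_iter: int = 100) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    The charge model is strictly decreasing in pH, so the root is unique.
    """
    lo, hi = 0.0, 14.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        c = charge_at_pH(sequence, mid)
        if abs(c) < tol and hi - lo < 1e-10:
            break
        if c > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    return sum(KYTE_DOOLITTLE[a] for a in sequence) / len(sequence)


def ss_fractions(sequence: str) -> tuple[float, float, float]:
    """Fractions of residues in the helix, turn and sheet propensity sets.

    The sets overlap (L is both helical and sheet-forming), so the three
    fractions need not sum to anything in particular.
    """
    L = len(sequence)
    helix = sum(1 for a in sequence if a in HELIX_SET) / L
    turn = sum(1 for a in sequence if a in TURN_SET) / L
    sheet = sum(1 for a in sequence if a in SHEET_SET) / L
    return helix, turn, sheet


def extinction_reduced(sequence: str) -> float:
    """Molar extinction at 280 nm assuming all cysteines reduced."""
    return EXTINCTION_W * sequence.count("W") + EXTINCTION_Y * sequence.count("Y")


def featurize(record: ProteinRecord, pre_sanitized: bool = False) -> FeatureVector:
    """Compute the full 431-component descriptor vector for one protein.

    Deterministic; propagates :class:`TooShortError` from sanitization.
    Set ``pre_sanitized`` when the sequence is already clean to skip the
    (idempotent) sanitization pass.
    """
    seq = record.sequence if pre_sanitized else sanitize(record.sequence)
    helix, turn, sheet = ss_fractions(seq)
    scalars = np.array(
        [
            float(len(seq)),
            molecular_weight(seq),
            aromaticity(seq),
            instability_index(seq),
            isoelectric_point(seq),
            gravy(seq),
            charge_at_pH(seq, 7.0),
            helix,
            turn,
            sheet,
            extinction_reduced(seq),
        ]
    )
    values = np.concatenate(
        [aa_composition(seq), dipeptide_composition(seq), scalars]
    )
    return FeatureVector(values)


def featurize_many(records: list[ProteinRecord]) -> tuple[np.ndarray, list[str]]:
    """Featurize a list of records into an (n, 431) matrix.

    Records failing sanitization are dropped with a logged warning.
    Returns the matrix and the ids of the rows kept, in input order.
    """
    rows, ids = [], []
    for rec in records:
        try:
            rows.append(featurize(rec).values)
        except TooShortError as exc:
            logger.warning("skipping %s: %s", rec.id, exc)
            continue
        ids.append(rec.id)
    matrix = np.vstack(rows) if rows else np.empty((0, N_FEATURES))
    return matrix, ids
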