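"""Naive reference implementations of the physicochemical descriptors.

Deliberately simple, loop-based code kept independent of the package's
vectorized/cached implementations; published constant tables are taken
straight from Biopython's data modules.  Used to validate every scalar
descriptor on random sequences.
"""

from collections import Counter

from Bio.Data.IUPACData import protein_weights
from Bio.SeqUtils.ProtParamData import DIWV, kd
from scipy.optimize import brentq

AA = "ACDEFGHIKLMNPQRSTVWY"
WATER = 18.0153

# flat Bjellqvist pKa convention (documented in the package constants)
_POS = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
_NEG = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}


def aac(seq):
    counts = Counter(seq)
    return [counts.get(a, 0) / len(seq) for a in AA]


def dpc(seq):
    counts = Counter(seq[i:i + 2] for i in range(len(seq) - 1))
    total = len(seq) - 1
    return [counts.get(a + b, 0) / total for a in AA for b in AA]


def mol_weight(seq):
    total = 0.0
    for c in seq:
        total += protein_weights[c]
    return total - (len(seq) - 1) * WATER


def aromaticity(seq):
    return sum(c in "FWY" for c in seq) / len(seq)


def instability(seq):
    total = 0.0
    for i in range(len(seq) - 1):
        total += DIWV[seq[i]][seq[i + 1]]
    return 10.0 / len(seq) * total


def gravy(seq):
    return sum(kd[c] for c in seq) / len(seq)


def charge(seq, pH):
    pos = 1.0 / (1.0 + 10.0 ** (pH - _POS["Nterm"]))
    neg = 1.0 / (1.0 + 10.0 ** (_NEG["Cterm"] - pH))
    for c in seq:
        if c in "KRH":
            pos += 1.0 / (1.0 + 10.0 ** (pH - _POS[c]))
        elif c in "DECY":
            neg += 1.0 / (1.0 + 10.0 ** (_NEG[c] - pH))
    return pos - neg


def pI(seq):
    return brentq(lambda p: charge(seq, p), 0.0, 14.0, xtol=1e-12)


def ss_fractions(seq):
    helix = sum(c in "VIYFWL" for c in seq) / len(seq)
    turn = sum(c in "NPGS" for c in seq) / len(seq)
    sheet = sum(c in "EMAL" for c in seq) / len(seq)
    return helix, turn, sheet


def extinction_reduced(seq):
    return 5500 * seq.count("W") + 1490 * seq.count("Y")


def brute_force_contacts(coords_a, coords_b, cutoff):
    """All-pairs interface search: residue indices of A with any atom
    within cutoff of any atom of B.  coords_* : {resnum: [(x,y,z), ...]}."""
    hits = set()
    for ra, atoms_a in coords_a.items():
        found = False
        for xa, ya, za in atoms_a:
            for atoms_b in coords_b.values():
                for xb, yb, zb in atoms_b:
                    d2 = (xa - xb) ** 2 + (ya - yb) ** 2 + (za - zb) ** 2
                    if d2 <= cutoff * cutoff:
                        hits.add(ra)
                        found = True
                        break
                if found:
                    break
            if found:
                break
    return hits
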