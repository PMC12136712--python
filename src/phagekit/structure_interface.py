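"""Protein-protein interface analysis and alignment conservation profiling.

Interface residues of one chain group are those with any heavy atom
within a distance cutoff (default 5 Å, inclusive) of any heavy atom of
the other group — the standard contact definition for e.g. a phage
receptor-binding protein docked on its host receptor.  Contiguous runs
of six or more interface residues delimit candidate interaction regions.
Alignment columns are profiled for occupancy (non-gap fraction),
conservation (modal-residue frequency) and information content, the
inputs to a sequence logo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from sklearn.decomposition import PCA

from .errors import ValidationError

GAP_CHARS = frozenset("-.")


@dataclass
class Residue:
    number: int  # author numbering
    name: str
    icode: str = ""
    atoms: list[tuple[str, float, float, float]] = field(default_factory=list)


@dataclass
class StructureModel:
    """chains -> ordered residues -> heavy-atom coordinates."""

    chains: dict[str, list[Residue]]

    def coords(self, chain_ids: set[str]) -> tuple[np.ndarray, list[tuple[str, Residue]]]:
        """Stacked heavy-atom coordinates and a parallel atom->residue map."""
        pts, owners = [], []
        for cid in sorted(chain_ids):
            if cid not in self.chains:
                raise ValidationError(f"unknown chain id {cid!r}")
            for res in self.chains[cid]:
                for _, x, y, z in res.atoms:
                    pts.append((x, y, z))
                    owners.append((cid, res))
        return np.asarray(pts, dtype=float), owners


@dataclass
class InterfaceResidue:
    chain_id: str
    number: int
    icode: str
    name: str
    min_distance: float


@dataclass
class InterfaceRegion:
    chain_id: str
    start_residue: int
    end_residue: int

    @property
    def length(self) -> int:
        return self.end_residue - self.start_residue + 1


@dataclass
class ColumnProfile:
    occupancy: float
    conservation: float  # NaN when the column is all-gap
    modal_residue: str
    information_bits: float
    low_alignment_ratio: bool


def interface_residues(
    model: StructureModel,
    group_a: set[str],
    group_b: set[str],
    cutoff: float = 5.0,
) -> list[InterfaceResidue]:
    """Residues of ``group_a`` with any heavy atom within ``cutoff`` Å
    (inclusive) of any heavy atom of ``group_b``.

    The per-residue minimum cross-group distance is reported.  Uses a
    k-d tree on the partner group, so the search is near-linear in atom
    count.
    """
    if not group_a or not group_b:
        raise ValidationError("both chain groups must be non-empty")
    if group_a & group_b:
        raise ValidationError("chain groups must be disjoint")
    pts_a, owners_a = model.coords(group_a)
    pts_b, _ = model.coords(group_b)
    if len(pts_a) == 0 or len(pts_b) == 0:
        return []
    tree = cKDTree(pts_b)
    dists, _ = tree.query(pts_a)
    best: dict[tuple[str, int, str], tuple[Residue, str, float]] = {}
    for (cid, res), dmin in zip(owners_a, dists):
        key = (cid, res.number, res.icode)
        if key not in best or dmin < best[key][2]:
            best[key] = (res, cid, float(dmin))
    out = [
        InterfaceResidue(cid, res.number, res.icode, res.name, dmin)
        for (res, cid, dmin) in best.values()
        if dmin <= cutoff
    ]
    out.sort(key=lambda r: (r.chain_id, r.number, r.icode))
    return out


def contiguous_regions(
    residue_numbers: set[int], min_len: int = 6, chain_id: str = ""
) -> list[InterfaceRegion]:
    """Maximal runs of consecutive residue numbers of length >= min_len."""
    if not residue_numbers:
        return []
    nums = sorted(residue_numbers)
    regions = []
    start = prev = nums[0]
    for x in nums[1:]:
        if x == prev + 1:
            prev = x
            continue
        if prev - start + 1 >= min_len:
            regions.append(InterfaceRegion(chain_id, start, prev))
        start = prev = x
    if prev - start + 1 >= min_len:
        regions.append(InterfaceRegion(chain_id, start, prev))
    return regions


def _column_array(msa: list[str]) -> np.ndarray:
    if not msa:
        raise ValidationError("empty alignment")
    L = len(msa[0])
    if any(len(s) != L for s in msa):
        raise ValidationError("sequences are not aligned (unequal lengths)")
    return np.array([list(s.upper()) for s in msa])


def column_profile(
    msa: list[str], occupancy_threshold: float = 0.5
) -> list[ColumnProfile]:
    """Per-column occupancy, conservation, modal residue and information.

    Conservation is the modal residue's frequency among non-gap symbols;
    information content is log2(20) minus the Shannon entropy of the
    non-gap residue distribution, in bits.  Columns with occupancy below
    ``occupancy_threshold`` are flagged as low-alignment-ratio; all-gap
    columns carry NaN conservation.
    """
    cols = _column_array(msa).T
    out = []
    for col in cols:
        residues = [c for c in col if c not in GAP_CHARS]
        occ = len(residues) / len(col)
        if not residues:
            out.append(ColumnProfile(0.0, float("nan"), "", 0.0, True))
            continue
        values, counts = np.unique(residues, return_counts=True)
        top = int(counts.argmax())
        cons = counts[top] / counts.sum()
        freqs = counts / counts.sum()
        entropy = float(-(freqs * np.log2(freqs)).sum())
        ic = math.log2(20) - entropy
        out.append(
            ColumnProfile(
                occupancy=occ,
                conservation=float(cons),
                modal_residue=str(values[top]),
                information_bits=ic,
                low_alignment_ratio=occ < occupancy_threshold,
            )
        )
    return out


def logo_matrix(
    msa: list[str], position_range: tuple[int, int] | None = None
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Position-frequency matrix and per-position information content.

    Frequencies are computed among non-gap symbols (gap columns render
    as blanks in a logo).  ``position_range`` is 1-based inclusive;
    default is the whole alignment.  Returns (freq matrix of shape
    (positions, alphabet), alphabet, IC bits per position).
    """
    from .constants import AMINO_ACIDS

    cols = _column_array(msa).T
    if position_range is not None:
        lo, hi = position_range
        if not (1 <= lo <= hi <= len(cols)):
            raise ValidationError("position range outside alignment")
        cols = cols[lo - 1:hi]
    alphabet = list(AMINO_ACIDS)
    freq = np.zeros((len(cols), len(alphabet)))
    ic = np.zeros(len(cols))
    for p, col in enumerate(cols):
        residues = [c for c in col if c not in GAP_CHARS]
        if not residues:
            continue
        for c in residues:
            if c in AMINO_ACIDS:
                freq[p, alphabet.index(c)] += 1
        total = freq[p].sum()
        if total:
            freq[p] /= total
            nz = freq[p][freq[p] > 0]
            ic[p] = math.log2(20) + float((nz * np.log2(nz)).sum())
    return freq, alphabet, ic


def pca_embed(
    feature_matrix: np.ndarray, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Column-centered SVD scores of a feature matrix.

    Sign convention: each component is flipped so its largest-magnitude
    loading is positive, making scores reproducible across runs.
    Returns (scores of shape (n, k), explained-variance fractions).
    """
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need a 2-D matrix with at least 2 rows")
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    for c in range(k):
        load = pca.components_[c]
        if load[np.abs(load).argmax()] < 0:
            scores[:, c] *= -1
            pca.components_[c] *= -1
    return scores, pca.explained_variance_ratio_
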