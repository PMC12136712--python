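"""Comparative genomics: genome statistics, hit filtering, functional-module
detection, greedy protein clustering with pan-genome partitioning,
fragment-based average nucleotide identity (ANI), and UPGMA trees.

ANI follows the orthologous-fragment scheme: both genomes are chopped
into consecutive 1020-bp windows, fragments are paired by reciprocal
best hits, and ANI is the mean identity over those pairs.  The hit
search seeds candidate fragment pairs on shared exact k-mers (as a
BLAST-style word match would) before running a full global alignment,
so unrelated fragments are never force-aligned.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .errors import ValidationError

logger = logging.getLogger(__name__)

# Global-alignment scoring used throughout (affine gaps).
MATCH_SCORE = 2
MISMATCH_SCORE = -1
GAP_OPEN = -4
GAP_EXTEND = -1

#: ANI defaults: published orthologous-fragment window, alignability floor,
#: and the exact-word seeding prerequisite.
ANI_FRAGMENT_LEN = 1020
ANI_IDENTITY_FLOOR = 35.0
ANI_SEED_K = 12
ANI_MIN_SEEDS = 8
ANI_MAX_CANDIDATES = 5


@dataclass
class Feature:
    """One annotated interval on a genome (1-based inclusive coordinates)."""

    kind: str  # CDS, tRNA or other
    start: int
    end: int
    strand: str  # '+' or '-'
    product: str = ""
    functional_category: str = ""
    id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("CDS", "tRNA", "other"):
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValidationError(f"bad coordinates [{self.start}, {self.end}]")


@dataclass
class GenomeRecord:
    """Nucleotide sequence plus annotated features."""

    id: str
    sequence: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValidationError(
                    f"feature [{f.start},{f.end}] exceeds genome length {len(self.sequence)}"
                )


@dataclass
class HitRecord:
    """One pairwise similarity hit (BLAST outfmt-6 style)."""

    query_id: str
    subject_id: str
    percent_identity: float
    query_coverage: float
    e_value: float
    bitscore: float

    def __post_init__(self) -> None:
        for name in ("percent_identity", "query_coverage", "e_value", "bitscore"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} is not finite")
        if not 0 <= self.percent_identity <= 100:
            raise ValidationError("percent_identity outside [0, 100]")
        if not 0 <= self.query_coverage <= 100:
            raise ValidationError("query_coverage outside [0, 100]")
        if self.e_value < 0:
            raise ValidationError("e_value must be >= 0")


@dataclass
class GeneRun:
    """A maximal run of co-oriented, co-categorized genes."""

    category: str
    strand: str
    member_ids: list[str]
    start: int
    end: int


@dataclass
class PanGenomeSummary:
    """Core / accessory / unique partition of protein clusters."""

    clusters: list[tuple[str, list[str], frozenset[str]]]
    core_count: int
    accessory_count: int
    unique_count: int


def genome_stats(g: GenomeRecord) -> tuple[int, float, float]:
    """(length in bp, GC percent, coding-density percent).

    Coding density is the fraction of the genome covered by the union of
    CDS intervals — overlapping genes are merged, not double-counted.
    """
    if not g.sequence:
        raise ValidationError("empty genome sequence")
    length = len(g.sequence)
    gc = (g.sequence.count("G") + g.sequence.count("C")) / length * 100.0
    intervals = sorted(
        (f.start, f.end) for f in g.features if f.kind == "CDS"
    )
    covered = 0
    cur_start, cur_end = None, None
    for s, e in intervals:
        if cur_end is None or s > cur_end + 1:
            if cur_end is not None:
                covered += cur_end - cur_start + 1
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        covered += cur_end - cur_start + 1
    return length, gc, covered / length * 100.0


def filter_hits(
    hits: list[HitRecord],
    min_identity: float = 50.0,
    min_coverage: float = 85.0,
    max_e: float = 1e-9,
) -> list[HitRecord]:
    """Keep hits passing all three thresholds (all boundaries inclusive)."""
    return [
        h
        for h in hits
        if h.percent_identity >= min_identity
        and h.query_coverage >= min_coverage
        and h.e_value <= max_e
    ]


def locate_modules(
    g: GenomeRecord, category: str, max_gap_genes: int = 2
) -> list[GeneRun]:
    """Find maximal runs of same-strand genes of one functional category.

    Genes of the category extend the current run if they lie on the same
    strand and at most ``max_gap_genes`` other genes intervene; a
    category gene on the opposite strand closes the run and starts a new
    one.  Used e.g. to call a lysis cassette (endolysin-holin-spanin
    block) from functional annotations.
    """
    ordered = sorted(enumerate(g.features), key=lambda t: (t[1].start, t[1].end))
    runs: list[GeneRun] = []
    cur: list[tuple[int, Feature]] = []

    def close() -> None:
        if cur:
            feats = [f for _, f in cur]
            runs.append(
                GeneRun(
                    category=category,
                    strand=feats[0].strand,
                    member_ids=[f.id or f.product for f in feats],
                    start=min(f.start for f in feats),
                    end=max(f.end for f in feats),
                )
            )

    for pos, (_, feat) in enumerate(ordered):
        if feat.functional_category != category:
            continue
        if cur:
            last_pos = cur[-1][0]
            gap = pos - last_pos - 1
            if feat.strand == cur[-1][1].strand and gap <= max_gap_genes:
                cur.append((pos, feat))
                continue
            close()
            cur = []
        cur.append((pos, feat))
    close()
    return runs


def _make_aligner(
    match: float = MATCH_SCORE,
    mismatch: float = MISMATCH_SCORE,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


_DEFAULT_ALIGNER = _make_aligner()


def pairwise_identity(
    seq_a: str, seq_b: str, aligner: Align.PairwiseAligner | None = None
) -> float:
    """Percent identity from one global alignment (affine gap penalties).

    Identity = matching columns / total alignment columns * 100, gaps
    counted as columns.
    """
    if not seq_a or not seq_b:
        raise ValidationError("cannot align an empty sequence")
    al = aligner or _DEFAULT_ALIGNER
    aln = al.align(seq_a, seq_b)[0]
    counts = aln.counts()
    return counts.identities / aln.length * 100.0


def greedy_cluster(
    seqs: list[tuple[str, str]], id_threshold: float = 0.5
) -> list[tuple[str, list[str]]]:
    """Centroid-greedy clustering at a fractional identity threshold.

    Sequences are processed longest-first (ties by id, so the outcome is
    deterministic); each joins the first existing centroid it matches at
    >= threshold, otherwise founds a new cluster.  Mirrors the greedy
    centroid search of the usual 50 %-identity protein clustering step.
    """
    ordered = sorted(seqs, key=lambda t: (-len(t[1]), t[0]))
    centroids: list[tuple[str, str]] = []
    members: dict[str, list[str]] = {}
    for sid, seq in ordered:
        placed = False
        for cid, cseq in centroids:
            if pairwise_identity(seq, cseq) / 100.0 >= id_threshold:
                members[cid].append(sid)
                placed = True
                break
        if not placed:
            centroids.append((sid, seq))
            members[sid] = [sid]
    return [(cid, members[cid]) for cid, _ in centroids]


def pan_genome(
    clusters: list[tuple[str, list[str]]],
    protein_to_genome: dict[str, str],
    n_genomes: int,
) -> PanGenomeSummary:
    """Partition clusters into core, accessory and unique gene families.

    Core: present in all genomes.  Unique: confined to a single genome.
    Accessory: everything in between.
    """
    out = []
    core = acc = uniq = 0
    for cid, member_ids in clusters:
        genomes = frozenset(protein_to_genome[m] for m in member_ids)
        if len(genomes) == n_genomes:
            core += 1
        elif len(genomes) == 1:
            uniq += 1
        else:
            acc += 1
        out.append((cid, member_ids, genomes))
    return PanGenomeSummary(out, core, acc, uniq)


def _fragment(seq: str, fragment_len: int) -> list[str]:
    n = len(seq) // fragment_len
    return [seq[i * fragment_len:(i + 1) * fragment_len] for i in range(n)]


def _kmer_sets(frags: list[str], k: int) -> list[set[str]]:
    return [{f[i:i + k] for i in range(len(f) - k + 1)} for f in frags]


def orthoani(
    g1: GenomeRecord | str,
    g2: GenomeRecord | str,
    fragment_len: int = ANI_FRAGMENT_LEN,
    identity_floor: float = ANI_IDENTITY_FLOOR,
    seed_k: int = ANI_SEED_K,
    min_seeds: int = ANI_MIN_SEEDS,
    max_candidates: int = ANI_MAX_CANDIDATES,
) -> float | None:
    """Fragment-based ANI between two genomes, in percent.

    Both genomes are cut into consecutive ``fragment_len`` windows (the
    sub-window tail is discarded).  Candidate fragment pairs must share
    at least ``min_seeds`` exact ``seed_k``-mers; the best-identity
    candidate per fragment in each direction defines best hits, and ANI
    is the mean identity over reciprocal best pairs at or above the
    alignability floor.  Returns ``None`` ("undefined") when no fragment
    pair qualifies — the genomes are not alignable at this granularity.
    """
    seq1 = g1.sequence if isinstance(g1, GenomeRecord) else g1.upper()
    seq2 = g2.sequence if isinstance(g2, GenomeRecord) else g2.upper()
    frags1, frags2 = _fragment(seq1, fragment_len), _fragment(seq2, fragment_len)
    if len(frags1) < 2 or len(frags2) < 2:
        raise ValidationError("too short: need at least 2 fragments per genome")
    kmers1, kmers2 = _kmer_sets(frags1, seed_k), _kmer_sets(frags2, seed_k)

    identity_cache: dict[tuple[int, int], float] = {}

    def ident(i: int, j: int) -> float:
        if (i, j) not in identity_cache:
            identity_cache[(i, j)] = pairwise_identity(frags1[i], frags2[j])
        return identity_cache[(i, j)]

    def best_hits(src_kmers, dst_kmers, forward: bool) -> dict[int, int]:
        hits: dict[int, int] = {}
        for i, ks in enumerate(src_kmers):
            seeded = [
                (len(ks & dk), j) for j, dk in enumerate(dst_kmers)
            ]
            seeded = [(c, j) for c, j in seeded if c >= min_seeds]
            seeded.sort(reverse=True)
            best_j, best_id = None, -1.0
            for _, j in seeded[:max_candidates]:
                pid = ident(i, j) if forward else ident(j, i)
                if pid > best_id:
                    best_id, best_j = pid, j
            if best_j is not None and best_id >= identity_floor:
                hits[i] = best_j
        return hits

    fwd = best_hits(kmers1, kmers2, forward=True)
    rev = best_hits(kmers2, kmers1, forward=False)
    pair_ids = [
        ident(i, j) for i, j in fwd.items() if rev.get(j) == i
    ]
    if not pair_ids:
        logger.info("ANI undefined: no reciprocal fragment pairs above floor")
        return None
    return float(np.mean(pair_ids))


def upgma(distance_matrix: np.ndarray, labels: list[str]) -> str:
    """Average-linkage (UPGMA) agglomeration to an ultrametric Newick tree.

    The matrix must be symmetric with a zero diagonal.  At each step the
    closest cluster pair merges at height d/2; ties are broken by the
    lexicographically smaller pair of cluster representatives (a
    cluster's representative is its smallest leaf label).  Branch length
    of a child = parent height - child height.
    """
    d = np.asarray(distance_matrix, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise ValidationError("distance matrix does not match labels")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0) or (d < 0).any():
        raise ValidationError("matrix must be symmetric, zero-diagonal, non-negative")
    if n == 1:
        return f"{labels[0]}:0;"

    # cluster id -> (newick, height, size, representative label)
    clusters = {i: (labels[i], 0.0, 1, labels[i]) for i in range(n)}
    dist = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }

    def fmt(x: float) -> str:
        return f"{x:.10g}"

    next_id = n
    while len(clusters) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (
                kv[1],
                tuple(sorted((clusters[kv[0][0]][3], clusters[kv[0][1]][3]))),
            ),
        )
        (i, j), dij = best
        ni, nj = clusters[i][2], clusters[j][2]
        height = dij / 2.0
        nwk_i, h_i, _, rep_i = clusters[i]
        nwk_j, h_j, _, rep_j = clusters[j]
        # display order: lexicographically smaller representative first
        first = (nwk_i, h_i, rep_i) if rep_i <= rep_j else (nwk_j, h_j, rep_j)
        second = (nwk_j, h_j, rep_j) if rep_i <= rep_j else (nwk_i, h_i, rep_i)
        newick = (
            f"({first[0]}:{fmt(height - first[1])},"
            f"{second[0]}:{fmt(height - second[1])})"
        )
        merged = (newick, height, ni + nj, min(rep_i, rep_j))
        for k in list(clusters):
            if k in (i, j):
                continue
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            dist[(min(next_id, k), max(next_id, k))] = (ni * dik + nj * djk) / (ni + nj)
        del dist[(i, j)]
        del clusters[i], clusters[j]
        clusters[next_id] = merged
        next_id += 1

    (newick, _, _, _), = clusters.values()
    return newick + ";"
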