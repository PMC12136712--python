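"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its arguments (including the
integer seed) and returns the generated object together with the ground
truth used to build it, so downstream estimators can be validated
against known parameters: multi-family proteomes with family-specific
residue compositions, triphasic one-step growth curves, genome pairs at
a controlled substitution divergence, two-chain complexes with a planted
contact set, and alignments with a prescribed per-column conservation
profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .genome_compare import GenomeRecord
from .phenotype import GrowthCurve
from .seq_features import AMINO_ACIDS, ProteinRecord

_BASES = "ACGT"


@dataclass
class FamilyProfile:
    """Residue-composition signature of one phage family's tail proteins."""

    name: str
    residue_freqs: np.ndarray  # 20-simplex over AMINO_ACIDS order
    length_range: tuple[int, int] = (150, 400)
    tail_count: int = 3

    def __post_init__(self) -> None:
        self.residue_freqs = np.asarray(self.residue_freqs, dtype=float)
        if self.residue_freqs.shape != (20,) or not np.isclose(
            self.residue_freqs.sum(), 1.0
        ):
            raise ValidationError("residue_freqs must be a 20-simplex")
        if self.length_range[0] < 30:
            raise ValidationError("minimum protein length is 30")


def dirichlet_profile(
    name: str,
    favored_residues: str,
    concentration: float = 50.0,
    seed: int = 0,
    **kwargs,
) -> FamilyProfile:
    """Draw a family profile concentrated on a residue subset.

    ``favored_residues`` get Dirichlet weight ``concentration``, the
    rest weight 1 — two families favoring disjoint subsets are separable
    by composition alone.
    """
    rng = np.random.default_rng(seed)
    alpha = np.ones(20)
    for c in favored_residues:
        alpha[AMINO_ACIDS.index(c)] = concentration
    return FamilyProfile(name, rng.dirichlet(alpha), **kwargs)


def gen_proteomes(
    profiles: list[FamilyProfile],
    genomes_per_family: int,
    seed: int,
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Sample tail proteomes for ``genomes_per_family`` genomes per family.

    Sequences are i.i.d. draws from each family's residue frequencies;
    product strings contain "tail" so the records pass tail-protein
    selection.  Returns the records and the genome_id -> family map.
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    records: list[ProteinRecord] = []
    label_map: dict[str, str] = {}
    for prof in profiles:
        for g in range(genomes_per_family):
            genome_id = f"{prof.name}_g{g:03d}"
            label_map[genome_id] = prof.name
            for p in range(prof.tail_count):
                L = int(rng.integers(prof.length_range[0], prof.length_range[1] + 1))
                seq = "".join(rng.choice(aa, size=L, p=prof.residue_freqs))
                records.append(
                    ProteinRecord(
                        id=f"{genome_id}_tail{p}",
                        sequence=seq,
                        product="tail fiber protein",
                        genome_id=genome_id,
                        family_label=prof.name,
                    )
                )
    return records, label_map


def gen_growth_curve(
    baseline: float = 1.0e5,
    plateau: float = 1.46e7,
    latent: float = 20.0,
    rise_duration: float = 40.0,
    noise_cv: float = 0.05,
    sampling_interval: float = 5.0,
    t_max: float = 90.0,
    seed: int = 0,
) -> tuple[GrowthCurve, dict]:
    """Triphasic one-step growth curve: flat baseline, linear rise, plateau.

    Multiplicative lognormal noise with coefficient of variation
    ``noise_cv`` is applied pointwise.  Defaults emulate a phage with a
    20-minute latent period and burst size 146 sampled every 5 minutes.
    Returns the curve and the ground-truth parameter dict.
    """
    if plateau < baseline:
        raise ValidationError("plateau must be >= baseline")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_max + sampling_interval / 2, sampling_interval)
    clean = np.empty_like(times)
    for i, t in enumerate(times):
        if t <= latent:
            clean[i] = baseline
        elif t >= latent + rise_duration:
            clean[i] = plateau
        else:
            clean[i] = baseline + (plateau - baseline) * (t - latent) / rise_duration
    if noise_cv > 0:
        sigma = np.sqrt(np.log(1.0 + noise_cv**2))
        noise = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=times.shape)
        titers = clean * noise
    else:
        titers = clean
    truth = {
        "baseline": baseline,
        "plateau": plateau,
        "latent_min": latent,
        "rise_duration_min": rise_duration,
        "burst_size": plateau / baseline,
        "noise_cv": noise_cv,
        "sampling_interval_min": sampling_interval,
        "seed": seed,
    }
    return GrowthCurve(times, titers), truth


def gen_genome(length: int, seed: int, gc: float = 0.5, genome_id: str = "synthetic") -> GenomeRecord:
    """Random genome with the given GC fraction."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(list(_BASES), size=length, p=p))
    return GenomeRecord(genome_id, seq)


def mutate_genome(
    g: GenomeRecord, substitution_rate: float, seed: int
) -> tuple[GenomeRecord, int]:
    """Per-site i.i.d. substitution to a different base at the given rate.

    Returns the mutated genome and the realized substitution count.
    """
    if not 0 <= substitution_rate <= 1:
        raise ValidationError("substitution rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    seq = np.array(list(g.sequence))
    hit = rng.random(len(seq)) < substitution_rate
    n_sub = int(hit.sum())
    for i in np.flatnonzero(hit):
        alternatives = [b for b in _BASES if b != seq[i]]
        seq[i] = alternatives[rng.integers(3)]
    return GenomeRecord(f"{g.id}_mut", "".join(seq)), n_sub


def gen_complex(
    n_contacts: int,
    n_decoys: int,
    cutoff: float = 5.0,
    margin: float = 1.0,
    seed: int = 0,
) -> tuple[str, list[tuple[int, int]]]:
    """Two-chain single-atom-per-residue complex with a planted contact set.

    Chain A and chain B each hold ``n_contacts + n_decoys`` residues.
    Contact pair k places residue k of A and residue k of B within
    ``cutoff`` of each other; every other cross-chain atom pair is
    farther than ``cutoff + margin`` by a widely spaced grid layout.
    Returns PDB-format text and the planted (resnum_A, resnum_B) pairs.
    Refuses a non-positive margin — the planted set would be ambiguous.
    """
    if margin <= 0:
        raise ValidationError("margin must be positive for an unambiguous contact set")
    if cutoff <= 0.5:
        raise ValidationError("cutoff too small")
    rng = np.random.default_rng(seed)
    spacing = 4.0 * (cutoff + margin)
    total = n_contacts + n_decoys

    coords_a: list[np.ndarray] = []
    coords_b: list[np.ndarray] = []
    side = int(np.ceil(np.sqrt(2 * total))) + 1
    cells = [(i, j) for i in range(side) for j in range(side)]
    rng.shuffle(cells)
    ci = iter(cells)
    for k in range(n_contacts):
        cx, cy = next(ci)
        base = np.array([cx * spacing, cy * spacing, 0.0])
        a = base + rng.normal(0, 0.3, 3)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        dist = rng.uniform(max(0.8, cutoff / 3), cutoff - 0.05)
        coords_a.append(a)
        coords_b.append(a + direction * dist)
    for _ in range(n_decoys):
        cx, cy = next(ci)
        coords_a.append(np.array([cx * spacing, cy * spacing, spacing / 2]) + rng.normal(0, 0.3, 3))
        cx, cy = next(ci)
        coords_b.append(np.array([cx * spacing, cy * spacing, -spacing / 2]) + rng.normal(0, 0.3, 3))

    lines = []
    serial = 1

    def atom_line(serial: int, chain: str, resnum: int, xyz: np.ndarray) -> str:
        x, y, z = xyz
        return (
            f"ATOM  {serial:5d}  CA  GLY {chain}{resnum:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )

    for r, xyz in enumerate(coords_a, start=1):
        lines.append(atom_line(serial, "A", r, xyz))
        serial += 1
    lines.append("TER")
    for r, xyz in enumerate(coords_b, start=1):
        lines.append(atom_line(serial, "B", r, xyz))
        serial += 1
    lines.append("TER")
    lines.append("END")
    contacts = [(k + 1, k + 1) for k in range(n_contacts)]
    return "\n".join(lines) + "\n", contacts


def gen_msa(
    n_seqs: int,
    length: int,
    conservation_profile: list[float] | np.ndarray,
    gap_rate: float = 0.0,
    seed: int = 0,
) -> list[str]:
    """Alignment whose column j shows its modal residue with probability
    conservation_profile[j] (others uniform over the remaining 19);
    gaps are i.i.d. at ``gap_rate``.
    """
    profile = np.asarray(conservation_profile, dtype=float)
    if profile.shape != (length,):
        raise ValidationError("conservation profile length must match alignment length")
    if not np.all((profile >= 0) & (profile <= 1)):
        raise ValidationError("conservation values must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    aa = list(AMINO_ACIDS)
    modal = [aa[rng.integers(20)] for _ in range(length)]
    seqs = []
    for _ in range(n_seqs):
        chars = []
        for j in range(length):
            if gap_rate > 0 and rng.random() < gap_rate:
                chars.append("-")
            elif rng.random() < profile[j]:
                chars.append(modal[j])
            else:
                others = [c for c in aa if c != modal[j]]
                chars.append(others[rng.integers(19)])
        seqs.append("".join(chars))
    return seqs
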