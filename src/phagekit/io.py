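"""Format readers and writers binding standard file formats to the
toolkit's domain types.

FASTA / GenBank / aligned-FASTA parsing is delegated to Biopython;
hit tables use the 12-column BLAST outfmt-6 dialect (optionally with a
13th query-coverage column); PDB files are read through Bio.PDB with
MODEL 1 only, heavy atoms only, solvent and heteroatoms excluded.
Coordinates are 1-based inclusive throughout (the GenBank convention).
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.PDB import PDBParser

from .constants import descriptor_constants
from .errors import ParseError
from .genome_compare import Feature, GenomeRecord, HitRecord
from .phenotype import AssayRow, AssayTable, GrowthCurve
from .seq_features import FEATURE_NAMES, ProteinRecord
from .structure_interface import Residue, StructureModel

logger = logging.getLogger(__name__)


def to_zero_based(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start_1based - 1, end_1based


def to_one_based(start_0based: int, end_0based: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start_0based + 1, end_0based


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file."""
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, FileNotFoundError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return [(r.id, str(r.seq).upper()) for r in records]


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    """Protein records; the description after the id becomes the product."""
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, FileNotFoundError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    out = []
    for r in records:
        product = r.description[len(r.id):].strip() if r.description.startswith(r.id) else r.description
        out.append(ProteinRecord(id=r.id, sequence=str(r.seq), product=product))
    return out


def read_genbank(path: str | Path) -> GenomeRecord:
    """One GenBank flat-file record -> GenomeRecord (1-based inclusive)."""
    try:
        rec = SeqIO.read(str(path), "genbank")
    except (ValueError, FileNotFoundError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    features = []
    for f in rec.features:
        if f.type in ("source",):
            continue
        kind = f.type if f.type in ("CDS", "tRNA") else "other"
        quals = f.qualifiers
        start, end = to_one_based(int(f.location.start), int(f.location.end))
        features.append(
            Feature(
                kind=kind,
                start=start,
                end=end,
                strand="-" if f.location.strand == -1 else "+",
                product=quals.get("product", [""])[0],
                functional_category=quals.get("function", [""])[0],
                id=quals.get("locus_tag", quals.get("protein_id", [""]))[0],
            )
        )
    return GenomeRecord(id=rec.id, sequence=str(rec.seq).upper(), features=features)


def genbank_cds_proteins(path: str | Path) -> list[ProteinRecord]:
    """CDS translations of a GenBank record as ProteinRecords."""
    try:
        rec = SeqIO.read(str(path), "genbank")
    except (ValueError, FileNotFoundError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    out = []
    for i, f in enumerate(rec.features):
        if f.type != "CDS" or "translation" not in f.qualifiers:
            continue
        quals = f.qualifiers
        pid = quals.get("locus_tag", quals.get("protein_id", [f"{rec.id}_cds{i}"]))[0]
        out.append(
            ProteinRecord(
                id=pid,
                sequence=quals["translation"][0],
                product=quals.get("product", [""])[0],
                genome_id=rec.id,
            )
        )
    return out


def read_pdb(path: str | Path, keep_het: bool = False) -> StructureModel:
    """PDB file -> StructureModel: MODEL 1 only, heavy atoms only.

    Waters and heteroatom groups are excluded unless ``keep_het``;
    for alternate locations the highest-occupancy conformer is kept.
    """
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure("s", str(path))
    except (ValueError, FileNotFoundError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise ParseError(f"{path}: no models found")
    if len(models) > 1:
        logger.warning("%s: %d models present, parsing MODEL 1 only", path, len(models))
    chains: dict[str, list[Residue]] = {}
    for chain in models[0]:
        residues = []
        for res in chain:
            het, num, icode = res.id
            if het.strip() and not keep_het:
                continue
            atoms = []
            for atom in res:  # disordered atoms yield their selected (highest-occupancy) conformer
                element = (atom.element or "").strip() or atom.get_name()[0]
                if element == "H":
                    continue
                x, y, z = atom.coord
                atoms.append((element, float(x), float(y), float(z)))
            if atoms:
                residues.append(Residue(number=num, name=res.get_resname(), icode=icode.strip(), atoms=atoms))
        if residues:
            chains[chain.id] = residues
    if not chains:
        raise ParseError(f"{path}: no usable residues")
    return StructureModel(chains)


def read_msa(path: str | Path) -> tuple[list[str], list[str]]:
    """Aligned FASTA -> (ids, aligned sequences)."""
    try:
        aln = AlignIO.read(str(path), "fasta")
    except (ValueError, FileNotFoundError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return [r.id for r in aln], [str(r.seq).upper() for r in aln]


def read_hits_table(
    path: str | Path, query_lengths: dict[str, int] | None = None
) -> list[HitRecord]:
    """BLAST outfmt-6 tabular hits.

    Accepts the common 13-column "std qcovs" dialect; with plain
    12-column input, query coverage is computed from the aligned query
    span and ``query_lengths`` (required in that case).
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    hits = []
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        vals = list(row)
        if len(vals) == 13:
            coverage = float(vals[12])
        elif len(vals) == 12:
            if query_lengths is None:
                raise ParseError(
                    f"{path}:{lineno}: 12-column table needs query_lengths to derive coverage"
                )
            qid = str(vals[0])
            if qid not in query_lengths:
                raise ParseError(f"{path}:{lineno}: unknown query id {qid!r}")
            coverage = (abs(int(vals[7]) - int(vals[6])) + 1) / query_lengths[qid] * 100.0
        else:
            raise ParseError(f"{path}:{lineno}: expected 12 or 13 columns, got {len(vals)}")
        hits.append(
            HitRecord(
                query_id=str(vals[0]),
                subject_id=str(vals[1]),
                percent_identity=float(vals[2]),
                query_coverage=coverage,
                e_value=float(vals[10]),
                bitscore=float(vals[11]),
            )
        )
    return hits


def read_assay_csv(path: str | Path) -> AssayTable:
    """Host-range assay CSV.

    Columns: strain_id, species, spot, then either pfu_rep1..repN or
    eop_percent; an optional is_host column (0/1) flags the reference.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    required = {"strain_id", "species", "spot"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    rep_cols = [c for c in df.columns if c.startswith("pfu_rep")]
    rows = []
    for _, r in df.iterrows():
        reps = [float(r[c]) for c in rep_cols if pd.notna(r[c])]
        rows.append(
            AssayRow(
                strain_id=str(r["strain_id"]),
                species=str(r["species"]),
                spot_result=str(r["spot"]),
                replicate_pfu=reps,
                eop_percent=float(r["eop_percent"]) if "eop_percent" in df.columns and pd.notna(r["eop_percent"]) else None,
                is_host=bool(r["is_host"]) if "is_host" in df.columns and pd.notna(r["is_host"]) else False,
            )
        )
    return AssayTable(rows)


def read_growth_csv(path: str | Path) -> GrowthCurve:
    """Growth-curve CSV with columns time_min, pfu_per_ml."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not {"time_min", "pfu_per_ml"}.issubset(df.columns):
        raise ParseError(f"{path}: need columns time_min, pfu_per_ml")
    return GrowthCurve(df["time_min"].to_numpy(), df["pfu_per_ml"].to_numpy())


def write_growth_csv(curve: GrowthCurve, path: str | Path) -> None:
    pd.DataFrame({"time_min": curve.times, "pfu_per_ml": curve.titers}).to_csv(
        path, index=False
    )


def write_feature_matrix(
    matrix: np.ndarray, ids: list[str], path: str | Path, sidecar: bool = True
) -> None:
    """Feature matrix CSV (id + 431 named columns) plus a sidecar JSON of
    the descriptor constants used."""
    df = pd.DataFrame(matrix, columns=list(FEATURE_NAMES))
    df.insert(0, "id", ids)
    df.to_csv(path, index=False)
    if sidecar:
        sidecar_path = Path(path).with_suffix(".constants.json")
        with open(sidecar_path, "w") as fh:
            json.dump(descriptor_constants(), fh, indent=2)


def read_feature_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Inverse of :func:`write_feature_matrix`; validates column names."""
    df = pd.read_csv(path)
    if list(df.columns[1:]) != list(FEATURE_NAMES):
        raise ParseError(f"{path}: feature column names do not match the frozen order")
    return df.iloc[:, 1:].to_numpy(dtype=float), df["id"].astype(str).tolist()
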