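"""Readers and writers for the formats the package touches.

FASTA and alignments go through Biopython, PDB Cα extraction through
Bio.PDB, and the pair-table CSV dialect through pandas; this module adds
the strict validation layer (duplicate ids, coverage ranges, missing
columns, missing Cα atoms) with errors that name the file, record and
rule violated.  Residue numbering is 1-based in structures and reports,
0-based internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.PDB import PDBParser
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import validate_sequence
from .pair_curation import PairRecord
from .structure_analysis import StructureModel

__all__ = [
    "SequenceRecord",
    "PAIR_TABLE_COLUMNS",
    "read_fasta",
    "write_fasta",
    "read_pair_table",
    "write_pair_table",
    "read_msa",
    "read_ca_coords",
    "write_pdb_ca",
]

PAIR_TABLE_COLUMNS = (
    "pair_id",
    "meso_id",
    "thermo_id",
    "meso_seq",
    "thermo_seq",
    "meso_ogt_K",
    "thermo_ogt_K",
    "cov_meso",
    "cov_thermo",
)


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    residues: str
    description: str = ""


def read_fasta(path: str | Path, *, allow_x: bool = True) -> list[SequenceRecord]:
    """Read a protein FASTA file into normalized (uppercase) records.

    Lowercase residues are uppercased with a warning; duplicate ids raise.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    dupes: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        if raw != raw.upper():
            warnings.warn(
                f"{path.name}: record {rec.id!r} contains lowercase residues; uppercasing",
                stacklevel=2,
            )
        residues = validate_sequence(
            raw, allow_x=allow_x, name=f"{path.name}: record {rec.id!r}"
        )
        if rec.id in seen:
            dupes.append(rec.id)
        seen.add(rec.id)
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    if dupes:
        raise ValueError(f"{path.name}: duplicate sequence ids: {', '.join(sorted(set(dupes)))}")
    return records


def write_fasta(path: str | Path, records: Iterable[SequenceRecord]) -> None:
    """Write records as wrapped FASTA; round-trips byte-stably with read_fasta."""
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_pair_table(path: str | Path) -> list[PairRecord]:
    """Read the homolog-pair CSV dialect into typed records.

    OGTs are parsed as Kelvin floats; coverages outside [0,1] and
    unparseable numerics reject the row with its line number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in PAIR_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s): {', '.join(missing)}")
    records: list[PairRecord] = []
    for row_idx, row in df.iterrows():
        line_no = int(row_idx) + 2  # 1-based, after header
        values = {}
        for col in ("meso_ogt_K", "thermo_ogt_K", "cov_meso", "cov_thermo"):
            try:
                values[col] = float(row[col])
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path.name} line {line_no}: cannot parse {col}={row[col]!r} as a number"
                ) from exc
        for col in ("cov_meso", "cov_thermo"):
            if not (0.0 <= values[col] <= 1.0):
                raise ValueError(
                    f"{path.name} line {line_no}: {col}={values[col]} outside [0,1]"
                )
        try:
            records.append(
                PairRecord(
                    pair_id=str(row["pair_id"]),
                    meso_id=str(row["meso_id"]),
                    thermo_id=str(row["thermo_id"]),
                    meso_seq=str(row["meso_seq"]),
                    thermo_seq=str(row["thermo_seq"]),
                    meso_ogt=values["meso_ogt_K"],
                    thermo_ogt=values["thermo_ogt_K"],
                    cov_meso=values["cov_meso"],
                    cov_thermo=values["cov_thermo"],
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path.name} line {line_no}: {exc}") from exc
    return records


def write_pair_table(path: str | Path, pairs: Sequence[PairRecord]) -> None:
    """Write pairs in the CSV dialect read by :func:`read_pair_table`."""
    df = pd.DataFrame(
        {
            "pair_id": [p.pair_id for p in pairs],
            "meso_id": [p.meso_id or f"{p.pair_id}_meso" for p in pairs],
            "thermo_id": [p.thermo_id or f"{p.pair_id}_thermo" for p in pairs],
            "meso_seq": [p.meso_seq for p in pairs],
            "thermo_seq": [p.thermo_seq for p in pairs],
            "meso_ogt_K": [p.meso_ogt for p in pairs],
            "thermo_ogt_K": [p.thermo_ogt for p in pairs],
            "cov_meso": [p.cov_meso for p in pairs],
            "cov_thermo": [p.cov_thermo for p in pairs],
        }
    )
    df.to_csv(path, index=False)


def read_msa(path: str | Path, fmt: str = "fasta") -> list[tuple[str, str]]:
    """Read an alignment (aligned FASTA or Stockholm) as (id, aligned seq) pairs."""
    if fmt not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format {fmt!r}")
    aln = AlignIO.read(str(path), fmt)
    pairs = [(rec.id, str(rec.seq).upper()) for rec in aln]
    ids = [i for i, _ in pairs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{Path(path).name}: duplicate ids in alignment")
    return pairs


_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def read_ca_coords(
    path: str | Path, chain: str | None = None
) -> tuple[StructureModel, str]:
    """Extract Cα coordinates (and a one-letter sequence) from a PDB file.

    One Cα per residue in residue-number order; the first altloc is kept
    with a warning.  A residue without a Cα, or an absent chain, raises.
    Unknown residue types map to ``X`` in the returned sequence.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    model = next(structure.get_models())
    chains = {c.id: c for c in model}
    if chain is None:
        if len(chains) > 1:
            raise ValueError(
                f"{path.name}: multiple chains ({', '.join(sorted(chains))}); specify one"
            )
        chain_obj = next(iter(chains.values()))
    else:
        if chain not in chains:
            raise ValueError(
                f"{path.name}: chain {chain!r} not found (has {', '.join(sorted(chains))})"
            )
        chain_obj = chains[chain]

    coords, numbers, letters = [], [], []
    for residue in chain_obj:
        hetfield, resseq, icode = residue.id
        if hetfield.strip():
            continue  # skip waters/heteroatoms
        if "CA" not in residue:
            raise ValueError(
                f"{path.name}: residue {residue.get_resname()} {resseq}{icode.strip()} "
                f"in chain {chain_obj.id!r} has no CA atom"
            )
        atom = residue["CA"]
        if atom.is_disordered():
            warnings.warn(
                f"{path.name}: altloc on CA of residue {resseq}; keeping first",
                stacklevel=2,
            )
            atom = atom.disordered_get_list()[0]
        coords.append(atom.get_coord())
        numbers.append(int(resseq))
        letters.append(_THREE_TO_ONE.get(residue.get_resname().upper(), "X"))
    if not coords:
        raise ValueError(f"{path.name}: no ATOM records in chain {chain_obj.id!r}")
    return (
        StructureModel(
            coords=np.asarray(coords, dtype=float),
            residue_numbers=tuple(numbers),
        ),
        "".join(letters),
    )


def write_pdb_ca(path: str | Path, sequence: str, coords: np.ndarray, chain: str = "A") -> None:
    """Write a minimal CA-only PDB (1-based residue numbering)."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(sequence), 3):
        raise ValueError(
            f"coords shape {coords.shape} does not match sequence length {len(sequence)}"
        )
    lines = []
    for i, (aa, (x, y, z)) in enumerate(zip(sequence.upper(), coords), start=1):
        resname = _ONE_TO_THREE.get(aa, "UNK")
        lines.append(
            f"ATOM  {i:5d}  CA  {resname} {chain}{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
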