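"""Protein structure and sequence I/O.

Reads single-chain Calpha traces (optionally full N/CA/C/O backbones) from
PDB files, writes per-residue prediction tables, and provides the minimal
FASTA bookkeeping the pipeline needs.  Residue indices are 0-based in
memory and 1-based in every file.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser

# 3-letter -> 1-letter, with the common modified residues mapped to their
# parent amino acid.  Anything else becomes 'X' and keeps its coordinates.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # modified residues with a standard parent
    "MSE": "M", "SEC": "C", "PYL": "K", "SEP": "S", "TPO": "T",
    "PTR": "Y", "CSO": "C", "HYP": "P", "MLY": "K",
}
ONE_TO_THREE = {v: k for k, v in reversed(list(THREE_TO_ONE.items()))}

# physically plausible Calpha-Calpha distance for consecutive residues
_MIN_CA_CA = 2.5
_MAX_CA_CA = 4.5


class StructureParseError(ValueError):
    """Raised when a structure file cannot be turned into a residue trace."""


@dataclass
class ProteinRecord:
    """A single protein chain: sequence, Calpha trace, optional extras.

    Attributes
    ----------
    id : str
        Identifier, conventionally ``"<pdbid>_<chain>"``.
    sequence : str
        One-letter amino-acid string of length n.
    ca_coords : (n, 3) float array
        Calpha coordinates in Angstrom.
    backbone : (n, 4, 3) float array, optional
        N/CA/C/O coordinates per residue, in that atom order.
    labels : (n,) int array, optional
        Binary binding-site labels.
    resnums : (n,) int array
        Author residue numbers (defaults to 1..n).
    chain_breaks : set of int
        Indices i such that the bond between residues i and i+1 is broken
        (residues dropped in between, or an implausible Calpha gap).
    """

    id: str
    sequence: str
    ca_coords: np.ndarray
    backbone: np.ndarray | None = None
    labels: np.ndarray | None = None
    resnums: np.ndarray | None = None
    chain_breaks: set = field(default_factory=set)

    def __post_init__(self):
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        n = len(self.sequence)
        if self.ca_coords.shape != (n, 3):
            raise ValueError(
                f"{self.id}: sequence length {n} != coordinate rows "
                f"{self.ca_coords.shape}"
            )
        if n == 0:
            raise ValueError(f"{self.id}: empty chain")
        if not np.all(np.isfinite(self.ca_coords)):
            raise ValueError(f"{self.id}: non-finite coordinates")
        if self.resnums is None:
            self.resnums = np.arange(1, n + 1)
        self.resnums = np.asarray(self.resnums, dtype=int)
        if self.resnums.shape != (n,):
            raise ValueError(f"{self.id}: resnums length mismatch")
        if self.backbone is not None:
            self.backbone = np.asarray(self.backbone, dtype=float)
            if self.backbone.shape != (n, 4, 3):
                raise ValueError(f"{self.id}: backbone must be (n, 4, 3)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError(f"{self.id}: labels length mismatch")
            if not np.isin(self.labels, [0, 1]).all():
                raise ValueError(f"{self.id}: labels must be 0/1")
        # flag implausible consecutive Calpha gaps as chain breaks
        if n > 1:
            d = np.linalg.norm(np.diff(self.ca_coords, axis=0), axis=1)
            bad = np.nonzero((d <= _MIN_CA_CA) | (d >= _MAX_CA_CA))[0]
            self.chain_breaks = set(self.chain_breaks) | set(bad.tolist())

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return self.n_residues


def read_structure(path, chain: str) -> ProteinRecord:
    """Read one chain of a PDB file into a :class:`ProteinRecord`.

    Residues without a Calpha atom are dropped and a chain break is
    flagged; HETATM entries other than mapped modified residues (MSE etc.)
    are ignored; alternate locations resolve to the highest-occupancy
    conformer (Biopython's convention); only the first model is read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise StructureParseError(f"{path}: no models")
    if chain not in [c.id for c in model]:
        raise StructureParseError(f"{path}: chain {chain!r} not found")

    seq, coords, resnums, backbone = [], [], [], []
    breaks = set()
    have_full_backbone = True
    dropped_since_last = False
    for res in model[chain]:
        hetflag, resseq, _icode = res.id
        resname = res.get_resname().strip()
        if hetflag != " " and resname not in THREE_TO_ONE:
            continue  # waters, ligands
        if "CA" not in res:
            dropped_since_last = True
            continue
        if dropped_since_last and coords:
            breaks.add(len(coords) - 1)
        dropped_since_last = False
        seq.append(THREE_TO_ONE.get(resname, "X"))
        coords.append(res["CA"].get_coord())
        resnums.append(resseq)
        if all(a in res for a in ("N", "CA", "C", "O")):
            backbone.append([res[a].get_coord() for a in ("N", "CA", "C", "O")])
        else:
            have_full_backbone = False
    if not coords:
        raise StructureParseError(
            f"{path}: chain {chain!r} has no residues with a Calpha atom"
        )
    return ProteinRecord(
        id=f"{path.stem}_{chain}",
        sequence="".join(seq),
        ca_coords=np.array(coords, dtype=float),
        backbone=np.array(backbone, dtype=float) if have_full_backbone else None,
        resnums=np.array(resnums, dtype=int),
        chain_breaks=breaks,
    )


def write_structure(record: ProteinRecord, path) -> None:
    """Write a record as PDB ATOM records (CA-only, or full backbone if present).

    Output is byte-deterministic for identical inputs.
    """
    lines = []
    serial = 1
    for i, aa in enumerate(record.sequence):
        resname = ONE_TO_THREE.get(aa, "UNK")
        atoms = (
            [("CA", record.ca_coords[i])]
            if record.backbone is None
            else list(zip(("N", "CA", "C", "O"), record.backbone[i]))
        )
        for name, xyz in atoms:
            elem = name[0]
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {resname:>3s} A"
                f"{int(record.resnums[i]):4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {elem:>2s}\n"
            )
            serial += 1
    lines.append("END\n")
    Path(path).write_text("".join(lines))


def write_predictions(record: ProteinRecord, scores, binary, path) -> None:
    """Write a per-residue prediction table (TSV).

    Columns: residue_index (1-based), resnum, amino_acid, probability
    (6 decimals), predicted_label.  Byte-deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    binary = np.asarray(binary, dtype=int)
    n = record.n_residues
    if scores.shape != (n,) or binary.shape != (n,):
        raise ValueError(
            f"{record.id}: expected {n} scores/labels, "
            f"got {scores.shape}/{binary.shape}"
        )
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError(f"{record.id}: scores outside [0, 1]")
    buf = io.StringIO()
    buf.write("residue_index\tresnum\tamino_acid\tprobability\tpredicted_label\n")
    for i in range(n):
        buf.write(
            f"{i + 1}\t{int(record.resnums[i])}\t{record.sequence[i]}\t"
            f"{scores[i]:.6f}\t{int(binary[i])}\n"
        )
    Path(path).write_text(buf.getvalue())


def read_predictions(path):
    """Read a prediction TSV back: (residue_index, resnum, aa, scores, binary)."""
    lines = Path(path).read_text().rstrip("\n").split("\n")
    header = lines[0].split("\t")
    expected = ["residue_index", "resnum", "amino_acid", "probability", "predicted_label"]
    if header != expected:
        raise ValueError(f"{path}: unexpected header {header}")
    rows = [ln.split("\t") for ln in lines[1:]]
    idx = np.array([int(r[0]) for r in rows])
    resnum = np.array([int(r[1]) for r in rows])
    aa = "".join(r[2] for r in rows)
    scores = np.array([float(r[3]) for r in rows])
    binary = np.array([int(r[4]) for r in rows])
    return idx, resnum, aa, scores, binary


def read_fasta(path) -> dict:
    """Read a FASTA file into an ``{id: sequence}`` dict."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict, path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
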