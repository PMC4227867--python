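"""Structure and sequence I/O.

Reads PDB coordinate files (via gemmi), extracts Calpha traces, and
reconciles construct numbering -- the numbering used when reporting
cross-linked residues -- with the author numbering of the coordinate file.
Residue numbers are taken verbatim from the file (including insertion
codes); every user-facing position passes through an explicit
:class:`SequenceMap` so that off-by-N errors between numbering schemes are
impossible to introduce silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import gemmi
import numpy as np
from Bio import Align


class StructureError(ValueError):
    """Unreadable file or missing model index."""


class MissingResidueError(KeyError):
    """The requested residue is not present in the chain."""


class MissingCalphaError(KeyError):
    """The residue exists but has no Calpha coordinates."""


class MappingError(ValueError):
    """Sequence mapping could not be derived (e.g. low identity)."""


@dataclass(frozen=True)
class ResidueRef:
    """A residue position in construct numbering.

    ``aa`` uses the one-letter alphabet extended with the photo-amino
    acids: ``z`` for photo-leucine, ``o`` for photo-methionine.
    """

    protein_id: str
    position: int
    aa: str = "X"

    def __post_init__(self):
        if self.position < 1:
            raise ValueError("construct positions are 1-based")

    @property
    def key(self) -> tuple:
        return (self.protein_id, self.position)


class ResidueEntry(NamedTuple):
    resnum: int
    icode: str
    resname: str
    ca: np.ndarray | None  # (3,) in Angstrom, or None when CA is unresolved


@dataclass
class StructureModel:
    """Calpha-level view of one model of a coordinate file."""

    model_id: str
    chains: dict[str, list[ResidueEntry]] = field(default_factory=dict)

    def chain(self, chain_id: str) -> list[ResidueEntry]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise MissingResidueError(f"no chain {chain_id!r} in {self.model_id}") from None

    def residue(self, chain_id: str, resnum: int, icode: str = "") -> ResidueEntry:
        for entry in self.chain(chain_id):
            if entry.resnum == resnum and entry.icode == icode:
                return entry
        raise MissingResidueError(f"residue {chain_id}/{resnum}{icode} not in {self.model_id}")


@dataclass
class SequenceMap:
    """Injective map: construct position -> structure (resnum, icode)."""

    protein_id: str
    chain_id: str
    mapping: dict[int, tuple[int, str]]
    method: str  # "explicit_offset" or "alignment"

    def __post_init__(self):
        if len(set(self.mapping.values())) != len(self.mapping):
            raise MappingError("sequence map is not injective")

    def to_structure(self, construct_pos: int) -> tuple[int, str]:
        try:
            return self.mapping[construct_pos]
        except KeyError:
            raise MappingError(
                f"construct position {construct_pos} of {self.protein_id} "
                f"has no structure residue"
            ) from None

    def inverse(self) -> dict[tuple[int, str], int]:
        return {v: k for k, v in self.mapping.items()}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("protein_id\tchain\tconstruct_pos\tstruct_resnum\ticode\n")
            for pos in sorted(self.mapping):
                num, icode = self.mapping[pos]
                fh.write(f"{self.protein_id}\t{self.chain_id}\t{pos}\t{num}\t{icode or '-'}\n")

    @classmethod
    def from_tsv(cls, path) -> "SequenceMap":
        mapping: dict[int, tuple[int, str]] = {}
        protein_id = chain_id = ""
        with open(path) as fh:
            fh.readline()
            for line in fh:
                if not line.strip():
                    continue
                protein_id, chain_id, pos, num, icode = line.rstrip("\n").split("\t")
                mapping[int(pos)] = (int(num), "" if icode == "-" else icode)
        return cls(protein_id, chain_id, mapping, method="explicit_offset")


def read_structure(path, model_index: int = 0) -> StructureModel:
    """Read one model of a PDB file as a Calpha-level :class:`StructureModel`.

    Residues without a CA record are kept with ``ca=None`` rather than
    dropped.  Alternate conformers resolve to the highest-occupancy CA
    (first encountered on ties).
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureError(f"cannot read structure {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    if model_index < 0 or model_index >= len(st):
        raise StructureError(f"model index {model_index} out of range (file has {len(st)})")
    model = st[model_index]
    out = StructureModel(model_id=str(path))
    for chain in model:
        entries: list[ResidueEntry] = []
        for res in chain:
            best_ca = None
            best_occ = -1.0
            for atom in res:
                if atom.name == "CA" and atom.element.name != "Ca":
                    if atom.occ > best_occ:
                        best_occ = atom.occ
                        best_ca = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            icode = res.seqid.icode.strip()
            entries.append(ResidueEntry(res.seqid.num, icode, res.name, best_ca))
        if entries:
            out.chains[chain.name] = entries
    return out


def write_structure(model: StructureModel, path) -> None:
    """Write a Calpha-only PDB file (one ATOM record per present CA)."""
    serial = 0
    with open(path, "w") as fh:
        for chain_id, entries in model.chains.items():
            for e in entries:
                if e.ca is None:
                    continue
                serial += 1
                fh.write(
                    f"ATOM  {serial:5d}  CA  {e.resname:<3s} {chain_id[:1]}"
                    f"{e.resnum:4d}{e.icode or ' ':1s}   "
                    f"{e.ca[0]:8.3f}{e.ca[1]:8.3f}{e.ca[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          "
                    f"{'C':>2s}\n"
                )
        fh.write("END\n")


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}
# synthetic three-letter codes for the photo-amino acids
_ONE_TO_THREE["z"] = "PLU"
_ONE_TO_THREE["o"] = "PME"
_THREE_TO_ONE["PLU"] = "z"
_THREE_TO_ONE["PME"] = "o"


def one_letter(resname: str) -> str:
    return _THREE_TO_ONE.get(resname.upper() if len(resname) == 3 else resname, "X")


def three_letter(aa: str) -> str:
    return _ONE_TO_THREE.get(aa, "UNK")


def build_sequence_map(
    construct_seq: str,
    structure: StructureModel,
    chain_id: str,
    mode: dict,
    protein_id: str = "",
) -> SequenceMap:
    """Map construct positions onto structure residue numbers.

    ``mode`` is ``{"offset": k}`` (structure number = construct position + k)
    or ``{"align": True}``, which aligns the construct sequence globally
    against the chain's observed residue sequence (match +1, mismatch -1,
    gap -2) and maps only aligned, identical positions.  Alignment-based
    mapping fails when identity over the aligned block is below 50%.
    """
    if not construct_seq:
        raise ValueError("construct sequence is empty")
    entries = structure.chain(chain_id)
    if "offset" in mode:
        offset = int(mode["offset"])
        by_num = {(e.resnum, e.icode): e for e in entries}
        mapping = {}
        for pos in range(1, len(construct_seq) + 1):
            key = (pos + offset, "")
            if key in by_num:
                mapping[pos] = key
        return SequenceMap(protein_id, chain_id, mapping, method="explicit_offset")
    if "align" not in mode:
        raise ValueError(f"unknown mapping mode {mode!r}")
    observed = [e for e in entries]
    if len(observed) < 10:
        raise MappingError("alignment mode needs >= 10 observed residues")
    obs_seq = "".join(one_letter(e.resname) for e in observed)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aln = aligner.align(construct_seq, obs_seq)[0]
    mapping: dict[int, tuple[int, str]] = {}
    aligned_cols = 0
    identical = 0
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        for i in range(a_end - a_start):
            aligned_cols += 1
            if construct_seq[a_start + i] == obs_seq[b_start + i]:
                identical += 1
                entry = observed[b_start + i]
                mapping[a_start + i + 1] = (entry.resnum, entry.icode)
    if aligned_cols == 0 or identical / aligned_cols < 0.5:
        raise MappingError(
            f"alignment identity {identical}/{aligned_cols} below 50%; "
            f"refusing to map {protein_id or construct_seq[:10]} onto chain {chain_id}"
        )
    return SequenceMap(protein_id, chain_id, mapping, method="alignment")


def identity_map(
    structure: StructureModel, chain_id: str, protein_id: str = ""
) -> SequenceMap:
    """Identity mapping (construct position == structure number) over the
    chain's residues; convenient for synthetic structures."""
    mapping = {
        e.resnum: (e.resnum, e.icode)
        for e in structure.chain(chain_id)
        if e.resnum >= 1
    }
    return SequenceMap(protein_id, chain_id, mapping, method="explicit_offset")


def ca_distance(
    structure: StructureModel,
    a: tuple[str, int] | tuple[str, int, str],
    b: tuple[str, int] | tuple[str, int, str],
) -> float:
    """Euclidean Calpha-Calpha distance in Angstrom.

    Raises :class:`MissingResidueError` when a residue is absent and
    :class:`MissingCalphaError` when it is present but has no CA.
    """
    coords = []
    for site in (a, b):
        chain_id, resnum = site[0], site[1]
        icode = site[2] if len(site) > 2 else ""
        entry = structure.residue(chain_id, resnum, icode)
        if entry.ca is None:
            raise MissingCalphaError(
                f"residue {chain_id}/{resnum}{icode} has no Calpha coordinates"
            )
        coords.append(entry.ca)
    return float(np.linalg.norm(coords[0] - coords[1]))


def chain_coords(structure: StructureModel, chain_id: str) -> np.ndarray:
    """(n, 3) array of the chain's present Calpha coordinates, in order."""
    return np.array([e.ca for e in structure.chain(chain_id) if e.ca is not None])
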