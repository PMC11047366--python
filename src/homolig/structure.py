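"""Structure input/output and confidence-based model trimming.

Coordinates are held in a small hierarchy (:class:`Structure` → chains →
:class:`Residue` → :class:`Atom`) that is convenient to slice and transform
with numpy. Parsing and PDB writing are delegated to :mod:`gemmi`; altloc
groups are resolved to the highest-occupancy conformer on read.

For predicted models the per-residue confidence score (pLDDT, 0–100) is
stored in the B-factor column; :func:`trim_by_confidence` removes the
low-confidence terminal tails that predicted models of membrane proteins
typically carry, while never deleting interior residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: 3-letter → 1-letter codes for the standard amino acids plus selenomethionine.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # (3,) Å
    bfactor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coords.copy(),
                    self.bfactor, self.occupancy, self.altloc)


@dataclass
class Residue:
    seq_id: int
    name: str
    atoms: list[Atom]
    icode: str = ""
    is_hetero: bool = False

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coords for a in self.atoms if a.element.upper() not in ("H", "D")]
        return np.array(pts) if pts else np.empty((0, 3))

    def copy(self) -> "Residue":
        return Residue(self.seq_id, self.name, [a.copy() for a in self.atoms],
                       self.icode, self.is_hetero)


@dataclass
class Structure:
    entry_id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def polymer_residues(self, chain_id: str) -> list[Residue]:
        return [r for r in self.chains[chain_id] if not r.is_hetero]

    def hetero_residues(self, chain_id: str | None = None) -> list[tuple[str, Residue]]:
        out = []
        for cid, residues in self.chains.items():
            if chain_id is not None and cid != chain_id:
                continue
            out.extend((cid, r) for r in residues if r.is_hetero)
        return out

    def first_polymer_chain(self) -> str:
        for cid, residues in self.chains.items():
            if any(not r.is_hetero for r in residues):
                return cid
        raise ValueError(f"structure {self.entry_id!r} has no polymer chain")

    def ca_array(self, chain_id: str) -> tuple[list[int], np.ndarray]:
        """seq_ids and an (n, 3) array of Cα positions for one chain."""
        ids, pts = [], []
        for r in self.polymer_residues(chain_id):
            ca = r.ca
            if ca is not None:
                ids.append(r.seq_id)
                pts.append(ca.coords)
        return ids, np.array(pts).reshape(-1, 3)

    def all_atoms(self):
        for cid, residues in self.chains.items():
            for r in residues:
                for a in r.atoms:
                    yield cid, r, a

    def copy(self) -> "Structure":
        return Structure(self.entry_id,
                         {c: [r.copy() for r in rs] for c, rs in self.chains.items()},
                         dict(self.metadata))


# hetero components that are solvent by construction, never treated as ligands
WATER_NAMES = {"HOH", "DOD"}


def _resolve_altlocs(raw: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc id."""
    by_name: dict[str, Atom] = {}
    for a in raw:
        prev = by_name.get(a.name)
        if prev is None:
            by_name[a.name] = a
        elif (a.occupancy, _altloc_rank(a.altloc)) > (prev.occupancy, _altloc_rank(prev.altloc)):
            by_name[a.name] = a
    return list(by_name.values())


def _altloc_rank(altloc: str) -> int:
    # earlier altloc letters win ties, hence negated ordinal
    return -ord(altloc) if altloc else 0


def read_structure(path: str | Path) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Altloc groups are reduced to the highest-occupancy conformer
    (ties broken by the alphabetically first altloc id).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot read structure file {path}: {exc}") from None
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models / no coordinates")
    model = st[0]
    out = Structure(entry_id=st.name or path.stem)
    out.metadata["method"] = (st.info["_exptl.method"]
                              if "_exptl.method" in st.info else None)
    if st.resolution:
        out.metadata["resolution"] = st.resolution
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            raw = [Atom(a.name, a.element.name, np.array([a.pos.x, a.pos.y, a.pos.z]),
                        a.b_iso, a.occ, a.altloc) for a in res]
            if not raw:
                continue
            atoms = _resolve_altlocs(raw)
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = res.name in THREE_TO_ONE or (info is not None and info.is_amino_acid())
            is_het = not is_aa
            residues.append(Residue(res.seqid.num, res.name, atoms,
                                    res.seqid.icode.strip(), is_het))
        if residues:
            out.chains[chain.name] = residues
    if not out.chains:
        raise ValueError(f"{path}: no residues with coordinates")
    return out


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write the structure in PDB format (fixed-width coordinate columns)."""
    st = gemmi.Structure()
    st.name = structure.entry_id
    model = gemmi.Model("1")
    for cid, residues in structure.chains.items():
        chain = gemmi.Chain(cid)
        for r in residues:
            res = gemmi.Residue()
            res.name = r.name
            res.seqid = gemmi.SeqId(r.seq_id, r.icode or " ")
            res.het_flag = "H" if r.is_hetero else "A"
            for a in r.atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*map(float, a.coords))
                atom.b_iso = float(a.bfactor)
                atom.occ = float(a.occupancy)
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def residue_plddt(residue: Residue) -> float:
    """Per-residue confidence: the Cα B-factor (predicted models write the
    same value on every atom of a residue; Cα is the canonical carrier)."""
    ca = residue.ca
    if ca is not None:
        return ca.bfactor
    return float(np.mean([a.bfactor for a in residue.atoms]))


def trim_by_confidence(model: Structure, min_plddt: float = 90.0) -> Structure:
    """Remove low-confidence terminal tails from a predicted model.

    The maximal contiguous N-terminal and C-terminal runs of residues with
    pLDDT < ``min_plddt`` are removed; interior residues are always kept (a
    global per-residue deletion would fragment the chain). Interior dips
    below the threshold are logged. Raises ``ValueError`` if every residue
    falls below the threshold.
    """
    chain_id = model.first_polymer_chain()
    residues = model.polymer_residues(chain_id)
    scores = np.array([residue_plddt(r) for r in residues])
    keep = scores >= min_plddt
    if not keep.any():
        raise ValueError("empty model: all residues below the confidence threshold")
    first = int(np.argmax(keep))
    last = len(keep) - 1 - int(np.argmax(keep[::-1]))
    dips = [residues[i].seq_id for i in range(first, last + 1) if not keep[i]]
    if dips:
        logger.info("retaining %d interior residue(s) below pLDDT %.0f: %s",
                    len(dips), min_plddt, dips)
    kept = [r.copy() for r in residues[first:last + 1]]
    out = Structure(model.entry_id, {chain_id: kept}, dict(model.metadata))
    out.metadata["trimmed"] = (kept[0].seq_id, kept[-1].seq_id)
    return out


def extract_sequence(structure: Structure, chain_id: str) -> str:
    """One-letter sequence of a chain's polymer residues, in seq_id order.

    Nonstandard residues map to ``X`` (selenomethionine maps to ``M``).
    """
    if chain_id not in structure.chains:
        raise KeyError(f"chain {chain_id!r} not in structure {structure.entry_id!r}")
    residues = sorted(structure.polymer_residues(chain_id), key=lambda r: (r.seq_id, r.icode))
    if not residues:
        logger.warning("chain %s has no polymer residues", chain_id)
        return ""
    return "".join(THREE_TO_ONE.get(r.name, "X") for r in residues)
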