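"""Chemical-component catalog and homology hit table.

Two inputs drive the homolog-selection stage of the pipeline: the wwPDB
Chemical Component Dictionary (CCD), from which each component's name and
SMILES descriptor are extracted, and a profile-HMM search hit table in the
HHR summary dialect (or the package's own TSV equivalent). Hits are kept
when their probability exceeds a threshold *and* they carry at least one
ligand bound to the hit's own chain — ligands sitting only on other chains
of the deposited entry do not count.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structure import Structure, WATER_NAMES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LigandRecord:
    """One CCD component: identifier, free-text name, optional SMILES."""
    ccd_id: str
    name: str = ""
    smiles: str | None = None

    def __post_init__(self):
        if not self.ccd_id or len(self.ccd_id) > 5:
            raise ValueError(f"invalid component id {self.ccd_id!r}")


@dataclass
class HomologHit:
    pdb_id: str
    chain_id: str
    probability: float  # percent, [0, 100]
    query_range: tuple[int, int]
    target_range: tuple[int, int]
    ligands: list[tuple[str, str]] = field(default_factory=list)  # (ccd_id, chain)

    def __post_init__(self):
        if not 0.0 <= self.probability <= 100.0:
            raise ValueError(f"probability {self.probability} outside [0, 100]")
        for lo, hi in (self.query_range, self.target_range):
            if lo > hi:
                raise ValueError(f"empty range {lo}-{hi}")

    @property
    def hit_id(self) -> str:
        return f"{self.pdb_id}_{self.chain_id}"

    def own_chain_ligands(self) -> list[tuple[str, str]]:
        return [(c, ch) for c, ch in self.ligands if ch == self.chain_id]


# ---------------------------------------------------------------------------
# component dictionary

# preference order for picking one SMILES among several CCD descriptors
_SMILES_RANK = {
    ("SMILES_CANONICAL", "openeye"): 0,
    ("SMILES_CANONICAL", "cactvs"): 1,
    ("SMILES_CANONICAL", "other"): 2,
    ("SMILES", "openeye"): 3,
    ("SMILES", "cactvs"): 4,
    ("SMILES", "other"): 5,
}


def _descriptor_rank(dtype: str, program: str) -> int:
    prog = "openeye" if "openeye" in program.lower() else (
        "cactvs" if "cactvs" in program.lower() else "other")
    return _SMILES_RANK.get((dtype.upper(), prog), 99)


def parse_component_dictionary(path: str | Path) -> dict[str, LigandRecord]:
    """Parse a CCD file (mmCIF, one block per component) or the package's
    TSV catalog dialect into ``{ccd_id: LigandRecord}``.

    When a component lists several SMILES descriptors, the canonical SMILES
    is preferred and programs are ranked OpenEye > CACTVS > other; the first
    match wins. Components without any SMILES are retained with
    ``smiles=None``. Duplicate component ids are a fatal error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text_head = path.open("r", errors="replace").read(4096)
    if path.suffix.lower() == ".cif" or text_head.lstrip().startswith("data_"):
        return _parse_ccd_mmcif(path)
    return _parse_catalog_tsv(path)


def _parse_ccd_mmcif(path: Path) -> dict[str, LigandRecord]:
    import gemmi.cif as cif

    try:
        doc = cif.read(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse component dictionary {path}: {exc}") from None
    catalog: dict[str, LigandRecord] = {}
    for block in doc:
        comp_id = block.find_value("_chem_comp.id")
        if comp_id is None:
            raise ValueError(f"{path}: block {block.name!r} lacks _chem_comp.id")
        comp_id = cif.as_string(comp_id).strip().upper()
        name = cif.as_string(block.find_value("_chem_comp.name") or "").strip()
        best: tuple[int, str] | None = None
        table = block.find("_pdbx_chem_comp_descriptor.",
                           ["type", "program", "descriptor"])
        for row in table:
            dtype = cif.as_string(row[0])
            if not dtype.upper().startswith("SMILES"):
                continue
            rank = _descriptor_rank(dtype, cif.as_string(row[1]))
            smi = cif.as_string(row[2]).strip()
            if smi and (best is None or rank < best[0]):
                best = (rank, smi)
        if comp_id in catalog:
            raise ValueError(f"{path}: duplicate component id {comp_id!r}")
        catalog[comp_id] = LigandRecord(comp_id, name, best[1] if best else None)
    if not catalog:
        logger.warning("component dictionary %s is empty", path)
    return catalog


def _parse_catalog_tsv(path: Path) -> dict[str, LigandRecord]:
    catalog: dict[str, LigandRecord] = {}
    header: list[str] | None = None
    for lineno, line in enumerate(path.open(), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            if "ccd_id" not in header:
                raise ValueError(f"{path}:{lineno}: catalog TSV needs a ccd_id column")
            continue
        row = dict(zip(header, fields))
        cid = row["ccd_id"].strip().upper()
        if cid in catalog:
            raise ValueError(f"{path}:{lineno}: duplicate component id {cid!r}")
        smiles = row.get("smiles", "").strip() or None
        catalog[cid] = LigandRecord(cid, row.get("name", "").strip(), smiles)
    if not catalog:
        logger.warning("ligand catalog %s is empty", path)
    return catalog


def write_catalog_tsv(catalog: dict[str, LigandRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ccd_id\tname\tsmiles\n")
        for cid in sorted(catalog):
            rec = catalog[cid]
            fh.write(f"{rec.ccd_id}\t{rec.name}\t{rec.smiles or ''}\n")


# ---------------------------------------------------------------------------
# hit table

_HHR_HIT_RE = re.compile(r"^\s*\d+\s+\S+")
_RANGE_RE = re.compile(r"^(\d+)-(\d+)$")


def _parse_range(token: str, where: str) -> tuple[int, int]:
    m = _RANGE_RE.match(token)
    if not m:
        raise ValueError(f"{where}: malformed residue range {token!r}")
    return int(m.group(1)), int(m.group(2))


def parse_hit_table(path: str | Path) -> list[HomologHit]:
    """Parse an HHR-style summary hit list or the package's hits TSV.

    Each hit line yields a :class:`HomologHit` with an empty ligand list
    (ligands are attached later from the deposited structure).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if any(l.lstrip().startswith("No Hit") for l in lines):
        return _parse_hhr(lines, path)
    return _parse_hits_tsv(lines, path)


def _parse_hhr(lines: list[str], path: Path) -> list[HomologHit]:
    hits: list[HomologHit] = []
    in_table = False
    for lineno, line in enumerate(lines, start=1):
        if line.lstrip().startswith("No Hit"):
            in_table = True
            continue
        if in_table:
            if not line.strip():
                break
            if not _HHR_HIT_RE.match(line):
                break
            tokens = line.split()
            # numeric tail: Prob E-value P-value Score SS Cols Query Template (Len)
            if len(tokens) < 10:
                raise ValueError(f"{path}:{lineno}: truncated hit line")
            where = f"{path}:{lineno}"
            hit_id = tokens[1]
            if "_" in hit_id:
                pdb_id, chain = hit_id.rsplit("_", 1)
            else:
                pdb_id, chain = hit_id, ""
            try:
                prob = float(tokens[-9])
            except ValueError:
                raise ValueError(f"{where}: malformed probability {tokens[-9]!r}") from None
            qrange = _parse_range(tokens[-3], where)
            trange = _parse_range(tokens[-2], where)
            hits.append(HomologHit(pdb_id, chain, prob, qrange, trange))
    return hits


def _parse_hits_tsv(lines: list[str], path: Path) -> list[HomologHit]:
    hits: list[HomologHit] = []
    header: list[str] | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            if "pdb_id" not in header:
                raise ValueError(f"{path}:{lineno}: hits TSV needs a pdb_id column")
            continue
        row = dict(zip(header, fields))
        where = f"{path}:{lineno}"
        try:
            prob = float(row["probability"])
        except (KeyError, ValueError):
            raise ValueError(f"{where}: malformed probability") from None
        ligands = []
        for item in row.get("ligands", "").split(","):
            item = item.strip()
            if item:
                cid, _, ch = item.partition(":")
                ligands.append((cid, ch))
        hits.append(HomologHit(row["pdb_id"], row.get("chain_id", ""), prob,
                               _parse_range(row["query_range"], where),
                               _parse_range(row["target_range"], where),
                               ligands))
    return hits


def write_hit_table(hits: list[HomologHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pdb_id\tchain_id\tprobability\tquery_range\ttarget_range\tligands\n")
        for h in hits:
            lig = ",".join(f"{c}:{ch}" for c, ch in h.ligands)
            fh.write(f"{h.pdb_id}\t{h.chain_id}\t{h.probability:g}\t"
                     f"{h.query_range[0]}-{h.query_range[1]}\t"
                     f"{h.target_range[0]}-{h.target_range[1]}\t{lig}\n")


# ---------------------------------------------------------------------------
# ligand attachment and hit selection

def attach_ligands(hit: HomologHit, structure: Structure,
                   contact_cutoff: float = 4.0,
                   deny_list: set[str] | None = None) -> HomologHit:
    """Fill ``hit.ligands`` from the deposited structure of the hit entry.

    A hetero component is "bound to" chain X when any of its heavy atoms lies
    within ``contact_cutoff`` (default 4.0 Å) of any polymer heavy atom of
    chain X; a component bridging two chains is listed once per chain.
    Waters (and anything on the deny list) are excluded.
    """
    deny = WATER_NAMES if deny_list is None else set(deny_list)
    if hit.chain_id and hit.chain_id not in structure.chains:
        raise ValueError(f"structure {structure.entry_id!r} lacks chain {hit.chain_id!r}")

    trees: dict[str, cKDTree] = {}
    for cid in structure.chains:
        pts = [a.coords for r in structure.polymer_residues(cid)
               for a in r.atoms if a.element.upper() not in ("H", "D")]
        if pts:
            trees[cid] = cKDTree(np.array(pts))

    ligands: list[tuple[str, str]] = []
    for _, res in structure.hetero_residues():
        if res.name in deny:
            continue
        lig_pts = res.heavy_coords()
        if lig_pts.size == 0:
            continue
        for cid, tree in trees.items():
            d, _ = tree.query(lig_pts, k=1)
            if float(np.min(d)) <= contact_cutoff:
                pair = (res.name, cid)
                if pair not in ligands:
                    ligands.append(pair)
    return replace(hit, ligands=ligands)


def apply_aliases(hits: list[HomologHit], alias_map: dict[str, str]) -> list[HomologHit]:
    """Apply user-supplied hit substitutions such as an apo→holo swap
    (e.g. ``{"4OD4_A": "4OD5_A"}``). Keys and values are ``PDBID_chain``."""
    out = []
    for h in hits:
        target = alias_map.get(h.hit_id)
        if target is None:
            out.append(h)
        else:
            pdb_id, _, chain = target.partition("_")
            out.append(replace(h, pdb_id=pdb_id, chain_id=chain or h.chain_id,
                               ligands=[]))
    return out


def select_hits(hits: list[HomologHit], min_probability: float = 50.0) -> list[HomologHit]:
    """Retain hits with probability strictly above the threshold and at
    least one ligand bound to the hit's own chain; collapse multiple hits to
    the same PDB entry, keeping the best probability."""
    if not 0.0 <= min_probability <= 100.0:
        raise ValueError("min_probability must be in [0, 100]")
    best: dict[str, HomologHit] = {}
    order: list[str] = []
    for h in hits:
        if h.probability <= min_probability:
            continue
        if not h.own_chain_ligands():
            continue
        key = h.pdb_id
        if key not in best:
            best[key] = h
            order.append(key)
        elif h.probability > best[key].probability:
            best[key] = h
    return [best[k] for k in order]
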