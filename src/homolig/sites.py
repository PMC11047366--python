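"""Ligand transfer into the query frame and binding-site annotation.

After a homolog has been superposed onto the query model, its bound ligands
are carried along by the same rigid transform, which places them in the
query's coordinate frame. Residues of the query model that come close to a
transferred ligand are candidate substrate-binding residues; residues whose
atoms overlap a ligand atom indicate a placement the query cannot
accommodate (or a genuinely different binding pose). Contacts are finally
annotated against the protein's membrane topology, conserved motifs and
known disease variants.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import Structure, WATER_NAMES
from .superpose import SuperpositionResult

logger = logging.getLogger(__name__)

#: components reported as cofactors rather than substrate analogues
COFACTOR_IDS = {"MG", "MN", "ZN", "CA", "NA", "K"}


@dataclass
class TransferredLigand:
    ccd_id: str
    source_chain: str
    source_seq_id: int
    atom_names: list[str]
    coords: np.ndarray  # (n, 3) heavy atoms, query frame
    category: str = "ligand"  # ligand | cofactor


@dataclass
class Contact:
    chain_id: str
    seq_id: int
    res_name: str
    min_distance: float


@dataclass
class Clash:
    chain_id: str
    seq_id: int
    res_name: str
    atom_name: str
    ligand_atom: str
    distance: float


@dataclass
class AnnotatedContact:
    contact: Contact
    segment: str | None = None
    side: str | None = None
    motifs: list[str] = field(default_factory=list)
    variant: str | None = None
    on_portal_helix: bool = False
    unannotated: bool = False


@dataclass
class BindingSiteReport:
    ccd_id: str
    source: str  # e.g. "4TQ3_B"
    category: str
    contacts: list[AnnotatedContact]
    clashes: list[Clash]


# ---------------------------------------------------------------------------
# transfer / geometry

def transfer_ligands(result: SuperpositionResult, target: Structure,
                     ligand_ids: list[str] | None = None,
                     deny_list: set[str] | None = None) -> list[TransferredLigand]:
    """Move the target's hetero components into the query frame.

    Each ligand's heavy atoms are transformed by ``result.transform``; the
    target structure itself is left untouched. ``ligand_ids`` restricts the
    transfer to specific component ids; a requested id absent from the
    target is an error. Metal ions are tagged as cofactors.
    """
    deny = WATER_NAMES if deny_list is None else set(deny_list)
    placed: list[TransferredLigand] = []
    seen_ids: set[str] = set()
    for cid, res in target.hetero_residues():
        if res.name in deny:
            continue
        seen_ids.add(res.name)
        if ligand_ids is not None and res.name not in ligand_ids:
            continue
        heavy = [(a.name, a.coords) for a in res.atoms if a.element.upper() not in ("H", "D")]
        if not heavy:
            continue
        coords = result.transform.apply(np.array([c for _, c in heavy]))
        placed.append(TransferredLigand(
            ccd_id=res.name, source_chain=cid, source_seq_id=res.seq_id,
            atom_names=[n for n, _ in heavy], coords=coords,
            category="cofactor" if res.name in COFACTOR_IDS else "ligand"))
    if ligand_ids is not None:
        missing = set(ligand_ids) - seen_ids
        if missing:
            raise ValueError(f"ligand id(s) absent from target: {sorted(missing)}")
    return placed


def _model_heavy_atoms(model: Structure):
    """Flat arrays of polymer heavy atoms: coords plus (chain, residue, atom) keys."""
    keys, pts = [], []
    for cid, residues in model.chains.items():
        for r in residues:
            if r.is_hetero:
                continue
            for a in r.atoms:
                if a.element.upper() in ("H", "D"):
                    continue
                keys.append((cid, r, a))
                pts.append(a.coords)
    return keys, np.array(pts).reshape(-1, 3)


def find_contact_residues(model: Structure, ligand: TransferredLigand,
                          cutoff: float = 5.0) -> list[Contact]:
    """Query-model residues with any heavy atom within ``cutoff`` Å of any
    ligand heavy atom, with the minimum pairwise distance, sorted by it."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    keys, pts = _model_heavy_atoms(model)
    if not len(pts) or not len(ligand.coords):
        return []
    tree = cKDTree(ligand.coords)
    dmin, _ = tree.query(pts, k=1)
    best: dict[tuple[str, int, str], Contact] = {}
    for (cid, res, _), d in zip(keys, dmin):
        if d > cutoff:
            continue
        key = (cid, res.seq_id, res.icode)
        if key not in best or d < best[key].min_distance:
            best[key] = Contact(cid, res.seq_id, res.name, float(d))
    return sorted(best.values(), key=lambda c: c.min_distance)


def detect_clashes(model: Structure, ligand: TransferredLigand,
                   clash_cutoff: float = 2.0) -> list[Clash]:
    """Heavy-atom pairs (model vs ligand) closer than ``clash_cutoff`` Å —
    closer than van-der-Waals contact, i.e. sterically impossible."""
    if clash_cutoff <= 0:
        raise ValueError("clash_cutoff must be positive")
    keys, pts = _model_heavy_atoms(model)
    if not len(pts) or not len(ligand.coords):
        return []
    tree = cKDTree(ligand.coords)
    neighbor_lists = tree.query_ball_point(pts, r=clash_cutoff)
    clashes = []
    for (cid, res, atom), neigh in zip(keys, neighbor_lists):
        for j in neigh:
            d = float(np.linalg.norm(atom.coords - ligand.coords[j]))
            clashes.append(Clash(cid, res.seq_id, res.name, atom.name,
                                 ligand.atom_names[j], d))
    clashes.sort(key=lambda c: c.distance)
    return clashes


# ---------------------------------------------------------------------------
# annotation tables (packaged defaults describe human COQ2)

def packaged_data_path(name: str) -> Path:
    return Path(importlib.resources.files("homolig.data") / name)


def load_topology(path: str | Path | None = None) -> pd.DataFrame:
    df = pd.read_csv(path or packaged_data_path("coq2_topology_synthetic.tsv"),
                     sep="\t", comment="#")
    prev_end = 0
    for _, row in df.iterrows():
        if row["start"] > row["end"] or row["start"] <= prev_end:
            raise ValueError("topology segments must be ordered and non-overlapping")
        prev_end = row["end"]
    return df


def load_motifs(path: str | Path | None = None) -> pd.DataFrame:
    return pd.read_csv(path or packaged_data_path("coq2_motifs.tsv"), sep="\t", comment="#")


def load_variants(path: str | Path | None = None) -> pd.DataFrame:
    return pd.read_csv(path or packaged_data_path("coq2_variants.tsv"), sep="\t", comment="#")


def load_correspondence(path: str | Path | None = None) -> pd.DataFrame:
    df = pd.read_csv(path or packaged_data_path("coq2_correspondence.tsv"), sep="\t", comment="#")
    if df["homolog_residue"].duplicated().any() or df["query_residue"].duplicated().any():
        raise ValueError("correspondence table must be one-to-one")
    return df


def annotate_contacts(contacts: list[Contact],
                      topology: pd.DataFrame | None = None,
                      motifs: pd.DataFrame | None = None,
                      variants: pd.DataFrame | None = None,
                      portal_segments: tuple[str, ...] = ("S1", "S9"),
                      ) -> list[AnnotatedContact]:
    """Flag each contact with its topology segment and membrane side, motif
    membership, disease-variant status and whether it sits on a helix
    delimiting the lateral portal. Positions outside the annotation range
    are flagged ``unannotated``."""
    topology = load_topology() if topology is None else topology
    motifs = load_motifs() if motifs is None else motifs
    variants = load_variants() if variants is None else variants
    out = []
    for c in contacts:
        ann = AnnotatedContact(contact=c)
        seg = topology[(topology["start"] <= c.seq_id) & (c.seq_id <= topology["end"])]
        if len(seg):
            ann.segment = str(seg.iloc[0]["label"])
            ann.side = str(seg.iloc[0]["side"])
            ann.on_portal_helix = ann.segment in portal_segments
        else:
            ann.unannotated = True
        hit = motifs[(motifs["start"] <= c.seq_id) & (c.seq_id <= motifs["end"])]
        ann.motifs = [str(n) for n in hit["name"]]
        var = variants[variants["position"] == c.seq_id]
        if len(var):
            ann.variant = str(var.iloc[0]["variant"])
        out.append(ann)
    return out


def annotate_report(ligand: TransferredLigand, source: str,
                    contacts: list[Contact], clashes: list[Clash],
                    topology: pd.DataFrame | None = None,
                    motifs: pd.DataFrame | None = None,
                    variants: pd.DataFrame | None = None,
                    portal_segments: tuple[str, ...] = ("S1", "S9"),
                    ) -> BindingSiteReport:
    return BindingSiteReport(
        ccd_id=ligand.ccd_id, source=source, category=ligand.category,
        contacts=annotate_contacts(contacts, topology, motifs, variants, portal_segments),
        clashes=clashes)


def report_to_frame(reports: list[BindingSiteReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        for ac in rep.contacts:
            c = ac.contact
            rows.append({
                "ccd_id": rep.ccd_id, "source": rep.source, "category": rep.category,
                "chain": c.chain_id, "seq_id": c.seq_id, "res_name": c.res_name,
                "min_distance": round(c.min_distance, 3),
                "segment": ac.segment or "", "side": ac.side or "",
                "motifs": ";".join(ac.motifs), "variant": ac.variant or "",
                "portal_helix": ac.on_portal_helix, "unannotated": ac.unannotated,
                "n_clashes": sum(1 for cl in rep.clashes if cl.seq_id == c.seq_id),
            })
    return pd.DataFrame(rows)


def write_report(reports: list[BindingSiteReport], tsv_path, json_path=None) -> None:
    df = report_to_frame(reports)
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = [
            {"ccd_id": r.ccd_id, "source": r.source, "category": r.category,
             "contacts": [
                 {"chain": a.contact.chain_id, "seq_id": a.contact.seq_id,
                  "res_name": a.contact.res_name,
                  "min_distance": round(a.contact.min_distance, 3),
                  "segment": a.segment, "side": a.side, "motifs": a.motifs,
                  "variant": a.variant, "portal_helix": a.on_portal_helix,
                  "unannotated": a.unannotated} for a in r.contacts],
             "clashes": [
                 {"chain": cl.chain_id, "seq_id": cl.seq_id, "res_name": cl.res_name,
                  "atom": cl.atom_name, "ligand_atom": cl.ligand_atom,
                  "distance": round(cl.distance, 3)} for cl in r.clashes]}
            for r in reports]
        Path(json_path).write_text(json.dumps(payload, indent=2))
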