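"""Structural-key fingerprints and Tanimoto similarity screening.

A candidate ligand is compared to the query substrate through the public
166-key MACCS structural-key set: each key flags the presence of a
predefined chemical feature in the molecular graph, and two molecules are
scored by the Tanimoto coefficient of their key sets,

    T(A, B) = |A ∩ B| / |A ∪ B|  ∈ [0, 1].

Key evaluation is delegated to RDKit; the rest of this module treats a
fingerprint as a plain set of integers in 1..166, which keeps the set
algebra transparent and independently checkable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys

from .ccd import LigandRecord

RDLogger.DisableLog("rdApp.*")
logger = logging.getLogger(__name__)

N_KEYS = 166


@dataclass(frozen=True)
class Fingerprint:
    """166-key structural-key fingerprint of one component."""
    source_ccd_id: str
    keys: frozenset[int]

    def __post_init__(self):
        bad = [k for k in self.keys if not 1 <= k <= N_KEYS]
        if bad:
            raise ValueError(f"keys outside 1..{N_KEYS}: {sorted(bad)}")


@dataclass(frozen=True)
class SimilarityResult:
    ccd_id: str
    name: str
    tanimoto: float
    passed: bool


def compute_fingerprint(record: LigandRecord) -> Fingerprint:
    """Evaluate the 166 public MACCS structural keys on a component's SMILES.

    Hydrogens are implicit. Raises ``ValueError`` for a missing or
    unparseable SMILES (callers screening a catalog skip such components
    with a warning).
    """
    if not record.smiles:
        raise ValueError(f"component {record.ccd_id} has no SMILES")
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise ValueError(f"component {record.ccd_id}: unparseable SMILES {record.smiles!r}")
    bv = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
    return Fingerprint(record.ccd_id, frozenset(int(b) for b in bv.GetOnBits()))


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient of two key sets; 0.0 when both sets are empty."""
    union = a.keys | b.keys
    if not union:
        return 0.0
    return len(a.keys & b.keys) / len(union)


def screen_ligands(catalog: dict[str, LigandRecord] | list[LigandRecord],
                   query: LigandRecord,
                   threshold: float = 0.3,
                   strict: bool = True) -> list[SimilarityResult]:
    """Rank catalog components by Tanimoto similarity to the query substrate.

    Results are sorted by descending coefficient, ties broken by component
    id; ``passed`` marks components above the threshold (strictly above by
    default — an inclusive boundary is available via ``strict=False``).
    Components without a usable SMILES are skipped with a warning; a query
    without SMILES is fatal.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    records = list(catalog.values()) if isinstance(catalog, dict) else list(catalog)
    query_fp = compute_fingerprint(query)  # fatal if absent/unparseable
    results = []
    for rec in records:
        try:
            fp = compute_fingerprint(rec)
        except ValueError as exc:
            logger.warning("skipping %s: %s", rec.ccd_id, exc)
            continue
        t = tanimoto(query_fp, fp)
        passed = t > threshold if strict else t >= threshold
        results.append(SimilarityResult(rec.ccd_id, rec.name, t, passed))
    results.sort(key=lambda r: (-r.tanimoto, r.ccd_id))
    return results


def write_similarity_tsv(results: list[SimilarityResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("ccd_id\tname\ttanimoto\tpassed\n")
        for r in results:
            fh.write(f"{r.ccd_id}\t{r.name}\t{r.tanimoto:.4f}\t{int(r.passed)}\n")
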