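"""Variant-model comparison against the wild-type structure.

Missense variants of the query protein are modelled externally (structure
prediction is out of scope here); this module consumes those models,
superposes each onto the wild type, and quantifies both the global
root-mean-square deviation and the per-residue Cα deviation profile.
Because point mutants are near-identical in sequence, the superposition is
sequence-dependent and, for the headline RMSD, outlier rejection is turned
off — rejecting the few residues that move is precisely what would hide the
signal. The rejection-on RMSD is reported alongside.

Locally altered regions are flagged with a robust rule: maximal runs of at
least ``min_run`` residues whose deviation exceeds median + 2·MAD of the
profile (the deviation distribution of a point mutant is tightly
concentrated, so a robust location/scale pair is appropriate).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .structure import Structure
from .superpose import SuperpositionResult, superpose, kabsch

logger = logging.getLogger(__name__)

_AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
_VARIANT_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")


@dataclass(frozen=True)
class VariantRecord:
    position: int  # 1-based
    wt_aa: str
    mut_aa: str
    location: str = ""
    labels: dict = field(default_factory=dict, hash=False, compare=False)

    @property
    def name(self) -> str:
        inv = {v: k for k, v in _AA3_TO_1.items()}
        return f"p.{inv[self.wt_aa]}{self.position}{inv[self.mut_aa]}"

    @classmethod
    def from_name(cls, name: str, location: str = "", labels: dict | None = None
                  ) -> "VariantRecord":
        m = _VARIANT_RE.match(name.strip())
        if not m:
            raise ValueError(f"cannot parse variant name {name!r}")
        return cls(int(m.group(2)), _AA3_TO_1[m.group(1)], _AA3_TO_1[m.group(3)],
                   location, labels or {})


def variants_from_table(df: pd.DataFrame) -> list[VariantRecord]:
    """Build records from a variant table with columns
    variant/position/wt_aa/mut_aa/location plus pathogenicity columns."""
    label_cols = [c for c in df.columns
                  if c not in ("variant", "position", "wt_aa", "mut_aa", "location")]
    return [VariantRecord(int(r["position"]), r["wt_aa"], r["mut_aa"],
                          r.get("location", ""),
                          {c: r[c] for c in label_cols})
            for _, r in df.iterrows()]


def apply_variant(sequence: str, variant: VariantRecord) -> str:
    """Single-position substitution; the stated wild-type residue must match."""
    pos = variant.position
    if not 1 <= pos <= len(sequence):
        raise ValueError(f"position {pos} outside sequence of length {len(sequence)}")
    if sequence[pos - 1] != variant.wt_aa:
        raise ValueError(f"reference mismatch at {pos}: sequence has "
                         f"{sequence[pos - 1]!r}, variant expects {variant.wt_aa!r}")
    if variant.wt_aa == variant.mut_aa:
        logger.warning("identity variant at position %d: sequence unchanged", pos)
        return sequence
    return sequence[:pos - 1] + variant.mut_aa + sequence[pos:]


@dataclass
class DeviationProfile:
    seq_ids: list[int]          # wild-type numbering, shared residues only
    deviations: np.ndarray      # per-residue Cα deviation (Å), ≥ 0
    flagged_regions: list[tuple[int, int]]  # seq_id intervals

    def rmsd(self) -> float:
        return float(np.sqrt(np.mean(self.deviations ** 2)))


def _flag_regions(seq_ids: list[int], dev: np.ndarray, n_mad: float = 2.0,
                  min_run: int = 3) -> list[tuple[int, int]]:
    med = float(np.median(dev))
    mad = float(np.median(np.abs(dev - med)))
    thr = med + n_mad * mad
    flagged = dev > thr
    regions = []
    i = 0
    while i < len(flagged):
        if flagged[i]:
            j = i
            while j + 1 < len(flagged) and flagged[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                regions.append((seq_ids[i], seq_ids[j]))
            i = j + 1
        else:
            i += 1
    return regions


def compare_models(wildtype: Structure, variant_model: Structure,
                   n_mad: float = 2.0, min_run: int = 3,
                   ) -> tuple[SuperpositionResult, DeviationProfile]:
    """Superpose a variant model onto the wild type and profile the deviation.

    Returns the sequence-dependent superposition with rejection disabled
    (global all-Cα RMSD — the headline number) and the per-residue Cα
    deviation profile over shared residues with its flagged regions. The
    rejection-on RMSD is stored in the result's ``rmsd_all_pairs``
    counterpart via a second fit and attached as ``retained`` metadata by
    callers that need it.
    """
    result = superpose(wildtype, variant_model, mode="sequence_dependent",
                       max_cycles=1)  # a single cycle = no rejection
    _, q_ids, q_ca, _ = _chain_data(wildtype)
    _, t_ids, t_ca, _ = _chain_data(variant_model)
    q_index = {s: k for k, s in enumerate(q_ids)}
    t_index = {s: k for k, s in enumerate(t_ids)}
    shared = [(qs, ts) for qs, ts in result.all_pairs]
    P = q_ca[[q_index[qs] for qs, _ in shared]]
    Q = t_ca[[t_index[ts] for _, ts in shared]]
    dev = np.linalg.norm(result.transform.apply(Q) - P, axis=1)
    seq_ids = [qs for qs, _ in shared]
    profile = DeviationProfile(seq_ids, dev, _flag_regions(seq_ids, dev, n_mad, min_run))
    return result, profile


def _chain_data(structure: Structure):
    from .superpose import _chain_ca
    return _chain_ca(structure, None)


def rejection_on_rmsd(wildtype: Structure, variant_model: Structure,
                      reject_cutoff: float = 2.0, max_cycles: int = 5) -> float:
    """Companion RMSD with outlier rejection enabled, for transparency."""
    return superpose(wildtype, variant_model, mode="sequence_dependent",
                     reject_cutoff=reject_cutoff, max_cycles=max_cycles).rmsd


def rank_variants(results: list[dict]) -> pd.DataFrame:
    """Order variant comparison results from most to least wild-type-like.

    ``results`` rows need at least ``variant`` and ``rmsd``; any
    pathogenicity columns are carried through. The sort is stable, so
    equal-RMSD variants keep their input order.
    """
    if not results:
        raise ValueError("no variant results to rank")
    df = pd.DataFrame(results)
    return df.sort_values("rmsd", kind="stable", ascending=True).reset_index(drop=True)


def pathogenicity_rmsd_correlation(table: pd.DataFrame,
                                   label_col: str = "sift",
                                   positive: str = "Pathogenic",
                                   ) -> tuple[float, float]:
    """Spearman rank correlation between a binary pathogenicity label and
    the variant RMSD. Returns (rho, p-value)."""
    labels = (table[label_col] == positive).astype(int).to_numpy()
    rho, p = spearmanr(labels, table["rmsd"].to_numpy())
    return float(rho), float(p)
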