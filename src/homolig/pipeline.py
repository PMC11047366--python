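"""End-to-end orchestration: hits → similarity → trim → superpose →
ligand transfer → binding-site report → variant comparison.

A run is driven by a :class:`RunConfig` (serialisable to YAML) and writes a
self-contained run directory: stage TSV/JSON outputs, a manifest with the
config hash and input checksums, and a log with per-stage timings. Stage
outputs are valid inputs for the corresponding standalone CLI subcommands.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .ccd import (apply_aliases, attach_ligands, parse_component_dictionary,
                  parse_hit_table, select_hits, write_catalog_tsv, write_hit_table)
from .chem import screen_ligands, write_similarity_tsv
from .sites import (annotate_report, detect_clashes, find_contact_residues,
                    transfer_ligands, write_report)
from .structure import Structure, read_structure, trim_by_confidence, write_pdb
from .superpose import superpose
from .variants import (compare_models, pathogenicity_rmsd_correlation,
                       rank_variants, rejection_on_rmsd)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All paths and thresholds of a pipeline run.

    Threshold defaults: hit probability 50 (strictly above), Tanimoto 0.3
    (strictly above), pLDDT 90, sequence-identity gate 0.30, contact 5.0 Å,
    clash 2.0 Å, outlier rejection 2.0 Å over at most 5 cycles, homolog
    exclusion at 10 Å RMSD.
    """
    model_path: str = ""
    hit_table_path: str = ""
    ccd_path: str = ""
    structure_dir: str = ""            # PDBID_CHAIN.{pdb,cif} files per hit
    query_ligand: str = "5TR"
    secondary_query_ligand: str | None = "PHB"
    variant_models_dir: str | None = None
    variant_table_path: str | None = None

    min_probability: float = 50.0
    tanimoto_threshold: float = 0.3
    tanimoto_strict: bool = True
    min_plddt: float = 90.0
    identity_gate: float = 0.30
    contact_cutoff: float = 5.0
    clash_cutoff: float = 2.0
    reject_cutoff: float = 2.0
    max_cycles: int = 5
    rmsd_exclusion: float = 10.0
    alias_map: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.min_probability <= 100:
            raise ValueError("min_probability outside [0, 100]")
        if not 0 <= self.tanimoto_threshold <= 1:
            raise ValueError("tanimoto_threshold outside [0, 1]")
        for name in ("contact_cutoff", "clash_cutoff", "reject_cutoff", "rmsd_exclusion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _find_structure(structure_dir: Path, hit_id: str) -> Path:
    for suffix in (".pdb", ".cif", ".ent"):
        for name in (hit_id, hit_id.split("_")[0]):
            p = structure_dir / f"{name}{suffix}"
            if p.exists():
                return p
    raise FileNotFoundError(f"no structure file for {hit_id} under {structure_dir}")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute every stage in order; any failure aborts with the stage name
    and leaves partial outputs plus a ``FAILED`` marker in the run directory."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict = {"version": __version__, "config_hash": config.digest(),
                      "inputs": {}, "seed": config.seed}
    config.to_yaml(out / "config.yaml")

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                (out / "FAILED").write_text(f"{name}: {exc}\n")
                raise StageFailure(name, exc) from exc
            timings[name] = time.perf_counter() - t0
            return result
        return deco

    # -- stage 1: hits ------------------------------------------------------
    @stage("hits")
    def hits():
        raw = parse_hit_table(config.hit_table_path)
        manifest["inputs"]["hit_table"] = _checksum(Path(config.hit_table_path))
        raw = apply_aliases(raw, config.alias_map)
        structure_dir = Path(config.structure_dir)
        structures: dict[str, Structure] = {}
        filled = []
        for h in raw:
            try:
                path = _find_structure(structure_dir, h.hit_id)
            except FileNotFoundError:
                logger.warning("no structure for hit %s; keeping ligand list empty", h.hit_id)
                filled.append(h)
                continue
            if h.hit_id not in structures:
                structures[h.hit_id] = read_structure(path)
            filled.append(attach_ligands(h, structures[h.hit_id]))
        selected = select_hits(filled, config.min_probability)
        write_hit_table(selected, out / "hits.tsv")
        return selected, structures

    selected, structures = hits
    if not selected:
        (out / "FAILED").write_text("hits: no hits retained\n")
        raise StageFailure("hits", ValueError("no hits retained"))

    # -- stage 2: ligand similarity ----------------------------------------
    @stage("similarity")
    def similarity():
        catalog = parse_component_dictionary(config.ccd_path)
        manifest["inputs"]["ccd"] = _checksum(Path(config.ccd_path))
        write_catalog_tsv(catalog, out / "catalog.tsv")
        if config.query_ligand not in catalog:
            raise ValueError(f"query component {config.query_ligand!r} not in catalog")
        results = screen_ligands(catalog, catalog[config.query_ligand],
                                 config.tanimoto_threshold, config.tanimoto_strict)
        write_similarity_tsv(results, out / "similarity.tsv")
        return {r.ccd_id for r in results if r.passed}

    passing_ligands = similarity

    # -- stage 3: model trimming -------------------------------------------
    @stage("trim")
    def trim():
        model = read_structure(config.model_path)
        manifest["inputs"]["model"] = _checksum(Path(config.model_path))
        trimmed = trim_by_confidence(model, config.min_plddt)
        write_pdb(trimmed, out / "model_trimmed.pdb")
        return trimmed

    model = trim

    # -- stage 4: superposition --------------------------------------------
    @stage("superpose")
    def superpositions():
        results = {}
        for h in selected:
            st = structures.get(h.hit_id)
            if st is None:
                st = read_structure(_find_structure(Path(config.structure_dir), h.hit_id))
            res = superpose(model, st, mode="auto",
                            target_chain=h.chain_id or None,
                            identity_gate=config.identity_gate,
                            reject_cutoff=config.reject_cutoff,
                            max_cycles=config.max_cycles)
            results[h.hit_id] = (res, st)
        ordered = sorted(results.items(), key=lambda kv: kv[1][0].rmsd)
        payload = [{"hit": k, "rmsd": round(r.rmsd, 3),
                    "rmsd_all_pairs": round(r.rmsd_all_pairs, 3),
                    "mode": r.mode, "identity": round(r.identity_fraction, 3),
                    "n_pairs_initial": r.n_pairs_initial,
                    "n_pairs_retained": r.n_pairs_retained,
                    "n_cycles": r.n_cycles}
                   for k, (r, _) in ordered]
        (out / "superposition.json").write_text(json.dumps(payload, indent=2))
        return ordered

    ordered = superpositions

    # -- stage 5: ligand transfer + report ---------------------------------
    @stage("map_sites")
    def map_sites():
        reports = []
        for hit_id, (res, st) in ordered:
            if res.rmsd > config.rmsd_exclusion:
                logger.info("excluding %s from site transfer (RMSD %.1f Å)",
                            hit_id, res.rmsd)
                continue
            hit = next(h for h in selected if h.hit_id == hit_id)
            wanted = sorted({cid for cid, ch in hit.own_chain_ligands()
                             if cid in passing_ligands or cid in ("MG",)})
            if not wanted:
                continue
            for lig in transfer_ligands(res, st, ligand_ids=wanted):
                contacts = find_contact_residues(model, lig, config.contact_cutoff)
                clashes = detect_clashes(model, lig, config.clash_cutoff)
                reports.append(annotate_report(lig, hit_id, contacts, clashes))
        write_report(reports, out / "binding_sites.tsv", out / "binding_sites.json")
        return reports

    map_sites

    # -- stage 6: variants (optional) --------------------------------------
    if config.variant_models_dir:
        @stage("variants")
        def variant_stage():
            import pandas as pd
            vdir = Path(config.variant_models_dir)
            rows = []
            table = (pd.read_csv(config.variant_table_path, sep="\t", comment="#")
                     if config.variant_table_path else None)
            for path in sorted(vdir.glob("*.pdb")):
                vm = read_structure(path)
                res, profile = compare_models(model, vm)
                row = {"variant": path.stem, "rmsd": round(res.rmsd, 3),
                       "rmsd_rejected": round(rejection_on_rmsd(model, vm), 3),
                       "flagged_regions": ";".join(f"{a}-{b}"
                                                   for a, b in profile.flagged_regions)}
                if table is not None:
                    match = table[table["variant"].str.replace(".", "", regex=False)
                                  .str.contains(path.stem.replace(".", ""), regex=False)]
                    if len(match):
                        row.update({c: match.iloc[0][c] for c in table.columns
                                    if c not in row})
                rows.append(row)
                pd.DataFrame({"seq_id": profile.seq_ids,
                              "deviation": np.round(profile.deviations, 4)}
                             ).to_csv(out / f"deviation_{path.stem}.tsv",
                                      sep="\t", index=False)
            if rows:
                ranked = rank_variants(rows)
                ranked.to_csv(out / "variant_ranking.tsv", sep="\t", index=False)
                if "sift" in ranked.columns:
                    rho, p = pathogenicity_rmsd_correlation(ranked)
                    (out / "variant_correlation.json").write_text(
                        json.dumps({"spearman_rho": rho, "p_value": p}))
            return rows

        variant_stage

    manifest["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    with open(out / "run.log", "w") as fh:
        for k, v in timings.items():
            fh.write(f"{k}\t{v:.3f}s\n")
    return out
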