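"""Ground-truth synthetic fixtures for every pipeline stage.

The generators build an idealised channel-like helical bundle — the fold
family the pipeline targets is all-helical with a central cavity — plus
"homolog" copies with a known sequence identity, coordinate noise, a known
rigid motion and a multi-atom ligand planted against a chosen set of pocket
residues. Because every perturbation is known, superposition, ligand
transfer and contact detection can be tested for exact recovery.

Geometry is deliberately simple: ideal α-helix Cα traces (1.5 Å rise and
100° turn per residue on a 2.3 Å radius) arranged on a ring, with a single
pseudo-side-chain atom (CB) per residue at canonical Cβ distance pointing
away from the helix axis. That is enough for contact/clash logic; rotamer
realism is a non-goal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ccd import LigandRecord
from .structure import Atom, Residue, Structure, ONE_TO_THREE
from .superpose import RigidTransform

logger = logging.getLogger(__name__)

_AA = "ACDEFGHIKLMNPQRSTVWY"

HELIX_RISE = 1.5       # Å per residue
HELIX_TURN = 100.0     # degrees per residue
HELIX_RADIUS = 2.3     # Å, Cα trace
CB_LENGTH = 1.53       # Å, pseudo-side-chain bond
AXIS_SPACING = 12.0    # Å between adjacent helix axes on the ring


@dataclass
class FixtureSpec:
    n_helices: int = 6
    residues_per_helix: int = 20
    ligand_offset: float = 3.5       # Å from pocket CB toward the bundle axis
    transform_axis: tuple = (0.0, 0.0, 1.0)
    transform_angle_deg: float = 0.0
    translation: tuple = (0.0, 0.0, 0.0)
    noise_sigma: float = 0.0         # Å, isotropic per-atom Gaussian
    identity: float = 1.0            # target sequence identity to the bundle
    n_pocket: int = 5
    pocket_margin: float = 6.0       # non-pocket residues must stay beyond this
    plddt: np.ndarray | None = None  # optional per-residue confidence profile
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be ≥ 0")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")

    @property
    def transform(self) -> RigidTransform:
        return RigidTransform.from_axis_angle(self.transform_axis,
                                              self.transform_angle_deg,
                                              self.translation)


def make_helical_bundle(spec: FixtureSpec) -> Structure:
    """Deterministic channel-like bundle of ideal α-helices on a ring.

    Residues are numbered consecutively across helices in one chain ``A``;
    each residue carries a Cα and a pseudo-Cβ. Adjacent helices run
    antiparallel. If ``spec.plddt`` is given it is written into the
    B-factor column per residue.
    """
    rng = np.random.default_rng(spec.seed)
    n, rph = spec.n_helices, spec.residues_per_helix
    seq = "".join(rng.choice(list(_AA), size=n * rph))
    ring_r = AXIS_SPACING / (2.0 * np.sin(np.pi / max(n, 2))) if n > 1 else 0.0

    residues: list[Residue] = []
    seq_id = 0
    for h in range(n):
        phi = 2.0 * np.pi * h / max(n, 1)
        axis_xy = np.array([ring_r * np.cos(phi), ring_r * np.sin(phi)])
        direction = 1.0 if h % 2 == 0 else -1.0
        z0 = -direction * HELIX_RISE * (rph - 1) / 2.0
        for i in range(rph):
            seq_id += 1
            theta = np.deg2rad(HELIX_TURN * i)
            local = np.array([HELIX_RADIUS * np.cos(theta),
                              HELIX_RADIUS * np.sin(theta)])
            ca = np.array([axis_xy[0] + local[0], axis_xy[1] + local[1],
                           z0 + direction * HELIX_RISE * i])
            radial = np.array([local[0], local[1], 0.0])
            radial /= np.linalg.norm(radial)
            cb = ca + CB_LENGTH * radial
            aa = seq[seq_id - 1]
            b = float(spec.plddt[seq_id - 1]) if spec.plddt is not None else 90.0
            residues.append(Residue(seq_id, ONE_TO_THREE[aa], [
                Atom("CA", "C", ca, bfactor=b),
                Atom("CB", "C", cb, bfactor=b),
            ]))
    return Structure(f"bundle-n{n}r{rph}s{spec.seed}", {"A": residues})


def _pocket_from_blocks(residues: list[Residue], n_pocket: int) -> list[int]:
    """One inward-facing mid-helix residue per helix (CB closest to the
    bundle axis, z nearest 0), for the first ``n_pocket`` helices."""
    n_total = len(residues)
    # infer block length: z-direction flips between helices; simpler to use CA xy jumps
    xy = np.array([r.ca.coords[:2] for r in residues])
    jumps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    block_ends = [i for i, d in enumerate(jumps) if d > 3.0 * HELIX_RADIUS]
    starts = [0] + [i + 1 for i in block_ends]
    ends = block_ends + [n_total - 1]
    chosen = []
    for h in range(min(n_pocket, len(starts))):
        lo, hi = starts[h], ends[h]
        third = (hi - lo + 1) // 3
        window = residues[lo + third: hi - third + 1] or residues[lo:hi + 1]
        best = min(window, key=lambda r: (np.linalg.norm(r.atom("CB").coords[:2]),
                                          abs(r.atom("CB").coords[2])))
        chosen.append(best.seq_id)
    return chosen


def make_homolog(bundle: Structure, spec: FixtureSpec
                 ) -> tuple[Structure, RigidTransform, list[int]]:
    """Perturbed, rigidly moved copy of the bundle with a planted ligand.

    The sequence is mutated down to ``spec.identity``, all atoms receive
    isotropic Gaussian noise of ``spec.noise_sigma`` Å, a linear multi-atom
    ligand is planted so that exactly the chosen pocket residues have a
    heavy atom within 4 Å of it (every other residue stays beyond
    ``spec.pocket_margin``), and the whole assembly is moved by the spec's
    rigid transform.

    Returns the homolog, the ground-truth *recovery* transform (the one a
    correct superposition of the homolog onto the bundle must find, i.e.
    the inverse of the applied motion), and the pocket residue numbers.
    Raises if the requested pocket cannot be realised with the required
    margins.
    """
    rng = np.random.default_rng(spec.seed + 10007)
    hom = bundle.copy()
    residues = hom.chains["A"]
    n_total = len(residues)

    n_mut = int(round((1.0 - spec.identity) * n_total))
    mut_positions = rng.choice(n_total, size=n_mut, replace=False)
    for idx in mut_positions:
        r = residues[idx]
        current = r.name
        options = [ONE_TO_THREE[a] for a in _AA if ONE_TO_THREE[a] != current]
        r.name = options[rng.integers(len(options))]

    pocket = _pocket_from_blocks(residues, spec.n_pocket)
    pocket_set = set(pocket)

    # plant the ligand against the *unnoised* geometry, then perturb ligand
    # and protein together so the construction margins refer to one frame
    lig_pts = []
    for sid in pocket:
        r = residues[sid - 1]
        cb = r.atom("CB").coords
        axis_pt = np.array([0.0, 0.0, cb[2]])
        d = axis_pt - cb
        nrm = np.linalg.norm(d)
        if nrm < 1e-9:
            raise ValueError(f"pocket residue {sid}: CB on the bundle axis")
        lig_pts.append(cb + spec.ligand_offset * d / nrm)
    lig_pts = np.array(lig_pts)

    # verify margins against every residue
    for r in residues:
        dmin = min(float(np.linalg.norm(a.coords - p))
                   for a in r.atoms for p in lig_pts)
        if r.seq_id in pocket_set:
            if dmin > 4.0:
                raise ValueError(f"pocket residue {r.seq_id} ended up {dmin:.2f} Å "
                                 "from the ligand; pocket not mutually placeable")
        elif dmin < spec.pocket_margin:
            raise ValueError(f"non-pocket residue {r.seq_id} lies {dmin:.2f} Å from "
                             "the planted ligand; pocket not mutually placeable")

    if spec.noise_sigma > 0:
        for r in residues:
            for a in r.atoms:
                a.coords = a.coords + rng.normal(0.0, spec.noise_sigma, 3)

    T = spec.transform
    for r in residues:
        for a in r.atoms:
            a.coords = T.apply(a.coords)
    lig_coords = T.apply(lig_pts)

    lig_atoms = [Atom(f"C{i + 1}", "C", c) for i, c in enumerate(lig_coords)]
    residues.append(Residue(900, "LIG", lig_atoms, is_hetero=True))
    hom.entry_id = bundle.entry_id + "-hom"
    return hom, T.inverse(), pocket


def displace_region(structure: Structure, chain_id: str, start: int, end: int,
                    vector, taper: bool = True) -> Structure:
    """Correlated displacement of a residue interval (variant-style local
    perturbation). With ``taper`` the displacement ramps up and down over
    the interval so the chain stays visually continuous."""
    out = structure.copy()
    vec = np.asarray(vector, dtype=float)
    span = max(end - start, 1)
    for r in out.chains[chain_id]:
        if start <= r.seq_id <= end:
            if taper:
                u = (r.seq_id - start) / span
                w = np.sin(np.pi * u) if span > 1 else 1.0
            else:
                w = 1.0
            for a in r.atoms:
                a.coords = a.coords + w * vec
    return out


def make_toy_catalog() -> dict[str, LigandRecord]:
    """Eight small molecules whose 166-key fingerprints are small enough to
    audit, shipped with an independently computed expected Tanimoto matrix
    (``data/toy_tanimoto_expected.tsv``)."""
    records = [
        LigandRecord("METH", "methane", "C"),
        LigandRecord("ETOH", "ethanol", "CCO"),
        LigandRecord("BENZ", "benzene", "c1ccccc1"),
        LigandRecord("PHEN", "phenol", "Oc1ccccc1"),
        LigandRecord("ACET", "acetic acid", "CC(=O)O"),
        LigandRecord("HEXA", "hexane", "CCCCCC"),
        LigandRecord("IPRO", "isopropanol", "CC(C)O"),
        LigandRecord("MGI", "magnesium ion", "[Mg+2]"),
    ]
    return {r.ccd_id: r for r in records}


def expected_toy_tanimoto() -> "pd.DataFrame":
    import importlib.resources
    import pandas as pd
    path = importlib.resources.files("homolig.data") / "toy_tanimoto_expected.tsv"
    return pd.read_csv(path, sep="\t", comment="#")
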