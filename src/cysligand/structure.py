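"""Ligand-contact labeling from 3D complexes and radial distribution analysis.

Contact labeling follows the heavy-atom rule: a residue is a ligand-binding
residue when its closest heavy-atom pair with the ligand is within the
cutoff (default 4.5 Angstrom).  The radial distribution analysis instead
uses minimum *all-atom* distances from a cysteine of interest to each
predicted binding residue — the two distance rules intentionally differ.

g(r) is a shell-density histogram: per-bin counts divided by the spherical
shell volume 4 pi r^2 dr, then normalized by the mean shell density over the
last 20% of the distance range, so a uniform point cloud has tail g(r) ~ 1.

PDB I/O goes through gemmi.  Altlocs keep the highest-occupancy copy;
insertion codes are folded into the residue key.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import CysligandError
from .metrics import PredictionSet

Site = tuple[str, int]

# average atomic masses for the elements the toy complexes use
_ATOMIC_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                "S": 32.06, "P": 30.974, "F": 18.998, "CL": 35.45,
                "BR": 79.904}


@dataclass
class Residue:
    position: int          # 1-based sequence position (insertion code appended)
    name: str
    atoms: list            # list of (element, xyz ndarray)

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        pts = [xyz for el, xyz in self.atoms if not (heavy_only and el == "H")]
        if not pts:
            raise CysligandError(
                f"residue {self.name}{self.position} has no "
                f"{'heavy ' if heavy_only else ''}atoms")
        return np.asarray(pts)


@dataclass
class StructureModel:
    uid: str
    residues: dict[int, Residue] = field(default_factory=dict)

    def residue(self, position: int) -> Residue:
        if position not in self.residues:
            raise CysligandError(f"{self.uid}: no residue at position {position}")
        return self.residues[position]


@dataclass
class LigandPose:
    ligand_id: str
    heavy_coords: np.ndarray    # (n, 3), heavy atoms only
    mw: float                   # Daltons
    elements: list | None = None  # per heavy atom, when known

    def __post_init__(self):
        self.heavy_coords = np.asarray(self.heavy_coords, dtype=float)
        if self.heavy_coords.ndim != 2 or len(self.heavy_coords) == 0:
            raise CysligandError("ligand pose needs at least one heavy atom")
        if self.mw <= 0:
            raise CysligandError("ligand molecular weight must be positive")


def molecular_weight(elements) -> float:
    try:
        return float(sum(_ATOMIC_MASS[e.upper()] for e in elements))
    except KeyError as exc:
        raise CysligandError(f"unknown element {exc.args[0]!r}") from None


def ligand_mw_filter(pose: LigandPose, lo: float = 150.0, hi: float = 600.0) -> bool:
    """Accept small molecules with molecular weight in [150, 600] Da."""
    return lo <= pose.mw <= hi


def label_binding_residues(structure: StructureModel, pose: LigandPose,
                           cutoff: float = 4.5) -> set[int]:
    """Residue positions whose nearest heavy-atom pair to the ligand <= cutoff."""
    labeled = set()
    for pos, res in structure.residues.items():
        pts = res.coords(heavy_only=True)
        d = np.linalg.norm(pts[:, None, :] - pose.heavy_coords[None, :, :], axis=2)
        if d.min() <= cutoff:
            labeled.add(pos)
    return labeled


def min_residue_distance(structure: StructureModel, pos_a: int, pos_b: int) -> float:
    """Minimum all-atom Euclidean distance between two residues."""
    a = structure.residue(pos_a).coords()
    b = structure.residue(pos_b).coords()
    return float(np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2).min())


# ---------------------------------------------------------------------------
# PDB I/O

def read_complex(path, uid: str | None = None,
                 ligand_name: str = "LIG") -> tuple[StructureModel, LigandPose | None]:
    """Read ATOM/HETATM records; the named HETATM residue becomes the pose."""
    st = gemmi.read_structure(str(path))
    st.remove_alternative_conformations()   # keeps highest occupancy
    model = st[0]
    out = StructureModel(uid=uid or st.name or "structure")
    lig_elements: list[str] = []
    lig_coords: list[np.ndarray] = []
    for chain in model:
        for res in chain:
            if res.name == ligand_name or res.het_flag == "H" and res.name == ligand_name:
                for atom in res:
                    el = atom.element.name.upper()
                    if el != "H":
                        lig_elements.append(el)
                        lig_coords.append(np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
                continue
            key = res.seqid.num
            if res.seqid.icode and res.seqid.icode.strip():
                # fold insertion codes into a distinct integer key space
                key = key * 100 + ord(res.seqid.icode) - ord("A") + 1
            atoms = [(atom.element.name.upper(),
                      np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
                     for atom in res]
            out.residues[key] = Residue(position=key, name=res.name, atoms=atoms)
    pose = None
    if lig_coords:
        pose = LigandPose(ligand_id=ligand_name,
                          heavy_coords=np.asarray(lig_coords),
                          mw=molecular_weight(lig_elements),
                          elements=lig_elements)
    return out, pose


def write_complex(path, structure: StructureModel, pose: LigandPose | None = None,
                  ligand_elements: list[str] | None = None) -> None:
    """Write a toy complex as a PDB file (chain A protein, chain B ligand)."""
    st = gemmi.Structure()
    st.name = structure.uid
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for pos in sorted(structure.residues):
        res = structure.residues[pos]
        g_res = gemmi.Residue()
        g_res.name = res.name
        g_res.seqid = gemmi.SeqId(pos, " ")
        for i, (el, xyz) in enumerate(res.atoms):
            atom = gemmi.Atom()
            atom.name = f"{el}{i + 1}"
            atom.element = gemmi.Element(el)
            atom.pos = gemmi.Position(*[float(v) for v in xyz])
            g_res.add_atom(atom)
        chain.add_residue(g_res)
    model.add_chain(chain)
    if pose is not None:
        lig_chain = gemmi.Chain("B")
        lig_res = gemmi.Residue()
        lig_res.name = pose.ligand_id
        lig_res.seqid = gemmi.SeqId(1, " ")
        lig_res.het_flag = "H"
        elements = ligand_elements or pose.elements or ["C"] * len(pose.heavy_coords)
        for i, xyz in enumerate(pose.heavy_coords):
            atom = gemmi.Atom()
            atom.name = f"{elements[i]}{i + 1}"
            atom.element = gemmi.Element(elements[i])
            atom.pos = gemmi.Position(*[float(v) for v in xyz])
            lig_res.add_atom(atom)
        lig_chain.add_residue(lig_res)
        model.add_chain(lig_chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# radial distribution function

@dataclass
class RDFResult:
    bin_edges: np.ndarray
    g: dict[str, np.ndarray]            # confusion class -> g(r)
    counts: dict[str, np.ndarray]       # raw per-bin pair counts
    norm_const: dict[str, float]        # tail mean shell density per class
    skipped: list[str] = field(default_factory=list)

    @property
    def r_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def compute_rdf(cys_classes: dict[Site, str],
                predicted_binding: dict[str, set],
                structures: dict[str, StructureModel],
                bin_width: float = 0.5, r_max: float = 20.0) -> RDFResult:
    """Tail-normalized radial density of predicted binding residues.

    For every classified cysteine, the minimum all-atom distance to each
    predicted binding residue of the same protein enters the histogram of
    its confusion class (the cysteine's own position is skipped).  Classes
    without any classified cysteine, or with an empty histogram, are listed
    in ``skipped`` rather than silently zeroed.
    """
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    classes = ("TP", "TN", "FP", "FN")
    dists: dict[str, list[float]] = {c: [] for c in classes}
    present: set[str] = set()
    for (uid, pos), cls in cys_classes.items():
        present.add(cls)
        if uid not in structures:
            continue
        st = structures[uid]
        for rpos in sorted(predicted_binding.get(uid, ())):
            if rpos == pos or rpos not in st.residues:
                continue
            d = min_residue_distance(st, pos, rpos)
            if d <= r_max:
                dists[cls].append(d)

    shell = 4.0 * np.pi * (0.5 * (edges[:-1] + edges[1:])) ** 2 * bin_width
    tail_start = 0.8 * r_max
    tail_bins = (0.5 * (edges[:-1] + edges[1:])) >= tail_start

    g: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    norm: dict[str, float] = {}
    skipped: list[str] = []
    for c in classes:
        if c not in present or not dists[c]:
            skipped.append(c)
            continue
        hist, _ = np.histogram(dists[c], bins=edges)
        density = hist / shell
        tail_mean = float(density[tail_bins].mean())
        counts[c] = hist
        if tail_mean <= 0:
            skipped.append(c)
            continue
        g[c] = density / tail_mean
        norm[c] = tail_mean
    return RDFResult(bin_edges=edges, g=g, counts=counts, norm_const=norm,
                     skipped=skipped)


def top_k_binding(predictions: PredictionSet, k: int = 20) -> dict[str, set]:
    """Score-ranked top-k predicted binding residues per protein."""
    out: dict[str, set] = {}
    for uid, sites in predictions.proteins().items():
        ranked = sorted(sites, key=lambda s: (-predictions.scores[s], s))
        out[uid] = {pos for _, pos in ranked[:k]}
    return out


def thresholded_binding(predictions: PredictionSet, threshold: float = 0.5) -> dict[str, set]:
    """Predicted binding residues by score threshold."""
    out: dict[str, set] = {}
    for (uid, pos), score in predictions.scores.items():
        if score >= threshold:
            out.setdefault(uid, set()).add(pos)
    return out


__all__ = [
    "Residue", "StructureModel", "LigandPose", "RDFResult",
    "molecular_weight", "ligand_mw_filter", "label_binding_residues",
    "min_residue_distance", "read_complex", "write_complex",
    "compute_rdf", "top_k_binding", "thresholded_binding",
]
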