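"""Deterministic generator of synthetic proteomes, records and complexes.

The generator emulates the data regime the pipeline is built for:

* a proteome whose cysteines carry short planted sequence motifs drawn from
  a fixed library; each motif hashes to one of a few latent *archetypes*
  (shared with the synthetic embedding provider, so embedding geometry and
  ground truth agree), and the archetype's ligandability probability drives
  each site's true label;
* several independent sources that each detect a site with some
  probability and then report it with false-positive / false-negative label
  noise — the multi-source inconsistency the consensus machinery exists to
  reconcile;
* toy protein-ligand complexes in which the planted binding residues are
  within the heavy-atom contact cutoff by construction, sit 4-6 Angstrom
  from the focal cysteine, and every non-binding residue is kept well
  outside the cutoff.

Everything is a pure function of the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._hash import rng_for
from .embeddings import window_archetype
from .records import POS, NEG, CuratedDB, ProteinEntry, SiteRecord, curate
from .structure import LigandPose, Residue, StructureModel, molecular_weight

Site = tuple[str, int]

# background alphabet excludes C so every cysteine comes from a planted motif
_BG_ALPHABET = "ADEFGHIKLMNPQRSTVWY"


@dataclass
class GeneratorConfig:
    n_proteins: int = 300
    length_range: tuple[int, int] = (100, 400)
    cys_freq: float = 0.03
    n_archetypes: int = 6
    embedding_dim: int = 64
    archetype_pos_probs: tuple[float, ...] = (1.0, 0.95, 0.9, 0.1, 0.05, 0.0)
    n_sources: int = 8
    detection_prob: float = 0.5
    fp_rate: float = 0.3
    fn_rate: float = 0.4
    n_motifs: int = 2000
    motif_window: int = 9
    seed: int = 0

    def __post_init__(self):
        probs = (self.cys_freq, self.detection_prob, self.fp_rate,
                 self.fn_rate, *self.archetype_pos_probs)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if len(self.archetype_pos_probs) != self.n_archetypes:
            raise ValueError("need one ligandability probability per archetype")
        if self.motif_window % 2 != 1:
            raise ValueError("motif window must be odd")


@dataclass
class GroundTruth:
    true_label: dict[Site, int] = field(default_factory=dict)
    archetype: dict[Site, int] = field(default_factory=dict)
    motif: dict[Site, int] = field(default_factory=dict)
    binding: dict[str, set] = field(default_factory=dict)   # uid -> residue set
    focus_cys: dict[str, int] = field(default_factory=dict)  # uid -> cys position


def _motif_library(config: GeneratorConfig) -> list[str]:
    rng = rng_for(config.seed, "motifs")
    half = config.motif_window // 2
    motifs = []
    seen = set()
    while len(motifs) < config.n_motifs:
        left = "".join(rng.choice(list(_BG_ALPHABET), half))
        right = "".join(rng.choice(list(_BG_ALPHABET), half))
        m = left + "C" + right
        if m not in seen:
            seen.add(m)
            motifs.append(m)
    return motifs


def gen_proteome(config: GeneratorConfig) -> tuple[list[ProteinEntry], GroundTruth]:
    """Generate proteins with motif-planted cysteines and their ground truth."""
    motifs = _motif_library(config)
    half = config.motif_window // 2
    rng = rng_for(config.seed, "proteome")
    proteins: list[ProteinEntry] = []
    gt = GroundTruth()
    for i in range(config.n_proteins):
        uid = f"P{i:04d}"
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        seq = list(rng.choice(list(_BG_ALPHABET), length))
        n_cys = int(rng.binomial(length, config.cys_freq))
        positions0 = _spaced_positions(rng, length, n_cys, half, config.motif_window)
        for p0 in positions0:
            p0 = int(p0)
            m_idx = int(rng.integers(config.n_motifs))
            motif = motifs[m_idx]
            seq[p0 - half:p0 + half + 1] = list(motif)
            site = (uid, p0 + 1)
            a = window_archetype(motif, config.n_archetypes, config.seed)
            gt.archetype[site] = a
            gt.motif[site] = m_idx
            gt.true_label[site] = int(rng.random() < config.archetype_pos_probs[a])
        proteins.append(ProteinEntry(uid=uid, sequence="".join(seq)))
    return proteins, gt


def _spaced_positions(rng, length, n, margin, min_sep, max_tries=200) -> list[int]:
    """n 0-based positions in [margin, length-margin) with pairwise gap >= min_sep."""
    if n == 0 or length < 2 * margin + 1:
        return []
    lo, hi = margin, length - margin - 1
    for _ in range(max_tries):
        cand = sorted(rng.integers(lo, hi + 1, size=n))
        if all(b - a >= min_sep for a, b in zip(cand, cand[1:])):
            return cand
    # dense case: fall back to a stride placement of as many as fit
    stride = list(range(lo, hi + 1, min_sep))
    return stride[:n]


def gen_abpp_records(ground_truth: GroundTruth,
                     config: GeneratorConfig) -> list[SiteRecord]:
    """Per-source noisy detection and labeling of every cysteine site.

    Each source independently detects each site with ``detection_prob``;
    detected ligandable sites are reported pos with probability 1 - FN,
    detected non-ligandable sites pos with probability FP, else neg.
    """
    records: list[SiteRecord] = []
    counter = 0
    for s in range(config.n_sources):
        source_id = f"S{s + 1:02d}"
        rng = rng_for(config.seed, "abpp", s)
        for site in sorted(ground_truth.true_label):
            if rng.random() >= config.detection_prob:
                continue
            truth = ground_truth.true_label[site]
            if truth:
                label = NEG if rng.random() < config.fn_rate else POS
            else:
                label = POS if rng.random() < config.fp_rate else NEG
            counter += 1
            records.append(SiteRecord(uid=site[0], position=site[1], label=label,
                                      source_id=source_id,
                                      record_id=f"R{counter:06d}"))
    return records


def build_database(proteins: list[ProteinEntry],
                   records: list[SiteRecord]) -> CuratedDB:
    """Assemble and fully curate a database from generated pieces."""
    db = CuratedDB(proteins={p.uid: p for p in proteins}, records=list(records))
    db.validate()
    return curate(db)


def simulate_database(config: GeneratorConfig) -> tuple[CuratedDB, GroundTruth]:
    """One-call generator: proteome -> records -> curated database."""
    proteins, gt = gen_proteome(config)
    records = gen_abpp_records(gt, config)
    return build_database(proteins, records), gt


# ---------------------------------------------------------------------------
# toy complexes

_LIG_DIST = 7.0          # cys -> ligand center (keeps the cys outside 4.5 A)
_LIG_SPREAD = 1.2        # ligand atom radius around its center
_BIND_RANGE = (4.6, 5.9)  # cys -> binding-residue distance band
_CONTACT_RANGE = (1.6, 4.2)   # binding residue -> nearest ligand heavy atom
_FAR_MIN = 6.5           # non-binding residue clearance from the ligand


def gen_complexes(ground_truth: GroundTruth, config: GeneratorConfig,
                  proteins: list[ProteinEntry], n_complexes: int = 40,
                  n_binding_range: tuple[int, int] = (3, 6),
                  ) -> tuple[dict[str, StructureModel], dict[str, LigandPose]]:
    """Toy coordinates with planted, margin-guarded binding residues.

    For each chosen protein the focal cysteine sits at the origin, the
    ligand center 7 Angstrom away, binding residues within the heavy-atom
    cutoff of the ligand and 4-6 Angstrom from the cysteine, and all
    other residues at least 6.5 Angstrom clear of every ligand atom.
    """
    by_uid: dict[str, list[int]] = {}
    for uid, pos in ground_truth.true_label:
        by_uid.setdefault(uid, []).append(pos)
    prot_map = {p.uid: p for p in proteins}
    chosen = sorted(by_uid)[:n_complexes]

    structures: dict[str, StructureModel] = {}
    poses: dict[str, LigandPose] = {}
    for uid in chosen:
        rng = rng_for(config.seed, "complex", uid)
        cys_positions = sorted(by_uid[uid])
        # prefer a truly ligandable focal cysteine when one exists
        ligandable = [p for p in cys_positions
                      if ground_truth.true_label[(uid, p)] == 1]
        focus = (ligandable or cys_positions)[0]
        length = len(prot_map[uid].sequence)

        u = _unit(rng.standard_normal(3))
        center = _LIG_DIST * u
        n_lig = int(rng.integers(14, 41))
        lig_elements = list(rng.choice(["C", "C", "C", "N", "O"], n_lig))
        lig_coords = center + _LIG_SPREAD * _ball(rng, n_lig)

        st = StructureModel(uid=uid)
        # focal cysteine: atoms within 0.3 A of the origin, so every
        # cys -> binding-residue min distance stays inside (4, 6) A
        st.residues[focus] = Residue(position=focus, name="CYS", atoms=[
            ("S", 0.15 * _unit(rng.standard_normal(3))),
            ("C", 0.30 * _unit(rng.standard_normal(3))),
        ])

        others = [p for p in range(1, length + 1) if p != focus]
        k = int(rng.integers(n_binding_range[0], n_binding_range[1] + 1))
        binding = sorted(rng.choice(others, size=min(k, len(others)), replace=False))
        gt_set = set(int(b) for b in binding)
        for b in binding:
            xyz = _sample_binding_point(rng, lig_coords)
            st.residues[int(b)] = Residue(position=int(b), name="ALA", atoms=[
                ("C", xyz), ("C", xyz + 0.15 * _unit(rng.standard_normal(3)))])
        for p in others:
            if p in gt_set:
                continue
            xyz = _sample_far_point(rng, lig_coords)
            st.residues[p] = Residue(position=p, name="GLY", atoms=[("C", xyz)])

        structures[uid] = st
        poses[uid] = LigandPose(ligand_id="LIG", heavy_coords=lig_coords,
                                mw=molecular_weight(lig_elements),
                                elements=[str(e) for e in lig_elements])
        ground_truth.binding[uid] = gt_set
        ground_truth.focus_cys[uid] = focus
    return structures, poses


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _ball(rng, n: int) -> np.ndarray:
    pts = rng.standard_normal((n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts * rng.random((n, 1)) ** (1 / 3)


def _sample_binding_point(rng, lig_coords: np.ndarray) -> np.ndarray:
    """Point 4.2-5.8 A from the origin and 1.6-4.2 A from a ligand heavy atom."""
    center_dir = _unit(lig_coords.mean(axis=0))
    for _ in range(10_000):
        d = rng.uniform(*_BIND_RANGE)
        w = _unit(center_dir + 0.35 * rng.standard_normal(3))
        x = d * w
        near = np.linalg.norm(lig_coords - x, axis=1).min()
        if _CONTACT_RANGE[0] <= near <= _CONTACT_RANGE[1]:
            return x
    raise RuntimeError("could not place a binding residue (geometry too tight)")


def _sample_far_point(rng, lig_coords: np.ndarray) -> np.ndarray:
    """Point 8-20 A from the origin and > 6.5 A from every ligand heavy atom."""
    for _ in range(10_000):
        x = rng.uniform(8.0, 20.0) * _unit(rng.standard_normal(3))
        if np.linalg.norm(lig_coords - x, axis=1).min() > _FAR_MIN:
            return x
    raise RuntimeError("could not place a far residue")


__all__ = [
    "GeneratorConfig", "GroundTruth", "gen_proteome", "gen_abpp_records",
    "gen_complexes", "build_database", "simulate_database",
]
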