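"""Residue-contact, occupancy, moiety and structural analysis of trajectories.

Works on ensembles of replicate simulations in which a single protein
copy is surrounded by several copies of a small organometallic ligand.
The central quantity is residue occupancy: the fraction of frames in
which a protein residue is within a heavy-atom distance cutoff of any
ligand copy.  Residues above an occupancy threshold (strictly more than
30% of the simulation time, by default) are called binding residues.
Ligand moieties (cyclopentadienyl ring, carbonyls, carboxymethyl group)
are scored separately to resolve which part of the ligand drives the
interaction, and simple geometric hydrogen-bond detection plus
RMSD/radius-of-gyration metrics round out the picture.

All coordinates are in nm.  Residue numbering is 1-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

__all__ = [
    "Topology",
    "TrajectoryEnsemble",
    "OccupancyTable",
    "MoietyProfile",
    "HBond",
    "StructureMetrics",
    "residue_contact_set",
    "occupancy",
    "binding_residues",
    "moiety_interaction_profile",
    "detect_hbonds",
    "structure_metrics",
    "trp_report",
]

DEFAULT_CUTOFF_NM = 0.4          # heavy-atom minimum-distance contact criterion
DEFAULT_OCC_THRESHOLD = 0.30     # "binding residue" occupancy threshold (strict >)

MOIETIES = ("ring", "carbonyl", "carboxyl")

# residues whose (coarse, one-bead) representation can donate/accept H-bonds
POLAR_RESIDUES = frozenset(
    {"SER", "THR", "TYR", "ASN", "GLN", "ASP", "GLU", "LYS", "ARG", "HIS", "TRP"}
)


@dataclass(frozen=True)
class Topology:
    """Per-atom annotation shared by all frames of an ensemble.

    ``ligand_copy`` is -1 for protein atoms and the 0-based copy index
    for ligand atoms; every ligand atom carries a moiety label
    (``ring``/``carbonyl``/``carboxyl``) or ``center`` for the metal.
    """

    atom_name: np.ndarray
    element: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    chain_id: np.ndarray
    ligand_copy: np.ndarray
    moiety: np.ndarray

    def __post_init__(self):
        arrays = {}
        n = None
        for name in ("atom_name", "element", "res_id", "res_name", "chain_id",
                     "ligand_copy", "moiety"):
            a = np.asarray(getattr(self, name))
            arrays[name] = a
            if n is None:
                n = a.size
            elif a.size != n:
                raise ValueError("all topology arrays must have equal length")
            object.__setattr__(self, name, a)
        lig = arrays["ligand_copy"] >= 0
        bad = lig & ~np.isin(arrays["moiety"], list(MOIETIES) + ["center"])
        if np.any(bad):
            raise ValueError("every ligand atom needs a moiety label or 'center'")

    @property
    def n_atoms(self) -> int:
        return int(self.atom_name.size)

    @property
    def protein_mask(self) -> np.ndarray:
        return self.ligand_copy < 0

    @property
    def ligand_mask(self) -> np.ndarray:
        return self.ligand_copy >= 0

    @property
    def heavy_mask(self) -> np.ndarray:
        return self.element != "H"

    def protein_residues(self) -> np.ndarray:
        """Sorted unique residue ids of the protein chain."""
        return np.unique(self.res_id[self.protein_mask])


@dataclass
class TrajectoryEnsemble:
    """Replicate trajectories over a shared topology.

    ``replicates`` is a list of (n_frames, n_atoms, 3) coordinate arrays
    in nm; ``ground_truth`` optionally carries generator-planted expected
    occupancies for validation.
    """

    topology: Topology
    replicates: list[np.ndarray]
    ground_truth: dict | None = None

    def __post_init__(self):
        if not self.replicates:
            raise ValueError("ensemble needs at least one replicate")
        reps = []
        for r in self.replicates:
            r = np.asarray(r, dtype=float)
            if r.ndim != 3 or r.shape[1] != self.topology.n_atoms or r.shape[2] != 3:
                raise ValueError("replicate shape must be (n_frames, n_atoms, 3)")
            reps.append(r)
        self.replicates = reps

    @property
    def n_frames_total(self) -> int:
        return int(sum(r.shape[0] for r in self.replicates))


@dataclass(frozen=True)
class OccupancyTable:
    """Per-residue fraction of frames in contact with any ligand copy."""

    res_ids: np.ndarray
    occupancy: np.ndarray
    n_frames_total: int
    cutoff_nm: float
    aggregation: str   # "pooled" | "per_replicate_mean"

    def __post_init__(self):
        occ = np.asarray(self.occupancy, dtype=float)
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "res_ids", np.asarray(self.res_ids, dtype=int))
        if occ.shape != self.res_ids.shape:
            raise ValueError("res_ids/occupancy length mismatch")
        if np.any(occ < 0) or np.any(occ > 1):
            raise ValueError("occupancies must lie in [0, 1]")

    def as_dict(self) -> dict[int, float]:
        return {int(r): float(o) for r, o in zip(self.res_ids, self.occupancy)}


@dataclass(frozen=True)
class MoietyProfile:
    """Interaction probability per ligand moiety (non-exclusive)."""

    probabilities: dict[str, float]
    conditional: bool
    n_contact_events: int

    def __getitem__(self, moiety: str) -> float:
        return self.probabilities[moiety]


@dataclass(frozen=True)
class HBond:
    donor_index: int
    acceptor_index: int
    distance_nm: float
    frame: int
    hydrogen_index: int | None = None
    angle_deg: float | None = None


@dataclass(frozen=True)
class StructureMetrics:
    """Per-frame RMSD (to frame 0) and radius of gyration, one replicate."""

    rmsd_nm: np.ndarray
    radius_of_gyration_nm: np.ndarray


def _contact_matrix(coords: np.ndarray, top: Topology, cutoff: float):
    """Boolean (protein heavy atom) x (ligand heavy atom) contact matrix."""
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates contain NaN/inf")
    pmask = top.protein_mask & top.heavy_mask
    lmask = top.ligand_mask & top.heavy_mask
    d = cdist(coords[pmask], coords[lmask])
    return d <= cutoff, top.res_id[pmask], top.ligand_copy[lmask], top.moiety[lmask]


def residue_contact_set(
    coords: np.ndarray,
    top: Topology,
    cutoff: float = DEFAULT_CUTOFF_NM,
) -> set[tuple[int, int]]:
    """All (residue id, ligand copy) pairs in heavy-atom contact.

    A residue contacts a ligand copy when the minimum distance over all
    heavy-atom pairs is at or below ``cutoff``; hydrogens are ignored.
    """
    within, res, copy, _ = _contact_matrix(np.asarray(coords, float), top, cutoff)
    pi, li = np.nonzero(within)
    return {(int(res[i]), int(copy[j])) for i, j in zip(pi, li)}


def occupancy(
    ensemble: TrajectoryEnsemble,
    cutoff: float = DEFAULT_CUTOFF_NM,
    aggregation: str = "per_replicate_mean",
) -> OccupancyTable:
    """Per-residue ligand-contact occupancy over an ensemble.

    A residue counts as "in contact" in a frame when ANY ligand copy
    touches it.  With ``per_replicate_mean`` (default) the per-replicate
    frame fractions are averaged, treating replicates as independent
    simulations; ``pooled`` lumps all frames together.
    """
    if aggregation not in ("pooled", "per_replicate_mean"):
        raise ValueError("aggregation must be 'pooled' or 'per_replicate_mean'")
    top = ensemble.topology
    residues = top.protein_residues()
    index = {int(r): k for k, r in enumerate(residues)}
    per_rep = []
    for rep in ensemble.replicates:
        counts = np.zeros(residues.size)
        for frame in rep:
            contacted = {r for r, _ in residue_contact_set(frame, top, cutoff)}
            for r in contacted:
                counts[index[r]] += 1
        per_rep.append(counts / rep.shape[0])
    if aggregation == "per_replicate_mean":
        occ = np.mean(per_rep, axis=0)
    else:
        total = sum(r.shape[0] for r in ensemble.replicates)
        occ = sum(p * r.shape[0] for p, r in zip(per_rep, ensemble.replicates)) / total
    return OccupancyTable(residues, occ, ensemble.n_frames_total, cutoff, aggregation)


def binding_residues(
    table: OccupancyTable,
    threshold: float = DEFAULT_OCC_THRESHOLD,
) -> set[int]:
    """Residues occupied strictly more than ``threshold`` of the time."""
    return {int(r) for r, o in zip(table.res_ids, table.occupancy) if o > threshold}


def moiety_interaction_profile(
    ensemble: TrajectoryEnsemble,
    cutoff: float = DEFAULT_CUTOFF_NM,
    conditional: bool = True,
) -> MoietyProfile:
    """Probability that each ligand moiety touches the protein.

    For every (frame, ligand copy) pair the copy is first tested for any
    heavy-atom protein contact; each moiety is then scored if at least
    one of its atoms is within ``cutoff`` of the protein.  By default the
    probabilities are conditioned on the copy being in contact at all
    (the moieties' role *in binding*); ``conditional=False`` divides by
    all (frame, copy) pairs instead.  Metal ``center`` atoms count for
    contact detection but belong to no moiety.
    """
    top = ensemble.topology
    if not np.any(np.isin(top.moiety, list(MOIETIES))):
        raise ValueError("topology has no moiety labels")
    n_pairs = 0
    n_contact = 0
    hits = {m: 0 for m in MOIETIES}
    for rep in ensemble.replicates:
        for frame in rep:
            within, _, copy, moiety = _contact_matrix(frame, top, cutoff)
            col_hit = within.any(axis=0)
            for c in np.unique(copy):
                cmask = copy == c
                n_pairs += 1
                if not col_hit[cmask].any():
                    continue
                n_contact += 1
                for m in MOIETIES:
                    if col_hit[cmask & (moiety == m)].any():
                        hits[m] += 1
    denom = n_contact if conditional else n_pairs
    probs = {m: (hits[m] / denom if denom else 0.0) for m in MOIETIES}
    return MoietyProfile(probs, conditional, n_contact)


def _donor_acceptor_masks(top: Topology):
    """Heavy-atom donor/acceptor flags from element + residue templates.

    Ligand side: carboxyl oxygens donate and accept, carbonyl oxygens
    accept.  Protein side: in coarse (one bead per residue) mode the bead
    of any polar residue both donates and accepts; in atomistic mode any
    protein N/O does.
    """
    lig = top.ligand_mask
    prot = top.protein_mask
    is_o = top.element == "O"
    don = np.zeros(top.n_atoms, bool)
    acc = np.zeros(top.n_atoms, bool)
    don |= lig & is_o & (top.moiety == "carboxyl")
    acc |= lig & is_o & np.isin(top.moiety, ["carboxyl", "carbonyl"])
    atomistic = np.any(prot & np.isin(top.element, ["N", "O"]))
    if atomistic:
        polar = prot & np.isin(top.element, ["N", "O"])
    else:
        polar = prot & np.isin(top.res_name, list(POLAR_RESIDUES))
    don |= polar
    acc |= polar
    return don, acc


def detect_hbonds(
    coords: np.ndarray,
    top: Topology,
    d_cut: float = 0.35,
    angle_min: float = 120.0,
    coarse_d_cut: float = 0.32,
    frame_index: int = 0,
) -> list[HBond]:
    """Geometric hydrogen-bond detection between ligand and protein.

    With explicit hydrogens: donor-acceptor distance <= ``d_cut`` and
    donor-H-acceptor angle >= ``angle_min`` (H assigned to the nearest
    donor within bonding range).  Without hydrogens a distance-only
    criterion at the tighter ``coarse_d_cut`` is used.  Only
    protein-ligand pairs are reported.
    """
    coords = np.asarray(coords, float)
    don, acc = _donor_acceptor_masks(top)
    h_idx = np.nonzero(top.element == "H")[0]
    have_h = h_idx.size > 0
    out: list[HBond] = []
    d_i = np.nonzero(don)[0]
    a_i = np.nonzero(acc)[0]
    if d_i.size == 0 or a_i.size == 0:
        return out
    dmat = cdist(coords[d_i], coords[a_i])
    limit = d_cut if have_h else coarse_d_cut
    seen_pairs: set[frozenset[int]] = set()
    for ii, jj in zip(*np.nonzero(dmat <= limit)):
        di, ai = int(d_i[ii]), int(a_i[jj])
        if di == ai:
            continue
        # inter-molecular only
        if (top.ligand_copy[di] < 0) == (top.ligand_copy[ai] < 0):
            continue
        if not have_h:
            # without hydrogens donor/acceptor roles are ambiguous:
            # report each atom pair once
            key = frozenset((di, ai))
            if key in seen_pairs:
                continue
            seen_pairs.add(key)
            out.append(HBond(di, ai, float(dmat[ii, jj]), frame_index))
            continue
        # hydrogens covalently attached to this donor (within 0.12 nm)
        dh = np.linalg.norm(coords[h_idx] - coords[di], axis=1)
        for hi in h_idx[dh <= 0.12]:
            v1 = coords[di] - coords[hi]
            v2 = coords[ai] - coords[hi]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if ang >= angle_min:
                out.append(HBond(di, ai, float(dmat[ii, jj]), frame_index, int(hi), ang))
    return out


def _kabsch_rmsd(ref: np.ndarray, mob: np.ndarray) -> float:
    """RMSD after optimal rigid superposition of ``mob`` onto ``ref``."""
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    _, rssd = Rotation.align_vectors(ref_c, mob_c)
    return float(rssd / np.sqrt(ref.shape[0]))


def structure_metrics(
    ensemble: TrajectoryEnsemble,
    superpose: bool = True,
) -> list[StructureMetrics]:
    """Protein RMSD to the first frame and radius of gyration, per replicate.

    RMSD uses optimal least-squares (Kabsch) superposition, so rigid
    rotations/translations of the whole protein score zero; pass
    ``superpose=False`` for raw coordinate deviation.  Rg is the
    root-mean-square atom distance from the centroid (unit masses).
    """
    pmask = ensemble.topology.protein_mask
    out = []
    for rep in ensemble.replicates:
        prot = rep[:, pmask, :]
        ref = prot[0]
        rmsd = np.empty(prot.shape[0])
        rg = np.empty(prot.shape[0])
        for t, fr in enumerate(prot):
            if superpose:
                rmsd[t] = _kabsch_rmsd(ref, fr)
            else:
                rmsd[t] = float(np.sqrt(np.mean(np.sum((fr - ref) ** 2, axis=1))))
            cen = fr - fr.mean(axis=0)
            rg[t] = float(np.sqrt(np.mean(np.sum(cen**2, axis=1))))
        rmsd[0] = 0.0
        out.append(StructureMetrics(rmsd, rg))
    return out


def trp_report(
    table: OccupancyTable,
    top: Topology,
    threshold: float = DEFAULT_OCC_THRESHOLD,
) -> dict:
    """Tryptophan accessibility summary and the predicted Lehrer fraction.

    Under the equal-quantum-yield assumption the fraction of emission
    accessible to the quencher is (# binding Trp)/(# Trp); with the two
    albumin tryptophans and one of them in a binding site this predicts
    fb = 0.5, directly comparable with the fluorescence fit.
    """
    trp = sorted(int(r) for r in np.unique(top.res_id[(top.ligand_copy < 0)
                                                      & (top.res_name == "TRP")]))
    if not trp:
        raise ValueError("topology contains no TRP residues")
    binding = binding_residues(table, threshold)
    binding_trp = sorted(r for r in trp if r in binding)
    occ = table.as_dict()
    return {
        "trp_residues": trp,
        "binding_trp_residues": binding_trp,
        "trp_occupancy": {r: occ.get(r, 0.0) for r in trp},
        "predicted_fb": len(binding_trp) / len(trp),
        "threshold": threshold,
    }
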