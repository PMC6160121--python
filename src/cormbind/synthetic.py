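"""Synthetic data generators with known ground truth.

Every analysis stage in this package can be exercised without external
data: titration curves follow the Lehrer model with multiplicative
detector noise, far-UV CD spectra mix fixed alpha-helix and random-coil
basis shapes, and trajectory ensembles are produced by a seeded
*kinematic* generator — a coarse self-avoiding protein chain surrounded
by ligand copies that jump-diffuse in a shell and dwell at planted
hotspot residues.  The generator is deliberately not physical dynamics;
it reproduces the statistical structure the analyses assume (per-frame
contacts, dwell times, moiety-orientation bias) with ground-truth
expected occupancies that are computable from its parameters.

The coarse ligand is an idealized four-legged piano-stool complex: a
metal center, a five-carbon aromatic ring ("seat"), three carbonyl legs
and one carboxymethyl leg.  Only its contact geometry matters here, so
bond lengths are free parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.transform import Rotation

from .cd import CDSpectrum
from .contacts import Topology, TrajectoryEnsemble
from .quenching import TitrationSeries, lehrer_intensity_ratio

__all__ = [
    "GeneratorConfig",
    "LigandModel",
    "default_ligand",
    "gen_titration",
    "gen_cd_spectrum",
    "gen_protein_model",
    "gen_trajectory_ensemble",
]

AMINO_ACIDS = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TYR VAL"
).split()  # TRP excluded from random draws; placed explicitly


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic study conditions.

    Defaults are desk-scale: 5 replicates x 400 frames x 5 ligand
    copies around a 60-residue chain (the full-scale configuration of
    50 replicates x 25 copies is reachable by overriding).  Hotspots are
    planted at a stationary bound fraction ``hotspot_occupancy`` with
    per-frame dwell continuation ``hotspot_dwell_prob``; when the two are
    equal the bound/free process is independent across frames.  A dwell
    probability of 0 disables planting entirely (a zero-length dwell is
    no binding), leaving hotspots at background level.
    """

    seed: int = 0
    n_replicates: int = 5
    n_frames_per_replicate: int = 400
    n_ligand_copies: int = 5
    n_residues: int = 60
    hotspot_residues: tuple[int, ...] = (5, 14, 30)
    hotspot_dwell_prob: float = 0.4
    hotspot_occupancy: float = 0.4
    noise_sd_rel: float = 0.02
    temperatures_c: tuple[float, ...] = (25.0, 37.0)
    face_weights: dict = field(
        default_factory=lambda: {"ring": 0.45, "carbonyl": 0.45, "carboxyl": 0.10}
    )

    def __post_init__(self):
        for name in ("n_replicates", "n_frames_per_replicate",
                     "n_ligand_copies", "n_residues"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("hotspot_dwell_prob", "hotspot_occupancy", "noise_sd_rel"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.hotspot_occupancy >= 1.0:
            raise ValueError("hotspot_occupancy must be < 1")
        if len(self.hotspot_residues) > self.n_ligand_copies:
            raise ValueError("need at least one ligand copy per hotspot")
        w = self.face_weights
        if set(w) != {"ring", "carbonyl", "carboxyl"} or abs(sum(w.values()) - 1) > 1e-9:
            raise ValueError("face_weights must cover ring/carbonyl/carboxyl and sum to 1")


@dataclass(frozen=True)
class LigandModel:
    """Coarse piano-stool ligand: atom annotations + local geometry (nm)."""

    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    moieties: tuple[str, ...]
    local_coords: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "local_coords",
                           np.asarray(self.local_coords, dtype=float))
        n = len(self.atom_names)
        if not (len(self.elements) == len(self.moieties) == n
                and self.local_coords.shape == (n, 3)):
            raise ValueError("inconsistent ligand atom table")
        ring_c = sum(1 for e, m in zip(self.elements, self.moieties)
                     if m == "ring" and e == "C")
        if ring_c != 5:
            raise ValueError("ligand must have exactly 5 ring carbons")
        co_c = sum(1 for e, m in zip(self.elements, self.moieties)
                   if m == "carbonyl" and e == "C")
        co_o = sum(1 for e, m in zip(self.elements, self.moieties)
                   if m == "carbonyl" and e == "O")
        if co_c != 3 or co_o != 3:
            raise ValueError("ligand must have exactly 3 carbonyl C-O pairs")
        cx = [e for e, m in zip(self.elements, self.moieties) if m == "carboxyl"]
        if cx.count("C") < 2 or cx.count("O") < 2:
            raise ValueError("carboxyl moiety must contain CH2 + COOH heavy atoms")
        if "center" not in self.moieties:
            raise ValueError("metal center must be labelled 'center'")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def face_frames(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-face (unit presentation direction, anchor point) pairs.

        The anchor is the part of the face pressed against the protein:
        the ring centroid, the carbonyl oxygen pointing away from the
        carboxyl leg (so carboxyl stays clear in CO-face binding), and
        the midpoint of the two carboxyl oxygens.
        """
        idx = {m: [i for i, mm in enumerate(self.moieties) if mm == m]
               for m in ("ring", "carbonyl", "carboxyl")}
        ring_anchor = self.local_coords[idx["ring"]].mean(axis=0)
        cx_sel = [i for i in idx["carboxyl"] if self.elements[i] == "O"]
        cx_anchor = self.local_coords[cx_sel].mean(axis=0)
        co_o = [i for i in idx["carbonyl"] if self.elements[i] == "O"]
        cx_dir = cx_anchor / np.linalg.norm(cx_anchor)
        co_pick = min(co_o, key=lambda i: float(np.dot(self.local_coords[i], cx_dir)))
        out = {}
        for m, anchor in (("ring", ring_anchor),
                          ("carbonyl", self.local_coords[co_pick]),
                          ("carboxyl", cx_anchor)):
            out[m] = (anchor / np.linalg.norm(anchor), anchor)
        return out


def default_ligand() -> LigandModel:
    """Idealized four-legged piano-stool geometry.

    The ring sits below the metal (-z), the three carbonyls and the
    carboxymethyl leg splay upward (+z) at four azimuths.
    """
    names, elements, moieties, coords = ["MO"], ["Mo"], ["center"], [[0.0, 0.0, 0.0]]
    for k in range(5):  # cyclopentadienyl ring ("seat", below the metal)
        a = 2 * np.pi * k / 5
        names.append(f"C{k + 1}")
        elements.append("C")
        moieties.append("ring")
        coords.append([0.12 * np.cos(a), 0.12 * np.sin(a), -0.26])
    for k, az in enumerate((0.0, 120.0, 240.0)):  # carbonyl legs
        a = np.radians(az)
        names += [f"CC{k + 1}", f"OC{k + 1}"]
        elements += ["C", "O"]
        moieties += ["carbonyl", "carbonyl"]
        coords.append([0.18 * np.cos(a), 0.18 * np.sin(a), 0.12])
        coords.append([0.30 * np.cos(a), 0.30 * np.sin(a), 0.20])
    a = np.radians(60.0)  # carboxymethyl leg: CH2 then COOH, reaching highest
    names += ["CM", "CX", "OX1", "OX2"]
    elements += ["C", "C", "O", "O"]
    moieties += ["carboxyl"] * 4
    coords.append([0.10 * np.cos(a), 0.10 * np.sin(a), 0.20])
    coords.append([0.16 * np.cos(a), 0.16 * np.sin(a), 0.38])
    coords.append([0.24 * np.cos(a - 0.5), 0.24 * np.sin(a - 0.5), 0.48])
    coords.append([0.24 * np.cos(a + 0.5), 0.24 * np.sin(a + 0.5), 0.48])
    return LigandModel(tuple(names), tuple(elements), tuple(moieties), np.array(coords))


def gen_titration(
    ksv_per_um: float,
    fb: float,
    q_grid_um,
    noise_sd_rel: float = 0.0,
    seed: int = 0,
    i0: float = 1000.0,
    temperature_c: float | None = None,
) -> TitrationSeries:
    """Simulate one fluorescence titration under the Lehrer model.

    Intensities are ``i0 * [(1-fb) + fb/(1+Ksv*q)]`` with multiplicative
    Gaussian noise of relative SD ``noise_sd_rel`` on the q > 0 points;
    the q = 0 point defines I0 noiselessly (a leading zero is prepended
    if the grid lacks one).
    """
    if ksv_per_um <= 0:
        raise ValueError("Ksv must be positive")
    if not (0 < fb <= 1):
        raise ValueError("fb must lie in (0, 1]")
    q = np.asarray(q_grid_um, dtype=float)
    if np.any(q < 0) or np.any(np.diff(q) <= 0):
        raise ValueError("q grid must be non-negative and strictly increasing")
    if q.size == 0 or q[0] != 0.0:
        q = np.concatenate(([0.0], q))
    ratio = lehrer_intensity_ratio(ksv_per_um, fb, q)
    intensity = i0 * np.asarray(ratio)
    if noise_sd_rel > 0:
        rng = np.random.default_rng(seed)
        intensity[1:] *= 1.0 + rng.normal(0.0, noise_sd_rel, size=q.size - 1)
        intensity = np.clip(intensity, 1e-9, None)
    return TitrationSeries(
        q_um=q, intensity=intensity, temperature_c=temperature_c,
        meta={"seed": seed, "ksv_true": ksv_per_um, "fb_true": fb,
              "noise_sd_rel": noise_sd_rel},
    )


# ---------------------------------------------------------------------------
# CD spectra

WAVELENGTH_GRID_NM = np.arange(195.0, 260.5, 0.5)


def _gauss(x, mu, sd):
    return np.exp(-0.5 * ((x - mu) / sd) ** 2)


def _helix_mrme(wl: np.ndarray) -> np.ndarray:
    """Alpha-helix basis: positive pi-pi* band near 192 nm, double minimum
    at 208 (pi-pi* parallel) and 222 nm (n-pi*).  deg*cm^2/dmol."""
    return (70000.0 * _gauss(wl, 192.0, 5.5)
            - 32000.0 * _gauss(wl, 208.0, 4.5)
            - 30000.0 * _gauss(wl, 222.0, 4.5))


def _coil_mrme(wl: np.ndarray) -> np.ndarray:
    """Random-coil basis: strong minimum near 197 nm, weak positive 218 nm."""
    return -42000.0 * _gauss(wl, 197.0, 6.0) + 2500.0 * _gauss(wl, 218.0, 8.0)


def gen_cd_spectrum(
    helix_fraction: float,
    conc_m: float = 3e-6,
    n_residues: int = 583,
    path_cm: float = 0.1,
    noise_sd_mdeg: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> CDSpectrum:
    """Synthetic far-UV CD spectrum on the fixed 195-260 nm grid.

    Mixes the helix and coil basis shapes by ``helix_fraction`` in MRME
    units, then converts to raw machine units (mdeg) for the given
    concentration, chain length and path, adding Gaussian noise in mdeg.
    Defaults mirror a serum-albumin measurement (3 uM protein, 583
    residues, 1 mm cell).
    """
    if not (0.0 <= helix_fraction <= 1.0):
        raise ValueError("helix_fraction must lie in [0, 1]")
    wl = WAVELENGTH_GRID_NM.copy()
    mrme = helix_fraction * _helix_mrme(wl) + (1 - helix_fraction) * _coil_mrme(wl)
    theta = mrme * (10.0 * conc_m * n_residues * path_cm)
    if noise_sd_mdeg > 0:
        theta = theta + np.random.default_rng(seed).normal(0, noise_sd_mdeg, wl.size)
    return CDSpectrum(
        wavelength_nm=wl, ellipticity_mdeg=theta, conc_m=conc_m,
        n_residues=n_residues, path_cm=path_cm, label=label,
        meta={"seed": seed, "helix_fraction": helix_fraction,
              "noise_sd_mdeg": noise_sd_mdeg},
    )


# ---------------------------------------------------------------------------
# Coarse protein model

MIN_BEAD_SEPARATION_NM = 0.34
BEAD_STEP_NM = 0.38


def gen_protein_model(
    n_residues: int,
    seed: int = 0,
    trp_positions: tuple[int, ...] | None = None,
    max_restarts: int = 200,
) -> tuple[Topology, np.ndarray]:
    """Compact self-avoiding coarse chain, one bead per residue.

    Beads are placed by a random walk with fixed step, a hard minimum
    separation and a spherical confinement radius that enforces a
    globular shape.  Residue names are drawn at random except at the
    tryptophan positions (default: two TRP at ~23% and ~36% of the
    chain, echoing the albumin Trp pair).  Coordinates are centered at
    the origin; residue ids are 1-based.
    """
    if n_residues < 10:
        raise ValueError("n_residues must be >= 10")
    if trp_positions is None:
        trp_positions = (max(1, round(0.23 * n_residues)),
                         max(2, round(0.36 * n_residues)))
    trp_positions = tuple(sorted(set(int(p) for p in trp_positions)))
    if len(trp_positions) < 2:
        raise ValueError("need at least 2 distinct TRP positions")
    if any(not (1 <= p <= n_residues) for p in trp_positions):
        raise ValueError("TRP positions outside the chain")
    rng = np.random.default_rng(seed)
    r_max = BEAD_STEP_NM * (1.3 * n_residues ** (1 / 3) + 1.0)
    for _ in range(max_restarts):
        pos = [np.zeros(3)]
        ok = True
        for _ in range(n_residues - 1):
            placed = False
            for _ in range(300):
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                cand = pos[-1] + BEAD_STEP_NM * d
                if np.linalg.norm(cand) > r_max:
                    continue
                if len(pos) > 1:
                    dists = np.linalg.norm(np.asarray(pos[:-1]) - cand, axis=1)
                    if dists.min() < MIN_BEAD_SEPARATION_NM:
                        continue
                pos.append(cand)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            coords = np.asarray(pos)
            coords -= coords.mean(axis=0)
            names = rng.choice(AMINO_ACIDS, size=n_residues)
            for p in trp_positions:
                names[p - 1] = "TRP"
            top = Topology(
                atom_name=np.full(n_residues, "CA"),
                element=np.full(n_residues, "C"),
                res_id=np.arange(1, n_residues + 1),
                res_name=names,
                chain_id=np.full(n_residues, "A"),
                ligand_copy=np.full(n_residues, -1),
                moiety=np.full(n_residues, ""),
            )
            return top, coords
    raise RuntimeError(
        f"failed to place a self-avoiding chain of {n_residues} beads "
        f"within {max_restarts} restarts"
    )


# ---------------------------------------------------------------------------
# Trajectory ensemble

PROTEIN_JITTER_SD_NM = 0.01
BOUND_ANCHOR_NM = 0.26          # face-centroid distance from the hotspot bead
FREE_STEP_SD_NM = 0.08


def _random_rotation(rng: np.random.Generator) -> Rotation:
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q))


def _align_to(direction_from: np.ndarray, direction_to: np.ndarray) -> Rotation:
    rot, _ = Rotation.align_vectors(direction_to[None, :], direction_from[None, :])
    return rot


def _clamp_radius(pos: np.ndarray, r_lo: float, r_hi: float) -> np.ndarray:
    r = np.linalg.norm(pos)
    if r < 1e-9:
        return np.array([r_lo, 0.0, 0.0])
    target = min(max(r, r_lo), r_hi)
    return pos * (target / r)


def gen_trajectory_ensemble(
    config: GeneratorConfig,
    protein: tuple[Topology, np.ndarray] | None = None,
    ligand: LigandModel | None = None,
) -> TrajectoryEnsemble:
    """Seeded kinematic trajectory ensemble with planted binding hotspots.

    One ligand copy is dedicated to each hotspot residue and follows a
    two-state (bound/free) Markov chain started from its stationary
    distribution, so the expected occupancy of hotspot residues equals
    ``config.hotspot_occupancy`` from the first frame.  While bound the
    copy is placed with a moiety face toward the hotspot bead (face
    drawn from ``config.face_weights``); while free it parks in an outer
    shell out of contact range.  Remaining copies jump-diffuse in a
    shell around the protein, occasionally grazing the surface, which
    provides unspecific background contacts.  The protein vibrates about
    its reference coordinates with a small isotropic jitter.

    Expected hotspot occupancies are stored in ``ensemble.ground_truth``.
    """
    ligand = ligand or default_ligand()
    if protein is None:
        protein = gen_protein_model(config.n_residues, seed=config.seed)
    prot_top, prot_xyz = protein
    prot_res = set(int(r) for r in prot_top.protein_residues())
    hotspots = tuple(int(h) for h in config.hotspot_residues)
    for h in hotspots:
        if h not in prot_res:
            raise ValueError(f"hotspot residue {h} not present in protein")

    n_copies = config.n_ligand_copies
    n_prot = prot_top.n_atoms
    faces = ligand.face_frames()
    face_names = ("ring", "carbonyl", "carboxyl")
    face_p = np.array([config.face_weights[f] for f in face_names])

    # combined topology: protein chain A + ligand copies chain B
    atom_name = list(prot_top.atom_name)
    element = list(prot_top.element)
    res_id = list(prot_top.res_id)
    res_name = list(prot_top.res_name)
    chain_id = list(prot_top.chain_id)
    lig_copy = list(prot_top.ligand_copy)
    moiety = list(prot_top.moiety)
    for c in range(n_copies):
        atom_name += list(ligand.atom_names)
        element += list(ligand.elements)
        res_id += [c + 1] * ligand.n_atoms
        res_name += ["ALF"] * ligand.n_atoms
        chain_id += ["B"] * ligand.n_atoms
        lig_copy += [c] * ligand.n_atoms
        moiety += list(ligand.moieties)
    top = Topology(np.array(atom_name), np.array(element), np.array(res_id),
                   np.array(res_name), np.array(chain_id), np.array(lig_copy),
                   np.array(moiety))

    r_prot = float(np.linalg.norm(prot_xyz, axis=1).max())
    shell = (r_prot + 0.25, r_prot + 1.2)      # grazing free copies
    park = (r_prot + 0.9, r_prot + 1.4)        # unbound designated copies

    dwell = config.hotspot_dwell_prob
    occ = config.hotspot_occupancy
    plant = dwell > 0.0 and occ > 0.0
    p_on = occ * (1.0 - dwell) / (1.0 - occ) if plant else 0.0
    if p_on > 1.0:
        raise ValueError(
            "hotspot_occupancy unreachable: implied per-frame bind probability "
            f"{p_on:.3f} exceeds 1; raise hotspot_dwell_prob"
        )

    n_designated = len(hotspots) if plant else 0
    hotspot_xyz_index = {h: int(np.nonzero(prot_top.res_id == h)[0][0]) for h in hotspots}
    # local outward normal per hotspot: away from the surrounding surface patch
    hotspot_normal = {}
    for h, bi in hotspot_xyz_index.items():
        near = prot_xyz[np.linalg.norm(prot_xyz - prot_xyz[bi], axis=1) < 1.0]
        n_vec = prot_xyz[bi] - near.mean(axis=0)
        if np.linalg.norm(n_vec) < 1e-6:
            n_vec = prot_xyz[bi]
        hotspot_normal[h] = n_vec / np.linalg.norm(n_vec)

    replicates = []
    for rep in range(config.n_replicates):
        rng = np.random.default_rng([config.seed, rep])
        n_frames = config.n_frames_per_replicate
        coords = np.empty((n_frames, top.n_atoms, 3))
        # initial free positions
        free_pos = []
        for c in range(n_copies):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            lo, hi = park if c < n_designated else shell
            free_pos.append(d * rng.uniform(lo, hi))
        bound = [
            (c < n_designated) and (rng.random() < occ) for c in range(n_copies)
        ]
        for t in range(n_frames):
            frame_prot = prot_xyz + rng.normal(0.0, PROTEIN_JITTER_SD_NM, prot_xyz.shape)
            coords[t, :n_prot] = frame_prot
            for c in range(n_copies):
                designated = c < n_designated
                if designated and t > 0:  # stationary init, then Markov update
                    bound[c] = (rng.random() < dwell) if bound[c] else (rng.random() < p_on)
                if designated and bound[c]:
                    h = hotspots[c]
                    bead = frame_prot[hotspot_xyz_index[h]]
                    n_vec = hotspot_normal[h]
                    face = face_names[rng.choice(3, p=face_p)]
                    d_f, c_f = faces[face]
                    rot = _align_to(d_f, -n_vec)
                    azim = Rotation.from_rotvec(rng.uniform(0, 2 * np.pi) * n_vec)
                    rot = azim * rot
                    d0 = float(np.clip(rng.normal(BOUND_ANCHOR_NM, 0.015), 0.21, 0.31))
                    anchor = bead + d0 * n_vec
                    lig_xyz = anchor + rot.apply(ligand.local_coords - c_f)
                else:
                    lo, hi = park if designated else shell
                    free_pos[c] = _clamp_radius(
                        free_pos[c] + rng.normal(0.0, FREE_STEP_SD_NM, 3), lo, hi)
                    rot = _random_rotation(rng)
                    lig_xyz = free_pos[c] + rot.apply(ligand.local_coords)
                start = n_prot + c * ligand.n_atoms
                coords[t, start:start + ligand.n_atoms] = lig_xyz
        replicates.append(coords)

    ground_truth = {
        "planted_occupancy": {int(h): (occ if plant else 0.0) for h in hotspots},
        "iid_frames": bool(plant and abs(dwell - occ) < 1e-12),
        "seed": config.seed,
        "config": asdict(config),
    }
    return TrajectoryEnsemble(topology=top, replicates=replicates,
                              ground_truth=ground_truth)
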