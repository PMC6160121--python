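"""File formats: titration/CD CSV, multi-model PDB ensembles, residue sets.

Trajectory ensembles are written one multi-model PDB per replicate
(MODEL/ENDMDL records, protein as chain A ATOM records, ligand copies as
chain B HETATM residues with distinct residue numbers) plus a JSON
topology/moiety map and a JSON ground-truth file.  Coordinates are nm in
memory and Angstrom on disk, converted at this boundary.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import biotite.structure as bstruct
import biotite.structure.io.pdb as bpdb
import numpy as np
import pandas as pd

from .cd import CDSpectrum
from .contacts import Topology, TrajectoryEnsemble
from .quenching import TitrationSeries

__all__ = [
    "write_titration_csv", "read_titration_csv",
    "write_cd_csv", "read_cd_csv",
    "write_ensemble", "read_ensemble",
    "read_fasta", "read_residue_set",
    "config_hash", "write_json_report",
]

NM_PER_ANGSTROM = 0.1


# ---------------------------------------------------------------------------
# titrations

def write_titration_csv(series: TitrationSeries, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if series.temperature_c is not None:
            fh.write(f"# temperature_C: {series.temperature_c}\n")
        for k, v in series.meta.items():
            fh.write(f"# {k}: {v}\n")
        cols = {"q_uM": series.q_um, "intensity": series.intensity}
        if series.a_ex is not None:
            cols["A_ex"] = series.a_ex
        if series.a_em is not None:
            cols["A_em"] = series.a_em
        pd.DataFrame(cols).to_csv(fh, index=False)


def read_titration_csv(path, temperature_c: float | None = None) -> TitrationSeries:
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith("#") and ":" in line:
            k, v = line[1:].split(":", 1)
            meta[k.strip()] = v.strip()
    df = pd.read_csv(path, comment="#")
    if "q_uM" not in df or "intensity" not in df:
        raise ValueError(f"{path}: need q_uM and intensity columns")
    if temperature_c is None and "temperature_C" in meta:
        temperature_c = float(meta.pop("temperature_C"))
    return TitrationSeries(
        q_um=df["q_uM"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        temperature_c=temperature_c,
        a_ex=df["A_ex"].to_numpy() if "A_ex" in df else None,
        a_em=df["A_em"].to_numpy() if "A_em" in df else None,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# CD spectra

def write_cd_csv(spec: CDSpectrum, path) -> None:
    with open(Path(path), "w") as fh:
        for k, v in (("conc_M", spec.conc_m), ("n_residues", spec.n_residues),
                     ("path_cm", spec.path_cm), ("label", spec.label)):
            if v not in (None, ""):
                fh.write(f"# {k}: {v}\n")
        pd.DataFrame({"wavelength_nm": spec.wavelength_nm,
                      "ellipticity_mdeg": spec.ellipticity_mdeg}).to_csv(fh, index=False)


def read_cd_csv(path) -> CDSpectrum:
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and ":" in line:
                k, v = line[1:].split(":", 1)
                meta[k.strip()] = v.strip()
    df = pd.read_csv(path, comment="#")
    return CDSpectrum(
        wavelength_nm=df["wavelength_nm"].to_numpy(),
        ellipticity_mdeg=df["ellipticity_mdeg"].to_numpy(),
        conc_m=float(meta["conc_M"]) if "conc_M" in meta else None,
        n_residues=int(meta["n_residues"]) if "n_residues" in meta else None,
        path_cm=float(meta["path_cm"]) if "path_cm" in meta else None,
        label=meta.get("label", path.stem),
    )


# ---------------------------------------------------------------------------
# trajectory ensembles

def _topology_to_atom_array(top: Topology) -> bstruct.AtomArray:
    arr = bstruct.AtomArray(top.n_atoms)
    arr.chain_id = top.chain_id.astype("U4")
    arr.res_id = top.res_id.astype(int)
    arr.res_name = top.res_name.astype("U5")
    arr.atom_name = top.atom_name.astype("U6")
    arr.element = np.char.upper(top.element.astype("U2"))
    arr.hetero = top.ligand_copy >= 0
    return arr


def write_ensemble(ensemble: TrajectoryEnsemble, outdir) -> list[Path]:
    """One multi-model PDB per replicate + topology.json (+ ground truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    top = ensemble.topology
    template = _topology_to_atom_array(top)
    written = []
    for i, rep in enumerate(ensemble.replicates):
        stack = bstruct.AtomArrayStack(rep.shape[0], top.n_atoms)
        for cat in template.get_annotation_categories():
            stack.set_annotation(cat, template.get_annotation(cat))
        stack.coord = rep / NM_PER_ANGSTROM
        pdb = bpdb.PDBFile()
        pdb.set_structure(stack)
        path = outdir / f"replicate_{i:02d}.pdb"
        pdb.write(path)
        written.append(path)
    topo = {
        "atoms": [
            {"atom_name": str(top.atom_name[i]), "element": str(top.element[i]),
             "res_id": int(top.res_id[i]), "res_name": str(top.res_name[i]),
             "chain_id": str(top.chain_id[i]), "ligand_copy": int(top.ligand_copy[i]),
             "moiety": str(top.moiety[i])}
            for i in range(top.n_atoms)
        ]
    }
    with open(outdir / "topology.json", "w") as fh:
        json.dump(topo, fh)
    if ensemble.ground_truth is not None:
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(_jsonable(ensemble.ground_truth), fh, indent=1)
    return written


def read_ensemble(indir) -> TrajectoryEnsemble:
    indir = Path(indir)
    with open(indir / "topology.json") as fh:
        atoms = json.load(fh)["atoms"]
    top = Topology(
        atom_name=np.array([a["atom_name"] for a in atoms]),
        element=np.array([a["element"] for a in atoms]),
        res_id=np.array([a["res_id"] for a in atoms]),
        res_name=np.array([a["res_name"] for a in atoms]),
        chain_id=np.array([a["chain_id"] for a in atoms]),
        ligand_copy=np.array([a["ligand_copy"] for a in atoms]),
        moiety=np.array([a["moiety"] for a in atoms]),
    )
    replicates = []
    for path in sorted(indir.glob("replicate_*.pdb")):
        stack = bpdb.PDBFile.read(path).get_structure(model=None)
        replicates.append(stack.coord * NM_PER_ANGSTROM)
    if not replicates:
        raise FileNotFoundError(f"no replicate_*.pdb files under {indir}")
    gt_path = indir / "ground_truth.json"
    ground_truth = None
    if gt_path.exists():
        with open(gt_path) as fh:
            ground_truth = json.load(fh)
    return TrajectoryEnsemble(topology=top, replicates=replicates,
                              ground_truth=ground_truth)


# ---------------------------------------------------------------------------
# sequences and residue sets

def read_fasta(path) -> dict[str, str]:
    """Minimal FASTA reading via biotite; returns {header: sequence}."""
    import biotite.sequence.io.fasta as bfasta
    f = bfasta.FastaFile.read(str(path))
    return dict(f.items())


def read_residue_set(path) -> set[int]:
    """Residue set from JSON (list of ints) or whitespace-separated text."""
    path = Path(path)
    text = path.read_text().strip()
    if path.suffix == ".json" or text.startswith("["):
        return {int(x) for x in json.loads(text)}
    return {int(tok) for tok in text.split()}


# ---------------------------------------------------------------------------
# provenance helpers

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for provenance."""
    payload = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_json_report(data: dict, path, config: dict | None = None,
                      seed: int | None = None) -> None:
    """JSON report with an embedded provenance block (config hash + seed)."""
    out = dict(_jsonable(data))
    prov = {}
    if config is not None:
        prov["config_hash"] = config_hash(config)
        prov["config"] = _jsonable(config)
    if seed is not None:
        prov["seed"] = int(seed)
    if prov:
        out["_provenance"] = prov
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True)
        fh.write("\n")
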