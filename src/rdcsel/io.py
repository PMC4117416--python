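"""File formats and result serialization.

Structures are exchanged as PDB files (multi-model files carry
conformer pools); experimental couplings as whitespace-delimited text
tables with columns ``residue_id atom1 atom2 value_Hz sigma_Hz`` and
``#`` comments.  Results are written as JSON plus CSV histograms so a
run can be replayed and re-analysed from its output directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBIO, PDBParser
from Bio.PDB.StructureBuilder import StructureBuilder

from .pool import ConformerPool, DomainDefinition
from .rdc import RDCSet
from .structure import Structure

__all__ = [
    "read_structure",
    "read_pool",
    "write_structure",
    "write_pool",
    "read_rdc_table",
    "write_rdc_table",
    "build_amide_hydrogens",
    "loop_residues",
    "write_results",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PDB


def _model_to_structure(model) -> Structure:
    resids, names, resnames, coords = [], [], [], []
    for chain in model:
        for residue in chain:
            het, seq, _ = residue.get_id()
            if het.strip():
                continue  # skip waters/heteroatoms
            for atom in residue:
                resids.append(seq)
                names.append(atom.get_name())
                resnames.append(residue.get_resname())
                coords.append(atom.get_coord())
        break  # single-chain convention
    if not resids:
        raise ValueError("no protein atoms found in model")
    return Structure(
        np.array(resids), np.array(names, dtype=object),
        np.array(coords, dtype=float), np.array(resnames, dtype=object),
    )


def _parse_pdb(path):
    parser = PDBParser(QUIET=True)
    try:
        return parser.get_structure("s", str(path))
    except Exception as err:  # biopython raises assorted types
        raise ValueError(f"cannot parse PDB file {path}: {err}") from err


def read_structure(path) -> Structure:
    """First model of a PDB file as a Structure (coordinates in A,
    author residue numbering preserved)."""
    models = list(_parse_pdb(path))
    if not models:
        raise ValueError(f"no models in {path}")
    return _model_to_structure(models[0])


def read_pool(path, domains: DomainDefinition) -> ConformerPool:
    """All models of a multi-model PDB file as a conformer pool."""
    models = list(_parse_pdb(path))
    if not models:
        raise ValueError(f"no models in {path}")
    conformers = [_model_to_structure(m) for m in models]
    return ConformerPool(conformers, domains, seed_info={"source": str(path)})


def _build_biopdb(structures):
    builder = StructureBuilder()
    builder.init_structure("s")
    for m, s in enumerate(structures):
        builder.init_model(m)
        builder.init_chain("A")
        builder.init_seg("    ")
        current = None
        serial = 1
        for resid, name, xyz, resname in zip(s.resids, s.atom_names, s.coords, s.resnames):
            if resid != current:
                builder.init_residue(str(resname), " ", int(resid), " ")
                current = resid
            element = "H" if str(name).upper().startswith("H") else str(name)[0].upper()
            builder.init_atom(str(name), np.asarray(xyz, dtype=float), 0.0, 1.0,
                              " ", str(name), serial, element=element)
            serial += 1
    return builder.get_structure()


def write_structure(structure: Structure, path) -> None:
    io = PDBIO()
    io.set_structure(_build_biopdb([structure]))
    io.save(str(path))


def write_pool(pool: ConformerPool, path) -> None:
    io = PDBIO()
    io.set_structure(_build_biopdb(pool.conformers))
    io.save(str(path))


# ---------------------------------------------------------------------------
# RDC tables


def read_rdc_table(path, origin: str = "experimental") -> RDCSet:
    """Whitespace-delimited table: residue_id atom1 atom2 value_Hz
    [sigma_Hz]; '#' comments ignored."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.split()
            if len(parts) not in (4, 5):
                raise ValueError(f"{path}:{lineno}: expected 4 or 5 columns, got {len(parts)}")
            try:
                resid = int(parts[0])
                value = float(parts[3])
                sigma = float(parts[4]) if len(parts) == 5 else np.nan
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({err})") from None
            rows.append((resid, parts[1], parts[2], value, sigma))
    if not rows:
        raise ValueError(f"{path}: empty RDC table")
    df = pd.DataFrame(rows, columns=["residue_id", "atom1", "atom2", "value", "sigma"])
    return RDCSet(df, origin=origin)


def write_rdc_table(rdcs: RDCSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("# residue_id atom1 atom2 value_Hz sigma_Hz\n")
        for (resid, a1, a2), v, s in zip(rdcs.keys, rdcs.values, rdcs.sigmas):
            fh.write(f"{resid} {a1} {a2} {v:.6g} {s:.4g}\n")


# ---------------------------------------------------------------------------
# amide hydrogens and loop filtering


def build_amide_hydrogens(structure: Structure, bond_length: float = 1.02) -> Structure:
    """Copy with an amide H added for every residue that has an N but
    no H, placed along the ideal amide geometry: anti to the bisector
    of the N->CA and N->C(i-1) directions.

    X-ray structures commonly lack hydrogens; residues that cannot be
    protonated (no preceding C or CA) are left untouched and logged.
    """
    resids = structure.residue_ids()
    new_resids, new_names, new_coords, new_resnames = (
        list(structure.resids), list(structure.atom_names),
        list(structure.coords), list(structure.resnames),
    )
    skipped = []
    for i, resid in enumerate(resids):
        if structure.has_atom(resid, "H") or not structure.has_atom(resid, "N"):
            continue
        prev = resid - 1
        anchor = None
        for name in ("C", "CA"):
            if prev in resids and structure.has_atom(prev, name):
                anchor = structure.coord(prev, name)
                break
        if anchor is None or not structure.has_atom(resid, "CA"):
            skipped.append(int(resid))
            continue
        n = structure.coord(resid, "N")
        u1 = structure.coord(resid, "CA") - n
        u2 = anchor - n
        u1 /= np.linalg.norm(u1)
        u2 /= np.linalg.norm(u2)
        h_dir = -(u1 + u2)
        norm = np.linalg.norm(h_dir)
        if norm < 1e-6:
            skipped.append(int(resid))
            continue
        idx = structure.atom_index(resid, "N") + 1
        new_resids.insert(idx, resid)
        new_names.insert(idx, "H")
        new_coords.insert(idx, n + bond_length * h_dir / norm)
        new_resnames.insert(idx, structure.resnames[structure.atom_index(resid, "N")])
        structure = Structure(
            np.array(new_resids), np.array(new_names, dtype=object),
            np.array(new_coords, dtype=float), np.array(new_resnames, dtype=object),
        )
        new_resids, new_names, new_coords, new_resnames = (
            list(structure.resids), list(structure.atom_names),
            list(structure.coords), list(structure.resnames),
        )
    if skipped:
        log.warning("could not build amide H for residues %s", skipped)
    return structure


def loop_residues(structure: Structure, window_tol: float = 40.0) -> list[int]:
    """Residues in irregular (loop-like) backbone geometry, assigned
    from C-alpha virtual dihedrals.

    A residue is "structured" when its virtual dihedral (CA i-1..i+2)
    agrees with either helix-like (~50 deg) or extended (~|180| deg)
    geometry within the tolerance; everything else, plus the chain
    termini, is a loop.  This is a deliberately simple stand-in for a
    secondary-structure assignment; explicit include/exclude lists
    override it downstream.
    """
    resids = structure.residue_ids()
    ca = structure.ca_coords(resids)
    loops = {int(resids[0]), int(resids[-1])}
    for i in range(1, len(resids) - 2):
        b1, b2, b3 = ca[i] - ca[i - 1], ca[i + 1] - ca[i], ca[i + 2] - ca[i + 1]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        denom = np.linalg.norm(n1) * np.linalg.norm(n2)
        if denom < 1e-9:
            loops.add(int(resids[i]))
            continue
        cosd = np.clip(np.dot(n1, n2) / denom, -1.0, 1.0)
        dihedral = np.degrees(np.arccos(cosd))
        helix_like = abs(dihedral - 50.0) <= window_tol
        extended = dihedral >= 180.0 - window_tol
        if not (helix_like or extended):
            loops.add(int(resids[i]))
    loops.add(int(resids[-2]))
    return sorted(loops)


def filter_rdc_keys(structure: Structure, keys, exclude_loops: bool = True,
                    include=None, exclude=None):
    """Apply the structured-region filter and explicit overrides to a
    key list.  ``include``/``exclude`` are residue-id collections that
    override the geometric loop assignment."""
    keys = list(keys)
    banned = set(exclude or ())
    forced = set(include or ())
    if exclude_loops:
        banned |= set(loop_residues(structure)) - forced
    return [k for k in keys if k[0] not in banned]


# ---------------------------------------------------------------------------
# results


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        return super().default(obj)


def write_results(outdir, result, pool: ConformerPool, basins=None,
                  bin_width: float = 2.0, config=None) -> Path:
    """Serialize a GAResult: result.json (members, scores, seeds,
    resolved config), dist.csv (angle histogram), populations.json."""
    from .analysis import basin_populations, build_distribution

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    payload = {
        "ensemble_size": result.n,
        "rng_seed": result.rng_seed,
        "config": dataclasses.asdict(config) if config is not None else None,
        "solutions": [
            {
                "members": ens.member_indices,
                "angles": pool.angles[ens.member_indices],
                "scale": ens.scale,
                "q_work": ens.q_work,
                "q_free": ens.q_free,
            }
            for ens in result.best
        ],
    }
    with open(outdir / "result.json", "w") as fh:
        json.dump(payload, fh, cls=_NumpyEncoder, indent=1)

    dist = build_distribution(result, pool, bin_width)
    ca = 0.5 * (dist.edges_ampbd[:-1] + dist.edges_ampbd[1:])
    cl = 0.5 * (dist.edges_lid[:-1] + dist.edges_lid[1:])
    ia, il = np.nonzero(dist.weights)
    pd.DataFrame(
        {"theta_ampbd_bin": ca[ia], "theta_lid_bin": cl[il],
         "weight": dist.weights[ia, il]}
    ).to_csv(outdir / "dist.csv", index=False)

    if basins is not None:
        with open(outdir / "populations.json", "w") as fh:
            json.dump(basin_populations(dist, basins), fh, cls=_NumpyEncoder, indent=1)
    log.info("results written to %s", outdir)
    return outdir
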