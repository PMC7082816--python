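"""File I/O: legacy-ASCII VTK meshes/states, YAML case configs, result JSON.

Meshes are written as VTK unstructured grids (hex8 cells) with cell-data
arrays ``sector``, ``fiber`` and the local frame vectors; facet sets and the
structured-grid metadata ride along as FIELD arrays so a written mesh can be
read back losslessly for mechanics.
"""

from __future__ import annotations

import json

import numpy as np
import yaml

from .case import Case
from .geometry import HexMesh, IdealizedGeometry, MeshDensity
from .materials import ActiveLaw, GlobalParameters, ScoreMap17
from .mechanics import PressureSet, SimulationState

__all__ = [
    "write_vtk_mesh",
    "read_vtk_mesh",
    "write_state_vtk",
    "load_case_config",
    "result_to_json",
]

_FACET_KEYS = ("endo", "epi", "base", "septal_epi")


def write_vtk_mesh(mesh: HexMesh, path, point_data=None, cell_data=None) -> None:
    """Legacy-ASCII VTK unstructured grid with hex8 cells.

    ``point_data`` / ``cell_data`` are optional name -> array mappings added
    on top of the standard sector/fiber/frame arrays.
    """
    pd_ = dict(point_data or {})
    cd = dict(cell_data or {})
    if mesh.element_sector is not None:
        cd.setdefault("sector", mesh.element_sector)
    for name, arr in (
        ("fiber", mesh.fiber_vector),
        ("frame_c", mesh.element_frame_c),
        ("frame_l", mesh.element_frame_l),
        ("frame_r", mesh.element_frame_r),
    ):
        if arr is not None:
            cd.setdefault(name, arr)

    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nlvmech mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.12g")
        ne = mesh.n_elements
        fh.write(f"CELLS {ne} {9 * ne}\n")
        cells = np.hstack([np.full((ne, 1), 8), mesh.elements])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {ne}\n")
        np.savetxt(fh, np.full(ne, 12), fmt="%d")

        # facet sets + structured metadata as FIELD arrays
        fields: list[tuple[str, np.ndarray]] = []
        for k in _FACET_KEYS:
            if k in mesh.facet_sets:
                fields.append((f"facets_{k}", mesh.facet_sets[k]))
        if mesh.element_layer is not None:
            fields.append(("element_layer", mesh.element_layer.reshape(-1, 1)))
        if mesh.is_cap is not None:
            fields.append(("is_cap", mesh.is_cap.astype(int).reshape(-1, 1)))
        fields.append(("n_transmural", np.array([[mesh.n_transmural]])))
        ea, eb = mesh.extra.get("fiber_angles", (60.0, -60.0))
        fields.append(("fiber_angles", np.array([[ea, eb]])))
        fh.write(f"FIELD meta {len(fields)}\n")
        for name, arr in fields:
            arr = np.asarray(arr)
            dtype = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
            fh.write(f"{name} {arr.shape[1]} {arr.shape[0]} {dtype}\n")
            np.savetxt(fh, arr, fmt="%d" if dtype == "int" else "%.12g")

        if pd_:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in pd_.items():
                _write_data_array(fh, name, np.asarray(arr))
        if cd:
            fh.write(f"CELL_DATA {ne}\n")
            for name, arr in cd.items():
                _write_data_array(fh, name, np.asarray(arr))


def _write_data_array(fh, name: str, arr: np.ndarray) -> None:
    if arr.ndim == 1:
        dtype = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
        fh.write(f"SCALARS {name} {dtype} 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, arr, fmt="%d" if dtype == "int" else "%.12g")
    elif arr.shape[1] == 3:
        fh.write(f"VECTORS {name} double\n")
        np.savetxt(fh, arr, fmt="%.12g")
    else:
        raise ValueError(f"unsupported data array shape {arr.shape} for {name}")


def read_vtk_mesh(path) -> HexMesh:
    """Read a mesh written by :func:`write_vtk_mesh` (lossless round trip)."""
    with open(path) as fh:
        tokens = fh.read().split("\n")
    i = 0

    def seek(prefix: str) -> list[str]:
        nonlocal i
        while i < len(tokens):
            line = tokens[i].strip()
            i += 1
            if line.upper().startswith(prefix):
                return line.split()
        raise ValueError(f"missing {prefix} section")

    def read_rows(n: int, dtype=float) -> np.ndarray:
        nonlocal i
        rows = []
        while len(rows) < n:
            line = tokens[i].strip()
            i += 1
            if line:
                rows.append([dtype(v) for v in line.split()])
        return np.array(rows, dtype=dtype)

    hdr = seek("POINTS")
    nodes = read_rows(int(hdr[1]))
    hdr = seek("CELLS")
    cells = read_rows(int(hdr[1]), int)
    elements = cells[:, 1:]
    seek("CELL_TYPES")
    read_rows(len(elements), int)

    facet_sets: dict[str, np.ndarray] = {}
    layer = is_cap = None
    n_trans = 0
    fiber_angles = (60.0, -60.0)
    def next_line() -> list[str]:
        nonlocal i
        while i < len(tokens):
            line = tokens[i].strip()
            i += 1
            if line:
                return line.split()
        raise ValueError("unexpected end of file")

    hdr = seek("FIELD")
    for _ in range(int(hdr[2])):
        name_line = next_line()
        name, ncomp, ntup, dtype = (
            name_line[0], int(name_line[1]), int(name_line[2]), name_line[3]
        )
        arr = read_rows(ntup, int if dtype == "int" else float)
        if name.startswith("facets_"):
            facet_sets[name[len("facets_"):]] = arr.astype(int)
        elif name == "element_layer":
            layer = arr.ravel().astype(int)
        elif name == "is_cap":
            is_cap = arr.ravel().astype(bool)
        elif name == "n_transmural":
            n_trans = int(arr[0, 0])
        elif name == "fiber_angles":
            fiber_angles = (float(arr[0, 0]), float(arr[0, 1]))

    mesh = HexMesh(
        nodes=nodes,
        elements=elements,
        facet_sets=facet_sets,
        element_sector=np.zeros(len(elements), dtype=int),
        element_layer=layer,
        n_transmural=n_trans,
        is_cap=is_cap,
    )
    mesh.extra["fiber_angles"] = fiber_angles

    # optional CELL_DATA arrays
    while i < len(tokens):
        line = tokens[i].strip()
        i += 1
        if line.upper().startswith("CELL_DATA"):
            break
    while i < len(tokens):
        line = tokens[i].strip()
        if not line:
            i += 1
            continue
        parts = line.split()
        if parts[0] == "SCALARS":
            i += 2  # skip header + lookup table
            arr = read_rows(len(elements), int if parts[2] == "int" else float)
            if parts[1] == "sector":
                mesh.element_sector = arr.ravel().astype(int)
        elif parts[0] == "VECTORS":
            i += 1
            arr = read_rows(len(elements))
            if parts[1] == "fiber":
                mesh.fiber_vector = arr
            elif parts[1] == "frame_c":
                mesh.element_frame_c = arr
            elif parts[1] == "frame_l":
                mesh.element_frame_l = arr
            elif parts[1] == "frame_r":
                mesh.element_frame_r = arr
        else:
            i += 1
    return mesh


def write_state_vtk(mesh: HexMesh, state: SimulationState, path,
                    cell_strains: np.ndarray | None = None) -> None:
    """Write a converged state: displacements as point data (plus optional
    per-element strain tensors flattened to cell data)."""
    cd = {}
    if cell_strains is not None:
        cd["E_diag"] = cell_strains
    write_vtk_mesh(
        mesh, path,
        point_data={"displacement": state.displacement.reshape(-1, 3)},
        cell_data=cd,
    )


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def load_case_config(path):
    """Build a :class:`~lvmech.synthetic.SyntheticCase` from a YAML config.

    Recognized sections: ``subject`` (fixture id), ``geometry``, ``density``,
    ``pressures``, ``scores`` (inline lge/sp lists), ``materials``
    (kappa/active constants), ``truth``, ``noise``, ``optimization``.
    Inline sections override fixture values.
    """
    from .synthetic import SyntheticCase, load_fixture

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}

    pressures = scores = None
    if "subject" in cfg:
        pressures, scores, _ = load_fixture(cfg["subject"])
    if "pressures" in cfg:
        pressures = PressureSet(**cfg["pressures"])
    if "scores" in cfg:
        scores = ScoreMap17(np.asarray(cfg["scores"]["lge"]),
                            np.asarray(cfg["scores"]["sp"]))
    if pressures is None or scores is None:
        raise ValueError("config needs 'subject' or explicit pressures+scores")

    geometry = IdealizedGeometry(**cfg.get("geometry", {}))
    density = MeshDensity(**cfg.get("density", {}))
    mat = cfg.get("materials", {})
    active = ActiveLaw(**mat.get("active", {}))
    truth_cfg = cfg.get("truth", {"C_H": 0.2, "Tmax_H": 350.0, "alpha": 0.0})
    truth = GlobalParameters(
        truth_cfg["C_H"], truth_cfg["Tmax_H"], truth_cfg["alpha"],
        cfg.get("optimization", {}).get("W_vol", 10.0),
    )
    noise = cfg.get("noise", {})
    case = SyntheticCase(
        geometry=geometry,
        density=density,
        pressures=pressures,
        scores=scores,
        active=active,
        kappa=mat.get("kappa", 1.0e3),
        W_vol=cfg.get("optimization", {}).get("W_vol", 10.0),
        truth=truth,
        sigma_strain=noise.get("sigma_strain", 0.0),
        seed=noise.get("seed", 0),
    )
    return case, cfg


def result_to_json(result, path, history_csv=None) -> None:
    """Serialize an OptimizationResult (parameters, fit, diagnostics)."""
    payload = {
        "C_H_kPa": result.C_H,
        "Tmax_H_kPa": result.Tmax_H,
        "alpha": result.alpha,
        "alpha_frozen": result.alpha_frozen,
        "objective": result.objective_value,
        "n_evaluations": result.n_evaluations,
        "termination": result.termination,
        "EDV_ml": result.fitted.edv,
        "ESV_ml": result.fitted.esv,
        "fitted_strains": result.fitted.df.to_dict(orient="list"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    if history_csv is not None:
        result.history.to_csv(history_csv, index=False)
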