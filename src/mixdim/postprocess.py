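"""Derived quantities and simulation output.

Compartment averages use the consistent (weighted, for axisymmetric runs)
mass matrix: avg = (1^T M u) / measure.  Totals convert volume
concentrations to molecules with the fixed Avogadro factor and integrate
surface densities directly; for axisymmetric meshes all integrals carry
the 2*pi r weighting.

Output files are text only: legacy-VTK field snapshots, a CSV time-series
table printed with 17 significant digits (bit-identical across repeat runs
of the same configuration), and a JSON run manifest with the
configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import math
import os

import numpy as np

from .errors import MixdimError
from .mesh import write_vtk
from .model import Model, to_config
from .stepping import BlockSystem, SolutionSeries
from .units import MOLECULES_PER_UM3

__all__ = ["compartment_average", "total_amount", "time_series_table",
           "write_outputs", "config_hash"]


def _axifactor(model: Model) -> float:
    return 2.0 * math.pi if model.axisymmetric else 1.0


def compartment_average(system: BlockSystem, state: np.ndarray,
                        species: str) -> float:
    """(1^T M u) / measure over the species' compartment."""
    model = system.model
    comp = model.species[species].compartment
    w = system.ops.lumped[comp]          # row sums of the consistent mass
    sl = system.dofmap.of(model, species)
    measure = float(w.sum())
    if measure <= 0:
        raise MixdimError(f"compartment {comp!r} has zero measure")
    return float(w @ state[sl] / measure)


def total_amount(system: BlockSystem, state: np.ndarray,
                 species_names) -> float:
    """Total molecules summed over species spanning compartments."""
    model = system.model
    axi = _axifactor(model)
    total = 0.0
    for name in species_names:
        comp = model.compartments[model.species[name].compartment]
        w = system.ops.lumped[comp.name]
        sl = system.dofmap.of(model, name)
        integral = float(w @ state[sl]) * axi
        if comp.kind == "volume":
            total += integral * MOLECULES_PER_UM3   # uM * um^3 -> molecules
        else:
            total += integral                       # molecule/um^2 * um^2
    return total


def time_series_table(series: SolutionSeries, system: BlockSystem):
    """DataFrame of averages (native units) and totals (molecules)."""
    import pandas as pd

    model = system.model
    rows = []
    for t, state in zip(series.times, series.states):
        row = {"time": t}
        for name in model.species:
            row[f"avg_{name}"] = compartment_average(system, state, name)
            row[f"total_{name}"] = total_amount(system, state, [name])
        for sc_name, val in series.scalars.items():
            row[f"scalar_{sc_name}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def config_hash(model: Model) -> str:
    doc = to_config(model.containers)
    doc["_extras"] = model.config_extras
    doc["_axisymmetric"] = model.axisymmetric
    blob = json.dumps(doc, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _fmt(x: float) -> str:
    return f"{x:.17g}"


def write_outputs(series: SolutionSeries, system: BlockSystem,
                  directory: str) -> dict:
    """Write VTK snapshots, the CSV time series and the run manifest.

    Returns the manifest dict.  Species fields are written as parent-mesh
    point data (zero outside their compartment).
    """
    model = system.model
    try:
        os.makedirs(directory, exist_ok=True)
    except OSError as exc:
        raise MixdimError(f"cannot create output directory "
                          f"{directory}: {exc}") from None
    mesh = model.mesh
    for k, (t, state) in enumerate(zip(series.times, series.states)):
        point_data = {}
        for name in model.species:
            comp = model.species[name].compartment
            sub = model.submeshes[comp]
            field = np.zeros(mesh.num_vertices)
            vals = state[system.dofmap.of(model, name)]
            # tiny negative values are clamped to zero at output only; the
            # in-state solution is never modified
            clamp = system.settings.negativity_tol * system.scales[name]
            vals = np.where((vals < 0) & (vals > -clamp), 0.0, vals)
            field[sub.vertex_parent] = vals
            point_data[name] = field
        write_vtk(mesh, os.path.join(directory, f"fields_{k:04d}.vtk"),
                  point_data=point_data)
    table = time_series_table(series, system)
    csv_path = os.path.join(directory, "timeseries.csv")
    with open(csv_path, "w") as fh:
        fh.write(",".join(table.columns) + "\n")
        for _, row in table.iterrows():
            fh.write(",".join(_fmt(v) for v in row.to_numpy()) + "\n")
    import scipy
    from . import __version__
    manifest = {
        "config_hash": config_hash(model),
        "solver_settings": {k: (v if np.isfinite(v) else "inf")
                            if isinstance(v, float) else v
                            for k, v in vars(system.settings).items()},
        "outputs": len(series.times),
        "steps": len(series.step_log),
        "versions": {"mixdim": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__},
    }
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(directory, "steps.jsonl"), "w") as fh:
        for entry in series.step_log:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
    return manifest
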