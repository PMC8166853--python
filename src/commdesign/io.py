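"""File formats and configuration: Newick/table registries, parameter and
ensemble serialization, tidy trajectory/prediction CSVs, and run configs.

All tabular output is comma-separated UTF-8 with one header row; every file
written here carries a leading ``#`` comment line recording the tool
version, a config hash, and the seed, and every reader skips such lines.
Missing values are empty cells.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .glv import GLVParameters, SpeciesRegistry, Trajectory
from .inference import ParameterEnsemble
from .production import ProductionModel

__all__ = [
    "read_registry",
    "write_registry",
    "read_params_csv",
    "write_params_csv",
    "params_to_json",
    "params_from_json",
    "write_ensemble",
    "read_ensemble",
    "write_production_model",
    "read_production_model",
    "write_trajectory",
    "read_table",
    "write_table",
    "load_run_config",
    "config_hash",
]


def config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header_comment(seed=None, extra=None) -> str:
    parts = [f"commdesign v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if extra:
        parts.append(f"config={config_hash(extra)}")
    return "# " + " ".join(parts)


def write_table(df: pd.DataFrame, path, seed=None, extra=None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_header_comment(seed, extra) + "\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# -- registry ----------------------------------------------------------------

def read_registry(path, butyrate_producers=None) -> SpeciesRegistry:
    """Load a species registry from a Newick tree (leaf order defines the
    phylogenetic order) or a CSV table with columns ``species_id`` and
    ``butyrate_producer`` (0/1), ordered phylogenetically."""
    path = Path(path)
    if path.suffix.lower() in {".nwk", ".newick", ".tre", ".tree"}:
        try:
            tree = dendropy.Tree.get(path=str(path), schema="newick")
        except Exception as exc:
            raise ValueError(f"invalid or duplicate-leaf Newick registry: {exc}") from exc
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(leaves)) != len(leaves):
            raise ValueError("duplicate leaf labels in tree")
        if butyrate_producers is None:
            raise ValueError("butyrate_producers must be given with a Newick registry")
        return SpeciesRegistry(
            tuple(sorted(leaves)), frozenset(butyrate_producers), tuple(leaves)
        )
    df = read_table(path)
    ids = tuple(df["species_id"].astype(str))
    bp = frozenset(df.loc[df["butyrate_producer"].astype(int) == 1, "species_id"].astype(str))
    return SpeciesRegistry(tuple(sorted(ids)), bp, ids)


def write_registry(registry: SpeciesRegistry, path, seed=None) -> None:
    df = pd.DataFrame(
        {
            "species_id": list(registry.phylo_order),
            "butyrate_producer": [
                int(s in registry.butyrate_producers) for s in registry.phylo_order
            ],
        }
    )
    write_table(df, path, seed=seed)


# -- gLV parameters ----------------------------------------------------------

def write_params_csv(
    params: GLVParameters, registry: SpeciesRegistry, path, seed=None
) -> None:
    """Matrix layout: one row per species; column ``r`` then ``a_<id>``
    interaction columns in registry order."""
    df = pd.DataFrame(params.a, columns=[f"a_{s}" for s in registry.species_ids])
    df.insert(0, "r", params.r)
    df.insert(0, "species_id", list(registry.species_ids))
    write_table(df, path, seed=seed)


def read_params_csv(path, registry: SpeciesRegistry) -> GLVParameters:
    df = read_table(path).set_index("species_id").loc[list(registry.species_ids)]
    r = df["r"].to_numpy()
    a = df[[f"a_{s}" for s in registry.species_ids]].to_numpy()
    return GLVParameters(r, a)


def params_to_json(params: GLVParameters, registry: SpeciesRegistry) -> str:
    return json.dumps(
        {
            "species_ids": list(registry.species_ids),
            "r": params.r.tolist(),
            "a": params.a.tolist(),
        }
    )


def params_from_json(text: str) -> tuple[GLVParameters, list[str]]:
    obj = json.loads(text)
    return GLVParameters(np.array(obj["r"]), np.array(obj["a"])), obj["species_ids"]


# -- ensembles ---------------------------------------------------------------

def write_ensemble(
    ens: ParameterEnsemble, registry: SpeciesRegistry, directory, seed=None
) -> None:
    """A directory of per-member parameter CSVs plus a manifest JSON with
    provenance (config, seed, member count)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, m in enumerate(ens.members):
        write_params_csv(m, registry, directory / f"member_{i:04d}.csv", seed=seed)
    manifest = {
        "n_members": len(ens),
        "species_ids": list(registry.species_ids),
        "provenance": ens.provenance,
        "version": __version__,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def read_ensemble(directory, registry: SpeciesRegistry) -> ParameterEnsemble:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    members = tuple(
        read_params_csv(directory / f"member_{i:04d}.csv", registry)
        for i in range(manifest["n_members"])
    )
    return ParameterEnsemble(members, manifest.get("provenance", {}))


# -- production model --------------------------------------------------------

def write_production_model(model: ProductionModel, path) -> None:
    obj = {
        "species_ids": list(model.registry.species_ids),
        "butyrate_producers": sorted(model.registry.butyrate_producers),
        "phylo_order": list(model.registry.phylo_order),
        "alpha0": model.alpha0,
        "alpha1": model.alpha1,
        "beta0": {f"{j}|{k}": v for (j, k), v in model.beta0.items()},
        "beta1": {f"{j}|{k}": v for (j, k), v in model.beta1.items()},
        "l1_coeff": model.l1_coeff,
        "cv_report": model.cv_report,
        "version": __version__,
    }
    Path(path).write_text(json.dumps(obj, indent=2))


def read_production_model(path) -> ProductionModel:
    obj = json.loads(Path(path).read_text())
    registry = SpeciesRegistry(
        tuple(obj["species_ids"]),
        frozenset(obj["butyrate_producers"]),
        tuple(obj["phylo_order"]),
    )
    unkey = lambda d: {tuple(k.split("|")): v for k, v in d.items()}
    return ProductionModel(
        registry,
        dict(obj["alpha0"]),
        dict(obj["alpha1"]),
        unkey(obj["beta0"]),
        unkey(obj["beta1"]),
        obj.get("l1_coeff", 0.0),
        obj.get("cv_report", {}),
    )


# -- trajectories ------------------------------------------------------------

def write_trajectory(
    traj: Trajectory, registry: SpeciesRegistry, path, seed=None
) -> None:
    """Tidy CSV: time, species, abundance."""
    rows = []
    for ti, t in enumerate(traj.t):
        for si, s in enumerate(registry.species_ids):
            rows.append({"time_h": float(t), "species": s, "abundance": traj.X[ti, si]})
    write_table(pd.DataFrame(rows), path, seed=seed)


# -- run configuration -------------------------------------------------------

def load_run_config(path) -> dict:
    """YAML run configuration; referenced input paths must exist."""
    cfg = yaml.safe_load(Path(path).read_text())
    for key in ("registry", "mono_timeseries", "endpoint_table"):
        if key in cfg and cfg[key] is not None and not Path(cfg[key]).exists():
            raise FileNotFoundError(f"run config references missing {key}: {cfg[key]}")
    return cfg
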