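"""Configuration loading, output writers and the file-emitting run drivers.

Formats: YAML for configuration, TSV for time series and cohort tables,
JSON for hierarchies and provenance, Newick for tree topologies.  All
writers are deterministic: rerunning with the same configuration and master
seed produces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .cohort import simulate_cohort, sweep
from .engine import PatientConfig, PatientResult
from .hierarchy import CloneNode, CohortResult, HierarchyTree, cohort_summary
from .model import HealthyParams
from .stochastic import ExtinctionModel, MutationConfig

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "write_hierarchy",
    "read_hierarchy_json",
    "write_patient",
    "run_cohort",
    "run_sweep",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1"

_EXPERIMENTS = ("cohort", "sweep_nu", "sweep_sigma", "cooperativity", "transplant")


@dataclass(frozen=True)
class RunConfig:
    """Top-level run description: patient defaults plus experiment driver."""

    patient: PatientConfig = field(default_factory=PatientConfig)
    n_patients: int = 100
    master_seed: int = 0
    experiment: str = "cohort"
    sweep_values: tuple[float, ...] = ()
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.experiment not in _EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; choose from {_EXPERIMENTS}"
            )
        if self.experiment.startswith("sweep") and len(self.sweep_values) == 0:
            raise ValueError("sweep experiments need a non-empty sweep grid")


_PATIENT_SECTIONS = {
    "healthy": HealthyParams,
    "mutation": MutationConfig,
    "extinction": ExtinctionModel,
}


def _build_dataclass(cls, payload: dict, context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown keys in {context}: {sorted(unknown)}")
    kwargs = dict(payload)
    for key in ("sigma_schedule", "snapshot_fractions", "sweep_values"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a RunConfig from YAML; unspecified fields take the defaults.

    The file is a nested mapping mirroring the dataclass structure::

        patient:
          healthy: {a_max: 0.87, p: 0.45, d: 2.3, k: 1.85e-9}
          mutation: {nu: 5.0e-9, sigma_schedule: 0.005}
          founder_sigma: 0.005
        n_patients: 100
        master_seed: 1

    Unknown keys and out-of-range values raise a validation error naming the
    offending fields.
    """
    payload: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"config root must be a mapping, got {type(loaded)}")
            payload = loaded
    if overrides:
        payload = _deep_merge(payload, overrides)

    patient_payload = dict(payload.pop("patient", {}) or {})
    sections = {}
    for name, cls in _PATIENT_SECTIONS.items():
        if name in patient_payload:
            sections[name] = _build_dataclass(
                cls, patient_payload.pop(name) or {}, f"patient.{name}"
            )
    patient = _build_dataclass(PatientConfig, patient_payload, "patient")
    if sections:
        patient = replace(patient, **sections)
    run = _build_dataclass(RunConfig, payload, "run")
    return replace(run, patient=patient)


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def config_to_dict(run: RunConfig) -> dict:
    d = dataclasses.asdict(run)
    # tuples to lists for YAML friendliness
    return json.loads(json.dumps(d))


def save_config(run: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(run), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# hierarchy writers
# ---------------------------------------------------------------------------


def _node_label(node: CloneNode) -> str:
    return f"F{node.id}" if node.parent is None else f"C{node.id}"


def hierarchy_to_newick(tree: HierarchyTree, annotations: bool = True) -> str:
    """Newick string of the full clone genealogy.

    Branch lengths are waiting times between parent and child emergence
    (days); per-node attributes travel in a NHX-style comment block."""
    children: dict[int, list[int]] = {}
    for n in tree.nodes.values():
        if n.parent is not None:
            children.setdefault(n.parent, []).append(n.id)

    def fmt(cid: int) -> str:
        node = tree.nodes[cid]
        subs = [fmt(c) for c in sorted(children.get(cid, []))]
        core = "(" + ",".join(subs) + ")" if subs else ""
        parent_birth = (
            tree.nodes[node.parent].birth_time if node.parent is not None else 0.0
        )
        length = node.birth_time - parent_birth
        label = f"{core}{_node_label(node)}:{length:.6f}"
        if annotations:
            label += (
                f"[&&NHX:a={node.params.a_max:.6g}:p={node.params.p:.6g}"
                f":depth={node.depth}]"
            )
        return label

    if tree.root_id is None:
        raise ValueError("empty tree")
    return fmt(tree.root_id) + ";"


def write_hierarchy(tree: HierarchyTree, basepath: str | Path,
                    formats: Sequence[str] = ("newick", "json")) -> list[Path]:
    """Write a hierarchy as Newick and/or JSON next to ``basepath``."""
    basepath = Path(basepath)
    written = []
    try:
        if "newick" in formats:
            p = basepath.with_suffix(".nwk")
            p.write_text(hierarchy_to_newick(tree) + "\n")
            written.append(p)
        if "json" in formats:
            p = basepath.with_suffix(".json")
            p.write_text(json.dumps(tree.to_dict(), indent=1, sort_keys=True) + "\n")
            written.append(p)
    except OSError as exc:
        raise OSError(f"failed writing hierarchy near {basepath}: {exc}") from exc
    return written


def read_hierarchy_json(path: str | Path) -> HierarchyTree:
    with open(path) as fh:
        return HierarchyTree.from_dict(json.load(fh))


def write_patient(result: PatientResult, directory: str | Path, index: int) -> None:
    """Per-patient outputs: hierarchy (Newick+JSON) and trajectory TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = directory / f"patient_{index:04d}"
    if len(result.hierarchy) > 0:
        write_hierarchy(result.hierarchy, stem)
    if result.trajectory is not None:
        result.trajectory.to_csv(
            stem.with_suffix(".trajectory.tsv"), sep="\t", index=False,
            float_format="%.8g",
        )


# ---------------------------------------------------------------------------
# run drivers (cohort + sweep with files)
# ---------------------------------------------------------------------------


def _provenance(run: RunConfig, seeds: list[int]) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "package_version": _pkg_version,
        "config": config_to_dict(run),
        "patient_seeds": seeds,
    }


def run_cohort(run: RunConfig, out_dir: str | Path | None = None,
               progress: bool = False) -> CohortResult:
    """Simulate a cohort and write all outputs below ``out_dir``.

    Outputs: ``patient_XXXX.{nwk,json,trajectory.tsv}``, ``summary.tsv``,
    ``provenance.json``.  Existing per-patient hierarchy JSONs are taken as
    completed patients (resumable runs) only in the sense that files are
    rewritten deterministically; simulation itself is always performed so
    the in-memory result is complete.
    """
    from .cohort import patient_seeds

    out = Path(out_dir) if out_dir is not None else (
        Path(run.output_dir) if run.output_dir else None
    )
    writer = None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        writer = lambda i, res: write_patient(res, out, i)
    cohort = simulate_cohort(
        run.patient, run.n_patients, run.master_seed,
        progress=progress, on_patient=writer,
    )
    if out is not None:
        df = cohort_summary(cohort)
        with open(out / "summary.tsv", "w") as fh:
            fh.write(f"# hemaclone cohort summary schema v{SCHEMA_VERSION}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.8g")
        prov = _provenance(run, patient_seeds(run.master_seed, run.n_patients))
        (out / "provenance.json").write_text(json.dumps(prov, indent=1, sort_keys=True) + "\n")
    return cohort


def run_sweep(run: RunConfig, parameter: str, out_dir: str | Path | None = None,
              progress: bool = False) -> pd.DataFrame:
    """Sweep ``nu`` or ``sigma`` over ``run.sweep_values``; write summary TSV."""
    table, _ = sweep(
        run.patient, parameter, run.sweep_values, run.n_patients,
        run.master_seed, progress=progress,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / f"sweep_{parameter}.tsv", "w") as fh:
            fh.write(f"# hemaclone sweep summary schema v{SCHEMA_VERSION}\n")
            table.to_csv(fh, sep="\t", index=False, float_format="%.8g")
        prov = _provenance(run, [])
        (out / "provenance.json").write_text(json.dumps(prov, indent=1, sort_keys=True) + "\n")
    return table
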