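"""Configuration loading, validation and report writers.

The run configuration is a JSON document holding either an inline
parameter set (under ``"parameters"``) or a path to one (under
``"parameter_file"``), plus run options.  Validation collects *all*
failures and reports them together with JSON-pointer-style locations.
Results are written as CSV/JSON files with deterministic names; every
output run is accompanied by a manifest recording the seed and a SHA-256
hash of the parameter document for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .costing import PERSPECTIVES, SOCIETAL
from .markov import STATES
from .params import ParameterSet, builtin_parameter_set

__all__ = ["ConfigError", "RunConfig", "load_config", "write_results", "params_hash"]


class ConfigError(ValueError):
    """Raised with every validation failure collected, one per line."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(f"  {e}" for e in errors))


@dataclass(frozen=True)
class RunConfig:
    """Validated run options."""

    perspective: str = SOCIETAL
    scenarios: tuple[str, ...] = ()
    n_iterations: int = 1000
    seed: int = 2020
    output_dir: Path = Path("results")
    verbosity: int = 0
    parameter_file: Path | None = None
    extra: dict = field(default_factory=dict)


def _validate_parameters_dict(d: dict, errors: list[str], where: str = "/parameters") -> None:
    """Structural checks with JSON-pointer locations; detailed numeric
    invariants are enforced by the dataclass constructors afterwards."""
    for key in ("strategies", "utilities", "utilization", "productivity"):
        if key not in d:
            errors.append(f"{where}/{key}: missing required key")
    for name, s in d.get("strategies", {}).items():
        tr = s.get("transitions")
        if tr is None:
            errors.append(f"{where}/strategies/{name}/transitions: missing required key")
            continue
        for phase in ("induction", "maintenance"):
            means = tr.get(phase, {}).get("means")
            if means is None:
                errors.append(
                    f"{where}/strategies/{name}/transitions/{phase}/means: missing required key"
                )
                continue
            for st in STATES:
                row = means.get(st)
                if row is None:
                    errors.append(
                        f"{where}/strategies/{name}/transitions/{phase}/means/{st}: missing row"
                    )
                elif sum(row) <= 0:
                    errors.append(
                        f"{where}/strategies/{name}/transitions/{phase}/means/{st}: "
                        f"row sums to {sum(row)} (must be positive)"
                    )
                elif any(x < 0 for x in row):
                    errors.append(
                        f"{where}/strategies/{name}/transitions/{phase}/means/{st}: "
                        "negative probability"
                    )
    if "utilities" in d and "base" not in d["utilities"]:
        errors.append(f"{where}/utilities/base: missing required utility set")


def load_config(path: str | Path) -> tuple[RunConfig, ParameterSet]:
    """Load and validate a run configuration plus its parameter set.

    Distinguishes parse errors (malformed JSON), schema violations
    (missing keys) and invariant violations (values out of range); the
    latter two are collected exhaustively before raising.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ConfigError([f"/: JSON parse error: {e}"]) from e
    if not isinstance(doc, dict):
        raise ConfigError(["/: configuration must be a JSON object"])

    errors: list[str] = []
    params_dict = None
    param_file = doc.get("parameter_file")
    if "parameters" in doc:
        params_dict = doc["parameters"]
    elif param_file is not None:
        ppath = (path.parent / param_file) if not Path(param_file).is_absolute() else Path(param_file)
        if not ppath.exists():
            raise ConfigError([f"/parameter_file: {ppath} does not exist"])
        try:
            params_dict = json.loads(ppath.read_text())
        except json.JSONDecodeError as e:
            raise ConfigError([f"/parameter_file: JSON parse error: {e}"]) from e

    perspective = doc.get("perspective", SOCIETAL)
    if perspective not in PERSPECTIVES:
        errors.append(f"/perspective: unknown perspective {perspective!r}; expected {PERSPECTIVES}")
    n_iterations = doc.get("n_iterations", 1000)
    if not isinstance(n_iterations, int) or n_iterations < 1:
        errors.append("/n_iterations: must be a positive integer")
    seed = doc.get("seed", 2020)
    if not isinstance(seed, int):
        errors.append("/seed: must be an integer")

    if params_dict is not None:
        _validate_parameters_dict(params_dict, errors)
    if errors:
        raise ConfigError(errors)

    if params_dict is None:
        params = builtin_parameter_set()
    else:
        try:
            params = ParameterSet.from_dict(params_dict)
        except (ValueError, KeyError) as e:
            raise ConfigError([f"/parameters: invariant violation: {e}"]) from e

    config = RunConfig(
        perspective=perspective,
        scenarios=tuple(doc.get("scenarios", ())),
        n_iterations=n_iterations,
        seed=seed,
        output_dir=Path(doc.get("output_dir", "results")),
        verbosity=int(doc.get("verbosity", 0)),
        parameter_file=Path(param_file) if param_file else None,
    )
    return config, params


def params_hash(params: ParameterSet) -> str:
    """SHA-256 of the canonical JSON parameter document."""
    return hashlib.sha256(params.to_json().encode()).hexdigest()


def write_results(
    output_dir: str | Path,
    params: ParameterSet,
    seed: int | None,
    base_case=None,
    psa=None,
    ceac_curve=None,
    ce_planes=(),
    scenario_tables=(),
) -> dict[str, str]:
    """Write result tables to ``output_dir`` and return the file manifest.

    Deterministic file names: ``base_case.csv``, ``psa_summary.csv``,
    ``psa_draws.csv``, ``ceac.csv``, ``ce_plane_<strategy>.csv`` plus
    ``ce_plane_<strategy>_ellipse.json``, ``scenario_<name>.csv``, and
    ``manifest.json`` carrying the seed and parameter-document hash.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def save_csv(df, name):
        p = out / name
        df.to_csv(p, index=False)
        manifest[name] = str(p)

    if base_case is not None:
        save_csv(base_case.summary(), "base_case.csv")
    if psa is not None:
        save_csv(psa.summary(), "psa_summary.csv")
        save_csv(psa.to_frame(), "psa_draws.csv")
    if ceac_curve is not None:
        save_csv(ceac_curve.to_frame(), "ceac.csv")
    for plane in ce_planes:
        save_csv(plane.to_frame(), f"ce_plane_{plane.strategy}.csv")
        if plane.ellipse is not None:
            name = f"ce_plane_{plane.strategy}_ellipse.json"
            (out / name).write_text(json.dumps(plane.ellipse.to_dict(), indent=2) + "\n")
            manifest[name] = str(out / name)
    for table in scenario_tables:
        name = f"scenario_{table['scenario'].iloc[0]}.csv"
        save_csv(table, name)

    meta = {
        "seed": seed,
        "parameter_document_sha256": params_hash(params),
        "files": sorted(manifest),
    }
    (out / "manifest.json").write_text(json.dumps(meta, indent=2) + "\n")
    manifest["manifest.json"] = str(out / "manifest.json")
    return manifest
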