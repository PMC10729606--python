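"""End-to-end pipeline: scenario config → deposition → obstruction → tables.

Every output CSV starts with a ``#``-prefixed header block carrying the
config hash, seed and version so a run can be traced back to its exact
inputs; ``manifest.json`` echoes the full configuration and constants.
On any failure the partially written output directory is cleaned up and the
error names the failing stage.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import config as cfg
from .aerosol import AerosolSpec, GasConditions
from .deposition import DepositionResult, ExposureScenario, VentilationPattern, run_deposition
from .geometry import AirwayTree, builtin_human_tree, read_tree, validate_tree, write_tree
from .obstruction import ObstructionProfile, bin_ratios, compare_profiles, obstruction_ratios
from .synthetic import TreeGenParams, generate_monopodial_tree, scenario_fixtures

__all__ = ["RunConfig", "run_pipeline", "load_scenarios", "PipelineError"]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline invocation."""

    scenario_files: list[str] = field(default_factory=list)
    use_fixtures: bool = False
    geometry: str = "builtin:human"  # builtin:human | <csv path> | generate
    tree_params: TreeGenParams | None = None
    output_dir: str = "results"
    bin_scheme: str | tuple = "human"  # rat | human | custom edges
    seed: int = 0
    n_bins: int = cfg.N_BINS_DEFAULT
    constants_file: str | None = None


def load_scenarios(path: str | Path, tree: AirwayTree) -> list[ExposureScenario]:
    """Read exposure scenarios from a YAML/JSON file.

    The file holds one mapping or a list of mappings with the exposure-table
    fields: ``species``, ``route``, ``tidal_volume_ml``, ``frequency_bpm``,
    ``concentration_mg_m3``, ``mmad_um``, ``gsd``, ``density_g_cm3``,
    ``inhalability``, ``duration_h`` and optional ``label``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if isinstance(raw, dict):
        raw = [raw]
    scenarios = []
    for i, row in enumerate(raw):
        try:
            scenarios.append(
                ExposureScenario(
                    aerosol=AerosolSpec(
                        mmad=float(row["mmad_um"]),
                        gsd=float(row["gsd"]),
                        density=float(row.get("density_g_cm3", 1.0)),
                        concentration=float(row["concentration_mg_m3"]),
                    ),
                    ventilation=VentilationPattern(
                        tidal_volume=float(row["tidal_volume_ml"]),
                        frequency=float(row["frequency_bpm"]),
                        route=str(row.get("route", "nasal")),
                        inspiratory_fraction=float(row.get("inspiratory_fraction", 0.5)),
                        pause_fraction=float(row.get("pause_fraction", 0.0)),
                    ),
                    tree=tree,
                    duration=float(row.get("duration_h", 4.0)),
                    inhalability_on=bool(row.get("inhalability", False)),
                    label=str(row.get("label", f"{path}:{i}")),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise PipelineError(f"scenario file {path}, entry {i}: {exc}") from exc
    return scenarios


def _header(run_cfg: RunConfig, extra: dict[str, Any]) -> str:
    from . import __version__

    lines = [
        f"# lungdosim_version: {__version__}",
        f"# config_hash: {cfg.config_hash(extra)}",
        f"# seed: {run_cfg.seed}",
    ]
    return "\n".join(lines) + "\n"


def _write_csv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.10g")


def _resolve_tree(run_cfg: RunConfig) -> AirwayTree:
    if run_cfg.geometry == "builtin:human":
        return builtin_human_tree()
    if run_cfg.geometry == "generate":
        params = run_cfg.tree_params or TreeGenParams(seed=run_cfg.seed)
        return generate_monopodial_tree(params)
    return read_tree(run_cfg.geometry)


def run_pipeline(run_cfg: RunConfig) -> dict[str, Any]:
    """Run scenarios end to end and write all report tables.

    Returns a dict with the deposition results, binned obstruction profiles
    and the output paths.  Rerunning with the same config and seed produces
    byte-identical CSVs.
    """
    out = Path(run_cfg.output_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run_pipeline_inner(run_cfg, out)
    except Exception:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        else:
            for f in out.glob("*.csv"):
                f.unlink(missing_ok=True)
            (out / "manifest.json").unlink(missing_ok=True)
        raise


def _run_pipeline_inner(run_cfg: RunConfig, out: Path) -> dict[str, Any]:
    try:
        tree = _resolve_tree(run_cfg)
        problems = validate_tree(tree)
        if problems:
            raise ValueError(f"invalid geometry: {problems[:5]}")
    except Exception as exc:
        raise PipelineError(f"geometry stage failed: {exc}") from exc

    try:
        if run_cfg.use_fixtures:
            rat_tree = tree if tree.species == "rat" else None
            scenarios = scenario_fixtures(seed=run_cfg.seed, rat_tree=rat_tree)
        else:
            scenarios = []
            for f in run_cfg.scenario_files:
                scenarios.extend(load_scenarios(f, tree))
        if not scenarios:
            raise ValueError("no scenarios given (use scenario files or fixtures)")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"scenario stage failed: {exc}") from exc

    echo = {
        "scenario_files": list(run_cfg.scenario_files),
        "use_fixtures": run_cfg.use_fixtures,
        "geometry": run_cfg.geometry,
        "bin_scheme": str(run_cfg.bin_scheme),
        "seed": run_cfg.seed,
        "n_bins": run_cfg.n_bins,
        "labels": [s.label for s in scenarios],
    }
    header = _header(run_cfg, echo)

    results: list[DepositionResult] = []
    profiles: list[ObstructionProfile] = []
    per_airway_rows = []
    regional_rows = []
    per_gen_rows = []
    hist_rows = []
    gen_ratio_rows = []
    for scen in scenarios:
        try:
            res = run_deposition(scen, n_bins=run_cfg.n_bins)
        except Exception as exc:
            raise PipelineError(f"deposition stage failed ({scen.label}): {exc}") from exc
        try:
            prof = bin_ratios(
                obstruction_ratios(res, scen.tree, density=scen.aerosol.density),
                run_cfg.bin_scheme,
            )
        except Exception as exc:
            raise PipelineError(f"obstruction stage failed ({scen.label}): {exc}") from exc
        results.append(res)
        profiles.append(prof)

        for aid, frac in res.per_airway_fraction.items():
            a = scen.tree.get(aid)
            per_airway_rows.append(
                {
                    "scenario": scen.label,
                    "airway_id": aid,
                    "generation": a.generation,
                    "region": a.region,
                    "lobe": a.lobe or "",
                    "multiplicity": a.multiplicity,
                    "deposition_fraction": frac,
                    "deposited_mass_ug": res.per_airway_mass[aid],
                    "obstruction_ratio": prof.per_airway_ratio.get(aid, float("nan")),
                }
            )
        for region in ("head", "TB", "PUL"):
            regional_rows.append(
                {
                    "scenario": scen.label,
                    "region": region,
                    "fraction_of_inhaled": res.regional[region],
                }
            )
        regional_rows.append(
            {
                "scenario": scen.label,
                "region": "exhaled",
                "fraction_of_inhaled": res.exhaled_fraction,
            }
        )
        regional_rows.append(
            {
                "scenario": scen.label,
                "region": "inhalable_fraction",
                "fraction_of_inhaled": res.inhalable_fraction,
            }
        )
        for g, frac in res.per_generation.items():
            per_gen_rows.append(
                {"scenario": scen.label, "generation": g, "deposition_fraction": frac}
            )
        edges = prof.bin_edges
        for region in ("TB", "PUL"):
            sub = prof.by_region[region]
            for i, lo in enumerate(edges):
                hi = edges[i + 1] if i + 1 < len(edges) else float("inf")
                hist_rows.append(
                    {
                        "scenario": scen.label,
                        "region": region,
                        "bin_low": lo,
                        "bin_high": hi,
                        "count": sub["counts"][i],
                        "percent": sub["percentages"][i],
                    }
                )
        gdf = prof.by_generation.copy()
        gdf.insert(0, "scenario", scen.label)
        gen_ratio_rows.append(gdf)

    try:
        _write_csv(pd.DataFrame(per_airway_rows), out / "per_airway.csv", header)
        _write_csv(pd.DataFrame(regional_rows), out / "regional.csv", header)
        _write_csv(pd.DataFrame(per_gen_rows), out / "per_generation.csv", header)
        _write_csv(pd.DataFrame(hist_rows), out / "obstruction_histogram.csv", header)
        _write_csv(
            pd.concat(gen_ratio_rows, ignore_index=True),
            out / "per_generation_ratios.csv",
            header,
        )
        comparison = None
        if len(profiles) >= 2:
            comparison = compare_profiles(profiles, [s.label for s in scenarios])
            _write_csv(comparison, out / "comparison.csv", header)
            with open(out / "comparison.txt", "w") as fh:
                fh.write(header)
                fh.write(comparison.to_string(index=False))
                fh.write("\n")
        manifest = {
            "config": echo,
            "constants": cfg.constants_dict(),
            "config_hash": cfg.config_hash(echo),
            "version": __import__("lungdosim").__version__,
            "outputs": sorted(p.name for p in out.glob("*.csv")),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"report stage failed: {exc}") from exc

    return {
        "results": results,
        "profiles": profiles,
        "comparison": comparison,
        "output_dir": out,
    }
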