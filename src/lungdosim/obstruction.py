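"""Airway-obstruction statistic.

The mass deposited in each tracheobronchial or pulmonary airway over the
exposure is assumed to coalesce into a single sphere; the ratio of that
sphere's diameter to the host airway's diameter indicates the potential for
physical obstruction (r ≥ 1: theoretical complete blockage, r > 0.5:
vulnerability to significant obstruction).  Ratios are binned into the
standard interval schemes for each species and summarized per region and
generation.  Extrathoracic (head) deposition is excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deposition import DepositionResult
from .geometry import AirwayTree

__all__ = [
    "ObstructionProfile",
    "BIN_EDGES",
    "coalesced_sphere_diameter",
    "obstruction_ratios",
    "bin_ratios",
    "compare_profiles",
]

#: Ratio-histogram breakpoints (half-open on the right, last bin unbounded).
BIN_EDGES = {
    "rat": (0.0, 0.25, 0.5, 0.75, 1.0),
    "human": (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
}


@dataclass
class ObstructionProfile:
    """Per-airway obstruction ratios with binned and rolled-up summaries."""

    label: str
    per_airway_ratio: dict[str, float]
    multiplicity: dict[str, int]
    region: dict[str, str]
    generation: dict[str, int]
    bin_edges: tuple[float, ...] | None = None
    bin_counts: list[int] | None = None
    bin_percentages: list[float] | None = None
    by_region: dict[str, dict[str, list]] | None = None
    by_generation: pd.DataFrame | None = None

    @property
    def total_airways(self) -> int:
        return sum(self.multiplicity.values())

    def max_ratio(self) -> float:
        return max(self.per_airway_ratio.values())

    def count_above(self, threshold: float) -> int:
        """Number of airways (with multiplicity) whose ratio exceeds threshold."""
        return sum(
            m
            for aid, m in self.multiplicity.items()
            if self.per_airway_ratio[aid] > threshold
        )


def coalesced_sphere_diameter(mass: float, density: float) -> float:
    """Diameter (cm) of the sphere holding ``mass`` µg at ``density`` g/cm³.

    d = (6·V/π)^(1/3) with V = mass/density; zero mass gives zero diameter.
    """
    if density <= 0:
        raise ValueError("density must be > 0")
    if mass < 0:
        raise ValueError("mass must be >= 0")
    volume_cm3 = (mass * 1e-6) / density
    return (6.0 * volume_cm3 / math.pi) ** (1.0 / 3.0)


def obstruction_ratios(
    result: DepositionResult, tree: AirwayTree, density: float = 1.0, label: str = ""
) -> ObstructionProfile:
    """Per-airway obstruction ratios r_j for every TB and pulmonary airway.

    Uses the per-*single*-airway deposited mass, so the ratios are invariant
    to whether a symmetric tree is stored per-generation or expanded.
    """
    ratios: dict[str, float] = {}
    mult: dict[str, int] = {}
    region: dict[str, str] = {}
    generation: dict[str, int] = {}
    for aid, mass in result.per_airway_mass.items():
        try:
            a = tree.get(aid)
        except KeyError as exc:
            raise ValueError(f"airway id {aid!r} not present in tree") from exc
        if a.region not in ("TB", "PUL"):
            continue
        ratios[aid] = coalesced_sphere_diameter(mass, density) / a.diameter
        mult[aid] = a.multiplicity
        region[aid] = a.region
        generation[aid] = a.generation
    if set(ratios) != {a.id for a in tree.airways if a.region in ("TB", "PUL")}:
        raise ValueError("deposition result does not cover the tree's lung airways")
    scenario_label = result.scenario.label if result.scenario is not None else ""
    return ObstructionProfile(
        label=label or scenario_label,
        per_airway_ratio=ratios,
        multiplicity=mult,
        region=region,
        generation=generation,
    )


def _bin_counts(
    values: np.ndarray, weights: np.ndarray, edges: tuple[float, ...]
) -> list[int]:
    """Counts per bin [e0,e1), [e1,e2), ..., [e_last, inf)."""
    counts = []
    for lo, hi in zip(edges, edges[1:] + (math.inf,)):
        mask = (values >= lo) & (values < hi)
        counts.append(int(weights[mask].sum()))
    return counts


def bin_ratios(profile: ObstructionProfile, species_bins: str = "human") -> ObstructionProfile:
    """Complete a profile with histograms, per-region and per-generation rollups.

    ``species_bins`` selects the published interval scheme: quartile bins up
    to 1.0 (plus >1.0) for rats, tenth-width bins up to 0.5 (plus >0.5) for
    humans; a custom tuple of breakpoints is also accepted.
    """
    if isinstance(species_bins, str):
        if species_bins not in BIN_EDGES:
            raise ValueError(f"unknown bin scheme {species_bins!r}")
        edges = BIN_EDGES[species_bins]
    else:
        edges = tuple(float(e) for e in species_bins)
    aids = list(profile.per_airway_ratio)
    vals = np.array([profile.per_airway_ratio[a] for a in aids])
    wts = np.array([profile.multiplicity[a] for a in aids])
    regions = np.array([profile.region[a] for a in aids])

    counts = _bin_counts(vals, wts, edges)
    total = int(wts.sum())
    pct = [100.0 * c / total for c in counts]
    by_region = {}
    for reg in ("TB", "PUL"):
        mask = regions == reg
        c = _bin_counts(vals[mask], wts[mask], edges)
        t = int(wts[mask].sum())
        by_region[reg] = {
            "counts": c,
            "percentages": [100.0 * x / t if t else 0.0 for x in c],
            "total": t,
        }
    gen_rows = []
    for g in sorted(set(profile.generation.values())):
        mask = np.array([profile.generation[a] == g for a in aids])
        gen_rows.append(
            {
                "generation": g,
                "n_airways": int(wts[mask].sum()),
                "max_ratio": float(vals[mask].max()),
                "mean_ratio": float(np.average(vals[mask], weights=wts[mask])),
            }
        )
    return ObstructionProfile(
        label=profile.label,
        per_airway_ratio=profile.per_airway_ratio,
        multiplicity=profile.multiplicity,
        region=profile.region,
        generation=profile.generation,
        bin_edges=edges,
        bin_counts=counts,
        bin_percentages=pct,
        by_region=by_region,
        by_generation=pd.DataFrame(gen_rows),
    )


def compare_profiles(
    profiles: list[ObstructionProfile], labels: list[str] | None = None
) -> pd.DataFrame:
    """Side-by-side bin counts/percentages for ≥2 binned profiles.

    Adds a ``monotone_increasing`` flag per bin: whether the airway count in
    that bin increases strictly across the profile order (e.g. across rising
    exposure concentrations).
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to compare")
    if any(p.bin_edges is None for p in profiles):
        raise ValueError("profiles must be binned first (bin_ratios)")
    edges = profiles[0].bin_edges
    if any(p.bin_edges != edges for p in profiles):
        raise ValueError("profiles have inconsistent bin edges")
    labels = labels or [p.label or f"profile_{i}" for i, p in enumerate(profiles)]
    rows = []
    for region in ("TB", "PUL"):
        for i, (lo, hi) in enumerate(zip(edges, edges[1:] + (math.inf,))):
            row: dict = {"region": region, "bin_low": lo, "bin_high": hi}
            counts = []
            for p, lab in zip(profiles, labels):
                row[f"count[{lab}]"] = p.by_region[region]["counts"][i]
                row[f"percent[{lab}]"] = p.by_region[region]["percentages"][i]
                counts.append(p.by_region[region]["counts"][i])
            row["monotone_increasing"] = all(b > a for a, b in zip(counts, counts[1:]))
            rows.append(row)
    return pd.DataFrame(rows)
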