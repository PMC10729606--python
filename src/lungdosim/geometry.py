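"""Airway-tree data model, validation, the builtin symmetric human tree, and I/O.

Trees come in two representations:

* ``symmetric`` — one :class:`Airway` record per generation with a
  ``multiplicity`` of 2**(generation-1); per-airway quantities always refer
  to a single physical airway.  The 16.7 million airways of the 24-generation
  human model are never materialized.
* ``asymmetric`` — one record per physical airway (multiplicity 1), as
  produced by the monopodial surrogate generator.

Internal length unit is cm throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import config

__all__ = [
    "Airway",
    "AirwayTree",
    "builtin_human_tree",
    "validate_tree",
    "read_tree",
    "write_tree",
    "GEOMETRY_COLUMNS",
]

REGIONS = ("ET", "TB", "PUL")

GEOMETRY_COLUMNS = [
    "id",
    "parent_id",
    "generation",
    "region",
    "length_cm",
    "diameter_cm",
    "branching_angle_deg",
    "gravity_angle_deg",
    "multiplicity",
    "lobe",
    "distal_volume_cm3",
]


@dataclass(frozen=True)
class Airway:
    """One airway segment (or one symmetric-generation record).

    ``branching_angle`` is measured from the parent's axis (0 = straight
    continuation); ``gravity_angle`` from the gravity vector (0 = vertical,
    flow along gravity).  ``distal_volume`` is the volume of the subtended
    subtree including alveoli, used for flow apportionment.
    """

    id: str
    parent_id: str | None
    generation: int
    region: str
    length: float  # cm
    diameter: float  # cm
    branching_angle: float = 0.0  # degrees
    gravity_angle: float = config.DEFAULT_GRAVITY_ANGLE_DEG  # degrees
    multiplicity: int = 1
    lobe: str | None = None
    distal_volume: float = 0.0  # cm³

    @property
    def lumen_volume(self) -> float:
        """Volume of a single airway lumen, cm³."""
        return math.pi / 4.0 * self.diameter**2 * self.length


@dataclass
class AirwayTree:
    """Directed rooted tree of airway segments with morphometry."""

    airways: list[Airway]
    species: str = "human"
    representation: str = "symmetric"
    body_weight: float | None = None  # g
    provenance: str = ""

    def __post_init__(self) -> None:
        self._by_id = {a.id: a for a in self.airways}
        self._children: dict[str, list[Airway]] = {a.id: [] for a in self.airways}
        roots = []
        for a in self.airways:
            if a.parent_id is None:
                roots.append(a)
            elif a.parent_id in self._children:
                self._children[a.parent_id].append(a)
        self._roots = roots

    def __len__(self) -> int:
        return len(self.airways)

    @property
    def root(self) -> Airway:
        if len(self._roots) != 1:
            raise ValueError(f"tree has {len(self._roots)} roots, expected 1")
        return self._roots[0]

    def children(self, airway_id: str) -> list[Airway]:
        return self._children[airway_id]

    def get(self, airway_id: str) -> Airway:
        return self._by_id[airway_id]

    def topological_order(self) -> list[Airway]:
        """Root-to-leaves order (parents before children)."""
        out: list[Airway] = []
        stack = [self.root]
        while stack:
            a = stack.pop()
            out.append(a)
            stack.extend(reversed(self._children[a.id]))
        return out

    @property
    def total_airway_count(self) -> int:
        return sum(a.multiplicity for a in self.airways)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": a.id,
                "parent_id": a.parent_id if a.parent_id is not None else "",
                "generation": a.generation,
                "region": a.region,
                "length_cm": a.length,
                "diameter_cm": a.diameter,
                "branching_angle_deg": a.branching_angle,
                "gravity_angle_deg": a.gravity_angle,
                "multiplicity": a.multiplicity,
                "lobe": a.lobe if a.lobe is not None else "",
                "distal_volume_cm3": a.distal_volume,
            }
            for a in self.airways
        ]
        return pd.DataFrame(rows, columns=GEOMETRY_COLUMNS)


# ---------------------------------------------------------------------------
# Builtin symmetric human geometry
# ---------------------------------------------------------------------------

# Typical-path whole-lung human model after Yeh & Schum (1980): one row per
# generation (trachea = generation 1); columns: length cm, diameter cm,
# branching angle deg, gravity angle deg.  Generations 1-17 are conducting
# (tracheobronchial), 18-24 are alveolated (pulmonary).
_YEH_SCHUM_HUMAN = [
    # L,     d,     theta, phi
    (10.00, 2.010, 0.0, 0.0),  # 1 trachea
    (4.360, 1.560, 33.0, 20.0),  # 2
    (1.780, 1.130, 34.0, 31.0),  # 3
    (0.965, 0.827, 22.0, 43.0),  # 4
    (0.995, 0.651, 20.0, 39.0),  # 5
    (1.010, 0.574, 18.0, 39.0),  # 6
    (0.890, 0.435, 19.0, 40.0),  # 7
    (0.962, 0.373, 22.0, 36.0),  # 8
    (0.867, 0.322, 28.0, 39.0),  # 9
    (0.667, 0.257, 22.0, 45.0),  # 10
    (0.556, 0.198, 33.0, 43.0),  # 11
    (0.446, 0.156, 34.0, 45.0),  # 12
    (0.359, 0.118, 37.0, 45.0),  # 13
    (0.275, 0.092, 39.0, 60.0),  # 14
    (0.212, 0.073, 39.0, 60.0),  # 15
    (0.168, 0.060, 51.0, 60.0),  # 16
    (0.134, 0.054, 45.0, 60.0),  # 17 terminal bronchiole
    (0.120, 0.050, 45.0, 60.0),  # 18
    (0.092, 0.047, 45.0, 60.0),  # 19
    (0.080, 0.045, 45.0, 60.0),  # 20
    (0.070, 0.044, 45.0, 60.0),  # 21
    (0.063, 0.044, 45.0, 60.0),  # 22
    (0.057, 0.043, 45.0, 60.0),  # 23
    (0.053, 0.043, 45.0, 60.0),  # 24 alveolar sac
]

N_TB_GENERATIONS_HUMAN = 17
N_GENERATIONS_HUMAN = 24

#: Total alveolar volume (cm³) at functional residual capacity, distributed
#: over the alveolated generations (18-24) in proportion to their airway
#: counts (alveoli are of roughly uniform size, so their volume tracks the
#: number of ducts/sacs carrying them).
HUMAN_ALVEOLAR_VOLUME_CM3 = 3000.0


def builtin_human_tree() -> AirwayTree:
    """The embedded symmetric (typical-path) 24-generation human tree.

    17 tracheobronchial generations (trachea = generation 1) with 7
    pulmonary generations appended to each terminal bronchiole; dichotomous
    branching, so generation g holds 2**(g-1) identical airways.
    """
    airways: list[Airway] = []
    # alveolar sleeve volume per generation, ∝ airway count for g >= 18
    n_alveolated = sum(
        2 ** (g - 1) for g in range(N_TB_GENERATIONS_HUMAN + 1, N_GENERATIONS_HUMAN + 1)
    )
    sleeve = [
        HUMAN_ALVEOLAR_VOLUME_CM3 * 2 ** (g - 1) / n_alveolated
        if g > N_TB_GENERATIONS_HUMAN
        else 0.0
        for g in range(1, N_GENERATIONS_HUMAN + 1)
    ]
    # distal volumes bottom-up: subtree lumen volume + alveolar sleeves
    distal = [0.0] * (N_GENERATIONS_HUMAN + 1)
    for g in range(N_GENERATIONS_HUMAN, 0, -1):
        length, diam, _, _ = _YEH_SCHUM_HUMAN[g - 1]
        n = 2 ** (g - 1)
        vol = math.pi / 4.0 * diam**2 * length * n + sleeve[g - 1]
        below = distal[g + 1] if g < N_GENERATIONS_HUMAN else 0.0
        distal[g] = vol + below
    for g, (length, diam, theta, phi) in enumerate(_YEH_SCHUM_HUMAN, start=1):
        n = 2 ** (g - 1)
        airways.append(
            Airway(
                id=f"G{g}",
                parent_id=f"G{g - 1}" if g > 1 else None,
                generation=g,
                region="TB" if g <= N_TB_GENERATIONS_HUMAN else "PUL",
                length=length,
                diameter=diam,
                branching_angle=theta,
                gravity_angle=phi,
                multiplicity=n,
                lobe=None,
                distal_volume=distal[g] / n,  # per single airway
            )
        )
    return AirwayTree(
        airways=airways,
        species="human",
        representation="symmetric",
        provenance="builtin symmetric typical-path human model after Yeh & Schum (1980)",
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_tree(tree: AirwayTree) -> list[str]:
    """Check every tree invariant; returns a list of violations (empty = valid)."""
    violations: list[str] = []
    ids = set()
    for a in tree.airways:
        if a.id in ids:
            violations.append(f"duplicate airway id {a.id!r}")
        ids.add(a.id)
    roots = [a for a in tree.airways if a.parent_id is None]
    if len(roots) != 1:
        violations.append(f"expected exactly one root, found {len(roots)}")
    by_id = {a.id: a for a in tree.airways}
    for a in tree.airways:
        if a.parent_id is not None and a.parent_id not in by_id:
            violations.append(f"orphan airway {a.id!r}: parent {a.parent_id!r} missing")
        if a.length <= 0 or a.diameter <= 0:
            violations.append(f"non-positive dimension on airway {a.id!r}")
        if not (0.0 <= a.branching_angle <= 180.0):
            violations.append(f"branching angle out of [0,180] on airway {a.id!r}")
        if not (0.0 <= a.gravity_angle <= 180.0):
            violations.append(f"gravity angle out of [0,180] on airway {a.id!r}")
        if a.multiplicity < 1:
            violations.append(f"multiplicity < 1 on airway {a.id!r}")
        if a.region not in REGIONS:
            violations.append(f"unknown region {a.region!r} on airway {a.id!r}")
        if a.region == "PUL" and a.generation <= 1:
            violations.append(f"pulmonary airway {a.id!r} at generation 1")
        if a.parent_id is not None and a.parent_id in by_id:
            parent = by_id[a.parent_id]
            if a.generation != parent.generation + 1:
                violations.append(
                    f"airway {a.id!r}: generation {a.generation} is not parent's + 1"
                )
    # connectivity / acyclicity: with unique parents, the tree is a forest
    # plus possible cycles; everything reachable from a root is acyclic.
    children: dict[str, list[str]] = {a.id: [] for a in tree.airways}
    for a in tree.airways:
        if a.parent_id is not None and a.parent_id in children:
            children[a.parent_id].append(a.id)
    reached: set[str] = set()
    stack = [a.id for a in roots]
    while stack:
        aid = stack.pop()
        if aid in reached:
            continue
        reached.add(aid)
        stack.extend(children[aid])
    unreached = len(tree.airways) - len(reached)
    if unreached and len(roots) == 1:
        violations.append(
            f"{unreached} airway(s) unreachable from the root (cycle or broken link)"
        )
    if tree.representation == "symmetric":
        for a in tree.airways:
            if a.multiplicity != 2 ** (a.generation - 1):
                violations.append(
                    f"symmetric representation: airway {a.id!r} multiplicity "
                    f"{a.multiplicity} != 2^(g-1)"
                )
    if tree.species not in ("rat", "human"):
        violations.append(f"unknown species {tree.species!r}")
    return sorted(set(violations))


# ---------------------------------------------------------------------------
# Geometry CSV I/O
# ---------------------------------------------------------------------------


def write_tree(tree: AirwayTree, path: str | Path) -> None:
    """Write the documented geometry CSV (one row per airway record)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# species: {tree.species}\n")
        fh.write(f"# representation: {tree.representation}\n")
        if tree.body_weight is not None:
            fh.write(f"# body_weight_g: {tree.body_weight}\n")
        fh.write(f"# provenance: {tree.provenance}\n")
        tree.to_frame().to_csv(fh, index=False, float_format="%.10g")


def read_tree(path: str | Path) -> AirwayTree:
    """Read a geometry CSV back into an :class:`AirwayTree`.

    ``read_tree(write_tree(t))`` is the identity on valid trees.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, dtype={"id": str, "parent_id": str, "lobe": str})
    missing = [c for c in GEOMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"geometry CSV {path} missing columns: {missing}")
    airways: list[Airway] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        rowno = i + 2  # header is row 1
        aid = str(row["id"])
        if aid in seen:
            raise ValueError(f"geometry CSV row {rowno}: duplicate id {aid!r}")
        seen.add(aid)
        parent = row["parent_id"]
        parent = None if (pd.isna(parent) or parent == "") else str(parent)
        lobe = row["lobe"]
        lobe = None if (pd.isna(lobe) or lobe == "") else str(lobe)
        try:
            airways.append(
                Airway(
                    id=aid,
                    parent_id=parent,
                    generation=int(row["generation"]),
                    region=str(row["region"]),
                    length=float(row["length_cm"]),
                    diameter=float(row["diameter_cm"]),
                    branching_angle=float(row["branching_angle_deg"]),
                    gravity_angle=float(row["gravity_angle_deg"]),
                    multiplicity=int(row["multiplicity"]),
                    lobe=lobe,
                    distal_volume=float(row["distal_volume_cm3"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"geometry CSV row {rowno}: {exc}") from exc
    tree = AirwayTree(
        airways=airways,
        species=meta.get("species", "human"),
        representation=meta.get("representation", "asymmetric"),
        body_weight=float(meta["body_weight_g"]) if "body_weight_g" in meta else None,
        provenance=meta.get("provenance", str(path)),
    )
    problems = [v for v in validate_tree(tree) if "cycle" in v or "orphan" in v]
    if problems:
        raise ValueError(f"geometry CSV {path}: {problems}")
    return tree
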