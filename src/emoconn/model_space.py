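"""The staged model space for emotion-modulated connectivity.

Stage 1 compares seven structural candidates for the intrinsic network over
V1, FG, amygdala (AMY) and lateral OFC, all driven by the all-faces input
into V1; the fully interconnected candidate (feedforward and feedback
connections among FG/AMY/OFC plus V1<->FG) is the designated winner. Stage 2
places 21 alternative profiles of emotional modulation on the winner's
connections among FG, AMY and OFC (six directed edges), partitioned into
seven families by shared features:

* Family 1 — the six single-edge models (models 1-6); model 2 modulates the
  forward FG->OFC connection, model 5 the backward OFC->FG connection;
* Families 2-4 — the three single bidirectional pairs (models 7-9);
* Families 5-6 — two-edge non-reciprocal patterns, grouped by whether both
  edges involve the amygdala (models 10-18);
* Family 7 — the three double-bidirectional models (models 19-21); model 21
  modulates OFC<->AMY together with OFC<->FG.

The builders are table-driven: the full enumeration lives in plain dicts
that serialize to YAML, so alternative family tables are a data edit.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .generative_model import DCMSpec, Edge

__all__ = [
    "StructuralModel",
    "ModulatoryModel",
    "build_structural_space",
    "build_modulatory_space",
    "winner_structural_model",
    "to_dcm_spec",
    "model_space_to_yaml",
    "model_space_from_yaml",
    "MODULATORY_EDGES",
]

#: The six directed edges among FG, AMY, OFC eligible for modulation.
MODULATORY_EDGES: tuple[Edge, ...] = (
    ("FG", "AMY"),
    ("FG", "OFC"),
    ("AMY", "OFC"),
    ("AMY", "FG"),
    ("OFC", "FG"),
    ("OFC", "AMY"),
)

_FF = [("V1", "FG"), ("FG", "AMY"), ("AMY", "OFC")]
_FULL = [
    ("V1", "FG"), ("FG", "V1"),
    ("FG", "AMY"), ("AMY", "FG"),
    ("FG", "OFC"), ("OFC", "FG"),
    ("AMY", "OFC"), ("OFC", "AMY"),
]

#: Structural candidates: serial feedforward, feedforward variants with a
#: V1-level skip, recurrent variants, and the fully interconnected winner.
_STRUCTURAL_TABLE: dict[int, list[Edge]] = {
    1: list(_FF),
    2: _FF + [("FG", "OFC")],
    3: _FF + [("OFC", "AMY"), ("AMY", "FG"), ("FG", "V1")],
    4: _FF + [("FG", "OFC"), ("OFC", "AMY"), ("AMY", "FG"), ("FG", "V1")],
    5: [("V1", "FG"), ("FG", "AMY"), ("FG", "OFC"), ("AMY", "OFC"), ("OFC", "AMY")],
    6: [("V1", "FG"), ("FG", "AMY"), ("AMY", "FG"), ("FG", "OFC"), ("OFC", "FG"), ("AMY", "OFC"), ("OFC", "AMY")],
    7: list(_FULL),
}
WINNER_STRUCTURAL_ID = 7

#: Modulatory models: id -> (family id, modulated directed edges).
_MODULATORY_TABLE: dict[int, tuple[int, list[Edge]]] = {
    # Family 1: single directed edges
    1: (1, [("FG", "AMY")]),
    2: (1, [("FG", "OFC")]),
    3: (1, [("AMY", "OFC")]),
    4: (1, [("AMY", "FG")]),
    5: (1, [("OFC", "FG")]),
    6: (1, [("OFC", "AMY")]),
    # Families 2-4: single bidirectional pairs
    7: (2, [("FG", "AMY"), ("AMY", "FG")]),
    8: (3, [("FG", "OFC"), ("OFC", "FG")]),
    9: (4, [("AMY", "OFC"), ("OFC", "AMY")]),
    # Family 5: two-edge non-reciprocal patterns, both edges involving AMY
    10: (5, [("FG", "AMY"), ("AMY", "OFC")]),
    11: (5, [("FG", "AMY"), ("OFC", "AMY")]),
    12: (5, [("AMY", "FG"), ("AMY", "OFC")]),
    13: (5, [("AMY", "FG"), ("OFC", "AMY")]),
    # Family 6: two-edge non-reciprocal patterns, one edge involving AMY
    14: (6, [("FG", "AMY"), ("FG", "OFC")]),
    15: (6, [("FG", "AMY"), ("OFC", "FG")]),
    16: (6, [("AMY", "FG"), ("FG", "OFC")]),
    17: (6, [("AMY", "FG"), ("OFC", "FG")]),
    18: (6, [("AMY", "OFC"), ("FG", "OFC")]),
    # Family 7: double bidirectional pairs
    19: (7, [("FG", "AMY"), ("AMY", "FG"), ("FG", "OFC"), ("OFC", "FG")]),
    20: (7, [("FG", "AMY"), ("AMY", "FG"), ("AMY", "OFC"), ("OFC", "AMY")]),
    21: (7, [("AMY", "OFC"), ("OFC", "AMY"), ("FG", "OFC"), ("OFC", "FG")]),
}


@dataclass(frozen=True)
class StructuralModel:
    """One stage-1 candidate for the intrinsic network."""

    id: int
    intrinsic_edges: frozenset[Edge]
    driving_region: str = "V1"

    def __post_init__(self) -> None:
        if not (1 <= self.id <= 7):
            raise ValueError("structural model id must be in 1..7")
        if self.driving_region != "V1":
            raise ValueError("the all-faces driving input must enter V1")


@dataclass(frozen=True)
class ModulatoryModel:
    """One stage-2 profile of emotional modulation."""

    id: int
    family: int
    modulated_edges: frozenset[Edge]

    def __post_init__(self) -> None:
        if not (1 <= self.id <= 21):
            raise ValueError("modulatory model id must be in 1..21")
        if not (1 <= self.family <= 7):
            raise ValueError("family id must be in 1..7")
        if not self.modulated_edges:
            raise ValueError("modulated edge set must be non-empty")
        bad = set(self.modulated_edges) - set(MODULATORY_EDGES)
        if bad:
            raise ValueError(f"non-modulatory edges {sorted(bad)}")


def build_structural_space() -> list[StructuralModel]:
    """The seven stage-1 structural candidates (distinct edge sets)."""
    models = [
        StructuralModel(id=i, intrinsic_edges=frozenset(edges))
        for i, edges in sorted(_STRUCTURAL_TABLE.items())
    ]
    edge_sets = {m.intrinsic_edges for m in models}
    if len(edge_sets) != len(models):
        raise ValueError("structural candidates must have distinct edge sets")
    return models


def winner_structural_model() -> StructuralModel:
    """The fully interconnected stage-1 winner."""
    return build_structural_space()[WINNER_STRUCTURAL_ID - 1]


def build_modulatory_space(
    table: dict[int, tuple[int, list[Edge]]] | None = None,
) -> list[ModulatoryModel]:
    """The 21 stage-2 modulation profiles with their family partition."""
    table = _MODULATORY_TABLE if table is None else table
    models = [
        ModulatoryModel(id=i, family=fam, modulated_edges=frozenset(edges))
        for i, (fam, edges) in sorted(table.items())
    ]
    _validate_modulatory_space(models)
    return models


def _validate_modulatory_space(models: list[ModulatoryModel]) -> None:
    if len(models) != 21:
        raise ValueError(f"expected 21 modulatory models, got {len(models)}")
    if sorted(m.id for m in models) != list(range(1, 22)):
        raise ValueError("model ids must be exactly 1..21")
    edge_sets = {m.modulated_edges for m in models}
    if len(edge_sets) != 21:
        raise ValueError("modulated edge sets must be pairwise distinct")
    families: dict[int, list[ModulatoryModel]] = {}
    for m in models:
        families.setdefault(m.family, []).append(m)
    if sorted(families) != list(range(1, 8)):
        raise ValueError("families must be exactly 1..7")
    by_id = {m.id: m for m in models}
    if len(families[1]) != 6 or any(len(m.modulated_edges) != 1 for m in families[1]):
        raise ValueError("family 1 must be the six single-edge models")
    if by_id[2].modulated_edges != frozenset({("FG", "OFC")}):
        raise ValueError("model 2 must modulate the single forward FG->OFC edge")
    if by_id[5].modulated_edges != frozenset({("OFC", "FG")}):
        raise ValueError("model 5 must modulate the single backward OFC->FG edge")
    if len(families[7]) != 3:
        raise ValueError("family 7 must contain exactly three models")
    m21 = frozenset({("AMY", "OFC"), ("OFC", "AMY"), ("FG", "OFC"), ("OFC", "FG")})
    if by_id[21].modulated_edges != m21 or by_id[21].family != 7:
        raise ValueError("model 21 must be the OFC<->AMY + OFC<->FG model in family 7")


def family_map(models: list[ModulatoryModel] | None = None) -> dict[int, int]:
    """Model id -> family id."""
    models = build_modulatory_space() if models is None else models
    return {m.id: m.family for m in models}


def to_dcm_spec(
    structural: StructuralModel,
    modulatory: ModulatoryModel | None,
    emotion: str | None = None,
    *,
    extra_modulators: dict[str, frozenset[Edge]] | None = None,
) -> DCMSpec:
    """Combine a structural candidate and a modulation profile into a DCMSpec.

    ``emotion`` names the sole modulatory input (e.g. ``"sad"``); pass
    ``modulatory=None`` for an unmodulated model. ``extra_modulators`` allows
    a multi-emotion generative spec (used by the simulator).
    """
    modulated: dict[str, frozenset[Edge]] = {}
    if modulatory is not None:
        if emotion is None:
            raise ValueError("emotion name required with a modulatory model")
        if not set(modulatory.modulated_edges) <= set(structural.intrinsic_edges):
            raise ValueError(
                f"model {modulatory.id} modulates edges absent from structural "
                f"model {structural.id}"
            )
        modulated[emotion] = modulatory.modulated_edges
    for name, edges in (extra_modulators or {}).items():
        if not set(edges) <= set(structural.intrinsic_edges):
            raise ValueError(f"modulator {name!r} modulates non-structural edges")
        modulated[name] = frozenset(edges)
    return DCMSpec(
        intrinsic_edges=structural.intrinsic_edges,
        modulated_edges=modulated,
        driving_inputs={"faces": frozenset({structural.driving_region})},
    )


# -- YAML round trip --------------------------------------------------------


def model_space_to_yaml(path) -> None:
    """Write the structural and modulatory tables to a YAML file."""
    doc = {
        "structural": [
            {"id": m.id, "edges": [list(e) for e in sorted(m.intrinsic_edges)]}
            for m in build_structural_space()
        ],
        "modulatory": [
            {
                "id": m.id,
                "family": m.family,
                "edges": [list(e) for e in sorted(m.modulated_edges)],
            }
            for m in build_modulatory_space()
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def model_space_from_yaml(path) -> tuple[list[StructuralModel], list[ModulatoryModel]]:
    """Load and validate a model-space YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    structural = [
        StructuralModel(
            id=int(m["id"]),
            intrinsic_edges=frozenset(tuple(e) for e in m["edges"]),
        )
        for m in doc["structural"]
    ]
    table = {
        int(m["id"]): (int(m["family"]), [tuple(e) for e in m["edges"]])
        for m in doc["modulatory"]
    }
    return structural, build_modulatory_space(table)
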