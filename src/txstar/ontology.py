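"""Basic i2b2 ontology (metadata tree) derived from the source structure.

Every concept code observed during the transform gets exactly one leaf whose
``c_basecode`` equals it; tables and columns become folders. Paths are
backslash-delimited with leading and trailing backslash, ``c_hlevel`` is the
segment count minus one, and the concept dimension is a projection of the
leaves. No external terminology mapping is attempted — the tree mirrors the
input structure so every loaded fact is navigable and queryable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

__all__ = [
    "ConceptRecord",
    "OntologyNode",
    "OntologyError",
    "build_ontology",
    "derive_concept_dimension",
]


class OntologyError(ValueError):
    pass


@dataclass(frozen=True)
class ConceptRecord:
    """One observed concept: its structural position and its code.

    ``column`` is ``None`` for EAV-ready tables (the concept value hangs
    directly under the table folder); ``value`` is set for categorical
    columns (one leaf per coded value).
    """

    table: str
    column: Optional[str]
    value: Optional[str]
    code: str

    def path_segments(self, prefix: str) -> tuple[str, ...]:
        segs = [prefix, self.table]
        if self.column is not None:
            segs.append(self.column)
        if self.value is not None:
            segs.append(str(self.value))
        return tuple(segs)


@dataclass(frozen=True)
class OntologyNode:
    c_hlevel: int
    c_fullname: str
    c_name: str
    c_basecode: Optional[str]
    c_visualattributes: str  # FA folder / LA leaf
    c_synonym_cd: str = "N"


def _fullname(segments: Sequence[str]) -> str:
    return "\\" + "\\".join(segments) + "\\"


def build_ontology(concepts: Iterable[ConceptRecord], prefix: str = "SRC") -> list[OntologyNode]:
    """Build the metadata tree for a set of observed concepts.

    Returns nodes sorted by full path; the root folder is always present.
    Duplicate paths with conflicting base codes are an error (impossible
    under the concept-code scheme, asserted defensively).
    """
    leaves: dict[tuple[str, ...], str] = {}
    for rec in concepts:
        segs = rec.path_segments(prefix)
        existing = leaves.get(segs)
        if existing is not None and existing != rec.code:
            raise OntologyError(f"path collision at {_fullname(segs)}: {existing} vs {rec.code}")
        leaves[segs] = rec.code

    folders: set[tuple[str, ...]] = {(prefix,)}
    for segs in leaves:
        for i in range(1, len(segs)):
            folders.add(segs[:i])
    collisions = folders & set(leaves)
    if collisions:
        raise OntologyError(
            f"leaf path also used as folder: {_fullname(sorted(collisions)[0])}"
        )

    nodes = [
        OntologyNode(
            c_hlevel=len(segs) - 1,
            c_fullname=_fullname(segs),
            c_name=segs[-1],
            c_basecode=None,
            c_visualattributes="FA",
        )
        for segs in folders
    ]
    nodes.extend(
        OntologyNode(
            c_hlevel=len(segs) - 1,
            c_fullname=_fullname(segs),
            c_name=segs[-1],
            c_basecode=code,
            c_visualattributes="LA",
        )
        for segs, code in leaves.items()
    )
    return sorted(nodes, key=lambda n: n.c_fullname)


def derive_concept_dimension(nodes: Iterable[OntologyNode]) -> list[tuple[str, str, str]]:
    """Project (concept_path, concept_cd, name_char) rows from the leaves."""
    return [
        (n.c_fullname, n.c_basecode, n.c_name)
        for n in nodes
        if n.c_visualattributes == "LA"
    ]
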