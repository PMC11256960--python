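"""Gene-set collections, cross-modality translation, and pathway masks.

Pathway prior knowledge enters the factor model as a binary marker-by-pathway
membership matrix ``C`` (one per modality).  This module reads gene-set
collections in the GMT dialect used by MSigDB downloads, translates sets from
one marker namespace into another (e.g. gene -> protein) via a user-supplied
mapping table, and assembles the membership matrix aligned to a given marker
universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "PathwayMask",
    "read_gmt",
    "write_gmt",
    "read_mapping",
    "translate_sets",
    "build_mask",
]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of marker identifiers."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if "" in self.members:
            raise ValueError(f"gene set {self.name!r} contains an empty member ID")


@dataclass
class GeneSetCollection:
    """Ordered list of gene sets with unique names."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene-set names: {dup}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (tab-separated: name, description, members...).

    Duplicate members within one line are collapsed; trailing empty fields
    are ignored.  Raises ``ValueError`` for lines with fewer than two fields
    or duplicated set names.
    """
    sets: list[GeneSet] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            # MSigDB exports occasionally pad lines with empty trailing cells.
            while fields and fields[-1] == "":
                fields.pop()
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, description, *members = fields
            sets.append(GeneSet(name, description, frozenset(m for m in members if m)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    """Write a collection in the same GMT dialect ``read_gmt`` accepts."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


def read_mapping(path: str | Path) -> list[tuple[str, str]]:
    """Read a headerless two-column TSV of (source-ID, target-ID) pairs."""
    pairs: list[tuple[str, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, "
                    f"got {len(fields)}"
                )
            pairs.append((fields[0], fields[1]))
    return pairs


def translate_sets(
    collection: GeneSetCollection, mapping: Iterable[tuple[str, str]]
) -> GeneSetCollection:
    """Map every set's members through a (possibly one-to-many) ID mapping.

    Members without any mapping are dropped silently (counted in the log);
    sets that lose all members are kept empty, with a warning, so pathway
    indices stay aligned across modalities.
    """
    lut: dict[str, set[str]] = {}
    for src, tgt in mapping:
        lut.setdefault(src, set()).add(tgt)

    out: list[GeneSet] = []
    n_unmapped = 0
    for s in collection:
        translated: set[str] = set()
        for member in s.members:
            targets = lut.get(member)
            if targets is None:
                n_unmapped += 1
            else:
                translated.update(targets)
        if not translated:
            logger.warning("gene set %r has no translated members", s.name)
        out.append(GeneSet(s.name, s.description, frozenset(translated)))
    if n_unmapped:
        logger.info("translate_sets: %d member IDs had no mapping", n_unmapped)
    return GeneSetCollection(out)


@dataclass
class PathwayMask:
    """Binary markers-by-pathways membership matrix ``C``.

    ``matrix[m, p] == 1`` iff marker ``m`` belongs to pathway ``p``.  Rows of
    all zeros (markers outside every pathway) are allowed: such markers are
    explained purely by observation noise.
    """

    matrix: np.ndarray
    marker_ids: list[str]
    pathway_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("mask matrix must be 2-D")
        if self.matrix.shape != (len(self.marker_ids), len(self.pathway_names)):
            raise ValueError(
                f"mask shape {self.matrix.shape} inconsistent with "
                f"{len(self.marker_ids)} markers x {len(self.pathway_names)} pathways"
            )
        if not np.isin(self.matrix, (0.0, 1.0)).all():
            raise ValueError("mask entries must be 0 or 1")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker_ids must be unique")
        if len(set(self.pathway_names)) != len(self.pathway_names):
            raise ValueError("pathway_names must be unique")

    @property
    def n_markers(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_pathways(self) -> int:
        return self.matrix.shape[1]

    @property
    def sparse(self):
        """CSR view of the membership matrix (cached; masks are ~5% dense)."""
        if not hasattr(self, "_sparse"):
            from scipy import sparse as sp

            object.__setattr__(self, "_sparse", sp.csr_array(self.matrix))
        return self._sparse


def build_mask(collection: GeneSetCollection, marker_ids: Sequence[str]) -> PathwayMask:
    """Build the binary membership matrix for a fixed marker universe.

    Set members absent from ``marker_ids`` are ignored.  Column order follows
    the collection's set order; empty columns are kept (with a warning) so
    that pathway indices stay comparable across modalities.
    """
    marker_ids = list(marker_ids)
    if len(set(marker_ids)) != len(marker_ids):
        raise ValueError("marker_ids must be unique")
    index = {m: i for i, m in enumerate(marker_ids)}
    matrix = np.zeros((len(marker_ids), len(collection)), dtype=float)
    for j, s in enumerate(collection):
        rows = [index[m] for m in s.members if m in index]
        matrix[rows, j] = 1.0
        if not rows:
            logger.warning("pathway %r covers no marker in this universe", s.name)
    return PathwayMask(matrix, marker_ids, collection.names)
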