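"""Domain types shared by every pipeline stage.

The analysis operates on five kinds of objects: a hierarchical brain-atlas
ontology (:class:`AtlasTree`), a per-animal experimental design
(:class:`AnimalDesign`), an animals x regions table of c-Fos+ cell counts
(:class:`CountMatrix`), a behavior table (:class:`BehaviorTable`), and an
origin x target connection-density matrix (:class:`ConnectivityMatrix`).
Readers and writers for the on-disk formats live in :mod:`fosmap.io`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FosmapError",
    "AtlasError",
    "ValidationError",
    "AtlasNode",
    "AtlasTree",
    "AnimalDesign",
    "CountMatrix",
    "BehaviorTable",
    "ConnectivityMatrix",
    "TIMEPOINT_HOURS",
    "validate_design",
]

#: Cohabitation timepoint coding: ordinal level -> hours of cohabitation.
TIMEPOINT_HOURS = {1: 0.0, 2: 2.5, 3: 6.0, 4: 22.0}


class FosmapError(Exception):
    """Base class for all package errors."""


class AtlasError(FosmapError):
    """Structural problem in an atlas ontology (duplicate id, cycle, ...)."""


class ValidationError(FosmapError):
    """A table or design violates one of its invariants."""


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtlasNode:
    node_id: str
    acronym: str
    name: str
    parent_id: str | None
    volume_voxels: int


class AtlasTree:
    """Hierarchical region ontology with ancestor/descendant queries.

    Node ids are strings; exactly one root (``parent_id is None``); parent
    links form a tree. Regions nest: a parent anatomically contains its
    children, which is what makes ancestor/descendant the right notion of
    anatomical overlap for region selection.
    """

    def __init__(self, nodes: Iterable[AtlasNode]):
        self.nodes: dict[str, AtlasNode] = {}
        for node in nodes:
            if node.node_id in self.nodes:
                raise AtlasError(f"duplicate node id {node.node_id!r}")
            self.nodes[node.node_id] = node
        roots = [n.node_id for n in self.nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise AtlasError(f"expected exactly one root, found {len(roots)}: {roots}")
        self.root: str = roots[0]
        self._children: dict[str, list[str]] = {nid: [] for nid in self.nodes}
        for node in self.nodes.values():
            if node.parent_id is not None:
                if node.parent_id not in self.nodes:
                    raise AtlasError(
                        f"node {node.node_id!r} has unknown parent {node.parent_id!r}"
                    )
                self._children[node.parent_id].append(node.node_id)
        # reachability check: every node must hang off the root
        seen = set()
        stack = [self.root]
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise AtlasError(f"cycle detected at node {nid!r}")
            seen.add(nid)
            stack.extend(self._children[nid])
        if seen != set(self.nodes):
            orphan = sorted(set(self.nodes) - seen)[0]
            raise AtlasError(f"node {orphan!r} not reachable from root (cycle?)")

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    def _check(self, node_id: str) -> None:
        if node_id not in self.nodes:
            raise AtlasError(f"unknown node id {node_id!r}")

    def children(self, node_id: str) -> list[str]:
        self._check(node_id)
        return list(self._children[node_id])

    def parent(self, node_id: str) -> str | None:
        self._check(node_id)
        return self.nodes[node_id].parent_id

    def ancestors(self, node_id: str) -> list[str]:
        """Strict ancestors, nearest first, ending at the root."""
        self._check(node_id)
        out = []
        cur = self.nodes[node_id].parent_id
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent_id
        return out

    def descendants(self, node_id: str) -> set[str]:
        """Strict descendants (the whole subtree below ``node_id``)."""
        self._check(node_id)
        out: set[str] = set()
        stack = list(self._children[node_id])
        while stack:
            nid = stack.pop()
            out.add(nid)
            stack.extend(self._children[nid])
        return out

    def is_ancestor(self, a: str, b: str) -> bool:
        """True iff ``a`` is a *strict* ancestor of ``b``."""
        self._check(a)
        self._check(b)
        if a == b:
            return False
        return a in self.ancestors(b)

    def leaves(self) -> list[str]:
        return [nid for nid in self.nodes if not self._children[nid]]

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict | list) -> "AtlasTree":
        if isinstance(data, list):
            if len(data) != 1:
                raise AtlasError(f"expected exactly one root, found {len(data)}")
            data = data[0]
        nodes: list[AtlasNode] = []

        def walk(obj: dict, parent: str | None) -> None:
            if not isinstance(obj, dict) or "id" not in obj:
                raise AtlasError(f"malformed node (missing 'id'): {obj!r}")
            nid = str(obj["id"])
            nodes.append(
                AtlasNode(
                    node_id=nid,
                    acronym=str(obj.get("acronym", nid)),
                    name=str(obj.get("name", nid)),
                    parent_id=parent,
                    volume_voxels=int(obj.get("volume_voxels", 0)),
                )
            )
            for child in obj.get("children", []):
                walk(child, nid)

        walk(data, None)
        return cls(nodes)

    def to_dict(self) -> dict:
        def build(nid: str) -> dict:
            node = self.nodes[nid]
            return {
                "id": node.node_id,
                "acronym": node.acronym,
                "name": node.name,
                "volume_voxels": node.volume_voxels,
                "children": [build(c) for c in self._children[nid]],
            }

        return build(self.root)


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnimalDesign:
    """One study subject.

    sex is F/M; partner is 'mate' (opposite-sex pairing) or 'sibling'
    (same-sex control pairing); timepoint is the ordinal cohabitation level
    1..4 coding 0, 2.5, 6 and 22 hr; block is the testing block 1..6;
    pair_id links the two co-housed members of a pair.
    """

    animal_id: str
    sex: str
    partner: str
    timepoint: int
    block: int
    pair_id: str

    def __post_init__(self):
        if self.sex not in ("F", "M"):
            raise ValidationError(f"{self.animal_id}: sex must be F or M, got {self.sex!r}")
        if self.partner not in ("mate", "sibling"):
            raise ValidationError(
                f"{self.animal_id}: partner must be mate or sibling, got {self.partner!r}"
            )
        if self.timepoint not in (1, 2, 3, 4):
            raise ValidationError(f"{self.animal_id}: timepoint must be 1..4")
        if not 1 <= self.block:
            raise ValidationError(f"{self.animal_id}: block must be >= 1")


def validate_design(rows: list[AnimalDesign]) -> None:
    """Check the pair invariants of a design.

    Every pair_id must map to exactly two animals; mate pairs are one F and
    one M; sibling pairs are same-sex; both members share partner,
    timepoint, and block.
    """
    ids = [r.animal_id for r in rows]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate animal ids")
    by_pair: dict[str, list[AnimalDesign]] = {}
    for r in rows:
        by_pair.setdefault(r.pair_id, []).append(r)
    for pid, members in by_pair.items():
        if len(members) != 2:
            raise ValidationError(f"pair {pid!r} has {len(members)} members, expected 2")
        a, b = members
        if (a.partner, a.timepoint, a.block) != (b.partner, b.timepoint, b.block):
            raise ValidationError(f"pair {pid!r}: members disagree on partner/timepoint/block")
        sexes = {a.sex, b.sex}
        if a.partner == "mate" and sexes != {"F", "M"}:
            raise ValidationError(f"mate pair {pid!r} must contain one F and one M")
        if a.partner == "sibling" and len(sexes) != 1:
            raise ValidationError(f"sibling pair {pid!r} must be same-sex")


def design_frame(rows: list[AnimalDesign]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in rows],
            "sex": [r.sex for r in rows],
            "partner": [r.partner for r in rows],
            "timepoint": [r.timepoint for r in rows],
            "block": [r.block for r in rows],
            "pair_id": [r.pair_id for r in rows],
        }
    ).set_index("animal_id")


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------


class CountMatrix:
    """Animals x ROIs matrix of non-negative integer c-Fos+ cell counts."""

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            raise ValidationError("duplicate animal ids in count matrix")
        if counts.columns.has_duplicates:
            raise ValidationError("duplicate ROI ids in count matrix")
        if counts.isna().any().any():
            cells = [
                (str(i), str(c))
                for i, c in zip(*np.nonzero(counts.isna().to_numpy()))
            ]
            raise ValidationError(f"missing cells in count matrix: {cells[:10]}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("count matrix contains non-numeric values")
        bad = (arr < 0) | (arr != np.floor(arr))
        if bad.any():
            rows, cols = np.nonzero(bad)
            cells = [
                f"({counts.index[i]}, {counts.columns[j]})={arr[i, j]}"
                for i, j in list(zip(rows, cols))[:10]
            ]
            raise ValidationError(
                f"count matrix has negative or non-integer entries: {', '.join(cells)}"
            )
        self.df = counts.astype(np.int64)

    @property
    def animal_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def roi_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def column(self, roi_id: str) -> np.ndarray:
        if roi_id not in self.df.columns:
            raise ValidationError(f"unknown ROI id {roi_id!r}")
        return self.df[roi_id].to_numpy()


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------


@dataclass
class BehaviorTable:
    """Named real-valued behavioral measures per animal.

    ``levels`` flags each measure as 'individual' (scored per animal) or
    'dyad' (scored once per pair, duplicated to both members when expanded
    to animals). Dyad-level measures must be identical within a pair.
    """

    df: pd.DataFrame
    levels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.df.index.has_duplicates:
            raise ValidationError("duplicate unit ids in behavior table")
        for m, lvl in self.levels.items():
            if lvl not in ("individual", "dyad"):
                raise ValidationError(f"measure {m!r}: level must be individual or dyad")
            if m not in self.df.columns:
                raise ValidationError(f"level given for unknown measure {m!r}")
        if "ejaculation" in self.df.columns and (self.df["ejaculation"] < 0).any():
            raise ValidationError("ejaculation counts must be >= 0")

    @property
    def measures(self) -> list[str]:
        return list(self.df.columns)

    def validate_dyad_consistency(self, design: list[AnimalDesign]) -> None:
        pair_of = {r.animal_id: r.pair_id for r in design}
        for m, lvl in self.levels.items():
            if lvl != "dyad":
                continue
            vals: dict[str, float] = {}
            for aid in self.df.index:
                pid = pair_of.get(str(aid))
                if pid is None:
                    continue
                v = self.df.loc[aid, m]
                if pid in vals and not np.isclose(vals[pid], v, equal_nan=True):
                    raise ValidationError(
                        f"dyad measure {m!r} differs within pair {pid!r}"
                    )
                vals[pid] = v


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------


class ConnectivityMatrix:
    """Origin x target normalized connection densities (may be asymmetric).

    The diagonal carries a NaN sentinel: within-region density is excluded
    from every downstream statistic. Off-diagonal entries must be >= 0.
    """

    def __init__(self, density: pd.DataFrame):
        if density.index.has_duplicates or density.columns.has_duplicates:
            raise ValidationError("duplicate ids in connectivity matrix")
        arr = density.to_numpy(dtype=float)
        off = ~np.eye(*arr.shape, dtype=bool) if arr.shape[0] == arr.shape[1] else np.ones_like(arr, dtype=bool)
        if np.isnan(arr[off]).any():
            raise ValidationError("missing off-diagonal entries in connectivity matrix")
        if (arr[off] < 0).any():
            raise ValidationError("connectivity densities must be >= 0")
        self.df = density.astype(float)

    @property
    def origin_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def target_ids(self) -> list[str]:
        return list(self.df.columns)

    def density(self, origin: str, target: str) -> float:
        return float(self.df.loc[origin, target])


def load_atlas(path) -> AtlasTree:
    """Read a nested-JSON ontology (Allen-ontology style) into an AtlasTree."""
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    return AtlasTree.from_dict(data)


def save_atlas(tree: AtlasTree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(tree.to_dict(), fh, indent=1)
        fh.write("\n")
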