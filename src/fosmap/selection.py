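"""Mutually exclusive region selection over the atlas hierarchy.

Screened regions nest (a parent anatomically contains its children), so a
significant parent and child report overlapping signal. The selection
keeps, among each overlapping family, the region with the higher ANOVA F
statistic: repeatedly take the unchosen significant region with the
highest F, add it, and drop its atlas ancestors and descendants from
contention. The chosen set is an antichain of the ontology.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import AtlasError, AtlasTree
from .glm import ScreenResult

__all__ = ["SelectionResult", "select_exclusive_rois"]


@dataclass
class SelectionResult:
    #: chosen ROI ids, ordered by descending F
    chosen_rois: list[str]
    #: (roi_id, reason) with reason "not-significant" or "overlapped-by:<roi>"
    dropped: list[tuple[str, str]]


def select_exclusive_rois(
    screen: list[ScreenResult], tree: AtlasTree, q_threshold: float = 0.1
) -> SelectionResult:
    """Greedy antichain selection of significant regions by F statistic.

    Significance is q < ``q_threshold`` (strict). Ties on F are broken by
    smaller atlas volume (prefer the more localized region), then
    lexicographic id.
    """
    for r in screen:
        if r.roi_id not in tree:
            raise AtlasError(f"screened ROI {r.roi_id!r} not in atlas")
    sig = [r for r in screen if r.q_value < q_threshold]
    nonsig = [(r.roi_id, "not-significant") for r in screen if r.q_value >= q_threshold]
    order = sorted(sig, key=lambda r: (-r.f_stat, tree.nodes[r.roi_id].volume_voxels, r.roi_id))

    chosen: list[str] = []
    overlapped: dict[str, str] = {}
    excluded: set[str] = set()
    for r in order:
        if r.roi_id in excluded:
            continue
        chosen.append(r.roi_id)
        kin = set(tree.ancestors(r.roi_id)) | tree.descendants(r.roi_id)
        for other in kin:
            if other not in excluded:
                excluded.add(other)
                overlapped[other] = r.roi_id
        excluded.add(r.roi_id)
    dropped = nonsig + [
        (r.roi_id, f"overlapped-by:{overlapped[r.roi_id]}")
        for r in sig
        if r.roi_id not in chosen
    ]
    return SelectionResult(chosen_rois=chosen, dropped=dropped)
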