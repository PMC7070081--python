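"""Detection and volume partitioning of microcolony merge events.

When neighboring communities grow into contact, the labeler sees one
connected component where there were several: a merge ("conurbation")
event.  To keep following each parent through the merged mass, the
merged element's voxels are attributed to parents by a contact-plane
rule: each parent-pair contributes the perpendicular bisector plane of
the segment joining their (pre-merge) centroids, which for any number of
parents is exactly a nearest-centroid (Voronoi) partition.  Parent
centroids are frozen at the last frame before the merge so the partition
does not drift with the merged mass.  Voxel conservation is exact: every
merged voxel goes to exactly one parent (plane ties to the lower track
id).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import Element
from .stacks_io import VoxelGeometry
from .tracking import Track


@dataclass
class MergeEvent:
    """One merge: ≥2 parent tracks absorbed into a child track."""

    child_track: int
    parent_tracks: list[int]
    merge_time: float
    merge_frame: int
    # per parent-pair bisector plane: {(id_lo, id_hi): (point_um, normal_um)}
    contact_planes: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict)
    parent_centroids: dict[int, np.ndarray] = field(default_factory=dict)
    # per parent: {track_id: (times, partitioned volumes µm³)}
    partitioned_volumes: dict[int, tuple[list[float], list[float]]] = field(
        default_factory=dict)


def detect_merges(tracks: list[Track], times: list[float]) -> list[MergeEvent]:
    """Collect merge events from linked tracks.

    A merge exists at the first frame where one element overlapped two or
    more previous-frame tracks; linking has already set ``merged_into``
    on the absorbed parents.  The surviving (child) track is itself a
    parent too: it keeps its identity but its pre-merge centroid takes
    part in the partition.
    """
    groups: dict[tuple[int, float], list[int]] = {}
    for tr in tracks:
        if tr.status == "merged":
            groups.setdefault((tr.merged_into, tr.merge_time), []).append(tr.track_id)
    events = []
    by_id = {tr.track_id: tr for tr in tracks}
    for (child_id, t_merge), absorbed in sorted(groups.items()):
        child = by_id[child_id]
        parents = sorted(absorbed + [child_id])
        frame = times.index(t_merge)
        ev = MergeEvent(child_track=child_id, parent_tracks=parents,
                        merge_time=t_merge, merge_frame=frame)
        for pid in parents:
            tr = by_id[pid]
            pre = [i for i, t in enumerate(tr.times) if t < t_merge]
            if not pre:
                raise ValueError(f"parent track {pid} has no pre-merge frame")
            ev.parent_centroids[pid] = np.asarray(tr.elements[pre[-1]].centroid,
                                                  dtype=float)
        for i, p in enumerate(parents):
            for q in parents[i + 1:]:
                cp, cq = ev.parent_centroids[p], ev.parent_centroids[q]
                if np.allclose(cp, cq):
                    raise ValueError(f"coincident parent centroids for {p}, {q}")
                ev.contact_planes[(p, q)] = ((cp + cq) / 2.0, cq - cp)
        events.append(ev)
    return events


def _assign_voxels(element: Element, geometry: VoxelGeometry,
                   parent_ids: list[int],
                   centroids: dict[int, np.ndarray]) -> dict[int, int]:
    """Voxel counts per parent under the nearest-centroid partition.

    Ties (equidistant voxels, i.e. exactly on a bisector plane) go to the
    lower track id — argmin over parents sorted ascending does this.
    """
    zz, yy, xx = element.voxels
    pts = np.column_stack([xx * geometry.dx, yy * geometry.dy, zz * geometry.dz])
    ids = sorted(parent_ids)
    cents = np.stack([centroids[p] for p in ids])          # (P, 3)
    d2 = ((pts[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)                            # first minimum = lower id
    counts = np.bincount(nearest, minlength=len(ids))
    return {p: int(c) for p, c in zip(ids, counts)}


def partition_merged_volume(event: MergeEvent, tracks: list[Track],
                            geometry: VoxelGeometry) -> dict[int, tuple[list[float], list[float]]]:
    """Per-parent V(t) through and after the merge.

    Before ``merge_time`` each parent keeps its own measured volumes;
    from the merge frame on, the child track's merged elements are split
    by the frozen-centroid nearest-centroid rule and each share is
    volume-summed per frame.  The shares sum to the merged element's
    volume exactly at every frame.
    """
    by_id = {tr.track_id: tr for tr in tracks}
    child = by_id[event.child_track]
    series: dict[int, tuple[list[float], list[float]]] = {
        p: ([], []) for p in event.parent_tracks}
    for pid in event.parent_tracks:
        tr = by_id[pid]
        for t, el in zip(tr.times, tr.elements):
            if t < event.merge_time:
                series[pid][0].append(t)
                series[pid][1].append(el.volume)
    for t, el in zip(child.times, child.elements):
        if t < event.merge_time:
            continue
        counts = _assign_voxels(el, geometry, event.parent_tracks,
                                event.parent_centroids)
        for pid, c in counts.items():
            series[pid][0].append(t)
            series[pid][1].append(c * geometry.voxel_volume)
    event.partitioned_volumes = series
    return series


def merge_growth_continuity(event: MergeEvent, tracks: list[Track],
                            geometry: VoxelGeometry, min_frames: int = 3) -> dict:
    """Descriptive growth-rate continuity across a merge boundary.

    For each parent, the dV/dt series of its partitioned trajectory and
    the ratio of mean rate after the merge to mean rate before.  Requires
    ``min_frames`` observed frames on each side; no hypothesis test is
    performed.
    """
    if not event.partitioned_volumes:
        partition_merged_volume(event, tracks, geometry)
    report: dict[int, dict] = {}
    for pid, (times, vols) in event.partitioned_volumes.items():
        times_arr = np.asarray(times, dtype=float)
        before = times_arr < event.merge_time
        if before.sum() < min_frames or (~before).sum() < min_frames:
            continue
        v = np.asarray(vols, dtype=float)
        rate = np.gradient(v, times_arr)
        mean_before = float(rate[before].mean())
        mean_after = float(rate[~before].mean())
        report[pid] = {
            "times": times,
            "rate": rate.tolist(),
            "mean_rate_before": mean_before,
            "mean_rate_after": mean_after,
            "rate_ratio": mean_after / mean_before if mean_before != 0 else np.inf,
        }
    return report
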