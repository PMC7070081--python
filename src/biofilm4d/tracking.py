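"""Linking population units across frames into per-colonizer tracks.

With 20-minute frames and slow surface growth, consecutive masks of the
same colonizer overlap heavily, so linking is by maximal voxel overlap
between consecutive frames (ties broken by nearest centroid, then lower
element id).  Elements with no predecessor start new tracks (late
attachers); an element overlapping two or more live tracks is a merge
candidate, resolved by :mod:`biofilm4d.merging`.

Each colonizer is classified by its volume trajectory: a *dynamic
colonizer* (DC) more than quintuples its initial volume by the 420-min
reference time (strict V(420) > 5·V(0)); otherwise it is a *static
colonizer* (SC).  Tracks that end (detach) before the reference time are
"unfit" for the classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import Element


@dataclass
class Track:
    """One colonizer's element chain across frames."""

    track_id: int
    times: list[float] = field(default_factory=list)          # observed frames
    elements: list[Element] = field(default_factory=list)     # same length
    origin_frame: int = 0
    status: str = "attached"            # attached | detached | merged
    detach_time: float | None = None    # first frame time with no successor
    merged_into: int | None = None      # absorbing track id
    merge_time: float | None = None
    dynamics_class: str | None = None   # SC | DC | unfit

    @property
    def volumes(self) -> np.ndarray:
        return np.array([el.volume for el in self.elements], dtype=float)

    @property
    def last_element(self) -> Element:
        return self.elements[-1]


def _overlap_counts(prev_elements: list[Element], next_elements: list[Element],
                    shape: tuple[int, int, int]) -> dict[tuple[int, int], int]:
    """Voxel-overlap counts between elements of consecutive frames.

    Returns ``{(prev_idx, next_idx): n_shared_voxels}`` using flat voxel
    indices; linear in total foreground size.
    """
    prev_owner = np.full(int(np.prod(shape)), -1, dtype=np.int64)
    for i, el in enumerate(prev_elements):
        flat = np.ravel_multi_index(el.voxels, shape)
        prev_owner[flat] = i
    counts: dict[tuple[int, int], int] = {}
    for j, el in enumerate(next_elements):
        flat = np.ravel_multi_index(el.voxels, shape)
        owners = prev_owner[flat]
        owners = owners[owners >= 0]
        for i, c in zip(*np.unique(owners, return_counts=True)):
            counts[(int(i), j)] = int(c)
    return counts


def link_tracks(per_frame_elements: list[list[Element]], times: list[float],
                shape: tuple[int, int, int], max_gap: int = 0) -> list[Track]:
    """Link per-frame elements into tracks by maximal voxel overlap.

    ``per_frame_elements[k]`` are the elements of frame ``k`` (time
    ``times[k]``); ``shape`` is the common stack extent.  A track
    unmatched for up to ``max_gap`` consecutive frames stays eligible and
    can recapture a reappearing element by overlap with its last mask.

    Each next-frame element extends at most one track (its maximal-overlap
    parent; ties → nearest centroid, then lower parent track id).  When
    one element overlaps several live tracks, the non-winning parents are
    recorded as merge candidates on the returned tracks
    (``status='merged'``, ``merged_into``/``merge_time`` set).
    """
    if len(per_frame_elements) < 2:
        raise ValueError("linking requires at least 2 frames")
    if len(per_frame_elements) != len(times):
        raise ValueError("times and per_frame_elements length mismatch")

    tracks: list[Track] = []
    live: list[tuple[Track, int]] = []   # (track, frames since last seen)
    for el in per_frame_elements[0]:
        tr = Track(track_id=len(tracks), times=[times[0]], elements=[el],
                   origin_frame=0)
        tracks.append(tr)
        live.append((tr, 0))

    for k in range(1, len(per_frame_elements)):
        nxt = per_frame_elements[k]
        prev_els = [tr.last_element for tr, _ in live]
        counts = _overlap_counts(prev_els, nxt, shape)

        # winner per next element: maximal overlap, centroid/track-id tie-break
        claims: dict[int, list[tuple[int, int]]] = {}   # next_idx -> [(ov, live_idx)]
        for (i, j), c in counts.items():
            claims.setdefault(j, []).append((c, i))
        assigned: dict[int, int] = {}                   # live_idx -> next_idx
        parents_of: dict[int, list[int]] = {}           # next_idx -> live idxs
        for j, cand in claims.items():
            best = max(c for c, _ in cand)
            tied = [i for c, i in cand if c == best]
            if len(tied) > 1:
                cxyz = np.array(nxt[j].centroid)
                tied.sort(key=lambda i: (float(np.linalg.norm(
                    np.array(prev_els[i].centroid) - cxyz)), live[i][0].track_id))
            parents_of[j] = sorted(i for _, i in cand)
            winner = tied[0]
            # a track can continue into only one element: largest-overlap child wins
            if winner in assigned:
                j_old = assigned[winner]
                if counts[(winner, j)] > counts[(winner, j_old)]:
                    assigned[winner] = j
            else:
                assigned[winner] = j

        next_live: list[tuple[Track, int]] = []
        extended: set[int] = set()
        child_track_of: dict[int, Track] = {}
        for i, j in assigned.items():
            tr = live[i][0]
            tr.times.append(times[k])
            tr.elements.append(nxt[j])
            extended.add(j)
            child_track_of[j] = tr
            next_live.append((tr, 0))
        # merge candidates: losing parents of a multi-parent element
        for j, parents in parents_of.items():
            if len(parents) < 2:
                continue
            child = child_track_of.get(j)
            if child is None:
                continue
            for i in parents:
                tr = live[i][0]
                if tr is child or i in assigned and assigned[i] == j:
                    continue
                if i not in assigned:       # parent fully absorbed
                    tr.status = "merged"
                    tr.merged_into = child.track_id
                    tr.merge_time = times[k]
        # unmatched tracks: keep within gap, unless merged
        for i, (tr, gap) in enumerate(live):
            if i in assigned or tr.status == "merged":
                continue
            if gap < max_gap:
                next_live.append((tr, gap + 1))
        # unmatched next elements start new tracks (late attachers)
        for j, el in enumerate(nxt):
            if j in extended:
                continue
            tr = Track(track_id=len(tracks), times=[times[k]], elements=[el],
                       origin_frame=k)
            tracks.append(tr)
            next_live.append((tr, 0))
        live = next_live
    return tracks


def detect_detachment(tracks: list[Track], times: list[float],
                      persistence: int = 1) -> list[Track]:
    """Mark tracks that left the surface.

    A track is detached at its first absent frame when the trailing
    absence lasts at least ``persistence`` frames; merged tracks are
    excluded (their mass was absorbed, not shed).  Short trailing gaps
    (< persistence) leave the track attached.
    """
    for tr in tracks:
        if tr.status == "merged":
            continue
        last_seen = times.index(tr.times[-1])
        trailing = len(times) - 1 - last_seen
        if trailing >= persistence:
            tr.status = "detached"
            tr.detach_time = times[last_seen + 1]
    return tracks


def classify_dynamics(track: Track, t_ref: float = 420.0, factor: float = 5.0) -> str:
    """SC/DC phenotype from the volume trajectory.

    DC iff V(t*) > factor · V(first frame), with t* the nearest observed
    frame at or after ``t_ref`` (nearest overall when the track is only
    sampled earlier but still attached at t_ref is impossible — a track
    that ends before t_ref is "unfit").
    """
    times = np.asarray(track.times)
    if track.status in ("detached", "merged") and times[-1] < t_ref:
        track.dynamics_class = "unfit"
        return "unfit"
    if times[-1] < t_ref:
        # attached but acquisition stopped short: use the last frame
        idx = len(times) - 1
    else:
        idx = int(np.argmax(times >= t_ref))
    v0 = track.elements[0].volume
    vt = track.elements[idx].volume
    track.dynamics_class = "DC" if vt > factor * v0 else "SC"
    return track.dynamics_class
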