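"""Per-frame order parameters for binding-and-folding trajectories.

A native contact is counted as formed when its C-alpha distance is within
1.0 A of the native distance; nonspecific intermolecular contacts use a
plain 10 A C-alpha cutoff.  All distances honor the minimum-image
convention, so every observable is invariant under periodic wrapping of the
input coordinates (groups are unwrapped internally about a reference
particle before centroids or superpositions are computed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .topology import GoTopology

CONTACT_TOLERANCE = 1.0     # A, |r - r_native| for a formed native contact
NONSPECIFIC_CUTOFF = 10.0   # A, C-alpha distance for a nonspecific contact


def _min_image(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.rint(d / box)


def _as_frames(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    if coords.ndim != 3:
        raise ValueError("coordinates must be (n, 3) or (frames, n, 3)")
    return coords


def pair_distances(coords, pairs, box: float) -> np.ndarray:
    """Minimum-image distances for index pairs; (frames, n_pairs)."""
    frames = _as_frames(coords)
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    d = frames[:, pairs[:, 0]] - frames[:, pairs[:, 1]]
    return np.linalg.norm(_min_image(d, box), axis=-1)


def contact_formed(r, r_native, tolerance: float = CONTACT_TOLERANCE):
    """A native contact is formed if |r - r_native| <= tolerance."""
    r = np.asarray(r, dtype=float)
    r_native = np.asarray(r_native, dtype=float)
    if np.any(r <= 0) or np.any(r_native <= 0):
        raise ValueError("distances must be positive")
    out = np.abs(r - r_native) <= tolerance
    return out if out.shape else bool(out)


def fraction_native(coords, pairs, r_native, box: float,
                    tolerance: float = CONTACT_TOLERANCE) -> np.ndarray:
    """Fraction of the given native contacts formed, per frame."""
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    if len(pairs) == 0:
        raise ValueError("contact subset is empty")
    r = pair_distances(coords, pairs, box)
    formed = np.abs(r - np.asarray(r_native, dtype=float)[None, :]) <= tolerance
    return formed.mean(axis=1)


def native_contact_count(coords, pairs, r_native, box: float,
                         tolerance: float = CONTACT_TOLERANCE) -> np.ndarray:
    """Number of the given native contacts formed, per frame."""
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    if len(pairs) == 0:
        return np.zeros(_as_frames(coords).shape[0], dtype=np.int64)
    r = pair_distances(coords, pairs, box)
    formed = np.abs(r - np.asarray(r_native, dtype=float)[None, :]) <= tolerance
    return formed.sum(axis=1)


def _cross_pairs(group_a, group_b) -> np.ndarray:
    a = np.asarray(group_a, dtype=np.int64)
    b = np.asarray(group_b, dtype=np.int64)
    return np.stack(np.meshgrid(a, b, indexing="ij"), axis=-1).reshape(-1, 2)


def nonspecific_contacts(coords, group_a, group_b, box: float,
                         cutoff: float = NONSPECIFIC_CUTOFF,
                         exclude_pairs=None) -> np.ndarray:
    """Count of inter-group C-alpha pairs within the cutoff, per frame.

    ``exclude_pairs`` (e.g., the native intermolecular contacts) removes
    those pairs from the count, which makes the collision-complex state
    ("at least one nonspecific but no specific contact") disjoint from the
    specific-contact coordinate.
    """
    pairs = _cross_pairs(group_a, group_b)
    if exclude_pairs is not None and len(exclude_pairs) > 0:
        excl = {(min(i, j), max(i, j))
                for i, j in np.asarray(exclude_pairs).reshape(-1, 2)}
        keep = [k for k, (i, j) in enumerate(pairs)
                if (min(i, j), max(i, j)) not in excl]
        pairs = pairs[keep]
    if len(pairs) == 0:
        return np.zeros(_as_frames(coords).shape[0], dtype=np.int64)
    r = pair_distances(coords, pairs, box)
    return (r <= cutoff).sum(axis=1)


def _unwrap_about(frames: np.ndarray, idx: np.ndarray, box: float) -> np.ndarray:
    """Make group coordinates internally consistent under PBC by unwrapping
    each particle's displacement from the group's first particle."""
    ref = frames[:, idx[0]][:, None, :]
    return ref + _min_image(frames[:, idx] - ref, box)


def center_separation(coords, group_a, group_b, box: float) -> np.ndarray:
    """Minimum-image distance between group centroids (uniform masses)."""
    frames = _as_frames(coords)
    a = np.asarray(group_a, dtype=np.int64)
    b = np.asarray(group_b, dtype=np.int64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    ca = _unwrap_about(frames, a, box).mean(axis=1)
    cb = _unwrap_about(frames, b, box).mean(axis=1)
    return np.linalg.norm(_min_image(ca - cb, box), axis=-1)


def _kabsch(mobile: np.ndarray, target: np.ndarray):
    """Optimal rotation + translation mapping mobile onto target."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, tc - rot @ mc


def binding_rmsd(coords, native_coords, align_subset, rmsd_subset,
                 box: float | None = None) -> np.ndarray:
    """RMSD of ``rmsd_subset`` after superposing ``align_subset`` onto the
    native structure (Kabsch).

    For an IDP bound to a folded substrate, aligning on the substrate and
    measuring the IDP gives the binding RMSD; passing the whole complex for
    both subsets gives the regular complex RMSD (the convention for
    synergistically folding IDP pairs).
    """
    frames = _as_frames(coords)
    native = np.asarray(native_coords, dtype=float)
    align_subset = np.asarray(align_subset, dtype=np.int64)
    rmsd_subset = np.asarray(rmsd_subset, dtype=np.int64)
    if len(align_subset) < 3:
        raise ValueError("need at least 3 alignment particles")
    if len(rmsd_subset) == 0:
        raise ValueError("RMSD subset is empty")
    all_idx = np.union1d(align_subset, rmsd_subset)
    pos_a = {g: k for k, g in enumerate(all_idx)}
    if box is not None:
        local = _unwrap_about(frames, all_idx, box)
    else:
        local = frames[:, all_idx]
    ai = np.array([pos_a[g] for g in align_subset])
    ri = np.array([pos_a[g] for g in rmsd_subset])
    out = np.empty(frames.shape[0])
    for f in range(frames.shape[0]):
        rot, trans = _kabsch(local[f, ai], native[align_subset])
        moved = local[f, ri] @ rot.T + trans
        out[f] = np.sqrt(np.mean(np.sum((moved - native[rmsd_subset]) ** 2, axis=1)))
    return out


def contact_probability_map(coords, group_a, group_b, box: float,
                            cutoff: float = NONSPECIFIC_CUTOFF) -> np.ndarray:
    """Per-residue probability of being in intermolecular contact.

    For every residue in either group: the fraction of frames in which it
    has at least one C-alpha pair within ``cutoff`` to the other group.
    Returned as an array over all particle indices (zero outside the
    groups).
    """
    frames = _as_frames(coords)
    if frames.shape[0] == 0:
        raise ValueError("ensemble is empty")
    a = np.asarray(group_a, dtype=np.int64)
    b = np.asarray(group_b, dtype=np.int64)
    d = np.linalg.norm(
        _min_image(frames[:, a][:, :, None, :] - frames[:, b][:, None, :, :], box),
        axis=-1,
    )  # (frames, |a|, |b|)
    close = d <= cutoff
    prob = np.zeros(frames.shape[1])
    prob[a] = close.any(axis=2).mean(axis=0)
    prob[b] = close.any(axis=1).mean(axis=0)
    return prob


def load_segment_table(path) -> dict[str, tuple[int, int]]:
    """Read a YAML segment table mapping names (e.g. helix labels) to
    global residue ranges, given inclusively as ``[start, stop]`` and
    returned as half-open ``(start, stop + 1)`` tuples."""
    import yaml
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    for name, rng in raw.items():
        lo, hi = int(rng[0]), int(rng[1])
        if hi < lo or lo < 0:
            raise ValueError(f"invalid residue range for segment {name!r}")
        out[str(name)] = (lo, hi + 1)
    return out


@dataclass
class ObservableSeries:
    """Named per-frame reaction-coordinate series."""

    times: np.ndarray
    series: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.series[name]

    def __contains__(self, name: str) -> bool:
        return name in self.series

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times, **self.series})

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def compute_observables(
    trajectory,
    topology: GoTopology,
    segments: dict[str, tuple[int, int]] | None = None,
    tolerance: float = CONTACT_TOLERANCE,
    nonspecific_cutoff: float = NONSPECIFIC_CUTOFF,
) -> ObservableSeries:
    """Standard observable set for a two-chain complex trajectory.

    Computes Q_inter, per-chain Q_intra, N_inter, the native-excluded
    nonspecific contact count, centre-of-mass separation and binding RMSD
    (substrate = first chain when it is the larger one, else whole-complex
    alignment).  ``segments`` maps names to global residue ranges
    [start, end) for per-segment intermolecular Q's.
    """
    frames = trajectory.coords
    box = trajectory.box
    chain = topology.chain_index
    groups = [np.nonzero(chain == k)[0] for k in range(len(topology.chain_ids))]
    if len(groups) != 2:
        raise ValueError("standard observable set expects a two-chain complex")
    ga, gb = groups

    out = ObservableSeries(times=trajectory.times)
    ipairs, irnat, _ = topology.contact_arrays("inter")
    if len(ipairs):
        out.series["Q_inter"] = fraction_native(frames, ipairs, irnat, box, tolerance)
        out.series["N_inter"] = native_contact_count(frames, ipairs, irnat, box, tolerance)
    for k, cid in enumerate(topology.chain_ids):
        sel = [c for c in topology.intra_contacts if c.kind == f"intra:{cid}"]
        if sel:
            pairs = np.array([[c.i, c.j] for c in sel])
            rnat = np.array([c.r_native for c in sel])
            out.series[f"Q_intra_{cid}"] = fraction_native(
                frames, pairs, rnat, box, tolerance)
    out.series["N_nonspec"] = nonspecific_contacts(
        frames, ga, gb, box, nonspecific_cutoff,
        exclude_pairs=ipairs if len(ipairs) else None)
    out.series["R_CM"] = center_separation(frames, ga, gb, box)
    if len(ga) >= max(3, len(gb)):
        align, rmsd_sel = ga, gb
    else:
        align = rmsd_sel = np.concatenate([ga, gb])
    out.series["binding_rmsd"] = binding_rmsd(
        frames, topology.native_coords, align, rmsd_sel, box)
    if segments:
        for name, (lo, hi) in segments.items():
            sel = [(p, r) for p, r in zip(ipairs, irnat)
                   if lo <= p[0] < hi or lo <= p[1] < hi]
            if sel:
                pairs = np.array([p for p, _ in sel])
                rnat = np.array([r for _, r in sel])
                out.series[f"Q_inter_{name}"] = fraction_native(
                    frames, pairs, rnat, box, tolerance)
    return out
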