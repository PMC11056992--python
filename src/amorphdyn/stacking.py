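"""F-ring stacking geometry: RDF x ADF maps and parallel/antiparallel census.

For every ordered intermolecular pair (i, j) the analysis records the
minimum-image distance r from the fluorine of molecule i to the
F-bearing ring carbon of molecule j, and the angle theta in [0, 180] deg
between the two F->C_ring_F unit vectors.  Accumulated over one or more
frames and normalised by the ideal-gas measure (radial shell volume times
the sin(theta) angular weight), the (r, theta) histogram becomes a 2D
distribution g(r, theta) that equals 1 everywhere for an ideal gas; the
raw counts are kept alongside.

Stacking pairs are classified from the same observables: parallel when
theta >= 150 deg with r in [3, 5] A, antiparallel when theta <= 30 deg
with r in [5, 7] A (windows configurable, centred on the characteristic
4 A/180 deg and 6 A/0 deg arrangements).  The census breaks counts down
by the chirality pair (R-R, S-S, R-S) of the partners.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .structures import Configuration, minimum_image_vector

PARALLEL_WINDOW = {"theta_min_deg": 150.0, "r_angstrom": (3.0, 5.0)}
ANTIPARALLEL_WINDOW = {"theta_max_deg": 30.0, "r_angstrom": (5.0, 7.0)}


@dataclass
class RingFrame:
    """Per-molecule stacking observables."""

    molecule_id: int
    chirality: str
    f_xyz: np.ndarray
    cring_xyz: np.ndarray
    fc_vector: np.ndarray  # unit vector F -> C_ring_F
    ring_normal: np.ndarray  # unit normal of the best-fit ring plane


@dataclass
class Map2D:
    r_edges_angstrom: np.ndarray
    angle_edges_deg: np.ndarray
    counts: np.ndarray  # raw 2D histogram, shape (n_r, n_theta)
    density: np.ndarray  # ideal-gas normalised g(r, theta)
    ideal_counts: np.ndarray  # expected ideal-gas counts per bin
    n_pairs: int  # ordered pairs accumulated (all distances)

    def to_frame(self) -> pd.DataFrame:
        r_mid = 0.5 * (self.r_edges_angstrom[:-1] + self.r_edges_angstrom[1:])
        a_mid = 0.5 * (self.angle_edges_deg[:-1] + self.angle_edges_deg[1:])
        return pd.DataFrame(self.density, index=pd.Index(r_mid, name="r_angstrom"),
                            columns=pd.Index(a_mid, name="theta_deg"))


# ---------------------------------------------------------------------------
# per-molecule frames
# ---------------------------------------------------------------------------

def _plane_normal(points: np.ndarray) -> np.ndarray:
    """Total-least-squares plane normal; sign chosen toward positive z."""
    c = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(c, full_matrices=False)
    if s[1] < 1e-8:  # collinear ring atoms span no plane
        raise ValueError("degenerate ring: atoms are collinear")
    n = vt[2]
    if n[2] < 0 or (n[2] == 0 and (n[1] < 0 or (n[1] == 0 and n[0] < 0))):
        n = -n
    return n / np.linalg.norm(n)


def ring_frames(config: Configuration) -> list[RingFrame]:
    frames = []
    for m in config.molecules:
        f = m.atom("F").xyz
        c = m.atom("C_ring_F").xyz
        ring = np.array([c] + [a.xyz for a in m.atoms_with_role("C_ring")])
        fc = c - f
        nrm = np.linalg.norm(fc)
        if nrm < 1e-10:
            raise ValueError("F and C_ring_F coincide")
        frames.append(RingFrame(
            molecule_id=m.molecule_id, chirality=m.chirality,
            f_xyz=f, cring_xyz=c, fc_vector=fc / nrm,
            ring_normal=_plane_normal(ring),
        ))
    return frames


# ---------------------------------------------------------------------------
# RDF x ADF map
# ---------------------------------------------------------------------------

def _pair_observables(frames: list[RingFrame], box: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """(r, theta) for all ordered intermolecular pairs in one frame."""
    n = len(frames)
    if n < 2:
        return np.empty(0), np.empty(0)
    F = np.array([fr.f_xyz for fr in frames])
    C = np.array([fr.cring_xyz for fr in frames])
    V = np.array([fr.fc_vector for fr in frames])
    dr = C[None, :, :] - F[:, None, :]
    dr = dr - box * np.round(dr / box)
    r = np.linalg.norm(dr, axis=2)
    cos = np.clip(V @ V.T, -1.0, 1.0)
    theta = np.degrees(np.arccos(cos))
    off = ~np.eye(n, dtype=bool)
    return r[off], np.broadcast_to(theta, r.shape)[off]


def rdf_adf_map(
    configs: Configuration | Iterable[Configuration],
    r_edges_angstrom: np.ndarray | None = None,
    angle_edges_deg: np.ndarray | None = None,
) -> Map2D:
    """Accumulate the F...C_ring_F RDF x ADF 2D map over one or more frames."""
    if isinstance(configs, Configuration):
        configs = [configs]
    configs = list(configs)
    if r_edges_angstrom is None:
        r_edges_angstrom = np.arange(0.0, 10.0 + 1e-9, 0.1)
    if angle_edges_deg is None:
        angle_edges_deg = np.arange(0.0, 180.0 + 1e-9, 2.0)
    r_edges = np.asarray(r_edges_angstrom, dtype=float)
    a_edges = np.asarray(angle_edges_deg, dtype=float)

    counts = np.zeros((len(r_edges) - 1, len(a_edges) - 1))
    ideal = np.zeros_like(counts)
    n_pairs = 0
    shell = 4.0 / 3.0 * np.pi * (r_edges[1:] ** 3 - r_edges[:-1] ** 3)
    ang_frac = 0.5 * (np.cos(np.radians(a_edges[:-1]))
                      - np.cos(np.radians(a_edges[1:])))
    for cfg in configs:
        if r_edges[-1] >= 0.5 * cfg.box_angstrom.min():
            raise ValueError("r range must stay below half the smallest box length")
        frames = ring_frames(cfg)
        n = len(frames)
        if n < 2:
            continue
        r, theta = _pair_observables(frames, cfg.box_angstrom)
        h, _, _ = np.histogram2d(r, theta, bins=(r_edges, a_edges))
        counts += h
        n_pairs += n * (n - 1)
        vol = float(np.prod(cfg.box_angstrom))
        ideal += (n * (n - 1) / vol) * shell[:, None] * ang_frac[None, :]

    with np.errstate(divide="ignore", invalid="ignore"):
        density = np.where(ideal > 0, counts / ideal, 0.0)
    return Map2D(r_edges_angstrom=r_edges, angle_edges_deg=a_edges,
                 counts=counts, density=density, ideal_counts=ideal,
                 n_pairs=n_pairs)


# ---------------------------------------------------------------------------
# classification & census
# ---------------------------------------------------------------------------

def classify_stacking(
    frame_i: RingFrame,
    frame_j: RingFrame,
    box: np.ndarray,
    parallel_window: dict = PARALLEL_WINDOW,
    antiparallel_window: dict = ANTIPARALLEL_WINDOW,
) -> str:
    """Label one molecule pair as 'parallel', 'antiparallel' or 'none'.

    r is taken as the smaller of the two F_i...C_j / F_j...C_i minimum-image
    distances so the label is symmetric in pair order; theta (angle between
    the two F->C vectors) is symmetric by construction.
    """
    box = np.asarray(box, dtype=float)
    r_ij = np.linalg.norm(minimum_image_vector(frame_j.cring_xyz - frame_i.f_xyz, box))
    r_ji = np.linalg.norm(minimum_image_vector(frame_i.cring_xyz - frame_j.f_xyz, box))
    r = min(r_ij, r_ji)
    cos = float(np.clip(np.dot(frame_i.fc_vector, frame_j.fc_vector), -1.0, 1.0))
    theta = float(np.degrees(np.arccos(cos)))

    lo, hi = parallel_window["r_angstrom"]
    if theta >= parallel_window["theta_min_deg"] and lo <= r <= hi:
        return "parallel"
    lo, hi = antiparallel_window["r_angstrom"]
    if theta <= antiparallel_window["theta_max_deg"] and lo <= r <= hi:
        return "antiparallel"
    return "none"


def stacking_census(
    configs: Configuration | Iterable[Configuration],
    parallel_window: dict = PARALLEL_WINDOW,
    antiparallel_window: dict = ANTIPARALLEL_WINDOW,
) -> dict:
    """Count parallel/antiparallel pairs, broken down by chirality pair."""
    if isinstance(configs, Configuration):
        configs = [configs]
    census = {
        "parallel": 0, "antiparallel": 0,
        "by_chirality": {lbl: {"R-R": 0, "S-S": 0, "R-S": 0}
                         for lbl in ("parallel", "antiparallel")},
    }
    for cfg in configs:
        frames = ring_frames(cfg)
        for i in range(len(frames)):
            for j in range(i + 1, len(frames)):
                label = classify_stacking(frames[i], frames[j], cfg.box_angstrom,
                                          parallel_window, antiparallel_window)
                if label == "none":
                    continue
                census[label] += 1
                pair = "".join(sorted((frames[i].chirality, frames[j].chirality)))
                key = {"RR": "R-R", "SS": "S-S", "RS": "R-S"}[pair]
                census["by_chirality"][label][key] += 1
    return census
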