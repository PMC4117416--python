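"""Angle distributions, basin populations and FRET-style projections.

Pooled GA solutions are histogrammed over the two inter-domain opening
angles; rectangular basins in (theta_AMPbd, theta_LID) space are
identified with conformational states whose populations are the
integrated weights.  Replica solutions from error propagation give the
population uncertainties, and projecting the weighted members onto an
inter-residue distance emulates a single-molecule FRET reaction
coordinate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .ga import GAResult
from .pool import ConformerPool

__all__ = [
    "AngleDistribution",
    "BasinSpec",
    "build_distribution",
    "basin_populations",
    "population_uncertainty",
    "fret_projection",
    "DEFAULT_BASINS",
]

log = logging.getLogger(__name__)


@dataclass
class AngleDistribution:
    """Normalized 2D histogram over (theta_AMPbd, theta_LID), degrees."""

    weights: np.ndarray  # (n_a, n_l), sums to 1
    edges_ampbd: np.ndarray
    edges_lid: np.ndarray

    def __post_init__(self):
        total = float(self.weights.sum())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"histogram weights sum to {total}, expected 1")
        if self.weights.shape != (len(self.edges_ampbd) - 1, len(self.edges_lid) - 1):
            raise ValueError("weight grid does not match bin edges")


@dataclass(frozen=True)
class BasinSpec:
    """A rectangular region of angle space identified with a state."""

    label: str
    ampbd_range: tuple[float, float]
    lid_range: tuple[float, float]

    def __post_init__(self):
        for lo, hi in (self.ampbd_range, self.lid_range):
            if not (0.0 <= lo < hi <= 180.0):
                raise ValueError(f"basin range ({lo}, {hi}) outside [0, 180]")

    def contains(self, theta_ampbd, theta_lid) -> np.ndarray:
        ta = np.asarray(theta_ampbd)
        tl = np.asarray(theta_lid)
        return (
            (ta >= self.ampbd_range[0]) & (ta <= self.ampbd_range[1])
            & (tl >= self.lid_range[0]) & (tl <= self.lid_range[1])
        )

    def overlaps(self, other: "BasinSpec") -> bool:
        (a0, a1), (b0, b1) = self.ampbd_range, other.ampbd_range
        (c0, c1), (d0, d1) = self.lid_range, other.lid_range
        return a0 < b1 and b0 < a1 and c0 < d1 and d0 < c1


#: basin rectangles centred on the printed closed-like and open state
#: angles of E. coli adenylate kinase; boundaries are a documented
#: choice, not a measured quantity
DEFAULT_BASINS = (
    BasinSpec("closed-like", (45.0, 70.0), (95.0, 120.0)),
    BasinSpec("open", (65.0, 85.0), (135.0, 160.0)),
)


def _member_angles(results, pool: ConformerPool):
    """Member angle arrays and per-member weights from one GAResult or
    a list of them; each ensemble member carries weight
    1 / (ensemble size x number of pooled solutions)."""
    if isinstance(results, GAResult):
        results = [results]
    idx, w = [], []
    total = sum(len(r.best) for r in results)
    if total == 0:
        raise ValueError("no GA solutions to pool")
    for r in results:
        for ens in r.best:
            members = ens.member_indices
            if members.max(initial=-1) >= len(pool):
                raise IndexError("ensemble member index outside pool")
            idx.append(members)
            w.append(np.full(len(members), 1.0 / (len(members) * total)))
    idx = np.concatenate(idx)
    w = np.concatenate(w)
    return pool.angles[idx], idx, w


def build_distribution(results, pool: ConformerPool, bin_width: float = 2.0) -> AngleDistribution:
    """Histogram the pooled solutions' member angles over [0, 180]^2."""
    angles, _, w = _member_angles(results, pool)
    n_bins = int(np.ceil(180.0 / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    hist, ea, el = np.histogram2d(
        angles[:, 0], angles[:, 1], bins=(edges, edges), weights=w
    )
    return AngleDistribution(hist / hist.sum(), ea, el)


def basin_populations(dist: AngleDistribution, basins) -> dict[str, float]:
    """Integrated histogram weight per basin rectangle; bins are
    assigned by their centres.  Weight outside every basin is reported
    as "unassigned"."""
    basins = list(basins)
    for i, a in enumerate(basins):
        for b in basins[i + 1:]:
            if a.overlaps(b):
                warnings.warn(f"basins {a.label!r} and {b.label!r} overlap")
    ca = 0.5 * (dist.edges_ampbd[:-1] + dist.edges_ampbd[1:])
    cl = 0.5 * (dist.edges_lid[:-1] + dist.edges_lid[1:])
    A, L = np.meshgrid(ca, cl, indexing="ij")
    out = {}
    assigned = np.zeros_like(dist.weights, dtype=bool)
    for basin in basins:
        mask = basin.contains(A, L)
        out[basin.label] = float(dist.weights[mask].sum())
        assigned |= mask
    out["unassigned"] = float(dist.weights[~assigned].sum())
    return out


def population_uncertainty(replica_results, pool: ConformerPool, basins,
                           bin_width: float = 2.0):
    """Mean and standard deviation of each basin population across
    replica GA solutions (e.g. from ``propagate_rdc_error``)."""
    replica_results = list(replica_results)
    if len(replica_results) < 2:
        raise ValueError("need >= 2 replicas for an uncertainty estimate")
    per_label: dict[str, list[float]] = {}
    for res in replica_results:
        pops = basin_populations(build_distribution(res, pool, bin_width), basins)
        for label, frac in pops.items():
            per_label.setdefault(label, []).append(frac)
    return {
        label: (float(np.mean(v)), float(np.std(v)))
        for label, v in per_label.items()
    }


def fret_projection(results, pool: ConformerPool, residue_pair: tuple[int, int],
                    open_cutoff: float) -> float:
    """Open-state fraction along a FRET-like distance coordinate.

    Computes the C-alpha distance between the two residues for every
    weighted ensemble member and returns the total weight with distance
    strictly greater than the cutoff (A).
    """
    if open_cutoff <= 0:
        raise ValueError("open_cutoff must be positive")
    _, idx, w = _member_angles(results, pool)
    r1, r2 = residue_pair
    dists = np.array(
        [np.linalg.norm(pool.conformers[i].coord(r1, "CA")
                        - pool.conformers[i].coord(r2, "CA")) for i in idx]
    )
    return float(w[dists > open_cutoff].sum())
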