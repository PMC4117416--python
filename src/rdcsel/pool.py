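"""Reference pools of inter-domain conformations.

The selection method needs a pool that covers inter-domain angle space
broadly and evenly; how the pool is made is otherwise immaterial.  This
module provides a deterministic rigid-body stand-in for simulation-based
pools: the two mobile domains (AMPbd, LID) of a three-domain protein are
rotated about hinge axes through the centers of mass of the residue
windows flanking each domain, with iterative correction so the measured
(theta_AMPbd, theta_LID) hit requested targets.  Pools from any
simulation engine can be imported as multi-model PDB files instead
(:func:`rdcsel.io.read_pool`).

A fully synthetic toy protein (C-alpha/N/H backbone, three globular
domains, AK-like angle ranges) is also built here and used throughout
the tests and validation experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import AKE_ANGLES, AngleDefinition, domain_angles
from .structure import Structure, rotation_about_axis

__all__ = [
    "DomainDefinition",
    "ConformerPool",
    "make_toy_structure",
    "generate_hinge_pool",
    "precompute_pool_rdcs",
    "default_angle_grid",
    "TOY_ANGLE_RANGES",
]

log = logging.getLogger(__name__)

#: angle ranges covered by the default pool: the AMP-binding domain
#: opens over ~30-90 degrees and the LID over ~90-160 degrees
TOY_ANGLE_RANGES = ((30.0, 90.0), (90.0, 160.0))

#: inter-domain C-alpha clash cutoff (A); excludes only physically
#: impossible overlaps, not force-field-level contacts
CLASH_CUTOFF = 3.0

#: open/closed preset targets (theta_AMPbd, theta_LID), degrees
PRESET_ANGLES = {"open": (88.0, 150.0), "closed": (45.0, 92.0)}


@dataclass(frozen=True)
class DomainDefinition:
    """Residue intervals (1-based inclusive) of the three domains, the
    hinge flank windows anchoring each mobile domain's rotation axis,
    and the angle windows used to measure the opening angles."""

    ampbd_range: tuple[int, int]
    lid_range: tuple[int, int]
    core_ranges: tuple[tuple[int, int], ...]
    ampbd_flanks: tuple[tuple[int, int], tuple[int, int]]
    lid_flanks: tuple[tuple[int, int], tuple[int, int]]
    angles: AngleDefinition

    def __post_init__(self):
        spans = [self.ampbd_range, self.lid_range, *self.core_ranges]
        for lo, hi in spans:
            if lo > hi:
                raise ValueError(f"empty residue interval ({lo}, {hi})")
        for i, a in enumerate(spans):
            for b in spans[i + 1:]:
                if a[0] <= b[1] and b[0] <= a[1]:
                    raise ValueError(f"overlapping domain intervals {a} and {b}")

    def residues(self, which: str) -> np.ndarray:
        if which == "ampbd":
            return np.arange(self.ampbd_range[0], self.ampbd_range[1] + 1)
        if which == "lid":
            return np.arange(self.lid_range[0], self.lid_range[1] + 1)
        if which == "core":
            return np.concatenate(
                [np.arange(lo, hi + 1) for lo, hi in self.core_ranges]
            )
        raise KeyError(which)


#: E. coli adenylate kinase domain layout
AKE_DOMAINS = DomainDefinition(
    ampbd_range=(28, 72),
    lid_range=(113, 176),
    core_ranges=((1, 27), (73, 112), (177, 214)),
    ampbd_flanks=((24, 27), (73, 76)),
    lid_flanks=((109, 112), (177, 180)),
    angles=AKE_ANGLES,
)


# ---------------------------------------------------------------------------
# toy structure


#: waypoint paths (A) for the five chain segments of the toy protein.
#: Both hinge junctions are short vertical "columns" so the two hinge
#: axes (through the flank-window centers of mass) are near-vertical;
#: the AMPbd lobe then swings in a horizontal slab below the CORE
#: (y ~ -6) and the LID lobe in a slab above it (y ~ +7.5), keeping the
#: mobile lobes and the CORE spatially separated at every rotation.
#: CORE3 climbs over the LID slab and descends far outside it to place
#: the reference window used by the LID angle.
_TOY_WAYPOINTS = {
    # approaches the first hinge from below the AMPbd slab and ascends
    # a vertical column to the junction
    "core1": [
        (-16.0, -14.0, -6.0), (-8.0, -14.0, -2.0), (-2.0, -13.0, 0.0),
        (0.0, -7.0, 0.0), (0.0, -1.5, 0.0),
    ],
    # lobe loops in the y ~ -6 slab, returns via an outer climb and an
    # inward bridge just above the junction
    "ampbd": [
        (2.5, -4.8, 2.5), (8.7, -6.0, 13.0), (15.2, -6.2, 13.6),
        (21.7, -6.0, 5.4), (20.6, -6.0, -4.3), (13.0, -6.0, -11.9),
        (6.5, -5.8, -7.6), (6.5, -4.8, -1.8), (6.0, -1.5, -1.4),
        (4.0, 0.3, 0.3),
    ],
    # vertical column up from the first junction, a low horizontal run
    # east, and a second vertical column up to the LID junction
    "core2": [
        (0.5, 0.8, 0.5), (0.5, 6.2, 0.5), (4.0, 2.0, 2.0),
        (12.0, 0.8, 3.0), (22.0, 0.8, 2.5), (30.0, 0.5, 1.5),
        (34.3, 0.3, 0.8), (34.5, 6.3, 0.8),
    ],
    # lobe loops in the y ~ +8 slab around the second junction,
    # returns via a climb above the slab
    "lid": [
        (34.8, 7.3, 1.5), (39.4, 8.1, 12.0), (47.0, 8.3, 14.1),
        (53.6, 8.3, 5.4), (53.0, 8.3, -4.4), (44.8, 8.1, -12.0),
        (37.8, 7.9, -6.5), (39.2, 9.4, -1.8), (38.6, 11.0, -1.2),
        (35.8, 11.2, 0.6),
    ],
    # column above the LID junction, an arc over the LID slab, then a
    # descent far outside both swing annuli to the reference window
    "core3": [
        (35.2, 11.4, 0.8), (35.2, 18.0, 0.8), (28.0, 16.5, 4.2),
        (20.0, 13.0, 8.5), (21.0, 3.0, 8.5), (20.0, -1.5, 8.5),
    ],
}

_WIGGLE_AMPLITUDE = 0.8  # A, helical offset giving the chain thickness
_WIGGLE_STEP_DEG = 100.0  # per-residue phase, alpha-helical twist


def _resample_path(waypoints: np.ndarray, n: int) -> np.ndarray:
    """n points at equal arc length along a polyline."""
    wp = np.asarray(waypoints, dtype=float)
    seg = np.linalg.norm(np.diff(wp, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, s[-1], n)
    out = np.empty((n, 3))
    for d in range(3):
        out[:, d] = np.interp(t, s, wp[:, d])
    return out


def _segment_ca(waypoints, n: int, phase0: float) -> np.ndarray:
    """C-alpha trace: resampled path plus a deterministic helical wiggle
    perpendicular to the local tangent."""
    path = _resample_path(waypoints, n)
    grad = np.gradient(path, axis=0)
    tang = grad / np.linalg.norm(grad, axis=1, keepdims=True)
    ref = np.array([0.137, 0.803, 0.580])
    b1 = np.cross(tang, ref)
    small = np.linalg.norm(b1, axis=1) < 1e-8
    b1[small] = np.cross(tang[small], [1.0, 0.0, 0.0])
    b1 /= np.linalg.norm(b1, axis=1, keepdims=True)
    b2 = np.cross(tang, b1)
    ph = np.deg2rad(phase0 + _WIGGLE_STEP_DEG * np.arange(n))
    return path + _WIGGLE_AMPLITUDE * (np.cos(ph)[:, None] * b1 + np.sin(ph)[:, None] * b2)


def _build_backbone(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Amide N and H positions for each residue from the C-alpha trace.

    N sits 1.45 A from CA toward the previous residue with a lateral
    offset; H sits 1.02 A from N along a deterministic direction that
    varies along the chain so bond vectors sample orientation space.
    """
    n = len(ca)
    prev = np.vstack([ca[0] - (ca[1] - ca[0]), ca[:-1]])
    nxt = np.vstack([ca[1:], ca[-1] + (ca[-1] - ca[-2])])
    back = prev - ca
    back /= np.maximum(np.linalg.norm(back, axis=1, keepdims=True), 1e-9)
    tang = nxt - prev
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-9)
    side = np.cross(tang, back)
    norms = np.linalg.norm(side, axis=1, keepdims=True)
    side = np.where(norms > 1e-8, side / np.maximum(norms, 1e-9),
                    np.cross(tang, [0.0, 0.0, 1.0]))
    n_pos = ca + 1.45 * (0.92 * back + 0.39 * side)
    ph = np.deg2rad(137.5 * np.arange(n))  # golden-angle spread
    u = (np.cos(ph)[:, None] * side + np.sin(ph)[:, None] * np.cross(back, side)
         + 0.55 * back)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return n_pos, n_pos + 1.02 * u


def _assemble(ca: np.ndarray) -> Structure:
    n_pos, h_pos = _build_backbone(ca)
    n = len(ca)
    resids = np.repeat(np.arange(1, n + 1), 3)
    names = np.tile(np.array(["N", "CA", "H"], dtype=object), n)
    coords = np.empty((3 * n, 3))
    coords[1::3] = ca
    coords[0::3] = n_pos
    coords[2::3] = h_pos
    return Structure(resids, names, coords)


def _toy_domains(n_core: int, n_lid: int, n_ampbd: int) -> tuple[dict, DomainDefinition]:
    nc1 = max(5, round(n_core * 15 / 46))
    nc3 = max(5, round(n_core * 11 / 46))
    nc2 = n_core - nc1 - nc3
    if nc2 < 5:
        raise ValueError("n_core too small: each CORE segment needs >=5 residues")
    seg_counts = {"core1": nc1, "ampbd": n_ampbd, "core2": nc2,
                  "lid": n_lid, "core3": nc3}
    start = {}
    pos = 1
    for name in ("core1", "ampbd", "core2", "lid", "core3"):
        start[name] = pos
        pos += seg_counts[name]

    def rng(name):
        return (start[name], start[name] + seg_counts[name] - 1)

    def mid_window(name, half):
        lo, hi = rng(name)
        mid = (lo + hi) // 2
        return (max(lo, mid - half), min(hi, mid + half))

    c2lo, c2hi = rng("core2")
    c3lo_, c3hi_ = rng("core3")
    angles = AngleDefinition.from_ranges(
        core_a=(c2lo, min(c2hi, c2lo + 3)),
        hinge=(max(c2lo, c2hi - 3), c2hi),
        ampbd=mid_window("ampbd", 4),
        core_b=(max(c3lo_, c3hi_ - 2), c3hi_),
        lid=mid_window("lid", 5),
    )
    c1lo, c1hi = rng("core1")
    c3lo, c3hi = rng("core3")
    alo, ahi = rng("ampbd")
    llo, lhi = rng("lid")
    domains = DomainDefinition(
        ampbd_range=(alo, ahi),
        lid_range=(llo, lhi),
        core_ranges=(rng("core1"), rng("core2"), rng("core3")),
        ampbd_flanks=((max(c1lo, c1hi - 3), c1hi), (c2lo, min(c2hi, c2lo + 3))),
        lid_flanks=((max(c2lo, c2hi - 3), c2hi), (c3lo, min(c3hi, c3lo + 3))),
        angles=angles,
    )
    return seg_counts, domains


def make_toy_structure(
    n_core: int = 46, n_lid: int = 32, n_ampbd: int = 22,
    preset: str | tuple[float, float] = "open",
) -> tuple[Structure, DomainDefinition]:
    """Deterministic toy three-domain protein.

    Five chain segments (CORE1, AMPbd, CORE2, LID, CORE3) are laid out
    along fixed waypoint paths; the mobile domains are then rotated to
    the preset opening angles ("open" = (88, 150), "closed" = (45, 92)
    degrees, or an explicit (theta_AMPbd, theta_LID) pair).  Atoms per
    residue: N, CA, H.
    """
    if min(n_core, n_lid, n_ampbd) < 5:
        raise ValueError("each domain needs at least 5 residues")
    seg_counts, domains = _toy_domains(n_core, n_lid, n_ampbd)
    pieces = []
    phase = 0.0
    for name in ("core1", "ampbd", "core2", "lid", "core3"):
        pieces.append(_segment_ca(_TOY_WAYPOINTS[name], seg_counts[name], phase))
        phase += 77.0  # decorrelate wiggle phases between segments
    structure = _assemble(np.vstack(pieces))
    targets = PRESET_ANGLES[preset] if isinstance(preset, str) else tuple(preset)
    structure, achieved = _set_domain_angles(structure, domains, targets)
    if max(abs(achieved[0] - targets[0]), abs(achieved[1] - targets[1])) > 2.0:
        raise RuntimeError(
            f"toy construction missed preset angles: wanted {targets}, got {achieved}"
        )
    return structure, domains


# ---------------------------------------------------------------------------
# hinge rotation machinery


def _window_com(structure: Structure, window: tuple[int, int]) -> np.ndarray:
    return structure.ca_coords(list(range(window[0], window[1] + 1))).mean(axis=0)


def _hinge_axis(structure: Structure, flanks) -> tuple[np.ndarray, np.ndarray]:
    p0 = _window_com(structure, flanks[0])
    p1 = _window_com(structure, flanks[1])
    axis = p1 - p0
    if np.linalg.norm(axis) < 1e-6:
        raise ValueError("degenerate hinge axis: flank windows coincide")
    return p0, axis / np.linalg.norm(axis)


def _rotate_point_about(p, p0, axis, psi):
    """Rotate point(s) p about the axis (p0, axis) by angle(s) psi."""
    psi = np.atleast_1d(np.asarray(psi, dtype=float))
    rel = np.asarray(p, dtype=float) - p0
    par = np.outer(rel @ axis, axis)
    perp = rel - par
    cross = np.cross(axis, rel)
    out = (p0 + par + np.cos(psi)[:, None] * perp + np.sin(psi)[:, None] * cross)
    return out


def _angle_at(vertex, a, b) -> np.ndarray:
    u = a - vertex
    v = b - vertex
    u = u / np.linalg.norm(u, axis=-1, keepdims=True)
    v = v / np.linalg.norm(v, axis=-1, keepdims=True)
    return np.degrees(np.arccos(np.clip(np.sum(u * v, axis=-1), -1.0, 1.0)))


def _solve_hinge_rotations(com, p0, axis, vertex, fixed, target, max_iter=20):
    """Rotation angles psi about (p0, axis) placing the window COM so
    the angle at `vertex` between rays to `fixed` and to the rotated
    COM equals `target` (degrees).

    The target angle is generally hit on two rotation branches; both
    are located by a coarse scan and polished by secant iteration.
    Returns a (possibly empty) list of psi values within 2 degrees.
    """

    def theta(psi):
        pts = _rotate_point_about(com, p0, axis, psi)
        return _angle_at(
            np.broadcast_to(vertex, pts.shape), np.broadcast_to(fixed, pts.shape), pts
        )

    scan = np.linspace(-np.pi, np.pi, 181)
    vals = theta(scan) - target
    absv = np.abs(vals)
    cand = [
        i for i in range(len(scan))
        if absv[i] <= absv[max(i - 1, 0)] and absv[i] <= absv[min(i + 1, len(scan) - 1)]
    ]
    solutions = []
    for i in sorted(cand, key=lambda i: absv[i])[:4]:
        psi, f = float(scan[i]), float(vals[i])
        j = i - 1 if i > 0 else i + 1
        psi_prev, f_prev = float(scan[j]), float(vals[j])
        for _ in range(max_iter):
            if abs(f) < 1e-6:
                break
            df = f - f_prev
            if abs(df) < 1e-12:
                break
            step = f * (psi - psi_prev) / df
            psi_prev, f_prev = psi, f
            psi = psi - step
            f = float(theta(psi)[0]) - target
        if abs(f) <= 2.0 and not any(abs(psi - s) < 1e-3 for s in solutions):
            solutions.append(psi)
    # canonical ordering: prefer the smallest rotation away from the
    # seed geometry, so neighbouring targets map to the same structural
    # family and the pool varies smoothly with the target angles
    return sorted(solutions, key=abs)[:2]


def _rotate_domain(structure: Structure, resid_range, p0, axis, psi) -> None:
    """In-place rigid rotation of all atoms of the residue interval."""
    lo, hi = resid_range
    mask = (structure.resids >= lo) & (structure.resids <= hi)
    structure.coords[mask] = _rotate_point_about(structure.coords[mask], p0, axis, psi)


def _set_domain_angles(structure: Structure, domains: DomainDefinition, targets,
                       check_clash: bool = True):
    """Copy of `structure` with AMPbd and LID rotated about their hinge
    axes so the measured angles match the targets within 2 degrees.

    Both rotation branches per domain are tried and the first
    combination that hits the targets (and, when requested, is free of
    inter-domain clashes) is returned as (structure, achieved_angles).
    Raises ValueError when no branch combination works.
    """
    defn = domains.angles

    pa0, a_axis = _hinge_axis(structure, domains.ampbd_flanks)
    vert_a = structure.ca_coords(list(defn.core_a)).mean(axis=0)
    fix_a = structure.ca_coords(list(defn.hinge)).mean(axis=0)
    com_a = structure.ca_coords(list(defn.ampbd)).mean(axis=0)
    psis_a = _solve_hinge_rotations(com_a, pa0, a_axis, vert_a, fix_a, targets[0])
    if not psis_a:
        raise ValueError(f"theta_AMPbd target {targets[0]:.1f} deg unreachable")

    pl0, l_axis = _hinge_axis(structure, domains.lid_flanks)
    vert_l = structure.ca_coords(list(defn.hinge)).mean(axis=0)
    fix_l = structure.ca_coords(list(defn.core_b)).mean(axis=0)
    com_l = structure.ca_coords(list(defn.lid)).mean(axis=0)
    psis_l = _solve_hinge_rotations(com_l, pl0, l_axis, vert_l, fix_l, targets[1])
    if not psis_l:
        raise ValueError(f"theta_LID target {targets[1]:.1f} deg unreachable")

    clash_seen = False
    for psi_a in psis_a:
        for psi_l in psis_l:
            out = structure.copy()
            _rotate_domain(out, domains.ampbd_range, pa0, a_axis, psi_a)
            _rotate_domain(out, domains.lid_range, pl0, l_axis, psi_l)
            ach = domain_angles(out, defn)
            if max(abs(ach[0] - targets[0]), abs(ach[1] - targets[1])) > 2.0:
                continue
            if check_clash and _has_interdomain_clash(out, domains):
                clash_seen = True
                continue
            return out, ach
    if clash_seen:
        raise ValueError(
            f"targets ({targets[0]:.1f}, {targets[1]:.1f}) deg reachable only "
            "with inter-domain clashes"
        )
    raise ValueError(
        f"angle correction failed for targets ({targets[0]:.1f}, {targets[1]:.1f}) deg"
    )


#: residue pairs closer than this in sequence are exempt from the
#: inter-domain clash test: they are hinge/linker neighbours whose
#: proximity is covalently imposed, not a packing overlap
_CLASH_SEQ_EXEMPT = 8


def _has_interdomain_clash(structure: Structure, domains: DomainDefinition) -> bool:
    """True when C-alphas of different domains come closer than the
    clash cutoff, ignoring near-in-sequence hinge/linker pairs."""
    groups = {w: domains.residues(w) for w in ("ampbd", "lid", "core")}
    cas = {w: structure.ca_coords(r) for w, r in groups.items()}
    names = list(groups)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = cdist(cas[a], cas[b])
            ri = groups[a][:, None]
            rj = groups[b][None, :]
            d[np.abs(ri - rj) <= _CLASH_SEQ_EXEMPT] = np.inf
            if d.min() < CLASH_CUTOFF:
                return True
    return False


# ---------------------------------------------------------------------------
# pools


@dataclass
class ConformerPool:
    """A pool of same-sequence conformers with per-conformer caches."""

    conformers: list[Structure]
    domains: DomainDefinition
    angles: np.ndarray = None  # (n, 2) degrees, cached
    tensors: list = None
    rdc_matrix: np.ndarray = None  # (n, n_keys) Hz
    rdc_keys: list = None
    seed_info: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.conformers:
            raise ValueError("empty conformer pool")
        if self.angles is None:
            self.angles = np.array(
                [domain_angles(s, self.domains.angles) for s in self.conformers]
            )
        else:
            self.angles = np.asarray(self.angles, dtype=float)

    def __len__(self) -> int:
        return len(self.conformers)

    def in_box(self, box) -> np.ndarray:
        """Indices of conformers inside a ((a_lo, a_hi), (l_lo, l_hi))
        angle rectangle (degrees, inclusive)."""
        (alo, ahi), (llo, lhi) = box
        th = self.angles
        mask = (th[:, 0] >= alo) & (th[:, 0] <= ahi) & (th[:, 1] >= llo) & (th[:, 1] <= lhi)
        return np.flatnonzero(mask)


def default_angle_grid(
    n_ampbd: int = 45, n_lid: int = 45, ranges=TOY_ANGLE_RANGES
) -> np.ndarray:
    """Rectangular grid of (theta_AMPbd, theta_LID) targets covering
    the default opening ranges."""
    (alo, ahi), (llo, lhi) = ranges
    a = np.linspace(alo, ahi, n_ampbd)
    b = np.linspace(llo, lhi, n_lid)
    A, B = np.meshgrid(a, b, indexing="ij")
    return np.column_stack([A.ravel(), B.ravel()])


def generate_hinge_pool(
    seed_structure: Structure,
    domains: DomainDefinition,
    angle_targets: np.ndarray,
    jitter: float = 0.0,
    rng_seed: int | None = None,
) -> ConformerPool:
    """Pool of conformers at the requested (theta_AMPbd, theta_LID)
    targets by rigid hinge rotation of the seed's mobile domains.

    Targets are perturbed by Gaussian angular jitter (degrees) when
    requested.  Conformers whose solved angles miss the target by more
    than 2 degrees and conformers with inter-domain clashes are skipped
    with a log entry; skipped targets are recorded in ``seed_info``.
    """
    targets = np.atleast_2d(np.asarray(angle_targets, dtype=float))
    rng = np.random.default_rng(rng_seed)
    if jitter > 0.0:
        targets = targets + rng.normal(0.0, jitter, size=targets.shape)

    conformers, angles, skipped = [], [], []
    for k, (ta, tl) in enumerate(targets):
        try:
            conf, ach = _set_domain_angles(seed_structure, domains, (ta, tl))
        except ValueError as err:
            log.warning("target (%.1f, %.1f) skipped: %s", ta, tl, err)
            skipped.append((k, float(ta), float(tl), str(err)))
            continue
        conformers.append(conf)
        angles.append(ach)
    if not conformers:
        raise ValueError("all pool targets failed; check domain definition")
    if skipped:
        log.info("hinge pool: %d of %d targets skipped", len(skipped), len(targets))
    return ConformerPool(
        conformers, domains, angles=np.array(angles),
        seed_info={"rng_seed": rng_seed, "jitter": jitter,
                   "n_requested": len(targets), "skipped": skipped},
    )


def precompute_pool_rdcs(pool: ConformerPool, keys, steric_config=None) -> ConformerPool:
    """Cache each conformer's predicted alignment tensor and
    back-calculated couplings; idempotent for identical keys."""
    from .rdc import back_calculate
    from .steric import StericConfig, predict_tensor_for_structure

    keys = list(keys)
    if pool.rdc_keys == keys and pool.rdc_matrix is not None:
        log.debug("pool RDC cache hit (%d conformers)", len(pool))
        return pool
    if steric_config is None:
        steric_config = StericConfig()
    tensors, rows = [], np.empty((len(pool), len(keys)))
    for i, conf in enumerate(pool.conformers):
        tensor = predict_tensor_for_structure(conf, steric_config)
        tensors.append(tensor)
        rows[i] = back_calculate(conf, tensor, keys).values
    pool.tensors = tensors
    pool.rdc_matrix = rows
    pool.rdc_keys = keys
    return pool


def default_rdc_keys(structure: Structure, domains: DomainDefinition | None = None):
    """(residue, N, H) keys for every residue with both atoms present,
    excluding the two chain termini."""
    resids = structure.residue_ids()
    keys = [
        (int(r), "N", "H")
        for r in resids[1:-1]
        if structure.has_atom(r, "N") and structure.has_atom(r, "H")
    ]
    return keys
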