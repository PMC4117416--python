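"""Control experiments probing what the selection can and cannot fit.

Four procedures establish that a recovered distribution is encoded in
the data rather than imposed by the pool or the algorithm:

* scrambling — randomly permuting the experimental couplings across
  residues must destroy the fit (best Q near or above 1);
* synthetic-target reconstruction — couplings computed from a designed
  box distribution, with Gaussian noise at a percentage of the largest
  coupling, must be recovered with the correct populations and a
  plateau ensemble size;
* alignment-magnitude error — per-conformer couplings are rescaled by
  a factor growing exponentially along the opening coordinate, up to a
  stated fold at the range endpoints, and the distribution shift is
  monitored;
* population recovery — two-state targets swept from 0 to 100%
  population map out the maximum recovery error per error level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .analysis import BasinSpec, basin_populations, build_distribution
from .ga import GAConfig, run_ga, select_ensemble_size
from .pool import ConformerPool
from .rdc import RDCSet

__all__ = [
    "SyntheticTarget",
    "scramble_rdcs",
    "make_synthetic_rdcs",
    "reconstruct_and_score",
    "tensor_error_robustness",
    "population_recovery_sweep",
    "scaled_pool_rdcs",
]

log = logging.getLogger(__name__)

#: noise ladder used for synthetic-target reconstructions, percent of
#: the maximum coupling
NOISE_LADDER_PCT = (1.0, 3.0, 6.0)

#: fold-error ladder for the alignment-magnitude robustness control
FOLD_LADDER = (2.0, 3.0, 10.0, 20.0, 50.0)


@dataclass(frozen=True)
class SyntheticTarget:
    """A designed distribution: basin boxes with target populations
    (summing to 1) and Gaussian noise as a percentage of the largest
    coupling magnitude."""

    boxes: tuple[BasinSpec, ...]
    populations: tuple[float, ...]
    noise_pct: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if len(self.boxes) != len(self.populations):
            raise ValueError("one population per box required")
        p = np.asarray(self.populations, dtype=float)
        if (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ValueError("populations must be >= 0 and sum to 1")
        if self.noise_pct < 0:
            raise ValueError("noise_pct must be >= 0")


def scramble_rdcs(exp: RDCSet, rng_seed: int | None = None) -> RDCSet:
    """Random permutation of the coupling values across keys; the value
    multiset is preserved exactly."""
    if len(exp) < 2:
        raise ValueError("need >= 2 records to scramble")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(len(exp))
    return exp.with_values(exp.values[perm], origin="synthetic")


def make_synthetic_rdcs(pool: ConformerPool, target: SyntheticTarget) -> RDCSet:
    """Couplings of the designed distribution: the population-weighted
    mean of the cached conformer couplings over each box (uniform
    within a box), plus Gaussian noise with standard deviation
    ``noise_pct`` percent of the maximum coupling magnitude.

    The returned set carries the per-box generating conformer indices
    as the attribute ``generator_indices``.
    """
    if pool.rdc_matrix is None:
        raise ValueError("pool RDCs not precomputed")
    total = np.zeros(pool.rdc_matrix.shape[1])
    generators = {}
    for box, p in zip(target.boxes, target.populations):
        idx = pool.in_box((box.ampbd_range, box.lid_range))
        if idx.size == 0:
            raise ValueError(f"synthetic box {box.label!r} contains no pool conformer")
        generators[box.label] = idx
        total += p * pool.rdc_matrix[idx].mean(axis=0)
    rng = np.random.default_rng(target.rng_seed)
    sigma = target.noise_pct / 100.0 * np.abs(total).max()
    values = total + rng.normal(0.0, sigma, size=total.shape)
    out = RDCSet.from_arrays(pool.rdc_keys, values, origin="synthetic")
    out.generator_indices = generators
    return out


def reconstruct_and_score(
    pool: ConformerPool,
    target: SyntheticTarget,
    config: GAConfig | None = None,
    sizes: tuple[int, ...] = (1, 2, 4, 8, 16, 32),
    n_holdout_sets: int = 3,
    runs_per_set: int = 3,
    bin_width: float = 2.0,
    score_margin: float = 5.0,
):
    """Full reconstruction of a synthetic target.

    Runs ensemble-size selection on the synthetic couplings, re-runs
    the GA at the selected size, and reports the recovered distribution
    and per-box population errors.

    Selected ensembles reproduce a box's average couplings, so their
    members scatter in a basin around the target box; populations are
    counted over the boxes dilated by ``score_margin`` degrees (the
    basin convention; 5 degrees by default, one third of a typical
    15-degree target box).

    Returns (distribution, errors, n_star, populations) where errors
    maps each box label to |recovered - target| population.
    """
    if config is None:
        config = GAConfig.scaled()
    synth = make_synthetic_rdcs(pool, target)
    n_star, summaries = select_ensemble_size(
        pool, synth, config, sizes=sizes,
        n_holdout_sets=n_holdout_sets, runs_per_set=runs_per_set,
    )
    result = run_ga(pool, synth, n_star, config)
    dist = build_distribution(result, pool, bin_width)
    score_boxes = [
        BasinSpec(
            box.label,
            (max(0.0, box.ampbd_range[0] - score_margin),
             min(180.0, box.ampbd_range[1] + score_margin)),
            (max(0.0, box.lid_range[0] - score_margin),
             min(180.0, box.lid_range[1] + score_margin)),
        )
        for box in target.boxes
    ]
    pops = basin_populations(dist, score_boxes)
    errors = {
        box.label: abs(pops[box.label] - p)
        for box, p in zip(target.boxes, target.populations)
    }
    return dist, errors, n_star, pops


def scaled_pool_rdcs(pool: ConformerPool, fold: float) -> ConformerPool:
    """Copy of the pool whose cached couplings are multiplied by an
    alignment-magnitude error growing exponentially along the opening
    coordinate.

    The error coordinate d of a conformer is its Euclidean distance
    from the pool's angle-range centre in normalized angle space
    (d = 1 at the range corners); each conformer's couplings are
    scaled by fold**d.  Scaling couplings is equivalent to scaling
    tensor magnitudes because the coupling is linear in the tensor.
    """
    if pool.rdc_matrix is None:
        raise ValueError("pool RDCs not precomputed")
    lo = pool.angles.min(axis=0)
    hi = pool.angles.max(axis=0)
    centre = 0.5 * (lo + hi)
    half = np.maximum(0.5 * (hi - lo), 1e-9)
    u = (pool.angles - centre) / half
    d = np.linalg.norm(u, axis=1) / np.sqrt(2.0)
    scale = np.asarray(fold, dtype=float) ** np.clip(d, 0.0, 1.0)
    out = ConformerPool(
        pool.conformers, pool.domains, angles=pool.angles,
        seed_info=dict(pool.seed_info, tensor_error_fold=fold),
    )
    out.tensors = pool.tensors
    out.rdc_keys = pool.rdc_keys
    out.rdc_matrix = pool.rdc_matrix * scale[:, None]
    return out


def tensor_error_robustness(
    pool: ConformerPool,
    exp: RDCSet,
    n_size: int,
    folds: tuple[float, ...] = FOLD_LADDER,
    config: GAConfig | None = None,
    basins=None,
    bin_width: float = 2.0,
):
    """Distributions recovered when the alignment magnitude carries a
    systematic error of the given folds along the opening coordinate.

    Returns a dict fold -> (distribution, populations); fold 1.0 (the
    unperturbed reference, always included first) uses the same seeds,
    so any shift is attributable to the injected error alone.
    """
    if config is None:
        config = GAConfig.scaled()
    out = {}
    for fold in (1.0, *folds):
        perturbed = scaled_pool_rdcs(pool, fold)
        result = run_ga(perturbed, exp, n_size, config)
        dist = build_distribution(result, perturbed, bin_width)
        pops = basin_populations(dist, basins) if basins is not None else None
        out[fold] = (dist, pops)
        log.info("tensor-error fold %g done", fold)
    return out


def bisection_basins(closed: BasinSpec, open_: BasinSpec):
    """Two half-plane scoring basins splitting angle space between two
    disjoint state boxes.

    Selected ensembles match a target box's *average* couplings, so
    their members scatter around the box rather than inside it; state
    populations are therefore counted over a partition of angle space
    (everything on the closed side vs everything on the open side), as
    when classifying a recovered distribution into closed/open states.
    The split runs along the angle axis with the wider gap between the
    boxes, at the gap midpoint.
    """
    gap_a = max(open_.ampbd_range[0] - closed.ampbd_range[1],
                closed.ampbd_range[0] - open_.ampbd_range[1])
    gap_l = max(open_.lid_range[0] - closed.lid_range[1],
                closed.lid_range[0] - open_.lid_range[1])
    if max(gap_a, gap_l) <= 0:
        raise ValueError("state boxes must be separated along one angle axis")
    if gap_a >= gap_l:
        lo_first = closed.ampbd_range[1] <= open_.ampbd_range[0]
        edges = (closed.ampbd_range[1], open_.ampbd_range[0]) if lo_first else \
                (open_.ampbd_range[1], closed.ampbd_range[0])
        mid = 0.5 * (edges[0] + edges[1])
        lo_basin = BasinSpec("closed" if lo_first else "open", (0.0, mid), (0.0, 180.0))
        hi_basin = BasinSpec("open" if lo_first else "closed", (mid, 180.0), (0.0, 180.0))
    else:
        lo_first = closed.lid_range[1] <= open_.lid_range[0]
        edges = (closed.lid_range[1], open_.lid_range[0]) if lo_first else \
                (open_.lid_range[1], closed.lid_range[0])
        mid = 0.5 * (edges[0] + edges[1])
        lo_basin = BasinSpec("closed" if lo_first else "open", (0.0, 180.0), (0.0, mid))
        hi_basin = BasinSpec("open" if lo_first else "closed", (0.0, 180.0), (mid, 180.0))
    closed_basin = lo_basin if lo_basin.label == "closed" else hi_basin
    open_basin = hi_basin if hi_basin.label == "open" else lo_basin
    return closed_basin, open_basin


def population_recovery_sweep(
    pool: ConformerPool,
    basins: tuple[BasinSpec, BasinSpec],
    n_size: int = 16,
    step: float = 0.05,
    folds: tuple[float, ...] = FOLD_LADDER,
    config: GAConfig | None = None,
    noise_pct: float = 0.0,
    bin_width: float = 2.0,
):
    """Maximum population-recovery error as a function of
    alignment-magnitude error.

    For each true closed-state population p on a [0, 1] grid with the
    given step, synthetic couplings for a two-box target (populations
    p and 1-p) are built and refit on pools carrying each fold error.
    Recovered populations are counted over the half-plane partition of
    :func:`bisection_basins` and compared with p.

    Returns (per-fold max |recovered - true|, per-fold recovery curves).
    """
    closed, open_ = basins
    if closed.overlaps(open_):
        raise ValueError("sweep basins must be disjoint")
    closed_score, open_score = bisection_basins(closed, open_)
    if config is None:
        config = GAConfig.scaled()
    ps = np.round(np.arange(0.0, 1.0 + 1e-9, step), 10)
    pools = {fold: scaled_pool_rdcs(pool, fold) for fold in (1.0, *folds)}
    max_dev, curves = {}, {}
    for fold, perturbed in pools.items():
        devs = np.empty(len(ps))
        for i, p in enumerate(ps):
            # degenerate weights: a single-box target at the endpoints
            if p <= 0.0:
                target = SyntheticTarget((open_,), (1.0,), noise_pct, config.rng_seed + i)
            elif p >= 1.0:
                target = SyntheticTarget((closed,), (1.0,), noise_pct, config.rng_seed + i)
            else:
                target = SyntheticTarget(
                    (closed, open_), (float(p), float(1.0 - p)), noise_pct,
                    config.rng_seed + i,
                )
            synth = make_synthetic_rdcs(pool, target)  # truth from the clean pool
            result = run_ga(perturbed, synth, n_size, config)
            pops = basin_populations(
                build_distribution(result, perturbed, bin_width),
                (closed_score, open_score),
            )
            devs[i] = abs(pops["closed"] - p)
        max_dev[fold] = float(devs.max())
        curves[fold] = dict(zip(ps.tolist(), devs.tolist()))
        log.info("sweep fold %g: max deviation %.3f", fold, max_dev[fold])
    return max_dev, curves
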