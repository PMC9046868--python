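"""Derived quantities: burden, heterogeneity, phases, resistance, zoning.

All metrics operate either on a single 4D density snapshot or on the
recorded burden time series.  Heterogeneity is quantified by the variance
(trace of the covariance) of the mass-weighted structural distribution and
by the number of modes of the structural marginal; the treatment response
is summarized by a shrink/MRD/regrow phase segmentation and the
time-to-resistance (first return to the pre-treatment burden); spatial
zoning of the six subpopulations is quantified by pairwise cosine overlap
of their spatial density fields and a scalar zonation index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ContractViolationError, MetricUndefinedError
from .geometry import GridSpec, SubpopulationAtlas, classify_grid

PHASE_LABELS = ("shrink", "MRD", "regrow")


@dataclass
class MetricsReport:
    """Summary of one trajectory's derived quantities."""

    time_to_resistance: float | None
    phases: list                      # (label, t_start, t_end)
    variance_series: np.ndarray
    mode_count_series: np.ndarray
    fraction_series: dict             # name -> series over snapshots
    snapshot_times: np.ndarray
    zoning_overlap: np.ndarray        # 6x6, final snapshot
    zonation_index: float
    n_cycles: int = 0                 # adaptive on->off->on cycles


# ---------------------------------------------------------------- burden

def total_mass(c: np.ndarray, grid: GridSpec) -> float:
    """Tumor burden: 4D midpoint quadrature of the density."""
    c = np.asarray(c)
    expected = (grid.n_spatial, grid.n_spatial, grid.n_structural, grid.n_structural)
    if c.shape != expected:
        raise ContractViolationError(f"density shape {c.shape} != {expected}")
    if np.any(c < 0):
        raise ContractViolationError("density must be nonnegative")
    return float(c.sum() * grid.cell_volume_4d)


def structural_marginal(c: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Density integrated over space: (ny, ny); integrates to total mass."""
    c = np.asarray(c)
    expected = (grid.n_spatial, grid.n_spatial, grid.n_structural, grid.n_structural)
    if c.shape != expected:
        raise ContractViolationError(f"density shape {c.shape} != {expected}")
    return c.sum(axis=(0, 1)) * grid.spatial_cell_area


def subpop_fractions(c: np.ndarray, atlas: SubpopulationAtlas, grid: GridSpec) -> dict:
    """Mass fraction classified to each subpopulation (plus 'unassigned').

    Classification is by structural cell center; with zero total mass all
    fractions are 0 and the 'undefined' flag is set.
    """
    marg = structural_marginal(c, grid)
    total = marg.sum() * grid.structural_cell_area
    labels = classify_grid(grid, atlas)
    out = {name: 0.0 for name in atlas.names}
    out["unassigned"] = 0.0
    if total <= 0:
        out["undefined"] = True
        return out
    out["undefined"] = False
    for i, name in enumerate(atlas.names):
        out[name] = float(marg[labels == i].sum() * grid.structural_cell_area / total)
    out["unassigned"] = float(marg[labels == -1].sum() * grid.structural_cell_area / total)
    return out


# -------------------------------------------------------- heterogeneity

def heterogeneity_variance(c: np.ndarray, grid: GridSpec) -> float:
    """Trace of the mass-weighted covariance of the structural coordinates."""
    marg = structural_marginal(c, grid)
    w = marg * grid.structural_cell_area
    total = w.sum()
    if total <= 0:
        raise MetricUndefinedError("heterogeneity variance undefined for zero mass")
    y1, y2 = grid.structural_mesh()
    m1 = (w * y1).sum() / total
    m2 = (w * y2).sum() / total
    return float((w * ((y1 - m1) ** 2 + (y2 - m2) ** 2)).sum() / total)


def count_modes(
    marginal: np.ndarray,
    smooth_width: float = 2.0,
    rel_threshold: float = 0.05,
) -> int:
    """Count strict 8-neighbor local maxima of the smoothed marginal.

    ``smooth_width`` is the Gaussian smoothing radius in grid cells;
    maxima below ``rel_threshold`` of the global maximum are ignored.
    """
    m = np.asarray(marginal, dtype=float)
    if np.any(m < 0):
        raise ContractViolationError("marginal must be nonnegative")
    if m.max() <= 0:
        return 0
    sm = ndimage.gaussian_filter(m, sigma=smooth_width, mode="nearest")
    peak = sm.max()
    if peak <= 0:
        return 0
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neigh_max = ndimage.maximum_filter(sm, footprint=footprint, mode="constant", cval=-np.inf)
    strict = (sm > neigh_max) & (sm >= rel_threshold * peak)
    return int(strict.sum())


# ------------------------------------------------------------ time series

def time_to_resistance(
    mass_series: np.ndarray,
    times: np.ndarray,
    baseline: float,
    start: float = 0.0,
    response_threshold: float = 0.05,
) -> float | None:
    """First day after ``start`` when the burden re-establishes ``baseline``.

    Resistance presupposes a response: the search for the upward baseline
    crossing begins once the burden has dropped below
    ``(1 - response_threshold) * baseline``.  If the tumor never responds,
    resistance is immediate (the first recorded time after ``start``).
    Crossings are linearly interpolated between samples; None if the
    baseline is never regained.
    """
    mass = np.asarray(mass_series, dtype=float)
    times = np.asarray(times, dtype=float)
    if mass.size == 0 or mass.size != times.size:
        raise ContractViolationError("mass series empty or misaligned with times")
    after = times > start
    below = np.nonzero(after & (mass < (1.0 - response_threshold) * baseline))[0]
    if below.size == 0:
        # the burden never responded: resistance is immediate
        i = int(np.nonzero(after)[0][0]) if after.any() else None
        return None if i is None else float(times[i])
    j0 = int(below[0])
    idx = np.nonzero((times > times[j0]) & (mass >= baseline))[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    t0, t1 = times[i - 1], times[i]
    m0, m1 = mass[i - 1], mass[i]
    if m1 > m0:
        return float(t0 + (baseline - m0) / (m1 - m0) * (t1 - t0))
    return float(times[i])


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x.astype(float), pad, mode="edge")
    sm = np.convolve(xp, kernel, mode="same")[pad: pad + x.size]
    return sm


def segment_phases(
    mass_series: np.ndarray,
    times: np.ndarray,
    slope_tol: float = 0.002,
    min_duration: float = 10.0,
) -> list:
    """Segment the burden curve into shrink / MRD / regrow phases.

    The series is smoothed with a moving average spanning ``min_duration``
    days; each sample is classified by the sign of the slope against
    ``+-slope_tol * M0`` per day; runs shorter than ``min_duration`` are
    merged into their neighbors.  Returns maximal (label, t_start, t_end)
    runs partitioning the time span.
    """
    mass = np.asarray(mass_series, dtype=float)
    times = np.asarray(times, dtype=float)
    if mass.size < 3:
        raise ContractViolationError("mass series must have at least 3 samples")
    dt = np.median(np.diff(times))
    window = max(1, int(round(min_duration / dt)))
    if window >= mass.size:
        raise ContractViolationError("mass series shorter than the smoothing window")
    sm = _moving_average(mass, window)
    slope = np.gradient(sm, times)
    m0 = mass[0] if mass[0] > 0 else max(mass.max(), 1.0)
    tol = slope_tol * m0
    labels = np.where(slope > tol, 2, np.where(slope < -tol, 0, 1))

    # maximal runs
    runs = []  # [label, i_start, i_end] inclusive
    start = 0
    for i in range(1, labels.size + 1):
        if i == labels.size or labels[i] != labels[start]:
            runs.append([int(labels[start]), start, i - 1])
            start = i

    # merge runs shorter than min_duration into the longer neighbor
    def duration(run):
        return times[run[2]] - times[run[1]]

    changed = True
    while changed and len(runs) > 1:
        changed = False
        for j, run in enumerate(runs):
            if duration(run) < min_duration:
                if j == 0:
                    neighbor = 1
                elif j == len(runs) - 1:
                    neighbor = j - 1
                else:
                    neighbor = j - 1 if duration(runs[j - 1]) >= duration(runs[j + 1]) else j + 1
                runs[neighbor][1] = min(runs[neighbor][1], run[1])
                runs[neighbor][2] = max(runs[neighbor][2], run[2])
                runs.pop(j)
                # re-merge adjacent runs with equal labels
                k = 1
                while k < len(runs):
                    if runs[k][0] == runs[k - 1][0]:
                        runs[k - 1][2] = runs[k][2]
                        runs.pop(k)
                    else:
                        k += 1
                changed = True
                break

    return [(PHASE_LABELS[label], float(times[i0]), float(times[i1])) for label, i0, i1 in runs]


def resistance_onset_from_phases(phases: list) -> float | None:
    """Start of the final regrow phase, if any."""
    for label, t0, _ in reversed(phases):
        if label == "regrow":
            return t0
    return None


def count_onoff_cycles(treatment_on: np.ndarray) -> int:
    """Number of complete on->off->on cycles in an adaptive dosing record."""
    on = np.asarray(treatment_on, dtype=bool).astype(int)
    if on.size < 3:
        return 0
    switches = np.diff(on)
    offs = np.nonzero(switches == -1)[0]
    ons = np.nonzero(switches == 1)[0]
    # a cycle = an off switch later followed by an on switch
    return int(sum(1 for i in offs if np.any(ons > i)))


# ----------------------------------------------------------------- zoning

def zoning_overlap(
    c_snapshot: np.ndarray,
    atlas: SubpopulationAtlas,
    grid: GridSpec,
    min_fraction: float = 0.005,
):
    """Pairwise spatial cosine overlap of the six subpopulations.

    For each subpopulation the spatial density m_s(x) integrates the 4D
    density over that state's structural disc.  The overlap matrix holds
    spatial cosine similarities (0 when either field vanishes, 1 on the
    diagonal for nonzero fields); the zonation index is 1 minus the mean
    off-diagonal overlap over pairs of *occupied* states.  A state counts
    as occupied when it carries at least ``min_fraction`` of the total
    mass: the numerical residue of an extinct subpopulation has no spatial
    pattern worth comparing.  Returns
    (overlap_matrix, zonation_index, fields_by_name).
    """
    c = np.asarray(c_snapshot)
    total = total_mass(c, grid)
    if total <= 0:
        raise MetricUndefinedError("zoning undefined for zero total mass")
    labels = classify_grid(grid, atlas)
    names = atlas.names
    fields = {}
    for i, name in enumerate(names):
        mask = labels == i
        fields[name] = c[:, :, mask].sum(axis=-1) * grid.structural_cell_area
    flat = np.stack([fields[n].ravel() for n in names])
    norms = np.linalg.norm(flat, axis=1)
    masses = flat.sum(axis=1) * grid.spatial_cell_area
    k = len(names)
    overlap = np.eye(k)
    nonzero = norms > 0
    occupied = masses >= min_fraction * total
    for i in range(k):
        for j in range(i + 1, k):
            if nonzero[i] and nonzero[j]:
                overlap[i, j] = overlap[j, i] = float(
                    flat[i] @ flat[j] / (norms[i] * norms[j])
                )
            else:
                overlap[i, j] = overlap[j, i] = 0.0
    pairs = [
        overlap[i, j]
        for i in range(k)
        for j in range(i + 1, k)
        if occupied[i] and occupied[j]
    ]
    if not pairs:
        raise MetricUndefinedError("zonation index undefined: fewer than two occupied states")
    index = float(1.0 - np.mean(pairs))
    return overlap, index, fields


# ------------------------------------------------------------- reporting

def compute_report(trajectory, grid=None, atlas=None, settings: dict | None = None) -> MetricsReport:
    """Full metrics report for a recorded trajectory."""
    from .config import as_scenario

    scn = as_scenario(trajectory.config)
    grid = grid or scn.grid()
    atlas = atlas or scn.atlas()
    s = {**scn.section("metrics"), **(settings or {})}
    schedule = scn.schedule()

    variances, modes, fracs = [], [], []
    for snap in trajectory.snapshots:
        marg = structural_marginal(snap.c, grid)
        variances.append(heterogeneity_variance(snap.c, grid))
        modes.append(count_modes(marg, s["smooth_width"], s["mode_rel_threshold"]))
        fracs.append(subpop_fractions(snap.c, atlas, grid))
    fraction_series = {
        name: np.asarray([f[name] for f in fracs]) for name in atlas.names + ("unassigned",)
    }
    # the response curve is segmented from treatment start; the resistance
    # baseline is the burden at that instant
    i0 = int(np.searchsorted(trajectory.times, schedule.start_time))
    i0 = min(i0, trajectory.mass.size - 3)
    phases = segment_phases(
        trajectory.mass[i0:], trajectory.times[i0:], s["slope_tol"], s["min_phase_duration"]
    )
    baseline = float(trajectory.mass[i0])
    ttr = time_to_resistance(
        trajectory.mass, trajectory.times, baseline, start=schedule.start_time
    )
    overlap, index, _ = zoning_overlap(trajectory.snapshots[-1].c, atlas, grid)
    return MetricsReport(
        time_to_resistance=ttr,
        phases=phases,
        variance_series=np.asarray(variances),
        mode_count_series=np.asarray(modes),
        fraction_series=fraction_series,
        snapshot_times=np.asarray(trajectory.snapshot_times),
        zoning_overlap=overlap,
        zonation_index=index,
        n_cycles=count_onoff_cycles(trajectory.treatment_on),
    )
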