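"""Circular-statistics analysis of torsion ensembles and water-site dynamics.

Torsion traces are circular data on (-180, 180]; densities use von Mises
kernels (the circular analogue of a Gaussian) on a periodic grid, with a
plug-in rule for the kernel concentration when none is given.  The 2D case
lives on the torus and is clustered by density peaks: frames are assigned
to the peak reached by steepest ascent on the smoothed density — a
deterministic, seed-free procedure that mirrors how contour-plot clusters
are read by eye.

The catalytic-water site is described in the radial coordinates (r, theta):
r is the distance from the ligand C5 to the water oxygen and theta the
torsion C4-C5-O_w-midpoint(H1, H2).  A residence trace thresholds r to
classify, frame by frame, whether the water occupies the pocket above the
ligand plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from . import geometry
from .geometry import wrap_degrees
from .structure_io import StructureModel

__all__ = [
    "TorsionSpec",
    "TorsionSeries",
    "CircularDensity",
    "TorsionCluster",
    "WaterSiteCoordinate",
    "ResidenceTrace",
    "torsion_series",
    "circular_density_1d",
    "density_modes",
    "torsion_density_2d",
    "cluster_torsions_2d",
    "water_site_coordinates",
    "residence_trace",
    "state_coupling",
    "circular_mean_deg",
    "plugin_concentration",
]


# ---------------------------------------------------------------------------
# torsion traces


@dataclass(frozen=True)
class TorsionSpec:
    """Four atom roles defining a named dihedral, e.g. Thr CA-CB-OG1-HG1."""

    label: str
    atoms: tuple  # four (chain, resnum, atomname[, altloc]) roles

    def resolve(self, model: StructureModel) -> list:
        idx = []
        for role in self.atoms:
            chain, resnum, name = role[0], int(role[1]), role[2]
            altloc = role[3] if len(role) > 3 else None
            a = model.atom(str(chain), resnum, name, altloc)
            if a is None:
                raise ValueError(
                    f"torsion {self.label!r}: atom {role} not found in model"
                )
            idx.append(a.index)
        return idx


@dataclass
class TorsionSeries:
    label: str
    values: np.ndarray  # degrees on (-180, 180]
    frames: np.ndarray  # frame indices

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.frames = np.asarray(self.frames, dtype=int)
        self.values = np.asarray(wrap_degrees(self.values))

    def __len__(self):
        return len(self.values)


def torsion_series(ensemble: StructureModel, spec: TorsionSpec) -> TorsionSeries:
    """Evaluate one dihedral across every frame of an ensemble (vectorized)."""
    ia, ib, ic, id_ = spec.resolve(ensemble)
    c = ensemble.coords
    vals = geometry.torsion(c[:, ia], c[:, ib], c[:, ic], c[:, id_])
    return TorsionSeries(spec.label, np.atleast_1d(vals),
                         np.arange(ensemble.n_frames))


def circular_mean_deg(values_deg) -> float:
    """Circular mean of angles in degrees, on (-180, 180]."""
    r = np.radians(np.asarray(values_deg, dtype=float))
    return float(wrap_degrees(np.degrees(
        np.arctan2(np.mean(np.sin(r)), np.mean(np.cos(r))))))


def _mean_resultant_length(values_deg) -> float:
    r = np.radians(np.asarray(values_deg, dtype=float))
    return float(np.hypot(np.mean(np.sin(r)), np.mean(np.cos(r))))


def _kappa_from_rbar(rbar: float) -> float:
    # Fisher's approximation to the inverse of A(kappa) = I1/I0
    rbar = min(rbar, 1.0 - 1e-6)  # degenerate (constant) samples
    if rbar < 1e-9:
        return 1e-9
    if rbar < 0.53:
        return 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)


def plugin_concentration(values_deg) -> float:
    """Plug-in von Mises kernel concentration (Taylor's circular rule).

    Fits a reference von Mises of concentration kappa-hat to the sample and
    returns the AMISE-optimal kernel concentration
    ``nu = [3 n kh^2 I2(2 kh) / (4 sqrt(pi) I0(kh)^2)]^(2/5)``.
    Mildly oversmooths multimodal data, as reference rules do; callers can
    always pass an explicit concentration.
    """
    n = len(np.asarray(values_deg))
    kh = _kappa_from_rbar(_mean_resultant_length(values_deg))
    kh = min(kh, 1e4)  # guard against near-degenerate samples
    # scaled Bessels: iv(2, 2k)/iv(0, k)^2 = ive(2, 2k)/ive(0, k)^2 exactly
    ratio = special.ive(2, 2 * kh) / special.ive(0, kh) ** 2
    nu = (3.0 * n * kh**2 * ratio / (4.0 * np.sqrt(np.pi))) ** 0.4
    return float(min(max(nu, 1e-3), 1e6))


@dataclass
class CircularDensity:
    """Normalized density on a periodic grid (1D circle or 2D torus).

    ``grid`` holds bin-center angles in degrees; ``values`` the density per
    degree (1D) or per square degree (2D).  ``sum(values) * step**ndim == 1``
    to 1e-9.
    """

    grid: tuple  # (angles,) or (angles_x, angles_y)
    values: np.ndarray
    concentration: tuple
    step: float

    @property
    def ndim(self) -> int:
        return self.values.ndim


def _vm_kernel_profile(grid_deg: np.ndarray, kappa: float) -> np.ndarray:
    """Von Mises kernel evaluated on a centered angular grid, density/degree."""
    r = np.radians(grid_deg)
    if kappa > 700:  # avoid overflow; exp(kappa(cos-1)) / (2 pi I0 e^-k)
        logk = kappa * (np.cos(r) - 1.0) - np.log(
            2 * np.pi * special.i0e(kappa))
        prof = np.exp(logk)
    else:
        prof = np.exp(kappa * np.cos(r)) / (2 * np.pi * special.i0(kappa))
    return prof * np.pi / 180.0  # radians^-1 -> degrees^-1


def circular_density_1d(
    s: TorsionSeries,
    concentration: float | None = None,
    grid_step: float = 1.0,
) -> CircularDensity:
    """Von Mises kernel density of a torsion trace on the full circle.

    The kernel concentration defaults to the plug-in rule.  Exact kernel
    sums are used up to moderate sample sizes; above that the sample is
    binned at grid resolution and convolved circularly (error far below
    line thickness), then renormalized exactly.
    """
    if len(s) < 1:
        raise ValueError("circular_density_1d(): empty series")
    if concentration is not None and concentration <= 0:
        raise ValueError("circular_density_1d(): concentration must be > 0")
    kappa = concentration if concentration is not None else plugin_concentration(s.values)
    nbin = int(round(360.0 / grid_step))
    grid = -180.0 + grid_step * (np.arange(nbin) + 0.5)
    x = s.values
    if len(x) * nbin <= 2_000_000:
        diffs = grid[:, None] - x[None, :]
        dens = _vm_kernel_profile(diffs, kappa).mean(axis=1)
    else:
        hist, _ = np.histogram(x, bins=np.linspace(-180, 180, nbin + 1))
        prof = _vm_kernel_profile(wrap_degrees(grid - grid[0]), kappa)
        dens = np.real(np.fft.ifft(np.fft.fft(hist) * np.fft.fft(prof))) / len(x)
    dens = np.maximum(dens, 0.0)
    dens /= dens.sum() * grid_step
    return CircularDensity((grid,), dens, (kappa,), grid_step)


def density_modes(d: CircularDensity, min_height: float = 1e-6) -> list:
    """Strict local maxima of a 1D circular density, highest first.

    Ties are broken by angle ascending.  Maxima below *min_height* times
    the global maximum are discarded (they are floating-point ripple in
    near-zero density regions).  A flat (uniform) density has no strict
    mode and yields an empty list.
    """
    if d.ndim != 1:
        raise ValueError("density_modes(): 1D density required")
    v = d.values
    left = np.roll(v, 1)
    right = np.roll(v, -1)
    is_mode = (v > left) & (v > right) & (v >= min_height * v.max())
    angles = d.grid[0][is_mode]
    heights = v[is_mode]
    order = np.lexsort((angles, -heights))
    return [(float(angles[i]), float(heights[i])) for i in order]


def torsion_density_2d(
    a: TorsionSeries,
    b: TorsionSeries,
    concentration: tuple | None = None,
    grid_step: float = 2.0,
) -> CircularDensity:
    """Toroidal kernel density of an angle-pair series.

    Product von Mises kernel; computed by binning onto the torus grid and
    circular FFT convolution, then exact renormalization.
    """
    if len(a) != len(b):
        raise ValueError("torsion_density_2d(): series length mismatch")
    if len(a) == 0:
        raise ValueError("torsion_density_2d(): empty series")
    ka, kb = concentration or (plugin_concentration(a.values),
                               plugin_concentration(b.values))
    if ka <= 0 or kb <= 0:
        raise ValueError("torsion_density_2d(): concentrations must be > 0")
    nbin = int(round(360.0 / grid_step))
    edges = np.linspace(-180, 180, nbin + 1)
    grid = -180.0 + grid_step * (np.arange(nbin) + 0.5)
    hist, _, _ = np.histogram2d(a.values, b.values, bins=(edges, edges))
    prof_a = _vm_kernel_profile(wrap_degrees(grid - grid[0]), ka)
    prof_b = _vm_kernel_profile(wrap_degrees(grid - grid[0]), kb)
    kernel = np.outer(prof_a, prof_b)
    dens = np.real(np.fft.ifft2(np.fft.fft2(hist) * np.fft.fft2(kernel))) / len(a)
    dens = np.maximum(dens, 0.0)
    dens /= dens.sum() * grid_step**2
    return CircularDensity((grid, grid), dens, (ka, kb), grid_step)


# ---------------------------------------------------------------------------
# toroidal clustering


@dataclass
class TorsionCluster:
    cluster_id: int
    center: tuple  # (deg, deg) circular means of members
    peak: tuple  # (deg, deg) density-peak location
    labels_mask: np.ndarray  # boolean per frame
    population: float  # member fraction of all frames

    @property
    def n_members(self) -> int:
        return int(self.labels_mask.sum())


def _ascend_basins(dens: np.ndarray) -> np.ndarray:
    """Label every grid cell with the local maximum reached by steepest ascent.

    8-neighborhood with periodic wrap; deterministic (ties go to the first
    neighbor in a fixed scan order).  Returns an int array of flat peak
    indices, one per cell.
    """
    n, m = dens.shape
    shifts = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)]
    stacked = np.stack(
        [np.roll(np.roll(dens, di, axis=0), dj, axis=1) for di, dj in shifts]
    )
    best = np.argmax(stacked, axis=0)  # index into shifts; 4 == (0,0) == stay
    # move only strictly uphill: plateaus are their own peaks, so the
    # pointer chain strictly increases in density and can never cycle
    stay = stacked.max(axis=0) <= dens
    best = np.where(stay, 4, best)
    di = np.array([s[0] for s in shifts])[best]
    dj = np.array([s[1] for s in shifts])[best]
    ii, jj = np.meshgrid(np.arange(n), np.arange(m), indexing="ij")
    nxt = ((ii - di) % n) * m + ((jj - dj) % m)  # roll by +1 moves source -1
    nxt = nxt.ravel()
    # pointer jumping until fixed point
    for _ in range(64):
        nn = nxt[nxt]
        if np.array_equal(nn, nxt):
            break
        nxt = nn
    return nxt.reshape(n, m)


def cluster_torsions_2d(
    a: TorsionSeries,
    b: TorsionSeries,
    concentration: tuple | None = None,
    grid_step: float = 2.0,
    density_floor: float = 0.05,
    min_population: float = 0.01,
) -> list:
    """Density-peak clustering of an angle-pair series on the torus.

    The smoothed toroidal density is segmented into basins of attraction of
    its local maxima; each frame inherits the basin of its grid cell.
    Peaks whose basin population is below *min_population*, and frames in
    cells below *density_floor* x (max density), are left unassigned.
    Entirely deterministic — no seed.

    Returns a list of :class:`TorsionCluster` sorted by population
    descending; unassigned frames appear in no cluster.
    """
    d = torsion_density_2d(a, b, concentration, grid_step)
    dens = d.values
    basins = _ascend_basins(dens)
    nbin = dens.shape[0]
    ix = np.clip(((a.values + 180.0) / grid_step).astype(int), 0, nbin - 1)
    iy = np.clip(((b.values + 180.0) / grid_step).astype(int), 0, nbin - 1)
    frame_basin = basins[ix, iy]
    frame_dens = dens[ix, iy]
    floor = density_floor * dens.max()
    assigned = frame_dens >= floor
    peaks, counts = np.unique(frame_basin[assigned], return_counts=True)
    order = np.argsort(-counts)
    clusters = []
    cid = 0
    n = len(a)
    grid = d.grid[0]
    for k in order:
        frac = counts[k] / n
        if frac < min_population:
            continue
        mask = assigned & (frame_basin == peaks[k])
        center = (circular_mean_deg(a.values[mask]),
                  circular_mean_deg(b.values[mask]))
        pi, pj = divmod(int(peaks[k]), nbin)
        clusters.append(
            TorsionCluster(cid, center, (float(grid[pi]), float(grid[pj])),
                           mask, float(frac))
        )
        cid += 1
    return clusters


def cluster_label_array(clusters: list, n_frames: int) -> np.ndarray:
    """Per-frame integer labels from a cluster list (-1 = unassigned)."""
    lab = np.full(n_frames, -1, dtype=int)
    for c in clusters:
        lab[c.labels_mask] = c.cluster_id
    return lab


# ---------------------------------------------------------------------------
# water-site coordinates and residence


@dataclass
class WaterSiteCoordinate:
    """Per-frame radial coordinates of a water site.

    r: ligand C5 to water oxygen distance (Å); theta: torsion
    C4-C5-O_w-midpoint(H1, H2), degrees.
    """

    r: np.ndarray
    theta: np.ndarray
    frames: np.ndarray


def water_site_coordinates(
    ensemble: StructureModel,
    c4_role,
    c5_role,
    ow_role,
    h1_role,
    h2_role,
) -> WaterSiteCoordinate:
    """Radial (r, theta) coordinates of a water over all frames.

    Roles are (chain, resnum, atomname) triples.  All five atoms must be
    present; hydrogens are required (there is no heavy-atom fallback, since
    theta is defined through the H-midpoint).
    """
    idx = []
    for role in (c4_role, c5_role, ow_role, h1_role, h2_role):
        a = ensemble.atom(str(role[0]), int(role[1]), role[2])
        if a is None:
            raise ValueError(f"water_site_coordinates: atom {role} not found")
        idx.append(a.index)
    c = ensemble.coords
    c4, c5, ow, h1, h2 = (c[:, i] for i in idx)
    mid = 0.5 * (h1 + h2)
    r = np.linalg.norm(c5 - ow, axis=-1)
    theta = np.atleast_1d(geometry.torsion(c4, c5, ow, mid))
    return WaterSiteCoordinate(np.atleast_1d(r), theta,
                               np.arange(ensemble.n_frames))


@dataclass
class ResidenceTrace:
    inside: np.ndarray  # per-frame boolean
    r_threshold: float  # Å
    occupancy: float  # fraction of frames inside
    segments: list  # (start, length, inside?) run-length segments
    mean_inside_segment: float  # frames; nan when never inside


def residence_trace(coords: WaterSiteCoordinate, r_threshold: float = 4.0) -> ResidenceTrace:
    """Classify frames as in/out of the site by r <= threshold.

    The default 4.0 Å sits between the bound-state distance range and the
    displaced-state maximum; it is configurable and echoed in the result.
    """
    if r_threshold <= 0:
        raise ValueError("residence_trace(): threshold must be positive")
    inside = coords.r <= r_threshold
    occ = float(inside.mean())
    segments = []
    start = 0
    for i in range(1, len(inside) + 1):
        if i == len(inside) or inside[i] != inside[start]:
            segments.append((start, i - start, bool(inside[start])))
            start = i
    in_lens = [ln for _, ln, flag in segments if flag]
    mean_in = float(np.mean(in_lens)) if in_lens else float("nan")
    return ResidenceTrace(inside, r_threshold, occ, segments, mean_in)


def state_coupling(labels: np.ndarray, trace: ResidenceTrace) -> dict:
    """Association between cluster labels and water residence.

    Builds the 2 x k contingency table of (inside, outside) x cluster,
    reports exact counts, the odds ratio of a 2 x 2 collapse (largest
    cluster vs the rest) and Cramér's V.  A zero cell makes the odds ratio
    infinite; this is flagged rather than smoothed.
    """
    labels = np.asarray(labels)
    if len(labels) != len(trace.inside):
        raise ValueError("state_coupling(): label/trace length mismatch")
    keep = labels >= 0
    if not np.any(keep):
        raise ValueError("state_coupling(): no assigned frames")
    lab = labels[keep]
    ins = trace.inside[keep]
    cats = np.unique(lab)
    table = np.array(
        [[int(np.sum((lab == c) & ins)) for c in cats],
         [int(np.sum((lab == c) & ~ins)) for c in cats]]
    )
    major = cats[np.argmax(table.sum(axis=0))]
    a_ = int(np.sum((lab == major) & ins))
    b_ = int(np.sum((lab != major) & ins))
    c_ = int(np.sum((lab == major) & ~ins))
    d_ = int(np.sum((lab != major) & ~ins))
    degenerate = (b_ * c_ == 0) or (a_ * d_ == 0)
    odds = float("inf") if b_ * c_ == 0 else (a_ * d_) / (b_ * c_)
    if table.shape[1] > 1 and table.sum() > 0 and np.all(table.sum(axis=0) > 0):
        chi2 = stats.chi2_contingency(table, correction=False)[0]
        ntot = table.sum()
        v = float(np.sqrt(chi2 / (ntot * (min(table.shape) - 1))))
    else:
        v = float("nan")
    return {
        "clusters": [int(c) for c in cats],
        "table_inside": table[0].tolist(),
        "table_outside": table[1].tolist(),
        "major_cluster": int(major),
        "odds_ratio_major_inside": odds,
        "odds_ratio_degenerate": bool(degenerate),
        "cramers_v": v,
    }


def per_frame_table(
    series: dict,
    coords: WaterSiteCoordinate | None = None,
    labels: np.ndarray | None = None,
    trace: ResidenceTrace | None = None,
) -> pd.DataFrame:
    """Assemble the per-frame CSV table (torsions, r, theta, cluster, in/out)."""
    data = {}
    for label, s in series.items():
        data[label] = s.values
    if coords is not None:
        data["r_A"] = coords.r
        data["theta_deg"] = coords.theta
    if labels is not None:
        data["cluster"] = labels
    if trace is not None:
        data["inside"] = trace.inside.astype(int)
    df = pd.DataFrame(data)
    df.insert(0, "frame", np.arange(len(df)))
    return df
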