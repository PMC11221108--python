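"""Synthetic TD-fNIRS acquisition: DTOF frame series with Poisson noise.

A measurement is a sequence of DTOF frames (photon-count histograms over
time-of-flight bins) sampled at rate fs for a duration Tmeas.  Per frame,
the noiseless reflectance curve for that frame's absorption state is scaled
by one fixed factor — chosen so the *baseline* curve integrates to the
average total photon number N̄tot — and each bin is replaced by an
independent Poisson draw.  Keeping the scale factor fixed across frames is
what lets absorption oscillations modulate the detected totals (the CW
signal).  The instrument response is an ideal delta by default; a synthetic
broadened IRF can be convolved in as optional plumbing.

Detector dead-time, afterpulsing and background counts are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .forward_models import (
    BilayerGeometry,
    BilayerMuaGridInterpolator,
    OpticalProperties,
    ReflectanceCurve,
    SlabGeometry,
    TimeGrid,
    cached_mua_grids,
    slab_td_reflectance,
)
from .tissue_dynamics import (
    ExtinctionTable,
    HemoTimeSeries,
    ScatteringLaw,
    scattering_at,
)

__all__ = [
    "AcquisitionSettings",
    "DTOFSeries",
    "GateSet",
    "GatedCountsSeries",
    "gaussian_irf",
    "convolve_irf",
    "synthesize_homogeneous_series",
    "synthesize_bilayer_series",
    "synthesize_dtof_series",
    "gate_counts",
    "integrate_to_cw",
]


@dataclass(frozen=True)
class AcquisitionSettings:
    """Acquisition parameters of one synthetic measurement.

    n_tot_avg : expected total photons per DTOF at baseline (N̄tot)
    tmeas : measurement length, s
    fs : sampling rate, Hz
    sdd : source-detector distance, cm
    wavelengths : operating wavelengths, nm
    rng_seed : master seed of the per-wavelength Poisson streams
    """

    n_tot_avg: float
    tmeas: float
    fs: float
    sdd: float
    wavelengths: tuple = (690.0, 830.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tot_avg <= 0 or self.fs <= 0 or self.sdd <= 0:
            raise ValueError("n_tot_avg, fs and sdd must be > 0")
        n = self.tmeas * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("Tmeas*fs must be an integer number of frames")

    @property
    def n_frames(self) -> int:
        return int(round(self.tmeas * self.fs))


@dataclass
class DTOFSeries:
    """Frame-indexed photon-count histograms (one synthetic TD measurement)."""

    counts: np.ndarray  # (n_frames, n_bins) unsigned integers
    time_grid: TimeGrid
    frame_times: np.ndarray  # s
    wavelength: float
    sdd: float
    n_tot_avg: float
    baseline_expectation: np.ndarray  # noiseless baseline counts per bin
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.ndim != 2 or self.counts.shape[1] != self.time_grid.n_bins:
            raise ValueError("counts shape does not match the time grid")
        if np.issubdtype(self.counts.dtype, np.signedinteger):
            if self.counts.min() < 0:
                raise ValueError("negative counts")
            self.counts = self.counts.astype(np.uint32)

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]

    def frame_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1, dtype=np.int64)


@dataclass(frozen=True)
class GateSet:
    """Ordered, contiguous, half-open time windows [start, end) in ns.

    Bins are assigned to gates by bin-center membership, which makes gate
    sums conserve frame totals exactly when the gates cover the grid.
    """

    edges: tuple

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.ndim != 1 or len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("gate edges must be strictly increasing")

    @classmethod
    def uniform(cls, t_max: float = 5.0, width: float = 0.5, t_min: float = 0.0):
        """The default windowing: contiguous gates of fixed width."""
        n = int(round((t_max - t_min) / width))
        return cls(tuple(t_min + width * np.arange(n + 1)))

    @property
    def n_gates(self) -> int:
        return len(self.edges) - 1

    def intervals(self) -> list:
        e = self.edges
        return [(e[i], e[i + 1]) for i in range(self.n_gates)]

    def bin_assignment(self, grid: TimeGrid) -> np.ndarray:
        """Gate index per time bin; -1 where a bin center falls outside."""
        centers = grid.centers()
        idx = np.searchsorted(np.asarray(self.edges), centers, side="right") - 1
        idx[(idx < 0) | (idx >= self.n_gates)] = -1
        if np.all(idx < 0):
            raise ValueError("gates do not overlap the time grid")
        return idx


@dataclass
class GatedCountsSeries:
    """Per-frame, per-gate photon counts."""

    counts: np.ndarray  # (n_frames, n_gates)
    gates: GateSet
    wavelength: float
    sdd: float
    baseline_expectation: np.ndarray  # noiseless baseline counts per gate

    def baseline_mean(self) -> np.ndarray:
        """Observed mean counts per gate over all frames."""
        return self.counts.mean(axis=0)


# ---------------------------------------------------------------------------
# IRF plumbing
# ---------------------------------------------------------------------------

def gaussian_irf(grid: TimeGrid, fwhm: float, t0: float = 0.25) -> np.ndarray:
    """Unit-area Gaussian IRF sampled on the grid (fwhm, t0 in ns)."""
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    vals = np.exp(-0.5 * ((grid.centers() - t0) / sigma) ** 2)
    total = vals.sum()
    if total <= 0:
        raise ValueError("IRF support does not overlap the grid")
    return vals / total


def convolve_irf(curve: ReflectanceCurve, irf: np.ndarray) -> ReflectanceCurve:
    """Discrete causal convolution of a curve with a unit-area IRF.

    A delta IRF (single unit bin) returns the input unchanged; any unit-area
    IRF conserves the curve integral up to the part shifted past the window
    end (negligible for IRFs much shorter than the window).
    """
    irf = np.asarray(irf, dtype=float)
    if irf.shape != curve.values.shape:
        raise ValueError("IRF must be sampled on the curve's grid")
    if np.any(irf < 0):
        raise ValueError("IRF must be non-negative")
    if abs(irf.sum() - 1.0) > 1e-9:
        raise ValueError("IRF must be normalized to unit area")
    out = np.convolve(curve.values, irf)[: curve.time_grid.n_bins]
    return ReflectanceCurve(curve.time_grid, out, curve.wavelength, curve.sdd)


# ---------------------------------------------------------------------------
# synthesis
# ---------------------------------------------------------------------------

def _poisson_series(
    expectation: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    if not np.all(np.isfinite(expectation)):
        raise ValueError("non-finite expectations")
    if expectation.max() > 2**63 / 4:
        raise OverflowError("expectation too large for integer counts")
    return rng.poisson(expectation).astype(np.uint32)


def synthesize_homogeneous_series(
    hemo: HemoTimeSeries,
    geom: SlabGeometry,
    grid: TimeGrid,
    sdd: float,
    wavelength: float,
    n_tot_avg: float,
    table: ExtinctionTable,
    law: ScatteringLaw,
    rng: np.random.Generator,
    n: float = 1.4,
    layer: str = "WHOLE",
    irf: Optional[np.ndarray] = None,
) -> DTOFSeries:
    """DTOF series for the homogeneous slab via absorption factorization.

    The slab Green's function depends on μa only through exp(−μa v t), so
    per-frame curves are the μa = 0 curve times a per-frame exponential —
    exact, and far cheaper than re-evaluating the model 10⁴ times.
    """
    musp = scattering_at(law, wavelength)
    props0 = OpticalProperties(0.0, musp, n)
    base_curve = slab_td_reflectance(props0, geom, sdd, grid)
    r_zero = base_curve.values
    if irf is not None:
        r_zero = convolve_irf(
            ReflectanceCurve(grid, r_zero, wavelength, sdd), irf
        ).values
    v = props0.speed
    t = grid.centers()

    mua_t = hemo.mua(layer, wavelength, table)
    mua_base = hemo.baseline_mua(wavelength, table)
    with np.errstate(under="ignore"):
        baseline = r_zero * np.exp(-mua_base * v * t)
        scale = n_tot_avg / baseline.sum()
        expectation = (scale * r_zero) * np.exp(-np.outer(mua_t, v * t))
    counts = _poisson_series(expectation, rng)
    return DTOFSeries(
        counts,
        grid,
        hemo.times,
        wavelength,
        sdd,
        n_tot_avg,
        baseline_expectation=scale * baseline,
        meta={"geometry": "homogeneous", "musp": musp},
    )


def synthesize_bilayer_series(
    hemo: HemoTimeSeries,
    geom: BilayerGeometry,
    grid: TimeGrid,
    sdd: float,
    wavelength: float,
    n_tot_avg: float,
    table: ExtinctionTable,
    law: ScatteringLaw,
    rng: np.random.Generator,
    n: float = 1.4,
    interp: Optional[BilayerMuaGridInterpolator] = None,
    grid_sdds: Optional[tuple] = None,
) -> DTOFSeries:
    """DTOF series for the bilayer cylinder via the precomputed μa grid.

    Per-frame curves are bilinear interpolations of log R on a small
    (μa_up, μa_dw) grid around the baseline (the perturbations stay within
    ±1% of baseline absorption).  Pass ``grid_sdds`` to precompute the grids
    for several SDDs in one go (the eigen-decomposition is shared).
    """
    musp = scattering_at(law, wavelength)
    mua_base = hemo.baseline_mua(wavelength, table)
    if interp is None:
        props = OpticalProperties(mua_base, musp, n)
        sdds = grid_sdds if grid_sdds is not None else (sdd,)
        interp = cached_mua_grids(props, props, geom, tuple(sdds), grid)[sdd]

    mua_up = hemo.mua("UP", wavelength, table)
    mua_dw = hemo.mua("DW", wavelength, table)
    curves = interp.curves(mua_up, mua_dw)
    baseline = interp.curves(np.array([mua_base]), np.array([mua_base]))[0]
    scale = n_tot_avg / baseline.sum()
    counts = _poisson_series(scale * curves, rng)
    return DTOFSeries(
        counts,
        grid,
        hemo.times,
        wavelength,
        sdd,
        n_tot_avg,
        baseline_expectation=scale * baseline,
        meta={"geometry": "bilayer", "musp": musp},
    )


def synthesize_dtof_series(
    hemo: HemoTimeSeries,
    geometry: Union[SlabGeometry, BilayerGeometry],
    grid: TimeGrid,
    settings: AcquisitionSettings,
    table: ExtinctionTable,
    law: ScatteringLaw,
    n: float = 1.4,
) -> dict:
    """Synthesize one DTOF series per wavelength.

    One independent Poisson stream per wavelength, spawned from the
    settings' master seed in wavelength order.
    """
    if hemo.n_frames != settings.n_frames:
        raise ValueError("hemo series length does not match acquisition settings")
    streams = np.random.SeedSequence(settings.rng_seed).spawn(
        len(settings.wavelengths)
    )
    out = {}
    for wl, ss in zip(settings.wavelengths, streams):
        rng = np.random.default_rng(ss)
        if isinstance(geometry, SlabGeometry):
            out[wl] = synthesize_homogeneous_series(
                hemo, geometry, grid, settings.sdd, wl, settings.n_tot_avg,
                table, law, rng, n=n,
            )
        else:
            out[wl] = synthesize_bilayer_series(
                hemo, geometry, grid, settings.sdd, wl, settings.n_tot_avg,
                table, law, rng, n=n,
            )
    return out


# ---------------------------------------------------------------------------
# gating and CW integration
# ---------------------------------------------------------------------------

def gate_counts(series: DTOFSeries, gates: GateSet) -> GatedCountsSeries:
    """Sum each frame's counts within each time gate."""
    assignment = gates.bin_assignment(series.time_grid)
    n_gates = gates.n_gates
    onehot = np.zeros((series.time_grid.n_bins, n_gates))
    valid = assignment >= 0
    onehot[np.nonzero(valid)[0], assignment[valid]] = 1.0
    gated = series.counts @ onehot
    base = series.baseline_expectation @ onehot
    return GatedCountsSeries(
        gated.astype(np.int64), gates, series.wavelength, series.sdd, base
    )


def integrate_to_cw(series: DTOFSeries) -> np.ndarray:
    """Per-frame total counts — the CW-equivalent intensity time series."""
    return series.frame_totals()
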