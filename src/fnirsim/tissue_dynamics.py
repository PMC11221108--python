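"""Hemoglobin dynamics and their mapping to tissue optical properties.

The probed medium is described by baseline oxy- (O2Hb) and deoxy-hemoglobin
(HHb) concentrations (defaults 30 and 20 μM), periodically perturbed by
small sinusoids — the synthetic stand-in for cardiac-band hemodynamic
oscillations.  Beer's law translates the concentration trajectories into
the absorption coefficient at the two operating wavelengths (690 and
830 nm); reduced scattering follows the Mie-approximation power law
``μs'(λ) = a (λ0/λ)^b`` and is held constant in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "HemodynamicBaseline",
    "PerturbationSpec",
    "ScatteringLaw",
    "ExtinctionTable",
    "HemoTimeSeries",
    "default_extinction_table",
    "scattering_at",
    "hemoglobin_to_mua",
    "resolve_phases",
    "make_hemo_series",
]

SPECIES = ("O2Hb", "HHb")


@dataclass(frozen=True)
class HemodynamicBaseline:
    """Baseline hemoglobin concentrations in μM."""

    o2hb: float = 30.0
    hhb: float = 20.0

    def __post_init__(self) -> None:
        if self.o2hb <= 0 or self.hhb <= 0:
            raise ValueError("baseline concentrations must be > 0")

    def concentration(self, species: str) -> float:
        return {"O2Hb": self.o2hb, "HHb": self.hhb}[species]


@dataclass(frozen=True)
class PerturbationSpec:
    """One sinusoidal perturbation of layer hemoglobin concentrations.

    amplitude_frac : peak amplitude as a fraction of the baseline value
    frequency : Hz
    phase : radians in [0, 2π), or None to draw a random phase
    target_layer : "UP", "DW" or "WHOLE" (homogeneous medium)
    target_species : "O2Hb", "HHb" or "both"
    """

    amplitude_frac: float
    frequency: float
    phase: Optional[float] = None
    target_layer: str = "WHOLE"
    target_species: str = "both"

    def __post_init__(self) -> None:
        if self.amplitude_frac < 0:
            raise ValueError("amplitude_frac must be >= 0")
        if self.frequency <= 0:
            raise ValueError("frequency must be > 0")
        if self.phase is not None and not 0 <= self.phase < 2 * np.pi:
            raise ValueError("phase must lie in [0, 2*pi)")
        if self.target_layer not in ("UP", "DW", "WHOLE"):
            raise ValueError(f"unknown layer {self.target_layer!r}")
        if self.target_species not in ("O2Hb", "HHb", "both"):
            raise ValueError(f"unknown species {self.target_species!r}")


@dataclass(frozen=True)
class ScatteringLaw:
    """Mie-approximation power law for the reduced scattering coefficient.

    The convention is fixed so that μs'(λ0) = a exactly and μs' decreases
    with increasing wavelength for b > 0.
    """

    a: float = 10.0
    b: float = 1.0
    lambda0: float = 690.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("scattering amplitude a must be > 0")


def scattering_at(law: ScatteringLaw, wavelength: float) -> float:
    """μs' (1/cm) at a wavelength (nm) from the power law."""
    if wavelength <= 0:
        raise ValueError("wavelength must be > 0")
    return law.a * (law.lambda0 / wavelength) ** law.b


class ExtinctionTable:
    """Specific absorption factors per wavelength.

    Stores, for each wavelength in nm, the pre-multiplied factors (1/cm per
    μM) such that ``mua = factor_o2hb * [O2Hb] + factor_hhb * [HHb]``.  The
    packaged default table documents the underlying decadic molar extinction
    compilation and the ln(10)·1e-6 conversion.
    """

    def __init__(self, factors: Mapping[float, tuple]) -> None:
        self._factors = {
            float(wl): (float(o), float(h)) for wl, (o, h) in factors.items()
        }
        for wl, (o, h) in self._factors.items():
            if o <= 0 or h <= 0:
                raise ValueError(f"non-positive extinction factor at {wl} nm")

    @property
    def wavelengths(self) -> tuple:
        return tuple(sorted(self._factors))

    def factors(self, wavelength: float) -> tuple:
        try:
            return self._factors[float(wavelength)]
        except KeyError:
            raise KeyError(f"wavelength {wavelength} nm not in extinction table")

    def matrix(self, wavelengths: Sequence[float]) -> np.ndarray:
        """Factor matrix, rows = wavelengths, columns = (O2Hb, HHb)."""
        m = np.array([self.factors(wl) for wl in wavelengths])
        if m.shape[0] == m.shape[1]:
            if abs(np.linalg.det(m)) < 1e-12 * np.abs(m).max() ** 2:
                raise ValueError("extinction matrix is singular")
        return m


def default_extinction_table() -> ExtinctionTable:
    """Load the packaged hemoglobin extinction factors (690 and 830 nm)."""
    text = resources.files("fnirsim").joinpath("data/extinction.yaml").read_text()
    raw = yaml.safe_load(text)["extinction"]
    return ExtinctionTable(
        {float(wl): (row["o2hb"], row["hhb"]) for wl, row in raw.items()}
    )


def hemoglobin_to_mua(o2hb, hhb, wavelength: float, table: ExtinctionTable):
    """Absorption coefficient (1/cm) from concentrations (μM) by Beer's law.

    Accepts scalars or arrays; linear in each concentration.
    """
    o2hb = np.asarray(o2hb, dtype=float)
    hhb = np.asarray(hhb, dtype=float)
    if np.any(o2hb < 0) or np.any(hhb < 0):
        raise ValueError("concentrations must be >= 0")
    f_o, f_h = table.factors(wavelength)
    out = f_o * o2hb + f_h * hhb
    return float(out) if out.ndim == 0 else out


@dataclass
class HemoTimeSeries:
    """Per-layer hemoglobin concentration trajectories on the frame grid.

    ``concentrations`` maps (layer, species) to a μM array of length
    round(Tmeas·fs); frame timestamps are k/fs, k = 0…N−1.
    """

    times: np.ndarray
    fs: float
    baseline: HemodynamicBaseline
    concentrations: dict
    phases: dict = field(default_factory=dict)

    @property
    def layers(self) -> tuple:
        return tuple(sorted({layer for layer, _ in self.concentrations}))

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def concentration(self, layer: str, species: str) -> np.ndarray:
        return self.concentrations[(layer, species)]

    def mua(self, layer: str, wavelength: float, table: ExtinctionTable) -> np.ndarray:
        """Frame-resolved absorption coefficient of one layer (1/cm)."""
        return hemoglobin_to_mua(
            self.concentrations[(layer, "O2Hb")],
            self.concentrations[(layer, "HHb")],
            wavelength,
            table,
        )

    def baseline_mua(self, wavelength: float, table: ExtinctionTable) -> float:
        return hemoglobin_to_mua(
            self.baseline.o2hb, self.baseline.hhb, wavelength, table
        )


def _expand_specs(perturbations: Sequence[PerturbationSpec]):
    """Expand 'both'-species specs into per-(layer, species) entries."""
    expanded = []
    for spec in perturbations:
        species = SPECIES if spec.target_species == "both" else (spec.target_species,)
        for sp in species:
            expanded.append((spec.target_layer, sp, spec))
    seen = set()
    for layer, sp, spec in expanded:
        key = (layer, sp, spec.frequency)
        if key in seen:
            raise ValueError(
                f"duplicate perturbation for layer={layer}, species={sp}, "
                f"f={spec.frequency} Hz"
            )
        seen.add(key)
    return expanded


def resolve_phases(
    perturbations: Sequence[PerturbationSpec],
    rng: np.random.Generator,
) -> dict:
    """Draw one random phase per (layer, species, frequency) entry.

    Entries with an explicit phase keep it; the draw order is the expansion
    order (deterministic), so identical seeds give identical phases.  O2Hb
    and HHb of one layer get independent random phases by default —
    explicit phases implement in-phase/out-of-phase layer relationships.
    """
    phases = {}
    for layer, sp, spec in _expand_specs(perturbations):
        key = (layer, sp, spec.frequency)
        if spec.phase is not None:
            phases[key] = float(spec.phase)
        else:
            phases[key] = float(rng.uniform(0.0, 2.0 * np.pi))
    return phases


def make_hemo_series(
    baseline: HemodynamicBaseline,
    perturbations: Sequence[PerturbationSpec],
    tmeas: float,
    fs: float,
    rng_seed=None,
    layers: Sequence[str] = ("WHOLE",),
    phases: Optional[dict] = None,
) -> HemoTimeSeries:
    """Generate layer concentration trajectories with sinusoidal perturbations.

    ``c(t) = baseline · (1 + Σ amplitude_frac · sin(2π f t + φ))`` per
    (layer, species); layers without a perturbation stay constant.  Random
    phases (``phase=None`` in a :class:`PerturbationSpec`) are drawn once per (layer, species,
    frequency) from U[0, 2π) — pass ``phases`` (from :func:`resolve_phases`)
    to share one draw across several acquisition settings.
    """
    n_frames = tmeas * fs
    if abs(n_frames - round(n_frames)) > 1e-9 or round(n_frames) < 2:
        raise ValueError("Tmeas*fs must be an integer >= 2")
    n_frames = int(round(n_frames))
    for spec in perturbations:
        if spec.target_layer not in layers:
            raise ValueError(
                f"perturbation targets layer {spec.target_layer!r} "
                f"not present in {layers}"
            )

    if phases is None:
        rng = np.random.default_rng(rng_seed)
        phases = resolve_phases(perturbations, rng)

    times = np.arange(n_frames) / fs
    concentrations = {}
    expanded = _expand_specs(perturbations)
    for layer in layers:
        for sp in SPECIES:
            c0 = baseline.concentration(sp)
            modulation = np.zeros(n_frames)
            for lay, spsp, spec in expanded:
                if lay != layer or spsp != sp:
                    continue
                phi = phases[(lay, spsp, spec.frequency)]
                modulation += spec.amplitude_frac * np.sin(
                    2.0 * np.pi * spec.frequency * times + phi
                )
            concentrations[(layer, sp)] = c0 * (1.0 + modulation)
    return HemoTimeSeries(times, fs, baseline, concentrations, dict(phases))
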