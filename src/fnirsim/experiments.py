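"""Scenario runner reproducing the named simulation grids.

The named cases come in two families:

* homogeneous-medium parameter sweeps (``H_Ntot``, ``H_Tmeas``, ``H_fs``,
  ``H_SDD``): a 5 cm slab with a 1%-amplitude, 1 Hz oscillation of both
  hemoglobin species, measured while one acquisition parameter is swept —
  used for the power-law scaling of peak amplitude, noise floor and
  contrast of the integrated (CW-equivalent) intensity;
* bilayer-medium depth-selectivity cases (``B_UP`` … ``B_AmpFreq``): a
  1 cm superficial layer over a 4 cm deep layer in a 10 cm-radius cylinder,
  with independent per-layer oscillations — used for gate-wise contrast
  profiles and TMPP/CW hemoglobin retrieval.

Every result is reproducible from (case id, master seed): hemoglobin
phases are drawn once per case and shared across all acquisition settings
of that case (the medium is physically the same however it is measured),
while each measurement point gets an independent Poisson stream derived
from a stable hash of its parameters.
"""

from __future__ import annotations

import pathlib
import zlib
from dataclasses import asdict, dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import acquisition as acq
from . import inversion as inv
from . import spectral_analysis as spec
from .forward_models import (
    BilayerGeometry,
    OpticalProperties,
    SlabGeometry,
    TimeGrid,
)
from .tissue_dynamics import (
    HemodynamicBaseline,
    PerturbationSpec,
    ScatteringLaw,
    default_extinction_table,
    make_hemo_series,
    resolve_phases,
    scattering_at,
)

__all__ = [
    "ScenarioConfig",
    "named_cases",
    "get_case",
    "load_config",
    "save_config",
    "case_phases",
    "simulate_point",
    "run_case",
    "scaling_report",
    "build_tmpp_operators",
    "gate_contrast_profile",
    "tmpp_retrieve",
    "cw_retrieve",
]

REFRACTIVE_INDEX = 1.4


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one simulation case.

    Tuple-valued acquisition fields hold the sweep grids; ``sweep`` names
    the parameter being varied.  ``dt`` is the DTOF resolution in ns (8 ps
    for the homogeneous medium, 20 ps for the bilayer medium, where the
    eigenfunction solver dominates the cost).
    """

    case_id: str
    medium: str  # "homogeneous" | "bilayer"
    sweep: str  # "n_tot" | "tmeas" | "fs" | "sdd"
    n_tot: tuple
    tmeas: tuple  # s
    fs: tuple  # Hz
    sdd: tuple  # cm
    perturbations: tuple
    wavelengths: tuple = (690.0, 830.0)
    phase_mode: str = "random"  # "random" | "in_phase" | "out_of_phase"
    master_seed: int = 0
    dt: float = 0.008
    slab_thickness: float = 5.0
    bilayer_radius: float = 10.0
    bilayer_thickness_up: float = 1.0
    bilayer_thickness_dw: float = 4.0
    baseline: HemodynamicBaseline = HemodynamicBaseline()
    scattering: ScatteringLaw = ScatteringLaw()
    detrend_order: int = 3
    threshold_db: float = spec.SIGNIFICANCE_THRESHOLD_DB
    scale_down: bool = False

    def __post_init__(self) -> None:
        if self.medium not in ("homogeneous", "bilayer"):
            raise ValueError(f"unknown medium {self.medium!r}")
        if self.sweep not in ("n_tot", "tmeas", "fs", "sdd"):
            raise ValueError(f"unknown sweep parameter {self.sweep!r}")
        if self.phase_mode not in ("random", "in_phase", "out_of_phase"):
            raise ValueError(f"unknown phase mode {self.phase_mode!r}")

    @property
    def layers(self) -> tuple:
        return ("WHOLE",) if self.medium == "homogeneous" else ("UP", "DW")

    @property
    def geometry(self):
        if self.medium == "homogeneous":
            return SlabGeometry(self.slab_thickness)
        return BilayerGeometry(
            self.bilayer_radius,
            self.bilayer_thickness_up,
            self.bilayer_thickness_dw,
        )

    @property
    def time_grid(self) -> TimeGrid:
        return TimeGrid(0.0, 5.0, self.dt)

    @property
    def target_frequencies(self) -> tuple:
        return tuple(sorted({p.frequency for p in self.perturbations}))

    def effective(self) -> "ScenarioConfig":
        """Apply the scaled-down execution override (shorter, dimmer runs).

        Contrast scales linearly with Tmeas and with N̄tot² (peak) /
        N̄tot (noise), so scaled runs keep every qualitative behavior
        while cutting runtime; thresholds must be rescaled accordingly
        when interpreting them.
        """
        if not self.scale_down:
            return self
        return replace(
            self,
            scale_down=False,
            tmeas=tuple(min(t, 120.0) for t in self.tmeas),
            n_tot=tuple(min(nt, 1e5) for nt in self.n_tot),
        )


def _homogeneous_case(case_id, sweep, n_tot, tmeas, fs, sdd, perturbations, seed):
    return ScenarioConfig(
        case_id=case_id,
        medium="homogeneous",
        sweep=sweep,
        n_tot=n_tot,
        tmeas=tmeas,
        fs=fs,
        sdd=sdd,
        perturbations=perturbations,
        master_seed=seed,
        dt=0.008,
    )


def named_cases(master_seed: int = 0, scale_down: bool = False) -> dict:
    """The named simulation grids, keyed by case id."""
    whole = (PerturbationSpec(0.01, 1.0, target_layer="WHOLE"),)

    def bilayer(case_id, perturbations):
        return ScenarioConfig(
            case_id=case_id,
            medium="bilayer",
            sweep="n_tot",
            n_tot=(1e4, 1e5, 1e6),
            tmeas=(900.0,),
            fs=(20.0,),
            sdd=(1.0, 4.0),
            perturbations=perturbations,
            master_seed=master_seed,
            dt=0.020,
            scale_down=scale_down,
        )

    up = lambda a, f: PerturbationSpec(a, f, target_layer="UP")  # noqa: E731
    dw = lambda a, f: PerturbationSpec(a, f, target_layer="DW")  # noqa: E731

    cases = {
        "H_Ntot": _homogeneous_case(
            "H_Ntot", "n_tot", (1e4, 1e5, 1e6), (900.0,), (20.0,), (1.0, 4.0),
            whole, master_seed,
        ),
        "H_Tmeas": _homogeneous_case(
            "H_Tmeas", "tmeas", (1e6,), (300.0, 600.0, 900.0), (20.0,),
            (1.0, 4.0), whole, master_seed,
        ),
        "H_fs": _homogeneous_case(
            "H_fs", "fs", (1e6,), (900.0,), (5.0, 10.0, 20.0), (1.0, 4.0),
            whole, master_seed,
        ),
        "H_SDD": _homogeneous_case(
            "H_SDD", "sdd", (1e6,), (900.0,), (20.0,),
            (1.0, 2.0, 3.0, 4.0, 5.0, 6.0), whole, master_seed,
        ),
        "B_UP": bilayer("B_UP", (up(0.01, 1.0),)),
        "B_DW": bilayer("B_DW", (dw(0.01, 1.0),)),
        "B_UPDW": bilayer("B_UPDW", (up(0.01, 1.0), dw(0.01, 1.0))),
        "B_Amp": bilayer("B_Amp", (up(0.01, 1.0), dw(0.005, 1.0))),
        "B_Freq": bilayer("B_Freq", (up(0.01, 0.2), dw(0.01, 1.0))),
        "B_AmpFreq": bilayer("B_AmpFreq", (up(0.01, 0.2), dw(0.005, 1.0))),
    }
    if scale_down:
        cases = {k: replace(v, scale_down=True) for k, v in cases.items()}
    return cases


def get_case(case_id: str, master_seed: int = 0, scale_down: bool = False):
    try:
        return named_cases(master_seed, scale_down)[case_id]
    except KeyError:
        raise KeyError(f"unknown case id {case_id!r}")


# ---------------------------------------------------------------------------
# structured-text (YAML) scenario configs
# ---------------------------------------------------------------------------

def save_config(config: ScenarioConfig, path) -> None:
    """Serialize a scenario to YAML (lossless round trip with load_config)."""
    import yaml

    raw = asdict(config)
    raw["baseline"] = {"o2hb": config.baseline.o2hb, "hhb": config.baseline.hhb}
    raw["scattering"] = {
        "a": config.scattering.a,
        "b": config.scattering.b,
        "lambda0": config.scattering.lambda0,
    }
    raw["perturbations"] = [
        {
            "amplitude_frac": p.amplitude_frac,
            "frequency": p.frequency,
            "phase": p.phase,
            "target_layer": p.target_layer,
            "target_species": p.target_species,
        }
        for p in config.perturbations
    ]
    pathlib.Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


def load_config(path) -> ScenarioConfig:
    """Load a scenario from the YAML schema written by :func:`save_config`."""
    import yaml

    raw = yaml.safe_load(pathlib.Path(path).read_text())
    raw["baseline"] = HemodynamicBaseline(**raw["baseline"])
    raw["scattering"] = ScatteringLaw(**raw["scattering"])
    raw["perturbations"] = tuple(
        PerturbationSpec(**p) for p in raw["perturbations"]
    )
    for key in ("n_tot", "tmeas", "fs", "sdd", "wavelengths"):
        raw[key] = tuple(raw[key])
    return ScenarioConfig(**raw)


# ---------------------------------------------------------------------------
# deterministic seeding
# ---------------------------------------------------------------------------

def _stable_hash(*parts) -> int:
    text = "|".join(repr(p) for p in parts)
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


def case_phases(config: ScenarioConfig) -> dict:
    """Perturbation phases of a case: one draw, shared by every sweep point."""
    rng = np.random.default_rng(
        np.random.SeedSequence([config.master_seed, _stable_hash(config.case_id)])
    )
    phases = resolve_phases(config.perturbations, rng)
    if config.phase_mode != "random":
        shift = 0.0 if config.phase_mode == "in_phase" else np.pi
        up_by_species = {
            sp: phi for (lay, sp, _f), phi in phases.items() if lay == "UP"
        }
        for (lay, sp, f), _phi in list(phases.items()):
            if lay == "DW" and sp in up_by_species:
                phases[(lay, sp, f)] = (up_by_species[sp] + shift) % (2 * np.pi)
    return phases


def _point_seed(config: ScenarioConfig, n_tot, tmeas, fs, sdd) -> int:
    return _stable_hash(config.case_id, config.master_seed, n_tot, tmeas, fs, sdd)


# ---------------------------------------------------------------------------
# simulation of one measurement point
# ---------------------------------------------------------------------------

def simulate_point(
    config: ScenarioConfig,
    n_tot: float,
    tmeas: float,
    fs: float,
    sdd: float,
    phases: Optional[dict] = None,
) -> dict:
    """Synthesize the DTOF series of one (N̄tot, Tmeas, fs, SDD) point.

    Returns ``{wavelength: DTOFSeries}``.  Fully deterministic given the
    case id and master seed.
    """
    table = default_extinction_table()
    if phases is None:
        phases = case_phases(config)
    hemo = make_hemo_series(
        config.baseline,
        config.perturbations,
        tmeas,
        fs,
        layers=config.layers,
        phases=phases,
    )
    settings = acq.AcquisitionSettings(
        n_tot_avg=n_tot,
        tmeas=tmeas,
        fs=fs,
        sdd=sdd,
        wavelengths=config.wavelengths,
        rng_seed=_point_seed(config, n_tot, tmeas, fs, sdd),
    )
    geometry = config.geometry
    grid = config.time_grid
    streams = np.random.SeedSequence(settings.rng_seed).spawn(
        len(config.wavelengths)
    )
    out = {}
    for wl, ss in zip(config.wavelengths, streams):
        rng = np.random.default_rng(ss)
        if config.medium == "homogeneous":
            out[wl] = acq.synthesize_homogeneous_series(
                hemo, geometry, grid, sdd, wl, n_tot, table,
                config.scattering, rng, n=REFRACTIVE_INDEX,
            )
        else:
            out[wl] = acq.synthesize_bilayer_series(
                hemo, geometry, grid, sdd, wl, n_tot, table,
                config.scattering, rng, n=REFRACTIVE_INDEX,
                grid_sdds=config.sdd,
            )
    return out


def _sweep_points(config: ScenarioConfig):
    """(value, n_tot, tmeas, fs, sdd) tuples of the case grid."""
    for n_tot in config.n_tot:
        for tmeas in config.tmeas:
            for fs in config.fs:
                for sdd in config.sdd:
                    value = {
                        "n_tot": n_tot,
                        "tmeas": tmeas,
                        "fs": fs,
                        "sdd": sdd,
                    }[config.sweep]
                    yield value, n_tot, tmeas, fs, sdd


# ---------------------------------------------------------------------------
# intensity-level (CW-equivalent) analysis of a case
# ---------------------------------------------------------------------------

def run_case(config: ScenarioConfig) -> pd.DataFrame:
    """Run the full pipeline of a case at the intensity level.

    For each grid point and wavelength the DTOF series is integrated to the
    CW-equivalent intensity, detrended, and the periodogram contrast is
    evaluated at each perturbation frequency (plus its second harmonic when
    it fits below Nyquist).  Returns one long-format record per
    (grid point, wavelength, frequency).
    """
    config = config.effective()
    phases = case_phases(config)
    records = []
    for value, n_tot, tmeas, fs, sdd in _sweep_points(config):
        series = simulate_point(config, n_tot, tmeas, fs, sdd, phases=phases)
        for wl, dtof in series.items():
            intensity = acq.integrate_to_cw(dtof).astype(float)
            detrended = spec.detrend_poly(intensity, config.detrend_order)
            spectrum = spec.noise_floor(spec.periodogram_psd(detrended, fs))
            for f0 in config.target_frequencies:
                spectrum, report = spec.contrast(
                    spectrum, f0, config.threshold_db
                )
                harmonic_db = np.nan
                if 2.0 * f0 <= fs / 2.0:
                    harmonic_db = spec.second_harmonic_check(
                        spectrum, f0, config.threshold_db
                    ).contrast_db
                records.append(
                    {
                        "case": config.case_id,
                        "sweep": config.sweep,
                        "value": value,
                        "n_tot": n_tot,
                        "tmeas": tmeas,
                        "fs": fs,
                        "sdd": sdd,
                        "wavelength": wl,
                        "frequency": f0,
                        "peak_amp": report.amplitude,
                        "eps": spectrum.eps,
                        "contrast": report.amplitude / spectrum.eps,
                        "contrast_db": report.contrast_db,
                        "significant": report.significant,
                        "harmonic2_db": harmonic_db,
                        "seed": _point_seed(config, n_tot, tmeas, fs, sdd),
                    }
                )
    return pd.DataFrame.from_records(records)


def scaling_report(
    table: pd.DataFrame,
    metrics: Sequence[str] = ("peak_amp", "eps", "contrast"),
    invariance_band: float = 0.03,
) -> pd.DataFrame:
    """Power-law fits and invariance checks of a sweep's result table.

    For each (sdd, wavelength, frequency, metric) series the power law
    ``metric ∝ value^exponent`` is fitted in log–log space; the maximum
    relative deviation from the series mean quantifies invariance claims
    (the conventional band is ±3%).
    """
    if table.empty:
        raise ValueError("empty result table")
    sweep = table["sweep"].iloc[0]
    rows = []
    group_cols = ["sdd", "wavelength", "frequency"]
    if sweep == "sdd":
        group_cols = ["wavelength", "frequency"]
    for keys, grp in table.groupby(group_cols):
        grp = grp.sort_values("value")
        if len(grp) < 3:
            raise ValueError("need at least 3 sweep points per series")
        for metric in metrics:
            y = grp[metric].to_numpy()
            fit = spec.fit_power_law(grp["value"].to_numpy(), y)
            max_dev = float(np.max(np.abs(y - y.mean())) / y.mean())
            row = dict(zip(group_cols, keys if isinstance(keys, tuple) else (keys,)))
            row.update(
                {
                    "case": grp["case"].iloc[0],
                    "sweep": sweep,
                    "metric": metric,
                    "exponent": fit.exponent,
                    "prefactor": fit.prefactor,
                    "r_squared": fit.r_squared,
                    "max_rel_dev": max_dev,
                    "invariant": max_dev <= invariance_band,
                }
            )
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bilayer depth-selectivity analyses
# ---------------------------------------------------------------------------

def gate_contrast_profile(
    config: ScenarioConfig,
    n_tot: float,
    sdd: float,
    wavelength: float = 690.0,
    gates: Optional[acq.GateSet] = None,
) -> pd.DataFrame:
    """Contrast of the perturbation peaks in each gate's count series.

    Produces one row per (gate, target frequency) plus the CW full-integral
    channel appended as gate 0 (labelled "CW").  Gates whose baseline
    expectation carries essentially no photons are flagged unusable; their
    contrast is NaN when the spectrum is degenerate.
    """
    config = config.effective()
    tmeas, fs = config.tmeas[0], config.fs[0]
    series = simulate_point(config, n_tot, tmeas, fs, sdd)[wavelength]
    if gates is None:
        gates = acq.GateSet.uniform(t_max=config.time_grid.t_end)
    gated = acq.gate_counts(series, gates)

    rows = []

    def analyze(values, label, gate_index, t_lo, t_hi, baseline_counts):
        for f0 in config.target_frequencies:
            if values.std() == 0:
                rows.append(
                    {
                        "case": config.case_id, "channel": label,
                        "gate": gate_index, "t_start": t_lo, "t_end": t_hi,
                        "baseline_counts": baseline_counts, "frequency": f0,
                        "contrast_db": np.nan, "significant": False,
                        "usable": False, "n_tot": n_tot, "sdd": sdd,
                        "wavelength": wavelength,
                    }
                )
                continue
            _, report = spec.analyze_series(
                values.astype(float), fs, f0,
                config.detrend_order, config.threshold_db,
            )
            rows.append(
                {
                    "case": config.case_id, "channel": label,
                    "gate": gate_index, "t_start": t_lo, "t_end": t_hi,
                    "baseline_counts": baseline_counts, "frequency": f0,
                    "contrast_db": report.contrast_db,
                    "significant": report.significant,
                    "usable": True, "n_tot": n_tot, "sdd": sdd,
                    "wavelength": wavelength,
                }
            )

    for g, (t_lo, t_hi) in enumerate(gated.gates.intervals()):
        analyze(
            gated.counts[:, g], f"gate{g + 1}", g + 1, t_lo, t_hi,
            float(gated.baseline_expectation[g]),
        )
    analyze(
        acq.integrate_to_cw(series), "CW", 0,
        config.time_grid.t_start, config.time_grid.t_end,
        float(series.baseline_expectation.sum()),
    )
    return pd.DataFrame(rows)


def build_tmpp_operators(
    config: ScenarioConfig,
    n_tot: float,
    sdd: float,
    gates: Optional[acq.GateSet] = None,
    known_props: bool = False,
) -> tuple:
    """Baseline characterization for the TMPP method at one SDD.

    Fits the homogeneous baseline to the case's mean DTOF per wavelength
    (or takes the nominal baseline when ``known_props``) and builds the
    per-wavelength pathlength operators from direct bilayer-model
    evaluations.  The operators depend only on the baseline medium, so one
    characterization serves every case sharing that baseline.

    Returns ``(fits, operators)``, both keyed by wavelength.
    """
    if config.medium != "bilayer":
        raise ValueError("TMPP retrieval applies to the bilayer medium")
    config = config.effective()
    tmeas, fs = config.tmeas[0], config.fs[0]
    table = default_extinction_table()
    grid = config.time_grid
    if gates is None:
        gates = acq.GateSet.uniform(t_max=grid.t_end)
    fits = {}
    operators = {}
    dtofs = None if known_props else simulate_point(config, n_tot, tmeas, fs, sdd)
    for wl in config.wavelengths:
        if known_props:
            props = OpticalProperties(
                config.baseline.o2hb * table.factors(wl)[0]
                + config.baseline.hhb * table.factors(wl)[1],
                scattering_at(config.scattering, wl),
                REFRACTIVE_INDEX,
            )
        else:
            fit = fit_baseline_for_config(
                config, dtofs[wl].counts.mean(axis=0), sdd, wl
            )
            fits[wl] = fit
            props = fit.props
        operators[wl] = inv.tmpp_pathlengths(
            props, props, config.geometry, sdd, grid, gates=gates
        )
    return fits, operators


def tmpp_retrieve(
    config: ScenarioConfig,
    n_tot: float,
    sdd: float,
    gates: Optional[acq.GateSet] = None,
    known_props: bool = False,
    operators: Optional[dict] = None,
    weighting: str = "uniform",
) -> dict:
    """Layer-resolved hemoglobin retrieval by the TMPP method.

    Pipeline per wavelength: mean-DTOF homogeneous baseline fit (or the
    known baseline when ``known_props``), pathlength operator from the
    bilayer model, per-frame gated inversion for (Δμa_UP, Δμa_DW); then
    chromophore unmixing per layer and contrast analysis of each retrieved
    species series at every target frequency.  Precomputed ``operators``
    (from :func:`build_tmpp_operators`) may be supplied to reuse one
    baseline characterization across the cases sharing a baseline medium.

    Returns ``{"records": DataFrame, "series": {(layer, species): array},
    "fits": {wavelength: BaselineFitResult}, "operators": {...}}``.
    """
    if config.medium != "bilayer":
        raise ValueError("TMPP retrieval applies to the bilayer medium")
    config = config.effective()
    tmeas, fs = config.tmeas[0], config.fs[0]
    table = default_extinction_table()
    grid = config.time_grid
    if gates is None:
        gates = acq.GateSet.uniform(t_max=grid.t_end)
    fits = {}
    if operators is None:
        fits, operators = build_tmpp_operators(
            config, n_tot, sdd, gates=gates, known_props=known_props
        )

    dtofs = simulate_point(config, n_tot, tmeas, fs, sdd)
    delta_mua = {}
    for wl, dtof in dtofs.items():
        gated = acq.gate_counts(dtof, gates)
        delta_mua[wl] = inv.tmpp_invert(
            gated, operators[wl], wavelength=wl, weighting=weighting
        )

    records = []
    series = {}
    for li, layer in enumerate(("UP", "DW")):
        per_wl = {wl: delta_mua[wl].delta_mua[:, li] for wl in dtofs}
        conc = inv.unmix_chromophores(per_wl, table)
        for sp, values in conc.items():
            series[(layer, sp)] = values
            for f0 in config.target_frequencies:
                _, report = spec.analyze_series(
                    values, fs, f0, config.detrend_order, config.threshold_db
                )
                records.append(
                    {
                        "case": config.case_id, "layer": layer, "species": sp,
                        "frequency": f0, "contrast_db": report.contrast_db,
                        "peak_amp": report.amplitude,
                        "significant": report.significant,
                        "n_tot": n_tot, "sdd": sdd, "method": "TMPP",
                    }
                )
    return {
        "records": pd.DataFrame(records),
        "series": series,
        "fits": fits,
        "operators": operators,
    }


def fit_baseline_for_config(
    config: ScenarioConfig,
    mean_dtof: np.ndarray,
    sdd: float,
    wavelength: float,
):
    """Homogeneous baseline fit with the case's nominal values as init."""
    table = default_extinction_table()
    init = OpticalProperties(
        config.baseline.o2hb * table.factors(wavelength)[0]
        + config.baseline.hhb * table.factors(wavelength)[1],
        scattering_at(config.scattering, wavelength),
        REFRACTIVE_INDEX,
    )
    return inv.fit_homogeneous_baseline(
        mean_dtof,
        config.time_grid,
        sdd,
        SlabGeometry(config.slab_thickness),
        init,
        n=REFRACTIVE_INDEX,
    )


def cw_retrieve(config: ScenarioConfig, n_tot: float, sdd: float) -> dict:
    """Hemoglobin retrieval from the CW-equivalent intensity by MBLL.

    Δμa(t) per wavelength from the modified Beer–Lambert law with the
    model's own photon-mean pathlength, then chromophore unmixing (a single
    whole-medium estimate — CW at one SDD has no depth resolution).
    """
    config = config.effective()
    tmeas, fs = config.tmeas[0], config.fs[0]
    table = default_extinction_table()
    dtofs = simulate_point(config, n_tot, tmeas, fs, sdd)

    delta_mua = {}
    for wl, dtof in dtofs.items():
        from .forward_models import ReflectanceCurve

        base = ReflectanceCurve(
            dtof.time_grid, dtof.baseline_expectation, wl, sdd
        )
        path = inv.mean_total_pathlength(base, n=REFRACTIVE_INDEX)
        intensity = acq.integrate_to_cw(dtof).astype(float)
        delta_mua[wl] = inv.cw_mbll(intensity, path)

    conc = inv.unmix_chromophores(delta_mua, table)
    records = []
    for sp, values in conc.items():
        for f0 in config.target_frequencies:
            _, report = spec.analyze_series(
                values, fs, f0, config.detrend_order, config.threshold_db
            )
            records.append(
                {
                    "case": config.case_id, "layer": "CW", "species": sp,
                    "frequency": f0, "contrast_db": report.contrast_db,
                    "peak_amp": report.amplitude,
                    "significant": report.significant,
                    "n_tot": n_tot, "sdd": sdd, "method": "CW-MBLL",
                }
            )
    return {"records": pd.DataFrame(records), "series": conc}
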