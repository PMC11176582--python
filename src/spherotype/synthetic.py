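"""Synthetic spheroid study generator.

Produces growth time courses, 3-channel (CAM/PI/TL) z-stack images and
dose-response tables with the statistical structure the downstream analysis
assumes, together with per-stack ground-truth records so every pipeline
stage can be tested end-to-end without external data.

Model choices (declared, not inferred from any particular dataset):

- Growth is exponential with a drug-modulated rate.  During drug exposure
  the rate ``k = ln(2)/doubling_time`` is multiplied by ``1 - I(C)`` where
  ``I(C) = emax * C^h / (C^h + gi50^h)`` is a Hill inhibition term; an
  ``I(C) > 1`` excess acts as shrinkage.  After washout, lines flagged
  ``regrows_after_washout`` resume the full rate; other lines retain a
  persistent fraction of the inhibition.
- Replicate noise on areas is multiplicative lognormal with a fixed CV.
- Images are radially symmetric: CAM is an annulus whose intensity falls
  with damage, PI a central soft-edged disk whose intensity and extent grow
  with damage, TL a bright background with a darker spheroid body and a
  darkest core.  Z-slices are cosine-apodized so the central slice is
  brightest.  Image noise is additive Gaussian plus a signal-dependent
  (Poisson-like) Gaussian term.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .profiles import SpheroidStack, write_stack

__all__ = [
    "CellLineSpec",
    "TreatmentSchedule",
    "SimulationConfig",
    "hill_inhibition",
    "deterministic_area_trajectory",
    "simulate_growth_timecourse",
    "Cohort",
    "generate_spheroid_stack",
    "generate_cohort",
    "default_cohort_specs",
    "write_cohort",
]

# Base channel amplitudes (arbitrary intensity units) for generated images.
_CAM_AMP = 1000.0
_PI_AMP = 600.0
_TL_BACKGROUND = 1000.0
_TL_BODY_DROP = 550.0   # spheroid body sits at background - drop
_TL_CORE_DROP = 200.0   # core darkens further


@dataclass(frozen=True)
class CellLineSpec:
    """Ground-truth parameters of one simulated cell line.

    ``rim_fraction`` is the CAM rim thickness as a fraction of the spheroid
    radius; ``core_fraction`` the PI core diameter as a fraction of the
    spheroid diameter.  ``washout_persistence`` is the fraction of the
    exposure-time inhibition retained after washout by lines that do not
    regrow (regrowing lines resume the full growth rate).
    """

    name: str
    doubling_time_h: float
    gi50_true: float
    emax_true: float
    hill: float
    rim_fraction: float
    core_fraction: float
    regrows_after_washout: bool
    ocr_ecar: float
    washout_persistence: float = 0.7

    def __post_init__(self) -> None:
        if self.doubling_time_h <= 0:
            raise ValueError("doubling_time_h must be > 0")
        if self.gi50_true <= 0:
            raise ValueError("gi50_true must be > 0")
        if not 0.0 <= self.emax_true <= 1.0:
            raise ValueError("emax_true must be in [0, 1]")
        if self.hill <= 0:
            raise ValueError("hill must be > 0")
        if not 0.0 < self.rim_fraction < 1.0:
            raise ValueError("rim_fraction must be in (0, 1)")
        if not 0.0 <= self.core_fraction < 1.0:
            raise ValueError("core_fraction must be in [0, 1)")
        if self.core_fraction >= 1.0 - self.rim_fraction:
            raise ValueError(
                "core_fraction must be < 1 - rim_fraction (rim and core overlap)"
            )
        if not 0.0 <= self.washout_persistence <= 1.0:
            raise ValueError("washout_persistence must be in [0, 1]")
        if self.ocr_ecar <= 0:
            raise ValueError("ocr_ecar must be > 0")


@dataclass(frozen=True)
class TreatmentSchedule:
    """Two-cycle treatment timeline in integer days relative to first dose.

    Cycles are half-open ``[start, end)`` day intervals during which drug is
    present.  ``washout_days`` are media-exchange days between the cycles.
    """

    seed_day: int = -3
    cycle1: tuple[int, int] = (0, 4)
    cycle2: tuple[int, int] = (14, 18)
    washout_days: tuple[int, ...] = (4, 6, 8, 10, 12)
    imaging_days: tuple[int, ...] = (1, 2, 3, 4, 7, 11, 14, 15, 16, 17, 18, 21)
    viability_days: tuple[int, ...] = (4, 18)

    def __post_init__(self) -> None:
        if not self.imaging_days:
            raise ValueError("schedule must include at least one imaging day")
        for lo, hi in (self.cycle1, self.cycle2):
            if hi <= lo:
                raise ValueError("cycle intervals must be non-empty half-open [lo, hi)")
        if self.cycle2[0] < self.cycle1[1]:
            raise ValueError("cycles must not overlap")
        allowed = set(self.imaging_days) | {self.cycle1[1], self.cycle2[1]}
        if not set(self.viability_days) <= allowed:
            raise ValueError("viability_days must be imaging days or cycle ends")

    @property
    def last_day(self) -> int:
        return max(self.imaging_days)

    def in_exposure(self, day: int) -> bool:
        """Drug present during the day interval [day, day+1)."""
        return (self.cycle1[0] <= day < self.cycle1[1]) or (
            self.cycle2[0] <= day < self.cycle2[1]
        )

    def post_washout(self, day: int) -> bool:
        """Day interval follows at least one completed exposure cycle."""
        return day >= self.cycle1[1]


@dataclass(frozen=True)
class SimulationConfig:
    concentrations: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0, 4.0, 16.0)
    n_growth_replicates: int = 40
    n_viability_replicates: int = 5
    noise_cv: float = 0.05
    rng_seed: int = 0
    image_size_px: int = 257
    pixel_size_um: float = 4.0
    n_z: int = 9
    initial_diameter_um: float = 350.0

    def __post_init__(self) -> None:
        if 0.0 not in self.concentrations:
            raise ValueError("concentrations must include 0 (untreated control)")
        if min(self.concentrations) < 0:
            raise ValueError("concentrations must be non-negative")
        if self.n_growth_replicates < 1 or self.n_viability_replicates < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.image_size_px < 16:
            raise ValueError("image_size_px too small")
        if self.pixel_size_um <= 0 or self.n_z < 1:
            raise ValueError("invalid image geometry")
        if self.initial_diameter_um <= 0:
            raise ValueError("initial_diameter_um must be > 0")

    @property
    def field_um(self) -> float:
        return self.image_size_px * self.pixel_size_um


def hill_inhibition(concentration: float, spec: CellLineSpec) -> float:
    """Hill inhibition fraction I(C) = emax * C^h / (C^h + gi50^h)."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if concentration == 0:
        return 0.0
    ch = concentration ** spec.hill
    return spec.emax_true * ch / (ch + spec.gi50_true ** spec.hill)


def _daily_rate(spec: CellLineSpec, schedule: TreatmentSchedule,
                inhibition: float, day: int) -> float:
    """Exponential growth rate (per day) in effect over [day, day+1)."""
    k = math.log(2.0) / (spec.doubling_time_h / 24.0)
    if schedule.in_exposure(day):
        return k * (1.0 - inhibition)
    if schedule.post_washout(day) and not spec.regrows_after_washout:
        return k * (1.0 - spec.washout_persistence * inhibition)
    return k


def deterministic_area_trajectory(
    spec: CellLineSpec,
    schedule: TreatmentSchedule,
    concentration: float,
    config: SimulationConfig,
) -> pd.Series:
    """Noise-free area (mm^2) at each integer day 0..last imaging day."""
    inhibition = hill_inhibition(concentration, spec)
    area0 = math.pi * (config.initial_diameter_um / 2000.0) ** 2
    days = range(0, schedule.last_day + 1)
    areas = [area0]
    for day in range(0, schedule.last_day):
        areas.append(areas[-1] * math.exp(_daily_rate(spec, schedule, inhibition, day)))
    return pd.Series(areas, index=pd.Index(days, name="day"), name="area_mm2")


def simulate_growth_timecourse(
    spec: CellLineSpec,
    schedule: TreatmentSchedule,
    concentration: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-replicate spheroid areas (mm^2) on each imaging day.

    Returns a tidy frame with columns ``cell_line, replicate, day,
    concentration_ug_ml, area_mm2``.  Noise is multiplicative lognormal with
    CV = ``config.noise_cv`` (mean-one), independent per observation.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    traj = deterministic_area_trajectory(spec, schedule, concentration, config)
    days = sorted(set(schedule.imaging_days) | {0})
    base = traj.loc[days].to_numpy()

    n = config.n_growth_replicates
    if config.noise_cv > 0:
        sigma2 = math.log(1.0 + config.noise_cv ** 2)
        noise = rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2), size=(n, len(days)))
    else:
        noise = np.ones((n, len(days)))
    rows = {
        "cell_line": np.repeat(spec.name, n * len(days)),
        "replicate": np.repeat(np.arange(n), len(days)),
        "day": np.tile(days, n),
        "concentration_ug_ml": concentration,
        "area_mm2": (base[None, :] * noise).ravel(),
    }
    return pd.DataFrame(rows)


def _radial_grid(config: SimulationConfig) -> np.ndarray:
    """Radius (μm) of each pixel from the image center."""
    n = config.image_size_px
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    return np.hypot(xx - c, yy - c) * config.pixel_size_um


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def generate_spheroid_stack(
    diameter_um: float,
    spec: CellLineSpec,
    damage: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[SpheroidStack, dict]:
    """Render one radially symmetric spheroid z-stack plus ground truth.

    CAM is a Gaussian annulus peaking mid-rim whose amplitude falls with
    ``damage`` (to 5% at damage 1); PI a soft-edged central disk whose
    radius and amplitude grow with damage; TL a bright background with a
    dark spheroid body and a darker core.
    """
    if not 0.0 <= damage <= 1.0:
        raise ValueError("damage must be in [0, 1]")
    if diameter_um <= 0:
        raise ValueError("diameter_um must be > 0")
    if diameter_um >= 0.95 * config.field_um:
        raise ValueError(
            f"diameter {diameter_um:.0f} μm does not fit the "
            f"{config.field_um:.0f} μm field of view"
        )
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)

    r = _radial_grid(config)
    radius = diameter_um / 2.0
    px = config.pixel_size_um
    edge_w = max(2.0 * px, 0.02 * radius)

    # CAM: annulus peaking mid-rim.
    r_cam = radius * (1.0 - spec.rim_fraction / 2.0)
    sigma_cam = max(radius * spec.rim_fraction / 4.0, 2.0 * px)
    cam_amp = _CAM_AMP * (1.0 - 0.95 * damage)
    cam = cam_amp * np.exp(-((r - r_cam) ** 2) / (2.0 * sigma_cam ** 2))

    # PI: central disk; extent grows with damage but stays inside the rim.
    core_r0 = radius * spec.core_fraction
    core_r_max = radius * (1.0 - spec.rim_fraction)
    core_r = core_r0 + damage * 0.8 * (core_r_max - core_r0)
    pi_amp = _PI_AMP * (1.0 + damage)
    pi = pi_amp * _sigmoid((core_r - r) / edge_w)

    # TL: bright background, darker body, darkest core.
    tl = (
        _TL_BACKGROUND
        - _TL_BODY_DROP * _sigmoid((radius - r) / edge_w)
        - _TL_CORE_DROP * _sigmoid((core_r - r) / edge_w)
    )

    planes = np.stack([cam, pi, tl])  # (3, H, W)
    zc = (config.n_z - 1) / 2.0
    z_w = np.cos(np.pi / 2.0 * (np.arange(config.n_z) - zc) / (zc + 1.0)) ** 2 \
        if config.n_z > 1 else np.ones(1)
    voxels = planes[:, None, :, :] * z_w[None, :, None, None]

    if config.noise_cv > 0:
        amps = np.array([max(cam_amp, 1.0), pi_amp, _TL_BACKGROUND])
        read = rng.normal(0.0, 1.0, voxels.shape) * (
            config.noise_cv * amps[:, None, None, None] * 0.5
        )
        shot = rng.normal(0.0, 1.0, voxels.shape) * (
            config.noise_cv
            * np.sqrt(np.clip(voxels, 0, None) * amps[:, None, None, None])
            * 0.5
        )
        voxels = np.clip(voxels + read + shot, 0.0, None)

    stack = SpheroidStack(voxels=voxels, pixel_size_um=px)
    truth = {
        "diameter_um": diameter_um,
        "damage": damage,
        "rim_fraction": spec.rim_fraction,
        "core_fraction": spec.core_fraction,
        "cam_peak_radius_um": r_cam,
        "cam_core_pct": 100.0 * 2.0 * r_cam / diameter_um,
        "pi_core_radius_um": core_r,
        "pi_core_pct": 100.0 * 2.0 * core_r / diameter_um,
        "tl_core_pct": 100.0 * 2.0 * core_r / diameter_um,
        "cam_peak_amplitude": cam_amp,
        "pi_amplitude": pi_amp,
    }
    return stack, truth


def default_cohort_specs() -> list[CellLineSpec]:
    """Four qualitative archetypes: sensitive, sensitive-but-slower,
    resistant, and resistant-with-regrowth."""
    return [
        CellLineSpec("SENS-A", doubling_time_h=120.0, gi50_true=0.7,
                     emax_true=0.95, hill=1.5, rim_fraction=0.35,
                     core_fraction=0.35, regrows_after_washout=False,
                     ocr_ecar=1.0),
        CellLineSpec("SENS-B", doubling_time_h=170.0, gi50_true=0.9,
                     emax_true=0.90, hill=1.3, rim_fraction=0.30,
                     core_fraction=0.40, regrows_after_washout=False,
                     ocr_ecar=1.6),
        CellLineSpec("RES-A", doubling_time_h=150.0, gi50_true=6.0,
                     emax_true=0.70, hill=1.2, rim_fraction=0.30,
                     core_fraction=0.45, regrows_after_washout=False,
                     ocr_ecar=3.0),
        CellLineSpec("RES-B", doubling_time_h=140.0, gi50_true=7.0,
                     emax_true=0.60, hill=1.0, rim_fraction=0.25,
                     core_fraction=0.50, regrows_after_washout=True,
                     ocr_ecar=3.5),
    ]


def _stack_damage(spec: CellLineSpec, schedule: TreatmentSchedule,
                  concentration: float, day: int) -> float:
    """Staining damage fraction at a viability day: one cycle's Hill
    inhibition at day 4, compounded over two cycles at day 18."""
    inh = hill_inhibition(concentration, spec)
    cycles = 1 if day <= schedule.cycle1[1] else 2
    return float(min(1.0, 1.0 - (1.0 - inh) ** cycles))


@dataclass
class Cohort:
    """In-memory synthetic study: growth table, viability stacks with
    ground truth and annotations, and the OCR/ECAR table."""

    specs: list[CellLineSpec]
    schedule: TreatmentSchedule
    config: SimulationConfig
    growth: pd.DataFrame
    stacks: list[tuple[dict, "SpheroidStack", dict]] = field(default_factory=list)
    ocr_ecar: pd.DataFrame | None = None


def generate_cohort(
    specs: Sequence[CellLineSpec],
    schedule: TreatmentSchedule | None = None,
    config: SimulationConfig | None = None,
    include_images: bool = True,
) -> Cohort:
    """Generate a full synthetic study for >= 2 cell lines.

    Each viability-day stack is paired with an annotation record
    (cell_line, day, concentration, replicate) and the generator's
    ground-truth geometry, enabling recovery tests downstream.
    """
    specs = list(specs)
    if len(specs) < 2:
        raise ValueError("need at least 2 cell-line specs")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate spec names")
    schedule = schedule or TreatmentSchedule()
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.rng_seed)

    growth_frames = []
    stacks: list[tuple[dict, SpheroidStack, dict]] = []
    max_diam = 0.8 * config.field_um
    for spec in specs:
        for conc in config.concentrations:
            growth_frames.append(
                simulate_growth_timecourse(spec, schedule, conc, config, rng=rng)
            )
            if not include_images:
                continue
            traj = deterministic_area_trajectory(spec, schedule, conc, config)
            for day in schedule.viability_days:
                diam = min(2000.0 * math.sqrt(traj.loc[day] / math.pi), max_diam)
                damage = _stack_damage(spec, schedule, conc, day)
                for rep in range(config.n_viability_replicates):
                    stack, truth = generate_spheroid_stack(
                        diam, spec, damage, config, rng=rng
                    )
                    ann = {
                        "cell_line": spec.name,
                        "day": int(day),
                        "concentration_ug_ml": float(conc),
                        "replicate": int(rep),
                    }
                    stacks.append((ann, stack, truth))

    growth = pd.concat(growth_frames, ignore_index=True)
    ocr = pd.DataFrame(
        {"cell_line": names, "ocr_ecar": [s.ocr_ecar for s in specs]}
    )
    return Cohort(specs=specs, schedule=schedule, config=config,
                  growth=growth, stacks=stacks, ocr_ecar=ocr)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write a cohort to disk: growth CSV, OCR/ECAR CSV, one TIFF plus a
    ground-truth/annotation JSON sidecar per stack."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.growth.to_csv(outdir / "growth.csv", index=False)
    cohort.ocr_ecar.to_csv(outdir / "ocr_ecar.csv", index=False)
    stack_dir = outdir / "stacks"
    stack_dir.mkdir(exist_ok=True)
    for ann, stack, truth in cohort.stacks:
        stem = (
            f"{ann['cell_line']}_day{ann['day']}"
            f"_c{ann['concentration_ug_ml']:g}_r{ann['replicate']}"
        )
        write_stack(stack, stack_dir / f"{stem}.tif")
        with open(stack_dir / f"{stem}.json", "w") as fh:
            json.dump({"annotation": ann, "truth": truth}, fh, indent=1,
                      sort_keys=True)
    with open(outdir / "cohort_config.json", "w") as fh:
        json.dump(
            {
                "specs": [asdict(s) for s in cohort.specs],
                "schedule": asdict(cohort.schedule),
                "config": asdict(cohort.config),
            },
            fh, indent=1, sort_keys=True,
        )
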