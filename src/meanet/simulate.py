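"""Synthetic developing MEA cultures.

Generates spike-list datasets with the statistical structure the analysis
assumes: spontaneous activity appearing at DIV 4, all wells active by
DIV 7, a plateau from DIV 10; activity organized into network bursts that
recruit a random electrode subset, each recruited electrode emitting a
short within-burst spike volley with a small onset jitter; independent
tonic background spiking per electrode; lognormal well-to-well rate
heterogeneity; a sex-specific baseline (more, slightly sparser network
bursts in male wells on DIV 10-17, preserving the total firing rate); and
compound effects as multiplicative changes to the generative knobs that
switch on at a hard onset DIV, emulating the 1-2 week latency of chronic
exposure effects.

Randomness is fully reproducible: every well x DIV gets its own stream
derived from (seed, plate, well, div), so adding wells or days never
perturbs existing ones, and identical config + seed gives byte-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Condition, SpikeTrain, WellRecording

__all__ = [
    "SimConfig",
    "CompoundEffect",
    "KNOBS",
    "development_curve",
    "simulate_well",
    "simulate_experiment",
    "default_plate_design",
    "well_name",
]

#: generative knobs a compound effect may scale
KNOBS = (
    "network_burst_rate",
    "within_burst_rate",
    "burst_duration",
    "recruitment",
    "background_rate",
    "sync_jitter",
)

CONTROL_COMPOUND = "DMSO"


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults of the generator.

    Rates are plateau values; the development curve scales event and
    background rates between onset and plateau.  The default sex effect
    gives male wells x1.25 network-burst rate and x0.8 within-burst spike
    rate on DIV 10-17: higher network-burst counts in males with an
    unchanged total firing rate.
    """

    n_plates: int = 1
    wells_per_plate: int = 48
    electrodes_per_well: int = 16
    recording_days: tuple[int, ...] = (7, 10, 14, 17, 21, 24, 28)
    recording_duration_s: float = 1800.0
    growth_onset_div: int = 4
    growth_plateau_div: int = 10
    baseline_network_burst_rate: float = 6.0  # events/min at plateau
    background_rate: float = 0.3  # tonic spikes/s per electrode at plateau
    within_burst_rate: float = 60.0  # spikes/s per recruited electrode
    burst_duration_mean_s: float = 0.25
    burst_duration_sigma: float = 0.4  # lognormal shape parameter
    recruitment_fraction: float = 0.6
    onset_jitter_s: float = 0.010
    well_heterogeneity_cv: float = 0.2
    sex_effect: dict = field(
        default_factory=lambda: {"network_burst_rate": (1.25, 1.0), "within_burst_rate": (0.8, 1.0)}
    )
    sex_effect_div_range: tuple[int, int] = (10, 17)
    seed: int = 0

    def __post_init__(self):
        for name in (
            "baseline_network_burst_rate",
            "background_rate",
            "within_burst_rate",
            "burst_duration_mean_s",
            "onset_jitter_s",
            "well_heterogeneity_cv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.recruitment_fraction <= 1):
            raise ValueError("recruitment_fraction must be in [0, 1]")
        days = self.recording_days
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("recording_days must be strictly increasing")
        if self.growth_plateau_div <= self.growth_onset_div:
            raise ValueError("growth_plateau_div must exceed growth_onset_div")
        for knob in self.sex_effect:
            if knob not in KNOBS:
                raise ValueError(f"unknown sex_effect knob {knob!r}")

    @property
    def baseline_electrode_rate(self) -> float:
        """Implied mean per-electrode firing rate at plateau (spikes/s)."""
        nb_hz = self.baseline_network_burst_rate / 60.0
        spikes_per_volley = self.within_burst_rate * self.burst_duration_mean_s
        return self.background_rate + nb_hz * self.recruitment_fraction * spikes_per_volley


@dataclass(frozen=True)
class CompoundEffect:
    """A compound x concentration perturbation of the generative knobs.

    Multipliers apply only from ``onset_div`` on (hard onset, the simplest
    mechanism reproducing effects that appear only after 1-2 weeks of
    exposure) and only to wells of a sex in ``sex_scope``.
    """

    compound: str
    concentration_um: float
    knob_multipliers: dict[str, float]
    sex_scope: str = "both"  # "male" | "female" | "both"
    onset_div: int = 14

    def __post_init__(self):
        if self.sex_scope not in ("male", "female", "both"):
            raise ValueError("sex_scope must be 'male', 'female' or 'both'")
        for knob, m in self.knob_multipliers.items():
            if knob not in KNOBS:
                raise ValueError(f"unknown knob {knob!r}")
            if m <= 0:
                raise ValueError("knob multipliers must be positive")

    def active(self, sex: str, div: int) -> bool:
        return div >= self.onset_div and self.sex_scope in ("both", sex)

    def factor(self, knob: str, sex: str, div: int) -> float:
        return self.knob_multipliers.get(knob, 1.0) if self.active(sex, div) else 1.0


def development_curve(config: SimConfig, div: float) -> float:
    """Developmental activity multiplier in [0, 1] at a given DIV.

    0 before activity onset, 1 from the plateau on, and a raised-cosine
    ramp in between (smooth, strictly increasing; only monotonicity and the
    endpoints are contractual).
    """
    if div < 0:
        raise ValueError("div must be >= 0")
    a, b = config.growth_onset_div, config.growth_plateau_div
    if div < a:
        return 0.0
    if div >= b:
        return 1.0
    x = (div - a) / (b - a)
    return 0.5 * (1.0 - math.cos(math.pi * x))


def well_name(index: int, n_cols: int = 8) -> str:
    """0-based well index -> plate label ('A1' ... 'F8' on a 48-well plate)."""
    return f"{chr(ord('A') + index // n_cols)}{index % n_cols + 1}"


def _well_multiplier(config: SimConfig, plate: int, well_index: int) -> float:
    """Lognormal well-level rate multiplier with mean 1 and the configured CV."""
    cv = config.well_heterogeneity_cv
    if cv == 0:
        return 1.0
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, plate, well_index]))
    sig = math.sqrt(math.log(1 + cv * cv))
    return float(rng.lognormal(mean=-0.5 * sig * sig, sigma=sig))


def _sex_factor(config: SimConfig, knob: str, sex: str, div: int) -> float:
    lo, hi = config.sex_effect_div_range
    if not (lo <= div <= hi) or knob not in config.sex_effect:
        return 1.0
    male, female = config.sex_effect[knob]
    return male if sex == "male" else female


def simulate_well(
    config: SimConfig,
    sex: str,
    div: int,
    plate: int = 0,
    well_index: int = 0,
    effect: CompoundEffect | None = None,
    experiment: str = "sim",
) -> WellRecording:
    """Simulate one well at one DIV.

    Network-burst events arrive as a homogeneous Poisson process at the
    development-, heterogeneity-, sex- and effect-scaled rate; each event
    recruits a Binomial(n_electrodes, recruitment) electrode subset, and
    every recruited electrode emits a Poisson-count volley at the
    within-burst rate over a lognormal duration, starting at the event time
    plus a Gaussian onset jitter.  Background spikes are independent
    homogeneous Poisson processes per electrode.
    """
    n_el = config.electrodes_per_well
    T = config.recording_duration_s
    dev = development_curve(config, div)
    m_w = _well_multiplier(config, plate, well_index)
    eff = effect.factor if effect is not None else (lambda k, s, d: 1.0)

    nb_rate = (
        config.baseline_network_burst_rate / 60.0 * dev * m_w
        * _sex_factor(config, "network_burst_rate", sex, div)
        * eff("network_burst_rate", sex, div)
    )
    wb_rate = (
        config.within_burst_rate
        * _sex_factor(config, "within_burst_rate", sex, div)
        * eff("within_burst_rate", sex, div)
    )
    recruit = min(1.0, config.recruitment_fraction * eff("recruitment", sex, div))
    bg = config.background_rate * dev * m_w * eff("background_rate", sex, div)
    dur_mean = config.burst_duration_mean_s * eff("burst_duration", sex, div)
    jitter = config.onset_jitter_s * eff("sync_jitter", sex, div)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, plate, well_index, int(div)]))
    spikes: list[list[np.ndarray]] = [[] for _ in range(n_el)]

    # network-burst events
    n_events = rng.poisson(nb_rate * T)
    event_times = np.sort(rng.uniform(0.0, T, size=n_events))
    sig = config.burst_duration_sigma
    mu_ln = math.log(dur_mean) - 0.5 * sig * sig if dur_mean > 0 else None
    for t_ev in event_times:
        k = rng.binomial(n_el, recruit)
        if k == 0:
            continue
        recruited = rng.choice(n_el, size=k, replace=False)
        for e in recruited:
            onset = t_ev + rng.normal(0.0, jitter) if jitter > 0 else t_ev
            dur = rng.lognormal(mu_ln, sig) if mu_ln is not None else 0.0
            n_sp = rng.poisson(wb_rate * dur)
            if n_sp:
                spikes[e].append(onset + rng.uniform(0.0, dur, size=n_sp))

    # tonic background
    for e in range(n_el):
        n_bg = rng.poisson(bg * T)
        if n_bg:
            spikes[e].append(rng.uniform(0.0, T, size=n_bg))

    trains = {}
    for e in range(n_el):
        t = np.concatenate(spikes[e]) if spikes[e] else np.empty(0)
        t = np.unique(t[(t >= 0.0) & (t <= T)])
        trains[e] = SpikeTrain(electrode=e, spike_times=t, window=(0.0, T))

    cond = Condition(
        compound=effect.compound if effect else CONTROL_COMPOUND,
        concentration_um=effect.concentration_um if effect else 0.0,
        sex=sex,
        experiment=experiment,
    )
    return WellRecording(
        well=f"P{plate}-{well_name(well_index)}",
        div=int(div),
        condition=cond,
        trains=trains,
        duration_s=T,
        n_electrodes=n_el,
        plate=plate,
    )


def default_plate_design(
    config: SimConfig,
    effects: list[CompoundEffect] = (),
    n_control_per_sex: int | None = None,
    plate: int = 0,
) -> pd.DataFrame:
    """Lay out one plate: per-sex solvent controls plus the given conditions.

    Wells alternate sexes and are filled controls-first, then each effect
    condition, split evenly between sexes, until the plate is full.  Returns
    a plate-map frame (plate, well_index, well, compound, concentration_um,
    sex).
    """
    n = config.wells_per_plate
    conds: list[tuple[str, float]] = []
    n_ctrl = n_control_per_sex if n_control_per_sex is not None else max(
        2, n // (2 * (len(effects) + 1))
    )
    conds += [(CONTROL_COMPOUND, 0.0)] * (2 * n_ctrl)
    per_cond = (n - len(conds)) // max(1, len(effects)) if effects else 0
    for e in effects:
        conds += [(e.compound, e.concentration_um)] * per_cond
    conds = conds[:n]
    rows = []
    for i, (comp, conc) in enumerate(conds):
        rows.append(
            dict(
                plate=plate,
                well_index=i,
                well=f"P{plate}-{well_name(i)}",
                compound=comp,
                concentration_um=conc,
                sex="male" if i % 2 == 0 else "female",
            )
        )
    return pd.DataFrame(rows)


def simulate_experiment(
    config: SimConfig,
    design: pd.DataFrame,
    effects: list[CompoundEffect] = (),
    experiment: str = "sim",
) -> tuple[list[WellRecording], pd.DataFrame]:
    """Simulate every well of a plate design at every recording day.

    ``design`` must assign exactly one condition to each well (columns
    plate, well_index, compound, concentration_um, sex).  Returns the
    well recordings (all DIVs) and the plate-map table.
    """
    design = pd.DataFrame(design)
    required = {"plate", "well_index", "compound", "concentration_um", "sex"}
    if missing := required - set(design.columns):
        raise ValueError(f"design is missing columns {sorted(missing)}")
    if design.duplicated(["plate", "well_index"]).any():
        raise ValueError("design assigns more than one condition to a well")
    if (design["well_index"] >= config.wells_per_plate).any() or (design["well_index"] < 0).any():
        raise ValueError("design references an unknown well")
    by_key = {(e.compound, e.concentration_um): e for e in effects}
    recordings = []
    for row in design.itertuples(index=False):
        key = (row.compound, row.concentration_um)
        effect = by_key.get(key)
        if effect is None and row.compound != CONTROL_COMPOUND:
            raise ValueError(f"no CompoundEffect given for condition {key}")
        for div in config.recording_days:
            recordings.append(
                simulate_well(
                    config,
                    sex=row.sex,
                    div=div,
                    plate=int(row.plate),
                    well_index=int(row.well_index),
                    effect=effect,
                    experiment=experiment,
                )
            )
    plate_map = design.assign(
        well=[f"P{int(p)}-{well_name(int(i))}" for p, i in zip(design["plate"], design["well_index"])],
        experiment=experiment,
    )[["well", "compound", "concentration_um", "sex", "experiment", "plate", "well_index"]]
    return recordings, plate_map
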