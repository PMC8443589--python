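"""In-vitro MPS pharmacokinetics.

Recovery against nominal input, rapid-equilibrium-dialysis protein binding,
log-linear half-life estimation, piecewise-exponential simulation of the
daily spike-to-nominal dosing regimen, and translation of clinical exposure
anchors into in-vitro dose levels.

Units are hours and micromolar throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from mpskit.errors import InputError

log = logging.getLogger(__name__)

LN2 = math.log(2.0)


@dataclass
class ConcentrationSeries:
    """Measured analyte concentration over time, with the nominal start."""

    analyte: str
    times_h: np.ndarray
    conc_uM: np.ndarray
    input_conc_uM: float | None = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.conc_uM = np.asarray(self.conc_uM, dtype=float)
        if self.times_h.shape != self.conc_uM.shape:
            raise InputError("times_h and conc_uM must have equal length")
        if self.times_h.size and np.any(np.diff(self.times_h) <= 0):
            raise InputError("times_h must be strictly increasing")
        if np.any(self.conc_uM < 0):
            raise InputError("conc_uM must be non-negative")


@dataclass
class RecoveryResult:
    percent_recovery: float
    n_points: int


@dataclass
class BindingResult:
    fraction_unbound: float
    percent_bound: float
    clipped: bool = False


@dataclass
class PKFit:
    k_per_h: float
    t_half_h: float | None
    c0_uM: float
    r_squared: float
    se_k: float
    n_used: int
    n_excluded: int = 0
    non_eliminating: bool = False


@dataclass
class DoseRegimen:
    """Timed schedule of media interventions.

    ``events`` holds ``(time_h, kind)`` with kind in ``{"full_change_redose",
    "spike_to_nominal"}``; both restore the nominal concentration, a full
    change additionally marks a complete media reset.
    """

    nominal_dose_uM: float
    events: list[tuple[float, str]] = field(default_factory=list)
    duration_h: float = 240.0

    VALID_KINDS = ("full_change_redose", "spike_to_nominal")

    def __post_init__(self) -> None:
        if self.nominal_dose_uM <= 0:
            raise InputError("nominal_dose_uM must be > 0")
        times = [t for t, _ in self.events]
        if any(np.diff(times) <= 0):
            raise InputError("event times must be strictly increasing")
        for t, kind in self.events:
            if not (0 < t <= self.duration_h):
                raise InputError(f"event at t={t} h lies outside (0, duration]")
            if kind not in self.VALID_KINDS:
                raise InputError(f"unknown event kind {kind!r}")

    @classmethod
    def daily(
        cls, nominal_dose_uM: float, duration_h: float = 240.0, full_change_every_h: float = 48.0
    ) -> "DoseRegimen":
        """Daily redosing: full media change every ``full_change_every_h``,
        spikes back to nominal on the intervening days."""
        events = []
        t = 24.0
        while t <= duration_h:
            kind = (
                "full_change_redose"
                if abs(t % full_change_every_h) < 1e-9
                else "spike_to_nominal"
            )
            events.append((t, kind))
            t += 24.0
        return cls(nominal_dose_uM=nominal_dose_uM, events=events, duration_h=duration_h)


@dataclass
class ExposureProfile:
    times_h: np.ndarray
    conc_uM: np.ndarray
    cmax_uM: float
    cmin_uM: float
    c_avg_uM: float
    auc_uM_h: float


@dataclass
class DoseLevel:
    dose_uM: float
    anchor: str
    multiplier: float


@dataclass
class ClinicalAnchor:
    plasma_cmax_uM: float
    liver_cmax_uM: float | None = None
    plasma_protein_binding_pct: float | None = None
    dose_multipliers: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.plasma_cmax_uM <= 0:
            raise InputError("plasma_cmax_uM must be > 0")
        if self.liver_cmax_uM is not None and self.liver_cmax_uM <= 0:
            raise InputError("liver_cmax_uM must be > 0")
        for anchor, mult in self.dose_multipliers:
            if anchor not in ("plasma", "liver"):
                raise InputError(f"unknown anchor {anchor!r}")
            if mult <= 0:
                raise InputError("multipliers must be > 0")


def estimate_recovery(series: ConcentrationSeries) -> RecoveryResult:
    """Percent of the nominal input concentration present at the final
    sampling point: ``100 * final / input``."""
    if series.input_conc_uM is None or series.input_conc_uM <= 0:
        raise InputError("series.input_conc_uM is required and must be > 0")
    if series.conc_uM.size < 1:
        raise InputError("at least one measurement is required")
    pct = 100.0 * float(series.conc_uM[-1]) / series.input_conc_uM
    return RecoveryResult(percent_recovery=pct, n_points=int(series.conc_uM.size))


def estimate_fu(buffer_conc_uM: float, chamber_conc_uM: float) -> BindingResult:
    """Fraction unbound from a rapid-equilibrium-dialysis pair.

    fu = buffer / chamber, clipped to [0, 1] (flagged when clipping fired);
    percent bound = 100 * (1 - fu).
    """
    if chamber_conc_uM <= 0:
        raise InputError("chamber_conc_uM must be > 0")
    if buffer_conc_uM < 0:
        raise InputError("buffer_conc_uM must be >= 0")
    fu = buffer_conc_uM / chamber_conc_uM
    clipped = fu > 1.0
    fu = min(fu, 1.0)
    return BindingResult(
        fraction_unbound=fu, percent_bound=100.0 * (1.0 - fu), clipped=clipped
    )


def fit_halflife(series: ConcentrationSeries) -> PKFit:
    """First-order elimination fit: OLS of ln(concentration) on time.

    k = -slope, t_half = ln 2 / k.  Non-positive concentrations are excluded
    (count logged); fewer than three usable points is an input error; a
    non-positive fitted k is flagged non-eliminating with t_half undefined.
    """
    usable = series.conc_uM > 0
    n_excluded = int((~usable).sum())
    if n_excluded:
        log.info("fit_halflife: excluded %d non-positive measurements", n_excluded)
    t = series.times_h[usable]
    y = np.log(series.conc_uM[usable])
    if t.size < 3:
        raise InputError(f"need >=3 positive measurements, got {t.size}")
    res = stats.linregress(t, y)
    k = -res.slope
    non_elim = k <= 0
    return PKFit(
        k_per_h=float(k),
        t_half_h=None if non_elim else float(LN2 / k),
        c0_uM=float(np.exp(res.intercept)),
        r_squared=float(res.rvalue**2),
        se_k=float(res.stderr),
        n_used=int(t.size),
        n_excluded=n_excluded,
        non_eliminating=bool(non_elim),
    )


def simulate_regimen(
    k_per_h: float, regimen: DoseRegimen, grid_step_h: float = 0.25
) -> ExposureProfile:
    """Piecewise-exponential concentration profile under a dosing schedule.

    Between events C(t) = C(t_e) * exp(-k (t - t_e)); every event resets the
    concentration to the nominal dose.  The grid includes each event time
    twice (pre-event trough, then the post-event reset).  AUC is the exact
    piecewise integral; cmin is the lowest pre-event/terminal trough.
    """
    if k_per_h < 0:
        raise InputError("k_per_h must be >= 0")
    dose = regimen.nominal_dose_uM
    boundaries = [0.0] + [t for t, _ in regimen.events] + [regimen.duration_h]

    times: list[float] = []
    concs: list[float] = []
    auc = 0.0
    troughs: list[float] = []
    for t0, t1 in zip(boundaries[:-1], boundaries[1:]):
        seg = np.arange(t0, t1, grid_step_h)
        if seg.size == 0 or seg[0] > t0:
            seg = np.insert(seg, 0, t0)
        seg = np.append(seg, t1)
        c = dose * np.exp(-k_per_h * (seg - t0))
        times.extend(seg.tolist())
        concs.extend(c.tolist())
        dt = t1 - t0
        if k_per_h == 0:
            auc += dose * dt
            troughs.append(dose)
        else:
            auc += dose / k_per_h * (1.0 - math.exp(-k_per_h * dt))
            troughs.append(dose * math.exp(-k_per_h * dt))

    duration = regimen.duration_h
    return ExposureProfile(
        times_h=np.asarray(times),
        conc_uM=np.asarray(concs),
        cmax_uM=dose,
        cmin_uM=min(troughs),
        c_avg_uM=auc / duration if duration > 0 else dose,
        auc_uM_h=auc,
    )


def translate_dose(anchor: ClinicalAnchor) -> list[DoseLevel]:
    """Clinical-exposure-anchored dose levels, sorted ascending.

    Each multiplier scales its named anchor concentration (plasma or liver
    Cmax); provenance is retained on every returned level.
    """
    levels = []
    for name, mult in anchor.dose_multipliers:
        if name == "plasma":
            base = anchor.plasma_cmax_uM
        else:
            if anchor.liver_cmax_uM is None:
                raise InputError("liver anchor requested but liver_cmax_uM is absent")
            base = anchor.liver_cmax_uM
        levels.append(DoseLevel(dose_uM=base * mult, anchor=name, multiplier=mult))
    return sorted(levels, key=lambda lv: lv.dose_uM)
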