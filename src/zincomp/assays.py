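"""Raw assay readouts -> concentrations and fractions.

Covers the four readout channels of the competition experiments: chromogenic
absorbance kinetics (Zn(PAR)2 at 492 nm), enzyme-rate inhibition (PTP1B with
pNPP), CD-monitored zinc-finger folding at 222 nm, and thiol/zinc
quantitation (DTNB/PAR stoichiometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "KineticTrace",
    "QuantitationResult",
    "PlateauResult",
    "ActivityResult",
    "SaturationResult",
    "absorbance_to_complex_conc",
    "detect_plateau",
    "activity_fraction",
    "cd_saturation_fraction",
    "zn_per_protein",
]


@dataclass(frozen=True)
class KineticTrace:
    """One time-resolved signal (absorbance) trace.

    ``reducing_agent`` records whether a reducing agent (TCEP) was present;
    without it thiol oxidation superimposes a continuous signal drift on the
    equilibration and no true plateau is reached.
    """

    time: np.ndarray  # s, strictly increasing
    signal: np.ndarray  # au
    reducing_agent: bool = True
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)
        if t.ndim != 1 or t.shape != s.shape or t.size < 2:
            raise ValidationError("time and signal must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("time must be strictly increasing")
        if not np.all(np.isfinite(s)):
            raise ValidationError("signal must be finite")


@dataclass(frozen=True)
class QuantitationResult:
    """Thiol/zinc quantitation of one protein sample."""

    thiol_conc: float  # M
    zinc_conc: float  # M
    n_cys: int = 20  # per protein chain; 20 for human MT2

    def __post_init__(self):
        if self.thiol_conc < 0 or self.zinc_conc < 0 or self.n_cys <= 0:
            raise ValidationError("concentrations must be >= 0 and n_cys > 0")

    @property
    def zn_per_protein(self) -> float:
        return zn_per_protein(self.thiol_conc, self.zinc_conc, self.n_cys)


@dataclass(frozen=True)
class PlateauResult:
    value: float  # au
    reached: bool
    tail_slope: float  # au/s
    slope_tol: float  # au/s


@dataclass(frozen=True)
class ActivityResult:
    percent: float
    over_range: bool


@dataclass(frozen=True)
class SaturationResult:
    fraction: float
    out_of_range: bool


def absorbance_to_complex_conc(a: float, epsilon: float, path: float = 1.0) -> float:
    """Beer-Lambert inversion ``A / (epsilon * path)``, in M."""
    if a < 0:
        raise ValidationError("absorbance must be >= 0")
    if epsilon <= 0 or path <= 0:
        raise ValidationError("epsilon and path must be > 0")
    return a / (epsilon * path)


def detect_plateau(
    trace: KineticTrace,
    window: float = 300.0,
    slope_tol: float | None = None,
) -> PlateauResult:
    """Equilibrium-plateau detection on a kinetic trace.

    The plateau value is the mean over the final ``window`` seconds; the
    trace counts as equilibrated when the magnitude of the least-squares
    slope over that window is below ``slope_tol``.

    The default tolerance adapts to the trace: a noise term (three times the
    standard error of a fitted slope under the trace's own point-to-point
    noise, estimated from the median absolute successive difference) plus a
    drift allowance of 0.1% of the full signal scale per window.  A trace
    with a sustained oxidative drift exceeds it; a flat or asymptotically
    saturating trace does not.
    """
    if window <= 0:
        raise ValidationError("window must be > 0")
    t, s = trace.time, trace.signal
    duration = t[-1] - t[0]
    if duration < 2 * window:
        raise ValidationError("trace must span at least twice the window")
    tail = t >= t[-1] - window
    tt, ss = t[tail], s[tail]
    if tt.size < 3:
        raise ValidationError("too few points in the final window")
    slope = float(np.polyfit(tt, ss, 1)[0])
    if slope_tol is None:
        diffs = np.abs(np.diff(s))
        sigma = 1.4826 * float(np.median(diffs)) / np.sqrt(2.0)
        n = tt.size
        se_slope = sigma * np.sqrt(12.0 / n) / window if sigma > 0 else 0.0
        scale = float(np.max(np.abs(s))) or 1.0
        slope_tol = 3.0 * se_slope + 1e-3 * scale / window
    return PlateauResult(
        value=float(np.mean(ss)),
        reached=abs(slope) < slope_tol,
        tail_slope=slope,
        slope_tol=float(slope_tol),
    )


def activity_fraction(rate_sample: float, rate_control: float) -> ActivityResult:
    """Residual enzyme activity, percent of an uninhibited control.

    ``100 * rate_sample / rate_control``, clipped to [0, 100] with an
    ``over_range`` flag when the sample nominally exceeds the control.
    """
    if rate_control <= 0:
        raise ValidationError("rate_control must be > 0")
    if rate_sample < 0:
        raise ValidationError("rate_sample must be >= 0")
    pct = 100.0 * rate_sample / rate_control
    over = pct > 100.0
    return ActivityResult(percent=min(pct, 100.0), over_range=over)


def cd_saturation_fraction(
    theta_obs: float, theta_apo: float, theta_holo: float
) -> SaturationResult:
    """Zinc-finger saturation from ellipticity at 222 nm.

    Linear interpolation between the metal-free and Zn-saturated baselines,
    clipped to [0, 1] with a flag when noise puts the reading outside them.
    """
    if theta_apo == theta_holo:
        raise ValidationError("degenerate baselines: theta_apo == theta_holo")
    frac = (theta_obs - theta_apo) / (theta_holo - theta_apo)
    out = frac < 0.0 or frac > 1.0
    return SaturationResult(fraction=float(np.clip(frac, 0.0, 1.0)), out_of_range=out)


def zn_per_protein(thiol_conc: float, zinc_conc: float, n_cys: int = 20) -> float:
    """Zn(II) equivalents per protein from thiol and zinc concentrations.

    ``zinc_conc * n_cys / thiol_conc``: the thiol assay counts ``n_cys``
    cysteines per chain, so protein = thiol/n_cys.  Scale-invariant in the
    two concentrations.  A Zn/thiol ratio of 0.335 with 20 Cys gives the
    full-loading hallmark of 6.7 Zn per protein.
    """
    if thiol_conc <= 0:
        raise ValidationError("thiol_conc must be > 0")
    if zinc_conc < 0:
        raise ValidationError("zinc_conc must be >= 0")
    if n_cys <= 0:
        raise ValidationError("n_cys must be > 0")
    return zinc_conc * n_cys / thiol_conc
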