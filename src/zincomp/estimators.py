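"""Affinity estimators for competition observations.

Three inference schemes convert a measured amount of transferred metal into
a dissociation constant of the donor protein:

* **step-wise** (:func:`kd1_stepwise`) -- only the weakest site exchanges;
  the exchange constant relates the fully loaded and once-depleted protein,
  and ``K_d1 = K_d(competitor) * K_ex``.
* **cooperative** (:func:`kdav_cooperative`) -- the deliberately simplified
  all-or-nothing model in which all ``n`` sites share one constant; it
  yields an *average* constant whose value depends on competitor strength
  and concentration.  Keeping the two schemes apart is the central point of
  this package: estimates carry a mandatory model tag and are never merged
  silently.
* **CI-based** (:func:`kd1_from_ci`) -- competition against a hypothetical
  1:1 aggregate ligand Z whose apparent constant is ``10**(-CI)``; used for
  low-molecular-weight ligands with mixed stoichiometries.

Plus probe-readout (:func:`free_metal_from_fluorescence`) and curve-level
(:func:`fit_transfer_isotherm`, :func:`match_hypothetical_site`) utilities.

Free-ligand concentrations are depletion-corrected: ``L_free = L_total -
stoich * transferred`` (competitions run up to ~235-fold ligand excess,
where the correction is small but nonzero).
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from lmfit import Model as LmfitModel

from .errors import (
    FitFailureError,
    NoTransferError,
    NoTransitionError,
    OutOfRegimeError,
    ProbeSaturationError,
    ValidationError,
)
from .system import CompetitorLigand

__all__ = [
    "CompetitionObservation",
    "FluorescenceCalibration",
    "CIContext",
    "AffinityEstimate",
    "IsothermFit",
    "kd1_stepwise",
    "kdav_cooperative",
    "kd1_from_ci",
    "free_metal_from_fluorescence",
    "fit_transfer_isotherm",
    "match_hypothetical_site",
    "combine_replicates",
]

ModelTag = Literal["stepwise", "cooperative", "ci_based", "grid_matched"]


@dataclass(frozen=True)
class CompetitionObservation:
    """One measured competition point.

    ``transferred_metal`` is the metal-complex concentration formed with the
    competitor (equivalents times receptor total, if reported per protein).
    """

    receptor_total: float
    competitor: CompetitorLigand
    transferred_metal: float
    replicate_id: str | None = None

    def __post_init__(self):
        if self.receptor_total <= 0:
            raise ValidationError("receptor_total must be > 0")
        if self.transferred_metal < 0:
            raise ValidationError("transferred_metal must be >= 0")


@dataclass(frozen=True)
class FluorescenceCalibration:
    """One fluorescence reading with its probe calibration.

    ``f`` is the measured intensity, ``f0`` the metal-free baseline,
    ``fmin``/``fmax`` the EDTA- and Zn-saturated calibration intensities,
    ``probe_kd`` the 1:1 probe constant in M.
    """

    f: float
    f0: float
    fmin: float
    fmax: float
    probe_kd: float

    def __post_init__(self):
        if self.probe_kd <= 0:
            raise ValidationError("probe_kd must be > 0")
        if not self.fmin < self.fmax:
            raise ValidationError("fmin must be < fmax")


@dataclass(frozen=True)
class CIContext:
    """Competitivity-index context for an LMW-ligand competition.

    ``ci`` is -log10 of the apparent dissociation constant of the aggregate
    1:1 ZnZ complex at ``ligand_total``.
    """

    ci: float
    ligand_total: float
    label: str = ""

    def __post_init__(self):
        if not np.isfinite(self.ci):
            raise ValidationError("ci must be finite")
        if self.ligand_total <= 0:
            raise ValidationError("ligand_total must be > 0")


@dataclass(frozen=True)
class AffinityEstimate:
    """A -log10 K_d with its inference-model tag.

    The tag is mandatory so cooperative and step-wise numbers are never
    conflated; ``inputs_digest`` fingerprints the inputs for provenance.
    """

    neg_log_kd: float
    model: ModelTag
    uncertainty: float = 0.0
    inputs_digest: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if not np.isfinite(self.neg_log_kd):
            raise ValidationError("neg_log_kd must be finite")


def _digest(*parts) -> str:
    raw = "|".join(repr(p) for p in parts).encode()
    return hashlib.sha1(raw).hexdigest()[:12]


def _single_event_concs(obs: CompetitionObservation) -> tuple[float, float, float]:
    """([donor depleted], [donor loaded], free ligand) in the one-event regime."""
    x = obs.transferred_metal
    r = obs.receptor_total
    if x == 0:
        raise NoTransferError("no metal transferred; K_d1 is undefined")
    if x >= r:
        raise OutOfRegimeError(
            "transferred metal >= receptor total: the second dissociation "
            "event dominates, outside the single-event regime"
        )
    free_lig = obs.competitor.total_conc - obs.competitor.stoich * x
    if free_lig <= 0:
        raise ValidationError("competitor fully depleted; totals inconsistent")
    return x, r - x, free_lig


def kd1_stepwise(obs: CompetitionObservation) -> AffinityEstimate:
    """Weakest-site constant from the step-wise exchange model.

    With transferred metal ``x``: the once-depleted protein concentration is
    ``x``, the loaded protein is ``R - x``, the metal-competitor complex is
    ``x``, and ``K_ex = x * x / ((R - x) * L_free**stoich)``.  Then
    ``K_d1 = K_d(competitor) * K_ex``.
    """
    x, loaded, free_lig = _single_event_concs(obs)
    log_kex = (
        2.0 * math.log10(x)
        - math.log10(loaded)
        - obs.competitor.stoich * math.log10(free_lig)
    )
    neg_log = -(math.log10(obs.competitor.kd) + log_kex)
    return AffinityEstimate(
        neg_log_kd=neg_log,
        model="stepwise",
        inputs_digest=_digest("stepwise", obs.receptor_total, obs.competitor,
                              obs.transferred_metal),
    )


def kdav_cooperative(
    obs: CompetitionObservation,
    n_sites: int = 7,
    per_ion: Literal["root", "divide"] = "root",
) -> AffinityEstimate:
    """Average constant under the all-or-nothing cooperative model.

    With transferred metal ``x`` and ``n`` sites assumed identical, the apo
    protein is ``x/n``, the loaded protein ``R - x/n``, and

        K_ex^coop = x**n * (x/n) / ((R - x/n) * L_free**(stoich*n))
        K_d(1..n)^av = K_d(competitor)**n * K_ex^coop      (units M^n)

    ``per_ion`` controls the reduction to a per-ion constant: ``"root"``
    (default) takes the n-th root (divide -log by n), the only reduction
    consistent with per-ion constants spanning ~1e-11..1e-8 M when the bulk
    constant spans 1e-78..1e-54 M^7; ``"divide"`` reproduces the literal
    arithmetic K^av = K_d(1..n)^av / n sometimes quoted, and is exposed for
    comparison only.
    """
    if n_sites < 1:
        raise ValidationError("n_sites must be >= 1")
    x = obs.transferred_metal
    r = obs.receptor_total
    if x == 0:
        raise NoTransferError("no metal transferred")
    if x >= n_sites * r:
        raise OutOfRegimeError("transferred metal >= site capacity")
    apo = x / n_sites
    loaded = r - apo
    free_lig = obs.competitor.total_conc - obs.competitor.stoich * x
    if free_lig <= 0:
        raise ValidationError("competitor fully depleted; totals inconsistent")
    log_kex = (
        n_sites * math.log10(x)
        + math.log10(apo)
        - math.log10(loaded)
        - obs.competitor.stoich * n_sites * math.log10(free_lig)
    )
    log_kd_bulk = n_sites * math.log10(obs.competitor.kd) + log_kex
    if per_ion == "root":
        neg_log = -log_kd_bulk / n_sites
    elif per_ion == "divide":
        neg_log = -(log_kd_bulk - math.log10(n_sites))
    else:
        raise ValidationError("per_ion must be 'root' or 'divide'")
    return AffinityEstimate(
        neg_log_kd=neg_log,
        model="cooperative",
        inputs_digest=_digest("cooperative", n_sites, per_ion, obs.receptor_total,
                              obs.competitor, obs.transferred_metal),
    )


def kd1_from_ci(obs: CompetitionObservation, ctx: CIContext) -> AffinityEstimate:
    """Weakest-site constant from competitivity-index arithmetic.

    The real ligand is replaced by a hypothetical 1:1 ligand Z with
    ``K_d(ZnZ) = 10**(-CI)`` at its stated total concentration:

        K_d1 = K_d(ZnZ) * [depleted][ZnZ] / ([loaded][Z])

    with ``[ZnZ] = x``, ``[Z] = Z_total - x``.  For a true 1:1 competitor
    with ``CI = -log10(kd)`` this is identical to :func:`kd1_stepwise`.
    """
    x = obs.transferred_metal
    r = obs.receptor_total
    if x == 0:
        raise NoTransferError("no metal transferred")
    if x >= r:
        raise OutOfRegimeError("transferred metal >= receptor total")
    free_z = ctx.ligand_total - x
    if free_z <= 0:
        raise ValidationError("aggregate ligand fully depleted")
    log_kd1 = -ctx.ci + 2.0 * math.log10(x) - math.log10(r - x) - math.log10(free_z)
    return AffinityEstimate(
        neg_log_kd=-log_kd1,
        model="ci_based",
        inputs_digest=_digest("ci", ctx, obs.receptor_total, obs.transferred_metal),
    )


def free_metal_from_fluorescence(cal: FluorescenceCalibration) -> float:
    """Free metal from a turn-on 1:1 probe reading.

    For a probe whose intensity rises from the metal-free level ``Fmin`` to
    the saturated level ``Fmax``, the bound:free probe ratio is
    ``(F - Fmin)/(Fmax - F)`` and

        [M]_free = K_d(probe) * (F - Fmin) / (Fmax - F).

    Readings at or below Fmin return 0 with an underflow warning; readings
    at or above Fmax mean the probe is saturated and free metal is not
    determinable.  (Published statements of this relation sometimes carry
    the ratio inverted; only this orientation is consistent with a turn-on
    calibration in which EDTA gives Fmin and excess metal gives Fmax.)
    """
    if cal.f >= cal.fmax:
        raise ProbeSaturationError(
            "F >= Fmax: probe saturated, free metal not determinable"
        )
    if cal.f <= cal.fmin:
        warnings.warn(
            "F <= Fmin: free metal below probe response, returning 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return cal.probe_kd * (cal.f - cal.fmin) / (cal.fmax - cal.f)


@dataclass(frozen=True)
class IsothermFit:
    """Logistic fit of a transfer isotherm in -log free-metal coordinates."""

    midpoint: float  # -logK_d at the inflection
    hill_n: float
    plateau: float
    midpoint_stderr: float
    hill_stderr: float


def _logistic(x, midpoint, hill_n, plateau):
    return plateau / (1.0 + 10.0 ** (hill_n * (midpoint - x)))


def fit_transfer_isotherm(
    points: Sequence[tuple[float, float]],
    noise_floor: float = 0.0,
    fix_plateau: float | None = None,
) -> IsothermFit:
    """Least-squares logistic fit of transferred equivalents vs -log[M]_free.

    The abscissa is ``-log10`` of free metal, so transfer *increases* with
    the abscissa (lower free metal at stronger competition draws more metal
    off the protein); the inflection abscissa equals the -logK_d of the
    transferring site and the fitted Hill slope ``n`` exceeds 1 when more
    than one site overlaps in the window.

    ``noise_floor`` is the smallest ordinate range that counts as a real
    transition; data with a smaller (or zero) range raise
    :class:`NoTransitionError`.  ``fix_plateau`` pins the upper plateau
    (e.g. at 1.0 equivalent when only the weakest site transfers in the
    fitted window) instead of fitting it.

    Initialisation: midpoint at the abscissa median, ``n = 1`` (bounded to
    [0.3, 5]), plateau at the maximum observed transfer.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 5:
        raise ValidationError("need >= 5 (x, y) points spanning a transition")
    x, y = pts[:, 0], pts[:, 1]
    span = float(np.ptp(y))
    if span == 0.0 or span <= noise_floor:
        raise NoTransitionError("data show no transition above the noise floor")
    model = LmfitModel(_logistic)
    plateau_spec = (
        dict(value=float(fix_plateau), vary=False)
        if fix_plateau is not None
        else dict(value=float(y.max()), min=1e-12)
    )
    params = model.make_params(
        midpoint=float(np.median(x)),
        hill_n=dict(value=1.0, min=0.3, max=5.0),
        plateau=plateau_spec,
    )
    result = model.fit(y, params, x=x)
    if not result.success:
        raise FitFailureError(f"isotherm fit did not converge: {result.message}")
    if result.covar is None or not np.all(np.isfinite(result.covar)):
        raise FitFailureError("isotherm fit has no finite covariance")
    p = result.params
    return IsothermFit(
        midpoint=float(p["midpoint"].value),
        hill_n=float(p["hill_n"].value),
        plateau=float(p["plateau"].value),
        midpoint_stderr=float(p["midpoint"].stderr or np.nan),
        hill_stderr=float(p["hill_n"].stderr or np.nan),
    )


def match_hypothetical_site(
    points: Sequence[tuple[float, float]],
    scenario: Callable[[float, float], float],
    family: Sequence[float] | None = None,
) -> AffinityEstimate:
    """Grid-match observations against a family of hypothetical donor sites.

    ``scenario(neg_log_kd, x)`` predicts the observable (saturation
    fraction, residual activity, ...) at abscissa ``x`` for a donor site of
    the given affinity.  The returned estimate is the grid member minimising
    the sum of squared residuals; ties break toward the weaker affinity
    (smaller -logK_d), and a best fit at either grid edge is flagged
    ``"boundary"`` -- the affinity lies outside the resolvable window.

    The default grid spans -logK_d 7..12 in steps of 0.1, mirroring the
    +/-0.1 resolution such overlays support.
    """
    pts = list(points)
    if len(pts) < 1:
        raise ValidationError("need at least one observation point")
    if family is None:
        family = np.round(np.arange(7.0, 12.0 + 1e-9, 0.1), 10)
    family = np.asarray(family, dtype=float)
    if family.size < 2:
        raise ValidationError("family grid needs >= 2 members")
    sse = np.empty(family.size)
    for i, nlk in enumerate(family):
        sse[i] = sum((scenario(float(nlk), float(x)) - float(obs)) ** 2
                     for x, obs in pts)
    best = int(np.argmin(sse))  # argmin takes the first (weakest) on ties
    step = float(np.min(np.diff(np.sort(family))))
    flags = ("boundary",) if best in (0, family.size - 1) else ()
    if flags:
        warnings.warn(
            "best grid match at the edge of the affinity window; the true "
            "constant is outside the resolvable range",
            RuntimeWarning,
            stacklevel=2,
        )
    return AffinityEstimate(
        neg_log_kd=float(family[best]),
        model="grid_matched",
        uncertainty=step,
        inputs_digest=_digest("grid", tuple(map(tuple, pts)), tuple(family)),
        flags=flags,
    )


def combine_replicates(estimates: Sequence[AffinityEstimate]) -> AffinityEstimate:
    """Mean +/- SD across replicate estimates of a *single* model tag.

    Mixing model tags (e.g. averaging a cooperative with a step-wise value)
    raises, by design: the two numbers answer different questions.
    """
    if len(estimates) == 0:
        raise ValidationError("no estimates to combine")
    tags = {e.model for e in estimates}
    if len(tags) > 1:
        raise ValidationError(
            f"refusing to average across model tags {sorted(tags)}; "
            "combine per-model estimates explicitly"
        )
    vals = np.array([e.neg_log_kd for e in estimates])
    return AffinityEstimate(
        neg_log_kd=float(vals.mean()),
        model=estimates[0].model,
        uncertainty=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        inputs_digest=_digest("combined", tuple(e.inputs_digest for e in estimates)),
        flags=tuple(sorted({f for e in estimates for f in e.flags})),
    )
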