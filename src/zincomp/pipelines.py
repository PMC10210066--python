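"""End-to-end analysis pipelines: raw assay tables -> affinity estimates.

These functions chain the assay-readout models and the estimators exactly
the way an analyst would process the corresponding experiment, and are the
inverse of the :mod:`zincomp.synth` generators -- the round-trip
(generate -> pipeline) recovers the generating constants and is the basis
of the parameter-recovery tests.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from . import constants
from .assays import KineticTrace, absorbance_to_complex_conc, detect_plateau
from .errors import ValidationError, ZincompError
from .estimators import (
    AffinityEstimate,
    CompetitionObservation,
    FluorescenceCalibration,
    IsothermFit,
    combine_replicates,
    fit_transfer_isotherm,
    free_metal_from_fluorescence,
    kd1_stepwise,
)
from .system import CompetitorLigand

__all__ = ["kd1_from_par_kinetics", "kd1_from_probe_titration"]


def kd1_from_par_kinetics(
    traces: Iterable[KineticTrace],
    mt_conc: float,
    epsilon: float = constants.EPSILON_PAR_492,
    path: float = 1.0,
) -> AffinityEstimate:
    """Weakest-site constant from chromogenic-chelator kinetic traces.

    Each trace must carry its competitor concentration in
    ``meta["par_conc"]``.  The equilibrium plateau is located, converted to
    metal-complex concentration by Beer-Lambert inversion, and fed to the
    step-wise estimator; traces that never reach a plateau (no reducing
    agent) or fall outside the single-event regime are skipped.  Replicate
    estimates are combined as mean +/- SD.
    """
    estimates = []
    for trace in traces:
        plateau = detect_plateau(trace)
        if not plateau.reached:
            continue
        conc = absorbance_to_complex_conc(max(plateau.value, 0.0), epsilon, path)
        par_conc = trace.meta.get("par_conc")
        if par_conc is None:
            raise ValidationError("trace.meta must carry 'par_conc'")
        obs = CompetitionObservation(
            receptor_total=mt_conc,
            competitor=CompetitorLigand(
                kd=constants.PAR_KD12, stoich=2, total_conc=par_conc, label="PAR"
            ),
            transferred_metal=conc,
        )
        try:
            estimates.append(kd1_stepwise(obs))
        except ZincompError:
            continue
    if not estimates:
        raise ValidationError("no usable equilibrated traces in the single-event regime")
    return combine_replicates(estimates)


def kd1_from_probe_titration(
    table: pd.DataFrame,
    mt_conc: float,
    probe_kd: float = constants.ZNAF2F_KD,
    max_released_eq: float = 0.95,
) -> tuple[IsothermFit, list[tuple[float, float]]]:
    """Weakest-site constant from a fluorescent-probe titration table.

    For each titration point the probe calibration gives the free metal
    (ratiometric inversion) and the probe-bound metal; the *released*
    equivalents per protein count both pools,

        released_eq = [M-probe]/[MT] + [M]_free/[MT],

    because at sub-micromolar probe a sizeable share of the mobilised metal
    stays free in solution rather than on the probe.  The released-vs-
    -log[M]_free isotherm is then fitted as a logistic restricted to the
    single-event window (``released_eq <= max_released_eq``) with the
    plateau pinned at one equivalent; its midpoint is the weakest-site
    -logK_d.

    Returns the fit and the (abscissa, released_eq) points used.
    """
    required = {"probe_conc_M", "f", "fmin", "fmax"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"titration table missing columns {sorted(missing)}")
    pts: list[tuple[float, float]] = []
    for _, row in table.iterrows():
        if row["probe_conc_M"] <= 0:
            continue
        try:
            cal = FluorescenceCalibration(
                f=row["f"], f0=row.get("f0", row["fmin"]),
                fmin=row["fmin"], fmax=row["fmax"], probe_kd=probe_kd,
            )
            free = free_metal_from_fluorescence(cal)
        except ZincompError:
            continue
        if free <= 0:
            continue
        bound_eq = (
            (row["f"] - row["fmin"]) / (row["fmax"] - row["fmin"])
            * row["probe_conc_M"] / mt_conc
        )
        pts.append((-float(np.log10(free)), bound_eq + free / mt_conc))
    window = [(x, y) for x, y in pts if y <= max_released_eq]
    fit = fit_transfer_isotherm(window, fix_plateau=1.0)
    return fit, pts
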