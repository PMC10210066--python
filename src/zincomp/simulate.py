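"""Model-critique and overlay simulations.

These reproduce, from the packaged constants, the computational arguments of
the analysis: the apparent-average-constant bias surface (the "average"
constant of a differentiated-site protein is an artefact of competitor
strength and concentration), the competitor-independent buffering isotherm,
hypothetical-donor transfer families for overlaying on zinc-finger
saturation or enzyme-inhibition data, and metal-loading titrations that pit
a metallothionein model against a single-site zinc finger.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import constants
from .equilibrium import pairwise_exchange, solve_speciation, transfer_fraction_vs_free_metal
from .errors import ValidationError, ZincompError
from .estimators import CompetitionObservation, kdav_cooperative
from .system import CompetitorLigand, MultiSiteReceptor, SystemDefinition

__all__ = [
    "CompetitorGrid",
    "BiasSurface",
    "simulate_bias_surface",
    "zf_saturation_scenario",
    "ptp1b_activity_scenario",
    "simulate_transfer_scenarios",
    "simulate_loading_titration",
    "buffering_isotherm",
]


@dataclass(frozen=True)
class CompetitorGrid:
    """A family of hypothetical 1:1 competitors.

    ``kds`` spans the probe-affinity axis (default 1e-14..1e-6 M), ``concs``
    the total-concentration axis.  Both must be positive and sorted
    ascending.
    """

    kds: tuple[float, ...]
    concs: tuple[float, ...]
    stoich: int = 1

    def __post_init__(self):
        object.__setattr__(self, "kds", tuple(self.kds))
        object.__setattr__(self, "concs", tuple(self.concs))
        for name, vals in (("kds", self.kds), ("concs", self.concs)):
            if len(vals) == 0 or any(v <= 0 for v in vals):
                raise ValidationError(f"{name} must be positive and non-empty")
            if any(vals[i] > vals[i + 1] for i in range(len(vals) - 1)):
                raise ValidationError(f"{name} must be sorted ascending")
        if self.stoich not in (1, 2):
            raise ValidationError("stoich must be 1 or 2")

    @classmethod
    def default(cls, n_kds: int = 17, n_concs: int = 12) -> "CompetitorGrid":
        """Probe affinities 1e-14..1e-6 M; totals from the 5 uM floor of the
        chromogenic competition up to 10 mM (tight-chelator excess)."""
        return cls(
            kds=tuple(np.geomspace(1e-14, 1e-6, n_kds)),
            concs=tuple(np.geomspace(5e-6, 1e-2, n_concs)),
        )


@dataclass(frozen=True)
class BiasSurface:
    """Tidy per-cell result of :func:`simulate_bias_surface`.

    ``table`` columns: ``kd``, ``conc``, ``transferred_pct`` (of total
    metal), ``neg_log_kdav`` (the naive cooperative per-ion estimate), and
    ``note`` (empty, or why the cell could not be evaluated).
    """

    table: pd.DataFrame

    def pivot(self, value: str = "neg_log_kdav") -> pd.DataFrame:
        return self.table.pivot(index="kd", columns="conc", values=value)


def simulate_bias_surface(
    receptor: MultiSiteReceptor,
    grid: CompetitorGrid,
    metal_eq: float | None = None,
) -> BiasSurface:
    """Naive average-constant bias across a competitor grid.

    For every (kd, conc) cell the *true* differentiated-site model is solved
    to equilibrium, and the transferred metal is then fed to the cooperative
    estimator exactly as a single-competition experiment would be analysed.
    The generating model is fixed; any variation of the returned
    ``neg_log_kdav`` across the surface is estimator bias, not protein
    chemistry.
    """
    if receptor.total_conc <= 0:
        raise ValidationError("receptor total_conc must be > 0")
    n = receptor.n_sites
    total_metal = (metal_eq if metal_eq is not None else n) * receptor.total_conc
    rows = []
    for kd in grid.kds:
        for conc in grid.concs:
            lig = CompetitorLigand(kd=kd, stoich=grid.stoich, total_conc=conc)
            note = ""
            pct = np.nan
            neg_log = np.nan
            try:
                state = solve_speciation(
                    SystemDefinition(
                        receptors=(receptor,), ligands=(lig,), total_metal=total_metal
                    )
                )
                transferred = state.complex_conc[0]
                pct = 100.0 * transferred / total_metal
                obs = CompetitionObservation(
                    receptor_total=receptor.total_conc,
                    competitor=lig,
                    transferred_metal=transferred,
                )
                neg_log = kdav_cooperative(obs, n_sites=n).neg_log_kd
            except ZincompError as exc:
                note = f"{type(exc).__name__}: {exc}"
            rows.append(
                {"kd": kd, "conc": conc, "transferred_pct": pct,
                 "neg_log_kdav": neg_log, "note": note}
            )
    return BiasSurface(table=pd.DataFrame(rows))


def zf_saturation_scenario(
    acceptor_kd: float = constants.ZF133_11_CE_KD,
    acceptor_total: float = 5e-6,
) -> Callable[[float, float], float]:
    """Zinc-finger saturation vs donor affinity, pairwise-exchange model.

    Returns ``f(neg_log_kd, ratio)``: the saturation fraction of the
    acceptor when titrated with ``ratio * acceptor_total`` of a single-site
    donor of the given -logK_d.
    """

    def predict(neg_log_kd: float, ratio: float) -> float:
        if ratio <= 0:
            return 0.0
        donor_total = ratio * acceptor_total
        _, bound = pairwise_exchange(
            10.0 ** (-neg_log_kd), donor_total, acceptor_kd, acceptor_total
        )
        return bound / acceptor_total

    return predict


def ptp1b_activity_scenario(
    enzyme_kd: float = constants.PTP1B_KD,
    enzyme_total: float = 0.1e-6,
) -> Callable[[float, float], float]:
    """Residual enzyme activity (percent) vs donor affinity.

    Returns ``f(neg_log_kd, ratio)``: percent activity remaining after
    equilibration with ``ratio * enzyme_total`` of a single-site donor
    (equimolar incubation is ``ratio = 1``).  Activity is 100 times the
    zinc-free enzyme fraction.
    """

    def predict(neg_log_kd: float, ratio: float = 1.0) -> float:
        if ratio <= 0:
            return 100.0
        donor_total = ratio * enzyme_total
        _, bound = pairwise_exchange(
            10.0 ** (-neg_log_kd), donor_total, enzyme_kd, enzyme_total
        )
        return 100.0 * (1.0 - bound / enzyme_total)

    return predict


def simulate_transfer_scenarios(
    scenario: Callable[[float, float], float],
    kd_family: Sequence[float],
    xs: Sequence[float],
) -> pd.DataFrame:
    """One transfer/inhibition curve per hypothetical donor affinity.

    ``kd_family`` lists donor -logK_d values; ``xs`` the abscissa (molar
    ratio).  Returns a tidy frame with columns ``neg_log_kd``, ``x``,
    ``value``.  Curves are strictly ordered: at any abscissa a tighter donor
    releases less metal.
    """
    fam = np.asarray(kd_family, dtype=float)
    xs = np.asarray(xs, dtype=float)
    if fam.size == 0 or xs.size == 0:
        raise ValidationError("kd_family and xs must be non-empty")
    rows = [
        {"neg_log_kd": float(nlk), "x": float(x), "value": scenario(float(nlk), float(x))}
        for nlk in fam
        for x in xs
    ]
    return pd.DataFrame(rows)


def simulate_loading_titration(
    receptor_a: MultiSiteReceptor,
    receptor_b: CompetitorLigand,
    metal_eq_grid: Sequence[float],
) -> pd.DataFrame:
    """Metal-loading titration of a metallothionein + zinc-finger mixture.

    ``metal_eq_grid`` counts added metal in equivalents of
    ``receptor_a.total_conc``.  At each point the full speciation is solved
    and the apo fraction of the single-site receptor B (the zinc finger) is
    reported alongside the mean site occupancy of A.  Swap ``receptor_a``
    between the packaged solution and ESI-MS constant sets to compare
    models.
    """
    if receptor_a.total_conc <= 0 or receptor_b.total_conc <= 0:
        raise ValidationError("both totals must be > 0")
    eqs = np.asarray(metal_eq_grid, dtype=float)
    if eqs.size == 0 or np.any(eqs < 0):
        raise ValidationError("metal_eq_grid must be non-negative and non-empty")
    rows = []
    for eq in eqs:
        total_metal = eq * receptor_a.total_conc
        state = solve_speciation(
            SystemDefinition(
                receptors=(receptor_a,), ligands=(receptor_b,), total_metal=total_metal
            )
        )
        bound_b = state.complex_conc[0]
        rows.append(
            {
                "metal_eq": float(eq),
                "free_metal": state.free_metal,
                "apo_fraction_b": 1.0 - bound_b / receptor_b.total_conc,
                "mean_occupancy_a": float(np.mean(state.site_occupancy[0])),
            }
        )
    return pd.DataFrame(rows)


def buffering_isotherm(
    receptor: MultiSiteReceptor,
    probe_kds: Sequence[float],
    probe_concs: Sequence[float],
    metal_eq: float | None = None,
) -> pd.DataFrame:
    """Released fraction vs the solver's own free metal, per competitor.

    Full speciation of the receptor against each (kd, conc) 1:1 probe; the
    released receptor fraction plotted against free metal collapses onto
    :func:`transfer_fraction_vs_free_metal` for *any* competitor -- the
    buffering isotherm is a property of the receptor alone.
    """
    n = receptor.n_sites
    total_metal = (metal_eq if metal_eq is not None else n) * receptor.total_conc
    rows = []
    for kd in probe_kds:
        for conc in probe_concs:
            lig = CompetitorLigand(kd=kd, stoich=1, total_conc=conc)
            state = solve_speciation(
                SystemDefinition(
                    receptors=(receptor,), ligands=(lig,), total_metal=total_metal
                )
            )
            bound = receptor.total_conc * sum(state.site_occupancy[0])
            loaded0 = n * receptor.total_conc
            released = 1.0 - bound / loaded0
            expected = transfer_fraction_vs_free_metal(receptor, [state.free_metal])[0, 1]
            rows.append(
                {
                    "probe_kd": kd,
                    "probe_conc": conc,
                    "free_metal": state.free_metal,
                    "released_fraction": released,
                    "isotherm_fraction": expected,
                }
            )
    return pd.DataFrame(rows)
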