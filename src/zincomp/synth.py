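"""Seeded synthetic assay datasets from a ground-truth binding model.

Every generator is a pure function of ``(truth, parameters, seed)``: the
equilibrium (or exchange) outcome is computed from the ground-truth
constants with the same machinery the estimators later invert, a
phenomenological kinetic/readout layer is applied, and a documented noise
model is added from a single ``numpy.random.default_rng(seed)`` stream.

Noise model: multiplicative Gaussian with relative sigma ``noise_sigma``
(spectroscopic readouts scale with concentration) plus an additive floor of
``noise_floor_frac`` of full scale.  Defaults: 2% multiplicative, 0.1%
floor.  ``noise_sigma = 0`` yields the exact noiseless forward model.

The generators emulate equilibrium readouts and simple first-order
approach kinetics; they do not emulate instrument drift correction,
inner-filter effects or mechanistic oxidation chemistry (the no-reducing-
agent drift is a phenomenological linear term).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from . import constants
from .assays import KineticTrace
from .equilibrium import pairwise_exchange, solve_speciation
from .errors import ValidationError
from .estimators import CIContext
from .system import CompetitorLigand, MultiSiteReceptor, SystemDefinition

__all__ = [
    "GroundTruth",
    "gen_par_kinetics",
    "gen_probe_titration",
    "gen_activity_assay",
    "gen_cd_titration",
    "gen_sec_partition",
]

_DEFAULT_RECEPTOR = MultiSiteReceptor(
    site_kds=constants.MT2_REF32_KDS, total_conc=1.7e-6, label="mt2_ref32"
)


class GroundTruth(BaseModel):
    """Ground-truth model behind every synthetic dataset.

    ``receptor`` defaults to the seven-site MT2 solution model at the
    1.7 uM working concentration of the chromogenic competition;
    individual generators rescale the concentration to their assay's
    stated conditions while keeping the site constants.
    """

    model_config = ConfigDict(frozen=True)

    receptor: MultiSiteReceptor = _DEFAULT_RECEPTOR
    noise_sigma: float = 0.02
    noise_floor_frac: float = 0.001
    seed: int = 0

    @field_validator("noise_sigma", "noise_floor_frac")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("noise parameters must be >= 0")
        return v

    @property
    def weakest_neg_log_kd(self) -> float:
        return -float(np.log10(self.receptor.site_kds[0]))


def _noisy(rng: np.random.Generator, values: np.ndarray, truth: GroundTruth,
           full_scale: float) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if truth.noise_sigma == 0 and truth.noise_floor_frac == 0:
        return v
    out = v * (1.0 + truth.noise_sigma * rng.standard_normal(v.shape))
    out = out + truth.noise_floor_frac * full_scale * rng.standard_normal(v.shape)
    return out


def _equilibrium_complex(truth: GroundTruth, ligand: CompetitorLigand,
                         mt_conc: float) -> float:
    receptor = truth.receptor.with_total(mt_conc)
    system = SystemDefinition(
        receptors=(receptor,),
        ligands=(ligand,),
        total_metal=receptor.n_sites * mt_conc,
    )
    return solve_speciation(system).complex_conc[0]


def gen_par_kinetics(
    truth: GroundTruth,
    par_concs: Sequence[float] = (5e-6, 10e-6, 20e-6, 50e-6, 100e-6,
                                  150e-6, 200e-6, 300e-6, 400e-6),
    with_reducing_agent: bool = True,
    seed: int | None = None,
    mt_conc: float = 1.7e-6,
    tau: float = 300.0,
    duration: float = 3600.0,
    dt: float = 10.0,
    epsilon: float = constants.EPSILON_PAR_492,
    path: float = 1.0,
    drift_frac_per_hour: float = 0.15,
) -> list[KineticTrace]:
    """Absorbance kinetics of chromogenic 1:2 chelator competition.

    Each trace approaches the speciation-solver equilibrium absorbance
    ``epsilon * path * [ZnL2]_eq`` as a saturating exponential with time
    constant ``tau`` (equilibration completes well before the 1 h trace
    ends).  Without a reducing agent a linear oxidative drift of
    ``drift_frac_per_hour`` of the equilibrium absorbance per hour is
    superimposed, emulating the continuous signal rise of unprotected
    thiols; no plateau is then reached.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    t = np.arange(0.0, duration + dt / 2, dt)
    traces = []
    for conc in par_concs:
        ligand = CompetitorLigand(
            kd=constants.PAR_KD12, stoich=2, total_conc=conc, label="PAR"
        )
        eq_complex = _equilibrium_complex(truth, ligand, mt_conc)
        a_eq = epsilon * path * eq_complex
        a = a_eq * (1.0 - np.exp(-t / tau))
        if not with_reducing_agent:
            a = a + (drift_frac_per_hour * a_eq / 3600.0) * t
        signal = _noisy(rng, a, truth, full_scale=a_eq)
        traces.append(
            KineticTrace(
                time=t,
                signal=signal,
                reducing_agent=with_reducing_agent,
                label=f"PAR {conc * 1e6:g} uM",
                meta={
                    "par_conc": conc,
                    "mt_conc": mt_conc,
                    "eq_complex_conc": eq_complex,
                    "epsilon": epsilon,
                    "path": path,
                },
            )
        )
    return traces


def gen_probe_titration(
    truth: GroundTruth,
    probe: CompetitorLigand | None = None,
    probe_concs: Sequence[float] = tuple(np.geomspace(0.05e-6, 5e-6, 16)),
    seed: int | None = None,
    mt_conc: float = 0.5e-6,
    fmax_per_molar: float = 2e8,
    enhancement: float = 60.0,
) -> pd.DataFrame:
    """Fluorescent 1:1 probe titration with per-point F/Fmin/Fmax calibration.

    The probe's bound fraction at equilibrium interpolates its intensity
    between the metal-free level ``Fmin`` and the Zn-saturated level
    ``Fmax``; both calibration intensities scale with probe concentration
    (``Fmax = fmax_per_molar * conc``; ``Fmin = Fmax / enhancement``,
    a typical turn-on factor for aminofluorescein probes).  ``F0`` is the
    metal-free baseline (equal to the Fmin level).  Each of F, Fmin and
    Fmax carries independent measurement noise, as in a real calibration.

    Columns: ``probe_conc_M, f, f0, fmin, fmax`` plus the ground-truth
    extras ``transferred_eq_true`` and ``free_zn_true``.
    """
    if probe is None:
        probe = CompetitorLigand(kd=constants.ZNAF2F_KD, stoich=1, label="ZnAF-2F")
    if probe.stoich != 1:
        raise ValidationError("fluorescent probe model requires 1:1 stoichiometry")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    rows = []
    for conc in probe_concs:
        if conc < 0:
            raise ValidationError("probe concentrations must be >= 0")
        fmax = fmax_per_molar * conc
        fmin = fmax / enhancement
        if conc == 0:
            rows.append({"probe_conc_M": 0.0, "f": 0.0, "f0": 0.0, "fmin": 0.0,
                         "fmax": 0.0, "transferred_eq_true": 0.0,
                         "free_zn_true": np.nan})
            continue
        lig = probe.with_total(conc)
        receptor = truth.receptor.with_total(mt_conc)
        state = solve_speciation(
            SystemDefinition(
                receptors=(receptor,), ligands=(lig,),
                total_metal=receptor.n_sites * mt_conc,
            )
        )
        bound_frac = state.complex_conc[0] / conc
        f_true = fmin + (fmax - fmin) * bound_frac
        f, fmin_m, fmax_m = _noisy(
            rng, np.array([f_true, fmin, fmax]), truth, full_scale=fmax
        )
        rows.append(
            {
                "probe_conc_M": conc,
                "f": f,
                "f0": fmin_m,
                "fmin": fmin_m,
                "fmax": fmax_m,
                "transferred_eq_true": state.complex_conc[0] / mt_conc,
                "free_zn_true": state.free_metal,
            }
        )
    return pd.DataFrame(rows)


def gen_activity_assay(
    truth: GroundTruth,
    enzyme: CompetitorLigand | None = None,
    seed: int | None = None,
    mt_conc: float = 0.1e-6,
    donor_neg_log_kd: float | None = None,
    control_rate: float = 1e-3,
    n_replicates: int = 4,
) -> pd.DataFrame:
    """Enzyme-inhibition rate pairs after equimolar incubation.

    The donor is the ground truth's weakest site (override with
    ``donor_neg_log_kd``); zinc transfer to the enzyme's inhibitory site
    follows the pairwise-exchange model, and the sample rate is the control
    rate scaled by the metal-free enzyme fraction.

    Columns: ``replicate, rate_sample, rate_control`` (au/s).
    """
    if enzyme is None:
        enzyme = CompetitorLigand(
            kd=constants.PTP1B_KD, stoich=1, total_conc=0.1e-6, label="PTP1B"
        )
    if enzyme.total_conc <= 0:
        raise ValidationError("enzyme total_conc must be > 0")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    donor_kd = (
        10.0 ** (-donor_neg_log_kd)
        if donor_neg_log_kd is not None
        else truth.receptor.site_kds[0]
    )
    _, bound = pairwise_exchange(donor_kd, mt_conc, enzyme.kd, enzyme.total_conc)
    active_frac = 1.0 - bound / enzyme.total_conc
    rows = []
    for i in range(n_replicates):
        sample, control = _noisy(
            rng,
            np.array([control_rate * active_frac, control_rate]),
            truth,
            full_scale=control_rate,
        )
        rows.append(
            {"replicate": i, "rate_sample": sample, "rate_control": control}
        )
    return pd.DataFrame(rows)


def gen_cd_titration(
    truth: GroundTruth,
    zf: CompetitorLigand | None = None,
    ratios: Sequence[float] = tuple(np.arange(0.1, 2.01, 0.1)),
    time_points: Sequence[float] = (180.0, 600.0, 1200.0, 3600.0),
    seed: int | None = None,
    n_donor_sites: int = 1,
    tau: float = 600.0,
    theta_apo: float = -4.0,
    theta_holo: float = -20.0,
) -> pd.DataFrame:
    """CD-monitored zinc-finger saturation during a donor titration.

    For every donor/acceptor molar ratio the equilibrium saturation of the
    zinc finger is computed -- by pairwise exchange for a single mobilisable
    donor site, or by full speciation over the ``n_donor_sites`` weakest
    sites (each protein then carries that many transferable metals).
    Ellipticity at 222 nm relaxes from the apo baseline toward the
    equilibrium value with time constant ``tau``.

    Columns: ``ratio, time_s, theta_mdeg, saturation_eq_true``.
    """
    if zf is None:
        zf = CompetitorLigand(
            kd=constants.ZF133_11_CE_KD, stoich=1, total_conc=5e-6, label="ZF133-11_C/E"
        )
    if zf.total_conc <= 0:
        raise ValidationError("zf total_conc must be > 0")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    rows = []
    for ratio in ratios:
        if ratio < 0:
            raise ValidationError("ratios must be >= 0")
        mt_conc = ratio * zf.total_conc
        if mt_conc == 0:
            sat_eq = 0.0
        elif n_donor_sites == 1:
            _, bound = pairwise_exchange(
                truth.receptor.site_kds[0], mt_conc, zf.kd, zf.total_conc
            )
            sat_eq = bound / zf.total_conc
        else:
            donor = truth.receptor.truncated(n_donor_sites).with_total(mt_conc)
            state = solve_speciation(
                SystemDefinition(
                    receptors=(donor,), ligands=(zf,),
                    total_metal=n_donor_sites * mt_conc,
                )
            )
            sat_eq = state.complex_conc[0] / zf.total_conc
        for t in time_points:
            sat_t = sat_eq * (1.0 - np.exp(-t / tau))
            theta = theta_apo + (theta_holo - theta_apo) * sat_t
            theta_noisy = float(
                _noisy(rng, np.array([theta]), truth, full_scale=abs(theta_holo))[0]
            )
            rows.append(
                {
                    "ratio": float(ratio),
                    "time_s": float(t),
                    "theta_mdeg": theta_noisy,
                    "saturation_eq_true": sat_eq,
                }
            )
    return pd.DataFrame(rows)


def gen_sec_partition(
    truth: GroundTruth,
    ligand: CIContext | None,
    seed: int | None = None,
    mt_conc: float = 38e-6,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Protein-fraction zinc content after LMW-ligand competition and SEC.

    The low-molecular-weight competitor is represented by its
    competitivity-index aggregate: a hypothetical 1:1 ligand Z with
    ``K_d = 10**(-CI)`` at the stated total concentration.  Transfer from
    the weakest donor site follows the exchange model; the protein fraction
    retains ``n_sites - transferred/mt_conc`` equivalents.  ``ligand=None``
    is the no-competitor control and returns full loading.

    Columns: ``replicate, zn_per_protein``.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n = truth.receptor.n_sites
    if ligand is None:
        eq_true = float(n)
    else:
        _, bound = pairwise_exchange(
            truth.receptor.site_kds[0], mt_conc, 10.0 ** (-ligand.ci),
            ligand.ligand_total,
        )
        eq_true = n - bound / mt_conc
    vals = _noisy(rng, np.full(n_replicates, eq_true), truth, full_scale=float(n))
    return pd.DataFrame(
        {"replicate": np.arange(n_replicates), "zn_per_protein": vals}
    )
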