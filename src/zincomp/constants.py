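"""Packaged conditional constants (pH 7.4 unless noted).

Receptor models
---------------
``mt2_ref32``
    Human Zn7-MT2 solution model from fluorimetric competition with
    FluoZin-3/RhodZin-3: four low-picomolar sites (1.6e-12 M), one moderate
    site (3.6e-11 M), one moderate site (1.1e-10 M) and one weak,
    nanomolar site (2e-8 M).  Weakest-first this is
    K_d1 = 2e-8 >= K_d2 = 1.1e-10 >= K_d3 = 3.6e-11 >= K_d4..7 = 1.6e-12.
``mt2_esi`` / ``mt1_esi``
    ESI-MS-derived per-site constants (gas phase); all picomolar.  Included
    so gas-phase and solution models can be compared in loading titrations.

Competitor constants
--------------------
1:1 or 1:2 conditional dissociation constants of the Zn(II) complexes of the
chromogenic/fluorogenic probes, zinc-finger peptides and the PTP1B inhibitory
site used in competition experiments, plus competitivity indices (CI) for the
low-molecular-weight ligands ATP, GSH and L-His.  CI is the -log10 of the
apparent dissociation constant of a hypothetical 1:1 aggregate complex ZnZ at
the stated total ligand concentration; it absorbs stoichiometry and
protonation of the real Zn_iH_jL_k species.
"""

from __future__ import annotations

from .errors import ValidationError
from .system import CompetitorLigand, MultiSiteReceptor

__all__ = [
    "MT2_REF32_KDS",
    "MT2_ESI_KDS",
    "MT1_ESI_KDS",
    "RECEPTOR_SETS",
    "receptor",
    "PAR_KD12",
    "ZNAF2F_KD",
    "ZF133_11_KD",
    "ZF133_11_CE_KD",
    "PTP1B_KD",
    "ZSCAN20_KD",
    "ZNF442_KD",
    "CP1_2015_KD",
    "COMPETITOR_KDS",
    "competitor",
    "CI_VALUES",
    "EPSILON_PAR_492",
    "EPSILON_TNB_412",
    "MT2_N_CYS",
    "NEG_LOG_KD1_SOLUTION",
    "NEG_LOG_KD1_LMW",
]

#: ref.-32 solution model, weakest site first (M).
MT2_REF32_KDS: tuple[float, ...] = (2e-8, 1.1e-10, 3.6e-11) + (1.6e-12,) * 4

#: ESI-MS per-site constants for human MT2, sorted weakest-first (M).
MT2_ESI_KDS: tuple[float, ...] = (
    2.5e-11, 2.0e-11, 1.3e-11, 2.0e-12, 1.6e-12, 1.3e-12, 1.0e-12,
)

#: ESI-MS per-site constants for human MT1, sorted weakest-first (M).
MT1_ESI_KDS: tuple[float, ...] = (
    1.6e-12, 8.9e-13, 6.2e-13, 4.5e-13, 4.3e-13, 3.4e-13, 3.0e-13,
)

RECEPTOR_SETS: dict[str, tuple[float, ...]] = {
    "mt2_ref32": MT2_REF32_KDS,
    "mt2_esi": MT2_ESI_KDS,
    "mt1_esi": MT1_ESI_KDS,
}


def receptor(name: str, total_conc: float) -> MultiSiteReceptor:
    """A packaged seven-site receptor model at the given concentration."""
    try:
        kds = RECEPTOR_SETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown constant set {name!r}; available: {sorted(RECEPTOR_SETS)}"
        ) from None
    return MultiSiteReceptor(site_kds=kds, total_conc=total_conc, label=name)


# -- competitor constants ---------------------------------------------------

#: K_d12 of Zn(PAR)2, M^2 (-log 12.1).  PAR forms only the 1:2 complex at
#: pH 7.4; the 1:1 ZnPAR species is excluded.
PAR_KD12 = 7.1e-13
#: K_d of the 1:1 ZnAF-2F complex, M (-log 8.3).
ZNAF2F_KD = 5.5e-9
#: K_d of the consensus-like zinc finger ZF133-11, M (-log 12.5).
ZF133_11_KD = 3.31e-13
#: K_d of the weakened C->E variant ZF133-11_C/E, M (-log 8.4).
ZF133_11_CE_KD = 3.63e-9
#: K_d of the inhibitory Zn(II) site of PTP1B, M (-log 7.8).
PTP1B_KD = 1.6e-8
#: ESI-MS zinc-finger competitors, M.
ZSCAN20_KD = 1.3e-8
ZNF442_KD = 4.0e-11
CP1_2015_KD = 5.0e-13

COMPETITOR_KDS: dict[str, tuple[float, int]] = {
    # name -> (kd, stoich)
    "PAR": (PAR_KD12, 2),
    "ZnAF-2F": (ZNAF2F_KD, 1),
    "ZF133-11": (ZF133_11_KD, 1),
    "ZF133-11_C/E": (ZF133_11_CE_KD, 1),
    "PTP1B": (PTP1B_KD, 1),
    "ZScan20": (ZSCAN20_KD, 1),
    "ZNF442": (ZNF442_KD, 1),
    "CP1-2015": (CP1_2015_KD, 1),
}


def competitor(name: str, total_conc: float) -> CompetitorLigand:
    """A packaged competitor ligand at the given total concentration."""
    try:
        kd, stoich = COMPETITOR_KDS[name]
    except KeyError:
        raise ValidationError(
            f"unknown competitor {name!r}; available: {sorted(COMPETITOR_KDS)}"
        ) from None
    return CompetitorLigand(kd=kd, stoich=stoich, total_conc=total_conc, label=name)


#: Competitivity index by (ligand, total concentration in M).  The higher
#: ligand concentration is assigned the higher CI of each printed range
#: (documented assumption; which end corresponds to which concentration is
#: not stated in the source data).
CI_VALUES: dict[tuple[str, float], float] = {
    ("ATP", 20e-3): 5.1,
    ("GSH", 20e-3): 6.4,
    ("GSH", 40e-3): 6.7,
    ("L-His", 20e-3): 6.8,
    ("L-His", 40e-3): 7.2,
}

# -- spectroscopic / stoichiometric constants -------------------------------

#: Molar absorption coefficient of Zn(PAR)2 at 492 nm, M^-1 cm^-1, pH 7.4.
EPSILON_PAR_492 = 71_500.0
#: Molar absorption coefficient of the TNB chromophore at 412 nm,
#: M^-1 cm^-1 (standard Ellman assay value; configurable, the competition
#: literature cites the assay by reference without printing epsilon).
EPSILON_TNB_412 = 14_150.0
#: Cysteine count of human MT2 (20 Cys per chain).
MT2_N_CYS = 20

# -- published per-competitor -logK_d1 results (solution methods) -----------

#: -logK_d1 of the weakest MT2 zinc site by competitor/preparation, as
#: determined by the solution experiments (used for printed-average checks).
NEG_LOG_KD1_SOLUTION: dict[str, float] = {
    "PTP1B": 8.2,
    "PAR": 8.6,
    "PAR_pH8": 8.1,
    "ZF133-11_C/E": 8.6,
    "ZnAF-2F": 8.32,
    "ZnAF-2F_pH8": 8.19,
    "ATP": 7.9,
    "GSH": 8.9,
    "L-His": 8.7,
}

#: The low-molecular-weight (SEC) subset of the above.
NEG_LOG_KD1_LMW: tuple[str, ...] = ("ATP", "GSH", "L-His")
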