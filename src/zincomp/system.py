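"""Domain types for metal-ligand competition systems.

One divalent metal (Zn(II) throughout this package) is distributed among

* a *multi-site receptor* -- a macromolecule (metallothionein) with ``n``
  independent sites described by conditional step dissociation constants,
  ordered weakest-first (``K_d1 >= K_d2 >= ...``; index 1 is the weakest
  site, i.e. the first metal to leave the fully loaded protein),
* zero or more *competitor ligands* -- chelators, probes, peptides or enzyme
  sites forming 1:1 or 1:2 metal:ligand complexes with a single conditional
  dissociation constant (units M for 1:1, M^2 for 1:2), and
* a free-ion pool.

All constants are conditional (apparent) constants at the stated pH
(pH 7.4 unless noted); protonation microstates are never modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator

from .errors import ValidationError

__all__ = [
    "MultiSiteReceptor",
    "CompetitorLigand",
    "SpeciationState",
    "SystemDefinition",
]


class MultiSiteReceptor(BaseModel):
    """A macromolecule binding one metal at ``n`` independent sites.

    Parameters
    ----------
    site_kds
        Conditional step dissociation constants in M, ordered weakest-first
        (non-increasing).  ``site_kds[0]`` is K_d1, the constant of the
        loosest-bound metal ion.
    total_conc
        Total receptor (protein) concentration in M.
    label
        Free-text identifier, e.g. ``"MT2 (ref. 32)"``.
    """

    model_config = ConfigDict(frozen=True)

    site_kds: tuple[float, ...]
    total_conc: float
    label: str = ""

    @field_validator("site_kds")
    @classmethod
    def _positive_and_ordered(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if len(v) == 0:
            raise ValueError("receptor needs at least one site")
        if any(k <= 0 or not np.isfinite(k) for k in v):
            raise ValueError("all site dissociation constants must be > 0")
        if any(v[i] < v[i + 1] for i in range(len(v) - 1)):
            raise ValueError("site_kds must be ordered weakest-first (non-increasing)")
        return v

    @field_validator("total_conc")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0 or not np.isfinite(v):
            raise ValueError("total_conc must be >= 0")
        return v

    @property
    def n_sites(self) -> int:
        return len(self.site_kds)

    def with_total(self, total_conc: float) -> "MultiSiteReceptor":
        """Same site model at a different protein concentration."""
        return self.model_copy(update={"total_conc": total_conc})

    def truncated(self, n: int) -> "MultiSiteReceptor":
        """Receptor restricted to its ``n`` weakest sites."""
        if not 1 <= n <= self.n_sites:
            raise ValidationError(f"n must be in [1, {self.n_sites}]")
        return MultiSiteReceptor(
            site_kds=self.site_kds[:n],
            total_conc=self.total_conc,
            label=f"{self.label}[weakest {n}]" if self.label else "",
        )


class CompetitorLigand(BaseModel):
    """A competing chelator or protein site.

    ``stoich`` is the number of ligand molecules per bound metal: 1 for 1:1
    complexes (fluorescent probes, zinc fingers, enzymes, the hypothetical
    aggregate ligand Z of the competitivity-index formalism) or 2 for 1:2
    complexes such as Zn(PAR)2.  ``kd`` is the conditional dissociation
    constant of the complex: M for 1:1, M^2 for 1:2 (K_d12 = [M][L]^2/[ML2]).
    """

    model_config = ConfigDict(frozen=True)

    kd: float
    stoich: int = 1
    total_conc: float = 0.0
    label: str = ""

    @field_validator("kd")
    @classmethod
    def _kd_pos(cls, v: float) -> float:
        if v <= 0 or not np.isfinite(v):
            raise ValueError("kd must be > 0")
        return v

    @field_validator("stoich")
    @classmethod
    def _stoich(cls, v: int) -> int:
        if v not in (1, 2):
            raise ValueError("stoich must be 1 or 2")
        return v

    @field_validator("total_conc")
    @classmethod
    def _conc(cls, v: float) -> float:
        if v < 0 or not np.isfinite(v):
            raise ValueError("total_conc must be >= 0")
        return v

    def with_total(self, total_conc: float) -> "CompetitorLigand":
        return self.model_copy(update={"total_conc": total_conc})


@dataclass(frozen=True)
class SpeciationState:
    """Equilibrium speciation of one metal among receptors, ligands and pool.

    Attributes
    ----------
    free_metal : float
        [M]_free in M.
    free_ligand : tuple of float
        Free (uncomplexed) concentration of each ligand, in input order.
    site_occupancy : tuple of tuple of float
        Fractional occupancy of every site of every receptor.
    complex_conc : tuple of float
        Metal-complex concentration of each ligand ([ML] or [ML2]).
    residual : float
        Worst relative mass-balance defect (dimensionless).
    """

    free_metal: float
    free_ligand: tuple[float, ...]
    site_occupancy: tuple[tuple[float, ...], ...]
    complex_conc: tuple[float, ...]
    residual: float

    def receptor_bound(self, system: "SystemDefinition") -> tuple[float, ...]:
        """Metal bound to each receptor, in M."""
        return tuple(
            r.total_conc * float(np.sum(occ))
            for r, occ in zip(system.receptors, self.site_occupancy)
        )

    def metal_in_complexes(self) -> float:
        return float(np.sum(self.complex_conc))


@dataclass(frozen=True)
class SystemDefinition:
    """Declarative description of one competition system.

    ``ph_note`` is annotation only: the solver works with conditional
    constants and computes no protonation microstates.
    """

    receptors: tuple[MultiSiteReceptor, ...] = ()
    ligands: tuple[CompetitorLigand, ...] = ()
    total_metal: float = 0.0
    ph_note: str = "conditional constants at pH 7.4"

    def __post_init__(self):
        object.__setattr__(self, "receptors", tuple(self.receptors))
        object.__setattr__(self, "ligands", tuple(self.ligands))
        if self.total_metal < 0 or not np.isfinite(self.total_metal):
            raise ValidationError("total_metal must be >= 0")
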