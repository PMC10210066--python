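"""Independent brute-force oracles for cross-checking the solver.

The speciation oracle is a plain nested bisection, deliberately sharing no
code with the package: the outer bisection runs on log10 free metal over
[-20, log10(total_metal)]; for each trial free metal, each ligand's free
concentration comes from an inner bisection on [0, L_total] (skipped when
ligand depletion at full free ligand would be below 0.1%).
"""

from __future__ import annotations

import math
import random

from zincomp.system import CompetitorLigand, MultiSiteReceptor, SystemDefinition


def oracle_free_ligand(kd: float, stoich: int, total: float, m: float,
                       iters: int = 110) -> float:
    """Free ligand by bisection of L + stoich*m*L**stoich/kd = L_total."""
    if total == 0.0 or m == 0.0:
        return total
    lo, hi = 0.0, total
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if mid + stoich * m * mid**stoich / kd - total > 0.0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _balance(system: SystemDefinition, m: float) -> float:
    tot = m
    for r in system.receptors:
        for k in r.site_kds:
            tot += r.total_conc * m / (m + k)
    for lig in system.ligands:
        if lig.total_conc > 0.0:
            free = oracle_free_ligand(lig.kd, lig.stoich, lig.total_conc, m)
            tot += m * free**lig.stoich / lig.kd
    return tot - system.total_metal


def oracle_solve(system: SystemDefinition, iters: int = 80):
    """Full speciation by nested log-grid bisection.

    Returns (free_metal, free_ligands, complexes, occupancies).
    """
    total = system.total_metal
    if total == 0.0:
        free_m = 0.0
    else:
        lo, hi = -20.0, math.log10(total)
        if _balance(system, 10.0**lo) > 0.0:
            free_m = total
        else:
            for _ in range(iters):
                mid = 0.5 * (lo + hi)
                if _balance(system, 10.0**mid) > 0.0:
                    hi = mid
                else:
                    lo = mid
            free_m = 10.0 ** (0.5 * (lo + hi))
    free_l = []
    complexes = []
    for lig in system.ligands:
        fl = oracle_free_ligand(lig.kd, lig.stoich, lig.total_conc, free_m)
        free_l.append(fl)
        complexes.append(free_m * fl**lig.stoich / lig.kd if lig.total_conc else 0.0)
    occ = [
        [free_m / (free_m + k) if free_m else 0.0 for k in r.site_kds]
        for r in system.receptors
    ]
    return free_m, free_l, complexes, occ


def random_system(rng: random.Random) -> SystemDefinition:
    """A randomized but physically sensible competition system."""
    n_sites = rng.randint(1, 8)
    kds = sorted(
        (10.0 ** rng.uniform(-13.0, -7.0) for _ in range(n_sites)), reverse=True
    )
    r_total = 10.0 ** rng.uniform(-7.0, -4.0)
    receptor = MultiSiteReceptor(site_kds=tuple(kds), total_conc=r_total)
    ligands = []
    for _ in range(rng.randint(0, 3)):
        stoich = rng.choice([1, 1, 2])
        if stoich == 1:
            kd = 10.0 ** rng.uniform(-13.0, -6.0)
        else:
            kd = 10.0 ** rng.uniform(-14.0, -10.0)
        ligands.append(
            CompetitorLigand(
                kd=kd, stoich=stoich, total_conc=10.0 ** rng.uniform(-7.0, -2.0)
            )
        )
    capacity = n_sites * r_total
    total_metal = rng.uniform(0.05, 1.4) * capacity
    return SystemDefinition(
        receptors=(receptor,), ligands=tuple(ligands), total_metal=total_metal
    )
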