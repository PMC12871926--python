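"""Solution specifications for the perfusion protocol.

Two physiological solutions drive the assay: a nominally CO2/HCO3- -free
saline buffered with HEPES ("ND96", pH 7.50) and the same saline with 10 mM
NaHCO3 equilibrated with 1.5% CO2. A solution is summarized by the species
the simulator needs: bulk pH, [CO2], [HCO3-], the non-CO2 buffer, and the
extracellular CA acceleration factor carried by dissolved bCA.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import constants as C


@dataclass(frozen=True)
class SolutionSpec:
    """Composition of a bulk perfusion solution.

    Concentrations are mol L^-1. ``bca_factor`` is the dimensionless
    acceleration of CO2 hydration/dehydration contributed by carbonic
    anhydrase dissolved in the solution (1 = uncatalysed).
    """

    name: str
    pH_bulk: float
    co2_conc: float = 0.0
    hco3_conc: float = 0.0
    non_co2_buffer_conc: float = C.HEPES_CONC
    non_co2_buffer_pk: float = C.HEPES_PK
    bca_factor: float = 1.0
    #: tolerance (pH units) for carbonate-equilibrium consistency
    equilibrium_tol: float = field(default=0.02, compare=False)

    def __post_init__(self) -> None:
        if not (6.0 <= self.pH_bulk <= 8.5):
            raise ValueError(f"bulk pH {self.pH_bulk} outside [6.0, 8.5]")
        for attr in ("co2_conc", "hco3_conc", "non_co2_buffer_conc"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if self.bca_factor < 1.0:
            raise ValueError("bca_factor must be >= 1")
        if self.co2_conc > 0 and self.hco3_conc > 0:
            pH_eq = C.PK1_CARBONIC + math.log10(self.hco3_conc / self.co2_conc)
            if abs(pH_eq - self.pH_bulk) > self.equilibrium_tol:
                raise ValueError(
                    f"solution '{self.name}' inconsistent with carbonate "
                    f"equilibrium: stated pH {self.pH_bulk:.3f} vs "
                    f"equilibrium pH {pH_eq:.3f}"
                )

    @property
    def h_conc(self) -> float:
        """Free [H+] in mol L^-1 implied by the bulk pH."""
        return 10.0 ** (-self.pH_bulk)


def nd96(bca: bool = False) -> SolutionSpec:
    """The CO2/HCO3- -free control saline (pH 7.50, 5 mM HEPES)."""
    return SolutionSpec(
        name="ND96" + ("+bCA" if bca else ""),
        pH_bulk=C.PH_ND96,
        co2_conc=0.0,
        hco3_conc=0.0,
        bca_factor=C.BCA_FACTOR if bca else 1.0,
    )


def co2_hco3(bca: bool = False, pct_co2: float = C.PCT_CO2,
             hco3: float = C.HCO3_CONC) -> SolutionSpec:
    """The 1.5% CO2 / 10 mM HCO3- solution.

    The stated pH is the carbonate-equilibrium pH implied by the effective
    pK and the CO2 solubility coefficient (7.494 for the defaults, i.e. the
    titrated 7.50 within the consistency tolerance).
    """
    co2 = C.K_H_CO2 * pct_co2 / 100.0
    pH = C.PK1_CARBONIC + math.log10(hco3 / co2)
    return SolutionSpec(
        name=f"{pct_co2:g}%CO2/{hco3 * 1e3:g}HCO3" + ("+bCA" if bca else ""),
        pH_bulk=pH,
        co2_conc=co2,
        hco3_conc=hco3,
        bca_factor=C.BCA_FACTOR if bca else 1.0,
    )
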