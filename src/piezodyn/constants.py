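"""Physical constants in the package's internal unit system.

Internal units are fixed globally: energy transfer ħω and Lorentzian HWHMs in
meV, momentum transfer q in Å⁻¹, time in ps, lengths in Å, temperature in K,
pressure in bar, enthalpies in kJ/mol, entropies in J/(mol·K).  Activation
energies are reported both in kJ/mol and kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable container for the constants used across the package."""

    hbar: float = 0.6582119  # meV·ps
    kB: float = 0.0861733  # meV/K
    Rgas: float = 0.0083145  # kJ/(mol·K)
    kJ_per_kcal: float = 4.184  # thermochemical calorie

    @property
    def kcal_per_kJ(self) -> float:
        return 1.0 / self.kJ_per_kcal


#: Module-level singleton; import this rather than instantiating.
CONSTANTS = PhysicalConstants()
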