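"""Physical constants (CODATA, via :mod:`scipy.constants`).

All enthalpies/entropies in this package are molar (kJ mol⁻¹ scale), so the
gas constant ``R_KJ`` (kJ mol⁻¹ K⁻¹) appears in every variance→heat-capacity
denominator, while ``KB`` and ``H_PLANCK`` (SI) appear only in the Eyring
prefactor kB·T/h.
"""

from __future__ import annotations

import scipy.constants as _sc

#: Boltzmann constant, J K⁻¹
KB: float = _sc.k

#: Planck constant, J s
H_PLANCK: float = _sc.h

#: Avogadro constant, mol⁻¹
N_A: float = _sc.Avogadro

#: Gas constant, kJ mol⁻¹ K⁻¹ (molar convention used throughout)
R_KJ: float = _sc.R / 1000.0

# R = kB·N_A must hold to numerical precision (consistency of the convention)
assert abs(KB * N_A / 1000.0 - R_KJ) < 1e-12
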