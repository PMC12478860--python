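"""Internal unit system: Å, g/mol, kcal/mol.

The derived time unit is tau = sqrt(g/mol * Å^2 / (kcal/mol)) ≈ 48.89 fs.
User-facing times (fs, ps, ns) are converted on input so that spring
constants and energies keep their literature values unchanged.
"""

import math

#: Boltzmann constant, kcal/mol/K.
KB = 0.0019872

#: One internal time unit, in femtoseconds:
#: sqrt((1e-3 kg/mol * 1e-20 m^2) / 4184 J/mol) expressed in fs.
TAU_FS = math.sqrt(1e-23 / 4184.0) * 1e15

FS_PER_PS = 1e3
FS_PER_NS = 1e6


def fs_to_internal(t_fs: float) -> float:
    """Convert a time given in femtoseconds to internal time units."""
    return t_fs / TAU_FS


def ps_to_internal(t_ps: float) -> float:
    return t_ps * FS_PER_PS / TAU_FS


def internal_to_fs(t_tau: float) -> float:
    return t_tau * TAU_FS
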