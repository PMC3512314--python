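"""Unit systems and conversions.

All internal analysis runs in whatever unit system the trajectories declare;
energies handed to the exponential estimators are always expressed in units of
kBT first, which is the one numerically hazardous spot.  Three unit systems are
recognised:

``reduced``
    kB = 1, so thermal energy equals the temperature parameter.  The synthetic
    simulator's native system.
``gromacs``
    nm, ps, kJ/mol, K — the MD-engine pull-output convention
    (kB = 0.00831446 kJ/(mol·K)).
``SI``
    m, s, J, K (kB = 1.380649e-23 J/K).

Conversions between ``gromacs`` and ``SI`` happen at exactly one place
(:func:`conversion_factors`); ``reduced`` has no absolute scale and cannot be
converted without user-supplied reference scales.
"""

from __future__ import annotations

from .errors import ValidationError

UNIT_SYSTEMS = ("reduced", "gromacs", "SI")

#: Boltzmann constant, J/K (2019 SI exact value).
KB_J = 1.380649e-23
#: Avogadro constant, 1/mol (2019 SI exact value).
N_AVOGADRO = 6.02214076e23
#: Boltzmann constant in kJ/(mol·K) = molar gas constant / 1000.
KB_KJ_MOL = KB_J * N_AVOGADRO / 1000.0


def boltzmann_constant(unit_system: str) -> float:
    """kB in the energy/temperature units of *unit_system*."""
    if unit_system == "reduced":
        return 1.0
    if unit_system == "gromacs":
        return KB_KJ_MOL
    if unit_system == "SI":
        return KB_J
    raise ValidationError(f"unknown unit system {unit_system!r}")


def thermal_energy(temperature: float, unit_system: str) -> float:
    """kB·T in the declared unit system."""
    if temperature < 0:
        raise ValidationError("temperature must be non-negative")
    return boltzmann_constant(unit_system) * temperature


def conversion_factors(src: str, dst: str) -> dict[str, float]:
    """Multiplicative factors for length, time, energy and force.

    Only ``gromacs`` <-> ``SI`` is defined; the pair is involutive to machine
    precision because each factor is the exact reciprocal of its inverse.
    """
    for s in (src, dst):
        if s not in UNIT_SYSTEMS:
            raise ValidationError(f"unknown unit system {s!r}")
    if src == dst:
        return {"length": 1.0, "time": 1.0, "energy": 1.0, "force": 1.0}
    if "reduced" in (src, dst):
        raise ValidationError(
            "reduced units carry no absolute scale; supply explicit reference "
            "scales instead of converting"
        )
    # gromacs -> SI: nm -> m, ps -> s, kJ/mol -> J, kJ/mol/nm -> N
    g2s = {
        "length": 1e-9,
        "time": 1e-12,
        "energy": 1000.0 / N_AVOGADRO,
        "force": 1000.0 / N_AVOGADRO / 1e-9,
    }
    if (src, dst) == ("gromacs", "SI"):
        return g2s
    return {k: 1.0 / v for k, v in g2s.items()}
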