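"""Unit constants and spherical-site geometry helpers.

Microdosimetric bookkeeping mixes keV, picograms, micrometres and gray.  The
single conversion constant used throughout is

    1 keV / 1 pg = 1.602e-16 J / 1e-15 kg = 0.1602 Gy,

kept here so no other module carries magic numbers.
"""

import math

#: Specific energy in Gy deposited by 1 keV in a 1 pg mass.
GY_PER_KEV_PER_PG = 0.1602

#: Default mass density of the sensitive volume (water), g/cm^3.
WATER_DENSITY = 1.0


def sphere_mass_pg(radius_um: float, rho: float = WATER_DENSITY) -> float:
    """Mass in picograms of a sphere of ``radius_um`` (um) and density ``rho``
    (g/cm^3).  1 um^3 at 1 g/cm^3 is exactly 1 pg."""
    return rho * (4.0 / 3.0) * math.pi * radius_um**3


def mean_chord_um(radius_um: float) -> float:
    """Cauchy mean chord length of a sphere, 4R/3 (um)."""
    return 4.0 * radius_um / 3.0
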