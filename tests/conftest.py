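import math

import pytest

# Printed experimental/calculated free energies (kcal/mol) for the six
# C3-substituted stepholidine derivatives, used as report-stage fixtures.
COMPOUNDS = ["1a", "1b", "1c", "1d", "1e", "1f"]
KI_NM = [40.0, 46.0, 51.0, 33.0, 26.0, 86.0]
DG_EXP = [-10.1, -10.0, -10.0, -10.2, -10.4, -9.6]
DG_CALC_WITHOUT = [-2.2, -2.3, -1.8, -0.3, -3.9, -3.1]
DG_CALC_WITH = [-8.8, -10.4, -11.5, -10.6, -12.5, -8.9]
DE_B_WITH = [-42.5, -44.7, -48.1, -55.6, -55.2, -43.2]


@pytest.fixture(scope="session")
def toy_pocket():
    from hydrabind import generate_toy_pocket

    return generate_toy_pocket(seed=11)


def lens_free_volume(R: float, r: float, d: float) -> float:
    """Analytic free volume of a sphere of radius R against one occluder.

    Independent closed-form oracle: full sphere volume minus the two-sphere
    lens (intersection) volume.
    """
    v_sphere = 4.0 / 3.0 * math.pi * R**3
    if d >= R + r:
        return v_sphere
    if d <= abs(R - r):
        return 0.0 if r >= R else v_sphere - 4.0 / 3.0 * math.pi * r**3
    lens = (
        math.pi
        * (R + r - d) ** 2
        * (d**2 + 2 * d * r - 3 * r**2 + 2 * d * R + 6 * r * R - 3 * R**2)
    ) / (12.0 * d)
    return v_sphere - lens
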