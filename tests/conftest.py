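import numpy as np
import pytest

from ciuscreen.binding import ITCDesign, KCAL_TO_UCAL
from ciuscreen.synthdata import NOISELESS, NoiseModel


@pytest.fixture
def noiseless() -> NoiseModel:
    return NOISELESS


def oracle_itc_heats(
    kd: float, n_stoich: float, dh_kcal: float, design: ITCDesign
) -> np.ndarray:
    """Brute-force ITC oracle: solve the binding quadratic per injection.

    Independent of the package's closed-form isotherm: the complex
    concentration [PL] is obtained directly as the smaller root of
    [PL]^2 - (nMt + Xt + Kd)[PL] + nMt*Xt = 0, then the heat bookkeeping
    (cumulative heat + displaced-volume correction) is applied.
    """
    v0_l = design.cell_volume_ul * 1e-6
    heats = []
    q_prev = 0.0
    for i in range(1, design.n_inj + 1):
        d = i * design.inj_volume_ul / design.cell_volume_ul
        mt = design.cell_conc * (1 - d / 2) / (1 + d / 2)
        xt = design.syringe_conc * d / (1 + d / 2)
        sites = n_stoich * mt
        s = sites + xt + kd
        pl = (s - np.sqrt(s * s - 4.0 * sites * xt)) / 2.0
        q = pl * v0_l * dh_kcal * KCAL_TO_UCAL
        frac = design.inj_volume_ul / design.cell_volume_ul
        heats.append(q + frac * (q + q_prev) / 2.0 - q_prev)
        q_prev = q
    return np.asarray(heats)
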