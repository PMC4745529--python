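"""Reference calibrations for the two-district household food-security survey.

Published item easiness values (sum-zero normalization, logits) and latent
ability moments for the Tororo (n = 577) and Busia (n = 598) district samples
of the 18-item adapted USDA household food-security module.  These drive the
synthetic-data presets and the arithmetic consistency checks: under sum-zero
normalization the easiness of item E1 is recoverable as minus the sum of the
remaining seventeen easiness values (equivalently, the sum of their printed
difficulties).
"""

from __future__ import annotations

import numpy as np

ITEM_IDS = tuple(f"E{i}" for i in range(1, 19))

#: Easiness beta_i (logits); difficulty is eta_i = -beta_i.
TORORO_BETA = {
    "E1": 3.177, "E2": 1.793, "E3": 2.191, "E4": 1.651, "E5": 1.616,
    "E6": 0.471, "E7": -0.164, "E8": -1.701, "E9": 1.297, "E10": 1.011,
    "E11": 0.185, "E12": -1.612, "E13": -3.150, "E14": -0.081,
    "E15": -1.496, "E16": -2.842, "E17": 0.185, "E18": -2.531,
}

BUSIA_BETA = {
    "E1": 3.328, "E2": 1.900, "E3": 1.877, "E4": 1.237, "E5": 1.108,
    "E6": 0.166, "E7": 0.916, "E8": -1.271, "E9": 1.293, "E10": 1.351,
    "E11": -0.133, "E12": -1.510, "E13": -3.110, "E14": 0.323,
    "E15": -1.282, "E16": -2.723, "E17": 0.041, "E18": -3.510,
}

#: Published per-item standard errors (same for easiness and difficulty).
TORORO_SE = {
    "E1": 0.169, "E2": 0.134, "E3": 0.141, "E4": 0.131, "E5": 0.131,
    "E6": 0.119, "E7": 0.116, "E8": 0.123, "E9": 0.126, "E10": 0.123,
    "E11": 0.117, "E12": 0.122, "E13": 0.156, "E14": 0.116,
    "E15": 0.120, "E16": 0.146, "E17": 0.117, "E18": 0.137,
}

BUSIA_SE = {
    "E1": 0.197, "E2": 0.150, "E3": 0.149, "E4": 0.134, "E5": 0.131,
    "E6": 0.117, "E7": 0.128, "E8": 0.110, "E9": 0.135, "E10": 0.136,
    "E11": 0.114, "E12": 0.111, "E13": 0.133, "E14": 0.119,
    "E15": 0.110, "E16": 0.125, "E17": 0.115, "E18": 0.144,
}

#: Household-score summary moments per district (latent scale, logits).
DISTRICT_MOMENTS = {
    "tororo": {"n": 577, "mu": 0.137, "sigma": 2.040},
    "busia": {"n": 598, "mu": 0.768, "sigma": 2.078},
}


def beta_vector(district: str) -> np.ndarray:
    """Easiness vector in E1..E18 order for ``district`` ('tororo' or 'busia')."""
    table = {"tororo": TORORO_BETA, "busia": BUSIA_BETA}[district.lower()]
    return np.array([table[i] for i in ITEM_IDS], dtype=float)


def se_vector(district: str) -> np.ndarray:
    table = {"tororo": TORORO_SE, "busia": BUSIA_SE}[district.lower()]
    return np.array([table[i] for i in ITEM_IDS], dtype=float)
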