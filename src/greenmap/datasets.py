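"""Reference label counts from four published drone survey campaigns.

Four central-Mexico sites were flown at ~30 m (0.0131 m/px ground sampling
distance) and their 200x200 px tiles hand-labelled with the eight terrain
classes: an urban park (Bicentenario), a university campus (ESCOM-IPN), a
suburban neighbourhood (Bonito Ecatepec), and a forested area. These tables
serve as worked inputs for the area and biomass accounting — no imagery is
needed to reproduce the terrain-level statistics from them.

``SURVEY_COUNTS`` holds per-class tile counts in canonical class order
(H, D, UNH, NV, HC, DC, UNHC, NVC). ``SURVEY_AREA_TOTALS_M2`` holds each
campaign's published total analysed ground surface in m^2. Note the
published per-terrain area totals contain small internal inconsistencies
relative to count x 6.86 m^2 arithmetic (see the per-class counts), so they
are recorded as published rather than recomputed.
"""

from __future__ import annotations

import numpy as np

from .taxonomy import CLASS_ORDER

__all__ = ["SURVEY_COUNTS", "SURVEY_AREA_TOTALS_M2", "survey_class_mix"]

SURVEY_COUNTS: dict[str, tuple[int, ...]] = {
    "bicentenario_park": (2677, 7917, 376, 5270, 5, 162, 247, 146),
    "escom_ipn": (5011, 5241, 204, 10829, 14, 76, 134, 91),
    "bonito_ecatepec": (321, 106, 41, 5350, 2, 18, 74, 88),
    "forested_area": (2258, 1429, 259, 1008, 6, 55, 242, 143),
}

SURVEY_AREA_TOTALS_M2: dict[str, float] = {
    "bicentenario_park": 115_439.10,
    "escom_ipn": 148_179.00,
    "bonito_ecatepec": 41_160.00,
    "forested_area": 37_044.08,
}


def survey_class_mix(survey: str) -> dict[str, float]:
    """Empirical class frequencies of a survey, usable as a synthetic
    scene's ``class_mix`` to emulate its class imbalance."""
    counts = np.asarray(SURVEY_COUNTS[survey], dtype=np.float64)
    freqs = counts / counts.sum()
    return dict(zip(CLASS_ORDER, freqs.tolist()))
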