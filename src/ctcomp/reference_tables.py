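"""Published summary statistics of a multicenter health check-up cohort.

These constants describe a prospective Korean health check-up population of
537 adults (345 male, 192 female) screened opportunistically on abdominal CT
across three institutions: per sex-and-age-decade group sizes, demographic
means/SDs, and body-composition means/SDs (areas in cm^2, SMA/BMI in
cm^2·m^2/kg).  They serve as generative inputs to
:func:`ctcomp.phantom.gen_checkup_cohort` for simulation studies and as the
reference point for cohort-level analyses.
"""

from __future__ import annotations

from .phantom import AGE_BANDS

__all__ = [
    "AGE_BANDS",
    "BAND_MIDPOINTS",
    "CHECKUP_GROUP_SIZES",
    "CHECKUP_BODYCOMP_STATS",
    "CHECKUP_DEMOGRAPHIC_STATS",
    "BODYCOMP_METRICS",
    "checkup_group_sizes",
    "checkup_group_stats",
]

# midpoint convention: decades at their center, open-ended 70+ band at 75
BAND_MIDPOINTS = {
    "20-29": 24.5, "30-39": 34.5, "40-49": 44.5,
    "50-59": 54.5, "60-69": 64.5, "70+": 75.0,
}

CHECKUP_GROUP_SIZES: dict[tuple[str, str], int] = {
    ("male", "20-29"): 20, ("male", "30-39"): 98, ("male", "40-49"): 109,
    ("male", "50-59"): 68, ("male", "60-69"): 35, ("male", "70+"): 15,
    ("female", "20-29"): 20, ("female", "30-39"): 34, ("female", "40-49"): 42,
    ("female", "50-59"): 51, ("female", "60-69"): 30, ("female", "70+"): 15,
}

BODYCOMP_METRICS = ("nama", "lama", "sma", "sma_over_bmi", "imat", "sfat", "vfat")

# (mean, sd) per metric, by sex and age band
_MALE = {
    "nama":         ((139.1, 19.8), (132.7, 22.7), (125.7, 20.1), (117.2, 23.2), (106.3, 22.0), (75.5, 26.0)),
    "lama":         ((28.8, 15.9), (37.4, 17.5), (40.7, 17.0), (40.3, 15.5), (46.4, 18.2), (59.7, 14.5)),
    "sma":          ((168.0, 21.7), (170.1, 25.4), (166.4, 22.9), (157.5, 21.7), (152.6, 18.8), (135.3, 23.2)),
    "sma_over_bmi": ((6.5, 0.9), (6.4, 0.6), (6.3, 0.7), (6.2, 0.7), (5.9, 0.7), (5.1, 0.6)),
    "imat":         ((13.3, 7.6), (16.7, 6.9), (16.9, 5.7), (17.2, 5.4), (19.0, 5.6), (28.4, 7.0)),
    "sfat":         ((200.2, 126.8), (220.6, 90.1), (192.3, 59.0), (158.9, 52.2), (158.4, 47.5), (168.5, 47.0)),
    "vfat":         ((92.2, 58.0), (125.5, 56.6), (152.8, 54.2), (146.5, 56.1), (184.0, 74.1), (213.9, 73.3)),
}
_FEMALE = {
    "nama":         ((81.2, 13.1), (85.0, 11.7), (73.2, 12.7), (69.0, 15.0), (57.4, 14.4), (55.3, 13.9)),
    "lama":         ((23.2, 10.8), (24.8, 6.6), (28.6, 8.6), (33.7, 9.6), (40.1, 8.8), (45.9, 10.9)),
    "sma":          ((104.5, 12.2), (110.0, 11.7), (102.7, 12.2), (102.7, 14.6), (97.6, 11.4), (101.5, 9.5)),
    "sma_over_bmi": ((4.6, 0.7), (5.0, 0.7), (4.5, 0.5), (4.3, 0.5), (4.1, 0.6), (4.2, 0.5)),
    "imat":         ((10.7, 5.3), (12.4, 4.2), (15.7, 6.6), (17.5, 5.4), (19.9, 5.1), (23.9, 7.1)),
    "sfat":         ((192.4, 121.7), (183.1, 70.1), (173.2, 67.9), (180.3, 57.1), (176.2, 60.3), (185.4, 60.0)),
    "vfat":         ((45.0, 23.8), (53.1, 29.0), (68.0, 33.7), (89.0, 41.4), (107.0, 47.6), (132.5, 61.3)),
}

CHECKUP_BODYCOMP_STATS: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    (sex, band): {m: table[m][i] for m in table}
    for sex, table in (("male", _MALE), ("female", _FEMALE))
    for i, band in enumerate(AGE_BANDS)
}

_DEMO_MALE = {
    "height_cm": ((174.6, 5.6), (174.3, 5.3), (174.9, 6.3), (171.0, 4.4), (169.6, 5.5), (165.5, 6.2)),
    "weight_kg": ((80.2, 17.3), (81.6, 14.2), (80.7, 11.9), (74.7, 9.6), (74.6, 8.1), (72.2, 9.5)),
    "bmi":       ((26.2, 5.0), (26.8, 3.9), (26.3, 3.1), (25.5, 2.8), (26.0, 2.7), (26.3, 2.6)),
}
_DEMO_FEMALE = {
    "height_cm": ((160.4, 5.1), (162.9, 5.8), (161.3, 5.5), (159.1, 4.9), (154.4, 5.1), (154.5, 4.5)),
    "weight_kg": ((58.8, 10.4), (59.4, 9.1), (59.6, 8.7), (60.0, 8.2), (58.0, 7.3), (59.5, 9.6)),
    "bmi":       ((23.0, 4.5), (22.4, 3.2), (22.9, 3.2), (23.8, 3.2), (24.3, 3.2), (24.2, 3.9)),
}

CHECKUP_DEMOGRAPHIC_STATS: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    (sex, band): {m: table[m][i] for m in table}
    for sex, table in (("male", _DEMO_MALE), ("female", _DEMO_FEMALE))
    for i, band in enumerate(AGE_BANDS)
}


def checkup_group_sizes(sex: str | None = None) -> dict[tuple[str, str], int]:
    """Group sizes, optionally restricted to one sex."""
    if sex is None:
        return dict(CHECKUP_GROUP_SIZES)
    return {k: v for k, v in CHECKUP_GROUP_SIZES.items() if k[0] == sex}


def checkup_group_stats(
    sex: str | None = None, metrics: tuple[str, ...] | None = None
) -> dict[tuple[str, str], dict[str, tuple[float, float]]]:
    """Body-composition group stats, optionally restricted by sex/metric."""
    out = {}
    for key, stats in CHECKUP_BODYCOMP_STATS.items():
        if sex is not None and key[0] != sex:
            continue
        out[key] = {m: v for m, v in stats.items() if metrics is None or m in metrics}
    return out
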