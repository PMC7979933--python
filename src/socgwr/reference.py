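"""Published summary tables from the continental-US RaCA/GWR SOC study.

These are reported values, not outputs of this package: per-ecoregion mean
SOC stocks (Mg/ha), ecoregion totals (Tg) under the current climate and the
SSP126 / SSP585 end-of-century scenarios, model residuals, national decadal
stock totals (Pg), and the headline sample counts.  They serve as fixed
inputs to arithmetic consistency checks — column sums, scenario deltas, and
the residual-percent convention — exercised by the test suite and the
acceptance script.
"""

from __future__ import annotations

import pandas as pd

#: profile/sample counts of the observational database
N_PROFILES = 4559
N_SAMPLES_TOTAL = 31472
N_SAMPLES_0_100CM = 24192
TRAIN_FRACTION = 0.75

_ECOREGION_ROWS = [
    # region, mean stock Mg/ha, current Tg, SSP126 Tg, SSP585 Tg,
    # residual Mg/ha (predicted - observed), residual %
    ("Everglades", 776.6, 304.9, 627.3, 970.0, -643.2, 82.8),
    ("Mixed Wood Shield", 661.1, 2539.5, 2603.5, 2663.5, -265.5, 40.2),
    ("Mississippi Alluvial and Southeast USA Coastal Plains",
     519.3, 3584.5, 4220.1, 4613.8, -210.0, 40.4),
    ("Atlantic Highlands", 457.0, 2949.8, 2652.5, 2405.5, -132.4, 29.0),
    ("Marine West Coast Forest", 403.5, 2101.9, 2002.5, 1939.6, -104.7, 25.9),
    ("Mixed Wood Plains", 352.4, 5266.9, 5000.3, 4772.7, -151.1, 42.9),
    ("Central USA Plains", 207.9, 2481.3, 2344.1, 2241.3, -74.2, 35.7),
    ("Temperate Prairies", 191.6, 7289.2, 7147.4, 7012.0, -21.9, 11.4),
    ("Western Cordillera", 170.5, 9557.8, 8751.5, 8177.0, -56.2, 33.0),
    ("Texas-Louisiana Coastal Plain", 163.7, 631.2, 633.4, 625.2, -41.2, 25.2),
    ("Ozark/Ouachita-Appalachian Forests", 123.5, 4617.0, 3881.1, 3488.3, -87.8, 71.1),
    ("West-Central Semiarid Prairies", 102.8, 5637.8, 5603.5, 5566.6, -7.3, 7.1),
    ("Upper Gila Mountains", 100.4, 708.7, 683.5, 664.0, -34.2, 34.0),
    ("Cold Deserts", 97.8, 6927.5, 6447.2, 6106.8, -27.4, 28.0),
    ("Southeastern USA Plains", 97.5, 8359.9, 8115.0, 7892.2, -11.6, 11.9),
    ("Mediterranean California", 91.2, 1134.4, 1120.3, 1129.2, -22.9, 25.1),
    ("South Central Semiarid Prairies", 87.0, 8184.3, 7283.2, 6703.1, -24.7, 28.4),
    ("Western Sierra Madre Piedmont", 76.5, 2339.7, 2262.6, 2215.0, -6.1, 8.0),
    ("Tamaulipas-Texas Semiarid Plain", 61.7, 368.9, 332.5, 300.0, -2.0, 3.3),
    ("Warm Deserts", 48.0, 223.1, 244.9, 264.0, 0.6, 1.2),
]

#: reported grand totals (Tg) of the ecoregion table
ECOREGION_TOTALS_TG = {"current": 75208.2, "ssp126": 71956.2, "ssp585": 69749.7}


def ecoregion_table() -> pd.DataFrame:
    """Reported per-ecoregion stocks, scenario totals, and residuals."""
    return pd.DataFrame(
        _ECOREGION_ROWS,
        columns=[
            "region",
            "mean_stock_mg_ha",
            "total_tg_current",
            "total_tg_ssp126",
            "total_tg_ssp585",
            "residual_mg_ha",
            "residual_pct",
        ],
    )


#: national decadal totals (Pg); the 2017 row is the current-climate baseline
_DECADAL_ROWS = [
    # year, SSP126 total Pg, SSP585 total Pg
    (2030, 69.6, 71.0),
    (2040, 73.6, 70.8),
    (2050, 71.8, 68.4),
    (2060, 71.2, 67.3),
    (2070, 71.2, 66.0),
    (2080, 71.3, 64.6),
    (2090, 70.6, 63.3),
    (2100, 73.2, 58.8),
]

BASELINE_TOTAL_PG = 74.5  # 2017, current climate
BASELINE_MEAN_MG_HA = 96.3


def decadal_totals() -> pd.DataFrame:
    """Reported national SOC totals (Pg) per decade and scenario."""
    return pd.DataFrame(_DECADAL_ROWS, columns=["year", "ssp126_pg", "ssp585_pg"])
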