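"""Published study constants for the 27-district Punjab wheat-yield study.

The original district-level panel (Pakistan Federal Bureau of Statistics,
1981-2013) is not publicly deposited; what *is* published are per-station
summary statistics, the per-target ant-colony feature counts, and the tuned
learner hyperparameters.  They are collected here so the synthetic generator
can emulate the study conditions and the pipeline can rerun the published
experimental design on any panel.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PUNJAB_STATIONS",
    "TARGET_PRESETS",
    "TargetPreset",
    "N_YEARS",
    "YEAR_START",
]

N_YEARS = 33
YEAR_START = 1981

# station_id, name, lat N, lon E, elevation m, mean, std, min, max, skew, kurtosis
# (annual wheat yield, kg ha^-1, 1981-2013)
PUNJAB_STATIONS: list[tuple[str, str, float, float, float, float, float, float, float, float, float]] = [
    ("shekhupura", "Shekhupura", 31.71, 73.98, 207, 2297.46, 519.54, 1087.89, 3062.99, -0.29, -0.65),
    ("okara", "Okara", 30.81, 73.45, 105, 2901.89, 528.93, 1888.08, 3588.10, -0.26, -1.16),
    ("sahiwal", "Sahiwal", 30.66, 71.11, 152, 2751.87, 411.29, 1955.17, 3792.40, 0.12, -0.10),
    ("vehari", "Vehari", 30.04, 72.34, 140, 2568.94, 456.80, 1846.00, 3462.03, 0.09, -0.87),
    ("multan", "Multan", 30.15, 71.52, 122, 2307.97, 377.77, 1713.03, 2952.97, 0.16, -1.17),
    ("muzaffar_garh", "Muzaffar Garh", 30.07, 71.18, 122, 2151.16, 470.69, 1157.47, 2890.72, -0.21, -0.99),
    ("dera_ghazi_khan", "Dera Ghazi Khan", 30.03, 70.38, 129, 2234.18, 457.67, 1050.86, 2914.07, -0.66, 0.32),
    ("bakkar", "Bakkar", 45.30, 14.53, 82, 2049.52, 601.05, 1222.01, 3440.61, 0.79, 0.18),
    ("layyah", "Layyah", 30.96, 70.94, 143, 2025.44, 485.42, 1160.59, 2900.23, 0.21, -0.88),
    ("khushab", "Khushab", 32.32, 71.90, 195, 1455.08, 345.98, 822.00, 2103.04, 0.09, -0.88),
    ("sargodha", "Sargodha", 32.08, 72.66, 189, 2253.13, 308.08, 1637.40, 2742.39, 0.02, -1.06),
    ("faisalabad", "Faisalabad", 31.45, 73.13, 184, 2487.44, 511.38, 1565.83, 3257.58, -0.07, -1.35),
    ("toba_tek_singh", "Toba Tek Singh", 30.97, 72.48, 149, 2757.25, 715.26, 1814.86, 3310.60, 2.20, 5.95),
    ("gujrat", "Gujrat", 32.57, 74.07, 233, 1632.04, 267.08, 996.51, 1985.37, -0.77, -0.03),
    ("rawalpindi", "Rawalpindi", 33.56, 73.01, 508, 1374.83, 372.15, 624.01, 1993.06, -0.26, -0.68),
    ("jhelum", "Jhelum", 32.74, 73.72, 234, 1418.49, 365.23, 752.09, 2110.03, -0.01, -0.64),
    ("mianwali", "Mianwali", 32.58, 71.53, 210, 1618.80, 332.99, 1037.09, 2510.39, 0.63, 0.28),
    ("lahore", "Lahore", 31.52, 74.35, 217, 2485.52, 431.22, 1385.93, 3209.78, -0.97, 1.08),
    ("khanewal", "Khanewal", 30.28, 71.93, 128, 2613.95, 436.54, 1850.94, 3600.46, 0.24, -0.67),
    ("rajanpur", "Rajanpur", 29.10, 70.32, 97, 2138.37, 512.46, 1009.88, 3012.48, -0.70, -0.10),
    ("bahawal_nagar", "Bahawal Nagar", 30.00, 73.24, 163, 2298.80, 544.52, 1401.50, 3773.33, 0.57, 0.08),
    ("attock", "Attock", 33.76, 72.36, 358, 1271.96, 326.45, 685.73, 2029.07, 0.28, -0.36),
    ("gujranwala", "Gujranwala", 32.15, 74.18, 229, 2437.28, 604.31, 1055.69, 3484.13, -0.29, -0.56),
    ("jhang", "Jhang", 31.30, 72.32, 158, 2353.19, 431.16, 1637.83, 3089.02, 0.03, -1.06),
    ("kasur", "Kasur", 31.11, 74.44, 218, 2495.00, 407.78, 1688.95, 3099.40, -0.07, -0.93),
    ("rahimyar_khan", "Rahimyar Khan", 28.42, 70.29, 80, 2308.74, 522.80, 1312.27, 3369.46, 0.29, -0.49),
    ("sialkot", "Sialkot", 32.49, 74.52, 256, 2051.86, 612.39, 598.89, 3018.60, -0.44, -0.47),
]


@dataclass(frozen=True)
class TargetPreset:
    """Published experimental settings for one test station."""

    station_id: str
    n_features: int  # number of predictor stations the ant colony must pick
    oselm_n_hidden: int
    oselm_activation: str
    oselm_block_size: int
    elm_n_hidden: int
    elm_activation: str
    rf_n_trees: int = 10_000
    rf_m_try: int = 2

    @property
    def raw_training_records(self) -> int:
        """Selected stations x 33 annual records per station."""
        return self.n_features * N_YEARS


# Six test stations of the published study, with the tuned model settings.
TARGET_PRESETS: dict[str, TargetPreset] = {
    p.station_id: p
    for p in [
        TargetPreset("rahimyar_khan", 22, 35, "rbf", 100, 15, "sig"),
        TargetPreset("dera_ghazi_khan", 20, 11, "rbf", 100, 15, "sig"),
        TargetPreset("kasur", 19, 7, "rbf", 100, 17, "rbf"),
        TargetPreset("sialkot", 17, 15, "rbf", 100, 9, "rbf"),
        TargetPreset("rawalpindi", 12, 35, "rbf", 100, 17, "rbf"),
        TargetPreset("jhang", 14, 10, "sig", 100, 15, "sin"),
    ]
}
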