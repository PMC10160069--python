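"""Run configuration: every numeric constant of the analysis lives here with
its citation string, so any number in a run report traces back to a config
entry or an input file. A run without a config file uses the documented
reference defaults; a TOML file overrides keys selectively.

The source-water characteristics shipped as defaults are synthetic
stand-ins consistent with the synthetic bottle generator, not observed
values: real analyses must supply their own via the config file.
"""

from __future__ import annotations

import copy
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from typing import Any

DEFAULTS: dict[str, Any] = {
    "reference_year": 2020,
    "pco2_atm_uatm": 414.0,
    # schematic meridional coastline; replace for real shorelines
    "coastline": [[14.0, -16.0], [14.0, -34.0]],
    "regions": {
        # latitude bounds of the two subsystems, split at the Luederitz cell
        "NBUS": {"lat_min": -26.0, "lat_max": -16.0},
        "SBUS": {"lat_min": -34.0, "lat_max": -26.0},
    },
    "grid": {
        "resolution_deg": 0.1,
        "max_dist_deg": 0.5,
        "min_neighbors": 5,
        "max_neighbors": 40,
        "variogram_n_lags": 15,
        "variogram_max_lag_deg": 1.5,
    },
    "zone": {"sd_threshold_uatm": 30.0, "bin_km": 10.0, "km_per_deg_lat": 111.0},
    "flux": {
        "k_params": ["KW14", "KW92", "WM99", "N2000", "McG2001", "Ho2006"],
        "baseline_param": "KW14",
        "rho_surface_kg_m3": 1025.0,
        "mode": "region_average",
    },
    "carbonate": {"ta_per_no3": 1.0, "surface_bottle_max_depth_m": 100.0},
    "production": {
        "redfield_c_n": 6.625,  # 106:16
        "kg_per_sv": 1.0e9,  # 1 Sv = 1e6 m3/s at rho = 1000 kg/m3
        "upwelling_sv": {"NBUS": 0.9, "SBUS": 0.4},
        "n_pref_umol_kg": {"NBUS": [6.44, 0.61], "SBUS": [7.44, 0.36]},  # value, s.e.
        "published_np_tgc_yr": {"NBUS": [68.0, 245.0], "SBUS": [13.5, 42.0]},  # low, high
        "preformed_fraction": {"NBUS": [0.24, 0.02], "SBUS": [0.38, 0.02]},  # value, s.e.
        "southern_ocean_outgassing_tgc_yr": 110.0,
        "prior_flux_tgc_yr": {"NBUS": 11.5, "SBUS": -1.4},
    },
    "reference_values": {
        # printed reference quantities used by consistency checks
        "boundary_km": {"NBUS": 340.0, "SBUS": 200.0},
        "seasonal_mean_pco2_nbus_uatm": [481.0, 560.7],  # Sep-Mar, Apr-Aug
        "flux_pairs_tgc_yr": {"NBUS": [15.64, 26.69], "SBUS": [2.94, 5.03]},
    },
    "source_water": {
        # SYNTHETIC stand-in characteristics (consistent with the bottle
        # generator), not observed values; se entries feed the uncertainty
        # propagation
        "NBUS": {
            "label": "SACW",
            "temp": 10.0,
            "sal": 34.9,
            "ta": 2290.0,
            "dic": 2220.0,
            "no3": 20.0,
            "po4": 1.6,
            "n_pref": 6.44,
            "se": {"ta": 6.0, "dic": 6.0, "temp": 0.3, "sal": 0.05, "no3": 0.8},
        },
        "SBUS": {
            "label": "ESACW",
            "temp": 9.0,
            "sal": 34.6,
            "ta": 2280.0,
            "dic": 2190.0,
            "no3": 18.0,
            "po4": 1.4,
            "n_pref": 7.44,
            "se": {"ta": 6.0, "dic": 6.0, "temp": 0.3, "sal": 0.05, "no3": 0.8},
        },
    },
    "synthetic": {
        "survey": {},  # overrides of synthetic.SurveyConfig fields
        "profiles": {},  # overrides of synthetic.ProfileConfig fields
    },
    "seed": 0,
}

# citation strings of the reference constants (provenance of the defaults)
CITATIONS: dict[str, str] = {
    "pco2_atm_uatm": "atmospheric pCO2 of the reference year 2020, Mauna Loa records",
    "regions": "NBUS 16-26 S and SBUS 26-34 S, split at the Luederitz cell (~26 S)",
    "grid.resolution_deg": "0.1 x 0.1 deg ordinary-kriging grid",
    "grid.max_dist_deg": "observations within a maximum of 0.5 deg spherical distance",
    "zone.sd_threshold_uatm": "s.d. decreases persistently to below +-30 uatm",
    "zone.bin_km": "averages over intervals of 10 km coastal distance",
    "zone.km_per_deg_lat": "111.0 km/deg reproduces the reference subsystem areas",
    "flux.k_params": "six published gas-transfer-velocity wind-speed parameterizations",
    "production.redfield_c_n": "Redfield ratio 106:16",
    "production.upwelling_sv": "upwelling volumes 0.9 Sv (NBUS) and 0.4 Sv (SBUS)",
    "production.n_pref_umol_kg": "preformed nitrate 6.44+-0.61 (NBUS), 7.44+-0.36 (SBUS) umol/kg",
    "production.published_np_tgc_yr": "published new production 68-245 (NBUS), 13.5-42 (SBUS) Tg C/yr",
    "production.preformed_fraction": "preformed contribution 24+-2% (NBUS), 38+-2% (SBUS)",
    "production.southern_ocean_outgassing_tgc_yr": "~110 Tg C/yr natural outgassing, Atlantic sector 44-58 S",
    "production.prior_flux_tgc_yr": "earlier area-integrated estimates 11.5 / -1.4 Tg C/yr",
    "reference_values.boundary_km": "offshore boundaries 340 km (NBUS) and 200 km (SBUS)",
    "reference_values.seasonal_mean_pco2_nbus_uatm": "NBUS seasonal means 481.0 / 560.7 uatm",
    "reference_values.flux_pairs_tgc_yr": "KW14 vs KW92 flux pairs 15.64/26.69 and -2.94/-5.03 Tg C/yr",
    "source_water": "synthetic stand-in source-water characteristics (user-supplied in real runs)",
}


def _deep_update(base: dict, override: dict) -> dict:
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], val)
        else:
            base[key] = val
    return base


@dataclass
class RunConfig:
    """Nested-dict run configuration with stable hashing."""

    values: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            override = tomllib.load(fh)
        return cls(_deep_update(copy.deepcopy(DEFAULTS), override))

    def __getitem__(self, key):
        return self.values[key]

    def get(self, *keys, default=None):
        node = self.values
        for key in keys:
            if not isinstance(node, dict) or key not in node:
                return default
            node = node[key]
        return node

    def with_overrides(self, **overrides) -> "RunConfig":
        return RunConfig(_deep_update(copy.deepcopy(self.values), overrides))

    @property
    def seed(self) -> int:
        return int(self.values["seed"])

    def hash(self) -> str:
        canon = json.dumps(self.values, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
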