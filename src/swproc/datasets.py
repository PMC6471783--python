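"""Bundled published summary tables from a ten-site vital-sign triage rollout.

These are the site-level quantitative process and context summaries of
a published 10-cluster, 9-step stepped-wedge trial of a blood-pressure
triage device in routine maternity care (Ethiopia, Haiti, Sierra Leone,
India, Zimbabwe, Uganda, Zambia, Malawi): trained-staff counts,
pre/post blood-pressure-measurement coverage, equipment availability,
device adoption, and cluster context (monthly deliveries by location,
caesarean proportions, blood/MgSO4 availability, referral distances).

They serve as worked-example inputs for the scoring, effects and
reporting layers.  Site-level staffing-by-cadre and intensive-care
columns of the source table are not included.  Fields that the trial
could not record (stepped-wedge right-censoring of the 6/12-month
adoption reviews, sites without BP-coverage denominators) are NaN.
"""

from __future__ import annotations

import io

import numpy as np
import pandas as pd

__all__ = [
    "load_implementation_table",
    "load_context_table",
    "load_trial_totals",
    "load_implementation_measures",
]

# Per-site implementation fidelity / reach / adoption summaries.
# staff_trained: HCP trained during rollout (count, % of maternity workforce)
# bp_*: women with a BP measurement in the 4-week windows before / 3 months
#       after implementation (count, % of attendees); four sites recorded it
# equip_*: % facilities with >=1 working BP device before/after
# sole_use_*, mixed_use_*: % clinical areas using solely / additionally the
#       study device at 6 and 12 months (NaN: review beyond trial window)
_IMPLEMENTATION_CSV = """\
site,staff_trained_n,staff_trained_pct,bp_pre_n,bp_pre_pct,bp_post_n,bp_post_pct,equip_pre_pct,equip_post_pct,sole_use_6mo_pct,mixed_use_6mo_pct,sole_use_12mo_pct,mixed_use_12mo_pct
Addis Ababa,192,36.9,,,,,100.0,100.0,33.3,66.7,,
Cap Haitien,189,73.5,,,,,100.0,100.0,76.2,23.8,,
Freetown,243,57.9,2199,87.7,3335,100.0,84.6,100.0,73.1,26.9,96.2,0.0
Gokak,297,87.1,,,,,97.5,100.0,72.3,27.7,,
Harare,405,69.9,,,,,92.0,100.0,,,,
Kampala,188,16.5,,,,,92.3,100.0,33.8,47.9,34.2,47.9
Lusaka,265,33.9,,,,,100.0,100.0,75.9,24.1,,
Mbale,314,59.2,4640,42.6,11300,96.2,92.0,100.0,87.3,9.9,,
Ndola,349,86.6,5673,98.2,5782,100.0,93.5,100.0,90.2,9.8,90.2,9.8
Zomba,305,89.2,11860,88.4,10783,94.1,100.0,100.0,,,,
"""

# Cluster context: mean monthly deliveries by location, caesarean %, mean %
# of facilities with blood transfusion / MgSO4, mean km from peripheral
# facility to nearest tertiary facility.
_CONTEXT_CSV = """\
site,central_deliveries_mean,peripheral_deliveries_mean,home_deliveries_mean,caesarean_pct,blood_pct,mgso4_pct,distance_km_mean
Addis Ababa,1114,657,,22,15.8,87.4,4.3
Cap Haitien,682,0,63,20,25.0,25.0,14.2
Freetown,704,403,84,14,7.7,100.0,7.5
Gokak,952,188,4,31,25.0,41.4,74.0
Harare,1026,785,108,22,12.0,100.0,16.3
Kampala,2223,4168,,22,38.5,61.5,8.7
Lusaka,2231,3507,436,9,14.1,79.8,3.3
Mbale,1442,1583,,12,31.7,78.6,19.6
Ndola,500,797,46,10,6.5,77.4,11.3
Zomba,2705,318,86,14,75.0,95.4,68.3
"""

# Trial-wide printed counts: pooled BP-measurement coverage (four recording
# sites), peripheral-facility referrals in the control vs intervention
# windows (nine sites with denominators), device fleet outcomes, caesarean
# deliveries over the trial.
_TOTALS = {
    "bp_measured_pre": (6093, 7693),
    "bp_measured_post": (7800, 7992),
    "referrals_pre": (2784, 74828),
    "referrals_post": (3212, 73371),
    "devices_broken": (180, 3868),
    "devices_missing": (23, 3868),
    "caesarean_deliveries": (91158, 536223),
    "staff_trained_total": (2747, None),
}


def load_implementation_table() -> pd.DataFrame:
    """Site-level implementation fidelity / reach / adoption summary table."""
    return pd.read_csv(io.StringIO(_IMPLEMENTATION_CSV))


def load_context_table() -> pd.DataFrame:
    """Site-level cluster context (deliveries, caesarean %, resources, distance)."""
    return pd.read_csv(io.StringIO(_CONTEXT_CSV))


def load_trial_totals() -> dict[str, tuple[int, int | None]]:
    """Trial-wide (numerator, denominator) count pairs."""
    return dict(_TOTALS)


def load_implementation_measures() -> pd.DataFrame:
    """The implementation table reshaped into the long measure format
    consumed by the scoring pipeline (cluster_id, measure_name, domain,
    direction, value, available).

    Measures mirror the quantities the rollout ranked sites on: staff
    trained (fidelity); BP-measurement coverage after implementation and
    the gain in equipment availability (reach); sole use of the study
    device at 6 months (adoption).
    """
    wide = load_implementation_table().set_index("site")
    spec = [
        ("staff_trained_pct", "staff_trained_pct", "fidelity", "higher_is_better"),
        ("bp_post_pct", "bp_post_pct", "reach", "higher_is_better"),
        ("equip_gain_pct", None, "reach", "higher_is_better"),
        ("sole_use_6mo_pct", "sole_use_6mo_pct", "adoption", "higher_is_better"),
    ]
    rows = []
    equip_gain = wide["equip_post_pct"] - wide["equip_pre_pct"]
    for name, col, domain, direction in spec:
        values = equip_gain if col is None else wide[col]
        for site, value in values.items():
            rows.append(
                {
                    "cluster_id": site,
                    "measure_name": name,
                    "domain": domain,
                    "direction": direction,
                    "value": float(value) if np.isfinite(value) else np.nan,
                    "available": bool(np.isfinite(value)),
                }
            )
    return pd.DataFrame(rows)
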