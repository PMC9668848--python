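"""Tracer pool sizes, relative excess and recovery fractions.

The accounting identity is

    tracer pool size = element pool mass * atom % excess / 100

(in g of excess 13C or 15N per subplot).  Two derived quantities make
transfer comparable across subplots:

* relative 13C excess — a pool's enrichment as a percentage of the *same
  subplot's* day-0 shoot enrichment (the initial amount of fixed 13C differs
  between subplots because photosynthesis does);
* recovery fraction — tracer pool size divided by the total tracer, taken at
  the reference day where each group's enrichment peaks: day 1 for plants
  and microbes, day 5 for soil fauna.  The 13C denominator is the subplot's
  initial (day-0) shoot 13C pool size; the 15N denominator is the injected
  15N mass.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import SUBPLOT_AREA_M2

__all__ = [
    "tracer_pool_size",
    "relative_excess",
    "recovery_fractions",
    "MICROBE_PLANT_POOLS",
    "FAUNA_POOLS",
]

#: pools whose recovery is evaluated at day 1
MICROBE_PLANT_POOLS = (
    "shoot", "root", "total_bacteria", "fungi", "amf",
)
#: pools whose recovery is evaluated at day 5 (enrichment peaks later)
FAUNA_POOLS = (
    "detritivorous_collembola", "detritivorous_mites", "annelids",
    "other_detritivores", "herbivores", "predaceous_mites", "predaceous_fauna",
)


def tracer_pool_size(pool_mass_g, atom_percent_excess):
    """Mass of tracer excess (g) in a pool: mass * excess / 100.

    Bilinear: doubling either factor doubles the result.  Accepts scalars or
    aligned arrays/Series; negative masses are rejected.
    """
    mass = np.asarray(pool_mass_g, dtype=float)
    if np.any(mass < 0):
        raise ValueError("pool mass must be non-negative")
    out = mass * np.asarray(atom_percent_excess, dtype=float) / 100.0
    return out.item() if np.isscalar(pool_mass_g) else out


def relative_excess(pool_excess, initial_shoot_excess):
    """Pool enrichment as % of the same subplot's initial shoot enrichment.

    A non-positive initial shoot excess makes the subplot's relative values
    meaningless; they are returned missing (NaN).
    """
    pool = np.asarray(pool_excess, dtype=float)
    init = np.asarray(initial_shoot_excess, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(init > 0, 100.0 * pool / init, np.nan)
    return out.item() if np.isscalar(pool_excess) and np.isscalar(initial_shoot_excess) else out


def recovery_fractions(
    budgets: pd.DataFrame,
    pulse_15N_mg: pd.Series | None = None,
    day_plants_microbes: float = 1.0,
    day_fauna: float = 5.0,
) -> pd.DataFrame:
    """Per-pool fraction of the total pulse recovered at the reference days.

    *budgets* is a long table with columns plot_id, day, pool, element
    ('13C'/'15N') and tracer_pool_size_g.  Plants and microbes are evaluated
    at ``day_plants_microbes``, fauna at ``day_fauna``.  The 13C denominator
    is each subplot's day-0 shoot 13C pool size; the 15N denominator is the
    injected 15N mass (``pulse_15N_mg``, indexed by plot_id).  A missing
    reference day or denominator yields a missing fraction, not an error.
    """
    required = {"plot_id", "day", "pool", "element", "tracer_pool_size_g"}
    missing = required - set(budgets.columns)
    if missing:
        raise ValueError(f"budgets table lacks columns {sorted(missing)}")

    init = (
        budgets.query("pool == 'shoot' and day == 0 and element == '13C'")
        .set_index("plot_id")["tracer_pool_size_g"]
    )
    rows = []
    for (plot, pool, element), sub in budgets.groupby(["plot_id", "pool", "element"]):
        ref_day = day_fauna if pool in FAUNA_POOLS else day_plants_microbes
        at_ref = sub.loc[sub["day"] == ref_day, "tracer_pool_size_g"]
        size = float(at_ref.iloc[0]) if len(at_ref) else np.nan
        if element == "13C":
            denom = init.get(plot, np.nan)
        else:
            denom = (
                float(pulse_15N_mg.get(plot, np.nan)) / 1000.0
                if pulse_15N_mg is not None
                else np.nan
            )
        frac = size / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        rows.append(
            {
                "plot_id": plot, "pool": pool, "element": element,
                "reference_day": ref_day, "tracer_pool_size_g": size,
                "denominator_g": denom if np.isfinite(denom) else np.nan,
                "recovery_fraction": frac,
            }
        )
    return pd.DataFrame(rows)
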