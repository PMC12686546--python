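"""Per-mouse insulin exposure and insulin-sensitivity indices.

Two indices summarise a mouse's OGTT:

* peripheral sensitivity IS_P = k_2 / <I>, the glucose elimination rate
  constant per unit of time-averaged insulin — how fast peripheral
  tissues clear glucose given the insulin on offer (larger = more
  sensitive);
* hepatic sensitivity IS_L, a study-normalised, dimensionless transform
  of the product <EGP> * <I>: a liver that keeps producing glucose
  despite high insulin is insensitive, so a *smaller* product means a
  *more* sensitive liver.  We report the inverse product scaled so the
  study-wide mean is 1, which keeps the index unit-free and invariant
  under any global rescaling of EGP or insulin units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SensitivityIndices",
    "time_average_insulin",
    "is_peripheral",
    "liver_index_from_products",
    "compute_indices",
]


@dataclass(frozen=True)
class SensitivityIndices:
    mouse_id: str
    avg_insulin: float | None  # mU/L; None when insulin unavailable
    is_p: float | None  # 1/min * L/mU
    egp_insulin_product: float | None  # (umol/kg/min) * (mU/L)
    is_l: float | None  # dimensionless, study mean 1


def time_average_insulin(times, insulin) -> float | None:
    """Trapezoidal time-average of insulin over the observed window.

    Returns None when the series is absent (the study retained such
    animals but excluded them from insulin-dependent statistics).
    """
    if insulin is None:
        return None
    times = np.asarray(times, float)
    insulin = np.asarray(insulin, float)
    if len(insulin) < 2 or len(times) != len(insulin):
        raise ValueError("need >= 2 paired insulin observations")
    return float(np.trapezoid(insulin, times) / (times[-1] - times[0]))


def is_peripheral(k_2: float, avg_insulin: float) -> float:
    """Peripheral sensitivity k_2 / <insulin> (1/min per mU/L)."""
    if not avg_insulin > 0:
        raise ValueError("average insulin must be > 0")
    return k_2 / avg_insulin


def liver_index_from_products(products) -> np.ndarray:
    """Study-normalised hepatic index from EGP x insulin products.

    IS_L_i = (1/P_i) / mean_j(1/P_j); by construction the mean over the
    included mice is exactly 1 and the index is invariant under any
    common rescaling of the products.
    """
    p = np.asarray(products, float)
    if p.size == 0:
        raise ValueError("no mice with defined EGP x insulin products")
    if np.any(p <= 0):
        raise ValueError("all products must be > 0")
    inv = 1.0 / p
    return inv / inv.mean()


def compute_indices(per_mouse: list[dict]) -> list[SensitivityIndices]:
    """Assemble indices for a study.

    ``per_mouse`` rows need mouse_id, k_2, avg_specific_egp and either
    an insulin series (times, insulin) or a precomputed avg_insulin
    (None marks it unavailable).  Mice without insulin get None for all
    insulin-dependent fields and never enter the IS_L normalising mean.
    """
    rows = []
    for m in per_mouse:
        avg_ins = m.get("avg_insulin")
        if avg_ins is None and m.get("insulin") is not None:
            avg_ins = time_average_insulin(m["times"], m["insulin"])
        rows.append({**m, "avg_insulin": avg_ins})

    products = [r["avg_specific_egp"] * r["avg_insulin"]
                for r in rows if r["avg_insulin"] is not None
                and r.get("avg_specific_egp") is not None]
    is_l_values = iter(liver_index_from_products(products)
                       if products else [])

    out = []
    for r in rows:
        if r["avg_insulin"] is None:
            out.append(SensitivityIndices(r["mouse_id"], None, None, None, None))
            continue
        prod = (r["avg_specific_egp"] * r["avg_insulin"]
                if r.get("avg_specific_egp") is not None else None)
        out.append(SensitivityIndices(
            mouse_id=r["mouse_id"],
            avg_insulin=r["avg_insulin"],
            is_p=is_peripheral(r["k_2"], r["avg_insulin"]),
            egp_insulin_product=prod,
            is_l=float(next(is_l_values)) if prod is not None else None,
        ))
    return out
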