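"""Medium construction and application.

A growth medium is a set of caps on exchange reactions (mmol/gDW/h, uptake
negative).  Where measured uptake rates are unavailable, caps are estimated
from paired concentration measurements:

    v = (Ct - C0) / (dt * X)

with C in mmol/L, dt in hours and X the biomass density in gDW/L — a
finite-difference specific exchange flux.  Negative v (falling
concentration) is an uptake cap, positive v a secretion cap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

from .engine import Medium
from .model import MetabolicModel

__all__ = [
    "ConcentrationSeries",
    "estimate_uptake_cap",
    "build_medium",
    "apply_medium",
    "AMINO_ACID_DEFAULT_UPTAKE",
]

#: Bulk uptake cap applied to amino-acid exchanges when a medium row uses
#: the ``amino_acid_default`` marker (mmol/gDW/h, uptake side).
AMINO_ACID_DEFAULT_UPTAKE = 0.5

_SECRETION_CAP = 1000.0


@dataclass
class ConcentrationSeries:
    """Paired concentration measurements for one metabolite.

    C0 at t0 and Ct at t0 + dt (mmol/L), with biomass density X (gDW/L).
    """

    metabolite_id: str
    C0: float
    Ct: float
    dt: float  # hours
    X: float   # gDW/L

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError(f"{self.metabolite_id}: dt must be > 0 (got {self.dt})")
        if self.X <= 0:
            raise ValueError(f"{self.metabolite_id}: X must be > 0 (got {self.X})")


def estimate_uptake_cap(series: ConcentrationSeries) -> float:
    """Average specific exchange flux v = (Ct - C0)/(dt * X), mmol/gDW/h.

    Signed with the exchange convention: consumption gives a negative
    value (an uptake lower bound), accumulation a positive one (a
    secretion upper bound).  Exactly invertible: a series generated from a
    known flux recovers it to machine precision.
    """
    return (series.Ct - series.C0) / (series.dt * series.X)


def build_medium(rows: Sequence[Mapping],
                 aa_default: float = AMINO_ACID_DEFAULT_UPTAKE,
                 default_uptake_policy: str = "closed") -> Medium:
    """Build a :class:`Medium` from table rows.

    Each row needs ``exchange_id`` plus one of:

    - ``lower_bound`` / ``upper_bound``: a direct cap;
    - ``C0, Ct, dt_h, X_gDW_per_L``: a concentration pair resolved through
      :func:`estimate_uptake_cap`;
    - ``lower_bound == "amino_acid_default"``: the bulk amino-acid uptake
      rate (default 0.5 mmol/gDW/h).

    An empty table yields a closed medium (all uptake forbidden).
    Conflicting duplicate rows raise ``ValueError``.
    """
    caps: Dict[str, Tuple[float, float]] = {}
    for row in rows:
        ex = row["exchange_id"]
        lb_raw = row.get("lower_bound", "")
        ub_raw = row.get("upper_bound", "")
        if str(lb_raw).strip() == "amino_acid_default":
            cap = (-abs(aa_default), _SECRETION_CAP)
        elif all(str(row.get(k, "")).strip() != ""
                 for k in ("C0", "Ct", "dt_h", "X_gDW_per_L")):
            series = ConcentrationSeries(
                metabolite_id=ex, C0=float(row["C0"]), Ct=float(row["Ct"]),
                dt=float(row["dt_h"]), X=float(row["X_gDW_per_L"]),
            )
            v = estimate_uptake_cap(series)
            # conservative finite cap on the matching side of the exchange
            cap = (v, _SECRETION_CAP) if v < 0 else (0.0, max(v, 0.0))
        else:
            lb = float(lb_raw) if str(lb_raw).strip() != "" else 0.0
            ub = float(ub_raw) if str(ub_raw).strip() != "" else _SECRETION_CAP
            cap = (lb, ub)
        if ex in caps and caps[ex] != cap:
            raise ValueError(f"conflicting duplicate medium rows for {ex}")
        caps[ex] = cap
    return Medium(caps=caps, default_uptake_policy=default_uptake_policy)


def apply_medium(model: MetabolicModel, medium: Medium,
                 overrides: Optional[Mapping[str, Tuple[float, float]]] = None,
                 ) -> MetabolicModel:
    """Return a copy with exchange bounds set from the medium.

    ``overrides`` are applied last — e.g. closing the cellobiose uptake
    with ``{"EX_cellb_e": (0.0, 1000.0)}`` regardless of the medium table.
    Idempotent, and commutes with itself for disjoint override sets.
    Overriding a non-exchange reaction is an error.
    """
    out = model.copy()
    for rxn in out.exchanges:
        rxn.bounds = medium.bounds_for(rxn)
    for rid, bounds in (overrides or {}).items():
        rxn = out.reactions.get(rid)
        if rxn is None or not rxn.is_exchange:
            raise ValueError(f"override target {rid!r} is not an exchange reaction")
        rxn.bounds = bounds
    return out
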