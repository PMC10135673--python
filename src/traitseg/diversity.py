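"""Per-site functional-diversity metrics from trait abundances.

For a site with trait proportions ``p_i = n_i / sum(n)`` the metrics are

* Shannon-Weaver  ``H  = -sum p_i ln p_i``  (natural log, nats)
* Simpson         ``D1 = 1 - sum p_i**2``
* inverse Simpson ``D2 = 1 / sum p_i**2``  (effective trait count)
* richness        ``S  = #{i : n_i > 0}``
* Pielou evenness ``J  = H / ln S``  for S > 1, undefined at S <= 1

The natural logarithm is used throughout so that J equals 1 exactly at
perfect evenness.  The convention 0*ln(0) = 0 applies.  Undefined values
(J at S = 1, every metric on an all-zero row) are reported as NaN, never
as 0 or 1; all-zero sites are retained with an ``undefined`` flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["compute_diversity", "diversity_profile"]

METRICS = ("H", "D1", "D2", "S", "J")


def compute_diversity(abundance_row: np.ndarray | list) -> dict[str, float]:
    """Diversity metrics for a single site's trait abundance vector."""
    n = np.asarray(abundance_row, dtype=float)
    if np.any(n < 0):
        raise ValidationError("abundances must be non-negative")
    total = n.sum()
    if total == 0:
        return {"H": np.nan, "D1": np.nan, "D2": np.nan, "S": 0, "J": np.nan}
    p = n[n > 0] / total
    H = float(-(p * np.log(p)).sum())
    sum_p2 = float((p**2).sum())
    S = int((n > 0).sum())
    J = H / np.log(S) if S > 1 else np.nan
    return {"H": H, "D1": 1.0 - sum_p2, "D2": 1.0 / sum_p2, "S": S, "J": J}


def diversity_profile(abundances: pd.DataFrame) -> pd.DataFrame:
    """Vectorised per-site profile: one row per site, columns H, D1, D2, S, J,
    plus an ``undefined`` flag for all-zero sites."""
    X = abundances.to_numpy(dtype=float)
    if np.any(X < 0):
        raise ValidationError("abundances must be non-negative")
    total = X.sum(axis=1)
    ok = total > 0
    safe_total = np.where(ok, total, 1.0)
    P = X / safe_total[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        logP = np.where(P > 0, np.log(np.where(P > 0, P, 1.0)), 0.0)
    H = -(P * logP).sum(axis=1)
    sum_p2 = (P**2).sum(axis=1)
    S = (X > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        J = np.where(S > 1, H / np.log(np.maximum(S, 2)), np.nan)
        D1 = 1.0 - sum_p2
        D2 = np.where(ok, 1.0 / np.where(ok, sum_p2, 1.0), np.nan)
    out = pd.DataFrame(
        {
            "H": np.where(ok, H, np.nan),
            "D1": np.where(ok, D1, np.nan),
            "D2": D2,
            "S": S,
            "J": J,
            "undefined": ~ok,
        },
        index=abundances.index,
    )
    out.index.name = "site_id"
    return out
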