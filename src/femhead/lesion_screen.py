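"""Subchondral bone-cyst candidate screening.

Cysts are fluid-filled voids: inside a VOI they inflate the spread of
the local trabecular separation, so a VOI whose Tb.Sp standard
deviation exceeds a threshold (default 585 μm) is flagged as a cyst
candidate.  Flagged VOIs with very low BV/TV are additionally annotated,
since sparse bone alone can mimic the signature; the screen reports
candidates for visual interrogation, it does not decide.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["flag_cysts"]


def flag_cysts(
    table: pd.DataFrame,
    threshold_um: float = 585.0,
    low_bvtv_cutoff: float = 10.0,
) -> pd.DataFrame:
    """Flag cyst-candidate VOIs from the per-region morphometry table.

    A VOI is flagged iff its Tb.Sp SD is strictly greater than
    ``threshold_um``; flagged VOIs with BV/TV below ``low_bvtv_cutoff``
    (%) carry ``low_bvtv_note`` marking a likely sparse-bone false
    positive.  Rows missing Tb.Sp SD are skipped with a warning.
    Aggregate rows (kind ``macro``/``all``) are screened too, matching
    per-VOI reporting.
    """
    rows = []
    for _, r in table.iterrows():
        sd = r.get("Tb_Sp_sd", np.nan)
        if not np.isfinite(sd):
            warnings.warn(
                f"VOI {r.get('name', '?')} has no Tb.Sp SD; skipped from cyst screen",
                stacklevel=2,
            )
            continue
        flagged = bool(sd > threshold_um)
        bvtv = r.get("BV_TV", np.nan)
        rows.append(
            dict(
                name=r["name"],
                kind=r.get("kind", "sub"),
                layer=r.get("layer", "n/a"),
                band=r.get("band", "n/a"),
                octant=r.get("octant", "n/a"),
                Tb_Sp_sd=float(sd),
                flagged=flagged,
                low_bvtv_note=bool(flagged and np.isfinite(bvtv) and bvtv < low_bvtv_cutoff),
            )
        )
    report = pd.DataFrame(
        rows,
        columns=["name", "kind", "layer", "band", "octant", "Tb_Sp_sd",
                 "flagged", "low_bvtv_note"],
    )
    n = int(report["flagged"].sum()) if len(report) else 0
    logger.info("cyst screen: %d candidate VOI(s) above %.0f μm", n, threshold_um)
    return report


def cyst_summary(report: pd.DataFrame) -> dict:
    """Flag counts overall and per layer/octant, for the JSON summary."""
    flagged = report[report["flagged"]]
    return {
        "n_flagged": int(len(flagged)),
        "n_low_bvtv": int(flagged["low_bvtv_note"].sum()) if len(flagged) else 0,
        "by_layer": flagged.groupby("layer").size().to_dict(),
        "by_octant": flagged.groupby("octant").size().to_dict(),
    }
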