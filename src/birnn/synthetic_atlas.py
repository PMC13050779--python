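"""Synthetic default 46-parcel atlas membership table.

The published network assignment of the 46 bilateral parcels used in the
original study is not publicly deposited, so this module ships a *synthetic
stand-in*: 46 placeholder bilateral parcels with a plausible split across
the four canonical systems (DMN, TPN, SN, Other).  It exists so that every
stage of the pipeline runs end to end with study-scale shapes; analyses of
real recordings should supply their own membership table in the same
two-column format (``parcel_id, network_name``).
"""

from __future__ import annotations

import pandas as pd

from .parcel_pipeline import NetworkProjection, build_network_projection

__all__ = ["default_membership", "default_projection", "N_PARCELS", "N_NETWORKS"]

N_PARCELS = 46
N_NETWORKS = 4

# Placeholder bilateral parcels: region stems are generic cortical landmarks,
# not the study's (unavailable) parcel list.  Counts per network: DMN 12,
# TPN 14, SN 8, Other 12.
_ASSIGNMENT: list[tuple[str, str]] = (
    [(f"DMN_{stem}_{h}", "DMN")
     for stem in ("mPFC", "PCC", "Precuneus", "AngularG", "LatTemp", "Hipp")
     for h in ("L", "R")]
    + [(f"TPN_{stem}_{h}", "TPN")
       for stem in ("dlPFC", "FEF", "IPS", "SPL", "MT", "preSMA", "aPFC")
       for h in ("L", "R")]
    + [(f"SN_{stem}_{h}", "SN")
       for stem in ("AntInsula", "dACC", "TPJ", "Operculum")
       for h in ("L", "R")]
    + [(f"Other_{stem}_{h}", "Other")
       for stem in ("V1", "V2", "A1", "S1", "M1", "OFC")
       for h in ("L", "R")]
)

assert len(_ASSIGNMENT) == N_PARCELS


def default_membership() -> pd.DataFrame:
    """Two-column membership table (``parcel_id, network_name``)."""
    return pd.DataFrame(_ASSIGNMENT, columns=["parcel_id", "network_name"])


def default_projection() -> NetworkProjection:
    """Projection built from the synthetic default membership (4 x 46)."""
    return build_network_projection(default_membership())
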