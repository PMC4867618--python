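"""Secondary chemical shifts and the chemical shift index (CSI).

The secondary shift Δδ = δ_obs − δ_rc measures the deviation of an observed
backbone shift from its residue-specific random-coil reference.  Helix
formation moves Cα downfield (Δδ(Cα) > 0) and Cβ slightly upfield; strand
formation does the opposite.  The two atoms are combined into the standard
composite Δδ(Cα) − Δδ(Cβ), which is positive in helices and negative in
strands, and thresholded into a per-residue index:

    index = +1  if composite > +threshold   (helix-like)
    index = −1  if composite < −threshold   (strand-like)
    index =  0  otherwise                   (coil)

Glycine has no Cβ, so its composite falls back to Δδ(Cα) alone.  The
random-coil reference table (Wishart-style values for the 20 standard
residues) ships with the package and can be swapped for any table with the
same layout.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_PPM = 0.7


def load_random_coil_table(path: str | Path | None = None) -> pd.DataFrame:
    """Random-coil Cα/Cβ shifts indexed by 3-letter residue name."""
    if path is None:
        with resources.files("hed.data").joinpath("random_coil.csv").open() as fh:
            rc = pd.read_csv(fh)
    else:
        rc = pd.read_csv(path)
    rc["resname"] = rc["resname"].str.upper()
    return rc.set_index("resname")


def secondary_shifts(shifts: pd.DataFrame,
                     rc: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-residue Δδ(Cα) and Δδ(Cβ) from a shift table.

    Returns a DataFrame with columns ``chain residue resname dCA dCB``;
    a residue lacking one of the atoms has NaN for that Δδ.  Residue names
    absent from the reference table, and Gly Cβ rows, are skipped with a
    warning.
    """
    if rc is None:
        rc = load_random_coil_table()
    sub = shifts[shifts["atom"].isin(["CA", "CB"])].copy()
    if sub.empty:
        raise ValidationError("shift table has no CA or CB rows")
    sub["resname"] = sub["resname"].str.upper()

    unknown = ~sub["resname"].isin(rc.index)
    if unknown.any():
        logger.warning("skipping residues with no random-coil reference: %s",
                       sorted(set(sub.loc[unknown, "resname"])))
        sub = sub[~unknown]
    gly_cb = (sub["resname"] == "GLY") & (sub["atom"] == "CB")
    if gly_cb.any():
        logger.warning("skipping %d Gly CB rows (Gly has no CB)", int(gly_cb.sum()))
        sub = sub[~gly_cb]

    ref = rc.stack().rename("rc_shift").reset_index()
    ref.columns = ["resname", "atom", "rc_shift"]
    sub = sub.merge(ref, on=["resname", "atom"], how="left")
    sub["delta"] = sub["shift"] - sub["rc_shift"]

    wide = sub.pivot_table(index=["chain", "residue", "resname"],
                           columns="atom", values="delta", aggfunc="first")
    wide = wide.rename(columns={"CA": "dCA", "CB": "dCB"}).reset_index()
    for col in ("dCA", "dCB"):
        if col not in wide.columns:
            wide[col] = np.nan
    wide.columns.name = None
    return wide.sort_values(["chain", "residue"]).reset_index(drop=True)


def csi_profile(shifts: pd.DataFrame,
                rc: pd.DataFrame | None = None,
                threshold_ppm: float = DEFAULT_THRESHOLD_PPM) -> pd.DataFrame:
    """Composite secondary shift and per-residue chemical shift index.

    Columns: ``chain residue resname dCA dCB composite index``; index is
    NaN where the required shifts are missing (both atoms for non-Gly,
    Cα for Gly).
    """
    if threshold_ppm <= 0:
        raise ValidationError("threshold must be positive")
    prof = secondary_shifts(shifts, rc)
    is_gly = prof["resname"] == "GLY"
    composite = prof["dCA"] - prof["dCB"]
    composite[is_gly] = prof.loc[is_gly, "dCA"]
    prof["composite"] = composite
    idx = np.where(composite > threshold_ppm, 1,
                   np.where(composite < -threshold_ppm, -1, 0)).astype(float)
    idx[~np.isfinite(composite)] = np.nan
    prof["index"] = idx
    return prof
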