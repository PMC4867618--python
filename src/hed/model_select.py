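"""Chemical-shift-based rescoring and two-stage model selection.

Candidate all-atom models from fragment assembly are rescored by how well
their predicted backbone chemical shifts reproduce the observed ones:

    chi2  = sum_ij ((delta_pred(i,j) - delta_obs(i,j)) / sigma(i,j))^2
    E_CS  = E_model + c * chi2            (weighting factor c = 0.25)

over the matched backbone atom types (HN, Hα, N, Cα, Cβ, C′).  Selection
is then two-stage: take the ``n_energy`` models with lowest E_CS, and among
those keep the ``n_final`` with lowest Cα-RMSD to the single lowest-E_CS
model.  Ties break on (E_CS, model_id) so the procedure is deterministic.

Shift prediction is deliberately an interface: any callable mapping a model
to a predicted-shift table (same schema as an observed shift table, with
per-value sigma) plugs in; a table-lookup predictor ships for testing.
"""

from __future__ import annotations

from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .errors import SelectionError, ValidationError
from .ensemble_geom import superpose
from .io import Model, StructureEnsemble

DEFAULT_C = 0.25

SCORE_COLUMNS = ["model_id", "e_rosetta", "chi2", "e_cs", "rmsd_to_ref"]

#: a shift predictor maps a Model to a predicted-shift DataFrame
ShiftPredictor = Callable[[Model], pd.DataFrame]


def chi2_shift_agreement(pred: pd.DataFrame, obs: pd.DataFrame) -> tuple[float, int]:
    """Chi-square agreement between predicted and observed shifts.

    Matches rows on (chain, residue, atom); sigma is the predictor's
    per-value uncertainty.  Returns (chi2, n_matched); unmatched keys are
    ignored, zero matches is an error.
    """
    merged = pred.merge(obs, on=["chain", "residue", "atom"],
                        suffixes=("_pred", "_obs"))
    merged = merged[np.isfinite(merged["shift_pred"])
                    & np.isfinite(merged["shift_obs"])]
    if merged.empty:
        raise ValidationError("predicted and observed shifts share no keys")
    sigma = merged["uncertainty_pred"].astype(float)
    if not np.all(sigma > 0):
        raise ValidationError("predictor sigma must be > 0 for every value")
    z = (merged["shift_pred"] - merged["shift_obs"]) / sigma
    return float(np.sum(z ** 2)), int(len(merged))


def rescore(e_rosetta: float | np.ndarray, chi2: float | np.ndarray,
            c: float = DEFAULT_C):
    """Shift-augmented model energy E_CS = E + c * chi2 (default c = 0.25)."""
    if c < 0:
        raise ValidationError("weighting factor c must be >= 0")
    if np.any(np.asarray(chi2) < 0):
        raise ValidationError("chi2 must be >= 0")
    return e_rosetta + c * np.asarray(chi2)


def rescore_table(scores: pd.DataFrame, c: float = DEFAULT_C) -> pd.DataFrame:
    """Add/refresh the e_cs column of a score table."""
    out = scores.copy()
    out["e_cs"] = rescore(out["e_rosetta"].to_numpy(float),
                          out["chi2"].to_numpy(float), c)
    return out


def select_core_models(scores: pd.DataFrame,
                       ensemble: StructureEnsemble,
                       selection: set[tuple[str, int]] | str | None = None,
                       n_energy: int = 20,
                       n_final: int = 10,
                       c: float = DEFAULT_C) -> tuple[list[str], pd.DataFrame]:
    """Two-stage energy-then-RMSD model selection.

    1. the single model with lowest E_CS becomes the RMSD reference;
    2. every model's core Cα-RMSD to that reference is computed;
    3. the ``n_energy`` lowest-E_CS models are shortlisted;
    4. of those, the ``n_final`` with lowest RMSD are returned, ordered by
       (rmsd, e_cs, model_id).

    Returns (selected model ids, score table with e_cs and rmsd_to_ref
    filled in).  ``scores`` needs columns model_id, e_rosetta, chi2; model
    ids must match ``ensemble.model_ids``.
    """
    if n_final > n_energy:
        raise SelectionError("n_final cannot exceed n_energy")
    if len(scores) < n_energy:
        raise SelectionError(
            f"score table has {len(scores)} models, need >= {n_energy}"
        )
    table = rescore_table(scores, c)
    table["model_id"] = table["model_id"].astype(str)
    if set(table["model_id"]) - set(ensemble.model_ids):
        raise ValidationError("score table names models absent from ensemble")

    by_model = {mid: ensemble.model(i) for i, mid in enumerate(ensemble.model_ids)}
    ref_id = table.sort_values(["e_cs", "model_id"]).iloc[0]["model_id"]
    ref = by_model[ref_id]
    table["rmsd_to_ref"] = [
        superpose(by_model[mid], ref, selection).rmsd for mid in table["model_id"]
    ]

    shortlist = table.sort_values(["e_cs", "model_id"]).head(n_energy)
    chosen = shortlist.sort_values(["rmsd_to_ref", "e_cs", "model_id"]).head(n_final)
    return list(chosen["model_id"]), table[SCORE_COLUMNS]


def select_tail_model(chi2_by_candidate: Mapping[str, float]) -> str:
    """Lowest-chi2 tail model; ties break on the lowest model id."""
    if not chi2_by_candidate:
        raise SelectionError("no candidate models")
    return min(chi2_by_candidate.items(), key=lambda kv: (kv[1], kv[0]))[0]


class TableLookupPredictor:
    """Shift predictor that ignores coordinates and returns a fixed table.

    Stands in for a real predictor (e.g. an empirical shift model) in tests
    and worked examples; per-model tables may be supplied keyed by model id.
    """

    def __init__(self, table: pd.DataFrame | None = None,
                 by_model: Mapping[str, pd.DataFrame] | None = None):
        if (table is None) == (by_model is None):
            raise ValidationError("pass exactly one of table / by_model")
        self._table = table
        self._by_model = by_model

    def __call__(self, model: Model) -> pd.DataFrame:
        if self._table is not None:
            return self._table
        assert self._by_model is not None
        return self._by_model[model.model_id]
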