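"""Shared covariate preparation for playback-response models.

The same design matrix must underlie both the synthetic trial generator and
the fitted models, so the mapping from trial records + index matrices to
named covariate columns lives here.  Conventions:

* information covariates follow the plotting convention of the analysis:
  body-size ratio, acoustic similarity, caller abundance and caller
  consistency are affinely scaled to [0, 1] over the community's
  receiver x vocal-caller grid (a data-independent, community-level scaling,
  so generation and refitting agree exactly); call reliability is already a
  probability and is left on its natural [0, 1] scale;
* receiver body size is log10 body mass scaled to [0, 1] over the community;
* quadratic and interaction terms are built from the scaled columns;
* environmental covariates (grass height, proximity to cover, speaker
  distance, wind speed, group size) are z-standardised within the dataset;
* control trials carry zeros in every caller-information column plus a
  ``control`` indicator; conspecific trials carry a ``conspecific`` indicator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .indices import DerivedIndices, scale_unit_interval

INFO_TERMS = [
    "receiver_size",
    "size_ratio",
    "size_ratio_sq",
    "rbs_x_ratio",
    "rbs_x_ratio_sq",
    "consistency",
    "reliability",
    "similarity",
    "abundance",
]
ENV_TERMS = [
    "grass_height",
    "cover_proximity",
    "speaker_distance",
    "wind_speed",
    "group_size",
]
DESIGN_TERMS = INFO_TERMS + ENV_TERMS
INDICATORS = ["conspecific", "control"]

__all__ = ["INFO_TERMS", "ENV_TERMS", "DESIGN_TERMS", "INDICATORS",
           "build_playback_design"]


def _scaled_lookup(matrix: pd.DataFrame, vocal: list) -> pd.DataFrame:
    """Unit-interval scaling of a receiver x caller matrix over vocal callers."""
    sub = matrix.loc[:, vocal]
    return scale_unit_interval(sub)


def build_playback_design(
    trials: pd.DataFrame,
    indices: DerivedIndices,
    masses: pd.Series,
    standardize_env: bool = True,
) -> pd.DataFrame:
    """Build the named covariate matrix for a playback-trial table.

    ``trials`` needs columns ``receiver_species``, ``caller_species``
    (NaN/None for control), ``call_kind`` and the five environmental
    covariates.  Returns a DataFrame aligned with ``trials`` containing
    DESIGN_TERMS + INDICATORS columns.
    """
    if indices.similarity is None:
        raise ValueError("build_playback_design: indices.similarity is required "
                         "(compute it from the acoustic feature table first)")
    vocal = [c for c in indices.L.columns if c in indices.similarity.columns]
    L_s = _scaled_lookup(indices.L, vocal)
    S_s = scale_unit_interval(indices.similarity)
    ratio_s = _scaled_lookup(indices.size_ratio, vocal)
    abund_s = scale_unit_interval(indices.abundance.loc[vocal])
    rbs = scale_unit_interval(np.log10(masses))

    recv = trials["receiver_species"]
    call = trials["caller_species"]
    is_control = trials["call_kind"].eq("control")
    is_consp = trials["call_kind"].eq("conspecific")

    def lookup(mat, default=0.0):
        out = np.full(len(trials), default)
        ok = ~is_control.to_numpy()
        r = recv.to_numpy()[ok]
        c = call.to_numpy()[ok]
        out[ok] = mat.to_numpy()[
            mat.index.get_indexer(r), mat.columns.get_indexer(c)]
        return out

    X = pd.DataFrame(index=trials.index)
    X["receiver_size"] = rbs.loc[recv].to_numpy()
    X["size_ratio"] = lookup(ratio_s)
    X["size_ratio_sq"] = X["size_ratio"] ** 2
    X["rbs_x_ratio"] = X["receiver_size"] * X["size_ratio"]
    X["rbs_x_ratio_sq"] = X["receiver_size"] * X["size_ratio_sq"]
    X["consistency"] = lookup(L_s)
    X["reliability"] = lookup(indices.V.loc[:, vocal])
    X["similarity"] = lookup(S_s)
    caller_abund = np.zeros(len(trials))
    ok = ~is_control.to_numpy()
    caller_abund[ok] = abund_s.loc[call[~is_control]].to_numpy()
    X["abundance"] = caller_abund
    for col in ENV_TERMS:
        v = trials[col].astype(float)
        if standardize_env:
            sd = v.std(ddof=1)
            v = (v - v.mean()) / sd if sd > 0 else v - v.mean()
        X[col] = v.to_numpy()
    X["conspecific"] = is_consp.astype(float).to_numpy()
    X["control"] = is_control.astype(float).to_numpy()
    return X
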