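"""Acoustic feature standardisation and between-species call similarity.

Alarm calls are summarised by seven structural features measured per call:
duration (s), visibility of harmonics (score), number of distinct structural
components, presence of pulses (0/1), the 25% energy quartile (Hz), the
25–75% energy-quartile bandwidth (Hz) and the third dominant frequency DF3
(Hz).  (DF1/DF2 are excluded upstream for collinearity with DF3.)  Each
feature is standardised by its column maximum so all features weigh equally,
and similarity between two species is one minus the Euclidean distance
between their per-species mean feature vectors, with the distance divided by
sqrt(7) so similarity stays in [0, 1] on max-standardised features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

FEATURES = [
    "duration_s",
    "harmonics",
    "n_components",
    "pulses",
    "q25_hz",
    "bandwidth_hz",
    "df3_hz",
]

__all__ = ["FEATURES", "standardize_features", "species_centroid", "acoustic_similarity"]


def _check_table(table: pd.DataFrame) -> None:
    missing = [f for f in FEATURES if f not in table.columns]
    if missing:
        raise ValueError(f"acoustic table missing feature columns: {missing}")
    if "species" not in table.columns:
        raise ValueError("acoustic table missing 'species' column")
    if (table[FEATURES] < 0).any().any():
        raise ValueError("acoustic features must be nonnegative")


def standardize_features(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each feature column by its maximum (idempotent, scale-free).

    Raises if a feature column has no positive values, naming the feature.
    """
    _check_table(table)
    out = table.copy()
    for f in FEATURES:
        m = out[f].max()
        if not m > 0:
            raise ValueError(f"standardize_features: feature '{f}' has no positive values")
        out[f] = out[f] / m
    return out


def species_centroid(table: pd.DataFrame, species) -> pd.Series:
    """Per-feature mean over all calls of one species."""
    _check_table(table)
    sub = table[table["species"] == species]
    if len(sub) == 0:
        raise ValueError(f"species_centroid: no calls for species {species!r}")
    return sub[FEATURES].mean(axis=0)


def acoustic_similarity(
    table: pd.DataFrame,
    method: str = "centroid",
    scale: bool = True,
    standardize: bool = True,
) -> pd.DataFrame:
    """Between-species similarity matrix S = 1 - d / sqrt(k).

    ``method='centroid'`` (default) measures the Euclidean distance between
    per-species mean vectors of max-standardised features; ``method='pairwise'``
    averages the distance over all between-species call pairs instead.  With
    ``scale=True`` the distance is divided by sqrt(k) (k = 7 features), the
    diameter of the unit feature box, guaranteeing S in [0, 1]; the raw
    ``1 - d`` variant is available with ``scale=False`` and can go negative.

    The matrix is symmetric with diagonal exactly 1 under the centroid
    method (a species compared with itself has zero distance).
    """
    if method not in ("centroid", "pairwise"):
        raise ValueError(f"acoustic_similarity: unknown method {method!r}")
    tab = standardize_features(table) if standardize else table.copy()
    _check_table(tab)
    species = list(pd.unique(tab["species"]))
    k = len(FEATURES)
    denom = np.sqrt(k) if scale else 1.0
    if method == "centroid":
        cents = np.vstack([species_centroid(tab, s).to_numpy() for s in species])
        d = cdist(cents, cents)
    else:
        d = np.zeros((len(species), len(species)))
        groups = {s: tab.loc[tab["species"] == s, FEATURES].to_numpy() for s in species}
        for i, a in enumerate(species):
            for j, b in enumerate(species):
                d[i, j] = cdist(groups[a], groups[b]).mean()
    S = pd.DataFrame(1.0 - d / denom, index=species, columns=species)
    if method == "centroid":
        np.fill_diagonal(S.values, 1.0)
    S.index.name = "species"
    S.columns.name = "species"
    return S
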