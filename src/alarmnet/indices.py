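"""Information-content indices for heterospecific alarm communication.

The value of a heterospecific alarm caller to a receiver depends on how
consistently the caller vocalises when the *receiver's* predators are around
(few false negatives) and on how often a single call actually denotes a
predator the receiver is vulnerable to (few false positives).  This module
computes the index family that formalises this:

* vulnerability weights ``epsilon(i, x)`` in [0, 1], obtained from Jacobs
  selectivity indices of predator x for prey i;
* alarm propensities ``I(x, j)``: the probability that caller species j
  alarm-calls when exposed to predator x, estimated from predator-model
  presentation trials;
* call profiles ``C(x, j)``: the distribution of j's alarm calls across
  predators under equal-frequency presentation (columns sum to one);
* caller consistency ``L(i, j)``: encounter-rate and vulnerability weighted
  average of j's alarm propensities from receiver i's perspective;
* call reliability ``V(i, j)``: the epsilon-weighted composition of j's calls,
  i.e. the chance a random call from j concerns a predator of i;
* the Lovich–Gibbons body-size ratio used as a predator-overlap proxy.

Matrices are pandas DataFrames throughout: vulnerability is receivers x
predators, propensity/profile matrices are predators x callers, and the
derived L / V / size-ratio matrices are receivers x callers.  Missing cells
are NaN, never silently zero: a zero propensity means "never alarms", which
is informative, while NaN means "not measured".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "jacobs_transform",
    "body_size_ratio",
    "scale_unit_interval",
    "estimate_alarm_propensity",
    "estimate_call_profile",
    "caller_consistency",
    "call_reliability",
    "size_ratio_matrix",
    "DerivedIndices",
    "derive_indices",
    "write_long",
]


def jacobs_transform(D, transform: Callable | None = None):
    """Map a Jacobs selectivity index D in [-1, 1] to a vulnerability in [0, 1].

    The default is the affine map ``(D + 1) / 2`` — the unique affine
    candidate taking the admissible range onto the unit interval; values
    close to 1 indicate high vulnerability of the prey to that predator.
    A different monotone map can be plugged in via ``transform``.

    Accepts scalars, arrays, Series or DataFrames.
    """
    arr = np.asarray(D, dtype=float)
    if np.any(np.isnan(arr)):
        raise ValueError("jacobs_transform: NaN in Jacobs index input")
    if np.any(arr < -1.0) or np.any(arr > 1.0):
        raise ValueError("jacobs_transform: Jacobs index outside [-1, 1]")
    if transform is None:
        out = (arr + 1.0) / 2.0
    else:
        out = np.asarray(transform(arr), dtype=float)
        if np.any(out < 0.0) or np.any(out > 1.0):
            raise ValueError("jacobs_transform: custom transform left [0, 1]")
    if isinstance(D, pd.DataFrame):
        return pd.DataFrame(out, index=D.index, columns=D.columns)
    if isinstance(D, pd.Series):
        return pd.Series(out, index=D.index, name=D.name)
    if np.isscalar(D):
        return float(out)
    return out


def body_size_ratio(receiver_mass, caller_mass):
    """Lovich–Gibbons asymmetric size ratio between receiver and caller.

    receiver:caller mass ratio when the receiver is larger, and
    ``2 - caller:receiver`` when the receiver is smaller.  The two branches
    meet continuously at 1 for equal masses; the ratio exceeds 1 when the
    receiver is larger and can become strongly negative for much larger
    callers (e.g. a gazelle receiving from a giraffe).
    """
    r = np.asarray(receiver_mass, dtype=float)
    c = np.asarray(caller_mass, dtype=float)
    if np.any(r <= 0) or np.any(c <= 0):
        raise ValueError("body_size_ratio: masses must be positive")
    out = np.where(r >= c, r / c, 2.0 - c / r)
    if np.isscalar(receiver_mass) and np.isscalar(caller_mass):
        return float(out)
    return out


def scale_unit_interval(values):
    """Affinely rescale a vector so min -> 0 and max -> 1 (order preserving).

    NaNs are passed through.  Raises on a constant vector, for which the
    scaling is undefined.
    """
    if isinstance(values, pd.DataFrame):
        arr = values.to_numpy(dtype=float)
        lo, hi = np.nanmin(arr), np.nanmax(arr)
        if hi == lo:
            raise ValueError("scale_unit_interval: constant input, scaling undefined")
        return (values - lo) / (hi - lo)
    ser = isinstance(values, pd.Series)
    arr = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(arr), np.nanmax(arr)
    if hi == lo:
        raise ValueError("scale_unit_interval: constant input, scaling undefined")
    out = (arr - lo) / (hi - lo)
    if ser:
        return pd.Series(out, index=values.index, name=values.name)
    return out


def estimate_alarm_propensity(
    trials: pd.DataFrame,
    species: list | None = None,
    predators: list | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimate I(x, j) from predator-model presentation trials.

    ``trials`` needs columns ``focal_species``, ``model_kind``,
    ``predator_id`` and ``alarm_given``; only predator trials contribute.
    Returns ``(I, n)``: the predators x callers propensity matrix (alarms /
    trials per cell) and the matching trial-count matrix.  Cells with zero
    trials are NaN in I — flagged missing, never imputed.
    """
    if len(trials) == 0:
        raise ValueError("estimate_alarm_propensity: empty trial table")
    pred = trials[trials["model_kind"] == "predator"]
    if len(pred) == 0:
        raise ValueError("estimate_alarm_propensity: no predator trials")
    counts = pred.pivot_table(
        index="predator_id", columns="focal_species", values="alarm_given",
        aggfunc="size", fill_value=0,
    )
    alarms = pred.pivot_table(
        index="predator_id", columns="focal_species", values="alarm_given",
        aggfunc="sum", fill_value=0,
    )
    if predators is not None:
        counts = counts.reindex(index=predators, fill_value=0)
        alarms = alarms.reindex(index=predators, fill_value=0)
    if species is not None:
        counts = counts.reindex(columns=species, fill_value=0)
        alarms = alarms.reindex(columns=species, fill_value=0)
    n = counts.astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        I = alarms.astype(float) / counts.replace(0, np.nan)
    I.index.name = "predator"
    I.columns.name = "caller"
    return I, n


def estimate_call_profile(I: pd.DataFrame) -> pd.DataFrame:
    """Normalise per-predator alarm rates into call profiles C(x, j).

    C(x, j) is the proportion of j's alarm calls elicited by predator x
    under equal-frequency presentation of all predators.  Using rates rather
    than raw call counts corrects for unequal per-cell trial numbers; with
    exactly balanced trials the two coincide.  Callers whose rates sum to
    zero (never alarm, e.g. a non-vocal species) get an all-NaN column —
    their profile is undefined, not uniform or zero.
    """
    col_sums = I.sum(axis=0, skipna=True)
    C = I.divide(col_sums.where(col_sums > 0), axis=1)
    C.index.name = "predator"
    C.columns.name = "caller"
    return C


def caller_consistency(
    I: pd.DataFrame,
    epsilon: pd.DataFrame,
    A,
    normalized: bool = True,
) -> pd.DataFrame:
    """Caller consistency L(i, j): how dependably caller j flags i's predators.

    Each propensity I(x, j) is weighted by the relative encounter probability
    of predator x (abundance share ``a_x = A_x / sum(A)``) times the
    receiver's vulnerability ``epsilon(i, x)``, summed over predators.  With
    ``normalized=True`` (default) the sum is divided by ``sum_x epsilon(i, x)
    a_x`` so that a perfect informant — one that always calls, whatever the
    predator — scores exactly 1; the raw weighted sum is kept behind the
    flag for sensitivity analysis and induces the same within-receiver
    ranking of callers.

    Receivers whose weights sum to zero (vulnerable to nothing that occurs)
    have an undefined, NaN row.
    """
    A = pd.Series(A, index=I.index) if not isinstance(A, pd.Series) else A
    A = A.reindex(I.index)
    if (A < 0).any() or not A.sum() > 0:
        raise ValueError("caller_consistency: predator abundances must be "
                         "nonnegative with a positive sum")
    eps = epsilon.reindex(columns=I.index)
    a = A / A.sum()
    weights = eps.mul(a, axis=1)                     # receivers x predators
    num = weights.to_numpy() @ I.to_numpy()          # receivers x callers
    L = pd.DataFrame(num, index=epsilon.index, columns=I.columns)
    if normalized:
        den = weights.sum(axis=1)
        L = L.divide(den.where(den > 0), axis=0)
    L.index.name = "receiver"
    L.columns.name = "caller"
    return L


def call_reliability(C: pd.DataFrame, epsilon: pd.DataFrame) -> pd.DataFrame:
    """Call reliability V(i, j) = sum_x C(x, j) * epsilon(i, x).

    The epsilon-weighted composition of caller j's calls: high when j's calls
    mostly concern predators to which receiver i is vulnerable.  Lies in
    [0, 1] because C columns are probability vectors and epsilon is bounded
    by 1.  Columns of C that are undefined (NaN) yield NaN reliabilities.
    """
    sums = C.sum(axis=0, skipna=False)
    defined = sums.notna()
    if not np.allclose(sums[defined], 1.0, atol=1e-9):
        raise ValueError("call_reliability: defined C columns must sum to 1")
    eps = epsilon.reindex(columns=C.index)
    V = pd.DataFrame(
        eps.to_numpy() @ C.to_numpy(),
        index=epsilon.index, columns=C.columns,
    )
    V.index.name = "receiver"
    V.columns.name = "caller"
    return V


def size_ratio_matrix(masses: pd.Series) -> pd.DataFrame:
    """Receiver x caller matrix of Lovich–Gibbons size ratios."""
    r = masses.to_numpy(dtype=float)[:, None]
    c = masses.to_numpy(dtype=float)[None, :]
    out = pd.DataFrame(body_size_ratio(r, c), index=masses.index.copy(),
                       columns=masses.index.copy())
    out.index.name = "receiver"
    out.columns.name = "caller"
    return out


@dataclass
class DerivedIndices:
    """Bundle of receiver x caller index matrices used by the response models.

    ``L`` (consistency) and ``V`` (reliability) are in [0, 1]; ``size_ratio``
    is the Lovich–Gibbons ratio; ``abundance`` is the relative abundance of
    each caller; ``similarity`` (optional) is the acoustic-similarity matrix
    over vocal species.
    """

    L: pd.DataFrame
    V: pd.DataFrame
    size_ratio: pd.DataFrame
    abundance: pd.Series
    similarity: pd.DataFrame | None = None


def derive_indices(
    I: pd.DataFrame,
    epsilon: pd.DataFrame,
    predator_abundances,
    masses: pd.Series,
    herbivore_abundances: pd.Series,
    similarity: pd.DataFrame | None = None,
    normalized: bool = True,
) -> DerivedIndices:
    """Compute the full DerivedIndices bundle from its ingredients."""
    C = estimate_call_profile(I)
    return DerivedIndices(
        L=caller_consistency(I, epsilon, predator_abundances, normalized=normalized),
        V=call_reliability(C, epsilon),
        size_ratio=size_ratio_matrix(masses),
        abundance=herbivore_abundances / herbivore_abundances.sum(),
        similarity=similarity,
    )


def write_long(matrix: pd.DataFrame, path, value_name: str = "value") -> None:
    """Write a receiver x caller matrix as long-format CSV (receiver, caller, value)."""
    long = matrix.stack(future_stack=True).rename(value_name).reset_index()
    long.columns = ["receiver", "caller", value_name]
    long.to_csv(path, index=False)
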