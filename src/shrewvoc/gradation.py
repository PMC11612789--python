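"""Typicality coefficients and discrete/graded call-type assignment.

The typicality coefficient of a call is the largest minus the second-largest
of its cluster membership values: near 1 for calls prototypical of their
cluster, near 0 for graded/ambiguous calls.  Coefficients are split into
*typical* / *atypical* / *neither* categories by two thresholds, and the
final call-type labels combine the hard cluster with the voiced-percentage
boundary rules (discrete tonal calls: voiced >= 95 %; discrete noisy calls:
voiced = 0 %; graded calls in between).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "typicality_coefficients", "compute_thresholds", "categorize_typicality",
    "infer_cluster_roles", "assign_call_types", "TypicalityResult",
]

CLUSTER_ROLES = ("long_tonal", "noisy", "short_tonal")

TONAL_BOUNDARY = 95.0  # voiced % at and above which a call counts as purely tonal


@dataclass(frozen=True)
class TypicalityResult:
    call_id: str
    typicality_coefficient: float
    category: str
    thresholds_used: tuple[float, float]


def typicality_coefficients(U: np.ndarray) -> np.ndarray:
    """Largest minus second-largest membership value per row."""
    U = np.asarray(U, dtype=float)
    if U.ndim != 2 or U.shape[1] < 2:
        raise ValueError("membership matrix must be n x c with c >= 2")
    part = np.partition(U, U.shape[1] - 2, axis=1)
    return part[:, -1] - part[:, -2]


def compute_thresholds(coefficients: np.ndarray, method: str = "tercile",
                       fixed: tuple[float, float] | None = None
                       ) -> tuple[float, float]:
    """Atypicality and typicality thresholds over a coefficient sample.

    The default method takes the lower and upper terciles of the empirical
    coefficient distribution; ``method='fixed'`` returns the supplied pair
    verbatim.  Returns ``(tau_atypical, tau_typical)``.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    if method == "fixed":
        if fixed is None:
            raise ValueError("fixed method requires the threshold pair")
        lo, hi = float(fixed[0]), float(fixed[1])
        if not lo < hi:
            raise ValueError("atypicality threshold must be below typicality threshold")
        return lo, hi
    if method != "tercile":
        raise ValueError(f"unknown threshold method {method!r}")
    if len(coefficients) < 10:
        raise ValueError("need at least 10 coefficients for empirical thresholds")
    if np.ptp(coefficients) == 0.0:
        raise ValueError("degenerate coefficient distribution (all equal)")
    lo = float(np.quantile(coefficients, 1.0 / 3.0))
    hi = float(np.quantile(coefficients, 2.0 / 3.0))
    return lo, hi


def categorize_typicality(coefficients: np.ndarray,
                          thresholds: tuple[float, float]) -> np.ndarray:
    """Categorize each coefficient: strictly above the typicality threshold
    -> 'typical', strictly below the atypicality threshold -> 'atypical',
    boundary values and everything between -> 'neither'."""
    lo, hi = thresholds
    if not lo < hi:
        raise ValueError("thresholds must satisfy tau_atypical < tau_typical")
    c = np.asarray(coefficients, dtype=float)
    out = np.full(len(c), "neither", dtype=object)
    out[c > hi] = "typical"
    out[c < lo] = "atypical"
    return out


def infer_cluster_roles(per_call: pd.DataFrame,
                        label_col: str = "hard_label") -> dict[int, str]:
    """Identify cluster roles from per-cluster acoustics.

    The cluster with the lowest mean voiced percentage is the noisy
    (screech) cluster; of the remaining clusters the one with the shortest
    mean duration is the short-tonal (chirp) cluster; the rest is the
    long-tonal (scream) cluster.  Requires columns ``voiced_percentage``,
    ``duration`` and the hard-label column.
    """
    stats = per_call.groupby(label_col).agg(
        voiced=("voiced_percentage", "mean"), dur=("duration", "mean"))
    if len(stats) < 3:
        raise ValueError("cluster-role inference expects three clusters")
    roles: dict[int, str] = {}
    noisy = int(stats.voiced.idxmin())
    roles[noisy] = "noisy"
    rest = stats.drop(index=noisy)
    chirp = int(rest.dur.idxmin())
    roles[chirp] = "short_tonal"
    for idx in rest.drop(index=chirp).index:
        roles[int(idx)] = "long_tonal"
    return roles


def assign_call_types(hard_labels: np.ndarray, cluster_roles: dict[int, str],
                      voiced_percentages: np.ndarray,
                      tonal_boundary: float = TONAL_BOUNDARY) -> np.ndarray:
    """Final call-type labels from hard cluster and voiced percentage.

    * long-tonal cluster, voiced >= 95 % -> scream; below -> screech_scream
    * noisy cluster, voiced = 0 % -> screech; above 0 % -> screech_scream
    * short-tonal cluster -> chirp, at any voiced percentage
    """
    hard_labels = np.asarray(hard_labels)
    vp = np.asarray(voiced_percentages, dtype=float)
    if hard_labels.shape != vp.shape:
        raise ValueError("labels and voiced percentages differ in length")
    unknown = set(np.unique(hard_labels)) - set(cluster_roles)
    if unknown:
        raise ValueError(f"no role mapped for cluster index(es) {sorted(unknown)}")
    out = np.empty(len(hard_labels), dtype=object)
    for i, (lab, v) in enumerate(zip(hard_labels, vp)):
        role = cluster_roles[int(lab)]
        if role == "short_tonal":
            out[i] = "chirp"
        elif role == "long_tonal":
            out[i] = "scream" if v >= tonal_boundary else "screech_scream"
        elif role == "noisy":
            out[i] = "screech" if v == 0.0 else "screech_scream"
        else:
            raise ValueError(f"unknown cluster role {role!r}")
    return out
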