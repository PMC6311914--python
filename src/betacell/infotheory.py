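"""Discrete entropy and mutual information on floor-binned expression.

Expression values (on the log2(x+1) display scale by default) are discretized
by taking the elementwise floor, turning each gene into a discrete symbol
sequence over the cells. Entropies are plug-in (maximum-likelihood) estimates
of the empirical symbol frequencies with base-2 logarithms, so every quantity
is in bits, and mutual information is computed through the entropy identity

    I(X;Y) = H(X) + H(Y) - H(X,Y).

No bias correction is applied: with n cells and k observed symbols the
plug-in MI of independent variables is positive of order (k_x-1)(k_y-1)/(2n
ln 2); :func:`mi_permutation_null` provides the matching permutation null for
judging whether an observed MI is distinguishable from 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def discretize(values, scale: str | None = None) -> np.ndarray:
    """Floor-discretize per-cell values into integer symbols.

    ``scale`` is advisory metadata only (callers pass "log2" on the standard
    path); values must be finite. Floor semantics apply to negatives too:
    -0.5 -> -1.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot discretize an empty vector")
    if not np.isfinite(arr).all():
        raise ValueError("non-finite values cannot be discretized")
    return np.floor(arr).astype(np.int64)


def entropy(x) -> float:
    """Plug-in entropy in bits of a discrete symbol vector (0*log 0 = 0)."""
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError("entropy of an empty vector is undefined")
    _, counts = np.unique(x, return_counts=True)
    p = counts / x.size
    return float(-(p * np.log2(p)).sum())


def joint_entropy(x, y) -> float:
    """Plug-in joint entropy H(X,Y) in bits of two paired symbol vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    pairs = np.stack([x, y])
    _, counts = np.unique(pairs, axis=1, return_counts=True)
    p = counts / x.size
    return float(-(p * np.log2(p)).sum())


@dataclass
class MIResult:
    """Entropies and mutual information (bits) of one variable pair."""

    h_x: float
    h_y: float
    h_xy: float
    mi: float
    p_x: dict
    p_y: dict
    p_xy: dict

    def as_row(self) -> dict:
        return {"entropy_x": self.h_x, "entropy_y": self.h_y,
                "joint_entropy": self.h_xy, "mutual_information": self.mi}


def mutual_information(x, y) -> MIResult:
    """I(X;Y) = H(X) + H(Y) - H(X,Y) on paired discrete symbol vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("mutual information needs at least 2 paired samples")
    h_x = entropy(x)
    h_y = entropy(y)
    h_xy = joint_entropy(x, y)
    n = x.size
    sym_x, cnt_x = np.unique(x, return_counts=True)
    sym_y, cnt_y = np.unique(y, return_counts=True)
    pairs, cnt_xy = np.unique(np.stack([x, y]), axis=1, return_counts=True)
    return MIResult(
        h_x=h_x, h_y=h_y, h_xy=h_xy, mi=h_x + h_y - h_xy,
        p_x={int(s): c / n for s, c in zip(sym_x, cnt_x)},
        p_y={int(s): c / n for s, c in zip(sym_y, cnt_y)},
        p_xy={(int(a), int(b)): c / n
              for a, b, c in zip(pairs[0], pairs[1], cnt_xy)},
    )


def mi_attribution(target, factors: dict, discretized: bool = False) -> pd.DataFrame:
    """Rank candidate factors by their mutual information with a target.

    Parameters
    ----------
    target
        Per-cell values of the response (INS log2 expression on the standard
        path), or an already-discretized symbol vector if ``discretized``.
    factors
        Mapping of factor name -> per-cell values over the same cells
        (typically the oxidative / ER / caspase representative genes).

    Returns a DataFrame with one row per factor, columns entropy_x (target),
    entropy_y, joint_entropy, mutual_information and rank (1 = largest MI),
    sorted by MI descending.
    """
    t = np.asarray(target) if discretized else discretize(target)
    rows = []
    for name, values in factors.items():
        v = np.asarray(values) if discretized else discretize(values)
        res = mutual_information(t, v)
        rows.append({"factor": name, **res.as_row()})
    table = pd.DataFrame(rows).sort_values(
        "mutual_information", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def mi_permutation_null(x, y, n_permutations: int = 200,
                        rng: np.random.Generator | int | None = None) -> np.ndarray:
    """MI values of ``x`` against permutations of ``y``.

    The returned distribution is the plug-in MI under the null of
    independence at the observed marginals; use its quantiles to judge
    whether an observed MI is 'near zero'.
    """
    rng = np.random.default_rng(rng)
    x = np.asarray(x)
    y = np.asarray(y)
    out = np.empty(n_permutations)
    for i in range(n_permutations):
        out[i] = mutual_information(x, rng.permutation(y)).mi
    return out
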