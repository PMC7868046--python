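"""Indicator-augmented design terms shared by the simulator and MIMI fits.

Term layout (after the ``p`` predictor main effects), for ``p``
predictors:

* indicator main effects        ``m1..mp``                     (p terms)
* own interactions              ``xj:mj``                      (p terms)
* cross interactions            ``xj:mk`` for j != k,          (p(p-1))
  ordered j-major: x1:m2, x1:m3, ..., x2:m1, ...

For p = 2 this reproduces, in order, the canonical two-covariate
missing-indicator mean model
``b0 + b1*x1 + b2*x2 + d1*m1 + d2*m2 + d3*x1m1 + d4*x2m2 + d5*x1m2 + d6*x2m1``
(note the own interactions come as x1:m1 then x2:m2, i.e. d3 then d4).
"""

from __future__ import annotations

import numpy as np

SCOPES = ("full", "own", "none")


def n_delta_terms(p: int, scope: str = "full") -> int:
    if scope == "none":
        return 0
    if scope == "own":
        return 2 * p
    return p * (p + 1)


def term_names(columns: list[str], scope: str = "full") -> list[str]:
    """Names of the non-intercept terms, X mains first then delta terms."""
    p = len(columns)
    names = list(columns)
    if scope == "none":
        return names
    names += [f"m{j + 1}" for j in range(p)]
    names += [f"{columns[j]}:m{j + 1}" for j in range(p)]
    if scope == "full":
        for j in range(p):
            for k in range(p):
                if k != j:
                    names.append(f"{columns[j]}:m{k + 1}")
    return names


def term_matrix(X: np.ndarray, M: np.ndarray, scope: str = "full") -> np.ndarray:
    """Non-intercept design columns [X | M | own XM | cross XM] for `scope`."""
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    if X.shape != M.shape:
        raise ValueError("X and M must have identical shapes")
    if scope == "none":
        return X.copy()
    p = X.shape[1]
    cols = [X, M, X * M]
    if scope == "full":
        cross = [X[:, [j]] * M[:, [k]] for j in range(p) for k in range(p) if k != j]
        if cross:
            cols.append(np.hstack(cross))
    return np.hstack(cols)
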