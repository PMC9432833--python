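"""State-spliced correlation networks and signed weighted clustering.

Traces are spliced to the frames of one behavior state, correlated pairwise
(Pearson), and the resulting signed matrix is split into positive and
negative parts.  Each part gets a weighted clustering coefficient per node
(Zhang-Horvath form on cube-rooted weights by default, Onnela as an
alternative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MIN_SPLICE_FRAMES = 3


def splice_by_state(C: np.ndarray, b_state: np.ndarray) -> np.ndarray:
    """Columns of C where the state vector is 1, concatenated in time order.

    An empty state errors; fewer than :data:`MIN_SPLICE_FRAMES` frames is
    allowed here but rejected by :func:`correlation_network`.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    b = np.asarray(b_state)
    if C.shape[1] != b.size:
        raise ValueError("state vector length must equal frame count")
    keep = b == 1
    if not keep.any():
        raise ValueError("state has no frames")
    return C[:, keep]


def correlation_network(spliced: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Pearson correlation matrix with unit diagonal.

    Returns (W, flagged) where ``flagged`` marks zero-variance neurons whose
    rows/columns are NaN (the diagonal stays 1).
    """
    X = np.atleast_2d(np.asarray(spliced, dtype=float))
    if X.shape[1] < MIN_SPLICE_FRAMES:
        raise ValueError("need at least 3 frames")
    sd = X.std(axis=1)
    flagged = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.corrcoef(X)
    W = np.atleast_2d(W)
    W[flagged, :] = np.nan
    W[:, flagged] = np.nan
    np.fill_diagonal(W, 1.0)
    return W, flagged


@dataclass
class SignedClustering:
    c_pos: np.ndarray
    c_neg: np.ndarray
    mean_pos: float
    mean_neg: float
    method: str
    isolated: np.ndarray  # nodes whose denominator vanished (coefficient 0)


def _zhang_horvath(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted clustering on a nonnegative zero-diagonal weight matrix.

    C_u = sum_{v,w} a_uv a_vw a_wu / [ (sum_v a_uv)^2 - sum_v a_uv^2 ].
    """
    num = np.einsum("uv,vw,wu->u", a, a, a)
    s1 = a.sum(axis=1)
    s2 = (a * a).sum(axis=1)
    den = s1 * s1 - s2
    isolated = den <= 0
    c = np.zeros(a.shape[0])
    np.divide(num, den, out=c, where=~isolated)
    return c, isolated


def _onnela(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Onnela et al. weighted clustering: geometric-mean triangle intensity."""
    amax = a.max()
    ahat = np.cbrt(a / amax) if amax > 0 else a.copy()
    num = np.einsum("uv,vw,wu->u", ahat, ahat, ahat)
    k = (a > 0).sum(axis=1)
    den = k * (k - 1)
    isolated = den <= 0
    c = np.zeros(a.shape[0])
    np.divide(num, den.astype(float), out=c, where=~isolated)
    return c, isolated


def signed_clustering(W: np.ndarray, method: str = "zhang") -> SignedClustering:
    """Positive/negative clustering coefficients of a signed network.

    The correlation matrix is split into W+ = max(W, 0) and W- = max(-W, 0)
    with zeroed diagonals; with the default ``zhang`` method the
    Zhang-Horvath formula is applied to the cube-rooted weights of each
    part, which reduces to the unweighted clustering coefficient on binary
    graphs.  NaN entries (flagged neurons) are treated as absent edges.
    Nodes with a vanishing denominator get coefficient 0 and are flagged.
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    Wc = np.nan_to_num(W, nan=0.0)
    if not np.allclose(Wc, Wc.T, atol=1e-12):
        raise ValueError("W must be symmetric")
    pos = np.clip(Wc, 0.0, None)
    neg = np.clip(-Wc, 0.0, None)
    np.fill_diagonal(pos, 0.0)
    np.fill_diagonal(neg, 0.0)
    if method == "zhang":
        c_pos, iso_p = _zhang_horvath(np.cbrt(pos))
        c_neg, iso_n = _zhang_horvath(np.cbrt(neg))
    elif method == "onnela":
        c_pos, iso_p = _onnela(pos)
        c_neg, iso_n = _onnela(neg)
    else:
        raise ValueError(f"unknown method {method!r}")
    return SignedClustering(
        c_pos=c_pos, c_neg=c_neg,
        mean_pos=float(c_pos.mean()) if c_pos.size else float("nan"),
        mean_neg=float(c_neg.mean()) if c_neg.size else float("nan"),
        method=method, isolated=iso_p | iso_n,
    )
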