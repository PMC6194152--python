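"""Robust correlation for co-expression networks.

The biweight midcorrelation (bicor) is a median/MAD-based correlation: each
vector is median-centred, downweighted by Tukey's biweight as a function of
the deviation in 9-MAD units, and the correlation of the weighted vectors is
returned.  Observations further than 9 MADs from the median get zero weight,
which makes bicor robust to single outlying samples while staying close to
Pearson on clean data.

A vector whose MAD is zero (more than half its values tied) has no robust
scale; for such rows the implementation falls back to the Pearson
standardisation, logged once per call.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import InputError

logger = logging.getLogger(__name__)


def _bicor_transform(X: np.ndarray) -> np.ndarray:
    """Row-wise biweight transform, unit-normalised.

    Returns a matrix W such that ``W @ W.T`` is the bicor matrix of the rows
    of X.  Rows with MAD = 0 are Pearson-standardised instead.
    """
    X = np.asarray(X, dtype=float)
    med = np.median(X, axis=1, keepdims=True)
    dev = X - med
    mad = np.median(np.abs(dev), axis=1, keepdims=True)
    zero_mad = (mad == 0).ravel()

    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        u = dev / (9.0 * mad)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    out = dev * w

    if zero_mad.any():
        logger.warning(
            "MAD = 0 for %d row(s); falling back to Pearson for them", zero_mad.sum()
        )
        mean = X[zero_mad].mean(axis=1, keepdims=True)
        out[zero_mad] = X[zero_mad] - mean

    norm = np.sqrt((out**2).sum(axis=1, keepdims=True))
    constant = (norm == 0).ravel()
    if constant.any():
        # constant rows have no correlation; leave them at 0 (correlations NaN-free)
        norm[constant] = 1.0
    return out / norm


def bicor(x, y) -> float:
    """Biweight midcorrelation of two equal-length sample vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("bicor expects two equal-length 1-D vectors")
    if x.size < 3:
        raise InputError("bicor needs at least 3 observations")
    W = _bicor_transform(np.vstack([x, y]))
    return float(np.clip(W[0] @ W[1], -1.0, 1.0))


def bicor_matrix(X, Y=None) -> np.ndarray:
    """Pairwise bicor between rows of X (and rows of Y, if given).

    Parameters
    ----------
    X : array-like, shape (g, n)
        Rows are genes, columns samples.
    Y : array-like, shape (h, n), optional
        If given, returns the (g, h) cross-correlation block.
    """
    WX = _bicor_transform(X)
    WY = WX if Y is None else _bicor_transform(Y)
    R = WX @ WY.T
    np.clip(R, -1.0, 1.0, out=R)
    if Y is None:
        np.fill_diagonal(R, 1.0)
    return R


def pearson_matrix(X, Y=None) -> np.ndarray:
    """Pairwise Pearson correlation between rows (cross-block if Y given)."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    nx = np.sqrt((Xc**2).sum(axis=1, keepdims=True))
    nx[nx == 0] = 1.0
    Xc /= nx
    if Y is None:
        Yc = Xc
    else:
        Y = np.asarray(Y, dtype=float)
        Yc = Y - Y.mean(axis=1, keepdims=True)
        ny = np.sqrt((Yc**2).sum(axis=1, keepdims=True))
        ny[ny == 0] = 1.0
        Yc /= ny
    R = Xc @ Yc.T
    np.clip(R, -1.0, 1.0, out=R)
    if Y is None:
        np.fill_diagonal(R, 1.0)
    return R


_KINDS = {"bicor": bicor_matrix, "pearson": pearson_matrix}


def correlation_matrix(X, kind: str = "bicor", Y=None) -> np.ndarray:
    """Dispatch on correlation kind ('bicor' or 'pearson')."""
    try:
        fn = _KINDS[kind]
    except KeyError:
        raise InputError(
            f"unknown correlation kind {kind!r}; use 'bicor' or 'pearson'"
        ) from None
    return fn(X, Y)
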