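"""Foci dose-response analysis.

Nuclear RelA foci counted per cell across an anti-IgM titration are the
imaging readout of NF-κB condensation.  This module computes per-dose
median responses, fits them to the four-parameter Hill model (see
:mod:`sehet.hill`), and predicts per-dose cell-activation fractions from
foci counts via a two-component Poisson mixture plus logistic
regression.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import poisson
from sklearn.linear_model import LogisticRegression

from .hill import HillFit, fit_hill  # noqa: F401  (re-exported fit entry point)

__all__ = ["median_response", "fit_hill", "activation_from_foci",
           "poisson_mixture_em"]


def _at_time(table: pd.DataFrame, time: float) -> pd.DataFrame:
    sub = table[table["time_min"] == time]
    if sub.empty:
        raise ValueError(f"no foci measurements at time {time} min")
    return sub


def median_response(table: pd.DataFrame, time: float = 20) -> dict[float, float]:
    """Per-dose median foci count at the requested time point.

    Even-sized groups take the mean of the two central order statistics.
    """
    sub = _at_time(table, time)
    doses = sorted(table["dose"].unique())
    if len(doses) < 2:
        raise ValueError("need at least 2 distinct doses")
    out = {}
    for d in doses:
        vals = sub.loc[sub["dose"] == d, "foci"].to_numpy()
        if vals.size == 0:
            raise ValueError(f"empty dose group at dose {d}")
        out[float(d)] = float(np.median(vals))
    return out


def poisson_mixture_em(
    counts: np.ndarray, max_iter: int = 500, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Two-component Poisson mixture via EM.

    Returns (lambdas ascending, responsibilities of the high component).
    """
    x = np.asarray(counts, dtype=float)
    lo, hi = np.quantile(x, [0.25, 0.75])
    lam = np.array([max(lo, 0.1), max(hi, lo + 1.0)])
    w = np.array([0.5, 0.5])
    ll_old = -np.inf
    for _ in range(max_iter):
        with np.errstate(divide="ignore"):
            logp = np.log(w) + poisson.logpmf(x[:, None], lam[None, :])
        m = logp.max(axis=1, keepdims=True)
        post = np.exp(logp - m)
        post /= post.sum(axis=1, keepdims=True)
        ll = float((m.ravel() + np.log(np.exp(logp - m).sum(axis=1))).sum())
        w = post.mean(axis=0)
        lam = (post * x[:, None]).sum(axis=0) / np.maximum(post.sum(axis=0), 1e-12)
        lam = np.maximum(lam, 1e-6)
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            break
        ll_old = ll
    order = np.argsort(lam)
    return lam[order], post[:, order][:, 1]


def activation_from_foci(table: pd.DataFrame, time: float = 20) -> pd.Series:
    """Predicted activated-cell fraction per dose from foci counts.

    Binary activation labels come from a two-component Poisson mixture
    over the pooled foci counts (posterior > 0.5 for the high-mean
    component); a logistic regression of label on foci count then yields
    per-cell activation probabilities, averaged per dose.  If the mixture
    components fail to separate (means within 0.5 counts) a fallback
    threshold at the overall median is used with a warning.
    """
    sub = _at_time(table, time)
    doses = sorted(sub["dose"].unique())
    top = doses[-1]
    for d in (0.0, top):
        if sub[sub["dose"] == d].empty:
            raise ValueError(f"no cells at reference dose {d}")
    counts = sub["foci"].to_numpy()
    lam, resp = poisson_mixture_em(counts)
    if lam[1] - lam[0] < 0.5:
        warnings.warn(
            "Poisson mixture failed to separate; falling back to a "
            "median-threshold labeling", stacklevel=2)
        labels = (counts > np.median(counts)).astype(int)
    else:
        labels = (resp > 0.5).astype(int)
    if labels.min() == labels.max():
        # degenerate labeling: constant fraction everywhere
        frac = float(labels.mean())
        return pd.Series({d: frac for d in doses}, name="activated_fraction")
    lr = LogisticRegression(C=1e3)
    lr.fit(counts.reshape(-1, 1), labels)
    prob = lr.predict_proba(counts.reshape(-1, 1))[:, 1]
    out = {}
    for d in doses:
        mask = (sub["dose"] == d).to_numpy()
        out[float(d)] = float(prob[mask].mean())
    return pd.Series(out, name="activated_fraction")
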