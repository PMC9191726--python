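"""Switch-likeness of gene dose-responses.

Per-gene fold-changes vs dose 0 (from
:func:`sehet.expression.dose_fold_changes`) are fitted with the
basal-free Hill model k*d^N/(Km^N + d^N).  The basal level is absorbed
by the fold-change floor of 1 at dose 0, so the fit is applied to the
response above baseline (FC - 1); only genes whose top-dose response
exceeds ``min_response`` are fitted.  Fitted coefficients are binned
into high / med / low switch-likeness, with implausible fits (N > 9 or
N < 0.3, over-fitted or non-fitting) excluded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hill import FitError, HillFit, categorize_hill, fit_hill

__all__ = ["fit_gene_hill", "categorize_hill", "fit_gene_panel"]


def fit_gene_hill(
    fold_changes: pd.Series | dict,
    min_response: float = 0.2,
    fit_above_baseline: bool = True,
) -> HillFit:
    """Basal-free Hill fit of a single gene's dose -> fold-change vector.

    Parameters
    ----------
    fold_changes
        Mapping of dose to mean-expression fold-change vs dose 0
        (so the value at dose 0 is 1).
    min_response
        Genes with (top-dose FC - 1) <= min_response are rejected as
        non-responsive (FitError).
    fit_above_baseline
        Fit FC - 1 rather than raw FC (default); set False to fit the
        raw ratio.
    """
    fc = dict(fold_changes)
    doses = sorted(fc)
    if len(doses) < 4:
        raise FitError("need fold-changes over at least 4 doses")
    top = doses[-1]
    if fc[top] - 1.0 <= min_response:
        raise FitError(
            f"top-dose response {fc[top] - 1.0:.3g} below threshold "
            f"{min_response}: gene not fitted")
    y = {d: (fc[d] - 1.0 if fit_above_baseline else fc[d]) for d in doses}
    if all(abs(v - list(y.values())[0]) < 1e-12 for v in y.values()):
        raise FitError("flat response: Hill coefficient unidentifiable")
    fit = fit_hill(y, with_basal=False)
    fit.category = categorize_hill(fit)
    return fit


def fit_gene_panel(
    fold_changes: pd.DataFrame,
    min_response: float = 0.2,
) -> pd.DataFrame:
    """Fit every gene in a gene x dose fold-change table.

    Returns a table of gene, N, Km, k, rss, category; genes failing the
    response filter or degenerate fits get category 'not_fitted'.
    """
    rows = []
    for gene, fc in fold_changes.iterrows():
        try:
            fit = fit_gene_hill(fc.to_dict(), min_response=min_response)
            rows.append({"gene": gene, "N": fit.N, "Km": fit.Km, "k": fit.k,
                         "rss": fit.rss, "category": fit.category})
        except FitError:
            rows.append({"gene": gene, "N": np.nan, "Km": np.nan,
                         "k": np.nan, "rss": np.nan, "category": "not_fitted"})
    return pd.DataFrame(rows).set_index("gene")
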