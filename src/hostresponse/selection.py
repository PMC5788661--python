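"""Information criteria, likelihood-ratio tests and model ranking.

AIC = -2 l(theta_hat, sigma_hat) + 2 P and
BIC = -2 l(theta_hat, sigma_hat) + P log(N_tot), with P counting the
estimated parameters including the residual standard deviation sigma.
Lower values indicate the preferable model. Nested models are compared with
the deviance D = 2 (l_alt - l_null) referenced to a chi-square distribution
with P_alt - P_null degrees of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .inference import FitResult
from .types import ValidationError

#: Deviances more negative than this trigger an optimization-failure warning
#: in the likelihood-ratio test (a richer nested model can never truly fit
#: worse than its null).
_LRT_TOL = 1e-6


def aic(loglik: float, n_params: int) -> float:
    """Akaike information criterion; ``n_params`` includes sigma."""
    if n_params < 0:
        raise ValidationError("n_params must be >= 0")
    return -2.0 * loglik + 2.0 * n_params


def bic(loglik: float, n_params: int, n_tot: int) -> float:
    """Bayesian information criterion on ``n_tot`` pooled observations."""
    if n_params < 0:
        raise ValidationError("n_params must be >= 0")
    if n_tot < 1:
        raise ValidationError("n_tot must be >= 1 for BIC")
    return -2.0 * loglik + n_params * math.log(n_tot)


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of a null model against a richer nested model."""

    d_stat: float
    df: int
    p_value: float
    null_label: str
    alt_label: str

    def to_dict(self) -> dict:
        return {"D": self.d_stat, "df": self.df, "p_value": self.p_value,
                "null": self.null_label, "alt": self.alt_label}


def likelihood_ratio_test(null_fit: FitResult, alt_fit: FitResult) -> LRTResult:
    """Test whether the richer model improves the fit significantly.

    Nesting (the null being a sub-model of the alternative) is the caller's
    responsibility — it is encoded in the tie structure of the model
    variants. A materially negative deviance indicates the richer model was
    under-optimized and is clamped to 0 with a warning.
    """
    df = alt_fit.n_params - null_fit.n_params
    if df < 1:
        raise ValidationError(
            f"alternative must have more parameters than the null "
            f"({alt_fit.model_label}: {alt_fit.n_params} vs "
            f"{null_fit.model_label}: {null_fit.n_params})")
    d = 2.0 * (alt_fit.loglik - null_fit.loglik)
    if d < -_LRT_TOL * max(1.0, abs(null_fit.loglik)):
        warnings.warn(
            f"richer model {alt_fit.model_label!r} has lower likelihood than "
            f"{null_fit.model_label!r} (D = {d:.4g}); optimization likely "
            "failed on the richer model", stacklevel=2)
    d = max(d, 0.0)
    p = float(stats.chi2.sf(d, df))
    return LRTResult(d_stat=d, df=df, p_value=p,
                     null_label=null_fit.model_label,
                     alt_label=alt_fit.model_label)


@dataclass
class SelectionTable:
    """Per-model goodness-of-fit criteria, ranked by AIC (ascending).

    Ties in AIC are broken by input position and flagged in the ``tied``
    column.
    """

    table: pd.DataFrame
    n_tot: int

    def to_dataframe(self) -> pd.DataFrame:
        return self.table.copy()

    @property
    def best(self) -> str:
        return str(self.table.iloc[0]["model"])

    def __len__(self) -> int:
        return len(self.table)


def rank_models(fits: list[FitResult], n_tot: int | None = None) -> SelectionTable:
    """Rank fitted models by AIC, reporting BIC alongside.

    All fits must come from the same dataset (identical ``n_tot``); the
    result is invariant to the input order up to tie-breaking.
    """
    if not fits:
        raise ValidationError("need at least one fit to rank")
    ns = {f.n_tot for f in fits}
    if len(ns) > 1:
        raise ValidationError(f"fits disagree on N_tot: {sorted(ns)}")
    n = n_tot if n_tot is not None else fits[0].n_tot
    if n_tot is not None and ns != {n_tot}:
        raise ValidationError(f"fits report N_tot={ns.pop()}, caller said {n_tot}")

    rows = []
    for f in fits:
        rows.append({"model": f.model_label, "loglik": f.loglik,
                     "aic": aic(f.loglik, f.n_params),
                     "bic": bic(f.loglik, f.n_params, n),
                     "n_params": f.n_params})
    df = pd.DataFrame(rows)
    order = np.argsort(df["aic"].to_numpy(), kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    a = df["aic"].to_numpy()
    tied = np.zeros(len(df), bool)
    for i in range(len(df) - 1):
        if math.isclose(a[i], a[i + 1], rel_tol=0.0, abs_tol=1e-12):
            tied[i] = tied[i + 1] = True
    df["tied"] = tied
    return SelectionTable(table=df, n_tot=n)
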