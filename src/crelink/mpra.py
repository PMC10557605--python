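"""Allelic reporter-assay (MPRA) statistics.

Per variant, activity ratios (RNA TPM / DNA TPM) are modeled as
Ratio = Allele + Strand + Batch by ordinary least squares; the allele effect
is tested with a Wald test under a heteroskedasticity-consistent ("sandwich")
covariance (HC0 by default, HC1-HC3 available), and p-values across variants
are corrected by the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests


class IdentifiabilityError(ValueError):
    """The design matrix is rank deficient (e.g. allele confounded with batch)."""


@dataclass
class AllelicFit:
    variant: str
    beta: float  # alt-vs-ref allele coefficient
    se: float  # sandwich standard error
    p_value: float  # two-sided Wald


def fit_allelic_activity(records: pd.DataFrame, cov_type: str = "HC0") -> AllelicFit:
    """OLS of ratio on allele + strand + batch with sandwich-variance Wald test."""
    alleles = set(records["allele"])
    if not {"ref", "alt"} <= alleles:
        raise ValueError("both ref and alt alleles are required")
    y = records["ratio"].to_numpy(dtype=float)
    X_parts = [pd.Series((records["allele"] == "alt").astype(float), name="allele_alt")]
    for col in ("strand", "batch"):
        if records[col].nunique() > 1:
            X_parts.append(pd.get_dummies(records[col], prefix=col, drop_first=True, dtype=float))
    X = pd.concat(X_parts, axis=1)
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise IdentifiabilityError("rank-deficient design: allele confounded with a nuisance term")
    res = sm.OLS(y, X).fit(cov_type=cov_type, use_t=False)
    variant = str(records["variant"].iloc[0]) if "variant" in records else ""
    return AllelicFit(
        variant=variant,
        beta=float(res.params["allele_alt"]),
        se=float(res.bse["allele_alt"]),
        p_value=float(res.pvalues["allele_alt"]),
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg FDR values (step-up)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_variants(table: pd.DataFrame, cov_type: str = "HC0") -> pd.DataFrame:
    """Fit every variant in a tidy MPRA table and BH-adjust across variants."""
    fits = [fit_allelic_activity(grp, cov_type=cov_type) for _, grp in table.groupby("variant")]
    out = pd.DataFrame(
        {
            "variant": [f.variant for f in fits],
            "beta": [f.beta for f in fits],
            "se": [f.se for f in fits],
            "p": [f.p_value for f in fits],
        }
    )
    out["fdr"] = bh_adjust(out["p"])
    return out
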