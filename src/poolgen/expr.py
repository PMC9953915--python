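"""qPCR expression statistics.

Relative quantification by the 2^-ddCt method (target Ct normalized to a
reference gene, then to a calibrator sample) and Pearson correlation with
the exact t-based two-tailed p-value, as used for expression time courses
across cell-differentiation stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t_stat: float
    df: int
    p: float


def ddct(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    calibrator: str,
    sample_col: str = "sample",
    gene_col: str = "gene",
    ct_col: str = "ct",
) -> pd.DataFrame:
    """Relative expression of ``target`` vs ``reference``, calibrated to one sample.

    Technical replicates are averaged (arithmetic mean of Ct) before
    differencing. Returns one row per sample with ``delta_ct``
    (Ct_target - Ct_reference), ``delta_delta_ct`` (relative to the
    calibrator sample) and ``rq`` = 2^-ddCt; the calibrator's RQ is exactly 1.
    """
    mean_ct = ct.groupby([sample_col, gene_col])[ct_col].mean().unstack(gene_col)
    for gene in (target, reference):
        if gene not in mean_ct.columns:
            raise ValueError(f"gene {gene!r} absent from the Ct table")
    missing_ref = mean_ct.index[mean_ct[reference].isna()].tolist()
    if missing_ref:
        raise ValueError(f"reference gene {reference!r} missing in samples: {missing_ref}")
    if calibrator not in mean_ct.index:
        raise ValueError(f"calibrator sample {calibrator!r} absent from the Ct table")
    delta = mean_ct[target] - mean_ct[reference]
    ddelta = delta - delta.loc[calibrator]
    out = pd.DataFrame(
        {
            "delta_ct": delta,
            "delta_delta_ct": ddelta,
            "rq": np.power(2.0, -ddelta),
        }
    )
    out.index.name = sample_col
    return out.reset_index()


def pearson_with_p(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with the exact two-tailed p-value.

    p comes from t = r sqrt(n-2) / sqrt(1-r^2) on n-2 degrees of freedom,
    the classical test of zero correlation under bivariate normality.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: an input has zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    return _result_from_r(r, n)


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-tailed p-value implied by a printed correlation coefficient and n."""
    return _result_from_r(r, n).p


def _result_from_r(r: float, n: int) -> CorrelationResult:
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must be in [-1, 1]")
    if n < 3:
        raise ValueError("need n >= 3 for a p-value")
    df = n - 2
    if abs(r) == 1.0:
        return CorrelationResult(r=r, n=n, t_stat=float("inf"), df=df, p=0.0)
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return CorrelationResult(r=r, n=n, t_stat=float(t), df=df, p=p)
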