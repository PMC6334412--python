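"""Two-library differential expression of miRNA counts.

Counts are normalized to transcripts per million (TPM) of each library's
clean reads.  Fold changes are log2 ratios of TPM with a floor of 0.01
applied before the ratio, so a miRNA absent from one library still yields a
finite, reportable fold change.  Significance comes from the Audic-Claverie
exact test — the conditional distribution of one library's count given the
other under a Poisson model,

    P(y | x) = (N2/N1)^y (x+y)! / (x! y! (1 + N2/N1)^(x+y)),

a negative binomial with x+1 successes and success probability N1/(N1+N2).
The reported p-value is two-sided (doubled smaller inclusive tail, capped at
one) and symmetrized by averaging the two conditioning directions, so
swapping the libraries swaps nothing.  With pooled libraries (n = 1 each)
this is the appropriate exact count test; no replicate dispersion is
modelled and no multiple-testing correction is applied by default (an
optional Benjamini-Hochberg flag exists but is off, matching single-tag
reporting practice for this design).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "tpm", "log2_fold", "two_library_test", "classify", "ddct",
    "build_expression_table",
]

DEFAULT_FLOOR = 0.01
DEFAULT_ALPHA = 0.05
DEFAULT_LFC = 1.0


def tpm(count: int, total: int) -> float:
    """Transcripts per million: count / library_total * 1e6 (unrounded)."""
    if total <= 0:
        raise ValueError("library total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / total * 1e6


def log2_fold(tpm_a: float, tpm_b: float, floor: float = DEFAULT_FLOOR) -> float:
    """log2(max(tpm_a, floor) / max(tpm_b, floor)).

    The floor makes condition-specific expression (zero in one library)
    finite; 0.01 reproduces the reporting convention for a miRNA present at
    1.51 TPM in one library and absent in the other -> log2(151) = 7.24.
    """
    if tpm_a < 0 or tpm_b < 0:
        raise ValueError("TPM values must be non-negative")
    return float(np.log2(max(tpm_a, floor) / max(tpm_b, floor)))


def _directional_p(x: int, y: int, n1: float, n2: float) -> float:
    """Doubled smaller inclusive tail of P(y|x); one conditioning direction."""
    # Y | x ~ NegBin(x+1 successes, p = N1/(N1+N2))
    p = n1 / (n1 + n2)
    lo = stats.nbinom.cdf(y, x + 1, p)       # P(Y <= y)
    hi = stats.nbinom.sf(y - 1, x + 1, p)    # P(Y >= y)
    return min(1.0, 2.0 * min(lo, hi))


def two_library_test(count_a: int, count_b: int, total_a: int, total_b: int) -> float:
    """Symmetrized two-sided Audic-Claverie p-value for one tag."""
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be positive")
    p1 = _directional_p(count_a, count_b, total_a, total_b)
    p2 = _directional_p(count_b, count_a, total_b, total_a)
    return min(1.0, 0.5 * (p1 + p2))


def build_expression_table(
    names: list[str],
    counts_a: list[int],
    counts_b: list[int],
    total_a: int,
    total_b: int,
    lib_a: str = "HIST",
    lib_b: str = "NC",
    floor: float = DEFAULT_FLOOR,
) -> pd.DataFrame:
    """Per-miRNA counts, TPM, fold change and exact-test p-value.

    TPM columns are kept unrounded; rounding to 2 decimals happens only at
    report-writing time.
    """
    rows = []
    for name, ca, cb in zip(names, counts_a, counts_b):
        ta = tpm(ca, total_a)
        tb = tpm(cb, total_b)
        rows.append({
            "name": name,
            f"count_{lib_a}": ca, f"count_{lib_b}": cb,
            f"tpm_{lib_a}": ta, f"tpm_{lib_b}": tb,
            "log2fc": log2_fold(ta, tb, floor),
            "p_value": two_library_test(ca, cb, total_a, total_b),
        })
    return pd.DataFrame(rows)


def classify(
    table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    lfc: float = DEFAULT_LFC,
    bh_correct: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Add direction and significance marks; return (table, summary).

    Significant = p < alpha AND |log2fc| > lfc, on unrounded values; '*' at
    p < 0.05, '**' at p < 0.01.  Direction from the fold-change sign.
    """
    df = table.copy()
    pvals = df["p_value"].to_numpy()
    if bh_correct:
        from statsmodels.stats.multitest import multipletests
        pvals = multipletests(pvals, method="fdr_bh")[1]
        df["p_adjusted"] = pvals
    lfc_vals = df["log2fc"].to_numpy()
    significant = (pvals < alpha) & (np.abs(lfc_vals) > lfc)
    df["significance"] = np.where(pvals < 0.01, "**",
                                  np.where(pvals < 0.05, "*", ""))
    df.loc[~significant, "significance"] = ""
    df["direction"] = np.where(~significant, "none",
                               np.where(lfc_vals > 0, "up", "down"))
    summary = {
        "n_sig": int(significant.sum()),
        "n_up": int((df["direction"] == "up").sum()),
        "n_down": int((df["direction"] == "down").sum()),
    }
    return df, summary


def ddct(ct_target_a: float, ct_ref_a: float,
         ct_target_b: float, ct_ref_b: float) -> float:
    """Relative expression by the 2^-ddCT method (condition a vs b)."""
    delta_delta = (ct_target_a - ct_ref_a) - (ct_target_b - ct_ref_b)
    return float(2.0 ** (-delta_delta))
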