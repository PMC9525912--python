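"""Shared two-group testing helpers (pooled-variance Student t by default)."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def two_sample_t(a, b, welch: bool = False):
    """Two-sided two-sample t-test; returns (t, p), NaN-safe.

    Pooled-variance Student test by default (the field's spreadsheet-default
    T.TEST type 2); Welch by flag. Degenerate inputs (fewer than 2 finite
    values per group, or zero pooled variance) return (nan, nan).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        return np.nan, np.nan
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            # identical constant groups: no evidence of difference
            return 0.0, 1.0
        return np.nan, np.nan
    t, p = stats.ttest_ind(b, a, equal_var=not welch)
    return float(t), float(p)


def log2_fold_change(mean_a: float, mean_b: float) -> float:
    """log2(mean_b / mean_a); +/-inf on a zero denominator/numerator."""
    if mean_a == 0:
        return np.inf if mean_b > 0 else np.nan
    if mean_b == 0:
        return -np.inf
    if mean_a < 0 or mean_b < 0:
        return np.nan
    return float(np.log2(mean_b / mean_a))


def group_table(
    values: pd.DataFrame,
    design: pd.DataFrame,
    group_a: str,
    group_b: str,
    welch: bool = False,
    already_log2: bool = False,
) -> pd.DataFrame:
    """Row-wise differential table for a feature x sample matrix.

    ``design`` maps sample_id -> group. Returns per-row mean_a, mean_b,
    log2fc, t, p, n_a, n_b. When ``already_log2`` the fold change is the
    difference of means.
    """
    groups = design.set_index("sample_id")["group"]
    cols_a = [c for c in values.columns if groups.get(c) == group_a]
    cols_b = [c for c in values.columns if groups.get(c) == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            f"need >= 2 samples per group; got {len(cols_a)} in {group_a!r} "
            f"and {len(cols_b)} in {group_b!r}"
        )
    rows = []
    for idx, row in values.iterrows():
        va = row[cols_a].to_numpy(dtype=float)
        vb = row[cols_b].to_numpy(dtype=float)
        ma = np.nanmean(va) if np.isfinite(va).any() else np.nan
        mb = np.nanmean(vb) if np.isfinite(vb).any() else np.nan
        t, p = two_sample_t(va, vb, welch=welch)
        if already_log2:
            lfc = mb - ma
        else:
            lfc = log2_fold_change(ma, mb) if np.isfinite(ma) and np.isfinite(mb) else np.nan
        rows.append(
            dict(
                mean_a=ma,
                mean_b=mb,
                log2fc=lfc,
                t=t,
                p=p,
                n_a=int(np.isfinite(va).sum()),
                n_b=int(np.isfinite(vb).sum()),
            )
        )
    out = pd.DataFrame(rows, index=values.index)
    out["neg_log10_p"] = -np.log10(out["p"])
    return out
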