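"""TMT6 reporter aggregation and SAM-style permutation differential analysis.

PSM-level reporter tables are filtered (posterior error probability
strictly below 0.05; proteins kept only with at least one accepted unique
peptide), summed into a protein x channel matrix, channel-normalized, and
log2-transformed. Differential expression between two conditions uses the
significance-analysis-of-microarrays (SAM) moderated statistic

    d_i = (mean_b - mean_a) / (s_i + s0)

with s_i the pooled two-sample standard error on log2 data and s0 an
exchangeability constant that damps small-variance artifacts (s0 = 0.32 in
log2 units corresponds to a ~1.25x fold-change cutoff, since
log2(1.25) = 0.32). Significance is calibrated by group-label permutation:
at a cutoff c, the estimated FDR is the median over permutations of the
number of null |d*| >= c, divided by the observed count; the decision
cutoff is the smallest c whose estimated FDR is at or below the target.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

TMT6_CHANNELS = ["126", "127", "128", "129", "130", "131"]
#: Study layout: two channels per macrophage state.
DEFAULT_CHANNEL_DESIGN: Dict[str, str] = {
    "126": "M0", "127": "M0", "128": "M1", "129": "M1", "130": "M2", "131": "M2",
}
PSM_COLUMNS = ["peptide", "protein_group", "unique", "pep"]


def load_psms(path_or_df: Union[str, pd.DataFrame]) -> pd.DataFrame:
    """Read a PSM TSV with reporter columns r126..r131."""
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, sep="\t")
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    missing += [f"r{ch}" for ch in TMT6_CHANNELS if f"r{ch}" not in df.columns]
    if missing:
        raise ValueError(f"PSM table missing columns: {missing}")
    if ((df["pep"] < 0) | (df["pep"] > 1)).any():
        raise ValueError("PEP values must lie in [0, 1]")
    for ch in TMT6_CHANNELS:
        if (df[f"r{ch}"] < 0).any():
            raise ValueError(f"negative reporter intensity in channel {ch}")
    df["unique"] = df["unique"].astype(bool)
    return df


def filter_psms(psms: pd.DataFrame, pep_max: float = 0.05) -> pd.DataFrame:
    """Keep PSMs with PEP strictly below ``pep_max``; drop proteins without
    at least one accepted unique peptide."""
    ok = psms[psms["pep"] < pep_max]
    keep = ok.groupby("protein_group")["unique"].any()
    return ok[ok["protein_group"].map(keep).fillna(False)].reset_index(drop=True)


def aggregate_protein_matrix(
    psms: pd.DataFrame,
    normalize_channels: bool = True,
    method: str = "sum",
) -> pd.DataFrame:
    """Protein-group x channel reporter matrix from filtered PSMs.

    ``method='sum'`` (default) sums reporter intensities per protein;
    ``'median'`` takes the per-channel median across PSMs. Channel
    normalization rescales every channel to the mean channel total.
    All-zero rows are flagged in the ``quantifiable`` attribute column.
    """
    rcols = [f"r{ch}" for ch in TMT6_CHANNELS]
    if method == "sum":
        mat = psms.groupby("protein_group")[rcols].sum()
    elif method == "median":
        mat = psms.groupby("protein_group")[rcols].median()
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    mat.columns = TMT6_CHANNELS
    if normalize_channels:
        totals = mat.sum(axis=0)
        target = totals.mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = mat * (target / totals)
    counts = psms.groupby("protein_group").agg(
        n_psms=("peptide", "size"),
        n_unique_peptides=("peptide", lambda s: s[psms.loc[s.index, "unique"]].nunique()),
    )
    mat = mat.join(counts)
    mat["quantifiable"] = mat[TMT6_CHANNELS].sum(axis=1) > 0
    return mat


def log2_matrix(matrix: pd.DataFrame, pseudocount: float = 0.0) -> pd.DataFrame:
    """log2 of the channel columns; non-quantifiable rows are dropped."""
    mat = matrix[matrix.get("quantifiable", True)] if "quantifiable" in matrix else matrix
    vals = mat[TMT6_CHANNELS].to_numpy(dtype=float) + pseudocount
    with np.errstate(divide="ignore"):
        out = pd.DataFrame(np.log2(vals), index=mat.index, columns=TMT6_CHANNELS)
    return out


def _distinct_assignments(n_a: int, n_b: int) -> List[np.ndarray]:
    """All distinct ways to relabel n_a + n_b columns into groups of the
    original sizes (including the identity)."""
    idx = list(range(n_a + n_b))
    return [np.array(c, dtype=int) for c in itertools.combinations(idx, n_a)]


def _sam_d(vals_a: np.ndarray, vals_b: np.ndarray, s0: float) -> np.ndarray:
    """Moderated statistic per row: (mean_b - mean_a) / (pooled SE + s0)."""
    n_a, n_b = vals_a.shape[1], vals_b.shape[1]
    ma, mb = vals_a.mean(axis=1), vals_b.mean(axis=1)
    ssa = ((vals_a - ma[:, None]) ** 2).sum(axis=1)
    ssb = ((vals_b - mb[:, None]) ** 2).sum(axis=1)
    sp2 = (ssa + ssb) / (n_a + n_b - 2)
    se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    return (mb - ma) / (se + s0)


class SamDifferential(BaseEstimator):
    """SAM permutation test on a log2 protein x channel matrix.

    Parameters
    ----------
    s0:
        Exchangeability constant in log2-intensity units added to the
        pooled standard error (default 0.32, a ~1.25x fold-change cutoff).
    fdr:
        Target permutation-estimated false discovery rate (default 0.01).
    n_perm:
        Number of group-label permutations; when fewer distinct balanced
        assignments exist, all of them are used.
    random_state:
        Seed for permutation sampling (required for reproducibility when
        permutations are subsampled).

    Fitted attributes: ``d_``, ``log2fc_``, ``significant_``, ``cutoff_``,
    ``n_perm_used_``, ``results_`` (a tidy per-protein DataFrame).
    """

    def __init__(
        self,
        s0: float = 0.32,
        fdr: float = 0.01,
        n_perm: int = 250,
        random_state: Optional[int] = None,
    ):
        self.s0 = s0
        self.fdr = fdr
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(
        self,
        matrix: pd.DataFrame,
        design: Union[Dict[str, str], pd.DataFrame] = None,
        group_a: str = "M1",
        group_b: str = "M2",
    ):
        if design is None:
            design = DEFAULT_CHANNEL_DESIGN
        if isinstance(design, pd.DataFrame):
            design = dict(zip(design["channel"].astype(str), design["condition"]))
        cols_a = [c for c in matrix.columns if design.get(str(c)) == group_a]
        cols_b = [c for c in matrix.columns if design.get(str(c)) == group_b]
        if len(cols_a) < 2 or len(cols_b) < 2:
            raise ValueError(
                f"need >= 2 channels per group, got {len(cols_a)} ({group_a}) "
                f"and {len(cols_b)} ({group_b})"
            )
        X = matrix[cols_a + cols_b].to_numpy(dtype=float)
        n_a = len(cols_a)
        d = _sam_d(X[:, :n_a], X[:, n_a:], self.s0)

        n_tot = n_a + len(cols_b)
        total = math.comb(n_tot, n_a)
        if total <= self.n_perm:
            assigns = _distinct_assignments(n_a, len(cols_b))
        elif total <= 100_000:
            rng = np.random.default_rng(self.random_state)
            universe = _distinct_assignments(n_a, len(cols_b))
            pick = rng.choice(total, size=self.n_perm, replace=False)
            assigns = [universe[i] for i in pick]
        else:
            # enumeration infeasible; draw random assignments (collisions
            # are vanishingly rare at this cardinality)
            rng = np.random.default_rng(self.random_state)
            assigns = [np.sort(rng.permutation(n_tot)[:n_a]) for _ in range(self.n_perm)]
        null_abs = np.empty((len(assigns), X.shape[0]))
        all_idx = np.arange(n_a + len(cols_b))
        for k, a_idx in enumerate(assigns):
            b_idx = np.setdiff1d(all_idx, a_idx)
            null_abs[k] = np.abs(_sam_d(X[:, a_idx], X[:, b_idx], self.s0))
        null_abs.sort(axis=1)

        obs_abs = np.abs(d)
        order = np.argsort(obs_abs)
        sorted_abs = obs_abs[order]
        # candidate cutoffs: each observed |d|; exceedance counts via searchsorted
        n = len(sorted_abs)
        obs_counts = n - np.searchsorted(sorted_abs, sorted_abs, side="left")
        null_counts = np.empty((len(assigns), n))
        for k in range(len(assigns)):
            null_counts[k] = n - np.searchsorted(null_abs[k], sorted_abs, side="left")
        med_null = np.median(null_counts, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            fdr_at = np.where(obs_counts > 0, med_null / obs_counts, np.inf)
        ok = np.nonzero(fdr_at <= self.fdr)[0]
        self.cutoff_ = float(sorted_abs[ok[0]]) if len(ok) else np.inf
        self.d_ = pd.Series(d, index=matrix.index, name="d")
        self.log2fc_ = pd.Series(
            X[:, n_a:].mean(axis=1) - X[:, :n_a].mean(axis=1),
            index=matrix.index,
            name="log2fc",
        )
        self.significant_ = pd.Series(
            obs_abs >= self.cutoff_, index=matrix.index, name="significant"
        )
        self.n_perm_used_ = len(assigns)
        self.results_ = pd.DataFrame(
            dict(
                d=self.d_,
                log2fc=self.log2fc_,
                significant=self.significant_,
                s0=self.s0,
            )
        )
        return self

    def fit_predict(self, matrix, design=None, group_a="M1", group_b="M2"):
        self.fit(matrix, design, group_a, group_b)
        return self.significant_


def sam_test(
    matrix: pd.DataFrame,
    design: Union[Dict[str, str], pd.DataFrame] = None,
    group_a: str = "M1",
    group_b: str = "M2",
    s0: float = 0.32,
    fdr: float = 0.01,
    n_perm: int = 250,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Functional wrapper over :class:`SamDifferential`; returns the tidy table."""
    est = SamDifferential(s0=s0, fdr=fdr, n_perm=n_perm, random_state=seed)
    est.fit(matrix, design, group_a, group_b)
    return est.results_


def zscore_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-standardize channel columns (mean 0, sd 1) for heat-map display.

    Constant rows become all zeros and are flagged in a ``constant`` column.
    """
    chans = [c for c in TMT6_CHANNELS if c in matrix.columns] or list(matrix.columns)
    if len(chans) < 2:
        raise ValueError("need >= 2 channels to z-score")
    vals = matrix[chans].to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mean) / sd
    z[constant] = 0.0
    out = pd.DataFrame(z, index=matrix.index, columns=chans)
    out["constant"] = constant
    return out
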