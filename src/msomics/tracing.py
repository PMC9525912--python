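"""Stable-isotope tracing: isotopologue envelopes, natural-abundance
correction, and labeled-fraction (enrichment) estimation.

An isotopologue envelope holds the intensities of the M+0 ... M+K ion
species of one analyte (a metabolite ion such as O-BHA-derivatized
pyruvate, or a histone peptide precursor). A tracer (e.g. uniformly
labeled 13C6-glucose) places a fixed mass shift n on the labeled species
of interest: +3 for 13C3-pyruvate/lactate, +2 for 13C2-succinate and for
the 13C2-acetyl group transferred to histone lysines via acetyl-CoA.

Two enrichment readouts are provided:

* ratio mode — the labeled/unlabeled intensity ratio I(M+n)/I(M+0), the
  literal "incorporation (or transfer) rate";
* fraction mode — the fraction of the species carrying the tracer shift,
  after correcting the envelope for naturally occurring heavy isotopes
  (mainly 13C at 1.07%).

The correction solves A x = observed, where column j of A is the
theoretical natural envelope of the species carrying j tracer atoms
(those positions fixed heavy, the rest at natural abundance), with x >= 0,
and normalizes x to sum 1. Carbon-only correction is the default (the
dominant term); full CHNOS mode is available by flag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin

from ._stats import two_sample_t
from .chem import ElementalFormula, as_formula, FormulaLike

#: Natural isotope abundances as unit-mass-shift distributions per element.
#: Index k of each vector is the probability of a +k mass shift for one atom.
NATURAL_ISOTOPES: Dict[str, np.ndarray] = {
    "C": np.array([0.9893, 0.0107]),
    "H": np.array([0.999885, 0.000115]),
    "N": np.array([0.99636, 0.00364]),
    "O": np.array([0.99757, 0.00038, 0.00205]),
    "S": np.array([0.9499, 0.0075, 0.0425, 0.0, 0.0001]),
}

P13C = 0.0107  # natural 13C abundance


@dataclass
class IsotopologueEnvelope:
    """M+0 ... M+K intensities of one species plus its tracer shift."""

    species_id: str
    formula: ElementalFormula
    intensities: np.ndarray
    label_shift: int

    def __post_init__(self):
        self.formula = as_formula(self.formula)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if (self.intensities < 0).any():
            raise ValueError("envelope intensities must be >= 0")
        if self.intensities.sum() <= 0:
            raise ValueError("envelope intensities must sum to > 0")
        if len(self.intensities) - 1 < self.label_shift:
            raise ValueError(
                f"envelope truncated at M+{len(self.intensities) - 1} but "
                f"label shift is {self.label_shift}; measure more isotopologues"
            )


@dataclass
class EnrichmentResult:
    """Labeled fraction in [0, 1] and the labeled/unlabeled intensity ratio."""

    species_id: str
    labeled_fraction: float
    labeled_over_unlabeled_ratio: float
    corrected: bool
    fractions: Optional[np.ndarray] = field(default=None, repr=False)


def natural_envelope(
    formula: FormulaLike, K: int, mode: str = "carbon"
) -> np.ndarray:
    """Theoretical M+0..M+K probabilities from natural isotope abundances.

    ``mode='carbon'`` spreads only the carbons (binomial in the 13C
    abundance); ``mode='full'`` convolves H, C, N, O and S contributions.
    Isotope-labeled atoms (``[13C]`` etc.) are fixed and contribute no
    spread. Probabilities are truncated at M+K and sum to <= 1.
    """
    if K < 0:
        raise ValueError(f"K must be >= 0, got {K}")
    f = as_formula(formula)
    elements = ("C",) if mode == "carbon" else ("C", "H", "N", "O", "S")
    if mode not in ("carbon", "full"):
        raise ValueError(f"mode must be 'carbon' or 'full', got {mode!r}")
    env = np.array([1.0])
    for el in elements:
        n = f.n_atoms(el)
        dist = NATURAL_ISOTOPES[el]
        for _ in range(n):
            env = np.convolve(env, dist)
            if len(env) > K + 1:
                env = env[: K + 1]
    out = np.zeros(K + 1)
    out[: len(env)] = env
    return out


def correction_matrix(
    formula: FormulaLike, K: int, label_shift: int, mode: str = "carbon"
) -> np.ndarray:
    """(K+1) x (label_shift+1) design matrix for natural-abundance correction.

    Column j is the natural envelope of the species with j tracer carbons
    fixed heavy (j fewer natural carbons), offset j mass units up.
    """
    f = as_formula(formula)
    n_c = f.n_atoms("C")
    if label_shift > n_c:
        raise ValueError(
            f"label shift {label_shift} exceeds the {n_c} correctable carbons of {f}"
        )
    A = np.zeros((K + 1, label_shift + 1))
    for j in range(label_shift + 1):
        sub = ElementalFormula({**f.counts, "C": n_c - j})
        env_j = natural_envelope(sub, K - j, mode=mode)
        A[j:, j] = env_j
    return A


class NaturalAbundanceCorrector(BaseEstimator, TransformerMixin):
    """Deconvolve natural heavy-isotope contributions from an envelope.

    Parameters
    ----------
    mode:
        'carbon' (default) corrects the dominant 13C term only; 'full'
        adds H/N/O/S.
    nonneg:
        Solve with a non-negativity constraint (default); plain least
        squares is available for diagnostics.
    """

    def __init__(self, mode: str = "carbon", nonneg: bool = True):
        self.mode = mode
        self.nonneg = nonneg

    def fit(self, X=None, y=None):
        return self

    def transform(self, envelope: IsotopologueEnvelope) -> np.ndarray:
        """Corrected isotopologue fractions x(0..label_shift), summing to 1."""
        obs = envelope.intensities
        K = len(obs) - 1
        if envelope.formula.n_atoms("C") == 0:
            # nothing to correct: identity, i.e. the normalized observed envelope
            return obs / obs.sum()
        A = correction_matrix(envelope.formula, K, envelope.label_shift, mode=self.mode)
        if K < envelope.label_shift:
            raise ValueError("envelope shorter than the label shift; enlarge K")
        if self.nonneg:
            x, _ = nnls(A, obs)
        else:
            x, *_ = np.linalg.lstsq(A, obs, rcond=None)
        tot = x.sum()
        if tot <= 0:
            raise ValueError(
                "correction produced an empty solution; the envelope may be "
                "truncated too early — measure a larger K"
            )
        return x / tot


def correct_natural_abundance(
    envelope: IsotopologueEnvelope, mode: str = "carbon", nonneg: bool = True
) -> np.ndarray:
    """Functional wrapper over :class:`NaturalAbundanceCorrector`."""
    return NaturalAbundanceCorrector(mode=mode, nonneg=nonneg).transform(envelope)


def enrichment(
    envelope: IsotopologueEnvelope, correct: bool = True, mode: str = "carbon"
) -> EnrichmentResult:
    """Enrichment of the tracer-shifted species.

    Ratio mode is I(M+n)/I(M+0) on raw intensities (undefined when M+0 is
    empty); fraction mode is x(M+n) after natural-abundance correction, or
    the raw intensity fraction when ``correct`` is off.
    """
    obs = envelope.intensities
    n = envelope.label_shift
    ratio = float(obs[n] / obs[0]) if obs[0] > 0 else float("nan")
    if correct:
        x = correct_natural_abundance(envelope, mode=mode)
        fraction = float(x[n])
    else:
        x = obs / obs.sum()
        fraction = float(x[n])
    return EnrichmentResult(
        species_id=envelope.species_id,
        labeled_fraction=fraction,
        labeled_over_unlabeled_ratio=ratio,
        corrected=bool(correct),
        fractions=x,
    )


ENVELOPE_COLUMNS = ["sample_id", "species_id", "formula", "m_offset", "intensity", "label_shift"]


def load_envelopes(path_or_df: Union[str, pd.DataFrame]) -> List[tuple]:
    """Read a long envelope TSV into (sample_id, IsotopologueEnvelope) pairs."""
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, sep="\t")
    missing = [c for c in ENVELOPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"envelope table missing columns: {missing}")
    out = []
    for (sample, species), grp in df.groupby(["sample_id", "species_id"], sort=True):
        grp = grp.sort_values("m_offset")
        K = int(grp["m_offset"].max())
        inten = np.zeros(K + 1)
        inten[grp["m_offset"].to_numpy(dtype=int)] = grp["intensity"].to_numpy(dtype=float)
        env = IsotopologueEnvelope(
            species_id=str(species),
            formula=str(grp["formula"].iloc[0]),
            intensities=inten,
            label_shift=int(grp["label_shift"].iloc[0]),
        )
        out.append((str(sample), env))
    return out


def trace_summary(
    envelopes: Union[str, pd.DataFrame, Sequence[tuple]],
    design: pd.DataFrame,
    correct: bool = True,
    mode: str = "carbon",
    value: str = "fraction",
) -> Dict[str, pd.DataFrame]:
    """Group-level enrichment summary and pairwise group comparisons.

    Returns ``{"per_sample": ..., "summary": ..., "comparisons": ...}``.
    Species present in only one group appear in the summary but get no
    comparison row (comparison = NA semantics).
    """
    if not isinstance(envelopes, (list, tuple)):
        envelopes = load_envelopes(envelopes)
    groups = design.set_index("sample_id")["group"]
    per_sample = []
    for sample_id, env in envelopes:
        res = enrichment(env, correct=correct, mode=mode)
        per_sample.append(
            dict(
                sample_id=sample_id,
                group=groups.get(sample_id),
                species_id=env.species_id,
                fraction=res.labeled_fraction,
                ratio=res.labeled_over_unlabeled_ratio,
            )
        )
    ps = pd.DataFrame(per_sample)
    summary = (
        ps.groupby(["species_id", "group"])[value]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    comparisons = []
    for species, sub in ps.groupby("species_id"):
        present = sorted(g for g in sub["group"].dropna().unique())
        for ga, gb in itertools.combinations(present, 2):
            va = sub.loc[sub["group"] == ga, value].to_numpy()
            vb = sub.loc[sub["group"] == gb, value].to_numpy()
            t, p = two_sample_t(va, vb)
            comparisons.append(
                dict(
                    species_id=species,
                    group_a=ga,
                    group_b=gb,
                    mean_a=float(np.nanmean(va)),
                    mean_b=float(np.nanmean(vb)),
                    difference=float(np.nanmean(vb) - np.nanmean(va)),
                    t=t,
                    p=p,
                )
            )
    comp = pd.DataFrame(
        comparisons,
        columns=["species_id", "group_a", "group_b", "mean_a", "mean_b", "difference", "t", "p"],
    )
    return {"per_sample": ps, "summary": summary, "comparisons": comp}
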