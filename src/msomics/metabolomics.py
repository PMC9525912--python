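"""Derivatization-aware metabolite identification and IS-based quantification.

Observed LC-MS features (MH+ ions of dansylated amines or O-BHA-derivatized
carboxyls/carbonyls) are matched against a compound library expanded over
the allowed derivatization states, at a relative mass tolerance of 5 ppm
(inclusive). Accepted matches are converted to concentrations by
normalizing the analyte signal against a spiked internal standard (IS) of
known amount:

    concentration = (I_analyte / I_IS) * amount_IS / protein_mg

IS assignment follows the two tracks of the protocol:

* dansyl track: compounds map to the zone-matched amino-acid IS — the
  serine analogue in the low retention-time zone, the glycine analogue in
  the high zone;
* O-BHA (TCA) track: compounds map to their exact isotope-labeled analogue
  when one was spiked, otherwise to the designated fallback (the malate IS).

Differential comparison is a per-compound two-sided Student t-test with
log2 fold change, i.e. volcano-plot coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import chem
from ._stats import group_table
from .chem import ElementalFormula, FormulaError, IonSpec

logger = logging.getLogger(__name__)

DEFAULT_TOL_PPM = 5.0

LIBRARY_COLUMNS = ["compound_id", "name", "formula", "amine_sites", "carbonyl_sites", "rt_zone"]
STANDARD_COLUMNS = ["is_id", "formula", "amount_nmol", "rt_zone", "scheme"]
RT_ZONES = ("low", "high", "tca")


@dataclass(frozen=True)
class FeatureRecord:
    """One observed LC-MS feature."""

    sample_id: str
    mz: float
    rt: float
    intensity: float
    charge: int = 1

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"mz must be > 0, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity}")
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")


def load_compound_library(path_or_df: Union[str, pd.DataFrame]) -> pd.DataFrame:
    """Read and validate a compound library TSV.

    Required columns: compound_id, name, formula (Hill-like, bracketed
    isotope labels allowed), amine_sites, carbonyl_sites, rt_zone
    ({low, high, tca}). Malformed formulas are rejected naming the row.
    """
    if isinstance(path_or_df, pd.DataFrame):
        lib = path_or_df.copy()
    else:
        lib = pd.read_csv(path_or_df, sep="\t", dtype={"compound_id": str})
    missing = [c for c in LIBRARY_COLUMNS if c not in lib.columns]
    if missing:
        raise ValueError(f"compound library missing columns: {missing}")
    for i, row in lib.iterrows():
        try:
            ElementalFormula.parse(str(row["formula"]))
        except FormulaError as exc:
            raise ValueError(f"library row {i} ({row['compound_id']}): {exc}") from exc
        if row["rt_zone"] not in RT_ZONES:
            raise ValueError(
                f"library row {i}: rt_zone {row['rt_zone']!r} not in {RT_ZONES}"
            )
    return lib


def expand_library(library: pd.DataFrame) -> pd.DataFrame:
    """Expand compounds over allowed derivatization states at charge 1.

    Each compound with ``a`` amine sites contributes dansyl states with
    1..a tags (site counts for multi-amine compounds are uncertain, so
    partial and full derivatization are both offered to the matcher);
    likewise O-BHA states for carbonyl/carboxyl sites. Compounds with no
    derivatizable site are offered underivatized.
    """
    rows = []
    for _, row in library.iterrows():
        formula = ElementalFormula.parse(str(row["formula"]))
        states = []
        for n in range(1, int(row["amine_sites"]) + 1):
            states.append(("dansyl", n))
        for n in range(1, int(row["carbonyl_sites"]) + 1):
            states.append(("obha", n))
        if not states:
            states.append(("none", 0))
        for scheme, n in states:
            rows.append(
                dict(
                    compound_id=row["compound_id"],
                    scheme=scheme,
                    n_sites=n,
                    rt_zone=row["rt_zone"],
                    theoretical_mz=chem.derivatized_mz(formula, n, scheme, IonSpec(1)),
                )
            )
    return pd.DataFrame(rows)


class FeatureMatcher(BaseEstimator, TransformerMixin):
    """Assign observed features to library compounds by exact mass.

    Parameters
    ----------
    tol_ppm:
        Inclusive acceptance bound on \\|ppm error\\| (default 5.0).

    After :meth:`fit` the expanded theoretical table is available as
    ``expanded_``. :meth:`transform` returns one row per feature with the
    best (min \\|ppm\\|) candidate, ties broken by fewer derivatization sites
    then lexicographic compound_id, and ``accepted`` true iff
    \\|ppm\\| <= tol_ppm.
    """

    def __init__(self, tol_ppm: float = DEFAULT_TOL_PPM):
        self.tol_ppm = tol_ppm

    def fit(self, library: pd.DataFrame, y=None):
        if self.tol_ppm <= 0:
            raise ValueError(f"tol_ppm must be > 0, got {self.tol_ppm}")
        lib = load_compound_library(library)
        if lib.empty:
            raise ValueError("compound library is empty")
        self.library_ = lib
        self.expanded_ = expand_library(lib).sort_values(
            ["theoretical_mz", "n_sites", "compound_id"], kind="mergesort"
        ).reset_index(drop=True)
        return self

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "expanded_"):
            raise RuntimeError("FeatureMatcher must be fit on a library first")
        feats = features.reset_index(drop=True)
        out = []
        exp = self.expanded_
        theo = exp["theoretical_mz"].to_numpy()
        for i, row in feats.iterrows():
            mz = float(row["mz"])
            ppm = (mz - theo) / theo * 1e6
            order = np.lexsort(
                (exp["compound_id"].to_numpy(), exp["n_sites"].to_numpy(), np.abs(ppm))
            )
            best = order[0]
            best_ppm = float(ppm[best])
            out.append(
                dict(
                    sample_id=row.get("sample_id"),
                    mz=mz,
                    rt=row.get("rt", np.nan),
                    intensity=row.get("intensity", np.nan),
                    compound_id=exp.at[best, "compound_id"],
                    scheme=exp.at[best, "scheme"],
                    n_sites=int(exp.at[best, "n_sites"]),
                    rt_zone=exp.at[best, "rt_zone"],
                    theoretical_mz=float(theo[best]),
                    ppm=best_ppm,
                    # inclusive bound; relative epsilon so a feature sitting
                    # exactly on the boundary is not rejected by rounding
                    accepted=bool(abs(best_ppm) <= self.tol_ppm + 1e-9),
                )
            )
        return pd.DataFrame(out)


def match_features(
    features: Union[pd.DataFrame, Sequence[FeatureRecord]],
    library: pd.DataFrame,
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> pd.DataFrame:
    """Match features against a library; see :class:`FeatureMatcher`."""
    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame([f.__dict__ for f in features])
    if features.empty:
        return pd.DataFrame(
            columns=["sample_id", "mz", "rt", "intensity", "compound_id", "scheme",
                     "n_sites", "rt_zone", "theoretical_mz", "ppm", "accepted"]
        )
    return FeatureMatcher(tol_ppm=tol_ppm).fit(library).transform(features)


def load_standards(path_or_df: Union[str, pd.DataFrame]) -> pd.DataFrame:
    """Read and validate the internal-standard manifest.

    Required columns: is_id, formula (isotope-labeled), amount_nmol,
    rt_zone, scheme. Optional: target_compound_id (exact-analogue link for
    the TCA track), n_sites (derivatization tags on the IS, default 1).
    """
    if isinstance(path_or_df, pd.DataFrame):
        std = path_or_df.copy()
    else:
        std = pd.read_csv(path_or_df, sep="\t", dtype={"is_id": str})
    missing = [c for c in STANDARD_COLUMNS if c not in std.columns]
    if missing:
        raise ValueError(f"standards manifest missing columns: {missing}")
    if (std["amount_nmol"] <= 0).any():
        bad = std.loc[std["amount_nmol"] <= 0, "is_id"].tolist()
        raise ValueError(f"IS amounts must be > 0 nmol: {bad}")
    if "n_sites" not in std.columns:
        std["n_sites"] = 1
    if "target_compound_id" not in std.columns:
        std["target_compound_id"] = ""
    std["target_compound_id"] = std["target_compound_id"].fillna("")
    for i, row in std.iterrows():
        ElementalFormula.parse(str(row["formula"]))
    return std


def assign_internal_standard(
    compound_rt_zone: str,
    scheme: str,
    standards: pd.DataFrame,
    compound_id: Optional[str] = None,
    fallback_target: str = "malate",
) -> str:
    """Pick the IS used to quantify a matched compound.

    Dansyl-track compounds map to the IS of their retention-time zone
    (serine analogue: low; glycine analogue: high). O-BHA compounds map to
    their exact labeled analogue when present, else the fallback IS (the
    one targeting malate).
    """
    std = standards
    if scheme == "obha":
        if compound_id is not None:
            exact = std[std["target_compound_id"] == compound_id]
            if len(exact):
                return str(exact.iloc[0]["is_id"])
        fb = std[(std["scheme"] == "obha") & (std["target_compound_id"] == fallback_target)]
        if len(fb):
            return str(fb.iloc[0]["is_id"])
        raise ValueError(
            f"no exact IS for compound {compound_id!r} and no fallback IS "
            f"targeting {fallback_target!r} in the manifest"
        )
    zone = std[(std["scheme"] == scheme) & (std["rt_zone"] == compound_rt_zone)]
    if not len(zone):
        raise ValueError(f"no internal standard configured for rt_zone {compound_rt_zone!r}")
    return str(zone.iloc[0]["is_id"])


def quantify_concentration(
    analyte_intensity: float,
    is_intensity: float,
    is_amount_nmol: float,
    protein_mass_mg: float = 1.0,
) -> float:
    """(I_analyte / I_IS) * amount_IS / protein_mg, in nmol per mg protein.

    A zero IS intensity yields NaN (missing value, not an exception).
    """
    if analyte_intensity < 0 or is_intensity < 0:
        raise ValueError("intensities must be >= 0")
    if is_amount_nmol <= 0:
        raise ValueError(f"IS amount must be > 0 nmol, got {is_amount_nmol}")
    if protein_mass_mg <= 0:
        raise ValueError(f"protein mass must be > 0 mg, got {protein_mass_mg}")
    if is_intensity == 0:
        return float("nan")
    return analyte_intensity / is_intensity * is_amount_nmol / protein_mass_mg


def _is_intensities(
    features: pd.DataFrame, standards: pd.DataFrame, tol_ppm: float
) -> pd.DataFrame:
    """Locate each IS in each sample's feature list by exact mass (MH+)."""
    rows = []
    for _, st in standards.iterrows():
        theo = chem.derivatized_mz(
            str(st["formula"]), int(st.get("n_sites", 1)), str(st["scheme"]), IonSpec(1)
        )
        for sample_id, sub in features.groupby("sample_id"):
            ppm = (sub["mz"].to_numpy() - theo) / theo * 1e6
            ok = np.abs(ppm) <= tol_ppm
            inten = float(sub["intensity"].to_numpy()[ok].sum()) if ok.any() else np.nan
            rows.append(dict(is_id=st["is_id"], sample_id=sample_id, intensity=inten))
    return pd.DataFrame(rows)


def quantify_samples(
    matches: pd.DataFrame,
    features: pd.DataFrame,
    standards: pd.DataFrame,
    design: Optional[pd.DataFrame] = None,
    tol_ppm: float = DEFAULT_TOL_PPM,
    per_mg_protein: bool = True,
) -> pd.DataFrame:
    """Concentration table (compound x sample) from accepted matches.

    ``design`` may carry a ``protein_mg`` column (bicinchoninic-assay
    value); absent values default to 1.0 mg with a warning, so relative
    comparisons remain valid.
    """
    standards = load_standards(standards)
    is_int = _is_intensities(features, standards, tol_ppm).set_index(["is_id", "sample_id"])
    protein_mg = {}
    if design is not None and "protein_mg" in design.columns:
        protein_mg = design.set_index("sample_id")["protein_mg"].to_dict()
    elif per_mg_protein:
        logger.warning("no protein_mg in design; defaulting to 1.0 mg per sample")
    amounts = standards.set_index("is_id")["amount_nmol"].to_dict()
    rows = []
    for _, m in matches[matches["accepted"]].iterrows():
        is_id = assign_internal_standard(
            m["rt_zone"], m["scheme"], standards, compound_id=m["compound_id"]
        )
        key = (is_id, m["sample_id"])
        isi = float(is_int.loc[key, "intensity"]) if key in is_int.index else np.nan
        mg = float(protein_mg.get(m["sample_id"], 1.0)) if per_mg_protein else 1.0
        conc = (
            quantify_concentration(float(m["intensity"]), isi, amounts[is_id], mg)
            if np.isfinite(isi) and isi > 0
            else np.nan
        )
        rows.append(
            dict(
                compound_id=m["compound_id"],
                sample_id=m["sample_id"],
                concentration=conc,
                is_id=is_id,
            )
        )
    return pd.DataFrame(rows)


def concentration_matrix(concentrations: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long concentration table to compound x sample (mean on ties)."""
    return concentrations.pivot_table(
        index="compound_id", columns="sample_id", values="concentration", aggfunc="mean"
    )


def differential_volcano(
    conc_matrix: pd.DataFrame,
    design: pd.DataFrame,
    group_a: str,
    group_b: str,
    welch: bool = False,
    bh: bool = False,
) -> pd.DataFrame:
    """Per-compound log2 fold change and two-sided t-test p-value.

    Raw p-values by default; Benjamini-Hochberg adjusted q-values are added
    when ``bh`` is set. Infinite fold changes (zero group mean) are kept in
    the table but flagged for exclusion from plots.
    """
    out = group_table(conc_matrix, design, group_a, group_b, welch=welch)
    out["plot_ok"] = np.isfinite(out["log2fc"]) & np.isfinite(out["p"])
    if bh:
        from statsmodels.stats.multitest import multipletests

        mask = np.isfinite(out["p"])
        q = np.full(len(out), np.nan)
        if mask.any():
            q[mask.to_numpy()] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
        out["q"] = q
    return out
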