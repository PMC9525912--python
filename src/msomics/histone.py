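"""PRM histone-modification quantification with SILAC normalization.

The modification level of a peptide is the ratio of the MS peak area of
the modified peptide over the peptide free of modifications (a "modification
percentage"; it may exceed 1). When a heavy-arginine (13C6,15N4; "10R")
SILAC histone standard is spiked into every sample, the same ratio computed
in the heavy channel serves as a per-peptide internal reference and the
reported level is the ratio of ratios:

    normalized = (mod/unmod)_light / (mod/unmod)_heavy

Because the heavy standard is one preparation shared by all samples, any
peptide-specific multiplicative response bias (ionization, digestion) hits
light and heavy channels identically and cancels exactly, so cross-sample
fold changes of normalized ratios equal fold changes of true modification
levels.

Positional isomers co-eluting in one PRM trace (e.g. H3K18/23ac) are one
modification label. Differential testing is a two-sided pooled-variance
t-test over replicate injections.
"""

from __future__ import annotations

import logging
from typing import Optional, Union

import numpy as np
import pandas as pd

from ._stats import group_table

logger = logging.getLogger(__name__)

UNMODIFIED = "unmodified"
PRM_COLUMNS = ["sample_id", "peptide", "modification", "channel", "area"]


def modification_level(area_mod: float, area_unmod: float) -> float:
    """Modified / unmodified peak-area ratio; NaN when the unmodified area is 0."""
    if area_mod < 0 or area_unmod < 0:
        raise ValueError("peak areas must be >= 0")
    if area_unmod == 0:
        return float("nan")
    return area_mod / area_unmod


def silac_normalize(light_ratio: float, heavy_ratio: float) -> float:
    """Ratio of ratios: light modification ratio over the heavy-standard ratio."""
    if not np.isfinite(heavy_ratio) or heavy_ratio <= 0:
        logger.warning("missing/zero heavy ratio; carrying raw ratio forward")
        return float("nan")
    return light_ratio / heavy_ratio


def load_prm_areas(path_or_df: Union[str, pd.DataFrame]) -> pd.DataFrame:
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, sep="\t")
    missing = [c for c in PRM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PRM area table missing columns: {missing}")
    if (df["area"] < 0).any():
        raise ValueError("PRM areas must be >= 0")
    bad = set(df["channel"]) - {"light", "heavy"}
    if bad:
        raise ValueError(f"unknown channels {sorted(bad)}; expected light/heavy")
    return df


def compute_levels(
    areas: pd.DataFrame, fraction_of_total: bool = False
) -> pd.DataFrame:
    """Raw and SILAC-normalized modification levels per (sample, peptide, mod).

    With ``fraction_of_total`` the ratio denominator is modified+unmodified
    (a bounded percentage) instead of the unmodified peptide alone.
    """
    areas = load_prm_areas(areas)
    piv = areas.pivot_table(
        index=["sample_id", "peptide", "modification"],
        columns="channel",
        values="area",
        aggfunc="sum",
    )
    rows = []
    for (sample, peptide), grp in areas.groupby(["sample_id", "peptide"]):
        def _area(mod, ch):
            try:
                v = piv.loc[(sample, peptide, mod), ch]
            except KeyError:
                return np.nan
            return float(v) if np.isfinite(v) else np.nan

        unmod_l = _area(UNMODIFIED, "light")
        unmod_h = _area(UNMODIFIED, "heavy") if "heavy" in piv.columns else np.nan
        if not np.isfinite(unmod_l):
            logger.warning("no unmodified light area for %s/%s; skipped", sample, peptide)
            continue
        for mod in sorted(set(grp["modification"]) - {UNMODIFIED}):
            mod_l = _area(mod, "light")
            mod_h = _area(mod, "heavy") if "heavy" in piv.columns else np.nan
            if fraction_of_total:
                raw = mod_l / (mod_l + unmod_l) if (mod_l + unmod_l) > 0 else np.nan
                heavy = (
                    mod_h / (mod_h + unmod_h)
                    if np.isfinite(mod_h) and np.isfinite(unmod_h) and (mod_h + unmod_h) > 0
                    else np.nan
                )
            else:
                raw = modification_level(mod_l, unmod_l) if np.isfinite(mod_l) else np.nan
                heavy = (
                    modification_level(mod_h, unmod_h)
                    if np.isfinite(mod_h) and np.isfinite(unmod_h)
                    else np.nan
                )
            normalized = np.isfinite(heavy) and heavy > 0 and np.isfinite(raw)
            rows.append(
                dict(
                    sample_id=sample,
                    peptide=peptide,
                    modification=mod,
                    raw_ratio=raw,
                    heavy_ratio=heavy,
                    normalized_ratio=raw / heavy if normalized else np.nan,
                    normalized=bool(normalized),
                )
            )
    return pd.DataFrame(rows)


def level_matrix(levels: pd.DataFrame, use_normalized: bool = True) -> pd.DataFrame:
    """(peptide, modification) x sample matrix of levels."""
    col = "normalized_ratio" if use_normalized else "raw_ratio"
    return levels.pivot_table(
        index=["peptide", "modification"], columns="sample_id", values=col, aggfunc="mean"
    )


def histone_differential(
    levels: pd.DataFrame,
    design: pd.DataFrame,
    group_a: str,
    group_b: str,
    use_normalized: bool = True,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-modification log2 fold change and t-test p between two groups."""
    mat = level_matrix(levels, use_normalized=use_normalized)
    return group_table(mat, design, group_a, group_b, welch=welch)


def load_panel(path_or_df: Union[str, pd.DataFrame]) -> pd.DataFrame:
    """Modification panel TSV: peptide, modification, site annotation."""
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, sep="\t", dtype=str)
    for c in ("peptide", "modification"):
        if c not in df.columns:
            raise ValueError(f"panel missing column {c!r}")
    return df


def write_panel(panel: pd.DataFrame, path: str) -> None:
    panel.to_csv(path, sep="\t", index=False)
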