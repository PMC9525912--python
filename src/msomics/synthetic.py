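"""Ground-truth simulators for every input the analysis modules consume.

The generators emulate the study design the analysis targets: three
macrophage polarization states (M0/M1/M2), at least eight LC-MS injections
per pooled sample, TMT6 with two channels per state, spiked isotope-labeled
internal standards at 1 nmol (10 ul of 0.1 mM), and lognormal multiplicative
intensity noise (default CV 10% for areas, 5% for isotopologue envelopes)
with Gaussian m/z jitter (sd 1 ppm).

Every simulator takes a :class:`SimulationConfig`, draws exclusively from a
single ``numpy`` generator seeded from ``config.seed`` (byte-identical
output under a fixed seed), and returns the emitted tables together with a
truth table sufficient to score recovery.

``forward_envelope`` is the brute-force forward-convolution model for
isotope tracing (natural abundance x planted label fractions); the tracing
module's correction must invert it, so it doubles as that module's oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import chem
from .chem import ElementalFormula, IonSpec
from .tracing import correction_matrix

TSV_FLOAT_FORMAT = "%.10g"


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=TSV_FLOAT_FORMAT)


@dataclass
class SimulationConfig:
    """Knobs for all four simulators; defaults mirror the study design."""

    seed: int = 0
    # metabolome
    n_compounds: int = 112
    n_injections: int = 8
    groups: Tuple[str, ...] = ("M1", "M2")
    cv: float = 0.10
    ppm_jitter_sd: float = 1.0
    n_effect_compounds: int = 5
    effect_log2: float = 1.0
    is_amount_nmol: float = 1.0
    protein_mg: float = 1.0
    # histone PRM
    n_modifications: int = 15
    n_effect_modifications: int = 5
    # tracing
    envelope_cv: float = 0.05
    enrichment_fractions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "pyruvate": {"M0": 0.005, "M1": 0.015, "M2": 0.010},
            "lactate": {"M0": 0.050, "M1": 0.150, "M2": 0.100},
            "succinate": {"M0": 0.005, "M1": 0.015, "M2": 0.010},
            "H3K18_23ac": {"M0": 0.150, "M1": 0.200, "M2": 0.250},
        }
    )
    # TMT proteomics
    n_proteins: int = 1000
    n_effect_proteins: int = 50
    channel_sd_log2: float = 0.2
    max_psms_per_protein: int = 4

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "groups" in raw:
            raw["groups"] = tuple(raw["groups"])
        return cls(**raw)


def _lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit median and the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# metabolome

_SEED_COMPOUNDS = [
    # compound_id, name, formula, amine_sites, carbonyl_sites, rt_zone
    ("serine", "L-serine", "C3H7NO3", 1, 0, "low"),
    ("glycine", "glycine", "C2H5NO2", 1, 0, "high"),
    ("alanine", "L-alanine", "C3H7NO2", 1, 0, "low"),
    ("methionine", "L-methionine", "C5H11NO2S", 1, 0, "low"),
    ("lysine", "L-lysine", "C6H14N2O2", 2, 0, "high"),
    ("ornithine", "L-ornithine", "C5H12N2O2", 2, 0, "high"),
    ("pyruvate", "pyruvic acid", "C3H4O3", 0, 2, "tca"),
    ("lactate", "lactic acid", "C3H6O3", 0, 1, "tca"),
    ("succinate", "succinic acid", "C4H6O4", 0, 2, "tca"),
    ("malate", "malic acid", "C4H6O5", 0, 2, "tca"),
    ("citrate", "citric acid", "C6H8O7", 0, 3, "tca"),
    ("fumarate", "fumaric acid", "C4H4O4", 0, 2, "tca"),
]

DEFAULT_STANDARDS = pd.DataFrame(
    [
        # labeled serine analogue (13C3, 2H3, 15N): low-RT-zone dansyl IS
        ("is_serine", "[13C]3H4[2H]3[15N]O3", 1.0, "low", "dansyl", "serine", 1),
        # labeled glycine analogue (13C2, 2,2-2H2, 15N): high-RT-zone dansyl IS
        ("is_glycine", "[13C]2H3[2H]2[15N]O2", 1.0, "high", "dansyl", "glycine", 1),
        # exact labeled TCA analogues + the malate fallback
        ("is_succinate", "[13C]4H6O4", 1.0, "tca", "obha", "succinate", 2),
        ("is_malate", "[13C]4H6O5", 1.0, "tca", "obha", "malate", 2),
    ],
    columns=["is_id", "formula", "amount_nmol", "rt_zone", "scheme",
             "target_compound_id", "n_sites"],
)


def _random_library(rng: np.random.Generator, n_compounds: int) -> pd.DataFrame:
    """Seed compounds plus random amine-bearing formulas, rejecting any
    candidate whose derivatized m/z falls within 30 ppm of an existing one
    (so planted +/-3 ppm features resolve unambiguously)."""
    from .metabolomics import expand_library, load_compound_library

    rows = list(_SEED_COMPOUNDS)
    existing = expand_library(
        load_compound_library(pd.DataFrame(rows, columns=[
            "compound_id", "name", "formula", "amine_sites", "carbonyl_sites", "rt_zone"]))
    )["theoretical_mz"].tolist()
    # keep the spiked internal standards' m/z clear as well
    existing += [
        chem.derivatized_mz(str(st["formula"]), int(st["n_sites"]), str(st["scheme"]), IonSpec(1))
        for _, st in DEFAULT_STANDARDS.iterrows()
    ]
    i = 0
    while len(rows) < n_compounds:
        i += 1
        counts = {
            "C": int(rng.integers(4, 14)),
            "H": int(rng.integers(6, 24)),
            "N": int(rng.integers(1, 4)),
            "O": int(rng.integers(1, 7)),
        }
        amine = int(rng.integers(1, 3))
        zone = "low" if rng.random() < 0.5 else "high"
        formula = ElementalFormula(counts)
        mzs = [
            chem.derivatized_mz(formula, n, "dansyl", IonSpec(1))
            for n in range(1, amine + 1)
        ]
        if any(
            abs(mz - e) / e * 1e6 < 30.0 for mz in mzs for e in existing
        ):
            continue
        rows.append(
            (f"cmpd{i:03d}", f"synthetic compound {i}", str(formula), amine, 0, zone)
        )
        existing.extend(mzs)
    return pd.DataFrame(
        rows,
        columns=["compound_id", "name", "formula", "amine_sites", "carbonyl_sites", "rt_zone"],
    )


def simulate_metabolome(
    config: SimulationConfig = SimulationConfig(), out_dir: Optional[str] = None
) -> Dict[str, pd.DataFrame]:
    """Per-sample LC-MS feature tables with planted concentrations.

    Features sit at the fully derivatized theoretical MH+ m/z with Gaussian
    ppm jitter and lognormal intensity noise; the spiked internal standards
    appear at their planted amounts. Returns library, standards, features,
    design and a truth table of per-group concentrations (nmol/mg).
    """
    rng = np.random.default_rng(config.seed)
    library = _random_library(rng, config.n_compounds)
    standards = DEFAULT_STANDARDS.copy()

    compounds = library["compound_id"].tolist()
    base_conc = 10.0 ** rng.uniform(-0.5, 1.5, size=len(compounds))  # 0.3..30 nmol/mg
    effect_idx = rng.choice(len(compounds), size=min(config.n_effect_compounds, len(compounds)), replace=False)
    effects = np.zeros(len(compounds))
    effects[effect_idx] = config.effect_log2 * rng.choice([-1.0, 1.0], size=len(effect_idx))

    # per-zone instrument response (area units per nmol on-column)
    response = {"low": 1e6, "high": 8e5, "tca": 1.2e6}

    truth_rows, feat_rows, design_rows = [], [], []
    for gi, group in enumerate(config.groups):
        for ci, cid in enumerate(compounds):
            conc = base_conc[ci] * (2.0 ** effects[ci] if gi == 1 else 1.0)
            truth_rows.append(dict(compound_id=cid, group=group, concentration=conc,
                                   effect_log2=effects[ci] if gi == 1 else 0.0))
        for inj in range(config.n_injections):
            sample_id = f"{group}_r{inj + 1}"
            design_rows.append(dict(sample_id=sample_id, group=group,
                                    protein_mg=config.protein_mg, injection=inj + 1))
            # analytes at the fully derivatized state
            for ci, row in library.iterrows():
                cid = row["compound_id"]
                conc = base_conc[ci] * (2.0 ** effects[ci] if gi == 1 else 1.0)
                if row["amine_sites"] > 0:
                    scheme, n_sites = "dansyl", int(row["amine_sites"])
                else:
                    scheme, n_sites = "obha", int(row["carbonyl_sites"])
                theo = chem.derivatized_mz(str(row["formula"]), n_sites, scheme, IonSpec(1))
                mz = theo * (1.0 + rng.normal(0.0, config.ppm_jitter_sd) * 1e-6)
                inten = (conc * config.protein_mg * response[row["rt_zone"]]
                         * float(_lognormal(rng, config.cv, ())))
                rt = {"low": 10.0, "high": 30.0, "tca": 20.0}[row["rt_zone"]] + rng.normal(0, 1)
                feat_rows.append(dict(sample_id=sample_id, mz=mz, rt=rt,
                                      intensity=inten, charge=1))
            # internal standards
            for _, st in standards.iterrows():
                theo = chem.derivatized_mz(str(st["formula"]), int(st["n_sites"]),
                                           str(st["scheme"]), IonSpec(1))
                mz = theo * (1.0 + rng.normal(0.0, config.ppm_jitter_sd) * 1e-6)
                inten = (st["amount_nmol"] * response[st["rt_zone"]]
                         * float(_lognormal(rng, config.cv, ())))
                rt = {"low": 10.0, "high": 30.0, "tca": 20.0}[st["rt_zone"]] + rng.normal(0, 1)
                feat_rows.append(dict(sample_id=sample_id, mz=mz, rt=rt,
                                      intensity=inten, charge=1))

    out = dict(
        library=library,
        standards=standards,
        features=pd.DataFrame(feat_rows),
        design=pd.DataFrame(design_rows),
        truth=pd.DataFrame(truth_rows),
    )
    if out_dir is not None:
        d = Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        for name, df in out.items():
            _write(df, d / f"{name}.tsv")
    return out


# ---------------------------------------------------------------------------
# histone PRM

def simulate_prm(
    config: SimulationConfig = SimulationConfig(), out_dir: Optional[str] = None
) -> Dict[str, pd.DataFrame]:
    """PRM light/heavy peak areas with planted modification levels.

    Peptide- and modification-specific response biases are shared between
    the light and heavy channels, so the SILAC ratio-of-ratios must cancel
    them; the first ``n_effect_modifications`` modifications carry a
    planted 2^effect_log2 group fold change.
    """
    rng = np.random.default_rng(config.seed)
    n_pep = max(1, config.n_modifications // 2)
    peptides = [f"pep{p + 1:02d}" for p in range(n_pep)]
    mods = [f"mod{m + 1:02d}" for m in range(config.n_modifications)]
    mod_pep = {m: peptides[i % n_pep] for i, m in enumerate(mods)}

    base_level = 10.0 ** rng.uniform(-1.5, -0.3, size=len(mods))  # 3%..50%
    effects = np.zeros(len(mods))
    effects[: config.n_effect_modifications] = config.effect_log2 * rng.choice(
        [-1.0, 1.0], size=config.n_effect_modifications
    )
    heavy_level = base_level * _lognormal(rng, 0.2, len(mods))
    pep_response = dict(zip(peptides, 10.0 ** rng.uniform(5.5, 6.5, size=n_pep)))
    mod_bias = dict(zip(mods, _lognormal(rng, 0.5, len(mods))))  # ionization bias
    heavy_scale = 0.5  # spiked heavy standard amount relative to sample histones

    rows, truth = [], []
    panel = pd.DataFrame(
        dict(peptide=[mod_pep[m] for m in mods], modification=mods,
             site=[f"site{m + 1}" for m in range(len(mods))])
    )
    design_rows = []
    for gi, group in enumerate(config.groups):
        for mi, m in enumerate(mods):
            level = base_level[mi] * (2.0 ** effects[mi] if gi == 1 else 1.0)
            truth.append(dict(modification=m, peptide=mod_pep[m], group=group,
                              level=level,
                              effect_log2=effects[mi] if gi == 1 else 0.0))
        for inj in range(config.n_injections):
            sample_id = f"{group}_r{inj + 1}"
            design_rows.append(dict(sample_id=sample_id, group=group, injection=inj + 1))
            for pep in peptides:
                a_pep = pep_response[pep]
                rows.append(dict(sample_id=sample_id, peptide=pep,
                                 modification="unmodified", channel="light",
                                 area=a_pep * float(_lognormal(rng, config.cv, ()))))
                rows.append(dict(sample_id=sample_id, peptide=pep,
                                 modification="unmodified", channel="heavy",
                                 area=a_pep * heavy_scale
                                 * float(_lognormal(rng, config.cv, ()))))
            for mi, m in enumerate(mods):
                pep = mod_pep[m]
                level = base_level[mi] * (2.0 ** effects[mi] if gi == 1 else 1.0)
                a_pep = pep_response[pep]
                rows.append(dict(sample_id=sample_id, peptide=pep, modification=m,
                                 channel="light",
                                 area=a_pep * mod_bias[m] * level
                                 * float(_lognormal(rng, config.cv, ()))))
                rows.append(dict(sample_id=sample_id, peptide=pep, modification=m,
                                 channel="heavy",
                                 area=a_pep * heavy_scale * mod_bias[m] * heavy_level[mi]
                                 * float(_lognormal(rng, config.cv, ()))))

    out = dict(
        areas=pd.DataFrame(rows),
        panel=panel,
        design=pd.DataFrame(design_rows),
        truth=pd.DataFrame(truth),
    )
    if out_dir is not None:
        d = Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        for name, df in out.items():
            _write(df, d / f"{name}.tsv")
    return out


# ---------------------------------------------------------------------------
# isotope tracing

TRACED_SPECIES = {
    # species_id: (measured-ion formula, tracer mass shift)
    "pyruvate": ("C3H4O3", 3),
    "lactate": ("C3H6O3", 3),
    "succinate": ("C4H6O4", 2),
    "H3K18_23ac": ("C47H84N14O15", 2),  # synthetic stand-in tryptic peptide ion
}


def forward_envelope(
    formula, fractions: Sequence[float], K: int, mode: str = "carbon"
) -> np.ndarray:
    """Forward model: observed envelope for planted isotopologue fractions.

    ``fractions[j]`` is the molar fraction of the species carrying j tracer
    atoms; the result is sum_j fractions[j] x natural envelope of that
    species (brute-force convolution). This is the model the tracing
    module's correction inverts.
    """
    fractions = np.asarray(fractions, dtype=float)
    A = correction_matrix(formula, K, len(fractions) - 1, mode=mode)
    return A @ fractions


def simulate_envelopes(
    config: SimulationConfig = SimulationConfig(),
    out_dir: Optional[str] = None,
    groups: Tuple[str, ...] = ("M0", "M1", "M2"),
    extra_margin: int = 3,
    species: Optional[Mapping[str, Tuple[str, int]]] = None,
) -> Dict[str, pd.DataFrame]:
    """Isotopologue envelope tables at the planted enrichment fractions.

    Each species/group/sample envelope is the natural-abundance forward
    convolution of a two-component mixture (1-f unlabeled, f fully
    tracer-shifted) scaled and perturbed by lognormal noise per peak.
    """
    rng = np.random.default_rng(config.seed)
    species_map = dict(species or TRACED_SPECIES)
    rows, truth, design_rows = [], [], []
    for group in groups:
        for inj in range(config.n_injections):
            sample_id = f"{group}_r{inj + 1}"
            design_rows.append(dict(sample_id=sample_id, group=group, injection=inj + 1))
            for sp_id, gf in config.enrichment_fractions.items():
                if group not in gf:
                    continue
                formula, shift = species_map[sp_id]
                f = float(gf[group])
                x = np.zeros(shift + 1)
                x[0], x[shift] = 1.0 - f, f
                K = shift + extra_margin
                env = forward_envelope(formula, x, K)
                scale = 10.0 ** rng.uniform(5.5, 6.5)
                noisy = env * scale * _lognormal(rng, config.envelope_cv, len(env))
                for k, inten in enumerate(noisy):
                    rows.append(dict(sample_id=sample_id, species_id=sp_id,
                                     formula=formula, m_offset=k,
                                     intensity=float(inten), label_shift=shift))
    for sp_id, gf in config.enrichment_fractions.items():
        for group, f in gf.items():
            if group in groups:
                truth.append(dict(species_id=sp_id, group=group, fraction=float(f)))

    out = dict(
        envelopes=pd.DataFrame(rows),
        design=pd.DataFrame(design_rows),
        truth=pd.DataFrame(truth),
    )
    if out_dir is not None:
        d = Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        for name, df in out.items():
            _write(df, d / f"{name}.tsv")
    return out


# ---------------------------------------------------------------------------
# TMT proteomics

def simulate_log2_matrix(
    n_proteins: int,
    n_effect: int,
    effect_log2: float,
    sd: float,
    seed: int,
    design: Optional[Mapping[str, str]] = None,
    group_b: str = "M2",
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Protein x channel log2 matrix with planted effects on ``group_b``.

    Returns (matrix, boolean truth vector of planted proteins). Used for
    SAM calibration at a controlled per-channel standard deviation.
    """
    from .proteomics import DEFAULT_CHANNEL_DESIGN, TMT6_CHANNELS

    design = dict(design or DEFAULT_CHANNEL_DESIGN)
    rng = np.random.default_rng(seed)
    base = rng.normal(20.0, 1.0, size=n_proteins)
    planted = np.zeros(n_proteins, dtype=bool)
    if n_effect:
        planted[rng.choice(n_proteins, size=n_effect, replace=False)] = True
    signs = rng.choice([-1.0, 1.0], size=n_proteins)
    vals = {}
    for ch in TMT6_CHANNELS:
        shift = np.where(planted & (design[ch] == group_b), signs * effect_log2, 0.0)
        vals[ch] = base + shift + rng.normal(0.0, sd, size=n_proteins)
    mat = pd.DataFrame(vals, index=[f"prot{i + 1:04d}" for i in range(n_proteins)])
    return mat, planted


def simulate_tmt(
    config: SimulationConfig = SimulationConfig(), out_dir: Optional[str] = None
) -> Dict[str, pd.DataFrame]:
    """PSM-level TMT6 reporter table with planted M2-vs-M1 effects.

    PSMs carry unique/shared flags and PEP values (a fraction fail the
    0.05 acceptance bound); reporter intensities follow the study's channel
    layout (126/127 M0, 128/129 M1, 130/131 M2).
    """
    from .proteomics import DEFAULT_CHANNEL_DESIGN, TMT6_CHANNELS

    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    base = rng.normal(20.0, 1.0, size=n)
    planted = np.zeros(n, dtype=bool)
    planted[rng.choice(n, size=min(config.n_effect_proteins, n), replace=False)] = True
    signs = rng.choice([-1.0, 1.0], size=n)

    rows, truth = [], []
    for i in range(n):
        pid = f"prot{i + 1:04d}"
        truth.append(dict(protein_group=pid, planted=bool(planted[i]),
                          effect_log2=float(signs[i] * config.effect_log2 * planted[i])))
        n_psm = int(rng.integers(1, config.max_psms_per_protein + 1))
        for k in range(n_psm):
            rep = {}
            for ch in TMT6_CHANNELS:
                shift = (signs[i] * config.effect_log2
                         if planted[i] and DEFAULT_CHANNEL_DESIGN[ch] == "M2" else 0.0)
                rep[f"r{ch}"] = float(
                    2.0 ** (base[i] + shift + rng.normal(0.0, config.channel_sd_log2))
                    / n_psm
                )
            pep = float(rng.beta(1.0, 30.0))  # mostly well below 0.05
            unique = bool(rng.random() < 0.9) or k == 0
            rows.append(dict(peptide=f"{pid}_psm{k + 1}", protein_group=pid,
                             unique=unique, pep=pep, **rep))

    out = dict(psms=pd.DataFrame(rows), truth=pd.DataFrame(truth))
    if out_dir is not None:
        d = Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        for name, df in out.items():
            _write(df, d / f"{name}.tsv")
    return out
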