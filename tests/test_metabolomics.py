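"""Feature matching at 5 ppm, IS assignment, quantification, volcano stats."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from msomics import chem
from msomics.chem import IonSpec
from msomics.metabolomics import (
    FeatureMatcher,
    assign_internal_standard,
    concentration_matrix,
    differential_volcano,
    expand_library,
    load_compound_library,
    load_standards,
    match_features,
    quantify_concentration,
    quantify_samples,
)
from msomics.synthetic import DEFAULT_STANDARDS

LIB = pd.DataFrame(
    [
        ("serine", "L-serine", "C3H7NO3", 1, 0, "low"),
        ("glycine", "glycine", "C2H5NO2", 1, 0, "high"),
        ("ornithine", "L-ornithine", "C5H12N2O2", 2, 0, "high"),
        ("succinate", "succinic acid", "C4H6O4", 0, 2, "tca"),
        ("malate", "malic acid", "C4H6O5", 0, 2, "tca"),
    ],
    columns=["compound_id", "name", "formula", "amine_sites", "carbonyl_sites", "rt_zone"],
)

SER_DANSYL_MH = 339.100919


def feat(mz, sample="s1", intensity=1e6):
    return pd.DataFrame(
        [dict(sample_id=sample, mz=mz, rt=10.0, intensity=intensity, charge=1)]
    )


class TestMatching:
    def test_exact_mass_accepted_at_zero_ppm(self):
        res = match_features(feat(SER_DANSYL_MH), LIB)
        assert res.loc[0, "compound_id"] == "serine"
        assert res.loc[0, "accepted"]
        assert res.loc[0, "ppm"] == pytest.approx(0.0, abs=0.01)

    def test_boundary_is_inclusive_at_5ppm(self):
        theo = chem.derivatized_mz("C3H7NO3", 1, "dansyl")
        exactly5 = theo * (1 + 5.0e-6)
        just_over = theo * (1 + 5.02e-6)
        assert match_features(feat(exactly5), LIB).loc[0, "accepted"]
        assert not match_features(feat(just_over), LIB).loc[0, "accepted"]

    def test_unmatched_feature_returned_not_dropped(self):
        res = match_features(feat(SER_DANSYL_MH * 1.01), LIB)
        assert len(res) == 1 and not res.loc[0, "accepted"]

    def test_empty_feature_list_gives_empty_result(self):
        res = match_features(pd.DataFrame(columns=["sample_id", "mz", "intensity"]), LIB)
        assert res.empty

    def test_malformed_library_formula_names_row(self):
        bad = LIB.copy()
        bad.loc[2, "formula"] = "C3H7Xq"
        with pytest.raises(ValueError, match="row 2"):
            load_compound_library(bad)

    def test_multi_amine_compound_expanded_over_site_counts(self):
        exp = expand_library(LIB)
        orn = exp[exp["compound_id"] == "ornithine"]
        assert sorted(orn["n_sites"]) == [1, 2]
        # the doubly dansylated state matches a feature at its m/z
        mz2 = chem.derivatized_mz("C5H12N2O2", 2, "dansyl")
        res = match_features(feat(mz2), LIB)
        assert res.loc[0, "compound_id"] == "ornithine"
        assert res.loc[0, "n_sites"] == 2

    def test_planted_jitter_recall(self):
        """+/-3 ppm perturbations all match; +/-7 ppm none (construction)."""
        rng = np.random.default_rng(0)
        exp = expand_library(LIB)
        for jitter, expect in [(3.0, True), (7.0, False)]:
            rows = []
            for _, e in exp.iterrows():
                sign = rng.choice([-1, 1])
                rows.append(dict(sample_id="s", mz=e["theoretical_mz"] * (1 + sign * jitter * 1e-6),
                                 rt=0.0, intensity=1.0, charge=1))
            res = match_features(pd.DataFrame(rows), LIB)
            assert res["accepted"].all() == expect
            if not expect:
                assert not res["accepted"].any()

    def test_tolerance_monotonicity(self, small_metabolome_sim):
        sim = small_metabolome_sim
        feats = sim["features"].head(200)
        at3 = match_features(feats, sim["library"], tol_ppm=3.0)
        at5 = match_features(feats, sim["library"], tol_ppm=5.0)
        accepted3 = set(at3[at3["accepted"]].index)
        accepted5 = set(at5[at5["accepted"]].index)
        assert accepted3 <= accepted5

    def test_matcher_requires_fit(self):
        with pytest.raises(RuntimeError):
            FeatureMatcher().transform(feat(SER_DANSYL_MH))

    def test_matcher_sklearn_params(self):
        m = FeatureMatcher(tol_ppm=3.0)
        assert m.get_params()["tol_ppm"] == 3.0
        m.set_params(tol_ppm=5.0)
        assert m.tol_ppm == 5.0


class TestInternalStandards:
    def test_zone_rule_low_serine_high_glycine(self):
        std = load_standards(DEFAULT_STANDARDS)
        assert assign_internal_standard("low", "dansyl", std) == "is_serine"
        assert assign_internal_standard("high", "dansyl", std) == "is_glycine"

    def test_obha_exact_analogue_then_malate_fallback(self):
        std = load_standards(DEFAULT_STANDARDS)
        assert assign_internal_standard("tca", "obha", std, "succinate") == "is_succinate"
        # no labeled citrate spiked -> malate IS
        assert assign_internal_standard("tca", "obha", std, "citrate") == "is_malate"

    def test_missing_zone_is_configuration_error(self):
        std = load_standards(DEFAULT_STANDARDS)
        with pytest.raises(ValueError, match="mid"):
            assign_internal_standard("mid", "dansyl", std)

    def test_nonpositive_amount_rejected(self):
        bad = DEFAULT_STANDARDS.copy()
        bad.loc[0, "amount_nmol"] = 0.0
        with pytest.raises(ValueError):
            load_standards(bad)


class TestQuantification:
    @pytest.mark.parametrize(
        "analyte, is_int, amount, mg, expected",
        [
            (2e6, 1e6, 1.0, 0.1, 20.0),
            (0.0, 1e6, 1.0, 0.1, 0.0),
            (2e6, 2e6, 1.0, 0.1, 10.0),  # doubling IS halves the result
        ],
    )
    def test_concentration_formula(self, analyte, is_int, amount, mg, expected):
        assert quantify_concentration(analyte, is_int, amount, mg) == expected

    def test_zero_is_intensity_flags_missing(self):
        assert np.isnan(quantify_concentration(1e6, 0.0, 1.0, 1.0))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            quantify_concentration(-1.0, 1e6, 1.0, 1.0)
        with pytest.raises(ValueError):
            quantify_concentration(1e6, 1e6, -1.0, 1.0)

    def test_global_rescaling_invariance(self, small_metabolome_sim):
        """Scaling every intensity of a sample leaves concentrations unchanged."""
        sim = small_metabolome_sim
        feats = sim["features"].copy()
        sample = feats["sample_id"].iloc[0]
        matches = match_features(feats, sim["library"])
        conc0 = quantify_samples(matches, feats, sim["standards"], sim["design"])
        scaled = feats.copy()
        scaled.loc[scaled["sample_id"] == sample, "intensity"] *= 7.3
        m2 = match_features(scaled, sim["library"])
        conc1 = quantify_samples(m2, scaled, sim["standards"], sim["design"])
        a = concentration_matrix(conc0)
        b = concentration_matrix(conc1)
        pd.testing.assert_frame_equal(a, b, rtol=1e-12)

    def test_planted_concentration_recovery(self, metabolome_sim):
        """CV 10%, n=8 injections: median relative error below 5%."""
        sim = metabolome_sim
        matches = match_features(sim["features"], sim["library"])
        conc = quantify_samples(matches, sim["features"], sim["standards"], sim["design"])
        mat = concentration_matrix(conc)
        truth = sim["truth"].pivot_table(
            index="compound_id", columns="group", values="concentration"
        )
        groups = sim["design"].set_index("sample_id")["group"]
        rec = mat.T.groupby(groups).mean().T
        rel = (rec / truth - 1).abs().to_numpy()
        assert np.nanmedian(rel) < 0.05


class TestVolcano:
    DESIGN = pd.DataFrame(
        dict(sample_id=[f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)],
             group=["A"] * 3 + ["B"] * 3)
    )

    def _mat(self, a, b):
        return pd.DataFrame([list(a) + list(b)], index=["c1"],
                            columns=self.DESIGN["sample_id"])

    def test_identical_groups_null_result(self):
        res = differential_volcano(self._mat([1, 2, 3], [1, 2, 3]), self.DESIGN, "A", "B")
        assert res.loc["c1", "log2fc"] == 0.0
        assert res.loc["c1", "p"] == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        d = pd.DataFrame(dict(sample_id=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)],
                              group=["A"] * 4 + ["B"] * 4))
        mat = pd.DataFrame([[10.0] * 4 + [20.0] * 4], index=["c1"], columns=d["sample_id"])
        res = differential_volcano(mat, d, "A", "B")
        assert res.loc["c1", "log2fc"] == 1.0
        assert np.isnan(res.loc["c1", "p"])
        assert not res.loc["c1", "plot_ok"]

    def test_matches_pooled_t_closed_form(self):
        """[9,10,11] vs [18,20,22]: t = 10 / sqrt(sp^2 * 2/3), sp^2 = 2.5."""
        res = differential_volcano(self._mat([9, 10, 11], [18, 20, 22]), self.DESIGN, "A", "B")
        expected_t = 10.0 / np.sqrt(2.5 * (2.0 / 3.0))
        assert res.loc["c1", "log2fc"] == pytest.approx(1.0)
        assert res.loc["c1", "t"] == pytest.approx(expected_t)
        assert res.loc["c1", "p"] == pytest.approx(
            2 * stats.t.sf(expected_t, df=4), rel=1e-9
        )

    def test_too_few_samples_per_group_rejected(self):
        d = pd.DataFrame(dict(sample_id=["a1", "b1", "b2"], group=["A", "B", "B"]))
        mat = pd.DataFrame([[1.0, 2.0, 3.0]], index=["c"], columns=d["sample_id"])
        with pytest.raises(ValueError):
            differential_volcano(mat, d, "A", "B")

    def test_bh_flag_adds_monotone_q(self):
        rng = np.random.default_rng(0)
        d = pd.DataFrame(dict(sample_id=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)],
                              group=["A"] * 4 + ["B"] * 4))
        mat = pd.DataFrame(rng.lognormal(0, 0.2, (50, 8)), columns=d["sample_id"])
        res = differential_volcano(mat, d, "A", "B", bh=True)
        assert (res["q"] >= res["p"] - 1e-12).all()

    def test_null_pvalues_uniform(self):
        """No-effect simulation: KS below the 1% critical value in >= 18/20 seeds."""
        design = pd.DataFrame(
            dict(sample_id=[f"{g}{i}" for g in "AB" for i in range(8)],
                 group=["A"] * 8 + ["B"] * 8)
        )
        crit = 1.6276 / np.sqrt(1000)
        sigma = np.sqrt(np.log(1.01))
        passed = 0
        seeds = range(20)
        for seed in seeds:
            rng = np.random.default_rng(seed)
            mat = pd.DataFrame(rng.lognormal(0, sigma, (1000, 16)),
                               columns=design["sample_id"])
            res = differential_volcano(mat, design, "A", "B")
            passed += stats.kstest(res["p"], "uniform").statistic < crit
        assert passed >= 18, f"uniformity held in {passed}/20 seeds {list(seeds)}"
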