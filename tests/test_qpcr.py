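"""qPCR ΔΔCt estimation, ANOVA with Šidák correction, effect classes."""

import numpy as np
import pandas as pd
import pytest

from crescan.qpcr import (
    analyze,
    anova_dunn_sidak,
    classify_effect,
    ddct_fold,
    delta_ct,
    sidak_adjust,
)
from crescan.simulate import simulate_qpcr


def _table(rows):
    return pd.DataFrame(
        rows, columns=["sample", "genotype", "gene", "replicate", "ct"]
    )


class TestDeltaCt:
    def test_arithmetic_mean_of_housekeeping_cts(self):
        table = _table(
            [
                ("s1", "wt", "hk1", 1, 20.0),
                ("s1", "wt", "hk2", 1, 21.0),
                ("s1", "wt", "hk3", 1, 22.0),
                ("s1", "wt", "target", 1, 25.0),
            ]
        )
        dct = delta_ct(table, ["hk1", "hk2", "hk3"])
        row = dct[dct["gene"] == "target"].iloc[0]
        assert row["delta_ct"] == pytest.approx(4.0)

    def test_geometric_mean_equivalence(self):
        """Subtracting the arithmetic mean of Ct equals normalizing by the
        geometric mean of the housekeeping quantities 2^-Ct."""
        hk_cts = [19.3, 21.7, 23.1]
        target = 26.4
        geo = np.prod([2.0**-c for c in hk_cts]) ** (1 / 3)
        expected = target - (-np.log2(geo))
        table = _table(
            [("s1", "wt", f"hk{i}", 1, c) for i, c in enumerate(hk_cts)]
            + [("s1", "wt", "t", 1, target)]
        )
        dct = delta_ct(table, ["hk0", "hk1", "hk2"])
        got = dct[dct["gene"] == "t"]["delta_ct"].iloc[0]
        assert got == pytest.approx(expected)

    def test_target_equal_to_summary_gives_zero(self):
        table = _table(
            [("s1", "wt", "hk", 1, 21.0), ("s1", "wt", "t", 1, 21.0)]
        )
        dct = delta_ct(table, ["hk"])
        assert dct[dct["gene"] == "t"]["delta_ct"].iloc[0] == 0.0

    def test_missing_housekeeping_rejected(self):
        table = _table([("s1", "wt", "t", 1, 20.0)])
        with pytest.raises(ValueError):
            delta_ct(table, ["hk"])

    def test_technical_replicates_averaged(self):
        table = _table(
            [
                ("s1", "wt", "hk", 1, 20.0),
                ("s1", "wt", "hk", 2, 22.0),
                ("s1", "wt", "t", 1, 24.0),
                ("s1", "wt", "t", 2, 26.0),
            ]
        )
        dct = delta_ct(table, ["hk"])
        assert dct[dct["gene"] == "t"]["delta_ct"].iloc[0] == pytest.approx(4.0)


class TestFold:
    def _dct(self, wt_vals, mut_vals, gene="t"):
        rows = [
            {"sample": f"w{i}", "genotype": "wt", "gene": gene, "delta_ct": v}
            for i, v in enumerate(wt_vals)
        ] + [
            {"sample": f"m{i}", "genotype": "mut", "gene": gene, "delta_ct": v}
            for i, v in enumerate(mut_vals)
        ]
        return pd.DataFrame(rows)

    @pytest.mark.parametrize(
        "shift, expected_fold", [(1.0, 0.5), (0.0, 1.0), (-2.0, 4.0)]
    )
    def test_fold_is_two_to_minus_ddct(self, shift, expected_fold):
        dct = self._dct([3.0, 3.5, 4.0], [3.0 + shift, 3.5 + shift, 4.0 + shift])
        out = ddct_fold(dct, "wt")
        mut = out[out["genotype"] == "mut"].iloc[0]
        assert mut["fold"] == pytest.approx(expected_fold)

    def test_control_fold_is_one_by_construction(self):
        dct = self._dct([2.0, 2.4], [5.0, 5.2])
        out = ddct_fold(dct, "wt")
        wt = out[out["genotype"] == "wt"].iloc[0]
        assert wt["fold"] == pytest.approx(1.0)

    def test_gene_absent_in_control_rejected(self):
        dct = pd.DataFrame(
            [
                {"sample": "m1", "genotype": "mut", "gene": "t", "delta_ct": 1.0},
                {"sample": "w1", "genotype": "wt", "gene": "u", "delta_ct": 1.0},
            ]
        )
        with pytest.raises(ValueError):
            ddct_fold(dct, "wt")


class TestAnovaSidak:
    def test_sidak_closed_form(self):
        assert sidak_adjust(0.01, 3) == pytest.approx(0.029701)
        assert sidak_adjust(0.2, 1) == pytest.approx(0.2)
        assert sidak_adjust(0.0, 5) == 0.0

    def test_adjustment_bounds_and_monotonicity(self):
        ps = np.linspace(0, 1, 21)
        adj = sidak_adjust(ps, 4)
        assert np.all(adj >= ps)
        assert np.all(adj <= 1.0)
        assert np.all(np.diff(adj) >= 0)
        small = ps[ps < 0.05]
        assert np.all(sidak_adjust(small, 4) <= 4 * small + 1e-12)

    def test_anova_matches_scipy_with_family_correction(self):
        rng = np.random.default_rng(2)
        rows = []
        for gene in ("a", "b"):
            for geno in ("wt", "mut"):
                shift = 1.0 if (gene, geno) == ("a", "mut") else 0.0
                for i in range(5):
                    rows.append(
                        {
                            "sample": f"{geno}{i}",
                            "genotype": geno,
                            "gene": gene,
                            "delta_ct": rng.normal(shift, 0.2),
                        }
                    )
        dct = pd.DataFrame(rows)
        out = anova_dunn_sidak(dct, family_size=2)
        from scipy.stats import f_oneway

        for gene in ("a", "b"):
            sub = dct[dct["gene"] == gene]
            p = f_oneway(
                sub[sub["genotype"] == "wt"]["delta_ct"],
                sub[sub["genotype"] == "mut"]["delta_ct"],
            ).pvalue
            row = out[out["gene"] == gene].iloc[0]
            assert row["p_value"] == pytest.approx(p)
            assert row["p_adjusted"] == pytest.approx(1 - (1 - p) ** 2)

    def test_zero_variance_equal_means_p_one(self):
        dct = pd.DataFrame(
            [
                {"sample": s, "genotype": g, "gene": "t", "delta_ct": 1.0}
                for g in ("wt", "mut")
                for s in (f"{g}1", f"{g}2")
            ]
        )
        out = anova_dunn_sidak(dct, family_size=3)
        assert out["p_value"].iloc[0] == 1.0


class TestClassification:
    def _results(self, fold, p_adj):
        return pd.DataFrame(
            [{"gene": "t", "genotype": "mut", "fold": fold, "p_adjusted": p_adj}]
        )

    @pytest.mark.parametrize(
        "fold, p_adj, expected",
        [
            (0.01, 1e-6, "abolished"),
            (0.4, 0.001, "reduced"),
            (0.95, 0.3, "spared"),
            (0.01, 0.5, "spared"),  # large effect but not significant
        ],
    )
    def test_effect_classes(self, fold, p_adj, expected):
        out = classify_effect(self._results(fold, p_adj))
        assert out["effect"].iloc[0] == expected


class TestClosedLoop:
    def test_noiseless_folds_recovered_exactly(self):
        table, _ = simulate_qpcr(
            {"t1": {"mutant": 0.5}, "t2": {"mutant": 0.1}},
            sigma=0.0, mouse_sigma=0.0, seed=4,
        )
        out = analyze(table, ["Bgus", "Gnal", "Ncam"], "wt")
        for gene, fold in (("t1", 0.5), ("t2", 0.1)):
            row = out[(out["gene"] == gene) & (out["genotype"] == "mutant")]
            assert row["fold"].iloc[0] == pytest.approx(fold)

    def test_housekeeping_self_normalization_fold_one(self):
        table, _ = simulate_qpcr({"t": {"mutant": 0.2}}, sigma=0.0, seed=8)
        out = analyze(table, ["Bgus", "Gnal", "Ncam"], "wt")
        for hk in ("Bgus", "Gnal", "Ncam"):
            rows = out[out["gene"] == hk]
            assert np.allclose(rows["fold"], 1.0)
            assert set(rows["effect"]) == {"spared"}

    def test_fold_one_everywhere_all_spared(self):
        table, _ = simulate_qpcr({"t1": {"mutant": 1.0}}, sigma=0.2, seed=3)
        out = analyze(table, ["Bgus", "Gnal", "Ncam"], "wt")
        assert set(out["effect"]) == {"spared"}

    def test_fold_recovery_within_twenty_percent(self):
        """Median estimated fold over seeded replicates is within +-20% of
        the truth for folds {1, 0.5, 0.1, 0.01} at Ct noise sigma = 0.2."""
        true_folds = [1.0, 0.5, 0.1, 0.01]
        genes = {f"g{i}": {"mutant": f} for i, f in enumerate(true_folds)}
        estimates = {g: [] for g in genes}
        for rep in range(200):
            table, _ = simulate_qpcr(genes, sigma=0.2, seed=50_000 + rep)
            dct = delta_ct(table, ["Bgus", "Gnal", "Ncam"])
            folds = ddct_fold(dct, "wt")
            for g in genes:
                row = folds[(folds["gene"] == g) & (folds["genotype"] == "mutant")]
                estimates[g].append(row["fold"].iloc[0])
        for (g, spec), true in zip(genes.items(), true_folds):
            med = float(np.median(estimates[g]))
            assert abs(med - true) / true <= 0.2, (g, med, true)

    def test_abolished_gene_detected(self):
        from crescan.simulate import ABOLISHED_FLOOR

        table, _ = simulate_qpcr(
            {"taar_like": {"mutant": ABOLISHED_FLOOR}, "control_or": {"mutant": 1.0}},
            sigma=0.2, seed=6,
        )
        out = analyze(table, ["Bgus", "Gnal", "Ncam"], "wt")
        mut = out[out["genotype"] == "mutant"].set_index("gene")
        assert mut.loc["taar_like", "effect"] == "abolished"
        assert mut.loc["control_or", "effect"] == "spared"
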