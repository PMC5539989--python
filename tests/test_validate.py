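import warnings

import numpy as np
import pytest
from scipy import optimize, stats

import varcallkit as vk
from varcallkit.model import Label, ModelSpec
from varcallkit.validate import (
    BENIGN,
    DAMAGING,
    MISSING,
    PredictorCalls,
    ReferencePanel,
    binarize_predictor,
    binary_call,
    clopper_pearson,
    concordance,
    confusion_metrics,
    loo_cv,
)


def _cp_oracle(x: int, n: int, level: float = 0.95):
    """Brute-force inversion of the binomial CDF (independent oracle)."""
    alpha = 1 - level
    if x == 0:
        lower = 0.0
    else:
        lower = optimize.brentq(
            lambda p: stats.binom.sf(x - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12,
            xtol=1e-12,
        )
    if x == n:
        upper = 1.0
    else:
        upper = optimize.brentq(
            lambda p: stats.binom.cdf(x, n, p) - alpha / 2, 1e-12, 1 - 1e-12,
            xtol=1e-12,
        )
    return lower, upper


class TestClopperPearson:
    def test_matches_brute_force_inversion_everywhere(self):
        for n in range(1, 51):
            for x in range(n + 1):
                lo, hi = clopper_pearson(x, n)
                olo, ohi = _cp_oracle(x, n)
                assert lo == pytest.approx(olo, abs=1e-6), (x, n)
                assert hi == pytest.approx(ohi, abs=1e-6), (x, n)

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for x, n in [(13, 13), (20, 20), (7, 19), (0, 5)]:
            lo, hi = clopper_pearson(x, n)
            slo, shi = proportion_confint(x, n, alpha=0.05, method="beta")
            assert lo == pytest.approx(slo, abs=1e-10)
            assert hi == pytest.approx(shi, abs=1e-10)

    def test_all_successes_closed_form(self):
        # lower bound for x = n is (alpha/2)^(1/n)
        lo, hi = clopper_pearson(13, 13)
        assert hi == 1.0
        assert lo == pytest.approx(0.025 ** (1 / 13), abs=1e-12)
        assert lo == pytest.approx(0.753, abs=5e-4)
        lo20, _ = clopper_pearson(20, 20)
        assert lo20 == pytest.approx(0.832, abs=5e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)
        with pytest.raises(ValueError):
            clopper_pearson(-1, 4)


class TestBinaryCall:
    def test_strict_inequality(self):
        assert binary_call(0.99) is Label.PATHOGENIC
        assert binary_call(0.5) is Label.NEUTRAL
        assert binary_call(0.49) is Label.NEUTRAL
        assert binary_call(0.51) is Label.PATHOGENIC

    def test_domain(self):
        with pytest.raises(ValueError):
            binary_call(1.2)
        with pytest.raises(ValueError):
            binary_call(0.5, threshold=1.0)


def _panel(n_path, n_neut):
    entries = [(f"P{i}", Label.PATHOGENIC) for i in range(n_path)]
    entries += [(f"N{i}", Label.NEUTRAL) for i in range(n_neut)]
    return ReferencePanel(entries=tuple(entries))


class TestConfusionMetrics:
    def test_perfect_panel_reproduces_printed_lower_bounds(self):
        panel = _panel(13, 20)
        calls = [(v, t) for v, t in panel.entries]
        report = confusion_metrics(calls, panel)
        assert report.sensitivity.point == 1.0
        assert report.specificity.point == 1.0
        assert report.sensitivity.lower == pytest.approx(0.753, abs=5e-4)
        assert report.specificity.lower == pytest.approx(0.832, abs=5e-4)
        assert report.accuracy.point == 1.0

    def test_half_correct_sensitivity(self):
        panel = _panel(4, 0)
        calls = [("P0", Label.PATHOGENIC), ("P1", Label.PATHOGENIC),
                 ("P2", Label.NEUTRAL), ("P3", Label.NEUTRAL)]
        report = confusion_metrics(calls, panel)
        assert report.sensitivity.point == 0.5
        assert report.tp == 2 and report.fn == 2

    def test_empty_class_reported_undefined(self):
        panel = _panel(0, 3)
        calls = [(f"N{i}", Label.NEUTRAL) for i in range(3)]
        report = confusion_metrics(calls, panel)
        assert not report.sensitivity.defined
        assert report.specificity.point == 1.0

    def test_row_order_invariance_and_accuracy_identity(self):
        panel = _panel(3, 3)
        calls = [("P0", Label.PATHOGENIC), ("P1", Label.NEUTRAL),
                 ("P2", Label.PATHOGENIC), ("N0", Label.NEUTRAL),
                 ("N1", Label.PATHOGENIC), ("N2", Label.NEUTRAL)]
        a = confusion_metrics(calls, panel)
        b = confusion_metrics(list(reversed(calls)), panel)
        assert (a.tp, a.fp, a.tn, a.fn) == (b.tp, b.fp, b.tn, b.fn)
        n = a.tp + a.fp + a.tn + a.fn
        assert a.accuracy.point == (a.tp + a.tn) / n

    def test_missing_call_is_error(self):
        panel = _panel(1, 1)
        with pytest.raises(KeyError):
            confusion_metrics([("P0", Label.PATHOGENIC)], panel)

    def test_lower_leq_point_leq_upper(self):
        panel = _panel(5, 5)
        calls = [("P0", Label.PATHOGENIC), ("P1", Label.PATHOGENIC),
                 ("P2", Label.PATHOGENIC), ("P3", Label.NEUTRAL),
                 ("P4", Label.NEUTRAL)] + [
            (f"N{i}", Label.NEUTRAL) for i in range(5)]
        r = confusion_metrics(calls, panel)
        for m in (r.sensitivity, r.specificity, r.ppv, r.npv, r.accuracy):
            assert m.lower <= m.point <= m.upper


class TestBinarizePredictor:
    @pytest.mark.parametrize(
        "tool, code, expected",
        [
            ("SIFT", "D", DAMAGING),
            ("SIFT", "T", BENIGN),
            ("PolyPhen2", "P", DAMAGING),  # "possibly damaging" pooled
            ("PolyPhen2", "B", BENIGN),
            ("MutationTaster2", "A", DAMAGING),
            ("MutationTaster2", "N", BENIGN),
        ],
    )
    def test_code_maps(self, tool, code, expected):
        calls = binarize_predictor({"V1": code}, tool)
        assert calls.calls["V1"] == expected

    def test_cadd_cutoff(self):
        calls = binarize_predictor({"V1": 25.0, "V2": 12.0}, "CADD")
        assert calls.calls == {"V1": DAMAGING, "V2": BENIGN}

    def test_missing_value_tallied(self):
        calls = binarize_predictor({"V1": None, "V2": float("nan")}, "SIFT")
        assert calls.calls == {"V1": MISSING, "V2": MISSING}

    def test_unknown_code_or_tool_error(self):
        with pytest.raises(ValueError, match="Q"):
            binarize_predictor({"V1": "Q"}, "SIFT")
        with pytest.raises(KeyError):
            binarize_predictor({"V1": "D"}, "NotATool")


class TestConcordance:
    def _fclass_calls(self):
        return [("A", 1), ("B", 2), ("C", 3), ("D", 4), ("E", 5)]

    def test_perfect_agreement_has_no_off_diagonal(self):
        pred = PredictorCalls(
            tool="SIFT", raw={},
            calls={"A": BENIGN, "B": BENIGN, "C": DAMAGING,
                   "D": DAMAGING, "E": DAMAGING},
        )
        table = concordance(self._fclass_calls(), [pred])
        by_group = table.set_index("group")
        assert by_group.loc["fClass1-2", "frac_damaging"] == 0.0
        assert by_group.loc["fClass4-5", "frac_benign"] == 0.0

    def test_all_damaging_predictor_shows_discordance(self):
        pred = PredictorCalls(
            tool="CADD", raw={},
            calls={v: DAMAGING for v, _ in self._fclass_calls()},
        )
        table = concordance(self._fclass_calls(), [pred])
        row = table[(table["group"] == "fClass1-2")].iloc[0]
        assert row["frac_damaging"] == 1.0

    def test_fractions_sum_to_one_without_missing(self):
        pred = PredictorCalls(
            tool="SIFT", raw={},
            calls={"A": DAMAGING, "B": BENIGN, "C": BENIGN,
                   "D": DAMAGING, "E": BENIGN},
        )
        table = concordance(self._fclass_calls(), [pred])
        for _, row in table.iterrows():
            assert row["frac_damaging"] + row["frac_benign"] == pytest.approx(1.0)

    def test_zero_overlap_rejected(self):
        pred = PredictorCalls(tool="SIFT", raw={}, calls={})
        with pytest.raises(ValueError):
            concordance(self._fclass_calls(), [pred])


class TestLooCV:
    def test_one_refit_per_panel_variant_and_error_on_absent(self, small_sim):
        _, dataset, truth, labels = small_sim
        known = {v: lab for v, lab in labels.mapping.items()
                 if lab is not Label.UNKNOWN and v not in ("WT", "NEG_CONTROL")}
        panel = ReferencePanel(entries=tuple(known.items()))
        spec = ModelSpec(chains=2, iterations=500, burn_in=250, seed=17)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = loo_cv(dataset, panel, spec)
        assert len(res) == len(panel.variants)
        assert set(res["variant"]) == set(panel.variants)
        # masked variants land on the correct side of 0.5
        for _, row in res.iterrows():
            if row["truth"] == "PATHOGENIC":
                assert row["prdel_loo"] > 0.5
            else:
                assert row["prdel_loo"] < 0.5

        bad = ReferencePanel(entries=(("Z9999Z", Label.NEUTRAL),))
        with pytest.raises(KeyError):
            loo_cv(dataset, bad, spec)

    def test_overlapping_components_degrade_metrics(self):
        # separation of 1 component SD: the exercise must report imperfect
        # classification rather than clamp to 1.0
        config = vk.GeneratorConfig(
            n_variants=24, n_labeled=12, mu1=-0.25, tau0=0.25, tau1=0.25,
            seed=29,
        )
        dataset, truth, labels = vk.generate(config)
        known = {v: lab for v, lab in labels.mapping.items()
                 if lab is not Label.UNKNOWN and v not in ("WT", "NEG_CONTROL")}
        panel = ReferencePanel(entries=tuple(known.items()))
        spec = ModelSpec(chains=2, iterations=500, burn_in=250, seed=31)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = loo_cv(dataset, panel, spec)
        calls = [(v, binary_call(p)) for v, p in
                 zip(res["variant"], res["prdel_loo"])]
        report = confusion_metrics(calls, panel)
        assert report.accuracy.point < 1.0

    def test_duplicate_panel_variant_rejected(self):
        with pytest.raises(ValueError):
            ReferencePanel(entries=(("A1A2G", Label.NEUTRAL),
                                    ("A1A2G", Label.NEUTRAL)))
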