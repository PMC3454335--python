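"""Reporter-screen workflow: normalization, selection, confirmation."""

import numpy as np
import pandas as pd
import pytest

from exoreg import simulate as sim
from exoreg.core import DataError
from exoreg.screen import (
    classify_call,
    confirm_rounds,
    normalize_screen,
    relative_activity,
    run_screen,
    select_candidates,
)
from exoreg.stats import pearson_r


def make_table(activities_by_batch, role="experimental", enzyme="Sau3AI"):
    rows = []
    for batch, acts in activities_by_batch.items():
        for i, a in enumerate(acts):
            rows.append({"clone_id": f"{batch}_{i}", "batch_id": batch,
                         "enzyme": enzyme, "well_role": role,
                         "relative_activity": float(a)})
    return pd.DataFrame(rows)


class TestRelativeActivity:
    def test_log_ratio(self):
        assert relative_activity(1000, 100) == pytest.approx(1.0)
        assert relative_activity(50, 5000) == pytest.approx(-2.0)

    def test_non_positive_rejected(self):
        with pytest.raises(DataError):
            relative_activity(100, 0)


class TestNormalizeScreen:
    def test_identical_plates_unchanged(self):
        t = make_table({"P1": [0.1, 0.2, 0.3], "P2": [0.1, 0.2, 0.3]})
        out = normalize_screen(t)
        np.testing.assert_allclose(out["normalized_activity"],
                                   out["relative_activity"])

    def test_constant_offset_removed(self, rng):
        base = rng.normal(size=30)
        t = make_table({"P1": base, "P2": base + 0.7})
        out = normalize_screen(t)
        a = np.sort(out.loc[out.batch_id == "P1", "normalized_activity"])
        b = np.sort(out.loc[out.batch_id == "P2", "normalized_activity"])
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_enzyme_groups_normalized_separately(self, rng):
        sau = make_table({"P1": rng.normal(0, 1, 20),
                          "P2": rng.normal(0, 1, 20)}, enzyme="Sau3AI")
        alu = make_table({"P3": rng.normal(3, 1, 20),
                          "P4": rng.normal(3, 1, 20)}, enzyme="AluI")
        out = normalize_screen(pd.concat([sau, alu], ignore_index=True))
        m_sau = out.loc[out.enzyme == "Sau3AI", "normalized_activity"].mean()
        m_alu = out.loc[out.enzyme == "AluI", "normalized_activity"].mean()
        assert m_alu - m_sau > 2.0  # separate normalization keeps groups apart

    def test_single_batch_passes_through_with_warning(self):
        t = make_table({"P1": [0.1, 0.2, 0.3]})
        with pytest.warns(UserWarning, match="single batch"):
            out = normalize_screen(t)
        np.testing.assert_allclose(out["normalized_activity"],
                                   t["relative_activity"])

    def test_controls_mapped_through_not_in_reference(self, rng):
        # two plates offset by a constant; the control well should move with
        # its plate's mapping but not distort the experimental reference
        base = np.linspace(-1, 1, 21)
        t = pd.concat([
            make_table({"P1": base, "P2": base + 0.5}),
            pd.DataFrame([{"clone_id": "ctrl", "batch_id": "P2",
                           "enzyme": "control", "well_role": "promoter_only",
                           "relative_activity": 0.5}]),
        ], ignore_index=True)
        out = normalize_screen(t)
        ctrl = out.loc[out.well_role == "promoter_only",
                       "normalized_activity"].iloc[0]
        # both plates map onto the common reference (offset +0.25, halfway
        # between the two plates), so P2's median well lands at 0.25
        assert ctrl == pytest.approx(0.25, abs=1e-9)
        # and the experimental reference was not distorted by the control
        exp2 = out.loc[(out.batch_id == "P2")
                       & (out.well_role == "experimental"),
                       "normalized_activity"]
        assert np.median(exp2) == pytest.approx(0.25, abs=1e-9)


class TestSelectCandidates:
    def test_constant_activities_select_nothing(self):
        t = make_table({"P1": [0.5] * 10})
        with pytest.warns(UserWarning, match="zero spread"):
            assert select_candidates(t) == set()

    def test_gaussian_tail_fraction(self, rng):
        t = make_table({"P1": rng.normal(size=10000)})
        frac = len(select_candidates(t)) / 10000
        assert frac == pytest.approx(0.0455, abs=0.01)

    def test_outlier_selected(self, rng):
        acts = list(rng.normal(size=99)) + [10.0]
        t = make_table({"P1": acts})
        assert "P1_99" in select_candidates(t)


def round_table(clone_acts: dict, n_ref: int = 8, ref_level: float = 0.0,
                sd: float = 0.0, rng=None):
    rows = []
    for cid, acts in clone_acts.items():
        for a in acts:
            rows.append({"clone_id": cid, "batch_id": "r", "enzyme": "Sau3AI",
                         "well_role": "experimental",
                         "firefly": 1000 * 10 ** a, "renilla": 1000.0})
    for k in range(n_ref):
        a = ref_level if rng is None else ref_level + rng.normal(0, sd)
        rows.append({"clone_id": f"po{k}", "batch_id": "r", "enzyme": "control",
                     "well_role": "promoter_only",
                     "firefly": 1000 * 10 ** a, "renilla": 1000.0})
    return pd.DataFrame(rows)


class TestConfirmRounds:
    def test_strong_enhancer_confirmed(self):
        r1 = round_table({"c1": [1.0, 1.01, 0.99]})
        r2 = round_table({"c1": [1.0, 1.02, 0.98, 1.0, 1.01, 0.99, 1.0, 1.0]})
        calls = confirm_rounds({"c1"}, r1, r2)
        assert calls["c1"].call == "enhancer"
        assert calls["c1"].q2 < 1e-6
        assert calls["c1"].round1.df == 2 and calls["c1"].round2.df == 7

    def test_replicates_at_reference_not_confirmed(self):
        r1 = round_table({"c1": [0.001, -0.002, 0.0005]})
        r2 = round_table({"c1": [0.0] * 8})
        calls = confirm_rounds({"c1"}, r1, r2)
        assert calls["c1"].call == "not_confirmed"

    def test_sign_flip_between_rounds_not_confirmed(self):
        r1 = round_table({"c1": [1.0, 1.01, 0.99]})
        r2 = round_table({"c1": [-1.0, -1.01, -0.99, -1.0, -1.0, -1.0, -1.0,
                                 -1.0]})
        calls = confirm_rounds({"c1"}, r1, r2)
        assert calls["c1"].call == "not_confirmed"
        assert any("sign flip" in n for n in calls["c1"].notes)

    def test_zero_variance_replicates_flagged(self):
        r1 = round_table({"c1": [1.0, 1.0, 1.0]})
        r2 = round_table({"c1": [1.0] * 8})
        calls = confirm_rounds({"c1"}, r1, r2)
        assert calls["c1"].call == "not_confirmed"
        assert any("zero variance" in n for n in calls["c1"].notes)


class TestClassifyCall:
    def test_direction(self):
        assert classify_call(1.0, 0.0) == "enhancer"
        assert classify_call(-1.0, 0.0) == "silencer"


class TestRunScreen:
    def test_stage_counts_telescope(self):
        s = sim.simulate_screen(sim.ScreenConfig(n_clones=300, n_plates=6),
                                seed=21)
        _, report = run_screen(s.plates, s.round1, s.round2)
        assert report["screened"] >= report["selected"] >= \
            report["exon_retained"] >= report["round1_pass"] >= \
            report["round2_pass"]
        assert report["round2_pass"] == report["enhancers"] + report["silencers"]

    def test_recovery_on_default_benchmark(self):
        # quick sanity at 3 seeds; the 50-seed bound lives in the
        # acceptance suite
        tp = fp = n_spiked = 0
        for seed in range(3):
            s = sim.simulate_screen(seed=seed)
            calls, _ = run_screen(s.plates, s.round1, s.round2)
            truth = s.truth.set_index("clone_id")
            spiked = set(truth.index[truth.true_class != "neutral"])
            conf = {c for c, call in calls.items()
                    if call.call != "not_confirmed"}
            tp += len(conf & spiked)
            fp += len(conf - spiked)
            n_spiked += len(spiked)
        assert tp / n_spiked >= 0.85
        assert fp / max(tp + fp, 1) <= 0.1

    def test_null_screen_confirms_nothing(self):
        cfg = sim.ScreenConfig(n_enhancers=0, n_silencers=0)
        total = 0
        for seed in range(3):
            s = sim.simulate_screen(cfg, seed=seed)
            _, report = run_screen(s.plates, s.round1, s.round2)
            total += report["round2_pass"]
        assert total <= 1

    def test_confirmed_classes_match_truth(self):
        s = sim.simulate_screen(seed=22)
        calls, _ = run_screen(s.plates, s.round1, s.round2)
        truth = s.truth.set_index("clone_id")
        for cid, call in calls.items():
            if call.call != "not_confirmed" and \
                    truth.loc[cid, "true_class"] != "neutral":
                assert call.call == truth.loc[cid, "true_class"]


def test_duplicate_replicates_perfectly_correlated(rng):
    # degenerate bound of the replicate-consistency check: identical
    # replicate vectors have Pearson r exactly 1
    x = rng.normal(size=50)
    assert pearson_r(x, x.copy()).statistic == pytest.approx(1.0)
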