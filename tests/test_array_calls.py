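"""Array caller: runs, promoter windows, extraction rules, patient calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from escapex.array_calls import (
    assign_promoter_probes,
    call_patient_abnormalities,
    concordance,
    extract_escape_candidates,
    extract_inactivated_candidates,
    max_run,
    selected_genes,
)
from escapex.model import BetaMatrix, ConfigurationError, GeneAnnotation, InputError

from conftest import build_matrix


def brute_force_max_run(flags):
    best_len, best_start = 0, None
    for i in range(len(flags)):
        for j in range(i, len(flags)):
            if all(flags[i : j + 1]) and (j - i + 1) > best_len:
                best_len, best_start = j - i + 1, i
    return best_len, best_start


class TestMaxRun:
    @pytest.mark.parametrize(
        "flags,expected",
        [
            ([], (0, None)),
            ([False, False], (0, None)),
            ([True, False, True, True], (2, 2)),
            ([True, True, False, True, True], (2, 0)),  # tie -> smallest start
            ([True] * 5, (5, 0)),
        ],
    )
    def test_examples(self, flags, expected):
        assert max_run(flags) == expected

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(st.lists(st.booleans(), max_size=15))
    def test_matches_bruteforce(self, flags):
        assert max_run(flags) == brute_force_max_run(flags)


class TestAssignPromoterProbes:
    def _genes(self, *tss):
        return [
            GeneAnnotation(f"g{i}", t, "+", "unknown") for i, t in enumerate(tss)
        ]

    def test_window_closed_on_both_ends(self):
        positions = pd.Series(
            [4000, 5000, 6000, 6001], index=["a", "b", "c", "d"], name="pos"
        )
        (ps,) = assign_promoter_probes(self._genes(5000), positions, window=1000)
        assert ps.probe_ids == ("a", "b", "c")  # 6001 is outside, 4000/6000 inside

    def test_probe_may_serve_overlapping_windows(self):
        positions = pd.Series([1500], index=["a"], name="pos")
        sets = assign_promoter_probes(self._genes(1000, 2000), positions, window=1000)
        assert all(ps.probe_ids == ("a",) for ps in sets)

    def test_gene_without_probes_gets_empty_set(self):
        positions = pd.Series([100], index=["a"], name="pos")
        sets = assign_promoter_probes(self._genes(50_000), positions)
        assert len(sets[0]) == 0

    def test_random_layouts_match_double_loop(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n_genes, n_probes = rng.integers(1, 10), rng.integers(0, 30)
            tss = np.sort(rng.choice(50_000, size=n_genes, replace=False))
            pos = np.sort(rng.choice(50_000, size=n_probes, replace=False))
            ids = [f"p{i}" for i in range(n_probes)]
            genes = [
                GeneAnnotation(f"g{i}", int(t), "+", "unknown")
                for i, t in enumerate(tss)
            ]
            sets = assign_promoter_probes(
                genes, pd.Series(pos, index=ids, name="pos"), window=1000
            )
            for g, ps in zip(genes, sets):
                expected = tuple(
                    ids[k]
                    for k in range(n_probes)
                    if g.tss - 1000 <= pos[k] <= g.tss + 1000
                )
                assert ps.probe_ids == expected

    def test_zero_window_rejected(self):
        with pytest.raises(ConfigurationError):
            assign_promoter_probes([], pd.Series(dtype=int), window=0)


def two_probe_sets(gene_id="g1"):
    return assign_promoter_probes(
        [GeneAnnotation(gene_id, 200, "+", "unknown")],
        pd.Series([100, 200], index=["p1", "p2"], name="pos"),
    )


class TestExtraction:
    def test_uniform_low_betas_select_escape(self, four_controls):
        mat = build_matrix({"p1": [0.05] * 4, "p2": [0.05] * 4}, four_controls)
        out = extract_escape_candidates(mat, two_probe_sets())
        assert selected_genes(out) == ["g1"]

    def test_female_mean_above_bound_blocks_escape(self, four_controls):
        mat = build_matrix({"p1": [0.05, 0.05, 0.16, 0.16]} | {"p2": [0.05, 0.05, 0.16, 0.16]}, four_controls)
        out = extract_escape_candidates(mat, two_probe_sets())
        assert selected_genes(out) == []

    def test_all_controls_bound_is_strict(self, four_controls):
        # one control exactly at 0.24 fails the "< 0.24" predicate
        mat = build_matrix({"p1": [0.05, 0.05, 0.24, 0.05], "p2": [0.05] * 4}, four_controls)
        out = extract_escape_candidates(mat, two_probe_sets())
        assert selected_genes(out) == []

    def test_inactivated_pattern_selected(self, four_controls):
        mat = build_matrix(
            {"p1": [0.05, 0.05, 0.45, 0.45], "p2": [0.05, 0.05, 0.45, 0.45]},
            four_controls,
        )
        out = extract_inactivated_candidates(mat, two_probe_sets())
        assert selected_genes(out) == ["g1"]

    def test_female_mean_at_half_blocks_inactivated(self, four_controls):
        mat = build_matrix(
            {"p1": [0.05, 0.05, 0.55, 0.55], "p2": [0.05, 0.05, 0.55, 0.55]},
            four_controls,
        )
        out = extract_inactivated_candidates(mat, two_probe_sets())
        assert selected_genes(out) == []

    def test_single_probe_gene_ineligible_not_negative(self, four_controls):
        mat = build_matrix({"p1": [0.05] * 4}, four_controls)
        sets = assign_promoter_probes(
            [GeneAnnotation("g1", 100, "+", "unknown")],
            pd.Series([100], index=["p1"], name="pos"),
        )
        out = extract_escape_candidates(mat, sets)
        row = out.set_index("gene_id").loc["g1"]
        assert not row["eligible"] and not row["selected"]

    def test_patient_columns_never_change_extraction(self, controls_and_patient):
        rows = {"p1": [0.05, 0.05, 0.45, 0.45, 0.99], "p2": [0.05, 0.05, 0.45, 0.45, 0.99]}
        mat = build_matrix(rows, controls_and_patient)
        ctrl = BetaMatrix(
            values=mat.values.drop(columns="P1"),
            positions=mat.positions,
            samples=mat.samples.drop(index="P1"),
        )
        a = extract_inactivated_candidates(mat, two_probe_sets())
        b = extract_inactivated_candidates(ctrl, two_probe_sets())
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_controls_rejected(self):
        samples = [("M1", "M", "adult", "control"), ("F1", "F", "adult", "control")]
        mat = build_matrix({"p1": [0.05, 0.05]}, samples)
        with pytest.raises(ConfigurationError):
            extract_escape_candidates(mat, two_probe_sets())


class TestConcordance:
    def test_worked_examples(self):
        ann = {f"e{i}": "escape" for i in range(32)}
        ann |= {f"x{i}": "inactive" for i in range(12)}
        n, hits, pct = concordance(list(ann), ann, ("escape", "mostly_escape"))
        assert (n, hits, pct) == (44, 32, 72.7)

        ann2 = {f"s{i}": "mostly_inactive" for i in range(125)}
        ann2 |= {f"u{i}": "variable" for i in range(12)}
        n, hits, pct = concordance(list(ann2), ann2, ("inactive", "mostly_inactive"))
        assert (n, hits, pct) == (137, 125, 91.2)

    def test_zero_concordant_and_empty(self):
        assert concordance(["a", "b"], {"a": "variable"}, ("escape",)) == (2, 0, 0.0)
        assert concordance([], {}, ("escape",)) == (0, 0, None)

    def test_unknown_candidates_count_discordant(self):
        n, hits, pct = concordance(["a", "zzz"], {"a": "escape"}, ("escape",))
        assert (n, hits, pct) == (2, 1, 50.0)

    def test_rounding_is_half_up(self):
        # 1/8 = 12.5% exactly; 7/8 = 87.5 -> both keep the .5, and
        # 5/16 = 31.25 -> 31.3 under half-up (banker's would give 31.2)
        assert concordance(["a"] * 0 + list("abcdefgh"), {"a": "escape"}, ("escape",))[2] == 12.5
        ann = {c: "escape" for c in "abcde"}
        n, hits, pct = concordance(list("abcdefghijklmnop"), ann, ("escape",))
        assert pct == 31.3


class TestPatientCalls:
    def _matrix(self, rows, controls_and_patient):
        return build_matrix(rows, controls_and_patient)

    def test_escape_hyper_on_two_consecutive(self, controls_and_patient):
        mat = self._matrix(
            {"p1": [0.05] * 4 + [0.30], "p2": [0.05] * 4 + [0.41]}, controls_and_patient
        )
        calls = call_patient_abnormalities(mat, "P1", ["g1"], [], two_probe_sets())
        assert [(c.call_type, c.run_length) for c in calls] == [("escape_hyper", 2)]
        assert calls[0].supporting_probes == ("p1", "p2")

    def test_inactive_hypo_on_deleted_pattern(self, controls_and_patient):
        mat = self._matrix(
            {"p1": [0.05, 0.05, 0.45, 0.45, 0.02], "p2": [0.05, 0.05, 0.45, 0.45, 0.03]},
            controls_and_patient,
        )
        calls = call_patient_abnormalities(mat, "P1", [], ["g1"], two_probe_sets())
        assert [c.call_type for c in calls] == ["inactive_hypo"]

    def test_hyper_margin_over_female_max_required(self, controls_and_patient):
        # second probe exceeds 0.5 but not max(female)+0.05 -> no call
        mat = self._matrix(
            {"p1": [0.05, 0.05, 0.45, 0.50, 0.60], "p2": [0.05, 0.05, 0.45, 0.60, 0.62]},
            controls_and_patient,
        )
        calls = call_patient_abnormalities(mat, "P1", [], ["g1"], two_probe_sets())
        assert [c for c in calls if c.call_type == "inactive_hyper"] == []

    def test_hyper_call_when_margin_met(self, controls_and_patient):
        mat = self._matrix(
            {"p1": [0.05, 0.05, 0.45, 0.50, 0.60], "p2": [0.05, 0.05, 0.45, 0.50, 0.62]},
            controls_and_patient,
        )
        calls = call_patient_abnormalities(mat, "P1", [], ["g1"], two_probe_sets())
        assert [c.call_type for c in calls] == ["inactive_hyper"]

    def test_missing_patient_beta_breaks_run(self, controls_and_patient):
        mat = self._matrix(
            {"p1": [0.05] * 4 + [0.30], "p2": [0.05] * 4 + [np.nan]}, controls_and_patient
        )
        calls = call_patient_abnormalities(mat, "P1", ["g1"], [], two_probe_sets())
        assert calls == []

    def test_unknown_patient_rejected(self, controls_and_patient):
        mat = self._matrix({"p1": [0.05] * 5, "p2": [0.05] * 5}, controls_and_patient)
        with pytest.raises(InputError):
            call_patient_abnormalities(mat, "nope", ["g1"], [], two_probe_sets())
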