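"""Shapley attribution: kernel weights, exactness against brute force,
efficiency, temporal pruning, ΔTimeSHAP rules and population ranking."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tildyn.attribution import (
    Attribution,
    DeltaRecord,
    delta_timeshap,
    kernel_weight,
    population_ranking,
    prune_temporal,
    solve_shapley,
    timeshap_for_day,
)
from tildyn.rnn import SequenceNet
from tildyn.tokenizer import tokenize_stay


def brute_force_shapley(table, M):
    """Permutation-average Shapley values from a full 2^M value table."""
    phi = np.zeros(M)
    for i in range(M):
        for mask in itertools.product([0, 1], repeat=M):
            if mask[i] == 1:
                continue
            s = sum(mask)
            w = math.factorial(s) * math.factorial(M - s - 1) / math.factorial(M)
            with_i = list(mask)
            with_i[i] = 1
            phi[i] += w * (table[tuple(with_i)] - table[mask])
    return phi


class TestKernelWeight:
    def test_hand_evaluated_values(self):
        assert kernel_weight(3, 1) == pytest.approx(1 / 3)
        assert kernel_weight(3, 2) == pytest.approx(1 / 3)  # s <-> M-s symmetry
        assert kernel_weight(2, 1) == pytest.approx(1 / 2)
        assert kernel_weight(5, 2) == pytest.approx(4 / (10 * 2 * 3))

    def test_empty_and_full_coalitions_are_constraints(self):
        for s in (0, 3):
            with pytest.raises(ValueError):
                kernel_weight(3, s)


class TestSolveShapley:
    def test_additive_model_recovers_weights_exactly(self, rng):
        M = 7
        w = rng.normal(size=M)
        phi = solve_shapley(lambda m: float(w @ m), M)
        assert np.allclose(phi, w, atol=1e-10)

    def test_interaction_model_matches_brute_force(self, rng):
        M = 3
        table = {m: float(rng.normal()) for m in itertools.product([0, 1], repeat=M)}
        f = lambda mask: table[tuple(int(x) for x in mask)]
        assert np.allclose(
            solve_shapley(f, M), brute_force_shapley(table, M), atol=1e-8
        )

    @pytest.mark.parametrize("M", [2, 5, 8, 10])
    def test_full_enumeration_equals_permutation_average(self, M, rng):
        table = {m: float(rng.normal()) for m in itertools.product([0, 1], repeat=M)}
        f = lambda mask: table[tuple(int(x) for x in mask)]
        assert np.allclose(
            solve_shapley(f, M), brute_force_shapley(table, M), atol=1e-6
        )

    def test_efficiency_identity_on_random_instances(self, rng):
        for M in (4, 6):
            table = {
                m: float(rng.normal()) for m in itertools.product([0, 1], repeat=M)
            }
            f = lambda mask: table[tuple(int(x) for x in mask)]
            phi = solve_shapley(f, M)
            assert phi.sum() == pytest.approx(
                f(np.ones(M, dtype=bool)) - f(np.zeros(M, dtype=bool)), abs=1e-9
            )

    def test_sampled_path_is_exact_for_additive_models(self, rng):
        M = 20  # above the enumeration limit
        w = rng.normal(size=M)
        phi = solve_shapley(lambda m: float(w @ m), M, n_coalitions=128, seed=0)
        assert np.allclose(phi, w, atol=1e-8)

    def test_sampled_budget_must_cover_design(self):
        with pytest.raises(ValueError):
            solve_shapley(lambda m: 0.0, 20, n_coalitions=5)


@pytest.fixture(scope="module")
def toy_setup(fitted_small=None):
    """Small trained-free net + tokenised stay for attribution mechanics."""
    from tildyn.simulate import (
        CohortConfig,
        generate_cohort,
        manifest_frame,
        small_manifest,
    )
    from tildyn.tokenizer import fit_vocabulary

    manifest = small_manifest(n_static=2, n_dynamic=4)
    cfg = CohortConfig(n_patients=12, max_day=5, seed=21,
                       variable_manifest=manifest, missing_rate=0.2)
    stays = generate_cohort(cfg)
    vocab = fit_vocabulary(stays, manifest_frame(manifest), embed_dim=128, seed=0)
    net = SequenceNet(vocab=vocab, hidden_dim=6, seed=2)
    net.params["Wy"] = np.random.default_rng(2).normal(0, 0.8, (6, 5))
    tok = [tokenize_stay(s, vocab) for s in stays]
    return net, vocab, tok


class TestPruning:
    def test_zero_tolerance_prunes_nothing(self, toy_setup):
        net, _, tok = toy_setup
        stay = max(tok, key=lambda s: len(s.days))
        day = stay.days[-1]
        kept, pruned = prune_temporal(net, stay, day, tolerance=0.0)
        assert pruned == []
        assert kept == list(range(len(stay.days[: stay.days.index(day) + 1])))

    def test_memoryless_net_prunes_all_past_windows(self, toy_setup):
        _, vocab, tok = toy_setup
        # GRU with z ~ 1 everywhere: hidden state rebuilt from the current
        # window only, so the past is irrelevant by construction
        net = SequenceNet(vocab=vocab, hidden_dim=6, seed=3)
        h = net.hidden_dim
        net.params["W"][:] = 0.0
        net.params["b"][:h] = 40.0  # update gate saturated at 1
        net.params["W"][: vocab.embed_dim, 2 * h:] = (
            np.random.default_rng(3).normal(0, 1.0, (vocab.embed_dim, h))
        )
        net.params["Wy"] = np.random.default_rng(4).normal(0, 0.8, (h, 5))
        stay = max(tok, key=lambda s: len(s.days))
        day = stay.days[-1]
        kept, pruned = prune_temporal(net, stay, day, tolerance=1e-9)
        assert pruned == list(range(len(stay.token_sets[: stay.days.index(day)])))
        att = timeshap_for_day(net, stay, day, tolerance=1e-9)
        assert abs(att.phi_pruned) < 1e-6

    def test_early_window_kept_when_tolerance_below_its_effect(self, toy_setup):
        net, _, tok = toy_setup
        stay = max(tok, key=lambda s: len(s.days))
        day = stay.days[-1]
        from tildyn.attribution import _baseline_window, _output

        t_idx = stay.days.index(day)
        windows = list(stay.token_sets[: t_idx + 1])
        masked = [_baseline_window(net, windows[0])] + windows[1:]
        effect = abs(_output(net, masked) - _output(net, windows))
        assert effect > 0
        kept, pruned = prune_temporal(net, stay, day, tolerance=effect / 2)
        assert 0 in kept


class TestTimeshap:
    def test_efficiency_holds_on_real_attributions(self, toy_setup):
        net, _, tok = toy_setup
        stay = tok[0]
        att = timeshap_for_day(net, stay, stay.days[-1], tolerance=0.05,
                               n_coalitions=256, seed=0)
        gap = att.phi.sum() + att.phi_pruned - (
            att.observed_output - att.baseline_output
        )
        assert abs(gap) < 1e-6  # also asserted in the constructor

    def test_ignored_token_is_a_null_player(self, toy_setup):
        net, vocab, tok = toy_setup
        net = net.clone()
        stay = tok[1]
        day = stay.days[-1]
        # make one observed token's embedding/relevance identical to its
        # variable's missing token: masking it becomes a no-op
        rev = {i: t for t, i in vocab.index.items()}
        target = next(
            int(i) for i in stay.token_sets[-1] if not rev[int(i)].endswith("=<NA>")
        )
        var = vocab.token_variable(rev[target])
        na_idx = vocab.index[vocab.missing_token(var)]
        net.params["E"][target] = net.params["E"][na_idx]
        net.params["rho"][target] = net.params["rho"][na_idx]
        att = timeshap_for_day(net, stay, day, tolerance=0.0)
        assert abs(att.token_phi(day, rev[target])) < 1e-3

    def test_symmetric_tokens_get_equal_phi(self, toy_setup):
        from tildyn.tokenizer import TokenizedStay

        net, vocab, tok = toy_setup
        net = net.clone()
        full = tok[2]
        # single-window stay so the solve enumerates all coalitions exactly
        stay = TokenizedStay(
            patient_id=full.patient_id,
            days=full.days[:1],
            token_sets=full.token_sets[:1],
            labels=full.labels[:1],
            last_til=full.last_til[:1],
        )
        day = stay.days[-1]
        rev = {i: t for t, i in vocab.index.items()}
        obs = [int(i) for i in stay.token_sets[-1]
               if not rev[int(i)].endswith("=<NA>")]
        t1, t2 = obs[0], obs[1]
        net.params["E"][t2] = net.params["E"][t1]
        net.params["rho"][t2] = net.params["rho"][t1]
        # their baselines must coincide too for exact symmetry
        na1 = vocab.index[vocab.missing_token(vocab.token_variable(rev[t1]))]
        na2 = vocab.index[vocab.missing_token(vocab.token_variable(rev[t2]))]
        net.params["E"][na2] = net.params["E"][na1]
        net.params["rho"][na2] = net.params["rho"][na1]
        att = timeshap_for_day(net, stay, day, tolerance=0.0)
        assert att.token_phi(day, rev[t1]) == pytest.approx(
            att.token_phi(day, rev[t2]), abs=1e-6
        )

    def test_out_of_range_day_raises(self, toy_setup):
        net, _, tok = toy_setup
        with pytest.raises(ValueError):
            timeshap_for_day(net, tok[0], 99)


class TestDeltaTimeshap:
    def test_change_on_day_two_or_earlier_yields_no_records(self, toy_setup):
        net, _, tok = toy_setup
        assert delta_timeshap(net, tok[0], 2) == []
        assert delta_timeshap(net, tok[0], 1) == []

    def test_records_only_for_actual_changes(self, toy_setup):
        net, _, tok = toy_setup
        for stay in tok:
            for t_idx, day in enumerate(stay.days):
                y, last = stay.labels[t_idx], stay.last_til[t_idx]
                if day + 1 <= 2 or y is None or last is None:
                    continue
                recs = delta_timeshap(net, stay, day + 1, tolerance=0.05,
                                      n_coalitions=128, seed=0)
                if y == last:
                    assert recs == []
                elif recs:
                    assert all(r.transition_day == day + 1 for r in recs)
                    assert all(
                        r.direction == ("escalation" if y > last else "de-escalation")
                        for r in recs
                    )

    def test_token_only_in_latest_window_has_delta_equal_phi(self, toy_setup):
        net, vocab, tok = toy_setup
        stay = next(
            s for s in tok
            if len(s.days) >= 3 and s.labels[-2] is not None
            and s.last_til[-2] is not None and s.labels[-2] != s.last_til[-2]
            and s.days[-1] > 2
        )
        t = stay.days[-2] + 1
        recs = delta_timeshap(net, stay, t, tolerance=0.0, seed=0)
        att1 = timeshap_for_day(net, stay, t - 1, tolerance=0.0, seed=0)
        att2 = timeshap_for_day(net, stay, t - 2, tolerance=0.0, seed=1)
        d1_tokens = {tok_ for (d, tok_) in att1.features if d == t - 1}
        d2_tokens = {tok_ for (d, tok_) in att2.features if d == t - 2}
        only_d1 = d1_tokens - d2_tokens
        by_token = {r.token: r for r in recs}
        for tok_ in only_d1:
            assert by_token[tok_].delta_phi == pytest.approx(
                att1.token_phi(t - 1, tok_), abs=1e-9
            )


class TestPopulationRanking:
    def make_records(self):
        rows = []
        # 25 variables with medians -12..12, 3 records each
        for i, med in enumerate(range(-12, 13)):
            for r in range(3):
                rows.append(
                    DeltaRecord(
                        patient_id=f"P{r}",
                        transition_day=3,
                        token=f"var{i:02d}=x",
                        variable=f"var{i:02d}",
                        delta_phi=float(med) + 0.1 * (r - 1),
                        direction="escalation",
                    )
                )
        rows.append(
            DeltaRecord("P0", 3, "var00=<NA>", "var00", -5.0, "escalation",
                        is_missing_token=True)
        )
        return rows

    def test_ten_plus_ten_selection(self):
        ranking, missing = population_ranking(self.make_records())
        assert len(ranking) == 20
        neg = ranking[ranking["block"] == "de-escalation"]
        pos = ranking[ranking["block"] == "escalation"]
        assert len(neg) == len(pos) == 10
        assert neg["median_delta"].max() < pos["median_delta"].min()
        assert list(neg["variable"])[:3] == ["var00", "var01", "var02"]
        assert missing.iloc[0]["variable"] == "var00"

    def test_partition_means_taken_before_medians(self):
        # same (patient, transition, token) seen in two partitions: the
        # per-record mean (0) must be used, not the raw values (+1, -1)
        rows = [
            DeltaRecord("P0", 3, "v=x", "v", +1.0, "escalation"),
            DeltaRecord("P0", 3, "v=x", "v", -1.0, "escalation"),
        ]
        ranking, _ = population_ranking(rows)
        assert ranking.iloc[0]["median_delta"] == pytest.approx(0.0)

    def test_median_ties_break_by_count_then_name(self):
        rows = []
        for name, n in (("b_var", 2), ("a_var", 2), ("c_var", 5)):
            for r in range(n):
                rows.append(DeltaRecord(f"P{r}", 3, f"{name}=x", name, -1.0,
                                        "escalation"))
        ranking, _ = population_ranking(rows, n_top=3)
        neg = ranking[ranking["block"] == "de-escalation"]
        assert list(neg["variable"]) == ["c_var", "a_var", "b_var"]

    def test_empty_records_give_empty_tables(self):
        ranking, missing = population_ranking([])
        assert ranking.empty and missing.empty


class TestDriverRecovery:
    def test_driver_delta_sign_matches_injected_effect(self, fitted):
        """On the session driver cohort, the escalation driver's median
        signed ΔTimeSHAP points in the injected (positive) direction."""
        net, vocab = fitted["net"], fitted["vocab"]
        deltas = []
        done = 0
        for stay in fitted["test"]:
            sc = stay.til_series.scores
            tokd = tokenize_stay(stay, vocab)
            for d in sorted(sc):
                if d + 1 in sc and d + 1 > 2 and sc[d + 1] != sc[d]:
                    recs = delta_timeshap(net, tokd, d + 1, n_coalitions=192,
                                          seed=0)
                    deltas += [
                        r.delta_phi if sc[d + 1] > sc[d] else -r.delta_phi
                        for r in recs
                        if r.variable == "icp_mean" and not r.is_missing_token
                    ]
                    done += 1
                    break
            if done >= 8:
                break
        assert len(deltas) >= 5
        assert np.median(deltas) > 0
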