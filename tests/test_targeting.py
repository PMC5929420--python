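"""Block ratios, group screens, and the greedy personalized target search."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pytarg import (
    FixtureScenario,
    PyTargConfig,
    block,
    fullconstrain,
    make_model,
    make_profiles,
    personal,
    pfba_flux,
    screen_targets,
)
from pytarg.targeting import _blocked_model

TOL = 1e-6


class TestBlock:
    def test_fully_coupled_chain_ratio_is_fraction(self, chain3_constrained):
        base = pfba_flux(chain3_constrained)
        res = block(chain3_constrained, base, ["R1"], fraction=0.1)
        assert res.ratio == pytest.approx(0.1, abs=TOL)
        assert res.baseline_objective == pytest.approx(0.108, abs=1e-6)

    def test_redundant_route_fully_compensates(self, parallel_constrained):
        base = pfba_flux(parallel_constrained)
        used = "R1" if abs(base.fluxes["R1"]) > abs(base.fluxes["R2"]) else "R2"
        assert block(parallel_constrained, base, [used]).ratio == pytest.approx(1.0, abs=TOL)

    def test_zero_flux_target_has_no_effect(self, parallel_constrained):
        base = pfba_flux(parallel_constrained)
        idle = "R1" if abs(base.fluxes["R1"]) < TOL else "R2"
        assert abs(base.fluxes[idle]) < TOL
        assert block(parallel_constrained, base, [idle]).ratio == pytest.approx(1.0, abs=TOL)

    def test_unknown_target_rejected(self, chain3_constrained):
        base = pfba_flux(chain3_constrained)
        with pytest.raises(ValueError, match="unknown target"):
            block(chain3_constrained, base, ["NOPE"])

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.1])
    def test_fraction_domain_enforced(self, chain3_constrained, fraction):
        base = pfba_flux(chain3_constrained)
        with pytest.raises(ValueError, match="fraction"):
            block(chain3_constrained, base, ["R1"], fraction=fraction)

    @pytest.mark.parametrize("name", ["CHAIN3", "PARALLEL", "SELECTIVE", "CYCLE"])
    def test_ratio_bracketed_when_bounds_bracket_zero(self, name):
        """With lb <= 0 <= ub everywhere, the fraction-scaled baseline stays
        feasible, so the ratio can never fall below the fraction."""
        sc = FixtureScenario(name)
        profile, _ = make_profiles(sc)
        model = fullconstrain(make_model(sc), profile)
        assert all(r.lower_bound <= 0 <= r.upper_bound for r in model.reactions)
        base = pfba_flux(model)
        for rid in model.reaction_ids:
            ratio = block(model, base, [rid], fraction=0.1).ratio
            assert 0.1 - TOL <= ratio <= 1.0 + TOL

    def test_superset_monotonicity(self, selective_pair):
        target, _ = selective_pair
        base = pfba_flux(target)
        rng = np.random.default_rng(0)
        ids = target.reaction_ids
        for _ in range(25):
            small = list(rng.choice(ids, size=1, replace=False))
            extra = [rid for rid in rng.choice(ids, size=2, replace=False) if rid not in small]
            r_small = block(target, base, small).ratio
            r_big = block(target, base, small + extra).ratio
            assert r_big <= r_small + TOL


def _coupled_pair_models(n_per_group: int = 3):
    """Target models fully coupled to R1; reference models with a bypass."""
    sc_chain, sc_par = FixtureScenario("CHAIN3"), FixtureScenario("PARALLEL")
    chain_profile, _ = make_profiles(sc_chain)
    par_profile, _ = make_profiles(sc_par)
    parallel = make_model(sc_par)
    # give both groups the same reaction ids: drop nothing, just constrain
    chain_like = parallel.copy()
    chain_like.reaction("R2").upper_bound = 0.0  # bypass silenced: fully coupled
    targets = [
        (f"t{i}", fullconstrain(chain_like, par_profile)) for i in range(n_per_group)
    ]
    refs = [(f"r{i}", fullconstrain(parallel, par_profile)) for i in range(n_per_group)]
    return targets, refs


class TestScreenTargets:
    def test_coupled_vs_uncoupled_groups_separate(self):
        targets, refs = _coupled_pair_models()
        table = screen_targets(targets, refs, ["R1"], PyTargConfig())
        row = table.iloc[0]
        assert row["mean_target"] == pytest.approx(0.1, abs=TOL)
        assert row["mean_reference"] == pytest.approx(1.0, abs=TOL)
        assert row["mean_difference"] == pytest.approx(0.9, abs=TOL)
        assert row["p"] < 0.05

    def test_identical_groups_give_p_one(self):
        targets, _ = _coupled_pair_models()
        more = [(f"m{i}", m.copy()) for i, (_, m) in enumerate(targets)]
        table = screen_targets(targets, more, ["R1", "EX_A"], PyTargConfig())
        assert np.allclose(table["p"].to_numpy(), 1.0, atol=1e-12)

    def test_empty_reaction_list(self):
        targets, refs = _coupled_pair_models(2)
        assert len(screen_targets(targets, refs, [], PyTargConfig())) == 0

    def test_requires_two_models_per_group(self):
        targets, refs = _coupled_pair_models(2)
        with pytest.raises(ValueError, match="at least 2"):
            screen_targets(targets[:1], refs, ["R1"], PyTargConfig())


class TestPersonal:
    def test_selective_fixture_recovers_synthesis_target(self, selective_pair, config):
        target, reference = selective_pair
        result = personal(target, reference, config)
        assert result.accepted == ["S"]
        assert result.converged
        assert result.final_target_ratio == pytest.approx(0.1, abs=TOL)
        assert result.final_reference_ratio == pytest.approx(1.0, abs=TOL)

    def test_brute_force_confirms_unique_minimal_set(self, selective_pair, config):
        """Exhaustive search over all 1- and 2-reaction throttled subsets:
        the synthesis reaction alone is the only subset that both halves the
        target's growth and spares the reference."""
        target, reference = selective_pair
        base_t, base_r = pfba_flux(target), pfba_flux(reference)
        candidates = [r for r in target.reaction_ids if r != target.objective_id]
        valid = []
        for size in (1, 2):
            for subset in itertools.combinations(candidates, size):
                rt = block(target, base_t, list(subset), config.block_fraction).ratio
                rr = block(reference, base_r, list(subset), config.block_fraction).ratio
                if (
                    rt < config.single_threshold
                    and (rr - rt) > config.selectivity_margin
                    and rt <= config.stop_ratio
                ):
                    valid.append(set(subset))
        assert {"S"} in valid
        assert all(v >= {"S"} for v in valid)

    def test_symmetric_profiles_find_nothing(self, selective, config):
        _, ref_prof = make_profiles(FixtureScenario("SELECTIVE"))
        same = fullconstrain(selective, ref_prof, config)
        result = personal(same, same.copy(), config)
        assert result.accepted == []
        assert not result.converged
        assert result.final_target_ratio == pytest.approx(1.0)

    def test_relaxed_thresholds_accept_first_coupled_candidate(self, selective_pair):
        target, reference = selective_pair
        cfg = PyTargConfig(
            single_threshold=0.999999, selectivity_margin=1e-9, stop_ratio=0.99
        )
        result = personal(target, reference, cfg)
        assert result.converged
        # the search stops at the very first candidate showing any selectivity
        assert result.accepted == ["S"]
        assert len(result.accepted) == 1
        assert result.final_target_ratio <= cfg.stop_ratio

    def test_trace_replay_reproduces_final_ratios(self, selective_pair, config):
        target, reference = selective_pair
        result = personal(target, reference, config)
        base_t, base_r = pfba_flux(target), pfba_flux(reference)
        rt = block(target, base_t, result.accepted, config.block_fraction).ratio
        rr = block(reference, base_r, result.accepted, config.block_fraction).ratio
        assert rt == pytest.approx(result.final_target_ratio, abs=TOL)
        assert rr == pytest.approx(result.final_reference_ratio, abs=TOL)

    def test_set_stays_small_on_fixture(self, selective_pair, config):
        result = personal(*selective_pair, config)
        assert 1 <= len(result.accepted) <= 5

    def test_infeasible_entry_is_contract_violation(self, selective_pair, config):
        target, reference = selective_pair
        dead = target.copy()
        dead.reaction("EX_A").lower_bound = 0.0
        dead.reaction("EX_Cext").lower_bound = 0.0
        with pytest.raises(ValueError, match="cannot grow"):
            personal(dead, reference, config)

    def test_blocked_model_helper_shrinks_magnitude(self, chain3_constrained):
        base = pfba_flux(chain3_constrained)
        blocked = _blocked_model(chain3_constrained, base, ["EX_A"], 0.1)
        ex = blocked.reaction("EX_A")
        assert ex.lower_bound == pytest.approx(0.1 * base.fluxes["EX_A"])
        assert ex.upper_bound >= ex.lower_bound
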