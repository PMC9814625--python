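import logging

import numpy as np
import pytest

from contextflux.contextualize import (
    choose_sample_count,
    contextualize,
    sample_fluxes,
)
from contextflux.lp import AbsFluxCap, LinearConstraint, LPSettings, fva
from contextflux.transcripts import (
    ReactionWeights,
    TranscriptProfile,
    abundance_to_weights,
    reaction_abundance,
)


def _profile(genes, group="case", sample_id="p1"):
    return TranscriptProfile(sample_id=sample_id, group=group, abundance=genes)


class TestContextualize:
    def test_expensive_parallel_route_is_pruned(self, parallel_network):
        # g1 >> g2 -> R1 cheap, R2 expensive; fraction 1 forces bio = 10
        ctx = contextualize(parallel_network, _profile({"g1": 9.0, "g2": 1.0}))
        assert "R2" in ctx.pruned
        assert sorted(ctx.retained) == ["R1", "bio", "uptake"]
        assert ctx.objective_value == pytest.approx(10.0, abs=1e-7)

    def test_equal_weight_tie_retains_both_routes(self, parallel_network):
        ctx = contextualize(parallel_network, _profile({"g1": 5.0, "g2": 5.0}))
        assert "R1" in ctx.retained and "R2" in ctx.retained
        lo, hi = ctx.flux_ranges["R1"]
        assert lo == pytest.approx(0.0, abs=1e-6)
        assert hi == pytest.approx(10.0, abs=1e-6)

    def test_pruned_count_bookkeeping(self, parallel_network):
        ctx = contextualize(parallel_network, _profile({"g1": 9.0, "g2": 1.0}))
        assert len(ctx.pruned) == parallel_network.n_reactions - len(ctx.retained)

    def test_deterministic(self, parallel_network):
        p = _profile({"g1": 7.0, "g2": 2.0})
        a = contextualize(parallel_network, p)
        b = contextualize(parallel_network, p)
        assert a == b

    def test_lower_abundance_pruned_first(self, parallel_network):
        """Of two otherwise identical parallel routes, the one with less
        transcript support is the one that gets pruned."""
        for hi, lo in (("g1", "g2"), ("g2", "g1")):
            ctx = contextualize(parallel_network, _profile({hi: 8.0, lo: 3.0}))
            pruned_rxn = "R2" if hi == "g1" else "R1"
            kept_rxn = "R1" if hi == "g1" else "R2"
            assert pruned_rxn in ctx.pruned
            assert kept_rxn in ctx.retained

    def test_pruning_soundness_on_cohort(self, default_cohort):
        """Pruned reactions cannot carry flux above tolerance under the
        parsimony cap; retained ones can (re-verified by fresh FVA)."""
        network = default_cohort["overlaid"]
        settings = LPSettings()
        for profile in default_cohort["profiles"][:3]:
            ctx = contextualize(network, profile)
            weights = abundance_to_weights(reaction_abundance(network, profile))
            cap = (1 + settings.parsimony_slack) * ctx.parsimony_value \
                + settings.feasibility_tolerance
            constraints = [
                LinearConstraint({network.objective_id: 1.0}, ">=",
                                 ctx.fraction * ctx.objective_value),
                AbsFluxCap(weights.weight, cap),
            ]
            ranges = fva(network, constraints, settings=settings)
            for rid in ctx.pruned:
                lo, hi = ranges[rid]
                assert max(abs(lo), abs(hi)) <= 1e-6
            for rid in ctx.retained:
                lo, hi = ranges[rid]
                assert max(abs(lo), abs(hi)) > 1e-6


class TestChooseSampleCount:
    @pytest.mark.parametrize(
        "width,expected", [(10.0, 50), (200.0, 200), (1e4, 500)]
    )
    def test_mean_width_clamp(self, width, expected):
        ranges = {"r1": (0.0, width), "r2": (0.0, width)}
        assert choose_sample_count(ranges) == expected

    def test_mixed_widths_use_mean(self):
        assert choose_sample_count({"a": (0.0, 100.0), "b": (0.0, 200.0)}) == 150


class TestSampleFluxes:
    def _tie_setup(self, parallel_network):
        profile = _profile({"g1": 5.0, "g2": 5.0})
        ctx = contextualize(parallel_network, profile)
        weights = abundance_to_weights(
            reaction_abundance(parallel_network, profile)
        )
        return ctx, weights

    def test_rows_satisfy_all_constraints(self, parallel_network):
        ctx, weights = self._tie_setup(parallel_network)
        ss = sample_fluxes(ctx, parallel_network, weights, 100, seed=42)
        S = parallel_network.stoichiometric_matrix()
        idx = [parallel_network.reaction_ids.index(r) for r in ss.reaction_ids]
        lb, ub = parallel_network.bounds_arrays()
        settings = LPSettings()
        cap = (1 + settings.parsimony_slack) * ctx.parsimony_value + 1e-6
        w = np.array([weights.weight[r] for r in ss.reaction_ids])
        j_obj = ss.reaction_ids.index("bio")
        for row in ss.samples:
            full = np.zeros(parallel_network.n_reactions)
            full[idx] = row
            assert np.max(np.abs(S @ full)) < 1e-6
            assert np.all(full >= lb[np.arange(len(lb))] - 1e-6)
            assert np.all(full <= ub + 1e-6)
            assert row[j_obj] >= ctx.fraction * ctx.objective_value - 1e-6
            assert float(w @ np.abs(row)) <= cap + 1e-6

    def test_seed_determinism(self, parallel_network):
        ctx, weights = self._tie_setup(parallel_network)
        a = sample_fluxes(ctx, parallel_network, weights, 60, seed=7)
        b = sample_fluxes(ctx, parallel_network, weights, 60, seed=7)
        c = sample_fluxes(ctx, parallel_network, weights, 60, seed=8)
        assert np.array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_tie_marginal_spans_segment(self, parallel_network):
        """With equal weights the feasible set is the segment
        v_R1 + v_R2 = 10; sampled R1 values should span most of [0, 10]."""
        ctx, weights = self._tie_setup(parallel_network)
        ss = sample_fluxes(ctx, parallel_network, weights, 500, seed=1)
        r1 = ss.samples[:, ss.reaction_ids.index("R1")]
        r2 = ss.samples[:, ss.reaction_ids.index("R2")]
        assert np.allclose(r1 + r2, 10.0, atol=1e-6)
        assert r1.min() < 2.0 and r1.max() > 8.0

    def test_degenerate_polytope_returns_copies(self, parallel_network, caplog):
        profile = _profile({"g1": 9.0, "g2": 1.0})
        ctx = contextualize(parallel_network, profile)
        weights = abundance_to_weights(
            reaction_abundance(parallel_network, profile)
        )
        with caplog.at_level(logging.WARNING, logger="contextflux.contextualize"):
            logging.getLogger("contextflux.contextualize").setLevel(logging.WARNING)
            ss = sample_fluxes(ctx, parallel_network, weights, 50, seed=3)
        assert ss.samples.shape == (50, len(ctx.retained))
        assert np.all(ss.samples == ss.samples[0])
        assert any("zero-volume" in r.message for r in caplog.records)

    def test_n_outside_clamp_rejected(self, parallel_network):
        ctx, weights = self._tie_setup(parallel_network)
        with pytest.raises(ValueError):
            sample_fluxes(ctx, parallel_network, weights, 10, seed=1)
        with pytest.raises(ValueError):
            sample_fluxes(ctx, parallel_network, weights, 600, seed=1)

    def test_write_tsv_and_sidecar(self, parallel_network, tmp_path):
        ctx, weights = self._tie_setup(parallel_network)
        ss = sample_fluxes(ctx, parallel_network, weights, 50, seed=2)
        ss.write(tmp_path / "p1")
        header = (tmp_path / "p1.tsv").read_text().splitlines()[0]
        assert header.split("\t") == ss.reaction_ids
        import json

        meta = json.loads((tmp_path / "p1.json").read_text())
        assert meta["n_samples"] == 50 and meta["seed"] == 2
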