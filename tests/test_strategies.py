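"""Selection strategies, coverage sweeps and non-native noise injection."""

import numpy as np
import pytest

from contactsr import (
    Contact,
    ContactMap,
    DistillerConfig,
    StrategySpec,
    compare_strategies,
    compute_contact_map,
    coverage_sweep,
    inject_nonnative,
    select,
)
from contactsr.distiller import ContactSR
from contactsr.errors import (
    CandidateExhaustionError,
    ParameterError,
    ShortfallError,
)
from conftest import constant_engine, make_sr_sum_engine


def _map_and_scores():
    """10 contacts with SR values 1.0 (best) down to 0.1 (worst)."""
    contacts = [Contact(i, 2 * i + 6) for i in range(10)]
    cmap = ContactMap(40, contacts)
    scores = [
        ContactSR(c, sr, sr, 0.0, 1, 0)
        for c, sr in zip(contacts, np.arange(1.0, 0.0, -0.1))
    ]
    return cmap, scores


class TestSelect:
    def test_most_relevant_takes_top_ranks(self):
        cmap, scores = _map_and_scores()
        chosen = select(StrategySpec("most_relevant", size=3), cmap, scores=scores)
        assert chosen.contacts == frozenset(s.contact for s in scores[:3])

    def test_least_relevant_takes_bottom_ranks(self):
        cmap, scores = _map_and_scores()
        chosen = select(StrategySpec("least_relevant", size=3), cmap, scores=scores)
        assert chosen.contacts == frozenset(s.contact for s in scores[-3:])

    def test_tie_break_is_order_independent(self):
        """All-equal SR: selection is by ascending (i, j) regardless of the
        order contacts were supplied in."""
        contacts = [Contact(i, 2 * i + 6) for i in range(10)]
        scores = [ContactSR(c, 0.5, 0.5, 0.0, 1, 0) for c in contacts]
        rng = np.random.default_rng(0)
        selections = set()
        for _ in range(5):
            perm = list(rng.permutation(len(contacts)))
            cmap = ContactMap(40, [contacts[k] for k in perm])
            chosen = select(
                StrategySpec("most_relevant", size=4), cmap,
                scores=[scores[k] for k in perm],
            )
            selections.add(chosen.contacts)
        assert selections == {frozenset(sorted(contacts)[:4])}

    def test_default_size_is_thirty_percent(self):
        cmap, scores = _map_and_scores()
        chosen = select(StrategySpec("most_relevant"), cmap, scores=scores)
        assert len(chosen) == 3

    def test_random_is_seeded_and_sized(self):
        cmap, _ = _map_and_scores()
        a = select(StrategySpec("random", size=4, seed=5), cmap)
        b = select(StrategySpec("random", size=4, seed=5), cmap)
        c = select(StrategySpec("random", size=4, seed=6), cmap)
        assert a == b
        assert len(a) == 4
        assert a != c  # overwhelmingly likely for C(10,4) subsets

    def test_relevance_requires_scores(self):
        cmap, _ = _map_and_scores()
        with pytest.raises(ParameterError):
            select(StrategySpec("most_relevant", size=3), cmap)

    def test_range_bin_and_complement_are_disjoint(self, bundle):
        cmap = bundle.contact_map
        n_short = len(cmap.by_range("short"))
        size = min(3, n_short)
        short = select(StrategySpec("short_range", size=size, seed=1), cmap)
        non_short = select(StrategySpec("non_short", size=size, seed=1), cmap)
        assert all(c.range_class == "short" for c in short)
        assert all(c.range_class != "short" for c in non_short)

    def test_shortfall_error_names_deficit(self):
        cmap, _ = _map_and_scores()  # all contacts are short or medium range
        n_long = len(cmap.by_range("long"))
        with pytest.raises(ShortfallError) as err:
            select(StrategySpec("long_range", size=n_long + 5), cmap)
        assert err.value.requested == n_long + 5

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ParameterError):
            StrategySpec("best_guess")


class TestInjectNonnative:
    def test_zero_fraction_is_identity(self, bundle):
        cmap = bundle.contact_map
        noisy = inject_nonnative(cmap, cmap, 0.0, seed=1)
        assert noisy.combined() == cmap
        assert noisy.injected == ()

    @pytest.mark.parametrize("f", [0.01, 0.05, 0.10, 0.5])
    def test_counting_contract(self, bundle, f):
        cmap = bundle.contact_map
        noisy = inject_nonnative(cmap, cmap, f, seed=2)
        expected = round(f * len(cmap))
        assert len(noisy.injected) == expected
        assert len(noisy.kept) == len(cmap) - expected
        assert len(noisy.combined()) == len(cmap)

    def test_injected_contacts_validated_exhaustively(self, bundle):
        cmap = bundle.contact_map
        noisy = inject_nonnative(cmap, cmap, 0.3, seed=3)
        native_pairs = {(c.i, c.j) for c in cmap.contacts}
        for c in noisy.injected:
            assert (c.i, c.j) not in native_pairs
            assert c.separation >= 6

    def test_candidate_exhaustion(self):
        # length 8: the single admissible pair (0,6),(0,7),(1,7) set is tiny
        contacts = [Contact(0, 6), Contact(0, 7), Contact(1, 7)]
        cmap = ContactMap(8, contacts)
        with pytest.raises(CandidateExhaustionError):
            inject_nonnative(cmap, cmap, 1.0, seed=0)


class TestCoverageSweep:
    def test_deterministic_rows(self, bundle, fast_config):
        a, _ = coverage_sweep(bundle.trace, [1.0], 2, config=fast_config,
                              engine=constant_engine)
        b, _ = coverage_sweep(bundle.trace, [1.0], 2, config=fast_config,
                              engine=constant_engine)
        assert a.equals(b)

    def test_small_fraction_rounds_to_minimum_count(self, coil40):
        real_map = compute_contact_map(coil40)
        sizes = []

        def probe(cmap_in, sse, native, config, seed):
            sizes.append(len(cmap_in))
            return constant_engine(cmap_in, sse, native, config, seed)

        fraction = 0.05
        table, _ = coverage_sweep(coil40, [fraction], 3,
                                  config=DistillerConfig(), engine=probe)
        expected = max(1, round(fraction * len(real_map)))
        assert all(s == expected for s in sizes)
        assert (table["n_contacts"] == expected).all()

    def test_fraction_validation(self, bundle):
        with pytest.raises(ParameterError):
            coverage_sweep(bundle.trace, [0.0], 1, engine=constant_engine)


class TestCompareStrategies:
    def test_closed_form_stub_orders_strategies(self, unique_bundle):
        """With RMSD = 5 − 0.01·ΣSR, relevance-sorted bins order exactly."""
        cmap = unique_bundle.contact_map
        ordered = sorted(cmap.contacts)
        sr_of = {c: float(k) for k, c in enumerate(ordered)}
        scores = [ContactSR(c, sr_of[c], 0.0, 0.0, 1, 0) for c in ordered]
        engine = make_sr_sum_engine(sr_of)
        specs = [
            StrategySpec("most_relevant", seed=1),
            StrategySpec("random", seed=1),
            StrategySpec("least_relevant", seed=1),
        ]
        table, summary = compare_strategies(
            unique_bundle.trace, specs, 5, config=DistillerConfig(seed=2),
            scores=scores, engine=engine,
        )
        by = summary.set_index("strategy")["median_rmsd"]
        assert by["most_relevant"] < by["random"] < by["least_relevant"]

    def test_single_strategy_single_rep_has_no_p_value(self, unique_bundle):
        table, summary = compare_strategies(
            unique_bundle.trace, [StrategySpec("random")], 1,
            config=DistillerConfig(), engine=constant_engine,
        )
        assert len(table) == 1
        assert np.isnan(summary["p_vs_random"]).all()
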