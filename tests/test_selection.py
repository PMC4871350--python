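"""Normalization, imputation, ratio ranking and matrix export."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from selpep import (
    ConfigurationError,
    EmptyScreenError,
    NormalizedScreen,
    RoleAssignment,
    ScreenStats,
    ScreenTable,
    build_matrix,
    depth_normalize,
    export_matrix,
    nonzero_mode,
    normalize_screens,
    read_matrix_tsv,
    reference_normalize,
    resort_with_roles,
    round_enrichment,
    sort_matrix,
)
from selpep.validation import (
    TOY_PATTERNS,
    TOY_PREDICTED_ORDER,
    TOY_SCREEN_IDS,
    toy_matrix,
    toy_screens,
)


def mk_table(sid, counts, total=None):
    acc = sum(counts.values())
    total = acc if total is None else total
    return ScreenTable(
        sid, "toy", dict(counts),
        ScreenStats(
            total_reads=total, accepted_reads=acc,
            rejected_no_flank=total - acc, unique_peptides=len(counts),
        ),
    )


def mk_norm(sid, values):
    return NormalizedScreen(sid, dict(values), total_reads_used=0,
                            nonzero_mode=nonzero_mode(values.values()))


class TestDepthNormalize:
    def test_frequency_per_read(self):
        out = depth_normalize(mk_table("s", {"A" * 7: 100}, total=1_000_000))
        assert out == {"A" * 7: 1.0e-4}

    def test_two_peptides(self):
        out = depth_normalize(mk_table("s", {"AAAAAAA": 2, "CCCCCCC": 1}, total=4))
        assert out == {"AAAAAAA": 0.5, "CCCCCCC": 0.25}

    def test_empty_screen_error(self):
        with pytest.raises(EmptyScreenError):
            depth_normalize(mk_table("s", {}, total=0))


class TestNonzeroMode:
    @pytest.mark.parametrize(
        "values,expected",
        [([1, 1, 1, 2, 3], 1), ([2, 2, 3, 3, 9], 2), ([7], 7), ([0, 0, 5, 5, 9], 5)],
    )
    def test_examples(self, values, expected):
        assert nonzero_mode(values) == expected

    def test_empty_is_contract_violation(self):
        with pytest.raises(ValueError):
            nonzero_mode([])
        with pytest.raises(ValueError):
            nonzero_mode([0, 0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=20), min_size=1, max_size=50))
    def test_matches_bruteforce_tally(self, values):
        tally = Counter(values)
        top = max(tally.values())
        assert nonzero_mode(values) == min(v for v, n in tally.items() if n == top)


class TestReferenceNormalize:
    def test_division_by_reference(self):
        ns = reference_normalize("s", {"AAAAAAA": 1.0e-4}, {"AAAAAAA": 2.0e-5}, 1e-6)
        assert ns.values["AAAAAAA"] == pytest.approx(5.0)

    def test_absent_from_reference_uses_mode(self):
        ns = reference_normalize("s", {"AAAAAAA": 1.0e-4}, {}, 1.0e-6)
        assert ns.values["AAAAAAA"] == pytest.approx(100.0)

    def test_nonpositive_mode_rejected(self):
        with pytest.raises(ValueError):
            reference_normalize("s", {}, {}, 0.0)


def oracle_toy_ranking():
    """Plain-arithmetic re-derivation of the A/L/H fixture ranking.

    Independent of the pipeline: dict loops and Counter only, following the
    stated rules — divide by totals, divide by reference (mode fallback),
    impute absences with each screen's non-zero mode, ratio of means, sort by
    (ratio desc, mean positive desc, peptide).
    """
    total = 10_000
    ref, p1, p2, n1, n2 = (
        {pep: pat[i] / total for pep, pat in TOY_PATTERNS.items() if pat[i] > 0}
        for i in range(5)
    )
    tally = Counter(ref.values())
    top = max(tally.values())
    ref_mode = min(v for v, n in tally.items() if n == top)
    screens = {}
    for sid, dn in (("pos1", p1), ("pos2", p2), ("neg1", n1), ("neg2", n2)):
        screens[sid] = {p: v / ref.get(p, ref_mode) for p, v in dn.items()}
    modes = {}
    for sid, vals in screens.items():
        t = Counter(vals.values())
        m = max(t.values())
        modes[sid] = min(v for v, n in t.items() if n == m)
    rows = {}
    universe = set().union(*screens.values())
    for pep in universe:
        pos = [screens[s].get(pep, modes[s]) for s in ("pos1", "pos2")]
        neg = [screens[s].get(pep, modes[s]) for s in ("neg1", "neg2")]
        rows[pep] = (sum(pos) / 2 / (sum(neg) / 2), sum(pos) / 2)
    order = sorted(rows, key=lambda p: (-rows[p][0], -rows[p][1], p))
    return order, {p: r for p, (r, _) in rows.items()}


class TestGoldenToyRanking:
    """The A/L/H sorting fixture: selective clones to the top, negative-only
    clones to the bottom, reference-high (parasitic) clones cancelled."""

    def test_full_ordering_matches_independent_oracle(self):
        order, ratios = oracle_toy_ranking()
        m = toy_matrix()
        assert m.peptides == order == TOY_PREDICTED_ORDER
        for pep in order:
            assert m.ratio[pep] == pytest.approx(ratios[pep], rel=1e-12)

    def test_qualitative_predictions(self):
        m = toy_matrix()
        rank = {p: i + 1 for i, p in enumerate(m.peptides)}
        n = len(rank)
        assert rank["GVTHKLQ"] == 1  # high in both positives, absent elsewhere
        assert rank["TPSIYFL"] == n  # high only in the negatives
        assert 2 < rank["RVSTPPQ"] < n - 1  # one positive and one negative high
        assert rank["SSDAALH"] > n / 2  # high everywhere: ratio cancels to ~1
        assert m.ratio["SSDAALH"] == pytest.approx(1.0)

    def test_absent_from_reference_is_finite_and_high(self):
        # a clone never seen in the naive library still gets a finite value
        m = toy_matrix()
        assert np.isfinite(m.data.loc["GVTHKLQ"]).all()
        assert m.ratio["GVTHKLQ"] > 100

    def test_imputed_mask_marks_absences(self):
        m = toy_matrix()
        for i, sid in enumerate(TOY_SCREEN_IDS):
            for pep, pat in TOY_PATTERNS.items():
                assert m.imputed.loc[pep, sid] == (pat[i] == 0)


class TestBuildAndSort:
    def test_equal_values_give_ratio_one(self):
        screens = {
            "r": mk_norm("r", {"AAAAAAA": 1.0}),
            "p": mk_norm("p", {"AAAAAAA": 3.0}),
            "n": mk_norm("n", {"AAAAAAA": 3.0}),
        }
        asg = RoleAssignment("r", ("p",), ("n",))
        m = build_matrix(screens, asg)
        assert m.ratio["AAAAAAA"] == pytest.approx(1.0)

    def test_lone_positive_observation_is_finite(self):
        screens = {
            "r": mk_norm("r", {"CCCCCCC": 1.0}),
            "p": mk_norm("p", {"AAAAAAA": 8.0, "CCCCCCC": 2.0}),
            "n": mk_norm("n", {"CCCCCCC": 2.0}),
        }
        m = build_matrix(screens, RoleAssignment("r", ("p",), ("n",)))
        # absent negative cell imputed with n's mode (2.0): ratio 8/2
        assert m.ratio["AAAAAAA"] == pytest.approx(4.0)
        assert m.imputed.loc["AAAAAAA", "n"]
        assert m.ratio["AAAAAAA"] > 0 and np.isfinite(m.ratio["AAAAAAA"])

    def test_sort_order_and_tiebreaks(self):
        screens = {
            "r": mk_norm("r", {"AAAAAAA": 1, "CCCCCCC": 1, "DDDDDDD": 1, "EEEEEEE": 1}),
            "p1": mk_norm("p1", {"AAAAAAA": 10, "CCCCCCC": 2, "DDDDDDD": 4, "EEEEEEE": 4}),
            "p2": mk_norm("p2", {"AAAAAAA": 10, "CCCCCCC": 2, "DDDDDDD": 8, "EEEEEEE": 8}),
            "n": mk_norm("n", {"AAAAAAA": 2, "CCCCCCC": 2, "DDDDDDD": 6, "EEEEEEE": 6}),
        }
        m = build_matrix(screens, RoleAssignment("r", ("p1", "p2"), ("n",)))
        # ratios: A=5, C=1, D=1, E=1; ties D/E (pos mean 6) above C (pos mean 2),
        # D before E lexicographically
        assert m.peptides == ["AAAAAAA", "DDDDDDD", "EEEEEEE", "CCCCCCC"]

    def test_sort_is_idempotent(self):
        m = toy_matrix()
        m2 = sort_matrix(m)
        assert m2.peptides == m.peptides
        assert (m2.data.values == m.data.values).all()

    def test_missing_screen_is_configuration_error(self):
        screens = {"r": mk_norm("r", {"AAAAAAA": 1.0}), "p": mk_norm("p", {"AAAAAAA": 1.0})}
        with pytest.raises(ConfigurationError):
            build_matrix(screens, RoleAssignment("r", ("p",), ("n",)))

    def test_negatives_required_unless_ubiquitous(self):
        screens = {"r": mk_norm("r", {"AAAAAAA": 1.0}), "p": mk_norm("p", {"AAAAAAA": 1.0})}
        asg = RoleAssignment("r", ("p",))
        with pytest.raises(ConfigurationError):
            build_matrix(screens, asg)
        m = build_matrix(screens, asg, ubiquitous=True)
        assert m.peptides == ["AAAAAAA"]


class TestRoles:
    def test_overlapping_roles_rejected(self):
        with pytest.raises(ConfigurationError):
            RoleAssignment("r", ("a", "b"), ("b",))

    def test_positives_required(self):
        with pytest.raises(ConfigurationError):
            RoleAssignment("r", ())

    def test_role_swap_gives_reciprocal_ratio(self):
        # every peptide present in every screen: no imputation anywhere
        peps = ["AAAAAAA", "CCCCCCC", "DDDDDDD"]
        counts = {
            "ref": {p: 5 + i for i, p in enumerate(peps)},
            "x": {p: 3 * (i + 1) for i, p in enumerate(peps)},
            "y": {p: 17 - 4 * i for i, p in enumerate(peps)},
        }
        tables = {sid: mk_table(sid, c, total=100) for sid, c in counts.items()}
        fwd = resort_with_roles(tables, RoleAssignment("ref", ("x",), ("y",)))
        rev = resort_with_roles(tables, RoleAssignment("ref", ("y",), ("x",)))
        assert not fwd.imputed[["x", "y"]].values.any()
        for p in peps:
            assert fwd.ratio[p] * rev.ratio[p] == pytest.approx(1.0, rel=1e-12)

    def test_ubiquitous_mode_surfaces_high_everywhere(self):
        counts = {
            "ref": {"AAAAAAA": 1, "CCCCCCC": 1, "DDDDDDD": 1},
            "s1": {"AAAAAAA": 50, "CCCCCCC": 50, "DDDDDDD": 1},
            "s2": {"AAAAAAA": 50, "CCCCCCC": 1, "DDDDDDD": 50},
        }
        tables = {sid: mk_table(sid, c, total=100) for sid, c in counts.items()}
        m = resort_with_roles(
            tables, RoleAssignment("ref", ("s1", "s2")), ubiquitous=True
        )
        assert m.peptides[0] == "AAAAAAA"  # the only clone high in all screens


class TestInvariants:
    def test_scale_invariance_of_normalization(self):
        tables, asg = toy_screens()
        base = normalize_screens(tables, asg)
        for c, exact in ((4, True), (3, False)):
            scaled_tables = {}
            for sid, t in tables.items():
                scaled_tables[sid] = mk_table(
                    sid, {p: n * c for p, n in t.counts.items()},
                    total=t.stats.total_reads * c,
                )
            scaled = normalize_screens(scaled_tables, asg)
            for sid in asg.screens:
                for p, v in base[sid].values.items():
                    if exact:
                        assert scaled[sid].values[p] == v
                    else:
                        assert scaled[sid].values[p] == pytest.approx(v, rel=1e-12)

    def test_monotonicity_in_positive_count(self):
        # a bulk of singletons keeps every screen's mode stable under the bump
        import random

        rng = random.Random(5)
        bulk = {f"B{i:06d}": 1 for i in range(200)}
        focal = "FOCALPP"
        counts = {
            "ref": dict(bulk),
            "p1": dict(bulk, **{focal: 4}),
            "p2": dict(bulk, **{focal: 6}),
            "n1": dict(bulk, **{focal: 3}),
        }
        tables = {sid: mk_table(sid, c, total=10_000) for sid, c in counts.items()}
        asg = RoleAssignment("ref", ("p1", "p2"), ("n1",))
        m0 = build_matrix(normalize_screens(tables, asg), asg)
        r0, rank0 = m0.ratio[focal], m0.peptides.index(focal)
        for bump in (2, 10, 50):
            counts2 = {sid: dict(c) for sid, c in counts.items()}
            counts2["p1"][focal] = 4 + bump
            tables2 = {sid: mk_table(sid, c, total=10_000) for sid, c in counts2.items()}
            m1 = build_matrix(normalize_screens(tables2, asg), asg)
            assert m1.ratio[focal] >= r0
            assert m1.peptides.index(focal) <= rank0

    def test_imputation_floor(self):
        m = toy_matrix()
        for sid in m.data.columns:
            observed_max = m.data[sid][~m.imputed[sid]].max()
            imputed_vals = m.data[sid][m.imputed[sid]]
            assert (imputed_vals > 0).all()
            assert (imputed_vals <= observed_max).all()

    @settings(
        max_examples=25, deadline=None, derandomize=True,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(st.integers(min_value=0, max_value=10**6))
    def test_imputed_value_is_an_observed_value(self, seed):
        import random

        rng = random.Random(seed)
        peps = [f"P{i:05d}" for i in range(30)]
        screens = {}
        for sid in ("r", "p", "n"):
            sub = rng.sample(peps, rng.randint(5, 30))
            screens[sid] = mk_norm(sid, {p: rng.randint(1, 9) / 8 for p in sub})
        m = build_matrix(screens, RoleAssignment("r", ("p",), ("n",)))
        for sid in m.data.columns:
            observed = set(screens[sid].values.values())
            for pep in m.peptides:
                if m.imputed.loc[pep, sid]:
                    assert m.data.loc[pep, sid] in observed


class TestRoundEnrichment:
    def test_single_positive_fold_change(self):
        r1 = {"p": mk_norm("p", {"HPQAAAA": 0.1, "CCCCCCC": 0.1})}
        r2 = {"p": mk_norm("p", {"HPQAAAA": 3.5, "CCCCCCC": 0.1})}
        out = round_enrichment(r1, r2, ("p",))
        assert out["HPQAAAA"] == pytest.approx(35.0)

    def test_identical_rounds_are_unity(self):
        r = {"p": mk_norm("p", {"AAAAAAA": 0.4, "CCCCCCC": 1.2})}
        out = round_enrichment(r, r, ("p",))
        assert all(v == pytest.approx(1.0) for v in out.values())

    def test_absent_in_round1_uses_round1_mode(self):
        r1 = {"p": mk_norm("p", {"CCCCCCC": 0.2, "DDDDDDD": 0.2, "EEEEEEE": 0.5})}
        r2 = {"p": mk_norm("p", {"AAAAAAA": 2.0, "CCCCCCC": 0.2})}
        out = round_enrichment(r1, r2, ("p",))
        assert out["AAAAAAA"] == pytest.approx(2.0 / 0.2)  # round-1 mode 0.2

    def test_no_shared_peptides_warns_and_empties(self, caplog):
        r1 = {"p": NormalizedScreen("p", {}, 0, 1.0)}
        with caplog.at_level("WARNING"):
            out = round_enrichment(r1, r1, ())
        assert out == {}


class TestExport:
    def test_top_n_and_roundtrip(self, tmp_path):
        m = toy_matrix()
        p = tmp_path / "matrix.tsv"
        export_matrix(m, p, top_n=3)
        back = read_matrix_tsv(p)
        assert len(back) == 3
        assert list(back.index) == m.peptides[:3]
        export_matrix(m, p, top_n=None)
        back = read_matrix_tsv(p)
        assert len(back) == len(m.peptides)
        for pep in m.peptides:
            assert back.loc[pep, "ratio"] == pytest.approx(m.ratio[pep], rel=1e-11)
        mask = tmp_path / "matrix.imputed.tsv"
        assert mask.exists()

    def test_heatmap_render(self, tmp_path):
        m = toy_matrix()
        export_matrix(m, tmp_path / "matrix.tsv", top_n=5,
                      heatmap_path=tmp_path / "heatmap.png")
        assert (tmp_path / "heatmap.png").stat().st_size > 0
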