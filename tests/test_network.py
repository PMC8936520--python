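import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import bh_oracle
from mir200.network import (
    bh_adjust,
    build_network,
    collapse_probes,
    correlate,
    filter_targets,
    network_stats,
)


def _matrices(rng, n_samples=12, n_genes=6):
    samples = [f"S{i}" for i in range(n_samples)]
    mirna = pd.DataFrame(
        rng.normal(size=(2, n_samples)), index=["miR-a", "miR-b"], columns=samples
    )
    genes = pd.DataFrame(
        rng.normal(size=(n_genes, n_samples)),
        index=[f"G{i}" for i in range(n_genes)],
        columns=samples,
    )
    return mirna, genes


class TestCorrelate:
    def test_perfect_monotone_relations(self):
        samples = [f"S{i}" for i in range(10)]
        mirna = pd.DataFrame([np.arange(10.0)], index=["miR-a"], columns=samples)
        genes = pd.DataFrame(
            [np.arange(10.0)[::-1], np.arange(10.0) ** 2], index=["down", "up"], columns=samples
        )
        out = correlate(mirna, genes, {"miR-a": {"down", "up"}}, "c1")
        rho = out.set_index("gene")["rho"]
        assert rho["down"] == pytest.approx(-1.0)
        assert rho["up"] == pytest.approx(1.0)

    def test_matches_scipy_pairwise(self, rng):
        mirna, genes = _matrices(rng, n_samples=15)
        cand = {"miR-a": set(genes.index), "miR-b": set(genes.index)}
        out = correlate(mirna, genes, cand, "c1").set_index(["mirna", "gene"])
        for mir in mirna.index:
            for g in genes.index:
                rho, p = stats.spearmanr(mirna.loc[mir], genes.loc[g])
                assert out.loc[(mir, g), "rho"] == pytest.approx(rho, abs=1e-12)
                assert out.loc[(mir, g), "p"] == pytest.approx(p, abs=1e-9)

    def test_null_false_positive_rate(self, rng):
        samples = [f"S{i}" for i in range(90)]
        mirna = pd.DataFrame(rng.normal(size=(1, 90)), index=["miR-a"], columns=samples)
        genes = pd.DataFrame(
            rng.normal(size=(2000, 90)),
            index=[f"G{i}" for i in range(2000)],
            columns=samples,
        )
        out = correlate(mirna, genes, {"miR-a": set(genes.index)}, "c1")
        assert abs((out["p"] < 0.05).mean() - 0.05) < 0.02

    def test_constant_gene_flagged_and_excluded_from_fdr(self, rng):
        mirna, genes = _matrices(rng)
        genes.loc["G0"] = 3.14
        out = correlate(mirna, genes, {"miR-a": set(genes.index)}, "c1")
        flat = out[out["gene"] == "G0"]
        assert flat["rho"].isna().all() and flat["q"].isna().all()
        assert out[out["gene"] != "G0"]["q"].notna().all()

    def test_unmatched_candidates_reported(self, rng):
        mirna, genes = _matrices(rng)
        out = correlate(mirna, genes, {"miR-a": {"G0", "NOT_A_GENE"}}, "c1")
        assert out.attrs["unmatched"] == ["NOT_A_GENE"]

    def test_mismatched_samples_rejected(self, rng):
        mirna, genes = _matrices(rng)
        with pytest.raises(ValueError):
            correlate(mirna, genes.iloc[:, ::-1], {"miR-a": {"G0"}}, "c1")


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_all_ones(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_stepup_definition(self, rng):
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)


def _corr_table(cohort, rows):
    return pd.DataFrame(rows, columns=["mirna", "gene", "rho", "p", "q"]).assign(cohort=cohort)


class TestFilterTargets:
    def test_inclusion_rule(self):
        c1 = _corr_table("c1", [("m", "g", -0.3, 0.01, 0.05)])
        c2 = _corr_table("c2", [("m", "g", -0.3, 0.01, 0.5)])
        out = filter_targets(c1, c2)
        assert out["genes"] == ["g"]

    def test_requires_nominal_p_in_both_cohorts(self):
        c1 = _corr_table("c1", [("m", "g", -0.3, 0.01, 0.05)])
        c2 = _corr_table("c2", [("m", "g", -0.2, 0.2, 0.5)])
        assert filter_targets(c1, c2)["genes"] == []

    def test_positive_correlation_excluded(self):
        c1 = _corr_table("c1", [("m", "g", 0.4, 0.001, 0.01)])
        c2 = _corr_table("c2", [("m", "g", 0.4, 0.001, 0.01)])
        assert filter_targets(c1, c2)["genes"] == []

    def test_single_cohort_pairs_reported(self):
        c1 = _corr_table("c1", [("m", "g", -0.3, 0.01, 0.05), ("m", "h", -0.5, 0.001, 0.01)])
        c2 = _corr_table("c2", [("m", "g", -0.3, 0.01, 0.05)])
        out = filter_targets(c1, c2)
        assert out["dropped_single_cohort"]["gene"].tolist() == ["h"]

    def test_monotone_in_thresholds(self, rng):
        rows1, rows2 = [], []
        for i in range(200):
            rows1.append(("m", f"g{i}", rng.uniform(-1, 1), rng.random(), rng.random()))
            rows2.append(("m", f"g{i}", rng.uniform(-1, 1), rng.random(), rng.random()))
        c1, c2 = _corr_table("c1", rows1), _corr_table("c2", rows2)
        strict = set(filter_targets(c1, c2, p_threshold=0.05, q_threshold=0.1)["genes"])
        loose = set(filter_targets(c1, c2, p_threshold=0.2, q_threshold=0.3)["genes"])
        assert strict <= loose


class TestNetwork:
    def test_empty_when_nothing_passes(self):
        pairs = filter_targets(
            _corr_table("c1", [("m", "g", 0.5, 0.5, 0.9)]),
            _corr_table("c2", [("m", "g", 0.5, 0.5, 0.9)]),
        )["pairs"]
        assert build_network(pairs).number_of_nodes() == 0

    def test_counting_example(self):
        rows = [("m1", "shared", -0.5, 0.01, 0.01), ("m1", "u1", -0.5, 0.01, 0.01),
                ("m2", "shared", -0.5, 0.01, 0.01), ("m2", "u2", -0.5, 0.01, 0.01)]
        pairs = filter_targets(_corr_table("c1", rows), _corr_table("c2", rows))["pairs"]
        g = build_network(pairs)
        s = network_stats(g)
        assert s["n_genes"] == 3
        assert g.number_of_edges() == 4
        assert s["multi_mirna_fraction"] == pytest.approx(1 / 3)

    def test_star_and_complete_bipartite_fractions(self):
        star = [("m1", f"g{i}", -0.5, 0.01, 0.01) for i in range(5)]
        pairs = filter_targets(_corr_table("c1", star), _corr_table("c2", star))["pairs"]
        assert network_stats(build_network(pairs))["multi_mirna_fraction"] == 0.0
        full = [(m, g, -0.5, 0.01, 0.01) for m in ("m1", "m2") for g in ("a", "b", "c")]
        pairs = filter_targets(_corr_table("c1", full), _corr_table("c2", full))["pairs"]
        assert network_stats(build_network(pairs))["multi_mirna_fraction"] == 1.0

    def test_stats_match_degree_enumeration(self, rng):
        rows = []
        for m in ("m1", "m2", "m3"):
            for g in rng.choice([f"g{i}" for i in range(12)], size=6, replace=False):
                rows.append((m, g, -0.5, 0.01, 0.01))
        pairs = filter_targets(_corr_table("c1", rows), _corr_table("c2", rows))["pairs"]
        net = build_network(pairs)
        s = network_stats(net)
        genes = {g for _, g, *_ in rows}
        deg = {g: sum(1 for r in set(rows) if r[1] == g) for g in genes}
        assert s["n_multi_mirna_genes"] == sum(d > 1 for d in deg.values())
        for m in ("m1", "m2", "m3"):
            assert s["per_mirna_targets"][m] == len({r[1] for r in set(rows) if r[0] == m})

    def test_q_rule_both_is_stricter(self):
        rows = [("m", "g", -0.5, 0.01, 0.05)]
        c1 = _corr_table("c1", rows)
        c2 = _corr_table("c2", [("m", "g", -0.5, 0.01, 0.5)])
        pairs = filter_targets(c1, c2)["pairs"]
        assert build_network(pairs, q_rule="any").number_of_edges() == 1
        assert build_network(pairs, q_rule="both").number_of_edges() == 0


class TestCollapseProbes:
    def test_keeps_largest_iqr_probe(self, rng):
        genes = pd.DataFrame(
            [np.zeros(8), rng.normal(0, 5, 8), rng.normal(size=8)],
            index=["p1", "p2", "p3"],
            columns=[f"S{i}" for i in range(8)],
        )
        mapping = pd.Series({"p1": "GENE1", "p2": "GENE1", "p3": "GENE2"})
        out = collapse_probes(genes, mapping)
        assert sorted(out.index) == ["GENE1", "GENE2"]
        np.testing.assert_allclose(out.loc["GENE1"], genes.loc["p2"])
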