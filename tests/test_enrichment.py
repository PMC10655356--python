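"""Tests for reference normalization, enrichment gates and spatial filtering."""

import numpy as np
import pandas as pd
import pytest

import lysokit as lk
from lysokit.errors import AlignmentError, DesignError, NormalizationError, ValidationError


class TestNormalizeToReference:
    def test_division_by_reference(self, small_protein_table):
        t = small_protein_table
        t.intensities.loc["PCCA"] = 2e6
        t.intensities.loc["P0"] = 1e6
        norm = lk.normalize_to_reference(t)
        assert norm.intensities.loc["P0"].to_numpy() == pytest.approx(0.5)
        assert norm.intensities.loc["PCCA"].to_numpy() == pytest.approx(1.0)

    def test_idempotence(self, small_protein_table):
        once = lk.normalize_to_reference(small_protein_table)
        twice = lk.normalize_to_reference(once)
        assert np.allclose(once.intensities, twice.intensities)

    def test_missing_reference_names_sample(self, small_protein_table):
        t = small_protein_table
        t.intensities.loc["PCCA", "bait_1"] = np.nan
        with pytest.raises(NormalizationError, match="bait_1"):
            lk.normalize_to_reference(t)

    def test_absent_reference_rejected(self, small_protein_table):
        with pytest.raises(NormalizationError):
            lk.normalize_to_reference(small_protein_table, reference="NOPE")


class TestDifferentialEnrichment:
    def test_planted_enrichment_recovered(self):
        table, truth = lk.generate_spatial(n_proteins=400, n_planted=40,
                                           planted_fold=4.0, cv=0.2, seed=8)
        model = lk.EnrichmentModel(table)
        res = model.fit(model.select_samples(group="bait"),
                        model.select_samples(group="control"))
        found, planted = res.enriched_set(), set(truth.enriched)
        assert len(found & planted) / len(planted) >= 0.9
        assert len(found - planted) <= max(1, 0.05 * len(found))

    def test_null_data_calls_at_most_alpha_fraction(self):
        calls = []
        for seed in range(20):
            table, _ = lk.generate_spatial(n_proteins=150, n_planted=0, seed=100 + seed)
            model = lk.EnrichmentModel(table)
            res = model.fit(model.select_samples(group="bait"),
                            model.select_samples(group="control"))
            calls.append(len(res.enriched_set()) / len(res.table))
        assert np.mean(calls) <= 0.05

    def test_replicate_minimum_filter(self, small_protein_table):
        t = small_protein_table
        t.intensities.loc["P1", ["bait_0", "bait_1"]] = np.nan
        model = lk.EnrichmentModel(t)
        res = model.fit(model.select_samples(group="bait"),
                        model.select_samples(group="control"))
        assert "P1" not in set(res.table["protein_id"]) and res.n_excluded == 1

    def test_too_few_samples_rejected(self, small_protein_table):
        model = lk.EnrichmentModel(small_protein_table)
        with pytest.raises(DesignError):
            model.fit(["bait_0"], model.select_samples(group="control"))

    def test_gate_consistency_and_label_flip(self):
        table, _ = lk.generate_spatial(n_proteins=200, n_planted=20, seed=9)
        model = lk.EnrichmentModel(table)
        bait = model.select_samples(group="bait")
        ctrl = model.select_samples(group="control")
        fwd = model.fit(bait, ctrl).table.set_index("protein_id")
        rev = model.fit(ctrl, bait).table.set_index("protein_id")
        assert (fwd["enriched"] <= (fwd["passes_p"] & fwd["passes_ratio"])).all()
        assert not (fwd["enriched"] & fwd["depleted"]).any()
        assert np.allclose(fwd["log2_ratio"], -rev.loc[fwd.index, "log2_ratio"])
        assert np.allclose(fwd["p_raw"], rev.loc[fwd.index, "p_raw"])
        assert fwd["enriched"].equals(rev.loc[fwd.index, "depleted"])

    def test_scale_invariance_after_normalization(self):
        table, _ = lk.generate_spatial(n_proteins=100, n_planted=10,
                                       sample_scale_sd=0.0, seed=10)
        scaled_int = table.intensities.copy()
        factors = {s: f for s, f in zip(scaled_int.columns, [0.5, 2.0, 1.3, 0.7] * 2)}
        for s, f in factors.items():
            scaled_int[s] *= f
        scaled = lk.ProteinIntensityTable(scaled_int, table.samples.copy(),
                                          table.gene_symbols.copy())
        m1, m2 = lk.EnrichmentModel(table), lk.EnrichmentModel(scaled)
        bait = m1.select_samples(group="bait")
        ctrl = m1.select_samples(group="control")
        r1 = m1.fit(bait, ctrl).table
        r2 = m2.fit(bait, ctrl).table
        assert np.allclose(r1["log2_ratio"], r2["log2_ratio"])
        assert np.allclose(r1["p_raw"], r2["p_raw"])


def _fake_results(rows, alpha=0.05):
    """Build EnrichmentResults-like objects from (protein, log2_ratio, q) rows."""
    t = pd.DataFrame(rows, columns=["protein_id", "log2_ratio", "q_bh"])
    gate = np.log2(1.5)
    t["p_raw"] = t["q_bh"]
    t["passes_p"] = t["q_bh"] < alpha
    t["passes_ratio"] = t["log2_ratio"].abs() >= gate
    t["enriched"] = t["passes_p"] & (t["log2_ratio"] >= gate)
    t["depleted"] = t["passes_p"] & (t["log2_ratio"] <= -gate)

    class _R:
        table = t
        alpha = 0.05

        def enriched_set(self):
            return set(t.loc[t["enriched"], "protein_id"])

        def universe(self):
            return set(t["protein_id"])

    return _R()


class TestSpatialFilter:
    def test_enriched_vs_both_controls_retained(self):
        noprobe = _fake_results([("P1", 2.0, 0.01), ("P2", 2.0, 0.01)])
        spatial = _fake_results([("P1", 1.5, 0.01), ("P2", 0.0, 0.9)])
        rep = lk.spatial_filter(noprobe, spatial)
        assert rep.retained == {"P1"}
        assert rep.removed_cytosolic == {"P2"}

    def test_flat_vs_noprobe_removed_nonspecific(self):
        noprobe = _fake_results([("P1", 0.1, 0.8), ("P2", 2.0, 0.01)])
        spatial = _fake_results([("P1", 1.5, 0.01), ("P2", 1.5, 0.01)])
        rep = lk.spatial_filter(noprobe, spatial)
        assert rep.removed_nonspecific == {"P1"} and rep.retained == {"P2"}

    def test_ip_mode_without_spatial_control(self):
        noprobe = _fake_results([("P1", 2.0, 0.01), ("P2", 0.0, 0.9)])
        rep = lk.spatial_filter(noprobe)
        assert rep.retained == {"P1"}
        assert rep.removed_cytosolic == set()
        assert rep.removed_nonspecific == {"P2"}

    def test_partition_invariant(self):
        noprobe = _fake_results([("P1", 2.0, 0.01), ("P2", 2.0, 0.01), ("P3", 0.0, 0.9)])
        spatial = _fake_results([("P1", 1.5, 0.01), ("P2", 0.0, 0.9), ("P3", 1.5, 0.01)])
        rep = lk.spatial_filter(noprobe, spatial)
        parts = [rep.retained, rep.removed_cytosolic, rep.removed_nonspecific]
        assert set.union(*parts) == {"P1", "P2", "P3"}
        assert sum(len(p) for p in parts) == 3  # disjoint

    def test_disjoint_universes_rejected(self):
        a = _fake_results([("P1", 2.0, 0.01)])
        b = _fake_results([("Q1", 2.0, 0.01)])
        with pytest.raises(AlignmentError):
            lk.spatial_filter(a, b)


class TestTranslocation:
    def test_rule_instantiation(self):
        lyso = _fake_results([("P1", 1.2, 0.01), ("P2", 1.2, 0.01), ("P3", -1.0, 0.01)])
        cyto = _fake_results([("P1", -0.8, 0.02), ("P2", 0.5, 0.01), ("P3", 0.9, 0.03)])
        calls = lk.translocation_calls(lyso, cyto, alpha=0.05)
        by_id = calls.set_index("protein_id")["direction"]
        assert by_id["P1"] == "to_lysosome"
        assert "P2" not in by_id.index  # same-direction change: no call
        assert by_id["P3"] == "from_lysosome"

    def test_planted_translocators_recovered(self):
        table, truth = lk.generate_spatial(n_proteins=300, n_planted=0,
                                           n_translocators=20, seed=12)
        model = lk.EnrichmentModel(table)
        lyso = model.fit(model.select_samples(group="KO", probe="lyso_bait"),
                         model.select_samples(group="WT", probe="lyso_bait"))
        cyto = model.fit(model.select_samples(group="KO", probe="spatial_control"),
                         model.select_samples(group="WT", probe="spatial_control"))
        calls = lk.translocation_calls(lyso, cyto).set_index("protein_id")["direction"]
        recovered = sum(1 for p, d in truth.translocators.items()
                        if p in calls.index and calls[p] == d)
        # a call needs joint BH significance in both probes, so power is
        # lower than for a single contrast
        assert recovered / len(truth.translocators) >= 0.7
        # no wrong-direction calls among the planted set
        for p, d in truth.translocators.items():
            if p in calls.index:
                assert calls[p] == d


class TestProbeOverlap:
    def test_set_algebra(self):
        out = lk.probe_overlap({"apex": {"A", "B", "C"}, "ip": {"B", "C", "D"}})
        assert out["pairwise_intersections"]["apex&ip"] == 2
        assert out["pairwise_unique"]["apex&ip"] == (1, 1)

    def test_identical_sets(self):
        out = lk.probe_overlap({"a": {"X", "Y"}, "b": {"X", "Y"}})
        assert out["full_intersection"] == 2 == out["sizes"]["a"]

    def test_three_sets_match_brute_force(self):
        rng = np.random.default_rng(13)
        universe = [f"P{i}" for i in range(20)]
        sets = {n: set(rng.choice(universe, size=rng.integers(3, 15), replace=False))
                for n in ("s1", "s2", "s3")}
        out = lk.probe_overlap(sets)
        # brute-force enumeration over the <= 20 elements
        full = sum(1 for p in universe if all(p in s for s in sets.values()))
        assert out["full_intersection"] == full
        for k, (n1, n2) in {"s1&s2": ("s1", "s2"), "s1&s3": ("s1", "s3"),
                            "s2&s3": ("s2", "s3")}.items():
            brute = sum(1 for p in universe if p in sets[n1] and p in sets[n2])
            assert out["pairwise_intersections"][k] == brute

    def test_single_set_rejected(self):
        with pytest.raises(ValidationError):
            lk.probe_overlap({"only": {"A"}})
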