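"""Engine-table filtering, consensus, network counts, restraint mapping."""

import numpy as np
import pandas as pd
import pytest

import ciliabase as cb
from ciliabase.errors import SchemaError
from ciliabase.xlms import KEY_COLUMNS


def make_table(rows):
    return pd.DataFrame(
        rows, columns=["protein_a", "residue_a", "protein_b", "residue_b", "score", "csm_fdr"]
    )


class TestLoadEngineTable:
    def test_fdr_filter_count(self):
        rows = [("P", i, "Q", i + 50, 10.0, 0.001 if i <= 7 else 0.2) for i in range(1, 11)]
        out = cb.load_engine_table(make_table(rows), "e", 0.01)
        assert len(out) == 7

    def test_duplicate_keeps_best_score(self):
        rows = [("P", 3, "Q", 9, 12.1, 0.001), ("P", 3, "Q", 9, 30.0, 0.002)]
        out = cb.load_engine_table(make_table(rows), "e", 0.01)
        assert len(out) == 1 and out.score.iloc[0] == 30.0

    def test_missing_column_named_in_error(self):
        df = make_table([("P", 1, "Q", 2, 1.0, 0.0)]).drop(columns=["csm_fdr"])
        with pytest.raises(SchemaError, match="csm_fdr"):
            cb.load_engine_table(df, "e", 0.01)

    def test_malformed_residues_dropped_not_fatal(self):
        df = make_table([("P", 1, "Q", 2, 1.0, 0.0), ("P", "x", "Q", 3, 1.0, 0.0)])
        out = cb.load_engine_table(df, "e", 0.01)
        assert len(out) == 1

    def test_canonical_side_order(self):
        out = cb.load_engine_table(
            make_table([("ZZZ", 5, "AAA", 7, 1.0, 0.0)]), "e", 0.01
        )
        assert out.protein_a.iloc[0] == "AAA" and out.protein_b.iloc[0] == "ZZZ"

    def test_isoform_suffix_normalization(self):
        out = cb.load_engine_table(
            make_table([("p12345-2", 5, "Q", 7, 1.0, 0.0)]), "e", 0.01
        )
        assert out.protein_a.iloc[0] == "P12345"


class TestConsensus:
    def test_identical_sets(self):
        t = cb.canonicalize(make_table([("P", 1, "Q", 2, 1.0, 0.0)]))
        out = cb.consensus(t, t)
        assert len(out) == 1

    def test_disjoint_sets_empty(self):
        a = cb.canonicalize(make_table([("P", 1, "Q", 2, 1.0, 0.0)]))
        b = cb.canonicalize(make_table([("P", 9, "Q", 2, 1.0, 0.0)]))
        assert len(cb.consensus(a, b)) == 0

    def test_commutative_and_subset(self, planted_crosslinks):
        _, _, ta, tb, _ = planted_crosslinks
        la = cb.load_engine_table(ta, "a", 0.01)
        lb = cb.load_engine_table(tb, "b", 0.05)
        ab = cb.consensus(la, lb)
        ba = cb.consensus(lb, la)
        kab = set(map(tuple, ab[KEY_COLUMNS].itertuples(index=False)))
        kba = set(map(tuple, ba[KEY_COLUMNS].itertuples(index=False)))
        assert kab == kba
        ka = set(map(tuple, la[KEY_COLUMNS].itertuples(index=False)))
        kb = set(map(tuple, lb[KEY_COLUMNS].itertuples(index=False)))
        assert kab <= ka and kab <= kb

    def test_monotone_in_inputs(self, planted_crosslinks):
        _, _, ta, tb, _ = planted_crosslinks
        la = cb.load_engine_table(ta, "a", 0.01)
        lb = cb.load_engine_table(tb, "b", 0.05)
        small = cb.consensus(la.iloc[:40], lb)
        full = cb.consensus(la, lb)
        ks = set(map(tuple, small[KEY_COLUMNS].itertuples(index=False)))
        kf = set(map(tuple, full[KEY_COLUMNS].itertuples(index=False)))
        assert ks <= kf

    def test_planted_truth_precision(self):
        """Consensus of two noisy engines is almost pure true links."""
        sm = cb.gen_structure(3, 150)
        n_true_all, n_false_all = 0, 0
        for seed in range(3):
            m = cb.XlSimModel(
                n_true=500, n_decoy=100, engine_detect_prob=(0.9, 0.8),
                decoy_rate=(0.02, 0.02), seed=seed,
            )
            ta, tb, truth = cb.gen_crosslinks(m, sm)
            cons = cb.consensus(
                cb.load_engine_table(ta, "a", 0.01),
                cb.load_engine_table(tb, "b", 0.05),
            )
            tk = set(map(tuple, truth[truth.is_true][KEY_COLUMNS].itertuples(index=False)))
            ck = set(map(tuple, cons[KEY_COLUMNS].itertuples(index=False)))
            n_true_all += len(ck & tk)
            n_false_all += len(ck - tk)
        precision = n_true_all / (n_true_all + n_false_all)
        assert precision >= 0.99


class TestNetworkStats:
    def test_enumeration_example(self):
        links = cb.canonicalize(
            make_table([("P", 3, "P", 90, 1.0, 0.0), ("P", 5, "Q", 7, 1.0, 0.0)])
        )
        net = cb.network_stats(links)
        assert net.stats() == {"n_unique_links": 2, "n_proteins": 2, "n_ppi": 1}

    def test_empty(self):
        net = cb.network_stats(make_table([]))
        assert net.stats() == {"n_unique_links": 0, "n_proteins": 0, "n_ppi": 0}

    def test_invariant_to_order_and_duplication(self, planted_crosslinks):
        _, _, ta, _, _ = planted_crosslinks
        la = cb.load_engine_table(ta, "a", 0.01)
        shuffled = pd.concat([la.iloc[::-1], la]).reset_index(drop=True)
        assert cb.network_stats(la).stats() == cb.network_stats(shuffled).stats()

    def test_homotypic_option(self):
        links = cb.canonicalize(make_table([("P", 3, "P", 90, 1.0, 0.0)]))
        assert cb.network_stats(links).n_ppi == 0
        assert cb.network_stats(links, include_homotypic_ppi=True).n_ppi == 1


class TestRestraintMapping:
    def test_same_coordinate_distance_zero(self):
        sm = cb.StructureMap()
        sm.add("P", 1, "A", [0, 0, 0])
        sm.add("Q", 2, "B", [0, 0, 0])
        links = cb.canonicalize(make_table([("P", 1, "Q", 2, 1.0, 0.0)]))
        d = cb.map_links(links, sm)
        assert d.distance.iloc[0] == 0.0
        assert cb.restraint_satisfaction(d, 35.0) == (1, 1.0)

    def test_linear_chain_violation(self):
        sm = cb.gen_structure(1, 100, rise=0.38)
        links = cb.canonicalize(make_table([("PROT1", 1, "PROT1", 100, 1.0, 0.0)]))
        d = cb.map_links(links, sm)
        assert np.isclose(d.distance.iloc[0], 376.2)
        n, frac = cb.restraint_satisfaction(d, 35.0)
        assert (n, frac) == (1, 0.0)

    def test_unmapped_links_excluded_from_denominator(self):
        sm = cb.gen_structure(1, 50)
        links = cb.canonicalize(
            make_table([("PROT1", 1, "PROT1", 40, 1.0, 0.0), ("ABSENT", 1, "PROT1", 5, 1.0, 0.0)])
        )
        d = cb.map_links(links, sm)
        assert len(d) == 1

    def test_zero_mapped_fraction_undefined(self):
        n, frac = cb.restraint_satisfaction(np.empty(0), 35.0)
        assert n == 0 and frac is None

    def test_matches_brute_force(self, planted_crosslinks):
        sm, model, _, _, truth = planted_crosslinks
        d = cb.map_links(truth, sm)
        # independent brute force: all-pairs chain-copy minimum per link
        for _, row in d.iterrows():
            ca = sm.coords(row.protein_a, row.residue_a)
            cbb = sm.coords(row.protein_b, row.residue_b)
            brute = min(
                float(np.linalg.norm(x - y)) for x in ca for y in cbb
            )
            assert np.isclose(row.distance, brute)
        n, frac = cb.restraint_satisfaction(d, model.cutoff)
        brute_frac = float((d.distance.to_numpy() <= model.cutoff).mean())
        assert frac == brute_frac

    def test_homodimer_minimum_over_chain_copies(self):
        sm = cb.StructureMap()
        sm.add("P", 10, "A", [0, 0, 0])
        sm.add("P", 10, "B", [30, 0, 0])
        sm.add("P", 80, "A", [100, 0, 0])
        sm.add("P", 80, "B", [40, 0, 0])
        links = cb.canonicalize(make_table([("P", 10, "P", 80, 1.0, 0.0)]))
        d = cb.map_links(links, sm)
        assert d.distance.iloc[0] == 10.0  # B10-B80; naive A10-A80 would be 100


class TestTubulinAndTopology:
    def _net(self, rows):
        return cb.network_stats(cb.canonicalize(make_table(rows)))

    def test_only_tubulin_tubulin_links(self):
        net = self._net([("TUBA", 1, "TUBB", 2, 1.0, 0.0)])
        assert cb.tubulin_partners(net, {"TUBA", "TUBB"}) == set()

    def test_toy_partner_enumeration(self):
        net = self._net(
            [
                ("TUBA", 1, "MLF1", 2, 1.0, 0.0),
                ("TUBA", 9, "DNAJB6", 4, 1.0, 0.0),
                ("MLF1", 5, "SPAG6", 6, 1.0, 0.0),
                ("CETN2", 1, "POC5", 2, 1.0, 0.0),
            ]
        )
        assert cb.tubulin_partners(net, {"TUBA"}) == {"MLF1", "DNAJB6"}

    def test_topology_rule(self):
        links = cb.canonicalize(
            make_table(
                [
                    ("TUBA", 370, "MLF1", 12, 1.0, 0.0),
                    ("TUBA", 370, "CFAP58", 3, 1.0, 0.0),
                    ("TUBA", 55, "CFAP58", 9, 1.0, 0.0),
                ]
            )
        )
        ann = lambda p, r: "lumen" if r == 370 else "exterior"
        assert cb.topology_call(links, "MLF1", {"TUBA"}, ann) == "lumen"
        assert cb.topology_call(links, "CFAP58", {"TUBA"}, ann) == "mixed"
        assert cb.topology_call(links, "ABSENT", {"TUBA"}, ann) == "unknown"
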