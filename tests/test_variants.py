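"""MAF ingestion, panel filtering, carrier frequencies, hotspot rule,
mutation summaries and the pathway graph."""

import pandas as pd
import pytest

import folate_response as fr
from folate_response import variants as var

MAF_HEADER = (
    "Hugo_Symbol\tChromosome\tStart_Position\tEnd_Position\tReference_Allele\t"
    "Tumor_Seq_Allele2\tVariant_Classification\tVariant_Type\tTumor_Sample_Barcode\n"
)


def _labels(resp_ids, nonresp_ids):
    return pd.DataFrame(
        {
            "patient_id": list(resp_ids) + list(nonresp_ids),
            "label": [fr.RESPONDER] * len(resp_ids)
            + [fr.NON_RESPONDER] * len(nonresp_ids),
        }
    )


def _record(pid="p1", gene="MTRR", chrom="1", pos=100, ref="C", alt="T",
            cls="missense", vtype="SNP"):
    return fr.VariantRecord(pid, gene, chrom, pos, ref, alt, cls, vtype)


class TestReadVariants:
    def test_three_line_fixture(self, tmp_path):
        maf = tmp_path / "t.maf"
        maf.write_text(
            MAF_HEADER
            + "MTRR\t5\t7870000\t7870000\tC\tT\tMissense_Mutation\tSNP\tp1\n"
            + "CHAT\t10\t49610000\t49610000\tG\tA\tSilent\tSNP\tp1\n"
            + "TYMS\t18\t657000\t657001\tCA\tC\tFrame_Shift_Del\tDEL\tp2\n"
        )
        records = var.read_variants(maf)
        assert len(records) == 3
        assert records[0].snv_class == "C>T"
        assert records[1].snv_class == "C>T"  # G>A collapses to the pyrimidine
        assert records[2].variant_type == "DEL" and records[2].snv_class is None

    def test_missing_column_named(self, tmp_path):
        maf = tmp_path / "bad.maf"
        maf.write_text("Hugo_Symbol\tChromosome\n" + "MTRR\t5\n")
        with pytest.raises(ValueError, match="Start_Position"):
            var.read_variants(maf)

    def test_unknown_classification_warns_to_other(self, tmp_path):
        maf = tmp_path / "u.maf"
        maf.write_text(
            MAF_HEADER + "MTRR\t5\t100\t100\tC\tT\tTranslation_Start_Site\tSNP\tp1\n"
        )
        with pytest.warns(UserWarning, match="other"):
            records = var.read_variants(maf)
        assert records[0].variant_classification == "other"

    def test_round_trip(self, tmp_path, dataset):
        path = tmp_path / "rt.maf"
        var.write_variants(dataset.variants, path)
        back = var.read_variants(path)
        assert [v.variant_key for v in back] == [
            v.variant_key for v in dataset.variants
        ]
        assert [v.variant_classification for v in back] == [
            v.variant_classification for v in dataset.variants
        ]


class TestPanelRestriction:
    REGION = [fr.PanelRegion("1", 100, 101, "G1")]

    def test_boundary_conventions(self):
        kept = var.restrict_to_panel([_record(pos=101)], self.REGION)
        assert len(kept) == 1  # 1-based 101 is the base at 0-based 100
        kept = var.restrict_to_panel([_record(pos=100)], self.REGION)
        assert kept == []
        kept = var.restrict_to_panel([_record(pos=102)], self.REGION)
        assert kept == []

    def test_planted_variants_survive_panel(self, dataset):
        on_panel = var.restrict_to_panel(dataset.variants, dataset.panel)
        assert len(on_panel) == len(dataset.variants)  # generator plants in-panel
        off = _record(chrom="9", pos=999_999_999)
        assert var.restrict_to_panel([off], dataset.panel) == []

    def test_empty_region_list_raises(self):
        with pytest.raises(ValueError):
            var.restrict_to_panel([_record()], [])


class TestAnnotationSplit:
    def test_uncertain_significance_counts_as_classified(self):
        v = _record()
        db = {v.variant_key: "Uncertain significance"}
        classified, unclassified = var.classify_by_annotation([v], db)
        assert classified == [v] and unclassified == []

    def test_absent_key_unclassified(self):
        v = _record()
        classified, unclassified = var.classify_by_annotation([v], {})
        assert classified == [] and unclassified == [v]

    def test_partition_is_exact(self, dataset):
        classified, unclassified = var.classify_by_annotation(
            dataset.variants, dataset.annotation_db
        )
        assert len(classified) + len(unclassified) == len(dataset.variants)
        assert not {id(v) for v in classified} & {id(v) for v in unclassified}

    def test_malformed_rows_skipped(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "variant_key\tclinical_significance\n"
            "1:100:C:T\tPathogenic\n"
            "garbage-row\n"
            "not:a:key\tBenign\n"
        )
        with pytest.warns(UserWarning, match="malformed"):
            db = var.read_annotation(path)
        assert db == {"1:100:C:T": "Pathogenic"}


class TestCarrierFrequency:
    @pytest.mark.parametrize(
        "carriers,size,percent",
        [(21, 22, 95.45), (1, 21, 4.76), (18, 22, 81.82), (16, 22, 72.73)],
    )
    def test_printed_fractions(self, carriers, size, percent):
        resp = [f"r{i}" for i in range(size)]
        nonresp = [f"n{i}" for i in range(size)]
        labels = _labels(resp, nonresp)
        records = [_record(pid=p) for p in nonresp[:carriers]]
        freq = var.carrier_frequency(records, labels, records[0].variant_key)
        assert freq[fr.NON_RESPONDER] == (carriers, size, percent)

    def test_multiplicity_counts_once(self):
        labels = _labels(["r1"], ["n1", "n2"])
        records = [_record(pid="n1"), _record(pid="n1")]
        freq = var.carrier_frequency(records, labels, records[0].variant_key)
        assert freq[fr.NON_RESPONDER] == (1, 2, 50.0)

    def test_unknown_patient_raises(self):
        labels = _labels(["r1"], ["n1"])
        with pytest.raises(ValueError, match="not a labeled patient"):
            var.carrier_frequency([_record(pid="ghost")], labels, _record().variant_key)

    def test_planted_frequencies_exact(self, dataset, labels):
        planted = {pv.variant_key: pv for pv in fr.SimConfig().planted_variants}
        freqs = {
            c.variant_key: c
            for c in var.compute_frequencies(dataset.variants, labels)
        }
        for key, pv in planted.items():
            call = freqs[key]
            assert call.carriers_responder == pv.carriers_responder
            assert call.carriers_nonresponder == pv.carriers_nonresponder


class TestHotspotRule:
    def _call(self, freq_r_carriers, freq_n_carriers, sizes=(10000, 10000)):
        return var.HotspotCall(
            "1:1:C:T", "G", "", "", freq_r_carriers, freq_n_carriers, *sizes
        )

    @pytest.mark.parametrize(
        "freq_n,freq_r,node,highlighted",
        [
            (95.45, 4.76, True, True),
            (70.00, 49.99, True, True),
            (69.99, 0.00, True, False),  # node (>= 50) but below highlight-in
            (70.00, 50.00, True, False),  # responder side fails strict < 50
            (49.90, 0.00, False, False),
        ],
    )
    def test_boundary_semantics(self, freq_n, freq_r, node, highlighted):
        call = self._call(round(freq_r * 100), round(freq_n * 100))
        assert call.freq_nonresponder == pytest.approx(freq_n)
        out = var.call_hotspots([call])[0]
        assert out.is_graph_node is node
        assert out.is_highlighted is highlighted

    def test_node_threshold_monotone(self, dataset, labels):
        freqs = var.compute_frequencies(dataset.variants, labels)
        nodes = None
        for thr in (30.0, 50.0, 70.0, 90.0):
            current = {
                c.variant_key
                for c in var.call_hotspots(freqs, node_threshold=thr)
                if c.is_graph_node
            }
            if nodes is not None:
                assert current <= nodes
            nodes = current


class TestMutationSummary:
    def test_multi_hit_rule(self):
        records = [
            _record(pid="p1", gene="MTRR", pos=100),
            _record(pid="p1", gene="MTRR", pos=200),
            _record(pid="p1", gene="CHAT", pos=300),
        ]
        summary = var.summarize_mutations(records)
        assert summary.oncomatrix.loc["MTRR", "p1"] == "Multi_Hit"
        assert summary.oncomatrix.loc["CHAT", "p1"] == "missense"

    def test_single_silent_cohort(self):
        summary = var.summarize_mutations([_record(cls="silent")])
        assert summary.classification_counts == {"silent": 1}

    def test_top_gene_tie_break_lexicographic(self):
        records = [
            _record(pid="p1", gene="ZZZ", pos=1),
            _record(pid="p1", gene="AAA", pos=2),
            _record(pid="p2", gene="MMM", pos=3),
        ]
        summary = var.summarize_mutations(records, top_k=2)
        assert summary.top_genes == ["AAA", "MMM"]

    def test_counts_sum_to_total(self, dataset):
        summary = var.summarize_mutations(dataset.variants)
        assert sum(summary.classification_counts.values()) == len(dataset.variants)
        assert sum(summary.type_counts.values()) == len(dataset.variants)


class TestBruteForceOracle:
    """Exhaustive-style equivalence on tiny cohorts against naive recounts."""

    def _random_cohort(self, rng):
        n_r = int(rng.integers(1, 3))
        n_n = int(rng.integers(1, 4))
        resp = [f"r{i}" for i in range(n_r)]
        nonresp = [f"n{i}" for i in range(n_n)]
        labels = _labels(resp, nonresp)
        pool = resp + nonresp
        genes = ["MTRR", "CHAT", "TYMS"]
        keys = [("1", 100 + k) for k in range(4)]
        records = []
        for _ in range(int(rng.integers(1, 11))):
            chrom, pos = keys[rng.integers(len(keys))]
            records.append(
                _record(
                    pid=pool[rng.integers(len(pool))],
                    gene=genes[rng.integers(len(genes))],
                    chrom=chrom,
                    pos=int(pos),
                )
            )
        db = {r.variant_key: "Pathogenic" for r in records[:: 2]}
        return labels, records, db

    def test_matches_naive_recount(self, rng):
        for _ in range(40):
            labels, records, db = self._random_cohort(rng)
            label_map = dict(zip(labels["patient_id"], labels["label"]))
            # naive carrier recount
            for call in var.compute_frequencies(records, labels):
                for group, attr in (
                    (fr.RESPONDER, "carriers_responder"),
                    (fr.NON_RESPONDER, "carriers_nonresponder"),
                ):
                    naive = len(
                        {
                            r.patient_id
                            for r in records
                            if r.variant_key == call.variant_key
                            and label_map[r.patient_id] == group
                        }
                    )
                    assert getattr(call, attr) == naive
            # naive classified split
            classified, unclassified = var.classify_by_annotation(records, db)
            assert [v in classified for v in records] == [
                bool(db.get(v.variant_key)) for v in records
            ]
            # naive Multi_Hit recount
            summary = var.summarize_mutations(records)
            for gene in summary.oncomatrix.index:
                for pid in summary.oncomatrix.columns:
                    hits = [
                        r for r in records if r.gene == gene and r.patient_id == pid
                    ]
                    cell = summary.oncomatrix.loc[gene, pid]
                    if len(hits) >= 2:
                        assert cell == "Multi_Hit"
                    elif len(hits) == 1:
                        assert cell == hits[0].variant_classification
                    else:
                        assert cell == ""


class TestPathwayGraph:
    def test_highlighted_edge_count(self, dataset, labels):
        freqs = var.compute_frequencies(dataset.variants, labels, dataset.pathway_map)
        hotspots = var.call_hotspots(freqs)
        graph = var.build_pathway_graph(hotspots, dataset.pathway_map)
        # one mutation node may fan out to several pathway hubs
        highlighted_muts = {
            u if graph.nodes[u]["kind"] == "mutation" else v
            for u, v, d in graph.edges(data=True)
            if d["highlighted"]
        }
        assert len(highlighted_muts) == 4
        genes = {graph.nodes[m]["gene"] for m in highlighted_muts}
        assert genes == {"PRMT3", "TYMS", "DNMT3A", "HIF3A"}

    def test_gene_in_two_pathways_two_edges(self):
        call = var.HotspotCall("1:1:C:T", "TYMS", "c.*89A > G", "", 1, 18, 21, 22)
        call = var.call_hotspots([call])[0]
        graph = var.build_pathway_graph([call], {"TYMS": ["methionine cycle", "folate cycle"]})
        mut = [n for n, d in graph.nodes(data=True) if d["kind"] == "mutation"]
        assert len(mut) == 1 and graph.degree(mut[0]) == 2

    def test_no_nodes_below_threshold(self):
        call = var.HotspotCall("1:1:C:T", "G", "", "", 0, 4, 21, 22)  # 18.18%
        call = var.call_hotspots([call])[0]
        with pytest.warns(UserWarning, match="graph is empty"):
            graph = var.build_pathway_graph([call], {"G": ["folate cycle"]})
        assert graph.number_of_nodes() == 0

    def test_unmapped_gene_goes_to_catch_all(self):
        call = var.call_hotspots(
            [var.HotspotCall("1:1:C:T", "NOVEL", "", "", 0, 22, 21, 22)]
        )[0]
        with pytest.warns(UserWarning, match="no pathway mapping"):
            graph = var.build_pathway_graph([call], {})
        assert var.UNMAPPED_PATHWAY in graph

    def test_dot_and_graphml_exports(self, tmp_path, dataset, labels):
        freqs = var.compute_frequencies(dataset.variants, labels, dataset.pathway_map)
        graph = var.build_pathway_graph(var.call_hotspots(freqs), dataset.pathway_map)
        var.write_graphml(graph, tmp_path / "g.graphml")
        var.write_dot(graph, tmp_path / "g.dot")
        dot = (tmp_path / "g.dot").read_text()
        assert dot.count("style=dashed") == sum(
            1 for _, _, d in graph.edges(data=True) if d["highlighted"]
        )
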