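import networkx as nx
import numpy as np
import pytest

from isoscan.core import GenomicInterval, Transcript
from isoscan.decode import (
    DecoderConfig,
    ScoredPath,
    cluster_loci,
    evaluate_predictions,
    kbest_decode,
    postfilter,
    predict_region,
)
from isoscan.ghmm import sample_with_paths

from helpers import assert_same_ranking, enumerate_paths, random_toy_sequence


def T(tid, exons, strand="+", gene=None, seq="chr1", tag="ALTSCAN"):
    ivs = tuple(GenomicInterval(seq, s, e, strand) for s, e in exons)
    return Transcript(
        tid, gene or tid, ivs, min(e.start for e in ivs), max(e.end for e in ivs), tag
    )


class TestDecoderConfig:
    def test_published_defaults(self):
        cfg = DecoderConfig()
        assert cfg.top_n == 250
        assert cfg.padding == 5000
        assert cfg.min_intron == 20

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            DecoderConfig(top_n=0)
        with pytest.raises(ValueError):
            DecoderConfig(padding=-1)


class TestKbestDecode:
    def test_top1_equals_head_of_top10(self, toy_multiexon_spec):
        rng = np.random.default_rng(7)
        for i in range(20):
            seq = random_toy_sequence(rng, 30, ("single_exon", "two_exon")[i % 2])
            one = kbest_decode(toy_multiexon_spec, seq, DecoderConfig(top_n=1, padding=0))
            ten = kbest_decode(toy_multiexon_spec, seq, DecoderConfig(top_n=10, padding=0))
            assert one[0].path == ten[0].path
            assert one[0].log_score == pytest.approx(ten[0].log_score, abs=1e-9)

    def test_prefix_property(self, toy_multiexon_spec):
        rng = np.random.default_rng(11)
        for i in range(20):
            seq = random_toy_sequence(rng, 30, ("single_exon", "two_exon")[i % 2])
            three = kbest_decode(toy_multiexon_spec, seq, DecoderConfig(top_n=3, padding=0))
            ten = kbest_decode(toy_multiexon_spec, seq, DecoderConfig(top_n=10, padding=0))
            assert [p.path for p in three] == [p.path for p in ten[: len(three)]]

    def test_scores_non_increasing_and_paths_distinct(self, toy_multiexon_spec):
        rng = np.random.default_rng(13)
        seq = random_toy_sequence(rng, 30, "two_exon")
        paths = kbest_decode(toy_multiexon_spec, seq, DecoderConfig(top_n=10, padding=0))
        scores = [p.log_score for p in paths]
        assert scores == sorted(scores, reverse=True)
        assert len({p.path for p in paths}) == len(paths)
        assert paths[0].is_suboptimal is False
        if len(paths) > 1:
            assert paths[1].is_suboptimal is True

    def test_matches_enumeration_on_small_inputs(self, toy_multiexon_spec):
        rng = np.random.default_rng(5)
        for i in range(30):
            kind = ("random", "single_exon", "two_exon")[i % 3]
            seq = random_toy_sequence(rng, 30, kind)
            enum = enumerate_paths(toy_multiexon_spec, seq)
            dec = kbest_decode(toy_multiexon_spec, seq, DecoderConfig(top_n=5, padding=0))
            assert_same_ranking(dec, enum, 5)

    def test_no_legal_path_returns_empty_list(self, toy_spec):
        import dataclasses

        # a model whose only start state cannot be used: no intergenic
        # duration model means no segmentation can begin
        crippled = dataclasses.replace(
            toy_spec, durations={k: v for k, v in toy_spec.durations.items() if k != "N"}
        )
        assert kbest_decode(crippled, "ACGTACGT", DecoderConfig(top_n=5, padding=0)) == []

    def test_empty_sequence_rejected(self, toy_spec):
        with pytest.raises(ValueError):
            kbest_decode(toy_spec, "", DecoderConfig(top_n=5))

    def test_decoded_scores_match_path_scorer(self, spec):
        from isoscan.ghmm import log_score_path

        seq, _, _ = sample_with_paths(spec, 1500, seed=21)
        for p in kbest_decode(spec, seq, DecoderConfig(top_n=20, max_intron=400))[:5]:
            assert log_score_path(spec, seq, p.path) == pytest.approx(
                p.log_score, abs=1e-6
            )

    def test_sampled_structures_recovered(self, spec):
        """Parameter recovery: every sampled transcript reappears among the
        postfiltered top-300 paths in >= 95% of 100 seeded trials."""
        hits = 0
        for seed in range(1, 101):
            seq, ts, _ = sample_with_paths(spec, 2000, seed)
            cfg = DecoderConfig(top_n=300, max_intron=500)
            paths = kbest_decode(spec, seq, cfg, sequence_id="chr_sim")
            kept = postfilter(paths, cfg, genome={"chr_sim": seq})
            if {t.cds_key() for t in ts} <= {t.cds_key() for t in kept}:
                hits += 1
        assert hits >= 95


class TestPostfilter:
    def _scored(self, rank, score, transcripts):
        return ScoredPath(rank=rank, log_score=score, path=(), transcripts=tuple(transcripts))

    def test_duplicate_cds_keeps_highest_scoring(self):
        a = T("a", [(0, 99)])
        b = T("b", [(0, 99)])
        paths = [self._scored(1, -10.0, [a]), self._scored(2, -20.0, [b])]
        kept = postfilter(paths, DecoderConfig(top_n=5))
        assert [t.transcript_id for t in kept] == ["a"]

    def test_short_intron_removed(self):
        t = T("t", [(0, 30), (49, 79)])  # 19 nt intron
        ok = T("u", [(0, 30), (50, 80)])  # 20 nt intron
        paths = [self._scored(1, -1.0, [t, ok])]
        kept = postfilter(paths, DecoderConfig(top_n=5))
        assert [x.transcript_id for x in kept] == ["u"]

    def test_incomplete_orf_removed_with_genome(self):
        genome = {"chr1": "A" * 10 + "ATG" + "GCC" * 4 + "TAA" + "A" * 40}
        good = T("g", [(10, 28)])
        bad = T("b", [(12, 30)])  # frame-shifted window, no ATG start
        paths = [self._scored(1, -1.0, [good, bad])]
        kept = postfilter(paths, DecoderConfig(top_n=5), genome=genome)
        assert [t.transcript_id for t in kept] == ["g"]

    def test_never_increases_transcript_count(self):
        rng = np.random.default_rng(3)
        paths = []
        for r in range(1, 20):
            s = int(rng.integers(0, 500))
            w = int(rng.integers(6, 60)) * 3
            paths.append(self._scored(r, -float(r), [T(f"t{r}", [(s, s + w)])]))
        assert len(postfilter(paths, DecoderConfig(top_n=50))) <= 19

    def test_matches_three_comprehension_oracle(self):
        """Random 50-path fixture versus sequential predicate filtering."""
        rng = np.random.default_rng(17)
        paths = []
        for r in range(1, 51):
            s = int(rng.integers(0, 2000))
            l1 = int(rng.integers(10, 100))
            gap = int(rng.integers(15, 30))  # some below the minimum intron
            l2 = int(rng.integers(10, 100))
            exons = [(s, s + l1), (s + l1 + gap, s + l1 + gap + l2)]
            paths.append(self._scored(r, -float(r), [T(f"t{r}", exons)]))
        cfg = DecoderConfig(top_n=100, min_intron=20)
        got = postfilter(paths, cfg)

        flat = [(p.log_score, t) for p in paths for t in p.transcripts]
        complete = [(s, t) for s, t in flat if t.cds_length() % 3 == 0 and t.cds_length() >= 6]
        no_short = [
            (s, t)
            for s, t in complete
            if all(e - b >= cfg.min_intron for b, e in t.introns())
        ]
        seen, expected = set(), []
        for s, t in sorted(no_short, key=lambda x: -x[0]):
            if t.cds_key() not in seen:
                seen.add(t.cds_key())
                expected.append(t.transcript_id)
        assert [t.transcript_id for t in got] == expected


class TestClusterLoci:
    def test_disjoint_transcripts_make_two_loci(self):
        loci = cluster_loci([T("a", [(0, 99)]), T("b", [(200, 299)])])
        assert len(loci) == 2

    def test_bridging_transcript_merges_loci(self):
        a = T("a", [(0, 100)])
        b = T("b", [(90, 210)])
        c = T("c", [(200, 300)])
        assert len(cluster_loci([a, b, c])) == 1
        assert len(cluster_loci([a, c])) == 2

    def test_strands_kept_separate(self):
        a = T("a", [(0, 100)], strand="+")
        b = T("b", [(50, 150)], strand="-")
        assert len(cluster_loci([a, b])) == 2

    def test_matches_graph_components_oracle(self):
        rng = np.random.default_rng(23)
        ts = []
        for i in range(100):
            s = int(rng.integers(0, 3000))
            ts.append(T(f"t{i}", [(s, s + int(rng.integers(30, 400)))]))
        loci = cluster_loci(ts)
        g = nx.Graph()
        g.add_nodes_from(t.transcript_id for t in ts)
        for i, a in enumerate(ts):
            for b in ts[i + 1 :]:
                if a.span.start < b.span.end and b.span.start < a.span.end:
                    g.add_edge(a.transcript_id, b.transcript_id)
        expected = {frozenset(c) for c in nx.connected_components(g)}
        got = {frozenset(t.transcript_id for t in members) for members in loci.values()}
        assert got == expected

    def test_adding_transcripts_never_increases_locus_count(self):
        rng = np.random.default_rng(29)
        ts = [
            T(f"t{i}", [(int(s), int(s) + 120)])
            for i, s in enumerate(rng.integers(0, 2000, size=30))
        ]
        n_before = len(cluster_loci(ts))
        extra = [T("x", [(0, 2500)])]  # bridges many
        assert len(cluster_loci(ts + extra)) <= n_before


class TestEvaluatePredictions:
    def test_perfect_prediction(self):
        ref = [T("r1", [(0, 99)], gene="g1"), T("r2", [(200, 350)], gene="g2")]
        out = evaluate_predictions(ref, ref)
        assert out["transcript_sn"] == out["transcript_sp"] == 1.0
        assert out["gene_sn"] == out["gene_sp"] == 1.0

    def test_counting_example(self):
        ref = [T(f"r{i}", [(i * 1000, i * 1000 + 99)], gene=f"g{i}") for i in range(4)]
        preds = [T("p0", [(0, 99)], gene="pg0")] + [
            T(f"p{i}", [(i * 1000 + 5, i * 1000 + 98)], gene=f"pg{i}")
            for i in range(1, 10)
        ]
        out = evaluate_predictions(preds, ref)
        assert out["transcript_sn"] == pytest.approx(0.25)
        assert out["transcript_sp"] == pytest.approx(0.1)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            evaluate_predictions([T("p", [(0, 99)])], [])

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(31)
        def rand_t(tag, i):
            s = int(rng.integers(0, 50)) * 100
            return T(f"{tag}{i}", [(s, s + 99)], gene=f"g_{tag}{s}")

        ref = [rand_t("r", i) for i in range(30)]
        preds = [rand_t("p", i) for i in range(40)]
        out = evaluate_predictions(preds, ref)
        matched_ref = sum(
            1 for r in ref if any(r.cds_key() == p.cds_key() for p in preds)
        )
        matched_pred = sum(
            1 for p in preds if any(r.cds_key() == p.cds_key() for r in ref)
        )
        assert out["transcript_sn"] == pytest.approx(matched_ref / 30)
        assert out["transcript_sp"] == pytest.approx(matched_pred / 40)


class TestPredictRegion:
    def test_reverse_strand_predictions_mirror_forward(self, spec, small_genome):
        from isoscan.ghmm import revcomp

        genome, ts = small_genome
        (seq_id, seq), = genome.items()
        flipped = {seq_id: revcomp(seq)}
        cfg = DecoderConfig(top_n=20, padding=0, max_intron=400)
        region_fwd = GenomicInterval(seq_id, 0, len(seq), "+")
        region_rev = GenomicInterval(seq_id, 0, len(seq), "-")
        fwd = predict_region(spec, genome, region_fwd, cfg)
        rev = predict_region(spec, flipped, region_rev, cfg)
        L = len(seq)
        mirrored = {
            tuple(sorted((L - e.end, L - e.start) for e in t.exons)) for t in rev
        }
        assert {tuple(sorted((e.start, e.end) for e in t.exons)) for t in fwd} == mirrored
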