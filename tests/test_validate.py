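import itertools

import numpy as np
import pytest

from isoscan.core import AlignmentRecord, GenomicInterval, Transcript
from isoscan.ghmm import revcomp
from isoscan.fixtures import FixtureConfig, make_genome, make_reads
from isoscan.validate import (
    ValidationConfig,
    build_mature,
    cds_coverage,
    pcr_panel_summary,
    saturation_curve,
    tally_junctions,
    validate_transcripts,
)


def two_exon_transcript(seq_id="chr1", strand="+", tag="ALTSCAN"):
    exons = (
        GenomicInterval(seq_id, 100, 160, strand),
        GenomicInterval(seq_id, 190, 280, strand),
    )
    return Transcript("t1", "g1", exons, 100, 280, tag)


@pytest.fixture()
def toy_genome():
    rng = np.random.default_rng(0)
    return {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, size=400))}


class TestValidationConfig:
    def test_standard_fixes_l10_m1(self):
        with pytest.raises(ValueError):
            ValidationConfig(strategy_name="standard", L=8, M=1)

    def test_stringent_requires_m6_l8(self):
        with pytest.raises(ValueError):
            ValidationConfig.stringent(L=7)
        with pytest.raises(ValueError):
            ValidationConfig.stringent(M=5)
        cfg = ValidationConfig.stringent()
        assert (cfg.L, cfg.M) == (8, 6)


class TestBuildMature:
    def test_flank_plus_spliced_cds_arithmetic(self, toy_genome):
        t = two_exon_transcript()
        mature = build_mature([t], toy_genome, ValidationConfig.standard())["t1"]
        assert len(mature.sequence) == 100 + 60 + 90 + 100
        ((off, key),) = mature.junctions
        assert off == 160
        assert key == ("chr1", 160, 190, "+")
        assert mature.cds_interval == (100, 250)

    def test_minus_strand_is_reverse_complement_of_plus(self, toy_genome):
        plus = build_mature([two_exon_transcript()], toy_genome)["t1"]
        minus = build_mature([two_exon_transcript(strand="-")], toy_genome)["t1"]
        assert minus.sequence == revcomp(plus.sequence)
        ((off_p, _),) = plus.junctions
        ((off_m, _),) = minus.junctions
        assert off_m == len(plus.sequence) - off_p

    def test_mature_equals_hand_spliced_string(self, toy_genome):
        t = two_exon_transcript()
        seq = toy_genome["chr1"]
        expected = seq[0:100] + seq[100:160] + seq[190:280] + seq[280:380]
        mature = build_mature([t], toy_genome)["t1"]
        assert mature.sequence == expected

    def test_flank_truncated_at_chromosome_start(self, toy_genome):
        exons = (GenomicInterval("chr1", 10, 70, "+"), GenomicInterval("chr1", 100, 160, "+"))
        t = Transcript("t", "g", exons, 10, 160, "ALTSCAN")
        mature = build_mature([t], toy_genome)["t"]
        assert len(mature.sequence) == 10 + 60 + 60 + 100
        assert mature.junctions[0][0] == 10 + 60


def reads_at(target, junction_offset, pairs, length=50, start_id=0):
    """Reads with prescribed (left, right) overhangs around a junction."""
    out = []
    for i, (left, right) in enumerate(pairs):
        s = junction_offset - left
        out.append(
            AlignmentRecord(f"r{start_id + i}", target, s, left + right)
        )
    return out


class TestTallyJunctions:
    def test_exact_boundary_counts_at_l(self, toy_genome):
        t = two_exon_transcript()
        mature = build_mature([t], toy_genome)
        cfg = ValidationConfig.standard()
        ok = reads_at("t1", 160, [(10, 10)])
        short = reads_at("t1", 160, [(9, 11)], start_id=1)
        key = ("chr1", 160, 190, "+")
        assert tally_junctions(ok, mature, cfg)[key].jc == 1
        assert tally_junctions(short, mature, cfg)[key].jc == 0

    def test_stringent_needs_m_reads(self, toy_genome):
        t = two_exon_transcript()
        mature = build_mature([t], toy_genome)
        cfg = ValidationConfig.stringent()  # L=8, M=6
        five = reads_at("t1", 160, [(8, 8)] * 5)
        ev = tally_junctions(five, mature, cfg)
        key = ("chr1", 160, 190, "+")
        assert ev[key].jc == 5
        assert ev[key].jc < cfg.M  # junction NOT covered
        six = reads_at("t1", 160, [(8, 8)] * 6)
        assert tally_junctions(six, mature, cfg)[key].jc >= cfg.M

    def test_unknown_targets_skipped(self, toy_genome):
        t = two_exon_transcript()
        mature = build_mature([t], toy_genome)
        recs = reads_at("nope", 160, [(10, 10)])
        ev = tally_junctions(recs, mature, ValidationConfig.standard())
        assert ev[("chr1", 160, 190, "+")].jc == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_read_oracle(self, seed):
        """Random reads over a 3-junction transcript vs brute force."""
        rng = np.random.default_rng(seed)
        exons = [(0, 60), (80, 150), (200, 260), (300, 390)]
        genome = {
            "c": "".join("ACGT"[i] for i in rng.integers(0, 4, size=500))
        }
        ivs = tuple(GenomicInterval("c", s, e, "+") for s, e in exons)
        t = Transcript("t", "g", ivs, 0, 390, "ALTSCAN")
        cfg = ValidationConfig.standard(flank=20)
        mature = build_mature([t], genome, cfg)
        mlen = len(mature["t"].sequence)
        reads = []
        for i in range(150):
            ln = int(rng.integers(20, 80))
            s = int(rng.integers(0, mlen - ln))
            reads.append(AlignmentRecord(f"r{i}", "t", s, ln))
        ev = tally_junctions(reads, mature, cfg)
        for off, key in mature["t"].junctions:
            expected = sum(
                1
                for r in reads
                if r.target_start <= off - cfg.L
                and r.target_start + r.aligned_length >= off + cfg.L
            )
            assert ev[key].jc == expected

    def test_jc_pooled_across_mature_transcripts(self, toy_genome):
        a = two_exon_transcript()
        b = Transcript("t2", "g1", a.exons, 100, 280, "MIXTURE")
        mature = build_mature([a, b], toy_genome)
        reads = reads_at("t1", 160, [(12, 12)]) + reads_at("t2", 160, [(12, 12)], start_id=5)
        ev = tally_junctions(reads, mature, ValidationConfig.standard())
        assert ev[("chr1", 160, 190, "+")].jc == 2


class TestValidateTranscripts:
    def _evidence(self, transcripts, genome, reads_by_ds, flank=100):
        cfg_std = ValidationConfig.standard(flank=flank)
        cfg_str = ValidationConfig.stringent(flank=flank)
        mature = build_mature(transcripts, genome, cfg_std)
        ev_std = {ds: tally_junctions(r, mature, cfg_std) for ds, r in reads_by_ds.items()}
        ev_str = {ds: tally_junctions(r, mature, cfg_str) for ds, r in reads_by_ds.items()}
        cov = {ds: cds_coverage(r, mature, cfg_std) for ds, r in reads_by_ds.items()}
        return ev_std, ev_str, cov, cfg_std, cfg_str

    def test_novel_with_nij_covered_stringently_is_vhc(self, toy_genome):
        t = two_exon_transcript()
        reads = {"ds1": reads_at("t1", 160, [(12, 12)] * 6)}
        ev_std, ev_str, cov, cs, cg = self._evidence([t], toy_genome, reads)
        (v,) = validate_transcripts([t], [], ev_std, ev_str, cs, cg, coverage_standard=cov)
        assert v.tier == "VHC"

    def test_novel_with_nij_standard_only_is_vmc(self, toy_genome):
        t = two_exon_transcript()
        reads = {"ds1": reads_at("t1", 160, [(12, 12)] * 2)}  # jc=2 < 6
        ev_std, ev_str, cov, cs, cg = self._evidence([t], toy_genome, reads)
        (v,) = validate_transcripts([t], [], ev_std, ev_str, cs, cg, coverage_standard=cov)
        assert v.tier == "VMC"

    def test_all_junctions_known_is_vlc_even_if_covered(self, toy_genome):
        novel = two_exon_transcript()
        # known isoform shares the junction but has a longer terminal exon
        exons = (
            GenomicInterval("chr1", 100, 160, "+"),
            GenomicInterval("chr1", 190, 300, "+"),
        )
        known = Transcript("k1", "g1", exons, 100, 300, "KNOWN")
        reads = {"ds1": reads_at("t1", 160, [(12, 12)] * 8)}
        ev_std, ev_str, cov, cs, cg = self._evidence([novel, known], toy_genome, reads)
        verdicts = validate_transcripts(
            [novel, known], [known], ev_std, ev_str, cs, cg, coverage_standard=cov
        )
        by_id = {v.transcript_id: v for v in verdicts}
        assert by_id["t1"].tier == "VLC"
        assert by_id["k1"].tier == "KNOWN_VALIDATED"

    def test_single_exon_validated_by_coverage_is_vlc(self, toy_genome):
        exon = (GenomicInterval("chr1", 100, 220, "+"),)
        t = Transcript("s1", "g1", exon, 100, 220, "ALTSCAN")
        mature = build_mature([t], toy_genome)
        mlen = len(mature["s1"].sequence)
        reads = [
            AlignmentRecord(f"r{i}", "s1", s, 60)
            for i, s in enumerate(range(0, mlen - 60, 30))
        ]
        ev_std, ev_str, cov, cs, cg = self._evidence([t], toy_genome, {"ds1": reads})
        (v,) = validate_transcripts([t], [], ev_std, ev_str, cs, cg, coverage_standard=cov)
        assert v.tier == "VLC"

    def test_zero_exon_rejected(self, toy_genome):
        t = two_exon_transcript()
        object.__setattr__(t, "exons", ())
        with pytest.raises((ValueError, IndexError)):
            validate_transcripts([t], [], {"d": {}}, None)

    def test_tissue_specific_flag(self, toy_genome):
        t = two_exon_transcript()
        reads = {f"ds{i}": reads_at("t1", 160, [(12, 12)]) for i in range(6)}
        ev_std, ev_str, cov, cs, cg = self._evidence([t], toy_genome, reads)
        (v,) = validate_transcripts([t], [], ev_std, ev_str, cs, cg, coverage_standard=cov)
        assert v.n_datasets_validated == 6
        assert not v.tissue_specific
        one = {"ds0": reads["ds0"]}
        ev_std, ev_str, cov, cs, cg = self._evidence([t], toy_genome, one)
        (v,) = validate_transcripts([t], [], ev_std, ev_str, cs, cg, coverage_standard=cov)
        assert v.tissue_specific

    def test_verdict_depends_only_on_own_junctions(self, toy_genome):
        """Locality: adding irrelevant transcripts leaves the verdict alone."""
        t = two_exon_transcript()
        other = Transcript(
            "zz",
            "g9",
            (GenomicInterval("chr1", 300, 360, "+"),),
            300,
            360,
            "ALTSCAN",
        )
        reads = {"ds1": reads_at("t1", 160, [(12, 12)] * 6)}
        ev_std, ev_str, cov, cs, cg = self._evidence([t], toy_genome, reads)
        (alone,) = validate_transcripts([t], [], ev_std, ev_str, cs, cg, coverage_standard=cov)
        ev_std2, ev_str2, cov2, _, _ = self._evidence([t, other], toy_genome, reads)
        both = validate_transcripts(
            [t, other], [], ev_std2, ev_str2, cs, cg, coverage_standard=cov2
        )
        assert both[0].tier == alone.tier
        assert both[0].n_datasets_validated == alone.n_datasets_validated

    @pytest.mark.parametrize("seed", range(4))
    def test_tiering_matches_predicate_oracle(self, seed):
        """Fixture transcripts across 3 datasets: tiers equal a brute-force
        re-evaluation of the three defining predicates."""
        cfg = FixtureConfig(seed=seed, genome_length=3000)
        genome, truth = make_genome(cfg)
        known = truth[: len(truth) // 2]
        cfg_std = ValidationConfig.standard(flank=cfg.flank)
        cfg_str = ValidationConfig.stringent(flank=cfg.flank)
        mature = build_mature(truth, genome, cfg_std)
        ev_std, ev_str, cov = {}, {}, {}
        rng = np.random.default_rng(seed)
        for ds in range(3):
            sub = [t for t in truth if rng.random() < 0.7]
            rs = make_reads(sub, genome, cfg, L=10, dataset_tag=f"d{ds}")
            recs = rs.records
            ev_std[f"d{ds}"] = tally_junctions(recs, mature, cfg_std)
            ev_str[f"d{ds}"] = tally_junctions(recs, mature, cfg_str)
            cov[f"d{ds}"] = cds_coverage(recs, mature, cfg_std)
        verdicts = validate_transcripts(
            truth, known, ev_std, ev_str, cfg_std, cfg_str, coverage_standard=cov
        )
        known_keys = {t.cds_key() for t in known}
        known_juncs = {j for t in known for j in t.internal_junctions()}
        for t, v in zip(truth, verdicts):
            juncs = t.internal_junctions()
            std_ok = set()
            str_ok = set()
            for ds in ev_std:
                if juncs:
                    if all(ev_std[ds][j].jc >= cfg_std.M for j in juncs if j in ev_std[ds]) and all(
                        j in ev_std[ds] for j in juncs
                    ):
                        std_ok.add(ds)
                    if all(
                        j in ev_str[ds] and ev_str[ds][j].jc >= cfg_str.M for j in juncs
                    ):
                        str_ok.add(ds)
                elif cov[ds].get(t.transcript_id, 0) >= 0.9:
                    std_ok.add(ds)
            nij = any(j not in known_juncs for j in juncs)
            if t.cds_key() in known_keys:
                want = "KNOWN_VALIDATED" if std_ok else "UNVALIDATED"
            elif std_ok and str_ok and nij:
                want = "VHC"
            elif std_ok and nij:
                want = "VMC"
            elif std_ok:
                want = "VLC"
            else:
                want = "UNVALIDATED"
            assert v.tier == want, t.transcript_id

    def test_raising_l_or_m_never_grows_validated_sets(self):
        cfg = FixtureConfig(seed=9, genome_length=3000, junction_coverage=7)
        genome, truth = make_genome(cfg)
        multi = [t for t in truth if t.is_multi_exon()]
        rs = make_reads(truth, genome, cfg, L=8)
        mature = rs.mature_index

        def validated(L, M):
            ev = tally_junctions(
                rs.records, mature, ValidationConfig.stringent(L=L, M=6)
            )
            return {
                t.transcript_id
                for t in multi
                if all(j in ev and ev[j].jc >= M for j in t.internal_junctions())
            }

        for M in (1, 3, 6):
            s8, s10, s12 = (validated(L, M) for L in (8, 10, 12))
            assert s12 <= s10 <= s8
        for L in (8, 10):
            s1, s3, s6 = (validated(L, M) for M in (1, 3, 6))
            assert s6 <= s3 <= s1


class TestSaturationCurve:
    def test_identical_sets_saturate_immediately(self):
        sets = {f"d{i}": {"a", "b", "c"} for i in range(4)}
        curve = saturation_curve(sets, n_permutations=10, seed=1)
        assert curve[0] == 3
        assert all(c == 0 for c in curve[1:])

    def test_disjoint_equal_sets_give_constant_curve(self):
        sets = {f"d{i}": {f"x{i}a", f"x{i}b"} for i in range(5)}
        curve = saturation_curve(sets, n_permutations=20, seed=1)
        assert np.allclose(curve, 2.0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        sets = {
            f"d{i}": {f"t{j}" for j in rng.integers(0, 50, size=20)} for i in range(6)
        }
        a = saturation_curve(sets, n_permutations=50, seed=9)
        b = saturation_curve(sets, n_permutations=50, seed=9)
        assert np.array_equal(a, b)

    def test_matches_exhaustive_orderings(self):
        """4 datasets: Monte-Carlo means approach the all-24-orderings mean."""
        rng = np.random.default_rng(2)
        sets = {
            f"d{i}": {f"t{j}" for j in rng.integers(0, 30, size=15)} for i in range(4)
        }
        names = sorted(sets)
        exact = np.zeros(4)
        for order in itertools.permutations(range(4)):
            seen = set()
            for step, idx in enumerate(order):
                exact[step] += len(sets[names[idx]] - seen)
                seen |= sets[names[idx]]
        exact /= 24
        mc = saturation_curve(sets, n_permutations=3000, seed=5)
        assert np.allclose(mc, exact, atol=0.8)


class TestPcrPanelSummary:
    def test_published_panel_rates(self):
        vmc_outcomes = {f"t{i}": i < 74 for i in range(88)}
        vmc = pcr_panel_summary(vmc_outcomes, {f"t{i}": "VMC" for i in range(88)})
        assert vmc["VMC"]["percent"] == 84.1
        vhc_outcomes = {f"v{i}": i < 29 for i in range(32)}
        vhc = pcr_panel_summary(vhc_outcomes, {f"v{i}": "VHC" for i in range(32)})
        assert vhc["VHC"]["percent"] == 90.6

    def test_zero_successes(self):
        out = pcr_panel_summary({f"t{i}": False for i in range(5)}, {f"t{i}": "VMC" for i in range(5)})
        assert out["VMC"]["percent"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pcr_panel_summary({}, {})
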