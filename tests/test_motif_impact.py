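"""PWM parsing/scanning and constructive/destructive impact calls."""

import math

import numpy as np
import pytest

from ashmscan import motif_impact as mi
from ashmscan._seq import revcomp
from ashmscan.io_core import GenomicInterval

from conftest import make_variant

JASPAR_TEXT = """\
>M1 first
A  [ 10  0  0  0 ]
C  [ 0  10  0  0 ]
G  [ 0  0  10  0 ]
T  [ 0  0  0  10 ]
>M2 second
A  [ 5 5 ]
C  [ 5 5 ]
G  [ 5 5 ]
T  [ 5 5 ]
>M3 third
A  [ 1 1 1 1 1 ]
C  [ 1 1 1 1 1 ]
G  [ 8 8 8 8 8 ]
T  [ 1 1 1 1 1 ]
"""


class TestParse:
    def test_minimal_motif(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(JASPAR_TEXT.split(">M2")[0])
        (pwm,) = mi.parse_jaspar(path)
        assert pwm.motif_id == "M1" and pwm.length == 4

    def test_multiple_motifs_order_preserved(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(JASPAR_TEXT)
        pwms = mi.parse_jaspar(path)
        assert [p.motif_id for p in pwms] == ["M1", "M2", "M3"]

    def test_malformed_rows_raise(self, tmp_path):
        path = tmp_path / "bad.jaspar"
        path.write_text(">MX broken\nA [ 1 2 3 ]\nC [ 1 2 ]\nG [ 1 2 3 ]\nT [ 1 2 3 ]\n")
        with pytest.raises(ValueError):
            mi.parse_jaspar(path)

    def test_round_trip(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(JASPAR_TEXT)
        pwms = mi.parse_jaspar(path)
        out = tmp_path / "copy.jaspar"
        mi.write_jaspar(pwms, out)
        back = mi.parse_jaspar(out)
        for a, b in zip(pwms, back):
            assert a.motif_id == b.motif_id and np.array_equal(a.counts, b.counts)


class TestScoring:
    def test_background_pwm_scores_zero_everywhere(self):
        pwm = mi.PWM("flat", np.full((4, 3), 5.0))
        score, _, _ = mi.best_score(pwm, "ACGTACGT")
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_exact_match_hand_summed(self):
        counts = np.full((4, 4), 1.0)
        for j, base in enumerate("ACGT"):
            counts["ACGT".index(base), j] = 97.0
        pwm = mi.PWM("onehot", counts, pseudocount=0.8)
        # per column: p = (97 + 0.2) / (100 + 0.8); score = 4 * log2(p / 0.25)
        expected = 4 * math.log2((97 + 0.2) / (100 + 0.8) / 0.25)
        score, offset, strand = mi.best_score(pwm, "GGACGTGG")
        assert score == pytest.approx(expected, abs=1e-12)
        assert (offset, strand) == (2, "+")

    def test_palindrome_strands_tie_to_plus(self):
        counts = np.full((4, 4), 1.0)
        for j, base in enumerate("ACGT"):
            counts["ACGT".index(base), j] = 97.0  # ACGT is its own revcomp
        pwm = mi.PWM("pal", counts)
        _, _, strand = mi.best_score(pwm, "TTACGTTT")
        assert strand == "+"

    def test_reverse_complement_invariance(self, rng):
        counts = rng.integers(0, 20, size=(4, 6)).astype(float)
        pwm = mi.PWM("r", counts)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=30))
            s1, _, _ = mi.best_score(pwm, seq)
            s2, _, _ = mi.best_score(pwm, revcomp(seq))
            assert s1 == pytest.approx(s2, abs=1e-9)

    def test_too_short_sequence(self):
        pwm = mi.PWM("x", np.full((4, 5), 1.0))
        with pytest.raises(ValueError):
            mi.best_score(pwm, "ACG")


def _one_hot_pwm(consensus, motif_id="probe"):
    counts = np.full((4, len(consensus)), 1.0)
    for j, base in enumerate(consensus):
        counts["ACGT".index(base), j] = 97.0
    return mi.PWM(motif_id, counts)


class TestClassifyImpact:
    def test_destroying_central_base_is_destructive(self):
        genome = {"c": "A" * 20 + "TACGTA" + "A" * 20}
        pwm = _one_hot_pwm("TACGTA")
        v = make_variant(24, "G", "A", chrom="c")  # central G of TACGTA
        (call,) = mi.classify_impact(v, genome, [pwm], pad=15)
        assert call.impact == "destructive" and call.delta < 0

    def test_creating_exact_match_is_constructive(self):
        genome = {"c": "A" * 20 + "TACATA" + "A" * 20}  # one mismatch from TACGTA
        pwm = _one_hot_pwm("TACGTA")
        v = make_variant(24, "A", "G", chrom="c")
        (call,) = mi.classify_impact(v, genome, [pwm], pad=15)
        assert call.impact == "constructive" and call.delta > 0

    def test_motif_absent_is_neutral(self):
        genome = {"c": "A" * 41}
        pwm = _one_hot_pwm("CCGGCC")
        v = make_variant(21, "A", "T", chrom="c")
        (call,) = mi.classify_impact(v, genome, [pwm], pad=15)
        assert call.impact == "neutral" and call.delta == pytest.approx(0.0, abs=1e-9)

    def test_reference_mismatch_raises(self):
        genome = {"c": "A" * 41}
        with pytest.raises(ValueError):
            mi.classify_impact(make_variant(21, "C", "T", chrom="c"), genome, [_one_hot_pwm("ACGT")])

    def test_alt_ref_swap_flips_class(self):
        genome_wt = {"c": "A" * 20 + "TACGTA" + "A" * 20}
        genome_mut = {"c": "A" * 20 + "TACATA" + "A" * 20}
        pwm = _one_hot_pwm("TACGTA")
        (fwd,) = mi.classify_impact(make_variant(24, "G", "A", chrom="c"), genome_wt, [pwm])
        (rev,) = mi.classify_impact(make_variant(24, "A", "G", chrom="c"), genome_mut, [pwm])
        assert fwd.impact == "destructive" and rev.impact == "constructive"
        assert fwd.delta == pytest.approx(-rev.delta, abs=1e-9)


class TestClusterSequences:
    GENOME = {"c": "AACCGGTTAACCGGTTAACC"}

    def test_single_mode_counts(self):
        cluster = GenomicInterval("c", 4, 14)
        variants = [make_variant(6, "G", "A", chrom="c"), make_variant(10, "A", "T", chrom="c")]
        seqs = mi.mutated_cluster_sequences(cluster, variants, self.GENOME, mode="single")
        assert len(seqs) == 3 and seqs[0][0] == "wt"

    def test_all_mode_adds_combined(self):
        cluster = GenomicInterval("c", 4, 14)
        variants = [make_variant(6, "G", "A", chrom="c"), make_variant(10, "A", "T", chrom="c")]
        seqs = mi.mutated_cluster_sequences(cluster, variants, self.GENOME, mode="all")
        assert len(seqs) == 4
        combined = dict(seqs)["all:6G>A,10A>T"]
        assert combined[6 - 1 - 4] == "A" and combined[10 - 1 - 4] == "T"

    def test_conflicting_alts_enumerated(self):
        cluster = GenomicInterval("c", 4, 14)
        variants = [
            make_variant(6, "G", "A", chrom="c"),
            make_variant(6, "G", "C", chrom="c"),
            make_variant(10, "A", "T", chrom="c"),
        ]
        seqs = mi.mutated_cluster_sequences(cluster, variants, self.GENOME, mode="all")
        labels = [l for l, _ in seqs if l.startswith("all:")]
        assert len(labels) == 2  # one combined sequence per conflicting alt

    def test_variant_outside_cluster_rejected(self):
        cluster = GenomicInterval("c", 4, 8)
        with pytest.raises(ValueError):
            mi.mutated_cluster_sequences(cluster, [make_variant(10, "A", "T", chrom="c")], self.GENOME)


class TestClusterSummary:
    def _call(self, impact, motif="M", wt=1.0, mut=1.0):
        return mi.ImpactCall(make_variant(5, "A", "C"), motif, wt, mut, mut - wt, impact)

    def test_majority_constructive(self):
        calls = [self._call("constructive")] * 3 + [self._call("neutral")]
        (s,) = mi.cluster_motif_summary(calls)
        assert s.majority == "constructive"

    def test_tie_resolves_neutral(self):
        calls = [self._call("constructive")] * 2 + [self._call("destructive")] * 2
        (s,) = mi.cluster_motif_summary(calls)
        assert s.majority == "neutral"

    def test_best_motif_first(self):
        calls = [self._call("neutral", motif="weak", wt=1.0), self._call("neutral", motif="strong", wt=9.0)]
        summaries = mi.cluster_motif_summary(calls)
        assert summaries[0].motif_id == "strong"
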