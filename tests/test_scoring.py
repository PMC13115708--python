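"""Gene-level cumulative scoring: per-transcript sums, transcript averaging,
ranking, top-percent export — checked against an independent brute-force
evaluation of the scoring formula on micro-cohorts."""

from __future__ import annotations

import math

import numpy as np
import pytest

from iqgene.analyzers import IntegratedScore
from iqgene.scoring import (
    build_gene_models,
    GeneScore,
    rank_genes,
    score_genes,
    top_percent,
    transcript_score,
)
from iqgene.variants import ConsequenceRecord, VariantFrequency, VariantKey


# ---------------------------------------------------------------------------
# independent oracle: a literal triple loop over (gene, transcript, variant)
# ---------------------------------------------------------------------------

def brute_force_scores(gene_transcripts, variants_on, normalized, flags, diffs, mode):
    """Direct evaluation of the cumulative score from plain dicts.

    gene_transcripts: {gene: {tid: length}}
    variants_on:      {(gene, tid): [variant keys]}
    normalized:       {(vkey, tid): {analyzer: normalized score}}
    flags:            {(vkey, tid): {analyzer: bool}}
    diffs:            {vkey: tumor - normal}
    """
    out = {}
    for gene, transcripts in gene_transcripts.items():
        n_g = len(transcripts)
        total = 0.0
        pathogenic = False
        for tid, length in transcripts.items():
            inner = 0.0
            for v in variants_on.get((gene, tid), []):
                norm = normalized.get((v, tid), {})
                flag = flags.get((v, tid), {})
                if mode == "integrative":
                    if not norm:
                        continue
                    score, deleterious = sum(norm.values()) / len(norm), any(flag.values())
                else:
                    if mode not in norm:
                        continue
                    score, deleterious = norm[mode], flag.get(mode, False)
                if deleterious:
                    inner += score * diffs[v]
                    pathogenic = True
            total += inner / math.log(length)
        if pathogenic:
            out[gene] = total / n_g
    return out


def _random_micro_cohort(seed, n_genes=4, max_tr=3, max_var=5):
    """A tiny random cohort built twice: once as package objects, once as the
    plain dicts the brute-force oracle consumes."""
    rng = np.random.default_rng(seed)
    analyzers = ["fathmm", "cadd", "sift", "polyphen"]
    records, integrated, freqs = [], {}, {}
    gene_transcripts, variants_on, normalized, flags, diffs = {}, {}, {}, {}, {}
    vcount = 0
    for gi in range(n_genes):
        gene = f"G{gi}"
        tids = {f"G{gi}T{j}": int(rng.integers(50, 5000))
                for j in range(rng.integers(1, max_tr + 1))}
        gene_transcripts[gene] = tids
        for tid, length in tids.items():
            for _ in range(rng.integers(0, max_var + 1)):
                vcount += 1
                v = VariantKey("chr1", vcount, "C", "T")
                t, n = int(rng.integers(0, 5)), int(rng.integers(0, 3))
                if t + n == 0:
                    t = 1
                freqs[v] = VariantFrequency(v, t, n)
                diffs[v] = t - n
                records.append(ConsequenceRecord(
                    variant=v, gene_symbol=gene, transcript_id=tid,
                    consequence="missense_variant", biotype="protein_coding",
                    transcript_length=length,
                ))
                norm, flag = {}, {}
                for a in analyzers:
                    if rng.random() < 0.8:  # ~20% missing per analyzer
                        norm[a] = float(np.round(rng.random(), 6))
                        flag[a] = bool(rng.random() < 0.6)
                if norm:
                    integrated[(v, tid)] = IntegratedScore(v, tid, norm, flag)
                    normalized[(v, tid)] = norm
                    flags[(v, tid)] = flag
                variants_on.setdefault((gene, tid), []).append(v)
    # the pipeline only sees transcripts that appear in annotation records,
    # so the oracle's transcript universe (and N_G) must match that view
    for gene in list(gene_transcripts):
        gene_transcripts[gene] = {
            tid: length for tid, length in gene_transcripts[gene].items()
            if (gene, tid) in variants_on
        }
        if not gene_transcripts[gene]:
            del gene_transcripts[gene]
    return (records, integrated, freqs,
            gene_transcripts, variants_on, normalized, flags, diffs)


@pytest.mark.parametrize("seed", range(6))
@pytest.mark.parametrize("mode", ["integrative", "fathmm", "cadd", "sift", "polyphen"])
def test_scores_match_brute_force(seed, mode):
    """The vectorized aggregation equals a literal triple-loop evaluation of
    the per-gene formula to 1e-12 on random micro-cohorts."""
    (records, integrated, freqs,
     gt, von, norm, flag, diffs) = _random_micro_cohort(seed)
    got = {g.gene_symbol: g.score for g in score_genes(records, integrated, freqs, mode)}
    expected = brute_force_scores(gt, von, norm, flag, diffs, mode)
    assert got.keys() == expected.keys()
    for gene in expected:
        assert got[gene] == pytest.approx(expected[gene], abs=1e-12)


class TestTranscriptScore:
    def test_single_variant_hand_arithmetic(self):
        # score 1.0, tumor 3, normal 0, length 100 -> 3 / ln(100)
        assert transcript_score(100, [(1.0, 3)]) == pytest.approx(3 / math.log(100))

    def test_equal_frequencies_contribute_zero(self):
        assert transcript_score(100, [(0.9, 0)]) == 0.0

    def test_two_variant_sum(self):
        expected = (0.5 * 2 + 1.0 * 1) / math.log(7)
        assert transcript_score(7, [(0.5, 2), (1.0, 1)]) == pytest.approx(expected)

    def test_length_below_two_is_hard_error(self):
        with pytest.raises(ValueError):
            transcript_score(1, [(1.0, 1)])

    def test_alternative_length_penalties(self):
        assert transcript_score(100, [(1.0, 2)], "sqrt") == pytest.approx(0.2)
        assert transcript_score(100, [(1.0, 2)], "linear") == pytest.approx(0.02)


def _one_gene_cohort(scores_and_diffs, lengths):
    """One gene; each transcript gets every variant (the usual annotation
    pattern); per-variant (ave score, diff) supplied directly."""
    records, integrated, freqs = [], {}, {}
    for i, (score, diff) in enumerate(scores_and_diffs):
        v = VariantKey("chr1", i + 1, "A", "G")
        freqs[v] = VariantFrequency(v, max(diff, 0) + 1, max(-diff, 0) + 1)
        assert freqs[v].diff == diff
        for j, length in enumerate(lengths):
            tid = f"T{j}"
            records.append(ConsequenceRecord(
                variant=v, gene_symbol="G", transcript_id=tid,
                consequence="missense_variant", biotype="protein_coding",
                transcript_length=length,
            ))
            integrated[(v, tid)] = IntegratedScore(
                v, tid, normalized={"fathmm": score}, deleterious={"fathmm": True})
    return records, integrated, freqs


class TestGeneScore:
    def test_single_transcript_gene_equals_transcript_score(self):
        records, integrated, freqs = _one_gene_cohort([(1.0, 3)], [100])
        (g,) = score_genes(records, integrated, freqs, "fathmm")
        assert g.score == pytest.approx(3 / math.log(100))
        assert (g.n_transcripts, g.n_variants) == (1, 1)

    def test_empty_transcript_still_counts_in_average(self):
        # second transcript carries the variant too here, so drop it from one:
        records, integrated, freqs = _one_gene_cohort([(1.0, 3)], [100, 200])
        v = records[0].variant
        del integrated[(v, "T1")]  # transcript T1 has no scored variant
        (g,) = score_genes(records, integrated, freqs, "fathmm")
        assert g.score == pytest.approx((3 / math.log(100)) / 2)

    def test_integrative_equals_single_analyzer_when_alone(self):
        records, integrated, freqs = _one_gene_cohort([(0.7, 2), (0.3, 1)], [100, 500])
        (q,) = score_genes(records, integrated, freqs, "fathmm")
        (iq,) = score_genes(records, integrated, freqs, "integrative")
        assert iq.score == pytest.approx(q.score)

    def test_linearity_in_frequency_difference(self):
        records, integrated, f1 = _one_gene_cohort([(0.7, 2), (0.4, 1)], [100])
        _, _, f2 = _one_gene_cohort([(0.7, 4), (0.4, 2)], [100])
        (g1,) = score_genes(records, integrated, f1, "fathmm")
        (g2,) = score_genes(records, integrated, f2, "fathmm")
        assert g2.score == pytest.approx(2 * g1.score)

    def test_adding_tumor_only_variant_never_decreases_score(self):
        records, integrated, freqs = _one_gene_cohort([(0.7, 2)], [100])
        base = score_genes(records, integrated, freqs, "fathmm")[0].score
        v = VariantKey("chr1", 99, "A", "G")
        freqs[v] = VariantFrequency(v, 2, 0)
        records.append(ConsequenceRecord(
            variant=v, gene_symbol="G", transcript_id="T0",
            consequence="missense_variant", biotype="protein_coding",
            transcript_length=100))
        integrated[(v, "T0")] = IntegratedScore(
            v, "T0", normalized={"fathmm": 0.5}, deleterious={"fathmm": True})
        grown = score_genes(records, integrated, freqs, "fathmm")[0].score
        assert grown >= base

    def test_gene_without_length_annotation_excluded(self):
        rec = ConsequenceRecord(
            variant=VariantKey("chr1", 1, "A", "G"), gene_symbol="G",
            transcript_id="T0", consequence="missense_variant",
            biotype="protein_coding", transcript_length=None)
        assert build_gene_models([rec]) == {}


def _gs(symbol, score):
    return GeneScore(symbol, score, "integrative", 1, 1)


class TestRanking:
    def test_competition_ranking_with_ties(self):
        ranked = rank_genes([_gs("A", 5), _gs("B", 3), _gs("C", 3), _gs("D", 1)])
        assert {g.gene_symbol: g.rank for g in ranked.genes} == {
            "A": 1, "B": 2, "C": 2, "D": 4}

    def test_single_gene_rank_one(self):
        ranked = rank_genes([_gs("A", 2.5)])
        assert ranked.genes[0].rank == 1 and ranked.p == 1

    def test_empty_input_empty_set(self):
        assert rank_genes([]).p == 0

    def test_tie_order_deterministic_by_symbol(self):
        ranked = rank_genes([_gs("B", 3), _gs("A", 3)])
        assert [g.gene_symbol for g in ranked.genes] == ["A", "B"]


class TestTopPercent:
    def test_ceiling_arithmetic(self):
        ranked = rank_genes([_gs(f"G{i:03d}", 200 - i) for i in range(200)])
        assert len(top_percent(ranked, 0.01)) == 2

    def test_full_fraction_returns_all(self):
        ranked = rank_genes([_gs(f"G{i:03d}", 149 - i) for i in range(149)])
        assert len(top_percent(ranked, 1.0)) == 149

    def test_boundary_tie_inclusion(self):
        # ceil(0.01 * 200) = 2, but genes ranked 2..4 tie on score
        scores = [_gs("A", 10)] + [_gs(f"T{i}", 5) for i in range(3)]
        scores += [_gs(f"G{i:03d}", 1) for i in range(196)]
        out = top_percent(rank_genes(scores), 0.01)
        assert len(out) == 4  # tie block straddling the cutoff fully included

    def test_fraction_out_of_range_rejected(self):
        ranked = rank_genes([_gs("A", 1)])
        with pytest.raises(ValueError):
            top_percent(ranked, 0.0)
        with pytest.raises(ValueError):
            top_percent(ranked, 1.5)
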