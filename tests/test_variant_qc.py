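"""Filter chain, substitution classes, genic context and coding effects."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from hypothesis import given
from hypothesis import strategies as st

from tillmap.synthetic import revcomp, simulate_ems_variants
from tillmap.variant_qc import (
    FilterThresholds,
    annotate_context,
    apply_variant_filters,
    cds_sequence,
    classify_effect,
    classify_substitution,
    remove_shared_variants,
    spectrum_summary,
    summarize_mutation_load,
)

from conftest import tiny_sim_config


def _rec(qual, depth, is_indel=False, **kw):
    row = dict(chrom="A1", pos=100, ref="C", alt="T", qual=qual, depth=depth,
               is_indel=is_indel, line_id="DH0001")
    if is_indel:
        row.update(ref="C", alt="CAT")
    row.update(kw)
    return row


class TestFilters:
    @pytest.mark.parametrize(
        "qual,depth,is_indel,kept",
        [
            (29, 50, False, False),   # just below the SNP quality bound
            (30, 5, False, True),     # inclusive lower bounds
            (30, 250, False, True),   # inclusive upper depth bound
            (30, 251, False, False),
            (30, 4, False, False),
            (49, 50, True, False),    # indels need qual >= 50
            (50, 9, True, False),     # ... and depth >= 10
            (50, 10, True, True),
        ],
    )
    def test_threshold_boundaries(self, qual, depth, is_indel, kept):
        df = pd.DataFrame([_rec(qual, depth, is_indel)])
        out = apply_variant_filters(df)
        assert (len(out) == 1) == kept

    def test_negative_values_raise(self):
        df = pd.DataFrame([_rec(-1, 50)])
        with pytest.raises(ValueError, match="negative"):
            apply_variant_filters(df)

    def test_order_preserved_and_idempotent(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            [_rec(q, d, pos=i) for i, (q, d) in
             enumerate(zip(rng.uniform(0, 80, 100), rng.integers(0, 300, 100)))]
        )
        once = apply_variant_filters(df)
        assert list(once.pos) == sorted(once.pos)  # input order kept
        pd.testing.assert_frame_equal(apply_variant_filters(once), once)

    def test_full_chain_idempotent(self):
        rng = np.random.default_rng(2)
        rows = [
            _rec(float(rng.uniform(20, 70)), int(rng.integers(1, 40)),
                 pos=int(rng.integers(1, 50)), line_id=f"L{rng.integers(8)}")
            for _ in range(300)
        ]
        df = pd.DataFrame(rows)
        t = FilterThresholds()
        once = remove_shared_variants(apply_variant_filters(df, t), t.shared_line_limit)
        twice = remove_shared_variants(apply_variant_filters(once, t), t.shared_line_limit)
        pd.testing.assert_frame_equal(once, twice)


def brute_force_shared_removal(df, limit):
    keep = []
    for i, r in df.iterrows():
        carriers = {
            rr.line_id
            for _, rr in df.iterrows()
            if (rr.chrom, rr.pos, rr.ref, rr.alt) == (r.chrom, r.pos, r.ref, r.alt)
        }
        if len(carriers) < limit:
            keep.append(i)
    return df.loc[keep]


class TestSharedRemoval:
    def test_boundary_five_lines_removed_four_kept(self):
        rows = [_rec(40, 20, line_id=f"L{i}") for i in range(5)]
        rows += [_rec(40, 20, pos=200, line_id=f"L{i}") for i in range(4)]
        df = pd.DataFrame(rows)
        out = remove_shared_variants(df, limit=5)
        assert (out.pos == 200).all() and len(out) == 4

    def test_matches_brute_force_on_random_cohorts(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(10, 60))
            df = pd.DataFrame(
                [
                    _rec(40, 20, pos=int(rng.integers(1, 8)),
                         alt=str(rng.choice(["T", "G", "A"])),
                         line_id=f"L{int(rng.integers(8))}")
                    for _ in range(n)
                ]
            )
            limit = int(rng.integers(2, 5))
            expected = brute_force_shared_removal(df, limit)
            got = remove_shared_variants(df, limit)
            pd.testing.assert_frame_equal(got, expected)

    def test_no_false_removal_of_private_variants(self, tiny_genome):
        cfg = tiny_sim_config(n_shared_artifacts=6)
        variants, _ = simulate_ems_variants(tiny_genome, cfg, np.random.default_rng(4))
        df = pd.concat(variants.values(), ignore_index=True)
        out = remove_shared_variants(df, limit=5)
        # every true (generator-private) variant must survive
        n_private = (df.origin == "true").sum()
        assert (out.origin == "true").sum() == n_private


BASES = "ACGT"


class TestSubstitutionClasses:
    def test_complement_pooling(self):
        assert classify_substitution("C", "T") == "C/G>T/A"
        assert classify_substitution("G", "A") == "C/G>T/A"
        assert classify_substitution("A", "C") == "A/T>C/G"

    @given(st.sampled_from(BASES), st.sampled_from(BASES))
    def test_strand_symmetry(self, ref, alt):
        if ref == alt:
            return
        assert classify_substitution(ref, alt) == classify_substitution(
            revcomp(ref), revcomp(alt)
        )

    def test_twelve_substitutions_partition_into_six_classes(self):
        classes = {}
        for r in BASES:
            for a in BASES:
                if r != a:
                    classes.setdefault(classify_substitution(r, a), []).append((r, a))
        assert len(classes) == 6
        assert all(len(v) == 2 for v in classes.values())

    def test_indel_input_raises(self):
        with pytest.raises(ValueError):
            classify_substitution("C", "CAT")

    def test_spectrum_frequencies_sum_to_one(self, tiny_genome):
        cfg = tiny_sim_config()
        variants, _ = simulate_ems_variants(tiny_genome, cfg, np.random.default_rng(5))
        df = pd.concat(variants.values())
        summ = spectrum_summary(df)
        assert abs(summ.frequency.sum() - 1.0) < 1e-9


class TestContext:
    def _mk(self, chrom, pos):
        return pd.DataFrame([dict(chrom=chrom, pos=pos, ref="C", alt="T")])

    def test_exon_intron_flank_intergenic(self, tiny_genome):
        genes = tiny_genome.genes
        exons = tiny_genome.exons
        plus = genes[genes.strand == "+"].iloc[0]
        first_exon = exons[exons.gene_id == plus.gene_id].sort_values("start").iloc[0]
        assert annotate_context(self._mk(plus.chrom, first_exon.start), tiny_genome)[0] == "exon"
        up = annotate_context(self._mk(plus.chrom, plus.start - 1500), tiny_genome)[0]
        # 1500 bp 5' of a +strand gene: upstream unless inside/adjacent another gene
        assert up in ("upstream_2kb", "exon", "intron")
        multi = genes.merge(
            exons.groupby("gene_id").size().rename("n").reset_index(), on="gene_id"
        )
        g = multi[multi.n > 1].iloc[0]
        ge = exons[exons.gene_id == g.gene_id].sort_values("start")
        intron_pos = int(ge.iloc[0].end) + (int(ge.iloc[1].start) - int(ge.iloc[0].end)) // 2
        assert annotate_context(self._mk(g.chrom, intron_pos), tiny_genome)[0] == "intron"

    def test_flanks_are_strand_aware(self, tiny_genome):
        # an isolated +strand gene: 1500 bp 3' of its end is downstream
        genes = tiny_genome.genes
        for r in genes[genes.strand == "+"].itertuples():
            nxt = genes[(genes.chrom == r.chrom) & (genes.start > r.end)]
            gap_next = (nxt.start.min() - r.end) if len(nxt) else 10**9
            if gap_next > 3600:
                ctx = annotate_context(self._mk(r.chrom, r.end + 1500), tiny_genome)[0]
                assert ctx == "downstream_2kb"
                break

    def test_far_from_genes_is_intergenic(self, tiny_genome):
        genes = tiny_genome.genes
        chrom = genes.chrom.iloc[0]
        length = len(tiny_genome.seqs[chrom])
        last_end = genes[genes.chrom == chrom].end.max()
        if length - last_end > 2500:
            ctx = annotate_context(self._mk(chrom, length - 10), tiny_genome)[0]
            assert ctx == "intergenic"

    def test_unknown_chromosome_warns_intergenic(self, tiny_genome):
        with pytest.warns(UserWarning, match="absent"):
            ctx = annotate_context(self._mk("Z9", 1000), tiny_genome)
        assert ctx[0] == "intergenic"

    def test_classes_exhaustive_and_exclusive(self, tiny_genome):
        rng = np.random.default_rng(6)
        chrom = "A1"
        pos = rng.integers(1, len(tiny_genome.seqs[chrom]), size=300)
        df = pd.DataFrame(dict(chrom=chrom, pos=pos, ref="C", alt="T"))
        ctx = annotate_context(df, tiny_genome)
        assert set(ctx) <= {"exon", "intron", "upstream_2kb", "downstream_2kb", "intergenic"}
        assert len(ctx) == len(df)


def translation_oracle(genome, gene_id, chrom, pos, ref, alt):
    """Independent effect call: apply the variant to the chromosome, rebuild
    the full CDS and compare the complete translations."""
    seq = genome.seqs[chrom]
    assert seq[pos - 1] == ref
    mutated = dict(genome.seqs)
    mutated[chrom] = seq[: pos - 1] + alt + seq[pos:]

    from tillmap.synthetic import Genome

    mut_genome = Genome(seqs=mutated, genes=genome.genes, exons=genome.exons)
    p0 = str(Seq(cds_sequence(genome, gene_id)).translate())
    p1 = str(Seq(cds_sequence(mut_genome, gene_id)).translate())
    if p1[0] != "M":
        return "start_lost"
    if p0 == p1:
        return "synonymous"
    stop0 = p0.index("*") if "*" in p0 else len(p0)
    stop1 = p1.index("*") if "*" in p1 else len(p1)
    if stop1 < stop0:
        return "stop_gained"
    if stop1 > stop0:
        return "stop_lost"
    return "missense"


class TestEffects:
    def test_stop_gain_and_synonymous_codon_changes(self, tiny_genome):
        # search the toy genes for a codon where a single change gives a stop
        found_stop = found_syn = False
        for g in tiny_genome.genes.itertuples():
            cds = cds_sequence(tiny_genome, g.gene_id)
            exons = tiny_genome.exons[tiny_genome.exons.gene_id == g.gene_id]
            exons = exons.sort_values("exon_rank")
            offsets = []
            for e in exons.itertuples():
                rng_pos = (
                    range(e.start, e.end + 1) if g.strand == "+" else range(e.end, e.start - 1, -1)
                )
                base = len(offsets)
                offsets.extend([(p, base + i) for i, p in enumerate(rng_pos)])
            # CAA -> TAA at a codon start
            for genome_pos, off in offsets:
                if off % 3 == 0 and off > 0 and cds[off : off + 3] == "CAA":
                    alt_c = "T"
                    ref_g = tiny_genome.seqs[g.chrom][genome_pos - 1]
                    alt_g = alt_c if g.strand == "+" else revcomp(alt_c)
                    call = classify_effect(g.chrom, genome_pos, ref_g, alt_g, tiny_genome)
                    assert call.klass == "stop_gained" and call.impact == "high"
                    found_stop = True
                    break
            if found_stop:
                break
        assert found_stop

    def test_random_exonic_snps_match_translation_oracle(self, tiny_genome):
        rng = np.random.default_rng(7)
        from tillmap.variant_qc import build_context_index

        index = build_context_index(tiny_genome)
        exons = tiny_genome.exons
        checked = 0
        while checked < 200:
            e = exons.iloc[int(rng.integers(len(exons)))]
            pos = int(rng.integers(e.start, e.end + 1))
            ref = tiny_genome.seqs[e.chrom][pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            call = classify_effect(e.chrom, pos, ref, alt, tiny_genome, index)
            expected = translation_oracle(
                tiny_genome, e.gene_id, e.chrom, pos, ref, alt
            )
            assert call.klass == expected, (e.gene_id, pos, ref, alt)
            checked += 1

    def test_splice_region_near_exon_boundary(self, tiny_genome):
        exons = tiny_genome.exons
        multi = exons.groupby("gene_id").size()
        gid = multi[multi > 1].index[0]
        ge = exons[exons.gene_id == gid].sort_values("start")
        pos = int(ge.iloc[0].end) + 3  # 3 bp into the intron
        chrom = ge.chrom.iloc[0]
        ref = tiny_genome.seqs[chrom][pos - 1]
        alt = "A" if ref != "A" else "G"
        call = classify_effect(chrom, pos, ref, alt, tiny_genome)
        assert call.klass == "splice_region" and call.impact == "low"

    def test_cds_indel_frameshift_vs_inframe(self, tiny_genome):
        e = tiny_genome.exons.iloc[0]
        pos = int(e.start) + 3
        ref = tiny_genome.seqs[e.chrom][pos - 1]
        fs = classify_effect(e.chrom, pos, ref, ref + "AT", tiny_genome)
        assert fs.klass == "frameshift" and fs.impact == "high"
        inf = classify_effect(e.chrom, pos, ref, ref + "ATG", tiny_genome)
        assert inf.klass == "inframe_indel" and inf.impact == "moderate"

    def test_broken_cds_raises_naming_gene(self, tiny_genome):
        from tillmap.synthetic import Genome

        exons = tiny_genome.exons.copy()
        gid = exons.gene_id.iloc[0]
        idx = exons[exons.gene_id == gid].index[0]
        exons.loc[idx, "end"] += 1  # CDS length now not divisible by 3
        broken = Genome(seqs=tiny_genome.seqs, genes=tiny_genome.genes, exons=exons)
        e = exons.loc[idx]
        ref = tiny_genome.seqs[e.chrom][e.start + 1 - 1]
        with pytest.raises(ValueError, match=gid):
            classify_effect(e.chrom, int(e.start) + 1, ref,
                            "A" if ref != "A" else "C", broken)


class TestLoadSummary:
    def test_density_arithmetic(self):
        df = pd.DataFrame([_rec(40, 20, pos=i + 1) for i in range(155)])
        per_line, pop = summarize_mutation_load(df, 1_000_000)
        assert per_line.snp_density_per_mb.iloc[0] == pytest.approx(155.0)

    def test_empty_records_no_crash(self):
        df = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "qual", "depth",
                                   "is_indel", "line_id"])
        per_line, pop = summarize_mutation_load(df, 1_000_000)
        assert pop["n_variants"] == 0 and per_line.empty

    def test_zero_genome_size_raises(self):
        with pytest.raises(ValueError):
            summarize_mutation_load(pd.DataFrame(), 0)

    def test_per_line_counts_match_generator_ledger(self, tiny_genome):
        cfg = tiny_sim_config(n_shared_artifacts=0)
        variants, truth = simulate_ems_variants(tiny_genome, cfg, np.random.default_rng(8))
        df = pd.concat(variants.values(), ignore_index=True)
        per_line, _ = summarize_mutation_load(df, tiny_genome.total_length)
        merged = per_line.merge(truth, on="line_id")
        assert (merged.n_snps_x == merged.n_snps_y).all()
        assert (merged.n_indels_x == merged.n_indels_y).all()
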