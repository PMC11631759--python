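"""Unique-variant filtering, indel typing, tract adjacency and fold change."""

import numpy as np
import pytest

from pequant import (
    ConfigurationError,
    classify_indels,
    count_region_variants,
    find_unique_variants,
    homopolymer_adjacent_fraction,
    indel_fold_change,
    is_tract_adjacent,
    load_family,
    trim_and_shift,
)
from pequant.wgs_family import (
    DEFAULT_EXCLUDED_CHROMS,
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    GT_MISSING,
    GT_OTHER_ALT,
    FamilyVariantTable,
    UniqueVariant,
    VariantRecord,
    variant_class,
)

SAMPLES = ["p1", "p2", "c1", "c2", "t1", "t2"]
ROLES = {
    "p1": "parent", "p2": "parent",
    "c1": "control_offspring", "c2": "control_offspring",
    "t1": "treated_offspring", "t2": "treated_offspring",
}


def record(chrom="chr1", pos=100, ref="A", alt="G", dp=None, ad=None, gt=None):
    n = len(SAMPLES)
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        dp=tuple(dp or [50] * n),
        alt_ad=tuple(ad or [0] * n),
        gt=tuple(gt or [GT_HOM_REF] * n),
    )


def table(variants):
    return FamilyVariantTable(variants=list(variants), samples=SAMPLES,
                              roles=ROLES)


def single_carrier(idx, vaf=0.45, dp=50, **kw):
    gt = [GT_HOM_REF] * len(SAMPLES)
    gt[idx] = GT_HET
    ad = [0] * len(SAMPLES)
    ad[idx] = int(vaf * dp)
    dps = [dp] * len(SAMPLES)
    return record(dp=dps, ad=ad, gt=gt, **kw)


class TestUniqueVariantRules:
    def test_clean_single_carrier_retained(self):
        uniq = find_unique_variants(table([single_carrier(4)]))
        assert len(uniq["t1"]) == 1
        assert uniq["t1"][0].vaf == pytest.approx(0.44)

    def test_low_depth_in_any_sample_drops_variant(self):
        rec = single_carrier(4)
        dp = list(rec.dp)
        dp[0] = 29
        rec = record(dp=dp, ad=rec.alt_ad, gt=rec.gt)
        assert all(not v for v in find_unique_variants(table([rec])).values())

    def test_two_carriers_dropped(self):
        gt = [GT_HOM_REF] * 6
        gt[2] = gt[4] = GT_HET
        rec = record(gt=gt, ad=[0, 0, 20, 0, 20, 0])
        assert all(not v for v in find_unique_variants(table([rec])).values())

    def test_low_vaf_carrier_dropped(self):
        rec = single_carrier(4, vaf=0.19)
        assert all(not v for v in find_unique_variants(table([rec])).values())

    def test_sex_chromosome_dropped(self):
        for chrom in ("chrX", "NC_000086.8"):
            rec = single_carrier(4, chrom=chrom)
            assert all(not v for v in find_unique_variants(table([rec])).values())

    def test_missing_or_other_alt_genotype_disqualifies(self):
        for code in (GT_MISSING, GT_OTHER_ALT):
            rec = single_carrier(4)
            gt = list(rec.gt)
            gt[1] = code
            rec = record(dp=rec.dp, ad=rec.alt_ad, gt=gt)
            assert all(not v for v in find_unique_variants(table([rec])).values())

    def test_hom_alt_carrier_counts_as_detection(self):
        gt = [GT_HOM_REF] * 6
        gt[3] = GT_HOM_ALT
        rec = record(gt=gt, ad=[0, 0, 0, 48, 0, 0])
        uniq = find_unique_variants(table([rec]))
        assert len(uniq["c2"]) == 1


def brute_force_unique(tbl, min_depth=30, min_vaf=0.2,
                       excluded=DEFAULT_EXCLUDED_CHROMS):
    """Independent re-statement of the four rules (oracle)."""
    out = {s: [] for s in tbl.samples}
    for rec in tbl.variants:
        autosomal = rec.chrom not in excluded
        deep = min(rec.dp) >= min_depth
        detections = [i for i in range(len(tbl.samples))
                      if rec.gt[i] in (GT_HET, GT_HOM_ALT)]
        clean_rest = all(rec.gt[i] == GT_HOM_REF for i in range(len(tbl.samples))
                         if i not in detections)
        if autosomal and deep and len(detections) == 1 and clean_rest:
            i = detections[0]
            if rec.dp[i] > 0 and rec.alt_ad[i] / rec.dp[i] >= min_vaf:
                out[tbl.samples[i]].append((rec.chrom, rec.pos, rec.ref, rec.alt))
    return out


def random_table(rng, n_variants=50):
    variants = []
    for _ in range(n_variants):
        chrom = rng.choice(["chr1", "chr2", "chrX"], p=[0.45, 0.45, 0.1])
        ref, alt = rng.choice(
            [("A", "G"), ("AT", "A"), ("A", "AC"), ("ATT", "A")]
        )
        dp = rng.integers(20, 60, size=len(SAMPLES))
        gt = rng.choice(
            [GT_HOM_REF, GT_HET, GT_HOM_ALT, GT_MISSING, GT_OTHER_ALT],
            size=len(SAMPLES),
            p=[0.55, 0.25, 0.08, 0.06, 0.06],
        )
        ad = np.where(
            np.isin(gt, [GT_HET, GT_HOM_ALT]),
            (dp * rng.uniform(0.05, 0.9, size=len(SAMPLES))).astype(int),
            0,
        )
        variants.append(record(chrom=str(chrom), pos=int(rng.integers(1e6)),
                               ref=ref, alt=alt, dp=dp.tolist(),
                               ad=ad.tolist(), gt=gt.tolist()))
    return table(variants)


def test_unique_filter_matches_bruteforce_oracle(rng):
    """Property: the filter equals an independent rule restatement."""
    for _ in range(200):
        tbl = random_table(rng)
        got = {
            s: [(u.record.chrom, u.record.pos, u.record.ref, u.record.alt)
                for u in vs]
            for s, vs in find_unique_variants(tbl).items()
        }
        assert got == brute_force_unique(tbl)


class TestIndelTyping:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [("AA", "A", "del_1"), ("A", "ACG", "ins_2"), ("A", "G", "SNV"),
         ("AT", "GC", "SNV"), ("ATTT", "A", "del_3")],
    )
    def test_variant_class(self, ref, alt, expected):
        assert variant_class(record(ref=ref, alt=alt)) == expected

    def test_histogram(self):
        uniq = {
            "t1": [UniqueVariant(record(ref="AA", alt="A"), "t1", 0.4, "del_1"),
                   UniqueVariant(record(ref="A", alt="G"), "t1", 0.4, "SNV")],
            "c1": [UniqueVariant(record(ref="A", alt="AC"), "c1", 0.4, "ins_1")],
        }
        hist = classify_indels(uniq)
        assert hist.loc["del_1", "t1"] == 1
        assert hist.loc["ins_1", "c1"] == 1
        assert hist.loc["SNV", "c1"] == 0


class TestNormalization:
    def test_multiallelic_style_trimming(self):
        # A->C SNV written with trailing shared context
        assert trim_and_shift("c", 10, "AG", "CG") == (10, "A", "C")
        # shared prefix advances the position
        assert trim_and_shift("c", 10, "TA", "TG") == (11, "A", "G")

    def test_deletion_left_alignment_against_reference(self):
        ref = {"c": "GGCAAAAGTT"}
        # deleting one A written at the tract's right edge -> shifts to the C
        pos, r, a = trim_and_shift("c", 5, "AA", "A", ref)
        assert (pos, r, a) == (2, "CA", "C")

    def test_insertion_left_alignment_against_reference(self):
        ref = {"c": "GGCAAAAGTT"}
        pos, r, a = trim_and_shift("c", 6, "A", "AA", ref)
        assert (pos, r, a) == (2, "C", "CA")

    def test_normalization_idempotent(self, rng):
        ref = {"c": "".join(rng.choice(list("ACGT"), size=200))}
        for _ in range(50):
            pos = int(rng.integers(10, 180))
            kind = rng.choice(["del", "ins", "snv"])
            seq = ref["c"]
            if kind == "snv":
                raw = (pos, seq[pos], "ACGT".replace(seq[pos], "")[0])
            elif kind == "del":
                raw = (pos, seq[pos : pos + 3], seq[pos])
            else:
                raw = (pos, seq[pos], seq[pos] + "CA")
            once = trim_and_shift("c", *raw, ref)
            twice = trim_and_shift("c", *once, ref)
            assert once == twice


class TestTractAdjacency:
    def test_deletion_abutting_right_tract_flagged(self):
        #        0123456789
        seq = "GCTAAAAGTC"
        flag, base = is_tract_adjacent(seq, 3)  # deleted A, run of 4 A's
        assert flag and base == "A"

    def test_deletion_inside_tract_flagged(self):
        seq = "GCTTTTTAGC"
        flag, base = is_tract_adjacent(seq, 5)
        assert flag and base == "T"

    def test_isolated_deletion_not_flagged(self):
        seq = "GACGCGTGTC"
        assert is_tract_adjacent(seq, 4) == (False, None)

    def test_gc_runs_never_flagged(self):
        seq = "ATGGGGGGAT"
        assert is_tract_adjacent(seq, 4) == (False, None)

    def test_fraction_and_undefined_semantics(self):
        ref = {"c": "GCTAAAAGTCGACGCGTGTCAA"}
        def del1(pos):
            return UniqueVariant(
                record(chrom="c", pos=pos, ref=ref["c"][pos : pos + 2],
                       alt=ref["c"][pos]),
                "t1", 0.4, "del_1",
            )
        uniq = {"t1": [del1(2), del1(13)],  # deleted bases 3 (tract), 14 (not)
                "c1": [UniqueVariant(record(chrom="c", pos=1, ref="C", alt="T"),
                                     "c1", 0.4, "SNV")]}
        fractions = homopolymer_adjacent_fraction(uniq, ref)
        assert fractions["t1"] == pytest.approx(0.5)
        assert fractions["c1"] is None  # no -1 bp deletions: undefined, not 0


class TestRegionCounts:
    REGIONS = [("chr1", 1000, 1100, "ms1"), ("chr2", 5000, 5050, "ot1")]

    def _uniq(self, chrom, pos):
        return {"t1": [UniqueVariant(record(chrom=chrom, pos=pos), "t1",
                                     0.4, "SNV")]}

    def test_pad_inclusion(self):
        counts = count_region_variants(self._uniq("chr1", 950), self.REGIONS,
                                       pad_bp=100)
        assert counts.loc["ms1", "t1"] == 1  # 50 bp upstream, pad 100

    def test_pad_exclusion(self):
        counts = count_region_variants(self._uniq("chr1", 850), self.REGIONS,
                                       pad_bp=100)
        assert counts.loc["ms1", "t1"] == 0  # 150 bp away

    def test_zero_pad_and_empty(self):
        counts = count_region_variants(self._uniq("chr1", 999), self.REGIONS,
                                       pad_bp=0)
        assert counts.values.sum() == 0
        counts = count_region_variants({"t1": []}, self.REGIONS, pad_bp=100)
        assert counts.values.sum() == 0


class TestFoldChange:
    def _uniques(self, counts):
        return {
            s: [UniqueVariant(record(ref="AA", alt="A", pos=i), s, 0.4, "del_1")
                for i in range(n)]
            for s, n in counts.items()
        }

    def test_fold_vs_control_mean(self):
        uniq = self._uniques({"p1": 4, "p2": 4, "c1": 4, "c2": 4,
                              "t1": 10, "t2": 10})
        res = indel_fold_change(uniq, ROLES)
        assert res.folds == {"t1": 2.5, "t2": 2.5}
        assert res.control_mean == 4.0

    def test_fold_one_when_equal(self):
        uniq = self._uniques({s: 5 for s in SAMPLES})
        res = indel_fold_change(uniq, ROLES)
        assert all(f == pytest.approx(1.0) for f in res.folds.values())

    def test_zero_control_mean_flagged_undefined(self):
        uniq = self._uniques({"p1": 0, "p2": 0, "c1": 0, "c2": 0,
                              "t1": 5, "t2": 3})
        res = indel_fold_change(uniq, ROLES)
        assert res.undefined
        assert all(f is None for f in res.folds.values())

    def test_snvs_not_counted_as_indels(self):
        uniq = {s: [UniqueVariant(record(), s, 0.4, "SNV")] for s in SAMPLES}
        res = indel_fold_change(uniq, ROLES)
        assert res.undefined  # all indel counts zero


MINI_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=10000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
chr1\t101\t.\tA\tC,T\t.\tPASS\t.\tGT:DP:AD\t0/1:50:30,20,0\t0/0:40:40,0,0\t0/2:44:22,0,22
chr1\t201\t.\tGA\tG\t.\tPASS\t.\tGT:DP:AD\t0/0:50:50,0\t0/1:52:30,22\t0/0:47:47,0
"""

PEDIGREE = "sample_id\trole\ns1\tparent\ns2\tparent\ns3\ttreated_offspring\n"


class TestLoadFamily:
    @pytest.fixture()
    def paths(self, tmp_path):
        vcf = tmp_path / "mini.vcf"
        vcf.write_text(MINI_VCF)
        ped = tmp_path / "ped.tsv"
        ped.write_text(PEDIGREE)
        return vcf, ped

    def test_multiallelic_decomposition(self, paths):
        tbl = load_family(*paths)
        assert tbl.samples == ["s1", "s2", "s3"]
        assert len(tbl.variants) == 3  # two alts + one indel row
        a_to_c, a_to_t = tbl.variants[0], tbl.variants[1]
        assert (a_to_c.ref, a_to_c.alt) == ("A", "C")
        assert a_to_c.gt == (GT_HET, GT_HOM_REF, GT_OTHER_ALT)
        assert a_to_t.gt == (GT_OTHER_ALT, GT_HOM_REF, GT_HET)
        assert a_to_c.alt_ad == (20, 0, 0)
        assert a_to_t.alt_ad == (0, 0, 22)

    def test_indel_row_and_coordinates(self, paths):
        tbl = load_family(*paths)
        indel = tbl.variants[2]
        assert (indel.pos, indel.ref, indel.alt) == (200, "GA", "G")
        assert indel.dp == (50, 52, 47)

    def test_pedigree_sample_missing_from_vcf(self, tmp_path, paths):
        vcf, _ = paths
        bad = tmp_path / "bad_ped.tsv"
        bad.write_text("sample_id\trole\ns1\tparent\ns9\tparent\n")
        with pytest.raises(ConfigurationError, match="s9"):
            load_family(vcf, bad)

    def test_simulated_family_roundtrip_preserves_records(self, tmp_path):
        """Generator output is already normalized: loading changes nothing."""
        from pequant import FamilySimConfig, simulate_family, write_family

        result = simulate_family(FamilySimConfig(seed=3))
        paths = write_family(result, tmp_path)
        tbl = load_family(paths["vcf"], paths["pedigree"],
                          reference=result.reference)
        raw = [tuple(line.split("\t")[:5])
               for line in result.vcf_text.splitlines()
               if not line.startswith("#")]
        got = [(v.chrom, str(v.pos + 1), ".", v.ref, v.alt)
               for v in tbl.variants]
        assert got == raw


def test_region_counts_from_bed_file(tmp_path):
    bed = tmp_path / "regions.bed"
    bed.write_text("chr1\t1000\t1100\tms1\nchr2\t5000\t5050\tot1\n")
    uniq = {"t1": [UniqueVariant(record(chrom="chr1", pos=950), "t1", 0.4, "SNV")]}
    counts = count_region_variants(uniq, bed, pad_bp=100)
    assert counts.loc["ms1", "t1"] == 1
    assert counts.loc["ot1", "t1"] == 0
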