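"""DS/QS scoring, site calling, zygosity, primary filter, indel detection."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from capscreen.io_formats import AlignedRead, Gap, TargetRegion
from capscreen.pileup_depth import PileupColumn, build_pileup
from capscreen.synthetic_data import SimConfig, generate_experiment
from capscreen.variant_calling import (
    HOMOZYGOUS_SENTINEL,
    VariantCall,
    allele_score,
    call_site,
    call_variants,
    classify_zygosity,
    detect_indels,
    primary_filter,
)

from conftest import naive_aligned_pairs


class TestAlleleScore:
    @pytest.mark.parametrize("v, r, expected", [(10, 10, 100.0), (9, 10, 90.0)])
    def test_ratio_form(self, v, r, expected):
        assert allele_score(v, r) == pytest.approx(expected)

    def test_absent_reference_gives_homozygous_sentinel(self):
        assert allele_score(5, 0) == HOMOZYGOUS_SENTINEL

    def test_no_variant_evidence_rejected(self):
        with pytest.raises(ValueError):
            allele_score(0, 10)

    def test_bounded_form(self):
        assert allele_score(5, 5, mode="bounded") == pytest.approx(100.0)
        assert allele_score(3, 1, mode="bounded") == pytest.approx(150.0)

    @settings(derandomize=True, max_examples=60)
    @given(a=st.integers(1, 500), b=st.integers(1, 500))
    def test_ratio_symmetry(self, a, b):
        assert allele_score(a, b) * allele_score(b, a) == pytest.approx(100.0**2)

    @settings(derandomize=True, max_examples=40)
    @given(xr=st.integers(0, 50), step=st.integers(1, 20))
    def test_ds_monotone_in_variant_depth(self, xr, step):
        low = allele_score(1, xr)
        high = allele_score(1 + step, xr)
        assert high >= low


def _column(tallies: dict[str, tuple[int, float]], ref="A", pos=100) -> PileupColumn:
    col = PileupColumn("chr1", pos, ref)
    for allele, (depth, qual) in tallies.items():
        for _ in range(depth):
            col.add(allele, qual, False)
    return col


class TestCallSite:
    def test_balanced_het_scores(self):
        call = call_site(_column({"A": (10, 30), "T": (5, 30)}))
        assert call is not None
        assert (call.alt, call.ds, call.qs) == ("T", 50.0, 100.0)
        assert call.zygosity == "het"

    def test_reference_only_column_gives_no_call(self):
        assert call_site(_column({"A": (10, 30)})) is None

    def test_quality_imbalance_reflected_in_qs(self):
        call = call_site(_column({"A": (10, 30.0), "T": (9, 28.0)}))
        assert call.ds == pytest.approx(90.0)
        assert call.qs == pytest.approx(100 * 28 / 30)  # ~93.3

    def test_min_variant_reads_enforced(self):
        assert call_site(_column({"A": (10, 30), "T": (1, 30)})) is None

    def test_alt_tie_breaking_is_deterministic(self):
        # equal depth and quality: lexicographically smaller allele wins
        call = call_site(_column({"A": (10, 30), "T": (5, 30), "C": (5, 30)}))
        assert call.alt == "C"
        # higher mean quality beats lexicographic order
        call = call_site(_column({"A": (10, 30), "T": (5, 35), "C": (5, 30)}))
        assert call.alt == "T"


class TestZygosity:
    @pytest.mark.parametrize(
        "x_v, x_r, depth, expected",
        [(12, 0, 12, "hom"), (6, 6, 12, "het"), (1, 0, 1, "hom")],
    )
    def test_absent_reference_rule(self, x_v, x_r, depth, expected):
        call = VariantCall("chr1", 1, "A", "T", "SNP", depth, x_v, x_r, 30, 30,
                           100, 100, "het")
        assert classify_zygosity(call) == expected

    def test_fraction_mode(self):
        call = VariantCall("chr1", 1, "A", "T", "SNP", 20, 18, 2, 30, 30, 900, 100, "het")
        assert classify_zygosity(call) == "het"
        assert classify_zygosity(call, mode="fraction") == "hom"


class TestPrimaryFilter:
    def _call(self, ds, depth):
        return VariantCall("chr1", 1, "A", "T", "SNP", depth, max(1, depth // 2),
                           depth - max(1, depth // 2), 30, 30, ds, 100, "het")

    def test_ds_boundary_fifty_survives(self):
        assert primary_filter([self._call(50.0, 20)]) == [self._call(50.0, 20)]
        assert primary_filter([self._call(49.0, 20)]) == []

    def test_depth_boundary(self):
        assert primary_filter([self._call(80.0, 10)]) != []
        assert primary_filter([self._call(80.0, 9)]) == []

    def test_matches_independent_predicate_on_random_calls(self):
        rng = np.random.default_rng(5)
        calls = [
            self._call(float(rng.integers(0, 200)), int(rng.integers(2, 60)))
            for _ in range(1000)
        ]
        survivors = primary_filter(calls, 10, 50.0)
        expected = [c for c in calls if not (c.global_depth < 10 or c.ds < 50.0)]
        assert survivors == expected


REF = {"chr1": "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"}
REGION = [TargetRegion("chr1", 1, 40)]


def _gap_read(read_id, pos, gap, bases="ACGTACGTAC"):
    return AlignedRead(read_id, "S", "chr1", pos, "+", bases, (30,) * len(bases), gap=gap)


def _plain_read(read_id, pos, n=12):
    return AlignedRead(read_id, "S", "chr1", pos, "+", "A" * n, (30,) * n)


class TestDetectIndels:
    def test_identical_deletions_aggregate_with_full_balance(self):
        reads = [
            _gap_read(f"d{i}", 5, Gap(offset=4, length=2, kind="DEL")) for i in range(3)
        ] + [_plain_read(f"p{i}", 5) for i in range(3)]
        (call,) = detect_indels(reads, REGION, REF)
        assert call.kind == "DEL"
        assert (call.x_v, call.x_r) == (3, 3)
        assert call.ds == pytest.approx(100.0)
        assert call.pos == 8 and len(call.ref) == 3 and len(call.alt) == 1

    def test_single_supporting_read_not_called(self):
        reads = [_gap_read("d0", 5, Gap(offset=4, length=2, kind="DEL"))]
        assert detect_indels(reads, REGION, REF) == []

    def test_insertion_and_deletion_at_same_position_stay_distinct(self):
        reads = (
            [_gap_read(f"d{i}", 5, Gap(offset=4, length=2, kind="DEL")) for i in range(2)]
            + [_gap_read(f"i{i}", 5, Gap(offset=4, length=2, kind="INS")) for i in range(2)]
        )
        calls = detect_indels(reads, REGION, REF)
        assert sorted(c.kind for c in calls) == ["DEL", "INS"]
        keys = {c.key for c in calls}
        assert len(keys) == 2

    def test_unopposed_indel_is_homozygous(self):
        reads = [_gap_read(f"d{i}", 5, Gap(offset=4, length=2, kind="DEL")) for i in range(2)]
        (call,) = detect_indels(reads, REGION, REF)
        assert call.zygosity == "hom"
        assert call.ds == HOMOZYGOUS_SENTINEL


class TestPlantedRecovery:
    """Caller performance on error-free synthetic data at 30x, balance 0.5."""

    def test_detection_recall_at_least_99_percent(self, recall_run):
        truth, calls = recall_run
        assert len(truth) >= 100
        detected = sum(t.key in calls for t in truth)
        assert detected / len(truth) >= 0.99

    def test_ds_filtered_recall_matches_binomial_expectation(self, recall_run):
        """The DS>=50 filter keeps a balanced het iff its variant reads reach a
        third of the site depth; the observed pass rate must sit inside the
        99% binomial envelope of that per-site probability."""
        truth, calls = recall_run
        passing, p_pass = 0, []
        for t in truth:
            call = calls.get(t.key)
            if call is None:
                p_pass.append(0.999)  # undetected sites are counted as failures
                continue
            d = call.x_v + call.x_r
            k_min = int(np.ceil(d / 3))
            p_pass.append(1 - stats.binom.cdf(k_min - 1, d, 0.5))
            if call.ds >= 50.0:
                passing += 1
        mean_p = float(np.mean(p_pass))
        sd = float(np.sqrt(np.sum(np.multiply(p_pass, np.subtract(1, p_pass)))))
        expected = mean_p * len(truth)
        assert abs(passing - expected) <= 2.58 * max(sd, 1.0)


class TestCallerBruteForce:
    def test_caller_equals_per_column_recomputation(self, oracle_bundle):
        """Every emitted SNP call must match a naive recount of the reads."""
        reads = oracle_bundle.sample_reads["S3"]
        region = [r for r in oracle_bundle.regions if r.chrom == "chr2"][0]
        pileup = build_pileup(reads, [region], oracle_bundle.reference)
        calls = call_variants(pileup)
        # naive recount: tally (base, qual) per position from raw reads
        tallies: dict[int, dict[str, list[int]]] = {}
        for read in reads:
            if read.n_hits > 5 or read.chrom != region.chrom:
                continue
            for p, b, q in naive_aligned_pairs(read):
                if region.start <= p <= region.end:
                    tallies.setdefault(p, {}).setdefault(b, []).append(q)
        recomputed = {}
        for p, alleles in tallies.items():
            ref_base = oracle_bundle.reference[region.chrom][p - 1]
            alts = {
                b: v for b, v in alleles.items() if b != ref_base and len(v) >= 2
            }
            if not alts:
                continue
            alt = sorted(
                alts, key=lambda b: (-len(alts[b]), -np.mean(alts[b]), b)
            )[0]
            x_r = len(alleles.get(ref_base, []))
            ds = 100.0 * len(alts[alt]) / x_r if x_r else HOMOZYGOUS_SENTINEL
            recomputed[(region.chrom, p, ref_base, alt)] = (len(alts[alt]), x_r, ds)
        assert {c.key for c in calls} == set(recomputed)
        for c in calls:
            x_v, x_r, ds = recomputed[c.key]
            assert (c.x_v, c.x_r) == (x_v, x_r)
            assert c.ds == pytest.approx(ds)
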