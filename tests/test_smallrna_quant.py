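"""Trimming, exact mapping, the overhang counting rule, RPM and QC."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cortimir import smallrna_quant as sq
from cortimir import synthetic_data as sd
from cortimir.synthetic_data import HairpinReference, MatureRegion

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


class TestTrimAdapter:
    @pytest.mark.parametrize(
        "read, expected_seq, expected_kept",
        [
            # partial adapter (10 nt prefix) at the 3' end, found by hand
            ("ACGTACGTACGTACGTAA" + "TGGAATTCTC", "ACGTACGTACGTACGTAA", True),
            (ADAPTER, "", False),  # read is pure adapter
            ("ACGTACGTACGTACGTCAGT", "ACGTACGTACGTACGTCAGT", True),  # no adapter
            ("", "", False),
        ],
    )
    def test_examples(self, read, expected_seq, expected_kept):
        result = sq.trim_adapter(read, ADAPTER)
        assert result.sequence == expected_seq
        assert result.kept is expected_kept

    def test_internal_adapter_requires_full_match(self):
        # a 5-nt adapter prefix mid-read is below min_overlap and internal
        read = "ACGTACGTACGTACGT" + ADAPTER[:5] + "ACGTACGTAC"
        assert sq.trim_adapter(read, ADAPTER).sequence == read

    def test_short_adapter_rejected(self):
        with pytest.raises(ValueError):
            sq.trim_adapter("ACGT", "ACG")

    @given(
        insert=st.text(alphabet="ACGT", min_size=16, max_size=30),
        adapter_len=st.integers(min_value=6, max_value=len(ADAPTER)),
    )
    @settings(max_examples=60, derandomize=True)
    def test_planted_adapter_recovered(self, insert, adapter_len):
        """A read built as insert+adapter-prefix trims back to the insert,
        unless the insert itself ends in an adapter prefix (earlier cut)."""
        read = insert + ADAPTER[:adapter_len]
        result = sq.trim_adapter(read, ADAPTER)
        assert result.sequence == insert or insert.endswith(
            ADAPTER[: len(insert) - len(result.sequence)]
        )


def _hairpin(seq: str, regions: list[tuple[str, int, int]], hid="h") -> HairpinReference:
    return HairpinReference(hid, seq, tuple(MatureRegion(m, hid, s, e) for m, s, e in regions))


class TestMapExact:
    def test_unique_planted_read(self, small_hairpins):
        hp = small_hairpins[0]
        region = hp.mature_regions[0]
        read = hp.mature_sequence(region)
        (aln,) = sq.map_exact(read, small_hairpins)
        assert (aln.hairpin_id, aln.start, aln.end) == (hp.hairpin_id, region.start, region.end)
        assert aln.n_placements == 1

    def test_absent_read_returns_empty(self, small_hairpins):
        assert sq.map_exact("T" * 20, small_hairpins) == []

    def test_multi_hairpin_placement_counted(self):
        shared = "ACGTTGCAACGTTGCAACGT"
        h1 = _hairpin("A" * 20 + shared + "C" * 25, [], hid="h1")
        h2 = _hairpin("G" * 30 + shared + "T" * 15, [], hid="h2")
        alns = sq.map_exact(shared, [h1, h2])
        assert {a.hairpin_id for a in alns} == {"h1", "h2"}
        assert all(a.n_placements == 2 for a in alns)

    def test_brute_force_substring_scan_agrees(self, rng):
        bases = np.array(list("ACGT"))
        hairpins = [
            _hairpin("".join(rng.choice(bases, 80)), [], hid=f"h{i}") for i in range(5)
        ]
        read = hairpins[2].sequence[10:30]
        alns = sq.map_exact(read, hairpins)
        expected = [
            (hp.hairpin_id, i)
            for hp in hairpins
            for i in range(len(hp.sequence) - len(read) + 1)
            if hp.sequence[i : i + len(read)] == read
        ]
        assert [(a.hairpin_id, a.start) for a in alns] == expected
        assert all(a.n_placements == len(expected) for a in alns)


def _bruteforce_counts(alignments, regions, overhang, policy="fractional"):
    """Independent per-read interval test of the counting rule."""
    totals = {r.mature_id: 0.0 for r in regions}
    for aln in alignments:
        if policy == "fractional":
            weight = 1.0 / aln.n_placements
        elif policy == "discard":
            weight = 1.0 if aln.n_placements == 1 else 0.0
        else:
            weight = 1.0
        for region in regions:
            if (
                region.hairpin_id == aln.hairpin_id
                and aln.start >= region.start - overhang
                and aln.end <= region.end + overhang
            ):
                totals[region.mature_id] += weight
    return totals


class TestCountMature:
    REGION = MatureRegion("m1", "h", 20, 42)

    @pytest.mark.parametrize("start,end,counted", [(16, 42, True), (15, 42, False), (20, 46, True), (20, 47, False)])
    def test_overhang_boundary(self, start, end, counted):
        aln = sq.HairpinAlignment("r1", "h", start, end)
        result = sq.count_mature([aln], [self.REGION], overhang=4)
        assert result.counts.loc["m1", "sample"] == (1.0 if counted else 0.0)

    def test_negative_overhang_rejected(self):
        with pytest.raises(ValueError):
            sq.count_mature([], [self.REGION], overhang=-1)

    def test_hundred_contained_reads_counted_once_each(self, rng):
        alns = []
        for i in range(100):
            start = int(rng.integers(20, 30))
            alns.append(sq.HairpinAlignment(f"r{i}", "h", start, start + 12))
        result = sq.count_mature(alns, [self.REGION])
        assert result.counts.loc["m1", "sample"] == 100.0

    def test_multimap_policies(self):
        regions = [MatureRegion("m1", "h1", 0, 20), MatureRegion("m2", "h2", 0, 20)]
        alns = [
            sq.HairpinAlignment("r1", "h1", 0, 20, n_placements=2),
            sq.HairpinAlignment("r1", "h2", 0, 20, n_placements=2),
        ]
        fractional = sq.count_mature(alns, regions, multimap_policy="fractional")
        assert fractional.counts["sample"].tolist() == [0.5, 0.5]
        everywhere = sq.count_mature(alns, regions, multimap_policy="all")
        assert everywhere.counts["sample"].tolist() == [1.0, 1.0]
        discarded = sq.count_mature(alns, regions, multimap_policy="discard")
        assert discarded.counts["sample"].sum() == 0.0

    def test_matches_bruteforce_on_random_instances(self, rng):
        """Counting-rule equivalence with a naive per-read interval check
        on 120 random read/region instances."""
        for case in range(120):
            n_regions = int(rng.integers(1, 4))
            regions = []
            for j in range(n_regions):
                start = int(rng.integers(0, 60))
                regions.append(
                    MatureRegion(f"m{j}", f"h{int(rng.integers(0, 2))}", start, start + int(rng.integers(18, 26)))
                )
            alns = []
            for i in range(int(rng.integers(1, 30))):
                a = int(rng.integers(0, 80))
                alns.append(
                    sq.HairpinAlignment(
                        f"r{i}", f"h{int(rng.integers(0, 2))}", a, a + int(rng.integers(16, 30)),
                        n_placements=int(rng.integers(1, 3)),
                    )
                )
            overhang = int(rng.integers(0, 6))
            result = sq.count_mature(alns, regions, overhang=overhang)
            expected = _bruteforce_counts(alns, regions, overhang)
            got = result.counts["sample"].to_dict()
            assert got == pytest.approx(expected)

    def test_assigned_sum_bounded_by_aligned_reads(self, rng):
        regions = [MatureRegion(f"m{j}", "h", j * 30, j * 30 + 22) for j in range(3)]
        alns = [
            sq.HairpinAlignment(f"r{i}", "h", int(rng.integers(0, 80)), int(rng.integers(0, 80)) + 20)
            for i in range(50)
        ]
        result = sq.count_mature(alns, regions)
        assert result.counts["sample"].sum() <= result.aligned_reads["sample"]


class TestEndToEnd:
    def test_trim_map_count_recovers_generator_abundances(self, small_hairpins):
        """With zero jitter and zero background the quant stage reproduces
        the generator's per-miRNA read numbers exactly."""
        regions = [r for hp in small_hairpins for r in hp.mature_regions]
        abundances = {r.mature_id: 30.0 for r in regions}
        reads = sd.gen_reads(
            small_hairpins, abundances, seed=6, max_jitter=0, background_fraction=0.0
        )
        truth: dict[str, int] = {}
        alns = []
        for read_id, seq, _ in reads:
            truth[read_id.split("|")[1]] = truth.get(read_id.split("|")[1], 0) + 1
            trimmed = sq.trim_adapter(seq, sd.TRUSEQ_SMALL_RNA_ADAPTER)
            assert trimmed.kept
            alns.extend(sq.map_exact(trimmed.sequence, small_hairpins, read_id=read_id))
        counts = sq.count_mature(alns, regions)
        for region in regions:
            assert counts.counts.loc[region.mature_id, "sample"] == truth.get(region.mature_id, 0)


class TestRpmNormalize:
    def _counts(self, matrix, aligned):
        return sq.MatureCounts(pd.DataFrame(matrix), pd.Series(aligned))

    def test_simple_value(self):
        counts = self._counts({"s1": [50.0]}, {"s1": 1_000_000})
        assert sq.rpm_normalize(counts).iloc[0, 0] == 50.0

    def test_zero_counts_stay_zero(self):
        counts = self._counts({"s1": [0.0, 0.0]}, {"s1": 10_000})
        assert (sq.rpm_normalize(counts) == 0).all().all()

    def test_column_sum_identity(self, rng):
        mat = pd.DataFrame(rng.integers(0, 500, size=(20, 3)).astype(float), columns=list("abc"))
        aligned = pd.Series([5000, 7000, 9000], index=list("abc"))
        rpm = sq.rpm_normalize(sq.MatureCounts(mat, aligned))
        expected = 1e6 * mat.sum(axis=0) / aligned
        assert np.allclose(rpm.sum(axis=0), expected)

    def test_zero_denominator_names_sample(self):
        counts = self._counts({"bad_sample": [1.0]}, {"bad_sample": 0})
        with pytest.raises(ValueError, match="bad_sample"):
            sq.rpm_normalize(counts)

    def test_invariant_under_read_duplication(self, rng):
        mat = pd.DataFrame(rng.integers(0, 100, size=(10, 2)).astype(float), columns=["a", "b"])
        aligned = pd.Series([2000, 3000], index=["a", "b"])
        rpm = sq.rpm_normalize(sq.MatureCounts(mat, aligned))
        doubled = sq.rpm_normalize(sq.MatureCounts(2 * mat, 2 * aligned))
        assert np.allclose(rpm, doubled)


class TestReplicateCorrelation:
    def test_duplicate_columns_correlate_perfectly(self, rng):
        col = rng.integers(0, 1000, 30).astype(float)
        counts = pd.DataFrame({"a": col, "b": col})
        assert sq.replicate_correlation(counts).loc["a", "b"] == pytest.approx(1.0)

    def test_reversed_ranking_is_minus_one(self):
        counts = pd.DataFrame({"a": np.arange(20.0), "b": np.arange(20.0)[::-1]})
        assert sq.replicate_correlation(counts).loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson(self, rng):
        counts = pd.DataFrame(rng.random((40, 3)), columns=list("abc"))
        result = sq.replicate_correlation(counts)
        for x in "abc":
            for y in "abc":
                ranks_x = stats.rankdata(counts[x])
                ranks_y = stats.rankdata(counts[y])
                expected = np.corrcoef(ranks_x, ranks_y)[0, 1]
                assert result.loc[x, y] == pytest.approx(expected)

    def test_constant_column_reported_missing(self, rng):
        counts = pd.DataFrame({"a": rng.random(10), "b": np.ones(10)})
        with pytest.warns(UserWarning, match="constant"):
            result = sq.replicate_correlation(counts)
        assert np.isnan(result.loc["a", "b"])
        assert result.loc["b", "b"] == 1.0

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            sq.replicate_correlation(pd.DataFrame({"a": [1.0, 2.0]}))


class TestPcaQc:
    def test_identical_columns_collapse_to_origin(self):
        rpm = pd.DataFrame({"a": [1.0, 5.0, 2.0], "b": [1.0, 5.0, 2.0], "c": [1.0, 5.0, 2.0]})
        coords, _ = sq.pca_qc(rpm)
        assert np.allclose(coords.to_numpy(), 0.0, atol=1e-9)

    def test_explained_variance_nonincreasing(self, rng):
        rpm = pd.DataFrame(rng.random((50, 6)))
        _, explained = sq.pca_qc(rpm)
        assert (np.diff(explained) <= 1e-9).all()

    def test_requires_three_samples(self, rng):
        with pytest.raises(ValueError):
            sq.pca_qc(pd.DataFrame(rng.random((10, 2))))

    def test_pc1_separates_simulated_conditions(self):
        config = sd.SimulationConfig(
            n_mirna=200, de_fraction=0.4, log2_effect=3.0, dispersion=0.05, seed=21
        )
        matrix, _ = sd.gen_count_experiment(config)
        rpm = np.log1p(matrix.rpm())
        coords, _ = sq.pca_qc(rpm)
        labels = matrix.conditions
        pc1 = coords["PC1"]
        # positive mean silhouette on PC1 with conditions as clusters
        silhouettes = []
        for sample in pc1.index:
            same = pc1[labels == labels[sample]].drop(sample)
            other = pc1[labels != labels[sample]]
            a = (same - pc1[sample]).abs().mean()
            b = (other - pc1[sample]).abs().mean()
            silhouettes.append((b - a) / max(a, b))
        assert np.mean(silhouettes) > 0
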