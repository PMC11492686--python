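import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitorecomb.align import AlignParams, WindowIndex, align_query
from mitorecomb.graph_model import ContigDef, GenomeModel, Oriented, RepeatElement, stitch_sequence
from mitorecomb.io_formats import SeqRecord, revcomp
from mitorecomb.read_sim import random_dna, toy_isoforms
from mitorecomb.recomb_support import (
    ReadAlignment,
    RepeatWindow,
    WindowError,
    align_reads,
    build_window_from_path,
    build_windows,
    classify_support,
    estimate_ratio,
    quantify_repeat,
    resolve_multimapping,
    tally,
)


@pytest.fixture(scope="module")
def toy_windows(toy_model):
    _, model, _ = toy_model
    return build_windows(model, model.repeats["R1"], flank=3000)


class TestBuildWindows:
    def test_full_flank_arithmetic(self, toy_model):
        _, model, _ = toy_model
        windows = build_windows(model, model.repeats["R1"], flank=5000)
        assert len(windows) == 4
        for w in windows:
            assert len(w.sequence) == 12_000
            assert w.repeat_interval == (5001, 7000)
            assert w.left_flank_len == w.right_flank_len == 5000
            assert not (w.truncated_left or w.truncated_right)
        assert {w.conformation for w in windows} == {"reference", "crossover"}

    def test_truncated_flank_recorded(self):
        rng = np.random.default_rng(0)
        model = GenomeModel()
        for name, length in (("a", 3100), ("b", 8000), ("c", 8000), ("d", 8000)):
            model.contigs[name] = ContigDef(name, length, sequence=random_dna(rng, length))
        model.repeats["R"] = RepeatElement(
            "R", 500,
            [(Oriented("a"), Oriented("b")), (Oriented("c"), Oriented("d"))],
            sequence=random_dna(rng, 500),
        )
        windows = build_windows(model, model.repeats["R"], flank=5000)
        w = next(w for w in windows if w.window_id == "a-R-b")
        assert w.left_flank_len == 3100
        assert w.truncated_left and not w.truncated_right
        assert w.repeat_interval == (3101, 3600)

    def test_window_equals_substring_of_stitched_molecule(self, toy_model):
        _, model, truth = toy_model
        flank = 2500
        windows = {w.window_id: w for w in build_windows(model, model.repeats["R1"], flank)}
        # independent oracle: cut the window out of the stitched molecule
        for label, mol, tag in toy_isoforms(model, truth):
            seq = stitch_sequence(mol.conformation, model)
            path = mol.conformation.path
            offset = 0
            for el in path:
                ln = len(model.element_sequence(el.name))
                if el.name == "R1":
                    doubled = seq * 2  # circular molecule
                    start = offset - flank
                    expected = doubled[start : start + flank + ln + flank]
                    left = path[(path.index(el) - 1) % len(path)].name
                    right = path[(path.index(el) + 1) % len(path)].name
                    window = windows[f"{left}-R1-{right}"]
                    assert window.sequence == expected
                offset += ln

    def test_inconsistent_interval_rejected(self):
        with pytest.raises(WindowError):
            RepeatWindow("w", "A" * 100, (11, 20), 5, 80, "reference")

    def test_multicopy_window_from_path(self):
        rng = np.random.default_rng(2)
        model = GenomeModel()
        for name, length in (("A", 3000), ("B", 500), ("C", 3000), ("D", 3000)):
            model.contigs[name] = ContigDef(name, length, sequence=random_dna(rng, length))
        model.repeats["R"] = RepeatElement(
            "R", 200,
            [(Oriented("A"), Oriented("B")), (Oriented("B"), Oriented("C"))],
            sequence=random_dna(rng, 200),
        )
        w = build_window_from_path(
            model,
            [Oriented("A"), Oriented("R"), Oriented("B"), Oriented("R"), Oriented("C")],
            "A-R-B-R-C",
            "reference",
            flank=1000,
        )
        assert len(w.sequence) == 1000 + 200 + 500 + 200 + 1000
        assert w.repeat_interval == (1001, 1900)


class TestAlignReads:
    def test_exact_substring_alignment(self, toy_windows):
        w = toy_windows[0]
        frag = w.sequence[1000:7000]
        alns = align_reads([SeqRecord("r1", frag)], [w])
        assert len(alns) == 1
        aln = alns[0]
        assert aln.window_cover == (1001, 7000)
        assert aln.read_cover == (1, 6000)
        assert aln.identity == 1.0
        assert aln.strand == "+"

    def test_reverse_strand_alignment(self, toy_windows):
        w = toy_windows[0]
        frag = revcomp(w.sequence[1000:7000])
        alns = align_reads([SeqRecord("r1", frag)], [w])
        assert alns and alns[0].strand == "-"
        assert alns[0].window_cover == (1001, 7000)
        assert alns[0].identity == 1.0

    def test_unrelated_read_not_aligned(self, toy_windows, rng):
        read = SeqRecord("junk", random_dna(rng, 4000))
        assert align_reads([read], toy_windows) == []

    def test_window_shorter_than_k_rejected(self):
        from mitorecomb.align import AlignmentError

        with pytest.raises(AlignmentError, match="shorter than k"):
            WindowIndex("w", "ACGT", k=15)

    def test_coordinates_accurate_under_substitutions(self, toy_windows):
        # 200 reads at 5% substitution from known window positions: the
        # inferred window cover must sit within +-10 bp of truth for >=95%
        rng = np.random.default_rng(99)
        w = toy_windows[0]
        n_good = 0
        reads, truths = [], []
        for i in range(200):
            start = int(rng.integers(0, len(w.sequence) - 3000))
            frag = np.frombuffer(
                w.sequence[start : start + 3000].encode(), dtype=np.uint8
            ).copy()
            mask = rng.random(3000) < 0.05
            bases = np.frombuffer(b"ACGT", dtype=np.uint8)
            idx = np.searchsorted(bases, frag[mask])
            frag[mask] = bases[(idx + rng.integers(1, 4, size=int(mask.sum()))) % 4]
            reads.append(SeqRecord(f"r{i}", frag.tobytes().decode()))
            truths.append((start + 1, start + 3000))
        alns = {a.read_id: a for a in align_reads(reads, [w])}
        for read, truth in zip(reads, truths):
            aln = alns.get(read.id)
            if aln and abs(aln.window_cover[0] - truth[0]) <= 10 and abs(
                aln.window_cover[1] - truth[1]
            ) <= 10:
                n_good += 1
        assert n_good >= 190


class TestClassifySupport:
    def _window(self):
        return RepeatWindow(
            "w", "A" * 12_000, (5001, 7000), 5000, 5000, "reference"
        )

    def _aln(self, cover):
        return ReadAlignment("r", "w", cover, (1, cover[1] - cover[0] + 1), "+", 1.0, 100)

    def test_boundary_exactly_50(self):
        assert classify_support(self._aln((4951, 7050)), self._window(), 50)

    def test_boundary_minus_one(self):
        assert not classify_support(self._aln((4952, 7050)), self._window(), 50)
        assert not classify_support(self._aln((4951, 7049)), self._window(), 50)

    def test_exhaustive_interval_oracle(self):
        # brute-force every integer cover interval on a small window and
        # compare with the inequality definition
        window = RepeatWindow("w", "A" * 60, (21, 40), 20, 20, "reference")
        min_flank = 5
        for start in range(1, 61):
            for end in range(start, 61):
                expected = start <= 21 - min_flank and end >= 40 + min_flank
                got = classify_support(self._aln((start, end)), window, min_flank)
                assert got == expected

    @given(
        start=st.integers(1, 5000),
        end=st.integers(7001, 12000),
        grow_l=st.integers(0, 100),
        grow_r=st.integers(0, 100),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_cover(self, start, end, grow_l, grow_r):
        window = self._window()
        small = classify_support(self._aln((start, end)), window)
        big = classify_support(
            self._aln((max(1, start - grow_l), min(12_000, end + grow_r))), window
        )
        assert big or not small


class TestResolveMultimapping:
    def _window(self, wid, conformation="reference"):
        return RepeatWindow(wid, "A" * 1000, (401, 600), 400, 400, conformation)

    def test_single_supporter_kept(self):
        windows = [self._window("w1"), self._window("w2", "crossover")]
        aln = ReadAlignment("r", "w1", (300, 700), (1, 401), "+", 1.0, 401)
        res = resolve_multimapping([aln], windows)
        assert res.assignments == {"r": "w1"}
        assert res.ambiguous == 0

    def test_strict_tie_discarded(self):
        windows = [self._window("w1"), self._window("w2", "crossover")]
        alns = [
            ReadAlignment("r", "w1", (300, 700), (1, 401), "+", 1.0, 401),
            ReadAlignment("r", "w2", (300, 700), (1, 401), "+", 1.0, 401),
        ]
        res = resolve_multimapping(alns, windows)
        assert res.assignments == {}
        assert res.ambiguous == 1

    def test_non_supporting_alignment_ignored(self):
        windows = [self._window("w1")]
        aln = ReadAlignment("r", "w1", (450, 700), (1, 251), "+", 1.0, 251)
        res = resolve_multimapping([aln], windows)
        assert res.assignments == {}


class TestTally:
    def test_carlesii_lr9_paper_percentages(self):
        support = tally(
            {"a1": 11, "a2": 4, "b1": 4, "b2": 7},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
            "LR9",
        )
        assert support.totals == {"A": 15, "B": 11}
        assert support.proportions["A"] == pytest.approx(15 / 26)

    def test_henryi_lr7_paper_percentages(self):
        support = tally(
            {"a1": 224, "a2": 264, "b1": 172, "b2": 208},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
            "LR7",
        )
        assert support.totals == {"A": 488, "B": 380}
        assert support.proportions["A"] == pytest.approx(488 / 868)

    def test_henryi_lr9_multicopy_mode(self):
        support = tally(
            {"p1": 271, "p2": 42}, {"p1": "A", "p2": "B"}, "LR9", mode="multicopy"
        )
        assert support.proportions["A"] == pytest.approx(271 / 313)
        assert support.proportions["B"] == pytest.approx(42 / 313)

    def test_sum_and_average_modes_agree_on_proportions(self):
        counts = {"a1": 13, "a2": 9, "b1": 4, "b2": 6}
        conf = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        p_sum = tally(counts, conf, "R", combine="sum").proportions
        p_avg = tally(counts, conf, "R", combine="average").proportions
        assert p_sum == pytest.approx(p_avg)

    def test_zero_reads_gives_none(self):
        support = tally({"a": 0, "b": 0}, {"a": "A", "b": "B"}, "R", mode="multicopy")
        assert support.proportions == {"A": None, "B": None}

    @given(counts=st.lists(st.integers(0, 1000), min_size=4, max_size=4))
    @settings(max_examples=100, deadline=None)
    def test_label_swap_symmetry(self, counts):
        labels = ["a1", "a2", "b1", "b2"]
        conf = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        swapped = {"a1": "B", "a2": "B", "b1": "A", "b2": "A"}
        s1 = tally(dict(zip(labels, counts)), conf, "R")
        s2 = tally(dict(zip(labels, counts)), swapped, "R")
        if sum(counts) > 0:
            assert s1.proportions["A"] == pytest.approx(s2.proportions["B"])
            assert s1.proportions["A"] + s1.proportions["B"] == pytest.approx(1.0)


class TestEstimateRatio:
    def test_point_estimate_paper(self):
        support = tally(
            {"a1": 11, "a2": 4, "b1": 4, "b2": 7},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
            "LR9",
        )
        est = estimate_ratio(support)
        assert est["A"].point == pytest.approx(0.5769, abs=1e-4)
        assert est["A"].lower < est["A"].point < est["A"].upper

    def test_zero_numerator_nondegenerate_interval(self):
        support = tally({"a": 0, "b": 10}, {"a": "A", "b": "B"}, "R", mode="multicopy")
        est = estimate_ratio(support)
        assert est["A"].point == 0.0
        assert est["A"].upper > 0.0

    def test_binomial_simulation_within_99_interval(self):
        rng = np.random.default_rng(123)
        n = 1000
        k = int(rng.binomial(n, 0.30))
        support = tally({"a": k, "b": n - k}, {"a": "A", "b": "B"}, "R", mode="multicopy")
        est = estimate_ratio(support, confidence=0.99)
        assert est["A"].lower <= 0.30 <= est["A"].upper


class TestQuantifyEndToEnd:
    def test_zero_error_no_ambiguity_and_truthful_counts(self, toy_reads):
        _, model, isoforms, reads, truth = toy_reads
        support, resolved = quantify_repeat(
            model, model.repeats["R1"], reads, flank=3000, min_flank=50
        )
        assert resolved.ambiguous == 0
        # every assigned read's window conformation matches its provenance
        prov = {r.read_id: r.conformation for r in truth.reads}
        window_conf = dict(support.path_conformation)
        for read_id, window_id in resolved.assignments.items():
            assert window_conf[window_id] == prov[read_id]
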