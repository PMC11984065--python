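import numpy as np
import pytest

from protoconv import textgrid
from protoconv.annotation import (
    AnnotationError,
    SessionAnnotation,
    Speaker,
    Utterance,
    apply_segmentation,
    filter_analysis_set,
    merge_close_sounds,
    read_session,
    read_textgrid,
    write_textgrid,
)

from _oracles import brute_force_merge
from conftest import random_session, random_stream


def utt(a, b, cat="speech", speaker=Speaker.CAREGIVER):
    return Utterance(a, b, speaker, cat)


class TestUtteranceValidation:
    def test_rejects_non_positive_duration(self):
        with pytest.raises(AnnotationError, match="positive duration"):
            utt(2.0, 2.0)

    def test_rejects_negative_onset(self):
        with pytest.raises(AnnotationError, match=">= 0"):
            utt(-0.5, 1.0)

    def test_rejects_category_wrong_speaker(self):
        with pytest.raises(AnnotationError, match="not legal"):
            Utterance(0.0, 1.0, Speaker.INFANT, "speech")


class TestSessionValidation:
    def test_sorts_utterances_by_onset(self):
        s = SessionAnnotation(
            "d1", "T1", "book_sharing", 300.0,
            (utt(5.0, 6.0), utt(1.0, 2.0)),
        )
        assert [u.onset for u in s.utterances] == [1.0, 5.0]

    def test_rejects_same_speaker_overlap(self):
        with pytest.raises(AnnotationError, match="overlap"):
            SessionAnnotation(
                "d1", "T1", "book_sharing", 300.0,
                (utt(0.0, 2.0), utt(1.5, 3.0)),
            )

    def test_cross_speaker_overlap_is_legal(self):
        s = SessionAnnotation(
            "d1", "T1", "book_sharing", 300.0,
            (utt(0.0, 2.0), utt(1.5, 3.0, "syllable", Speaker.INFANT)),
        )
        assert len(s.utterances) == 2

    def test_spillover_rejected_by_default_and_tolerated_on_request(self):
        args = ("d1", "T1", "book_sharing", 300.0, (utt(299.5, 300.4),))
        with pytest.raises(AnnotationError, match="past the session duration"):
            SessionAnnotation(*args)
        s = SessionAnnotation(*args, spillover_tol=0.5)
        assert s.utterances[0].offset == 300.4

    def test_contiguous_intervals_are_not_overlap(self):
        s = SessionAnnotation(
            "d1", "T1", "book_sharing", 300.0,
            (utt(0.0, 1.0), utt(1.0, 2.0)),
        )
        assert len(s.utterances) == 2


class TestMergeCloseSounds:
    def test_pause_at_most_200ms_fuses(self):
        merged = merge_close_sounds([utt(0.0, 1.0), utt(1.15, 2.0)])
        assert [(u.onset, u.offset) for u in merged] == [(0.0, 2.0)]

    def test_pause_over_200ms_splits(self):
        merged = merge_close_sounds([utt(0.0, 1.0), utt(1.25, 2.0)])
        assert len(merged) == 2

    def test_exact_200ms_boundary_fuses(self):
        # the rule splits only on pauses *greater than* the threshold
        merged = merge_close_sounds([utt(0.0, 1.0), utt(1.2, 2.0)])
        assert [(u.onset, u.offset) for u in merged] == [(0.0, 2.0)]

    def test_category_boundary_blocks_fusion(self):
        merged = merge_close_sounds([utt(0.0, 1.0, "speech"), utt(1.1, 2.0, "singing")])
        assert len(merged) == 2

    def test_merge_across_categories_flag(self):
        merged = merge_close_sounds(
            [utt(0.0, 1.0, "speech"), utt(1.1, 2.0, "singing")],
            merge_across_categories=True,
        )
        assert [(u.onset, u.offset) for u in merged] == [(0.0, 2.0)]

    def test_fusion_is_transitive(self):
        chain = [utt(0.0, 1.0), utt(1.1, 2.0), utt(2.1, 3.0), utt(3.5, 4.0)]
        merged = merge_close_sounds(chain)
        assert [(u.onset, u.offset) for u in merged] == [(0.0, 3.0), (3.5, 4.0)]

    def test_rejects_overlapping_input(self):
        with pytest.raises(AnnotationError):
            merge_close_sounds([utt(0.0, 1.0), utt(0.5, 2.0)])

    def test_rejects_mixed_speakers(self):
        with pytest.raises(AnnotationError, match="single-speaker"):
            merge_close_sounds(
                [utt(0.0, 1.0), utt(2.0, 3.0, "syllable", Speaker.INFANT)]
            )

    @pytest.mark.parametrize("across", [False, True])
    def test_matches_brute_force_fuser_and_is_idempotent(self, rng, across):
        for _ in range(300):
            stream = random_stream(rng, Speaker.CAREGIVER, n_max=15, length=60.0)
            once = merge_close_sounds(stream, merge_across_categories=across)
            expected = brute_force_merge(stream, 0.200, merge_across_categories=across)
            assert [(u.onset, u.offset, u.category) for u in once] == expected
            twice = merge_close_sounds(once, merge_across_categories=across)
            assert twice == once
            # fused chains keep their extremes and never lose voiced time
            if stream:
                assert once[0].onset == stream[0].onset
                assert once[-1].offset == stream[-1].offset
                assert sum(u.duration for u in once) >= sum(
                    u.duration for u in stream
                ) - 1e-12


class TestFilterAnalysisSet:
    def test_reflexive_infant_sounds_removed(self):
        s = SessionAnnotation(
            "d1", "T1", "book_sharing", 300.0,
            tuple(
                Utterance(i * 2.0, i * 2.0 + 1.0, Speaker.INFANT, c)
                for i, c in enumerate(
                    ["syllable", "syllable", "syllable", "cry", "cry"]
                )
            ),
        )
        out = filter_analysis_set(s)
        assert len(out.utterances) == 3
        assert out.meta["filtered"] == {"infant:cry": 2}

    def test_caregiver_laughter_removed_speech_singing_kept(self):
        s = SessionAnnotation(
            "d1", "T1", "book_sharing", 300.0,
            (utt(0.0, 1.0, "speech"), utt(2.0, 3.0, "laughter"),
             utt(4.0, 5.0, "singing")),
        )
        out = filter_analysis_set(s)
        assert [u.category for u in out.utterances] == ["speech", "singing"]

    def test_empty_session_passes_through(self):
        s = SessionAnnotation("d1", "T1", "book_sharing", 300.0, ())
        assert filter_analysis_set(s).utterances == ()

    def test_pure_subset(self, rng):
        for _ in range(50):
            s = random_session(rng, n_max=20)
            out = filter_analysis_set(s)
            assert set(out.utterances) <= set(s.utterances)


class TestSegmentationPolicy:
    def test_infant_stream_not_merged_by_default(self):
        s = SessionAnnotation(
            "d1", "T1", "book_sharing", 300.0,
            (Utterance(0.0, 1.0, Speaker.INFANT, "syllable"),
             Utterance(1.1, 2.0, Speaker.INFANT, "syllable"),
             utt(5.0, 6.0), utt(6.1, 7.0)),
        )
        out = apply_segmentation(s)
        assert len(out.speaker_utterances(Speaker.INFANT)) == 2
        assert len(out.speaker_utterances(Speaker.CAREGIVER)) == 1
        both = apply_segmentation(s, merge_infant=True)
        assert len(both.speaker_utterances(Speaker.INFANT)) == 1


class TestTextGridIO:
    def test_single_interval_mapping(self, tmp_path):
        s = SessionAnnotation(
            "d1", "T1", "book_sharing", 300.0,
            (Utterance(1.0, 2.0, Speaker.INFANT, "syllable"),),
        )
        path = tmp_path / "s.TextGrid"
        write_textgrid(s, path)
        grid = textgrid.read(path)
        infant = grid.get_tier("infant")
        assert [(iv.xmin, iv.xmax, iv.text) for iv in infant.intervals] == [
            (0.0, 1.0, ""), (1.0, 2.0, "syllable"), (2.0, 300.0, ""),
        ]
        utts = read_textgrid(path)
        assert utts == [Utterance(1.0, 2.0, Speaker.INFANT, "syllable")]

    def test_empty_session_tiles_with_silence(self, tmp_path):
        s = SessionAnnotation("d1", "T1", "book_sharing", 300.0, ())
        path = tmp_path / "e.TextGrid"
        write_textgrid(s, path)
        grid = textgrid.read(path)
        for tier in grid.tiers:
            assert [(iv.xmin, iv.xmax, iv.text) for iv in tier.intervals] == [
                (0.0, 300.0, "")
            ]
        assert read_textgrid(path) == []

    def test_random_roundtrip_identity(self, rng, tmp_path):
        for i in range(100):
            s = random_session(rng, n_max=15, duration=90.0, dyad_id=f"d{i}")
            path = tmp_path / f"r{i}.TextGrid"
            write_textgrid(s, path)
            back = read_session(path, s.dyad_id, s.timepoint, s.task, s.duration)
            assert len(back.utterances) == len(s.utterances)
            for a, b in zip(s.utterances, back.utterances):
                assert abs(a.onset - b.onset) <= 1e-9
                assert abs(a.offset - b.offset) <= 1e-9
                assert (a.speaker, a.category) == (b.speaker, b.category)

    def test_missing_tier_error_names_tier(self, tmp_path):
        grid = textgrid.TextGrid(0.0, 10.0)
        grid.tiers = [textgrid.IntervalTier("infant", 0.0, 10.0,
                                            [textgrid.Interval(0.0, 10.0, "")])]
        path = tmp_path / "m.TextGrid"
        textgrid.write(grid, path)
        with pytest.raises(textgrid.TextGridError, match="'caregiver'"):
            read_textgrid(path)

    def test_unknown_label_error_lists_label_and_interval(self, tmp_path):
        grid = textgrid.TextGrid(0.0, 10.0)
        grid.tiers = [
            textgrid.IntervalTier("infant", 0.0, 10.0,
                                  [textgrid.Interval(1.0, 2.0, "mystery")]),
            textgrid.IntervalTier("caregiver", 0.0, 10.0, []),
        ]
        path = tmp_path / "u.TextGrid"
        textgrid.write(grid, path)
        with pytest.raises(AnnotationError, match=r"'mystery'.*\[1\.0, 2\.0\]"):
            read_textgrid(path, label_map={"bab": "syllable"})

    def test_label_map_translates_coder_labels(self, tmp_path):
        grid = textgrid.TextGrid(0.0, 10.0)
        grid.tiers = [
            textgrid.IntervalTier("infant", 0.0, 10.0,
                                  [textgrid.Interval(1.0, 2.0, "SYL")]),
            textgrid.IntervalTier("caregiver", 0.0, 10.0, []),
        ]
        path = tmp_path / "l.TextGrid"
        textgrid.write(grid, path)
        utts = read_textgrid(path, label_map={"SYL": "syllable"})
        assert utts[0].category == "syllable"

    def test_overlap_repair_clip(self, tmp_path):
        grid = textgrid.TextGrid(0.0, 10.0)
        grid.tiers = [
            textgrid.IntervalTier(
                "infant", 0.0, 10.0,
                [textgrid.Interval(0.0, 3.0, "syllable"),
                 textgrid.Interval(2.0, 4.0, "protophone")],
            ),
            textgrid.IntervalTier("caregiver", 0.0, 10.0, []),
        ]
        path = tmp_path / "o.TextGrid"
        textgrid.write(grid, path)
        with pytest.raises(AnnotationError, match="overlap"):
            read_textgrid(path)
        utts = read_textgrid(path, repair="clip")
        assert [(u.onset, u.offset) for u in utts] == [(0.0, 2.0), (2.0, 4.0)]
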