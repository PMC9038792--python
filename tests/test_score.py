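import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lohscape.errors import QCFailureError, UndefinedScoreError
from lohscape.genome import toy_genome
from lohscape.gloh import (CNSegment, apply_exclusions, compute_percent_gloh,
                           percent_gloh_from_segments)
from lohscape.gloh.pipeline import TumorProfile

from .oracles import interval_gloh_oracle


def _seg(chrom, start, end, loh, excluded=False, reason="none"):
    return CNSegment(chrom=chrom, start=start, end=end, ci=1 if loh else 2,
                     mi=0 if loh else 1, is_loh=loh, n_snps=50, margin=100.0,
                     excluded=excluded, exclusion_reason=reason)


def test_all_het_scores_zero():
    segs = [_seg(1, 0, 60, False), _seg(1, 60, 100, False)]
    assert percent_gloh_from_segments(segs).percent_gloh == 0.0


def test_simple_forty_percent():
    segs = [_seg(1, 0, 40, True), _seg(1, 40, 100, False)]
    res = percent_gloh_from_segments(segs)
    assert res.percent_gloh == 40.0
    assert res.loh_len_included == 40
    assert res.total_len_included == 100


def test_worked_exclusion_example():
    """chr1 fully LOH (excluded), chr2 LOH on [0,30): 100*30/(100+5) = 28.57."""
    g = toy_genome(n_chrom=2, length=100, centromere=50)
    segs = [_seg(1, 0, 95, True), _seg(1, 95, 100, False),
            _seg(2, 0, 30, True), _seg(2, 30, 100, False)]
    out = apply_exclusions(segs, g)
    res = percent_gloh_from_segments(out)
    assert res.percent_gloh == pytest.approx(100 * 30 / 105)
    oracle = interval_gloh_oracle([(s.length, s.is_loh, s.excluded) for s in out])
    assert res.percent_gloh == pytest.approx(oracle)
    assert res.len_excluded_arm == 95


def test_undefined_when_everything_excluded():
    segs = [_seg(1, 0, 100, True, excluded=True, reason="whole_chrom_or_arm")]
    with pytest.raises(UndefinedScoreError):
        percent_gloh_from_segments(segs)


def test_qc_gate():
    profile = TumorProfile(sample_id="s", qc_pass=False, qc_reason="low_tumor_content")
    profile.segments = [_seg(1, 0, 100, False)]
    with pytest.raises(QCFailureError) as exc:
        compute_percent_gloh(profile)
    assert exc.value.reason == "low_tumor_content"
    profile.score_on_qc_fail = True
    assert compute_percent_gloh(profile).percent_gloh == 0.0


@settings(max_examples=40, deadline=None)
@given(st.lists(st.tuples(st.integers(1, 500),          # length
                          st.booleans(),                # is_loh
                          st.sampled_from(["none", "whole_chrom_or_arm", "ambiguous"])),
                min_size=1, max_size=20))
def test_bounds_and_conservation(pieces):
    segs, pos = [], 0
    for length, loh, reason in pieces:
        segs.append(CNSegment(chrom=1, start=pos, end=pos + length,
                              ci=1 if loh else 2, mi=0 if loh else 1, is_loh=loh,
                              excluded=reason != "none", exclusion_reason=reason))
        pos += length
    total = sum(s.length for s in segs)
    try:
        res = percent_gloh_from_segments(segs)
    except UndefinedScoreError:
        assert all(s.excluded for s in segs)
        return
    assert 0.0 <= res.percent_gloh <= 100.0
    # bookkeeping closes exactly
    assert res.total_len_included + res.len_excluded_arm + res.len_excluded_ambiguous == total
    assert res.percent_gloh == pytest.approx(
        interval_gloh_oracle([(s.length, s.is_loh, s.excluded) for s in segs]))


def test_adding_loh_never_decreases_score():
    rng = np.random.default_rng(0)
    for _ in range(25):
        n = rng.integers(2, 12)
        lens = rng.integers(1, 100, size=n)
        loh = rng.random(n) < 0.4
        segs, pos = [], 0
        for length, is_loh in zip(lens, loh):
            segs.append(_seg(1, pos, pos + int(length), bool(is_loh)))
            pos += int(length)
        base = percent_gloh_from_segments(segs).percent_gloh
        het_idx = [i for i, s in enumerate(segs) if not s.is_loh]
        if not het_idx:
            continue
        i = int(rng.choice(het_idx))
        segs[i] = _seg(1, segs[i].start, segs[i].end, True)
        assert percent_gloh_from_segments(segs).percent_gloh >= base
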