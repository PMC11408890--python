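"""Brute-force reference implementations of the epoch rules.

These scanners implement the stated rules directly with explicit loops,
independently of the run-length-merge algorithms in the package: candidate
regions are split at any disqualifying run, trimmed to their core minutes,
and tested against the span threshold.
"""
from __future__ import annotations


def nonwear_mask_oracle(
    cpm,
    min_zero_run: int = 60,
    sub_threshold: int = 100,
    max_interruption: int = 2,
    strict_gt: bool = False,
) -> list[bool]:
    """Per-minute non-wear flags for one day's CPM sequence."""
    n = len(cpm)
    mask = [False] * n

    def mark_segment(a: int, b: int) -> None:
        # trim to the first/last zero-count minute
        while a < b and cpm[a] != 0:
            a += 1
        while b > a and cpm[b - 1] != 0:
            b -= 1
        span = b - a
        if span > min_zero_run or (span == min_zero_run and not strict_gt):
            for k in range(a, b):
                mask[k] = True

    i = 0
    while i < n:
        if cpm[i] >= sub_threshold:
            i += 1
            continue
        # maximal region of sub-threshold minutes
        j = i
        while j < n and cpm[j] < sub_threshold:
            j += 1
        # split the region at runs of >= max_interruption nonzero minutes
        seg_start = i
        k = i
        while k < j:
            if cpm[k] > 0:
                r = k
                while r < j and cpm[r] > 0:
                    r += 1
                if r - k >= max_interruption:
                    mark_segment(seg_start, k)
                    seg_start = r
                k = r
            else:
                k += 1
        mark_segment(seg_start, j)
        i = j
    return mask


def bouts_oracle(
    labels,
    min_span: int = 10,
    max_interruption: int = 2,
    mvpa_codes=(2, 3),
    wear_codes=(0, 1, 2, 3),
) -> list[tuple[int, int, int, int, int]]:
    """Qualifying bouts as (start, end, moderate, vigorous, interruption)."""
    n = len(labels)
    out = []

    def emit(a: int, b: int) -> None:
        while a < b and labels[a] not in mvpa_codes:
            a += 1
        while b > a and labels[b - 1] not in mvpa_codes:
            b -= 1
        span = b - a
        if span >= min_span:
            mod = sum(1 for k in range(a, b) if labels[k] == 2)
            vig = sum(1 for k in range(a, b) if labels[k] == 3)
            out.append((a, b - 1, mod, vig, span - mod - vig))

    i = 0
    while i < n:
        if labels[i] not in wear_codes:
            i += 1
            continue
        j = i
        while j < n and labels[j] in wear_codes:
            j += 1
        seg_start = i
        k = i
        while k < j:
            if labels[k] not in mvpa_codes:
                r = k
                while r < j and labels[r] in wear_codes and labels[r] not in mvpa_codes:
                    r += 1
                if r - k >= max_interruption:
                    emit(seg_start, k)
                    seg_start = r
                k = r
            else:
                k += 1
        emit(seg_start, j)
        i = j
    return out
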