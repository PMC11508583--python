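"""Nucleotide-composition statistics and sliding-window profiles.

AT/GC skew measure strand asymmetry of base composition:
``at_skew = (A - T)/(A + T)`` and ``gc_skew = (G - C)/(G + C)``.  With
this orientation an A-rich majority strand gives a positive AT skew and a
C-rich one a negative GC skew, the typical signature of insect
mitochondrial genomes.  Skews with a zero denominator are reported as
missing (``None``), never as 0 — zero would assert a balance that was
never observed.

Ambiguous bases (N, R, Y, ...) are excluded from every numerator and
denominator; percentages are taken on the unambiguous total.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CompositionStats", "WindowProfile", "composition_stats", "windowed_profile"]


@dataclass(frozen=True)
class CompositionStats:
    length: int
    count_a: int
    count_c: int
    count_g: int
    count_t: int
    pct_a: float
    pct_c: float
    pct_g: float
    pct_t: float
    at_content: float
    gc_content: float
    at_skew: float | None
    gc_skew: float | None


@dataclass(frozen=True)
class WindowProfile:
    window_size: int
    step: int
    circular: bool
    #: ordered (start_position 0-based, gc_content, gc_skew) triples
    values: tuple[tuple[int, float, float | None], ...]


def composition_stats(seq: str) -> CompositionStats:
    """Base counts, percentages, AT/GC content and skews of a sequence."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper().replace("U", "T")
    a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
    n = a + c + g + t
    if n == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return CompositionStats(
        length=len(seq),
        count_a=a, count_c=c, count_g=g, count_t=t,
        pct_a=100.0 * a / n,
        pct_c=100.0 * c / n,
        pct_g=100.0 * g / n,
        pct_t=100.0 * t / n,
        at_content=100.0 * (a + t) / n,
        gc_content=100.0 * (g + c) / n,
        at_skew=(a - t) / (a + t) if a + t else None,
        gc_skew=(g - c) / (g + c) if g + c else None,
    )


def windowed_profile(
    seq: str, window: int, step: int = 1, circular: bool = True
) -> WindowProfile:
    """GC content and GC skew in sliding windows.

    Circular mode (the default, matching a circular mitogenome) wraps
    windows past the end and yields one window per start position under
    step 1; linear mode requires ``window <= len(seq)``.
    """
    length = len(seq)
    if step < 1:
        raise ValueError("step must be >= 1")
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > length:
        if not circular:
            raise ValueError(
                f"window {window} exceeds sequence length {length} in linear mode"
            )
        raise ValueError("window must not exceed sequence length")

    s = seq.upper().replace("U", "T")
    doubled = s + s if circular else s
    starts = range(0, length if circular else length - window + 1, step)
    values = []
    for start in starts:
        win = doubled[start : start + window]
        stats = composition_stats(win)
        values.append((start, stats.gc_content, stats.gc_skew))
    return WindowProfile(
        window_size=window, step=step, circular=circular, values=tuple(values)
    )
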