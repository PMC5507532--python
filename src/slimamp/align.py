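"""Banded affine-gap Smith-Waterman local alignment.

Row-vectorised Gotoh dynamic programming over numpy, with an optional
diagonal band.  The horizontal (deletion) state is computed with a
prefix-max scan — opening a gap out of an existing horizontal gap is never
better than extending it, so the scan loses no optimal path — which keeps
every row a handful of vector operations.  The banded score equals the
unbanded one whenever the optimal path drifts less than the band
half-width off the centre diagonal (true indel size up to half the band).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NEG = np.int32(-(10 ** 8))

_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[b + 32] = i  # lower case


def encode(seq: str) -> np.ndarray:
    """ACGT string -> int8 codes 0..3."""
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValueError("sequence contains non-ACGT characters")
    return codes


@dataclass(frozen=True)
class AlignScores:
    """Affine-gap scoring: a gap of length L costs gap_open + L*gap_extend."""

    match: int = 2
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1


@dataclass
class Alignment:
    """A local alignment of *read* against *ref*.

    ``cigar`` covers only the aligned core (ends outside it are soft
    clipped); ops are "M" (match/mismatch, consumes both), "I" (insertion,
    consumes read) and "D" (deletion, consumes ref).
    """

    score: int
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    cigar: list[tuple[str, int]] = field(default_factory=list)


def smith_waterman(
    read: str | np.ndarray,
    ref: str | np.ndarray,
    scores: AlignScores | None = None,
    band_center: int | None = None,
    band_halfwidth: int | None = None,
) -> Alignment:
    """Optimal local alignment; optionally banded around a diagonal.

    ``band_center`` is the expected ref-minus-read offset of the read
    start (0 for a read anchored at the reference start); cells with
    |j - i - band_center| > band_halfwidth are unreachable.
    """
    sc = scores or AlignScores()
    x = encode(read) if isinstance(read, str) else read
    y = encode(ref) if isinstance(ref, str) else ref
    m, n = len(x), len(y)
    if m == 0:
        raise ValueError("cannot align an empty read")
    go, ge = np.int32(sc.gap_open), np.int32(sc.gap_extend)

    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)   # horizontal (D ops)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)   # vertical (I ops)
    js = np.arange(n + 1, dtype=np.int64)
    banded = band_center is not None and band_halfwidth is not None

    for i in range(1, m + 1):
        sub = np.where(y == x[i - 1], sc.match, sc.mismatch).astype(np.int32)
        diag = H[i - 1, :-1] + sub
        F[i, 1:] = np.maximum(H[i - 1, 1:] + go + ge, F[i - 1, 1:] + ge)
        d = np.maximum(diag, F[i, 1:])
        d = np.maximum(d, 0)
        # horizontal state by prefix-max scan over gap-opening cells
        a = np.full(n + 1, NEG, dtype=np.int64)
        a[1:] = d.astype(np.int64) - ge * js[1:]
        a[0] = -ge * 0  # opening from column 0 (H=0)
        run = np.maximum.accumulate(a)
        E[i, 1:] = (run[:-1] + go + ge * js[1:]).clip(NEG).astype(np.int32)
        H[i, 1:] = np.maximum(d, E[i, 1:])
        if banded:
            off = js - i - band_center
            out = np.abs(off) > band_halfwidth
            H[i, out] = 0
            E[i, out] = NEG
            F[i, out] = NEG

    flat = int(np.argmax(H))
    i, j = divmod(flat, n + 1)
    best = int(H[i, j])
    read_end, ref_end = i, j

    ops: list[str] = []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            sub = sc.match if x[i - 1] == y[j - 1] else sc.mismatch
            if H[i, j] == H[i - 1, j - 1] + sub:
                ops.append("M")
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = "F"
            elif H[i, j] == E[i, j]:
                state = "E"
            else:  # pragma: no cover - matrices are self-consistent
                raise AssertionError("traceback failure")
        elif state == "F":
            ops.append("I")
            if F[i, j] == F[i - 1, j] + ge:
                i -= 1
            else:
                i -= 1
                state = "H"
        else:  # E: deletion, consume ref
            ops.append("D")
            if E[i, j] == E[i, j - 1] + ge:
                j -= 1
            else:
                j -= 1
                state = "H"
    read_start, ref_start = i, j

    cigar: list[tuple[str, int]] = []
    for op in reversed(ops):
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return Alignment(score=best, read_start=read_start, read_end=read_end,
                     ref_start=ref_start, ref_end=ref_end, cigar=cigar)
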