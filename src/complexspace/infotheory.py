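"""Shannon entropy and minimal run-length description length.

The information-theoretic grounding for the complexity indices: a
system configuration can be written as a 'message', and configurations
that compress to fewer characters are less complex.  The encoder here
is a deliberately simple run-length scheme — a repeated block B written
k times may be encoded ``(B)k`` — with minimality found by dynamic
programming, so that e.g.::

    A B A B A B A B C D   ->   (AB)4CD     (10 characters -> 7)
    A B D C B D A A B D   ->   ABDCBDAABD  (no reduction possible)

Cost model: every symbol, parenthesis and count digit costs one
character; ties between a compressed and a literal form resolve to the
literal.  Nested runs (runs of runs) are not considered.  Description
length under any such scheme depends on the scheme itself; this module
is illustrative and is not one of the complexity-profile indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter
from collections.abc import Iterable

import numpy as np
from scipy.stats import entropy as _scipy_entropy

__all__ = [
    "SymbolSequence",
    "CompressionResult",
    "shannon_entropy",
    "compress_min_rle",
    "decompress_rle",
    "description_length",
]

_FORBIDDEN = set("()0123456789")


@dataclass(frozen=True)
class SymbolSequence:
    """Ordered sequence over a finite alphabet of single characters."""

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("sequence must be non-empty")
        for s in self.symbols:
            if not isinstance(s, str) or len(s) != 1:
                raise ValueError(f"symbols must be single characters, got {s!r}")
            if s in _FORBIDDEN:
                raise ValueError(
                    f"symbol {s!r} collides with the encoding syntax"
                )
        object.__setattr__(self, "symbols", tuple(self.symbols))

    @classmethod
    def from_string(cls, text: str) -> "SymbolSequence":
        """Build from a plain string or comma-separated symbols."""
        if "," in text:
            parts = [p.strip() for p in text.split(",") if p.strip()]
        else:
            parts = list(text.strip())
        return cls(tuple(parts))

    @property
    def alphabet(self) -> frozenset[str]:
        return frozenset(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return "".join(self.symbols)


@dataclass(frozen=True)
class CompressionResult:
    """A minimal lossless run-length description of a sequence."""

    encoded: str
    length: int
    scheme: str = "min-rle-dp"

    def __post_init__(self) -> None:
        if self.length != len(self.encoded):
            raise ValueError("length must equal the character count of encoded")


def shannon_entropy(
    p: Iterable[float] | SymbolSequence | str,
) -> float:
    """Shannon entropy in bits.

    Accepts a probability vector (non-negative, summing to 1) or a
    symbol sequence, which is converted to empirical frequencies.
    ``0 * log(0)`` is taken as 0.
    """
    if isinstance(p, (SymbolSequence, str)):
        seq = p if isinstance(p, SymbolSequence) else SymbolSequence.from_string(p)
        counts = np.array(list(Counter(seq.symbols).values()), dtype=float)
        probs = counts / counts.sum()
    else:
        probs = np.asarray(list(p), dtype=float)
        if probs.size == 0 or np.any(probs < 0):
            raise ValueError("probabilities must be non-negative and non-empty")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {probs.sum()}, not 1")
    return float(_scipy_entropy(probs, base=2))


def _digits(k: int) -> int:
    return len(str(k))


def _run_cost(block_len: int, k: int) -> int:
    # "(B)k": block symbols + two parentheses + decimal digits of k
    return block_len + 2 + _digits(k)


def compress_min_rle(s: SymbolSequence | str) -> CompressionResult:
    """Minimal run-length description by dynamic programming.

    ``best[i]`` is the cheapest encoding of the first ``i`` symbols.
    Each position extends either by one literal symbol (cost 1) or by a
    run ``(B)k`` where block B of length b repeats k >= 2 times ending
    at ``i``.  Literal extensions are applied first and runs replace
    them only when strictly cheaper, so ties resolve to the literal
    form.  Decoding is exact (see :func:`decompress_rle`).
    """
    if isinstance(s, str):
        s = SymbolSequence.from_string(s)
    sym = s.symbols
    n = len(sym)
    INF = float("inf")
    best = [0] + [INF] * n
    best_enc: list[str] = [""] + [None] * n  # type: ignore[list-item]
    for i in range(1, n + 1):
        # literal extension first: ties resolve to literal
        best[i] = best[i - 1] + 1
        best_enc[i] = best_enc[i - 1] + sym[i - 1]
        # run extensions: block length b repeated k times, segment length b*k
        for b in range(1, i // 2 + 1):
            block = sym[i - b : i]
            k = 1
            while i - (k + 1) * b >= 0 and sym[i - (k + 1) * b : i - k * b] == block:
                k += 1
            if k < 2:
                continue
            # any repeat count 2..k of this block is a candidate run
            for reps in range(2, k + 1):
                j = i - reps * b
                cost = best[j] + _run_cost(b, reps)
                if cost < best[i]:
                    best[i] = cost
                    best_enc[i] = (
                        best_enc[j] + "(" + "".join(block) + ")" + str(reps)
                    )
    encoded = best_enc[n]
    result = CompressionResult(encoded=encoded, length=int(best[n]))
    assert decompress_rle(result) == s, "internal error: lossy encoding"
    return result


def decompress_rle(r: CompressionResult | str) -> SymbolSequence:
    """Exact inverse of :func:`compress_min_rle`'s encoding."""
    text = r.encoded if isinstance(r, CompressionResult) else r
    out: list[str] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "(":
            close = text.index(")", i)
            block = text[i + 1 : close]
            i = close + 1
            j = i
            while j < len(text) and text[j].isdigit():
                j += 1
            if j == i:
                raise ValueError(f"run at position {i} lacks a count")
            out.extend(block * int(text[i:j]))
            i = j
        elif ch.isdigit() or ch == ")":
            raise ValueError(f"unexpected character {ch!r} at position {i}")
        else:
            out.append(ch)
            i += 1
    return SymbolSequence(tuple(out))


def description_length(s: SymbolSequence | str) -> int:
    """Character count of the minimal run-length description."""
    return compress_min_rle(s).length
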