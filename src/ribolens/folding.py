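"""Local RNA secondary-structure annotation with a span cap.

The default engine is a deterministic base-pair maximization folder
(Nussinov-style dynamic programme) restricted so that every pair (i, j)
satisfies j - i <= max_bp_span, with a minimum hairpin loop of 3 unpaired
bases and Watson-Crick plus G.U pairing. Because every pair is local, the
optimal structure decomposes into a chain of local blocks, which the
implementation exploits: a banded interval DP over widths up to the span cap
followed by a linear chain DP over the whole sequence. Complexity is
O(L * span^2) and the inner loops are vectorized.

A thermodynamic engine (ViennaRNA's RNAfold with maxBPspan) can be plugged
in behind the same interface when the bindings are installed.
"""

from __future__ import annotations

from typing import Optional, Protocol

import numpy as np

from .corpus import CANONICAL_PAIRS

MIN_LOOP = 3  # unpaired bases enclosed by the innermost pair


class FoldingEngine(Protocol):
    """sequence -> dot-bracket, honouring a maximum base-pair span."""

    def fold(self, sequence: str, max_bp_span: int) -> str: ...


def _canpair_arrays(seq: str, max_span: int) -> dict[int, np.ndarray]:
    """canpair[d][i] == True iff (seq[i], seq[i+d]) can pair."""
    s = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    L = len(s)
    pairs = {(ord(a), ord(b)) for a, b in CANONICAL_PAIRS}
    out = {}
    for d in range(MIN_LOOP + 1, max_span + 1):
        if d >= L:
            break
        a, b = s[: L - d], s[d:]
        ok = np.zeros(L - d, dtype=bool)
        for x, y in pairs:
            ok |= (a == x) & (b == y)
        out[d] = ok
    return out


class MaxPairSpanFolder:
    """Built-in span-constrained base-pair maximization engine."""

    def fold(self, sequence: str, max_bp_span: int) -> str:
        L = len(sequence)
        if L < MIN_LOOP + 2:
            return "." * L
        S = min(max_bp_span, L - 1)
        can = _canpair_arrays(sequence, S)

        # N[w, i]: max pairs on the interval [i, i+w-1]; zero-padded so that
        # out-of-range reads contribute nothing.
        N = np.zeros((S + 2, L + 2), dtype=np.int32)
        for w in range(MIN_LOOP + 2, S + 2):
            n = L - w + 1  # number of intervals of width w
            if n <= 0:
                break
            best = N[w - 1, 1 : n + 1].copy()  # leave position i unpaired
            for d in range(MIN_LOOP + 1, w):
                if d not in can:
                    continue
                ok = can[d][:n]
                val = 1 + N[d - 1, 1 : n + 1] + N[w - 1 - d, d + 1 : n + d + 1]
                best = np.where(ok, np.maximum(best, val), best)
            N[w, :n] = best

        # chain DP over prefixes: last block is a local fold of width <= S+1
        G = np.zeros(L + 1, dtype=np.int32)
        widths = np.arange(MIN_LOOP + 2, S + 2)
        for j in range(1, L + 1):
            g = G[j - 1]
            ws = widths[widths <= j]
            if len(ws):
                cand = G[j - ws] + N[ws, j - ws]
                g = max(g, int(cand.max()))
            G[j] = g

        pairs = self._traceback(G, N, can, L, S)
        db = ["."] * L
        for i, j in pairs:
            db[i], db[j] = "(", ")"
        return "".join(db)

    @staticmethod
    def _traceback(G, N, can, L, S) -> list[tuple[int, int]]:
        pairs: list[tuple[int, int]] = []

        def nval(i: int, j: int) -> int:
            return int(N[j - i + 1, i]) if j >= i else 0

        def trace_interval(i0: int, j0: int) -> None:
            stack = [(i0, j0)]
            while stack:
                i, j = stack.pop()
                while i < j:
                    target = nval(i, j)
                    if target == 0:
                        break
                    if nval(i + 1, j) == target:
                        i += 1
                        continue
                    for d in range(MIN_LOOP + 1, j - i + 1):
                        if d in can and i < len(can[d]) and can[d][i]:
                            if 1 + nval(i + 1, i + d - 1) + nval(i + d + 1, j) == target:
                                pairs.append((i, i + d))
                                stack.append((i + d + 1, j))
                                i, j = i + 1, i + d - 1
                                break
                    else:
                        break

        j = L
        while j > 0:
            if G[j] == G[j - 1]:
                j -= 1
                continue
            for w in range(MIN_LOOP + 2, min(S + 1, j) + 1):
                if G[j - w] + nval(j - w, j - 1) == G[j]:
                    trace_interval(j - w, j - 1)
                    j -= w
                    break
            else:  # pragma: no cover - defensive
                j -= 1
        return pairs


class ViennaRNAEngine:
    """Thermodynamic folding through the ViennaRNA bindings (optional)."""

    def fold(self, sequence: str, max_bp_span: int) -> str:
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover
            raise ImportError(
                "ViennaRNA python bindings are required for ViennaRNAEngine"
            ) from exc
        md = RNA.md()
        md.max_bp_span = max_bp_span
        fc = RNA.fold_compound(sequence, md)
        db, _ = fc.mfe()
        return db


_DEFAULT_ENGINE = MaxPairSpanFolder()


def annotate_local_structure(
    sequence: str,
    max_bp_span: int = 30,
    engine: Optional[FoldingEngine] = None,
) -> str:
    """Dot-bracket annotation of local structure for one sequence.

    Sequences shorter than 5 nt cannot hold a pair and return all dots.
    """
    engine = engine or _DEFAULT_ENGINE
    db = engine.fold(sequence, max_bp_span)
    if len(db) != len(sequence):
        raise ValueError("engine returned structure of wrong length")
    return db


def parse_pairs(dotbracket: str) -> list[tuple[int, int]]:
    """Pair list from a dot-bracket string; raises on unbalanced brackets."""
    stack: list[int] = []
    pairs = []
    for idx, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket: unmatched ')'")
            pairs.append((stack.pop(), idx))
        elif ch != ".":
            raise ValueError(f"foreign character {ch!r} in dot-bracket")
    if stack:
        raise ValueError("unbalanced dot-bracket: unmatched '('")
    return sorted(pairs)
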