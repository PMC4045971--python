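"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (quadratic scans, exhaustive
enumeration) and shares no code with the package internals it checks.
"""

from __future__ import annotations


def brute_force_maximal_matches(
    probe: str, transcript: str, min_len: int
) -> set[tuple[int, int, int]]:
    """All maximal exact shared substrings as (probe_start, t_start, length).

    Quadratic dynamic program: match[i][j] = length of the common substring
    ending at probe[i-1]/transcript[j-1]; a match is maximal when the next
    characters differ or a sequence ends.
    """
    n, m = len(probe), len(transcript)
    prev = [0] * (m + 1)
    out: set[tuple[int, int, int]] = set()
    dna = set("ACGT")
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            if probe[i - 1] == transcript[j - 1] and probe[i - 1] in dna:
                cur[j] = prev[j - 1] + 1
                length = cur[j]
                right_end = (
                    i == n
                    or j == m
                    or probe[i] != transcript[j]
                    or probe[i] not in dna
                )
                if right_end and length >= min_len:
                    out.add((i - length, j - length, length))
        prev = cur
    return out


def brute_force_survival(
    target_len: int,
    footprints: list[tuple[int, int]],
    min_len: int,
    max_len: int,
    min_duplex: int,
    p_cut: float,
) -> list[float]:
    """Exhaustive per-position expected surviving fraction of 5' ends."""
    out = []
    for s in range(target_len):
        total = 0
        surv = 0.0
        for L in range(min_len, max_len + 1):
            if s + L > target_len:
                continue
            total += 1
            cleavable = any(
                min(s + L, e) - max(s, b) >= min_duplex for b, e in footprints
            )
            surv += (1.0 - p_cut) if cleavable else 1.0
        out.append(surv / total if total else 1.0)
    return out


def enumerate_escaping_inserts(
    target_len: int,
    footprints: list[tuple[int, int]],
    min_insert: int,
    max_insert: int,
    min_duplex: int,
) -> list[tuple[int, int]]:
    """All (start, length) inserts of length >= min_insert escaping every
    footprint (overlap < min_duplex with each)."""
    escapes = []
    for s in range(target_len):
        for L in range(min_insert, max_insert + 1):
            if s + L > target_len:
                break
            if all(min(s + L, e) - max(s, b) < min_duplex for b, e in footprints):
                escapes.append((s, L))
    return escapes


def birthday_expected_duplicates(n: int, positions: int) -> float:
    """E[duplicates] when n reads land uniformly on P positions."""
    return n - positions * (1.0 - (1.0 - 1.0 / positions) ** n)
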