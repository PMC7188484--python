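"""Independent brute-force oracles, kept deliberately naive.

These re-derive the definitions directly — every-window scanning with
explicit IUPAC set membership, and full substring enumeration for shared
blocks — without touching the package's scanning or block-finding code
paths (only ``revcomp`` is shared, itself covered by its own tests).
"""

from __future__ import annotations

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def naive_mismatches(pattern: str, word: str) -> int:
    return sum(1 for p, b in zip(pattern, word) if b not in IUPAC[p])


def naive_scan(residues: str, pattern: str, max_mm: int,
               strands=("+", "-")) -> set[tuple[int, str, int]]:
    """Every-window both-strand scan: {(start, strand, n_mismatch)}."""
    k = len(pattern)
    out: set[tuple[int, str, int]] = set()
    for i in range(len(residues) - k + 1):
        window = residues[i:i + k]
        if "+" in strands:
            mm = naive_mismatches(pattern, window)
            if mm <= max_mm:
                out.add((i, "+", mm))
        if "-" in strands:
            mm = naive_mismatches(pattern, naive_revcomp(window))
            if mm <= max_mm:
                out.add((i, "-", mm))
    return out


def _naive_find_all(text: str, sub: str) -> list[int]:
    return [i for i in range(len(text) - len(sub) + 1) if text[i:i + len(sub)] == sub]


def naive_shared_blocks(texts: dict[str, str], min_len: int,
                        allow_inversion: bool) -> dict[str, dict[str, list[tuple[int, str]]]]:
    """All maximal shared blocks by full substring enumeration.

    Candidates are every N-free substring of the first sequence (length >=
    min_len) present in all sequences (reverse complement allowed when
    inversions are on).  A candidate is pruned iff a single longer candidate
    covers all of its occurrence intervals.  Returns
    {canonical_seq: {seq_id: [(start, orientation), ...]}} where the
    canonical form is min(word, revcomp(word)) under inversion, else the
    word itself.
    """
    ids = list(texts)
    ref = texts[ids[0]]

    def present_everywhere(w: str) -> bool:
        for t in texts.values():
            if w in t or (allow_inversion and naive_revcomp(w) in t):
                continue
            return False
        return True

    def occurrences(w: str) -> dict[str, list[tuple[int, str]]]:
        rc = naive_revcomp(w)
        occ = {}
        for sid, t in texts.items():
            places = [(i, "forward") for i in _naive_find_all(t, w)]
            if allow_inversion and rc != w:
                places += [(i, "inverted") for i in _naive_find_all(t, rc)]
            occ[sid] = sorted(places)
        return occ

    candidates: dict[str, dict[str, list[tuple[int, str]]]] = {}
    for i in range(len(ref)):
        for j in range(i + min_len, len(ref) + 1):
            w = ref[i:j]
            if "N" in w:
                break
            if not present_everywhere(w):
                break  # longer extensions cannot be present either
            key = min(w, naive_revcomp(w)) if allow_inversion else w
            if key not in candidates:
                candidates[key] = occurrences(key)

    def covered(inner: str, outer: str) -> bool:
        occ_in, occ_out = candidates[inner], candidates[outer]
        li, lo = len(inner), len(outer)
        for sid, places in occ_in.items():
            for (s, _ori) in places:
                if not any(os <= s and s + li <= os + lo for (os, _o) in occ_out[sid]):
                    return False
        return True

    kept = {}
    for w in sorted(candidates, key=len, reverse=True):
        if not any(len(o) > len(w) and covered(w, o) for o in kept):
            kept[w] = candidates[w]
    return kept
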