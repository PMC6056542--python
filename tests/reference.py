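"""Independent reference implementations used as oracles in tests.

Deliberately written as naive position-by-position enumeration, sharing no
code with the package's scanner: every -35 core occurrence is paired with
every allowed spacer, mapped onto its maximal A-run, re-checked against the
spacer bounds measured from the run's 3' end, and deduplicated.
"""

from __future__ import annotations

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def brute_force_scan(
    seq: str,
    spacer_min: int = 12,
    spacer_max: int = 15,
    minus10: str = "CGHH",
    core35: str = "AAA",
) -> set[tuple[int, int, int, int]]:
    """All (atract_start, atract_end, minus10_start, spacer_len) promoter
    sites, by exhaustive triple enumeration with maximal-A-run dedup."""
    n = len(seq)
    k35, k10 = len(core35), len(minus10)
    hits: set[tuple[int, int, int, int]] = set()
    for i in range(n - k35 + 1):
        if seq[i: i + k35] != "A" * k35:
            continue
        for sp in range(spacer_min, spacer_max + 1):
            j = i + k35 + sp
            if j + k10 > n:
                continue
            if not all(seq[j + k] in _IUPAC[minus10[k]] for k in range(k10)):
                continue
            a = i
            while a > 0 and seq[a - 1] == "A":
                a -= 1
            b = i + k35
            while b < n and seq[b] == "A":
                b += 1
            spacer = j - b
            if spacer_min <= spacer <= spacer_max:
                hits.add((a, b, j, spacer))
    return hits


def match_keys(matches) -> set[tuple[int, int, int, int]]:
    """Project scanner output onto the oracle's tuple space."""
    return {
        (m.atract_start, m.atract_end, m.minus10_start, m.spacer_len) for m in matches
    }
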