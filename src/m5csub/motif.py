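"""IUPAC motif occurrence counting over RNA windows.

Used to tally the regulator-associated motifs CAYC (i.e. CA(U/C)C, YBX1)
and NGGG (NSUN2) in labeled window sets.  Matching is on the sense strand
only — windows are already transcript-oriented — and an 'N' in the
*sequence* (a padded position) matches nothing.
"""

from __future__ import annotations

from typing import Iterable, Sequence

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "W": frozenset("AU"),
    "S": frozenset("CG"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}


def _pattern_sets(pattern: str) -> list[frozenset]:
    pattern = pattern.upper().replace("T", "U")
    if not pattern:
        raise ValueError("empty motif pattern")
    sets = []
    for ch in pattern:
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code {ch!r} in pattern {pattern!r}")
        sets.append(IUPAC[ch])
    return sets


def contains_motif(window: str, pattern: str) -> bool:
    """True iff the IUPAC pattern matches at >= 1 position of the window."""
    sets = _pattern_sets(pattern)
    seq = window.upper().replace("T", "U")
    m = len(sets)
    for start in range(len(seq) - m + 1):
        if all(seq[start + k] in sets[k] for k in range(m)):
            return True
    return False


def count_motif_sequences(
    windows: Sequence[str], pattern: str
) -> tuple[int, float]:
    """Number and fraction of windows containing >= 1 motif match."""
    if not windows:
        raise ValueError("empty window list")
    hits = sum(contains_motif(w, pattern) for w in windows)
    return hits, hits / len(windows)


def motif_hit_table(windows: Iterable[str], pattern: str) -> list[tuple[int, bool]]:
    """Per-window hit flags (index, contains) for TSV export."""
    return [(i, contains_motif(w, pattern)) for i, w in enumerate(windows)]
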