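"""Independent brute-force oracles shared across the test suite.

These deliberately avoid the package's interval and counting code paths:
segmentation is checked against per-position labeling, composition against
character-level counting on concatenated strings.
"""

from __future__ import annotations

from domlink.seq_io import STANDARD_AMINO_ACIDS


def label_positions(length: int, intervals: list[tuple[int, int]]) -> dict[int, str]:
    """Label every position of a protein as domain, linker or tail.

    A position is a domain position if it falls inside any annotated interval;
    a linker position if it lies between the leftmost and rightmost domain
    positions without being one; a tail position otherwise.
    """
    in_domain = set()
    for start, end in intervals:
        in_domain.update(range(start, end + 1))
    labels = {}
    lo = min(in_domain) if in_domain else None
    hi = max(in_domain) if in_domain else None
    for pos in range(1, length + 1):
        if pos in in_domain:
            labels[pos] = "domain"
        elif lo is not None and lo < pos < hi:
            labels[pos] = "linker"
        else:
            labels[pos] = "tail"
    return labels


def char_counts(fragments: list[str]) -> dict[str, int]:
    """Character-level counting on the concatenated string, via str.count."""
    pooled = "".join(fragments)
    return {aa: pooled.count(aa) for aa in STANDARD_AMINO_ACIDS}


def char_percentages(fragments: list[str]) -> dict[str, float] | None:
    counts = char_counts(fragments)
    total = sum(counts.values())
    if total == 0:
        return None
    return {aa: 100.0 * c / total for aa, c in counts.items()}
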