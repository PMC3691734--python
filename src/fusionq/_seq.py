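"""Small nucleotide-string helpers shared across modules."""

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMP)[::-1]


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length strings.

    `N` never counts as equal to any base, including another `N`.
    """
    if len(a) != len(b):
        raise ValueError("hamming() requires equal-length strings")
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mm += 1
    return mm
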