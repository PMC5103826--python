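"""DNA sequence helpers: reverse complement and canonical k-mers."""

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

DNA_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc
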