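"""Reference sequence access.

Two genome backends share one small interface: ``lengths`` (chrom -> length)
and ``fetch(chrom, start, end)`` returning an upper-case string, clamped to
chromosome bounds (a fetch beyond either edge is silently truncated; callers
that care about truncation compare the returned length).
"""

from __future__ import annotations

from typing import Mapping

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_COMP)[::-1]


class DictGenome:
    """In-memory genome backed by per-chromosome byte arrays.

    Mutable: the synthetic-data generator writes motif and cleavage-context
    bases in place before reads are drawn, so emitted reads are always
    consistent with the final sequence.
    """

    def __init__(self, seqs: Mapping[str, str | bytes | bytearray]):
        self._seqs: dict[str, bytearray] = {}
        for chrom, seq in seqs.items():
            if isinstance(seq, str):
                seq = seq.encode("ascii")
            self._seqs[chrom] = bytearray(seq.upper())

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def chroms(self) -> list[str]:
        return list(self._seqs)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self._seqs[chrom]
        start = max(0, start)
        end = min(len(seq), end)
        if start >= end:
            return ""
        return self._seqs[chrom][start:end].decode("ascii")

    def write_base(self, chrom: str, pos: int, base: str) -> None:
        """Overwrite a single base (forward-strand letter)."""
        self._seqs[chrom][pos] = ord(base)

    def write_fasta(self, path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self._seqs.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width].decode("ascii") + "\n")


class FastaGenome:
    """Genome read from an indexed FASTA file (pyfaidx)."""

    def __init__(self, path):
        import pyfaidx

        self._fa = pyfaidx.Fasta(str(path))
        self._lengths = {name: len(rec) for name, rec in self._fa.items()}

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self._lengths)

    def chroms(self) -> list[str]:
        return list(self._lengths)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        start = max(0, start)
        end = min(self._lengths[chrom], end)
        if start >= end:
            return ""
        return str(self._fa[chrom][start:end]).upper()
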