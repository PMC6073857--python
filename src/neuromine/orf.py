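"""Six-frame translation and longest-ORF extraction from transcripts.

Assembled transcripts carry no curated CDS annotation, so candidate
proteins are recovered by translating all six reading frames and keeping
maximal open reading frames. 5'-truncated fragments can be retained
(flagged incomplete) because fragmented receptors are biologically
informative even when no start codon was assembled.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    _CODON[_stop] = "*"

_VALID_NT = set("ACGTN")

#: frame labels in reporting order
FRAMES = (1, 2, 3, -1, -2, -3)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class OrfRecord:
    """One open reading frame located on a transcript.

    Coordinates are 0-based half-open on the *forward* transcript strand;
    the spanned codons translate exactly to ``aa_sequence`` (stop codon
    excluded from the span).
    """

    transcript_id: str
    frame: int
    nt_start: int
    nt_end: int
    aa_sequence: str
    is_complete: bool

    def header(self) -> str:
        comp = "complete" if self.is_complete else "partial"
        return f"{self.transcript_id}|{self.frame:+d}|{self.nt_start}-{self.nt_end}|{comp}"


def reverse_complement(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


def _translate_frame(nt: str) -> str:
    aa = []
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if "N" in codon:
            aa.append("X")
        else:
            aa.append(_CODON[codon])
    return "".join(aa)


def _validate(nt: str) -> None:
    bad = set(nt) - _VALID_NT
    if bad:
        raise ValueError(f"non-IUPAC (A/C/G/T/N) characters in sequence: {sorted(bad)}")


def six_frame_translate(nt: str) -> list[str]:
    """Translate all six frames; order +1, +2, +3, -1, -2, -3.

    Codons containing N translate to X; reverse frames read the reverse
    complement. Stops appear as ``*``.
    """
    nt = nt.upper()
    _validate(nt)
    rc = reverse_complement(nt)
    return [_translate_frame(nt[off:]) for off in range(3)] + [
        _translate_frame(rc[off:]) for off in range(3)
    ]


def _frame_coords(frame: int, aa_start: int, aa_end: int, n: int) -> tuple[int, int]:
    """Map an aa interval [aa_start, aa_end) in a frame translation to
    forward-strand nucleotide coordinates (0-based half-open)."""
    off = abs(frame) - 1
    if frame > 0:
        return off + 3 * aa_start, off + 3 * aa_end
    return n - off - 3 * aa_end, n - off - 3 * aa_start


def find_orfs(
    nt: str,
    min_aa: int = 50,
    transcript_id: str = "seq",
    include_partial: bool = True,
) -> list[OrfRecord]:
    """All maximal ORFs of at least ``min_aa`` residues across six frames.

    Per inter-stop chunk one ORF is reported: Met-to-stop when a start
    codon exists, or (``include_partial``) the open-to-stop run when the
    frame's first chunk carries no Met at all (a 5'-truncated CDS). ORFs
    never overlap within a frame. Sorted by descending length, then frame
    order (+1,+2,+3,-1,-2,-3), then start coordinate.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    nt = nt.upper()
    _validate(nt)
    n = len(nt)
    records: list[OrfRecord] = []
    translations = six_frame_translate(nt)
    for frame, aa in zip(FRAMES, translations):
        pos = 0
        first_chunk = True
        while pos <= len(aa):
            stop = aa.find("*", pos)
            chunk_end = stop if stop != -1 else len(aa)
            chunk = aa[pos:chunk_end]
            has_stop = stop != -1
            m = chunk.find("M")
            orf_span = None
            if m >= 0:
                orf_span = (pos + m, chunk_end, True)
            elif first_chunk and include_partial and chunk:
                orf_span = (pos, chunk_end, False)
            if orf_span is not None:
                a0, a1, has_start = orf_span
                seq = aa[a0:a1]
                if len(seq) >= min_aa:
                    s, e = _frame_coords(frame, a0, a1, n)
                    records.append(
                        OrfRecord(
                            transcript_id=transcript_id,
                            frame=frame,
                            nt_start=s,
                            nt_end=e,
                            aa_sequence=seq,
                            is_complete=has_start and has_stop,
                        )
                    )
            if stop == -1:
                break
            pos = stop + 1
            first_chunk = False
    frame_rank = {f: i for i, f in enumerate(FRAMES)}
    records.sort(key=lambda r: (-len(r.aa_sequence), frame_rank[r.frame], r.nt_start))
    return records


def longest_orf(
    nt: str, min_aa: int = 50, transcript_id: str = "seq"
) -> OrfRecord | None:
    """Longest ORF, preferring complete (Met-to-stop) ORFs over partial
    ones of any length; None when nothing reaches ``min_aa``."""
    orfs = find_orfs(nt, min_aa=min_aa, transcript_id=transcript_id)
    complete = [r for r in orfs if r.is_complete]
    if complete:
        return complete[0]
    return orfs[0] if orfs else None
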