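"""Neuropeptide precursor annotation.

A neuropeptide precursor (preprohormone) is processed in three steps that
this module models explicitly:

1. an N-terminal signal peptide (10-40 aa) is removed by signal peptidase,
   which favours small residues (Ala/Gly/Ser/Cys) at the -3 and -1
   positions and requires a hydrophobic h-region upstream;
2. prohormone convertases cut the proprotein at mono/dibasic motifs
   (KR, RR, KK, optionally furin-style R-X-X-R and spaced monobasic R),
   and carboxypeptidase trims the exposed basic residues;
3. a C-terminal Gly left on a fragment is converted into an amide on the
   preceding residue, and an N-terminal Gln cyclizes to pyroglutamate.

Mature peptides are rendered the way the neuropeptide literature prints
them, e.g. ``pQLNFSPGWamide``. Family assignment matches rendered peptides
against a table of conserved family motifs, and a reference-panel search
(Smith-Waterman local alignment) supports homology mining of peptides such
as phoenixin in new transcriptomes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .hydropathy import KYTE_DOOLITTLE

SMALL_RESIDUES = set("AGSC")
BASIC_RESIDUES = set("KR")

#: dibasic convertase motifs, always reported
DIBASIC_MOTIFS = ("KR", "RR", "KK")


# ---------------------------------------------------------------------------
# signal peptide


@dataclass(frozen=True)
class SignalPrediction:
    present: bool
    cleavage_after: int | None  # 1-based index of the signal's last residue
    score: float
    reason: str = ""


@dataclass(frozen=True)
class SignalParams:
    """Tunable weights of the signal-peptide heuristic."""

    min_pos: int = 10
    max_pos: int = 40
    h_window: int = 8
    small_bonus: float = 1.0  # per small residue at -3 / -1
    basic_bonus: float = 0.5  # >=1 Lys/Arg among the first 5 residues
    gap_free: int = 3  # c-region residues between h-window and cleavage
    gap_penalty: float = 0.25  # per extra residue beyond gap_free
    cutoff: float = 3.5


def predict_signal_peptide(aa: str, params: SignalParams | None = None) -> SignalPrediction:
    """Heuristic signal-peptide call.

    Each candidate cleavage position ``p`` (signal = residues 1..p) is
    scored as the hydropathy mean of the best 8-residue h-window ending at
    least ``gap_free`` residues upstream (penalised when it sits further
    away), plus bonuses for small residues at -3/-1 and a basic residue in
    the n-region. The best-scoring position wins (ties to the smallest
    ``p``); the peptide is called present when that score reaches the
    cutoff. Deterministic.
    """
    params = params or SignalParams()
    if len(aa) < 15:
        return SignalPrediction(False, None, float("-inf"), "sequence shorter than 15 residues")
    kd = np.array([KYTE_DOOLITTLE.get(r, 0.0) for r in aa])
    w = params.h_window
    if len(aa) >= w:
        win_means = np.convolve(kd, np.ones(w) / w, mode="valid")  # index e-w of window ending e
    else:  # pragma: no cover - guarded by length check above
        win_means = np.array([])
    n_bonus = params.basic_bonus if BASIC_RESIDUES & set(aa[:5]) else 0.0
    best_p, best_score = None, float("-inf")
    max_p = min(params.max_pos, len(aa) - 1)
    for p in range(params.min_pos, max_p + 1):
        # h-windows ending at 1-based position e, w <= e <= p - gap_free
        hi_end = p - params.gap_free
        if hi_end < w:
            continue
        ends = np.arange(w, hi_end + 1)
        means = win_means[ends - w]
        gaps = p - ends
        h_scores = means - params.gap_penalty * np.maximum(0, gaps - params.gap_free)
        score = float(h_scores.max()) + n_bonus
        if aa[p - 1] in SMALL_RESIDUES:
            score += params.small_bonus
        if aa[p - 3] in SMALL_RESIDUES:
            score += params.small_bonus
        if score > best_score:
            best_score, best_p = score, p
    if best_p is None or best_score < params.cutoff:
        return SignalPrediction(False, None, best_score, "no candidate reached the cutoff")
    return SignalPrediction(True, best_p, best_score)


# ---------------------------------------------------------------------------
# convertase cleavage


@dataclass(frozen=True)
class CleavageSite:
    position: int  # 1-based index of the motif's last residue
    motif: str  # KR | RR | KK | RXXR | R
    score: float = 1.0

    @property
    def n_removed(self) -> int:
        """Basic residues trimmed by carboxypeptidase (motif suffix)."""
        return 2 if self.motif in DIBASIC_MOTIFS else 1


@dataclass(frozen=True)
class CleavageRules:
    """Configurable convertase motif grammar."""

    dibasic: bool = True
    monobasic: bool = True
    monobasic_offsets: tuple[int, ...] = (2, 4, 6)  # upstream basic spacing
    monobasic_at_terminus: bool = True
    rxxr: bool = False


def predict_cleavage_sites(
    proprotein: str, rules: CleavageRules | None = None
) -> list[CleavageSite]:
    """Scan a signal-less proprotein for convertase sites, left to right.

    Dibasic motifs (KR/RR/KK) are always reported. A monobasic R is
    reported only when a basic residue sits at -2/-4/-6 or the R ends the
    sequence. Motif residues are consumed greedily so reported sites never
    overlap; positions are strictly increasing.
    """
    rules = rules or CleavageRules()
    aa = proprotein
    used: set[int] = set()  # 1-based positions consumed by a motif
    sites: list[CleavageSite] = []
    n = len(aa)
    for i in range(1, n + 1):
        res = aa[i - 1]
        if rules.dibasic and i >= 2:
            pair = aa[i - 2 : i]
            if pair in DIBASIC_MOTIFS and i - 1 not in used and i not in used:
                sites.append(CleavageSite(i, pair))
                used.update({i - 1, i})
                continue
        if rules.rxxr and i >= 4 and res == "R" and aa[i - 4] == "R" and i not in used:
            sites.append(CleavageSite(i, "RXXR"))
            used.add(i)
            continue
        if rules.monobasic and res == "R" and i not in used:
            upstream = any(
                i - off >= 1 and aa[i - off - 1] in BASIC_RESIDUES
                for off in rules.monobasic_offsets
            )
            if upstream or (rules.monobasic_at_terminus and i == n):
                sites.append(CleavageSite(i, "R"))
                used.add(i)
    return sites


# ---------------------------------------------------------------------------
# mature peptides


@dataclass(frozen=True)
class MaturePeptide:
    sequence: str  # residues after processing (amide Gly removed)
    span: tuple[int, int]  # 1-based inclusive, pre-modification fragment
    n_term: str = "none"  # none | pyroGlu
    c_term: str = "none"  # none | amide
    cys_count: int = 0

    @property
    def rendered(self) -> str:
        """Literature-style rendering, e.g. ``pQLNFSPGWamide``."""
        body = "pQ" + self.sequence[1:] if self.n_term == "pyroGlu" else self.sequence
        return body + ("amide" if self.c_term == "amide" else "")


def fragment_partition(
    proprotein: str, sites: list[CleavageSite]
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Partition the proprotein into fragment and removed-motif intervals.

    Returns ``(fragments, removed)`` as lists of 1-based inclusive spans.
    Their union tiles the proprotein exactly, so concatenating the
    corresponding substrings in order reconstructs the input. Overlapping
    sites are rejected.
    """
    spans = []
    for s in sites:
        if not (1 <= s.position <= len(proprotein)):
            raise ValueError(f"site position {s.position} outside proprotein")
        start = s.position - s.n_removed + 1
        motif_region = proprotein[s.position - len(s.motif) : s.position]
        if s.motif != "RXXR" and motif_region != s.motif:
            raise ValueError(
                f"motif {s.motif} does not match proprotein at position {s.position}"
            )
        spans.append((start, s.position))
    spans.sort()
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 <= a1:
            raise ValueError("overlapping cleavage sites")
    fragments = []
    cursor = 1
    for a0, a1 in spans:
        if cursor <= a0 - 1:
            fragments.append((cursor, a0 - 1))
        cursor = a1 + 1
    if cursor <= len(proprotein):
        fragments.append((cursor, len(proprotein)))
    return fragments, spans


def derive_mature_peptides(
    proprotein: str,
    sites: list[CleavageSite],
    min_peptide_len: int = 4,
) -> list[MaturePeptide]:
    """Cut at the given sites and apply terminal modifications.

    Fragments between consecutive sites lose the motif's basic residues; a
    trailing Gly is removed as the amide donor (c_term=amide) and a leading
    Gln marks pyroglutamate. Fragments shorter than ``min_peptide_len``
    after processing are discarded.
    """
    fragments, _ = fragment_partition(proprotein, sites)
    peptides = []
    for a0, a1 in fragments:
        frag = proprotein[a0 - 1 : a1]
        c_term = "none"
        seq = frag
        if seq.endswith("G") and len(seq) > 1:
            seq = seq[:-1]
            c_term = "amide"
        n_term = "pyroGlu" if seq.startswith("Q") else "none"
        if len(seq) < min_peptide_len:
            continue
        peptides.append(
            MaturePeptide(
                sequence=seq,
                span=(a0, a1),
                n_term=n_term,
                c_term=c_term,
                cys_count=seq.count("C"),
            )
        )
    return peptides


# ---------------------------------------------------------------------------
# family assignment


@dataclass(frozen=True)
class FamilyMotif:
    family: str
    pattern: re.Pattern
    min_matches: int = 1


def load_motif_table(path: str | Path | None = None) -> list[FamilyMotif]:
    """Load the family→pattern table (TSV: family, regex, min_matches).

    Row order is priority order. Malformed patterns raise at load time.
    """
    if path is None:
        path = resources.files("neuromine.data") / "motifs.tsv"
    motifs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("family\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed motif row: {line!r}")
            family, pattern = parts[0], parts[1]
            min_matches = int(parts[2]) if len(parts) > 2 and parts[2] else 1
            try:
                compiled = re.compile(pattern)
            except re.error as exc:
                raise ValueError(f"malformed pattern for family {family}: {exc}") from exc
            motifs.append(FamilyMotif(family, compiled, min_matches))
    return motifs


def assign_family(
    peptides: list[MaturePeptide], motif_table: list[FamilyMotif]
) -> tuple[str, str | None, bool]:
    """(family, matched pattern, repetitive) for a peptide set.

    The highest-priority family whose pattern matches at least
    ``min_matches`` rendered peptides wins; ``repetitive`` is set when two
    or more peptides match that family's pattern.
    """
    rendered = [p.rendered for p in peptides]
    for motif in motif_table:
        hits = [r for r in rendered if motif.pattern.search(r)]
        if len(hits) >= motif.min_matches:
            return motif.family, motif.pattern.pattern, len(hits) >= 2
    return "unassigned", None, False


# ---------------------------------------------------------------------------
# precursor annotation


@dataclass
class PrecursorAnnotation:
    protein_id: str
    sequence: str
    signal: SignalPrediction
    sites: list[CleavageSite]
    peptides: list[MaturePeptide]
    family: str = "unassigned"
    family_evidence: str | None = None
    has_signal: bool = False
    repetitive: bool = False
    full_length: bool = False
    amidated: bool = False


def annotate_precursor(
    aa: str,
    protein_id: str = "protein",
    motif_table: list[FamilyMotif] | None = None,
    signal_params: SignalParams | None = None,
    cleavage_rules: CleavageRules | None = None,
    min_peptide_len: int = 4,
    is_complete: bool | None = None,
) -> PrecursorAnnotation:
    """Full precursor call: signal → cleavage → matures → family.

    Cleavage runs on the proprotein (signal removed when present); peptide
    spans are reported on the full precursor. ``full_length`` records
    whether the protein is a complete ORF product (defaults to "starts
    with Met"). Deterministic and idempotent.
    """
    if motif_table is None:
        motif_table = load_motif_table()
    signal = predict_signal_peptide(aa, signal_params)
    offset = signal.cleavage_after if signal.present else 0
    proprotein = aa[offset:]
    sites = predict_cleavage_sites(proprotein, cleavage_rules)
    peptides = derive_mature_peptides(proprotein, sites, min_peptide_len=min_peptide_len)
    if offset:
        sites = [CleavageSite(s.position + offset, s.motif, s.score) for s in sites]
        peptides = [
            MaturePeptide(
                p.sequence,
                (p.span[0] + offset, p.span[1] + offset),
                p.n_term,
                p.c_term,
                p.cys_count,
            )
            for p in peptides
        ]
    family, evidence, repetitive = assign_family(peptides, motif_table)
    return PrecursorAnnotation(
        protein_id=protein_id,
        sequence=aa,
        signal=signal,
        sites=sites,
        peptides=peptides,
        family=family,
        family_evidence=evidence,
        has_signal=signal.present,
        repetitive=repetitive,
        full_length=aa.startswith("M") if is_complete is None else is_complete,
        amidated=any(p.c_term == "amide" for p in peptides),
    )


# ---------------------------------------------------------------------------
# reference-panel homology search


def _local_aligner(gap_open: float = 11.0, gap_extend: float = 1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # a gap of length k costs gap_open + (k - 1) * gap_extend
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def search_reference(
    aa: str,
    panel: list[tuple[str, str]],
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> list[tuple[str, float]]:
    """Smith-Waterman search of a query against a mature-peptide panel.

    BLOSUM62, affine gaps (open 11, extend 1; a length-k gap costs
    ``11 + (k-1)``). Returns (panel id, score) pairs ranked by descending
    score, entries with score <= 0 dropped (no-hit).
    """
    if not aa:
        raise ValueError("empty query")
    if not panel:
        raise ValueError("empty reference panel")
    aligner = _local_aligner(gap_open, gap_extend)
    hits = []
    for pid, pseq in panel:
        score = float(aligner.score(aa, pseq))
        if score > 0:
            hits.append((pid, score))
    hits.sort(key=lambda h: (-h[1], h[0]))
    return hits
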