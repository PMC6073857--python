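"""Hydropathy-based GPCR detection and class assignment.

Candidate receptors are called from ORF proteins by sliding-window
Kyte-Doolittle hydropathy: maximal runs of high window-mean hydropathy are
transmembrane (TM) helix calls. Candidates with fewer than five helices
are discarded (fragmented receptors fail this filter by design), exact
duplicate sequences are collapsed, and the survivors are classified:

* class A (Rhodopsin-like) — D[RK]Y motif just after TM3 or NPxxY in TM7;
* class B (Secretin-like)  — an extracellular cysteine pair (C-x(3,12)-C)
  in the TM1→TM2 loop without any class-A motif;
* other — a seven-TM protein with neither diagnostic.

The cysteine-pair rule is a pragmatic sequence proxy for the Secretin
family's conserved ectodomain disulfides; evidence strings record which
diagnostics fired. Coordinates are 1-based inclusive in all reports.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .hydropathy import hydropathy_profile, residue_hydropathy


@dataclass(frozen=True)
class TmSegment:
    start: int  # 1-based inclusive
    end: int
    mean_hydropathy: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GpcrCandidate:
    protein_id: str
    sequence: str
    tms: list[TmSegment]
    tm_count: int
    class_label: str  # A | B | other | rejected
    evidence: list[str] = field(default_factory=list)
    duplicate_group: str | None = None
    long_n_terminus: bool = False  # ectodomain > 300 aa (glycoprotein-hormone LGR-like)


@dataclass(frozen=True)
class TmParams:
    window: int = 19
    threshold: float = 1.6
    min_len: int = 15
    merge_gap: int = 5


def predict_tm_segments(aa: str, params: TmParams | None = None) -> list[TmSegment]:
    """Maximal runs where the window-mean hydropathy reaches the threshold.

    Runs separated by fewer than ``merge_gap`` residues are merged, then
    runs shorter than ``min_len`` are dropped. Ordered by start.
    """
    params = params or TmParams()
    if len(aa) < params.window:
        return []
    profile = hydropathy_profile(aa, window=params.window)
    mask = profile >= params.threshold
    runs: list[list[int]] = []
    i = 0
    n = len(aa)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < params.merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    kd = residue_hydropathy(aa)
    segments = []
    for a, b in merged:
        if b - a + 1 < params.min_len:
            continue
        segments.append(
            TmSegment(start=a + 1, end=b + 1, mean_hydropathy=float(kd[a : b + 1].mean()))
        )
    return segments


_CLASS_A_DRY = re.compile(r"D[RK]Y")
_CLASS_A_NPXXY = re.compile(r"NP..Y")
_CLASS_B_CYS = re.compile(r"C.{3,12}C")


def classify_gpcr(
    aa: str,
    tms: list[TmSegment],
    protein_id: str = "protein",
    min_tm: int = 5,
    long_n_term: int = 300,
) -> GpcrCandidate:
    """Assign a receptor class from TM topology plus diagnostic motifs."""
    evidence: list[str] = []
    tm_count = len(tms)
    if tm_count < min_tm:
        return GpcrCandidate(
            protein_id, aa, tms, tm_count, "rejected",
            evidence=[f"tm_count {tm_count} < {min_tm}"],
        )
    is_a = False
    if tm_count >= 3:
        after_tm3 = aa[tms[2].end : tms[2].end + 10]
        m = _CLASS_A_DRY.search(after_tm3)
        if m:
            is_a = True
            evidence.append(f"{m.group(0)} after TM3")
    if tm_count >= 7:
        tm7 = aa[tms[6].start - 1 : tms[6].end]
        m = _CLASS_A_NPXXY.search(tm7)
        if m:
            is_a = True
            evidence.append(f"{m.group(0)} in TM7")
    is_b = False
    if not is_a and tm_count >= 2:
        loop12 = aa[tms[0].end : tms[1].start - 1]
        m = _CLASS_B_CYS.search(loop12)
        if m:
            is_b = True
            evidence.append("Cys pair in TM1-TM2 loop (Secretin-family ectodomain proxy)")
    label = "A" if is_a else "B" if is_b else "other"
    if label == "other":
        evidence.append("no class diagnostic matched")
    return GpcrCandidate(
        protein_id, aa, tms, tm_count, label,
        evidence=evidence,
        long_n_terminus=(tms[0].start - 1 > long_n_term) if tms else False,
    )


def filter_candidates(
    cands: list[GpcrCandidate], min_tm: int = 5
) -> tuple[list[GpcrCandidate], list[tuple[str, str]]]:
    """Deduplicate identical sequences, then apply the >= min_tm filter.

    One representative survives per identical amino-acid sequence (longest
    protein; ties by lexicographically smallest id). Every removal is
    logged with a reason. The retained list is sorted by protein id, so
    the result is invariant to input order.
    """
    rejections: list[tuple[str, str]] = []
    groups: dict[str, list[GpcrCandidate]] = {}
    for c in cands:
        groups.setdefault(c.sequence, []).append(c)
    retained = []
    for gi, (seq, members) in enumerate(
        sorted(groups.items(), key=lambda kv: min(m.protein_id for m in kv[1]))
    ):
        members.sort(key=lambda c: (-len(c.sequence), c.protein_id))
        rep = members[0]
        group_id = f"dup{gi:04d}"
        rep.duplicate_group = group_id
        for dup in members[1:]:
            dup.duplicate_group = group_id
            rejections.append((dup.protein_id, f"duplicate of {rep.protein_id}"))
        if rep.tm_count < min_tm:
            rejections.append(
                (rep.protein_id, f"fewer than {min_tm} transmembrane helices ({rep.tm_count})")
            )
            continue
        retained.append(rep)
    retained.sort(key=lambda c: c.protein_id)
    return retained, rejections


def topology_string(aa: str, tms: list[TmSegment]) -> str:
    """Per-residue i/o/M topology with an extracellular N-terminus."""
    topo = []
    side = "o"  # GPCR N-terminus is extracellular
    cursor = 0
    for tm in tms:
        topo.append(side * (tm.start - 1 - cursor))
        topo.append("M" * tm.length)
        side = "i" if side == "o" else "o"
        cursor = tm.end
    topo.append(side * (len(aa) - cursor))
    return "".join(topo)
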