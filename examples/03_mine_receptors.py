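"""Detect and classify GPCR candidates by hydropathy and motifs.

Seven hydrophobic helices plus the D-R-Y motif after TM3 make a
Rhodopsin-class (A) call; an extracellular Cys pair in the TM1-TM2 loop
marks Secretin-class (B). Candidates with fewer than five helices are
discarded — a receptor fragmented into 3-TM and 4-TM pieces is lost,
which is exactly how a fragmented corazonin receptor escapes detection.
"""

from neuromine import build_receptor, classify_gpcr, filter_candidates, predict_tm_segments

candidates = []
for pid, tm_count, hint in [
    ("npr_A", 7, "A"), ("npr_B", 7, "B"), ("npr_other", 7, "other"),
    ("crz_frag1", 3, "A"), ("crz_frag2", 4, "A"),
]:
    protein = build_receptor(tm_count, hint, seed=7)
    tms = predict_tm_segments(protein)
    candidates.append(classify_gpcr(protein, tms, protein_id=pid))

retained, rejected = filter_candidates(candidates)
for c in retained:
    print(f"retained {c.protein_id}: {c.tm_count} TM, class {c.class_label} ({'; '.join(c.evidence)})")
for pid, reason in rejected:
    print(f"rejected {pid}: {reason}")
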