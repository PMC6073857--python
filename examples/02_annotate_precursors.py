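"""Annotate neuropeptide precursors: signal, cleavage, matures, family.

The worked-example stand-ins reproduce published architecture numbers:
GPB5 is 143 aa (17 aa signal + 126 aa mature), GPA2 is 120 aa, and
phoenixin is a 70 aa signal-less precursor releasing 20 and 14 aa
amidated peptides. RPCH renders as pQLNFSPGWamide.
"""

from neuromine import annotate_precursor, worked_example_precursors

for name, protein in worked_example_precursors().items():
    ann = annotate_precursor(protein, protein_id=name)
    signal = f"signal 1..{ann.signal.cleavage_after}" if ann.has_signal else "no signal"
    print(f"{name:10s} {len(protein):4d} aa  {signal:15s} family={ann.family}")
    for p in ann.peptides:
        print(f"    {p.rendered}  span {p.span[0]}-{p.span[1]}  Cys={p.cys_count}")
# "pQ" marks pyroglutamate (cyclised N-terminal Gln); "amide" marks a
# C-terminus amidated from its Gly donor — rendered as the literature prints.
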