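"""Synthetic decapod transcriptomes with known ground truth.

Real crustacean neuropeptidome studies start from a de novo multi-tissue
assembly that is rarely deposited, so this module emulates one: it builds
transcripts that embed (i) neuropeptide precursor architectures — signal
peptide, dibasic-flanked mature cores with Gly amidation donors and
N-terminal Gln — (ii) seven-transmembrane receptor ORFs derived from a
reference receptor panel, and (iii) shuffled decoy proteins, together
with a per-tissue count matrix showing the CNS-high and immature-ovary
biased expression patterns typical of neuropeptide genes.

All mature cores in the catalog are fixed strings: the classic short
peptides (RPCH, corazonin, ACP, CCAP, proctolin ...) are the canonical
crustacean sequences, while the long cores (GPA2, GPB5, CHH-like,
phoenixin) are synthetic stand-ins whose architecture numbers (precursor/
signal/mature lengths) mirror the published worked examples. Every
transcript gets exactly one truth-table row; all randomness flows from a
single seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

TISSUES = ("brain", "thoracic_ganglia", "eyestalk", "hepatopancreas", "ovary")
STAGES = ("immature", "mature")
CNS_TISSUES = ("brain", "thoracic_ganglia", "eyestalk")

#: hydrophilic, non-basic linker alphabet (no Q/G/K/R: no spurious
#: pyroGlu starts, amide donors or cleavage motifs)
LINKER_ALPHABET = "STNDEPH"
#: strongly hydrophobic residues for signal h-regions and TM helices
HYDROPHOBIC_ALPHABET = "LIVF"
#: hydrophilic receptor-loop alphabet
LOOP_ALPHABET = "STNDEGPHQ"

# ---------------------------------------------------------------------------
# fixed synthetic cores for the long-precursor worked examples

GPA2_CORE = (
    "HSIECAHAHANPCTNEHVVTLPMNDAICEHFHIFHWIVACDDHYFLNTMSAIDEMPTANY"
    "HDTNCTNCCNAVPCMLHDCIISICPIFWFFYNFTWTH"
)
GPB5_CORE = (
    "YFDTNDDWSFPWCHCCVYNHFMMTTNEFNSSYCLSWCNNVFYALVMFIMACFFVWPSSSI"
    "FHEPIDTPDHYSHSHCSTTYHDMLAHIDCECVVNSCHYYVAMVTYAHFEAHSWNYYSAYI"
    "SSWIFP"
)
CHH_CORE = "PATEYPTIWDVAEPILLAMEFSHIYECPEFENAEFECPLPPNSCPSCAMYCVLTFPLPCI"
PNX20_CORE = "LSSVPIIAMYENSTETDHPF"
PNX14_CORE = "NSSPEYDMPIMMDW"


@dataclass(frozen=True)
class Segment:
    """One mature-peptide cassette inside a precursor."""

    core: str
    amidated: bool  # a Gly donor immediately follows the core
    left_flank: str = "KR"
    right_flank: str = "KR"

    @property
    def length(self) -> int:
        return len(self.left_flank) + len(self.core) + int(self.amidated) + len(self.right_flank)


@dataclass(frozen=True)
class PrecursorArchitecture:
    name: str
    family: str
    signal_length: int  # 0 = none (phoenixin-style), else 10..40
    segments: tuple[Segment, ...]
    linkers: tuple[int, ...]  # n_segments + 1 entries
    total_length: int
    expression_pattern: str = "cns_high"  # cns_high | immature_ovary | hep_mature

    def validate(self) -> None:
        if not (self.signal_length == 0 or 10 <= self.signal_length <= 40):
            raise ValueError(f"{self.name}: signal_length must be 0 or within [10, 40]")
        if len(self.linkers) != len(self.segments) + 1:
            raise ValueError(f"{self.name}: need n_segments + 1 linker lengths")
        budget = self.signal_length + sum(self.linkers) + sum(s.length for s in self.segments)
        if budget != self.total_length:
            raise ValueError(
                f"{self.name}: inconsistent length budget "
                f"(parts sum to {budget}, total_length is {self.total_length})"
            )


def _arch(name, family, signal, linkers, segments, pattern="cns_high"):
    segs = tuple(segments)
    total = signal + sum(linkers) + sum(s.length for s in segs)
    arch = PrecursorArchitecture(name, family, signal, segs, tuple(linkers), total, pattern)
    arch.validate()
    return arch


ARCHITECTURES: tuple[PrecursorArchitecture, ...] = (
    _arch("rpch", "AKH/RPCH", 22, [0, 30], [Segment("QLNFSPGW", True, "", "KR")]),
    _arch("corazonin", "corazonin", 24, [0, 38], [Segment("QTFQYSRGWTN", True, "", "KR")]),
    _arch("acp", "ACP", 23, [0, 42], [Segment("QITFSRSWVPQ", True, "", "KR")]),
    _arch("ccap", "CCAP", 21, [4, 36], [Segment("PFCNAFTGC", True, "KR", "KR")],
          pattern="immature_ovary"),
    _arch("proctolin", "proctolin", 19, [0, 44], [Segment("RYLPT", False, "", "KR")]),
    _arch("sifamide", "SIFamide", 20, [5, 30], [Segment("GYRKPPFNGSIF", True, "", "KR")]),
    _arch("myosuppressin", "myosuppressin", 22, [6, 28],
          [Segment("QDLDHVFLRF", True, "KR", "KR")]),
    _arch("tachykinin", "tachykinin", 23, [4, 0, 0, 22],
          [Segment("APSGFLGMR", True, "", "KR")] * 3, pattern="immature_ovary"),
    _arch("allatostatin_a", "allatostatin-A", 21, [3, 2, 2, 20],
          [Segment("APYAFGL", True, "", "KR"), Segment("AGPYSFGL", True, "", "KR"),
           Segment("PRDYAFGL", True, "", "KR")]),
    _arch("fmrfamide", "FMRFamide-like", 22, [4, 3, 24],
          [Segment("DGNFLRF", True, "", "KR"), Segment("GNSNFLRF", True, "", "KR")]),
    _arch("ryamide", "RYamide", 20, [5, 3, 26],
          [Segment("FVGGSRY", True, "", "KR"), Segment("SGFYANRY", True, "", "KR")]),
    _arch("snpf", "sNPF", 24, [3, 30], [Segment("APALSLRF", True, "", "KR")]),
    _arch("npf", "NPF", 26, [2, 10],
          [Segment("KPDPSQLANMAEALKYLQELDKYYSQVSAPRF", True, "", "KR")],
          pattern="immature_ovary"),
    _arch("kinin", "kinin", 21, [4, 3, 24],
          [Segment("DPAFSSWG", True, "", "KR")] * 2, pattern="immature_ovary"),
    _arch("sulfakinin", "sulfakinin", 22, [5, 26],
          [Segment("GGDDQFDDYGHMRF", True, "", "KR")]),
    _arch("pdh", "PDH", 20, [6, 24], [Segment("NSELINSLLGLPKVMNDA", True, "", "KR")]),
    _arch("orcokinin", "orcokinin", 23, [3, 2, 2, 18],
          [Segment("NFDEIDRSGFGFN", False, "", "KR"), Segment("NFDEIDRSSFGFN", False, "", "KR"),
           Segment("NFDEIDRSGFGFV", False, "", "KR")]),
    _arch("dh31", "DH31", 22, [3, 12],
          [Segment("GLDLGLSRGFSGSQAAKHLMGLAAANYAGGP", True, "", "KR")]),
    _arch("chh_like", "CHH/MIH/GIH", 25, [10, 0], [Segment(CHH_CORE, False, "KR", "")]),
    _arch("gpa2", "GPA2", 23, [0, 0], [Segment(GPA2_CORE, False, "", "")]),
    _arch("gpb5", "GPB5", 17, [0, 0], [Segment(GPB5_CORE, False, "", "")],
          pattern="immature_ovary"),
    _arch("pnx", "phoenixin", 0, [3, 0, 25],
          [Segment(PNX20_CORE, True, "KR", "KR"), Segment(PNX14_CORE, True, "", "KR")],
          pattern="hep_mature"),
)

ARCHITECTURE_BY_NAME = {a.name: a for a in ARCHITECTURES}


def _subseed(seed: int, *tags) -> np.random.Generator:
    """Independent generator derived from a master seed and string tags."""
    h = hashlib.sha256(("|".join(map(str, tags))).encode()).digest()
    return np.random.default_rng([int(seed) % (2**31), int.from_bytes(h[:4], "big")])


def build_signal(length: int, rng: np.random.Generator) -> str:
    """Signal peptide: Met + basic n-region, L/V/I/F h-region, and an
    Ala-X-Ala c-region obeying the (-3, -1) small-residue rule."""
    if length < 10:
        raise ValueError("signal peptides shorter than 10 residues are not modelled")
    n_region = "M" + rng.choice(list("KR"))
    c_region = "A" + rng.choice(list("TNH")) + "A"
    h_len = length - len(n_region) - len(c_region)
    h_region = "".join(rng.choice(list(HYDROPHOBIC_ALPHABET), size=h_len))
    return n_region + h_region + c_region


def build_precursor(arch: PrecursorArchitecture, seed: int) -> str:
    """Deterministic precursor protein realising an architecture.

    The signal h-region and linker residues are drawn from the seeded rng;
    mature cores appear verbatim, flanked by their cleavage motifs, with a
    Gly donor appended after amidated cores. Raises if the architecture's
    length budget is inconsistent.
    """
    arch.validate()
    rng = _subseed(seed, "precursor", arch.name)
    parts = []
    if arch.signal_length:
        parts.append(build_signal(arch.signal_length, rng))
    for i, seg in enumerate(arch.segments):
        linker = "".join(rng.choice(list(LINKER_ALPHABET), size=arch.linkers[i]))
        if i == 0 and arch.signal_length == 0 and arch.linkers[0] > 0:
            linker = "M" + linker[1:]  # complete ORFs need a start codon
        parts.append(linker)
        parts.append(seg.left_flank)
        parts.append(seg.core)
        if seg.amidated:
            parts.append("G")
        parts.append(seg.right_flank)
    parts.append("".join(rng.choice(list(LINKER_ALPHABET), size=arch.linkers[-1])))
    protein = "".join(parts)
    assert len(protein) == arch.total_length
    return protein


# ---------------------------------------------------------------------------
# receptors

#: families of the bundled reference receptor panel; class and ectodomain
#: length mirror the ligand systems they stand in for
RECEPTOR_FAMILIES: tuple[tuple[str, str, int], ...] = (
    ("FMRFamide receptor", "A", 24),
    ("myosuppressin receptor", "A", 22),
    ("allatostatin-A receptor", "A", 26),
    ("proctolin receptor", "A", 21),
    ("CCAP receptor", "A", 28),
    ("ACP receptor", "A", 25),
    ("RPCH receptor", "A", 23),
    ("vasopressin-neurophysin receptor", "A", 27),
    ("CCHamide receptor", "A", 24),
    ("TRH receptor", "A", 22),
    ("SIFamide receptor", "A", 26),
    ("tachykinin receptor", "A", 25),
    ("NPF receptor", "A", 28),
    ("sNPF receptor", "A", 24),
    ("GPA2/GPB5 receptor", "A", 320),  # LGR-type: very long ectodomain
    ("DH31 receptor", "B", 30),
    ("DH44 receptor", "B", 32),
    ("PDH receptor", "B", 28),
)

_TM_LEN = 23
_LOOP_LEN = 14
_CTAIL_LEN = 25


def _receptor_layout(tm_count: int, n_term_len: int) -> list[tuple[str, int]]:
    layout: list[tuple[str, int]] = [("nterm", n_term_len)]
    for k in range(tm_count):
        layout.append(("tm", _TM_LEN))
        if k < tm_count - 1:
            layout.append(("loop", _LOOP_LEN))
    layout.append(("ctail", _CTAIL_LEN))
    return layout


def build_receptor(
    tm_count: int,
    class_hint: str = "other",
    seed: int = 0,
    n_term_len: int = 24,
    tag: str = "receptor",
) -> str:
    """Synthetic membrane protein with ``tm_count`` hydrophobic helices.

    Class A inserts the D-R-Y diagnostic right after TM3; class B inserts
    an extracellular Cys pair into the TM1→TM2 loop. ``tm_count`` 0 gives
    a plain soluble protein.
    """
    if not 0 <= tm_count <= 9:
        raise ValueError("tm_count must be within [0, 9]")
    rng = _subseed(seed, tag, tm_count, class_hint, n_term_len)
    parts = []
    loop_idx = 0
    for kind, length in _receptor_layout(tm_count, n_term_len):
        if kind == "tm":
            parts.append("".join(rng.choice(list(HYDROPHOBIC_ALPHABET), size=length)))
            continue
        chunk = "".join(rng.choice(list(LOOP_ALPHABET), size=length))
        if kind == "nterm":
            chunk = "M" + chunk[1:]
            if length >= 6:  # one basic residue in the n-region
                chunk = chunk[:3] + "K" + chunk[4:]
        elif kind == "loop":
            loop_idx += 1
            if class_hint == "A" and loop_idx == 3:
                chunk = "DRY" + chunk[3:]
            if class_hint == "B" and loop_idx == 1:
                chunk = "C" + chunk[1:6] + "C" + chunk[7:]
        parts.append(chunk)
    return "".join(parts)


def mutate_receptor(
    protein: str, tm_count: int, n_term_len: int, rate: float, rng: np.random.Generator
) -> str:
    """Point-mutate loop/terminus residues, keeping TM helices and the
    first eight residues of each loop (the diagnostic motifs) intact."""
    seq = list(protein)
    pos = 0
    for kind, length in _receptor_layout(tm_count, n_term_len):
        if kind in ("loop", "nterm", "ctail"):
            start = pos + (8 if kind == "loop" else 1)
            for i in range(start, pos + length):
                if rng.random() < rate:
                    seq[i] = rng.choice(list(LOOP_ALPHABET))
        pos += length
    return "".join(seq)


def reference_receptor_panel(seed: int = 2018) -> list[tuple[str, str, str]]:
    """The deorphanized-receptor reference panel: (id, family, protein).

    Synthetic exemplars (one per family) built deterministically; the
    shipped ``data/synthetic_receptor_panel.fasta`` is this panel at the
    default seed.
    """
    panel = []
    for family, klass, n_term in RECEPTOR_FAMILIES:
        pid = "REF_" + family.replace(" ", "_").replace("/", "-")
        panel.append((pid, family, build_receptor(7, klass, seed=seed, n_term_len=n_term,
                                                  tag=family)))
    return panel


def reference_peptide_panel() -> list[tuple[str, str]]:
    """Mature-peptide panel (id, unmodified peptide sequence) drawn from
    the architecture catalog — the homology-search target set."""
    panel = []
    for arch in ARCHITECTURES:
        for i, seg in enumerate(arch.segments):
            if seg.core not in [s for _, s in panel]:
                panel.append((f"{arch.name}_peptide{i + 1}", seg.core))
    return panel


# ---------------------------------------------------------------------------
# transcripts

_BACK_TABLE: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _BACK_TABLE.setdefault(_aa, tuple())
for _codon, _aa in sorted(CodonTable.unambiguous_dna_by_id[1].forward_table.items()):
    _BACK_TABLE[_aa] = _BACK_TABLE[_aa] + (_codon,)
_STOP_CODONS = tuple(sorted(CodonTable.unambiguous_dna_by_id[1].stop_codons))


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform choice over synonymous codons, seeded."""
    return "".join(_BACK_TABLE[aa][rng.integers(len(_BACK_TABLE[aa]))] for aa in protein)


@dataclass(frozen=True)
class TranscriptRecord:
    transcript_id: str
    nt: str
    description: str = ""


def embed_in_transcript(
    protein: str, rng: np.random.Generator, utr5: tuple[int, int] = (20, 60),
    utr3: tuple[int, int] = (20, 60),
) -> str:
    """CDS plus UTRs. The 5' UTR avoids A so no upstream start codon or
    in-frame stop shadows the true ORF."""
    n5 = int(rng.integers(utr5[0], utr5[1] + 1))
    n3 = int(rng.integers(utr3[0], utr3[1] + 1))
    u5 = "".join(rng.choice(list("CGT"), size=n5))
    u3 = "".join(rng.choice(list("ACGT"), size=n3))
    cds = reverse_translate(protein, rng) + _STOP_CODONS[rng.integers(len(_STOP_CODONS))]
    return u5 + cds + u3


# ---------------------------------------------------------------------------
# generator spec / truth / counts


@dataclass
class TissueProfiles:
    """Mean expression multipliers per truth pattern and tissue_stage."""

    cns: float = 10.0
    cns_background: float = 0.2  # hepatopancreas leak of CNS genes
    ovary_immature: float = 5.0
    hep_mature: float = 3.0
    receptor: float = 1.0
    decoy: float = 0.5

    def weights(self, category: str, pattern: str) -> dict[str, float]:
        cols = {f"{t}_{s}": 0.0 for t in TISSUES for s in STAGES}
        if category == "gpcr":
            return {c: self.receptor for c in cols}
        if category == "decoy":
            return {c: self.decoy for c in cols}
        for t in CNS_TISSUES:
            for s in STAGES:
                cols[f"{t}_{s}"] = self.cns
        cols["hepatopancreas_immature"] = self.cns_background
        cols["hepatopancreas_mature"] = self.cns_background
        if pattern == "immature_ovary":
            cols["ovary_immature"] = self.ovary_immature
            cols["ovary_mature"] = 0.0
        elif pattern == "hep_mature":
            cols["hepatopancreas_mature"] = self.hep_mature
            cols["hepatopancreas_immature"] = 0.0
        return cols


@dataclass
class GeneratorSpec:
    n_precursors: int = 22
    n_receptors: int = 18
    n_decoys: int = 20
    tissue_profiles: TissueProfiles = field(default_factory=TissueProfiles)
    read_length: int = 100
    depth: int = 200_000
    dispersion: float = 10.0
    mutation_rate: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_precursors, self.n_receptors, self.n_decoys) < 0:
            raise ValueError("counts must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")


def generate_transcriptome(
    spec: GeneratorSpec,
) -> tuple[list[TranscriptRecord], pd.DataFrame]:
    """Transcripts plus a complete truth table (one row per transcript)."""
    spec.validate()
    records: list[TranscriptRecord] = []
    rows = []
    panel = reference_receptor_panel()
    for i in range(spec.n_precursors):
        arch = ARCHITECTURES[i % len(ARCHITECTURES)]
        protein = build_precursor(arch, seed=spec.seed + i // len(ARCHITECTURES))
        rng = _subseed(spec.seed, "tx-np", i)
        tid = f"NP{i:04d}_{arch.name}"
        records.append(TranscriptRecord(tid, embed_in_transcript(protein, rng), arch.family))
        expected = []
        from .annotate import CleavageRules, derive_mature_peptides, predict_cleavage_sites

        proprotein = protein[arch.signal_length :]
        peps = derive_mature_peptides(proprotein, predict_cleavage_sites(proprotein))
        expected = [p.rendered for p in peps]
        rows.append(
            dict(transcript_id=tid, category="neuropeptide", architecture=arch.name,
                 family=arch.family, expected_peptides=";".join(expected),
                 expected_tm_count=0, expected_class="",
                 signal_length=arch.signal_length, protein_length=len(protein),
                 expression_pattern=arch.expression_pattern)
        )
    for i in range(spec.n_receptors):
        pid, family, ref_protein = panel[i % len(panel)]
        klass = dict((f, c) for f, c, _ in RECEPTOR_FAMILIES)[family]
        n_term = dict((f, n) for f, _, n in RECEPTOR_FAMILIES)[family]
        rng = _subseed(spec.seed, "tx-gr", i)
        protein = mutate_receptor(ref_protein, 7, n_term, spec.mutation_rate, rng)
        tid = f"GR{i:04d}_{family.split()[0].replace('/', '-')}"
        records.append(TranscriptRecord(tid, embed_in_transcript(protein, rng), family))
        rows.append(
            dict(transcript_id=tid, category="gpcr", architecture="7tm",
                 family=family, expected_peptides="", expected_tm_count=7,
                 expected_class=klass, signal_length=0, protein_length=len(protein),
                 expression_pattern="background")
        )
    pool = [build_precursor(a, seed=spec.seed) for a in ARCHITECTURES]
    pool += [p for _, _, p in panel[:4]]
    for i in range(spec.n_decoys):
        rng = _subseed(spec.seed, "tx-dc", i)
        src = pool[int(rng.integers(len(pool)))]
        protein = "".join(rng.permutation(list(src)))
        tid = f"DC{i:04d}_decoy"
        records.append(TranscriptRecord(tid, embed_in_transcript(protein, rng), "decoy"))
        rows.append(
            dict(transcript_id=tid, category="decoy", architecture="shuffled",
                 family="", expected_peptides="", expected_tm_count=0,
                 expected_class="", signal_length=0, protein_length=len(protein),
                 expression_pattern="background")
        )
    columns = ["transcript_id", "category", "architecture", "family", "expected_peptides",
               "expected_tm_count", "expected_class", "signal_length", "protein_length",
               "expression_pattern"]
    truth = pd.DataFrame(rows, columns=columns).set_index("transcript_id")
    return records, truth


def simulate_counts(truth: pd.DataFrame, spec: GeneratorSpec) -> pd.DataFrame:
    """Per-tissue counts with negative-binomial-style overdispersion.

    Each transcript's expected share of a tissue library is its profile
    multiplier; overdispersion follows the Gamma-Poisson construction of
    the negative binomial (fixed dispersion ``spec.dispersion``),
    conditioned on the stated per-tissue depth — so column sums equal
    ``spec.depth`` exactly and zero-multiplier cells are exactly zero.
    """
    spec.validate()
    rng = _subseed(spec.seed, "counts")
    cols = [f"{t}_{s}" for t in TISSUES for s in STAGES]
    if truth.empty:
        return pd.DataFrame(0, index=truth.index, columns=cols, dtype=int)
    weights = pd.DataFrame(
        [
            spec.tissue_profiles.weights(row.category, row.expression_pattern)
            for row in truth.itertuples()
        ],
        index=truth.index,
    )[cols]
    counts = pd.DataFrame(0, index=truth.index, columns=cols, dtype=int)
    r = spec.dispersion
    for col in cols:
        w = weights[col].to_numpy(float)
        gamma = np.zeros_like(w)
        pos = w > 0
        if pos.any():
            gamma[pos] = rng.gamma(shape=r, scale=w[pos] / r)
            if gamma[pos].sum() == 0:  # pragma: no cover - measure zero
                gamma[pos] = w[pos]
            counts[col] = rng.multinomial(spec.depth, gamma / gamma.sum())
    return counts


def worked_example_precursors() -> dict[str, str]:
    """The published worked-example precursors, reconstructed as synthetic
    stand-ins at a fixed seed: phoenixin (70 aa, no signal, 20+14 aa
    amidated matures), GPA2 (120 aa), GPB5 (143 = 17 + 126 aa), and the
    GnRH-superfamily trio RPCH / corazonin / ACP."""
    names = ("pnx", "gpa2", "gpb5", "rpch", "corazonin", "acp")
    return {n: build_precursor(ARCHITECTURE_BY_NAME[n], seed=0) for n in names}
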