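import numpy as np
import pandas as pd
import pytest

from neuromine.expression import (
    MappingParams,
    assign_reads,
    fpkm,
    percentile_bins,
    stage_contrast,
)


def _mutate(seq, n, rng):
    out = list(seq)
    for i in rng.choice(len(seq), n, replace=False):
        out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
    return "".join(out)


# ---------------------------------------------------------------------------
# read assignment


def test_exact_substring_read_assigned(rng):
    t = "".join(rng.choice(list("ACGT"), 500))
    counts, table = assign_reads([("r", t[100:200])], {"t": t})
    assert counts["t"] == 1.0
    assert table.loc[0, "assigned"] == "t"


def test_twenty_percent_mismatch_unassigned_at_default_085(rng):
    t = "".join(rng.choice(list("ACGT"), 500))
    read = _mutate(t[100:200], 20, rng)
    counts, _ = assign_reads([("r", read)], {"t": t})
    assert counts["t"] == 0.0


def test_multimapping_read_split_equally(rng):
    t = "".join(rng.choice(list("ACGT"), 300))
    counts, table = assign_reads([("r", t[50:150])], {"a": t, "b": t})
    assert counts["a"] == counts["b"] == 0.5
    assert table.loc[0, "n_hits"] == 2


def _oracle_assign(read, transcripts, params):
    """Exhaustive all-positions scorer, written independently."""
    min_ov = int(np.ceil(params.min_length_fraction * len(read)))
    best_score, hits = 0, []
    for tid, t in transcripts.items():
        t_best = 0
        for off in range(-len(read), len(t)):
            r0, t0 = max(0, -off), max(0, off)
            ov = min(len(read) - r0, len(t) - t0)
            if ov < min_ov:
                continue
            matches = sum(
                read[r0 + k] == t[t0 + k] for k in range(ov)
            )
            if matches / ov >= params.min_similarity_fraction:
                t_best = max(t_best, matches)
        if t_best > best_score:
            best_score, hits = t_best, [tid]
        elif t_best == best_score and t_best > 0:
            hits.append(tid)
    return sorted(hits)


def test_assignment_matches_exhaustive_oracle(rng):
    params = MappingParams()
    transcripts = {
        f"t{k}": "".join(rng.choice(list("ACGT"), 200)) for k in range(3)
    }
    reads = []
    for k in range(30):
        src = transcripts[f"t{k % 3}"]
        start = int(rng.integers(0, 140))
        read = _mutate(src[start : start + 60], int(rng.integers(0, 12)), rng)
        reads.append((f"r{k}", read))
    counts, table = assign_reads(reads, transcripts, params)
    for (rid, rseq), row in zip(reads, table.itertuples()):
        got = sorted(row.assigned.split(";")) if row.assigned else []
        assert got == _oracle_assign(rseq, transcripts, params), rid


# ---------------------------------------------------------------------------
# fpkm


def test_fpkm_formula():
    counts = pd.DataFrame({"lib": [100, 0]}, index=["a", "b"])
    lengths = pd.Series({"a": 1000, "b": 500})
    out = fpkm(counts, lengths, pd.Series({"lib": 10**6}))
    assert out.loc["a", "lib"] == pytest.approx(100.0)
    assert out.loc["b", "lib"] == 0.0


def test_fpkm_conservation_identity(rng):
    counts = pd.DataFrame(
        rng.integers(0, 500, (20, 4)).astype(float),
        index=[f"t{i}" for i in range(20)],
        columns=list("ABCD"),
    )
    lengths = pd.Series(rng.integers(200, 3000, 20).astype(float), index=counts.index)
    libs = counts.sum(axis=0)
    out = fpkm(counts, lengths, libs)
    back = out.mul(lengths / 1e3, axis=0).mul(libs / 1e6, axis=1)
    assert np.abs(back.to_numpy() - counts.to_numpy()).max() < 1e-9


def test_zero_library_size_rejected():
    counts = pd.DataFrame({"lib": [1]}, index=["a"])
    with pytest.raises(ValueError):
        fpkm(counts, pd.Series({"a": 100}), pd.Series({"lib": 0}))


# ---------------------------------------------------------------------------
# percentile bins


def test_identical_positive_values_share_one_bin():
    m = pd.DataFrame({"x": [5.0, 5.0, 5.0]})
    assert set(percentile_bins(m).x) == {"Q1"}


def test_quartile_edges_tie_to_lower_bin():
    m = pd.DataFrame({"x": np.arange(1.0, 101.0)})
    bins = percentile_bins(m)
    assert bins.x[24] == "Q1"  # value 25
    assert bins.x[25] == "Q2"  # value 26


def test_zero_cells_get_absent_bin_and_counts_sum():
    m = pd.DataFrame(dict(a=[0.0, 1.0, 2.0], b=[3.0, 0.0, 4.0]))
    bins = percentile_bins(m)
    flat = bins.to_numpy().ravel().tolist()
    assert flat.count("absent") == 2
    assert len(flat) == m.size


def test_binning_invariant_to_permutation(rng):
    m = pd.DataFrame(rng.uniform(0, 10, (12, 4)), columns=list("abcd"))
    bins = percentile_bins(m)
    perm_rows = rng.permutation(m.index)
    perm_cols = ["c", "a", "d", "b"]
    bins_perm = percentile_bins(m.loc[perm_rows, perm_cols])
    pd.testing.assert_frame_equal(bins_perm.loc[m.index, list("abcd")], bins)


def test_all_zero_matrix_is_all_absent():
    m = pd.DataFrame(np.zeros((3, 2)))
    assert (percentile_bins(m) == "absent").all().all()


# ---------------------------------------------------------------------------
# stage contrast


def test_immature_only_switch_call():
    m = pd.DataFrame(
        {"ovary_immature": [50.0, 0.0], "ovary_mature": [0.0, 0.0]},
        index=["switch", "silent"],
    )
    calls, summary = stage_contrast(m)
    assert calls.loc["switch", "ovary"] == "immature-only"
    assert calls.loc["silent", "ovary"] == "absent"
    assert summary["immature-only"] == 1


def test_all_zero_matrix_yields_no_positive_calls():
    m = pd.DataFrame(
        {"ovary_immature": [0.0], "ovary_mature": [0.0]}, index=["t"]
    )
    calls, summary = stage_contrast(m)
    assert (calls == "absent").all().all()
    assert "immature-only" not in summary


def test_threshold_zero_counts_everything_present():
    m = pd.DataFrame(
        {"ovary_immature": [0.1, 0.0], "ovary_mature": [0.0, 0.2]}, index=["a", "b"]
    )
    calls, _ = stage_contrast(m, presence_threshold=0.0)
    assert (calls["ovary"] == "both").all()


def test_unpaired_tissue_skipped(caplog):
    m = pd.DataFrame({"brain_immature": [1.0]}, index=["t"])
    calls, _ = stage_contrast(m)
    assert calls.empty
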