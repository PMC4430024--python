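import numpy as np
import pytest

from crossreg import conservation, motif, seqio
from crossreg.conservation import Alignment
from crossreg.synthetic_data import delta_pfm


def _hit(seq_id, start, end, tf="TF", strand="+"):
    return motif.MotifHit(
        seq_id=seq_id,
        interval=seqio.GenomicInterval(seq_id, start, end, strand),
        strand=strand,
        tf_name=tf,
        family="fam",
        raw_score=1.0,
        rel_score=1.0,
        matched_seq="A" * (end - start),
    )


# --- parsing ----------------------------------------------------------------

def test_parse_clustal_and_fasta(tmp_path):
    clustal = tmp_path / "a.aln"
    clustal.write_text(
        "CLUSTAL W (2.1) multiple sequence alignment\n\n"
        "human       AC-GT\nmouse       ACAGT\n"
    )
    aln = conservation.parse_alignment(clustal, fmt="clustal")
    assert aln.n_cols == 5
    assert aln.species() == ["human", "mouse"]
    assert aln.ungapped("human") == "ACGT"

    fasta = tmp_path / "a.fa"
    fasta.write_text(">s1\nACGTACGTAC\n>s2\nACGTACGTAC\n")
    aln2 = conservation.parse_alignment(fasta, fmt="fasta")
    assert aln2.n_cols == 10


def test_alignment_rejects_unequal_rows():
    with pytest.raises(ValueError, match="unequal"):
        Alignment(rows=[("a", "ACGTA"), ("b", "ACGTAC")])
    with pytest.raises(ValueError, match="empty"):
        Alignment(rows=[])


# --- coordinate maps --------------------------------------------------------

@pytest.mark.parametrize(
    "row,expected",
    [
        ("ACGT", [0, 1, 2, 3]),
        ("AC-GT", [0, 1, 3, 4]),
        ("--AC", [2, 3]),
    ],
)
def test_seq_to_aln_map(row, expected):
    assert conservation.seq_to_aln_map(row).tolist() == expected


# --- identity profiles and regions -----------------------------------------

def test_identity_profile_extremes():
    aln = Alignment(rows=[("a", "ACGTACGT"), ("b", "ACGTACGT")])
    assert np.allclose(conservation.identity_profile(aln, window=5), 1.0)
    aln2 = Alignment(rows=[("a", "AAAA"), ("b", "TTTT")])
    assert np.allclose(conservation.identity_profile(aln2, window=3), 0.0)


def test_identity_profile_window_one_is_columnwise():
    aln = Alignment(rows=[("a", "AATT"), ("b", "AAAA")])
    assert conservation.identity_profile(aln, window=1).tolist() == [1, 1, 0, 0]


def test_identity_profile_truncated_edges():
    aln = Alignment(rows=[("a", "AATT"), ("b", "AAAA")])
    profile = conservation.identity_profile(aln, window=3)
    # edge windows shrink: col0 averages cols {0,1}, col3 averages {2,3}
    assert profile.tolist() == [1.0, 2 / 3, 1 / 3, 0.0]


def test_call_conserved_regions():
    assert conservation.call_conserved_regions(np.ones(50), 0.7, 21) == [(0, 50)]
    assert conservation.call_conserved_regions(np.zeros(50), 0.7, 21) == []
    profile = np.array([1, 1, 1, 0, 1, 1, 1], dtype=float)
    assert conservation.call_conserved_regions(profile, 0.5, 3) == [(0, 3), (4, 7)]


def test_conserved_region_monotonicity(rng):
    profile = rng.random(400)
    base = conservation.call_conserved_regions(profile, 0.5, 10)
    total = sum(e - s for s, e in base)
    for ident, mlen in [(0.6, 10), (0.5, 20), (0.7, 30)]:
        regions = conservation.call_conserved_regions(profile, ident, mlen)
        assert sum(e - s for s, e in regions) <= total


# --- pairwise identity ------------------------------------------------------

@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("ACGT", "ACGT", 100.0),
        ("AAAA", "AATT", 50.0),
        ("AA--", "AAAA", 50.0),  # one-gap columns count as mismatches
    ],
)
def test_pairwise_identity(a, b, expected):
    aln = Alignment(rows=[("a", a), ("b", b)])
    assert conservation.pairwise_identity(aln) == pytest.approx(expected)
    assert conservation.pairwise_identity(aln, ("b", "a")) == pytest.approx(expected)


def test_pairwise_identity_excludes_gap_gap_columns():
    aln = Alignment(rows=[("a", "AA--"), ("b", "AA--")])
    assert conservation.pairwise_identity(aln) == pytest.approx(100.0)
    with pytest.raises(ValueError):
        conservation.pairwise_identity(Alignment(rows=[("a", "--"), ("b", "--")]))


# --- conserved hits ---------------------------------------------------------

def test_conserved_hits_identical_sites():
    aln = Alignment(rows=[("human", "ACGTACGTAC"), ("mouse", "ACGTACGTAC")])
    hits = {"human": [_hit("h", 3, 7)], "mouse": [_hit("m", 3, 7)]}
    out = conservation.conserved_hits(hits, aln, [(0, 10)], reference="human")
    assert len(out) == 1
    assert out[0].col_overlap_fraction == pytest.approx(1.0)
    assert out[0].region == (0, 10)


def test_conserved_hits_requires_partner():
    aln = Alignment(rows=[("human", "ACGTACGTAC"), ("mouse", "ACGTACGTAC")])
    hits = {"human": [_hit("h", 3, 7)], "mouse": []}
    assert conservation.conserved_hits(hits, aln, [(0, 10)]) == []


def test_conserved_hits_offset_overlap_fraction():
    aln = Alignment(rows=[("human", "A" * 12), ("mouse", "A" * 12)])
    hits = {"human": [_hit("h", 2, 6)], "mouse": [_hit("m", 4, 8)]}
    out = conservation.conserved_hits(hits, aln, [(0, 12)], min_col_overlap=0.5)
    assert len(out) == 1 and out[0].col_overlap_fraction == pytest.approx(0.5)
    assert conservation.conserved_hits(hits, aln, [(0, 12)], min_col_overlap=0.6) == []


def test_conserved_hits_need_conserved_region():
    aln = Alignment(rows=[("human", "A" * 12), ("mouse", "A" * 12)])
    hits = {"human": [_hit("h", 2, 6)], "mouse": [_hit("m", 2, 6)]}
    assert conservation.conserved_hits(hits, aln, regions=[]) == []
    assert conservation.conserved_hits(hits, aln, regions=[(8, 12)]) == []


def test_conserved_hits_are_subset_of_reference(rng):
    aln = Alignment(rows=[("human", "A" * 50), ("mouse", "A" * 50)])
    ref = [_hit("h", int(s), int(s) + 4) for s in rng.integers(0, 46, size=8)]
    oth = [_hit("m", int(s), int(s) + 4) for s in rng.integers(0, 46, size=8)]
    out = conservation.conserved_hits(
        {"human": ref, "mouse": oth}, aln, [(0, 50)], min_col_overlap=0.5
    )
    assert {id(c.hit_a) for c in out} <= {id(h) for h in ref}


def test_conserved_hit_outside_row_raises():
    aln = Alignment(rows=[("human", "ACGT"), ("mouse", "ACGT")])
    with pytest.raises(ValueError, match="outside"):
        conservation.conserved_hits(
            {"human": [_hit("h", 2, 6)], "mouse": []}, aln, [(0, 4)]
        )


# --- pairwise aligner -------------------------------------------------------

def test_align_pair_identical():
    aln = conservation.align_pair("ACGT", "ACGT")
    assert aln.rows == [("a", "ACGT"), ("b", "ACGT")]
    assert aln.score == 4.0


def test_align_pair_internal_gap():
    aln = conservation.align_pair("ACGT", "ACT")
    assert aln.rows == [("a", "ACGT"), ("b", "AC-T")]
    assert aln.score == 1.0


def test_align_pair_single_mismatch_and_empty():
    aln = conservation.align_pair("A", "T")
    assert aln.rows == [("a", "A"), ("b", "T")] and aln.score == -1.0
    with pytest.raises(ValueError):
        conservation.align_pair("", "ACGT")


def test_align_pair_score_matches_biopython_oracle(rng):
    from Bio import Align

    oracle = Align.PairwiseAligner()
    oracle.mode = "global"
    oracle.match_score = 1
    oracle.mismatch_score = -1
    oracle.open_gap_score = -2
    oracle.extend_gap_score = -2
    for _ in range(25):
        a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 30))))
        b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 30))))
        ours = conservation.align_pair(a, b)
        assert ours.score == pytest.approx(oracle.score(a, b))
        # and the emitted alignment must realize the claimed score
        ga, gb = ours.rows[0][1], ours.rows[1][1]
        realized = sum(
            -2.0 if "-" in (x, y) else (1.0 if x == y else -1.0)
            for x, y in zip(ga, gb)
        )
        assert realized == ours.score
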