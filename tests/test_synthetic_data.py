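import json
import math

import numpy as np
import pytest

from crossreg import conservation, motif, seqio, synthetic_data
from crossreg.synthetic_data import (
    delta_pfm,
    generate_ortholog_family,
    generate_peak_file,
    generate_synthetic_utr,
    plant_motifs,
    sample_motif_instance,
)

HI = "GATCCATGCAATTGCAGATCGAGT"  # high-information 24-mer consensus


def test_sample_motif_instance_delta_and_reproducible():
    pfm = delta_pfm("ACGT")
    assert all(sample_motif_instance(pfm, s) == "ACGT" for s in range(5))
    pfm2 = motif.PFM("u", np.ones((4, 6)))
    assert sample_motif_instance(pfm2, 7) == sample_motif_instance(pfm2, 7)


def test_sample_motif_instance_column_frequencies():
    pfm = motif.PFM("u", np.ones((4, 2)))
    rng = np.random.default_rng(0)
    draws = [sample_motif_instance(pfm, rng) for _ in range(10_000)]
    for col in range(2):
        for base in "ACGT":
            freq = sum(1 for d in draws if d[col] == base) / len(draws)
            assert abs(freq - 0.25) <= 3 * math.sqrt(0.25 * 0.75 / len(draws))


def test_plant_motifs_truth_and_recovery():
    pfm = delta_pfm(HI, tf_name="HI")
    rec, truth = plant_motifs(1000, pfm, 3, seed=5)
    assert len(rec.seq) == 1000 and len(truth.planted_sites) == 3
    ivs = sorted((s.interval.start, s.interval.end) for s in truth.planted_sites)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        assert e1 <= s2  # pairwise disjoint
    pwm = motif.pfm_to_pwm(pfm, pseudocount=0.0)
    hits = motif.scan(pwm, rec, rel_threshold=1.0)
    assert {(h.start, h.end, h.strand) for h in hits} == {
        (s.interval.start, s.interval.end, s.strand) for s in truth.planted_sites
    }


def test_plant_motifs_zero_and_infeasible():
    rec, truth = plant_motifs(100, delta_pfm("ACGT"), 0, seed=1)
    assert truth.planted_sites == []
    with pytest.raises(ValueError):
        plant_motifs(10, delta_pfm(HI), 1, seed=1)


def test_ortholog_family_zero_divergence():
    recs, aln, _ = generate_ortholog_family(
        300, {"human": 0.0, "mouse": 0.0}, [(50, 150)], seed=3
    )
    assert recs["human"].seq == recs["mouse"].seq
    assert conservation.pairwise_identity(aln) == pytest.approx(100.0)


def test_ortholog_family_divergence_matches_mutation_model():
    """Outside-block identity between reference (d=0) and one lineage at
    divergence d is 1-d per site: substitutions always change the base."""
    d = 0.4
    recs, aln, _ = generate_ortholog_family(
        4000, {"human": 0.0, "mouse": d}, [(0, 1)], seed=8
    )
    h, m = recs["human"].seq, recs["mouse"].seq
    matches = sum(a == b for a, b in zip(h[1:], m[1:]))
    p = 1 - d
    sd = math.sqrt(p * (1 - p) * 3999)
    assert abs(matches - p * 3999) <= 3 * sd


def test_ortholog_family_plants_identical_across_species():
    pfm = delta_pfm(HI, tf_name="HI")
    recs, aln, truth = generate_ortholog_family(
        600, {"human": 0.5, "mouse": 0.5}, [(100, 250)], [(pfm, 120)], seed=6
    )
    sites = {s.seq_id: s for s in truth.planted_sites}
    for sp in ("human", "mouse"):
        site = sites[f"synth_gene_{sp}"]
        window = recs[sp].seq[site.interval.start : site.interval.end]
        oriented = window if site.strand == "+" else seqio.reverse_complement(window)
        assert oriented == site.sampled_sequence == HI


def test_ortholog_family_validates_plants_and_blocks():
    pfm = delta_pfm(HI)
    with pytest.raises(ValueError, match="block"):
        generate_ortholog_family(600, {"h": 0.1}, [(100, 110)], [(pfm, 120)])
    with pytest.raises(ValueError):
        generate_ortholog_family(600, {"h": 0.1}, [(700, 800)])


def test_ortholog_family_indel_mode_keeps_alignment_truth():
    recs, aln, _ = generate_ortholog_family(
        500, {"human": 0.1, "mouse": 0.1}, [(100, 200)], seed=2, indel_rate=0.05
    )
    for sp in ("human", "mouse"):
        assert aln.ungapped(sp) == recs[sp].seq
    assert aln.n_cols >= 500


def test_generate_synthetic_utr_profiles():
    rec, truth = generate_synthetic_utr(1, 0, 0, at_target=0.5, length=300, seed=1)
    assert [c for _, _, c in truth.are_sites] == ["I"]
    rec2, truth2 = generate_synthetic_utr(2, 1, 3, at_target=0.5, length=1200, seed=1)
    assert sorted(c for _, _, c in truth2.are_sites) == ["I", "I", "II", "III", "III", "III"]
    with pytest.raises(ValueError):
        generate_synthetic_utr(5, 5, 5, length=100)


def test_generators_bit_reproducible_and_truth_serializable(tmp_path):
    a = generate_synthetic_utr(2, 1, 2, length=900, seed=13)
    b = generate_synthetic_utr(2, 1, 2, length=900, seed=13)
    assert a[0].seq == b[0].seq and a[1].are_sites == b[1].are_sites
    ra, _, ta = generate_ortholog_family(400, {"h": 0.2, "m": 0.3}, [(50, 150)], seed=13)
    rb, _, tb = generate_ortholog_family(400, {"h": 0.2, "m": 0.3}, [(50, 150)], seed=13)
    assert {k: v.seq for k, v in ra.items()} == {k: v.seq for k, v in rb.items()}
    ta.to_json(tmp_path / "t.json")
    payload = json.loads((tmp_path / "t.json").read_text())
    assert set(payload) == {
        "planted_sites", "conserved_blocks", "are_sites", "peak_coverage_fraction",
    }


def test_peak_coverage_extremes_and_binomial():
    pfm = delta_pfm(HI, tf_name="HI")
    rec, truth = plant_motifs(5000, pfm, 20, seed=3)
    lengths = {rec.id: len(rec.seq)}

    full = generate_peak_file(truth, 1.0, lengths, seed=1)
    assert len(full) == 20
    none = generate_peak_file(truth, 0.0, lengths, n_decoys=4, seed=1)
    assert len(none) == 4 and all(p.name.startswith("decoy") for p in none)
    for p in none:  # decoys avoid true sites
        for s in truth.planted_sites:
            assert p.interval.overlap_bp(s.interval) == 0

    # coverage 0.5 over 200 sites within 3 binomial SD
    big_truth = synthetic_data.SyntheticTruth()
    for rep in range(10):
        r, t = plant_motifs(5000, pfm, 20, seed=100 + rep, seq_id=f"p{rep}")
        big_truth.planted_sites.extend(t.planted_sites)
        lengths[f"p{rep}"] = 5000
    peaks = generate_peak_file(big_truth, 0.5, lengths, seed=21)
    n = len(big_truth.planted_sites)
    sd = math.sqrt(n * 0.25)
    assert abs(len(peaks) - 0.5 * n) <= 3 * sd


def test_support_fraction_estimates_coverage():
    """With one planted site per promoter (independent trials), the fraction
    of scan hits supported by the generated peaks is within 3 binomial SD of
    the requested coverage."""
    from crossreg.chipseq_xref import intersect_hits_peaks

    pfm = delta_pfm(HI, tf_name="HI")
    pwm = motif.pfm_to_pwm(pfm, pseudocount=0.0)
    truth_all = synthetic_data.SyntheticTruth()
    recs, lengths = [], {}
    for k in range(150):
        r, t = plant_motifs(800, pfm, 1, seed=3000 + k, seq_id=f"q{k}")
        recs.append(r)
        lengths[f"q{k}"] = 800
        truth_all.planted_sites.extend(t.planted_sites)
    coverage = 0.6
    peaks = generate_peak_file(truth_all, coverage, lengths, jitter_bp=10, seed=17)
    hits = [h for r in recs for h in motif.scan(pwm, r, rel_threshold=1.0)]
    assert len(hits) == 150
    frac = sum(s.supported for s in intersect_hits_peaks(hits, peaks)) / len(hits)
    sd = math.sqrt(coverage * (1 - coverage) / len(hits))
    assert abs(frac - coverage) <= 3 * sd


def test_write_narrowpeak_round_trip(tmp_path):
    from crossreg import chipseq_xref

    pfm = delta_pfm(HI, tf_name="HI")
    rec, truth = plant_motifs(2000, pfm, 5, seed=9)
    peaks = generate_peak_file(truth, 1.0, {rec.id: 2000}, seed=2)
    path = tmp_path / "p.narrowPeak"
    synthetic_data.write_narrowpeak(peaks, path)
    back = chipseq_xref.read_peaks(path)
    assert [(p.interval.start, p.interval.end) for p in back] == [
        (p.interval.start, p.interval.end) for p in peaks
    ]
    assert back[0].summit_offset == peaks[0].summit_offset
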